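"""Simulation and pipeline configuration.

The default :class:`SimConfig` is sized to emulate a collection of 14
closely related lactic-acid-bacterium genomes of ~1.8 Mb: ~1650 shared
core genes plus enough strain-variable accessory content that each
strain carries on the order of 1800 intact protein-coding genes and
~100 pseudogenes, a handful of prophage insertions at tRNA attachment
sites (full and fragmentary, one tandemly duplicated), near-identity
imports from a divergent donor pool, variable gene cassettes at three
anchored loci, and small plasmids in a minority of strains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml


@dataclass(frozen=True)
class CassetteLocusConfig:
    """A cassette locus: alternative gene blocks between two core anchors."""

    anchor_index: int          # inserted between core gene anchor_index and +1
    n_variants: int
    genes_per_variant: int


@dataclass(frozen=True)
class PhageInsertConfig:
    """One prophage insertion event at a tRNA attachment site."""

    site: int                  # tRNA site index (0-based)
    strains: tuple[int, ...]   # strain indices carrying this insertion
    phage_class: str           # "full" | "fragment"
    copy_number: int = 1       # tandem copies of the element


@dataclass(frozen=True)
class HgtSegmentConfig:
    """A block of genes imported from a donor genus."""

    donor: str
    n_genes: int
    strains: tuple[int, ...]
    identity_percent: float    # amino-acid identity of recipient vs donor


def _default_phage_configs() -> tuple[PhageInsertConfig, ...]:
    return (
        PhageInsertConfig(0, (1, 4, 7), "full"),
        PhageInsertConfig(1, (2, 9), "full"),
        PhageInsertConfig(1, (5,), "full", copy_number=2),
        PhageInsertConfig(2, (3,), "full"),
        PhageInsertConfig(3, (6, 10), "full"),
        PhageInsertConfig(4, (0, 8, 12), "fragment"),
        PhageInsertConfig(5, (11,), "fragment"),
    )


def _default_hgt_segments() -> tuple[HgtSegmentConfig, ...]:
    return (
        HgtSegmentConfig("donorA", 8, (0, 2, 3, 5, 8, 10, 13), 95.0),
        HgtSegmentConfig("donorA", 5, (4,), 95.0),
        HgtSegmentConfig("donorA", 4, (9,), 95.0),
    )


def _default_cassettes() -> tuple[CassetteLocusConfig, ...]:
    return (
        CassetteLocusConfig(400, 7, 6),
        CassetteLocusConfig(800, 3, 5),
        CassetteLocusConfig(1200, 3, 5),
    )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the forward simulation.

    Branch lengths are in expected nucleotide substitutions per site.
    ``substitution_rate_per_branch`` is the root-to-tip depth of the
    main clade; the designated basal strain pair (the last two strains)
    hangs from the root at depth ``basal_pair_depth``.
    """

    n_strains: int = 14
    n_core_genes: int = 1650
    accessory_pool_size: int = 420
    accessory_share_p: float = 0.45    # carriage k ~ 1 + Binomial(n-1, p)
    cassette_loci: tuple[CassetteLocusConfig, ...] = field(default_factory=_default_cassettes)
    mean_gene_len: int = 250           # codons; lengths ~ U(mean-100, mean+100)
    substitution_rate_per_branch: float = 0.01
    basal_pair_depth: float = 0.02
    pseudogene_rate: float = 0.05
    n_trna_sites: int = 6
    phage_configs: tuple[PhageInsertConfig, ...] = field(default_factory=_default_phage_configs)
    hgt_segments: tuple[HgtSegmentConfig, ...] = field(default_factory=_default_hgt_segments)
    n_donor_pool_genes: int = 300
    n_paralog_pairs: int = 20
    paralog_divergence: float = 0.35
    n_tandem_dups: int = 5
    tandem_divergence: float = 0.03
    plasmid_strains: tuple[int, ...] = (4, 8, 11, 13)
    n_plasmid_genes: int = 10
    outgroup_divergence: float = 0.20
    outgroup_coverage: float = 0.9
    n_published_omitted: int = 25
    n_pathway_enzymes: int = 3
    pts_cluster: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_strains < 2:
            raise ValueError("n_strains must be >= 2")
        for name in ("accessory_share_p", "pseudogene_rate", "paralog_divergence",
                     "tandem_divergence", "outgroup_divergence", "outgroup_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_gene_len < 110:
            raise ValueError("mean_gene_len must be >= 110 codons")
        seen_site_strain: set[tuple[int, int]] = set()
        for p in self.phage_configs:
            if p.site >= self.n_trna_sites or p.site < 0:
                raise ValueError(f"phage config references unknown tRNA site {p.site}")
            if p.phage_class not in ("full", "fragment"):
                raise ValueError(f"bad phage class {p.phage_class!r}")
            if p.copy_number < 1:
                raise ValueError("phage copy_number must be >= 1")
            for s in p.strains:
                if not 0 <= s < self.n_strains:
                    raise ValueError(f"phage config references unknown strain {s}")
                if (p.site, s) in seen_site_strain:
                    raise ValueError(
                        f"overlapping phage insertions at site {p.site} in strain {s}")
                seen_site_strain.add((p.site, s))
        for h in self.hgt_segments:
            if not 0.0 < h.identity_percent <= 100.0:
                raise ValueError("donor identity must be in (0, 100]")
            for s in h.strains:
                if not 0 <= s < self.n_strains:
                    raise ValueError(f"HGT segment references unknown strain {s}")
        for c in self.cassette_loci:
            if not 0 <= c.anchor_index < self.n_core_genes - 1:
                raise ValueError("cassette anchor_index outside the core gene range")
            if c.n_variants > self.n_strains:
                raise ValueError("more cassette variants than strains")
        for s in self.plasmid_strains:
            if not 0 <= s < self.n_strains:
                raise ValueError(f"plasmid config references unknown strain {s}")
        n_gaps_needed = (self.accessory_pool_size + len(self.cassette_loci)
                         + len(self.hgt_segments) + self.n_paralog_pairs
                         + self.n_trna_sites + (4 if self.pts_cluster else 0))
        if n_gaps_needed > self.n_core_genes - 1:
            raise ValueError("not enough intergenic gaps for the configured insertions")

    def strain_names(self) -> list[str]:
        return [f"S{i:02d}" for i in range(self.n_strains)]


def config_to_yaml(cfg: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"sim": asdict(cfg)}, fh, sort_keys=True)


def sim_config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "cassette_loci" in d:
        d["cassette_loci"] = tuple(
            CassetteLocusConfig(**c) if isinstance(c, dict) else CassetteLocusConfig(*c)
            for c in d["cassette_loci"])
    if "phage_configs" in d:
        d["phage_configs"] = tuple(
            PhageInsertConfig(**{**c, "strains": tuple(c["strains"])})
            if isinstance(c, dict) else c
            for c in d["phage_configs"])
    if "hgt_segments" in d:
        d["hgt_segments"] = tuple(
            HgtSegmentConfig(**{**c, "strains": tuple(c["strains"])})
            if isinstance(c, dict) else c
            for c in d["hgt_segments"])
    for k in ("plasmid_strains",):
        if k in d:
            d[k] = tuple(d[k])
    return SimConfig(**d)


def config_from_yaml(path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return sim_config_from_dict(data.get("sim", data))
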