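"""Ground truth emitted by the simulator, with lossless TSV/JSON round-trip.

The truth object is the benchmark key for every analysis stage: which
gene belongs to which ortholog family, which copies are pseudogenes,
where donor-derived segments and prophage elements sit, which cassette
variant each strain carries, and the generating strain tree.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import pandas as pd


@dataclass(frozen=True)
class HgtTruth:
    strain: str
    replicon: str
    start: int
    end: int
    donor: str
    segment: str                  # segment id, e.g. "hgt0"
    families: tuple[str, ...]     # ortholog families inside the span


@dataclass(frozen=True)
class PhageTruth:
    strain: str
    trna_id: str
    replicon: str
    start: int
    end: int
    phage_class: str              # "full" | "fragment"
    copy_number: int


@dataclass
class SimulationTruth:
    strains: list[str]
    families: list[str]
    family_replicon: dict[str, str]               # family -> chromosome|plasmid
    ortholog_map: dict[str, str]                  # feature id -> family
    feature_strain: dict[str, str]                # feature id -> strain
    status_map: dict[tuple[str, str], str]        # (strain, family) -> status
    hgt_truth: list[HgtTruth] = field(default_factory=list)
    phage_truth: list[PhageTruth] = field(default_factory=list)
    cassette_truth: dict[tuple[int, str], str] = field(default_factory=dict)
    cassette_anchors: dict[int, tuple[str, str]] = field(default_factory=dict)
    cassette_signatures: dict[tuple[int, str], tuple[str, ...]] = field(default_factory=dict)
    strain_tree_newick: str = ""
    published_reference_ids: list[str] = field(default_factory=list)
    role_map: dict[str, str] = field(default_factory=dict)

    def status(self, strain: str, family: str) -> str:
        return self.status_map.get((strain, family), "absent")

    def intact_count(self, strain: str, chromosomal_only: bool = True) -> int:
        return sum(
            1 for (s, f), st in self.status_map.items()
            if s == strain and st == "intact"
            and (not chromosomal_only or self.family_replicon[f] == "chromosome")
        )

    def ortholog_pairs(self) -> set[tuple[str, str]]:
        """All cross-strain feature pairs belonging to the same family."""
        by_family: dict[str, list[str]] = {}
        for fid, fam in self.ortholog_map.items():
            by_family.setdefault(fam, []).append(fid)
        pairs = set()
        for members in by_family.values():
            members = sorted(members)
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    if self.feature_strain[a] != self.feature_strain[b]:
                        pairs.add((a, b))
        return pairs


def write_truth(truth: SimulationTruth, path) -> None:
    """Deterministic, sorted serialization under directory ``path``."""
    os.makedirs(path, exist_ok=True)

    pd.DataFrame(
        sorted((fid, truth.feature_strain[fid], fam)
               for fid, fam in truth.ortholog_map.items()),
        columns=["feature_id", "strain", "family"],
    ).to_csv(os.path.join(path, "ortholog_map.tsv"), sep="\t", index=False)

    pd.DataFrame(
        sorted((s, f, st) for (s, f), st in truth.status_map.items()),
        columns=["strain", "family", "status"],
    ).to_csv(os.path.join(path, "status.tsv"), sep="\t", index=False)

    pd.DataFrame(
        sorted((h.strain, h.replicon, h.start, h.end, h.donor, h.segment,
                ",".join(h.families)) for h in truth.hgt_truth),
        columns=["strain", "replicon", "start", "end", "donor", "segment", "families"],
    ).to_csv(os.path.join(path, "hgt.tsv"), sep="\t", index=False)

    pd.DataFrame(
        sorted((p.strain, p.trna_id, p.replicon, p.start, p.end,
                p.phage_class, p.copy_number) for p in truth.phage_truth),
        columns=["strain", "trna_id", "replicon", "start", "end", "class", "copy_number"],
    ).to_csv(os.path.join(path, "phage.tsv"), sep="\t", index=False)

    pd.DataFrame(
        sorted((locus, strain, variant,
                truth.cassette_anchors[locus][0], truth.cassette_anchors[locus][1],
                ",".join(truth.cassette_signatures[(locus, variant)]))
               for (locus, strain), variant in truth.cassette_truth.items()),
        columns=["locus", "strain", "variant", "anchor_up", "anchor_down", "signature"],
    ).to_csv(os.path.join(path, "cassettes.tsv"), sep="\t", index=False)

    meta = {
        "strains": truth.strains,
        "families": truth.families,
        "family_replicon": truth.family_replicon,
        "published_reference_ids": sorted(truth.published_reference_ids),
        "role_map": truth.role_map,
    }
    with open(os.path.join(path, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    with open(os.path.join(path, "tree.nwk"), "w") as fh:
        fh.write(truth.strain_tree_newick + "\n")


def read_truth(path) -> SimulationTruth:
    with open(os.path.join(path, "meta.json")) as fh:
        meta = json.load(fh)
    with open(os.path.join(path, "tree.nwk")) as fh:
        tree = fh.read().strip()

    om = pd.read_csv(os.path.join(path, "ortholog_map.tsv"), sep="\t")
    st = pd.read_csv(os.path.join(path, "status.tsv"), sep="\t")
    hg = pd.read_csv(os.path.join(path, "hgt.tsv"), sep="\t")
    ph = pd.read_csv(os.path.join(path, "phage.tsv"), sep="\t")
    ca = pd.read_csv(os.path.join(path, "cassettes.tsv"), sep="\t")

    truth = SimulationTruth(
        strains=list(meta["strains"]),
        families=list(meta["families"]),
        family_replicon=dict(meta["family_replicon"]),
        ortholog_map=dict(zip(om.feature_id, om.family)),
        feature_strain=dict(zip(om.feature_id, om.strain)),
        status_map={(r.strain, r.family): r.status for r in st.itertuples()},
        hgt_truth=[
            HgtTruth(r.strain, r.replicon, int(r.start), int(r.end), r.donor,
                     r.segment, tuple(str(r.families).split(",")))
            for r in hg.itertuples()],
        phage_truth=[
            PhageTruth(r.strain, r.trna_id, r.replicon, int(r.start), int(r.end),
                       getattr(r, "_6"), int(r.copy_number))
            for r in ph.itertuples()],
        strain_tree_newick=tree,
        published_reference_ids=list(meta["published_reference_ids"]),
        role_map=dict(meta["role_map"]),
    )
    for r in ca.itertuples():
        truth.cassette_truth[(int(r.locus), r.strain)] = r.variant
        truth.cassette_anchors[int(r.locus)] = (r.anchor_up, r.anchor_down)
        truth.cassette_signatures[(int(r.locus), r.variant)] = tuple(
            str(r.signature).split(","))
    return truth
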