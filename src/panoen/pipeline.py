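"""End-to-end orchestration with a config file and a deterministic run report.

Stages write their outputs under the run directory and re-read upstream
outputs from disk, so any stage can be re-run in isolation:

* ``simulate``   -> sim/genomes/*.fna|gff3|faa, donor/outgroup/role FASTAs, truth/
* ``annotate``   -> annotations re-loaded from FASTA+GFF3 (ORFs called
                    naively when a genome has no GFF3), proteomes/*.faa
* ``orthologs``  -> pan_loci.tsv, representatives.faa
* ``stats``      -> matrix.tsv, rarefaction.tsv, inventory.tsv
* ``scan``       -> hgt_scan.tsv, hgt_regions.tsv
* ``phage``      -> phage_elements.tsv
* ``cassettes``  -> cassettes.tsv (discovered variable loci)
* ``completeness`` -> completeness.tsv (roles from annotation product tags)
* ``tree``       -> tree.nwk, distances.tsv

The single config seed fans out to per-stage child seeds by stable
hashing of the stage name, so reruns (whole or per stage) are
byte-identical.
"""

from __future__ import annotations

import glob
import hashlib
import json
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .config import SimConfig, sim_config_from_dict
from .io import (StrainAnnotation, load_strain, naive_orf_call, load_proteome,
                 write_features_gff3, write_proteome)
from .orthology import build_pan_loci, loci_to_table, PanLocus
from .pangenome import (build_matrix, matrix_to_tsv, non_reference_inventory,
                        rarefaction, rarefaction_to_tsv)
from .phylo import PhyloFilterParams, build_core_tree
from .scans import (ScanParams, detect_phage_elements, genotype_cassette_locus,
                    hgt_window_scan, role_completeness)
from .simulate import simulate_collection

STAGES = ("simulate", "annotate", "orthologs", "stats", "scan", "phage",
          "cassettes", "completeness", "tree")

NON_ROLE_PRODUCTS = {"hypothetical protein", "plasmid protein",
                     "phage_protein", ""}


def stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class AnalysisParams:
    reference: str | None = None
    min_identity: float = 40.0
    min_coverage: float = 0.5
    min_shared_kmers: int = 8     # genome-scale prefilter strength
    synteny_window: int = 5
    scan: ScanParams = field(default_factory=ScanParams)
    phage_max_len: int = 60_000
    min_outgroup_identity: float = 60.0
    bootstrap: int = 100
    rarefaction_exact_limit: int = 10_000
    rarefaction_samples: int = 1000


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    _check_schema(data)
    sim = sim_config_from_dict(data.get("sim", {}))
    a = data.get("analysis", {})
    scan = ScanParams(**a.pop("scan")) if "scan" in a else ScanParams()
    analysis = AnalysisParams(scan=scan, **a)
    seed = int(data.get("seed", sim.seed))
    sim = sim_config_from_dict({**_sim_dict(sim), "seed": seed})
    return RunConfig(sim=sim, analysis=analysis, seed=seed)


def _sim_dict(sim: SimConfig) -> dict:
    from dataclasses import asdict
    return asdict(sim)


def _check_schema(data: dict) -> None:
    allowed_top = {"sim", "analysis", "seed"}
    for k in data:
        if k not in allowed_top:
            raise ValueError(f"unknown config key: {k}")
    import dataclasses
    sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
    for k in data.get("sim", {}):
        if k not in sim_fields:
            raise ValueError(f"unknown config key: sim.{k}")
    ana_fields = {f.name for f in dataclasses.fields(AnalysisParams)}
    for k in data.get("analysis", {}):
        if k not in ana_fields:
            raise ValueError(f"unknown config key: analysis.{k}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class Pipeline:
    """Stateful runner; stages persist everything under ``out_dir``."""

    def __init__(self, config: RunConfig, out_dir):
        self.cfg = config
        self.out = str(out_dir)
        os.makedirs(self.out, exist_ok=True)
        self.report = {
            "version": __version__,
            "seed": config.seed,
            "parameters": {
                "sim": _sim_dict(config.sim),
                "analysis": {
                    **{k: v for k, v in vars(config.analysis).items()
                       if k != "scan"},
                    "scan": vars(config.analysis.scan),
                },
            },
            "stages": {},
            "headline": {},
        }
        self._annotations: dict[str, StrainAnnotation] | None = None
        self._loci: list[PanLocus] | None = None

    # -- helpers ----------------------------------------------------------

    def path(self, *parts) -> str:
        return os.path.join(self.out, *parts)

    def _record(self, stage: str, outputs: list[str]) -> None:
        self.report["stages"][stage] = {
            "seed": stage_seed(self.cfg.seed, stage),
            "outputs": {os.path.relpath(p, self.out): _sha256(p)
                        for p in sorted(outputs) if os.path.isfile(p)},
        }

    def _require(self, stage: str, path: str) -> str:
        if not os.path.exists(path):
            raise FileNotFoundError(
                f"stage '{stage}' needs missing upstream output {path}; "
                f"run the producing stage first")
        return path

    def annotations(self) -> dict[str, StrainAnnotation]:
        if self._annotations is None:
            gdir = self._require("annotate", self.path("sim", "genomes"))
            anns = {}
            for fna in sorted(glob.glob(os.path.join(gdir, "*.fna"))):
                strain = os.path.basename(fna)[:-4]
                gff = fna[:-4] + ".gff3"
                if not os.path.exists(gff):
                    from Bio import SeqIO
                    seqs = {r.id: str(r.seq)
                            for r in SeqIO.parse(fna, "fasta")}
                    write_features_gff3(naive_orf_call(seqs), seqs, gff)
                anns[strain] = load_strain(fna, gff, strain_id=strain)
            if not anns:
                raise FileNotFoundError(f"no genomes under {gdir}")
            self._annotations = anns
        return self._annotations

    def loci(self) -> list[PanLocus]:
        if self._loci is None:
            path = self._require("stats", self.path("pan_loci.tsv"))
            table = pd.read_csv(path, sep="\t")
            anns = self.annotations()
            by_id: dict[int, PanLocus] = {}
            for r in table.itertuples():
                l = by_id.setdefault(int(r.pan_id), PanLocus(pan_id=int(r.pan_id)))
                l.members.setdefault(r.strain, []).append(r.feature_id)
                l.status[r.strain] = r.status
            loci = [by_id[k] for k in sorted(by_id)]
            from .orthology import classify_member_status
            for l in loci:
                for s in anns:
                    l.members.setdefault(s, [])
                classify_member_status(l, anns)
            self._loci = loci
        return self._loci

    def reference(self) -> str:
        return self.cfg.analysis.reference or sorted(self.annotations())[0]

    # -- stages -----------------------------------------------------------

    def simulate(self) -> None:
        sim_cfg = sim_config_from_dict({**_sim_dict(self.cfg.sim),
                                        "seed": stage_seed(self.cfg.seed, "simulate")})
        out = simulate_collection(sim_cfg, out_dir=self.path("sim"))
        self._annotations = out.strains
        outputs = [p for pat in ("sim/genomes/*", "sim/truth/*", "sim/*.faa")
                   for p in glob.glob(self.path(*pat.split("/")))]
        self._record("simulate", outputs)
        self.report["headline"]["n_strains"] = len(out.strains)

    def annotate(self) -> None:
        anns = self.annotations()
        pdir = self.path("proteomes")
        os.makedirs(pdir, exist_ok=True)
        outputs = []
        for s, ann in sorted(anns.items()):
            p = os.path.join(pdir, f"{s}.faa")
            write_proteome(ann.proteome, p)
            outputs.append(p)
        self._record("annotate", outputs)
        self.report["headline"]["cds_per_strain"] = {
            s: len(a.cds) for s, a in sorted(anns.items())}

    def orthologs(self) -> None:
        anns = self.annotations()
        a = self.cfg.analysis
        loci = build_pan_loci(
            anns, reference_strain=self.reference(),
            min_identity=a.min_identity, min_coverage=a.min_coverage,
            min_shared_kmers=a.min_shared_kmers, window=a.synteny_window)
        self._loci = loci
        table = loci_to_table(loci)
        table.to_csv(self.path("pan_loci.tsv"), sep="\t", index=False)
        reps = {}
        for l in loci:
            s = next(s for s, ms in l.members.items() if l.representative in ms)
            reps[f"pan{l.pan_id:05d}|{l.representative}"] = \
                anns[s].proteome[l.representative]
        write_proteome(reps, self.path("representatives.faa"))
        self._record("orthologs", [self.path("pan_loci.tsv"),
                                   self.path("representatives.faa")])
        self.report["headline"]["n_pan_loci"] = len(loci)

    def stats(self) -> None:
        anns = self.annotations()
        loci = self.loci()
        matrix = build_matrix(loci, anns, chromosomal_only=True)
        matrix_to_tsv(matrix, self.path("matrix.tsv"))
        curve = rarefaction(
            matrix,
            exact_limit=self.cfg.analysis.rarefaction_exact_limit,
            n_samples=self.cfg.analysis.rarefaction_samples,
            seed=stage_seed(self.cfg.seed, "stats"))
        rarefaction_to_tsv(curve, self.path("rarefaction.tsv"))
        outputs = [self.path("matrix.tsv"), self.path("rarefaction.tsv")]
        published_path = self.path("sim", "truth", "meta.json")
        if os.path.exists(published_path):
            with open(published_path) as fh:
                published = json.load(fh)["published_reference_ids"]
            inv = non_reference_inventory(
                matrix, loci, self.reference(), published, anns,
                external_proteomes=self._external_proteomes())
            inv.to_csv(self.path("inventory.tsv"), sep="\t", index=False)
            outputs.append(self.path("inventory.tsv"))
            self.report["headline"]["inventory"] = \
                inv["class"].value_counts().to_dict()
        self._record("stats", outputs)
        self.report["headline"].update({
            "n_core": matrix.core_size(),
            "n_pan": matrix.pan_size(),
            "pseudogenes_per_strain": {
                s: int((matrix.values[:, j] == 1).sum())
                for j, s in enumerate(matrix.strains)},
        })

    def _external_proteomes(self) -> dict:
        out = {}
        for faa in sorted(glob.glob(self.path("sim", "donor*.faa"))):
            out[os.path.basename(faa)[:-4]] = load_proteome(faa)
        return out

    def scan(self) -> None:
        anns = self.annotations()
        donors = self._external_proteomes()
        if not donors:
            raise FileNotFoundError(
                "stage 'scan' needs donor proteome FASTAs (sim/donor*.faa)")
        tables = []
        regions = []
        for s in sorted(anns):
            tbl, regs = hgt_window_scan(anns[s], donors,
                                        params=self.cfg.analysis.scan)
            tables.append(tbl)
            regions.extend(regs)
        pd.concat(tables, ignore_index=True).to_csv(
            self.path("hgt_scan.tsv"), sep="\t", index=False,
            float_format="%.4f")
        pd.DataFrame(
            [(r.strain, r.replicon, r.first_index, r.last_index, r.start,
              r.end, ",".join(r.feature_ids)) for r in regions],
            columns=["strain", "replicon", "first_index", "last_index",
                     "start", "end", "features"],
        ).to_csv(self.path("hgt_regions.tsv"), sep="\t", index=False)
        self._record("scan", [self.path("hgt_scan.tsv"),
                              self.path("hgt_regions.tsv")])
        self.report["headline"]["hgt_regions"] = len(regions)

    def phage(self) -> None:
        anns = self.annotations()
        refs_path = self._require("phage", self.path("sim", "phage_roles.faa"))
        role_refs = load_proteome(refs_path)
        rows = []
        for s in sorted(anns) if role_refs else []:
            for el in detect_phage_elements(
                    anns[s], role_refs, max_len=self.cfg.analysis.phage_max_len):
                rows.append((el.strain, el.trna_id, el.replicon, el.start,
                             el.end, el.phage_class, el.copy_number,
                             ",".join(el.roles_found)))
        pd.DataFrame(rows, columns=[
            "strain", "trna_id", "replicon", "start", "end", "class",
            "copy_number", "roles"]).to_csv(
            self.path("phage_elements.tsv"), sep="\t", index=False)
        self._record("phage", [self.path("phage_elements.tsv")])
        self.report["headline"]["phage_elements"] = len(rows)

    def cassettes(self) -> None:
        anns = self.annotations()
        loci = self.loci()
        matrix = build_matrix(loci, anns, chromosomal_only=True)
        entries = discover_cassettes(loci, matrix, anns)
        rows = []
        for (up, down), geno in entries:
            for s in sorted(geno.variant_of):
                rows.append((up, down, s, geno.variant_of[s],
                             ",".join(map(str, geno.signatures.get(
                                 geno.variant_of[s], ())))))
        pd.DataFrame(rows, columns=[
            "anchor_up", "anchor_down", "strain", "variant", "signature"]
        ).to_csv(self.path("cassettes.tsv"), sep="\t", index=False)
        self._record("cassettes", [self.path("cassettes.tsv")])
        self.report["headline"]["cassette_loci"] = len(entries)

    def completeness(self) -> None:
        anns = self.annotations()
        loci = self.loci()
        matrix = build_matrix(loci, anns, chromosomal_only=True)
        role_map = role_map_from_annotations(loci, anns)
        if not role_map:
            pd.DataFrame(columns=["group", "strain", "complete", "blocking"]
                         ).to_csv(self.path("completeness.tsv"), sep="\t",
                                  index=False)
        else:
            groups: dict[str, list[str]] = {}
            for role in sorted(set(role_map.values())):
                group = role.split("_")[0] if "_" in role else role
                groups.setdefault(group, []).append(role)
            report = role_completeness(matrix, role_map,
                                       sorted(set(role_map.values())), groups)
            report.to_csv(self.path("completeness.tsv"), sep="\t", index=False)
        self._record("completeness", [self.path("completeness.tsv")])

    def tree(self) -> None:
        anns = self.annotations()
        if len(anns) < 3:
            raise ValueError("tree stage needs at least three strains; "
                             "this run has fewer")
        loci = self.loci()
        matrix = build_matrix(loci, anns, chromosomal_only=True)
        og_path = self.path("sim", "outgroup.faa")
        outgroup = load_proteome(og_path) if os.path.exists(og_path) else None
        params = PhyloFilterParams(
            min_outgroup_identity=self.cfg.analysis.min_outgroup_identity)
        tree, aln, selected = build_core_tree(
            loci, matrix, anns, outgroup, params,
            n_bootstrap=self.cfg.analysis.bootstrap,
            seed=stage_seed(self.cfg.seed, "tree"),
            min_shared_kmers=self.cfg.analysis.min_shared_kmers)
        with open(self.path("tree.nwk"), "w") as fh:
            fh.write(tree.newick() + "\n")
        from .phylo import distance_matrix
        distance_matrix(aln).to_csv(self.path("distances.tsv"), sep="\t",
                                    float_format="%.8f")
        self._record("tree", [self.path("tree.nwk"), self.path("distances.tsv")])
        self.report["headline"]["phylogeny_loci"] = len(selected)

    # -- driver -----------------------------------------------------------

    def run(self, stages=("all",)) -> dict:
        expanded: list[str] = []
        for s in stages:
            if s == "all":
                expanded.extend(STAGES)
            elif s in STAGES:
                expanded.append(s)
            else:
                raise ValueError(f"unknown stage {s!r}")
        for s in expanded:
            getattr(self, s)()
        self.write_report()
        return self.report

    def write_report(self) -> None:
        with open(self.path("report.json"), "w") as fh:
            json.dump(self.report, fh, indent=1, sort_keys=True)
            fh.write("\n")


def role_map_from_annotations(loci, annotations) -> dict[int, str]:
    """Role labels per pan locus, read from GFF3 ``product`` tags."""
    product_of: dict[str, str] = {}
    for ann in annotations.values():
        for f in ann.cds:
            product_of[f.id] = f.attributes.get("product", "")
    role_map: dict[int, str] = {}
    for l in loci:
        products = {product_of.get(m, "") for m in l.all_members()}
        roles = sorted(p for p in products if p not in NON_ROLE_PRODUCTS)
        if roles:
            role_map[l.pan_id] = roles[0]
    return role_map


def discover_cassettes(loci, matrix, annotations):
    """Variable loci between consecutive single-copy core anchors.

    Every consecutive pair of anchor-grade loci (intact, single copy in
    all strains) whose intervening gene content is non-empty somewhere
    is genotyped; pairs with at least two distinct variants are the
    cassette loci.
    """
    from .pangenome import INTACT
    row_of = {pid: i for i, pid in enumerate(matrix.pan_ids)}
    anchors = []
    for l in loci:
        if l.pan_id not in row_of:
            continue
        row = matrix.values[row_of[l.pan_id]]
        if (row == INTACT).all() and all(
                len(ms) == 1 for ms in l.members.values() if ms):
            anchors.append(l)
    anchors.sort(key=lambda l: l.pan_id)
    from .scans import FeatureOrderIndex
    index = FeatureOrderIndex(annotations)
    locus_of = {m: l.pan_id for l in loci for m in l.all_members()}
    out = []
    for a, b in zip(anchors, anchors[1:]):
        geno = genotype_cassette_locus(loci, annotations, (a.pan_id, b.pan_id),
                                       index=index, locus_of=locus_of)
        non_empty = [sig for sig in geno.signatures.values() if sig]
        if len(geno.signatures) >= 2 and non_empty:
            out.append(((a.pan_id, b.pan_id), geno))
    return out
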