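"""Forward simulation of a bacterial strain collection with ground truth.

The generator builds an ancestral chromosome (core genes in random
orientation separated by intergenic spacers, with tRNA genes at
configured attachment sites), evolves it down a random coalescent tree
by per-branch nucleotide substitutions, and then applies per-strain
events: accessory-gene carriage, cassette-variant choice at anchored
loci, pseudogenisation by premature stop insertion, prophage insertion
at tRNA sites (flanked by exact 20-bp direct repeats of the tRNA 3'
end), near-identity gene imports from a simulated donor pool, private
tandem duplications, and small plasmids.

Two deliberate detectability contracts:

* substitutions never create or destroy start/stop codons inside
  annotated genes, so reading frames are stable and pseudogenes exist
  only where a premature stop was explicitly inserted;
* every intergenic spacer starts and ends with a 12-bp block carrying
  stop codons in all six frames and no start codons, so naive ORF
  calling recovers annotated gene coordinates exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .config import SimConfig
from .io import (GeneFeature, Replicon, StrainAnnotation, translate_cds,
                 write_proteome, write_strain)
from .truth import HgtTruth, PhageTruth, SimulationTruth, write_truth

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_B2I = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _B2I[_b] = _i

# stop codons in all six frames, no A/G-containing start codons anywhere
SPACER_BLOCK = "TTAATTAATTAA"

STOPS = {"TAA", "TAG", "TGA"}
STARTS = {"ATG", "GTG", "TTG"}

_CODON_TABLE: dict[str, str] = {}
_AA_CODONS: dict[str, list[str]] = {}


def _init_code() -> None:
    from Bio.Seq import Seq
    for i in "ACGT":
        for j in "ACGT":
            for k in "ACGT":
                codon = i + j + k
                aa = str(Seq(codon).translate(table=11))
                _CODON_TABLE[codon] = aa
                _AA_CODONS.setdefault(aa, []).append(codon)


_init_code()


def _enc(s: str) -> np.ndarray:
    return _B2I[np.frombuffer(s.encode(), dtype=np.uint8)].copy()


def _dec(a: np.ndarray) -> str:
    return BASES[a].tobytes().decode()


# ---------------------------------------------------------------------------
# strain tree


@dataclass
class TreeNode:
    name: str
    height: float
    children: list["TreeNode"] = field(default_factory=list)

    def newick(self, parent_height: float | None = None) -> str:
        if self.children:
            inner = ",".join(c.newick(self.height) for c in self.children)
            label = f"({inner}){self.name}"
        else:
            label = self.name
        if parent_height is None:
            return label + ";"
        return f"{label}:{parent_height - self.height:.8f}"


def _coalescent(names: list[str], rng: np.random.Generator,
                height: float, min_branch: float = 1e-4,
                prefix: str = "n") -> TreeNode:
    nodes = [TreeNode(n, 0.0) for n in names]
    if len(nodes) == 1:
        return nodes[0]
    h = 0.0
    counter = 0
    while len(nodes) > 1:
        k = len(nodes)
        h += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(TreeNode(f"{prefix}{counter}", h, [a, b]))
        counter += 1
    root = nodes[0]
    if height <= 0.0:
        def zero(n: TreeNode):
            n.height = 0.0
            for c in n.children:
                zero(c)
        zero(root)
        return root
    scale = height / root.height

    def rescale(n: TreeNode):
        n.height *= scale
        for c in n.children:
            rescale(c)
            if n.height - c.height < min_branch:
                # enforce a resolvable minimum internal branch
                n.height += min_branch - (n.height - c.height)

    rescale(root)
    return root


def build_strain_tree(cfg: SimConfig, rng: np.random.Generator) -> TreeNode:
    """Coalescent main clade plus, when n >= 4, a deep basal strain pair."""
    names = cfg.strain_names()
    if cfg.n_strains < 4:
        return _coalescent(names, rng, cfg.substitution_rate_per_branch)
    main = _coalescent(names[:-2], rng, cfg.substitution_rate_per_branch)
    cherry = _coalescent(names[-2:], rng,
                         cfg.substitution_rate_per_branch * 0.2, prefix="b")
    root_h = max(cfg.basal_pair_depth, main.height * 1.2, cherry.height * 1.2)
    return TreeNode("root", root_h, [main, cherry])


def tree_branches(root: TreeNode) -> list[tuple[TreeNode, TreeNode]]:
    out = []
    stack = [root]
    while stack:
        n = stack.pop()
        for c in n.children:
            out.append((n, c))
            stack.append(c)
    return out


def tree_tip_paths(root: TreeNode) -> dict[tuple[str, str], float]:
    """Path lengths between all tip pairs."""
    tips: dict[str, float] = {}
    anc: dict[str, list[tuple[str, float]]] = {}

    def walk(n: TreeNode, path: list[tuple[str, float]]):
        path = path + [(n.name, n.height)]
        if not n.children:
            anc[n.name] = path
        for c in n.children:
            walk(c, path)

    walk(root, [])
    out = {}
    names = sorted(anc)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pa = {x for x, _ in anc[a]}
            mrca_h = min(h for x, h in anc[b] if x in pa and h > 0)
            out[(a, b)] = 2 * mrca_h  # tips at height 0
    return out


# ---------------------------------------------------------------------------
# sequence construction helpers


def random_gene(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random internal non-stop codons + random stop."""
    sense = [c for c in _CODON_TABLE if _CODON_TABLE[c] != "*"]
    sense.sort()
    body = rng.choice(len(sense), size=n_codons - 2)
    stop = sorted(STOPS)[rng.integers(3)]
    return "ATG" + "".join(sense[i] for i in body) + stop


def random_spacer(rng: np.random.Generator) -> str:
    interior = rng.integers(26, 377)
    mid = _dec(rng.integers(0, 4, size=interior).astype(np.uint8))
    return SPACER_BLOCK + mid + SPACER_BLOCK


def mutate_gene_aa(gene: str, divergence: float, rng: np.random.Generator) -> str:
    """Replace a fraction of internal codons with codons of other residues."""
    n_codons = len(gene) // 3
    k = int(round(divergence * (n_codons - 2)))
    if k <= 0:
        return gene
    positions = rng.choice(np.arange(1, n_codons - 1), size=k, replace=False)
    codons = [gene[3 * i:3 * i + 3] for i in range(n_codons)]
    for p in positions:
        old_aa = _CODON_TABLE[codons[p]]
        choices = sorted(c for c, aa in _CODON_TABLE.items()
                         if aa not in ("*", old_aa))
        codons[p] = choices[rng.integers(len(choices))]
    return "".join(codons)


# ---------------------------------------------------------------------------
# evolvable ancestral material


@dataclass
class Element:
    """One evolvable piece of ancestral sequence."""

    key: str            # family id for genes, unique key otherwise
    kind: str           # "gene" | "spacer" | "trna"
    offset: int = 0
    length: int = 0


class AncestralPool:
    """Concatenated ancestral sequences evolved down the tree as a unit."""

    def __init__(self):
        self.elements: dict[str, Element] = {}
        self._parts: list[np.ndarray] = []
        self._offset = 0

    def add(self, key: str, kind: str, seq: str) -> None:
        if key in self.elements:
            raise ValueError(f"duplicate ancestral element {key}")
        enc = _enc(seq)
        self.elements[key] = Element(key, kind, self._offset, enc.size)
        self._parts.append(enc)
        self._offset += enc.size

    def finalize(self) -> np.ndarray:
        return np.concatenate(self._parts) if self._parts else np.empty(0, np.uint8)

    def slice(self, tip_seq: np.ndarray, key: str) -> np.ndarray:
        e = self.elements[key]
        return tip_seq[e.offset:e.offset + e.length]

    def cds_mask(self) -> np.ndarray:
        """Per-position: -1 outside genes, else codon phase anchor offset."""
        mask = np.full(self._offset, -1, dtype=np.int64)
        for e in self.elements.values():
            if e.kind == "gene":
                mask[e.offset:e.offset + e.length] = e.offset
        return mask


def _evolve(seq: np.ndarray, rate: float, cds_anchor: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Apply ~Binomial(L, rate) substitutions, protecting reading frames.

    A substitution is reverted when it hits the first or last codon of a
    gene or would turn an internal codon into a stop.
    """
    out = seq.copy()
    n = int(rng.binomial(seq.size, rate)) if rate > 0 else 0
    if n == 0:
        return out
    pos = rng.choice(seq.size, size=n, replace=False)
    shift = rng.integers(1, 4, size=n).astype(np.uint8)
    for p, s in zip(pos, shift):
        old = out[p]
        out[p] = (out[p] + s) % 4
        a = cds_anchor[p]
        if a < 0:
            continue
        codon_i = (p - a) // 3
        cstart = a + 3 * codon_i
        codon = _dec(out[cstart:cstart + 3])
        # protect the start codon and never create an in-frame stop
        if codon_i == 0 or codon in STOPS:
            out[p] = old
    return out


# ---------------------------------------------------------------------------
# simulation output


@dataclass
class SimulationOutput:
    strains: dict[str, StrainAnnotation]
    truth: SimulationTruth
    donor_proteomes: dict[str, dict[str, str]]
    outgroup_proteome: dict[str, str]
    phage_role_refs: dict[str, str]
    config: SimConfig


def simulate_collection(cfg: SimConfig, out_dir=None) -> SimulationOutput:
    """Run the forward simulation; optionally write all inputs + truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    strains = cfg.strain_names()
    n = cfg.n_strains

    tree = build_strain_tree(cfg, rng)

    pool = AncestralPool()

    def gene_len() -> int:
        return int(rng.integers(cfg.mean_gene_len - 100, cfg.mean_gene_len + 101))

    # --- core genes with their trailing spacers
    core_families = [f"core_{i:05d}" for i in range(cfg.n_core_genes)]
    core_strand = {}
    for fam in core_families:
        pool.add(fam, "gene", random_gene(rng, gene_len()))
        pool.add(f"{fam}.sp", "spacer", random_spacer(rng))
        core_strand[fam] = "+" if rng.random() < 0.5 else "-"

    # --- gap bookkeeping: insertions attach after core gene index g
    free_gaps = list(range(cfg.n_core_genes - 1))
    order = rng.permutation(len(free_gaps))
    free_gaps = [free_gaps[i] for i in order]
    reserved = {c.anchor_index for c in cfg.cassette_loci}
    free_gaps = [g for g in free_gaps if g not in reserved]

    def take_gap() -> int:
        return free_gaps.pop()

    # --- tRNA sites
    trna_gap = {}
    trna_sites = [f"trna_site{t}" for t in range(cfg.n_trna_sites)]
    for t, site in enumerate(trna_sites):
        pool.add(site, "trna", _dec(rng.integers(0, 4, size=76).astype(np.uint8)))
        pool.add(f"{site}.sp", "spacer", random_spacer(rng))
        step = max(1, cfg.n_core_genes // (cfg.n_trna_sites + 1))
        g = (t + 1) * step - 1
        trna_gap[t] = g

    # --- ancient paralog duplicates (present in every strain); their
    # sequences are derived below once the ancestral array exists
    paralog_src = sorted(
        int(i) for i in rng.choice(cfg.n_core_genes, size=cfg.n_paralog_pairs,
                                   replace=False))
    paralog_families = [f"par_{k:03d}" for k in range(len(paralog_src))]
    paralog_gap: dict[str, int] = {}

    # --- accessory pool
    accessory_families = [f"acc_{i:04d}" for i in range(cfg.accessory_pool_size)]
    accessory_gap = {}
    accessory_carriers = {}
    for fam in accessory_families:
        pool.add(fam, "gene", random_gene(rng, gene_len()))
        pool.add(f"{fam}.sp", "spacer", random_spacer(rng))
        accessory_gap[fam] = take_gap()
        k = 1 + int(rng.binomial(n - 1, cfg.accessory_share_p))
        carriers = rng.choice(n, size=k, replace=False)
        accessory_carriers[fam] = set(int(c) for c in carriers)

    # --- cassette loci
    cassette_variants = {}   # (locus, variant label) -> list of families
    cassette_assignment = {}  # (locus, strain idx) -> variant label
    for li, c in enumerate(cfg.cassette_loci):
        for v in range(c.n_variants):
            fams = [f"cas_l{li}v{v}_{g}" for g in range(c.genes_per_variant)]
            for fam in fams:
                pool.add(fam, "gene", random_gene(rng, gene_len()))
                pool.add(f"{fam}.sp", "spacer", random_spacer(rng))
            cassette_variants[(li, f"V{v + 1}")] = fams
        perm = rng.permutation(n)
        for rank, s in enumerate(perm):
            v = rank if rank < c.n_variants else int(rng.integers(c.n_variants))
            cassette_assignment[(li, int(s))] = f"V{v + 1}"

    # --- PTS-like role cluster (accessory complex with subunit roles)
    pts_families = []
    pts_carriers: set[int] = set()
    pts_gap = None
    if cfg.pts_cluster:
        for role in ("IIA", "IIB", "IIC", "IID"):
            fam = f"pts1_{role}"
            pts_families.append(fam)
            pool.add(fam, "gene", random_gene(rng, gene_len()))
            pool.add(f"{fam}.sp", "spacer", random_spacer(rng))
        pts_gap = take_gap()
        k = max(1, int(rng.binomial(n, 0.6)))
        pts_carriers = set(int(c) for c in rng.choice(n, size=k, replace=False))

    # --- plasmid genes
    plasmid_families = [f"pl_{i:02d}" for i in range(cfg.n_plasmid_genes)]
    for fam in plasmid_families:
        pool.add(fam, "gene", random_gene(rng, gene_len()))
        pool.add(f"{fam}.sp", "spacer", random_spacer(rng))

    ancestral = pool.finalize()
    cds_anchor = pool.cds_mask()

    # paralog duplicates: derived from the ancestral core copy, then added
    # as independent evolvable elements at their own genomic position
    paralog_pool = AncestralPool()
    for k, src in enumerate(paralog_src):
        fam = paralog_families[k]
        e = pool.elements[core_families[src]]
        src_seq = _dec(ancestral[e.offset:e.offset + e.length])
        paralog_pool.add(fam, "gene",
                         mutate_gene_aa(src_seq, cfg.paralog_divergence, rng))
        paralog_pool.add(f"{fam}.sp", "spacer", random_spacer(rng))
        paralog_gap[fam] = take_gap()
    paralog_anc = paralog_pool.finalize()
    paralog_anchor = paralog_pool.cds_mask()

    # --- evolve both pools down the tree
    tip_seqs: dict[str, np.ndarray] = {}
    tip_paralog: dict[str, np.ndarray] = {}

    def descend(node: TreeNode, seq: np.ndarray, pseq: np.ndarray):
        for child in node.children:
            blen = node.height - child.height
            cseq = _evolve(seq, blen, cds_anchor, rng)
            cpseq = _evolve(pseq, blen, paralog_anchor, rng)
            if child.children:
                descend(child, cseq, cpseq)
            else:
                tip_seqs[child.name] = cseq
                tip_paralog[child.name] = cpseq

    if tree.children:
        descend(tree, ancestral, paralog_anc)
    else:
        tip_seqs[tree.name] = ancestral
        tip_paralog[tree.name] = paralog_anc

    # --- donor pool and HGT segments (recent: identical across carriers)
    donor_genes: dict[str, str] = {}
    donor_ids: set[str] = {h.donor for h in cfg.hgt_segments} or {"donorA"}
    for d in sorted(donor_ids):
        for i in range(cfg.n_donor_pool_genes):
            donor_genes[f"{d}_g{i:04d}"] = random_gene(rng, gene_len())
    hgt_material = []  # (segment id, cfg, [(family, recipient nt)], gap)
    for si, seg in enumerate(cfg.hgt_segments):
        genes = []
        for gi in range(seg.n_genes):
            donor_gene = random_gene(rng, gene_len())
            donor_id = f"{seg.donor}_hgt{si}_{gi}"
            donor_genes[donor_id] = donor_gene
            recip = mutate_gene_aa(
                donor_gene, 1.0 - seg.identity_percent / 100.0, rng)
            genes.append((f"hgt{si}_{gi:02d}", recip, random_spacer(rng)))
        hgt_material.append((f"hgt{si}", seg, genes, take_gap()))

    donor_proteomes = {
        d: {gid: translate_cds(g) for gid, g in sorted(donor_genes.items())
            if gid.startswith(d)}
        for d in sorted(donor_ids)
    }

    # --- phage element types, one per tRNA site used
    phage_types: dict[tuple[int, str], list[tuple[str, str, str, str]]] = {}
    phage_role_refs: dict[str, str] = {}
    for p in cfg.phage_configs:
        key = (p.site, p.phage_class)
        if key in phage_types:
            continue
        genes = [("int", f"phage_s{p.site}_{p.phage_class}_int",
                  random_gene(rng, 400))]
        if p.phage_class == "full":
            genes.append(("lys", f"phage_s{p.site}_{p.phage_class}_lys",
                          random_gene(rng, 300)))
            for k in range(8):
                genes.append(("phage_protein",
                              f"phage_s{p.site}_{p.phage_class}_f{k}",
                              random_gene(rng, int(rng.integers(150, 251)))))
        else:
            genes.append(("phage_protein",
                          f"phage_s{p.site}_{p.phage_class}_f0",
                          random_gene(rng, int(rng.integers(150, 251)))))
        phage_types[key] = [(role, fam, seq, random_spacer(rng))
                            for role, fam, seq in genes]
        for role, fam, seq, _sp in phage_types[key]:
            if role in ("int", "lys"):
                phage_role_refs[fam] = translate_cds(seq)

    phage_by_site_strain: dict[tuple[int, int], "PhageInsert"] = {}
    for p in cfg.phage_configs:
        for s in p.strains:
            phage_by_site_strain[(p.site, s)] = p

    # --- tandem duplications (strain-private, near-identical neighbours)
    tandem_plan = []  # (strain idx, core gene idx, family)
    if cfg.n_tandem_dups:
        srcs = rng.choice(cfg.n_core_genes, size=cfg.n_tandem_dups, replace=False)
        who = rng.integers(0, n, size=cfg.n_tandem_dups)
        for k, (src, s) in enumerate(zip(srcs, who)):
            tandem_plan.append((int(s), int(src), f"td_{k:02d}"))

    # --- pathway roles on core genes
    role_map: dict[str, str] = {}
    pathway_base = cfg.n_core_genes // 3
    pathway_roles = []
    for e in range(cfg.n_pathway_enzymes):
        fam = core_families[pathway_base + e]
        role = f"path1_E{e + 1}"
        role_map[fam] = role
        pathway_roles.append(role)
    for i, fam in enumerate(pts_families):
        role_map[fam] = f"pts1_{('IIA', 'IIB', 'IIC', 'IID')[i]}"
    for key, genes in phage_types.items():
        for role, fam, _seq, _sp in genes:
            if role in ("int", "lys"):
                role_map[fam] = role

    # --- pseudogene plan over inherited chromosomal families
    pseudogenizable = core_families + paralog_families + accessory_families + \
        [f for fams in cassette_variants.values() for f in fams] + pts_families

    def carried(fam: str, s: int) -> bool:
        if fam in accessory_carriers:
            return s in accessory_carriers[fam]
        if fam.startswith("cas_"):
            li = int(fam.split("_")[1][1:].split("v")[0])
            v = "V" + str(int(fam.split("v")[1].split("_")[0]) + 1)
            return cassette_assignment[(li, s)] == v
        if fam in pts_families:
            return s in pts_carriers
        return True  # core and paralog duplicates

    pseudo_plan: dict[tuple[int, str], int] = {}
    for fam in pseudogenizable:
        n_cod = pool.elements[fam].length // 3 if fam in pool.elements \
            else paralog_pool.elements[fam].length // 3
        for s in range(n):
            if carried(fam, s) and rng.random() < cfg.pseudogene_rate:
                pseudo_plan[(s, fam)] = int(rng.integers(1, n_cod - 1))

    # ------------------------------------------------------------------
    # assemble strains
    truth = SimulationTruth(
        strains=strains, families=[], family_replicon={},
        ortholog_map={}, feature_strain={}, status_map={},
        strain_tree_newick=tree.newick(), role_map=dict(role_map),
    )
    annotations: dict[str, StrainAnnotation] = {}

    gap_insertions: dict[int, list[tuple[str, object]]] = {}
    for fam in accessory_families:
        gap_insertions.setdefault(accessory_gap[fam], []).append(("acc", fam))
    for fam in paralog_families:
        gap_insertions.setdefault(paralog_gap[fam], []).append(("par", fam))
    if pts_gap is not None:
        gap_insertions.setdefault(pts_gap, []).append(("pts", None))
    for seg_id, seg, genes, gap in hgt_material:
        gap_insertions.setdefault(gap, []).append(("hgt", (seg_id, seg, genes)))
    for li, c in enumerate(cfg.cassette_loci):
        gap_insertions.setdefault(c.anchor_index, []).append(("cas", li))
    tandem_by_gene: dict[int, list[tuple[int, str]]] = {}
    for s, src, fam in tandem_plan:
        tandem_by_gene.setdefault(src, []).append((s, fam))
    trna_at_gap = {g: t for t, g in trna_gap.items()}

    for si, strain in enumerate(strains):
        tip = tip_seqs[strain]
        ptip = tip_paralog[strain]
        parts: list[str] = []
        feats: list[GeneFeature] = []
        pos = 0
        ordinal = 0
        chrom = f"{strain}_chr"

        def emit(seq: str):
            nonlocal pos
            parts.append(seq)
            pos += len(seq)

        def emit_gene(fam: str, coding: str, strand: str, product: str,
                      replicon: str = None):
            nonlocal ordinal, pos
            rep = replicon or chrom
            fid = f"{strain}_{ordinal:05d}"
            ordinal += 1
            genomic = coding if strand == "+" else _revcomp(coding)
            attrs = {"ID": fid, "locus_tag": fid, "product": product}
            feats.append(GeneFeature(
                id=fid, replicon=rep, start=pos, end=pos + len(genomic),
                strand=strand, kind="CDS", attributes=attrs))
            emit(genomic)
            truth.ortholog_map[fid] = fam
            truth.feature_strain[fid] = strain
            return fid

        def gene_seq(fam: str, source: str = "main") -> str:
            if source == "paralog":
                coding = _dec(paralog_pool.slice(ptip, fam))
            else:
                coding = _dec(pool.slice(tip, fam))
            stop_at = pseudo_plan.get((si, fam))
            if stop_at is not None:
                coding = coding[:3 * stop_at] + "TAA" + coding[3 * stop_at + 3:]
            return coding

        def record_status(fam: str):
            st = "pseudogene" if (si, fam) in pseudo_plan else "intact"
            truth.status_map[(strain, fam)] = st

        def product_for(fam: str) -> str:
            return role_map.get(fam, "hypothetical protein")

        for gi, fam in enumerate(core_families):
            emit_gene(fam, gene_seq(fam), core_strand[fam], product_for(fam))
            record_status(fam)
            emit(_dec(pool.slice(tip, f"{fam}.sp")))
            # private tandem duplication directly downstream of its source
            for (ts, tfam) in tandem_by_gene.get(gi, []):
                if ts == si:
                    dup = mutate_gene_aa(_dec(pool.slice(tip, fam)),
                                         cfg.tandem_divergence, rng)
                    emit_gene(tfam, dup, core_strand[fam], "hypothetical protein")
                    truth.status_map[(strain, tfam)] = "intact"
                    emit(random_spacer(rng))
            # tRNA site after this gap?
            t = trna_at_gap.get(gi)
            if t is not None:
                site = trna_sites[t]
                tseq = _dec(pool.slice(tip, site))
                tid = f"{strain}_t{t}"
                feats.append(GeneFeature(
                    id=tid, replicon=chrom, start=pos, end=pos + len(tseq),
                    strand="+", kind="tRNA",
                    attributes={"ID": tid, "locus_tag": tid,
                                "product": f"tRNA-{site}", "Name": site}))
                emit(tseq)
                ins = phage_by_site_strain.get((t, si))
                if ins is not None:
                    att = tseq[-20:]
                    el_start = pos
                    genes = phage_types[(ins.site, ins.phage_class)]
                    for _copy in range(ins.copy_number):
                        for role, pfam, pseq, psp in genes:
                            emit_gene(pfam, pseq, "+", role)
                            truth.status_map[(strain, pfam)] = "intact"
                            emit(psp)
                        emit(att)
                    truth.phage_truth.append(PhageTruth(
                        strain=strain, trna_id=tid, replicon=chrom,
                        start=el_start, end=pos, phage_class=ins.phage_class,
                        copy_number=ins.copy_number))
                emit(_dec(pool.slice(tip, f"{site}.sp")))
            # other insertions registered at this gap
            for kind, payload in gap_insertions.get(gi, []):
                if kind == "acc":
                    fam2 = payload
                    if si in accessory_carriers[fam2]:
                        emit_gene(fam2, gene_seq(fam2), "+", product_for(fam2))
                        record_status(fam2)
                        emit(_dec(pool.slice(tip, f"{fam2}.sp")))
                elif kind == "par":
                    fam2 = payload
                    emit_gene(fam2, gene_seq(fam2, "paralog"), "+",
                              product_for(fam2))
                    record_status(fam2)
                    emit(_dec(paralog_pool.slice(ptip, f"{fam2}.sp")))
                elif kind == "pts":
                    if si in pts_carriers:
                        for fam2 in pts_families:
                            emit_gene(fam2, gene_seq(fam2), "+", product_for(fam2))
                            record_status(fam2)
                            emit(_dec(pool.slice(tip, f"{fam2}.sp")))
                elif kind == "hgt":
                    seg_id, seg, genes = payload
                    if si in seg.strains:
                        h_start = pos
                        fams = []
                        for fam2, recip, sp in genes:
                            emit_gene(fam2, recip, "+", "hypothetical protein")
                            truth.status_map[(strain, fam2)] = "intact"
                            fams.append(fam2)
                            emit(sp)
                        truth.hgt_truth.append(HgtTruth(
                            strain=strain, replicon=chrom, start=h_start,
                            end=pos, donor=seg.donor, segment=seg_id,
                            families=tuple(fams)))
                elif kind == "cas":
                    li = payload
                    v = cassette_assignment[(li, si)]
                    for fam2 in cassette_variants[(li, v)]:
                        emit_gene(fam2, gene_seq(fam2), "+", product_for(fam2))
                        record_status(fam2)
                        emit(_dec(pool.slice(tip, f"{fam2}.sp")))
                    truth.cassette_truth[(li, strain)] = v

        chrom_seq = "".join(parts)
        replicons = [Replicon(chrom, len(chrom_seq), circular=False,
                              kind="chromosome")]
        sequences = {chrom: chrom_seq}

        if si in cfg.plasmid_strains:
            pname = f"{strain}_p1"
            parts = []
            pos = 0
            emit(random_spacer(rng))
            for fam in plasmid_families:
                emit_gene(fam, gene_seq(fam), "+", "plasmid protein",
                          replicon=pname)
                truth.status_map[(strain, fam)] = "intact"
                emit(_dec(pool.slice(tip, f"{fam}.sp")))
            pseq = "".join(parts)
            replicons.append(Replicon(pname, len(pseq), circular=True,
                                      kind="plasmid"))
            sequences[pname] = pseq

        ann = StrainAnnotation(
            strain_id=strain, replicons=replicons, features=feats,
            sequences=sequences)
        for f in ann.features:
            if f.kind == "CDS":
                ann.proteome[f.id] = translate_cds(ann.feature_seq(f))
        annotations[strain] = ann

    # --- finalize truth bookkeeping
    all_families = sorted(set(truth.ortholog_map.values()))
    truth.families = all_families
    for fam in all_families:
        truth.family_replicon[fam] = "plasmid" if fam.startswith("pl_") \
            else "chromosome"
    for li, _c in enumerate(cfg.cassette_loci):
        up = core_families[cfg.cassette_loci[li].anchor_index]
        down = core_families[cfg.cassette_loci[li].anchor_index + 1]
        truth.cassette_anchors[li] = (up, down)
        for v in range(cfg.cassette_loci[li].n_variants):
            label = f"V{v + 1}"
            truth.cassette_signatures[(li, label)] = tuple(
                cassette_variants[(li, label)])

    # --- reference "published annotation": intact reference genes minus a
    # deterministic sample of omitted families (annotation differences)
    ref = strains[0]
    ref_intact = sorted(
        fid for fid, fam in truth.ortholog_map.items()
        if truth.feature_strain[fid] == ref
        and truth.status_map.get((ref, fam)) == "intact"
        and truth.family_replicon[fam] == "chromosome")
    omit_count = min(cfg.n_published_omitted, len(ref_intact))
    omitted = set(
        int(i) for i in rng.choice(len(ref_intact), size=omit_count,
                                   replace=False))
    truth.published_reference_ids = [
        fid for i, fid in enumerate(ref_intact) if i not in omitted]

    # --- outgroup proteome from the ancestral core sequences
    outgroup: dict[str, str] = {}
    for fam in core_families + paralog_families:
        if rng.random() < cfg.outgroup_coverage:
            e = pool.elements.get(fam) or paralog_pool.elements.get(fam)
            src = ancestral if fam in pool.elements else paralog_anc
            seq = _dec(src[e.offset:e.offset + e.length])
            og = mutate_gene_aa(seq, cfg.outgroup_divergence, rng)
            outgroup[f"OG_{fam}"] = translate_cds(og)

    out = SimulationOutput(
        strains=annotations, truth=truth, donor_proteomes=donor_proteomes,
        outgroup_proteome=outgroup, phage_role_refs=phage_role_refs,
        config=cfg)

    if out_dir is not None:
        write_simulation(out, out_dir)
    return out


def _revcomp(s: str) -> str:
    comp = str.maketrans("ACGT", "TGCA")
    return s.translate(comp)[::-1]


def write_simulation(out: SimulationOutput, out_dir) -> None:
    gdir = os.path.join(out_dir, "genomes")
    os.makedirs(gdir, exist_ok=True)
    for strain, ann in out.strains.items():
        write_strain(ann,
                     os.path.join(gdir, f"{strain}.fna"),
                     os.path.join(gdir, f"{strain}.gff3"),
                     os.path.join(gdir, f"{strain}.faa"))
    for donor, prot in out.donor_proteomes.items():
        write_proteome(prot, os.path.join(out_dir, f"{donor}.faa"))
    write_proteome(out.outgroup_proteome, os.path.join(out_dir, "outgroup.faa"))
    write_proteome(out.phage_role_refs, os.path.join(out_dir, "phage_roles.faa"))
    write_truth(out.truth, os.path.join(out_dir, "truth"))
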