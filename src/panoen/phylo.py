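"""Core-gene phylogenies: single-copy ortholog selection, family
alignment and concatenation, distance matrices, and neighbour-joining
trees with column-bootstrap support.

Distance-based NJ stands in for maximum-likelihood inference: it is
deterministic, fast at desk scale, and recovers the generating topology
exactly on additive distance matrices (which is also how it is tested).
Ties in the Q criterion break to the lexicographically smallest pair of
cluster labels, so the tree is reproducible across runs and platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._aligner import align_encoded, encode
from .homology import ProteomeIndex, best_hits
from .io import StrainAnnotation
from .orthology import PanLocus
from .pangenome import INTACT, PresenceAbsenceMatrix


@dataclass(frozen=True)
class PhyloFilterParams:
    min_outgroup_identity: float = 60.0
    require_single_copy: bool = True
    require_all_strains_intact: bool = True
    paralog_score_fraction: float = 0.7   # second-best/self score guard

    def __post_init__(self):
        if not 0.0 < self.min_outgroup_identity <= 100.0:
            raise ValueError("min_outgroup_identity must be in (0, 100]")


def _self_score(seq: str) -> int:
    from ._aligner import BLOSUM62
    enc = encode(seq)
    return int(BLOSUM62[enc, enc].sum())


def within_proteome_second_best(
    proteome: Mapping[str, str],
    min_shared_kmers: int = 2,
) -> dict[str, int]:
    """Best non-self alignment score per protein within its own proteome."""
    idx = ProteomeIndex(proteome)
    out: dict[str, int] = {}
    cache: dict[tuple[int, int], int] = {}
    for ia in range(len(idx)):
        best = 0
        for ib in idx.query_candidates(idx.encoded[ia], min_shared_kmers):
            ib = int(ib)
            if ib == ia:
                continue
            key = (min(ia, ib), max(ia, ib))
            if key not in cache:
                cache[key] = align_encoded(idx.encoded[key[0]],
                                           idx.encoded[key[1]])[0]
            best = max(best, cache[key])
        out[idx.ids[ia]] = best
    return out


def select_core_single_copy(
    loci: Sequence[PanLocus],
    matrix: PresenceAbsenceMatrix,
    annotations: Mapping[str, StrainAnnotation],
    outgroup_proteome: Mapping[str, str] | None = None,
    params: PhyloFilterParams = PhyloFilterParams(),
    min_shared_kmers: int = 2,
) -> list[PanLocus]:
    """Phylogeny-grade loci: intact everywhere, single copy, no paralogs.

    A locus is dropped when any member has another gene in its own
    proteome scoring >= 70% of the member's self-alignment score (a
    paralog that could confound the tree), and - when an outgroup is
    supplied - when its representative has no outgroup hit at the
    minimum identity.
    """
    row_of = {pid: i for i, pid in enumerate(matrix.pan_ids)}
    second_best: dict[str, dict[str, int]] = {}
    if params.require_single_copy:
        for s in sorted(annotations):
            second_best[s] = within_proteome_second_best(
                annotations[s].proteome, min_shared_kmers)
    og_index = ProteomeIndex(outgroup_proteome) if outgroup_proteome else None

    selected = []
    for l in loci:
        if l.pan_id not in row_of:
            continue
        row = matrix.values[row_of[l.pan_id]]
        if params.require_all_strains_intact and not (row == INTACT).all():
            continue
        members = {s: ms for s, ms in l.members.items() if ms}
        if any(len(ms) != 1 for ms in members.values()):
            continue
        if params.require_single_copy:
            confounded = False
            for s, (m,) in members.items():
                self_sc = _self_score(annotations[s].proteome[m])
                if second_best[s][m] >= params.paralog_score_fraction * self_sc:
                    confounded = True
                    break
            if confounded:
                continue
        if og_index is not None:
            s = next(s for s, ms in members.items() if l.representative in ms)
            rep = annotations[s].proteome[l.representative]
            tbl = best_hits({"rep": rep}, og_index,
                            min_identity=params.min_outgroup_identity,
                            min_coverage=0.5)
            if not len(tbl):
                continue
        selected.append(l)
    return selected


# ---------------------------------------------------------------------------
# family alignment and concatenation


def align_family(seqs: Mapping[str, str]) -> dict[str, str]:
    """Center-star progressive alignment.

    Families of equal-length members (the substitution-only case) stack
    without gaps.  Otherwise the longest member (ties to the smallest
    key) seeds the star, every other member is pairwise-aligned to it
    (BLOSUM62, affine gaps, free end gaps), and per-center-position
    insertions are merged to their maximum length, preserving each
    pairwise alignment in the final columns.
    """
    if len(seqs) < 2:
        raise ValueError("align_family needs >= 2 sequences")
    keys = sorted(seqs)
    if len({len(seqs[k]) for k in keys}) == 1:
        return {k: seqs[k] for k in keys}
    center = min(keys, key=lambda k: (-len(seqs[k]), k))
    center_seq = seqs[center]
    Lc = len(center_seq)
    paths = {k: _pairwise_path(center_seq, seqs[k])
             for k in keys if k != center}
    ins = [0] * (Lc + 1)
    for aligned, own_ins in paths.values():
        for cpos, gap in own_ins.items():
            ins[cpos] = max(ins[cpos], gap)
    out = {}
    chunks = []
    for i in range(Lc):
        chunks.append("-" * ins[i])
        chunks.append(center_seq[i])
    chunks.append("-" * ins[Lc])
    out[center] = "".join(chunks)
    for k in keys:
        if k == center:
            continue
        aligned, own_ins = paths[k]
        other = seqs[k]
        opos = 0
        chunks = []
        for i in range(Lc + 1):
            own = own_ins.get(i, 0)
            chunks.append(other[opos:opos + own] + "-" * (ins[i] - own))
            opos += own
            if i < Lc:
                o = aligned.get(i)
                if o is None:
                    chunks.append("-")
                else:
                    chunks.append(other[o])
                    opos = o + 1
        out[k] = "".join(chunks)
    width = len(out[center])
    for k, v in out.items():
        if len(v) != width:
            raise AssertionError(f"ragged center-star merge for {k}")
    return {k: out[k] for k in keys}


_FAMILY_ALIGNER = None


def _get_family_aligner():
    global _FAMILY_ALIGNER
    if _FAMILY_ALIGNER is None:
        from Bio import Align
        from Bio.Align import substitution_matrices
        a = Align.PairwiseAligner()
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -12.0
        a.extend_gap_score = -1.0
        a.end_gap_score = 0.0
        _FAMILY_ALIGNER = a
    return _FAMILY_ALIGNER


def _pairwise_path(center: str, other: str) -> tuple[dict[int, int], dict[int, int]]:
    """Map ``other`` onto center coordinates.

    Returns (aligned, insertions): ``aligned[cpos] = opos`` for matched
    columns, and ``insertions[cpos]`` = number of ``other`` residues
    emitted immediately before center position ``cpos``.
    """
    aln = _get_family_aligner().align(center, other)[0]
    cblocks, oblocks = aln.aligned
    aligned: dict[int, int] = {}
    insertions: dict[int, int] = {}
    prev_o = 0
    prev_c = 0
    for (cs, ce), (os_, oe) in zip(cblocks, oblocks):
        if os_ > prev_o:
            insertions[cs] = insertions.get(cs, 0) + (os_ - prev_o)
        for i in range(ce - cs):
            aligned[cs + i] = os_ + i
        prev_o, prev_c = oe, ce
    if len(other) > prev_o:
        insertions[len(center)] = insertions.get(len(center), 0) + \
            (len(other) - prev_o)
    return aligned, insertions


@dataclass
class ConcatenatedAlignment:
    """Per-taxon concatenated alignment with a locus partition map."""

    taxa: list[str]
    sequences: dict[str, str]
    partitions: dict[object, tuple[int, int]]
    molecule: str = "aa"

    def __post_init__(self):
        widths = {len(self.sequences[t]) for t in self.taxa}
        if len(widths) > 1:
            raise ValueError("unequal concatenated lengths")

    @property
    def width(self) -> int:
        return len(self.sequences[self.taxa[0]])

    def as_array(self) -> np.ndarray:
        return np.vstack([
            np.frombuffer(self.sequences[t].encode(), dtype=np.uint8)
            for t in self.taxa])


def concatenate(
    alignments: Mapping[object, Mapping[str, str]],
    taxa: Sequence[str],
    molecule: str = "aa",
) -> ConcatenatedAlignment:
    """Join per-locus alignments in sorted locus order."""
    taxa = list(taxa)
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    partitions = {}
    off = 0
    for key in sorted(alignments, key=lambda k: (str(type(k)), k)):
        aln = alignments[key]
        missing = [t for t in taxa if t not in aln]
        if missing:
            raise ValueError(f"alignment {key!r} missing taxa {missing}")
        w = len(next(iter(aln.values())))
        for t in taxa:
            parts[t].append(aln[t])
        partitions[key] = (off, off + w)
        off += w
    return ConcatenatedAlignment(
        taxa=taxa,
        sequences={t: "".join(parts[t]) for t in taxa},
        partitions=partitions,
        molecule=molecule)


# ---------------------------------------------------------------------------
# distances


def distance_matrix(
    aln: ConcatenatedAlignment,
    correction: str = "none",
) -> pd.DataFrame:
    """Pairwise p-distances over shared non-gap columns, optionally
    Jukes-Cantor (nucleotide) or Poisson (protein) corrected."""
    if len(aln.taxa) < 2:
        raise ValueError("need >= 2 taxa")
    if correction == "jc" and aln.molecule != "nt":
        raise ValueError("Jukes-Cantor correction applies to nucleotides")
    if correction == "poisson" and aln.molecule != "aa":
        raise ValueError("Poisson correction applies to amino acids")
    if correction not in ("none", "jc", "poisson"):
        raise ValueError(f"unknown correction {correction!r}")
    arr = aln.as_array()
    gap = ord("-")
    n = len(aln.taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = (arr[i] != gap) & (arr[j] != gap)
            nv = int(valid.sum())
            diff = int(((arr[i] != arr[j]) & valid).sum())
            p = diff / nv if nv else 0.0
            if correction == "jc":
                p = -0.75 * math.log(1.0 - 4.0 * p / 3.0) if p < 0.75 else float("inf")
            elif correction == "poisson":
                p = -math.log(1.0 - p) if p < 1.0 else float("inf")
            D[i, j] = D[j, i] = p
    return pd.DataFrame(D, index=aln.taxa, columns=aln.taxa)


# ---------------------------------------------------------------------------
# neighbour joining


@dataclass
class PhyloNode:
    name: str | None
    children: list[tuple["PhyloNode", float]] = field(default_factory=list)
    support: float | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        return [x for c, _ in self.children for x in c.leaves()]

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if self.is_leaf():
            return self.name
        inner = ",".join(f"{c._nwk()}:{bl:.6f}" for c, bl in self.children)
        label = "" if self.support is None else f"{self.support:.2f}"
        return f"({inner}){label}"


def neighbor_joining(dist: pd.DataFrame) -> PhyloNode:
    """Canonical NJ; Q-criterion ties break to the smallest label pair.

    Fewer than three taxa yield a cherry or single leaf without error.
    """
    labels = list(dist.index)
    D = dist.to_numpy(dtype=float).copy()
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("distance matrix must be non-negative")
    nodes = [PhyloNode(l) for l in labels]
    tags = list(labels)  # lexicographic tie-break identity per cluster
    if len(nodes) == 1:
        return nodes[0]
    if len(nodes) == 2:
        root = PhyloNode(None)
        root.children = [(nodes[0], D[0, 1] / 2), (nodes[1], D[0, 1] / 2)]
        return root
    active = list(range(len(nodes)))
    while len(active) > 3:
        n = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(n):
            for aj in range(ai + 1, n):
                i, j = active[ai], active[aj]
                q = (n - 2) * D[i, j] - r[i] - r[j]
                tag = tuple(sorted((tags[i], tags[j])))
                cand = (q, tag, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _q, _tag, i, j = best
        vi = (D[i, j] + (r[i] - r[j]) / (len(active) - 2)) / 2
        vj = D[i, j] - vi
        new = PhyloNode(None)
        new.children = [(nodes[i], vi), (nodes[j], vj)]
        D = np.pad(D, ((0, 1), (0, 1)))
        k = D.shape[0] - 1
        for m in active:
            if m in (i, j):
                continue
            D[k, m] = D[m, k] = (D[i, m] + D[j, m] - D[i, j]) / 2
        nodes.append(new)
        tags.append(min(tags[i], tags[j]))
        active = [m for m in active if m not in (i, j)] + [k]
    i, j, k = active
    vi = (D[i, j] + D[i, k] - D[j, k]) / 2
    vj = (D[i, j] + D[j, k] - D[i, k]) / 2
    vk = (D[i, k] + D[j, k] - D[i, j]) / 2
    root = PhyloNode(None)
    order = sorted([(tags[i], i, vi), (tags[j], j, vj), (tags[k], k, vk)])
    root.children = [(nodes[m], bl) for _t, m, bl in order]
    return root


def bipartitions(tree: PhyloNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each named by its smaller/canonical side."""
    all_taxa = frozenset(tree.leaves())
    out = set()

    def walk(node: PhyloNode):
        for child, _bl in node.children:
            side = frozenset(child.leaves())
            if 1 < len(side) < len(all_taxa) - 1:
                other = all_taxa - side
                out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
            walk(child)

    walk(tree)
    return out


def nj_tree(
    dist: pd.DataFrame,
    alignment: ConcatenatedAlignment | None = None,
    n_bootstrap: int = 0,
    seed: int = 0,
    correction: str = "none",
) -> PhyloNode:
    """NJ tree, optionally with column-bootstrap bipartition support."""
    tree = neighbor_joining(dist)
    if alignment is not None and n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        arr = alignment.as_array()
        gap = ord("-")
        taxa = alignment.taxa
        npairs = []
        n = len(taxa)
        diff = []
        valid = []
        for i in range(n):
            for j in range(i + 1, n):
                v = (arr[i] != gap) & (arr[j] != gap)
                diff.append(((arr[i] != arr[j]) & v).astype(np.float64))
                valid.append(v.astype(np.float64))
                npairs.append((i, j))
        diff = np.vstack(diff)
        valid = np.vstack(valid)
        counts: dict[frozenset[str], int] = {}
        width = arr.shape[1]
        for _rep in range(n_bootstrap):
            w = rng.multinomial(width, np.full(width, 1.0 / width)).astype(float)
            dsum = diff @ w
            vsum = valid @ w
            D = np.zeros((n, n))
            for (i, j), ds, vs in zip(npairs, dsum, vsum):
                p = ds / vs if vs else 0.0
                if correction == "poisson":
                    p = -math.log(1 - p) if p < 1 else 10.0
                elif correction == "jc":
                    p = -0.75 * math.log(1 - 4 * p / 3) if p < 0.75 else 10.0
                D[i, j] = D[j, i] = p
            rep_tree = neighbor_joining(pd.DataFrame(D, index=taxa, columns=taxa))
            for bp in bipartitions(rep_tree):
                counts[bp] = counts.get(bp, 0) + 1

        def annotate(node: PhyloNode):
            all_taxa = frozenset(tree.leaves())
            for child, _bl in node.children:
                side = frozenset(child.leaves())
                if 1 < len(side) < len(all_taxa) - 1:
                    canon = min(side, all_taxa - side,
                                key=lambda s: (len(s), sorted(s)))
                    child.support = counts.get(canon, 0) / n_bootstrap
                annotate(child)

        annotate(tree)
    return tree


def build_core_tree(
    loci: Sequence[PanLocus],
    matrix: PresenceAbsenceMatrix,
    annotations: Mapping[str, StrainAnnotation],
    outgroup_proteome: Mapping[str, str] | None = None,
    params: PhyloFilterParams = PhyloFilterParams(),
    n_bootstrap: int = 100,
    seed: int = 0,
    min_shared_kmers: int = 2,
) -> tuple[PhyloNode, ConcatenatedAlignment, list[PanLocus]]:
    """Select single-copy core loci, concatenate, and build the NJ tree."""
    selected = select_core_single_copy(
        loci, matrix, annotations, outgroup_proteome, params,
        min_shared_kmers=min_shared_kmers)
    if len(matrix.strains) < 3:
        raise ValueError("tree inference needs at least three strains")
    alignments = {}
    for l in selected:
        seqs = {s: annotations[s].proteome[l.members[s][0]]
                for s in matrix.strains}
        alignments[l.pan_id] = align_family(seqs)
    aln = concatenate(alignments, matrix.strains, molecule="aa")
    dist = distance_matrix(aln, correction="none")
    tree = nj_tree(dist, aln, n_bootstrap=n_bootstrap, seed=seed)
    return tree, aln, selected
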