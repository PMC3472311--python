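"""Pan-genome locus construction: RBH clustering refined by synteny.

Reciprocal best hits between every strain pair are clustered into
connected components; components in which one strain contributes more
than one gene (paralogs, tandem duplicates, split genes) are resolved
by long-range genomic synteny: members are grouped so that each strain
contributes at most one gene per locus and the total neighbourhood
agreement (shared neighbour loci within a +-w gene window) is
maximised.  Loci are then numbered along a reference strain, with
non-reference loci interleaved at their flanking position by majority
vote, and every member is classified intact or pseudogene.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .homology import ProteomeIndex, reciprocal_best_hits
from .io import StrainAnnotation

SYNTENY_WINDOW = 5        # genes per side
MIN_JOIN_AGREEMENT = 2    # below this a paralog founds its own locus
PSEUDO_LENGTH_FRACTION = 0.8
EXACT_REFINE_LIMIT = 12   # exhaustive search below, iterative sweeps above


@dataclass
class PanLocus:
    """One ortholog group with per-strain members and status."""

    members: dict[str, list[str]] = field(default_factory=dict)
    status: dict[str, str] = field(default_factory=dict)
    pan_id: int | None = None
    representative: str | None = None

    def all_members(self) -> list[str]:
        return [m for ms in self.members.values() for m in ms]

    def strains_present(self) -> list[str]:
        return [s for s, ms in self.members.items() if ms]

    def key(self) -> str:
        return min(self.all_members())


def compute_all_rbh(
    annotations: Mapping[str, StrainAnnotation],
    min_identity: float = 40.0,
    min_coverage: float = 0.5,
    min_shared_kmers: int = 2,
    indexes: Mapping[str, ProteomeIndex] | None = None,
) -> dict[tuple[str, str], set[tuple[str, str]]]:
    """Reciprocal best hits for every unordered strain pair."""
    strains = sorted(annotations)
    if indexes is None:
        indexes = {s: ProteomeIndex(annotations[s].proteome) for s in strains}
    out = {}
    for a, b in itertools.combinations(strains, 2):
        out[(a, b)] = reciprocal_best_hits(
            indexes[a], indexes[b],
            min_identity=min_identity, min_coverage=min_coverage,
            min_shared_kmers=min_shared_kmers)
    return out


def cluster_rbh(
    rbh: Mapping[tuple[str, str], set[tuple[str, str]]],
    annotations: Mapping[str, StrainAnnotation],
) -> list[list[str]]:
    """Connected components of the RBH graph over all CDS features.

    Every CDS appears in exactly one component (singletons included).
    Components where one strain contributes >= 2 members are the
    conflicted ones that synteny refinement resolves.
    """
    g = nx.Graph()
    strain_of = {}
    for s, ann in annotations.items():
        for f in ann.cds:
            g.add_node(f.id)
            strain_of[f.id] = s
    for (a, b), pairs in rbh.items():
        for x, y in pairs:
            g.add_edge(x, y)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: c[0])
    return comps


def is_conflicted(component: Iterable[str], strain_of: Mapping[str, str]) -> bool:
    seen = set()
    for m in component:
        s = strain_of[m]
        if s in seen:
            return True
        seen.add(s)
    return False


class SyntenyContext:
    """Ordered CDS neighbours within a window on each side, per feature."""

    def __init__(self, annotations: Mapping[str, StrainAnnotation],
                 window: int = SYNTENY_WINDOW):
        self.window = window
        self.neighbors: dict[str, list[str]] = {}
        self.strain_of: dict[str, str] = {}
        self.position: dict[str, tuple[str, str, int]] = {}
        self.strand_of: dict[str, str] = {}
        self.length_of: dict[str, int] = {}
        for s, ann in annotations.items():
            by_rep: dict[str, list] = {}
            for f in ann.cds:
                by_rep.setdefault(f.replicon, []).append(f)
            for rep, feats in by_rep.items():
                feats.sort(key=lambda f: f.start)
                ids = [f.id for f in feats]
                for i, f in enumerate(feats):
                    lo = max(0, i - window)
                    self.neighbors[f.id] = ids[lo:i] + ids[i + 1:i + 1 + window]
                    self.strain_of[f.id] = s
                    self.position[f.id] = (s, rep, i)
                    self.strand_of[f.id] = f.strand
                    self.length_of[f.id] = f.length


def _neighbor_profile(member: str, ctx: SyntenyContext,
                      comp_of: Mapping[str, int]) -> set[int]:
    own = comp_of.get(member)
    return {comp_of[x] for x in ctx.neighbors.get(member, [])
            if x in comp_of and comp_of[x] != own}


def _pairwise_agreement(profiles: list[set[int]]) -> list[list[int]]:
    n = len(profiles)
    agree = [[0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            a = len(profiles[i] & profiles[j])
            agree[i][j] = agree[j][i] = a
    return agree


def _merge_split_fragments(members: list[str], ctx: SyntenyContext) -> list[list[str]]:
    """Group same-strain adjacent co-oriented short fragments as one unit.

    Fragments (length < 0.8 x median member length) sitting next to each
    other on the same strand are the two halves of a broken gene; they
    must stay in one locus and count once.
    """
    lengths = sorted(ctx.length_of[m] for m in members)
    median = lengths[len(lengths) // 2]
    units: list[list[str]] = []
    by_strain: dict[str, list[str]] = {}
    for m in sorted(members):
        by_strain.setdefault(ctx.strain_of[m], []).append(m)
    for s, ms in sorted(by_strain.items()):
        ms.sort(key=lambda m: ctx.position[m])
        used = [False] * len(ms)
        for i, m in enumerate(ms):
            if used[i]:
                continue
            unit = [m]
            used[i] = True
            if ctx.length_of[m] < PSEUDO_LENGTH_FRACTION * median:
                for j in range(i + 1, len(ms)):
                    nm = ms[j]
                    if used[j]:
                        continue
                    same_rep = ctx.position[nm][1] == ctx.position[unit[-1]][1]
                    adjacent = abs(ctx.position[nm][2] - ctx.position[unit[-1]][2]) <= 2
                    co_oriented = ctx.strand_of[nm] == ctx.strand_of[m]
                    short = ctx.length_of[nm] < PSEUDO_LENGTH_FRACTION * median
                    if same_rep and adjacent and co_oriented and short:
                        unit.append(nm)
                        used[j] = True
                    else:
                        break
            units.append(unit)
    return units


def _refine_component(members: list[str], ctx: SyntenyContext,
                      comp_of: Mapping[str, int]) -> list[list[str]]:
    """Split one conflicted component into loci (<=1 unit per strain).

    Maximises the total pairwise neighbour agreement within loci; a
    unit only joins a locus when its agreement with that locus is at
    least MIN_JOIN_AGREEMENT, otherwise it founds a new locus.  Small
    components are solved exactly by enumeration, larger ones by
    deterministic greedy sweeps.
    """
    units = _merge_split_fragments(members, ctx)
    units.sort(key=lambda u: (ctx.strain_of[u[0]], ctx.position[u[0]]))
    n = len(units)
    profiles = [set().union(*(_neighbor_profile(m, ctx, comp_of) for m in u))
                for u in units]
    strains = [ctx.strain_of[u[0]] for u in units]
    agree = _pairwise_agreement(profiles)

    def group_gain(group: list[int], k: int) -> int:
        return sum(agree[k][g] for g in group)

    if n <= EXACT_REFINE_LIMIT:
        best_groups: list[list[int]] | None = None
        best_score = -1

        def recurse(k: int, groups: list[list[int]], score: int):
            nonlocal best_groups, best_score
            if k == n:
                if score > best_score:
                    best_score = score
                    best_groups = [list(g) for g in groups]
                return
            for gi, g in enumerate(groups):
                if any(strains[x] == strains[k] for x in g):
                    continue
                gain = group_gain(g, k)
                if gain >= MIN_JOIN_AGREEMENT:
                    g.append(k)
                    recurse(k + 1, groups, score + gain)
                    g.pop()
            groups.append([k])
            recurse(k + 1, groups, score)
            groups.pop()

        recurse(0, [], 0)
        groups = best_groups or [[i] for i in range(n)]
    else:
        groups = []
        for k in range(n):
            best_gi, best_gain = None, MIN_JOIN_AGREEMENT - 1
            for gi, g in enumerate(groups):
                if any(strains[x] == strains[k] for x in g):
                    continue
                gain = group_gain(g, k)
                if gain > best_gain:
                    best_gi, best_gain = gi, gain
            if best_gi is None:
                groups.append([k])
            else:
                groups[best_gi].append(k)
        # reassignment sweeps to escape order effects
        for _sweep in range(3):
            moved = False
            for k in range(n):
                src = next(gi for gi, g in enumerate(groups) if k in g)
                cur_gain = group_gain([x for x in groups[src] if x != k], k)
                best_gi, best_gain = src, max(cur_gain, MIN_JOIN_AGREEMENT - 1)
                for gi, g in enumerate(groups):
                    if gi == src:
                        continue
                    if any(strains[x] == strains[k] for x in g):
                        continue
                    gain = group_gain(g, k)
                    if gain > best_gain:
                        best_gi, best_gain = gi, gain
                if best_gi != src:
                    groups[src].remove(k)
                    groups[best_gi].append(k)
                    moved = True
            groups = [g for g in groups if g]
            if not moved:
                break
    return [sorted(m for u in (units[i] for i in g) for m in u)
            for g in groups]


def refine_with_synteny(
    components: list[list[str]],
    ctx: SyntenyContext,
) -> list[PanLocus]:
    """Resolve conflicted components; return the final locus set."""
    comp_of = {m: ci for ci, comp in enumerate(components) for m in comp}
    loci: list[PanLocus] = []
    for comp in components:
        if is_conflicted(comp, ctx.strain_of):
            parts = _refine_component(comp, ctx, comp_of)
        else:
            parts = [comp]
        for part in parts:
            locus = PanLocus()
            for m in sorted(part):
                locus.members.setdefault(ctx.strain_of[m], []).append(m)
            loci.append(locus)
    loci.sort(key=lambda l: l.key())
    return loci


def classify_member_status(
    locus: PanLocus, annotations: Mapping[str, StrainAnnotation]
) -> dict[str, str]:
    """Intact / pseudogene call per strain.

    A member is a pseudogene when its translation carries an internal
    stop, when it is shorter than 0.8 x the median length of unflagged
    members, or when the strain contributes split fragments.
    """
    prot = {}
    flagged = {}
    for s, ms in locus.members.items():
        for m in ms:
            aa = annotations[s].proteome[m]
            prot[m] = aa
            flagged[m] = "*" in aa
    clean_lengths = sorted(len(prot[m]) for m in prot if not flagged[m])
    median = clean_lengths[len(clean_lengths) // 2] if clean_lengths else 0
    status = {}
    for s, ms in locus.members.items():
        if not ms:
            status[s] = "absent"
            continue
        if len(ms) > 1:
            status[s] = "pseudogene"  # split gene fragments, counted once
            continue
        m = ms[0]
        if flagged[m]:
            status[s] = "pseudogene"
        elif clean_lengths and len(prot[m]) < PSEUDO_LENGTH_FRACTION * median:
            status[s] = "pseudogene"
        else:
            status[s] = "intact"
    locus.status = status
    # representative: longest intact member, ties to lexicographic id
    intact = [(len(prot[m]), m) for s, ms in locus.members.items()
              for m in ms if status[s] == "intact"]
    pool = intact or [(len(prot[m]), m) for m in prot]
    locus.representative = min(pool, key=lambda t: (-t[0], t[1]))[1]
    return status


def assign_pan_numbers(
    loci: list[PanLocus],
    annotations: Mapping[str, StrainAnnotation],
    reference_strain: str,
) -> list[PanLocus]:
    """Number loci 1..N along the reference gene order.

    Loci without a reference member are interleaved after the reference
    locus that most carriers place them behind (majority vote, ties to
    the earlier anchor), ordered within a gap by carrier consensus
    offset then by smallest member id.
    """
    if reference_strain not in annotations:
        raise ValueError(f"unknown reference strain {reference_strain!r}")
    ref_order: dict[str, int] = {}
    for i, f in enumerate(annotations[reference_strain].cds):
        ref_order[f.id] = i
    with_ref = [l for l in loci if l.members.get(reference_strain)]
    with_ref.sort(key=lambda l: min(ref_order[m]
                                    for m in l.members[reference_strain]))
    anchored_rank = {id(l): i for i, l in enumerate(with_ref)}

    locus_of: dict[str, PanLocus] = {}
    for l in loci:
        for m in l.all_members():
            locus_of[m] = l
    order_in_strain: dict[str, list[str]] = {}
    for s, ann in annotations.items():
        by_rep: dict[str, list] = {}
        for f in ann.cds:
            by_rep.setdefault(f.replicon, []).append(f)
        for rep, feats in sorted(by_rep.items()):
            feats.sort(key=lambda f: f.start)
            order_in_strain[(s, rep)] = [f.id for f in feats]

    index_in_rep: dict[str, tuple[tuple[str, str], int]] = {}
    for key, ids in order_in_strain.items():
        for i, m in enumerate(ids):
            index_in_rep[m] = (key, i)

    def left_anchor(member: str) -> tuple[int, int] | None:
        key, i = index_in_rep[member]
        ids = order_in_strain[key]
        for back in range(i - 1, -1, -1):
            l2 = locus_of[ids[back]]
            r = anchored_rank.get(id(l2))
            if r is not None:
                return r, i - back
        return None

    inserts: dict[int, list[tuple[float, str, PanLocus]]] = {}
    for l in loci:
        if l.members.get(reference_strain):
            continue
        votes = []
        dists = []
        for m in l.all_members():
            la = left_anchor(m)
            if la is not None:
                votes.append(la[0])
                dists.append(la[1])
        if votes:
            counts: dict[int, int] = {}
            for v in votes:
                counts[v] = counts.get(v, 0) + 1
            anchor = min(counts, key=lambda v: (-counts[v], v))
            mean_d = sum(d for v, d in zip(votes, dists) if v == anchor) / \
                max(1, sum(1 for v in votes if v == anchor))
        else:
            anchor, mean_d = -1, 0.0
        inserts.setdefault(anchor, []).append((mean_d, l.key(), l))

    numbered: list[PanLocus] = []
    for batch in sorted(inserts.get(-1, [])):
        numbered.append(batch[2])
    for i, l in enumerate(with_ref):
        numbered.append(l)
        for batch in sorted(inserts.get(i, [])):
            numbered.append(batch[2])
    for n, l in enumerate(numbered, start=1):
        l.pan_id = n
    return numbered


def build_pan_loci(
    annotations: Mapping[str, StrainAnnotation],
    reference_strain: str | None = None,
    min_identity: float = 40.0,
    min_coverage: float = 0.5,
    min_shared_kmers: int = 2,
    window: int = SYNTENY_WINDOW,
    indexes: Mapping[str, ProteomeIndex] | None = None,
) -> list[PanLocus]:
    """Full orthology stage: RBH -> clusters -> synteny -> numbers -> status."""
    rbh = compute_all_rbh(annotations, min_identity, min_coverage,
                          min_shared_kmers, indexes=indexes)
    comps = cluster_rbh(rbh, annotations)
    ctx = SyntenyContext(annotations, window=window)
    loci = refine_with_synteny(comps, ctx)
    ref = reference_strain or sorted(annotations)[0]
    loci = assign_pan_numbers(loci, annotations, ref)
    for l in loci:
        for s in annotations:
            l.members.setdefault(s, [])
        classify_member_status(l, annotations)
    return loci


def loci_to_table(loci: list[PanLocus]):
    """Long-format pan-locus table (pan_id, strain, feature_id, status)."""
    import pandas as pd
    rows = []
    for l in loci:
        for s in sorted(l.members):
            ms = l.members[s]
            if not ms:
                continue
            for m in ms:
                rows.append((l.pan_id, s, m, l.status.get(s, "")))
    return pd.DataFrame(rows, columns=["pan_id", "strain", "feature_id", "status"])
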