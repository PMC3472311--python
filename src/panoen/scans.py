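"""Locus-level screens: HGT identity windows, prophage elements at tRNA
attachment sites, cassette-locus genotypes, role-set completeness, and
fusion ORFs.

The HGT scan follows the classic sliding-window design: each gene gets
the amino-acid identity of its best donor-proteome hit, a 10-gene
window mean is reported for plotting, and a region is flagged when at
least ``min_run`` consecutive genes each individually exceed the
identity threshold (the run rule is conjunctive, not window-mean
based).

Prophage elements are delimited by direct repeats of the tRNA 3' core
(the attL/attR structure left by integrase-mediated insertion), then
classified by gene content: integrase plus endolysin means a full,
presumably functional element, integrase alone a fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._aligner import align_encoded, encode
from .homology import ProteomeIndex, align_pair, best_hits
from .io import StrainAnnotation
from .orthology import PanLocus
from .pangenome import INTACT, PSEUDOGENE, PresenceAbsenceMatrix


@dataclass(frozen=True)
class ScanParams:
    window: int = 10          # loci per sliding window (plotting mean)
    min_run: int = 5          # consecutive qualifying loci to flag
    min_identity: float = 90.0

    def __post_init__(self):
        if not (self.window >= self.min_run >= 1):
            raise ValueError("require window >= min_run >= 1")
        if not 0.0 < self.min_identity <= 100.0:
            raise ValueError("min_identity must be in (0, 100]")


@dataclass(frozen=True)
class HgtRegion:
    strain: str
    replicon: str
    first_index: int      # gene order index of first flagged locus
    last_index: int       # inclusive
    start: int            # genomic span, 0-based half-open
    end: int
    feature_ids: tuple[str, ...]


def hgt_window_scan(
    annotation: StrainAnnotation,
    donor_proteomes: Mapping[str, Mapping[str, str]],
    params: ScanParams = ScanParams(),
    min_coverage: float = 0.5,
) -> tuple[pd.DataFrame, list[HgtRegion]]:
    """Per-gene best donor identity, window means and flagged runs.

    Genes are taken in genome order per replicon; windows never span a
    replicon boundary.  A gene with no donor hit at >=``min_coverage``
    mutual coverage scores identity 0.
    """
    if not donor_proteomes or all(not p for p in donor_proteomes.values()):
        raise ValueError("empty donor proteome set")
    combined: dict[str, str] = {}
    for donor, prot in sorted(donor_proteomes.items()):
        for pid, seq in prot.items():
            combined[f"{donor}::{pid}"] = seq
    donor_index = ProteomeIndex(combined)

    hits = best_hits(annotation.proteome, donor_index,
                     min_identity=0.0, min_coverage=min_coverage)
    ident = dict(zip(hits["query"], hits["identity"]))

    rows = []
    regions: list[HgtRegion] = []
    by_rep: dict[str, list] = {}
    for f in annotation.cds:
        by_rep.setdefault(f.replicon, []).append(f)
    for rep in sorted(by_rep):
        feats = sorted(by_rep[rep], key=lambda f: f.start)
        idents = np.array([ident.get(f.id, 0.0) for f in feats])
        means = np.full(len(feats), np.nan)
        w = params.window
        for i in range(0, len(feats) - w + 1):
            means[i] = idents[i:i + w].mean()
        qual = idents >= params.min_identity
        i = 0
        flag = np.zeros(len(feats), dtype=bool)
        while i < len(feats):
            if qual[i]:
                j = i
                while j + 1 < len(feats) and qual[j + 1]:
                    j += 1
                if j - i + 1 >= params.min_run:
                    flag[i:j + 1] = True
                    regions.append(HgtRegion(
                        strain=annotation.strain_id, replicon=rep,
                        first_index=i, last_index=j,
                        start=feats[i].start, end=feats[j].end,
                        feature_ids=tuple(f.id for f in feats[i:j + 1])))
                i = j + 1
            else:
                i += 1
        for i, f in enumerate(feats):
            rows.append((annotation.strain_id, rep, i, f.id,
                         float(idents[i]),
                         float(means[i]) if not np.isnan(means[i]) else None,
                         bool(flag[i])))
    table = pd.DataFrame(rows, columns=[
        "strain", "replicon", "order_index", "feature_id",
        "identity", "window_mean", "flagged"])
    return table, regions


# ---------------------------------------------------------------------------
# prophage detection


@dataclass(frozen=True)
class PhageElement:
    strain: str
    trna_id: str
    replicon: str
    start: int
    end: int
    phage_class: str          # "full" | "fragment"
    copy_number: int
    roles_found: tuple[str, ...]
    feature_ids: tuple[str, ...] = ()


def _approx_occurrences(haystack: str, needle: str, min_identity: float) -> list[int]:
    n = len(needle)
    if len(haystack) < n:
        return []
    hs = np.frombuffer(haystack.encode(), dtype=np.uint8)
    nd = np.frombuffer(needle.encode(), dtype=np.uint8)
    win = np.lib.stride_tricks.sliding_window_view(hs, n)
    matches = (win == nd).sum(axis=1)
    hits = np.nonzero(matches >= min_identity * n)[0]
    # collapse overlapping candidate positions to the best local match
    out: list[int] = []
    for p in hits:
        if out and p - out[-1] < n:
            if matches[p] > matches[out[-1]]:
                out[-1] = int(p)
        else:
            out.append(int(p))
    return out


def _role_of_ref(ref_id: str) -> str:
    tail = ref_id.rsplit("_", 1)[-1].lower()
    return tail if tail in ("int", "lys") else ref_id


def detect_phage_elements(
    annotation: StrainAnnotation,
    role_refs: Mapping[str, str],
    trna_ids: Iterable[str] | None = None,
    max_len: int = 60_000,
    att_core_len: int = 20,
    min_repeat_identity: float = 0.9,
    min_role_identity: float = 40.0,
) -> list[PhageElement]:
    """Scan downstream of each tRNA 3' end for att-delimited elements.

    Direct repeats of the tRNA 3' core (>=15 bp, >=90% identity) bound
    the element copies; consecutive phage-positive copies merge into one
    element with their count as the copy number.
    """
    if not role_refs:
        raise ValueError("role_refs must be non-empty")
    ref_index = ProteomeIndex(role_refs)
    wanted = set(trna_ids) if trna_ids is not None else None
    out: list[PhageElement] = []
    trnas = [t for t in annotation.trnas
             if wanted is None or t.id in wanted or
             t.attributes.get("Name") in wanted]
    if wanted is not None:
        known = {t.id for t in annotation.trnas} | {
            t.attributes.get("Name") for t in annotation.trnas}
        for w in sorted(wanted - known):
            import warnings
            warnings.warn(f"tRNA {w} absent from {annotation.strain_id}; skipped")
    for t in trnas:
        seq = annotation.sequences[t.replicon]
        core_len = min(att_core_len, t.length)
        if core_len < 15:
            continue
        if t.strand == "+":
            core = seq[t.end - core_len:t.end]
            region = seq[t.end:t.end + max_len]
            to_genomic = lambda off: t.end + off
        else:
            core = _revcomp(seq[t.start:t.start + core_len])
            start0 = max(0, t.start - max_len)
            region = _revcomp(seq[start0:t.start])
            to_genomic = lambda off: t.start - off
        occ = _approx_occurrences(region, core, min_repeat_identity)
        if not occ:
            continue
        # copy i occupies (boundary_{i-1}, occ_i); boundaries at repeat ends
        boundaries = [0] + [p + core_len for p in occ]
        copies = []
        for ci, p in enumerate(occ):
            span_lo, span_hi = boundaries[ci], p
            g1, g2 = to_genomic(span_lo), to_genomic(p + core_len)
            lo, hi = min(g1, g2), max(g1, g2)
            feats = [f for f in annotation.cds
                     if f.replicon == t.replicon and f.start >= lo and f.end <= hi]
            roles = set()
            for f in feats:
                prot = annotation.proteome[f.id]
                tbl = best_hits({f.id: prot}, ref_index,
                                min_identity=min_role_identity, min_coverage=0.5)
                for r in tbl.itertuples():
                    roles.add(_role_of_ref(r.subject))
            if "int" in roles and "lys" in roles:
                cls = "full"
            elif "int" in roles:
                cls = "fragment"
            else:
                cls = None
            copies.append((cls, lo, hi, roles, feats))
        # leading run of phage-positive copies = the element at this site
        run = []
        for c in copies:
            if c[0] is None:
                break
            run.append(c)
        if not run:
            continue
        lo = min(c[1] for c in run)
        hi = max(c[2] for c in run)
        roles = sorted(set().union(*(c[3] for c in run)))
        cls = "full" if any(c[0] == "full" for c in run) else "fragment"
        feature_ids = tuple(f.id for c in run for f in c[4])
        out.append(PhageElement(
            strain=annotation.strain_id, trna_id=t.id, replicon=t.replicon,
            start=lo, end=hi, phage_class=cls, copy_number=len(run),
            roles_found=tuple(roles), feature_ids=feature_ids))
    return out


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# ---------------------------------------------------------------------------
# cassette genotyping


@dataclass
class CassetteGenotype:
    anchors: tuple[int, int]                    # (upstream, downstream) pan ids
    variant_of: dict[str, str]                  # strain -> label or "unresolved"
    signatures: dict[str, tuple[int, ...]]      # label -> ordered pan ids
    inverted: dict[str, bool] = field(default_factory=dict)

    def n_variants(self) -> int:
        return len(self.signatures)


class FeatureOrderIndex:
    """Per-strain CDS order lookup, shared across many genotyping calls."""

    def __init__(self, annotations: Mapping[str, StrainAnnotation]):
        self.order: dict[tuple[str, str], list] = {}
        self.pos: dict[str, tuple[str, str, int]] = {}
        for s, ann in annotations.items():
            by_rep: dict[str, list] = {}
            for f in ann.cds:
                by_rep.setdefault(f.replicon, []).append(f)
            for rep, feats in by_rep.items():
                feats.sort(key=lambda f: f.start)
                self.order[(s, rep)] = feats
                for i, f in enumerate(feats):
                    self.pos[f.id] = (s, rep, i)


def genotype_cassette_locus(
    loci: Sequence[PanLocus],
    annotations: Mapping[str, StrainAnnotation],
    anchors: tuple[int, int],
    index: FeatureOrderIndex | None = None,
    locus_of: Mapping[str, int] | None = None,
) -> CassetteGenotype:
    """Group strains by the ordered locus content between two anchors.

    Content is orientation-normalised (read from the upstream anchor);
    a strain whose region is inverted relative to the anchors yields the
    same variant as the uninverted content, flagged ``inverted``.
    Variant labels are ordered by frequency, then by signature.
    """
    by_pan = {l.pan_id: l for l in loci}
    if locus_of is None:
        locus_of = {m: l.pan_id for l in loci for m in l.all_members()}
    if index is None:
        index = FeatureOrderIndex(annotations)
    up, down = anchors
    if up not in by_pan or down not in by_pan:
        raise ValueError("anchor pan_id not found")
    sigs: dict[str, tuple[int, ...]] = {}
    inverted: dict[str, bool] = {}
    for s in sorted(annotations):
        ups = by_pan[up].members.get(s, [])
        downs = by_pan[down].members.get(s, [])
        if len(ups) != 1 or len(downs) != 1:
            sigs[s] = None
            continue
        su, rep_u, iu = index.pos[ups[0]]
        sd, rep_d, idn = index.pos[downs[0]]
        if rep_u != rep_d:
            sigs[s] = None
            continue
        lo_i, hi_i = sorted((iu, idn))
        between = index.order[(s, rep_u)][lo_i + 1:hi_i]
        ids = [locus_of.get(f.id, -1) for f in between]
        inv = iu > idn
        if inv:
            ids = ids[::-1]
        sigs[s] = tuple(ids)
        inverted[s] = inv

    counts: dict[tuple[int, ...], int] = {}
    for s, sig in sigs.items():
        if sig is not None:
            counts[sig] = counts.get(sig, 0) + 1
    ordered = sorted(counts, key=lambda sig: (-counts[sig], sig))
    label_of = {sig: f"V{i + 1}" for i, sig in enumerate(ordered)}
    variant_of = {s: (label_of[sig] if sig is not None else "unresolved")
                  for s, sig in sigs.items()}
    return CassetteGenotype(
        anchors=anchors,
        variant_of=variant_of,
        signatures={label_of[sig]: sig for sig in ordered},
        inverted=inverted,
    )


# ---------------------------------------------------------------------------
# role-set completeness


def role_completeness(
    matrix: PresenceAbsenceMatrix,
    role_map: Mapping[int, str],
    required_roles: Sequence[str],
    grouping: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Per strain (and role group): is every required role intact?

    A blocked role is reported with its cause: ``pseudogenization`` when
    a pseudogene copy exists, ``absence`` otherwise.
    """
    if not required_roles:
        raise ValueError("required_roles must be non-empty")
    available = set(role_map.values())
    missing = [r for r in required_roles if r not in available]
    if missing:
        raise ValueError(f"roles not present in role_map: {missing}")
    if grouping is None:
        grouping = {"all": list(required_roles)}
    loci_by_role: dict[str, list[int]] = {}
    for pid, role in role_map.items():
        loci_by_role.setdefault(role, []).append(pid)
    row_of = {pid: i for i, pid in enumerate(matrix.pan_ids)}
    rows = []
    for group, roles in sorted(grouping.items()):
        for j, s in enumerate(matrix.strains):
            blocks = []
            for role in roles:
                states = [matrix.values[row_of[pid], j]
                          for pid in loci_by_role.get(role, [])
                          if pid in row_of]
                if any(v == INTACT for v in states):
                    continue
                cause = "pseudogenization" if any(v == PSEUDOGENE for v in states) \
                    else "absence"
                blocks.append(f"{role}:{cause}")
            rows.append((group, s, not blocks, ";".join(blocks)))
    return pd.DataFrame(rows, columns=["group", "strain", "complete", "blocking"])


# ---------------------------------------------------------------------------
# fusion ORFs


def detect_fusions(
    proteome: Mapping[str, str],
    family_representatives: Mapping[str, str],
    min_identity: float = 40.0,
    single_cover: float = 0.8,
    part_cover: float = 0.3,
    max_overlap: float = 0.1,
) -> pd.DataFrame:
    """Flag ORFs matched piecewise by two different families.

    An ORF is a fusion candidate when no single family hit covers
    >=80% of it, but hits from two families cover >=30% each with
    <=10% mutual overlap.  The breakpoint estimate is the midpoint of
    the gap between the two hit spans on the ORF.
    """
    fams = set(family_representatives)
    if len(fams) < 2:
        raise ValueError("need representatives from at least two families")
    rep_index = ProteomeIndex(dict(family_representatives))
    rows = []
    for orf_id in sorted(proteome):
        seq = proteome[orf_id]
        if not seq:
            continue
        hits = []
        for ridx in rep_index.query_candidates(encode(seq), 2):
            fam = rep_index.ids[int(ridx)]
            h = align_pair(seq, rep_index.seqs[fam], query_id=orf_id,
                           subject_id=fam)
            if h.identity_percent >= min_identity and h.coverage_subject >= 0.5:
                span = _query_span(seq, rep_index.seqs[fam])
                hits.append((fam, span, h))
        if not hits:
            continue
        L = len(seq)
        if any((sp[1] - sp[0]) / L >= single_cover for _f, sp, _h in hits):
            continue
        best = None
        for i in range(len(hits)):
            for j in range(i + 1, len(hits)):
                fa, sa, ha = hits[i]
                fb, sb, hb = hits[j]
                if fa == fb:
                    continue
                ca, cb = (sa[1] - sa[0]) / L, (sb[1] - sb[0]) / L
                if ca < part_cover or cb < part_cover:
                    continue
                ov = max(0, min(sa[1], sb[1]) - max(sa[0], sb[0])) / L
                if ov > max_overlap:
                    continue
                key = ca + cb
                if best is None or key > best[0]:
                    if sa[0] > sb[0]:
                        (fa, sa, ha), (fb, sb, hb) = (fb, sb, hb), (fa, sa, ha)
                    best = (key, fa, fb, sa, sb)
        if best is not None:
            _key, fa, fb, sa, sb = best
            gap_lo, gap_hi = sa[1], sb[0]
            breakpoint = (gap_lo + max(gap_lo, gap_hi)) / 2
            rows.append((orf_id, fa, fb,
                         round((sa[1] - sa[0]) / L, 3),
                         round((sb[1] - sb[0]) / L, 3),
                         int(breakpoint)))
    return pd.DataFrame(rows, columns=[
        "orf", "family_n", "family_c", "cov_n", "cov_c", "breakpoint"])


def _query_span(query: str, subject: str) -> tuple[int, int]:
    _s, _m, _c, q0, _s0, q1, _s1 = align_encoded(encode(query), encode(subject))
    return q0, q1
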