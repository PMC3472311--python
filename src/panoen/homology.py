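"""Pairwise protein similarity and reciprocal-best-hit tables.

This is the "sequence homology" half of the orthology assignment: every
protein of one strain is searched against the proteome of another, and
pairs that are each other's top-scoring match (reciprocal best hits,
RBH) become candidate orthologs.  A shared-5-mer prefilter skips pairs
that cannot plausibly align; it never alters a computed score.

Identity is reported as matches / aligned columns x 100, with terminal
gap columns excluded (the closest analogue of a local aligner's
identity on full-length orthologs).  Coverage is the aligned span
divided by the sequence length, per sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._aligner import align_encoded, encode

DEFAULT_MIN_IDENTITY = 40.0
DEFAULT_MIN_COVERAGE = 0.5
KMER_SIZE = 5
DEFAULT_MIN_SHARED_KMERS = 2

HIT_COLUMNS = ["query", "subject", "identity", "cov_q", "cov_s", "score"]


@dataclass(frozen=True)
class HomologyHit:
    """One query/subject alignment summary."""

    query: str
    subject: str
    identity_percent: float
    coverage_query: float
    coverage_subject: float
    score: int


def align_pair(a: str, b: str, gap_open: int = 11, gap_extend: int = 1,
               query_id: str = "query", subject_id: str = "subject") -> HomologyHit:
    """Globally align two proteins with free end gaps (BLOSUM62, 11+k gaps)."""
    if not a or not b:
        raise ValueError("align_pair requires non-empty sequences")
    score, matches, cols, a0, b0, a1, b1 = align_encoded(
        encode(a), encode(b), gap_open, gap_extend
    )
    return HomologyHit(
        query=query_id,
        subject=subject_id,
        identity_percent=100.0 * matches / cols,
        coverage_query=(a1 - a0) / len(a),
        coverage_subject=(b1 - b0) / len(b),
        score=score,
    )


class ProteomeIndex:
    """Encoded proteome plus a 5-mer inverted index for the prefilter."""

    def __init__(self, proteome: Mapping[str, str]):
        if not proteome:
            raise ValueError("empty proteome")
        self.ids: list[str] = sorted(proteome)
        self.seqs: dict[str, str] = dict(proteome)
        self.encoded: list[np.ndarray] = [encode(proteome[i]) for i in self.ids]
        self.lengths = np.array([len(proteome[i]) for i in self.ids])
        kmers = []
        owners = []
        base = 32  # > alphabet size
        for idx, enc in enumerate(self.encoded):
            if enc.size < KMER_SIZE:
                continue
            e = enc.astype(np.int64)
            km = np.zeros(e.size - KMER_SIZE + 1, dtype=np.int64)
            for k in range(KMER_SIZE):
                km = km * base + e[k : e.size - KMER_SIZE + 1 + k]
            km = np.unique(km)
            kmers.append(km)
            owners.append(np.full(km.size, idx, dtype=np.int64))
        if kmers:
            allk = np.concatenate(kmers)
            allo = np.concatenate(owners)
            order = np.argsort(allk, kind="stable")
            self._kmers = allk[order]
            self._owners = allo[order]
        else:
            self._kmers = np.empty(0, dtype=np.int64)
            self._owners = np.empty(0, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.ids)

    def query_candidates(self, enc: np.ndarray, min_shared: int) -> np.ndarray:
        """Indices of proteins sharing >= min_shared distinct 5-mers."""
        if enc.size < KMER_SIZE or self._kmers.size == 0:
            return np.empty(0, dtype=np.int64)
        e = enc.astype(np.int64)
        km = np.zeros(e.size - KMER_SIZE + 1, dtype=np.int64)
        for k in range(KMER_SIZE):
            km = km * 32 + e[k : e.size - KMER_SIZE + 1 + k]
        km = np.unique(km)
        lo = np.searchsorted(self._kmers, km, side="left")
        hi = np.searchsorted(self._kmers, km, side="right")
        span = hi - lo
        if span.sum() == 0:
            return np.empty(0, dtype=np.int64)
        hits = np.concatenate([self._owners[l:h] for l, h in zip(lo, hi) if h > l])
        owners, counts = np.unique(hits, return_counts=True)
        return owners[counts >= min_shared]


def _as_index(p) -> ProteomeIndex:
    return p if isinstance(p, ProteomeIndex) else ProteomeIndex(p)


class PairwiseScores:
    """Cache of alignments between two indexed proteomes."""

    def __init__(self, A: ProteomeIndex, B: ProteomeIndex,
                 gap_open: int = 11, gap_extend: int = 1):
        self.A, self.B = A, B
        self.gap_open, self.gap_extend = gap_open, gap_extend
        self._cache: dict[tuple[int, int], tuple[int, int, int, int, int, int, int]] = {}

    def get(self, ia: int, ib: int):
        key = (ia, ib)
        if key not in self._cache:
            self._cache[key] = align_encoded(
                self.A.encoded[ia], self.B.encoded[ib],
                self.gap_open, self.gap_extend,
            )
        return self._cache[key]


def _hit_row(A: ProteomeIndex, B: ProteomeIndex, ia: int, ib: int, res):
    score, matches, cols, a0, b0, a1, b1 = res
    return (
        A.ids[ia], B.ids[ib],
        100.0 * matches / cols,
        (a1 - a0) / A.lengths[ia],
        (b1 - b0) / B.lengths[ib],
        score,
    )


def best_hits(
    A: Mapping[str, str] | ProteomeIndex,
    B: Mapping[str, str] | ProteomeIndex,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    kmer_prefilter: bool = True,
    min_shared_kmers: int = DEFAULT_MIN_SHARED_KMERS,
    scores: PairwiseScores | None = None,
) -> pd.DataFrame:
    """Top-scoring subject per query, subject to identity/coverage cut-offs.

    Score ties break to the lexicographically smallest subject id.  With
    the prefilter enabled, query/subject pairs sharing fewer than
    ``min_shared_kmers`` distinct 5-mers are skipped entirely.
    """
    A = _as_index(A)
    B = _as_index(B)
    if scores is None:
        scores = PairwiseScores(A, B)
    rows = []
    nB = len(B)
    for ia in range(len(A)):
        if kmer_prefilter:
            cands = B.query_candidates(A.encoded[ia], min_shared_kmers)
        else:
            cands = np.arange(nB)
        best_row = None
        for ib in cands:
            row = _hit_row(A, B, ia, int(ib), scores.get(ia, int(ib)))
            if row[2] < min_identity or row[3] < min_coverage or row[4] < min_coverage:
                continue
            if best_row is None or (-row[5], row[1]) < (-best_row[5], best_row[1]):
                best_row = row
        if best_row is not None:
            rows.append(best_row)
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def all_hits(
    A: Mapping[str, str] | ProteomeIndex,
    B: Mapping[str, str] | ProteomeIndex,
    min_identity: float = 0.0,
    min_coverage: float = 0.0,
    kmer_prefilter: bool = True,
    min_shared_kmers: int = DEFAULT_MIN_SHARED_KMERS,
) -> pd.DataFrame:
    """All prefilter-passing query/subject alignments above the cut-offs."""
    A = _as_index(A)
    B = _as_index(B)
    scores = PairwiseScores(A, B)
    rows = []
    for ia in range(len(A)):
        if kmer_prefilter:
            cands = B.query_candidates(A.encoded[ia], min_shared_kmers)
        else:
            cands = np.arange(len(B))
        for ib in cands:
            row = _hit_row(A, B, ia, int(ib), scores.get(ia, int(ib)))
            if row[2] >= min_identity and row[3] >= min_coverage and row[4] >= min_coverage:
                rows.append(row)
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def reciprocal_best_hits(
    A: Mapping[str, str] | ProteomeIndex,
    B: Mapping[str, str] | ProteomeIndex,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    kmer_prefilter: bool = True,
    min_shared_kmers: int = DEFAULT_MIN_SHARED_KMERS,
) -> set[tuple[str, str]]:
    """Pairs (a, b) that are each other's unique top hit.

    Score ties for a query's top hit break first to the candidate whose
    own ranking places the query highest (rank agreement), then to the
    lexicographically smallest id, which makes the relation symmetric:
    ``reciprocal_best_hits(A, B)`` is the transpose of
    ``reciprocal_best_hits(B, A)``.
    """
    A = _as_index(A)
    B = _as_index(B)
    scores = PairwiseScores(A, B)

    # candidate pair scores, computed once (alignment is symmetric)
    pair_rows: dict[tuple[int, int], tuple] = {}
    for ia in range(len(A)):
        if kmer_prefilter:
            cands = B.query_candidates(A.encoded[ia], min_shared_kmers)
        else:
            cands = np.arange(len(B))
        for ib in cands:
            pair_rows[(ia, int(ib))] = _hit_row(A, B, ia, int(ib), scores.get(ia, int(ib)))
    if kmer_prefilter:
        # the 5-mer filter is symmetric in principle; make it so exactly
        for ib in range(len(B)):
            cands = A.query_candidates(B.encoded[ib], min_shared_kmers)
            for ia in cands:
                key = (int(ia), ib)
                if key not in pair_rows:
                    pair_rows[key] = _hit_row(A, B, int(ia), ib, scores.get(int(ia), ib))

    passing = {
        k: r for k, r in pair_rows.items()
        if r[2] >= min_identity and r[3] >= min_coverage and r[4] >= min_coverage
    }
    by_a: dict[int, list[tuple[int, int]]] = {}
    by_b: dict[int, list[tuple[int, int]]] = {}
    for (ia, ib), r in passing.items():
        by_a.setdefault(ia, []).append((ia, ib))
        by_b.setdefault(ib, []).append((ia, ib))

    def rank(entries, score):
        return sum(1 for k in entries if passing[k][5] > score)

    def top_for_a(ia):
        entries = by_a[ia]
        smax = max(passing[e][5] for e in entries)
        tied = [e for e in entries if passing[e][5] == smax]
        tied.sort(key=lambda e: (rank(by_b[e[1]], smax), B.ids[e[1]]))
        return tied[0][1]

    def top_for_b(ib):
        entries = by_b[ib]
        smax = max(passing[e][5] for e in entries)
        tied = [e for e in entries if passing[e][5] == smax]
        tied.sort(key=lambda e: (rank(by_a[e[0]], smax), A.ids[e[0]]))
        return tied[0][0]

    out = set()
    for ia in by_a:
        ib = top_for_a(ia)
        if top_for_b(ib) == ia:
            out.add((A.ids[ia], B.ids[ib]))
    return out


def hits_to_tsv(hits: pd.DataFrame, path) -> None:
    hits.sort_values(["query", "subject"]).to_csv(
        path, sep="\t", index=False, float_format="%.4f"
    )
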