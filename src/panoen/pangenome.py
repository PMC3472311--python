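"""Presence/absence matrix, core/pan rarefaction and gene inventories.

The tri-state matrix (absent / pseudogene / intact, coded 0/1/2) is the
substrate for every pan-genome statistic.  Rarefaction recomputes core
and pan sizes over strain subsets of every size; subsets are enumerated
exhaustively whenever the number of combinations is below a limit
(always the case at the 14-strain study scale, where the largest level
has C(14,7)=3432 combinations), otherwise sampled with a seeded RNG.

By default a pseudogene counts as absent for the core (the core is the
set of loci *functional* in every strain) and as present for the pan
(the locus exists in the species); both conventions are configurable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .homology import ProteomeIndex, best_hits
from .orthology import PanLocus

ABSENT, PSEUDOGENE, INTACT = 0, 1, 2
_CODE = {"absent": ABSENT, "pseudogene": PSEUDOGENE, "intact": INTACT}


@dataclass
class PresenceAbsenceMatrix:
    """loci x strains tri-state matrix with pan_id row labels."""

    values: np.ndarray              # int8, coded 0/1/2
    pan_ids: list[int]
    strains: list[str]

    def __post_init__(self):
        if self.values.shape != (len(self.pan_ids), len(self.strains)):
            raise ValueError("matrix shape does not match labels")
        if (self.values == ABSENT).all(axis=1).any():
            raise ValueError("all-absent locus row")

    @property
    def n_loci(self) -> int:
        return len(self.pan_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.pan_ids, columns=self.strains)

    def core_size(self, pseudogene_as_present: bool = False) -> int:
        thr = PSEUDOGENE if pseudogene_as_present else INTACT
        return int((self.values >= thr).all(axis=1).sum())

    def pan_size(self, pseudogene_as_present: bool = True) -> int:
        thr = PSEUDOGENE if pseudogene_as_present else INTACT
        return int((self.values >= thr).any(axis=1).sum())


def build_matrix(
    loci: Sequence[PanLocus],
    annotations: Mapping[str, "StrainAnnotation"] | None = None,
    chromosomal_only: bool = False,
) -> PresenceAbsenceMatrix:
    """Tri-state matrix from classified pan loci.

    With ``chromosomal_only`` set, loci whose members all sit on plasmid
    replicons are dropped (the headline pan/core counts are chromosomal).
    """
    strains = sorted({s for l in loci for s in l.members})
    kind_of: dict[str, str] = {}
    if chromosomal_only:
        if annotations is None:
            raise ValueError("chromosomal_only requires annotations")
        for s, ann in annotations.items():
            kinds = {r.name: r.kind for r in ann.replicons}
            for f in ann.cds:
                kind_of[f.id] = kinds[f.replicon]
    keep: list[PanLocus] = []
    for l in loci:
        if chromosomal_only:
            kinds = {kind_of[m] for ms in l.members.values() for m in ms}
            if kinds == {"plasmid"}:
                continue
        keep.append(l)
    vals = np.zeros((len(keep), len(strains)), dtype=np.int8)
    for i, l in enumerate(keep):
        for j, s in enumerate(strains):
            vals[i, j] = _CODE[l.status.get(s, "absent")]
    pan_ids = [l.pan_id if l.pan_id is not None else -(i + 1)
               for i, l in enumerate(keep)]
    return PresenceAbsenceMatrix(vals, pan_ids, strains)


@dataclass
class RarefactionCurve:
    """Core/pan sizes over strain subsets of every size."""

    x: list[int]
    per_subset: dict[int, list[tuple[int, int]]]   # x -> [(core, pan), ...]
    mean_core: dict[int, float]
    mean_pan: dict[int, float]
    mode: dict[int, str]                           # x -> "exact" | "sampled"
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for x in self.x:
            for i, (c, p) in enumerate(self.per_subset[x]):
                rows.append((x, i, c, p))
        return pd.DataFrame(rows, columns=["x", "subset_index", "core", "pan"])


def rarefaction(
    matrix: PresenceAbsenceMatrix,
    core_pseudogene_as_present: bool = False,
    pan_pseudogene_as_present: bool = True,
    exact_limit: int = 10_000,
    n_samples: int = 1000,
    seed: int | None = 0,
) -> RarefactionCurve:
    """Core/pan accumulation over all (or sampled) strain combinations."""
    S = len(matrix.strains)
    if S < 1:
        raise ValueError("need at least one strain")
    core_thr = PSEUDOGENE if core_pseudogene_as_present else INTACT
    pan_thr = PSEUDOGENE if pan_pseudogene_as_present else INTACT
    core_mask = matrix.values >= core_thr          # loci x strains
    pan_mask = matrix.values >= pan_thr
    rng = np.random.default_rng(seed)
    per_subset: dict[int, list[tuple[int, int]]] = {}
    mode: dict[int, str] = {}
    for x in range(1, S + 1):
        n_comb = comb(S, x)
        vals = []
        if n_comb <= exact_limit:
            mode[x] = "exact"
            for cols in itertools.combinations(range(S), x):
                idx = list(cols)
                core = int(core_mask[:, idx].all(axis=1).sum())
                pan = int(pan_mask[:, idx].any(axis=1).sum())
                vals.append((core, pan))
        else:
            mode[x] = "sampled"
            for _ in range(n_samples):
                idx = rng.choice(S, size=x, replace=False)
                core = int(core_mask[:, idx].all(axis=1).sum())
                pan = int(pan_mask[:, idx].any(axis=1).sum())
                vals.append((core, pan))
        per_subset[x] = vals
    return RarefactionCurve(
        x=list(range(1, S + 1)),
        per_subset=per_subset,
        mean_core={x: float(np.mean([c for c, _ in v]))
                   for x, v in per_subset.items()},
        mean_pan={x: float(np.mean([p for _, p in v]))
                  for x, v in per_subset.items()},
        mode=mode,
        seed=seed,
    )


def group_specific_loci(
    matrix: PresenceAbsenceMatrix, strain_group: Iterable[str]
) -> list[int]:
    """Loci intact in every group member and absent from all other strains."""
    group = sorted(set(strain_group))
    if not group:
        raise ValueError("empty strain group")
    unknown = [s for s in group if s not in matrix.strains]
    if unknown:
        raise ValueError(f"unknown strains in group: {unknown}")
    in_idx = [matrix.strains.index(s) for s in group]
    out_idx = [i for i, s in enumerate(matrix.strains) if s not in group]
    mask = (matrix.values[:, in_idx] == INTACT).all(axis=1)
    if out_idx:
        mask &= (matrix.values[:, out_idx] == ABSENT).all(axis=1)
    return [matrix.pan_ids[i] for i in np.nonzero(mask)[0]]


INVENTORY_CLASSES = ("annotation_difference", "reference_pseudogene",
                     "strain_specific_insertion")


def non_reference_inventory(
    matrix: PresenceAbsenceMatrix,
    loci: Sequence[PanLocus],
    reference_strain: str,
    reference_published_ids: Iterable[str],
    annotations: Mapping[str, "StrainAnnotation"] | None = None,
    external_proteomes: Mapping[str, Mapping[str, str]] | None = None,
    min_identity: float = 40.0,
) -> pd.DataFrame:
    """Partition loci missing from the published reference annotation.

    Each locus that exists in the collection but has no member in the
    externally supplied reference id set falls in exactly one class:

    * ``annotation_difference`` - this pipeline finds an intact
      reference gene the published annotation lacks;
    * ``reference_pseudogene`` - the reference copy is a pseudogene
      while at least one other strain carries an intact copy;
    * ``strain_specific_insertion`` - the reference has no copy at all.

    When external proteomes are given, loci whose best external identity
    exceeds their best cross-strain identity within the collection are
    flagged ``closest_homology_external``.
    """
    if reference_strain not in matrix.strains:
        raise ValueError(f"unknown reference strain {reference_strain!r}")
    published = set(reference_published_ids)
    by_pan = {l.pan_id: l for l in loci}
    rows = []
    for pid in matrix.pan_ids:
        l = by_pan[pid]
        ref_members = l.members.get(reference_strain, [])
        if any(m in published for m in ref_members):
            continue  # represented in the published annotation
        ref_status = l.status.get(reference_strain, "absent")
        others_intact = any(st == "intact" for s, st in l.status.items()
                            if s != reference_strain)
        if ref_status == "intact":
            cls = "annotation_difference"
        elif ref_status == "pseudogene" and others_intact:
            cls = "reference_pseudogene"
        elif ref_status == "pseudogene":
            cls = "reference_pseudogene"
        else:
            cls = "strain_specific_insertion"
        rows.append({"pan_id": pid, "class": cls,
                     "representative": l.representative})
    report = pd.DataFrame(rows, columns=["pan_id", "class", "representative"])

    if external_proteomes and annotations is not None and len(report):
        from .homology import align_pair
        rep_seqs = {}
        for r in report.itertuples():
            l = by_pan[r.pan_id]
            s = next(s for s, ms in l.members.items() if l.representative in ms)
            rep_seqs[r.pan_id] = (s, annotations[s].proteome[l.representative])
        ext_index = {name: ProteomeIndex(p) for name, p in external_proteomes.items()
                     if p}
        flags = []
        for r in report.itertuples():
            strain, seq = rep_seqs[r.pan_id]
            l = by_pan[r.pan_id]
            best_internal = 0.0
            for s, ms in l.members.items():
                if s == strain:
                    continue
                for m in ms:
                    hit = align_pair(seq, annotations[s].proteome[m])
                    best_internal = max(best_internal, hit.identity_percent)
            best_external = 0.0
            for name, idx in ext_index.items():
                tbl = best_hits({l.representative: seq}, idx,
                                min_identity=0.0, min_coverage=0.5)
                if len(tbl):
                    best_external = max(best_external, float(tbl.identity.max()))
            flags.append(best_external > best_internal)
        report["closest_homology_external"] = flags
    return report


def matrix_to_tsv(matrix: PresenceAbsenceMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="pan_id")


def rarefaction_to_tsv(curve: RarefactionCurve, path) -> None:
    curve.to_frame().to_csv(path, sep="\t", index=False)
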