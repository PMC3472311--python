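"""Matrix construction, rarefaction and inventories."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from panoen.orthology import PanLocus
from panoen.pangenome import (ABSENT, INTACT, PSEUDOGENE,
                              PresenceAbsenceMatrix, build_matrix,
                              group_specific_loci, non_reference_inventory,
                              rarefaction)

from oracles import brute_force_rarefaction


def random_matrix(rng, n_loci, n_strains):
    vals = rng.integers(0, 3, size=(n_loci, n_strains)).astype(np.int8)
    # no all-absent rows
    for i in range(n_loci):
        if (vals[i] == ABSENT).all():
            vals[i, int(rng.integers(n_strains))] = INTACT
    return PresenceAbsenceMatrix(vals, list(range(1, n_loci + 1)),
                                 [f"S{j:02d}" for j in range(n_strains)])


def test_two_strains_sharing_everything_is_all_intact():
    loci = [PanLocus(members={"A": [f"A_g{i}"], "B": [f"B_g{i}"]},
                     status={"A": "intact", "B": "intact"}, pan_id=i + 1)
            for i in range(4)]
    m = build_matrix(loci)
    assert (m.values == INTACT).all()
    assert m.core_size() == m.pan_size() == 4


def test_all_absent_row_rejected():
    with pytest.raises(ValueError, match="all-absent"):
        PresenceAbsenceMatrix(np.zeros((1, 2), dtype=np.int8), [1], ["A", "B"])


def test_matrix_equals_truth_status_map(small_sim, small_loci, small_matrix):
    tr = small_sim.truth
    fam_of_locus = {}
    for l in small_loci:
        fams = {tr.ortholog_map[m] for m in l.all_members()}
        assert len(fams) == 1
        fam_of_locus[l.pan_id] = fams.pop()
    code = {"absent": ABSENT, "pseudogene": PSEUDOGENE, "intact": INTACT}
    mismatches = 0
    seen_fams: dict[str, int] = {}
    for i, pid in enumerate(small_matrix.pan_ids):
        fam = fam_of_locus[pid]
        if fam in seen_fams:
            continue  # extra locus from a tandem copy; checked via first
        seen_fams[fam] = pid
        for j, s in enumerate(small_matrix.strains):
            if small_matrix.values[i, j] != code[tr.status(s, fam)]:
                mismatches += 1
    assert mismatches == 0


def test_chromosomal_flag_excludes_exactly_the_plasmid_loci(
        small_sim, small_loci):
    tr = small_sim.truth
    full = build_matrix(small_loci, small_sim.strains, chromosomal_only=False)
    chrom = build_matrix(small_loci, small_sim.strains, chromosomal_only=True)
    n_plasmid_fams = sum(1 for f in tr.families
                         if tr.family_replicon[f] == "plasmid")
    assert full.n_loci - chrom.n_loci == n_plasmid_fams


def test_rarefaction_all_intact_matrix_is_flat():
    vals = np.full((10, 4), INTACT, dtype=np.int8)
    m = PresenceAbsenceMatrix(vals, list(range(10)), list("ABCD"))
    curve = rarefaction(m)
    for x in curve.x:
        assert curve.mean_core[x] == 10.0
        assert curve.mean_pan[x] == 10.0
        assert curve.mode[x] == "exact"


def test_two_strain_hand_case():
    # locus A in both strains, locus B only in strain 1
    vals = np.array([[2, 2], [2, 0]], dtype=np.int8)
    m = PresenceAbsenceMatrix(vals, [1, 2], ["s1", "s2"])
    curve = rarefaction(m)
    assert curve.per_subset[2] == [(1, 2)]
    assert curve.per_subset[1] == [(2, 2), (1, 1)]


def test_exact_rarefaction_equals_brute_force_enumeration(rng):
    for _ in range(10):
        m = random_matrix(rng, 50, 8)
        curve = rarefaction(m)
        for x in curve.x:
            core_sum, pan_sum, count = brute_force_rarefaction(m.values, x)
            assert sum(c for c, _ in curve.per_subset[x]) == core_sum
            assert sum(p for _, p in curve.per_subset[x]) == pan_sum
            assert len(curve.per_subset[x]) == count


def test_pseudogene_counting_conventions_are_configurable(rng):
    vals = np.array([[1, 1], [2, 1]], dtype=np.int8)
    m = PresenceAbsenceMatrix(vals, [1, 2], ["a", "b"])
    strict = rarefaction(m)
    lenient = rarefaction(m, core_pseudogene_as_present=True,
                          pan_pseudogene_as_present=True)
    assert strict.per_subset[2] == [(0, 2)]
    assert lenient.per_subset[2] == [(2, 2)]


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_rarefaction_monotone_in_subset_size(seed):
    rng = np.random.default_rng(seed)
    m = random_matrix(rng, 30, 6)
    curve = rarefaction(m)
    for x in curve.x[1:]:
        assert curve.mean_core[x] <= curve.mean_core[x - 1] + 1e-12
        assert curve.mean_pan[x] >= curve.mean_pan[x - 1] - 1e-12
    # per-subset identity at x = 1 (when core and pan share one
    # pseudogene convention, as the identity presumes)
    same_conv = rarefaction(m, core_pseudogene_as_present=True,
                            pan_pseudogene_as_present=True)
    assert all(c == p for c, p in same_conv.per_subset[1])


def test_sampled_mode_agrees_with_exact_within_three_se(rng):
    m = random_matrix(rng, 60, 8)
    exact = rarefaction(m, exact_limit=10_000)
    sampled = rarefaction(m, exact_limit=1, n_samples=600, seed=4)
    for x in (3, 4, 5):
        assert sampled.mode[x] == "sampled"
        vals = [c for c, _ in exact.per_subset[x]]
        se = np.std(vals) / np.sqrt(600)
        assert abs(sampled.mean_core[x] - exact.mean_core[x]) <= 3 * se + 1e-9


def test_rarefaction_endpoints_match_matrix_totals(small_matrix):
    curve = rarefaction(small_matrix)
    S = len(small_matrix.strains)
    assert curve.mean_core[S] == small_matrix.core_size()
    assert curve.mean_pan[S] == small_matrix.pan_size()


def test_group_specific_loci_trivial_cases():
    vals = np.array([
        [2, 2, 2],   # core
        [2, 2, 0],   # private to A+B
        [2, 0, 0],   # private to A
        [2, 1, 0],   # pseudogene copy outside -> not strictly absent
    ], dtype=np.int8)
    m = PresenceAbsenceMatrix(vals, [1, 2, 3, 4], ["A", "B", "C"])
    assert group_specific_loci(m, ["A", "B", "C"]) == [1]
    assert group_specific_loci(m, ["A", "B"]) == [2]
    assert group_specific_loci(m, ["A"]) == [3]
    with pytest.raises(ValueError):
        group_specific_loci(m, [])


def test_group_specific_recovers_programmed_private_genes(
        small_sim, small_loci, small_matrix):
    tr = small_sim.truth
    fam_of_locus = {l.pan_id: tr.ortholog_map[l.all_members()[0]]
                    for l in small_loci}
    group = ["S00", "S04"]  # the HGT segment carriers
    got = {fam_of_locus[pid] for pid in group_specific_loci(small_matrix, group)}
    hgt_fams = {f for h in tr.hgt_truth for f in h.families}
    assert hgt_fams <= got


def _inventory_fixture():
    """10 annotation differences, 8 reference pseudogenes, 12 insertions."""
    loci = []
    published = []
    pid = 0
    strains = ("R", "X")
    for i in range(5):  # published, intact in reference
        pid += 1
        loci.append(PanLocus(pan_id=pid, members={"R": [f"R_p{pid}"],
                                                  "X": [f"X_p{pid}"]},
                             status={"R": "intact", "X": "intact"},
                             representative=f"R_p{pid}"))
        published.append(f"R_p{pid}")
    for i in range(10):  # intact in reference but missing from published ids
        pid += 1
        loci.append(PanLocus(pan_id=pid, members={"R": [f"R_a{pid}"],
                                                  "X": [f"X_a{pid}"]},
                             status={"R": "intact", "X": "intact"},
                             representative=f"R_a{pid}"))
    for i in range(8):  # pseudogene in reference, intact elsewhere
        pid += 1
        loci.append(PanLocus(pan_id=pid, members={"R": [f"R_b{pid}"],
                                                  "X": [f"X_b{pid}"]},
                             status={"R": "pseudogene", "X": "intact"},
                             representative=f"X_b{pid}"))
    for i in range(12):  # absent from the reference entirely
        pid += 1
        loci.append(PanLocus(pan_id=pid, members={"X": [f"X_c{pid}"]},
                             status={"R": "absent", "X": "intact"},
                             representative=f"X_c{pid}"))
    vals = np.zeros((pid, 2), dtype=np.int8)
    code = {"absent": ABSENT, "pseudogene": PSEUDOGENE, "intact": INTACT}
    for i, l in enumerate(loci):
        vals[i, 0] = code[l.status.get("R", "absent")]
        vals[i, 1] = code[l.status.get("X", "absent")]
    matrix = PresenceAbsenceMatrix(vals, [l.pan_id for l in loci],
                                   ["R", "X"])
    return loci, matrix, published


def test_inventory_partition_counts_match_construction():
    loci, matrix, published = _inventory_fixture()
    report = non_reference_inventory(matrix, loci, "R", published)
    counts = report["class"].value_counts().to_dict()
    assert counts == {"annotation_difference": 10,
                      "reference_pseudogene": 8,
                      "strain_specific_insertion": 12}


def test_inventory_classes_disjoint_and_exhaustive():
    loci, matrix, published = _inventory_fixture()
    report = non_reference_inventory(matrix, loci, "R", published)
    assert report.pan_id.is_unique
    published_loci = {l.pan_id for l in loci
                      if any(m in set(published)
                             for m in l.members.get("R", []))}
    assert set(report.pan_id) == set(matrix.pan_ids) - published_loci
    assert set(report["class"]) <= {"annotation_difference",
                                    "reference_pseudogene",
                                    "strain_specific_insertion"}


def test_inventory_annotation_difference_count_matches_sim_omissions(
        small_sim, small_loci, small_matrix):
    report = non_reference_inventory(
        small_matrix, small_loci, "S00",
        small_sim.truth.published_reference_ids)
    counts = report["class"].value_counts().to_dict()
    assert counts.get("annotation_difference", 0) == \
        small_sim.config.n_published_omitted
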