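"""HGT windows, prophage detection, cassettes, completeness, fusions."""

import numpy as np
import pytest

from panoen.orthology import PanLocus
from panoen.pangenome import PresenceAbsenceMatrix
from panoen.scans import (ScanParams, detect_fusions, detect_phage_elements,
                          genotype_cassette_locus, hgt_window_scan,
                          role_completeness)

from test_orthology import make_annotation, fam_protein


def _donor_scenario(rng, run_lengths, identity=1.0):
    """One strain whose genes at chosen runs are donor-derived.

    ``identity`` < 1 mutates the strain's copies away from the donor.
    """
    n = 40
    genes = []
    donor = {}
    flags = np.zeros(n, dtype=bool)
    pos = 0
    for start, length in run_lengths:
        flags[start:start + length] = True
    for i in range(n):
        aa = fam_protein(rng, 80)
        if flags[i]:
            donor[f"d{i}"] = aa
            copy = list(aa)
            k = int(round((1 - identity) * len(aa)))
            for p in rng.choice(len(aa), k, replace=False):
                cur = copy[p]
                copy[p] = next(c for c in "ACDEFGHIKLMNPQRSTVWY" if c != cur)
            genes.append((f"g{i:02d}", "".join(copy)))
        else:
            genes.append((f"g{i:02d}", aa))
    # donor also carries unrelated background genes
    for i in range(10):
        donor[f"bg{i}"] = fam_protein(rng, 80)
    return make_annotation("Q", genes), {"donorA": donor}


def test_no_donor_hits_means_all_zero_and_no_flags(rng):
    ann, _ = _donor_scenario(rng, [])
    donors = {"donorA": {f"x{i}": fam_protein(rng, 80) for i in range(10)}}
    table, regions = hgt_window_scan(ann, donors)
    assert (table.identity == 0).all()
    assert regions == []
    assert not table.flagged.any()


def test_run_of_five_flagged_run_of_four_not(rng):
    ann, donors = _donor_scenario(rng, [(5, 5), (20, 4)])
    table, regions = hgt_window_scan(ann, donors)
    assert len(regions) == 1
    assert (regions[0].first_index, regions[0].last_index) == (5, 9)
    flagged = set(table[table.flagged].order_index)
    assert flagged == {5, 6, 7, 8, 9}


def test_sixty_percent_identity_donor_is_not_flagged(rng):
    ann, donors = _donor_scenario(rng, [(5, 8)], identity=0.60)
    table, regions = hgt_window_scan(ann, donors)
    assert regions == []


def test_flagged_loci_each_pass_threshold_individually(rng):
    ann, donors = _donor_scenario(rng, [(3, 6)], identity=0.95)
    table, regions = hgt_window_scan(ann, donors)
    assert len(regions) == 1
    flagged = table[table.flagged]
    assert (flagged.identity >= 90.0).all()


def test_min_identity_100_on_mutated_donor_finds_nothing(rng):
    ann, donors = _donor_scenario(rng, [(3, 6)], identity=0.95)
    _t, regions = hgt_window_scan(
        ann, donors, ScanParams(min_identity=100.0))
    assert regions == []


def test_window_means_reported_over_ten_locus_windows(rng):
    ann, donors = _donor_scenario(rng, [(0, 10)])
    table, _ = hgt_window_scan(ann, donors)
    first = table[table.order_index == 0].window_mean.iloc[0]
    assert first == pytest.approx(100.0)
    # last window starting positions have means; trailing loci do not
    assert table[table.order_index == 39].window_mean.isna().all()


def test_empty_donor_set_rejected(rng):
    ann, _ = _donor_scenario(rng, [])
    with pytest.raises(ValueError):
        hgt_window_scan(ann, {})


def test_scan_params_validation():
    with pytest.raises(ValueError):
        ScanParams(window=3, min_run=5)
    with pytest.raises(ValueError):
        ScanParams(min_identity=0)


# ---------------------------------------------------------------------------
# phage


def test_genome_without_att_repeats_yields_no_elements(small_sim):
    ann = small_sim.strains["S00"]  # S00 has no phage insertion
    refs = small_sim.phage_role_refs
    assert detect_phage_elements(ann, refs) == []


def test_full_fragment_and_tandem_classification(small_sim):
    refs = small_sim.phage_role_refs
    truth = {(p.strain, p.trna_id): p for p in small_sim.truth.phage_truth}
    found = {}
    for s, ann in small_sim.strains.items():
        for el in detect_phage_elements(ann, refs):
            found[(el.strain, el.trna_id)] = el
    assert set(found) == set(truth)
    for key, p in truth.items():
        el = found[key]
        assert el.phage_class == p.phage_class
        assert el.copy_number == p.copy_number
        assert el.start == p.start and el.end == p.end


def test_missing_trna_warns_and_skips(small_sim):
    ann = small_sim.strains["S00"]
    with pytest.warns(UserWarning, match="absent"):
        els = detect_phage_elements(ann, small_sim.phage_role_refs,
                                    trna_ids=["nonexistent_trna"])
    assert els == []


def test_empty_role_refs_rejected(small_sim):
    with pytest.raises(ValueError):
        detect_phage_elements(small_sim.strains["S00"], {})


# ---------------------------------------------------------------------------
# cassettes


def _cassette_scenario(rng, contents):
    """Strains with anchors u,d and per-strain content in between."""
    fam_u, fam_d = fam_protein(rng), fam_protein(rng)
    all_mid = sorted({f for mids in contents.values() for f in mids})
    fams = {f: fam_protein(rng) for f in all_mid}
    anns = {}
    loci_members = {"u": {}, "d": {}}
    mid_members = {f: {} for f in all_mid}
    for s, mids in contents.items():
        genes = [(f"{s}_u", fam_u)]
        genes += [(f"{s}_{f}", fams[f]) for f in mids]
        genes += [(f"{s}_d", fam_d)]
        anns[s] = make_annotation(s, genes)
        loci_members["u"][s] = [f"{s}_u"]
        loci_members["d"][s] = [f"{s}_d"]
        for f in mids:
            mid_members[f][s] = [f"{s}_{f}"]
    loci = [PanLocus(pan_id=1, members=loci_members["u"],
                     status={s: "intact" for s in contents}),
            PanLocus(pan_id=2, members=loci_members["d"],
                     status={s: "intact" for s in contents})]
    for i, f in enumerate(all_mid):
        loci.append(PanLocus(pan_id=3 + i, members=mid_members[f]))
    return anns, loci


def test_identical_content_is_one_variant(rng):
    anns, loci = _cassette_scenario(
        rng, {s: ["m1", "m2"] for s in ("A", "B", "C")})
    geno = genotype_cassette_locus(loci, anns, (1, 2))
    assert geno.n_variants() == 1
    assert set(geno.variant_of.values()) == {"V1"}


def test_variants_partition_strains_and_order_by_frequency(rng):
    anns, loci = _cassette_scenario(
        rng, {"A": ["m1"], "B": ["m1"], "C": ["m2", "m3"], "D": []})
    geno = genotype_cassette_locus(loci, anns, (1, 2))
    assert geno.n_variants() == 3
    assert geno.variant_of["A"] == geno.variant_of["B"] == "V1"
    assert len({geno.variant_of["C"], geno.variant_of["D"]}) == 2
    assert sorted(geno.variant_of) == ["A", "B", "C", "D"]


def test_strain_missing_anchor_is_unresolved(rng):
    anns, loci = _cassette_scenario(rng, {"A": ["m1"], "B": ["m1"]})
    loci[0].members["B"] = []  # anchor lost in B
    geno = genotype_cassette_locus(loci, anns, (1, 2))
    assert geno.variant_of["B"] == "unresolved"
    assert geno.variant_of["A"] == "V1"


def test_inverted_cassette_normalises_to_same_variant(rng):
    fam_u, fam_d = fam_protein(rng), fam_protein(rng)
    fm1, fm2 = fam_protein(rng), fam_protein(rng)
    anns = {
        "A": make_annotation("A", [("A_u", fam_u), ("A_m1", fm1),
                                   ("A_m2", fm2), ("A_d", fam_d)]),
        # B carries the whole region inverted: d, m2, m1, u
        "B": make_annotation("B", [("B_d", fam_d), ("B_m2", fm2),
                                   ("B_m1", fm1), ("B_u", fam_u)]),
    }
    loci = [
        PanLocus(pan_id=1, members={"A": ["A_u"], "B": ["B_u"]}),
        PanLocus(pan_id=2, members={"A": ["A_d"], "B": ["B_d"]}),
        PanLocus(pan_id=3, members={"A": ["A_m1"], "B": ["B_m1"]}),
        PanLocus(pan_id=4, members={"A": ["A_m2"], "B": ["B_m2"]}),
    ]
    geno = genotype_cassette_locus(loci, anns, (1, 2))
    assert geno.variant_of["A"] == geno.variant_of["B"]
    assert geno.inverted == {"A": False, "B": True}


# ---------------------------------------------------------------------------
# completeness


def _completeness_matrix():
    # rows: E1, E2, E3(locus a), E3(locus b)
    vals = np.array([
        [2, 2, 2],
        [2, 1, 2],
        [2, 2, 0],
        [2, 0, 1],
    ], dtype=np.int8)
    m = PresenceAbsenceMatrix(vals, [1, 2, 3, 4], ["A", "B", "C"])
    role_map = {1: "E1", 2: "E2", 3: "E3", 4: "E3"}
    return m, role_map


def test_pathway_complete_when_every_role_intact_somewhere():
    m, role_map = _completeness_matrix()
    rep = role_completeness(m, role_map, ["E1", "E2", "E3"])
    by_strain = rep.set_index("strain")
    assert bool(by_strain.loc["A", "complete"]) is True
    assert bool(by_strain.loc["B", "complete"]) is False
    assert by_strain.loc["B", "blocking"] == "E2:pseudogenization"
    # strain C: E3 absent at one locus, pseudogene at the other
    assert by_strain.loc["C", "blocking"] == "E3:pseudogenization"


def test_role_present_only_as_pseudogene_blocks_every_strain():
    vals = np.array([[1, 1, 1]], dtype=np.int8)
    m = PresenceAbsenceMatrix(vals, [1], ["A", "B", "C"])
    rep = role_completeness(m, {1: "E1"}, ["E1"])
    assert not rep.complete.any()
    assert (rep.blocking == "E1:pseudogenization").all()


def test_unknown_required_role_is_a_configuration_error():
    m, role_map = _completeness_matrix()
    with pytest.raises(ValueError, match="not present"):
        role_completeness(m, role_map, ["E9"])


def test_pathway_block_recovered_from_simulation(small_sim, small_loci,
                                                 small_matrix):
    tr = small_sim.truth
    fam_of_locus = {l.pan_id: tr.ortholog_map[l.all_members()[0]]
                    for l in small_loci}
    role_map = {pid: tr.role_map[f] for pid, f in fam_of_locus.items()
                if f in tr.role_map}
    path_roles = sorted(r for r in set(role_map.values())
                        if r.startswith("path1"))
    rep = role_completeness(small_matrix, role_map, path_roles)
    fam_of_role = {v: k for k, v in tr.role_map.items()}
    for r in rep.itertuples():
        expect = all(tr.status(r.strain, fam_of_role[role]) == "intact"
                     for role in path_roles)
        assert bool(r.complete) == expect, r.strain


# ---------------------------------------------------------------------------
# fusions


def test_concatenated_representatives_flagged_with_breakpoint(rng):
    fa = fam_protein(rng, 120)
    fb = fam_protein(rng, 140)
    reps = {"famA": fa, "famB": fb, "famC": fam_protein(rng, 100)}
    fusion = fa + fb
    out = detect_fusions({"orf1": fusion}, reps)
    assert len(out) == 1
    row = out.iloc[0]
    assert {row.family_n, row.family_c} == {"famA", "famB"}
    true_junction = len(fa)
    assert abs(row.breakpoint - true_junction) <= 0.1 * len(fusion)


def test_full_length_single_family_protein_not_flagged(rng):
    fa = fam_protein(rng, 120)
    reps = {"famA": fa, "famB": fam_protein(rng, 90)}
    assert len(detect_fusions({"orf1": fa}, reps)) == 0


def test_two_hits_to_same_family_not_flagged(rng):
    fa = fam_protein(rng, 100)
    reps = {"famA": fa, "famB": fam_protein(rng, 90)}
    doubled = fa + fa
    out = detect_fusions({"orf1": doubled}, reps)
    assert len(out) == 0


def test_fusion_needs_at_least_two_families(rng):
    with pytest.raises(ValueError):
        detect_fusions({"o": "MKL"}, {"famA": "MKL"})
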