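"""Clustering, synteny refinement, numbering and status classification."""

import numpy as np
import pytest

from panoen.io import GeneFeature, Replicon, StrainAnnotation
from panoen.orthology import (PanLocus, SyntenyContext, assign_pan_numbers,
                              classify_member_status, cluster_rbh,
                              is_conflicted, refine_with_synteny,
                              _merge_split_fragments, _neighbor_profile,
                              _pairwise_agreement, _refine_component)

from oracles import brute_force_conflict_partition


def make_annotation(strain: str, genes: list[tuple[str, str]],
                    strand: str = "+") -> StrainAnnotation:
    """Fake annotation: genes in the given order, 100 aa / 1 kb apart."""
    feats = []
    pos = 0
    proteome = {}
    for gid, aa in genes:
        feats.append(GeneFeature(
            id=gid, replicon=f"{strain}_chr", start=pos, end=pos + 3 * len(aa),
            strand=strand, kind="CDS"))
        proteome[gid] = aa
        pos += 3 * len(aa) + 200
    ann = StrainAnnotation(
        strain_id=strain,
        replicons=[Replicon(f"{strain}_chr", pos + 10)],
        features=feats,
        sequences={f"{strain}_chr": "A" * (pos + 10)})
    ann.proteome = proteome
    return ann


def fam_protein(rng, n=60):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), n))


def test_perfect_rbh_triangle_gives_one_cluster_per_gene(rng):
    prots = {f"f{i}": fam_protein(rng) for i in range(5)}
    anns = {s: make_annotation(s, [(f"{s}_g{i}", prots[f"f{i}"])
                                   for i in range(5)])
            for s in ("A", "B", "C")}
    rbh = {
        (a, b): {(f"{a}_g{i}", f"{b}_g{i}") for i in range(5)}
        for a, b in (("A", "B"), ("A", "C"), ("B", "C"))
    }
    comps = cluster_rbh(rbh, anns)
    sizes = sorted(len(c) for c in comps)
    assert sizes == [3] * 5
    strain_of = {f.id: s for s, ann in anns.items() for f in ann.cds}
    assert not any(is_conflicted(c, strain_of) for c in comps)


def test_within_strain_duplicate_marks_component_conflicted():
    strain_of = {"A_g1": "A", "A_g2": "A", "B_g1": "B"}
    assert is_conflicted(["A_g1", "A_g2", "B_g1"], strain_of)
    assert not is_conflicted(["A_g1", "B_g1"], strain_of)


def _duplicate_scenario(rng):
    """Strains A,B,C carry families n1-5, g, m1-5 (+ x/y in D); D carries a
    translocated duplicate d2 of g with zero shared neighbours."""
    fams = {f: fam_protein(rng) for f in
            [f"n{i}" for i in range(5)] + ["g"] + [f"m{i}" for i in range(5)]
            + [f"x{i}" for i in range(5)] + [f"y{i}" for i in range(5)]}
    order_abc = [f"n{i}" for i in range(5)] + ["g"] + [f"m{i}" for i in range(5)]
    anns = {}
    for s in ("A", "B", "C"):
        anns[s] = make_annotation(s, [(f"{s}_{f}", fams[f]) for f in order_abc])
    order_d = order_abc + [f"x{i}" for i in range(5)] + ["g2"] + \
        [f"y{i}" for i in range(5)]
    anns["D"] = make_annotation(
        "D", [(f"D_{f}", fams[f if f != "g2" else "g"]) for f in order_d])
    components = []
    for f in order_abc:
        if f == "g":
            continue
        components.append(sorted(f"{s}_{f}" for s in "ABCD"))
    for f in [f"x{i}" for i in range(5)] + [f"y{i}" for i in range(5)]:
        components.append([f"D_{f}"])
    conflicted = sorted(["A_g", "B_g", "C_g", "D_g", "D_g2"])
    components.append(conflicted)
    return anns, components, conflicted


def test_translocated_duplicate_founds_its_own_locus(rng):
    anns, components, conflicted = _duplicate_scenario(rng)
    ctx = SyntenyContext(anns)
    loci = refine_with_synteny(components, ctx)
    containing = [l for l in loci if "D_g2" in l.all_members()]
    assert len(containing) == 1
    assert containing[0].all_members() == ["D_g2"]
    main = next(l for l in loci if "A_g" in l.all_members())
    assert sorted(main.all_members()) == ["A_g", "B_g", "C_g", "D_g"]


def test_refinement_leaves_unconflicted_components_untouched(rng):
    prots = {f"f{i}": fam_protein(rng) for i in range(4)}
    anns = {s: make_annotation(s, [(f"{s}_g{i}", prots[f"f{i}"])
                                   for i in range(4)])
            for s in ("A", "B")}
    components = [sorted([f"A_g{i}", f"B_g{i}"]) for i in range(4)]
    ctx = SyntenyContext(anns)
    loci = refine_with_synteny(components, ctx)
    got = sorted(tuple(sorted(l.all_members())) for l in loci)
    assert got == sorted(tuple(c) for c in components)


def test_each_strain_contributes_at_most_one_unit_after_refinement(small_loci):
    for l in small_loci:
        for s, ms in l.members.items():
            assert len(ms) <= 1  # no split genes simulated at default settings


def test_exact_refinement_matches_exhaustive_partition_search(rng):
    """Production conflict resolution reaches the brute-force optimum."""
    for trial in range(12):
        n_strains = int(rng.integers(3, 6))
        strains = [chr(65 + i) for i in range(n_strains)]
        shared = [f"s{i}" for i in range(8)]
        fams = {f: fam_protein(rng, 40) for f in shared + ["g"]}
        anns = {}
        for si, s in enumerate(strains):
            order = shared[:4] + ["g"] + shared[4:]
            if si == 0:
                # duplicate with a randomly shuffled context
                insert_at = int(rng.integers(0, 8))
                order = order[:insert_at] + ["g2"] + order[insert_at:]
            anns[s] = make_annotation(
                s, [(f"{s}_{f}", fams[f if f != "g2" else "g"]) for f in order])
        components = [sorted(f"{s}_{f}" for s in strains) for f in shared]
        conflicted = sorted([f"{s}_g" for s in strains] + [f"{strains[0]}_g2"])
        components.append(conflicted)
        ctx = SyntenyContext(anns)
        comp_of = {m: ci for ci, c in enumerate(components) for m in c}
        units = _merge_split_fragments(conflicted, ctx)
        units.sort(key=lambda u: (ctx.strain_of[u[0]], ctx.position[u[0]]))
        profiles = [set().union(*(_neighbor_profile(m, ctx, comp_of)
                                  for m in u)) for u in units]
        agree = _pairwise_agreement(profiles)
        unit_strains = [ctx.strain_of[u[0]] for u in units]
        best_score, _groups = brute_force_conflict_partition(
            unit_strains, agree)
        got = _refine_component(conflicted, ctx, comp_of)
        member_to_unit = {m: ui for ui, u in enumerate(units) for m in u}
        score = 0
        for part in got:
            us = sorted({member_to_unit[m] for m in part})
            for i, a in enumerate(us):
                for b in us[i + 1:]:
                    score += agree[a][b]
        assert score == best_score


def test_internal_stop_member_is_pseudogene(rng):
    aa = fam_protein(rng)
    broken = aa[:20] + "*" + aa[21:]
    locus = PanLocus(members={"A": ["A_g"], "B": ["B_g"]})
    anns = {"A": make_annotation("A", [("A_g", aa)]),
            "B": make_annotation("B", [("B_g", broken)])}
    status = classify_member_status(locus, anns)
    assert status == {"A": "intact", "B": "pseudogene"}
    assert locus.representative == "A_g"


def test_equal_length_members_without_stops_all_intact(rng):
    aa = fam_protein(rng)
    locus = PanLocus(members={s: [f"{s}_g"] for s in "ABC"})
    anns = {s: make_annotation(s, [(f"{s}_g", aa)]) for s in "ABC"}
    status = classify_member_status(locus, anns)
    assert set(status.values()) == {"intact"}


def test_truncated_member_is_pseudogene(rng):
    aa = fam_protein(rng, 100)
    locus = PanLocus(members={"A": ["A_g"], "B": ["B_g"], "C": ["C_g"]})
    anns = {"A": make_annotation("A", [("A_g", aa)]),
            "B": make_annotation("B", [("B_g", aa)]),
            "C": make_annotation("C", [("C_g", aa[:50])])}
    status = classify_member_status(locus, anns)
    assert status["C"] == "pseudogene"
    assert status["A"] == status["B"] == "intact"


def test_split_fragments_share_one_pseudogene_status(rng):
    aa = fam_protein(rng, 100)
    locus = PanLocus(members={"A": ["A_g"], "B": ["B_g1", "B_g2"]})
    anns = {"A": make_annotation("A", [("A_g", aa)]),
            "B": make_annotation("B", [("B_g1", aa[:40]), ("B_g2", aa[40:])])}
    status = classify_member_status(locus, anns)
    assert status == {"A": "intact", "B": "pseudogene"}


def test_reference_loci_numbered_by_reference_order(rng):
    prots = {f"f{i}": fam_protein(rng) for i in range(5)}
    anns = {s: make_annotation(s, [(f"{s}_g{i}", prots[f"f{i}"])
                                   for i in range(5)])
            for s in ("A", "B")}
    loci = [PanLocus(members={"A": [f"A_g{i}"], "B": [f"B_g{i}"]})
            for i in (3, 1, 4, 0, 2)]
    numbered = assign_pan_numbers(loci, anns, "A")
    by_member = {l.members["A"][0]: l.pan_id for l in numbered}
    assert by_member == {f"A_g{i}": i + 1 for i in range(5)}


def test_non_reference_locus_interleaved_between_flanking_loci(rng):
    prots = {f"f{i}": fam_protein(rng) for i in range(4)}
    extra = fam_protein(rng)
    anns = {
        "A": make_annotation("A", [(f"A_g{i}", prots[f"f{i}"])
                                   for i in range(4)]),
        "B": make_annotation("B", [("B_g0", prots["f0"]),
                                   ("B_g1", prots["f1"]),
                                   ("B_extra", extra),
                                   ("B_g2", prots["f2"]),
                                   ("B_g3", prots["f3"])]),
    }
    loci = [PanLocus(members={"A": [f"A_g{i}"], "B": [f"B_g{i}"]})
            for i in range(4)]
    loci.append(PanLocus(members={"B": ["B_extra"]}))
    numbered = assign_pan_numbers(loci, anns, "A")
    order = [l.key() for l in numbered]
    assert order.index("B_extra") == order.index("A_g1") + 1
    assert [l.pan_id for l in numbered] == list(range(1, 6))


def test_numbering_is_idempotent(small_sim, small_loci):
    first = {l.key(): l.pan_id for l in small_loci}
    again = assign_pan_numbers(small_loci, small_sim.strains, "S00")
    second = {l.key(): l.pan_id for l in again}
    assert first == second


def test_unknown_reference_strain_rejected(small_sim, small_loci):
    with pytest.raises(ValueError, match="unknown reference"):
        assign_pan_numbers(small_loci, small_sim.strains, "nope")
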