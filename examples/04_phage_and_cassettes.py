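"""Prophage detection at tRNA attachment sites and cassette genotyping.

Temperate phages integrate at tRNA genes, duplicating the tRNA 3' end
as direct repeats (attL/attR) around the element.  The detector walks
downstream of each tRNA for those repeats and classifies the element
by gene content: integrase + endolysin = full element, integrase only
= fragment.  Cassette loci are genotyped by the ordered ortholog
content between two conserved anchor genes.
"""

from panoen import (SimConfig, build_pan_loci, detect_phage_elements,
                    genotype_cassette_locus, simulate_collection)
from panoen.config import CassetteLocusConfig, PhageInsertConfig

config = SimConfig(
    n_strains=6, n_core_genes=150, accessory_pool_size=10,
    cassette_loci=(CassetteLocusConfig(40, 3, 4),),
    phage_configs=(PhageInsertConfig(0, (1, 4), "full"),
                   PhageInsertConfig(1, (2,), "full", copy_number=2),
                   PhageInsertConfig(2, (3,), "fragment")),
    hgt_segments=(), n_trna_sites=4, plasmid_strains=(),
    pseudogene_rate=0.0, seed=47)
out = simulate_collection(config)

print("prophage elements found:")
for strain in sorted(out.strains):
    for el in detect_phage_elements(out.strains[strain], out.phage_role_refs):
        print(f"  {el.strain} at {el.trna_id}: {el.phage_class:8s} "
              f"x{el.copy_number}  span {el.end - el.start:,} bp  "
              f"roles={','.join(el.roles_found)}")

loci = build_pan_loci(out.strains, min_shared_kmers=8)
truth = out.truth
locus_of_fam = {truth.ortholog_map[l.all_members()[0]]: l.pan_id for l in loci}
up, down = truth.cassette_anchors[0]
geno = genotype_cassette_locus(loci, out.strains,
                               (locus_of_fam[up], locus_of_fam[down]))
print(f"\ncassette locus between pan loci {geno.anchors}: "
      f"{geno.n_variants()} variants")
for strain in sorted(geno.variant_of):
    print(f"  {strain}: {geno.variant_of[strain]}")
# The x2 element is a tandem duplication: one merged span, two copies.
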