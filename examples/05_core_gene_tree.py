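"""Distance-based phylogeny from concatenated single-copy core genes.

Selects loci intact and single-copy in every strain (with an outgroup
identity filter and a paralog guard), concatenates their protein
alignments, and builds a neighbour-joining tree with column-bootstrap
support — recovering the simulated strain tree including its deep
basal pair.
"""

import dendropy

from panoen import (PhyloFilterParams, SimConfig, build_matrix,
                    build_pan_loci, build_core_tree, simulate_collection)

config = SimConfig(
    n_strains=8, n_core_genes=250, accessory_pool_size=30,
    cassette_loci=(), phage_configs=(), hgt_segments=(),
    n_trna_sites=2, plasmid_strains=(), seed=5)
out = simulate_collection(config)

loci = build_pan_loci(out.strains, min_shared_kmers=8)
matrix = build_matrix(loci, out.strains, chromosomal_only=True)
tree, aln, selected = build_core_tree(
    loci, matrix, out.strains, out.outgroup_proteome, PhyloFilterParams(),
    n_bootstrap=100, seed=5, min_shared_kmers=8)

print(f"phylogeny loci (intact, single-copy, outgroup >=60% identity): "
      f"{len(selected)} of {matrix.n_loci}")
print(f"concatenated alignment: {len(aln.taxa)} taxa x {aln.width:,} aa")
print("\nNJ tree with bootstrap support:")
print(tree.newick())

tns = dendropy.TaxonNamespace()
t1 = dendropy.Tree.get(data=tree.newick(), schema="newick",
                       taxon_namespace=tns)
t2 = dendropy.Tree.get(data=out.truth.strain_tree_newick, schema="newick",
                       taxon_namespace=tns)
rf = dendropy.calculate.treecompare.unweighted_robinson_foulds_distance(t1, t2)
print(f"\nRobinson-Foulds distance to the generating tree: {int(rf)}")
# S06/S07 form the deep basal clade; its bipartition should carry
# support 1.00 from 100 bootstrap replicates.
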