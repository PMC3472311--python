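"""Simulate a small strain collection and inspect its ground truth.

Builds six ~0.35 Mb genomes sharing 300 core genes, with accessory
genes, a cassette locus, prophage insertions, a donor-derived segment
and two plasmids, then prints what each strain carries.  The same
generator at its defaults produces the 14-strain, ~1.8 Mb study
conditions.
"""

from panoen import (CassetteLocusConfig, HgtSegmentConfig, PhageInsertConfig,
                    SimConfig, simulate_collection)

config = SimConfig(
    n_strains=6, n_core_genes=300, accessory_pool_size=60,
    cassette_loci=(CassetteLocusConfig(100, 3, 4),),
    phage_configs=(PhageInsertConfig(0, (1,), "full"),
                   PhageInsertConfig(2, (3,), "full", copy_number=2)),
    hgt_segments=(HgtSegmentConfig("donorA", 5, (0, 4), 95.0),),
    n_trna_sites=4, plasmid_strains=(1, 3), seed=7)

out = simulate_collection(config)
truth = out.truth

print("strain  CDS  intact  pseudo  genome_bp  plasmid")
for strain, ann in out.strains.items():
    intact = truth.intact_count(strain)
    pseudo = sum(1 for (s, f), v in truth.status_map.items()
                 if s == strain and v == "pseudogene")
    plasmid = "yes" if len(ann.replicons) > 1 else "-"
    print(f"{strain}   {len(ann.cds):4d}   {intact:4d}   {pseudo:4d}  "
          f"{ann.replicons[0].length:9,d}  {plasmid}")

print(f"\ntruth families: {len(truth.families)} "
      f"(chromosomal pan genome of the simulated species)")
print(f"phage insertions: {len(truth.phage_truth)}, "
      f"donor-derived segments: {len(truth.hgt_truth)}")
print("strain tree:", truth.strain_tree_newick[:70], "...")
# Each strain carries ~340 genes: the 300-gene core minus nothing, plus
# its private accessory draw, cassette variant and mobile elements.
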