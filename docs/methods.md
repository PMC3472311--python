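# Methods

This note records the models, parameter choices and numerical
conventions behind `panoen`, and what the simulation-based validation
does and does not establish about real data.

## The simulator

`simulate_collection` is a forward simulator for a clonal bacterial
species observed through a small strain collection. Its default
configuration describes the study conditions all genome-scale tests
run under: 14 strains, 1650 single-copy core families of 150–350
codons (uniform), intergenic spacers of 50–400 bp, six tRNA sites, an
accessory pool of 420 families each carried by 1 + Binomial(13, 0.45)
strains, three cassette loci with 7/3/3 variants of 6/5/5 genes,
three donor-derived segments (8, 5 and 4 genes at 95% amino-acid
identity to the donor), 20 ancient paralog duplicates at 35% amino-acid
divergence, five strain-private tandem duplicates at 3%, thirteen
prophage insertions (full and fragment, one tandemly duplicated)
across the six tRNA sites, one small plasmid in four strains, and a
per-gene, per-strain pseudogenisation probability of 0.05. Those
numbers were chosen once so that the realised collection matches the
scale of published *O. oeni* comparisons — 1800 ± 52 intact ORFs and
roughly a hundred pseudogenes per ~1.8 Mb chromosome — with accessory
sharing set for testability because no empirical sharing distribution
is available.

**Evolution model.** Strains descend from a Kingman coalescent over the
first n−2 strains (root-to-tip depth = `substitution_rate_per_branch`,
default 0.01 substitutions/site, minimum internal branch 10⁻⁴) joined
at the root by a two-strain cherry at depth `basal_pair_depth`
(default 0.02) — the deep basal pair seen in real strain phylogenies.
Branches accumulate uniform random nucleotide substitutions; there are
no indels inside genes, substitutions never touch a start codon and
never create an in-frame stop, so frames are stable and pseudogenes
arise *only* from the explicit premature-stop events recorded in the
truth. Donor imports, phage elements and plasmid content are recent
acquisitions and are emitted identically across carriers rather than
evolved.

**Detectability contracts.** Two constructions are deliberate
idealisations: phage elements are flanked by *exact* 20-bp direct
repeats of the tRNA 3′ end (with internal repeats for tandem copies),
and every spacer begins and ends with `TTAATTAATTAA`, a 12-mer that
contains stop codons in all six frames and no start codons, which
makes naive ORF calls land exactly on the annotated coordinates.

**What passing tests do not show.** The simulator uses uniform codon
usage, no recombination within genes, no assembly gaps or
contamination, no gene-boundary annotation errors, and divergence well
inside the aligner's comfortable range. Truth-recovery rates measured
here are therefore upper bounds on real-data performance; they
validate the *logic* of each stage (thresholds, run rules, tie-breaks,
bookkeeping), not robustness to annotation noise.

## Alignment

All homology scores come from one deterministic aligner: semi-global
(free end gaps) dynamic programming under BLOSUM62 with affine gap
cost 11 + k. Among co-optimal alignments it maximises score, then the
number of identical columns, then minimises aligned columns, so
identity (= matches / aligned columns, terminal gaps excluded) and
coverage (aligned span / length) are well-defined quantities. A
shared-5-mer prefilter (≥2 distinct shared 5-mers by default) skips
hopeless pairs and never alters a computed score. Genome-scale
pipeline runs raise the prefilter to 8 shared 5-mers
(`AnalysisParams.min_shared_kmers`): true orthologs at ≤5% divergence
share ~190 distinct 5-mers, so the stronger filter only removes noise
pairs, which was verified against the weaker setting on a small
collection before adoption.

## Orthology and synteny refinement

RBH uses integer scores, so ties are real (identical duplicates): a
query's top hit breaks ties by rank agreement (the candidate whose own
ranking places the query highest) and then lexicographic id, making
the relation symmetric. Conflicted RBH components are partitioned to
≤1 member per strain, maximising total pairwise neighbour agreement
over a ±5-gene window (order- and strand-insensitive); a member joins
a locus only at agreement ≥2, otherwise it founds a new locus —
splitting is preferred to merging so chimeric loci cannot inflate the
core. Components of ≤12 units are solved exactly by enumeration
(verified against an independent brute-force partition search in the
tests); larger ones use greedy assignment plus reassignment sweeps.
Same-strain adjacent co-oriented fragments shorter than 0.8× the
median member length are pre-merged as one split-gene unit that counts
once and carries pseudogene status. Identical tandem copies have no
cross-strain RBH partner, so each extra copy founds its own locus;
tandemly duplicated phage elements therefore add their gene count to
the pan total relative to the truth family count (≈0.4% at default
scale).

Pan numbering follows the reference strain's gene order; loci with no
reference member are interleaved after the anchor the majority of
carriers place them behind, ties toward the earlier anchor.

## Statistics conventions

The presence/absence matrix is tri-state (absent / pseudogene /
intact). The headline counts are chromosomal (plasmid-only loci
excluded). Because published species comparisons separate "full
length" from "potential pseudogene" ORFs without fixing a rarefaction
convention, both conventions are exposed: default core = intact in
every subset strain (pseudogene counts as absent), default pan =
present in any form. With mixed conventions core < pan already at
x = 1; with a single convention core = pan at x = 1, which is the form
the monotonicity tests use. Rarefaction enumerates all C(S, x) subsets
whenever C(S, x) ≤ 10 000 — always true at S = 14, whose largest level
is C(14,7) = 3432 — and otherwise samples a configurable number of
subsets with a seeded generator.

## Screens

The HGT flag rule is conjunctive — ≥5 *consecutive* genes each ≥90%
best-donor identity — not window-mean based; the 10-gene window mean is
computed for plotting only. "More than five" printed in figure legends
is resolved as ≥5, matching the accompanying data tables, and is a
parameter. Phage element boundaries come from the att repeats, not
from gene content; classification needs ≥40% identity to integrase or
endolysin references, with full = int + lys and fragment = int only
(whether a "full, presumably functional" element needs more than those
two genes is undecidable from printed criteria; int + lys is used).
Spurious repeat matches are vanishingly rare (~10⁻⁴ per 60 kb window),
and copies whose span contains no phage-role genes terminate the
element. Fusion ORFs are flagged when no single family covers ≥80% of
the ORF but two different families cover ≥30% each with ≤10% overlap;
the breakpoint estimate is the midpoint of the inter-hit gap.

## Phylogeny

Maximum-likelihood inference is deliberately replaced by
neighbour-joining on p-distances of the concatenated single-copy core
protein alignment: deterministic, seconds at 14 taxa, exact on
additive matrices (tested against random additive trees and an
independent NJ implementation), and sufficient for topology-level
claims. Q-criterion ties break to the lexicographically smallest
cluster-label pair. The orthoMCL-style paralog filter is approximated
by a within-proteome guard: a locus is dropped if any member has
another gene in its own proteome scoring ≥70% of the member's
self-alignment score. Bootstrap resamples alignment columns via a
multinomial weight vector (seeded); support is the fraction of 100
replicates containing each bipartition. Family alignment is
center-star seeded from the longest member; substitution-only families
(the simulator's regime) stack without gaps by construction.

## Pipeline and determinism

The single run seed fans out per stage as
`sha256("{seed}:{stage}") mod 2³¹`, so stages rerun in isolation
reproduce their outputs; all TSV/newick/JSON outputs are byte-stable
across reruns (no timestamps). Problem sizes used by the test suite
and acceptance script: the full 14-strain default for orthology,
pseudogene and tree checks; 4–8 strain collections with 150–250 core
genes for the HGT, phage, cassette and determinism checks, which
exercise the identical code paths at smaller n.

## Known limitations

Identity thresholds (40% hit, 90% HGT, 60% outgroup) are declared
defaults, not estimates; the aligner is exact but O(len²) per pair, so
collections far beyond ~20 strains × 2000 genes would need a faster
search stage; `non_reference_inventory` trusts the supplied published
id set; and the split-gene rule assumes fragments stay adjacent and
co-oriented, which real rearrangements can violate.
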