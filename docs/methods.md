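# Methods

This note records the models, parameter choices and known limitations of
the nlrforge pipeline, in the order the method runs.

## Profile HMMs and E-values

The search instrument is a plan-7-style profile HMM: M match states with
position-specific emissions, insert states fixed to the background
distribution (so inserts score 0 bits), and per-node {M,I,D} transitions.
Models are estimated from seed alignments with a 0.5 gap-fraction rule for
match columns and Laplace (+1) pseudocounts on emissions and transitions;
the rare I→D / D→I steps implied by an alignment are skipped, as they have
no plan-7 edge. Search is local on both axes: flanking residues are
absorbed at zero log-odds, the model may be entered at any match state (a
−log₂M bit charge, i.e. uniform entry) and left from any match state for
free. Scores are log₂-odds in bits against Robinson–Robinson background
frequencies.

E-values are calibrated per model rather than delegated to an external
tool: Viterbi scores of `n_null = 1000` i.i.d. background sequences of
length 350 are fitted with a maximum-likelihood Gumbel law
(`scipy.stats.gumbel_r`), and E = N·P(S ≥ s) for a database of N proteins.
The empirical tail of an independent null sample reproduces the fitted
tail within a factor ~2 at P = 0.01 (tested). The two search cutoffs are
the classic funnel values: strict E < 10⁻⁶⁰ to select the high-confidence
set that seeds the species-specific model, relaxed E < 10⁻² for the final
candidate screen. Planted intact NLR domains score far into the strict
regime (hundreds of bits), so the funnel semantics carry over to the
synthetic data unchanged.

Two exclusion steps follow the relaxed screen. The kinase filter removes a
candidate iff its bit score against a protein-kinase profile exceeds its
NBS score — the automated version of discarding the P-loop-sharing kinase
family. Additionally a candidate must show at least two of the four
ordered NBS subdomain motifs (`min_nbs_subdomains = 2`); this is the
automated counterpart of manually curating marginal E-value hits, and on
the packaged data it separates cleanly (planted genes, including
terminally truncated pseudogenes, retain ≥ 2 motifs; background proteins
show ≤ 1).

## Domain architecture

TIR and LRR are PSSM window scans (log₂-odds vs background, Laplace
pseudocounts); a matrix's acceptance threshold is 0.5 of its consensus
score, which on the packaged families sits several standard deviations
above background windows. Hits are made non-overlapping greedily by score.

The coiled-coil scan is a Lupas-style sliding window (28 residues, best of
the seven heptad phases) over a two-class propensity table (hydrophobic
core positions a/d vs outer positions), mapped to a probability by a
logistic with midpoint 18 and scale 3 chosen so an ideal four-heptad
window maps to ≈ 1 and background to ≈ 0. Full coiled-coil HMMs and
pairwise-correlation methods are deliberately not re-implemented; their
two published working points map onto one probability threshold (detect at
0.9) plus a stricter validation margin (flag at 1 − 0.025 = 0.975), which
preserves the decision-boundary semantics at desk scale.

The four NBS motifs are selected as the maximum-total-score subset
consistent with the canonical order P-loop < kinase-2 < kinase-3a < GLPL
(exhaustive over ≤ 3 candidates per motif). The NBS signature is typed
primarily by the kinase-2 terminal residue (W ⇒ CC-lineage, D ⇒
TIR-lineage) with lineage sub-profile Viterbi scores as fallback and
consistency check. Architecture assignment: TIR present → TNL/TN; else CC
→ CNL/CN; neither → the signature decides the subscript branch;
NBS-model coverage < 0.5 → PARTIAL. Proteins showing both CC and TIR
resolve toward TIR (rarer, higher specificity) and are logged;
undetermined signatures default to the predominant CC branch and are
logged.

Motif discovery for subdomain comparison is one-occurrence-per-sequence
EM with background-proportional pseudocounts (total 0.5 per column) and
10 random restarts; the monotone quantity is the penalized objective
(log-likelihood + Dirichlet prior), which the implementation exposes for
testing.

## Synthetic genomes and what they do (not) emulate

The generator is the package's test bed, and its defaults are the packaged
study conditions: 60 NLR genes covering all eight architecture codes
(42:18 CC:TIR lineage split, with CC genes drawn 3:1 from two divergent
CC sub-lineages), 40 % pseudogenes (cause mix 40 % premature stop, 40 %
frameshift, 15 % partial deletion, 5 % scaffold-end truncation, apportioned
by largest remainder), 10 clusters with 2–8 genes at 5–60 kb spacing,
singleton genes placed > 3 Mb apart, ~15 % of singleton scaffolds left
unanchored, 40 kinase decoys (P-loop but no kinase-2/GLPL), 200
random-codon background genes, and six unannotated NBS-derived relics near
clusters. Genes may carry 0–2 introns (GT..AG, codon-boundary insertion)
and sit on either strand; scaffolds are anchored in both orientations.
Everything derives from one RNG stream seeded by the spec, and equal specs
give byte-identical outputs.

Lesion placement is deliberately constrained, mirroring the survey design
in which every annotated pseudogene retains at least a partial NBS: stops
and frameshifts fall between kinase-3a and GLPL (inside the region every
reference covers, so the alignment pins the breakpoint and the gene stays
detectable), terminal truncations cut shortly after kinase-2 (so reference
coverage reads as loss; the expected architecture becomes PARTIAL). The
truth table records the architecture *expected after the lesion* via a
domain-survival rule (a domain counts as lost when the lesion removes it
or, for the LRR, when fewer than one full repeat survives), and the
kinase-2 terminal residue is held fixed as the lineage signature.

Passing tests on this generator show the pipeline recovers exactly what
was planted under realistic domain grammar, divergence (~10 % in linkers,
~3 % in motifs) and genomic layout. They do not show robustness to
features the generator omits: alternative isoforms, transposon insertions,
nested or tandem-duplicated gene models, assembly gaps inside genes,
annotation errors, or NBS domains far outside the packaged consensus
family. The packaged seed alignments and reference R-protein set are
synthetic stand-ins built from the field's canonical motif vocabulary; on
real data they should be replaced by curated seed alignments and a real
reference database through the same interfaces.

## Mapping, windows and the NBS-derived screen

Anchoring is exact interval arithmetic (reverse-oriented scaffolds mirror
coordinates and flip strands). Clustering is single-linkage chaining of
NBS genes at ≤ 100 kb start-to-start — the distance inside which the
large majority of NBS pseudogenes sit next to another NBS gene — and is
provably identical to connected components of the ≤ 100 kb adjacency
graph (tested). Super-clusters group cluster spans within 500 kb and are
reported separately; "alone" genes use a strict > 3 Mb rule. Flanking
windows extend 100 kb (two NBS genes) or 200 kb (three or more) from the
outermost NBS gene boundaries, symmetric, clipped at scaffold ends; ORFs
are ATG-to-stop, three frames, both strands, ≥ 80 codons. The homology
screen is Smith–Waterman (BLOSUM62, 11/1) with Karlin–Altschul E-values
(λ = 0.267, K = 0.041) at E ≤ 10⁻⁵, ≥ 30 % identity over ≥ 50 % of the
reference; an NLR-homologous ORF with no NBS-model signal (< 25 bits) is
"NBS-derived", with model coverage below 0.5 "partial NBS", and ORFs
matching only non-NLR stress references are "resistance-like". The ≥ 50 %
reference-coverage rule means relics whose best reference is NBS-heavy can
be missed — a conservative bias accepted by design.

## Pseudogene calling

The comparison engine is a local dynamic program over (reference residue ×
DNA position): a residue consumes 3 bases (BLOSUM62 on the translated
codon), or 2/4 bases at a frameshift penalty of 12 (about half a typical
doubled gap-open), with affine codon gaps (11/1) on either axis and a zero
floor. Stop codons score at the BLOSUM62 floor (−4) and are recorded as
events; frame switches are recorded as frameshift events. DP optimality is
verified against exhaustive recursion on tiny instances.

The best reference is chosen by alignment score among the four references
sharing most protein 4-mers with the gene's frame translations; among
near-tie scores (within 10 %) the reference with the highest aligned
coverage wins — a shorter same-family reference should beat a longer one
whose extra domains simply fail to align. Cause priority is scaffold-end
(gene ≤ 500 bp from a scaffold terminus *and* the alignment truncated on
that side) > premature stop > frameshift > partial deletion (reference
coverage < 0.8) > intact; the priority is a package decision, with stops
outranking frameshifts because they are directly observable in frame. A
frameshift whose shifted frame happens to expose an in-frame stop may be
called a premature stop (observed at ~4 % on the packaged data); breakpoint
placement inside repeat arrays can wander a few codons. Transposition and
exon-skipping causes are out of scope (they need TE libraries and
transcript evidence); the cause enumeration is extensible.

## Phylogeny

NBS domains are trimmed to [P-loop start, GLPL end + 30) and proteins
lacking either anchor are excluded — the package's interpretation of
"complete NBS only". Alignment is progressive: UPGMA guide tree
(scipy) on shared-3-mer distances, profile–profile global affine DP
(gap open 10, extend 0.5); the pairwise case is provably optimal (tested
against an independent Gotoh implementation). Manual end-curation is
replaced by an automatic rule trimming leading/trailing columns with gap
fraction > 0.8 (configurable). Distances are pairwise-deletion p-distances
(optionally Poisson-corrected, the pipeline default). Neighbor joining
follows Saitou–Nei with deterministic tie-breaking (lexicographically
smallest pair of cluster keys, a cluster's key being its smallest leaf
label); negative branch estimates are clamped to zero and counted, the
MEGA-compatible convention. Bootstrap (default 500 replicates) resamples
columns; the support of an internal edge is the percentage of replicate
trees containing its leaf bipartition, canonicalised to the side not
containing the alphabetically first taxon. Clade labels (CC(I), CC(II),
TIR) propagate from reference leaves: a leaf takes the label of its
smallest enclosing clade — computed on the unrooted topology, i.e. both
sides of every edge — containing references of exactly one label, else
"unassigned".

## Tables and e-PCR

Percentages round half-up at the quoted precision (decimal arithmetic, dot
decimals). The architecture table totals the eight full codes with
CNL-type and TNL-type subtotals; PARTIAL calls are the separate
partial-NBS row. The pseudogene table has one row per chromosome, a "-"
row for unanchored genes and a totals row.

The in-silico PCR screen matches each primer semi-globally; at each
template position the *minimum-edit* alignment (fewest substitutions +
indels, ties toward fewer indels) is evaluated and the site binds iff that
alignment carries ≤ 3 substitutions and ≤ 3 indels, budgeted separately.
Evaluating the minimum-edit alignment (rather than any feasible one)
prevents a clean 4-mismatch site from being re-interpreted as 3
mismatches plus an indel pair. Runs of nearby end positions collapse to
their best representative; amplicons pair a forward site with a
downstream reverse-complement site within 5 kb.

## Problem sizes

Test and acceptance runs use the packaged study-condition genome (300
annotated genes, ~4.7 Mb of scaffold sequence over 5 pseudomolecules), a
reduced 13-NLR genome for orchestration tests, 100 planted lesions for the
pseudogene accuracy check, 100 bootstrap replicates for the clade-support
check and tiny instances (M ≤ 3, sequences ≤ 5; proteins ≤ 8, DNA ≤ 30)
for the exhaustive oracles. The full pipeline on the default genome runs
in well under a minute on one CPU, dominated by E-value calibration and
the bootstrap.
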