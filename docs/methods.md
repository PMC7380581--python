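# Methods

This note documents the models and procedures magprov implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic generators do and do not emulate.

## Compositional screen

A genome leaves a compositional signature in its oligonucleotide usage.
The screen represents a sequence by its GC fraction (G+C over unambiguous
bases; N excluded from numerator and denominator, an all-N sequence is
undefined rather than 0) and by a canonical tetranucleotide spectrum:
sliding 4-mer windows at step 1, each window merged with its reverse
complement into the lexicographically smaller key (136 keys), windows
containing N skipped rather than imputed — draft MAGs contain assembly
gaps, and imputation would bias the spectrum. Genome spectra pool raw
counts across contigs before normalizing, so no artificial junction
windows exist.

A candidate region is scored against its host genome by the Manhattan
distance between spectra (a metric bounded by 2) and ranked among
equal-length background windows tiled non-overlapping across the genome
(terminal fragments shorter than half a window are dropped, longer ones
kept as short windows). The region is flagged when its empirical
percentile exceeds `flag_quantile` (default 0.95) or its GC departs from
the genome mean by more than `gc_flag` (default 0.05). These defaults
follow common genomic-island practice and are exposed in configuration.
The percentile rule is a deliberate operationalization: published analyses
typically show profile "consistency" qualitatively, and a nonparametric
rank against the genome's own windows makes consistency testable without
distributional assumptions. The background window length defaults to the
region length rounded to the nearest kb, so the rank compares like with
like.

A quantile rule needs enough background windows to be meaningful: with N
windows the flag `percentile > 0.95` covers roughly N/20 top ranks, so
below ~40 windows rank granularity inflates the false-alarm probability
(with ~20 windows the top two ranks flag, ≈9% instead of ≈5%). The
replicate studies therefore use hosts of 360 kb with 6 kb operons (~60
windows); real MAGs at 1.4–1.7 Mb give 200+ windows and are comfortably
past this regime.

## Complex presence calls

A complex is present when `|detected| / |subunits| >= threshold` with
threshold 0.75 by default, compared exactly in rational arithmetic so the
6-of-8 boundary is inclusive by construction. Matching is case-insensitive
on gene label or KO id after a synonym map (the shipped catalog lists
alternates such as bcd/acox/fadE for acyl-CoA dehydrogenase); paralog
copies of one subunit count once — whether paralogs should count is
genuinely unspecified in the figure convention this reproduces, and
distinct-subunit counting is the conservative reading. Single-gene
catalog entries default to threshold 1.0.

## HGT evidence and verdicts

Each operon report carries three evidence lines, each with the thresholds
used. Mobile-element hallmarks are collected from a flank window of
`flank_bp` (default 10 kb, truncated at contig edges — draft assemblies
are fragmented) on each side of the operon, never from the operon itself:
tRNA and repeat annotations directly from the feature table, integron and
transposon calls from tabular similarity hits after the published filter
semantics (integron screen inclusive at 30% identity / 75% coverage with
no E-value cap; transposon screen strictly above 30% and 75% with
E < 1e-5). The similarity searches themselves are external; the package
applies the filters. Neighborhood discordance is the fraction of labelled
flanking CDS whose best-hit taxon differs from the modal taxon of the
operon members, undefined below 3 labelled flank genes; modal ties break
toward the higher discordance (conservative), and the flag threshold
defaults to 0.5 (a majority-discordant neighborhood). Any triggered line
gives `hgt_suspected`; all lines computable and negative give
`vertical_consistent`; otherwise `indeterminate`. A clean screen is
evidence for vertical inheritance or ancient transfer — composition
ameliorates toward the host over time, and the verdict vocabulary is
chosen to avoid overclaiming.

## Tree machinery

Splits are handled in unrooted semantics throughout (the convention of
the classic consensus programs), canonically encoded as the leaf block not
containing the smallest leaf. Robinson–Foulds distance is the symmetric
difference of split sets, with a normalized variant dividing by 2(n−3).
The extended majority rule keeps all splits with frequency strictly above
1/2, then greedily adds remaining observed splits in decreasing frequency
while compatible; frequency ties break on the lexicographic encoding of
the split (the side containing the smallest leaf, as a sorted tuple).
This tie-break is the package's own determinism choice — the reference
implementation's internal order is undocumented — and is fixed so reruns
are byte-identical. Input trees are weighted equally; consensus edges
carry frequencies, never inferred branch lengths (branch-length estimation
belongs to the phylogeny programs, out of scope here). Correctness is
checked against a brute-force oracle that enumerates every possible
nontrivial split: exhaustively for all resolved tree pairs on 6 leaves and
all triples on 5 leaves, and on a seeded sample of 6-leaf triples (the
full 6-leaf triple space, ~1.2M combinations, exceeds the value of the
check); split extraction is additionally cross-checked against dendropy's
independent bipartition encoding.

Placement congruence orients both trees at the same deterministic outgroup
(the smallest shared non-focal leaf), requires the focal clade to be
monophyletic in both (else `unresolvable`), and compares the sets of
sister lineages encountered walking rootward for the first k steps
(default k = 2, exposed in configuration: the congruence claims this
supports concern immediate branching order). Leaves may be mapped through
a lineage labelling so sister comparison happens at the lineage level.

Alignment post-processing keeps exactly the columns with gap fraction
strictly below 10% (so an exactly-10% column is removed), and subunit
concatenation requires identical taxon sets unless `pad_missing` fills
all-gap rows (reported). Trimming commutes with concatenation since both
are columnwise.

## Delineation

Orthologs are reciprocal best hits by alignment score, ties broken on
partner id for determinism, with filters at 30% identity and 70% coverage
(standard AAI practice; the rank thresholds cited below come from the
genome-aggregate literature, which does not fix search parameters). The
internal similarity provider is local affine-gap alignment under BLOSUM62
(open −11, extend −1), with a global edit-distance prefilter that skips
pairs whose distance ratio exceeds 0.65 — such pairs cannot approach the
30% identity floor, and the prefilter cuts all-vs-all runtime by an order
of magnitude at test scale. External tabular hits can replace the internal
provider at scale. AAI is the unweighted mean identity over RBH pairs,
undefined (not zero) with no pairs. 16S identity is global-alignment
matches over columns excluding terminal overhangs, because fragments
(hundreds of bp) are compared against full-length genes; inputs under
200 bp yield a warning-tagged result. Rank suggestion: AAI ≥ 95 same
species, ≥ 65 same genus, ≥ 45 new genus candidate (requiring AAI < 65
against every supplied same-family reference), else higher rank; a
supplied 16S identity is annotated as supporting (< 94.5%) or conflicting
(≥ 94.5%) evidence without overriding the AAI call.

## Expression

Alignments are kept at MAPQ strictly greater than 2; unmapped, secondary
and supplementary records never count. FPKM uses the total mapped
fragments over all genes in the table as denominator, making it invariant
to count rescaling. Bin fractions partition filtered primary fragments
over bins plus an explicit "unbinned" remainder (summing to 1), and are
undefined — not zero — with no fragments. Multireads are counted once via
their primary alignment; expectation-maximization reassignment of
multireads is deliberately not reimplemented, a documented divergence from
EM-based quantifiers. Multi-subunit complexes are summarized by the
average FPKM of their transcribed members.

## Synthetic generators

Genomes are drawn from an order-3 Markov chain in which every 3-mer
context carries its own split of the GC mass between G and C and of the
AT mass between A and T (splits uniform on [0.2, 0.8]), so the per-step
probability of G+C equals the target exactly while the chain carries a
strong, genome-specific tetranucleotide signature. This matters for the
screen's specificity test: native operons are drawn from the *same*
chain, making them genuinely indistinguishable from the host by the 4-mer
statistic — a weaker (i.i.d.) background would make that test vacuous.
Measured GC converges within ±0.01 of target from ~100 kb.

Planted operons splice a donor-chain draw into the longest contig at a
recorded locus, tile labelled member genes across it, surround it with
host-taxon context genes, and optionally add a tRNA feature and a
transposase gene (with a screen-passing similarity hit) within 5 kb. Tree
sets build a random species tree containing the focal clade, copy it as
the vertical gene tree, and produce the transferred gene tree by pruning
the clade and regrafting it onto the leaf branch most nodally distant
from its original sister group. Proteome pairs share a controlled
fraction of genes, with shared copies mutated site-wise to a different
residue at rate 1 − identity/100 — always to a different residue and with
no indels in shared cores, so the identity target is analytic rather than
calibrated. All generators are byte-identical under a fixed seed.

What the generators do not emulate: real gene content (member genes are
labelled placeholders), read-level data (no FASTQ), repeat structure,
amelioration of transferred sequence over time, indel evolution in
proteins, and rate heterogeneity across sites or lineages. Passing the
replicate studies therefore demonstrates that the statistics behave as
designed under their own assumptions — correct flag rates when the
compositional contrast exists, correct nulls when it does not — not that
those operating characteristics transfer verbatim to real MAGs, where
contrasts are weaker and annotation is noisy.

## Problem sizes and numerics

The replicate studies run 100 seeded replicates per condition with 360 kb
hosts, 6 kb operons and a donor GC offset of 0.08; delineation recovery
uses 60-gene proteomes at shared fraction 0.72 and identity 63; the
study-regime bin summaries use the real bin dimensions (45/133/126
contigs, 1.40–1.66 Mb, GC 0.455–0.476). Spectrum normalization tolerates
1e-9; presence fractions compare in exact rational arithmetic; GC is
printed at one decimal with round-half-up. Degenerate inputs follow one
rule: quantities with an empty denominator (all-N GC, AAI with no pairs,
fractions with no reads, discordance with under 3 labelled genes) are
undefined markers, never zero.
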