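# Methods

This note records the models, conventions and numerical choices behind each
stage of the pipeline, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Germline reference

A reference is a set of V and J gene segments per chain (TRA, TRB), each with
the 0-based offset of its anchor codon: the conserved Cys104 codon for V
segments and the conserved Phe118 codon for J segments, with the following
Gly119 codon (anchor + 3) checked as a secondary validation anchor on J
segments. Validation is strict for the reference (only A/C/G/T; anchor codons
must translate to C, F and G respectively; names unique) and lenient for
reads, which are data. Allele suffixes (`*01`) are stripped to gene level on
load; hyphenated names such as TRAV7D-2 are gene-level and kept verbatim.
Every violation is collected and reported together, not just the first.

No curated germline download is bundled. `synthetic_reference()` builds a
stand-in with the full murine gene-space sizes (112 TRAV, 51 TRAJ, 23 TRBV,
13 TRBJ) so "occupied of N genes" denominators are meaningful: random
non-stop codon sequences with valid anchors, all V segments 81 nt and all J
segments 48 nt. Equal lengths are deliberate — they make an exact full-length
substring hit provably optimal among all candidates, which the caller
exploits (below). The canonical iNKT genes are wired in: TRAV11D ends with
codons for C-V-V and TRAJ18 begins with codons for D-R-G-S-A-L-G-R-L-H before
its Phe codon, so the invariant junction CVVGDRGSALGRLHF is constructible
with a single glycine insert. A real (e.g. IMGT-derived) reference can be
supplied as FASTA + anchor TSV; which release/allele set to use is the
user's choice.

## Synthetic study generator

The generator emulates a 2 group × 2 tissue × 3 replicate design
(ACM/ICM × OM/Ly) with a configurable read depth per sample and chain
(default 50,000).

**Clone pools.** Each sample type has its own clone pool; clone sizes follow
a Zipf law with exponent 1.2 over the first 50 ranks (the expanded head) and
a uniform tail. Default pool sizes are 2000 (ACM OM), 2000 (ACM Ly), 1200
(ICM Ly) and 300 (ICM OM); the small ICM OM pool is what plants the lower
clonal diversity of the irritant mucosa. These sizes are scaled-down study
conditions chosen once so that the qualitative structure of the real study —
diversity ordering, nested sharing counts, detectable gene skew — holds
robustly at desk-scale read depths; they do not attempt to reproduce absolute
unique-read counts from deeply sequenced animals.

**Sharing.** A top-biased fraction of the ACM OM pool (default 0.30,
including the most-expanded clones) is also placed at the top of the ACM Ly
pool; independent random fractions are shared with ICM Ly (0.05) and ICM OM
(0.01). All other clones are unique across pools by construction (the factory
rejects duplicate (V, J, CDR3aa) triples and raises once the junction model
cannot produce new unique clones).

**Skew.** Clones shared between ACM OM and ACM Ly draw their V and J genes
with a 5× weight on the configured skew genes (defaults: TRAV7D-2, TRAV14-1,
TRAJ18, TRBV5, TRBJ2-7); private clones draw uniformly. This is the signal
the mean + 2·SD rule is expected to find.

**Junctions.** A clone's read is full V segment + random insert + full J
segment; its CDR3 runs from the V anchor codon through the J anchor codon
inclusive, so in-frame junctions always start with C and end with F. A
configurable fraction of clones (default 0.2) is out-of-frame (insert length
not a multiple of three); in-frame junctions are redrawn if a stop codon
lands in the insert. There is no D-segment model for TRB — random inserts
subsume it — and no PCR bias, chimeras or quality scores.

**iNKT spike.** `inkt_frequency` values are targets on the *in-frame* read
scale (the scale on which repertoire frequencies are reported); the generator
solves `a = f·I / (1 − f·(1 − I))` for the raw abundance `a`, where `I` is
the pool's in-frame mass, so the expected in-frame frequency is exactly `f`.
Defaults: 0.02% in ACM OM, 1% in ICM OM, 0.2% in the lymph nodes.

**Error model.** Each base is substituted independently with probability
`error_rate` (default 0), uniformly over the three alternatives. The same
uniform draw decides both whether a base is hit and the substitute, so under
one seed the corrupted positions at a lower rate are a subset of those at a
higher rate; this monotone coupling is what makes "higher error never
recovers more clonotypes" a per-seed property rather than only an average.

**Determinism.** One global seed drives everything; per-sample multinomial
draws use seeds derived from (seed, fixed sample index, chain index), so
adding replicates or samples never reshuffles existing ones. Read identifiers
embed the ground-truth clone id.

## Clonotype calling

**Assignment.** Each read is scored against every candidate segment with
local alignment (match +1, mismatch −1, linear gap −2; Smith–Waterman via
Biopython's PairwiseAligner). The chain is decided by the best V hit across
both chains' V pools; J is then assigned within that chain. Ties break to the
lexicographically smaller gene name; assignments scoring below `min_score`
(default 20) are counted as unassigned. These parameters are not biological
constants — they were chosen for determinism and are echoed in every run
manifest. An exact-substring fast path skips dynamic programming when a
candidate matches in full: a local alignment can only reach
score = len(segment) through a full-length exact match, so candidates whose
ceiling cannot beat the current best are skipped without changing the
optimum. Reads are searched on the given strand only (amplicon orientation is
known); `revcomp=True` enables both strands for external data. Identical read
sequences are classified once and re-weighted, which leaves results unchanged.

**CDR3.** Anchor codons are projected through the alignment blocks onto read
coordinates; extraction fails (and is counted) when an anchor codon does not
project contiguously or when the V and J intervals overlap or are reordered.
The junction includes both anchor codons (C…F); Gly119 is validation-only and
not part of the CDR3. Translation is from position 0 of the junction; codons
containing N give X (without affecting the frame flag); a junction is
out-of-frame when its length is not a multiple of three or contains a stop.
X-containing junctions are excluded from the clonotype key space (ambiguity
must not create phantom clonotypes) and counted as unassigned.

**Aggregation.** The unique-read key is the (V gene, J gene, CDR3aa) triple.
Copy counts are read counts per key; ranks run 1..K by non-increasing copy
count with lexicographic tie-break; percent frequencies are computed over
in-frame reads only. Out-of-frame clonotypes are retained and flagged, with
no frequency. In the pathological case where an in-frame and an out-of-frame
nucleotide junction collapse to the same amino-acid string, the table keeps
separate productive and non-productive rows; the simulator cannot produce
this (it de-duplicates on the triple). The representative `junction`
nucleotide sequence is the most frequent one for the key (ties: smallest
lexicographically).

## Metrics

Shannon diversity is H = −Σ pᵢ ln pᵢ over in-frame clonotype read proportions
(copy-count weighted, not unique-read weighted). Natural log is the default;
base 2 is available and the base is recorded in the output, since it only
rescales comparisons. An empty sample yields a missing value, not zero. V–J
matrices sum each sample's in-frame clonotype frequencies per (V, J) cell
(each sample's matrix totals 100%) and then average element-wise across
replicates. Group-level significance testing of diversity is deliberately
out of scope: with three replicates per group an exact rank-sum test cannot
reach two-sided p < 0.05, so the package reports the per-sample indices and
leaves inference to the reader.

## Commonality and skew

A group repertoire pools a sample type's replicates: the clonotype set is the
union of productive triples and the mean %frequency averages over *all*
replicates with absence as zero. "Increased in ACM Ly over ICM" means
strictly greater mean frequency in ACM Ly than in ICM Ly (absence = 0); a
config switch (`icm_both`) compares against the maximum over both ICM
samples instead, since either reading is defensible. "Only in ACM Ly"
additionally requires absence from both ICM clonotype sets. These definitions
make `only ⊆ increased ⊆ shared` an identity.

For gene-usage skew the mean is total unique reads divided by *occupied*
genes (count ≥ 1) — the convention fixed by the reported means, which equal
filtered-set size / occupied-gene count — and the SD follows the same
occupied-only convention as the sample (n−1) standard deviation. A gene is
flagged when its count strictly exceeds mean + 2·SD. With one occupied gene
the SD is undefined and reported as such. Note a boundary property of this
rule: with very few occupied genes (e.g. five) a single outlier inflates the
SD enough that it can never be flagged; the rule is meant for, and tested at,
realistic occupied-gene counts (tens of genes).

## What passing tests do and do not show

The generator produces idealized amplicons: perfect primers, no chimeras or
PCR bias, uniform substitution errors only, sense strand, one allele per
gene. Exact ground-truth recovery at zero error therefore validates the
bookkeeping (assignment, anchor projection, translation, aggregation,
frequencies), not robustness to real library artifacts. The planted-structure
checks (diversity ordering, nesting, skew flag rate ≥ 95% over 20 seeds, iNKT
spike recovery within 3 binomial SDs) validate that the analysis recovers the
statistical structure the study design assumes at the default conditions;
absolute values from deeply sequenced animal tissue are not reproducible from
a desk and are not targets.

## Problem sizes

Defaults used by the acceptance script: the full default design (12 samples ×
2 chains × 50,000 reads) for exact recovery; 20 truth-level studies at 8,000
reads/sample for the skew flag rate; 50,000-read single-replicate TRA studies
for iNKT spike recovery; 500 reads over the toy reference for the aligner
oracle. The whole script completes in about a minute on one CPU.
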