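# Methods

This note documents the models and algorithms behind each stage, the
parameters that matter, what the synthetic data does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Structural model of a full-length element

An element is called from structure alone, independent of coding capacity:

* two direct repeats (LTRs) of 100–6000 bp with pair identity ≥
  `min_identity` (default 0.80), separated by ≥ 500 bp of internal
  sequence, total length ≤ 12 000 bp;
* an exact target-site duplication of 4–6 bp immediately flanking both
  LTRs (longest match wins);
* primer-binding-site and polypurine-tract signals just inside the 5′ and
  3′ LTRs respectively, recorded as evidence but not required for
  acceptance unless `strict` is set. The TSD is kept mandatory because it
  is the one signal created by the insertion mechanism itself; PBS/PPT
  detection depends on the completeness of the tRNA library and on element
  degradation, and making them mandatory would bias the collection toward
  young, intact elements.

The identity default of 0.80 sits below typical observed collection means
(~0.90) so that older, more diverged pairs remain detectable; raising it
trades sensitivity for specificity symmetrically.

### Detection algorithm

Exact k-mer seeding (k = 13) on the forward/forward diagonal; seed pairs
with separation in range are grouped into diagonal bands (tolerance 16 bp,
allowing small indels between the repeats), chained along the sequence
(chain break at 300 bp gaps — far larger than the expected spacing of
conserved k-mers at any detectable divergence), and extended outward
ungapped with an x-drop rule (+1/−2, X = 15). Pair identity is then
computed from a global edit-distance alignment of the two repeat copies
(edlib). Seeds never span N; candidates with > 10 % N in either LTR are
dropped. LTRs are direct repeats, so only the forward strand is scanned;
element orientation is recovered later from protein-domain frames.

Boundary refinement searches TSD matches over boundary shifts up to ±6 bp,
preferring (i) adjusted boundaries whose termini are the canonical TG…CA
dinucleotides, then (ii) longer TSDs, then (iii) smaller shifts. Without
the termini preference, a chance 4-mer duplication at a wrong shift
occasionally truncates the call by a few bp.

Overlapping accepted elements are resolved greedily by descending
(identity, length); output ordering is deterministic by (scaffold, start).

## Domain annotation and classification

Six-frame translation (standard code, stops as `*`, N as `X`) followed by
local alignment of every frame against every labelled reference (BLOSUM62,
gap open −11 / extend −1). E-values use the Karlin–Altschul formula with
gapped BLOSUM62 constants (λ = 0.267, K = 0.041) and database size equal to
the library residue count; the cutoff is 1e-4. A cheap amino-acid 4-mer
prefilter skips frame/reference pairs sharing fewer than two 4-mers; an
exact planted domain shares hundreds, a random frame almost none, so the
filter only removes pairs that could not reach the cutoff anyway.

Frameshift-aware (splice-style) alignment is deliberately not implemented:
same-kind hits within 300 bp in different frames are merged into one
census entry, which preserves exactly what classification consumes —
domain presence and order — while tolerating the 1-bp frameshifts and
premature stops that degrade real elements.

Classification: no RT/INT/RH ⇒ RXX-NA (GAG and/or PR alone allowed, the
TR-GAG-like configuration); otherwise majority vote of the core-domain
reference labels, ties broken by integrase position (upstream of RT ⇒
*Copia*, downstream of RNaseH ⇒ *Gypsy*). Orientation is the majority hit
strand of the core domains; no majority ⇒ unknown.

The census summary reports the five-domain share under two denominators
(RLC+RLG and the whole collection) because the two conventions give very
different numbers and published tables are not always explicit about which
one they use.

## RT phylogeny and lineage assignment

The best RT hit of each element is translated in its frame and kept if
≥ 150 residues. Distances are Poisson-corrected pairwise-alignment
distances, d = −ln(1 − p) over aligned non-gap columns (toggleable to raw
p), capped at 5. Pairwise global alignments replace a progressive multiple
alignment: only the tree topology near labelled references is consumed,
and the substitution removes a heavy dependency.

Neighbor joining is the canonical Saitou–Nei agglomeration with
deterministic lexicographic tie-breaking; negative branch lengths are
clamped to zero with the deficit moved to the sister branch. On additive
matrices the algorithm is exact (path distances reproduce the input to
1e-9, verified over random additive trees), and on noisy matrices it
matches scikit-bio's independent implementation topologically.

An element takes the lineage of the smallest surrounding clade containing
references of exactly one lineage. Two degenerate cases need explicit
handling:

* **RT identical to a reference.** Zero-length branches make the tree
  placement an arbitrary resolution of a polytomy, so the clade rule can
  see a "mixed" neighborhood that is an artifact. An element whose RT
  distance to a reference is < 1e-6 is therefore assigned that reference's
  lineage directly (undefined if several lineages tie at zero).
* **Equidistant elements.** NJ always attaches an equidistant taxon as
  sister to one reference (the Q-criterion breaks the tie through row
  sums), so "equidistant ⇒ undefined" cannot emerge from topology alone.
  If the runner-up lineage's nearest reference is within 0.05 of the
  winner's, the assignment is ambiguous and reported undefined.

## Family clustering

Greedy longest-first incremental clustering: each element joins the first
family whose representative it matches at ≥ 70 % identity over ≥ 70 %
coverage, else founds a new family. The shorter sequence is aligned in
full inside the longer (infix alignment); identity is computed over aligned
columns and the coverage denominator is the shorter sequence — so a clean
fragment of a longer element has coverage 1.0 and clusters whenever its
identity passes. Verified against an unbanded dynamic-programming oracle:
the greedy partitions coincide on planted family structures.

Family references are chosen among members whose LTR-pair identity is
within 2 percentage points of the family maximum, longest first. The
2-point margin quantifies "high identity" and is flagged as an
interpretation; it is configurable.

The canonical stricter 80/80 criterion never produces fewer families than
70/70 (monotonicity is tested); on diverse collections 80/80 tends to leave
everything a singleton, which is why the relaxed rule is the default.

## Copy counting, masking and densities

Family references are searched on both strands by k-mer seeding, diagonal
chaining (single-seed chains are discarded as chance matches), ungapped
x-drop extension of the chain, and an edit-distance identity check of the
matched segment. Coverage is the matched fraction of the reference; a copy
is complete at coverage ≥ 0.70 and identity ≥ 0.70. Because related
references cross-match, overlapping hits (> 50 % of the shorter interval)
are collapsed to the best by matched bases, and counting is reported per
superfamily. Masking lower-cases all segments matching any library
sequence at ≥ 80 % identity (the conventional masking direction) and
reports coverage both including and excluding N.

Window densities use 1 Mbp windows sliding by 500 kbp; a feature belongs to
every window containing its start, and the last window of a scaffold
absorbs the remainder (densities are scaled by actual window length).
Track correlation is Pearson's r with a two-sided t-test, chosen over rank
correlation because the quantity of interest is a linear density trend.

## Insertion dating

LTR pairs are aligned globally (match 2, mismatch −3, gap −8/−2, end gaps
penalized, deterministic first-optimal traceback; scores verified against
an independent Gotoh implementation). Over gap-free columns, P and Q are
the transition and transversion fractions and

K = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q),  T = K / (2r).

Gapped columns are excluded (the convention of standard distance tools);
saturated pairs (either logarithm undefined) are reported with a status
rather than dropped, because a tail of undatable old elements is itself a
result. The default rate r = 1.3e-8 substitutions/site/year is a standard
average plant nuclear rate; no further molecular-clock calibration is
attempted, and T scales trivially as 1/r for any other rate choice.

## Expression

Reads are assigned by shared k-mers (k = 15, sampled every 7 bp of the
read) to candidate offsets in each element on both strands, scored by
ungapped identity; a read counts toward its best element at identity ≥
0.95, with ties split fractionally — element families are similar by
construction, and winner-takes-all would systematically favor family
references. Conservation (assigned + unassigned = total) is tested.

TMM normalization follows the published recipe exactly: reference column =
median library size (lower median for even counts, overridable); log₂
ratios M and abundances A on rows nonzero in both libraries; 30 % two-sided
trim on M and 5 % on A by ranks; inverse-asymptotic-variance weights
(N−n)/(Nn) + (N_r−n_r)/(N_r·n_r); factor 2^(weighted mean M); factors
rescaled to geometric mean 1. The implementation agrees with a literal
step-by-step recomputation to 1e-6 and with edgeR's `calcNormFactors` to
6 decimals on random matrices.

"Expressed" elements are those above 1 count-per-million (normalized) in at
least one tissue — a conventional, configurable floor; shares are
percentages of the summed normalized expression of expressed elements.

## The synthetic generator: what it does and does not emulate

Backgrounds are i.i.d. nucleotides at a chosen GC (default 0.45, typical of
plant genomes) with optional N runs of 200–2000 bp. Elements follow the
structural model exactly: TG…CA termini (toggleable), PBS complementary to
a bundled tRNA 3′ end within 20 bp of the 5′ LTR, a 15-bp purine-rich PPT
near the 3′ LTR, and a single codon-aware ORF carrying the requested
domains back-translated from the labelled references (disruption injects
one 1-bp insertion and one premature stop at in-frame positions). The 3′
LTR is the 5′ LTR diverged by an expected K substitutions/site under the
Kimura two-parameter model (per-site sampling from the exact K2P transition
probabilities; transition/transversion ratio default 2.0, a stated
assumption, not an inference). Mutating one LTR only is equivalent in
expectation to symmetric divergence at half the rate per branch, which is
exactly what pairwise dating measures.

Planting duplicates the target site on both flanks; genes are
non-overlapping intervals whose density decreases linearly along each
scaffold, and a placement bias in [0, 1] gives *Copia* elements the
mirrored (increasing) gradient so that TE-vs-gene density correlation
tests have signal. Reads are drawn multinomially with uniform start
positions, substitution errors at a stated rate, and constant qualities.

Not emulated: nested or fragmented insertions, solo LTRs, indel-rich LTR
evolution, sequencing indels, paired-end structure, and realistic genomic
repeat landscapes. Consequently, passing tests demonstrate correctness of
the algorithms under the structural model, not performance on degraded
real-genome copies; the false-positive guarantees (zero calls on random
sequence) do carry over, but recall on real assemblies will be lower than
the near-perfect synthetic recall.

Default element geometry (LTRs 200–1500 bp, internal 3–5.2 kb, total well
under the 12 kb cap, TSD 4–6 bp, divergence up to 0.10) matches the ranges
typical of plant LTR retrotransposon collections. Two same-lineage planted
elements share back-translated domain ORFs (~80 % nucleotide identity over
the ORF), so occasionally such elements fall into one 70/70 family; this
mirrors the real ambiguity of family boundaries within lineages and is why
family counts on mixed simulations can be slightly below the number of
planted founders.

## Problem sizes and determinism

The bundled validation study uses a 3 Mb genome (3 × 1 Mb scaffolds), 30
planted elements at divergence ≤ 0.10, 60 genes; the correlation study
uses 3 Mb, 70 elements, 150 genes, bias 0.95, 250 kbp/125 kbp windows
(sized for adequate statistical power at desk scale); divergence recovery
uses 300 LTR pairs of 1 kb per stratum K ∈ {0.02, 0.05, 0.10, 0.20};
false-positive scans use five independent 1 Mb random sequences. All
randomness flows from a single seed through deterministic per-stage
`SeedSequence` derivations; reruns with the same seed produce byte-identical
outputs.

## Known limitations

* The detector reports the best boundary interpretation; in tandem or
  nested repeat regions the greedy overlap resolution keeps only one call.
* E-values use fixed Karlin–Altschul constants rather than fitted ones;
  they are accurate enough for a 1e-4 cutoff but are not BLAST-identical.
* Lineage assignment quality is bounded by the reference library; the
  bundled library is a small synthetic stand-in (see
  `scripts/make_ref_library.py`) and should be replaced by a curated
  domain library for real analyses.
* Copy counting collapses overlapping hits to one reference, so per-family
  (as opposed to per-superfamily) copy numbers are not meaningful for
  closely related families.
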