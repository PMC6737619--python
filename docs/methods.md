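# Methods

## Problem and model

`asmqual` evaluates a de novo genome assembly against a trusted reference
genome and reduces the evaluation to one number. The procedure has two
levels.

### Per-scaffold score

Each scaffold *s* is aligned to the reference (externally, e.g. with
minimap2; or via ground-truth alignments for synthetic data), its
alignments are filtered to a best consistent chain, and it receives

```
Q(s) = L(s) · R(s) / (1 + P(s))
```

* **Reward** `R(s)` — aligned query bases (union, no double counting)
  divided by the scaffold's non-gap length `l_s − gap bp`. Scaffolding
  gaps are maximal runs of N/n of at least `min_gap_len` (default 10 bp)
  and are excluded from the denominator: a scaffold should not be docked
  for Ns it declares. R is clamped at 1 to guard against residual
  query-side double counting, keeping Q(s) in [0, 1].
* **Penalty** `P(s) = log₁₀₀(m_s − ε_s)` when the excess of observed
  misassemblies `m_s` over the expected artifact `ε_s` exceeds 1,
  otherwise 0. The base-100 logarithm makes the penalty grow slowly: 10
  excess events halve Q(s), 100 divide it by 2 at P = 1, etc.
* **Length scaling** `L(s) = 1` if `l_s ≥ θ_G` (the shortest reference
  chromosome length), else `−1/(log₁₀(l_s/θ_G) − 1)` — a ramp in (0, 1)
  that is gentler than the raw length ratio on mid-sized scaffolds.

### Misassembly counting

The filtered chain is scanned pairwise in query order; each junction gets
exactly one classification with precedence **translocation** (different
chromosomes) > **inversion** (same chromosome, opposite strands) >
**relocation** (same chromosome and strand, |d| > t). The relocation
distance is `d = reference separation − query separation`, with reference
separation measured against descending reference order for '−'-strand
pairs; an overlap is simply d < −t, no separate branch. The query-aware
form means a junction whose reference distance is fully explained by its
query-side spacing (e.g. an N-gap joint spanning true genomic distance)
is not penalised; `query_aware=False` restores the literal
reference-separation reading. The default threshold `t = 1000` bp is
user-adjustable.

### Alignment filtering

Per scaffold, the filter keeps the maximum-total-weight subset of
alignments (weight = exact match count) such that any two retained
alignments overlap on the query by at most `overlap_frac` (default 0.5)
of the shorter one's query span, and no retained alignment is contained
in another's query interval. Only the query axis is constrained —
reference-side consistency must not be enforced, or translocations and
inversions would be removed before they can be counted. The optimum is
found by dynamic programming over alignments sorted by query end; the
containment exclusion makes query starts nondecreasing along any valid
chain, so checking each element against its immediate predecessor is
sufficient for all-pairs feasibility (verified against a brute-force
subset oracle in the tests). Filtering is keep/drop only; alignments are
never trimmed. Ties between equal-weight optima are broken toward larger
aligned query coverage and then by a fixed sort key, so output is
deterministic regardless of input order.

### Artifact calibration

Aligning a genome to itself does not yield zero misassemblies: repeats,
ambiguous bases and aligner heuristics fragment alignments. The expected
artifact for a scaffold of length *l* at threshold *t*, assigned to
chromosome *c* (the chromosome receiving most of its aligned bases), is
modelled as `ε = α_c·l + β_c·t + k_c`, fit per chromosome by ordinary
least squares. Observations come from cutting each chromosome into random
contiguous fragments (uniform lengths in [50 kb, 1 Mb], capped by the
chromosome; exact 1X tiling), aligning them back to the whole reference,
and counting misassemblies at every threshold in 100…10,000 step 100.
The alignment is done once; only the relocation re-evaluation varies with
t. When an external aligner is used, the whole chromosome itself is
pooled with its fragments in the same regression. Predictions are clamped
below at 0, and a chromosome absent from the model contributes ε = 0
(conservative: no artifact credit). In truth-alignment mode the fragment
chains are perfect, all artifacts are 0 and the fitted model is
(0, 0, 0); a pipeline run without a calibration table likewise uses the
zero model. Coefficients persist as a 4-column TSV so calibration runs
once per reference.

### Assembly score

```
Q(A) = (Δ_A · Ω_A · Π_A)^(1/3)
```

* `Δ_A` — area under the curve of the assembly base-pair fraction held in
  scaffolds with `Q(s) ≥ q`, q = 0.00…1.00 step 0.01. Unaligned
  scaffolds count in the denominator only.
* `Ω_A` — area under the analogous genome-coverage curve: the union of
  reference intervals of qualifying scaffolds over the total reference
  length, ambiguous bases included (this is why a gapped genome cannot
  self-score 1).
* `Π_A = Φ_A / Σλ_i` — the union of all covered reference bases over the
  summed per-scaffold aligned reference bases. λ_i is measured on the
  reference axis with within-scaffold overlaps deduplicated;
  between-scaffold overlap is exactly the redundancy being measured.

Grid inclusion is `Q(s) ≥ q` at grid points, so a perfect assembly
attains Δ_A = 1 exactly; areas use the trapezoidal rule on the 101-point
grid, exact for these step functions up to the grid resolution. If
nothing aligns, Π_A is undefined and Q(A) falls back to 0 with a warning.

## Synthetic data generator

`synthetic` builds toy references (i.i.d. nucleotides at a configurable
GC, default 0.41, mammalian-like) and four assembly designs, each
stressing one score component: mean scaffold length, planted
misassemblies per scaffold, fractional genome coverage, and N-fold
redundancy. Scaffold lengths are drawn from a normal distribution
truncated to [1, chromosome length]; scaffolds are a random **disjoint
tiling** of each chromosome, subsampled to the requested coverage
fraction. The disjoint construction was chosen over independent uniform
placement so that the design identities hold exactly: covered fraction ≈
coverage_fold, inverted redundancy ≈ 1 at 1X and ≈ 1/fold for
fold-replicated assemblies (independent uniform placement would give a
1X union of only ~63% and Π ≈ 0.63, conflating coverage with
redundancy). Misassemblies are planted by rebuilding a scaffold as k+1
reference segments (each ≥ 1 kb) whose junctions each violate
collinearity by exactly one event, drawn uniformly from the three types;
relocation offsets are uniform in (t, 10t] — unambiguously above
threshold yet local — falling back to any placement with |d| > t when a
segment sits too close to a chromosome edge for a local offset.
Scaffold sequences are copied verbatim from the reference so truth
alignments are exact; an optional per-base substitution rate exists for
aligner-in-the-loop tests only. All randomness flows from explicit seeds
(one spawned generator per operation), and generation parameters are
recorded in a JSON manifest.

What the generator does **not** emulate: repeats and low-complexity
sequence (so real aligner artifacts are far richer than the ε ≈ 0 the
toy calibration produces), sequencing error profiles, heterozygosity,
and realistic chromosome length distributions. Passing tests therefore
demonstrate the correctness of the scoring machinery and its monotone
responses, not performance on real genomes.

## Problem sizes and numerical choices

The test and acceptance workloads use a 5 × 500 kb reference (θ_G =
500,000), chosen so every stage — including brute-force filter oracles on
≤ 12 alignments and 5-replicate trend suites over three levels of each
design — completes in seconds while leaving every code path exercised.
Trend suites use mean scaffold lengths 1/10/100 kb, 0/10/100 planted
misassemblies at 150 kb mean length, coverages 0.1/0.5/1.0X and
redundancy folds 1/2/5, five replicates per level.

Numerical details worth knowing:

* Quality-bin assignment uses `floor(Q·10 + 1e−9)` so binary-unrepresentable
  values like 0.3 land in their intended left-closed bin; the top bin
  [0.9, 1] is closed.
* Partitioning (greedy longest-first onto the lightest partition) bounds
  the load spread by the longest scaffold and affects scheduling only;
  results are reduced in scaffold-id order and are bit-identical for any
  partition count.
* OLS uses `numpy.linalg.lstsq`; a rank-deficient per-chromosome design
  (e.g. a short chromosome yielding a single fragment, so fragment length
  is constant) falls back to an intercept-only fit with a warning.
* Relocation at exactly |d| = t is not an event (strictly greater-than).
* All internal coordinates are 0-based half-open; PAF query coordinates
  are forward-strand regardless of alignment strand.

## Known limitations

* Filtering is O(n²) per scaffold in the number of raw alignments —
  fine for long-read assemblies with few hits per scaffold, slow for
  pathologically repetitive queries with thousands.
* The artifact model is linear in (l, t); real artifact counts saturate,
  so extrapolation far outside the calibrated fragment-length range is
  unreliable.
* Only PAF is ingested; other alignment dialects must be converted.
* The pipeline holds the reference and per-scaffold chains in memory;
  multi-gigabase genomes need the partitioned mode and a machine sized
  accordingly.
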