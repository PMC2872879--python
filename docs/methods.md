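# Methods

## Model and objective

`motifrank` treats motif discovery as a search for the partition of a
region set S = {s₁,…,s_d} that best separates high- from low-evidence
regions.  A candidate motif m (an IUPAC consensus string, length 5–20)
defines the positive set S⁺(m) of regions containing at least one exact
match; DNA-TF binding is approximated as a binary presence/absence event.
The objective is the centered, scaled average evidence of the positive set,

    J(m) = √n · (mean(E⁺) − mean(E)) / σ(E),   n = |S⁺(m)|,

with σ the population standard deviation of the full evidence vector.  J is
invariant to positive affine rescaling of E, so the choice of log base in
the evidence transforms affects reported magnitudes but never rankings.  An
optional finite-population correction multiplies the denominator by
√((d−n)/(d−1)) (`finite_population_correction=True`); the plain z-form is
the default and both are exposed because the exact variance convention of
the underlying rank statistic admits either reading.  A selection variant
J_sel binarizes the evidence at a threshold k before scoring
(`objective="selection"`); k applies to the transformed evidence vector.
Degenerate cases score 0: constant evidence, an empty positive set, or a
positive set equal to S.

### Set-size constraint

Averages over very small or near-global positive sets are noise-dominated,
so n is constrained to [a, ⌊b·d⌋], both bounds inclusive.  Defaults follow
the two experimental regimes the tool targets: a = 20, b = 0.15 for
ChIP-chip and overexpression data (`chip-chip` preset) and a = 100,
b = 0.30 for ChIP-seq (`chip-seq` preset).  The constraint is realized
inside the objective: out-of-range motifs score −∞ rather than being
unreachable.  This matters for the seeds — on realistic region lengths a
non-degenerate 5-mer matches far more than b·d regions (≈32% of 200-nt
regions), so a rule that discards such seeds outright would discard all of
them.  Instead every trajectory starts at its seed, skips out-of-range
candidates during scoring, and is reported invalid only if it never reaches
an in-range motif (e.g. when every motif matches every region).

## Evidence transforms

* **Binding P-values** — e = ln B₁₀(p) with B₁₀(p) = 1/(−e·p·ln p) for
  p < 1/e, clamped to B₁₀ = 1 (e = 0) otherwise.  The bound is the standard
  calibration of a P-value into a maximum Bayes factor under a Beta(θ,1)
  alternative; it corrects the "P-value fallacy" (p = 0.001 supports odds
  of ≈53, not 1000).  Only the closed-form bound is computed; θ is never
  estimated.  p = 0 is floored at 10⁻³⁰⁰ with a warning; a switch
  substitutes the naive e = −ln p for comparison runs.
* **ChIP-seq peak densities** — per-region maxima of a kernel density over
  read starts (consumed from a peak caller, not recomputed; a plain
  Gaussian-kernel helper exists for fixtures).  The background b is the
  85th percentile (linear-interpolation method) of the strictly positive
  scores; e = ln(score/b), with zero scores floored at min-positive × 10⁻³.
* **Expression fold-changes** — e = −log₂(x_after/x_before), so
  down-regulation upon regulator induction (the miRNA transfection setting)
  is positive evidence; a flag flips the sign for activator studies.

## Search

Seeds are all non-degenerate 5-mers; in DNA mode each word is pooled with
its reverse complement (canonical = lexicographic minimum), giving 512
seeds; RNA mode keeps all 1024 because matching is forward-strand only.
The neighborhood of a motif is the union of three move families:

* extension: prepend or append each base (8 candidates, none at length 20);
* truncation: drop the first or last symbol (length ≥ 6 only);
* degeneracy: widen one position — A→{M,R,W}, C→{M,S,Y}, G→{K,R,S},
  T→{K,W,Y}; a double-degenerate symbol widens to N except at terminal
  positions; N is terminal in the lattice.

Hill climbing adopts the best strictly improving candidate, breaking score
ties by the lexicographically smallest motif string, so a run is fully
deterministic with no RNG.  Results from all seeds are de-duplicated by
final motif and sorted by score.  User-supplied motifs with terminal N are
accepted for matching; only move-generated motifs avoid terminal N.

Occurrence queries run on a suffix array (Manber–Myers prefix doubling)
over the concatenated regions with sentinel separators, answered by
branching interval descent over the degenerate positions — equivalent to
naive scanning (tested exhaustively) but independent of how many literal
words the motif expands to.  Sequence N is matched only by motif N, so
masked stretches cannot join positive sets.  Soft-masked lowercase is
uppercased by default (configurable to N).  Positive sets depend only on
sequence, so they are memoized across seeds, steps and permutations.

### Conservation refinement

With orthologs attached (per-species FASTA keyed by primary region id), a
region stays in S⁺(m) only if m matches every available ortholog; regions
without orthologs are kept unconditionally.  The filter is a strict subset
operation and is applied inside the search (every scored candidate uses the
refined set).

### miRNA seed baseline

For miRNA experiments the objective of the best evolved motif is compared
against the canonical seed matches: DNA reverse complements of miRNA
positions 2–7, 1–7, 2–8, 1–8, matched forward-strand against 3' UTRs.  The
baseline scorer does not apply the set-size constraint — it is a fixed
comparison point, not a search.

## Post-processing

Each reported motif is summarized as a PSSM from the empirical counts of
its exact instantiations in its positive set (reverse-strand hits flipped
into motif orientation; pseudocount 0 by default, configurable for
downstream scanning).  PSSM distance is the average per-position Euclidean
column distance D = (1/w)Σᵢ√(½Σ_L(a−b)²); similarity is 1 − D maximized
over overlap alignments (both orientations in DNA mode) with minimum
overlap 6, relaxed to 5 when either motif is 5 wide.  Two motifs are
redundant when similarity ≥ 0.75 **and** they co-occur within τ = 50 nt
(nearest match starts) in significantly more regions than chance — an
upper-tail hypergeometric test at p ≤ 0.05.  Clustering greedily peels the
top-scoring remaining motif and absorbs everything similar to it
(membership is judged against the representative, not transitively).  The
cluster PSSM is the score-weighted average of member PSSMs aligned to the
representative's frame via their best overlap; negative weights are floored
at zero with a warning.

## Significance

The null distribution of the top score is built by shuffling the evidence
vector across regions (sequences fixed) and re-running the full greedy
search per permutation; a cheap variant (`evolve=False`) scores seeds only.
Π defaults to 100 permutations.  Maxima are summarized by a
maximum-likelihood Gamma fit (scipy's analytic digamma-equation solver;
shape·scale equals the sample mean exactly), which smooths outliers and
extrapolates tail P-values below 1/Π — necessary whenever stringent cutoffs
such as 10⁻⁴ are applied.  Because Gamma support is positive, samples with
non-positive minima are shifted by (min − 10⁻⁶); the offset is recorded and
subtracted before evaluating p = 1 − F_Γ(J − offset).

## ChIP-seq preprocessing

Tabular alignments (read id, chrom, pos, strand, hit count) pass three
filters in order: drop reads with more than four genomic hits; remove
single-base pile-ups (a centered 30-bp window holding more than 10 reads of
which ≥70% start at one base drops that base's reads); cap tags per
location at five.  Called peaks are width-normalized into [100, 1000] bp
with flanks resized proportionally to their distance from the summit, after
discarding extreme-score peaks (default: above the 99.9th score percentile;
the cutoff is configurable because published descriptions of this step are
ambiguous about the intended absolute threshold).  The "ensemble" region
set pools each factor's top 5000 peaks, merges overlapping intervals, and
names regions `chrom:start-end`; factor-specific evidence is the maximum
score among peaks overlapping a region (0 without overlap), then
transformed by the ChIP-seq log-odds above.  Summit-containment vs
any-overlap was an open choice; any-overlap is implemented.

## Synthetic data

The generator emulates the core modeling assumption — a true motif whose
carriers have elevated evidence: i.i.d. sequences under a base composition
(uniform by default), one exact instantiation of the planted IUPAC motif at
a uniform position in ⌈fraction·d⌉ randomly chosen regions, and evidence
Δ·indicator + N(0, sd²).  Defaults (d = 500, 200 nt, TGACTCA planted in
10%, Δ = 3, sd = 1) are the parameter-recovery study conditions.  What it
does **not** emulate: positional and strand biases of real binding sites,
dinucleotide composition and repeats, correlated evidence noise, multiple
or degenerate site instances per region, and co-occurring partner motifs.
Passing recovery tests therefore demonstrates correctness of the machinery
under the model's own assumptions, not field performance on genomic data.

## Problem sizes and numerical choices

The test and reference workloads use deliberately compact designs: full
512-seed searches on d = 500 × 200 nt (seconds on one core); the
permutation-uniformity study uses 300 regions of 300 nt with 6-mer seeds,
no evolution and Π = 100 across 200 replicates, sized so that typical
6-mer positive sets (n ≈ 40) fall inside the [20, 45] constraint window.
Unit fixtures are smaller still.  Score comparisons in the climb are exact
float comparisons (deterministic given deterministic arithmetic);
`sd(E) = 0` defines J = 0 throughout; the Gamma fit refuses fewer than 20
samples or constant samples.  Percentiles use numpy's linear-interpolation
definition.  Reported percentage rates round half away from zero.

## Known limitations

Gapped/spaced and two-block dimer motifs are out of scope, as are PSSM
re-scoring during the search, stochastic search moves, FM-indexes, and
multiple-testing correction across experiments.  Consensus-based search can
under-represent motif degeneracy; the output PSSMs summarize predicted
occurrences and should not be read as quantitative binding-affinity models.
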