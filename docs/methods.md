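# Methods

This note records the models implemented in `srnakit`, the assumptions
behind them, the defaults and why they were chosen, and what the
simulation-backed tests do and do not establish about real libraries.

## SPRI size-selection model

Binding of single-stranded DNA to carboxylated paramagnetic beads is
treated as a purely empirical function e(L, Q) of oligo length L (nt) and
final isopropanol concentration Q (%), at a fixed 7.5% PEG background.
The packaged calibration (`srnakit/data/spri_calibration.tsv`) tabulates
e for seven lengths (19–66 nt) and nine concentrations (30–54.5%);
untested cells are missing values ("ND"), never zeros, and a transcription
guard test freezes the per-row sums of non-missing entries.

Assumptions and numerical choices:

* **Monotonicity.** For fixed L, e is non-decreasing in Q. The packaged
  table satisfies this; loading a table that violates it raises a warning
  (not an error) because the property is empirical, not definitional.
* **Interpolation** is linear in Q between adjacent non-missing cells of
  the same length, and exact at the cells. There is no interpolation
  across lengths: the calibration offers no model of e in L, and
  inventing one would let the planner assert separations that were never
  measured. Queries outside the bracketing cells return "missing".
* **Planning rule.** `plan_separation` scans tabulated concentrations in
  increasing order and returns the first where e(keep) ≥ 40 and
  e(remove) ≤ 5 (defaults). Both cells must be non-missing, directly or
  by interpolation — an untested condition never supports a separation
  claim. Ties resolve to the lowest concentration because short-fragment
  carry-over grows with isopropanol; this maximizes purity of the kept
  fraction at some cost in yield. On failure the error carries the best
  trade-off found, since a user may accept a looser threshold.
* **Mixing equation.** `compute_mix` solves X + 5PV/100 + QV/100 = V in
  closed form, V = X / (1 − 5P/100 − Q/100), where the factor 5 encodes
  the 20% PEG stock. Feasibility requires 5P/100 + Q/100 < 1; infeasible
  requests raise a dedicated error naming the constraint. The solution is
  validated to 1e-9 relative error by a property test.
* **Two-step selection** is expectation-only: elution1 = pool·e1,
  elution2 = (pool − elution1)·e2, discarded = the rest, conserving mass
  per length exactly. Stochastic binding is deliberately left to the
  library simulator's RNG discipline so the planner stays deterministic.

## Library simulator

The simulator is the oracle for everything downstream, so its structure
mirrors the physical process rather than a distributional shortcut:

1. **Population.** Species are distinct random RNA sequences with
   class-specific constraints — miRNA 22–23 nt; 21U 21 nt with 5′ U;
   primary siRNA 26 nt with 5′ G (monophosphate); secondary siRNA
   21–22 nt, 5′ triphosphate; rRNA degradation fragments 20–40 nt.
   Abundances are lognormal (log-mean 3, log-sd 1.2), rounded, min 1 —
   a heavy-tailed mix typical of small-RNA populations, where a few
   species dominate; documented here as a package choice.
2. **Ligation.** Triphosphate species are dropped unless the library is
   flagged as pyrophosphatase (RppH) treated — direct 5′-adapter ligation
   requires a monophosphate. Each remaining molecule ligates with a
   per-species probability drawn from Uniform(0.2, 1), representing
   adapter sequence preference; the magnitude of real ligation bias is
   not well quantified, so the spread is a documented free parameter,
   not a claim.
3. **UMI labeling.** Every ligated molecule draws an 8-nt UMI uniformly
   with replacement from K = 4⁸ = 65 536 labels, so collisions arise
   naturally as the copy/label ratio grows — required to exercise the
   saturation regime the correction model targets.
4. **PCR** is an exact Galton–Watson branching process: each copy
   duplicates per cycle with its species' efficiency, drawn once per
   species from Uniform(0.5, 1). Defaults: 12 cycles. This produces the
   duplicate-family structure that collapsing must undo, unlike a
   lognormal depth shortcut which has no families at all.
5. **Sequencing** samples reads from the amplified pool without
   replacement while the pool lasts (with replacement beyond, i.e.
   resequencing), builds `barcode + UMI + insert(U→T) + adapter`,
   pads with 'A' to 50 bp and truncates; substitution errors only
   (defaults 1e-3; indels are out of scope because trimming and
   alignment are exact-match). Adapter-dimer reads (empty insert, with
   their own UMI) are mixed in at a configurable fraction, default 1%,
   consistent with the <2% these libraries show in practice.

All randomness flows from one seeded `numpy` generator per library;
equal seeds give byte-identical output.

What the simulator does **not** model: 5′-adapter sequence on the read
(the sequencer starts after it by construction), quality-score
structure, indels, position-dependent error profiles, partial-ligation
chimeras, and gel-based protocol artifacts. Tests that pass on simulated
libraries therefore validate the pipeline's bookkeeping and statistics
under the stated bias mechanisms — not robustness to every artifact of
real instruments.

## Read processing

* **Demultiplexing** is an exact match on the read's first 4 bases; the
  prefix is retained because collapsing operates on the full trimmed
  sequence (merge identical sequences *then* strip barcode + UMI —
  stripping first would merge distinct UMIs and undercount molecules).
* **Adapter trimming** scans candidate start positions from the 3′ end
  of the read toward the 5′ end in 1-nt steps and takes the first exact
  match — i.e. the rightmost occurrence. Where the adapter would run off
  the read end, a prefix match of ≥ 5 bases qualifies (configurable);
  with 50-bp reads, a 12-nt barcode+UMI prefix and ≤ 30-nt inserts the
  full adapter is usually present, so the partial rule rarely fires.
  Rightmost-vs-leftmost matters only when an insert itself contains the
  adapter motif — a pathological case either way — so the direction is a
  config switch, defaulting to the scan direction implied by "from the
  3′ end". A brute-force oracle (enumerate all positions, pick the
  rightmost) checks the scan on randomized reads.
* **Statuses.** Empty insert after trimming = adapter dimer; adapter not
  found = kept and reported as `no_adapter` (long RNAs are excluded by
  bead selection upstream, not silently by software); insert shorter
  than 15 nt (the lower edge of the standard small-RNA length window) =
  `too_short`.
* **Collapsing** counts reads per insert (raw) and distinct
  (UMI, insert) pairs per insert (collapsed) within one barcode. It is
  order-invariant and exact-sequence only. Error-tolerant UMI network
  dedup (directional adjacency as in UMI-tools) is an extension point,
  deliberately not implemented: sequencing errors can only split UMI
  families under exact collapsing (inflating collapsed counts), never
  merge them, and the tests pin that direction.

## Quantification

Alignment is exact full-length substring matching (seed-and-verify on
12-mers, equal to a naive scan by construction and by randomized test).
Stranded annotation indexes (mature miRNA, 21U) match the forward strand
only; genome indexes match both strands. Hit gates follow common aligner
policy for this assay: against an annotation set, more than one hit makes
an insert "ambiguous" and excluded from counting (as `-m 1` reports
multireads as unaligned — consequently "did not align to miRNA" includes
miRNA multireads); against a genome, up to 10 hits count the sequence
once (a keep/discard gate, not fractional weighting). Counting runs on
distinct insert sequences with weights so the raw and collapsed flavors
share one alignment pass, and mass is conserved:
assigned + ambiguous + unassigned = total weight. The classification
tiers (genome-aligned → of those, non-miRNA → of those, non-21U) are
nested by construction.

## Statistics

* **Replicate dispersion** is ((hi − lo)/lo)² for a feature's two
  normalized replicate counts (mean over pairs for > 2 replicates) — the
  worked definition under which a 10% difference scores 0.01. It is
  scale-invariant; lo = 0 with hi > 0 returns +inf and all-zero features
  are skipped with this documented. A squared-CV mode (var/mean²) is
  offered as the quantity a standard NB dispersion estimator targets;
  the relative-difference form is the package default because it
  reproduces the worked example exactly.
* **Normalization** is median-of-ratios: factor_j = median over
  all-positive features of count_ij / geometric-mean_i. Note the factors
  themselves are only defined up to the geometric-mean anchor — scaling
  one of m libraries by c multiplies its factor by c^(1−1/m) and the
  others by c^(−1/m); the factor *ratios* scale by c and normalized
  counts are invariant, which is what the tests assert.
* **Differential expression** fits, per feature, a pooled NB dispersion
  α by method of moments (var = μ + αμ², floored at 1e-8 for degenerate
  zero-variance features) and tests equality of group means with a Wald
  statistic on log means, delta-method variance
  Var(log μ̂) ≈ (1/n)(1/μ + α). A group mean of zero gets a half-count
  continuity floor (0.5/n) inside the statistic to stay finite; the 0.5
  pseudocount otherwise appears only in the reported log2 fold change.
  Calls require |fold| ≥ 5 and BH-adjusted p < 0.01; "up" means higher
  in the second condition, which the CLI makes explicit via
  `--reference`/`--contrast`. Method-of-moments with 3 replicates is
  noisy but unbiased enough for the large effects these thresholds
  target; shrinkage is out of scope. A cross-check test shows ≥ 0.8
  Jaccard agreement of called sets with an independent full NB-GLM
  implementation (pydeseq2) on simulated data.
* **UMI saturation.** n molecules drawing uniformly from K labels show
  E[d] = K(1 − (1 − 1/K)^n) distinct labels; the estimator
  n̂ = −K ln(1 − d/K) inverts this in expectation. The analytic
  undercount 1 − E[d]/n rises from ~9% to ~25% as the copy/label ratio
  goes 0.2 → 0.6, which is why 8-nt UMIs under-report the most abundant
  species at high depth; the model is verified against Monte Carlo to
  0.5% and the round trip recovers n to 0.5% for n ≤ K/2. Beyond
  d = K the correction is undefined (saturated) and raises.
* **Adapter bias** between two barcode libraries is
  |log2((c1 + 0.5)/(c2 + 0.5))| per feature on normalized counts, with
  the pseudocount keeping zero-count features finite. The direction —
  collapsing reduces the between-barcode bias — is the tested claim; the
  metric itself is a reasonable stand-in, as no canonical definition
  exists, so its magnitude is not asserted anywhere.
* **Chi-square** on 2×2 tables is Pearson's without continuity
  correction, df = 1, zero margins rejected.

## Pipeline and problem sizes

`run_pipeline` is a pure function of (inputs, config, seed): simulate or
ingest, demultiplex, trim, collapse, count against the miRNA reference
(simulation mode derives it from the simulated population when no FASTA
is supplied), then dispersion summaries, truth correlations and an
optional two-condition DE table. Sub-seeds are spawned from the run seed
(kept below 2³¹), so reports are byte-identical across reruns.

Tests and examples run simulations of 40–150 species and 2 000–10 000
reads with 6–12 PCR cycles — sizes at which every property under test
(truth recovery, bias direction, dispersion ordering, DE power) is
already well resolved while the whole suite stays fast. The Monte-Carlo
check of the UMI model uses 10⁵ trials at n = 64, K = 256.

## Known limitations

* The calibration covers 19–66 nt ssDNA; RNA binding and lengths 60–100
  nt would need their own table (the loader accepts any TSV in the same
  format).
* Exact-match alignment cannot place reads with sequencing errors;
  error-bearing reads inflate the unaligned tally rather than being
  rescued, and UMI errors inflate collapsed counts (bounded and
  direction-tested, not corrected).
* The DE module is two-group only, no covariates, no shrinkage.
* The planner never extrapolates beyond tabulated concentrations — by
  design it will refuse conditions a bench scientist might confidently
  extrapolate (e.g. a 58-nt fragment above 44% isopropanol).
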