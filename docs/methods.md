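# Methods

## Study design and model

The pipeline analyzes a paired longitudinal design: animals in four groups
(condition CT or LPS × endpoint T50 or T90, six animals per group), each
sampled at baseline T0 and at its endpoint, each sample acquired in technical
duplicate, and every sample spiked with a fixed amount of yeast enolase
(P00924) as an internal standard. Because each animal is its own control, the
inferential unit is the per-animal paired log2 fold change of
spike-normalized, replicate-averaged intensity, endpoint vs T0. No
distributional model is fitted: the deregulation call is a count rule, chosen
for robustness at n = 6 where parametric moderation is fragile and the paired
design already removes between-animal level differences.

## Stages, parameters and defaults

1. **Spike normalization** (`normalize_to_spike`). Sample *j* is divided by
   `spike_j / geomean(spike)`. The geometric-mean reference makes the output
   invariant to sample order and keeps intensities on their original scale.
   Note that rescaling one raw column (spike included) changes the geometric
   mean, so the normalized matrix changes by a single global constant rather
   than being literally unchanged; every downstream ratio, and hence every
   DEP call, is exactly invariant. The operation is idempotent to 1e−12.
   Spike missing or non-positive in any sample is a hard error — the standard
   is added to every sample, so its absence indicates a broken export.
2. **Replicate collapsing** (`collapse_tech_reps`). Arithmetic mean of the
   observed replicate intensities (not the log-mean; configurable by
   averaging logs upstream if desired); the collapsed value is missing only
   when all replicates are missing. Collapsing after normalization means the
   replicates being averaged are already on a common signal scale.
3. **Quantifiability filter**: keep proteins with ≥ 2 unique peptides and
   identification quality score ≥ 6 (both boundaries inclusive).
4. **Missingness filter**: a protein is removed if any (group × time point)
   cell of six animal-level columns contains more than 2 missing values
   (i.e. ≥ 3 NA). The cell is defined after replicate collapsing.
5. **Coverage filter**: keep sequence coverage ≥ 15 %. The inclusive
   boundary follows the rule "below 15 % is withdrawn"; an exclusive variant
   is a one-line configuration change (`min_coverage_pct`).
6. **DEP call** (`call_dep`): up if ≥ 4 of the 6 animals have Log2FC ≥ +1,
   down if ≥ 4 have Log2FC ≤ −1 (boundaries inclusive; threshold and quorum
   configurable). Up and down tallies are counted independently; at the 4-of-6
   default they can never both reach quorum. Animals with a missing fold
   change count toward neither tally and the denominator stays at the group
   size — the rule is an absolute count, not a proportion of observed
   animals, so missingness can only make a call harder. Summary statistics
   (median, min, max) are computed over the qualifying animals only, with
   "min" the qualifying value nearest the threshold (smallest magnitude) and
   "max" the most extreme.
7. **Control exclusion**: any protein deregulated (either direction) in the
   time-matched CT group is removed from that endpoint's LPS DEP list.
   Exclusion is per endpoint; a protein control-deregulated only at T90 still
   counts at T50.
8. **Partitioning**: the two endpoints' retained identification lists are
   split into common / T50-specific / T90-specific by set intersection and
   difference. The universe of the partition is the union of the two retained
   lists.
9. **Over-representation** (`enrich`): hypergeometric upper tail
   P(X ≥ k) per term, equivalent to one-sided Fisher exact;
   Benjamini–Hochberg adjustment across tested terms; terms with fewer than
   2 universe members are skipped. The universe is the set of proteins
   surviving the funnel at that endpoint, not the whole proteome — a
   detection-conditioned background avoids trivially enriching abundant
   plasma proteins. Up- and down-regulated sets are tested separately.

Each filter returns a `FilterReport` (stage, n_before, n_after, removed ids);
the orchestrator asserts the chain is gap-free and records it in the run
manifest. The manifest contains the analytic configuration and its hash, the
seed, per-stage counts and output names, but no wall-clock state, so a rerun
with identical inputs is byte-identical.

## Synthetic data: what it emulates, what it does not

`generate_dataset` draws per-protein log-normal baselines (log10 mean uniform
on [4, 8]), animal-level biological variation (sd 0.20 log10), an endpoint
biological noise of sd 0.30 on the log2 fold change, multiplicative
technical-replicate noise (sd 0.05 log10), and per-sample global scale
factors log-uniform on [0.5, 2] applied to all rows including the spike — so
the normalization stage is load-bearing, not decorative. Planted effects
multiply an animal's endpoint value by 2^(±effect_log2fc) (default magnitude
2) for 5 % up and 5 % down proteins in the LPS groups; 2 % "control drift"
proteins receive the effect in every group and are the known targets of the
control-exclusion stage. Missing values are injected at an overall rate of
10 % with probability proportional to `logistic(−mnar_strength · z(log10
intensity))`, emulating the low-abundance dropout that dominates plasma
label-free data. Planted counts use `floor(n_proteins × fraction)` so they
are deterministic. A small fraction (5 %) of proteins is emitted with one
peptide or a sub-6 score to exercise the quantifiability filter, and coverage
is uniform on [5, 95] % so the coverage filter removes a predictable slice.

All noise knobs are configuration fields; setting the biological and
technical sds and the missing rate to zero yields data in which the
per-animal post-normalization log2 ratio of a planted protein equals the
planted effect to floating-point tolerance — the form in which the
exactness invariant is tested. With the default noise on, the planted effect
of magnitude 2 against sd 0.30 noise is recovered with sensitivity 1 and the
count rule cannot fire for null proteins whose noise stays below the
threshold in three or more animals; both properties are asserted.

The generator does not simulate spectra, peptides, retention-time drift,
shared-peptide ambiguity, batch structure beyond the per-sample scale factor,
or correlated missingness between technical replicates. Passing tests
therefore demonstrate the correctness of the pipeline's logic under a clean
intensity model, not the behaviour of any upstream identification software
on real acquisitions.

## Reference fixtures

The package ships the 43 per-protein DEP summaries reported for the rat
LPS-shock plasma secretome experiment the defaults reproduce (identification
set, endpoint, direction, Log2FC median, min, max, n of 6). Blank n/6 cells
in the source tables are carried down from the row above, which reproduces
the per-section prose counts. Because only summaries are published,
six-animal vectors are reconstructed deterministically as
`[min] + [median]·(n−2) + [max]` for the qualifying entries (the median of
that multiset equals the printed median whenever min ≤ median ≤ max) and 0
for the 6−n non-qualifying entries.

Three source rows are internally inconsistent and flagged: two have medians
whose sign contradicts their (min; max) range (direction is taken from table
placement, vectors built from absolute magnitudes with that sign) and one has
a median outside its own range (the median fill is clamped to the nearer
range boundary). All 43 rows reproduce their printed direction and n/6 when
re-called; the 40 consistent rows also reproduce median, min and max exactly.
Re-calling the vectors yields the headline counts: 10 DEP at T50 (5 up and 1
down in the common set, 3 up and 1 down T50-specific) and 33 at T90 (10 up
and 12 down common, 1 up and 10 down T90-specific) — the numbers
`scripts/acceptance.py` recomputes.

The identification-scale counts of the source experiment (401/514 proteins
quantified, 140/132 retained, 79 common, 14 control-excluded) depend on the
deposited raw acquisitions and are not reproducible from summaries; the suite
covers that ground with property-based tests instead (brute-force caller
agreement on 10,000 random vectors with missing entries, planted-effect
recovery, per-sample scale invariance of all calls, funnel-chain consistency,
Fisher agreement of enrichment p-values, end-to-end determinism). The source
prose also contains two internal count discrepancies — a 57 vs 61
T50-specific count against its own arithmetic, and a 10 vs 11 T50 DEP total
between summary and discussion — which this package does not attempt to
reconcile; set arithmetic and the summary tables govern.

## Numerical choices and degenerate inputs

Missing values are an explicit marker ("NA" on disk, NaN in memory), never
zero; an observed zero intensity inside a paired comparison is a hard error
because its log-ratio is undefined — silent dropping would masquerade as
missingness. Boundary values qualify at every threshold (score 6.0, coverage
15.0, |Log2FC| = 1.0 all pass). Ties in result-table ordering are broken by
accession for determinism. `min_qualifying` larger than the group size is
rejected before any computation. Empty matrices pass through the filters as
empty tables with headers. Simulation problem sizes in the tests (80–400
proteins, 24 animals, 96 samples) were chosen as the smallest sizes at which
every planted class is populated and group-level behaviour is stable.

## Known limitations

- The count rule reports no error control; it is a reproduction of a
  screening protocol, not a calibrated test. Moderated-variance testing is
  deliberately out of scope.
- Fixture vectors are *a* consistent reconstruction, not the unpublished
  per-animal values; any statistic beyond direction, n, median, min and max
  (e.g. the mean) is not faithful to the source data.
- Enrichment treats annotation as a flat table: no ontology DAG traversal,
  redundancy reduction, or protein-network clustering.
- The normalization trusts a single spike protein; a degraded spike biases
  all intensities in a sample. Multi-standard or median-sweep normalization
  is not implemented.
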