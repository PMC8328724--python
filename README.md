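# secretodep

A tested, reusable pipeline for paired label-free quantitative proteomics of
the plasma secretome: from protein-level intensity matrices to
deregulated-protein (DEP) calls, control-based exclusion, time-point set
partitioning, per-protein summary tables, and term over-representation
analysis.

The design it targets is a longitudinal shock experiment in which each animal
is its own control: four groups (CT50, LPS50, CT90, LPS90) of six rats,
each sampled at baseline (T0) and at one endpoint (50 or 90 minutes after
lipopolysaccharide or vehicle injection), every sample measured in technical
duplicate, and a fixed amount of yeast enolase (UniProt P00924) spiked into
every sample as an internal standard.

## Method

For protein *p* and animal *a* in a group, the statistic is the paired log
fold change on spike-normalized, replicate-averaged intensities

    Log2FC(p, a) = log2( I(p, a, Tend) / I(p, a, T0) )

where each sample column was first divided by its spike signal relative to
the geometric mean of the spike across samples. Before calling, proteins pass
an inclusion funnel: quantified from ≥ 2 unique peptides with identification
score ≥ 6, at most 2 missing values in every 6-animal (group × time point)
cell, and sequence coverage ≥ 15 %.

A protein is called deregulated in a group when

    #{a : Log2FC(p, a) ≥ +1} ≥ 4    (up)    or
    #{a : Log2FC(p, a) ≤ −1} ≥ 4    (down)

out of the 6 animals (missing fold changes count toward neither tally and the
denominator stays 6). Proteins deregulated in the time-matched control group
are excluded. The retained identification lists of the two endpoints are
partitioned into common, T50-specific and T90-specific sets, summarized as
median (min; max) over the qualifying animals with *n*/6, and each DEP set is
tested for term over-representation with the hypergeometric upper tail
against the detected-protein universe, Benjamini–Hochberg adjusted.

All thresholds (spike accession, peptide/score/coverage/NA cutoffs, fold
change threshold, quorum) are configurable; the defaults above are the
reference protocol. A synthetic-data generator with planted ground truth
(effect sizes, control-drift proteins, MNAR missingness, per-sample scale
drift) makes every stage testable without raw mass-spectrometry data.

## Worked example

```sh
secretodep simulate --out-dir demo --seed 3 --n-proteins 80
secretodep run-all --quant demo/quant.tsv --design demo/design.tsv \
    --gmt demo/annotations.gmt --out-dir demo/results --seed 3
```

prints

```json
{
  "n_common": 66,
  "n_t50_specific": 0,
  "n_t90_specific": 0,
  "n_control_excluded": 1
}
```

i.e. of the 80 simulated proteins, 66 survived the funnel at both endpoints
(endpoint-specific sets arise from endpoint-specific missingness and are
empty at this small, lightly-missing size), and 1 protein was dropped because
it was also deregulated in a control group (it was planted as a control-drift
protein). `demo/results/` then contains the per-set DEP tables
(`common_t50.tsv`, …, each row an accession with direction, Log2FC
median (min; max) over qualifying animals and *n*/6), the machine-readable
`dep_calls.tsv`, per-endpoint enrichment tables, a `filter_report`-style
funnel audit inside `manifest.json`, and the manifest itself (config hash,
seed, per-stage counts). Reruns with the same inputs and seed are
byte-identical.

The packaged reference fixtures — the published per-protein DEP summaries the
pipeline's defaults reproduce, with six-animal fold-change vectors
reconstructed from each row's median/min/max/n — are written by

```sh
secretodep make-fixtures --out-dir fixtures
```

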