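# brainrev

Temporal-asymmetry (irreversibility) analysis of parcellated brain time
series, with a synthetic cohort generator for testing and calibration.

The core statistic compares lag-`T` Pearson correlations of a multivariate
signal with those of its time-reversed copy. Correlations are mapped through
the Gaussian mutual-information transform `-0.5 * ln(1 - r^2)`; the
elementwise squared difference of the forward and reversal matrices measures
departure from detailed balance, and its mean is the global irreversibility
`I`. Evaluated over sliding windows (default: 90 timepoints, 85 overlap),
each subject is summarized by the mean of the per-window values (*average
reversibility*) and their sample standard deviation (*deviation
reversibility*, a non-stationarity measure). The same statistic restricted
to network blocks of a 7-network parcel atlas yields within/between-network
summaries. Groups are compared with two-sided Mann-Whitney U tests under
Benjamini-Hochberg FDR correction.

## Library overview

| module | contents |
|---|---|
| `brainrev.core` | `shifted_pearson`, `pairwise_irreversibility`, `fs_matrix`, `reversibility_matrix`, `global_irreversibility` |
| `brainrev.windows` | `WindowingScheme`, `make_windows`, `subject_profile` |
| `brainrev.networks` | `submatrix_irreversibility`, `network_profile` |
| `brainrev.stats` | `ranksum_test`, `bh_adjust`, `compare_global`, `compare_networks`, `binarize_significance` |
| `brainrev.synthetic` | `make_default_atlas`, `asymmetric_coupling`, `simulate_var_subject`, `simulate_cohort`, `study_like_spec` |
| `brainrev.io` / `brainrev.pipeline` / `brainrev.cli` | TSV formats, orchestration, CLI |

Notable conventions (each has a config switch):

* **Window count** is `floor((L - W) / step)` — one fewer than the usual
  convention; the last admissible window is dropped. This reproduces the
  reference counts 195 -> 21 and 175 -> 17 windows.
  `include_final_window=True` restores the usual convention.
* **Correlation estimator**: segment-normalized sample Pearson on the
  `L - T` overlapping pairs (default). Under it the reversal FS matrix is
  exactly the transpose of the forward one — this identity is used as a test
  oracle. An alternative `full_window` estimator normalizes by whole-window
  moments, under which the identity holds only to `O(1/L)`.
* The global mean includes the (zero) diagonal; `include_diagonal=False`
  excludes it.

## Synthetic cohorts

`simulate_var_subject` draws from a lag-1 Gaussian VAR whose coupling matrix
interpolates between symmetric (time-reversible, `asymmetry=0`) and fully
directed (`asymmetry=1`); a slow multiplicative envelope on the coupling
scale (amplitude = `nonstationarity`) makes the windowed asymmetry
fluctuate. `study_like_spec` builds a three-group cohort (CNT n=13 / 195
timepoints, MCS n=31 / 175, UWS n=24 / 175) with graded asymmetry and
non-stationarity.

## CLI

```sh
brainrev simulate --out data/ --seed 1 --regions 100      # cohort + manifest + atlas
brainrev run --manifest data/manifest.tsv --atlas data/atlas.tsv --out results/
# or stepwise (composes to identical tables):
brainrev cohort --manifest data/manifest.tsv --atlas data/atlas.tsv --out profiles/
brainrev stats --profiles profiles/ --out stats/
brainrev report --profiles profiles/
```

Flags mirror the analysis config: `--shift`, `--window`, `--overlap`,
`--alpha`, `--estimator`, `--include-final-window`, `--zero-variance`,
`--seed`.

File formats (all tab-separated text): time series files have a header row
of region ids and one row per timepoint; the atlas maps `region_id` to
`network`; the manifest lists `subject_id`, `group`, `path` (relative paths
resolved against the manifest's directory).

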