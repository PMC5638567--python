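# File formats

All inputs and outputs are plain text. Numbers in TSV outputs carry 6
significant digits; JSON outputs keep full precision. Frequencies are
fractions in [0, 1] in machine outputs.

## Fluorescence CSV (input)

Long format, header required, one row per well × channel × cycle.

| column       | type   | notes                                   |
|--------------|--------|-----------------------------------------|
| well         | str    | plate well label, e.g. `S03R1`          |
| cycle        | int    | 1..n, consecutive per well × channel    |
| channel      | str    | `FAM` or `VIC` (case-insensitive)       |
| fluorescence | float  | raw instrument units                    |

Duplicate (well, channel, cycle) rows, unknown channel labels, missing
columns and non-numeric fluorescence are rejected with the offending row
named.

## Sample sheet CSV (input)

One row per well.

| column    | type  | notes                                              |
|-----------|-------|----------------------------------------------------|
| well      | str   | unique; must exist in the fluorescence CSV         |
| role      | str   | `STANDARD` or `UNKNOWN`                            |
| x_true    | float | required for STANDARD: known mixture fraction [0,1]|
| sample_id | str   | required for UNKNOWN                               |
| tissue    | str   | required for UNKNOWN (e.g. ovary, brain, gill, gDNA)|
| replicate | int   | technical replicate index (1-based)                |

## k′ table TSV (`taqase fit`, pipeline `kprime.tsv`)

Columns: `well, branch, r_prime, k_prime` (pipeline output adds the
per-channel fit parameters `a/b/c/y0_fam`, `a/b/c/y0_vic`). `branch` is
`EQ1` (FAM inflected first), `EQ2` (VIC first) or `TIE`.

## Precomputed k′ TSV (`taqase calibrate --from-kprime`)

Columns `x_true` and `k` (or `k_mean`), one row per replicate (or per
standard if pre-averaged). `x_true` may be a fraction or a percentage;
values > 1 are interpreted as percent.

## Estimates TSV (pipeline `estimates.tsv`)

`sample_id, tissue, n_replicates, k_mean, x_hat, clamped`.

## Statistics report JSON (pipeline `stats.json`, `taqase report`)

Keys: `calibration` (assay, slope, intercept, r_squared, n_points,
excluded_pure), `tissues` (per-tissue n, mean_x, sd_x, t/p against 0.5,
significance flag), `anova` (F, dfs, p, Tukey-adjusted pairwise p).

## Pipeline log JSON (`pipeline_log.json`)

One record per analysed well: branch taken, k′, truncation cycles and
convergence flags for both channels; plus records for skipped wells
(`no_amplification`, `fit_error`, `missing_channel`) and clamped
estimates. Sufficient to reconstruct every number in the results bundle.

## Promoter FASTA (input/output)

Multi-record FASTA over the alphabet A, C, G, T, N (case-insensitive).
`taqase variants` aligns the first two records.

## Variants TSV (`taqase variants`)

`seq_a_id, seq_b_id, position, kind, allele_a, allele_b` — `position` is
1-based on the first sequence; `kind` is SNP, INSERTION or DELETION; one
allele string is empty for indels.

## Islands TSV (`taqase cpg`)

`seq_id, start, end, length, gc, obs_exp` — 1-based inclusive coordinates;
`gc` and `obs_exp` are fractions recomputed over the merged region.
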