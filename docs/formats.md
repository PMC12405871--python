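# Tabular formats

All tables are RFC-4180 CSV with a header row, UTF-8 encoded, with a
locale-independent decimal point. Unicode minus signs (U+2212) in numeric
fields are normalized to ASCII `-` on input. Schema version: 1.

## `germination`

One row per seed sample.

| column | type | notes |
| --- | --- | --- |
| `sample_id` | text | unique per sample |
| `rc_dosage` | int in {0,1,2} | functional-allele dosage at the first locus |
| `pb_dosage` | int in {0,1,2} | dosage at the second locus |
| `n_total` | int > 0 | seeds in the sample |
| `d<day>` ... | int >= 0 | one column per counting day, e.g. `d2..d7` or `d3,d5,d7` |

Day columns hold *incremental* counts (seeds newly germinated on that day).
Pass `--counts cumulative` (CLI) or `counts="cumulative"` to difference
running totals at ingestion; decreasing cumulative sequences are rejected.

## `f2_phenotype`

One row per plant/observation, for `digenic fit`.

Required: `rc_dosage`, `pb_dosage`. The response column is named with
`--response` (e.g. `gp`, `gi`, or a flavonoid content column). The
`genotype_time` model additionally needs a two-level development-time column
(default name `dpa`).

## `imbibition` (long format)

One row per sample x time point.

| column | type | notes |
| --- | --- | --- |
| `sample_id` | text | groups rows into series |
| `rc_dosage`, `pb_dosage` | int in {0,2} | homozygous classes only |
| `time_h` | float | hours after soaking, strictly increasing per sample |
| `weight` | float >= 0 | sample weight (g); requires `w0` |
| `w0` | float > 0 | initial dry weight (g) |
| `wc` | float | ready-made water-content fraction (alternative to `weight`/`w0`) |

Use `--input-kind weight` (default) or `--input-kind wc`.

## `flavonoid`

One row per replicate measurement: `rc_dosage`, `pb_dosage`, `dpa`,
`chemical`, `replicate`, `value` (ug/g), optional `detected` (bool).
Non-detectable measurements are exact zeros with `detected=False`.

## `fit_report`

Output of `digenic fit` / `write_fit_report`; columns `term`, `effect`,
`se`, `p_value`, `r2`, `entry_order`. Rows: `mu` (model mean), one row per
retained term in entry order, `Total` (model R2), plus `_meta`
(residual variance, n) and `_model` bookkeeping rows. Numbers are written
with full precision (`repr`) so a read-back is bit-exact.

## Simulation config (YAML)

Mirrors `digenic.synthetic_data.SimulationConfig`:

```yaml
seed: 0            # overridden by --seed
n: 259             # population / sample budget
mu: 78.6           # background of the phenotype simulator
effects: {a1: -15.0, d1: -3.9, a2: -8.2, i_a1a2: -6.2}
residual_sd: 14.0
germination:
  n_total: 60
  schedule: [2, 3, 4, 5, 6, 7]
  horizon: 7
  per_genotype:        # keys are "<rc_dosage>:<pb_dosage>"
    "0:0": {p_g: 0.82, mean_day: 2.6, dispersion: 0.6}
    "2:2": {p_g: 0.16, mean_day: 4.2, dispersion: 0.6}
imbibition:
  breakpoints: [28.0, 52.0]
  slopes: [0.0115, 0.0008, 0.0030]
  noise_sd: 0.004
  w0: 2.0
  effects:             # term -> [size on wc scale, onset hour]
    a1: [-0.010, 28.0]
    a2: [-0.012, 6.0]
flavonoid:
  n_replicates: 3
  detect_floor: 0.0
  cells:               # keys are "<rc>:<pb>:<dpa>"; null = not detectable
    "2:0:40": {CA: [10167.0, 637.0], PB3: [3072.0, 168.0]}
```

Omitted sections fall back to the shipped reference defaults
(`digenic.reference`, `digenic.synthetic_data.default_config`).
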