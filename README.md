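# digenic

Quantitative-genetics toolkit for two-locus (digenic) seed phenotypes:
germination dormancy statistics, orthogonal-contrast linear models with
forward selection and sequential variance partitioning, imbibition
time-course analysis, and seeded simulators for every input format.

The package targets experiments built around four homozygous introgression
lines (a 2x2 functional-allele design), an F2 population from selfing a
double heterozygote, genotype-by-development-time flavonoid panels, and
triphasic seed water-uptake curves.

## What it computes

- **metrics** — cumulative germination percentage (GP), the weighted
  germination index (GI, weight `T+1-d` for day `d` with horizon `T`),
  seed water content `(w_i - w0)/w0`, and `2^-dCt` relative expression.
- **genetic_design** — orthogonal contrast coding (additive `-1/0/+1`,
  dominance `+0.5/-0.5`, two-level time `0/1`), design matrices for three
  model families (`additive`, `f2`, `genotype_time`), and an orthogonality
  report of centered column inner products.
- **model_fitting** — OLS with partial F/t tests, forward selection at a
  configurable alpha (default 0.05), sequential R2 increments in entry
  order, dominance ratios `|d/a|`, and exact moment-matched replicate
  reconstruction from published cell means/SEs.
- **timecourse** — per-timepoint digenic fits of water-content panels
  (effect trajectories with significance flags) and three-phase piecewise
  linear segmentation of the background trajectory by exhaustive breakpoint
  search on the measurement grid.
- **synthetic_data** — seeded generators for F2 genotypes (independent
  1:2:1 segregation), linear-model phenotypes, daily germination counts
  (discretized-logistic timing), flavonoid replicate panels with
  non-detect handling, and triphasic imbibition curves with genotype
  effects switching on at configurable onset times.
- **io / cli** — validated CSV readers/writers (see `docs/formats.md`) and
  a `digenic` command with `metrics`, `fit`, `timecourse`, and `simulate`
  subcommands.

`digenic.reference` ships the published summary statistics (class means,
flavonoid cell means/SEs, fitted effects) used as simulator defaults and as
frozen inputs for deterministic re-analysis.

## CLI examples

```sh
# simulate an F2 germination-percentage dataset and fit the full digenic model
digenic simulate f2 --seed 11 -o f2.csv
digenic fit f2.csv --model f2 --response gp -o fit_report.csv

# germination metrics from a counts table (days d2..d7 or d3,d5,d7)
digenic simulate germination --seed 3 -o germ.csv
digenic metrics germ.csv -o gp_gi.csv

# imbibition panel: per-timepoint effect trajectories + phase segmentation
digenic simulate imbibition --seed 4 -o imb.csv
digenic timecourse imb.csv -o trajectory.csv --segmentation phases.csv

# genotype x development-time flavonoid model with forward selection
digenic fit flavonoids.csv --model genotype_time --response value -o report.csv
```

Exit codes: 0 success, 2 validation/input error, 1 internal error.

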