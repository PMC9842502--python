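# croplandn

Cropland is the dominant source of global nitrogen pollution: more than
half of the nitrogen applied to fields is lost to the air (NH₃, NOₓ,
N₂O) and to water (nitrate leaching and runoff) instead of leaving in
the harvest.  `croplandn` is a pipeline for asking, quantitatively, what
a package of on-farm management measures — enhanced-efficiency
fertilizers, organic amendments, legume rotation, buffer zones, the 4R
fertilizer-stewardship practices, new cultivars, no-tillage, optimized
irrigation — could do about it, and what that would cost and be worth.

It is written for agro-environmental modellers and agricultural
economists who want each link of that chain as a tested, reusable
library component rather than a spreadsheet.

## What it computes

**Effect sizes.** Each field trial contributes a response ratio
r = x̄_t / x̄_c (treatment over control mean), analysed as ln r and
reported as the percentage change (r − 1) × 100.  Per measure × outcome
cell the estimate is the unweighted mean of log ratios with a 95%
bootstrap confidence interval (4,999 resamples; bias-corrected
percentile endpoints with a t-calibrated expansion); an effect is
substantial when the interval excludes zero.

**N budgets.** Per region, total input
N_input = N_fer + N_man + N_fix + N_dep + N_irr and output
N_output = N_harvest + N_gas + N_leach + N_runoff; nitrogen use
efficiency NUE = N_harvest / N_input; a target input
N_harvest,target / NUE_target and the signed surplus against it.

**Abatement.** The reduction of loss pathway j in region i by measure k
is ΔE = A × EF × η × X — activity times uncontrolled emission factor
times abatement efficacy (from the meta-analysis) times implementation
rate.  Measures add unless an interaction table supplies a joint
efficacy; adoption stops once a region reaches its NUE target.  The
fertilizer balance closes via ΔN_fer = ΔN_input + ΔN_man − ΔN_dep with a
non-negativity clamp on post-mitigation fertilizer use.

**Money.** Implementation cost IC = ΔE × UC; societal benefit
SOC = EH + HH + YD + GHG, where the ecosystem term transfers US unit
damage costs through willingness-to-pay and per-capita-GDP ratios,
health and climate terms price each loss form (climate prices are
signed: abating NH₃/NOₓ forgoes aerosol cooling), and the yield term
prices the extra harvested N.  Fertilizer savings offset part of the
gross cost; uncertainty is propagated by Monte Carlo (mean ± 1 SD).

**Scenarios.** BAU and three cumulative tier packages projected to 2050
under a common harvest-demand trajectory, with NUE, fertilizer use,
area and losses per region-year.

A synthetic-data module generates all five input table families
(observations, budgets, measures, economic parameters, scenario tables)
with known ground truth, so everything downstream is testable end to
end without any external data.

## Worked example

```python
from croplandn import RunConfig, run_study

cfg = RunConfig(seed=42, n_regions=6, n_draws=500)
res = run_study(cfg)

eef = next(e for e in res.effects
           if e.measure == "EEF" and e.outcome == "total N loss")
print(f"EEF effect on total N loss: {eef.mean_pct_change:+.1f}% "
      f"(95% CI [{eef.ci_low:+.1f}, {eef.ci_high:+.1f}], n={eef.n_obs})")
print(f"Global NUE: {res.global_nue():.2f} -> {res.global_nue(post=True):.2f}")
g = res.cba_global
print(f"Net mitigation cost: {g.net_cost/1e9:.2f} B USD "
      f"(gross {g.ic/1e9:.2f} - fertilizer saving {g.fertilizer_saving/1e9:.2f})")
print(f"Societal benefit: {g.soc/1e9:.2f} B USD "
      f"({g.soc/g.net_cost:.1f}x the net cost)")
```

prints

```
EEF effect on total N loss: -40.1% (95% CI [-45.9, -32.4], n=17)
Global NUE: 0.59 -> 0.78
Net mitigation cost: 1.68 B USD (gross 2.34 - fertilizer saving 0.66)
Societal benefit: 17.60 B USD (10.5x the net cost)
```

The enhanced-efficiency-fertilizer cell was generated with a true −47%
effect; the estimate and interval recover it from 17 noisy
observations.  Applying the estimated package raises the six-region
world's NUE from 0.59 to 0.78, and the monetized societal benefit
exceeds the net implementation cost roughly tenfold — fertilizer savings
alone repay about a quarter of the gross cost.

The same chain is available from a shell, stage by stage or end to end:

```sh
croplandn all --seed 42 --n-regions 6 --out out/
croplandn validate --observations out/observations.csv
```

which writes the documented CSV tables (`observations.csv`,
`effects.csv`, `budget_summary.csv`, `reductions.csv`, `cba.csv`,
`trajectories.csv`, …) plus a JSON manifest that reproduces the run.

## Layout

| module                 | contents                                             |
| ---------------------- | ---------------------------------------------------- |
| `croplandn.synthetic`  | ground-truth synthetic tables for all input families |
| `croplandn.meta`       | response-ratio meta-analysis, bootstrap CIs          |
| `croplandn.budget`     | N mass-balance budgets, NUE, targets, surpluses      |
| `croplandn.mitigation` | ΔE = A·EF·η·X, measure combination, fertilizer chain |
| `croplandn.econ`       | costs, four benefit streams, Monte-Carlo spreads     |
| `croplandn.scenario`   | tier filtering and 2050 trajectories                 |
| `croplandn.io`         | CSV schemas, validation, manifests                   |
| `croplandn.pipeline`   | stage orchestration (`run_study`, `run_pipeline`)    |
| `croplandn.cli`        | `croplandn` command                                  |

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
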