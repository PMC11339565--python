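# infodemic

Stochastic SIR modelling of health-misinformation spread and of the
question: **when must an official intervention happen to shorten a fake
news outbreak?**

When a health rumour (for instance, a miracle-cure claim circulating
among cancer patients) spreads through an online community, authorities
can respond with warnings and debunking statements — but how much the
response helps depends on *when* it lands.  `infodemic` models the
rumour as a discrete-time stochastic epidemic and measures how the
**duration of circulation** (days until no believers remain) depends on
the intervention day.

## Model

A population of N agents is split into susceptibles S, believers I and
fact-checkers R (S + I + R = N).  One tick is one day.  Each day

* ΔS→I ~ Binomial(S, 1 − (1 − β·I/N)^c) — each susceptible makes c
  contacts; a contact with a believer transmits belief with probability β;
* ΔI→R ~ Binomial(I, γ) — each believer fact-checks with probability γ,

the chain-binomial (Reed–Frost-type) discretization of the SIR system,
with basic reproduction number R₀ = β·c/γ.  An intervention on day T
multiplies γ by κ and β by ρ from that day on.  Defaults emulate a
moderate rumour in a community of 6000: β = γ = 0.05, with the
unobservable contact rate c, seeding i0 and intervention strength κ
calibrated by grid search against two observed circulation durations
(278 days without intervention, 247 days with a day-100 intervention),
subject to the constraint that the intervention tips the spread
subcritical.  Earlier intervention days (54, 16, 10) are genuine
out-of-sample predictions.  A mean-field ODE solver and the classical
final-size equation z = 1 − e^(−R₀z) serve as analytic oracles.

## Worked example

```python
import infodemic as inf

p = inf.ModelParams(contacts=1.05, i0=5)          # calibrated point
table = inf.sweep([None, 100, 10], p, gamma_mult=1.25,
                  n_reps=100, base_seed=20190903)
print(table.table)
res = inf.compare(table.samples[0], table.samples[2])
print(res.statistic, res.p_value, res.significant)
```

prints

```
scenario  intervention_day    n  mean_days    sd_days      ci95  censored
    none               NaN  100 275.882979 259.393911 53.129014         6
 day-100             100.0  100 181.130000 133.827165 26.554213         0
  day-10              10.0  100 113.410000 100.868561 20.014511         0
5.68 9.60e-08 True
```

Each row summarizes 100 seeded replicates of one scenario (scenarios
share replicate seeds, so differences are due to the intervention day
alone): without intervention the rumour circulates for ~276 days on
average; intervening on day 10 cuts that to ~113 days, and the Welch
test confirms the contrast (t = 5.68, p ≈ 1e-7).  `censored` counts
replicates still alive at the 1000-day cap; they are excluded from the
means.

The same experiments are available from the shell:

```bash
infodemic calibrate --out out/          # joint grid calibration
infodemic sweep --config out/calibrated_config.yaml --out out/sweep
infodemic compare 5 10 --config out/calibrated_config.yaml
infodemic run --config out/calibrated_config.yaml
```

`sweep` writes per-scenario duration CSVs, a summary table, believer
curves (susceptibles blue, believers red, fact-checkers green, as a
percentage of the population) and a `manifest.json` with the settings
and a checksum for every file.

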