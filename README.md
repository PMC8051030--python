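# kidneyce

Decision-analytic cost-effectiveness models for a question kidney services
face daily: should a patient accept a marginal-quality deceased-donor kidney
(Kidney Donor Profile Index, KDPI, above 74 — higher means lower donor
quality) or remain waitlisted on dialysis?

The package implements the same comparison twice, with shared parameters, so
the two standard modelling methods can be compared head to head:

* **Cohort Markov model** — transplant arm with states
  *functioning graft → dialysis after graft failure → dead*, waitlist arm
  with *waitlisted on dialysis → dead*; time-dependent per-cycle transition
  probabilities derived from Weibull survivor functions via
  `p_k = 1 − S(k·u) / S((k−1)·u)`; cycle lengths of 6 or 12 months,
  horizons of 5 or 20 years, life-table half-cycle correction.
* **Discrete-event simulation (DES)** — patient-level walks of the same
  event graph in continuous time, with competing event times drawn by
  inverse-transform sampling from the same Weibull distributions
  (`T = (−ln U / λ)^{1/γ}`), and — unlike the Markov cohort — a memory:
  the post-graft-failure survival clock restarts at the failure time.

All transitions use the rate-scale Weibull survivor function
`S(t) = exp(−λ t^γ)`. Outputs per arm are discounted cost (2020 AUD),
discounted quality-adjusted life years (QALYs, utility 0.82/yr with a
functioning graft, 0.70/yr on dialysis), and net monetary benefit
`NMB = WTP × QALY − cost` at a willingness-to-pay of AUD 28,000 per QALY,
with costs and effects discounted at 5 %/yr. Supporting machinery covers the
full workflow: parametric survival fitting under right-censoring
(exponential / Weibull / log-logistic / log-normal, AIC/BIC selection),
synthetic registry-style cohorts for testing the fitting stage,
probabilistic sensitivity analysis (PSA), DES population-size stabilization
analysis, and incremental analysis with dominance classification.

## Worked example

Base case at a 1-year cycle and 5-year horizon:

```sh
$ kidneyce markov --arm transplant --cycle-length 1 --horizon 5 --out m_tx
transplant: discounted cost 175,594 AUD, QALY 3.198, NMB -86,058 AUD
$ kidneyce markov --arm waitlist --cycle-length 1 --horizon 5 --out m_wl
waitlist: discounted cost 321,238 AUD, QALY 2.753, NMB -244,162 AUD
$ kidneyce des --arm transplant --horizon 5 --n-patients 4000 --seed 1 --out d_tx
transplant (n=4000): mean cost 173,769 AUD, mean QALY 3.187, NMB -84,545 AUD; event proportions {'death': 0.222, 'graft_failure': 0.114}
```

Reading the numbers: over five years a transplanted patient accrues about
AUD 176k in discounted costs (first-year transplant care at 115,725/yr, then
follow-up at 16,110/yr, plus dialysis at 81,689/yr for the ~12 % whose graft
fails) and 3.20 QALYs, versus AUD 321k and 2.75 QALYs for a patient who
stays on dialysis. Transplanting the marginal kidney is therefore
**dominant** — cheaper *and* more effective — and both modelling methods
agree, here and in every configuration:

```python
import kidneyce as k

tr, econ = k.default_transitions(), k.default_econ()
tx, _ = k.run_cohort(k.MarkovSpec.transplant(tr), k.CycleConfig(1.0, 5.0), econ)
wl, _ = k.run_cohort(k.MarkovSpec.waitlist(tr), k.CycleConfig(1.0, 5.0), econ)
inc = k.incremental(tx, wl)
print(inc.dominance, round(inc.delta_cost), round(inc.delta_effect, 2))
# dominant 145644 0.45
```

The full comparison — all four Markov configurations, the DES at both
horizons, PSA, stabilization curve, event proportions and time-to-event
densities — is one command:

```sh
kidneyce run-study --outdir study_output
```

which writes `table4.csv`, `stabilization.csv`, `event_proportions.csv`,
`densities.csv`, figures and a seed manifest. See `docs/methods.md` for the
model assumptions, accrual/discounting conventions and their consequences.

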