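# faers-signal

Pharmacovigilance signal detection on FAERS spontaneous reports, built for
case-series safety analyses of the anti-BCMA CAR-T products idecabtagene
vicleucel (ide-cel) and ciltacabtagene autoleucel (cilta-cel) — and reusable
for any target drug.

The FDA Adverse Event Reporting System publishes quarterly "$"-delimited
tables (DEMO, DRUG, REAC, OUTC, THER, ...) of voluntarily submitted adverse
event reports. There is no denominator of exposed patients, so safety
screening works by *disproportionality*: for each drug–event pair, the 2×2
table over deduplicated reports

|                 | event | no event |
|-----------------|-------|----------|
| **target drug** | a     | b        |
| **other drugs** | c     | d        |

yields the reporting odds ratio ROR = (a·d)/(b·c) with a 95% Wald CI
(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)) and the BCPNN information component
IC = log₂((a+0.5)/(E+0.5)), E = (a+b)(a+c)/N, with its lower credibility
bound IC025 = IC − 3.3(a+0.5)^−1/2 − 2(a+0.5)^−3/2. A pair is flagged when
ROR CI lower bound > 1 with ≥3 cases, or IC025 > 0. Time-to-onset is
modelled with a two-parameter Weibull MLE whose shape β classifies the
hazard trend (β<1 early failure, β≈1 random, β>1 wear-out).

The package covers the full workflow:

- `faers_io` — quarterly-file parsing, report assembly, FDA-style
  deduplication (per CASEID keep the latest FDA_DT, ties to the higher
  PRIMARYID);
- `cohort` — pattern-based target-drug cohort selection (PS/SS roles),
  user-supplied MedDRA PT→SOC annotation, Table-1-style demographics;
- `signal_stats` — contingency construction, ROR/IC, signal flags, top-k
  ranking, unexpected-signal labelling against a product-label term list;
- `special_analyses` — sex/age subgroup screens, female-vs-male reporting
  ratios, death-outcome subset, grouped secondary-malignancy IC screen;
- `tto_weibull` — onset extraction, onset-window summaries, Weibull MLE with
  Wald CIs and failure-type classification;
- `synthetic` — a FAERS-format generator with implanted signals and
  closed-form expected contingency tables, so every stage is testable with
  known ground truth;
- `pipeline` / `cli` — one-command orchestration into a TSV/JSON bundle.

## Worked example

```python
from faers_signal import (SimulationConfig, simulate, deduplicate,
                          DrugQuery, select_cohort, screen)

sim = simulate(SimulationConfig(), seed=1)        # 5000 synthetic reports
universe = deduplicate(sim.assemble()).reports    # 5500 versions -> 5000 cases
cohort = select_cohort(universe, DrugQuery("ide-cel", ("abecma",)))
for r in screen(universe, cohort):
    if r.ror_signal:
        print(f"{r.event}: n={r.n_cases} ROR={r.ror:.1f} "
              f"({r.ror_ci_low:.1f}-{r.ror_ci_high:.1f}) IC025={r.ic025:.2f}")
```

prints (among a handful of background false positives expected at the
nominal threshold):

```
Cytokine release syndrome: n=136 ROR=42.6 (31.4-57.7) IC025=3.03
Immune effector cell-associated neurotoxicity syndrome: n=85 ROR=63.8 (42.0-97.0) IC025=3.30
Myelodysplastic syndrome: n=13 ROR=6.2 (3.3-11.8) IC025=1.12
```

The generator implanted those three associations on the ide-cel-like product
at relative reporting rates 50, 30 and 8; the screen recovers them, with each
ROR CI covering its closed-form expectation
(`faers_signal.synthetic.expected_contingency`). The full bundle — subgroup
tables, death-outcome screen, malignancy screen, Weibull onset fits — comes
from `faers-signal run --out bundle/ --seed 1` or
`faers_signal.pipeline.run_pipeline`.

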