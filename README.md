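# clz-cea

Cost-effectiveness analysis of HLA-guided clozapine treatment schedules.

Clozapine is the drug of choice for treatment-resistant schizophrenia, but it
can cause agranulocytosis/granulocytopenia (CIAG), so every patient is kept on
a mandatory blood-monitoring schedule and must stop the drug permanently when
the absolute neutrophil count (ANC) falls below a cutoff (1500 cells/mm³ in
Japan and the UK).  Genotyping risk HLA variants before starting clozapine
(HLA-B\*59:01 in Japanese patients; HLA-B 158T / HLA-DQB1 126Q in Caucasian
patients) flags a high-risk subgroup in whom a fraction of CIAG onsets can be
averted — at the price of testing everyone.  This package implements the
decision model that asks whether that trade is worth it, for health-economics
researchers and for anyone who wants to re-run the analysis with their own
parameter table.

## Model

A two-state, time-inhomogeneous Markov cohort model with monthly cycles:

* **State 1 — on clozapine.**  Accrues daily drug cost, the CPMS monitoring
  cost (weekly blood tests for the first 26 weeks in Japan / 18 in the UK,
  biweekly thereafter), and utility 0.693/year.
* **State 2 — on substitute antipsychotic** (absorbing; re-challenge is
  prohibited).  Accrues substitute drug cost and utility 0.560/year.

In cycle *t* a fraction *q·* of those still on clozapine develops CIAG,
pays a one-time episode cost, and switches.  The HLA-guided arm multiplies
every *qₜ* by (1 − *r*), where *r* is the CIAG **prevention rate** (base
30%), and pays a one-time HLA typing cost at cycle 0.  Death and sepsis
states are omitted (mortality under registry monitoring is negligible).
Costs *C* and QALYs *Q* are discounted at 2%/yr (Japan) or 3.5%/yr (UK) over
a 10-year horizon, and strategies compared by

ICER = (C_guided − C_unguided) / (Q_guided − Q_unguided),

against willingness-to-pay thresholds of £37,650.6/QALY (5,000,000 JPY at
132.8 JPY/£) and £30,000/QALY.  On top of the engine sit: dominance-aware
ICER/NMB metrics and the cost-effectiveness frontier, one-way (tornado)
sensitivity analysis, bisection threshold search, a 3–20-year horizon sweep,
a Monte Carlo probabilistic sensitivity analysis with CEAC output, and a
six-option scenario grid (ANC cutoffs 500/1000/1500 × HLA test yes/no).

The bundled Japan/UK configurations reproduce every value printed in the
source Methods verbatim; quantities that exist only in supplementary
material (per-cutoff onset curves, the per-test and HLA typing fees) are
clearly flagged placeholders — see `docs/methods.md` for what that means for
interpreting the outputs.

## Worked example

```bash
$ clz-cea basecase --fixture japan_basecase --out out/
delta_cost=33.87 delta_qalys=0.00525 status=icer icer=6454.6
```

Screening the whole cohort costs an extra £33.87 per patient over 10 years
(the typing fee minus the savings from averted CIAG episodes and avoided
switches to the costlier substitute) and buys 0.00525 QALYs, i.e.
£6,454.6 per QALY — well under the Japanese £37,650.6 threshold, so the
HLA-guided schedule is cost-effective under these inputs.  The same model is
available as a library:

```python
import clz_cea as cc

params = cc.load_fixture("japan_basecase")
guided = cc.Strategy(anc_cutoff=1500, hla_guided=True)
unguided = cc.Strategy(anc_cutoff=1500, hla_guided=False)
_, out_g = cc.run_cohort(guided, params)
_, out_u = cc.run_cohort(unguided, params)
print(cc.icer(out_g, out_u, wtp=params.country.wtp_threshold).icer)  # 6454.57...
```

A quick Bayes check of what a positive HLA test means
(`clz-cea epi ppv 0.24 0.015 0.04` → `0.090000`): with 24% test sensitivity,
1.5% cumulative CIAG incidence, and a 4% carrier rate, a carrier's CIAG risk
is 9%.

Other subcommands: `psa`, `tornado`, `threshold`, `horizon`, `explore`
(all emit plot-ready CSVs plus a JSON bundle; see `clz-cea --help`).

To run the model on your own parameter table, export a starting
configuration with `clz_cea.dump_parameters(cc.study_fixture("JPN"), "my.yaml")`,
edit it, and pass `--config my.yaml`.

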