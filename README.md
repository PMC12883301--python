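# milancost

Decision-analytic cost model for the diagnostic work-up of salivary gland
lesions: fine-needle aspiration cytology (FNAC) reported under the Milan
System (MSRSGC), followed by surgery only where indicated, versus upfront
surgery without cytologic triage.

Salivary gland lesions are mostly benign, but 20–30 % are malignant, and
the procedures that settle the question differ enormously in price — an
ultrasound-guided FNAC costs a few euros to a few hundred dollars, while a
parotidectomy with neck dissection costs five figures. The Milan System
stratifies cytology into seven categories (I non-diagnostic, II
non-neoplastic, III AUS, IVa benign neoplasm, IVb SUMP, V suspicious, VI
malignant), each with a risk of malignancy (ROM) and a management
recommendation. `milancost` encodes the two strategies as decision trees,
computes their exact expected per-case cost by roll-back, and simulates
patient cohorts through them by seeded Monte Carlo.

## Model

Each strategy arm is a tree of chance nodes with incremental costs; the
expected cost of an arm is

```
E[C] = Σ_paths  P(path) · Σ_{nodes on path} c(node)
```

**Upfront surgery** — gland-conserving excision (partial parotidectomy or
submandibulectomy, by site) with intraoperative frozen section; with
probability *p*<sub>mal</sub> histology is malignant and a completion
oncologic procedure is appended (total parotidectomy + neck dissection,
or neck dissection alone for an already-excised submandibular gland).

**FNAC first** — FNAC is reported in category *k* with probability
π<sub>k</sub>; each category follows its MSRSGC pathway: repeat FNAC for
I/III (a second I/III result goes straight to partial surgery); follow-up
only for II; surgery with probability `iva_surgery_rate` for IVa (the
scenario knob: 100 % / 70 % / 0 %); surgery for IVb; surgery with frozen
section for V/VI, oncologic if malignant (probability ROM<sub>k</sub>).
Malignancy found after a partial excision appends a revision neck
dissection.

Three built-in parameter sets pair category distributions and ROMs with a
tariff: `1a` (MSRSGC literature estimates, US CPT fees), `1b` (MSRSGC
estimates, German DRG/OPS + EBM fees), `1c` (a 1289-patient real-world
cohort, German fees). A synthetic-cohort generator and recovery harness
(exact binomial CIs) validate the probabilistic structure end to end.

## Worked example

```
$ milancost run --model 1c --arm fnac_first --iva-rate 0.7 --n 10000 --seed 1
{
  "model": "1c",
  "arm": "fnac_first",
  "iva_rate": 0.7,
  "n": 10000,
  "seed": 1,
  "currency": "EUR",
  "mean": 4278.786359000001,
  "sd": 4093.5322815584504,
  "se": 40.935322815584506,
  "median": 5062.71,
  "q025": 15.37,
  "q975": 14942.82,
  "analytic_expected": 4280.098156330075
}
```

A real-world-data cohort of 10,000 patients managed FNAC-first with 70 %
of benign neoplasms (IVa) operated costs on average 4279 € per case —
within one standard error (41 €) of the exact tree expectation 4280 €.
The 2.5 % quantile is a patient whose pathway ends after the 15.37 € FNAC;
the 97.5 % quantile had oncologic surgery. The full scenario grid:

```
$ milancost grid --model 1c --seed 1 | cut -d, -f1,2,3,4,6,16
model,arm,iva_rate,currency,mean,percent_saving
1c,upfront_surgery,1.0,EUR,8042,
1c,fnac_first,1.0,EUR,5019,37.58826569375987
1c,fnac_first,0.7,EUR,4295,46.5858857047582
1c,fnac_first,0.0,EUR,2557,68.19808718788333
```

FNAC-first is 37 % cheaper per case than upfront surgery when every IVa
lesion is still operated, and 68 % cheaper under conservative IVa
management (the full CSV also carries sd/se, quantiles, the exact tree
expectation, and the truncated-percent reporting convention).
The same holds in the US model and the German MSRSGC-estimate model; the
library exposes everything programmatically
(`build_fnac_arm`, `expected_cost`, `simulate`, `compare_arms`, ...).

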