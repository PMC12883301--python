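# Methods

## Model structure

Both strategy arms are finite decision trees. Costs attach to nodes as
increments summed along a path, which makes a revision procedure a node
appended to an existing pathway rather than a replacement tariff. Chance
nodes carry branch probabilities that must sum to one within 1e-9;
decision nodes carry a single pre-chosen branch — the analysis compares
two fixed strategies and never optimizes a policy. Two exact evaluators
(recursive roll-back and exhaustive path enumeration) are implemented
independently and serve as each other's oracle in the tests, at 1e-6
relative tolerance.

The Monte Carlo engine resolves each chance node with one uniform draw
against the cumulative branch probabilities in declared order. A single
master seed derives one sub-stream per (model, arm, scenario) via
`numpy.random.SeedSequence(seed, spawn_key=...)`, so runs are
bit-reproducible and arms are independently reproducible. Cohort size
defaults to 10,000, matching the scale at which such analyses are usually
reported; the Monte Carlo standard error of a mean per-case cost at that
size is roughly 40–85 currency units for the built-in models.

## Pathway rules

* Category I and III receive exactly one repeat FNAC; a second I/III
  result proceeds to immediate partial surgery (never a third pass).
  After any other second result the patient continues down that
  category's ordinary pathway without being charged a third FNAC.
* Category II ends in clinical/radiological follow-up without surgery.
* Category IVa is operated with probability `iva_surgery_rate`
  (scenarios 1.0 / 0.7 / 0.0 — the 0.7 scenario reflects that only some
  benign neoplasms, chiefly pleomorphic and basal cell adenomas, carry a
  malignant-transformation argument for excision).
* Category IVb is operated; V and VI are operated with intraoperative
  frozen section, receiving the primary oncologic procedure if malignant
  and a partial excision otherwise.
* Malignant histology after a partial excision appends a revision neck
  dissection — the gland is already out, so re-billing a combined
  gland-plus-neck procedure would double-count the excision.
* In the upfront arm the malignant completion for a parotid lesion is a
  second full procedure (total parotidectomy + neck dissection); a
  `completion_mode="replace"` option bills only the tariff difference,
  for sensitivity analysis.
* Malignancy missed under conservative management (II, non-operated IVa)
  incurs no modeled downstream cost: the model covers one diagnostic
  episode, not lifetime follow-up.
* Complication rates are reported descriptively only and never enter the
  simulation; they vary too widely across patient collectives to price
  without overfitting the model.

## Parameters, units, defaults

* **Tariffs** (one table per jurisdiction, USD or EUR, 2025 fee
  catalogs): six published procedure fees per currency. The frozen
  section defaults to 0 incremental cost (bundled into the surgical
  DRG/CPT fee), the repeat FNAC to the FNAC fee, and follow-up to 0 —
  conservative choices that keep the FNAC arm's advantage attributable
  to the published numbers. All three are configurable.
* **Category distribution and ROM.** The real-world set (`1c`) uses the
  cohort's raw category counts (314/182/113/501/72/54/53 of 1289), which
  sum exactly, rather than the rounded percentages (which sum to 99.5 %).
  The MSRSGC-estimate sets (`1a`, `1b`) take midpoints of the published
  frequency ranges, with open bounds "< x" read as x/2 and "> x" as the
  midpoint of (x, 100), renormalized to sum to one. ROM point estimates
  are used where published (15/11/30/35/83 %), with "< 3" → 1.5 % and
  "> 98" → 99 %.
* **Site mix** defaults to 0.8 parotid. The sources never state the
  parotid/submandibular split; the default reflects the typical
  predominance of parotid lesions and is explicit and overridable.
* **Second-FNAC distribution** defaults to the first-pass category
  distribution. Only the consequence of a second I/III result is
  specified by the pathway rules; reusing the marginal distribution is
  the minimal assumption and is overridable from config.
* **Upfront malignancy prevalence** defaults to 0.28. See below.

## Calibration of the upfront arm

The published description of this comparison fixes the pathway logic and
the tariff and category tables, but three quantities are not recoverable
from printed tables alone: the site mix, the repeat-FNAC redistribution,
and the malignancy prevalence of the upfront arm (where no cytology
exists to stratify risk). The published upfront-arm mean costs of the two
German models are nearly identical (8018 € vs 7988 €) even though their
category-weighted ROMs differ substantially (0.239 vs 0.198), which
indicates a common fixed prevalence rather than a category-derived one.
A single prevalence of 0.28 at site mix 0.8 reproduces all three
published upfront means within 0.5 % (predicted 17,390 $ / 8024 € /
8024 € against 17,472 $ / 8018 € / 7988 €) and lies inside the 20–30 %
malignancy range reported for salivary gland tumors; it is therefore the
calibrated default. The rule-based alternative — the category-weighted
mean ROM — is available as `weighted_rom()` and can be passed through
`upfront_malignancy_rate`.

With these defaults the FNAC-arm expected costs land within about 3–9 %
of the published means at IVa surgery rates 1.0 and 0.7, but 15–30 %
above them at rate 0.0. The discrepancy is structural: the published
results imply an IVa-dependent cost amplitude larger than any composition
of the printed tariffs under the stated pathway rules (for the
real-world model, whose IVa share is fixed by counts at 0.389, the
implied IVa surgical pathway would need to cost ≈ 8900 € against the
4898 € that partial surgery plus ROM-weighted revision yields). Absent
the graphical tree's node annotations this cannot be resolved, and no
attempt is made to force agreement; the deviation is reported as-is.

## Synthetic cohorts

The generator draws site, Milan category, and true malignancy status
independently per patient (site ⫫ category — no category-by-site
cross-tabulation is published). It emulates the registry's statistical
structure only: no histologic subtypes, no correlation between site and
category, no repeat-visit dynamics. Passing recovery tests therefore
demonstrate correctness of the sampling and estimation machinery, not
fidelity to any real registry beyond its category/ROM margins.

Recovery uses exact Clopper–Pearson binomial intervals, which remain
valid for the small V/VI counts at registry scale (≈ 54 of 1289). The
joint "all cells recovered" acceptance check applies a Bonferroni
adjustment across its 14 cells (family-wise 99 %); per-cell 99 %
calibration is verified separately by a 500-replicate coverage
simulation, whose observed failure rate must stay below twice nominal.

## Numerical choices

* Probability sums validated to 1e-9 (pure floating-point construction,
  no measurement noise); oracle comparisons at 1e-6 relative.
* Built-in distributions absorb the renormalization residual into the
  largest cell so sums are exactly 1.0.
* Monte Carlo sampling guards against cumulative-probability round-off
  by routing residual mass to the last declared branch.
* Percent savings are truncated toward zero for reporting (the
  convention consistent with the published percentages, e.g. 39.8 → 39);
  full precision is always retained alongside.
* Monetary means are rounded to whole currency units only in
  presentation tables; computation keeps full precision.
* Convergence checks flag a cohort whose mean deviates from the exact
  tree expectation by more than 3.5 standard errors (false-alarm
  probability < 1/2000 per check).

## Problem sizes

Tests and the acceptance script simulate 10,000-patient cohorts per
scenario (the standard reporting scale for this analysis), 100,000 for
convergence and recovery demonstrations, 500 replicates of 2,000
patients for coverage calibration, and 1,000 random trees for oracle
equivalence. The full grid — 12 arm-scenario cohorts of 10,000 — runs in
about one second on a single core.

## Known limitations

* Single-episode horizon: no long-term surveillance, recurrence, or
  missed-malignancy costs; no discounting; no quality-of-life weights or
  ICERs — the outcome is cost only.
* No currency conversion; US and German results are not comparable in
  level.
* Complications, core-needle biopsy pathways, and histologic subtype
  structure are out of scope.
* The calibrated upfront prevalence and the default site mix are modeling
  choices constrained by published aggregate means, not patient-level
  data; the low-IVa-rate scenarios are underdetermined as described
  above.
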