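"""Synthetic patient-level cohorts and parameter-recovery checks.

The generator emulates the statistical structure of a salivary-gland FNAC
registry: each patient has an anatomic site (parotid/submandibular drawn
from the site mix), a Milan category drawn from the category distribution,
and a true malignancy status drawn per-category from the risk of malignancy
(ROM).  Site is drawn independently of category — the published sources
give no category-by-site cross-tabulation, so independence is the minimal
assumption.

``estimate_parameters`` recovers category frequencies and per-category
malignancy fractions with exact (Clopper-Pearson) binomial confidence
intervals, which behave correctly for the small counts of categories V/VI
at registry-scale n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .params import MilanCategory, ModelParameters

__all__ = ["generate_cohort", "estimate_parameters", "RecoveryReport"]

PAROTID = "parotid"
SUBMANDIBULAR = "submandibular"


def generate_cohort(
    params: ModelParameters,
    n: int,
    seed: Union[int, np.random.Generator, None] = 0,
) -> pd.DataFrame:
    """Draw ``n`` independent synthetic patients.

    Returns a DataFrame with columns ``patient_id``, ``site``,
    ``category``, ``malignant``.
    """
    if n < 0:
        raise ValueError(f"cohort size must be >= 0, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cats = [c.value for c in MilanCategory]
    probs = np.array([params.category_dist[c] for c in MilanCategory])
    rom = np.array([params.rom[c] for c in MilanCategory])
    idx = rng.choice(len(cats), size=n, p=probs)
    malignant = rng.random(n) < rom[idx]
    site = np.where(rng.random(n) < params.site_mix, PAROTID, SUBMANDIBULAR)
    return pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "site": site,
            "category": pd.Categorical.from_codes(idx, categories=cats),
            "malignant": malignant,
        }
    )


def _exact_ci(k: int, n: int, confidence: float) -> tuple:
    if n == 0:
        return (0.0, 1.0)
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=confidence, method="exact")
    return (float(ci.low), float(ci.high))


@dataclass
class RecoveryReport:
    """Estimated frequencies/ROMs with exact binomial CIs, per category.

    ``table`` has one row per Milan category: observed counts, point
    estimates, CI bounds, and — when the generating parameters are known —
    the true values and per-cell coverage flags.
    """

    table: pd.DataFrame
    confidence: float

    @property
    def all_covered(self) -> bool:
        cols = [c for c in ("freq_covered", "rom_covered") if c in self.table]
        if not cols:
            raise ValueError("no generating parameters were supplied")
        # ROM cells with zero category count carry no information; a (0, 1)
        # interval always covers, so they do not spoil the check
        return bool(self.table[cols].all().all())

    @property
    def n_failures(self) -> int:
        cols = [c for c in ("freq_covered", "rom_covered") if c in self.table]
        return int((~self.table[cols]).sum().sum())


def estimate_parameters(
    cohort: pd.DataFrame,
    truth: Optional[ModelParameters] = None,
    confidence: float = 0.99,
) -> RecoveryReport:
    """Estimate category frequencies and per-category ROM from a cohort."""
    n = len(cohort)
    if n == 0:
        raise ValueError("cohort is empty")
    rows = []
    for cat in MilanCategory:
        sub = cohort[cohort["category"] == cat.value]
        k = len(sub)
        k_mal = int(sub["malignant"].sum())
        f_lo, f_hi = _exact_ci(k, n, confidence)
        r_lo, r_hi = _exact_ci(k_mal, k, confidence)
        row = {
            "category": cat.value,
            "count": k,
            "freq_hat": k / n,
            "freq_lo": f_lo,
            "freq_hi": f_hi,
            "n_malignant": k_mal,
            "rom_hat": k_mal / k if k else float("nan"),
            "rom_lo": r_lo,
            "rom_hi": r_hi,
        }
        if truth is not None:
            fq, rm = truth.category_dist[cat], truth.rom[cat]
            row.update(
                freq_true=fq,
                rom_true=rm,
                freq_covered=f_lo <= fq <= f_hi,
                rom_covered=r_lo <= rm <= r_hi,
            )
        rows.append(row)
    return RecoveryReport(table=pd.DataFrame(rows), confidence=confidence)
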