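"""Cohort preparation: SCD questionnaire scoring, covariate centering, and
attrition audits.

The subjective-cognitive-decline measure is the Memory Functioning
Questionnaire Frequency-of-Forgetting subscale (MFQ-FoF): 7-point Likert
items where 1 = frequent concern and 7 = no concern.  Scoring inverts the
items so that larger means more perceived decline, averages them, and
subtracts one, giving a 0-6 scale with interpretable growth-model
intercepts.  Baseline age is centered at 70 before entering any model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["SubjectRecord", "score_mfq", "center_age", "audit_missingness",
           "goodness_of_fit_chi2", "MissingnessAudit", "prep_covariates"]

AGE_CENTER = 70.0


@dataclass
class SubjectRecord:
    """One participant's covariates, wave presence, and cognitive indices."""

    subject_id: str
    age_years: float
    mfq_fof: float
    wave_present: tuple
    mfq_items: tuple | None = None
    cognitive: dict = field(default_factory=dict)  # index name -> per-wave values
    sex: str | None = None
    racial_identity: str | None = None

    def __post_init__(self):
        if not (0.0 <= self.mfq_fof <= 6.0):
            raise ValueError(
                f"mfq_fof must be in [0, 6], got {self.mfq_fof}")
        if not self.wave_present or not self.wave_present[0]:
            raise ValueError("included subjects must be present at wave 1")

    @property
    def age_centered(self):
        return center_age(self.age_years)


def score_mfq(items):
    """Score MFQ-FoF items onto the 0-6 scale.

    Each 7-point Likert response (1 = frequent concern ... 7 = no concern)
    is inverted to ``8 - item``, the inverted items are averaged, and 1 is
    subtracted, so 0 means no perceived decline and 6 maximal concern.
    """
    items = np.asarray(items, float)
    if items.size == 0:
        raise ValueError("need at least one MFQ item")
    bad = np.flatnonzero((items < 1) | (items > 7) | (items != np.round(items)))
    if bad.size:
        raise ValueError(
            f"MFQ items must be integers in 1..7; offending index {bad[0]} "
            f"(value {items[bad[0]]})")
    return float(np.mean(8.0 - items) - 1.0)


def center_age(age_years):
    """Baseline age centered at 70 (years)."""
    return np.asarray(age_years, float) - AGE_CENTER


@dataclass
class MissingnessAudit:
    odds_ratio: float
    p: float
    coefficients: tuple  # (intercept, slope)
    separated: bool = False


def audit_missingness(baseline_covariate, missing_at_wave):
    """Univariate logistic regression of follow-up missingness on a baseline
    covariate.

    Returns the odds ratio ``exp(slope)`` per covariate unit with a
    two-sided Wald p-value.  Complete separation (or a constant covariate)
    is flagged rather than raised, since no finite MLE exists there.
    """
    x = np.asarray(baseline_covariate, float)
    y = np.asarray(missing_at_wave, float)
    if x.shape != y.shape:
        raise ValueError("covariate and missingness vectors differ in length")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("missingness must be binary")
    n1 = int(y.sum())
    if n1 < 2 or len(y) - n1 < 2:
        raise ValueError("need >=2 subjects in each missingness class")
    if np.ptp(x) == 0:
        return MissingnessAudit(1.0, 1.0, (np.nan, 0.0), separated=False)
    design = sm.add_constant(x)
    try:
        fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        separated = (not fit.mle_retvals.get("converged", True)
                     or np.abs(fit.params).max() > 1e3)
    except Exception:
        return MissingnessAudit(np.nan, np.nan, (np.nan, np.nan),
                                separated=True)
    if separated:
        return MissingnessAudit(np.nan, np.nan, tuple(fit.params),
                                separated=True)
    slope = fit.params[1]
    return MissingnessAudit(float(np.exp(slope)), float(fit.pvalues[1]),
                            tuple(fit.params), separated=False)


def goodness_of_fit_chi2(observed_counts, expected_proportions):
    """Pearson goodness-of-fit chi-square against stated proportions.

    ``chi2 = sum (O - E)^2 / E`` with ``E = N * proportion``; df = k - 1.
    """
    obs = np.asarray(observed_counts, float)
    props = np.asarray(expected_proportions, float)
    if obs.shape != props.shape:
        raise ValueError("counts and proportions differ in length")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("expected proportions must sum to 1")
    expected = obs.sum() * props
    if (expected == 0).any():
        raise ValueError("zero expected cell count")
    chi2, p = stats.chisquare(obs, expected)
    return {"chi2": float(chi2), "df": obs.size - 1, "p": float(p)}


def prep_covariates(frame):
    """Score and center a raw covariate table.

    Expects columns ``subject``, ``age`` and either ``mfq_fof`` or MFQ item
    columns ``mfq_item_*``; adds ``age_c`` (centered at 70) and, when items
    are present, the derived ``mfq_fof`` score.
    """
    out = frame.copy()
    item_cols = [c for c in out.columns if c.startswith("mfq_item_")]
    if "mfq_fof" not in out.columns:
        if not item_cols:
            raise ValueError("need mfq_fof column or mfq_item_* columns")
        out["mfq_fof"] = [score_mfq(r) for r in
                          out[item_cols].to_numpy(float)]
    out["age_c"] = center_age(out["age"].to_numpy(float))
    return out
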