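"""Manual TFF3 gland-count statistics.

Pathologists count TFF3-positive gland groups on two slides cut from each
Cytosponge block (slide 2, superficial; slide 15, deep).  Four summary
parameters are derived per patient — each slide's count, their average,
and their maximum — and compared between patients with clinically
relevant Barrett's oesophagus and those with focal intestinal-metaplasia
pathologies.

Group variances differ (Levene's test), so means are compared with
Welch's t-test: the standard error is sqrt(s1^2/n1 + s2^2/n2) and the
degrees of freedom follow Welch–Satterthwaite.  Discriminative value is
summarised by the AUROC of each parameter, which for a single monotone
feature equals the Mann–Whitney concordance probability; its confidence
interval uses DeLong's variance estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .relevance import FOCAL, RELEVANT, PatientRecord

__all__ = [
    "GlandCountParameters",
    "WelchResult",
    "AurocResult",
    "derive_parameters",
    "levene_test",
    "welch_from_summary",
    "welch_from_data",
    "univariate_logit_auroc",
    "table1_report",
    "PARAMETER_NAMES",
]

PARAMETER_NAMES = ("slide2", "slide15", "average", "highest")


@dataclass(frozen=True)
class GlandCountParameters:
    """The four per-patient gland-count parameters."""

    slide2: int
    slide15: int

    @property
    def average(self) -> float:
        return (self.slide2 + self.slide15) / 2.0

    @property
    def highest(self) -> int:
        return max(self.slide2, self.slide15)

    def value(self, name: str) -> float:
        if name not in PARAMETER_NAMES:
            raise ValueError(f"unknown parameter {name!r}; choose from {PARAMETER_NAMES}")
        return getattr(self, name)


def derive_parameters(slide2: Optional[int], slide15: Optional[int]) -> Optional[GlandCountParameters]:
    """Build the four parameters; ``None`` marks a record for exclusion.

    Records missing either slide's count cannot contribute to any of the
    four parameters and are flagged for exclusion rather than imputed.
    """
    if slide2 is None or slide15 is None:
        return None
    if slide2 < 0 or slide15 < 0:
        raise ValueError(f"gland counts must be non-negative, got ({slide2}, {slide15})")
    return GlandCountParameters(int(slide2), int(slide15))


def levene_test(
    x: Sequence[float], y: Sequence[float], center: str = "mean"
) -> tuple[float, float]:
    """Levene's test for equality of variances between two groups.

    ``center="mean"`` is the original form (absolute deviations from the
    group mean); ``"median"`` gives the Brown–Forsythe variant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return 0.0, 1.0  # no within-group spread at all: nothing to compare
    res = stats.levene(x, y, center=center)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class WelchResult:
    """Welch two-sample comparison of means."""

    mean_diff: float
    se: float
    df: float
    ci_low: float
    ci_high: float
    p_value: float
    conf: float = 0.95

    def formatted_p(self, floor: float = 0.001) -> str:
        return f"<{floor:g}" if self.p_value < floor else f"{self.p_value:.3f}"


def welch_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int, conf: float = 0.95
) -> WelchResult:
    """Welch t-test from group summaries (means, SDs, sizes).

    mean_diff = mean1 - mean2; se = sqrt(sd1^2/n1 + sd2^2/n2); df by
    Welch–Satterthwaite; the CI is mean_diff +/- t(df) * se.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be non-negative")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    se = math.sqrt(v1 + v2)
    diff = mean1 - mean2
    if se == 0:
        return WelchResult(diff, 0.0, float(n1 + n2 - 2), diff, diff, 1.0 if diff == 0 else 0.0, conf)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    tcrit = float(stats.t.ppf(0.5 + conf / 2, df))
    tstat = diff / se
    p = 2 * float(stats.t.sf(abs(tstat), df))
    return WelchResult(diff, se, df, diff - tcrit * se, diff + tcrit * se, p, conf)


def welch_from_data(x: Sequence[float], y: Sequence[float], conf: float = 0.95) -> WelchResult:
    """Welch t-test from raw group data (delegates to the summary path)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    return welch_from_summary(
        float(x.mean()), float(x.std(ddof=1)), x.size,
        float(y.mean()), float(y.std(ddof=1)), y.size,
        conf,
    )


# ---------------------------------------------------------------------------
# AUROC with DeLong confidence interval


def _auroc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC as the tie-corrected concordant-pair fraction (rank formula)."""
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = stats.rankdata(scores)  # average ranks on ties
    return (ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def _delong_variance(scores: np.ndarray, labels: np.ndarray, auc: float) -> float:
    """DeLong's AUROC variance from placement values."""
    x = scores[labels == 1]
    y = scores[labels == 0]
    m, n = x.size, y.size
    # V10[i] = P(Y < x_i) + 0.5 P(Y = x_i); V01[j] analogous
    v10 = np.array([((y < xi).mean() + 0.5 * (y == xi).mean()) for xi in x])
    v01 = np.array([((x > yj).mean() + 0.5 * (x == yj).mean()) for yj in y])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


@dataclass(frozen=True)
class AurocResult:
    auroc: float
    ci_low: float
    ci_high: float
    conf: float = 0.95


def univariate_logit_auroc(
    parameter_values: Sequence[float],
    class_labels: Sequence[str],
    conf: float = 0.95,
) -> AurocResult:
    """AUROC of one gland-count parameter for clinical relevance.

    A univariate logistic regression's score is a strictly increasing
    function of the feature (for a positive slope), so the model's AUROC
    equals the raw feature's Mann–Whitney AUROC; we compute the latter and
    attach a DeLong confidence interval clipped to [0, 1].
    """
    scores = np.asarray(parameter_values, dtype=float)
    labels = np.asarray([1 if c == RELEVANT else 0 for c in class_labels])
    if scores.size != labels.size:
        raise ValueError("values and labels differ in length")
    if scores.size < 4:
        raise ValueError("need n >= 4")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    auc = float(_auroc_mann_whitney(scores, labels))
    var = _delong_variance(scores, labels, auc)
    z = float(stats.norm.ppf(0.5 + conf / 2))
    half = z * math.sqrt(var)
    return AurocResult(auc, max(0.0, auc - half), min(1.0, auc + half), conf)


# ---------------------------------------------------------------------------
# Cohort-level report


def _collect(records: Sequence[PatientRecord]):
    rows = []
    for r in records:
        params = derive_parameters(r.gland_count_slide2, r.gland_count_slide15)
        if params is None or r.class_label is None:
            continue  # records missing counts or lengths are omitted, not imputed
        rows.append((r.class_label, params))
    return rows


def table1_report(
    records: Sequence[PatientRecord], precision: int = 2, with_auroc: bool = False
) -> pd.DataFrame:
    """Per-parameter group means/SDs with Welch comparisons (and AUROC).

    One row per gland-count parameter: relevant-group and focal-group mean
    (SD), Welch mean difference with 95% CI and p-value (formatted
    ``<0.001`` below that threshold), optionally the parameter's AUROC.
    Records missing gland counts or a class label are omitted, and the
    group sizes in the output reflect that.
    """
    rows = _collect(records)
    rel = [p for c, p in rows if c == RELEVANT]
    foc = [p for c, p in rows if c == FOCAL]
    if len(rel) < 2 or len(foc) < 2:
        raise ValueError(
            f"need n >= 2 per class with complete gland counts, got {len(rel)} vs {len(foc)}"
        )
    out = []
    for name in PARAMETER_NAMES:
        xr = np.array([p.value(name) for p in rel], dtype=float)
        xf = np.array([p.value(name) for p in foc], dtype=float)
        w = welch_from_data(xr, xf)
        lev_stat, lev_p = levene_test(xr, xf)
        row = {
            "parameter": name,
            "n_relevant": len(xr),
            "n_focal": len(xf),
            "mean_relevant": round(float(xr.mean()), precision),
            "sd_relevant": round(float(xr.std(ddof=1)), precision),
            "mean_focal": round(float(xf.mean()), precision),
            "sd_focal": round(float(xf.std(ddof=1)), precision),
            "mean_diff": round(w.mean_diff, precision),
            "ci_low": round(w.ci_low, precision),
            "ci_high": round(w.ci_high, precision),
            "p_value": w.formatted_p(),
            "levene_p": round(lev_p, 3),
        }
        if with_auroc:
            values = np.concatenate([xr, xf])
            labels = [RELEVANT] * len(xr) + [FOCAL] * len(xf)
            a = univariate_logit_auroc(values, labels)
            row["auroc_pct"] = round(100 * a.auroc, 1)
            row["auroc_ci_low_pct"] = round(100 * a.ci_low, 1)
            row["auroc_ci_high_pct"] = round(100 * a.ci_high, 1)
        out.append(row)
    return pd.DataFrame(out)
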