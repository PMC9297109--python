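"""Tile-count threshold model for clinically relevant Barrett's oesophagus.

A patient whose oesophageal segment measures C >= 1 cm or M >= 3 cm on the
Prague scale is *clinically relevant*; shorter segments and intestinal
metaplasia confined to the gastro-oesophageal junction are *focal*.  The
model is a univariate logistic regression of that binary label on the
(optionally log-transformed) number of TFF3-positive tiles counted on the
patient's Cytosponge whole-slide image.  Because the feature is a single
monotone score, the fitted model is equivalent to a tile-count cut-off:
the count at which the predicted probability crosses 0.5.

The module provides the label rule, the logistic fit with an invertible
tile threshold, stratified cross-validation, external-cohort transfer, and
the gastroscopy-triage arithmetic (how many patients fall below threshold
and how many true positives are missed among them).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "RELEVANT",
    "FOCAL",
    "PatientRecord",
    "FittedCountModel",
    "ClassMetrics",
    "TriageSummary",
    "CVResult",
    "label_clinical_relevance",
    "fit_count_model",
    "predict",
    "compute_metrics",
    "cross_validate",
    "train_and_transfer",
    "triage_summary",
]

RELEVANT = "clinically_relevant"
FOCAL = "focal"

#: Prague cut-offs defining the positive class: C >= 1 cm or M >= 3 cm.
C_CUTOFF_CM = 1.0
M_CUTOFF_CM = 3.0


def label_clinical_relevance(C_cm: float, M_cm: float) -> str:
    """Classify a Prague (C, M) measurement pair.

    Returns :data:`RELEVANT` iff C >= 1 cm or M >= 3 cm, else :data:`FOCAL`.

    Raises
    ------
    ValueError
        If either length is negative or C > M (the circumferential extent
        cannot exceed the maximal extent).
    """
    if C_cm < 0 or M_cm < 0:
        raise ValueError(f"segment lengths must be non-negative, got C={C_cm}, M={M_cm}")
    if C_cm > M_cm:
        raise ValueError(f"Prague geometry requires C <= M, got C={C_cm} > M={M_cm}")
    return RELEVANT if (C_cm >= C_CUTOFF_CM or M_cm >= M_CUTOFF_CM) else FOCAL


@dataclass
class PatientRecord:
    """One study participant.

    ``class_label`` is derived from the Prague lengths when they are
    available; records with missing lengths carry ``None`` and are excluded
    from modelling stages.
    """

    patient_id: str
    cohort: str = "train_like"  # train_like | test_like
    C_cm: Optional[float] = None
    M_cm: Optional[float] = None
    tile_count: int = 0
    gastric_tile_count: int = 0
    gland_count_slide2: Optional[int] = None
    gland_count_slide15: Optional[int] = None
    qc_pass: bool = True
    class_label: Optional[str] = field(default=None)

    def __post_init__(self) -> None:
        if self.tile_count < 0 or self.gastric_tile_count < 0:
            raise ValueError(f"{self.patient_id}: tile counts must be non-negative")
        if self.class_label is None and self.C_cm is not None and self.M_cm is not None:
            self.class_label = label_clinical_relevance(self.C_cm, self.M_cm)


# ---------------------------------------------------------------------------
# Feature transforms


_TRANSFORMS = {
    "identity": (lambda c: np.asarray(c, dtype=float), lambda x: x),
    "log1p": (np.log1p, np.expm1),
}


def _get_transform(name: str):
    try:
        return _TRANSFORMS[name]
    except KeyError:
        raise ValueError(
            f"unknown feature_transform {name!r}; choose from {sorted(_TRANSFORMS)}"
        ) from None


# ---------------------------------------------------------------------------
# Model fitting


@dataclass(frozen=True)
class FittedCountModel:
    """Logistic model on a tile-count transform, expressed as a cut-off.

    ``tile_threshold`` is the count at which predicted probability crosses
    0.5, i.e. ``inverse_transform(-intercept / slope)``.  ``discrete_threshold``
    rounds it down to an operational integer cut-off.  ``separated`` marks a
    degenerate fit where the classes did not overlap in the feature and the
    threshold is the midpoint of the empirical gap instead of a maximum
    likelihood estimate.
    """

    intercept: float
    slope: float
    feature_transform: str
    tile_threshold: float
    separated: bool = False

    @property
    def discrete_threshold(self) -> int:
        return int(math.floor(self.tile_threshold))

    def predict_proba(self, counts: Sequence[float]) -> np.ndarray:
        if self.separated:
            # step surrogate for the diverged likelihood
            return (np.asarray(counts, dtype=float) >= self.tile_threshold).astype(float)
        from scipy.special import expit

        fwd, _ = _get_transform(self.feature_transform)
        eta = self.intercept + self.slope * fwd(np.asarray(counts, dtype=float))
        return expit(eta)


def _counts_and_labels(records: Iterable[PatientRecord]):
    recs = [r for r in records if r.qc_pass and r.class_label is not None]
    counts = np.array([r.tile_count for r in recs], dtype=float)
    y = np.array([1 if r.class_label == RELEVANT else 0 for r in recs], dtype=int)
    return recs, counts, y


def fit_count_model(
    records: Iterable[PatientRecord],
    feature_transform: str = "log1p",
) -> FittedCountModel:
    """Maximum-likelihood logistic fit of clinical relevance on tile count.

    Only QC-passed, labelled records enter the fit.  Under complete
    separation the unpenalised likelihood diverges; the model then reports
    the midpoint of the empirical count gap as the threshold and warns.

    Raises
    ------
    ValueError
        If fewer than one record per class remains, or every count is
        identical (no information in the feature).
    """
    import statsmodels.api as sm

    _, counts, y = _counts_and_labels(records)
    if len(counts) == 0:
        raise ValueError("no usable records (QC-passed with class labels)")
    if y.min() == y.max():
        raise ValueError("both classes must be present to fit the model")
    if np.ptp(counts) == 0:
        raise ValueError("all tile counts identical; threshold undefined")

    fwd, inv = _get_transform(feature_transform)
    x = fwd(counts)

    max_focal = counts[y == 0].max()
    min_relevant = counts[y == 1].min()
    if max_focal < min_relevant:
        thr = (max_focal + min_relevant) / 2.0
        warnings.warn(
            "complete separation: classes do not overlap in tile count; "
            f"reporting midpoint-of-gap threshold {thr:.3g}",
            stacklevel=2,
        )
        return FittedCountModel(math.nan, math.nan, feature_transform, float(thr), separated=True)

    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels chatters near-separation
        result = sm.Logit(y, X).fit(disp=0, maxiter=200)
    b0, b1 = float(result.params[0]), float(result.params[1])
    if b1 <= 0:
        warnings.warn(
            f"fitted slope {b1:.3g} is not positive; tile count is not "
            "positively associated with relevance in this cohort",
            stacklevel=2,
        )
    thr = float(inv(-b0 / b1))
    return FittedCountModel(b0, b1, feature_transform, thr)


def predict(model: FittedCountModel, records_or_counts) -> list[str]:
    """Threshold rule: clinically relevant iff predicted probability >= 0.5.

    For a positive slope this is exactly ``tile_count >= tile_threshold``;
    the probability-0.5 tie goes to the relevant class (a conservative
    choice for a screening test, where a miss is the costly error).
    """
    counts = np.asarray(
        [r.tile_count if isinstance(r, PatientRecord) else r for r in records_or_counts],
        dtype=float,
    )
    p = model.predict_proba(counts)
    return [RELEVANT if pi >= 0.5 else FOCAL for pi in p]


# ---------------------------------------------------------------------------
# Metrics


@dataclass(frozen=True)
class ClassMetrics:
    """Two-class confusion counts and derived metrics.

    The clinically relevant class plays the role of "positive"; balanced
    accuracy is the mean of the two per-class recalls (sensitivity and
    specificity), which is robust to class imbalance.  Metrics whose
    denominator is empty are NaN.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @staticmethod
    def _ratio(num: float, den: float) -> float:
        return num / den if den > 0 else math.nan

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return self._ratio(self.tp + self.tn, self.n)

    @property
    def recall_relevant(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def recall_focal(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def balanced_accuracy(self) -> float:
        return (self.recall_relevant + self.recall_focal) / 2.0

    @property
    def precision_relevant(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def precision_focal(self) -> float:
        return self._ratio(self.tn, self.tn + self.fn)

    @staticmethod
    def _f1(p: float, r: float) -> float:
        if math.isnan(p) or math.isnan(r) or (p + r) == 0:
            return math.nan
        return 2 * p * r / (p + r)

    @property
    def f1_relevant(self) -> float:
        return self._f1(self.precision_relevant, self.recall_relevant)

    @property
    def f1_focal(self) -> float:
        return self._f1(self.precision_focal, self.recall_focal)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "precision_relevant": self.precision_relevant,
            "precision_focal": self.precision_focal,
            "recall_relevant": self.recall_relevant,
            "recall_focal": self.recall_focal,
            "f1_relevant": self.f1_relevant,
            "f1_focal": self.f1_focal,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
        }


def compute_metrics(y_true: Sequence[str], y_pred: Sequence[str]) -> ClassMetrics:
    """Confusion counts of predicted vs true relevance labels."""
    if len(y_true) == 0:
        raise ValueError("empty label vectors")
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    bad = (set(y_true) | set(y_pred)) - {RELEVANT, FOCAL}
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    t = np.asarray(y_true) == RELEVANT
    p = np.asarray(y_pred) == RELEVANT
    return ClassMetrics(
        tp=int((t & p).sum()),
        fp=int((~t & p).sum()),
        tn=int((~t & ~p).sum()),
        fn=int((t & ~p).sum()),
    )


# ---------------------------------------------------------------------------
# Cross-validation


_METRIC_FIELDS = (
    "accuracy",
    "balanced_accuracy",
    "precision_relevant",
    "precision_focal",
    "recall_relevant",
    "recall_focal",
    "f1_relevant",
    "f1_focal",
)


@dataclass
class CVResult:
    """Per-fold validation metrics and thresholds plus mean/SD summary rows.

    Mean and SD (sample SD, ddof=1) are computed over the per-fold values,
    so the summary rows recompute exactly from the fold rows.
    """

    fold_metrics: list[dict]
    fold_thresholds: list[float]

    @classmethod
    def from_folds(
        cls, metrics: Sequence[ClassMetrics | dict], thresholds: Sequence[float]
    ) -> "CVResult":
        rows = [m.as_dict() if isinstance(m, ClassMetrics) else dict(m) for m in metrics]
        return cls(rows, [float(t) for t in thresholds])

    def _column(self, name: str) -> np.ndarray:
        return np.array([row[name] for row in self.fold_metrics], dtype=float)

    @property
    def mean_threshold(self) -> float:
        return float(np.mean(self.fold_thresholds))

    @property
    def sd_threshold(self) -> float:
        return float(np.std(self.fold_thresholds, ddof=1))

    def mean_row(self) -> dict:
        row = {f: float(np.mean(self._column(f))) for f in _METRIC_FIELDS if f in self.fold_metrics[0]}
        row["tile_threshold"] = self.mean_threshold
        return row

    def sd_row(self) -> dict:
        row = {f: float(np.std(self._column(f), ddof=1)) for f in _METRIC_FIELDS if f in self.fold_metrics[0]}
        row["tile_threshold"] = self.sd_threshold
        return row

    def as_table(self) -> "list[dict]":
        rows = []
        for i, (m, t) in enumerate(zip(self.fold_metrics, self.fold_thresholds), start=1):
            rows.append({"fold": str(i), **{k: m[k] for k in m if k in _METRIC_FIELDS}, "tile_threshold": t})
        rows.append({"fold": "mean", **self.mean_row()})
        rows.append({"fold": "sd", **self.sd_row()})
        return rows


def cross_validate(
    records: Sequence[PatientRecord],
    k: int = 5,
    seed: int = 0,
    feature_transform: str = "log1p",
) -> CVResult:
    """Stratified k-fold cross-validation of the tile-count model.

    Each fold's model is fitted on the other k-1 folds; metrics and the
    fold's tile threshold are taken on the held-out fold.  Stratification
    keeps both classes in every fold whenever class counts allow it.
    """
    recs, counts, y = _counts_and_labels(records)
    if k > len(recs):
        raise ValueError(f"k={k} exceeds usable cohort size {len(recs)}")
    if y.min() == y.max():
        raise ValueError("both classes must be present for cross-validation")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_metrics: list[ClassMetrics] = []
    fold_thresholds: list[float] = []
    for train_idx, test_idx in skf.split(counts, y):
        model = fit_count_model([recs[i] for i in train_idx], feature_transform)
        test = [recs[i] for i in test_idx]
        y_pred = predict(model, test)
        y_true = [r.class_label for r in test]
        fold_metrics.append(compute_metrics(y_true, y_pred))
        fold_thresholds.append(model.tile_threshold)
    return CVResult.from_folds(fold_metrics, fold_thresholds)


# ---------------------------------------------------------------------------
# Transfer to an external cohort and triage arithmetic


@dataclass(frozen=True)
class TriageSummary:
    """Gastroscopy-avoidance arithmetic for a threshold rule.

    Patients predicted focal fall below the threshold and would avoid
    confirmatory gastroscopy; the truly relevant patients among them are
    the screening misses.  Percentages are on the full cohort.
    """

    n_total: int
    n_below_threshold: int
    n_false_negative: int

    @property
    def pct_avoid_gastroscopy(self) -> float:
        return 100.0 * self.n_below_threshold / self.n_total

    @property
    def pct_missed(self) -> float:
        return 100.0 * self.n_false_negative / self.n_total

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_below_threshold": self.n_below_threshold,
            "n_false_negative": self.n_false_negative,
            "pct_avoid_gastroscopy": self.pct_avoid_gastroscopy,
            "pct_missed": self.pct_missed,
        }


def triage_summary(model: FittedCountModel, records: Sequence[PatientRecord]) -> TriageSummary:
    """Count patients spared gastroscopy by the threshold, and the misses."""
    if len(records) == 0:
        raise ValueError("empty cohort")
    y_pred = predict(model, records)
    below = [r for r, p in zip(records, y_pred) if p == FOCAL]
    fn = sum(1 for r in below if r.class_label == RELEVANT)
    return TriageSummary(len(records), len(below), fn)


def train_and_transfer(
    train_records: Sequence[PatientRecord],
    test_records: Sequence[PatientRecord],
    feature_transform: str = "log1p",
) -> tuple[FittedCountModel, ClassMetrics, TriageSummary]:
    """Fit on one cohort without cross-validation and evaluate on another.

    The threshold travels with the model: no recalibration on the test
    cohort.  Returns the fitted model, test-set metrics, and the triage
    summary on the test cohort.
    """
    model = fit_count_model(train_records, feature_transform)
    usable = [r for r in test_records if r.qc_pass and r.class_label is not None]
    if not usable:
        raise ValueError("no usable test records")
    y_pred = predict(model, usable)
    y_true = [r.class_label for r in usable]
    return model, compute_metrics(y_true, y_pred), triage_summary(model, usable)
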