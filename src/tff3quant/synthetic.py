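"""Synthetic cohorts and annotated slides with the study's statistical shape.

The generators emulate two screening-trial cohorts of TFF3-positive
Cytosponge patients:

* a *BEST2-like* surveillance cohort, enriched for long Barrett's segments
  (about 59.5% clinically relevant, C >= 1 or M >= 3), and
* a *BEST3-like* primary-care screening cohort dominated by focal disease
  (about 29.6% relevant).

Per patient we draw Prague lengths (a point mass of focal intestinal
metaplasia at M = 0 plus a discretised exponential tail capped at 15 cm),
an automated TFF3-positive tile count whose log-mean rises linearly with
the M length (negative binomial, so the marginal count histogram is
long-tailed), an independent gastric-control tile count, manual gland
counts for slides 2 and 15 drawn per class from moment-matched truncated
normals, and a QC flag (failures model sponges with no gastric cardia
mucosa, so their gastric control count is zero).

A single seed drives the whole cohort through a splittable
``numpy.random.SeedSequence``, so each sub-stream (lengths, counts, gland
counts, QC) is independently reproducible.

``simulate_annotated_slide`` paints coloured convex regions on a plain
background and returns the raster together with the generating polygons
and a pixel-exact label mask — a stand-in for a scanned whole-slide image
with pathologist annotations, used to exercise the tiling and counting
stages end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy import optimize, stats
from shapely.geometry import Polygon

from .relevance import FOCAL, RELEVANT, PatientRecord, label_clinical_relevance
from .tiling import LABEL_GASTRIC, LABEL_TFF3, AnnotatedSlide, Annotation, rasterize_polygon

__all__ = [
    "LengthModel",
    "CountModel",
    "GlandClassModel",
    "GlandModel",
    "GastricModel",
    "CohortSimParams",
    "SlideSimParams",
    "BEST2_LIKE",
    "BEST3_LIKE",
    "simulate_cohort",
    "simulate_gland_counts",
    "simulate_threshold_cohort",
    "simulate_annotated_slide",
]


def _check_fraction(name: str, value: float) -> None:
    if not (0 <= value <= 1):
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class LengthModel:
    """Prague C/M generator.

    Relevant patients get M = 3 + an exponential tail (scale ``tail_scale_cm``)
    capped at ``max_length_cm``; focal patients get M = 0 with probability
    ``zero_mass`` or 1-2 cm otherwise.  C = max(0, M - gap) with an
    exponential gap, clamped to C = 0 for focal patients so the derived
    label always matches the drawn class.  Lengths are rounded to whole cm,
    as endoscopy reports them.
    """

    zero_mass: float = 0.35
    tail_scale_cm: float = 3.0
    max_length_cm: float = 15.0
    gap_scale_cm: float = 1.5

    def __post_init__(self) -> None:
        _check_fraction("zero_mass", self.zero_mass)
        if self.max_length_cm < 0:
            raise ValueError(f"max_length_cm must be >= 0, got {self.max_length_cm}")
        if self.tail_scale_cm <= 0 or self.gap_scale_cm <= 0:
            raise ValueError("length scales must be positive")


@dataclass(frozen=True)
class CountModel:
    """Negative-binomial tile counts with log-mean linear in M.

    ``E[count | M] = exp(baseline_log_mean + slope_per_cm * M)``; the
    dispersion is the NB size parameter (smaller = heavier tail).
    """

    baseline_log_mean: float = 1.0
    slope_per_cm: float = 0.32
    dispersion: float = 2.5

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError(f"dispersion must be > 0, got {self.dispersion}")

    def mean_at(self, M: np.ndarray) -> np.ndarray:
        return np.exp(self.baseline_log_mean + self.slope_per_cm * np.asarray(M, float))


@dataclass(frozen=True)
class GlandClassModel:
    """Target mean/SD of the rounded, zero-truncated gland-count draw."""

    slide2_mean: float
    slide2_sd: float
    slide15_mean: float
    slide15_sd: float

    def __post_init__(self) -> None:
        if min(self.slide2_sd, self.slide15_sd) < 0:
            raise ValueError("gland-count SDs must be >= 0")
        if min(self.slide2_mean, self.slide15_mean) < 0:
            raise ValueError("gland-count means must be >= 0")


@dataclass(frozen=True)
class GlandModel:
    relevant: GlandClassModel = field(
        default_factory=lambda: GlandClassModel(6.71, 4.44, 7.58, 5.04)
    )
    focal: GlandClassModel = field(
        default_factory=lambda: GlandClassModel(2.86, 3.09, 3.15, 3.05)
    )

    def for_class(self, class_label: str) -> GlandClassModel:
        if class_label == RELEVANT:
            return self.relevant
        if class_label == FOCAL:
            return self.focal
        raise ValueError(f"unknown class label {class_label!r}")


@dataclass(frozen=True)
class GastricModel:
    """Gastric-control tile counts, independent of segment length."""

    mean: float = 20.0
    dispersion: float = 5.0

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.dispersion <= 0:
            raise ValueError("gastric mean and dispersion must be positive")


@dataclass(frozen=True)
class CohortSimParams:
    n_patients: int = 529
    prevalence_relevant: float = 0.595
    length_model: LengthModel = field(default_factory=LengthModel)
    count_model: CountModel = field(default_factory=CountModel)
    gland_model: GlandModel = field(default_factory=GlandModel)
    gastric_model: GastricModel = field(default_factory=GastricModel)
    qc_fail_rate: float = 0.02
    cohort_tag: str = "train_like"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError(f"n_patients must be positive, got {self.n_patients}")
        _check_fraction("prevalence_relevant", self.prevalence_relevant)
        _check_fraction("qc_fail_rate", self.qc_fail_rate)


def BEST2_LIKE(n_patients: int = 529, seed: int = 0, **kw) -> CohortSimParams:
    """Surveillance-cohort defaults: 59.5% clinically relevant."""
    return CohortSimParams(
        n_patients=n_patients, prevalence_relevant=0.595, cohort_tag="train_like",
        seed=seed, **kw,
    )


def BEST3_LIKE(n_patients: int = 158, seed: int = 0, **kw) -> CohortSimParams:
    """Screening-cohort defaults: 29.6% clinically relevant."""
    return CohortSimParams(
        n_patients=n_patients, prevalence_relevant=0.296, cohort_tag="test_like",
        seed=seed, **kw,
    )


# ---------------------------------------------------------------------------
# Gland counts: moment matching for the zero-truncated normal


@lru_cache(maxsize=64)
def _truncnorm_params(target_mean: float, target_sd: float) -> tuple[float, float]:
    """Underlying (mu, sigma) whose zero-truncated normal matches the target.

    The truncated distribution's mean/SD ratio cannot fall below 1 (the
    exponential limit), so a target with sd > mean is matched in mean
    exactly and in SD as closely as the family allows.
    """

    def trunc_moments(mu: float, sigma: float) -> tuple[float, float]:
        a = -mu / sigma
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        return float(m), float(np.sqrt(v))

    def mean_err(mu: float, sigma: float) -> float:
        return trunc_moments(mu, sigma)[0] - target_mean

    def mu_for_sigma(sigma: float) -> float:
        lo, hi = -20 * sigma, target_mean + 10 * sigma
        return optimize.brentq(lambda mu: mean_err(mu, sigma), lo, hi, xtol=1e-10)

    def sd_gap(sigma: float) -> float:
        mu = mu_for_sigma(sigma)
        return (trunc_moments(mu, sigma)[1] - target_sd) ** 2

    res = optimize.minimize_scalar(
        sd_gap, bounds=(target_sd / 10, target_sd * 10), method="bounded",
        options={"xatol": 1e-8},
    )
    sigma = float(res.x)
    return mu_for_sigma(sigma), sigma


def _draw_gland(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, int(round(mean)), dtype=int)
    mu, sigma = _truncnorm_params(mean, sd)
    a = -mu / sigma
    draws = stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=size, random_state=rng)
    return np.rint(draws).astype(int)


def simulate_gland_counts(
    class_label: str,
    gland_model: GlandModel | None = None,
    seed: int | np.random.Generator = 0,
    size: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (slide 2, slide 15) manual gland counts for one class.

    Counts are zero-truncated, rounded normal draws whose underlying
    parameters are moment-matched so the *post-truncation* mean hits the
    configured class mean.  Returns two integer arrays of length ``size``.
    """
    gm = (gland_model or GlandModel()).for_class(class_label)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s2 = _draw_gland(rng, gm.slide2_mean, gm.slide2_sd, size)
    s15 = _draw_gland(rng, gm.slide15_mean, gm.slide15_sd, size)
    return s2, s15


# ---------------------------------------------------------------------------
# Cohort simulation


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def _draw_lengths(
    rng: np.random.Generator, relevant: np.ndarray, lm: LengthModel
) -> tuple[np.ndarray, np.ndarray]:
    n = relevant.size
    M = np.zeros(n)
    C = np.zeros(n)
    nr = int(relevant.sum())
    nf = n - nr
    if nr:
        Mr = np.minimum(3 + np.round(rng.exponential(lm.tail_scale_cm, nr)), lm.max_length_cm)
        gap = np.round(rng.exponential(lm.gap_scale_cm, nr))
        M[relevant] = Mr
        C[relevant] = np.maximum(0.0, Mr - gap)
    if nf:
        Mf = np.where(
            rng.random(nf) < lm.zero_mass, 0.0, rng.integers(1, 3, nf).astype(float)
        )
        M[~relevant] = Mf
        C[~relevant] = 0.0  # clamp: keeps the derived label consistent with the class
    return C, M


def simulate_cohort(params: CohortSimParams) -> list[PatientRecord]:
    """Generate a cohort of :class:`PatientRecord` with the configured structure.

    The class label is drawn first (Bernoulli at the configured prevalence)
    and the Prague lengths are drawn class-conditionally so that the label
    derived from (C, M) equals the drawn class for every record.  Tile
    counts depend on M only; gastric counts are independent of length; QC
    failures get a zero gastric count.
    """
    ss = np.random.SeedSequence(params.seed)
    r_class, r_len, r_count, r_gland, r_gastric, r_qc = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    n = params.n_patients
    relevant = r_class.random(n) < params.prevalence_relevant
    C, M = _draw_lengths(r_len, relevant, params.length_model)
    counts = _nb_draw(r_count, params.count_model.mean_at(M), params.count_model.dispersion)
    gastric = _nb_draw(
        r_gastric, np.full(n, params.gastric_model.mean), params.gastric_model.dispersion
    )
    qc_pass = r_qc.random(n) >= params.qc_fail_rate
    gastric = np.where(qc_pass, gastric, 0)  # QC failure = no gastric cardia sampled

    s2 = np.empty(n, dtype=int)
    s15 = np.empty(n, dtype=int)
    for cls, idx in ((RELEVANT, np.flatnonzero(relevant)), (FOCAL, np.flatnonzero(~relevant))):
        if idx.size:
            a, b = simulate_gland_counts(cls, params.gland_model, r_gland, size=idx.size)
            s2[idx], s15[idx] = a, b

    records = []
    for i in range(n):
        rec = PatientRecord(
            patient_id=f"{params.cohort_tag}-{i:05d}",
            cohort=params.cohort_tag,
            C_cm=float(C[i]),
            M_cm=float(M[i]),
            tile_count=int(counts[i]),
            gastric_tile_count=int(gastric[i]),
            gland_count_slide2=int(s2[i]),
            gland_count_slide15=int(s15[i]),
            qc_pass=bool(qc_pass[i]),
        )
        expected = RELEVANT if relevant[i] else FOCAL
        assert rec.class_label == expected, "length draw violated class-conditional support"
        records.append(rec)
    return records


def simulate_threshold_cohort(
    n_patients: int = 529,
    true_threshold: float = 16.0,
    steepness: float = 6.0,
    length_model: LengthModel | None = None,
    count_model: CountModel | None = None,
    relevant_length_fraction: float = 0.595,
    cohort_tag: str = "train_like",
    seed: int = 0,
) -> list[PatientRecord]:
    """Cohort whose labels follow a known logistic link in the tile count.

    Counts are drawn as in :func:`simulate_cohort`; the class label is then
    Bernoulli with ``P(relevant | count) = sigmoid(steepness * (log1p(count)
    - log1p(true_threshold)))``, so the generative decision boundary sits
    exactly at ``true_threshold`` tiles.  Prague lengths consistent with the
    drawn label are back-filled so records remain schema-complete.  Used
    for threshold-recovery and transfer-stability experiments where the
    ground-truth cut-off must be known.
    """
    lm = length_model or LengthModel()
    cm = count_model or CountModel()
    ss = np.random.SeedSequence(seed)
    r_len_class, r_len, r_count, r_label, r_fill = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    long_seg = r_len_class.random(n_patients) < relevant_length_fraction
    _, M = _draw_lengths(r_len, long_seg, lm)
    counts = _nb_draw(r_count, cm.mean_at(M), cm.dispersion)

    p_rel = 1.0 / (1.0 + np.exp(-steepness * (np.log1p(counts) - np.log1p(true_threshold))))
    relevant = r_label.random(n_patients) < p_rel
    C, M = _draw_lengths(r_fill, relevant, lm)

    return [
        PatientRecord(
            patient_id=f"{cohort_tag}-{i:05d}",
            cohort=cohort_tag,
            C_cm=float(C[i]),
            M_cm=float(M[i]),
            tile_count=int(counts[i]),
        )
        for i in range(n_patients)
    ]


# ---------------------------------------------------------------------------
# Annotated slide fixtures


@dataclass(frozen=True)
class SlideSimParams:
    """Geometry and colours for a painted synthetic slide."""

    width_px: int = 1600
    height_px: int = 1200
    n_positive_regions: int = 3
    n_gastric_regions: int = 1
    region_size_range_px: tuple[int, int] = (200, 600)
    positive_color: tuple[int, int, int] = (140, 70, 30)   # DAB-brown-ish
    gastric_color: tuple[int, int, int] = (70, 110, 180)
    background_color: tuple[int, int, int] = (235, 230, 240)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("slide dimensions must be positive")
        lo, hi = self.region_size_range_px
        if not (0 < lo <= hi):
            raise ValueError(f"invalid region_size_range_px {self.region_size_range_px}")
        if hi > self.width_px or hi > self.height_px:
            raise ValueError(
                f"region size {hi} exceeds slide dimensions "
                f"{self.width_px}x{self.height_px}"
            )
        for name in ("positive_color", "gastric_color", "background_color"):
            col = getattr(self, name)
            if len(col) != 3 or any(not (0 <= c <= 255) for c in col):
                raise ValueError(f"{name} must be an 8-bit RGB triple, got {col}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _random_convex_polygon(
    rng: np.random.Generator, cx: float, cy: float, radius: float
) -> Polygon:
    """Convex polygon: hull of 5-9 points on a jittered circle."""
    k = int(rng.integers(5, 10))
    angles = np.sort(rng.uniform(0, 2 * np.pi, k))
    radii = radius * rng.uniform(0.6, 1.0, k)
    pts = np.column_stack([cx + radii * np.cos(angles), cy + radii * np.sin(angles)])
    return Polygon(pts).convex_hull


def simulate_annotated_slide(params: SlideSimParams) -> AnnotatedSlide:
    """Paint non-overlapping convex regions and return raster + polygons + mask.

    The mask is produced by rasterising each polygon (pixel-centre rule)
    and the raster is painted *from the mask*, so polygons, mask and image
    agree exactly by construction.  Regions are placed by rejection
    sampling; overlapping candidates are re-drawn.
    """
    rng = np.random.default_rng(params.seed)
    W, H = params.width_px, params.height_px
    raster = np.empty((H, W, 3), dtype=np.uint8)
    raster[:] = np.asarray(params.background_color, dtype=np.uint8)
    mask = np.zeros((H, W), dtype=np.uint8)

    specs = [(LABEL_TFF3, AnnotatedSlide.MASK_TFF3, params.positive_color)] * params.n_positive_regions
    specs += [(LABEL_GASTRIC, AnnotatedSlide.MASK_GASTRIC, params.gastric_color)] * params.n_gastric_regions

    annotations: list[Annotation] = []
    placed: list[Polygon] = []
    for idx, (label, mask_value, color) in enumerate(specs):
        for _attempt in range(200):
            size = rng.uniform(*params.region_size_range_px)
            radius = size / 2.0
            cx = rng.uniform(radius, W - radius)
            cy = rng.uniform(radius, H - radius)
            poly = _random_convex_polygon(rng, cx, cy, radius)
            if all(not poly.intersects(other) for other in placed):
                break
        else:
            raise RuntimeError(
                f"could not place region {idx} without overlap after 200 attempts; "
                "reduce n_regions or region size"
            )
        placed.append(poly)
        region = rasterize_polygon(poly, W, H)
        mask[region] = mask_value
        raster[region] = np.asarray(color, dtype=np.uint8)
        annotations.append(Annotation(f"ann-{idx:03d}", label, poly))

    if params.noise_sd > 0:
        noisy = raster.astype(float) + rng.normal(0.0, params.noise_sd, raster.shape)
        raster = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)

    return AnnotatedSlide(raster, annotations, mask)
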