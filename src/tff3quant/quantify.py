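"""Per-patient tile counting, QC filtering, and correlation analyses.

The biomarker is simply the number of whole-slide grid tiles a classifier
calls TFF3-positive; a parallel count of gastric-cardia tiles serves as a
negative control (gastric sampling reflects whether the sponge reached the
stomach, not how long the Barrett's segment is).  Samples with no gastric
cardia mucosa fail quality control and are excluded from analysis.

The deep network that performs tile classification in production is out of
scope here; :func:`reference_classifier` is a deterministic colour-rule
classifier for synthetic slides that honours the same contract (pure
function from pixels to a label).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .tiling import AnnotatedSlide, TilingConfig, grid_tile_slide

__all__ = [
    "SlideQuantification",
    "reference_classifier",
    "make_reference_classifier",
    "count_positive_tiles",
    "qc_filter",
    "spearman_correlation",
    "negative_control_check",
    "NegativeControlResult",
]

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class SlideQuantification:
    """Automated tile counts for one patient's slide."""

    patient_id: str
    tff3_positive_tile_count: int
    gastric_tile_count: int
    qc_pass: bool = True

    def __post_init__(self) -> None:
        if self.tff3_positive_tile_count < 0 or self.gastric_tile_count < 0:
            raise ValueError("tile counts must be non-negative")


def reference_classifier(
    tile_pixels: np.ndarray,
    positive_color: Sequence[int],
    color_tolerance: float = 40.0,
    min_positive_pixel_fraction: float = 0.5,
) -> str:
    """Colour-rule tile classifier: the CNN contract's deterministic stand-in.

    A tile is ``"positive"`` iff the fraction of its pixels lying within
    ``color_tolerance`` (Chebyshev distance per channel) of
    ``positive_color`` is at least ``min_positive_pixel_fraction``.
    """
    px = np.asarray(tile_pixels)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"tile pixels must be (edge, edge, 3), got shape {px.shape}")
    target = np.asarray(positive_color, dtype=float)
    close = np.all(np.abs(px.astype(float) - target) <= color_tolerance, axis=-1)
    return POSITIVE if close.mean() >= min_positive_pixel_fraction else NEGATIVE


def make_reference_classifier(
    positive_color: Sequence[int],
    color_tolerance: float = 40.0,
    min_positive_pixel_fraction: float = 0.5,
) -> Callable[[np.ndarray], str]:
    """Bind the colour rule's parameters into a pixels -> label callable."""

    def classify(tile_pixels: np.ndarray) -> str:
        return reference_classifier(
            tile_pixels, positive_color, color_tolerance, min_positive_pixel_fraction
        )

    return classify


def count_positive_tiles(
    slide: AnnotatedSlide,
    classifier: Callable[[np.ndarray], str],
    config: TilingConfig,
    gastric_classifier: Optional[Callable[[np.ndarray], str]] = None,
    patient_id: str = "",
    qc_pass: bool = True,
) -> SlideQuantification:
    """Run a classifier over the whole-slide grid and count positive tiles.

    Counting is annotation-free: at screening time no annotations exist, so
    the grid covers the full raster.  ``gastric_classifier``, when given,
    is applied to the same tiles to produce the negative-control count.
    A classifier exception is re-raised with the offending tile's origin.
    """
    tileset = grid_tile_slide(slide, config)
    e = config.tile_edge_px
    n_pos = 0
    n_gastric = 0
    for tile in tileset.tiles:
        block = slide.raster[tile.y0 : tile.y0 + e, tile.x0 : tile.x0 + e]
        try:
            if classifier(block) == POSITIVE:
                n_pos += 1
            if gastric_classifier is not None and gastric_classifier(block) == POSITIVE:
                n_gastric += 1
        except Exception as exc:  # pragma: no cover - defensive reporting path
            raise RuntimeError(f"classifier failed on tile at ({tile.x0}, {tile.y0})") from exc
    return SlideQuantification(patient_id, n_pos, n_gastric, qc_pass)


def qc_filter(records: Iterable) -> tuple[list, list[tuple[object, str]]]:
    """Split records on the QC flag, preserving order.

    Returns ``(kept, excluded)`` where each excluded entry is
    ``(record, reason)``.  Records without a ``qc_pass`` attribute (or with
    ``qc_pass=None``) are excluded with reason ``"missing QC"`` rather than
    guessed at.
    """
    kept: list = []
    excluded: list[tuple[object, str]] = []
    for rec in records:
        flag = getattr(rec, "qc_pass", None)
        if flag is None:
            excluded.append((rec, "missing QC"))
        elif flag:
            kept.append(rec)
        else:
            excluded.append((rec, "no gastric cardia mucosa (QC fail)"))
    return kept, excluded


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN (the correlation is undefined, not zero) when either
    vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError(f"need n >= 3, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    return float(stats.spearmanr(x, y).statistic)


@dataclass(frozen=True)
class NegativeControlResult:
    rho_C: float
    rho_M: float
    bound: float

    @property
    def passed(self) -> bool:
        return abs(self.rho_C) < self.bound and abs(self.rho_M) < self.bound


def negative_control_check(
    gastric_counts: Sequence[float],
    C: Sequence[float],
    M: Sequence[float],
    bound: float = 0.2,
) -> NegativeControlResult:
    """Correlate gastric-control counts against both Prague lengths.

    Gastric tile counts should carry no information about segment length;
    the check fails when either |rho| reaches ``bound``.
    """
    return NegativeControlResult(
        rho_C=spearman_correlation(gastric_counts, C),
        rho_M=spearman_correlation(gastric_counts, M),
        bound=bound,
    )
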