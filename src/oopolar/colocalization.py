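"""Masked Pearson/Manders colocalization with a 90-degree rotation null.

All statistics are computed over a boolean region of interest (typically
the cytoplasm of one oocyte in a single confocal plane).  The negative
control rotates one channel — and the mask — by 90 degrees and re-computes
Pearson's r on the overlap of the original and rotated masks, a
configuration in which only chance colocalization remains.

The Manders coefficients here are the thresholded fractions: ``m1`` is the
share of above-threshold channel-1 signal that lies on above-threshold
channel-2 support, and symmetrically for ``m2``.  The classic intensity
overlap coefficient is also available (:func:`overlap_coefficient`) for
comparison, since the two are often conflated in the literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.filters import threshold_otsu

from .errors import (
    InsufficientOverlapError,
    InvalidInputError,
    ThresholdError,
    UndefinedCorrelationError,
)


@dataclass
class MaskedPair:
    """Two aligned intensity channels and the analysis mask.

    ``thresholds`` may be ``(t1, t2)`` grey levels or ``None`` to derive
    them per channel with :func:`auto_threshold`.
    """

    ch1: np.ndarray
    ch2: np.ndarray
    mask: np.ndarray
    thresholds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.ch1 = np.asarray(self.ch1, dtype=float)
        self.ch2 = np.asarray(self.ch2, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.ch1.shape == self.ch2.shape == self.mask.shape):
            raise InvalidInputError("channels and mask must share one shape")
        if not self.mask.any():
            raise InvalidInputError("mask is empty")
        if self.thresholds is not None and any(t < 0 for t in self.thresholds):
            raise InvalidInputError("thresholds must be >= 0")

    def resolved_thresholds(self) -> tuple[float, float]:
        if self.thresholds is not None:
            return self.thresholds
        return (auto_threshold(self.ch1, self.mask),
                auto_threshold(self.ch2, self.mask))


@dataclass
class ColocResult:
    pearson_r: float
    m1: float | None
    m2: float | None
    null_r: float
    thresholds: tuple[float, float]
    n_pixels: int


def pearson(pair: MaskedPair) -> float:
    """Sample Pearson correlation of the two channels over masked pixels."""
    x = pair.ch1[pair.mask]
    y = pair.ch2[pair.mask]
    if x.size < 2:
        raise InvalidInputError("need at least two masked pixels")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "a channel is constant within the mask; correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def auto_threshold(channel: np.ndarray, mask: np.ndarray,
                   method: str = "otsu") -> float:
    """Deterministic per-channel threshold from the masked histogram."""
    values = np.asarray(channel, dtype=float)[np.asarray(mask, dtype=bool)]
    if values.size == 0:
        raise InvalidInputError("mask is empty")
    if np.ptp(values) == 0:
        raise ThresholdError("channel is constant within the mask")
    if method != "otsu":
        raise InvalidInputError(f"unknown threshold method {method!r}")
    return float(threshold_otsu(values))


def manders(pair: MaskedPair) -> tuple[float | None, float | None]:
    """Thresholded Manders fractions (m1, m2).

    ``m1 = sum(ch1 over ch1>t1 & ch2>t2) / sum(ch1 over ch1>t1)`` within the
    mask, and symmetrically for ``m2``.  A coefficient whose channel has no
    above-threshold signal is returned as ``None`` (undefined), not 0.
    """
    t1, t2 = pair.resolved_thresholds()
    in1 = pair.mask & (pair.ch1 > t1)
    in2 = pair.mask & (pair.ch2 > t2)

    def fraction(ch: np.ndarray, own: np.ndarray,
                 other: np.ndarray) -> float | None:
        denom = ch[own].sum()
        if denom <= 0:
            return None
        return float(ch[own & other].sum() / denom)

    return fraction(pair.ch1, in1, in2), fraction(pair.ch2, in2, in1)


def overlap_coefficient(pair: MaskedPair) -> float:
    """Classic intensity overlap coefficient over above-threshold pixels."""
    t1, t2 = pair.resolved_thresholds()
    sel = pair.mask & ((pair.ch1 > t1) | (pair.ch2 > t2))
    x, y = pair.ch1[sel], pair.ch2[sel]
    denom = np.sqrt((x ** 2).sum() * (y ** 2).sum())
    if denom == 0:
        raise InvalidInputError("no above-threshold signal in either channel")
    return float((x * y).sum() / denom)


def rotation_null(pair: MaskedPair, min_overlap: int = 100) -> float:
    """Pearson's r after rotating channel 2 (and the mask) by 90 degrees.

    Only chance colocalization survives the rotation, so this estimates the
    correlation floor for the pair.  On non-square frames the full frame is
    rotated (its shape transposes) and the statistic is taken on the
    overlapping region of the original and rotated masks.  Note the control
    is blind to patterns that are themselves 90-degree rotation symmetric.
    """
    ch2r = np.rot90(pair.ch2)
    maskr = np.rot90(pair.mask)
    m = min(pair.mask.shape[0], pair.mask.shape[1])
    inter = pair.mask[:m, :m] & maskr[:m, :m]
    if inter.sum() < min_overlap:
        raise InsufficientOverlapError(
            f"mask and rotated mask overlap on {int(inter.sum())} px "
            f"(< {min_overlap})")
    x = pair.ch1[:m, :m][inter]
    y = ch2r[:m, :m][inter]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "a channel is constant on the rotation overlap")
    return float(stats.pearsonr(x, y).statistic)


def coloc_analysis(pair: MaskedPair) -> ColocResult:
    """Pearson, Manders fractions and the rotation null in one pass."""
    thresholds = pair.resolved_thresholds()
    m1, m2 = manders(pair)
    return ColocResult(pearson_r=pearson(pair), m1=m1, m2=m2,
                       null_r=rotation_null(pair), thresholds=thresholds,
                       n_pixels=int(pair.mask.sum()))
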