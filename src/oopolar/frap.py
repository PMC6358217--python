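"""FRAP recovery quantification for the anterior and posterior domains.

A FRAP acquisition is a time stack: several pre-bleach frames (six in the
standard protocol), a photobleach of the nurse cells plus the anterior
membrane, then time-lapse recovery.  Each frame is quantified with the same
band measurement as the still-image pipeline, reusing the trace and
partition from the first frame, giving per-frame anterior and posterior
quantities.  Two normalizations are derived:

* **rebased** — the quantity at the first post-bleach frame is subtracted,
  so each domain's curve starts at 0 at the bleach and its sign shows gain
  (anterior recovery) or loss (posterior exclusion);
* **pre-bleach normalized** — each domain is divided by its own pre-bleach
  mean, so 1.0 is the unbleached level and the post-bleach plateau reads
  directly as a recovered fraction.

Recovery is summarized non-parametrically by the mean of the last three
frames and the sign of the post-bleach trend; an optional
saturating-exponential fit is provided for rate estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import BleachDetectionError, InvalidInputError
from .membrane_geometry import AnchorPoints
from .quantification import QuantConfig, measure_domain, partition_domains, \
    snap_anchors, trace_perimeter

DOMAINS = ("anterior", "posterior")


@dataclass
class FrapSeries:
    """Raw per-frame quantities for the anterior and posterior domains."""

    times: np.ndarray
    quantities: dict[str, np.ndarray]
    bleach_index: int | None = None
    n_prebleach: int = 6

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.quantities = {k: np.asarray(v, dtype=float)
                           for k, v in self.quantities.items()}
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("frame times must be strictly increasing")
        for k, v in self.quantities.items():
            if len(v) != len(self.times):
                raise InvalidInputError(f"domain {k!r}: one quantity per frame")
            if np.any(v < 0):
                raise InvalidInputError(f"domain {k!r}: quantities must be >= 0")
        if self.n_prebleach < 1:
            raise InvalidInputError("need at least one pre-bleach frame")
        if self.bleach_index is not None \
                and self.bleach_index < self.n_prebleach:
            raise InvalidInputError("bleach_index must be >= n_prebleach")


@dataclass
class FrapResult:
    """Both normalizations plus a non-parametric recovery summary."""

    times: np.ndarray
    rebased: dict[str, np.ndarray]             # frames >= bleach_index
    rebased_times: np.ndarray
    prebleach_normalized: dict[str, np.ndarray]  # all frames
    bleach_index: int
    n_prebleach: int
    recovery_summary: dict[str, dict[str, float]]


def detect_bleach_frame(series: FrapSeries,
                        declared_index: int | None = None,
                        min_drop: float = 0.2,
                        reference: str = "anterior") -> int:
    """Locate the first post-bleach frame.

    The bleach event is normally known from the acquisition, in which case
    ``declared_index`` is passed straight through.  Otherwise the frame with
    the largest single-step fractional drop of the reference domain's
    quantity is returned, provided that drop exceeds ``min_drop``.
    """
    n = len(series.times)
    if declared_index is not None:
        if not 0 < declared_index < n:
            raise InvalidInputError("declared bleach index out of range")
        return int(declared_index)
    if n < 3:
        raise InvalidInputError("need at least three frames to detect a bleach")
    q = series.quantities[reference]
    prev = q[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        drops = np.where(prev > 0, (prev - q[1:]) / prev, 0.0)
    best = int(np.argmax(drops))
    if drops[best] <= min_drop:
        raise BleachDetectionError(
            f"no single-frame drop exceeds {min_drop:.0%}; "
            "pass the bleach index explicitly")
    return best + 1


def rebase_to_zero(series: FrapSeries,
                   bleach_index: int) -> dict[str, np.ndarray]:
    """Post-bleach curves with the bleach-frame value subtracted."""
    if not 0 <= bleach_index < len(series.times):
        raise InvalidInputError("bleach_index out of range")
    return {k: v[bleach_index:] - v[bleach_index]
            for k, v in series.quantities.items()}


def normalize_prebleach(series: FrapSeries, bleach_index: int,
                        n_prebleach: int = 6) -> dict[str, np.ndarray]:
    """Every frame divided by the domain's mean over its pre-bleach frames."""
    if not 0 < bleach_index <= len(series.times):
        raise InvalidInputError("bleach_index out of range")
    if n_prebleach < 1 or n_prebleach > bleach_index:
        raise InvalidInputError(
            "n_prebleach must be in [1, bleach_index]")
    out = {}
    for k, v in series.quantities.items():
        pre = v[bleach_index - n_prebleach:bleach_index].mean()
        if pre <= 0:
            raise InvalidInputError(f"domain {k!r}: zero pre-bleach mean")
        out[k] = v / pre
    return out


def analyze_frap(series: FrapSeries, declared_index: int | None = None,
                 end_window: int = 3) -> FrapResult:
    """Bleach detection, both normalizations and the recovery summary."""
    bleach = detect_bleach_frame(series, declared_index
                                 if declared_index is not None
                                 else series.bleach_index)
    rebased = rebase_to_zero(series, bleach)
    normalized = normalize_prebleach(series, bleach, series.n_prebleach)
    summary = {}
    for k in series.quantities:
        tail_rb = rebased[k][-end_window:]
        tail_nm = normalized[k][-end_window:]
        summary[k] = {
            "rebased_end_mean": float(tail_rb.mean()),
            "normalized_end_mean": float(tail_nm.mean()),
            "trend_sign": float(np.sign(tail_rb.mean())),
        }
    return FrapResult(times=series.times, rebased=rebased,
                      rebased_times=series.times[bleach:],
                      prebleach_normalized=normalized, bleach_index=bleach,
                      n_prebleach=series.n_prebleach,
                      recovery_summary=summary)


def fit_recovery(times: np.ndarray, values: np.ndarray
                 ) -> dict[str, float]:
    """Optional saturating-exponential fit ``A * (1 - exp(-k t))``.

    ``times`` should be relative to the bleach frame and ``values`` rebased
    to zero there.  Returns the plateau ``A`` and rate ``k`` (1/s).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) < 3:
        raise InvalidInputError("need at least three post-bleach frames to fit")

    def model(t, amp, k):
        return amp * (1.0 - np.exp(-k * t))

    a0 = values[-1] if values[-1] != 0 else 1.0
    popt, _ = curve_fit(model, times, values, p0=(a0, 0.01), maxfev=10000)
    return {"plateau": float(popt[0]), "rate": float(popt[1])}


def measure_stack(stack: np.ndarray, anchors: AnchorPoints,
                  frame_interval_s: float,
                  config: QuantConfig | None = None,
                  bleach_index: int | None = None,
                  n_prebleach: int = 6) -> FrapSeries:
    """Per-frame anterior/posterior quantities from a FRAP time stack.

    The membrane trace and partition are built once on the first (pre-bleach)
    frame and reused for every frame — the standard assumption that the egg
    chamber does not drift over the recording.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise InvalidInputError("stack must be (frames, rows, cols)")
    config = config or QuantConfig()
    snapped = snap_anchors(stack[0], anchors, config.snap_radius)
    trace = trace_perimeter(stack[0], snapped, config.tracing,
                            pixel_size=config.pixel_size)
    partition = partition_domains(trace, snapped, config.posterior_fraction)

    quantities = {d: np.empty(len(stack)) for d in DOMAINS}
    for i, frame in enumerate(stack):
        quantities["anterior"][i] = measure_domain(
            frame, partition, "anterior", config.band_width).quantity
        quantities["posterior"][i] = measure_domain(
            frame, partition, "posterior", config.band_width).quantity
    times = np.arange(len(stack), dtype=float) * frame_interval_s
    return FrapSeries(times=times, quantities=quantities,
                      bleach_index=bleach_index, n_prebleach=n_prebleach)


def analyze_frap_stack(stack: np.ndarray, anchors: AnchorPoints,
                       frame_interval_s: float,
                       config: QuantConfig | None = None,
                       bleach_index: int | None = None,
                       n_prebleach: int = 6) -> FrapResult:
    """Convenience wrapper: :func:`measure_stack` then :func:`analyze_frap`."""
    series = measure_stack(stack, anchors, frame_interval_s, config,
                           bleach_index, n_prebleach)
    return analyze_frap(series)
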