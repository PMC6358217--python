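"""Membrane tracing and four-domain partition of the oocyte cortex.

The quantification workflow starts from three user-supplied anchor points:
two flanking the anterior plasma membrane (``a1``, ``a2``, on either side of
the oocyte/nurse-cell interface) and one at the midpoint of the posterior
membrane (``p``).  From a single-plane fluorescence image and these anchors
this module

1. snaps the anchors onto the membrane intensity ridge (:func:`snap_anchors`),
2. traces a closed, 8-connected pixel path around the oocyte perimeter
   (:func:`trace_perimeter`), and
3. partitions that path into the four cortical domains — anterior, lateral 1,
   lateral 2 and posterior (:func:`partition_domains`).

Anterior is the arc between ``a1`` and ``a2`` that does not contain ``p``;
the posterior domain is an arc of configurable fraction of the non-anterior
perimeter, centred (by arc length) on ``p``; the two laterals are what
remains, ``lateral1`` being the arc that meets ``a1``.

Coordinates are 0-based ``(row, col)`` pixel centres throughout.  Arc length
is, by default, measured on a periodically smoothed copy of the pixel chain;
see :class:`TracingConfig.arc_rule`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.ndimage import gaussian_filter1d
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.morphology import disk

from .errors import (
    ConfigurationError,
    InvalidAnchorError,
    InvalidInputError,
    SnapFailureError,
    TracingError,
)

DOMAIN_LABELS = ("anterior", "lateral1", "lateral2", "posterior")

#: clockwise Moore neighbourhood starting at west, used by the boundary tracer
_MOORE = ((0, -1), (-1, -1), (-1, 0), (-1, 1),
          (0, 1), (1, 1), (1, 0), (1, -1))


@dataclass(frozen=True)
class AnchorPoints:
    """The three manual anchor points, as 0-based ``(row, col)`` pixels.

    ``a1`` and ``a2`` flank the anterior membrane; ``p`` marks the middle of
    the posterior membrane.
    """

    a1: tuple[int, int]
    a2: tuple[int, int]
    p: tuple[int, int]

    def as_dict(self) -> dict[str, tuple[int, int]]:
        return {"a1": self.a1, "a2": self.a2, "p": self.p}

    def validate(self, shape: tuple[int, int]) -> None:
        pts = self.as_dict()
        for label, (r, c) in pts.items():
            if not (0 <= r < shape[0] and 0 <= c < shape[1]):
                raise InvalidInputError(
                    f"anchor {label!r} at ({r}, {c}) outside image of shape {shape}")
        if len({tuple(v) for v in pts.values()}) != 3:
            raise InvalidInputError("anchor points must be pairwise distinct")


@dataclass(frozen=True)
class TracingConfig:
    """Parameters of the automated perimeter tracer.

    threshold_method
        ``"auto"`` (default): candidate thresholds from three- and
        four-class Otsu splits of the histogram are tried brightest-first
        and the first whose membrane component reaches all three anchors is
        kept — robust both to diffuse cytoplasmic signal and to membrane
        domains of very different brightness.  ``"multiotsu"``: only the top
        three-class Otsu boundary.  ``"percentile"``: pixels strictly
        brighter than ``threshold_percentile`` of the whole image — adequate
        for images that are mostly background.
    threshold_percentile
        Percentile used by the ``"percentile"`` method (default 75).
    closing_radius
        Radius (px) of the morphological closing that bridges small gaps in
        the thresholded membrane band.
    snap_radius
        Maximum distance (px) between a snapped anchor and the final trace.
    arc_rule
        ``"smoothed"`` (default): per-step lengths measured on a periodic
        Gaussian-smoothed copy of the pixel chain, which tracks analytic
        perimeters of smooth shapes to ~1%.  ``"chain"``: raw Euclidean chain
        steps (1 axial, sqrt(2) diagonal); simple but overestimates smooth
        perimeters by ~5%.
    smooth_sigma
        Smoothing scale (in vertices) for the ``"smoothed"`` rule.
    """

    threshold_method: str = "auto"
    threshold_percentile: float = 75.0
    closing_radius: int = 2
    snap_radius: int = 5
    arc_rule: str = "smoothed"
    smooth_sigma: float = 3.0


@dataclass
class MembraneTrace:
    """Ordered closed pixel path of the oocyte plasma membrane.

    ``points`` has shape ``(n + 1, 2)`` with ``points[0] == points[-1]``
    (closed); consecutive points are 8-connected.  ``step_lengths[i]`` is the
    arc length of the step from point ``i`` to ``i + 1`` under the configured
    arc rule, in pixels; multiply by ``pixel_size`` for physical units.
    """

    points: np.ndarray
    step_lengths: np.ndarray
    closed: bool = True
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=int)
        self.step_lengths = np.asarray(self.step_lengths, dtype=float)
        if not np.array_equal(self.points[0], self.points[-1]):
            raise InvalidInputError("trace must be closed (first point == last)")
        if len(self.step_lengths) != len(self.points) - 1:
            raise InvalidInputError("need one step length per trace edge")

    @property
    def n_points(self) -> int:
        """Number of distinct trace points (the closing duplicate excluded)."""
        return len(self.points) - 1

    @property
    def perimeter(self) -> float:
        """Total arc length in pixels."""
        return float(self.step_lengths.sum())

    @property
    def perimeter_um(self) -> float:
        return self.perimeter * self.pixel_size

    @property
    def arc_positions(self) -> np.ndarray:
        """Cumulative arc position of each distinct point, ``s[0] = 0``."""
        return np.concatenate([[0.0], np.cumsum(self.step_lengths[:-1])])

    def enclosed_area(self) -> float:
        """Unsigned shoelace area of the closed polygon, in px^2."""
        y = self.points[:, 0].astype(float)
        x = self.points[:, 1].astype(float)
        return abs(float(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1])) / 2.0)

    def nearest_index(self, point: tuple[int, int]) -> int:
        d = np.linalg.norm(self.points[:-1] - np.asarray(point, float), axis=1)
        return int(np.argmin(d))


@dataclass
class DomainPartition:
    """The four contiguous cortical arcs on a :class:`MembraneTrace`.

    ``segments[label] = (start, stop)`` is a half-open cyclic index range on
    the distinct trace points (``stop`` may be numerically smaller than
    ``start`` when the segment wraps past the trace origin).  The segments
    are disjoint and jointly cover the trace; their lengths sum exactly to
    the perimeter.
    """

    segments: dict[str, tuple[int, int]]
    lengths: dict[str, float]
    trace: MembraneTrace = field(repr=False)

    def indices(self, label: str) -> np.ndarray:
        """Trace-point indices of a domain, in trace order."""
        start, stop = self.segments[label]
        n = self.trace.n_points
        if start <= stop:
            return np.arange(start, stop)
        return np.concatenate([np.arange(start, n), np.arange(0, stop)])

    def label_of(self) -> np.ndarray:
        """Array mapping each distinct trace index to its domain label."""
        out = np.empty(self.trace.n_points, dtype=object)
        for label in DOMAIN_LABELS:
            out[self.indices(label)] = label
        return out

    def lengths_um(self) -> dict[str, float]:
        px = self.trace.pixel_size
        return {k: v * px for k, v in self.lengths.items()}


# ---------------------------------------------------------------------------
# anchor snapping


def snap_anchors(image: np.ndarray, anchors: AnchorPoints,
                 snap_radius: int = 5,
                 background_percentile: float = 50.0) -> AnchorPoints:
    """Move each anchor to the brightest pixel within ``snap_radius``.

    Makes manual clicks reproducible: the anchor lands on the local membrane
    ridge.  Ties break deterministically to the lowest row, then lowest
    column.  With ``snap_radius == 0`` the anchors are returned unchanged.

    Raises
    ------
    InvalidInputError
        If an anchor lies outside the image.
    SnapFailureError
        If no pixel within the radius exceeds the image's
        ``background_percentile`` intensity (nothing membrane-like nearby).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise InvalidInputError("snap_anchors expects a single-channel 2D image")
    if snap_radius < 0:
        raise InvalidInputError("snap_radius must be >= 0")
    anchors.validate(image.shape)
    if snap_radius == 0:
        return anchors

    background = np.percentile(image, background_percentile)
    snapped = {}
    for label, (r, c) in anchors.as_dict().items():
        r0, r1 = max(0, r - snap_radius), min(image.shape[0], r + snap_radius + 1)
        c0, c1 = max(0, c - snap_radius), min(image.shape[1], c + snap_radius + 1)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        within = (rr - r) ** 2 + (cc - c) ** 2 <= snap_radius ** 2
        window = np.where(within, image[r0:r1, c0:c1], -np.inf)
        best = window.max()
        if not best > background:
            raise SnapFailureError(label)
        # ties (flat-topped ridge): nearest max to the click, then (row, col)
        ties = np.argwhere(window == best)
        d2 = (ties[:, 0] + r0 - r) ** 2 + (ties[:, 1] + c0 - c) ** 2
        order = np.lexsort((ties[:, 1], ties[:, 0], d2))
        tr_, tc_ = ties[order[0]]
        snapped[label] = (r0 + int(tr_), c0 + int(tc_))
    return AnchorPoints(**snapped)


# ---------------------------------------------------------------------------
# perimeter tracing


def _moore_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered closed boundary pixel chain of a filled binary region.

    Moore-neighbour tracing with Jacob's stopping criterion.  Returns an
    array of (row, col) without the closing duplicate.
    """
    padded = np.pad(mask, 1)
    pts = np.argwhere(padded)
    start = tuple(pts[np.lexsort((pts[:, 1], pts[:, 0]))[0]])
    backtrack = (start[0], start[1] - 1)  # west of start is background
    path = [start]
    cur, back = start, backtrack
    first_move: tuple[int, int] | None = None
    limit = 4 * padded.size
    for _ in range(limit):
        d = (back[0] - cur[0], back[1] - cur[1])
        i0 = _MOORE.index(d)
        nxt = None
        for k in range(1, 9):
            off = _MOORE[(i0 + k) % 8]
            cand = (cur[0] + off[0], cur[1] + off[1])
            if padded[cand]:
                nxt = cand
                prev_off = _MOORE[(i0 + k - 1) % 8]
                back = (cur[0] + prev_off[0], cur[1] + prev_off[1])
                break
        if nxt is None:  # isolated pixel
            break
        if cur == start and first_move is None:
            first_move = nxt
        elif cur == start and nxt == first_move:
            break
        path.append(nxt)
        cur = nxt
    else:  # pragma: no cover - safety net
        raise TracingError("boundary tracing did not terminate")
    if path[-1] == start:
        path.pop()
    return np.array(path) - 1  # undo padding


def _signed_area(points: np.ndarray) -> float:
    """Shoelace area in the (x=col, y=row) plane (y axis pointing down)."""
    y = points[:, 0].astype(float)
    x = points[:, 1].astype(float)
    xc = np.concatenate([x, x[:1]])
    yc = np.concatenate([y, y[:1]])
    return float(np.sum(xc[:-1] * yc[1:] - xc[1:] * yc[:-1])) / 2.0


def _step_lengths(points: np.ndarray, config: TracingConfig) -> np.ndarray:
    """Arc length of each edge of the closed chain (one per distinct point)."""
    closed = np.vstack([points, points[:1]]).astype(float)
    if config.arc_rule == "chain":
        return np.linalg.norm(np.diff(closed, axis=0), axis=1)
    if config.arc_rule != "smoothed":
        raise InvalidInputError(f"unknown arc_rule {config.arc_rule!r}")
    smooth = gaussian_filter1d(points.astype(float), sigma=config.smooth_sigma,
                               axis=0, mode="wrap")
    sm_closed = np.vstack([smooth, smooth[:1]])
    return np.linalg.norm(np.diff(sm_closed, axis=0), axis=1)


def _candidate_thresholds(image: np.ndarray, config: TracingConfig
                          ) -> list[float]:
    """Candidate membrane thresholds, brightest-first.

    ``"auto"`` collects every class boundary of three- and four-class Otsu
    splits of the histogram; ``"multiotsu"`` keeps only the top three-class
    boundary; ``"percentile"`` uses the configured percentile.  Images with
    too few grey levels fall back to a plain two-class Otsu split.
    """
    if config.threshold_method == "percentile":
        return [float(np.percentile(image, config.threshold_percentile))]
    if config.threshold_method not in ("auto", "multiotsu"):
        raise InvalidInputError(
            f"unknown threshold_method {config.threshold_method!r}")
    cands: list[float] = []
    for classes in ((3, 4) if config.threshold_method == "auto" else (3,)):
        try:
            splits = threshold_multiotsu(image, classes=classes)
            cands.extend(float(t) for t in
                         (splits if config.threshold_method == "auto"
                          else splits[-1:]))
        except ValueError:
            pass
    if not cands:
        try:
            cands = [float(threshold_otsu(image))]
        except ValueError:
            raise TracingError("image has no intensity structure "
                               "(constant grey level)") from None
    cands = sorted(set(cands))
    # sparse membrane classes can leave the cytoplasm/membrane boundary
    # unsampled; midpoints between neighbouring splits fill those gaps
    cands += [(a + b) / 2 for a, b in zip(cands, cands[1:])]
    return sorted(set(cands), reverse=True)


def _band_at_threshold(image: np.ndarray, thresh: float,
                       config: TracingConfig) -> np.ndarray | None:
    """Largest connected membrane component above a threshold, or None."""
    band = image > thresh
    if config.closing_radius > 0:
        band = ndimage.binary_closing(band, disk(config.closing_radius))
    labels, n = ndimage.label(band, structure=np.ones((3, 3), int))
    if n == 0:
        return None
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def membrane_mask(image: np.ndarray, config: TracingConfig,
                  anchors: AnchorPoints | None = None) -> np.ndarray:
    """Binary mask of the membrane band.

    Candidate thresholds are tried brightest-first; the first whose largest
    connected component passes within ``config.snap_radius`` of all anchors
    (when given) wins, so a membrane whose domains differ strongly in
    brightness is still captured whole.  Without anchors the brightest
    candidate that yields any component is used.
    """
    def reaches_anchors(band: np.ndarray) -> bool:
        if anchors is None:
            return True
        dist = ndimage.distance_transform_edt(~band)
        return all(dist[pt] <= config.snap_radius
                   for pt in anchors.as_dict().values())

    def is_closed_ring(band: np.ndarray) -> bool:
        # a closed membrane band encloses an interior much larger than itself
        filled = ndimage.binary_fill_holes(band)
        return filled.sum() - band.sum() > band.sum()

    candidates = [band for thresh in _candidate_thresholds(image, config)
                  if (band := _band_at_threshold(image, thresh, config))
                  is not None]
    if not candidates:
        raise TracingError("no membrane-like pixels above threshold")
    for band in candidates:  # prefer a closed ring through all anchors
        if reaches_anchors(band) and is_closed_ring(band):
            return band
    for band in candidates:  # fall back to a solid blob through the anchors
        if reaches_anchors(band):
            return band
    raise TracingError(
        "no threshold yields a membrane component reaching all three "
        "anchors; are the anchors on the same structure?",
        diagnostic_mask=candidates[0])


def trace_perimeter(image: np.ndarray, anchors: AnchorPoints,
                    config: TracingConfig | None = None,
                    pixel_size: float = 1.0) -> MembraneTrace:
    """Trace the closed oocyte membrane contour through the three anchors.

    The membrane band is segmented by intensity (see :func:`membrane_mask`),
    holes are filled, the filled blob is eroded by half the estimated band
    thickness so the boundary follows the intensity ridge rather than the
    band's outer edge, and the boundary is extracted as an ordered pixel
    chain.  The trace is oriented counter-clockwise (as displayed, row axis
    down) and rotated to start at the point nearest ``a1``.

    Raises
    ------
    TracingError
        If no contour exists or the contour misses one of the anchors by
        more than ``config.snap_radius`` (e.g. anchors on different
        structures, or an open membrane).
    """
    config = config or TracingConfig()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise InvalidInputError("trace_perimeter expects a single-channel 2D image")
    anchors.validate(image.shape)

    band = membrane_mask(image, config, anchors)
    filled = ndimage.binary_fill_holes(band)
    if filled.sum() < 9:
        raise TracingError("membrane region too small to trace",
                           diagnostic_mask=band)

    outer = _moore_boundary(filled)
    # erode by half the band thickness so the trace rides the ridge
    thickness = band.sum() / max(len(outer), 1)
    # cap: a solid (non-ring) mask would otherwise suggest a huge erosion
    erode_r = min(int(round((thickness - 1) / 2)), 3)
    if erode_r > 0:
        eroded = ndimage.binary_erosion(filled, disk(erode_r))
        if eroded.sum() >= 9:
            filled = eroded
            outer = _moore_boundary(filled)

    points = outer
    if _signed_area(points) > 0:  # positive shoelace here = clockwise on screen
        points = points[::-1]

    # verify the contour passes near every anchor, then start at a1
    tol = max(config.snap_radius, erode_r + 1)
    for label, pt in anchors.as_dict().items():
        d = np.linalg.norm(points - np.asarray(pt, float), axis=1).min()
        if d > tol:
            raise TracingError(
                f"traced contour misses anchor {label!r} by {d:.1f} px "
                f"(tolerance {tol}); anchors may lie on different structures",
                diagnostic_mask=band)
    i1 = int(np.argmin(np.linalg.norm(points - np.asarray(anchors.a1, float),
                                      axis=1)))
    points = np.roll(points, -i1, axis=0)

    steps = _step_lengths(points, config)
    closed_pts = np.vstack([points, points[:1]])
    return MembraneTrace(points=closed_pts, step_lengths=steps,
                         pixel_size=pixel_size)


def densify_polygon(vertices: np.ndarray, config: TracingConfig | None = None,
                    pixel_size: float = 1.0) -> MembraneTrace:
    """Build a :class:`MembraneTrace` from a user-supplied polygon.

    Manual escape hatch for images the automatic tracer cannot handle: the
    vertex list is densified to an 8-connected pixel chain by Bresenham-style
    interpolation between consecutive vertices.
    """
    config = config or TracingConfig()
    vertices = np.asarray(vertices, dtype=int)
    if len(vertices) < 3:
        raise InvalidInputError("polygon needs at least 3 vertices")
    if np.array_equal(vertices[0], vertices[-1]):
        vertices = vertices[:-1]
    chain: list[tuple[int, int]] = []
    for v0, v1 in zip(vertices, np.roll(vertices, -1, axis=0)):
        n = int(max(abs(v1[0] - v0[0]), abs(v1[1] - v0[1])))
        for t in range(max(n, 1)):
            r = int(round(v0[0] + (v1[0] - v0[0]) * t / max(n, 1)))
            c = int(round(v0[1] + (v1[1] - v0[1]) * t / max(n, 1)))
            if not chain or (r, c) != chain[-1]:
                chain.append((r, c))
    points = np.array(chain)
    if _signed_area(points) > 0:
        points = points[::-1]
    steps = _step_lengths(points, config)
    return MembraneTrace(points=np.vstack([points, points[:1]]),
                         step_lengths=steps, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# domain partition


def _nearest_arc_index(s: np.ndarray, perimeter: float, target: float) -> int:
    d = np.abs(s - (target % perimeter))
    d = np.minimum(d, perimeter - d)
    return int(np.argmin(d))


def partition_domains(trace: MembraneTrace, anchors: AnchorPoints,
                      posterior_fraction: float = 0.20) -> DomainPartition:
    """Split the trace into anterior, lateral1, lateral2 and posterior arcs.

    The anterior domain is the arc between the snapped ``a1`` and ``a2`` not
    containing ``p``.  The posterior domain has arc length
    ``posterior_fraction * (perimeter - anterior length)`` and is centred, by
    arc length, on ``p`` — a fixed-fraction rule that is independent of the
    oogenesis stage.  ``lateral1`` is the remaining arc adjacent to ``a1``.

    Raises
    ------
    InvalidAnchorError
        If ``p`` falls on the anterior arc.
    ConfigurationError
        If the posterior arc would overlap the anterior one.
    """
    if not 0.0 < posterior_fraction < 1.0:
        raise InvalidInputError("posterior_fraction must be in (0, 1)")
    n = trace.n_points
    perimeter = trace.perimeter
    s = trace.arc_positions

    ia2 = trace.nearest_index(anchors.a2)
    ip = trace.nearest_index(anchors.p)
    if ia2 == 0 or ip == 0 or ia2 == ip:
        raise InvalidAnchorError("anchors collapse onto the same trace point")
    sa2, sp = s[ia2], s[ip]

    # anterior = arc between a1 (s=0) and a2 not containing p
    forward = sp > sa2  # p lies on the arc a2 -> end; anterior is [0, sa2]
    if forward:
        ant_lo, ant_hi = 0.0, sa2
        ant_len = sa2
    else:
        ant_lo, ant_hi = sa2, perimeter
        ant_len = perimeter - sa2

    post_len = posterior_fraction * (perimeter - ant_len)
    p_lo, p_hi = sp - post_len / 2.0, sp + post_len / 2.0
    if forward:
        if p_lo < ant_hi or p_hi > perimeter:
            raise ConfigurationError(
                "posterior arc would overlap the anterior arc; reduce "
                "posterior_fraction or re-place anchors")
        i_plo = _nearest_arc_index(s, perimeter, p_lo)
        i_phi = _nearest_arc_index(s, perimeter, p_hi)
        segments = {
            "anterior": (0, ia2),
            "lateral2": (ia2, i_plo),
            "posterior": (i_plo, i_phi),
            "lateral1": (i_phi, 0),
        }
    else:
        if p_lo < 0.0 or p_hi > ant_lo:
            raise ConfigurationError(
                "posterior arc would overlap the anterior arc; reduce "
                "posterior_fraction or re-place anchors")
        i_plo = _nearest_arc_index(s, perimeter, p_lo)
        i_phi = _nearest_arc_index(s, perimeter, p_hi)
        segments = {
            "lateral1": (0, i_plo),
            "posterior": (i_plo, i_phi),
            "lateral2": (i_phi, ia2),
            "anterior": (ia2, 0),
        }

    lengths = {}
    for label, (start, stop) in segments.items():
        hi = s[stop] if stop != 0 else perimeter
        lengths[label] = float(hi - s[start])
        if lengths[label] <= 0:
            raise InvalidAnchorError(
                f"domain {label!r} degenerated to zero length; anchors too close")
    return DomainPartition(segments=segments, lengths=lengths, trace=trace)
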