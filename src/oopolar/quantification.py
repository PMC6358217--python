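"""Per-domain signal measurement and the normalized polarity metrics.

Given a traced membrane and its four-domain partition this module measures,
for each cortical domain, the mean fluorescence in a thin band normal to the
trace and the domain's arc length; measures the cytoplasm inside the trace;
removes the nurse-cell membrane contribution from the anterior signal; and
derives the normalized metrics:

* **quantity** — mean band intensity x domain length, the band-integrated
  grey-level signal of a domain (additive across domains);
* **fraction** — quantity divided by the oocyte total
  (APM + LPM + PPM + cytoplasm), which cancels expression-level and
  acquisition differences between oocytes;
* **density** — a membrane domain's fraction divided by its length, which
  cancels membrane growth between stages.  Densities of the cortical
  domains do not sum to 1 by construction;
* **posterior exclusion ratio** — LPM density / PPM density (values above 1
  mean the protein is excluded from the posterior membrane, below 1 that it
  accumulates there);
* **asymmetry ratio** — APM density / PPM density, the antero-posterior
  polarization of the signal;
* **cytoplasmic fraction** — cytoplasm quantity / total.

The anterior interface carries the oocyte's own membrane plus the apposed
nurse-cell membrane.  The correction estimates the one-membrane nurse
signal from the user-measured mean intensities of a simple and a double
nurse–nurse membrane (their difference cancels the diffuse background) and
subtracts it from the anterior band mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.ndimage import distance_transform_edt, gaussian_filter1d

from .errors import DegenerateGeometryError, InvalidInputError
from .membrane_geometry import (
    AnchorPoints,
    DomainPartition,
    MembraneTrace,
    TracingConfig,
    partition_domains,
    snap_anchors,
    trace_perimeter,
)

MEMBRANE_KEYS = ("APM", "LPM", "PPM")


@dataclass
class DomainMeasurement:
    """Band measurement of one cortical domain.

    ``quantity = mean_intensity * length`` is the band-integrated signal;
    ``profile`` holds one band-averaged intensity per trace point of the
    segment, in trace order.
    """

    label: str
    mean_intensity: float
    length: float
    quantity: float = field(init=False)
    profile: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise InvalidInputError(f"domain {self.label!r}: length must be > 0")
        if self.mean_intensity < 0:
            raise InvalidInputError("mean intensity must be >= 0")
        self.quantity = self.mean_intensity * self.length


@dataclass
class CytoplasmMeasurement:
    mean_intensity: float
    area: float
    quantity: float = field(init=False)

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise InvalidInputError("cytoplasm area must be > 0")
        self.quantity = self.mean_intensity * self.area


@dataclass
class NurseBackground:
    """Per-unit-length nurse membrane signal at the anterior interface.

    ``contribution`` is what one extra membrane adds on top of the local
    background: the difference between a double and a simple nurse membrane
    (mode ``"difference"``), or the raw simple-membrane mean (mode
    ``"simple"``, which also subtracts the diffuse background).
    """

    simple_mean: float
    double_mean: float
    contribution: float
    clamped: bool = False


@dataclass
class PolarityMetrics:
    """The normalized per-oocyte readout."""

    fractions: dict[str, float]           # APM, LPM, PPM, cytoplasm
    densities: dict[str, float]           # APM, LPM, PPM (per px or um)
    exclusion_ratio: float                # LPM density / PPM density
    asymmetry_ratio: float                # APM density / PPM density
    cytoplasm_fraction: float
    ppm_zero: bool = False                # ratios are +inf sentinels if True


# ---------------------------------------------------------------------------
# measurements


def _band_offsets(band_width: int) -> np.ndarray:
    if band_width < 1 or band_width % 2 == 0:
        raise InvalidInputError("band_width must be odd and >= 1")
    half = (band_width - 1) // 2
    return np.arange(-half, half + 1, dtype=float)


def _trace_normals(trace: MembraneTrace, sigma: float = 3.0) -> np.ndarray:
    """Unit normals at every distinct trace point, from a smoothed tangent."""
    pts = trace.points[:-1].astype(float)
    smooth = gaussian_filter1d(pts, sigma=sigma, axis=0, mode="wrap")
    tangent = np.roll(smooth, -1, axis=0) - np.roll(smooth, 1, axis=0)
    norms = np.linalg.norm(tangent, axis=1)
    norms[norms == 0] = 1.0
    tangent /= norms[:, None]
    return np.column_stack([-tangent[:, 1], tangent[:, 0]])


def measure_domain(image: np.ndarray, partition: DomainPartition, label: str,
                   band_width: int = 3) -> DomainMeasurement:
    """Mean intensity and quantity of one domain over a normal band.

    At each trace point of the segment the image is sampled at
    ``band_width`` pixel offsets along the local normal; the per-point band
    means form the along-membrane intensity profile, and their grand mean is
    the domain's mean intensity.  Samples falling outside the image are
    clipped to the border with a warning.
    """
    image = np.asarray(image, dtype=float)
    idx = partition.indices(label)
    if len(idx) == 0:
        raise InvalidInputError(f"segment {label!r} is empty")
    trace = partition.trace
    pts = trace.points[:-1][idx].astype(float)
    normals = _trace_normals(trace)[idx]
    offsets = _band_offsets(band_width)

    rows = np.round(pts[:, 0:1] + offsets[None, :] * normals[:, 0:1]).astype(int)
    cols = np.round(pts[:, 1:2] + offsets[None, :] * normals[:, 1:2]).astype(int)
    if (rows < 0).any() or (cols < 0).any() \
            or (rows >= image.shape[0]).any() or (cols >= image.shape[1]).any():
        warnings.warn(f"measurement band for {label!r} clipped at image border",
                      stacklevel=2)
        rows = np.clip(rows, 0, image.shape[0] - 1)
        cols = np.clip(cols, 0, image.shape[1] - 1)
    profile = image[rows, cols].mean(axis=1)
    return DomainMeasurement(label=label,
                             mean_intensity=float(profile.mean()),
                             length=partition.lengths[label],
                             profile=profile)


def cytoplasm_mask(trace: MembraneTrace, margin: int, shape: tuple[int, int],
                   nucleus_mask: np.ndarray | None = None) -> np.ndarray:
    """Trace-enclosed region more than ``margin`` px from the trace.

    Built from the rasterized trace with a hole fill and a Euclidean
    distance transform, so the region is exactly equivariant under 90-degree
    image rotations (a scanline polygon fill is not).
    """
    if margin < 0:
        raise InvalidInputError("margin must be >= 0")
    raster = np.zeros(shape, dtype=bool)
    raster[trace.points[:, 0], trace.points[:, 1]] = True
    mask = ndimage.binary_fill_holes(raster)
    mask &= distance_transform_edt(~raster) > margin
    if nucleus_mask is not None:
        mask &= ~nucleus_mask
    if not mask.any():
        raise DegenerateGeometryError(
            "cytoplasm region empty after erosion; reduce margin")
    return mask


def measure_cytoplasm(image: np.ndarray, trace: MembraneTrace, margin: int = 6,
                      nucleus_mask: np.ndarray | None = None,
                      ) -> CytoplasmMeasurement:
    """Mean signal of the cytoplasm: trace interior eroded by ``margin``."""
    image = np.asarray(image, dtype=float)
    mask = cytoplasm_mask(trace, margin, image.shape, nucleus_mask)
    return CytoplasmMeasurement(mean_intensity=float(image[mask].mean()),
                                area=float(mask.sum()))


def estimate_nurse_background(simple_mean: float, double_mean: float,
                              mode: str = "difference") -> NurseBackground:
    """Net signal of one nurse membrane from simple/double membrane means."""
    if simple_mean < 0 or double_mean < 0:
        raise InvalidInputError("membrane means must be >= 0")
    if mode == "simple":
        return NurseBackground(simple_mean, double_mean,
                               contribution=simple_mean)
    if mode != "difference":
        raise InvalidInputError(f"unknown nurse correction mode {mode!r}")
    contribution = double_mean - simple_mean
    clamped = contribution < 0
    if clamped:
        warnings.warn("double-membrane mean below simple-membrane mean; "
                      "nurse contribution clamped to 0", stacklevel=2)
        contribution = 0.0
    return NurseBackground(simple_mean, double_mean, contribution, clamped)


def correct_anterior(anterior: DomainMeasurement,
                     nb: NurseBackground) -> DomainMeasurement:
    """Subtract the nurse membrane contribution from the anterior band mean."""
    if anterior.label not in ("anterior", "APM"):
        raise InvalidInputError("correct_anterior expects the anterior domain")
    corrected = anterior.mean_intensity - nb.contribution
    if corrected < 0:
        warnings.warn("anterior mean below nurse contribution; clamped to 0",
                      stacklevel=2)
        corrected = 0.0
    profile = None
    if anterior.profile is not None:
        profile = np.clip(anterior.profile - nb.contribution, 0.0, None)
    return DomainMeasurement(label=anterior.label, mean_intensity=corrected,
                             length=anterior.length, profile=profile)


# ---------------------------------------------------------------------------
# metrics


def compute_metrics(apm: DomainMeasurement, lat1: DomainMeasurement,
                    lat2: DomainMeasurement, ppm: DomainMeasurement,
                    cyto: CytoplasmMeasurement) -> PolarityMetrics:
    """Two-step normalization: fractions of the oocyte total, then densities.

    The two lateral segments are pooled into one LPM compartment (quantities
    and lengths summed) before normalizing.
    """
    lpm_quantity = lat1.quantity + lat2.quantity
    lpm_length = lat1.length + lat2.length
    quantities = {"APM": apm.quantity, "LPM": lpm_quantity,
                  "PPM": ppm.quantity, "cytoplasm": cyto.quantity}
    total = sum(quantities.values())
    if total <= 0:
        raise InvalidInputError("total oocyte intensity is zero")
    fractions = {k: v / total for k, v in quantities.items()}
    lengths = {"APM": apm.length, "LPM": lpm_length, "PPM": ppm.length}
    densities = {k: fractions[k] / lengths[k] for k in MEMBRANE_KEYS}

    ppm_zero = densities["PPM"] == 0.0
    if ppm_zero:
        exclusion = asymmetry = float("inf")
    else:
        exclusion = densities["LPM"] / densities["PPM"]
        asymmetry = densities["APM"] / densities["PPM"]
    return PolarityMetrics(fractions=fractions, densities=densities,
                           exclusion_ratio=exclusion,
                           asymmetry_ratio=asymmetry,
                           cytoplasm_fraction=fractions["cytoplasm"],
                           ppm_zero=ppm_zero)


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass(frozen=True)
class QuantConfig:
    """Tunable parameters of the quantification pipeline."""

    band_width: int = 3
    posterior_fraction: float = 0.20
    margin: int = 6
    nurse_correction: str = "difference"
    snap_radius: int = 5
    pixel_size: float = 1.0
    tracing: TracingConfig = field(default_factory=TracingConfig)

    def __post_init__(self) -> None:
        if self.margin < self.band_width / 2:
            raise InvalidInputError(
                "margin must be at least half the band width so the "
                "cytoplasm region excludes the measurement band")


@dataclass
class OocyteResult:
    """Full output of one oocyte quantification."""

    metrics: PolarityMetrics
    measurements: dict[str, DomainMeasurement]
    cytoplasm: CytoplasmMeasurement
    nurse: NurseBackground | None
    partition: DomainPartition
    trace: MembraneTrace
    anchors: AnchorPoints

    def profile_table(self) -> pd.DataFrame:
        """Along-membrane intensity profile with arc position and domain."""
        rows = []
        s = self.trace.arc_positions
        for label in ("anterior", "lateral1", "lateral2", "posterior"):
            meas = self.measurements[label]
            for j, i in enumerate(self.partition.indices(label)):
                rows.append((int(i), float(s[i]), label,
                             float(meas.profile[j])))
        df = pd.DataFrame(rows, columns=["index", "arc_position", "domain",
                                         "intensity"])
        return df.sort_values("index", ignore_index=True)

    def to_row(self) -> dict[str, float]:
        """Flat record for a batch results table."""
        row: dict[str, float] = {}
        for label, m in self.measurements.items():
            row[f"{label}_mean"] = m.mean_intensity
            row[f"{label}_length_px"] = m.length
            row[f"{label}_quantity"] = m.quantity
        row["cytoplasm_mean"] = self.cytoplasm.mean_intensity
        row["cytoplasm_area_px2"] = self.cytoplasm.area
        row["cytoplasm_quantity"] = self.cytoplasm.quantity
        for k, v in self.metrics.fractions.items():
            row[f"fraction_{k}"] = v
        for k, v in self.metrics.densities.items():
            row[f"density_{k}"] = v
        row["exclusion_ratio"] = self.metrics.exclusion_ratio
        row["asymmetry_ratio"] = self.metrics.asymmetry_ratio
        row["cytoplasm_fraction"] = self.metrics.cytoplasm_fraction
        if self.nurse is not None:
            row["nurse_contribution"] = self.nurse.contribution
        return row


def quantify_oocyte(image: np.ndarray, anchors: AnchorPoints,
                    config: QuantConfig | None = None,
                    simple_mean: float | None = None,
                    double_mean: float | None = None,
                    nucleus_mask: np.ndarray | None = None) -> OocyteResult:
    """Run the whole pipeline on one image.

    Snap the anchors, trace the perimeter, partition it, measure the four
    domains and the cytoplasm, apply the nurse anterior correction when
    simple/double nurse membrane means are supplied, and compute the
    normalized metrics.
    """
    config = config or QuantConfig()
    image = np.asarray(image, dtype=float)
    snapped = snap_anchors(image, anchors, config.snap_radius)
    trace = trace_perimeter(image, snapped, config.tracing,
                            pixel_size=config.pixel_size)
    partition = partition_domains(trace, snapped, config.posterior_fraction)

    measurements = {
        label: measure_domain(image, partition, label, config.band_width)
        for label in ("anterior", "lateral1", "lateral2", "posterior")
    }
    nurse = None
    if simple_mean is not None and double_mean is not None:
        nurse = estimate_nurse_background(simple_mean, double_mean,
                                          config.nurse_correction)
        measurements["anterior"] = correct_anterior(measurements["anterior"],
                                                    nurse)
    cyto = measure_cytoplasm(image, trace, config.margin, nucleus_mask)
    metrics = compute_metrics(measurements["anterior"],
                              measurements["lateral1"],
                              measurements["lateral2"],
                              measurements["posterior"], cyto)
    return OocyteResult(metrics=metrics, measurements=measurements,
                        cytoplasm=cyto, nurse=nurse, partition=partition,
                        trace=trace, anchors=snapped)
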