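"""Synthetic stage-9 oocyte images with known ground truth.

Real confocal images of egg chambers are not redistributable, so every
quantification routine in this package is validated against images built
here, whose geometry and photometry are known exactly:

* a closed elliptical membrane band whose anterior, lateral and posterior
  arcs carry distinct programmed mean intensities (the anterior pole points
  to the left, toward the nurse cells);
* an apposed nurse-cell compartment at the anterior interface — the
  oocyte/nurse membranes are painted as one unresolvable line carrying the
  sum of both intensities, as in a confocal section — plus one simple and
  one nurse–nurse double membrane inside the nurse region, so the
  simple/double background estimator has something to measure;
* diffuse cytoplasmic signal, and optional Poisson (shot) and Gaussian
  (read) noise.

Because every membrane domain is painted with a uniform mean, the
programmed *density* ratios reduce to intensity-mean ratios
(``asymmetry = APM/PPM``, ``posterior exclusion = LPM/PPM``), which is what
the recovery tests assert.

The module also builds punctum pairs with a programmed colocalized fraction
(:func:`make_coloc_pair`) and FRAP time stacks with programmed recovery
kinetics (:func:`make_frap_stack`).  All outputs are deterministic in
``(spec, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import distance_transform_edt

from .errors import PlacementError, SpecError
from .membrane_geometry import AnchorPoints

__all__ = [
    "NurseSpec", "NoiseSpec", "OocyteSpec", "OocyteGroundTruth",
    "ColocGroundTruth", "FrapGroundTruth",
    "make_oocyte", "make_coloc_pair", "make_frap_stack",
]


@dataclass(frozen=True)
class NurseSpec:
    present: bool = True
    membrane_mean: float = 60.0   # one nurse membrane, above nurse cytoplasm
    cytoplasm_mean: float = 30.0


@dataclass(frozen=True)
class NoiseSpec:
    gaussian_sd: float = 5.0
    poisson: bool = False


@dataclass(frozen=True)
class OocyteSpec:
    """Geometry and photometry of one synthetic stage-9 oocyte.

    ``semi_axes = (a, b)`` are the ellipse semi-axes along the image column
    (antero-posterior) and row axes, in px.  The anterior arc spans
    ``anterior_half_angle`` degrees either side of the anterior pole, the
    posterior arc ``posterior_half_angle`` either side of the posterior
    pole; the rest is lateral.  Intensities are grey levels.
    """

    shape: tuple[int, int] = (200, 300)
    center: tuple[float, float] = (100.0, 170.0)   # (row, col)
    semi_axes: tuple[float, float] = (80.0, 50.0)  # (along cols, along rows)
    anterior_half_angle: float = 35.0
    posterior_half_angle: float = 25.0
    membrane_width: float = 3.0
    membrane_means: dict[str, float] = field(
        default_factory=lambda: {"APM": 200.0, "LPM": 100.0, "PPM": 100.0})
    cytoplasm_mean: float = 30.0
    background: float = 5.0
    nurse: NurseSpec = field(default_factory=NurseSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def validate(self) -> None:
        a, b = self.semi_axes
        cr, cc = self.center
        h, w = self.shape
        if a <= 0 or b <= 0 or self.membrane_width < 1:
            raise SpecError("semi-axes must be positive, membrane_width >= 1")
        pad = self.membrane_width
        if not (pad <= cr - b and cr + b <= h - 1 - pad
                and pad <= cc - a and cc + a <= w - 1 - pad):
            raise SpecError("ellipse plus membrane band must fit inside image")
        if not (0 < self.anterior_half_angle < 90
                and 0 < self.posterior_half_angle < 90):
            raise SpecError("half angles must be in (0, 90) degrees")
        if set(self.membrane_means) != {"APM", "LPM", "PPM"}:
            raise SpecError("membrane_means must have keys APM, LPM, PPM")
        if any(v < 0 for v in self.membrane_means.values()) \
                or self.cytoplasm_mean < 0 or self.background < 0:
            raise SpecError("intensities must be >= 0")


@dataclass
class OocyteGroundTruth:
    """Everything knowable about a synthetic oocyte before noise."""

    anchors: AnchorPoints
    domain_masks: dict[str, np.ndarray]
    arc_lengths: dict[str, float]          # APM, LPM, PPM, in px
    perimeter: float
    matched_posterior_fraction: float      # posterior_fraction reproducing PPM
    membrane_means: dict[str, float]       # oocyte-only (nurse removed)
    nurse_contribution: float              # grey levels added on the APM line
    nurse_simple_mean: float
    nurse_double_mean: float
    cytoplasm_mean: float
    cytoplasm_area: float
    true_fractions: dict[str, float]
    true_densities: dict[str, float]
    true_ratios: dict[str, float]          # asymmetry, exclusion
    spec: OocyteSpec
    seed: int


def _wrapped_diff(t: np.ndarray | float, center: float) -> np.ndarray | float:
    """Absolute angular difference on the circle, in radians."""
    d = np.abs((t - center + np.pi) % (2 * np.pi) - np.pi)
    return d


def _domain_of_angle(t, ant_half: float, post_half: float):
    """0 = APM (around pi), 2 = PPM (around 0), 1 = LPM elsewhere."""
    t = np.asarray(t, dtype=float)
    out = np.ones(t.shape, dtype=int)
    out[_wrapped_diff(t, np.pi) <= ant_half] = 0
    out[_wrapped_diff(t, 0.0) <= post_half] = 2
    return out


def make_oocyte(spec: OocyteSpec) -> tuple[np.ndarray, OocyteGroundTruth]:
    """Render one synthetic oocyte image and its ground truth."""
    spec.validate()
    h, w = spec.shape
    cr, cc = spec.center
    a, b = spec.semi_axes
    ant_half = np.deg2rad(spec.anterior_half_angle)
    post_half = np.deg2rad(spec.posterior_half_angle)
    half_w = spec.membrane_width / 2.0

    # dense parametric contour; angle pi is the anterior (left) pole
    n_dense = 8192
    t = np.linspace(0.0, 2 * np.pi, n_dense, endpoint=False)
    xs = cc + a * np.cos(t)
    ys = cr + b * np.sin(t)

    contour = np.zeros(spec.shape, dtype=bool)
    angle_grid = np.zeros(spec.shape, dtype=float)
    ri = np.round(ys).astype(int)
    ci = np.round(xs).astype(int)
    contour[ri, ci] = True
    angle_grid[ri, ci] = t

    dist, (nr, nc) = distance_transform_edt(~contour, return_indices=True)
    nearest_angle = angle_grid[nr, nc]
    band = dist <= half_w

    yy, xx = np.mgrid[0:h, 0:w]
    inside = ((xx - cc) / a) ** 2 + ((yy - cr) / b) ** 2 < 1.0
    cytoplasm = inside & ~band

    dom = _domain_of_angle(nearest_angle, ant_half, post_half)
    apm_mask = band & (dom == 0)
    lpm_mask = band & (dom == 1)
    ppm_mask = band & (dom == 2)

    image = np.full(spec.shape, spec.background, dtype=float)
    image[cytoplasm] = spec.cytoplasm_mean
    image[apm_mask] = spec.membrane_means["APM"]
    image[lpm_mask] = spec.membrane_means["LPM"]
    image[ppm_mask] = spec.membrane_means["PPM"]

    masks: dict[str, np.ndarray] = {
        "APM": apm_mask, "LPM": lpm_mask, "PPM": ppm_mask,
        "cytoplasm": cytoplasm, "band": band,
    }

    nurse_contribution = 0.0
    n_cyto = spec.nurse.cytoplasm_mean
    n_mem = spec.nurse.membrane_mean
    simple_mean = n_cyto
    double_mean = n_cyto
    if spec.nurse.present:
        nurse_region = (~inside) & (~band) & (dom == 0)
        image[nurse_region] = n_cyto
        # apposed oocyte + nurse membranes are one unresolved line
        image[apm_mask] += n_mem
        nurse_contribution = n_mem

        mw = max(1, int(round(spec.membrane_width)))
        r0, r1 = int(round(cr - 0.6 * b)), int(round(cr + 0.6 * b))
        left = cc - a
        col_s = int(round(left - 20))
        col_d = int(round(left - 40))
        if col_d - mw < 0:
            raise SpecError("image too narrow for the nurse membrane lines")
        simple = np.zeros(spec.shape, dtype=bool)
        double = np.zeros(spec.shape, dtype=bool)
        simple[r0:r1, col_s:col_s + mw] = True
        double[r0:r1, col_d:col_d + mw] = True
        simple &= nurse_region
        double &= nurse_region
        if simple.sum() < 10 or double.sum() < 10:
            raise SpecError("nurse membrane lines fall outside the nurse region")
        simple_mean = n_cyto + n_mem
        double_mean = n_cyto + 2 * n_mem
        image[simple] = simple_mean
        image[double] = double_mean
        masks["nurse_region"] = nurse_region & ~simple & ~double
        masks["nurse_simple"] = simple
        masks["nurse_double"] = double

    # analytic arc lengths from the dense contour
    seg = np.linalg.norm(
        np.diff(np.column_stack([xs, ys]), axis=0, append=[[xs[0], ys[0]]]),
        axis=1)
    dom_dense = _domain_of_angle(t, ant_half, post_half)
    arc = {name: float(seg[dom_dense == code].sum())
           for name, code in (("APM", 0), ("LPM", 1), ("PPM", 2))}
    perimeter = float(seg.sum())

    # anchors on the ridge at the true domain boundaries / posterior pole
    def ridge_point(angle: float) -> tuple[int, int]:
        return (int(round(cr + b * np.sin(angle))),
                int(round(cc + a * np.cos(angle))))

    anchors = AnchorPoints(a1=ridge_point(np.pi - ant_half),
                           a2=ridge_point(np.pi + ant_half),
                           p=ridge_point(0.0))

    means = dict(spec.membrane_means)
    q = {k: means[k] * arc[k] for k in arc}
    cyto_area = float(cytoplasm.sum())
    q["cytoplasm"] = spec.cytoplasm_mean * cyto_area
    total = sum(q.values())
    fractions = {k: v / total for k, v in q.items()}
    densities = {k: fractions[k] / arc[k] for k in arc}
    ratios = {
        "asymmetry": densities["APM"] / densities["PPM"],
        "exclusion": densities["LPM"] / densities["PPM"],
    }

    rng = np.random.default_rng(spec.seed)
    noisy = image
    if spec.noise.poisson:
        noisy = rng.poisson(noisy).astype(float)
    if spec.noise.gaussian_sd > 0:
        noisy = noisy + rng.normal(0.0, spec.noise.gaussian_sd, spec.shape)
    noisy = np.clip(noisy, 0.0, None)

    truth = OocyteGroundTruth(
        anchors=anchors,
        domain_masks=masks,
        arc_lengths=arc,
        perimeter=perimeter,
        matched_posterior_fraction=arc["PPM"] / (perimeter - arc["APM"]),
        membrane_means=means,
        nurse_contribution=nurse_contribution,
        nurse_simple_mean=simple_mean,
        nurse_double_mean=double_mean,
        cytoplasm_mean=spec.cytoplasm_mean,
        cytoplasm_area=cyto_area,
        true_fractions=fractions,
        true_densities=densities,
        true_ratios=ratios,
        spec=spec,
        seed=spec.seed,
    )
    return noisy, truth


def noiseless_image(spec: OocyteSpec) -> np.ndarray:
    """The same render with all noise turned off (for oracles)."""
    quiet = replace(spec, noise=NoiseSpec(gaussian_sd=0.0, poisson=False))
    image, _ = make_oocyte(quiet)
    return image


# ---------------------------------------------------------------------------
# colocalization punctum pairs


@dataclass
class ColocGroundTruth:
    centres_ch1: np.ndarray
    centres_ch2: np.ndarray
    shared: np.ndarray          # bool per ch1 punctum
    coloc_fraction: float
    punctum_sigma: float
    intensity: float
    seed: int


def make_coloc_pair(n_puncta: int, coloc_fraction: float,
                    punctum_sigma: float = 1.5, intensity: float = 100.0,
                    noise_sd: float = 2.0, seed: int = 0,
                    shape: tuple[int, int] = (200, 200),
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                               ColocGroundTruth]:
    """Two punctate channels with a programmed colocalized fraction.

    ``round(n_puncta * coloc_fraction)`` ch1 puncta share centres with ch2
    puncta; the remainder are placed at centre-to-centre distance greater
    than ``4 * punctum_sigma`` from every ch2 punctum, so their supports are
    disjoint.  Returns ``(ch1, ch2, mask, truth)``; the mask covers the
    whole frame minus an edge margin.
    """
    if not 0.0 <= coloc_fraction <= 1.0:
        raise SpecError("coloc_fraction must be in [0, 1]")
    if n_puncta < 1:
        raise SpecError("need at least one punctum")
    rng = np.random.default_rng(seed)
    h, w = shape
    margin = int(np.ceil(4 * punctum_sigma)) + 1
    if h - 2 * margin < 4 or w - 2 * margin < 4:
        raise PlacementError("mask too small to place puncta")

    def draw_centres(n: int) -> np.ndarray:
        return np.column_stack([
            rng.uniform(margin, h - margin, n),
            rng.uniform(margin, w - margin, n)])

    centres2 = draw_centres(n_puncta)
    n_shared = int(round(n_puncta * coloc_fraction))
    shared_centres = centres2[:n_shared]

    min_d = 4 * punctum_sigma
    lone: list[np.ndarray] = []
    attempts = 0
    while len(lone) < n_puncta - n_shared:
        cand = draw_centres(1)[0]
        d = np.linalg.norm(centres2 - cand, axis=1).min()
        if d > min_d:
            lone.append(cand)
        attempts += 1
        if attempts > 200 * n_puncta:
            raise PlacementError(
                "could not place non-colocalized puncta disjointly; "
                "reduce n_puncta or punctum_sigma")
    centres1 = (np.vstack([shared_centres] + [np.array(lone)])
                if lone else shared_centres.copy())
    shared_flag = np.zeros(len(centres1), dtype=bool)
    shared_flag[:n_shared] = True

    def render(centres: np.ndarray) -> np.ndarray:
        img = np.zeros(shape, dtype=float)
        half = int(np.ceil(4 * punctum_sigma))
        for r, c in centres:
            r0, c0 = int(np.floor(r)) - half, int(np.floor(c)) - half
            r1, c1 = r0 + 2 * half + 1, c0 + 2 * half + 1
            yy, xx = np.mgrid[r0:r1, c0:c1]
            blob = intensity * np.exp(-((yy - r) ** 2 + (xx - c) ** 2)
                                      / (2 * punctum_sigma ** 2))
            img[max(r0, 0):min(r1, h), max(c0, 0):min(c1, w)] += \
                blob[max(-r0, 0):2 * half + 1 - max(r1 - h, 0),
                     max(-c0, 0):2 * half + 1 - max(c1 - w, 0)]
        return img

    ch1 = render(centres1)
    ch2 = render(centres2)
    if noise_sd > 0:
        ch1 = np.clip(ch1 + rng.normal(0, noise_sd, shape), 0, None)
        ch2 = np.clip(ch2 + rng.normal(0, noise_sd, shape), 0, None)
    mask = np.zeros(shape, dtype=bool)
    mask[1:-1, 1:-1] = True

    truth = ColocGroundTruth(centres_ch1=centres1, centres_ch2=centres2,
                             shared=shared_flag,
                             coloc_fraction=coloc_fraction,
                             punctum_sigma=punctum_sigma,
                             intensity=intensity, seed=seed)
    return ch1, ch2, mask, truth


# ---------------------------------------------------------------------------
# FRAP stacks


@dataclass
class FrapGroundTruth:
    times: np.ndarray
    anterior_factor: np.ndarray   # programmed APM intensity factor per frame
    posterior_factor: np.ndarray
    bleach_index: int
    n_prebleach: int
    plateau: float
    recovery_rate: float
    floor: float
    decay_rate: float
    oocyte: OocyteSpec
    seed: int


def make_frap_stack(oocyte: OocyteSpec, bleach_index: int = 6,
                    anterior_recovery: dict[str, float] | None = None,
                    posterior_decay: dict[str, float] | None = None,
                    n_frames: int = 30, frame_interval_s: float = 10.0,
                    seed: int = 0) -> tuple[np.ndarray, FrapGroundTruth]:
    """Time stack emulating anterior photobleaching of a stage-9 oocyte.

    Six (or ``bleach_index``) pre-bleach frames at the programmed means;
    from the bleach frame on, the anterior membrane intensity follows a
    saturating-exponential recovery toward ``plateau`` (fraction of its
    pre-bleach level) while the posterior declines exponentially toward
    ``floor``.  The nurse compartment is omitted so the anterior quantity is
    purely the oocyte's APM.
    """
    anterior_recovery = anterior_recovery or {"plateau": 0.6, "rate": 0.02}
    posterior_decay = posterior_decay or {"floor": 0.5, "rate": 0.01}
    if bleach_index < 6:
        raise SpecError("need at least six pre-bleach frames")
    if n_frames <= bleach_index:
        raise SpecError("n_frames must exceed bleach_index")
    plateau = float(anterior_recovery["plateau"])
    k_rec = float(anterior_recovery["rate"])
    floor = float(posterior_decay["floor"])
    k_dec = float(posterior_decay["rate"])
    if plateau < 0 or floor < 0 or k_rec < 0 or k_dec < 0:
        raise SpecError("kinetic parameters must be >= 0")

    times = np.arange(n_frames, dtype=float) * frame_interval_s
    fa = np.ones(n_frames)
    fp = np.ones(n_frames)
    tp = times[bleach_index:] - times[bleach_index]
    fa[bleach_index:] = plateau * (1.0 - np.exp(-k_rec * tp))
    fp[bleach_index:] = floor + (1.0 - floor) * np.exp(-k_dec * tp)

    seeds = np.random.SeedSequence(seed).generate_state(n_frames) % (2 ** 31)
    frames = []
    for i in range(n_frames):
        means = dict(oocyte.membrane_means)
        means["APM"] = means["APM"] * fa[i]
        means["PPM"] = means["PPM"] * fp[i]
        spec_i = replace(oocyte, membrane_means=means,
                         nurse=NurseSpec(present=False),
                         seed=int(seeds[i]))
        img, _ = make_oocyte(spec_i)
        frames.append(img)
    stack = np.stack(frames)

    truth = FrapGroundTruth(times=times, anterior_factor=fa,
                            posterior_factor=fp, bleach_index=bleach_index,
                            n_prebleach=bleach_index, plateau=plateau,
                            recovery_rate=k_rec, floor=floor, decay_rate=k_dec,
                            oocyte=oocyte, seed=seed)
    return stack, truth
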