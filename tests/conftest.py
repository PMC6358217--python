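"""Shared fixtures: synthetic images every module is validated against."""

import numpy as np
import pytest
from scipy.ndimage import distance_transform_edt

from oopolar.membrane_geometry import AnchorPoints
from oopolar.synthetic import NoiseSpec, OocyteSpec, make_oocyte


def ring_image(shape, center, semi_axes, width=3.0, value=200.0, bg=20.0,
               n_dense=4096):
    """Noiseless elliptical band image plus the contour-distance map."""
    cr, cc = center
    a, b = semi_axes
    t = np.linspace(0, 2 * np.pi, n_dense, endpoint=False)
    cont = np.zeros(shape, dtype=bool)
    cont[np.round(cr + b * np.sin(t)).astype(int),
         np.round(cc + a * np.cos(t)).astype(int)] = True
    dist = distance_transform_edt(~cont)
    return np.where(dist <= width / 2, value, bg), dist


def circle_anchors(center, radius, half_angle_deg=30.0):
    """a1/a2 at +/-half_angle from the leftmost point, p at the rightmost."""
    c = np.deg2rad(half_angle_deg)
    cr, cc = center

    def pt(theta):
        return (int(round(cr + radius * np.sin(theta))),
                int(round(cc + radius * np.cos(theta))))

    return AnchorPoints(a1=pt(np.pi - c), a2=pt(np.pi + c), p=pt(0.0))


@pytest.fixture(scope="session")
def ellipse_band():
    """Noiseless 80x50 ellipse band with anchors, plus truth helpers."""
    shape, center, axes = (200, 300), (100, 150), (80, 50)
    img, dist = ring_image(shape, center, axes)
    c = np.deg2rad(35)
    cr, cc = center
    a, b = axes
    anchors = AnchorPoints(
        a1=(int(round(cr + b * np.sin(np.pi - c))),
            int(round(cc + a * np.cos(np.pi - c)))),
        a2=(int(round(cr + b * np.sin(np.pi + c))),
            int(round(cc + a * np.cos(np.pi + c)))),
        p=(cr, cc + a))
    return {"image": img, "dist": dist, "anchors": anchors,
            "semi_axes": axes, "center": center}


@pytest.fixture(scope="session")
def oocyte_noisy():
    """Default synthetic oocyte (2:1 anterior enrichment, nurse present)."""
    spec = OocyteSpec(seed=1)
    image, truth = make_oocyte(spec)
    return image, truth


@pytest.fixture(scope="session")
def oocyte_noiseless():
    spec = OocyteSpec(seed=1, noise=NoiseSpec(gaussian_sd=0.0, poisson=False))
    image, truth = make_oocyte(spec)
    return image, truth


def ramanujan_perimeter(a, b):
    h = ((a - b) / (a + b)) ** 2
    return np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
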