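"""Fibre typing from the brightfield MHC double stain.

Slow myosin heavy chain is visualised with DAB (brown) and fast MHC
with a Vector-SG-type chromogen (blue-grey) on the same section.  Pixel
colours are converted to optical density via Beer–Lambert
(OD = −log10 I, white = no absorbance) and unmixed into per-stain
densities by least-squares colour deconvolution in the Ruifrok–Johnston
style: the 3×3 stain matrix is the two stain vectors plus their
normalised cross product as residual channel.  A fibre's type is called
from the *median* stain densities over its pixels (robust to nuclear
counterstain speckle) against two OD thresholds:

=========  ==========================  =========================
call       median slow OD              median fast OD
=========  ==========================  =========================
slow       ≥ slow_density_threshold    < fast_density_threshold
fast       < slow_density_threshold    ≥ fast_density_threshold
hybrid     ≥ slow_density_threshold    ≥ fast_density_threshold
unclass.   < slow_density_threshold    < fast_density_threshold
=========  ==========================  =========================

Thresholds are in OD units, so illumination must be white-balanced;
they should be calibrated once on control sections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import ConfigurationError

__all__ = ["TypingParams", "stain_densities", "classify_fibre_type"]

_EPS = 1e-6

# Published DAB absorbance vector (Ruifrok & Johnston) for the slow stain.
DAB_VECTOR = (0.268, 0.570, 0.776)
# Measured blue-grey (Vector SG-like) absorbance direction for the fast stain.
SG_VECTOR = (0.735, 0.508, 0.449)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ConfigurationError("stain vector must be non-zero")
    return v / n


@dataclass
class TypingParams:
    """Stain vectors and OD thresholds of the MHC typing stage."""

    slow_stain_vector: tuple[float, float, float] = DAB_VECTOR
    fast_stain_vector: tuple[float, float, float] = SG_VECTOR
    slow_density_threshold: float = 0.2
    fast_density_threshold: float = 0.2

    def __post_init__(self) -> None:
        if self.slow_density_threshold <= 0 or self.fast_density_threshold <= 0:
            raise ValueError("density thresholds must be positive")
        vs, vf = _unit(self.slow_stain_vector), _unit(self.fast_stain_vector)
        if np.linalg.norm(np.cross(vs, vf)) < 1e-3:
            raise ConfigurationError("stain vectors are (near-)collinear")
        self.slow_stain_vector = tuple(vs)
        self.fast_stain_vector = tuple(vf)

    @property
    def stain_matrix(self) -> np.ndarray:
        """Rows: slow, fast, residual absorbance unit vectors."""
        vs = np.asarray(self.slow_stain_vector)
        vf = np.asarray(self.fast_stain_vector)
        vr = _unit(np.cross(vs, vf))
        return np.stack([vs, vf, vr])


def stain_densities(
    mhc: np.ndarray, params: TypingParams
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel slow and fast stain densities of an RGB image in [0, 1].

    Optical density is −log10(max(I, ε)) per channel; the OD vectors are
    unmixed by solving the stain-matrix system, and negative densities
    are clipped to zero.
    """
    mhc = np.asarray(mhc, dtype=float)
    if mhc.ndim != 3 or mhc.shape[2] != 3:
        raise ValueError("mhc must be an (H, W, 3) RGB raster")
    od = -np.log10(np.clip(mhc, _EPS, None))
    m = params.stain_matrix  # od_pixel = densities @ m
    dens = od.reshape(-1, 3) @ np.linalg.inv(m)
    dens = np.clip(dens, 0.0, None).reshape(mhc.shape[:2] + (3,))
    return dens[..., 0], dens[..., 1]


def classify_fibre_type(
    fibre_region: np.ndarray,
    slow_od: np.ndarray,
    fast_od: np.ndarray,
    params: TypingParams,
) -> str:
    """Type one fibre from the median stain densities over its pixels.

    ``fibre_region`` is a boolean mask or an (N, 2) array of (row, col)
    coordinates; it must be non-empty.
    """
    region = np.asarray(fibre_region)
    if region.ndim == 2 and region.dtype == bool:
        if not region.any():
            raise ValueError("cannot type an empty fibre region")
        s = float(np.median(slow_od[region]))
        f = float(np.median(fast_od[region]))
    else:
        if len(region) == 0:
            raise ValueError("cannot type an empty fibre region")
        rows, cols = region[:, 0].astype(int), region[:, 1].astype(int)
        s = float(np.median(slow_od[rows, cols]))
        f = float(np.median(fast_od[rows, cols]))
    slow_pos = s >= params.slow_density_threshold
    fast_pos = f >= params.fast_density_threshold
    if slow_pos and fast_pos:
        return "hybrid"
    if slow_pos:
        return "slow"
    if fast_pos:
        return "fast"
    return "unclassified"
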