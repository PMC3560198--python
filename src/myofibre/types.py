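"""Shared domain types for muscle-section morphometry.

Conventions used throughout the package:

* rasters are numpy arrays indexed ``(row, col)``, 0-based, with pixel
  centres at integer coordinates;
* binary masks are boolean arrays, label images are non-negative integer
  arrays with 0 = background (scikit-image convention);
* all reported lengths are in micrometres (µm), converted through an
  isotropic :class:`Calibration`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Calibration",
    "ChannelSet",
    "FibreRecord",
    "NucleusRecord",
    "SectionSummary",
    "FormatError",
    "DimensionError",
    "ConsistencyError",
    "ConfigurationError",
    "DegenerateThresholdError",
    "FeasibilityError",
]


class FormatError(ValueError):
    """An input file could not be read in a supported image format."""


class DimensionError(ValueError):
    """Array shapes that must agree do not."""


class ConsistencyError(ValueError):
    """Cross-referenced records and label images disagree."""


class ConfigurationError(ValueError):
    """Invalid parameter combination (e.g. collinear stain vectors)."""


class DegenerateThresholdError(ValueError):
    """Automatic thresholding was requested on a constant image."""


class FeasibilityError(ValueError):
    """A synthetic section cannot be packed with the requested geometry."""


@dataclass(frozen=True)
class Calibration:
    """Isotropic spatial calibration in micrometres per pixel."""

    microns_per_pixel: float

    def __post_init__(self) -> None:
        mpp = float(self.microns_per_pixel)
        if not np.isfinite(mpp) or mpp <= 0:
            raise ValueError(
                f"microns_per_pixel must be a finite positive real, got {mpp!r}"
            )
        object.__setattr__(self, "microns_per_pixel", mpp)

    def to_um(self, pixels: float) -> float:
        """Convert a length in pixels to micrometres."""
        return float(pixels) * self.microns_per_pixel

    def to_um2(self, pixels: float) -> float:
        """Convert an area in pixels to square micrometres."""
        return float(pixels) * self.microns_per_pixel**2

    def to_px(self, microns: float) -> float:
        """Convert a length in micrometres to pixels."""
        return float(microns) / self.microns_per_pixel


@dataclass
class ChannelSet:
    """The three registered same-field images of one muscle section.

    ``membrane`` (WGA-type membrane stain) and ``nuclei`` (Hoechst-type
    nuclear stain) are 2-D grayscale rasters; ``mhc`` is the RGB
    brightfield image of the myosin-heavy-chain double stain.  All three
    share one shape and are scaled to [0, 1].
    """

    membrane: np.ndarray
    nuclei: np.ndarray
    mhc: np.ndarray
    calibration: Calibration

    def __post_init__(self) -> None:
        self.membrane = np.asarray(self.membrane, dtype=float)
        self.nuclei = np.asarray(self.nuclei, dtype=float)
        self.mhc = np.asarray(self.mhc, dtype=float)
        if self.membrane.ndim != 2 or self.nuclei.ndim != 2:
            raise DimensionError("membrane and nuclei channels must be 2-D grayscale")
        if self.mhc.ndim != 3 or self.mhc.shape[2] != 3:
            raise DimensionError("mhc channel must be an RGB (H, W, 3) raster")
        shapes = (self.membrane.shape, self.nuclei.shape, self.mhc.shape[:2])
        if len({s for s in shapes}) != 1:
            raise DimensionError(
                "channel shapes differ: membrane %s, nuclei %s, mhc %s"
                % (self.membrane.shape, self.nuclei.shape, self.mhc.shape[:2])
            )
        for name in ("membrane", "nuclei", "mhc"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)) or arr.min() < 0:
                raise ValueError(f"{name} intensities must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.membrane.shape


@dataclass
class FibreRecord:
    """One segmented myofibre and its per-fibre outcome measures."""

    fibre_id: int
    area_um2: float
    min_feret_um: float
    max_feret_um: float
    centroid_px: tuple[float, float]
    touches_border: bool = False
    n_nuclei: int = 0
    n_internal_nuclei: int = 0
    nucleation_class: str = "peripheral"  # {peripheral, internal}
    fibre_type: str = "unclassified"  # {slow, fast, hybrid, unclassified}
    qc_pass: bool = True

    def __post_init__(self) -> None:
        if self.fibre_id <= 0:
            raise ValueError("fibre_id must be positive")
        if not 0 < self.min_feret_um <= self.max_feret_um:
            raise ValueError(
                "need 0 < min_feret_um <= max_feret_um, got "
                f"{self.min_feret_um} / {self.max_feret_um}"
            )
        if self.n_internal_nuclei > self.n_nuclei:
            raise ValueError("n_internal_nuclei cannot exceed n_nuclei")


@dataclass
class NucleusRecord:
    """One detected nucleus, optionally assigned to a fibre.

    ``fibre_id`` 0 means the nucleus overlaps no fibre (interstitial or
    on the membrane network); such nuclei carry ``position_class``
    ``"unassigned"`` and are excluded from per-fibre counts.
    """

    nucleus_id: int
    fibre_id: int
    centroid_px: tuple[float, float]
    area_um2: float
    boundary_distance_um: float = 0.0
    position_class: str = "unassigned"  # {internal, peripheral, unassigned}

    def __post_init__(self) -> None:
        if self.nucleus_id <= 0:
            raise ValueError("nucleus_id must be positive")
        if self.fibre_id < 0:
            raise ValueError("fibre_id must be >= 0 (0 = unassigned)")
        if (self.position_class == "unassigned") != (self.fibre_id == 0):
            raise ValueError("position_class is 'unassigned' iff fibre_id == 0")


@dataclass
class SectionSummary:
    """Per-section headline statistics.

    ``variance_coefficient`` is the dimensionless fibre-size variability
    index 1000 × SD / mean of the minimal Feret diameters.
    ``size_histogram`` is an ordered list of ``(bin_low_um, bin_high_um,
    pct)`` triples whose percentages sum to 100.
    """

    n_fibres: int
    pct_internally_nucleated: float
    mean_min_feret_um: float
    sd_min_feret_um: float
    variance_coefficient: float
    size_histogram: list[tuple[float, float, float]]
    type_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_internally_nucleated <= 100.0:
            raise ValueError("pct_internally_nucleated out of [0, 100]")
        if self.n_fibres > 0 and self.size_histogram:
            total = sum(p for _, _, p in self.size_histogram)
            if abs(total - 100.0) > 1e-6:
                raise ValueError(f"size histogram sums to {total}, not 100")
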