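"""Synthetic three-channel muscle sections with exact ground truth.

Real stained sections cannot be redistributed, so every pipeline stage
is exercised on generated fields whose geometry is known exactly.  A
section is built as a Lloyd-relaxed Voronoi tessellation of a random
point set — space-filling convex polygons with shared boundaries, the
geometry a transverse muscle cross-section actually shows — in which
each interior cell is shrunk about its centroid to draw its minimal
width from a lognormal diameter distribution.  From the polygons three
registered channels are rendered:

* membrane: polygon boundaries as bright ridges of configurable width,
  with a fraction of ridge pixels deleted (staining-gap defects), then
  Gaussian blur and additive Gaussian noise;
* nuclei: bright elliptical blobs placed either deep inside a fibre
  (internal, centroid more than twice the analysis band from the
  boundary) or in the subsarcolemmal rim (peripheral, within half a
  band of the boundary);
* MHC: a Beer–Lambert rendering of per-fibre slow/fast stain optical
  densities according to the planted fibre type.

Only cells clear of the image border become ground-truth fibres; the
construction enforces that the rendered membrane encloses exactly those
fibres, so a correct pipeline must recover them one-to-one.  All
randomness flows through one seeded generator: identical spec + seed
give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from scipy import ndimage as ndi
from scipy.spatial import Voronoi
from shapely import affinity
from shapely.geometry import MultiPoint, Point, Polygon, box
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon
from skimage.filters import gaussian
from skimage.measure import label as cc_label

from .fibretype import TypingParams
from .morphometry import SizeHistogramSpec, feret_diameters, summarize_section
from .types import Calibration, ChannelSet, FeasibilityError, FibreRecord, SectionSummary

__all__ = [
    "SectionSpec",
    "TrueFibre",
    "GroundTruth",
    "generate_section",
    "expected_summary",
    "truth_records",
    "match_labels_to_truth",
]

_MEMBRANE_HI = 0.9
_MEMBRANE_LO = 0.03
_NUCLEI_BG = 0.02
_NUCLEI_HI = 0.9
# per-type (slow OD, fast OD) used in the Beer-Lambert MHC rendering
_TYPE_OD = {
    "slow": (0.8, 0.05),
    "fast": (0.05, 0.8),
    "hybrid": (0.5, 0.5),
}


@dataclass(frozen=True)
class SectionSpec:
    """Study conditions of one synthetic section.

    Defaults emulate a mildly affected adult mouse section imaged at
    20×-like sampling (0.5 µm/px): ~35 µm median minimal Feret with
    lognormal spread, 30 % internally nucleated fibres, a mixed
    slow/fast/hybrid type composition, a 3-px (1.5 µm) membrane ridge
    with 5 % staining-gap defects and 5 % additive noise.
    """

    n_fibres: int = 50
    field_px: tuple[int, int] = (640, 640)
    cal: Calibration = Calibration(0.5)
    diameter_lognormal: tuple[float, float] = (35.0, 0.30)  # median µm, sigma(log)
    pct_internal: float = 30.0
    nuclei_per_fibre: tuple[int, int] = (1, 3)
    type_mix: tuple[float, float, float] = (30.0, 60.0, 10.0)  # slow, fast, hybrid %
    membrane_width_px: int = 3
    membrane_gap_rate: float = 0.05
    noise_sd: float = 0.05
    blur_sigma_px: float = 0.7
    band_um: float = 3.0  # analysis band the nucleus placement margins refer to
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fibres <= 0:
            raise ValueError("n_fibres must be positive")
        if not 0.0 <= self.pct_internal <= 100.0:
            raise ValueError("pct_internal out of [0, 100]")
        if abs(sum(self.type_mix) - 100.0) > 1e-6:
            raise ValueError("type_mix must sum to 100")
        if self.membrane_width_px < 1:
            raise ValueError("membrane_width_px must be >= 1")
        if self.membrane_gap_rate < 0 or self.noise_sd < 0 or self.blur_sigma_px < 0:
            raise ValueError("defect rates must be non-negative")
        if self.nuclei_per_fibre[0] < 0 or self.nuclei_per_fibre[1] < self.nuclei_per_fibre[0]:
            raise ValueError("invalid nuclei_per_fibre range")


@dataclass
class TrueFibre:
    """Ground truth of one planted fibre.

    ``polygon`` is in (x=col, y=row) pixel coordinates; ``nuclei`` is a
    list of (row, col, is_internal) centroid triples.
    """

    fibre_id: int
    polygon: Polygon
    min_feret_um: float
    max_feret_um: float
    area_um2: float
    fibre_type: str
    internal: bool
    nuclei: list[tuple[float, float, bool]] = field(default_factory=list)


@dataclass
class GroundTruth:
    """All planted fibres of one section plus the generating spec."""

    fibres: list[TrueFibre]
    spec: SectionSpec


# ---------------------------------------------------------------- geometry


def _voronoi_cells(points: np.ndarray, width: float, height: float) -> list[Polygon]:
    """Bounded Voronoi cells of ``points`` inside the field rectangle.

    Points are mirrored across the four field edges so every cell of an
    original point is finite; cells are clipped to the field box.
    """
    pts = np.asarray(points, dtype=float)
    mirrored = np.concatenate(
        [
            pts,
            np.column_stack([-pts[:, 0], pts[:, 1]]),
            np.column_stack([2 * width - pts[:, 0], pts[:, 1]]),
            np.column_stack([pts[:, 0], -pts[:, 1]]),
            np.column_stack([pts[:, 0], 2 * height - pts[:, 1]]),
        ]
    )
    vor = Voronoi(mirrored)
    field_box = box(0.0, 0.0, width, height)
    cells = []
    for i in range(len(pts)):
        region = vor.regions[vor.point_region[i]]
        verts = vor.vertices[region]
        poly = MultiPoint(verts).convex_hull.intersection(field_box)
        cells.append(poly)
    return cells


def _tessellate(
    rng: np.random.Generator, spec: SectionSpec
) -> tuple[list[Polygon], list[int]]:
    """Lloyd-relaxed tessellation with exactly ``n_fibres`` interior cells."""
    height, width = spec.field_px
    n = spec.n_fibres
    margin = spec.membrane_width_px + 3.0
    typical = np.sqrt(height * width / max(n, 1))
    if typical < 8.0:
        raise FeasibilityError(
            f"{n} fibres cannot be packed into a {height}x{width} px field"
        )
    m = max(n + 4, int(round(n * 1.6)))
    points = np.column_stack(
        [rng.uniform(0, width, size=m), rng.uniform(0, height, size=m)]
    )
    for _ in range(2):  # Lloyd relaxation evens out cell sizes
        cells = _voronoi_cells(points, width, height)
        points = np.array([[c.centroid.x, c.centroid.y] for c in cells])
    inner = box(margin, margin, width - margin, height - margin)
    for _ in range(120):
        cells = _voronoi_cells(points, width, height)
        interior = [i for i, c in enumerate(cells) if inner.contains(c)]
        k = len(interior)
        if k == n:
            return cells, interior
        if k > n:
            drop = rng.choice(interior, size=k - n, replace=False)
            points = np.delete(points, drop, axis=0)
        else:
            pad = margin + typical / 2
            extra = np.column_stack(
                [
                    rng.uniform(pad, width - pad, size=n - k),
                    rng.uniform(pad, height - pad, size=n - k),
                ]
            )
            points = np.concatenate([points, extra])
    raise FeasibilityError(
        f"could not reach exactly {n} interior fibres in a "
        f"{height}x{width} px field"
    )


def _raster(poly, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a (Multi)Polygon in (x, y) coords to a boolean mask."""
    mask = np.zeros(shape, dtype=bool)
    geoms = getattr(poly, "geoms", [poly])
    for geom in geoms:
        if geom.is_empty or not isinstance(geom, Polygon):
            continue
        xs, ys = np.asarray(geom.exterior.coords).T
        rr, cc = draw_polygon(ys, xs, shape=shape)
        mask[rr, cc] = True
        for ring in geom.interiors:
            xs, ys = np.asarray(ring.coords).T
            rr, cc = draw_polygon(ys, xs, shape=shape)
            mask[rr, cc] = False
    return mask


def _paint(mask: np.ndarray, poly, value: bool = True) -> None:
    """Rasterize ``poly`` into ``mask`` in place, cropped to its bbox."""
    geoms = getattr(poly, "geoms", [poly])
    h, w = mask.shape
    for geom in geoms:
        if geom.is_empty or not isinstance(geom, Polygon):
            continue
        minx, miny, maxx, maxy = geom.bounds
        r0, c0 = max(int(miny) - 1, 0), max(int(minx) - 1, 0)
        r1, c1 = min(int(maxy) + 2, h), min(int(maxx) + 2, w)
        if r1 <= r0 or c1 <= c0:
            continue
        sub = _raster(
            affinity.translate(geom, xoff=-c0, yoff=-r0), (r1 - r0, c1 - c0)
        )
        mask[r0:r1, c0:c1][sub] = value


def _polygon_feret_um(poly: Polygon, cal: Calibration) -> tuple[float, float]:
    lo, hi = feret_diameters(np.asarray(poly.exterior.coords))
    return cal.to_um(lo), cal.to_um(hi)


# ---------------------------------------------------------------- generator


def generate_section(spec: SectionSpec) -> tuple[ChannelSet, GroundTruth]:
    """Render one synthetic section and its exact ground truth."""
    rng = np.random.default_rng(spec.seed)
    height, width = spec.field_px
    mpp = spec.cal.microns_per_pixel
    cells, interior_idx = _tessellate(rng, spec)

    # shrink interior cells to draw minimal widths from the lognormal law
    median_px, sigma = spec.diameter_lognormal[0] / mpp, spec.diameter_lognormal[1]
    min_width_px = spec.membrane_width_px + 6.0
    fibre_polys: list[Polygon] = []
    for i in interior_idx:
        cell = cells[i]
        w0, _ = feret_diameters(np.asarray(cell.exterior.coords))
        target = float(rng.lognormal(mean=np.log(median_px), sigma=sigma))
        scale = target / w0
        scale = min(scale, 0.95)
        scale = max(scale, min(min_width_px / w0, 0.95), 0.35)
        fibre_polys.append(
            affinity.scale(cell, xfact=scale, yfact=scale, origin="centroid")
        )

    # ---- membrane channel
    # Each fibre paints its parent cell bright, then carves out its own
    # interior (shrunk polygon eroded by the membrane half-width): shared
    # boundaries become ridges of ~membrane_width_px and the space freed by
    # shrinking stays bright, like WGA-positive endomysial matrix.
    half = spec.membrane_width_px / 2.0
    membrane = np.full((height, width), _MEMBRANE_LO)
    ridge = np.zeros((height, width), dtype=bool)
    for i, poly in zip(interior_idx, fibre_polys):
        _paint(ridge, cells[i].buffer(0.25), True)
    for poly in fibre_polys:
        _paint(ridge, poly.buffer(-half), False)
    membrane[ridge] = _MEMBRANE_HI
    # construction guarantee: enclosed background pockets that are neither a
    # fibre interior nor connected to the border are painted as membrane, so
    # ground truth and rendered image agree exactly
    comp = cc_label(~ridge, connectivity=1)
    border_ids = np.unique(
        np.concatenate([comp[0, :], comp[-1, :], comp[:, 0], comp[:, -1]])
    )
    keep = set(int(b) for b in border_ids if b != 0)
    for poly in fibre_polys:
        c = poly.representative_point()
        keep.add(int(comp[int(round(c.y)), int(round(c.x))]))
    pocket = (comp != 0) & ~np.isin(comp, sorted(keep))
    membrane[pocket] = _MEMBRANE_HI
    ridge |= pocket
    if spec.membrane_gap_rate > 0:
        rr, cc = np.nonzero(ridge)
        gaps = rng.random(len(rr)) < spec.membrane_gap_rate
        membrane[rr[gaps], cc[gaps]] = _MEMBRANE_LO

    # ---- nucleus placement and channel
    band_px = spec.band_um / mpp
    n = spec.n_fibres
    edts, bboxes = [], []
    for poly in fibre_polys:
        minx, miny, maxx, maxy = poly.bounds
        r0, r1 = max(int(miny) - 2, 0), min(int(maxy) + 3, height)
        c0, c1 = max(int(minx) - 2, 0), min(int(maxx) + 3, width)
        sub = _raster(
            affinity.translate(poly, xoff=-c0, yoff=-r0), (r1 - r0, c1 - c0)
        )
        edts.append(ndi.distance_transform_edt(sub))
        bboxes.append((r0, c0))
    deep_margin = 2.0 * band_px + 2.0
    eligible = [i for i, e in enumerate(edts) if e.max() >= deep_margin]
    n_internal = int(round(n * spec.pct_internal / 100.0))
    if len(eligible) < n_internal:
        raise FeasibilityError(
            f"only {len(eligible)} of {n} fibres can host an internal nucleus "
            f"at the requested band ({spec.band_um} um); need {n_internal}"
        )
    internal_fibres = set(
        int(i) for i in rng.choice(eligible, size=n_internal, replace=False)
    )

    nuclei_img = np.full((height, width), _NUCLEI_BG)
    nuclei_per_fibre: list[list[tuple[float, float, bool]]] = []
    ax_major = 2.5 / mpp  # myonucleus semi-axes, µm -> px
    ax_minor = 1.7 / mpp
    for i, (edt, (r0, c0)) in enumerate(zip(edts, bboxes)):
        k = int(rng.integers(spec.nuclei_per_fibre[0], spec.nuclei_per_fibre[1] + 1))
        placed: list[tuple[float, float, bool]] = []
        if i in internal_fibres:
            cand = np.argwhere(edt >= deep_margin)
            r, c = cand[rng.integers(len(cand))]
            placed.append((float(r + r0), float(c + c0), True))
            k = max(k - 1, 0)
        peri = np.argwhere((edt >= 1.0) & (edt <= 0.5 * band_px))
        for _ in range(k):
            if len(peri) == 0:
                break
            r, c = peri[rng.integers(len(peri))]
            placed.append((float(r + r0), float(c + c0), False))
        for r, c, _flag in placed:
            rr, cc = draw_ellipse(
                r,
                c,
                ax_major * rng.uniform(0.9, 1.1),
                ax_minor * rng.uniform(0.9, 1.1),
                shape=(height, width),
                rotation=rng.uniform(0, np.pi),
            )
            nuclei_img[rr, cc] = _NUCLEI_HI
        nuclei_per_fibre.append(placed)

    # ---- fibre types and MHC channel
    n_slow = int(round(n * spec.type_mix[0] / 100.0))
    n_fast = int(round(n * spec.type_mix[1] / 100.0))
    n_hybrid = max(n - n_slow - n_fast, 0)
    n_slow = n - n_fast - n_hybrid  # absorb rounding into the slow count
    type_list = ["slow"] * n_slow + ["fast"] * n_fast + ["hybrid"] * n_hybrid
    types = [type_list[j] for j in rng.permutation(n)]
    params = TypingParams()
    vs = np.asarray(params.slow_stain_vector)
    vf = np.asarray(params.fast_stain_vector)
    true_labels = np.zeros((height, width), dtype=np.int32)
    for i, poly in enumerate(fibre_polys):
        _paint(true_labels, poly, i + 1)
    od_lut = np.zeros((n + 1, 3))
    for i, ftype in enumerate(types):
        od_s, od_f = _TYPE_OD[ftype]
        od_lut[i + 1] = od_s * vs + od_f * vf
    mhc = np.power(10.0, -od_lut[true_labels])

    # ---- defects shared by all channels
    if spec.blur_sigma_px > 0:
        membrane = gaussian(membrane, sigma=spec.blur_sigma_px, preserve_range=True)
        nuclei_img = gaussian(nuclei_img, sigma=spec.blur_sigma_px, preserve_range=True)
    if spec.noise_sd > 0:
        membrane = membrane + rng.normal(0, spec.noise_sd, membrane.shape)
        nuclei_img = nuclei_img + rng.normal(0, spec.noise_sd, nuclei_img.shape)
        mhc = mhc + rng.normal(0, spec.noise_sd, mhc.shape)
    membrane = np.clip(membrane, 0.0, 1.0)
    nuclei_img = np.clip(nuclei_img, 0.0, 1.0)
    mhc = np.clip(mhc, 0.0, 1.0)

    fibres = []
    for i, poly in enumerate(fibre_polys):
        lo, hi = _polygon_feret_um(poly, spec.cal)
        fibres.append(
            TrueFibre(
                fibre_id=i + 1,
                polygon=poly,
                min_feret_um=lo,
                max_feret_um=hi,
                area_um2=poly.area * mpp**2,
                fibre_type=types[i],
                internal=i in internal_fibres,
                nuclei=nuclei_per_fibre[i],
            )
        )
    channels = ChannelSet(
        membrane=membrane, nuclei=nuclei_img, mhc=mhc, calibration=spec.cal
    )
    return channels, GroundTruth(fibres=fibres, spec=spec)


def control_like_spec(seed: int, **overrides) -> SectionSpec:
    """Healthy-muscle study condition: rare internal nuclei, narrow sizes."""
    kwargs = dict(
        n_fibres=30,
        field_px=(512, 512),
        diameter_lognormal=(34.0, 0.25),
        pct_internal=5.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return SectionSpec(**kwargs)


def dystrophic_like_spec(seed: int, **overrides) -> SectionSpec:
    """Dystrophic-muscle study condition: frequent internal nuclei,
    smaller median fibre size with a wider (regenerating + hypertrophic)
    spread."""
    kwargs = dict(
        n_fibres=30,
        field_px=(512, 512),
        diameter_lognormal=(26.0, 0.45),
        pct_internal=60.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return SectionSpec(**kwargs)


# ---------------------------------------------------------------- evaluation


def truth_records(truth: GroundTruth) -> list[FibreRecord]:
    """Ground-truth fibres expressed as FibreRecords (polygon-exact sizes)."""
    records = []
    for fib in truth.fibres:
        n_int = sum(1 for _, _, flag in fib.nuclei if flag)
        records.append(
            FibreRecord(
                fibre_id=fib.fibre_id,
                area_um2=fib.area_um2,
                min_feret_um=fib.min_feret_um,
                max_feret_um=fib.max_feret_um,
                centroid_px=(fib.polygon.centroid.y, fib.polygon.centroid.x),
                n_nuclei=len(fib.nuclei),
                n_internal_nuclei=n_int,
                nucleation_class="internal" if n_int >= 1 else "peripheral",
                fibre_type=fib.fibre_type,
                qc_pass=True,
            )
        )
    return records


def expected_summary(
    truth: GroundTruth, spec: SizeHistogramSpec = SizeHistogramSpec()
) -> SectionSummary:
    """Section summary computed from the exact planted geometry."""
    return summarize_section(truth_records(truth), spec)


def match_labels_to_truth(
    fibre_labels: np.ndarray, truth: GroundTruth
) -> dict[int, TrueFibre]:
    """Map recovered label ids to planted fibres by centroid containment."""
    labels = np.asarray(fibre_labels)
    out: dict[int, TrueFibre] = {}
    for lbl in np.unique(labels):
        if lbl == 0:
            continue
        rows, cols = np.nonzero(labels == lbl)
        pt = Point(cols.mean(), rows.mean())
        for fib in truth.fibres:
            if fib.polygon.contains(pt):
                out[int(lbl)] = fib
                break
    return out
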