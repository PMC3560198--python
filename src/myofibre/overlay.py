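"""Annotated result overlay.

Mirrors the processed-image semantics of the original analysis output:
fibres with only peripheral nuclei are filled yellow, internally
nucleated fibres orange; peripheral nucleus centroids are marked as
green dots and internal ones as blue dots; each fibre carries its id at
the centroid; background (and the membrane network) stays black.
"""

from __future__ import annotations

import numpy as np
from PIL import Image, ImageDraw

from .types import ConsistencyError, FibreRecord, NucleusRecord

__all__ = ["render_overlay", "PERIPHERAL_FILL", "INTERNAL_FILL", "PERIPHERAL_DOT", "INTERNAL_DOT"]

PERIPHERAL_FILL = (255, 255, 0)  # yellow
INTERNAL_FILL = (255, 140, 0)  # orange
PERIPHERAL_DOT = (0, 200, 0)  # green
INTERNAL_DOT = (40, 80, 255)  # blue
_DOT_RADIUS = 2


def render_overlay(
    fibre_labels: np.ndarray,
    records: list[FibreRecord],
    nuclei: list[NucleusRecord],
    annotate_ids: bool = True,
) -> np.ndarray:
    """Render the classified section as an RGB uint8 image.

    Every label present in ``fibre_labels`` must have a record;
    otherwise a :class:`ConsistencyError` is raised.
    """
    labels = np.asarray(fibre_labels)
    present = np.unique(labels)
    present = present[present != 0]
    by_id = {r.fibre_id: r for r in records}
    missing = [int(p) for p in present if int(p) not in by_id]
    if missing:
        raise ConsistencyError(f"no FibreRecord for labels {missing}")
    lut = np.zeros((int(labels.max()) + 1 if labels.size else 1, 3), dtype=np.uint8)
    for p in present:
        rec = by_id[int(p)]
        lut[int(p)] = (
            INTERNAL_FILL if rec.nucleation_class == "internal" else PERIPHERAL_FILL
        )
    rgb = lut[labels]
    img = Image.fromarray(rgb, mode="RGB")
    draw = ImageDraw.Draw(img)
    for nuc in nuclei:
        if nuc.fibre_id == 0:
            continue
        colour = INTERNAL_DOT if nuc.position_class == "internal" else PERIPHERAL_DOT
        r, c = nuc.centroid_px
        draw.ellipse(
            [c - _DOT_RADIUS, r - _DOT_RADIUS, c + _DOT_RADIUS, r + _DOT_RADIUS],
            fill=colour,
        )
    if annotate_ids:
        for p in present:
            rec = by_id[int(p)]
            r, c = rec.centroid_px
            draw.text((c, r), str(rec.fibre_id), fill=(0, 0, 0), anchor="mm")
    return np.asarray(img)
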