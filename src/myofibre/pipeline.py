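"""End-to-end section analysis and the method-comparison command.

``analyze_channel_set`` is the in-memory pipeline: membrane mask →
fibre extraction → border exclusion → optional user exclusion mask →
boundary reclaim → QC screen → nucleus detection/assignment/position →
MHC typing → per-fibre morphometry → section summary.
``run_pipeline`` wraps it with file I/O and writes the output bundle
(fibres.csv + means, nuclei.csv, summary.csv, overlay.png,
run_metadata.json).  The whole path is deterministic: no randomness is
used anywhere in analysis.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparison import BlandAltmanResult, PairedMeasurements, bland_altman
from .fibretype import TypingParams, classify_fibre_type, stain_densities
from .io import load_channel_set, load_image, write_fibre_table, write_nucleus_table
from .morphometry import SizeHistogramSpec, min_feret, summarize_section
from .nuclei import NucleiParams, analyse_nuclei, nucleate_fibres
from .overlay import render_overlay
from .segmentation import (
    QCParams,
    SegmentationParams,
    apply_exclusion_mask,
    exclude_border,
    fibres_from_membrane,
    membrane_mask,
    qc_filter,
    reclaim_boundary,
    register_channels,
)
from .types import Calibration, ChannelSet, FibreRecord, NucleusRecord, SectionSummary

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "analyze_channel_set",
    "run_pipeline",
    "compare_command",
]


@dataclass
class PipelineConfig:
    """Everything one analysis run depends on, in one auditable object."""

    membrane_path: str = ""
    nuclei_path: str = ""
    mhc_path: str = ""
    microns_per_pixel: float = 0.5
    segmentation: SegmentationParams = dc_field(default_factory=SegmentationParams)
    qc: QCParams = dc_field(default_factory=QCParams)
    nuclei: NucleiParams = dc_field(default_factory=NucleiParams)
    typing: TypingParams = dc_field(default_factory=TypingParams)
    histogram: SizeHistogramSpec = dc_field(default_factory=SizeHistogramSpec)
    exclusion_mask_path: str | None = None
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = dict(data)
        for key, klass in (
            ("segmentation", SegmentationParams),
            ("qc", QCParams),
            ("nuclei", NucleiParams),
            ("typing", TypingParams),
            ("histogram", SizeHistogramSpec),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    def set_override(self, dotted_key: str, value: str) -> None:
        """Apply a ``--set section.key=value`` style override in place."""
        parts = dotted_key.split(".")
        target = self
        for part in parts[:-1]:
            target = getattr(target, part)
        current = getattr(target, parts[-1])
        if isinstance(current, bool):
            value = value.lower() in ("1", "true", "yes", "on")
        elif isinstance(current, int) and not isinstance(current, bool):
            value = int(value)
        elif isinstance(current, float):
            value = float(value)
        setattr(target, parts[-1], value)


@dataclass
class PipelineResult:
    """In-memory artefacts of one analysed section."""

    fibre_labels: np.ndarray
    records: list[FibreRecord]
    nuclei: list[NucleusRecord]
    summary: SectionSummary | None
    rejected: list[tuple[int, str]]
    removed_border_ids: list[int]
    status: str  # {ok, empty}


def analyze_channel_set(
    channels: ChannelSet,
    seg: SegmentationParams | None = None,
    qc: QCParams | None = None,
    nuc: NucleiParams | None = None,
    typ: TypingParams | None = None,
    hist: SizeHistogramSpec | None = None,
    exclusion_mask: np.ndarray | None = None,
) -> PipelineResult:
    """Run the full analysis on an in-memory channel set."""
    seg = seg or SegmentationParams()
    qc = qc or QCParams()
    nuc = nuc or NucleiParams()
    typ = typ or TypingParams()
    hist = hist or SizeHistogramSpec()
    cal = channels.calibration
    if seg.register_translation:
        channels = register_channels(channels)

    mask = membrane_mask(channels.membrane, seg)
    labels = fibres_from_membrane(mask, seg, qc, cal)
    labels, removed_border = exclude_border(labels)
    if exclusion_mask is not None:
        labels = apply_exclusion_mask(labels, exclusion_mask)
    labels = reclaim_boundary(labels, seg.boundary_reclaim_px)
    labels, rejected = qc_filter(labels, qc, cal)

    present = [int(v) for v in np.unique(labels) if v != 0]
    if not present:
        return PipelineResult(
            fibre_labels=labels,
            records=[],
            nuclei=[],
            summary=None,
            rejected=rejected,
            removed_border_ids=removed_border,
            status="empty",
        )

    slow_od, fast_od = stain_densities(channels.mhc, typ)
    records: list[FibreRecord] = []
    for lbl in present:
        region = labels == lbl
        coords = np.argwhere(region)
        lo, hi = min_feret(coords, cal)
        records.append(
            FibreRecord(
                fibre_id=lbl,
                area_um2=cal.to_um2(len(coords)),
                min_feret_um=lo,
                max_feret_um=hi,
                centroid_px=(float(coords[:, 0].mean()), float(coords[:, 1].mean())),
                fibre_type=classify_fibre_type(region, slow_od, fast_od, typ),
            )
        )
    nuclei_records = analyse_nuclei(channels.nuclei, labels, nuc, cal)
    records = nucleate_fibres(records, nuclei_records)
    summary = summarize_section(records, hist)
    return PipelineResult(
        fibre_labels=labels,
        records=records,
        nuclei=nuclei_records,
        summary=summary,
        rejected=rejected,
        removed_border_ids=removed_border,
        status="ok",
    )


def _summary_frame(summary: SectionSummary) -> pd.DataFrame:
    row = {
        "n_fibres": summary.n_fibres,
        "pct_internally_nucleated": summary.pct_internally_nucleated,
        "mean_min_feret_um": summary.mean_min_feret_um,
        "sd_min_feret_um": summary.sd_min_feret_um,
        "variance_coefficient": summary.variance_coefficient,
    }
    for t, c in sorted(summary.type_counts.items()):
        row[f"n_type_{t}"] = c
    for lo, hi, pct in summary.size_histogram:
        top = "inf" if np.isinf(hi) else f"{hi:g}"
        row[f"pct_feret_{lo:g}_{top}_um"] = pct
    return pd.DataFrame([row])


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Analyse one section from files and write the output bundle."""
    os.makedirs(config.output_dir, exist_ok=True)
    cal = Calibration(config.microns_per_pixel)
    channels = load_channel_set(
        config.membrane_path, config.nuclei_path, config.mhc_path, cal
    )
    exclusion = None
    if config.exclusion_mask_path:
        exclusion = load_image(config.exclusion_mask_path, as_gray=True) > 0.5
    result = analyze_channel_set(
        channels,
        seg=config.segmentation,
        qc=config.qc,
        nuc=config.nuclei,
        typ=config.typing,
        hist=config.histogram,
        exclusion_mask=exclusion,
    )
    out = config.output_dir
    write_fibre_table(result.records, result.nuclei, os.path.join(out, "fibres.csv"))
    write_nucleus_table(result.nuclei, os.path.join(out, "nuclei.csv"))
    if result.summary is not None:
        _summary_frame(result.summary).to_csv(
            os.path.join(out, "summary.csv"), index=False, float_format="%.4f"
        )
        overlay = render_overlay(result.fibre_labels, result.records, result.nuclei)
        from PIL import Image

        Image.fromarray(overlay).save(os.path.join(out, "overlay.png"))
    metadata = {
        "package_version": __version__,
        "status": result.status,
        "n_fibres": len(result.records),
        "n_rejected_qc": len(result.rejected),
        "n_removed_border": len(result.removed_border_ids),
        "config": config.to_dict(),
    }
    with open(os.path.join(out, "run_metadata.json"), "w", encoding="utf-8") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)
    return result


def compare_command(
    manual_csv: str | os.PathLike,
    automated_csv: str | os.PathLike,
    output_dir: str | os.PathLike | None = None,
) -> dict[str, BlandAltmanResult]:
    """Bland–Altman agreement per shared parameter of two paired CSVs.

    Both CSVs need an ``id`` column; every other shared numeric column
    is compared (automated − manual).  Unmatched ids raise a pairing
    error naming the offenders.  With ``output_dir`` the bias/limits
    table, per-pair plot data and a plot are written.
    """
    manual = pd.read_csv(manual_csv)
    automated = pd.read_csv(automated_csv)
    for name, df in (("manual", manual), ("automated", automated)):
        if "id" not in df.columns:
            raise ValueError(f"{name} CSV lacks an 'id' column")
    only_m = sorted(set(manual["id"]) - set(automated["id"]))
    only_a = sorted(set(automated["id"]) - set(manual["id"]))
    if only_m or only_a:
        raise ValueError(
            f"unmatched ids: manual-only {only_m}, automated-only {only_a}"
        )
    merged = manual.merge(automated, on="id", suffixes=("_manual", "_automated"))
    merged = merged.sort_values("id")
    params = [
        c
        for c in manual.columns
        if c != "id" and c in automated.columns and pd.api.types.is_numeric_dtype(manual[c])
    ]
    results = {}
    for p in params:
        pairs = PairedMeasurements(
            method_a=merged[f"{p}_manual"].to_numpy(),
            method_b=merged[f"{p}_automated"].to_numpy(),
            label=p,
        )
        results[p] = bland_altman(pairs)
    if output_dir is not None:
        os.makedirs(output_dir, exist_ok=True)
        rows = [
            {
                "parameter": p,
                "n": len(r.diffs),
                "bias": r.bias,
                "sd_diff": r.sd_diff,
                "loa_lower": r.loa_lower,
                "loa_upper": r.loa_upper,
            }
            for p, r in results.items()
        ]
        pd.DataFrame(rows).to_csv(
            os.path.join(output_dir, "bland_altman.csv"), index=False, float_format="%.4f"
        )
        for p, r in results.items():
            pd.DataFrame({"id": merged["id"], "mean": r.means, "diff": r.diffs}).to_csv(
                os.path.join(output_dir, f"bland_altman_{p}_pairs.csv"),
                index=False,
                float_format="%.4f",
            )
        _plot_bland_altman(results, output_dir)
    return results


def _plot_bland_altman(results: dict[str, BlandAltmanResult], output_dir) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, max(len(results), 1), figsize=(5 * max(len(results), 1), 4))
    if len(results) <= 1:
        axes = [axes]
    for ax, (p, r) in zip(axes, results.items()):
        ax.scatter(r.means, r.diffs, s=12)
        for y, style in ((r.bias, "-"), (r.loa_lower, "--"), (r.loa_upper, "--")):
            ax.axhline(y, linestyle=style, color="k", linewidth=0.8)
        ax.set_title(p)
        ax.set_xlabel("mean of methods")
        ax.set_ylabel("automated - manual")
    fig.tight_layout()
    fig.savefig(os.path.join(output_dir, "bland_altman.png"), dpi=120)
    plt.close(fig)
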