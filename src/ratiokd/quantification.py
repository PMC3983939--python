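"""Per-cell intensity measurement, background subtraction and GFP gating.

Green (EGFP reference) and red (reporter) intensities are averaged over each
nuclear ROI, background-subtracted against an untransfected sample, and cells
are gated as transfectants by thresholding the green signal.  The R/G ratio
is defined only for gated cells; cells below the gate are excluded from all
downstream statistics, never zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .segmentation import (
    FieldImageSet,
    NucleusROI,
    SegmentationConfig,
    compute_dna_threshold,
    filter_nuclei,
    segment_nuclei,
)


class QuantificationError(ValueError):
    pass


@dataclass(frozen=True)
class BackgroundEstimate:
    """Per-channel scalar background from nuclear ROIs of untransfected cells.

    ``green_sd``/``red_sd`` are the standard deviations of the per-ROI mean
    intensities, used by the ``from_control_k_sd`` gating mode.
    """

    green_bg: float
    red_bg: float
    green_sd: float
    red_sd: float
    source: str = ""
    n_rois: int = 0


@dataclass(frozen=True)
class CellRecord:
    """One cell's background-subtracted intensities and gating state."""

    field_id: str
    roi_label: int
    mean_green: float
    mean_red: float
    transfected: bool | None = None
    rg_ratio: float = float("nan")


@dataclass
class GateConfig:
    """EGFP transfectant gate on the background-subtracted green scale.

    ``preset`` uses ``gfp_threshold`` as-is (reproducing any externally chosen
    value); ``from_control_k_sd`` sets the threshold to ``k_sd`` × the
    untransfected sample's green standard deviation (default 3 SD).
    """

    gfp_threshold: float = 0.0
    gfp_threshold_mode: Literal["preset", "from_control_k_sd"] = "from_control_k_sd"
    k_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.gfp_threshold < 0:
            raise ValueError("gfp_threshold must be >= 0")
        if self.gfp_threshold_mode not in ("preset", "from_control_k_sd"):
            raise ValueError(f"unknown gate mode {self.gfp_threshold_mode!r}")

    def resolve_threshold(self, bg: BackgroundEstimate | None) -> float:
        if self.gfp_threshold_mode == "preset":
            return float(self.gfp_threshold)
        if bg is None:
            raise QuantificationError(
                "from_control_k_sd gating requires a background estimate"
            )
        return float(self.k_sd * bg.green_sd)


def estimate_background(
    untransfected_fields: Sequence[FieldImageSet],
    seg_config: SegmentationConfig,
) -> BackgroundEstimate:
    """Estimate per-channel background from an untransfected sample.

    Each field is segmented with ``seg_config``; the background is the mean of
    per-ROI mean intensities pooled over all filtered nuclei, and the SDs of
    those per-ROI means are recorded for SD-based gating.
    """
    if not untransfected_fields:
        raise QuantificationError("background estimation failed: no fields given")
    greens, reds = [], []
    sources = []
    for fs in untransfected_fields:
        thr = compute_dna_threshold(fs.dna, seg_config)
        rois = filter_nuclei(segment_nuclei(fs.dna, thr), seg_config)
        for roi in rois:
            rr, cc = roi.coords[:, 0], roi.coords[:, 1]
            greens.append(float(fs.green.pixels[rr, cc].mean()))
            reds.append(float(fs.red.pixels[rr, cc].mean()))
        sources.append(fs.sample_id)
    if not greens:
        raise QuantificationError(
            "background estimation failed: no nuclei found in untransfected sample"
        )
    g = np.asarray(greens)
    r = np.asarray(reds)
    ddof = 1 if len(g) > 1 else 0
    return BackgroundEstimate(
        green_bg=float(g.mean()),
        red_bg=float(r.mean()),
        green_sd=float(g.std(ddof=ddof)),
        red_sd=float(r.std(ddof=ddof)),
        source="+".join(s for s in sources if s),
        n_rois=len(g),
    )


def measure_cells(
    field: FieldImageSet,
    rois: Sequence[NucleusROI],
    bg: BackgroundEstimate,
) -> list[CellRecord]:
    """Mean background-subtracted green/red intensity per ROI.

    Negative subtracted means clamp to 0 (intensities are physical).  The
    transfection flag and R/G ratio are left unset; see
    :func:`gate_transfectants`.
    """
    rows, cols = field.shape
    out = []
    for roi in rois:
        rr, cc = roi.coords[:, 0], roi.coords[:, 1]
        if rr.min() < 0 or cc.min() < 0 or rr.max() >= rows or cc.max() >= cols:
            raise QuantificationError(
                f"ROI {roi.label} extends outside the image bounds"
            )
        mg = float(field.green.pixels[rr, cc].mean()) - bg.green_bg
        mr = float(field.red.pixels[rr, cc].mean()) - bg.red_bg
        out.append(
            CellRecord(
                field_id=field.sample_id,
                roi_label=roi.label,
                mean_green=max(mg, 0.0),
                mean_red=max(mr, 0.0),
            )
        )
    return out


def gate_transfectants(
    records: Sequence[CellRecord],
    gate: GateConfig,
    bg: BackgroundEstimate | None = None,
) -> list[CellRecord]:
    """Flag transfectants by strict green-threshold comparison.

    A cell is a transfectant iff ``mean_green > threshold`` (a cell exactly at
    the threshold is gated out).  The R/G ratio is computed for transfectants
    only and left NaN otherwise.
    """
    thr = gate.resolve_threshold(bg)
    out = []
    for rec in records:
        is_tx = rec.mean_green > thr
        rg = rec.mean_red / rec.mean_green if is_tx else float("nan")
        out.append(replace(rec, transfected=is_tx, rg_ratio=rg))
    return out


def records_to_frame(records: Sequence[CellRecord]) -> pd.DataFrame:
    """Per-cell table (the CSV exchange format with the ratiometry stage)."""
    return pd.DataFrame(
        {
            "field": [r.field_id for r in records],
            "label": [r.roi_label for r in records],
            "mean_green": [r.mean_green for r in records],
            "mean_red": [r.mean_red for r in records],
            "transfected": [r.transfected for r in records],
            "rg_ratio": [r.rg_ratio for r in records],
        }
    )


def frame_to_records(df: pd.DataFrame) -> list[CellRecord]:
    """Inverse of :func:`records_to_frame` for CSV re-analysis."""
    required = {"field", "label", "mean_green", "mean_red"}
    missing = required - set(df.columns)
    if missing:
        raise QuantificationError(f"per-cell table missing columns: {sorted(missing)}")
    recs = []
    for row in df.itertuples(index=False):
        tx = getattr(row, "transfected", None)
        tx = None if tx is None or (isinstance(tx, float) and np.isnan(tx)) else bool(tx)
        rg = float(getattr(row, "rg_ratio", float("nan")))
        recs.append(
            CellRecord(
                field_id=str(row.field),
                roi_label=int(row.label),
                mean_green=float(row.mean_green),
                mean_red=float(row.mean_red),
                transfected=tx,
                rg_ratio=rg,
            )
        )
    return recs


def relative_protein_level(
    if_records: Sequence[CellRecord], untransfected_mean: float
) -> tuple[np.ndarray, float]:
    """Immunofluorescence re-analysis: per-cell protein level in percent.

    Each transfected cell's stain intensity (carried in ``mean_red``) is
    normalized to the average intensity of untransfected cells; returns the
    per-cell percentages and their median.
    """
    if untransfected_mean <= 0:
        raise QuantificationError("untransfected mean intensity must be > 0")
    levels = np.array(
        [
            100.0 * r.mean_red / untransfected_mean
            for r in if_records
            if r.transfected
        ]
    )
    if levels.size == 0:
        raise QuantificationError("no transfected cells in immunofluorescence table")
    return levels, float(np.median(levels))
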