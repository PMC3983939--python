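"""R/G ratio statistics, the δ correction and the knockdown (KD) index.

The KD index compares the median per-cell red/green ratio of a test sample
(reporter + candidate shRNA) with that of a control sample (reporter + empty
vector)::

    KD = 100 · (m_test / m_control) · δ

where ``m`` denotes the median R/G ratio.  0% means complete knockdown (no
reporter left), 100% means none.  δ compensates for shRNA constructs whose
hairpin insertion lowers EGFP expression from the same plasmid: it is fixed by
a scrambled-target experiment so that the scramble's own KD reads exactly
100%, giving δ = m_scramble_control / m_scramble_test.  In the three-plasmid
assay variant (shRNA, green reference and red reporter on separate plasmids)
no such coupling exists and δ ≡ 1.

Medians (not means) are used throughout because a minority of RNAi-insensitive
cells with unusually bright red fluorescence drags the mean but barely moves
the median.  These outliers are reported (fraction above a median + 3·IQR
fence) but never removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

from .quantification import (
    BackgroundEstimate,
    CellRecord,
    GateConfig,
    estimate_background,
    gate_transfectants,
    measure_cells,
)
from .segmentation import (
    FieldImageSet,
    SegmentationConfig,
    compute_dna_threshold,
    filter_nuclei,
    segment_nuclei,
)


class RatiometryError(ValueError):
    pass


class SmallSampleWarning(UserWarning):
    """Fewer transfectants than the recommended minimum (default 300)."""


@dataclass(frozen=True)
class SampleStats:
    """Summary of one sample's R/G ratios over its transfectants.

    ``ratios`` keeps the underlying per-cell values so that downstream
    bootstrap resampling can work on cells, not on summaries.
    """

    n: int
    median: float
    mean: float
    sd: float
    outlier_fraction: float
    ratios: np.ndarray

    @property
    def m(self) -> float:
        """The median, in the assay's m_test / m_control notation."""
        return self.median


@dataclass(frozen=True)
class DeltaEstimate:
    """δ from a scrambled-target pair: m_scramble_control / m_scramble_test."""

    delta: float
    m_scramble_test: float
    m_scramble_control: float
    n_test: int
    n_control: int


@dataclass(frozen=True)
class KDResult:
    kd_percent: float
    delta: float
    m_test: float
    m_control: float
    n_test: int
    n_control: int
    ci_low: float
    ci_high: float
    mode: Literal["two_plasmid", "three_plasmid"]


def summarize_sample(
    records: Sequence[CellRecord], min_n: int = 300
) -> SampleStats:
    """Median/mean/SD of R/G over transfected records.

    Warns (``SmallSampleWarning``) when fewer than ``min_n`` transfectants are
    available; the assay recommends pooling >300 cells per sample.  The
    outlier fraction is the share of ratios above median + 3·IQR — reported
    for QC, the cells themselves stay in.
    """
    ratios = np.array(
        [r.rg_ratio for r in records if r.transfected], dtype=float
    )
    if ratios.size == 0:
        raise RatiometryError("no transfected records to summarize")
    if not np.all(np.isfinite(ratios)):
        raise RatiometryError("non-finite R/G ratio among transfected records")
    n = int(ratios.size)
    if n < min_n:
        warnings.warn(
            f"only {n} transfectants (recommended minimum {min_n})",
            SmallSampleWarning,
            stacklevel=2,
        )
    med = float(np.median(ratios))
    iqr = float(np.subtract(*np.percentile(ratios, [75, 25])))
    fence = med + 3.0 * iqr
    return SampleStats(
        n=n,
        median=med,
        mean=float(ratios.mean()),
        sd=float(ratios.std(ddof=1)) if n > 1 else 0.0,
        outlier_fraction=float(np.mean(ratios > fence)),
        ratios=ratios,
    )


def estimate_delta(
    scramble_test: SampleStats, scramble_control: SampleStats
) -> DeltaEstimate:
    """δ such that the scrambled-target experiment's KD equals exactly 100%."""
    if scramble_test.median <= 0 or scramble_control.median <= 0:
        raise RatiometryError("scramble medians must be positive to estimate delta")
    return DeltaEstimate(
        delta=scramble_control.median / scramble_test.median,
        m_scramble_test=scramble_test.median,
        m_scramble_control=scramble_control.median,
        n_test=scramble_test.n,
        n_control=scramble_control.n,
    )


def _kd_value(m_test: float, m_control: float, d_num: float, d_den: float) -> float:
    # factored form, ratio taken first: with a DeltaEstimate from the same
    # pair the numerator and denominator products are identical floats, the
    # ratio is exactly 1.0 and KD exactly 100.0
    return 100.0 * ((m_test * d_num) / (m_control * d_den))


def compute_kd_index(
    test: SampleStats,
    control: SampleStats,
    delta: DeltaEstimate | float = 1.0,
    mode: Literal["two_plasmid", "three_plasmid"] = "two_plasmid",
    n_boot: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> KDResult:
    """KD index with a percentile-bootstrap confidence interval.

    Cells are resampled independently within each arm; δ is held fixed (its
    scramble arms are a separate experiment).  ``mode="three_plasmid"``
    forces δ = 1.  KD above 100% is reported as-is, never clipped.
    """
    if control.median <= 0:
        raise RatiometryError("control median must be > 0")
    if mode not in ("two_plasmid", "three_plasmid"):
        raise RatiometryError(f"unknown mode {mode!r}")
    if mode == "three_plasmid":
        d_num, d_den, delta_value = 1.0, 1.0, 1.0
    elif isinstance(delta, DeltaEstimate):
        d_num, d_den = delta.m_scramble_control, delta.m_scramble_test
        delta_value = delta.delta
    else:
        d_num, d_den, delta_value = float(delta), 1.0, float(delta)
        if d_num <= 0:
            raise RatiometryError("delta must be > 0")

    kd = _kd_value(test.median, control.median, d_num, d_den)

    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if n_boot > 0:
        ti = rng.integers(0, test.n, size=(n_boot, test.n))
        ci_ = rng.integers(0, control.n, size=(n_boot, control.n))
        mt = np.median(test.ratios[ti], axis=1)
        mc = np.median(control.ratios[ci_], axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            kds = 100.0 * ((mt * d_num) / (mc * d_den))
        kds = kds[np.isfinite(kds)]
        if kds.size == 0:
            lo = hi = kd
        else:
            lo, hi = np.percentile(kds, [2.5, 97.5])
    else:
        lo = hi = kd
    return KDResult(
        kd_percent=float(kd),
        delta=float(delta_value),
        m_test=test.median,
        m_control=control.median,
        n_test=test.n,
        n_control=control.n,
        ci_low=float(min(lo, kd)),
        ci_high=float(max(hi, kd)),
        mode=mode,
    )


def linearity_qc(
    records: Sequence[CellRecord],
) -> tuple[float, float, float]:
    """Pearson r, slope and intercept of red vs green over transfectants.

    Control arms should show tight linear green–red coupling over the whole
    expression range; a poor r flags unequal expression cassettes, bleed-
    through or saturation problems.
    """
    g = np.array([r.mean_green for r in records if r.transfected], dtype=float)
    rr = np.array([r.mean_red for r in records if r.transfected], dtype=float)
    if g.size < 3:
        raise RatiometryError("linearity QC needs at least 3 transfected records")
    if np.ptp(g) == 0 or np.ptp(rr) == 0:
        raise RatiometryError("degenerate (zero-variance) input for linearity QC")
    res = sps.linregress(g, rr)
    return float(res.rvalue), float(res.slope), float(res.intercept)


@dataclass(frozen=True)
class ExperimentResult:
    """End-to-end result bundle for one test-vs-control experiment."""

    kd: KDResult
    test_stats: SampleStats
    control_stats: SampleStats
    delta_estimate: DeltaEstimate | None
    background: BackgroundEstimate
    control_linearity_r: float


def _arm_records(
    fields: Sequence[FieldImageSet],
    seg_config: SegmentationConfig,
    gate: GateConfig,
    bg: BackgroundEstimate,
) -> list[CellRecord]:
    records: list[CellRecord] = []
    for fs in fields:
        thr = compute_dna_threshold(fs.dna, seg_config)
        rois = filter_nuclei(segment_nuclei(fs.dna, thr), seg_config)
        records.extend(measure_cells(fs, rois, bg))
    return gate_transfectants(records, gate, bg)


def kd_from_experiment(
    test_fields: Sequence[FieldImageSet],
    control_fields: Sequence[FieldImageSet],
    untransfected_fields: Sequence[FieldImageSet],
    seg_config: SegmentationConfig | None = None,
    gate: GateConfig | None = None,
    scramble_test_fields: Sequence[FieldImageSet] | None = None,
    scramble_control_fields: Sequence[FieldImageSet] | None = None,
    mode: Literal["two_plasmid", "three_plasmid"] = "two_plasmid",
    min_n: int = 300,
    n_boot: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> ExperimentResult:
    """Full pipeline: threshold → segment → filter → background → measure →
    gate → summarize → (δ) → KD.

    Cells are pooled across fields within each arm before the medians are
    taken.  A scrambled-target pair, when provided in two-plasmid mode, fixes
    δ; otherwise δ = 1.
    """
    seg_config = seg_config or SegmentationConfig()
    gate = gate or GateConfig()
    bg = estimate_background(untransfected_fields, seg_config)

    test_records = _arm_records(test_fields, seg_config, gate, bg)
    control_records = _arm_records(control_fields, seg_config, gate, bg)
    test_stats = summarize_sample(test_records, min_n=min_n)
    control_stats = summarize_sample(control_records, min_n=min_n)

    delta_est: DeltaEstimate | None = None
    delta: DeltaEstimate | float = 1.0
    if (
        mode == "two_plasmid"
        and scramble_test_fields is not None
        and scramble_control_fields is not None
    ):
        scr_t = summarize_sample(
            _arm_records(scramble_test_fields, seg_config, gate, bg), min_n=min_n
        )
        scr_c = summarize_sample(
            _arm_records(scramble_control_fields, seg_config, gate, bg), min_n=min_n
        )
        delta_est = estimate_delta(scr_t, scr_c)
        delta = delta_est

    kd = compute_kd_index(
        test_stats, control_stats, delta, mode=mode, n_boot=n_boot, rng=rng
    )
    r, _, _ = linearity_qc(control_records)
    return ExperimentResult(
        kd=kd,
        test_stats=test_stats,
        control_stats=control_stats,
        delta_estimate=delta_est,
        background=bg,
        control_linearity_r=r,
    )


def repeat_summary(kds: Sequence[float]) -> tuple[float, float]:
    """Mean and SD of KD indexes over independent experiment repeats,
    mirroring bar-graph reporting of 2–3 repeats per construct."""
    arr = np.asarray(kds, dtype=float)
    if arr.size == 0:
        raise RatiometryError("no KD values to aggregate")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd
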