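"""Measurement, background subtraction and gating tests."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ratiokd as rk
from ratiokd.quantification import BackgroundEstimate, CellRecord
from ratiokd.segmentation import ChannelImage, FieldImageSet, NucleusROI


def square_field(green_blobs, red_value=0.0, size=64, blob=5, pixel_size=1.0):
    """A field with one square 'nucleus' per requested green value."""
    dna = np.zeros((size, size))
    green = np.zeros((size, size))
    red = np.zeros((size, size))
    positions = [(8 + 12 * i, 8) for i in range(len(green_blobs))]
    for (r, c), gv in zip(positions, green_blobs):
        dna[r : r + blob, c : c + blob] = 10.0
        green[r : r + blob, c : c + blob] = gv
        red[r : r + blob, c : c + blob] = red_value
    return FieldImageSet(
        dna=ChannelImage(dna, "dna", pixel_size),
        green=ChannelImage(green, "green", pixel_size),
        red=ChannelImage(red, "red", pixel_size),
        sample_id="fab",
    )


SQ_CFG = rk.SegmentationConfig(
    threshold_mode="manual", manual_threshold=1.0, area_min=1.0, area_max=1000.0
)


def simple_bg(green_bg=0.0, red_bg=0.0, green_sd=0.0):
    return BackgroundEstimate(
        green_bg=green_bg, red_bg=red_bg, green_sd=green_sd, red_sd=0.0, n_rois=1
    )


def roi_at(r, c, blob=5, label=1):
    rr, cc = np.meshgrid(range(r, r + blob), range(c, c + blob), indexing="ij")
    coords = np.column_stack([rr.ravel(), cc.ravel()])
    return NucleusROI(label, coords, float(blob * blob), (r + 2.0, c + 2.0), 0.0)


# --- background -------------------------------------------------------------


def test_constant_background_recovered_exactly(noise_free_params, default_seg):
    import dataclasses

    params = dataclasses.replace(
        noise_free_params, transfected_fraction=0.0, background_level=100.0
    )
    fs, _ = rk.generate_scene(params, "control")
    bg = rk.estimate_background([fs], default_seg)
    assert bg.green_bg == 100.0
    assert bg.red_bg == 100.0
    assert bg.green_sd == 0.0


def test_background_is_mean_of_per_roi_means():
    f1 = square_field([10.0, 20.0])
    f2 = square_field([30.0])
    bg = rk.estimate_background([f1, f2], SQ_CFG)
    assert bg.n_rois == 3
    assert bg.green_bg == pytest.approx(20.0)


def test_background_noise_within_standard_error_bound():
    params = rk.SceneParams(
        transfected_fraction=0.0, read_noise_sd=5.0, shot_noise=False, seed=11
    )
    fs, _ = rk.generate_scene(params, "control")
    cfg = rk.SegmentationConfig()
    bg = rk.estimate_background([fs], cfg)
    thr = rk.compute_dna_threshold(fs.dna, cfg)
    rois = rk.filter_nuclei(rk.segment_nuclei(fs.dna, thr), cfg)
    total_px = sum(r.n_pixels for r in rois)
    assert abs(bg.green_bg - 100.0) < 5.0 / np.sqrt(total_px) * 10


def test_background_without_nuclei_errors(default_seg):
    empty = square_field([])
    with pytest.raises(rk.QuantificationError, match="background estimation"):
        rk.estimate_background([empty], SQ_CFG)


# --- measurement ------------------------------------------------------------


def test_measure_uniform_region_subtracts_background():
    fs = square_field([100.0])
    recs = rk.measure_cells(fs, [roi_at(8, 8)], simple_bg(green_bg=20.0))
    assert recs[0].mean_green == pytest.approx(80.0)


def test_measure_clamps_below_background_to_zero():
    fs = square_field([10.0])
    recs = rk.measure_cells(fs, [roi_at(8, 8)], simple_bg(green_bg=50.0))
    assert recs[0].mean_green == 0.0


def test_measure_roi_outside_image_errors():
    fs = square_field([10.0])
    with pytest.raises(rk.QuantificationError, match="bounds"):
        rk.measure_cells(fs, [roi_at(62, 62)], simple_bg())


def test_noise_free_ratios_equal_truth(noise_free_params, default_seg):
    import dataclasses

    params = dataclasses.replace(
        noise_free_params,
        knockdown_efficiency=0.8,
        outlier_fraction=0.0,
        green_gain=1.0,
        red_gain=2.0,
        seed=29,
    )
    fs, truth = rk.generate_scene(params, "test")
    cfg = dataclasses.replace(
        default_seg, threshold_mode="manual", manual_threshold=101.0
    )
    rois = rk.filter_nuclei(rk.segment_nuclei(fs.dna, 101.0), cfg)
    bg = simple_bg(green_bg=100.0)
    bg = BackgroundEstimate(100.0, 100.0, 0.0, 0.0, n_rois=1)
    recs = rk.measure_cells(fs, rois, bg)
    matched = rk.match_to_truth(
        np.array([r.centroid for r in rois]), truth, max_dist=1.5
    )
    checked = 0
    for rec, ti in zip(recs, matched):
        row = truth.iloc[ti]
        if row.transfected and not row.outlier:
            assert rec.mean_red / rec.mean_green == pytest.approx(
                2.0 * 0.2, rel=1e-9
            )
            checked += 1
    assert checked > 10


# --- gating -----------------------------------------------------------------


def rec(g, r=1.0):
    return CellRecord("f", 1, mean_green=g, mean_red=r)


def test_zero_threshold_gates_in_all_positive_cells():
    gate = rk.GateConfig(gfp_threshold=0.0, gfp_threshold_mode="preset")
    out = rk.gate_transfectants([rec(0.0), rec(0.1), rec(5.0)], gate)
    assert [r.transfected for r in out] == [False, True, True]


def test_cell_exactly_at_threshold_is_gated_out():
    gate = rk.GateConfig(gfp_threshold=5.0, gfp_threshold_mode="preset")
    out = rk.gate_transfectants([rec(5.0), rec(5.0000001)], gate)
    assert [r.transfected for r in out] == [False, True]
    assert np.isnan(out[0].rg_ratio)
    assert out[1].rg_ratio == pytest.approx(1.0 / 5.0000001)


def test_sd_gate_sensitivity_and_specificity():
    params = rk.SceneParams(transfected_fraction=0.5, seed=5)
    bundle = rk.generate_experiment(params, 2, 2, seed=5)
    cfg = rk.SegmentationConfig()
    gate = rk.GateConfig()
    bg = rk.estimate_background([bundle.untransfected_field], cfg)
    tp = fp = tn = fn = 0
    for fs, truth in zip(
        bundle.test_fields + bundle.control_fields,
        bundle.test_truths + bundle.control_truths,
    ):
        thr = rk.compute_dna_threshold(fs.dna, cfg)
        rois = rk.filter_nuclei(rk.segment_nuclei(fs.dna, thr), cfg)
        recs = rk.gate_transfectants(rk.measure_cells(fs, rois, bg), gate, bg)
        matched = rk.match_to_truth(
            np.array([r.centroid for r in rois]), truth, max_dist=2.0
        )
        for r, ti in zip(recs, matched):
            if ti < 0:
                continue
            true_tx = bool(truth.iloc[ti].transfected)
            if r.transfected and true_tx:
                tp += 1
            elif r.transfected and not true_tx:
                fp += 1
            elif not r.transfected and not true_tx:
                tn += 1
            else:
                fn += 1
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    assert sensitivity >= 0.95
    assert specificity >= 0.95


@given(st.lists(st.floats(0, 100), min_size=1, max_size=30), st.data())
def test_gating_monotone_in_threshold(greens, data):
    records = [rec(g) for g in greens]
    t1 = data.draw(st.floats(0, 50))
    t2 = data.draw(st.floats(0, 50))
    lo, hi = sorted((t1, t2))
    count = lambda thr: sum(
        r.transfected
        for r in rk.gate_transfectants(
            records, rk.GateConfig(gfp_threshold=thr, gfp_threshold_mode="preset")
        )
    )
    assert count(hi) <= count(lo)


def test_record_order_independence():
    fs = square_field([10.0, 40.0, 90.0])
    rois = [roi_at(8, 8, label=1), roi_at(20, 8, label=2), roi_at(32, 8, label=3)]
    bg = simple_bg()
    fwd = {r.roi_label: r for r in rk.measure_cells(fs, rois, bg)}
    rev = {r.roi_label: r for r in rk.measure_cells(fs, rois[::-1], bg)}
    assert fwd == rev


# --- scale covariance -------------------------------------------------------


def test_channel_scaling_covariance():
    fs = square_field([50.0], red_value=30.0)
    roi = roi_at(8, 8)
    base = rk.measure_cells(fs, [roi], simple_bg(green_bg=10.0, red_bg=5.0))[0]
    scaled_fs = FieldImageSet(
        dna=fs.dna,
        green=ChannelImage(fs.green.pixels * 3.0, "green", 1.0),
        red=ChannelImage(fs.red.pixels, "red", 1.0),
        sample_id="fab",
    )
    scaled = rk.measure_cells(
        scaled_fs, [roi], simple_bg(green_bg=30.0, red_bg=5.0)
    )[0]
    assert scaled.mean_green == pytest.approx(3.0 * base.mean_green)
    assert scaled.mean_red == pytest.approx(base.mean_red)
    # common scaling of both channels leaves the R/G ratio invariant
    both = FieldImageSet(
        dna=fs.dna,
        green=ChannelImage(fs.green.pixels * 3.0, "green", 1.0),
        red=ChannelImage(fs.red.pixels * 3.0, "red", 1.0),
        sample_id="fab",
    )
    gate = rk.GateConfig(gfp_threshold=0.0, gfp_threshold_mode="preset")
    r1 = rk.gate_transfectants(
        rk.measure_cells(fs, [roi], simple_bg(10.0, 5.0)), gate
    )[0]
    r2 = rk.gate_transfectants(
        rk.measure_cells(both, [roi], simple_bg(30.0, 15.0)), gate
    )[0]
    assert r2.rg_ratio == pytest.approx(r1.rg_ratio, rel=1e-12)


# --- immunofluorescence re-analysis -----------------------------------------


def test_relative_protein_level_trivial_points():
    recs = [
        CellRecord("f", 1, 10.0, 200.0, transfected=True),
        CellRecord("f", 2, 10.0, 0.0, transfected=True),
        CellRecord("f", 3, 10.0, 999.0, transfected=False),  # excluded
    ]
    levels, median = rk.relative_protein_level(recs, untransfected_mean=200.0)
    assert list(levels) == [100.0, 0.0]
    assert median == 50.0
    with pytest.raises(rk.QuantificationError):
        rk.relative_protein_level(recs, untransfected_mean=0.0)


def test_relative_protein_level_recovers_known_knockdown():
    rng = np.random.default_rng(19)
    untx_mean = 500.0
    intensities = 0.2 * untx_mean * rng.lognormal(0.0, 0.3, 200)
    recs = [
        CellRecord("f", i, 10.0, float(v), transfected=True)
        for i, v in enumerate(intensities)
    ]
    _, median = rk.relative_protein_level(recs, untx_mean)
    assert abs(median - 20.0) <= 3.0
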