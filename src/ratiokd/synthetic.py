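"""Synthetic dual-fluorescence microscope fields with ground truth.

The generator emulates the statistical structure of the reporter assay on
which every downstream stage relies:

* per-cell expression ``E`` is log-normal, spanning a wide intensity range;
* in transfected cells the green (reference) signal is ``f·a·E`` and the red
  (reporter) signal is ``b·E·(1−k)``, so control cells (``k = 0``, ``f = 1``)
  fall exactly on the line ``red = (b/a)·green`` — the linear coupling the
  assay's R/G ratio exploits;
* a small fraction of transfected cells is RNAi-insensitive ("outliers"):
  their red output ignores the knockdown and stays at ``b·E``, producing the
  unusually bright red tail that motivates median-based statistics;
* untransfected cells carry only the DNA stain;
* images have a constant per-channel background offset, optional Poisson shot
  noise on the signal, Gaussian read noise, and 16-bit saturation.

Nuclei are non-overlapping, randomly rotated ellipses with a gentle radial
DNA-brightness profile (bright chromatin-rich centre, dimmer rim), which is
what makes quantile thresholding behave as it does on real Hoechst images.
The green and red signals are spatially flat inside each nucleus so that
noise-free ROI means equal the ground-truth per-cell values exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd

from .segmentation import ChannelImage, FieldImageSet

SATURATION = 65535.0

#: DNA radial profile: rim factor + span * (1 - rho^2); centre is ~1.3x, rim
#: ~0.85x of the per-cell DNA level.
_DNA_RIM = 0.85
_DNA_SPAN = 0.45


class SceneTooCrowdedError(RuntimeError):
    """Raised when nuclei cannot be placed without overlap."""


@dataclass
class SceneParams:
    """Parameters of one simulated field.

    Defaults describe a moderately dense field of Rat2-like nuclei imaged at
    0.1 µm/pixel: ~150 nuclei per 512×512 field, 70% transfection efficiency,
    decade-spanning log-normal expression, equal green/red gains, 2% of
    transfected cells RNAi-insensitive, constant background of 100 counts and
    5-count read noise with shot noise enabled.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.1  # µm / pixel
    n_cells: int = 150
    transfected_fraction: float = 0.7
    expression_meanlog: float = 5.5  # log intensity units
    expression_sdlog: float = 1.0
    green_gain: float = 1.0
    red_gain: float = 1.0
    knockdown_efficiency: float = 0.0  # k: fraction of red output suppressed
    outlier_fraction: float = 0.02  # RNAi-insensitive transfectants
    shrna_gfp_bias: float = 1.0  # f: green multiplier in the test condition
    nucleus_area_range: tuple[float, float] = (1.3, 2.5)  # µm²
    nucleus_eccentricity_max: float = 0.85
    dna_level: float = 1200.0  # mean DNA-stain signal above background
    dna_cell_sdlog: float = 0.15  # cell-to-cell DNA brightness spread
    background_level: float | tuple[float, float, float] = 100.0
    read_noise_sd: float = 5.0
    shot_noise: bool = True
    seed: int = 0

    def backgrounds(self) -> tuple[float, float, float]:
        """Background offsets as (dna, green, red)."""
        b = self.background_level
        if np.isscalar(b):
            return (float(b), float(b), float(b))
        b = tuple(float(x) for x in b)  # type: ignore[arg-type]
        if len(b) != 3:
            raise ValueError("background_level must be scalar or length-3")
        return b  # type: ignore[return-value]

    def validate(self) -> None:
        probs = {
            "transfected_fraction": self.transfected_fraction,
            "knockdown_efficiency": self.knockdown_efficiency,
            "outlier_fraction": self.outlier_fraction,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        nonneg = {
            "green_gain": self.green_gain,
            "red_gain": self.red_gain,
            "read_noise_sd": self.read_noise_sd,
            "dna_level": self.dna_level,
            "expression_sdlog": self.expression_sdlog,
        }
        for name, v in nonneg.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if any(b < 0 for b in self.backgrounds()):
            raise ValueError("background_level must be >= 0")
        if self.shrna_gfp_bias <= 0:
            raise ValueError("shrna_gfp_bias must be > 0")
        amin, amax = self.nucleus_area_range
        if not (0 < amin < amax):
            raise ValueError("nucleus_area_range must satisfy 0 < min < max")
        if not (0.0 <= self.nucleus_eccentricity_max < 1.0):
            raise ValueError("nucleus_eccentricity_max must lie in [0, 1)")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        rows, cols = self.image_shape
        if rows < 8 or cols < 8:
            raise ValueError("image_shape too small")
        # coarse packing bound: random sequential placement jams well below
        # ~50% coverage, so refuse clearly infeasible requests up front
        amax_px = amax / self.pixel_size**2
        if self.n_cells * amax_px > 0.45 * rows * cols:
            raise SceneTooCrowdedError(
                "field too crowded: requested nuclei cannot fit without overlap"
            )


@dataclass(frozen=True)
class _Nucleus:
    row: float
    col: float
    semi_major: float  # pixels
    semi_minor: float
    theta: float
    area_px: int
    coords: np.ndarray  # (n, 2) member pixels
    rho2: np.ndarray  # squared normalized elliptical radius per pixel


def _rasterize_ellipse(
    row: float, col: float, a: float, b: float, theta: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Member pixels of a rotated ellipse and their normalized radius²."""
    rad = int(np.ceil(max(a, b))) + 1
    r0, r1 = int(np.floor(row)) - rad, int(np.ceil(row)) + rad
    c0, c1 = int(np.floor(col)) - rad, int(np.ceil(col)) + rad
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, shape[0] - 1), min(c1, shape[1] - 1)
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    dr, dc = rr - row, cc - col
    ct, st = np.cos(theta), np.sin(theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    rho2 = (u / a) ** 2 + (v / b) ** 2
    inside = rho2 <= 1.0
    coords = np.column_stack([rr[inside], cc[inside]]).astype(np.intp)
    return coords, rho2[inside]


def _place_nuclei(params: SceneParams, rng: np.random.Generator) -> list[_Nucleus]:
    rows, cols = params.image_shape
    ps2 = params.pixel_size**2
    amin_px = params.nucleus_area_range[0] / ps2
    amax_px = params.nucleus_area_range[1] / ps2
    placed: list[_Nucleus] = []
    centers = np.empty((0, 2))
    radii = np.empty((0,))
    max_tries = 200
    for _ in range(params.n_cells):
        for attempt in range(max_tries):
            area = rng.uniform(amin_px, amax_px)
            ecc = rng.uniform(0.0, params.nucleus_eccentricity_max)
            ratio = np.sqrt(1.0 - ecc**2)  # b/a
            a = np.sqrt(area / (np.pi * ratio))
            b = a * ratio
            theta = rng.uniform(0.0, np.pi)
            margin = a + 2.0
            if rows - margin <= margin or cols - margin <= margin:
                continue
            r = rng.uniform(margin, rows - margin)
            c = rng.uniform(margin, cols - margin)
            if len(placed):
                d = np.hypot(centers[:, 0] - r, centers[:, 1] - c)
                if np.any(d <= radii + a + 1.0):
                    continue
            coords, rho2 = _rasterize_ellipse(r, c, a, b, theta, (rows, cols))
            placed.append(
                _Nucleus(r, c, a, b, theta, len(coords), coords, rho2)
            )
            centers = np.vstack([centers, [r, c]])
            radii = np.append(radii, a)
            break
        else:
            raise SceneTooCrowdedError(
                f"field too crowded: failed to place nucleus {len(placed) + 1} "
                f"of {params.n_cells} after {max_tries} attempts"
            )
    return placed


def generate_scene(
    params: SceneParams,
    condition: Literal["test", "control"] = "control",
    rng: np.random.Generator | None = None,
) -> tuple[FieldImageSet, pd.DataFrame]:
    """Simulate one field and its ground-truth table.

    ``condition="control"`` forces ``k = 0`` and ``f = 1`` (empty-vector
    co-transfection); ``"test"`` applies the configured knockdown efficiency
    and green-expression bias.  Deterministic for a fixed ``params.seed``
    when no explicit ``rng`` is passed.
    """
    params.validate()
    if condition not in ("test", "control"):
        raise ValueError(f"condition must be 'test' or 'control', got {condition!r}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    k = params.knockdown_efficiency if condition == "test" else 0.0
    f = params.shrna_gfp_bias if condition == "test" else 1.0

    rows, cols = params.image_shape
    bg_dna, bg_green, bg_red = params.backgrounds()
    nuclei = _place_nuclei(params, rng)
    n = len(nuclei)

    transfected = rng.random(n) < params.transfected_fraction
    outlier = (rng.random(n) < params.outlier_fraction) & transfected
    expression = rng.lognormal(params.expression_meanlog, params.expression_sdlog, n)
    dna_cell = params.dna_level * rng.lognormal(0.0, params.dna_cell_sdlog, n)

    k_eff = np.where(outlier, 0.0, k)
    true_green = np.where(transfected, f * params.green_gain * expression, 0.0)
    true_red = np.where(transfected, params.red_gain * expression * (1.0 - k_eff), 0.0)

    dna_sig = np.zeros((rows, cols))
    green_sig = np.zeros((rows, cols))
    red_sig = np.zeros((rows, cols))
    ps2 = params.pixel_size**2
    records = []
    for i, nuc in enumerate(nuclei):
        rr, cc = nuc.coords[:, 0], nuc.coords[:, 1]
        dna_sig[rr, cc] = dna_cell[i] * (_DNA_RIM + _DNA_SPAN * (1.0 - nuc.rho2))
        green_sig[rr, cc] = true_green[i]
        red_sig[rr, cc] = true_red[i]
        records.append(
            {
                "cell_id": i + 1,
                "centroid_row": rr.mean(),
                "centroid_col": cc.mean(),
                "area_um2": nuc.area_px * ps2,
                "expression": expression[i],
                "transfected": bool(transfected[i]),
                "outlier": bool(outlier[i]),
                "true_mean_green": true_green[i],
                "true_mean_red": true_red[i],
            }
        )
    truth = pd.DataFrame(
        records,
        columns=[
            "cell_id",
            "centroid_row",
            "centroid_col",
            "area_um2",
            "expression",
            "transfected",
            "outlier",
            "true_mean_green",
            "true_mean_red",
        ],
    )

    def finish(sig: np.ndarray, bg: float) -> np.ndarray:
        img = rng.poisson(sig).astype(float) if params.shot_noise else sig.copy()
        img += bg
        if params.read_noise_sd > 0:
            img += rng.normal(0.0, params.read_noise_sd, img.shape)
        return np.clip(img, 0.0, SATURATION)

    ps = params.pixel_size
    fieldset = FieldImageSet(
        dna=ChannelImage(finish(dna_sig, bg_dna), "dna", ps),
        green=ChannelImage(finish(green_sig, bg_green), "green", ps),
        red=ChannelImage(finish(red_sig, bg_red), "red", ps),
        sample_id="synthetic",
        condition=condition,
    )
    return fieldset, truth


@dataclass
class ExperimentBundle:
    """Paired test/control fields plus an untransfected background field."""

    test_fields: list[FieldImageSet]
    test_truths: list[pd.DataFrame]
    control_fields: list[FieldImageSet]
    control_truths: list[pd.DataFrame]
    untransfected_field: FieldImageSet
    untransfected_truth: pd.DataFrame

    def pooled_truth(self, arm: Literal["test", "control"]) -> pd.DataFrame:
        truths = self.test_truths if arm == "test" else self.control_truths
        out = []
        for i, t in enumerate(truths):
            t = t.copy()
            t.insert(0, "field", i)
            out.append(t)
        return pd.concat(out, ignore_index=True)


def generate_experiment(
    params: SceneParams,
    n_fields_test: int = 1,
    n_fields_control: int = 1,
    seed: int | None = None,
) -> ExperimentBundle:
    """Simulate a complete test-vs-control experiment.

    Test fields use the configured (k, f); control fields use k=0, f=1.  One
    additional field with ``transfected_fraction = 0`` is generated for
    background estimation.  Each field draws from an independent substream of
    ``seed`` (default: ``params.seed``).
    """
    if n_fields_test < 1 or n_fields_control < 1:
        raise ValueError("field counts must be >= 1")
    params.validate()
    if seed is None:
        seed = params.seed
    streams = np.random.SeedSequence(seed).spawn(n_fields_test + n_fields_control + 1)
    rngs = [np.random.default_rng(s) for s in streams]

    test_fields, test_truths = [], []
    for i in range(n_fields_test):
        fs, tr = generate_scene(params, "test", rng=rngs[i])
        test_fields.append(replace(fs, sample_id=f"test_{i}"))
        test_truths.append(tr)
    control_fields, control_truths = [], []
    for j in range(n_fields_control):
        fs, tr = generate_scene(params, "control", rng=rngs[n_fields_test + j])
        control_fields.append(replace(fs, sample_id=f"control_{j}"))
        control_truths.append(tr)
    bg_params = replace(params, transfected_fraction=0.0)
    fs, tr = generate_scene(bg_params, "control", rng=rngs[-1])
    fs = replace(fs, sample_id="untransfected", condition="untransfected")
    return ExperimentBundle(
        test_fields, test_truths, control_fields, control_truths, fs, tr
    )


def match_to_truth(
    centroids: np.ndarray, truth: pd.DataFrame, max_dist: float = 3.0
) -> np.ndarray:
    """Match measured centroids to ground-truth nuclei by nearest distance.

    Returns, per input centroid, the positional index of the closest truth
    row, or −1 when nothing lies within ``max_dist`` pixels.  Intended for
    validating segmentation and gating against the generator's truth table.
    """
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    tr = truth[["centroid_row", "centroid_col"]].to_numpy()
    out = np.full(len(centroids), -1, dtype=int)
    if len(tr) == 0 or len(centroids) == 0:
        return out
    d = np.hypot(
        centroids[:, 0:1] - tr[None, :, 0], centroids[:, 1:2] - tr[None, :, 1]
    )
    idx = np.argmin(d, axis=1)
    ok = d[np.arange(len(centroids)), idx] <= max_dist
    out[ok] = idx[ok]
    return out
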