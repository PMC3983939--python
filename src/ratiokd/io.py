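"""File formats, configuration and the end-to-end pipeline driver.

Images travel as grayscale TIFF — either one 3-page file per field (page
order DNA, green, red) or three single-page files sharing a stem with
``_dna`` / ``_gfp`` / ``_rfp`` suffixes.  Tables are CSV, results JSON,
configuration and run manifests YAML.  All schemas carry a version string;
loaders reject unknown major versions.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .quantification import GateConfig, records_to_frame
from .ratiometry import (
    ExperimentResult,
    SmallSampleWarning,
    kd_from_experiment,
)
from .segmentation import ChannelImage, FieldImageSet, SegmentationConfig
from .synthetic import SATURATION, ExperimentBundle

log = logging.getLogger("ratiokd")

SCHEMA_VERSION = "1.0"
_PAGE_ORDER = ("dna", "green", "red")
_SUFFIXES = {"dna": "_dna", "green": "_gfp", "red": "_rfp"}


class FormatError(ValueError):
    pass


class ManifestError(ValueError):
    pass


def check_schema_version(version: str, what: str = "file") -> None:
    """Accept any minor revision of the current major schema version."""
    major = str(version).split(".")[0]
    if major != SCHEMA_VERSION.split(".")[0]:
        raise FormatError(
            f"unsupported {what} schema version {version!r} "
            f"(this build reads major version {SCHEMA_VERSION.split('.')[0]})"
        )


# ---------------------------------------------------------------------------
# image I/O


def write_field(field_set: FieldImageSet, path: str | Path) -> Path:
    """Write one field as a 3-page 16-bit grayscale TIFF (DNA, green, red)."""
    path = Path(path)
    pages = [
        np.clip(np.round(getattr(field_set, ch).pixels), 0, SATURATION).astype(
            np.uint16
        )
        for ch in _PAGE_ORDER
    ]
    tifffile.imwrite(path, np.stack(pages), photometric="minisblack")
    return path


def read_field(
    path: str | Path,
    pixel_size: float,
    sample_id: str | None = None,
    condition: str = "",
) -> FieldImageSet:
    """Read one field from a 3-page TIFF or a ``_dna``/``_gfp``/``_rfp``
    single-page triplet (pass any one of the three paths).

    ``pixel_size`` (µm/pixel) comes from the assay configuration; a TIFF
    resolution tag, if present, is ignored in favour of the configured value.
    """
    path = Path(path)
    stem = path.stem
    for ch, suf in _SUFFIXES.items():
        if stem.endswith(suf):
            base = stem[: -len(suf)]
            arrays = {}
            for ch2, suf2 in _SUFFIXES.items():
                p2 = path.with_name(base + suf2 + path.suffix)
                if not p2.exists():
                    raise FormatError(
                        f"three-file field layout incomplete: missing {p2.name}"
                    )
                a = tifffile.imread(p2)
                if a.ndim != 2:
                    raise FormatError(
                        f"{p2.name}: expected a single-page grayscale image"
                    )
                arrays[ch2] = a
            return _assemble_field(
                arrays, pixel_size, sample_id or base, condition
            )
    data = tifffile.imread(path)
    if data.ndim != 3 or data.shape[0] != 3:
        raise FormatError(
            f"{path.name}: expected a 3-page grayscale TIFF with page order "
            "DNA, green, red (or a _dna/_gfp/_rfp file triplet), got shape "
            f"{data.shape}"
        )
    arrays = dict(zip(_PAGE_ORDER, data))
    return _assemble_field(arrays, pixel_size, sample_id or stem, condition)


def _assemble_field(
    arrays: dict[str, np.ndarray],
    pixel_size: float,
    sample_id: str,
    condition: str,
) -> FieldImageSet:
    shapes = {a.shape for a in arrays.values()}
    if len(shapes) != 1:
        raise FormatError(f"channel shape mismatch: {sorted(shapes)}")
    n_sat = int(sum((a >= SATURATION).sum() for a in arrays.values()))
    if n_sat:
        log.warning("%s: %d saturated pixel(s)", sample_id, n_sat)
    return FieldImageSet(
        dna=ChannelImage(arrays["dna"].astype(float), "dna", pixel_size),
        green=ChannelImage(arrays["green"].astype(float), "green", pixel_size),
        red=ChannelImage(arrays["red"].astype(float), "red", pixel_size),
        sample_id=sample_id,
        condition=condition,
    )


# ---------------------------------------------------------------------------
# configuration


@dataclass
class AssayConfig:
    """Complete analysis configuration; round-trips losslessly through YAML."""

    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    gate: GateConfig = field(default_factory=GateConfig)
    pixel_size: float = 0.1
    min_n: int = 300
    bootstrap_replicates: int = 2000
    seed: int = 0
    mode: Literal["two_plasmid", "three_plasmid"] = "two_plasmid"

    def to_dict(self) -> dict:
        return {
            "schema": SCHEMA_VERSION,
            "segmentation": asdict(self.segmentation),
            "gate": asdict(self.gate),
            "pixel_size": self.pixel_size,
            "min_n": self.min_n,
            "bootstrap_replicates": self.bootstrap_replicates,
            "seed": self.seed,
            "mode": self.mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AssayConfig":
        check_schema_version(d.get("schema", SCHEMA_VERSION), "config")
        return cls(
            segmentation=SegmentationConfig(**d.get("segmentation", {})),
            gate=GateConfig(**d.get("gate", {})),
            pixel_size=float(d.get("pixel_size", 0.1)),
            min_n=int(d.get("min_n", 300)),
            bootstrap_replicates=int(d.get("bootstrap_replicates", 2000)),
            seed=int(d.get("seed", 0)),
            mode=d.get("mode", "two_plasmid"),
        )


def save_config(config: AssayConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    return path


def load_config(path: str | Path) -> AssayConfig:
    return AssayConfig.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# run manifest


CONDITIONS = ("test", "control", "scramble_test", "scramble_control", "untransfected")


@dataclass
class RunManifest:
    """Maps assay conditions to field image files."""

    fields: dict[str, list[Path]]
    seed: int = 0
    version: str = __version__

    def validate(self, mode: str = "two_plasmid") -> None:
        unknown = set(self.fields) - set(CONDITIONS)
        if unknown:
            raise ManifestError(f"unknown condition label(s): {sorted(unknown)}")
        required = {"test", "control", "untransfected"}
        missing = required - {c for c, fl in self.fields.items() if fl}
        if missing:
            raise ManifestError(f"missing required condition(s): {sorted(missing)}")
        scr = {"scramble_test", "scramble_control"}
        present = scr & {c for c, fl in self.fields.items() if fl}
        if present and present != scr:
            raise ManifestError(
                "scramble_test and scramble_control must be provided together"
            )
        for cond, files in self.fields.items():
            for f in files:
                if not Path(f).exists():
                    raise ManifestError(f"{cond}: file not found: {f}")


def save_manifest(manifest: RunManifest, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "schema": SCHEMA_VERSION,
        "seed": manifest.seed,
        "version": manifest.version,
        "fields": {c: [str(p) for p in fl] for c, fl in manifest.fields.items()},
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def load_manifest(path: str | Path) -> RunManifest:
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    check_schema_version(doc.get("schema", SCHEMA_VERSION), "manifest")
    fields = {
        c: [Path(path.parent, p) if not Path(p).is_absolute() else Path(p) for p in fl]
        for c, fl in doc.get("fields", {}).items()
    }
    return RunManifest(
        fields=fields,
        seed=int(doc.get("seed", 0)),
        version=str(doc.get("version", __version__)),
    )


def manifest_from_directories(
    test: str | Path,
    control: str | Path,
    untransfected: str | Path,
    scramble_test: str | Path | None = None,
    scramble_control: str | Path | None = None,
    seed: int = 0,
) -> RunManifest:
    """Build a manifest from per-condition directories of TIFF fields."""

    def tiffs(d: str | Path | None) -> list[Path]:
        if d is None:
            return []
        return sorted(
            p
            for p in Path(d).iterdir()
            if p.suffix.lower() in (".tif", ".tiff")
            and not any(p.stem.endswith(s) for s in ("_gfp", "_rfp"))
        )

    fields = {
        "test": tiffs(test),
        "control": tiffs(control),
        "untransfected": tiffs(untransfected),
    }
    if scramble_test or scramble_control:
        fields["scramble_test"] = tiffs(scramble_test)
        fields["scramble_control"] = tiffs(scramble_control)
    return RunManifest(fields=fields, seed=seed)


# ---------------------------------------------------------------------------
# experiment writer (synthetic data)


def write_experiment(
    bundle: ExperimentBundle,
    outdir: str | Path,
    seed: int = 0,
    params_doc: dict | None = None,
) -> RunManifest:
    """Write a synthetic experiment as TIFFs + truth CSVs + manifest YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fields: dict[str, list[Path]] = {c: [] for c in ("test", "control", "untransfected")}
    for cond, fsets, truths in (
        ("test", bundle.test_fields, bundle.test_truths),
        ("control", bundle.control_fields, bundle.control_truths),
        ("untransfected", [bundle.untransfected_field], [bundle.untransfected_truth]),
    ):
        sub = outdir / cond
        sub.mkdir(exist_ok=True)
        for i, (fs, truth) in enumerate(zip(fsets, truths)):
            p = sub / f"field_{i:02d}.tif"
            write_field(fs, p)
            truth.to_csv(sub / f"field_{i:02d}_truth.csv", index=False)
            fields[cond].append(p)
    manifest = RunManifest(fields=fields, seed=seed)
    doc = {
        "schema": SCHEMA_VERSION,
        "seed": seed,
        "version": __version__,
        "fields": {c: [str(p.relative_to(outdir)) for p in fl] for c, fl in fields.items()},
    }
    if params_doc:
        doc["scene_params"] = params_doc
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(doc, sort_keys=False))
    return manifest


# ---------------------------------------------------------------------------
# results


def histogram_table(ratios: np.ndarray, n_bins: int = 40) -> pd.DataFrame:
    """R/G histogram as a (bin_left, bin_right, count) table."""
    ratios = np.asarray(ratios, dtype=float)
    counts, edges = np.histogram(ratios, bins=n_bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def result_to_dict(result: ExperimentResult) -> dict:
    def stats_dict(s):
        return {
            "n": s.n,
            "median": s.median,
            "mean": s.mean,
            "sd": s.sd,
            "outlier_fraction": s.outlier_fraction,
        }

    out = {
        "schema": SCHEMA_VERSION,
        "software_version": __version__,
        "kd": asdict(result.kd),
        "test_stats": stats_dict(result.test_stats),
        "control_stats": stats_dict(result.control_stats),
        "background": asdict(result.background),
        "qc": {"control_linearity_r": result.control_linearity_r},
    }
    if result.delta_estimate is not None:
        out["delta_estimate"] = asdict(result.delta_estimate)
    return out


def run_pipeline(
    manifest: RunManifest, config: AssayConfig, outdir: str | Path
) -> ExperimentResult:
    """Run the full analysis described by a manifest and write all outputs.

    Produces per-cell CSVs per arm, ``results.json`` (KD, sample stats, δ,
    QC), and R/G histogram CSVs.  All randomness (the bootstrap) derives from
    ``config.seed``; a rerun with the same inputs is byte-identical.
    """
    manifest.validate(config.mode)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def load_arm(cond: str) -> list[FieldImageSet]:
        files = manifest.fields.get(cond, [])
        sets = []
        for p in files:
            fs = read_field(p, config.pixel_size, condition=cond)
            sets.append(replace(fs, sample_id=f"{cond}/{Path(p).stem}"))
        log.info("%s: %d field(s)", cond, len(sets))
        return sets

    arms = {c: load_arm(c) for c in manifest.fields if manifest.fields[c]}
    scr_t = arms.get("scramble_test")
    scr_c = arms.get("scramble_control")

    small_sample_notes: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", SmallSampleWarning)
        result = kd_from_experiment(
            arms["test"],
            arms["control"],
            arms["untransfected"],
            seg_config=config.segmentation,
            gate=config.gate,
            scramble_test_fields=scr_t,
            scramble_control_fields=scr_c,
            mode=config.mode,
            min_n=config.min_n,
            n_boot=config.bootstrap_replicates,
            rng=np.random.default_rng(config.seed),
        )
        small_sample_notes = [
            str(w.message) for w in caught if issubclass(w.category, SmallSampleWarning)
        ]

    # per-arm cell tables and histograms
    from .ratiometry import _arm_records

    bg = result.background
    for cond in ("test", "control", "scramble_test", "scramble_control"):
        if cond not in arms:
            continue
        recs = _arm_records(arms[cond], config.segmentation, config.gate, bg)
        records_to_frame(recs).to_csv(outdir / f"cells_{cond}.csv", index=False)
        ratios = np.array([r.rg_ratio for r in recs if r.transfected])
        if ratios.size:
            histogram_table(ratios).to_csv(
                outdir / f"histogram_{cond}.csv", index=False
            )

    doc = result_to_dict(result)
    doc["qc"]["warnings"] = small_sample_notes
    doc["seed"] = config.seed
    (outdir / "results.json").write_text(json.dumps(doc, indent=2, sort_keys=True))
    return result
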