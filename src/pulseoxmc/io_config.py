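"""Configuration loading, packaged fixtures, table writers and manifests.

All numerical computation elsewhere runs at full precision; the printed
one-decimal rounding of the published tables is applied only here, in
the writers.  Fixture files are transcriptions of published tables and
are pinned by SHA-256 checksum.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from . import __version__
from .oximetry_calibration import round_half_away

__all__ = [
    "FIXTURE_CHECKSUMS",
    "RunManifest",
    "config_hash",
    "load_fixture",
    "load_config",
    "write_tables",
]

#: SHA-256 checksums pinning the packaged transcriptions.
FIXTURE_CHECKSUMS = {
    "table2_acdc": (
        "table2_acdc.csv",
        "c29bc814784475166b2ac19921c05d9161c6ee49271229841428f281bb195f85",
    ),
    "table3_cohort": (
        "table3_cohort.csv",
        "cec0ce66bd693d100fc81f8a58ede4d276b14d427a1272f480c935f5dcfea58d",
    ),
    "calibration_coefficients": (
        "calibration_coefficients.json",
        "0b3dbcfa8cc5fce686f0419fb7ca7bfe0c6fcf6340ca4f4c50d1ea754d76d1f0",
    ),
}


def config_hash(config_dict: dict) -> str:
    """Stable hash of a configuration mapping (key order irrelevant)."""
    canonical = json.dumps(config_dict, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()


@dataclass(frozen=True)
class RunManifest:
    """Reproducibility metadata for one experiment run."""

    config_hash: str
    seed: int
    software_version: str = __version__
    photon_budgets: dict = field(default_factory=dict)
    launched: dict = field(default_factory=dict)
    timestamp: str | None = None

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "software_version": self.software_version,
            "photon_budgets": self.photon_budgets,
            "launched": self.launched,
            "timestamp": self.timestamp,
        }


def load_fixture(name: str):
    """Load a packaged fixture table, verifying its checksum.

    Known names: ``table2_acdc`` (published AC/DC values),
    ``table3_cohort`` (clinical cohort bias table),
    ``calibration_coefficients`` (published calibration-line
    coefficients and cohort summary figures).
    """
    if name not in FIXTURE_CHECKSUMS:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURE_CHECKSUMS)}"
        )
    filename, expected = FIXTURE_CHECKSUMS[name]
    data = resources.files("pulseoxmc.data").joinpath(filename).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != expected:
        raise ValueError(
            f"fixture {filename} checksum mismatch: {digest} != {expected}"
        )
    if filename.endswith(".json"):
        return json.loads(data)
    from io import BytesIO

    return pd.read_csv(BytesIO(data))


_EXPERIMENT_KEYS = {
    "phenotypes",
    "sao2_grid",
    "wavelengths",
    "target_detected",
    "max_launched",
    "seed",
    "preset",
    "similarity_reduction",
    "batch_size",
    "roulette_threshold",
    "roulette_survival",
}
_GEOMETRY_KEYS = {
    "total_thickness",
    "stratum_corneum",
    "epidermis",
    "papillary_dermis",
    "upper_blood_net",
    "reticular_dermis",
    "deep_blood_net",
    "fat",
    "bone_radius",
    "half_width",
    "refractive_index",
    "ambient_index",
}
_SOURCE_KEYS = {"beam_radius"}
_DETECTOR_KEYS = {"radius", "acceptance_half_angle"}


def load_config(path):
    """Parse and validate a TOML experiment configuration.

    An empty file yields all documented defaults; unknown keys anywhere
    are rejected with the offending field named.  Layout::

        schema_version = 1
        [experiment]
        preset = "ci"
        seed = 1
        [geometry]
        bone_radius = 2.0
        [source]
        beam_radius = 1.0
        [detector]
        radius = 1.0
    """
    from .experiment_pipeline import ExperimentConfig, PRESETS
    from .mc_engine import DetectorSpec, SourceSpec
    from .tissue_model import FingerGeometry

    raw = tomllib.loads(Path(path).read_text())
    version = raw.pop("schema_version", 1)
    if version != 1:
        raise ValueError(f"unsupported config schema_version {version}")
    sections = {"experiment", "geometry", "source", "detector"}
    unknown = set(raw) - sections
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")

    def take(section, allowed):
        table = raw.get(section, {})
        bad = set(table) - allowed
        if bad:
            raise ValueError(f"unknown keys in [{section}]: {sorted(bad)}")
        return dict(table)

    exp = take("experiment", _EXPERIMENT_KEYS)
    geometry = take("geometry", _GEOMETRY_KEYS)
    source = take("source", _SOURCE_KEYS)
    detector = take("detector", _DETECTOR_KEYS)

    for key in ("phenotypes", "sao2_grid", "wavelengths"):
        if key in exp:
            exp[key] = tuple(exp[key])
    if geometry:
        exp["geometry"] = FingerGeometry(**geometry)
    if source:
        exp["source"] = SourceSpec(**source)
    if detector:
        exp["detector"] = DetectorSpec(**detector)

    preset = exp.pop("preset", None)
    if preset is not None:
        return ExperimentConfig.from_preset(preset, **exp)
    return ExperimentConfig(**exp)


def _write_text(path: Path, text: str) -> None:
    path.write_text(text)


def _format_curves(curves) -> dict:
    return {
        skin: {
            "intercept": curve.intercept,
            "slope": curve.slope,
            "r_squared": curve.r_squared,
            "residual_sd": curve.residual_sd,
            "n_points": curve.n_points,
        }
        for skin, curve in sorted(curves.items())
    }


def write_tables(result, out_dir) -> list[Path]:
    """Write the assembled experiment result as CSV/JSON files.

    Output is byte-identical for identical inputs: fixed column order,
    fixed float formatting, sorted JSON keys.  Printed-table rounding
    (one decimal, half away from zero) is applied to the bias tables
    only; full-precision companions are always written alongside.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, text: str):
        path = out / name
        _write_text(path, text)
        written.append(path)

    if result.transmittance is not None:
        emit(
            "transmittance.csv",
            result.transmittance.to_csv(index=False, float_format="%.8e"),
        )

    acdc_wide = result.acdc.pivot_table(
        index=["wavelength", "skin"], columns="sao2", values="acdc", sort=False
    )
    emit("acdc_table.csv", acdc_wide.to_csv(float_format="%.4f"))
    emit(
        "ratios.csv",
        result.ratios.to_csv(index=False, float_format="%.6f"),
    )
    emit(
        "calibration_curves.json",
        json.dumps(_format_curves(result.curves), indent=2, sort_keys=True) + "\n",
    )

    for skin, report in sorted(result.bias.items()):
        table = report.to_table()
        mean_row = pd.DataFrame(
            {
                "sao2": ["mean"],
                "spo2": [""],
                "bias": [round_half_away(report.mean_bias)],
            }
        )
        full = pd.concat([table, mean_row], ignore_index=True)
        emit(f"bias_{skin}.csv", full.to_csv(index=False))

    correction = {
        "multipliers": {k: v for k, v in sorted(result.multipliers.items())},
        "bias_ratios": {k: v for k, v in sorted(result.bias_ratios.items())},
        "adjusted_curves": _format_curves(result.adjusted_curves),
    }
    if result.dark_profile is not None:
        correction["dark_profile"] = {
            "sao2": [float(s) for s in result.dark_profile.sao2_grid],
            "factor": [float(f) for f in result.dark_profile.profile],
            "mean": result.dark_profile.applied_factor,
        }
    emit(
        "correction_factors.json",
        json.dumps(correction, indent=2, sort_keys=True) + "\n",
    )
    emit(
        "run_manifest.json",
        json.dumps(result.metadata, indent=2, sort_keys=True, default=str) + "\n",
    )
    return written
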