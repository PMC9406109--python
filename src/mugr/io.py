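"""File formats: CSV object tables, TIFF images with JSON calibration
sidecars, and run manifests.

Conventions: the longitudinal axis is µm from the proximal (oral) end and
maps to image x; all tables carry µm-valued columns; CSV round-trips are
lossless (shortest-round-trip float formatting).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import CalibrationError, SchemaError
from .render import CHANNELS, RenderedSection

__all__ = [
    "TABLE_SCHEMAS",
    "read_table",
    "write_table",
    "save_section",
    "load_section",
    "sha256_file",
    "write_manifest",
]

TABLE_SCHEMAS: dict[str, tuple[str, ...]] = {
    "cells": ("id", "x_um", "y_um", "cell_class"),
    "nuclei": ("id", "x_um", "y_um", "area_um2"),
    "components": ("id", "x_um", "y_um", "width_um", "area_um2", "contains_neuron"),
    "ganglia": ("id", "x_um", "y_um", "n_dapi", "n_neurons", "n_glia", "n_other"),
    "junctions": ("position_um", "depth_um"),
    "profile": ("position_um", "depth_um"),
    "intervals": ("midpoint_um", "unit_count", "zone"),
    "meta": ("patient_id", "segment", "haec"),
}


def write_table(df: pd.DataFrame, path: str | Path, kind: str) -> Path:
    """Write an object table, validating its schema first."""
    path = Path(path)
    _check_schema(df, kind)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")  # exact round-trip
    return path


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_schema(df, kind)
    return df


def _check_schema(df: pd.DataFrame, kind: str) -> None:
    if kind not in TABLE_SCHEMAS:
        raise SchemaError(f"unknown table kind {kind!r}")
    missing = [c for c in TABLE_SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{kind} table missing required column(s): {', '.join(missing)}"
        )


# --------------------------------------------------------------------------
# images
# --------------------------------------------------------------------------
def save_section(rendered: RenderedSection, stem: str | Path) -> dict[str, Path]:
    """Write a rendered section: multi-page channel TIFF, 16-bit label masks,
    a JSON calibration sidecar and the nuclei truth table."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": stem.with_suffix(".tiff"),
        "calibration": stem.with_name(stem.name + ".calibration.json"),
        "nuclei_mask": stem.with_name(stem.name + ".nuclei_labels.tiff"),
        "muscle_mask": stem.with_name(stem.name + ".muscle_mask.tiff"),
        "s100b_mask": stem.with_name(stem.name + ".s100b_labels.tiff"),
        "truth": stem.with_name(stem.name + ".truth_nuclei.csv"),
    }
    tifffile.imwrite(
        paths["image"],
        rendered.stack().astype(np.float32),
        photometric="minisblack",
        planarconfig="separate",
    )
    tifffile.imwrite(paths["nuclei_mask"], rendered.nuclei_labels)
    tifffile.imwrite(paths["muscle_mask"],
                     rendered.muscle_mask.astype(np.uint16))
    tifffile.imwrite(paths["s100b_mask"], rendered.s100b_labels)
    paths["calibration"].write_text(
        json.dumps(
            {
                "um_per_px": rendered.um_per_px,
                "channels": list(CHANNELS),
                "axis": "image x = longitudinal axis, origin proximal/oral",
            },
            indent=2,
        )
    )
    rendered.truth_table.to_csv(paths["truth"], index=False)
    return paths


def load_section(stem: str | Path) -> dict:
    """Load a saved section: channel dict, muscle mask and calibration."""
    stem = Path(stem)
    sidecar = stem.with_name(stem.name + ".calibration.json")
    if not sidecar.exists():
        raise CalibrationError(f"calibration sidecar not found: {sidecar}")
    cal = json.loads(sidecar.read_text())
    stack = tifffile.imread(stem.with_suffix(".tiff"))
    channels = {name: stack[i] for i, name in enumerate(cal["channels"])}
    muscle = tifffile.imread(
        stem.with_name(stem.name + ".muscle_mask.tiff")
    ).astype(bool)
    return {
        "channels": channels,
        "muscle_mask": muscle,
        "um_per_px": float(cal["um_per_px"]),
    }


# --------------------------------------------------------------------------
# manifests
# --------------------------------------------------------------------------
def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    config: dict,
    outputs: dict[str, str | Path],
    warnings_seen: list[str] | None = None,
) -> Path:
    from . import __version__

    path = Path(path)
    manifest = {
        "software": {"mugr": __version__, "numpy": np.__version__},
        "config": config,
        "outputs": {
            k: {"path": str(p), "sha256": sha256_file(p)}
            for k, p in outputs.items()
            if Path(p).exists()
        },
        "warnings": warnings_seen or [],
    }
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
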