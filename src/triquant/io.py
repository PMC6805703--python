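"""File-level plumbing: brain directories, manifests, CSV tables.

A brain on disk is a directory of slice scans named
``<brainid>_s<k>.<ext>`` (k = 1..6, ext png/tif/tiff) or an explicit
manifest CSV with columns ``brain_id, slice_index, path``.  Measurement
output is a flat per-slice CSV plus a brain-level JSON.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import InputError
from .imaging import SliceImage, SliceMeasurement, load_slice_image
from .spectro import StandardPoint, TissueSample
from .synthgen import PhantomTruth

__all__ = [
    "read_brain_dir",
    "read_manifest",
    "write_brain",
    "slice_measurements_frame",
    "read_plate_csv",
    "read_tissue_csv",
]

_SLICE_RE = re.compile(r"^(?P<brain>.+)_s(?P<idx>\d+)\.(png|tif|tiff)$", re.IGNORECASE)

_PLATE_COLUMNS = {"role", "fluorescence", "ttc_condition"}
_TISSUE_COLUMNS = {"sample_id", "weight_g", "fluorescence"}


def read_brain_dir(path: str | Path) -> tuple[str, list[SliceImage]]:
    """Load all ``<brainid>_s<k>`` slice scans from one directory."""
    path = Path(path)
    found: dict[int, Path] = {}
    brain_id = None
    for f in sorted(path.iterdir()) if path.is_dir() else []:
        m = _SLICE_RE.match(f.name)
        if not m:
            continue
        brain_id = brain_id or m.group("brain")
        idx = int(m.group("idx"))
        if idx in found:
            raise InputError(f"{path}: duplicate slice index {idx}")
        found[idx] = f
    if not found:
        raise InputError(f"{path}: no slice images matching '<brainid>_s<k>.<ext>'")
    images = [load_slice_image(found[i], i) for i in sorted(found)]
    return brain_id, images


def read_manifest(path: str | Path) -> dict[str, list[SliceImage]]:
    """Load brains listed in a manifest CSV (brain_id, slice_index, path)."""
    df = pd.read_csv(path)
    missing = {"brain_id", "slice_index", "path"} - set(df.columns)
    if missing:
        raise InputError(f"manifest missing column(s): {sorted(missing)}")
    root = Path(path).parent
    brains: dict[str, list[SliceImage]] = {}
    for row in df.itertuples():
        p = Path(row.path)
        if not p.is_absolute():
            p = root / p
        brains.setdefault(str(row.brain_id), []).append(
            load_slice_image(p, int(row.slice_index))
        )
    return brains


def write_brain(
    outdir: str | Path,
    brain_id: str,
    images: Sequence[SliceImage],
    truth: PhantomTruth | None = None,
) -> Path:
    """Write slice PNGs (plus truth JSON for phantoms) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for img in images:
        Image.fromarray(img.pixels).save(outdir / f"{brain_id}_s{img.slice_index}.png")
    if truth is not None:
        payload = {
            "brain_id": brain_id,
            "seed": truth.params.seed,
            "midline_col": truth.midline_col,
            "infarct_percent": truth.infarct_percent,
            "edema_percent": truth.edema_percent,
            "bbb_image_percent": truth.bbb_image_percent,
            "eb_total_px": truth.eb_total_px,
            "tissue_total_px": truth.tissue_total_px,
            "slices": [
                {
                    "slice_index": s.slice_index,
                    "left_area_px": s.left_area_px,
                    "right_area_px": s.right_area_px,
                    "infarct_area_px": s.infarct_area_px,
                    "blue_area_px": s.blue_area_px,
                }
                for s in truth.measurement.slices
            ],
            "params": {
                "n_slices": truth.params.n_slices,
                "swelling_factor": truth.params.swelling_factor,
                "infarct_fraction": truth.params.infarct_fraction,
                "eb_fraction": truth.params.eb_fraction,
                "noise_sd": truth.params.noise_sd,
            },
        }
        with open(outdir / f"{brain_id}_truth.json", "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
    return outdir


def slice_measurements_frame(
    brain_id: str, slices: Iterable[SliceMeasurement]
) -> pd.DataFrame:
    """Per-slice CSV layout: one row per slice with areas and flags."""
    return pd.DataFrame(
        [
            {
                "brain_id": brain_id,
                "slice_index": s.slice_index,
                "left_area_px": s.left_area_px,
                "right_area_px": s.right_area_px,
                "infarct_area_px": s.infarct_area_px,
                "blue_area_px": s.blue_area_px,
                "flags": ";".join(s.flags),
            }
            for s in slices
        ]
    )


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    """Plate table: role (standard|blank|sample), fluorescence, condition.

    Standards additionally need ``amount_ng`` or ``concentration_ng_ml``.
    """
    df = pd.read_csv(path)
    missing = _PLATE_COLUMNS - set(df.columns)
    if missing:
        raise InputError(f"plate CSV missing column(s): {sorted(missing)}")
    has_conc = {"amount_ng", "concentration_ng_ml"} & set(df.columns)
    if not has_conc:
        raise InputError("plate CSV needs an 'amount_ng' or 'concentration_ng_ml' column")
    return df


def standards_from_frame(df: pd.DataFrame, condition: str) -> list[StandardPoint]:
    rows = df[(df["ttc_condition"] == condition) & df["role"].isin(["standard", "blank"])]
    points = []
    for row in rows.itertuples():
        amount = getattr(row, "amount_ng", None)
        conc = getattr(row, "concentration_ng_ml", None)
        amount = None if amount is None or np.isnan(amount) else float(amount)
        conc = None if conc is None or (isinstance(conc, float) and np.isnan(conc)) else float(conc)
        if amount is not None:
            conc = None  # amount wins when both columns are present
        points.append(
            StandardPoint(
                fluorescence=float(row.fluorescence),
                amount_ng=amount,
                concentration_ng_ml=conc,
                ttc_condition=condition,
            )
        )
    return points


def read_tissue_csv(
    path: str | Path,
    homogenate_volume_ml: float = 1.0,
    dilution_factor: float = 4.0,
) -> list[TissueSample]:
    """Tissue table: sample_id, hemisphere, weight_g, fluorescence."""
    df = pd.read_csv(path)
    missing = _TISSUE_COLUMNS - set(df.columns)
    if missing:
        raise InputError(f"tissue CSV missing column(s): {sorted(missing)}")
    return [
        TissueSample(
            sample_id=str(row.sample_id),
            hemisphere=str(getattr(row, "hemisphere", "right")),
            fluorescence=float(row.fluorescence),
            tissue_weight_g=float(row.weight_g),
            homogenate_volume_ml=float(getattr(row, "homogenate_volume_ml", homogenate_volume_ml)),
            dilution_factor=float(getattr(row, "dilution_factor", dilution_factor)),
        )
        for row in df.itertuples()
    ]
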