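"""File formats: long trait tables, maturity tables, image directories and
run manifests.

The canonical trait table is tidy/long with the header
``plant_id,genotype,treatment,das,trait,value``; (plant_id, das, trait) is a
unique key, ``das`` a positive integer, ``value`` numeric or empty for a
missing observation (e.g. EB on days without a usable top view).  All CSVs
are UTF-8 with ``.`` as the decimal separator, independent of locale.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

TRAIT_COLUMNS = ["plant_id", "genotype", "treatment", "das", "trait", "value"]
KNOWN_TREATMENTS = {"control", "stress"}


class TraitTableError(ValueError):
    pass


def read_trait_table(path) -> pd.DataFrame:
    """Read and validate a long-format trait table.

    Raises :class:`TraitTableError` naming the offending line for malformed
    rows, unknown treatment labels or duplicated (plant_id, das, trait) keys.
    """
    df = pd.read_csv(path, dtype={"plant_id": str, "genotype": str,
                                  "treatment": str, "trait": str})
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise TraitTableError(f"{path}: missing columns {missing}")
    das = pd.to_numeric(df["das"], errors="coerce")
    bad = das.isna() | (das != das.round()) | (das < 1)
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header is line 1
        raise TraitTableError(f"{path}: invalid das on line {line}")
    df["das"] = das.astype(int)
    value = pd.to_numeric(df["value"], errors="coerce")
    malformed = value.isna() & df["value"].notna() & (df["value"].astype(str).str.strip() != "")
    if malformed.any():
        line = int(df.index[malformed][0]) + 2
        raise TraitTableError(f"{path}: non-numeric value on line {line}")
    df["value"] = value.astype(float)
    unknown = ~df["treatment"].isin(KNOWN_TREATMENTS)
    if unknown.any():
        line = int(df.index[unknown][0]) + 2
        raise TraitTableError(
            f"{path}: unknown treatment {df['treatment'][unknown].iloc[0]!r} "
            f"on line {line}"
        )
    dup = df.duplicated(subset=["plant_id", "das", "trait"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise TraitTableError(f"{path}: duplicate (plant, das, trait) key on line {line}")
    return df[TRAIT_COLUMNS]


def write_trait_table(df: pd.DataFrame, path) -> None:
    df[TRAIT_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def write_images(image_sets, out_dir) -> None:
    """PNG layout ``<plant_id>/<das>/{top,side000,side045,side090}.png`` with
    truth masks as parallel ``*_mask.png``."""
    out_dir = Path(out_dir)
    for s in image_sets:
        d = out_dir / s.plant_id / str(s.das)
        d.mkdir(parents=True, exist_ok=True)
        views = {"top": s.top, "side000": s.sides[0],
                 "side045": s.sides[1], "side090": s.sides[2]}
        for name, img in views.items():
            iio.imwrite(d / f"{name}.png", img)
            if s.truth_masks is not None:
                mask = (s.truth_masks[name].astype(np.uint8)) * 255
                iio.imwrite(d / f"{name}_mask.png", mask)


def read_image_sets(root, mm_per_pixel: float):
    """Load a PNG directory tree written by :func:`write_images` back into
    ``PlantImageSet`` objects (truth masks included when present)."""
    from .synthetic import PlantImageSet

    root = Path(root)
    sets = []
    for plant_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for das_dir in sorted((p for p in plant_dir.iterdir() if p.is_dir()),
                              key=lambda p: int(p.name)):
            views = {}
            masks = {}
            for name in ("top", "side000", "side045", "side090"):
                views[name] = iio.imread(das_dir / f"{name}.png")
                mask_path = das_dir / f"{name}_mask.png"
                if mask_path.exists():
                    masks[name] = iio.imread(mask_path) > 127
            sets.append(PlantImageSet(
                plant_id=plant_dir.name,
                das=int(das_dir.name),
                top=views["top"],
                sides=[views["side000"], views["side045"], views["side090"]],
                truth_masks=masks or None,
                mm_per_pixel=mm_per_pixel,
            ))
    return sets


def config_digest(path) -> str:
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()


def write_manifest(path, *, seed: int, config_path=None, inputs=None,
                   outputs=None, status: str = "ok") -> dict:
    """JSON run manifest: seed, config digest, tool version, timestamps and
    the artifact paths — enough to re-derive every output."""
    from . import __version__

    manifest = {
        "tool": "phenocycle",
        "version": __version__,
        "seed": seed,
        "config": str(config_path) if config_path else None,
        "config_sha256": config_digest(config_path) if config_path else None,
        "timestamp_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
        "inputs": [str(p) for p in (inputs or [])],
        "outputs": [str(p) for p in (outputs or [])],
        "status": status,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return manifest
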