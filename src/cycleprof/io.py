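"""Record-table and image IO.

Per-cell record tables are CSV files with a versioned schema header line
(``# cycleprof-records v1``) so that downstream stages can refuse files
they do not understand. Extra columns (e.g. instrument exports with their
own features) are preserved on round trip. Tiles are written as multi-page
TIFFs (page order: protein, marker, bright field) with the pixel size in
the image description.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import SchemaError
from .synthetic import CellSpec, ImageTile

SCHEMA_HEADER = "# cycleprof-records v1"
REQUIRED_COLUMNS = ("length_um", "mean_intensity")

__all__ = ["read_records", "write_records", "write_tile", "read_tile",
           "write_specs", "SCHEMA_HEADER"]


def write_records(path, records: pd.DataFrame) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(SCHEMA_HEADER + "\n")
        records.to_csv(fh, index=False)


def read_records(path) -> pd.DataFrame:
    """Read a record CSV, checking the schema header and required columns."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# cycleprof-records"):
            raise SchemaError(f"{path}: missing cycleprof-records schema header")
        if header != SCHEMA_HEADER:
            raise SchemaError(f"{path}: unknown schema version {header!r}")
        df = pd.read_csv(fh)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return df


def write_tile(path, tile: ImageTile) -> None:
    """Write a tile as a 3-page TIFF (protein, marker, bright field)."""
    stack = np.stack([tile.protein, tile.marker, tile.bf]).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack",
                     description=json.dumps({"pixel_size_um": tile.pixel_size,
                                             "channels": ["protein", "marker", "bf"]}))


def read_tile(path) -> ImageTile:
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        try:
            meta = json.loads(tf.pages[0].description)
        except (json.JSONDecodeError, TypeError):
            raise SchemaError(f"{path}: missing tile metadata")
    return ImageTile(protein=stack[0].astype(float),
                     marker=stack[1].astype(float),
                     bf=stack[2].astype(float),
                     pixel_size=float(meta["pixel_size_um"]))


def write_mask(path, mask, pixel_size: float) -> None:
    """Write a binary mask as a single-page 8-bit TIFF."""
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint8) * 255,
                     photometric="minisblack",
                     description=json.dumps({"pixel_size_um": pixel_size,
                                             "kind": "binary_mask"}))


def read_mask(path):
    """Read a binary mask TIFF back as ``(bool array, pixel_size)``."""
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray() > 0
        try:
            meta = json.loads(tf.pages[0].description)
        except (json.JSONDecodeError, TypeError):
            raise SchemaError(f"{path}: missing mask metadata")
    return arr, float(meta["pixel_size_um"])


def write_specs(path, specs: list[CellSpec]) -> None:
    """Write ground-truth cell specs alongside simulated tiles."""
    rows = []
    for i, s in enumerate(specs):
        rows.append({
            "cell_id": i,
            "length_um": s.length,
            "stage": s.stage.value,
            "cycle_position": s.cycle_position,
            "n_nuclei": len(s.nucleus_centers),
            "nucleus_centers_um": ";".join(f"{c:.4f}" for c in s.nucleus_centers),
            "nucleus_radius_um": s.nucleus_radius,
            "true_wholecell_conc": s.true_wholecell_conc,
            "true_nuclear_conc": s.true_nuclear_conc,
            "septum_position_um": s.septum_position if s.septum_position is not None else "",
        })
    pd.DataFrame(rows).to_csv(path, index=False)
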