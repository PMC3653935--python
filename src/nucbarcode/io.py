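"""Readers and writers for on-disk formats.

Images travel as single-plane grayscale 16-bit TIFFs holding 12-bit data;
tables (object tables, plate layouts, calibrations, well counts) are plain
comma-separated UTF-8 CSV with a mandatory header row.  Mixtures in the
plate layout are pipe-separated line labels, e.g. ``mCherry2|mPlum2``.
"""

from __future__ import annotations

import os
import re
from collections.abc import Mapping
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .model import (
    Channel,
    ChannelImage,
    FieldImageSet,
    MAX_COUNT,
    ObjectTable,
    PlateLayout,
    ValidationError,
    WellSpec,
    as_channel,
)

MIXTURE_SEP = "|"

LAYOUT_COLUMNS = ["well_id", "role", "mixture", "treatment", "concentration"]


def read_channel_tiff(path: str | os.PathLike, channel: Channel | str) -> ChannelImage:
    """Read one single-plane grayscale TIFF and validate the 12-bit contract."""
    channel = as_channel(channel)
    try:
        arr = tifffile.imread(path)
    except FileNotFoundError as exc:
        raise FileNotFoundError(
            f"channel {channel.value}: image file not found: {path}"
        ) from exc
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValidationError(
            f"channel {channel.value}: expected a single-plane grayscale image, "
            f"got shape {arr.shape} from {path}"
        )
    if arr.max(initial=0) > MAX_COUNT:
        raise ValidationError(
            f"channel {channel.value}: {path} contains values above {MAX_COUNT}; "
            "images must hold 12-bit data in their 16-bit container"
        )
    return ChannelImage(pixels=arr, channel=channel)


def load_field(
    paths: Mapping[Channel | str, str | os.PathLike],
    plate_id: str,
    well_id: str,
    field_index: int,
    day: int,
) -> FieldImageSet:
    """Load all channel TIFFs of one field and validate equal dimensions."""
    channels = {
        as_channel(ch): read_channel_tiff(p, ch) for ch, p in paths.items()
    }
    return FieldImageSet(
        plate_id=plate_id,
        well_id=well_id,
        field_index=field_index,
        day=day,
        channels=channels,
    )


def field_filename(field: FieldImageSet, channel: Channel | str) -> str:
    ch = as_channel(channel)
    return (
        f"{field.plate_id}_day{field.day}_{field.well_id}"
        f"_f{field.field_index}_{ch.value}.tif"
    )


def write_field(field: FieldImageSet, out_dir: str | os.PathLike) -> dict[Channel, Path]:
    """Write every channel of a field as uint16 TIFF; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[Channel, Path] = {}
    for ch, image in field.channels.items():
        p = out / field_filename(field, ch)
        tifffile.imwrite(p, image.pixels.astype(np.uint16))
        paths[ch] = p
    return paths


_FIELD_RE = re.compile(
    r"(?P<plate>.+)_day(?P<day>\d+)_(?P<well>[^_]+)_f(?P<fi>\d+)"
    r"_(?P<ch>em1|em2|yfp|hoechst)\.tif{1,2}$"
)


def scan_image_dir(image_dir: str | os.PathLike) -> list[FieldImageSet]:
    """Discover and load every field written by :func:`write_field`.

    Filenames follow ``{plate}_day{day}_{well}_f{field}_{channel}.tif``;
    channels of the same (plate, day, well, field) are grouped into one
    :class:`FieldImageSet`.
    """
    groups: dict[tuple[str, int, str, int], dict[str, Path]] = {}
    for p in sorted(Path(image_dir).rglob("*.tif*")):
        m = _FIELD_RE.match(p.name)
        if not m:
            continue
        key = (m["plate"], int(m["day"]), m["well"], int(m["fi"]))
        groups.setdefault(key, {})[m["ch"]] = p
    fields = []
    for (plate, day, well, fi), paths in sorted(groups.items()):
        fields.append(load_field(paths, plate, well, fi, day))
    return fields


def write_object_table(table: ObjectTable, path: str | os.PathLike) -> None:
    """Write one CSV row per nucleus with a stable, documented column order."""
    df = table.to_dataframe()
    df.to_csv(path, index=False)


def read_object_table(path: str | os.PathLike) -> ObjectTable:
    df = pd.read_csv(
        path,
        dtype={"well_id": str, "flags": str},
        keep_default_na=True,
    )
    df["flags"] = df["flags"].fillna("")
    return ObjectTable.from_dataframe(df, provenance={"source": str(path)})


def write_plate_layout(layout: PlateLayout, path: str | os.PathLike) -> None:
    rows = [
        {
            "well_id": w.well_id,
            "role": w.role,
            "mixture": MIXTURE_SEP.join(w.mixture),
            "treatment": w.treatment,
            "concentration": w.concentration,
        }
        for w in layout
    ]
    pd.DataFrame(rows, columns=LAYOUT_COLUMNS).to_csv(path, index=False)


def load_plate_layout(path: str | os.PathLike) -> PlateLayout:
    """Parse and validate a plate-layout CSV.

    Columns: ``well_id, role, mixture, treatment, concentration``; the
    mixture cell is a ``|``-separated list of line labels, empty for
    media-only background wells.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"plate layout {path}: missing columns {missing}")
    wells = []
    for row in df.itertuples(index=False):
        mixture = tuple(
            lab.strip() for lab in row.mixture.split(MIXTURE_SEP) if lab.strip()
        )
        wells.append(
            WellSpec(
                well_id=row.well_id.strip(),
                role=row.role.strip().lower(),
                mixture=mixture,
                treatment=row.treatment.strip(),
                concentration=row.concentration.strip(),
            )
        )
    return PlateLayout(wells=wells)
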