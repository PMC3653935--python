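"""Core data model for ratiometric nuclear bar-code analysis.

Images are single-plane grayscale frames holding 12-bit camera counts
(0-4095) in 16-bit containers.  A *field* is one camera position within a
well; each field carries two red emission channels (em1: 635-675 nm,
em2: 608-648 nm) and optionally a YFP reporter channel and a Hoechst
counterstain channel.  Per-nucleus measurements are collected into an
:class:`ObjectTable`, the central tabular container that every downstream
stage (calibration, demultiplexing, growth statistics) consumes.
"""

from __future__ import annotations

import dataclasses
import enum
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAX_COUNT = 4095  # 12-bit full scale

SATURATED = "saturated"
LOW_SIGNAL = "low_signal"
AMBIGUOUS = "ambiguous"


class ValidationError(ValueError):
    """Raised when an input violates a data-model contract."""


class Channel(str, enum.Enum):
    """Acquisition channels.  em1/em2 are the two red emission passbands."""

    EM1 = "em1"
    EM2 = "em2"
    YFP = "yfp"
    HOECHST = "hoechst"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def as_channel(value: "Channel | str") -> Channel:
    if isinstance(value, Channel):
        return value
    try:
        return Channel(str(value).lower())
    except ValueError as exc:
        raise ValidationError(f"unknown channel {value!r}") from exc


@dataclass
class ChannelImage:
    """One single-plane grayscale frame of integer camera counts.

    Parameters
    ----------
    pixels
        2-D integer array; every value must lie in [0, 4095].  Values above
        4095 are rejected rather than clipped so acquisition errors surface.
    channel
        Which passband/stain the frame was collected in.
    exposure_ms
        Exposure time, metadata only.
    """

    pixels: np.ndarray
    channel: Channel
    exposure_ms: float = 100.0

    def __post_init__(self) -> None:
        self.channel = as_channel(self.channel)
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.size == 0:
            raise ValidationError(
                f"channel {self.channel.value}: expected a non-empty 2-D image, "
                f"got shape {arr.shape}"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValidationError(
                    f"channel {self.channel.value}: pixel values must be integer counts"
                )
            arr = arr.astype(np.uint16)
        if arr.min() < 0 or arr.max() > MAX_COUNT:
            raise ValidationError(
                f"channel {self.channel.value}: pixel values outside the 12-bit "
                f"range [0, {MAX_COUNT}] (found min={arr.min()}, max={arr.max()})"
            )
        if self.exposure_ms <= 0:
            raise ValidationError("exposure_ms must be positive")
        self.pixels = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class FieldImageSet:
    """All channel frames of one (plate, well, field, day) acquisition."""

    plate_id: str
    well_id: str
    field_index: int
    day: int
    channels: dict[Channel, ChannelImage] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.field_index < 0 or self.day < 0:
            raise ValidationError("field_index and day must be non-negative")
        self.channels = {as_channel(k): v for k, v in self.channels.items()}
        shapes = {im.shape for im in self.channels.values()}
        if len(shapes) > 1:
            raise ValidationError(
                f"{self.plate_id}/{self.well_id} field {self.field_index}: channel "
                f"dimensions differ: { {c.value: im.shape for c, im in self.channels.items()} }"
            )

    @property
    def shape(self) -> tuple[int, int]:
        if not self.channels:
            raise ValidationError("field has no channels")
        return next(iter(self.channels.values())).shape

    def pixels(self, channel: Channel | str) -> np.ndarray:
        return self.channels[as_channel(channel)].pixels

    def require_barcode_channels(self) -> None:
        missing = {Channel.EM1, Channel.EM2} - set(self.channels)
        if missing:
            raise ValidationError(
                f"bar-code analysis requires em1 and em2; missing "
                f"{sorted(c.value for c in missing)}"
            )


@dataclass(frozen=True)
class WellSpec:
    """One plate-layout row: what was plated in a well."""

    well_id: str
    role: str  # "sample" or "background"
    mixture: tuple[str, ...] = ()
    treatment: str = ""
    concentration: str = ""


@dataclass
class PlateLayout:
    """Maps wells to cell-line mixtures, treatments and background wells.

    Background wells are plated with media only and supply the reference
    background image; at least one must exist when background correction
    is enabled.
    """

    wells: list[WellSpec]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for w in self.wells:
            if w.role not in ("sample", "background"):
                raise ValidationError(
                    f"well {w.well_id}: unknown role {w.role!r} "
                    "(expected 'sample' or 'background')"
                )
            if w.well_id in seen:
                raise ValidationError(f"duplicate well_id {w.well_id!r} in layout")
            seen.add(w.well_id)
            if w.role == "background" and w.mixture:
                raise ValidationError(
                    f"background well {w.well_id} must have an empty mixture"
                )

    def __iter__(self) -> Iterator[WellSpec]:
        return iter(self.wells)

    def __len__(self) -> int:
        return len(self.wells)

    def well(self, well_id: str) -> WellSpec:
        for w in self.wells:
            if w.well_id == well_id:
                return w
        raise KeyError(well_id)

    @property
    def background_wells(self) -> list[WellSpec]:
        return [w for w in self.wells if w.role == "background"]

    @property
    def sample_wells(self) -> list[WellSpec]:
        return [w for w in self.wells if w.role == "sample"]

    def monoculture_wells(self, label: str) -> list[WellSpec]:
        """Wells plated with exactly one line, ``label`` (calibration wells)."""
        return [w for w in self.sample_wells if w.mixture == (label,)]

    @property
    def lines(self) -> list[str]:
        out: list[str] = []
        for w in self.sample_wells:
            for lab in w.mixture:
                if lab not in out:
                    out.append(lab)
        return out


@dataclass
class NucleusRecord:
    """One segmented nucleus and its per-channel measurements.

    ``intensity`` holds background-subtracted summed counts per channel and
    may be negative after subtraction.  ``ratio_em1_em2`` is defined only
    when the em2 sum clears the low-signal floor; otherwise it is ``None``
    and the ``low_signal`` flag is set.  ``saturated`` means at least one
    member pixel hit 4095 in the raw em1 or em2 frame.
    """

    object_id: int
    well_id: str
    field_index: int
    day: int
    centroid: tuple[float, float]
    area_px: int
    intensity: dict[Channel, float]
    ratio_em1_em2: float | None = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.area_px <= 0:
            raise ValidationError("area_px must be positive")
        self.intensity = {as_channel(k): float(v) for k, v in self.intensity.items()}
        self.flags = frozenset(self.flags)

    @property
    def excluded(self) -> bool:
        return bool(self.flags & {SATURATED, LOW_SIGNAL})


_TABLE_COLUMNS = [
    "object_id",
    "well_id",
    "field_index",
    "day",
    "centroid_row",
    "centroid_col",
    "area_px",
    "em1",
    "em2",
    "yfp",
    "ratio_em1_em2",
    "flags",
]


@dataclass
class ObjectTable:
    """Ordered collection of nucleus records plus processing provenance."""

    records: list[NucleusRecord] = field(default_factory=list)
    provenance: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, int, int]] = set()
        for r in self.records:
            key = (r.well_id, r.field_index, r.day, r.object_id)
            if key in seen:
                raise ValidationError(
                    f"duplicate object_id {r.object_id} in well {r.well_id} "
                    f"field {r.field_index} day {r.day}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[NucleusRecord]:
        return iter(self.records)

    def extend(self, other: "ObjectTable") -> None:
        self.records.extend(other.records)
        self.__post_init__()

    def ratios(self, include_flagged: bool = False) -> np.ndarray:
        """Defined em1/em2 ratios, by default excluding flagged objects."""
        vals = [
            r.ratio_em1_em2
            for r in self.records
            if r.ratio_em1_em2 is not None and (include_flagged or not r.excluded)
        ]
        return np.asarray(vals, dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "object_id": r.object_id,
                    "well_id": r.well_id,
                    "field_index": r.field_index,
                    "day": r.day,
                    "centroid_row": r.centroid[0],
                    "centroid_col": r.centroid[1],
                    "area_px": r.area_px,
                    "em1": r.intensity.get(Channel.EM1, np.nan),
                    "em2": r.intensity.get(Channel.EM2, np.nan),
                    "yfp": r.intensity.get(Channel.YFP, np.nan),
                    "ratio_em1_em2": (
                        np.nan if r.ratio_em1_em2 is None else r.ratio_em1_em2
                    ),
                    "flags": ";".join(sorted(r.flags)),
                }
            )
        return pd.DataFrame(rows, columns=_TABLE_COLUMNS)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, provenance: Mapping[str, object] | None = None
    ) -> "ObjectTable":
        records = []
        for row in df.itertuples(index=False):
            intensity: dict[Channel, float] = {}
            for ch, col in ((Channel.EM1, "em1"), (Channel.EM2, "em2"), (Channel.YFP, "yfp")):
                val = getattr(row, col)
                if not pd.isna(val):
                    intensity[ch] = float(val)
            flags = frozenset(f for f in str(row.flags).split(";") if f) if not pd.isna(row.flags) else frozenset()
            ratio = None if pd.isna(row.ratio_em1_em2) else float(row.ratio_em1_em2)
            records.append(
                NucleusRecord(
                    object_id=int(row.object_id),
                    well_id=str(row.well_id),
                    field_index=int(row.field_index),
                    day=int(row.day),
                    centroid=(float(row.centroid_row), float(row.centroid_col)),
                    area_px=int(row.area_px),
                    intensity=intensity,
                    ratio_em1_em2=ratio,
                    flags=flags,
                )
            )
        return cls(records=records, provenance=dict(provenance or {}))


def concat_tables(tables: Iterable[ObjectTable]) -> pd.DataFrame:
    """Stack several object tables into one DataFrame."""
    frames = [t.to_dataframe() for t in tables]
    if not frames:
        return pd.DataFrame(columns=_TABLE_COLUMNS)
    return pd.concat(frames, ignore_index=True)
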