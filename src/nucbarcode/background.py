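"""Two-stage background model.

Stage 1: a per-channel *reference background image* — the pixel-wise mean
of many media-only (no-cell) fields — captures camera offset, media
fluorescence and the optics' illumination non-uniformity (vignetting).

Stage 2: a per-field scalar *residual offset* delta absorbs the small
(typically 1-3 count) well-to-well drift of the background level.  It is
the mean of (field - reference) over pixels outside a dilated all-object
mask, with the same mask applied to both grids.  The corrected frame is

    corrected = field - reference - delta

kept real-valued and never clipped, so negative pixels are preserved and
per-object sums stay unbiased.  The offset step matters most for nuclei
with little signal above background, whose em1/em2 ratio a few stray
counts per pixel would otherwise bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Channel, FieldImageSet, ValidationError, as_channel
from .segment import permissive_mask


class BackgroundError(ValueError):
    """Raised when a background model cannot be built or applied."""


@dataclass
class BackgroundModel:
    """Per-channel reference grids plus accumulated per-field offsets."""

    reference: dict[Channel, np.ndarray]
    n_fields_averaged: dict[Channel, int]
    offsets: dict[tuple[str, int, int, Channel], float] = field(default_factory=dict)

    def record_offset(
        self, well_id: str, field_index: int, day: int, channel: Channel | str, delta: float
    ) -> None:
        self.offsets[(well_id, field_index, day, as_channel(channel))] = float(delta)


def build_reference_background(
    media_only_fields: list[FieldImageSet],
    channel: Channel | str,
    max_masked_fraction: float = 0.005,
    dilation_px: int = 3,
) -> tuple[np.ndarray, int]:
    """Average media-only fields into a real-valued reference grid.

    Fields showing unusual fluorescent debris are rejected: any field whose
    permissive object mask covers more than ``max_masked_fraction`` of
    pixels is dropped.  Raises if every field is rejected, listing reasons.
    """
    channel = as_channel(channel)
    if not media_only_fields:
        raise BackgroundError("no media-only fields supplied")
    accepted: list[np.ndarray] = []
    reasons: list[str] = []
    shape = None
    for f in media_only_fields:
        if channel not in f.channels:
            reasons.append(f"{f.well_id}/f{f.field_index}: channel {channel.value} missing")
            continue
        px = f.pixels(channel).astype(float)
        if shape is None:
            shape = px.shape
        elif px.shape != shape:
            raise ValidationError(
                f"{f.well_id}/f{f.field_index}: dimensions {px.shape} differ from {shape}"
            )
        frac = float(permissive_mask(px, dilation_px=dilation_px).mean())
        if frac > max_masked_fraction:
            reasons.append(
                f"{f.well_id}/f{f.field_index}: {frac:.2%} of pixels masked as "
                f"debris (limit {max_masked_fraction:.2%})"
            )
            continue
        accepted.append(px)
    if not accepted:
        raise BackgroundError(
            "all media-only fields rejected:\n  " + "\n  ".join(reasons)
        )
    return np.mean(accepted, axis=0), len(accepted)


def estimate_field_offset(
    field_image: np.ndarray,
    reference: np.ndarray,
    exclusion_mask: np.ndarray,
    min_unmasked_fraction: float = 0.01,
) -> float:
    """Residual scalar offset delta of a cell-containing field.

    delta = mean(field - reference) over pixels where ``exclusion_mask`` is
    False; the identical mask restricts both grids to the same area.
    """
    field_arr = np.asarray(field_image, dtype=float)
    ref = np.asarray(reference, dtype=float)
    mask = np.asarray(exclusion_mask, dtype=bool)
    if field_arr.shape != ref.shape or field_arr.shape != mask.shape:
        raise ValidationError("field, reference and mask dimensions differ")
    unmasked = ~mask
    frac = float(unmasked.mean())
    if frac < min_unmasked_fraction:
        raise BackgroundError(
            f"only {frac:.2%} of pixels available for background estimation "
            f"(need >= {min_unmasked_fraction:.0%}); sample a sparser field or "
            "reduce the mask dilation"
        )
    return float(np.mean(field_arr[unmasked] - ref[unmasked]))


def correct_field(
    field_image: np.ndarray, reference: np.ndarray, delta: float = 0.0
) -> np.ndarray:
    """Apply both correction stages: field - reference - delta (real-valued)."""
    field_arr = np.asarray(field_image, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if field_arr.shape != ref.shape:
        raise ValidationError("field and reference dimensions differ")
    return field_arr - ref - float(delta)


def correct_field_auto(
    field_image: np.ndarray,
    reference: np.ndarray,
    dilation_px: int = 3,
    min_unmasked_fraction: float = 0.01,
) -> tuple[np.ndarray, float]:
    """Estimate delta behind a permissive object mask, then correct.

    Convenience composition used by the pipeline: mask all objects in the
    field (dilated), estimate the residual offset outside the mask, and
    return the corrected frame together with the delta used.
    """
    mask = permissive_mask(
        np.asarray(field_image, dtype=float) - np.asarray(reference, dtype=float),
        dilation_px=dilation_px,
    )
    delta = estimate_field_offset(
        field_image, reference, mask, min_unmasked_fraction=min_unmasked_fraction
    )
    return correct_field(field_image, reference, delta), delta


def edge_background_warnings(
    offsets_by_well: dict[str, float], sd_limit: float = 3.0
) -> list[str]:
    """Flag edge-row wells whose background offset is anomalous.

    Plate walls can reflect stray light into edge wells.  Wells in the
    first/last plate row whose offset deviates from the plate median by
    more than ``sd_limit`` robust standard deviations are reported.
    """
    if len(offsets_by_well) < 4:
        return []
    values = np.array(list(offsets_by_well.values()), dtype=float)
    med = float(np.median(values))
    sd = 1.4826 * float(np.median(np.abs(values - med)))
    if sd == 0:
        return []
    rows = sorted({w[0] for w in offsets_by_well})
    edge_rows = {rows[0], rows[-1]}
    warnings = []
    for well, delta in offsets_by_well.items():
        if well[0] in edge_rows and abs(delta - med) > sd_limit * sd:
            warnings.append(
                f"edge well {well}: background offset {delta:.2f} deviates from "
                f"plate median {med:.2f} by more than {sd_limit:g} sd; check for "
                "plate-wall reflections"
            )
    return warnings
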