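"""End-to-end composition of the analysis stages.

Orchestrates: reference-background construction from media-only wells,
per-field residual-offset correction, stringent segmentation on the
corrected em1 frame, per-object measurement, monoculture calibration and
co-culture demultiplexing.  The CLI is a thin wrapper over these
functions; tests drive them directly on simulated plates.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
from skimage.segmentation import expand_labels

from . import background as bg
from . import barcode, segment
from .model import Channel, FieldImageSet, ObjectTable, PlateLayout, ValidationError

log = logging.getLogger("nucbarcode")


@dataclass
class PipelineParams:
    """Tunable knobs of the image-analysis pipeline.

    ``noise_sd`` feeds the low-signal floor for ratio emission
    (5 * noise_sd * sqrt(area) on the em2 sum); ``k_sd`` the window
    half-width multiplier; ``dilation_px`` the permissive-mask growth used
    for background-offset estimation.
    """

    min_area_px: int = 30
    min_separation_px: int = 6
    split_touching: bool = True
    threshold_floor: float | None = None
    dilation_px: int = 3
    max_masked_fraction: float = 0.005
    noise_sd: float = 2.0
    k_sd: float = 3.0
    min_calibration_n: int = 500
    measure_expand_px: int = 2
    measure_channels: tuple[Channel, ...] = (Channel.EM1, Channel.EM2, Channel.YFP)


def build_backgrounds(
    fields: Sequence[FieldImageSet],
    layout: PlateLayout,
    params: PipelineParams | None = None,
    channels: Iterable[Channel] = (Channel.EM1, Channel.EM2, Channel.YFP),
) -> bg.BackgroundModel:
    """Average media-only wells into per-channel reference images."""
    params = params or PipelineParams()
    bg_wells = {w.well_id for w in layout.background_wells}
    if not bg_wells:
        raise ValidationError(
            "layout has no background (media-only) wells; background "
            "correction needs at least one"
        )
    media_fields = [f for f in fields if f.well_id in bg_wells]
    reference: dict[Channel, np.ndarray] = {}
    n_avg: dict[Channel, int] = {}
    for ch in channels:
        usable = [f for f in media_fields if ch in f.channels]
        if not usable:
            continue
        ref, n = bg.build_reference_background(
            usable, ch,
            max_masked_fraction=params.max_masked_fraction,
            dilation_px=params.dilation_px,
        )
        reference[ch] = ref
        n_avg[ch] = n
        log.info("reference background for %s averaged from %d fields", ch.value, n)
    return bg.BackgroundModel(reference=reference, n_fields_averaged=n_avg)


def process_field(
    fieldset: FieldImageSet,
    model: bg.BackgroundModel,
    params: PipelineParams | None = None,
) -> ObjectTable:
    """Correct, segment and measure one field.

    The permissive all-object mask is the union over em1 and em2 of the
    reference-subtracted frames, dilated; the residual offset delta is
    estimated per channel outside that mask, then the corrected em1 frame
    drives stringent segmentation and all channels are summed per object.
    """
    params = params or PipelineParams()
    fieldset.require_barcode_channels()
    mask = np.zeros(fieldset.shape, dtype=bool)
    for ch in (Channel.EM1, Channel.EM2):
        residual = fieldset.pixels(ch).astype(float) - model.reference[ch]
        mask |= segment.permissive_mask(residual, dilation_px=params.dilation_px)

    corrected: dict[Channel, np.ndarray] = {}
    raw: dict[Channel, np.ndarray] = {}
    deltas: dict[Channel, float] = {}
    for ch, ref in model.reference.items():
        if ch not in fieldset.channels:
            continue
        px = fieldset.pixels(ch)
        delta = bg.estimate_field_offset(px, ref, mask)
        corrected[ch] = bg.correct_field(px, ref, delta)
        raw[ch] = px
        deltas[ch] = delta
        model.record_offset(
            fieldset.well_id, fieldset.field_index, fieldset.day, ch, delta
        )

    labels, _ = segment.segment_nuclei(
        corrected[Channel.EM1],
        min_area_px=params.min_area_px,
        split_touching=params.split_touching,
        min_separation_px=params.min_separation_px,
        threshold_floor=params.threshold_floor,
    )
    if params.measure_expand_px > 0:
        # measuring over slightly expanded labels decorrelates the mask
        # boundary (chosen on noisy em1) from the pixels being summed,
        # removing the upward selection bias on the em1 sum
        labels = expand_labels(labels, distance=params.measure_expand_px)
    table = barcode.measure_objects(
        labels,
        corrected={ch: g for ch, g in corrected.items() if ch in params.measure_channels},
        raw=raw,
        well_id=fieldset.well_id,
        field_index=fieldset.field_index,
        day=fieldset.day,
        noise_sd=params.noise_sd,
        provenance={
            "plate_id": fieldset.plate_id,
            "deltas": {ch.value: d for ch, d in deltas.items()},
            "dilation_px": params.dilation_px,
        },
    )
    log.info(
        "%s/f%d day %d: %d objects segmented (deltas %s)",
        fieldset.well_id, fieldset.field_index, fieldset.day, len(table),
        {ch.value: round(d, 3) for ch, d in deltas.items()},
    )
    return table


def process_plate(
    fields: Sequence[FieldImageSet],
    layout: PlateLayout,
    params: PipelineParams | None = None,
) -> tuple[list[ObjectTable], bg.BackgroundModel]:
    """Background-correct and measure every sample-well field of a plate."""
    params = params or PipelineParams()
    model = build_backgrounds(fields, layout, params)
    sample_wells = {w.well_id for w in layout.sample_wells}
    tables = [
        process_field(f, model, params)
        for f in fields
        if f.well_id in sample_wells
    ]
    return tables, model


def calibrate_plate(
    tables: Sequence[ObjectTable],
    layout: PlateLayout,
    lines: Sequence[str] | None = None,
    params: PipelineParams | None = None,
) -> barcode.BarcodeCalibration:
    """Calibrate per-line windows from the plate's monoculture wells."""
    params = params or PipelineParams()
    labels = list(lines) if lines else layout.lines
    cals = []
    for lab in labels:
        wells = {w.well_id for w in layout.monoculture_wells(lab)}
        if not wells:
            raise barcode.CalibrationError(
                f"layout has no monoculture wells for line {lab!r}"
            )
        mono_tables = [t for t in tables if t and t.records[0].well_id in wells]
        cals.append(
            barcode.calibrate_line(mono_tables, lab, min_n=params.min_calibration_n)
        )
        log.info(
            "calibrated %s: mu=%.4f sigma=%.4f n=%d",
            lab, cals[-1].mu, cals[-1].sigma, cals[-1].n,
        )
    return barcode.make_windows(cals, k=params.k_sd)


def demux_tables(
    tables: Sequence[ObjectTable],
    calibration: barcode.BarcodeCalibration,
) -> list[tuple[ObjectTable, list[str]]]:
    """Classify every object table; returns (table, assignments) pairs."""
    out = []
    totals: dict[str, int] = {}
    for t in tables:
        assignments, counts = barcode.classify_objects(t, calibration)
        for cat, n in counts.items():
            totals[cat] = totals.get(cat, 0) + n
        out.append((t, assignments))
    n_all = sum(totals.values())
    if n_all:
        log.info(
            "demultiplexed %d objects: %s",
            n_all,
            ", ".join(f"{k}={v} ({100*v/n_all:.2f}%)" for k, v in sorted(totals.items())),
        )
    return out
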