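"""Synthetic plates of multi-channel field images with known ground truth.

The generator reproduces the statistical structure the analysis assumes:
nuclei are smooth bright blobs whose em1:em2 split follows a per-line
Gaussian ratio distribution; total red signal per nucleus is lognormal
(expression heterogeneity); the background is a flat media/camera level
shaded by a radially symmetric vignette bowl plus a small per-well scalar
offset (a few counts); camera noise is Poisson shot noise plus Gaussian
read noise with integer rounding and clipping at the 12-bit ceiling;
fields also contain small dim debris blobs of arbitrary ratio, and a
configurable fraction of nuclei is forced to contain a saturated pixel.
Per-line, per-day growth follows N0 * g^day with optional treatment
modifiers.

Every simulated field returns a ground-truth table (true line, ratio,
signal, position) so downstream stages can be scored exactly.
"""

from __future__ import annotations

import math
import zlib
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    Channel,
    ChannelImage,
    FieldImageSet,
    MAX_COUNT,
    PlateLayout,
    ValidationError,
)

TRUTH_COLUMNS = [
    "plate_id",
    "well_id",
    "field_index",
    "day",
    "line",
    "center_row",
    "center_col",
    "radius_px",
    "total_signal",
    "true_ratio",
    "yfp_total",
    "saturated",
    "is_debris",
]


class PlacementError(RuntimeError):
    """Raised when requested objects cannot be placed without overlap."""

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"could only place {achieved} of {requested} objects without "
            "overlap; reduce counts, shrink nuclei or enlarge the field"
        )


@dataclass
class LinePhenotype:
    """Generative parameters of one bar-coded cell line.

    ``ratio_mean``/``ratio_sd`` define the Gaussian em1/em2 ratio
    distribution measured in monocultures; ``brightness_logmean``/
    ``brightness_logsd`` the lognormal total red signal per nucleus
    (summed counts over the blob); ``growth_per_day`` the fold change in
    cell number per day; ``reporter_response`` maps treatment names to the
    mean nuclear YFP intensity they induce (``reporter_baseline`` is used
    for unlisted treatments).
    """

    label: str
    ratio_mean: float
    ratio_sd: float
    # default total gives a typical nuclear pixel ~1000 counts on the
    # 12-bit scale for a 6 px radius nucleus
    brightness_logmean: float = math.log(1.2e5)
    brightness_logsd: float = 0.35
    growth_per_day: float = 1.0
    nucleus_radius_px: float = 6.0
    nucleus_radius_sd_px: float = 0.8
    reporter_response: dict[str, float] = field(default_factory=dict)
    reporter_baseline: float = 10.0

    def __post_init__(self) -> None:
        if self.ratio_mean <= 0:
            raise ValidationError(f"line {self.label}: ratio_mean must be positive")
        if self.ratio_sd <= 0:
            raise ValidationError(f"line {self.label}: ratio_sd must be positive")
        if self.growth_per_day <= 0:
            raise ValidationError(f"line {self.label}: growth_per_day must be positive")

    def reporter_mean(self, treatment: str) -> float:
        return self.reporter_response.get(treatment, self.reporter_baseline)


def default_phenotypes() -> list[LinePhenotype]:
    """Three-line bar-code panel with well-separated ratio distributions.

    The ratio means/sds (0.560 +/- 0.025, 0.737 +/- 0.031, 1.067 +/- 0.045)
    and per-day growth rates follow the monoculture regime of the
    homogeneous-mCherry, mRaspberry/mKate2 and homogeneous-mPlum nuclear
    markers; adjacent means sit >6 pooled sd apart, the regime in which
    k=3 windows stay disjoint.
    """
    return [
        LinePhenotype(
            label="mCherry2", ratio_mean=0.560, ratio_sd=0.025, growth_per_day=1.155
        ),
        LinePhenotype(
            label="mRaspKate2", ratio_mean=0.737, ratio_sd=0.031, growth_per_day=1.048
        ),
        LinePhenotype(
            label="mPlum2", ratio_mean=1.067, ratio_sd=0.045, growth_per_day=1.171
        ),
    ]


@dataclass
class SimulationConfig:
    """Imaging/noise model shared by all simulated fields.

    Units are 12-bit camera counts.  ``baseline_background`` is the flat
    media + camera level; ``vignette_amplitude`` the fractional dimming of
    that background at the field corners; ``per_well_offset_sd`` the sd of
    the per-well scalar background drift (a few counts at most);
    ``read_noise_sd`` the Gaussian camera noise.  ``debris_rate`` is the
    mean number of small dim debris blobs per sample-well field
    (``background_debris_rate`` applies to media-only wells, where fields
    with visible debris are later screened out of the reference average).
    """

    image_size: tuple[int, int] = (256, 256)
    vignette_amplitude: float = 0.10
    baseline_background: float = 100.0
    per_well_offset_sd: float = 1.5
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    debris_rate: float = 5.0
    background_debris_rate: float = 0.5
    saturation_fraction: float = 0.0
    plating_cv: float = 0.10
    max_place_attempts: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "vignette_amplitude",
            "baseline_background",
            "per_well_offset_sd",
            "read_noise_sd",
            "debris_rate",
            "background_debris_rate",
            "saturation_fraction",
            "plating_cv",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if not (0 <= self.saturation_fraction <= 1):
            raise ValidationError("saturation_fraction must be in [0, 1]")


def vignette_surface(shape: tuple[int, int], amplitude: float) -> np.ndarray:
    """Radially symmetric multiplicative bowl 1 - a r^2 / r_max^2."""
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    cr, ccol = (rows - 1) / 2.0, (cols - 1) / 2.0
    r2 = (rr - cr) ** 2 + (cc - ccol) ** 2
    r2max = cr**2 + ccol**2
    if r2max == 0:
        return np.ones(shape)
    return 1.0 - amplitude * r2 / r2max


def _gaussian_kernel(radius_px: float) -> np.ndarray:
    """Isotropic 2-D Gaussian blob truncated at 3 sigma, unit total mass.

    ``radius_px`` is the nominal nucleus radius; the profile sigma is half
    of it, so the blob's visible extent (~2 sigma) matches the radius and
    the rendered support ends at 3 sigma.
    """
    sigma = max(radius_px / 2.0, 0.5)
    half = int(math.ceil(3.0 * sigma))
    ax = np.arange(-half, half + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    r2 = xx**2 + yy**2
    kernel = np.exp(-r2 / (2.0 * sigma**2))
    kernel[r2 > (3.0 * sigma) ** 2] = 0.0
    total = kernel.sum()
    return kernel / total


def render_nucleus(
    canvas_em1: np.ndarray,
    canvas_em2: np.ndarray,
    center: tuple[int, int],
    radius_px: float,
    total_signal: float,
    ratio: float,
) -> np.ndarray:
    """Add one nucleus blob to both channel canvases in place.

    The added integrals split the total red signal so that
    added_em1 / added_em2 == ratio exactly before any noise:
    em1 gets total * R/(1+R), em2 gets total / (1+R).  Returns the blob
    footprint (boolean array over the full canvas).
    """
    if ratio <= 0:
        raise ValidationError("ratio must be positive")
    if total_signal <= 0:
        raise ValidationError("total_signal must be positive")
    rows, cols = canvas_em1.shape
    r, c = int(round(center[0])), int(round(center[1]))
    if not (0 <= r < rows and 0 <= c < cols):
        raise ValidationError(f"nucleus center {center} outside canvas {canvas_em1.shape}")
    kernel = _gaussian_kernel(radius_px)
    half = kernel.shape[0] // 2
    r0, r1 = r - half, r + half + 1
    c0, c1 = c - half, c + half + 1
    kr0, kc0 = max(0, -r0), max(0, -c0)
    kr1 = kernel.shape[0] - max(0, r1 - rows)
    kc1 = kernel.shape[1] - max(0, c1 - cols)
    sub = kernel[kr0:kr1, kc0:kc1]
    rs, cs = slice(max(0, r0), min(rows, r1)), slice(max(0, c0), min(cols, c1))
    em1_part = total_signal * ratio / (1.0 + ratio)
    em2_part = total_signal / (1.0 + ratio)
    canvas_em1[rs, cs] += em1_part * sub
    canvas_em2[rs, cs] += em2_part * sub
    footprint = np.zeros((rows, cols), dtype=bool)
    footprint[rs, cs] = sub > 0
    return footprint


def _place_centers(
    rng: np.random.Generator,
    shape: tuple[int, int],
    radii: Sequence[float],
    existing: list[tuple[float, float, float]],
    max_attempts: int,
    requested_total: int,
) -> list[tuple[int, int]]:
    """Rejection-sample non-overlapping centers (kernels fully disjoint)."""
    rows, cols = shape
    centers: list[tuple[int, int]] = []
    for radius in radii:
        extent = math.ceil(3.0 * max(radius / 2.0, 0.5))
        placed = False
        for _ in range(max_attempts):
            r = int(rng.integers(extent, rows - extent))
            c = int(rng.integers(extent, cols - extent))
            ok = True
            for (er, ec, eext) in existing:
                if (r - er) ** 2 + (c - ec) ** 2 < (extent + eext) ** 2:
                    ok = False
                    break
            if ok:
                centers.append((r, c))
                existing.append((float(r), float(c), float(extent)))
                placed = True
                break
        if not placed:
            raise PlacementError(requested_total, len(existing))
    return centers


def field_seed_sequence(
    master_seed: int, well_id: str, field_index: int, day: int
) -> np.random.SeedSequence:
    """Deterministic per-field sub-seed: every field is reproducible alone.

    The child entropy is (master_seed, day, field_index, crc32(well_id)),
    so any field of a plate can be regenerated without simulating the rest.
    """
    return np.random.SeedSequence(
        entropy=(
            int(master_seed) % (2**31),
            int(day),
            int(field_index),
            zlib.crc32(well_id.encode("utf-8")),
        )
    )


def simulate_field(
    phenotypes: Sequence[LinePhenotype],
    counts: Sequence[int],
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
    plate_id: str = "SIM",
    well_id: str = "B02",
    field_index: int = 0,
    day: int = 0,
    treatment: str = "",
    well_offsets: Mapping[Channel, float] | None = None,
    include_yfp: bool = False,
    include_hoechst: bool = False,
    hoechst_negative_fraction: float = 0.0,
    debris_rate: float | None = None,
) -> tuple[FieldImageSet, pd.DataFrame]:
    """Render one field and return it with its ground-truth table.

    ``counts[i]`` nuclei of ``phenotypes[i]`` are placed without blob
    overlap (rejection sampling; :class:`PlacementError` reports the
    achievable count on failure).  ``well_offsets`` are the per-well
    scalar background offsets per channel (drawn from
    ``config.per_well_offset_sd`` when not supplied).
    """
    if len(phenotypes) != len(counts):
        raise ValidationError("phenotypes and counts must align")
    if any(c < 0 for c in counts):
        raise ValidationError("counts must be non-negative")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(
            config.seed if rng is None else rng
        )
    rows, cols = config.image_size
    shape = (rows, cols)

    if well_offsets is None:
        well_offsets = {
            ch: float(rng.normal(0.0, config.per_well_offset_sd))
            for ch in (Channel.EM1, Channel.EM2, Channel.YFP)
        }

    ideal = {ch: np.zeros(shape) for ch in (Channel.EM1, Channel.EM2)}
    if include_yfp:
        ideal[Channel.YFP] = np.zeros(shape)
    if include_hoechst:
        ideal[Channel.HOECHST] = np.zeros(shape)

    existing: list[tuple[float, float, float]] = []
    truth_rows: list[dict] = []
    requested_total = int(sum(counts))

    for pheno, n in zip(phenotypes, counts):
        radii = np.maximum(
            rng.normal(pheno.nucleus_radius_px, pheno.nucleus_radius_sd_px, size=n),
            2.0,
        )
        centers = _place_centers(
            rng, shape, radii, existing, config.max_place_attempts, requested_total
        )
        ratios = rng.normal(pheno.ratio_mean, pheno.ratio_sd, size=n)
        ratios = np.maximum(ratios, 0.05)
        totals = rng.lognormal(pheno.brightness_logmean, pheno.brightness_logsd, size=n)
        forced_sat = rng.random(n) < config.saturation_fraction
        yfp_mean = pheno.reporter_mean(treatment)
        hoechst_neg = rng.random(n) < hoechst_negative_fraction
        for j in range(n):
            footprint = render_nucleus(
                ideal[Channel.EM1],
                ideal[Channel.EM2],
                centers[j],
                radii[j],
                totals[j],
                ratios[j],
            )
            yfp_total = 0.0
            if include_yfp:
                cell_factor = rng.lognormal(0.0, 0.3)
                yfp_total = yfp_mean * cell_factor * footprint.sum()
                kernel_total = _gaussian_kernel(radii[j])
                render_into(ideal[Channel.YFP], centers[j], kernel_total, yfp_total)
            if include_hoechst and not hoechst_neg[j]:
                render_into(
                    ideal[Channel.HOECHST],
                    centers[j],
                    _gaussian_kernel(radii[j]),
                    2.0e4,
                )
            truth_rows.append(
                {
                    "plate_id": plate_id,
                    "well_id": well_id,
                    "field_index": field_index,
                    "day": day,
                    "line": pheno.label,
                    "center_row": centers[j][0],
                    "center_col": centers[j][1],
                    "radius_px": float(radii[j]),
                    "total_signal": float(totals[j]),
                    "true_ratio": float(ratios[j]),
                    "yfp_total": yfp_total,
                    "saturated": bool(forced_sat[j]),
                    "is_debris": False,
                }
            )

    # small, dim, arbitrary-ratio debris blobs
    rate = config.debris_rate if debris_rate is None else debris_rate
    n_debris = int(rng.poisson(rate)) if rate > 0 else 0
    if n_debris:
        mean_radius = float(np.mean([p.nucleus_radius_px for p in phenotypes])) if phenotypes else 6.0
        deb_radii = rng.uniform(1.0, mean_radius / 2.0, size=n_debris)
        try:
            deb_centers = _place_centers(
                rng, shape, deb_radii, existing, config.max_place_attempts,
                requested_total + n_debris,
            )
        except PlacementError:
            deb_centers = []
        for j, ctr in enumerate(deb_centers):
            deb_ratio = float(rng.uniform(0.2, 1.6))
            deb_total = float(rng.uniform(100.0, 800.0))
            render_nucleus(
                ideal[Channel.EM1], ideal[Channel.EM2], ctr, deb_radii[j],
                deb_total, deb_ratio,
            )
            truth_rows.append(
                {
                    "plate_id": plate_id,
                    "well_id": well_id,
                    "field_index": field_index,
                    "day": day,
                    "line": "debris",
                    "center_row": ctr[0],
                    "center_col": ctr[1],
                    "radius_px": float(deb_radii[j]),
                    "total_signal": deb_total,
                    "true_ratio": deb_ratio,
                    "yfp_total": 0.0,
                    "saturated": False,
                    "is_debris": True,
                }
            )

    vignette = vignette_surface(shape, config.vignette_amplitude)
    channels: dict[Channel, ChannelImage] = {}
    for ch, signal in ideal.items():
        offset = float(well_offsets.get(ch, 0.0)) if well_offsets else 0.0
        expected = config.baseline_background * vignette + offset + signal
        expected = np.clip(expected, 0.0, None)
        if config.shot_noise:
            noisy = rng.poisson(expected).astype(float)
        else:
            noisy = expected.copy()
        if config.read_noise_sd > 0:
            noisy += rng.normal(0.0, config.read_noise_sd, size=shape)
        counts_img = np.clip(np.rint(noisy), 0, MAX_COUNT).astype(np.uint16)
        channels[ch] = ChannelImage(pixels=counts_img, channel=ch)

    # force saturated pixels into flagged nuclei (em1, at the blob center)
    for row in truth_rows:
        if row["saturated"]:
            channels[Channel.EM1].pixels[row["center_row"], row["center_col"]] = MAX_COUNT

    fieldset = FieldImageSet(
        plate_id=plate_id,
        well_id=well_id,
        field_index=field_index,
        day=day,
        channels=channels,
    )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return fieldset, truth


def render_into(
    canvas: np.ndarray,
    center: tuple[int, int],
    kernel: np.ndarray,
    total: float,
) -> None:
    """Add ``total`` counts with the given unit-mass kernel at ``center``."""
    rows, cols = canvas.shape
    r, c = int(round(center[0])), int(round(center[1]))
    half = kernel.shape[0] // 2
    r0, r1 = r - half, r + half + 1
    c0, c1 = c - half, c + half + 1
    kr0, kc0 = max(0, -r0), max(0, -c0)
    kr1 = kernel.shape[0] - max(0, r1 - rows)
    kc1 = kernel.shape[1] - max(0, c1 - cols)
    canvas[max(0, r0):min(rows, r1), max(0, c0):min(cols, c1)] += (
        total * kernel[kr0:kr1, kc0:kc1]
    )


def simulate_plate_experiment(
    layout: PlateLayout,
    phenotypes: Mapping[str, LinePhenotype],
    days: Sequence[int],
    config: SimulationConfig,
    seed: int,
    n_fields: int = 2,
    n0_per_line: int | Mapping[str, int] = 60,
    treatment_effects: Mapping[str, Mapping[str, float]] | None = None,
    include_yfp: bool = False,
    plate_id: str = "SIM",
) -> tuple[list[FieldImageSet], pd.DataFrame]:
    """Simulate a longitudinal plate: all wells, fields and days.

    ``n0_per_line`` is the target Day-0 count per line per well, either a
    single number or a per-well mapping (mixed wells are denser than
    monocultures, so they often get a smaller per-line target).
    Day-0 per-(well, line) counts are drawn once with the plating CV, then
    day-t counts follow round(N0 * growth^day * treatment_modifier) and
    are split across ``n_fields`` fields.  Background (media-only) wells
    contain no nuclei; per-well background offsets are drawn once per
    (well, day, channel).  Treatment modifiers are keyed
    ``treatment -> line -> fold modifier`` (default 1.0).
    """
    days = sorted(days)
    if not days or days[0] != 0:
        raise ValidationError("days must be ascending and include day 0")
    for w in layout.sample_wells:
        for lab in w.mixture:
            if lab not in phenotypes:
                raise ValidationError(
                    f"well {w.well_id}: unknown line label {lab!r} in layout"
                )
    effects = treatment_effects or {}
    plate_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=(int(seed) % (2**31), 1))
    )

    # Day-0 plating counts, drawn once per (well, line)
    n0: dict[tuple[str, str], int] = {}
    for w in layout.sample_wells:
        target = (
            n0_per_line
            if isinstance(n0_per_line, int)
            else int(n0_per_line.get(w.well_id, 60))
        )
        for lab in w.mixture:
            base = target * max(
                0.0, 1.0 + config.plating_cv * float(plate_rng.standard_normal())
            )
            n0[(w.well_id, lab)] = max(1, int(round(base)))

    fields: list[FieldImageSet] = []
    truths: list[pd.DataFrame] = []
    for day in days:
        for w in layout:
            well_rng = np.random.default_rng(
                field_seed_sequence(seed, w.well_id, 9999, day)
            )
            offsets = {
                ch: float(well_rng.normal(0.0, config.per_well_offset_sd))
                for ch in (Channel.EM1, Channel.EM2, Channel.YFP)
            }
            if w.role == "background":
                line_labels: list[str] = []
                day_counts: list[int] = []
            else:
                line_labels = list(w.mixture)
                mods = effects.get(w.treatment, {})
                day_counts = [
                    int(
                        round(
                            n0[(w.well_id, lab)]
                            * phenotypes[lab].growth_per_day ** day
                            * float(mods.get(lab, 1.0))
                        )
                    )
                    for lab in line_labels
                ]
            for fi in range(n_fields):
                frng = np.random.default_rng(
                    field_seed_sequence(seed, w.well_id, fi, day)
                )
                # deterministic near-even split of the well count over fields
                fcounts = [
                    n // n_fields + (1 if fi < n % n_fields else 0)
                    for n in day_counts
                ]
                fset, truth = simulate_field(
                    [phenotypes[lab] for lab in line_labels],
                    fcounts,
                    config,
                    rng=frng,
                    plate_id=plate_id,
                    well_id=w.well_id,
                    field_index=fi,
                    day=day,
                    treatment=w.treatment,
                    well_offsets=offsets,
                    include_yfp=include_yfp,
                    debris_rate=(
                        config.background_debris_rate
                        if w.role == "background"
                        else config.debris_rate
                    ),
                )
                fields.append(fset)
                truths.append(truth)
    truths = [t for t in truths if not t.empty]
    truth = (
        pd.concat(truths, ignore_index=True)
        if truths
        else pd.DataFrame(columns=TRUTH_COLUMNS)
    )
    return fields, truth
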