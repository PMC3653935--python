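"""Ratiometric bar-code measurement, calibration and demultiplexing.

Each nucleus carries a two-FP nuclear marker whose emission, after a single
560-590 nm excitation, is split between two red passbands (em1: 635-675 nm,
em2: 608-648 nm).  The per-nucleus statistic is

    R = sum(em1 counts) / sum(em2 counts)

over the background-corrected object pixels.  Monocultures of each marked
line give a Gaussian-looking ratio distribution (mu_i, sigma_i); the
classification window for line i is [mu_i - k sigma_i, mu_i + k sigma_i]
(k = 3 by default, 5 supported).  In a co-culture, an object is assigned to
the line whose window contains its ratio, to "other" (debris) if no window
does, or "excluded" if it is saturated or too dim in em2 for a reliable
ratio.

The module also predicts theoretical ratios from emission spectra
(passband integrals corrected by the instrument's relative em1/em2
detection efficiency) and the no-FRET ratio of a two-FP fusion as the
brightness-weighted combination of its constituents' channel emissions.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .model import (
    AMBIGUOUS,
    Channel,
    LOW_SIGNAL,
    MAX_COUNT,
    NucleusRecord,
    ObjectTable,
    SATURATED,
    ValidationError,
    as_channel,
)

OTHER = "other"
EXCLUDED = "excluded"

#: Relative efficiency of the instrument at detecting em1 vs em2 emissions
#: (optics + camera + filter absorption), determined by instrument
#: calibration.  Override per instrument.
DEFAULT_DETECTOR_FACTOR = 0.893

#: Standard top-hat passbands (nm).
EM1_BAND = (635.0, 675.0)
EM2_BAND = (608.0, 648.0)


class CalibrationError(ValueError):
    """Raised when monoculture calibration or window construction fails."""


# ---------------------------------------------------------------------------
# Per-object measurement
# ---------------------------------------------------------------------------

def measure_objects(
    labels: np.ndarray,
    corrected: dict[Channel | str, np.ndarray],
    raw: dict[Channel | str, np.ndarray] | None = None,
    well_id: str = "",
    field_index: int = 0,
    day: int = 0,
    noise_sd: float = 0.0,
    low_signal_floor: float | None = None,
    provenance: dict | None = None,
) -> ObjectTable:
    """Measure every labeled nucleus in the corrected channel grids.

    Parameters
    ----------
    labels
        Label image from stringent segmentation (0 = background).
    corrected
        Background-corrected real-valued grids, keyed by channel; must
        contain em1 and em2 for ratio computation.
    raw
        The uncorrected integer frames, used only to flag saturation
        (any member pixel at 4095 in em1 or em2).
    noise_sd
        Per-pixel background noise sd; the low-signal floor for the em2
        sum defaults to ``5 * noise_sd * sqrt(area)`` (noise propagated
        over the object sum).  ``low_signal_floor`` overrides with an
        absolute threshold.  Objects at or below the floor (or with a
        non-positive em2 sum) get no ratio and the ``low_signal`` flag.
    """
    labels = np.asarray(labels)
    corr = {as_channel(c): np.asarray(g, dtype=float) for c, g in corrected.items()}
    for ch, grid in corr.items():
        if grid.shape != labels.shape:
            raise ValidationError(
                f"channel {ch.value}: grid shape {grid.shape} != labels {labels.shape}"
            )
    n = int(labels.max())
    if n == 0:
        return ObjectTable(records=[], provenance=dict(provenance or {}))
    idx = np.arange(1, n + 1)
    ones = np.ones(labels.shape, dtype=float)
    areas = ndi.sum_labels(ones, labels, index=idx)
    present = areas > 0
    idx = idx[present]
    areas = areas[present]
    centroids = ndi.center_of_mass(ones, labels, index=idx)
    sums = {ch: ndi.sum_labels(grid, labels, index=idx) for ch, grid in corr.items()}

    saturated = np.zeros(idx.size, dtype=bool)
    if raw is not None:
        for ch in (Channel.EM1, Channel.EM2):
            raw_grid = next(
                (np.asarray(g) for c, g in raw.items() if as_channel(c) == ch), None
            )
            if raw_grid is not None:
                maxima = ndi.maximum(raw_grid.astype(float), labels, index=idx)
                saturated |= maxima >= MAX_COUNT

    records: list[NucleusRecord] = []
    for j, lab in enumerate(idx):
        area = int(round(areas[j]))
        intensity = {ch: float(vals[j]) for ch, vals in sums.items()}
        flags: set[str] = set()
        if saturated[j]:
            flags.add(SATURATED)
        ratio: float | None = None
        em1 = intensity.get(Channel.EM1)
        em2 = intensity.get(Channel.EM2)
        if em1 is not None and em2 is not None:
            floor = (
                float(low_signal_floor)
                if low_signal_floor is not None
                else 5.0 * noise_sd * math.sqrt(area)
            )
            if em2 > max(floor, 0.0):
                ratio = em1 / em2
            else:
                flags.add(LOW_SIGNAL)
        records.append(
            NucleusRecord(
                object_id=int(lab),
                well_id=well_id,
                field_index=field_index,
                day=day,
                centroid=(float(centroids[j][0]), float(centroids[j][1])),
                area_px=area,
                intensity=intensity,
                ratio_em1_em2=ratio,
                flags=frozenset(flags),
            )
        )
    return ObjectTable(records=records, provenance=dict(provenance or {}))


# ---------------------------------------------------------------------------
# Calibration and windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LineCalibration:
    """Monoculture ratio statistics and the derived window for one line."""

    label: str
    mu: float
    sigma: float
    n: int
    k: float = math.nan
    lo: float = math.nan
    hi: float = math.nan


@dataclass
class BarcodeCalibration:
    """Set of per-line windows used to demultiplex a co-culture."""

    lines: list[LineCalibration]
    k: float
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        labels = [c.label for c in self.lines]
        if len(set(labels)) != len(labels):
            raise CalibrationError(f"duplicate line labels in calibration: {labels}")

    def window(self, label: str) -> tuple[float, float]:
        for c in self.lines:
            if c.label == label:
                return (c.lo, c.hi)
        raise KeyError(label)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "label": c.label,
                    "mu": c.mu,
                    "sigma": c.sigma,
                    "n": c.n,
                    "k": c.k,
                    "lo": c.lo,
                    "hi": c.hi,
                }
                for c in self.lines
            ]
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "BarcodeCalibration":
        df = pd.read_csv(path, dtype={"label": str})
        lines = [
            LineCalibration(
                label=row.label,
                mu=float(row.mu),
                sigma=float(row.sigma),
                n=int(row.n),
                k=float(row.k),
                lo=float(row.lo),
                hi=float(row.hi),
            )
            for row in df.itertuples(index=False)
        ]
        k = lines[0].k if lines else math.nan
        return cls(lines=lines, k=k)


def calibrate_line(
    monoculture_tables: Iterable[ObjectTable],
    label: str,
    min_n: int = 500,
) -> LineCalibration:
    """Estimate (mu, sigma, n) of a line's ratio from monoculture wells.

    Saturated and low-signal objects are excluded; sigma is the sample
    standard deviation (n-1 denominator).
    """
    ratios = np.concatenate(
        [t.ratios(include_flagged=False) for t in monoculture_tables]
        or [np.empty(0)]
    )
    n = ratios.size
    if n < min_n:
        raise CalibrationError(
            f"line {label!r}: only {n} usable objects, need at least {min_n}; "
            "image more monoculture fields"
        )
    mu = float(np.mean(ratios))
    sigma = float(np.std(ratios, ddof=1))
    return LineCalibration(label=label, mu=mu, sigma=sigma, n=n)


def make_windows(
    calibrations: Sequence[LineCalibration],
    k: float = 3.0,
    allow_overlap: bool = False,
) -> BarcodeCalibration:
    """Build the +/- k sd classification windows.

    Windows must be pairwise disjoint; on overlap the error names the
    offending pair and the largest k that would keep all windows disjoint.
    ``allow_overlap=True`` builds anyway, and objects falling in more than
    one window are later flagged ambiguous rather than assigned.
    """
    if k <= 0:
        raise CalibrationError("k must be positive")
    if not calibrations:
        raise CalibrationError("no line calibrations supplied")
    for c in calibrations:
        if not (c.sigma > 0):
            raise CalibrationError(
                f"line {c.label!r}: sigma must be positive to build a window "
                f"(got {c.sigma})"
            )
    lines = [
        LineCalibration(
            label=c.label, mu=c.mu, sigma=c.sigma, n=c.n,
            k=k, lo=c.mu - k * c.sigma, hi=c.mu + k * c.sigma,
        )
        for c in calibrations
    ]
    if not allow_overlap and len(lines) > 1:
        by_mu = sorted(lines, key=lambda c: c.mu)
        k_max = min(
            (b.mu - a.mu) / (a.sigma + b.sigma)
            for a, b in zip(by_mu, by_mu[1:])
        )
        for a, b in zip(by_mu, by_mu[1:]):
            if a.hi >= b.lo:
                raise CalibrationError(
                    f"windows for {a.label!r} ([{a.lo:.4f}, {a.hi:.4f}]) and "
                    f"{b.label!r} ([{b.lo:.4f}, {b.hi:.4f}]) overlap at k={k:g}; "
                    f"largest non-overlapping k is {k_max:.3f}"
                )
    return BarcodeCalibration(lines=lines, k=k, allow_overlap=allow_overlap)


def classify_ratios(
    ratios: np.ndarray, calibration: BarcodeCalibration
) -> np.ndarray:
    """Assign each ratio to a line window, ``other``, or ``ambiguous``.

    Returns an object array of labels.  NaN ratios map to ``excluded``.
    """
    r = np.asarray(ratios, dtype=float)
    out = np.full(r.shape, OTHER, dtype=object)
    hits = np.zeros(r.shape, dtype=int)
    for c in calibration.lines:
        inside = (r >= c.lo) & (r <= c.hi)
        out[inside & (hits == 0)] = c.label
        hits += inside.astype(int)
    out[hits > 1] = AMBIGUOUS
    out[~np.isfinite(r)] = EXCLUDED
    return out


def classify_objects(
    table: ObjectTable, calibration: BarcodeCalibration
) -> tuple[list[str], dict[str, int]]:
    """Demultiplex an object table against calibrated windows.

    Every object receives exactly one category: a line label, ``other``
    (ratio in no window — debris), or ``excluded`` (saturated or
    low-signal; their results are dropped from further analysis).  Returns
    per-object assignments in table order plus category counts.
    """
    ratios = np.array(
        [
            math.nan
            if (r.excluded or r.ratio_em1_em2 is None)
            else r.ratio_em1_em2
            for r in table
        ],
        dtype=float,
    )
    assignments = classify_ratios(ratios, calibration).tolist()
    counts: dict[str, int] = {c.label: 0 for c in calibration.lines}
    counts[OTHER] = 0
    counts[EXCLUDED] = 0
    counts[AMBIGUOUS] = 0
    for a in assignments:
        counts[a] = counts.get(a, 0) + 1
    return assignments, counts


# ---------------------------------------------------------------------------
# Spectral prediction
# ---------------------------------------------------------------------------

@dataclass
class FPSpectrum:
    """Emission spectrum and excitation/brightness weights of one FP.

    ``excitation_efficiency`` is the fraction of molecules excited by the
    560-590 nm band (defaults to 1.0; it cancels in homogeneous
    predictions and only reweights two-FP mixtures).  ``brightness`` is
    quantum yield x molar extinction in relative units.
    """

    name: str
    wavelength_nm: np.ndarray
    intensity: np.ndarray
    excitation_efficiency: float = 1.0
    brightness: float = 1.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if wl.ndim != 1 or wl.shape != inten.shape or wl.size < 2:
            raise ValidationError("spectrum needs matching 1-D wavelength/intensity arrays")
        if np.any(np.diff(wl) <= 0):
            raise ValidationError("wavelength grid must be strictly increasing")
        if np.any(inten < 0):
            raise ValidationError("spectral intensities must be non-negative")
        if not (0 < self.excitation_efficiency <= 1):
            raise ValidationError("excitation_efficiency must be in (0, 1]")
        if self.brightness <= 0:
            raise ValidationError("brightness must be positive")
        self.wavelength_nm = wl
        self.intensity = inten

    @property
    def weight(self) -> float:
        """Mixture weight w = excitation efficiency x brightness."""
        return self.excitation_efficiency * self.brightness

    @classmethod
    def from_csv(cls, path, name: str | None = None, **kwargs) -> "FPSpectrum":
        """Read a two-column (wavelength_nm, relative_intensity) CSV."""
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValidationError(f"spectrum CSV {path} needs two columns")
        return cls(
            name=name or str(path),
            wavelength_nm=df.iloc[:, 0].to_numpy(float),
            intensity=df.iloc[:, 1].to_numpy(float),
            **kwargs,
        )


def band_integral(
    wavelength_nm: np.ndarray,
    intensity: np.ndarray,
    band: tuple[float, float],
    transmission: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Trapezoid integral of spectrum x filter over a passband.

    With ``transmission=None`` the filter is an ideal top-hat over
    ``band``; the band edges are inserted by linear interpolation so the
    integral is exact for piecewise-linear spectra regardless of where the
    grid samples fall.  A tabulated (wavelength, transmission) pair is
    interpolated onto the spectrum grid instead.
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    inten = np.asarray(intensity, dtype=float)
    lo, hi = float(band[0]), float(band[1])
    if lo >= hi:
        raise ValidationError("band lower edge must be below upper edge")
    if lo < wl[0] or hi > wl[-1]:
        raise ValidationError(
            f"passband {band} not covered by spectrum support "
            f"[{wl[0]:g}, {wl[-1]:g}] nm"
        )
    if transmission is not None:
        t_wl = np.asarray(transmission[0], dtype=float)
        t_val = np.asarray(transmission[1], dtype=float)
        trans = np.interp(wl, t_wl, t_val, left=0.0, right=0.0)
        return float(np.trapezoid(inten * trans, wl))
    inside = (wl > lo) & (wl < hi)
    grid = np.concatenate(([lo], wl[inside], [hi]))
    vals = np.interp(grid, wl, inten)
    return float(np.trapezoid(vals, grid))


def predict_em_ratio_from_spectrum(
    spectrum: FPSpectrum,
    em1_band: tuple[float, float] = EM1_BAND,
    em2_band: tuple[float, float] = EM2_BAND,
    detector_factor: float = DEFAULT_DETECTOR_FACTOR,
    em1_transmission: tuple[np.ndarray, np.ndarray] | None = None,
    em2_transmission: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Theoretical em1/em2 ratio: passband area ratio x detector factor.

    R = d * integral(S T_em1) / integral(S T_em2), where d corrects the
    instrument's relative ability to detect em1 vs em2 emissions.
    """
    if detector_factor <= 0:
        raise ValidationError("detector_factor must be positive")
    num = band_integral(
        spectrum.wavelength_nm, spectrum.intensity, em1_band, em1_transmission
    )
    den = band_integral(
        spectrum.wavelength_nm, spectrum.intensity, em2_band, em2_transmission
    )
    if den == 0:
        raise ValidationError(
            f"{spectrum.name}: zero emission integral in the em2 passband"
        )
    return detector_factor * num / den


def predict_mixture_ratio(
    ratio_n: float,
    ratio_c: float,
    weight_n: float = 1.0,
    weight_c: float = 1.0,
) -> float:
    """No-FRET em1/em2 ratio of a two-FP fusion.

    Each constituent FP i with homogeneous ratio R_i and weight
    w_i = excitation efficiency x brightness contributes channel parts
    e_i,em1 = w_i R_i / (1 + R_i) and e_i,em2 = w_i / (1 + R_i); the fusion
    ratio is the sum of em1 parts over the sum of em2 parts.  The result
    always lies between the two constituent ratios.
    """
    if ratio_n <= 0 or ratio_c <= 0:
        raise ValidationError("constituent ratios must be positive")
    if weight_n <= 0 or weight_c <= 0:
        raise ValidationError("weights must be positive")
    e1 = weight_n * ratio_n / (1 + ratio_n) + weight_c * ratio_c / (1 + ratio_c)
    e2 = weight_n / (1 + ratio_n) + weight_c / (1 + ratio_c)
    return e1 / e2
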