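"""Plate-level statistics built on demultiplexed object tables.

Covers longitudinal growth (per-well Day-t / Day-0 fold change, which
cancels plating variability), 3-sd false-negative scoring of growth
assays, the Z'-factor screening-quality statistic, per-population nuclear
reporter quantification, and a two-way ANOVA equivalence test between
monoculture and bar-code-separated co-culture measurements.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .barcode import EXCLUDED, OTHER
from .model import Channel, ObjectTable, ValidationError

TOTAL = "total"

COUNT_COLUMNS = ["well_id", "day", "line", "count"]


def count_per_well(
    assigned_tables: Sequence[tuple[ObjectTable, Sequence[str]]],
) -> pd.DataFrame:
    """Aggregate assignments into per-(well, day, line) counts.

    Fields of the same well are summed.  Rows are emitted per line label,
    plus ``other`` and ``excluded`` categories and a ``total`` row; the
    total counts assigned + other objects, while excluded objects are
    tallied separately and never enter line totals.
    """
    tally: dict[tuple[str, int, str], int] = {}
    for table, assignments in assigned_tables:
        if len(table) != len(assignments):
            raise ValidationError("assignments length differs from table length")
        for rec, assigned in zip(table, assignments):
            key = (rec.well_id, rec.day, str(assigned))
            tally[key] = tally.get(key, 0) + 1
    rows = []
    wells = sorted({(w, d) for (w, d, _) in tally})
    for well_id, day in wells:
        total = 0
        for (w, d, line), count in sorted(tally.items()):
            if (w, d) != (well_id, day):
                continue
            rows.append({"well_id": w, "day": d, "line": line, "count": count})
            if line != EXCLUDED:
                total += count
        rows.append({"well_id": well_id, "day": day, "line": TOTAL, "count": total})
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def _lookup_count(counts: pd.DataFrame, well: str, line: str, day: int) -> int:
    sel = counts[
        (counts["well_id"] == well)
        & (counts["line"] == line)
        & (counts["day"] == day)
    ]
    if sel.empty:
        raise KeyError(f"no count for well {well!r}, line {line!r}, day {day}")
    return int(sel["count"].sum())


def growth_fold(
    counts: pd.DataFrame,
    well: str,
    line: str,
    day_t: int,
    day_0: int = 0,
) -> float:
    """Per-well fold change G = N(day_t) / N(day_0) for one line.

    Dividing by the same well's baseline removes well-to-well plating
    variability.  Undefined (raises) when the baseline count is zero.
    """
    n0 = _lookup_count(counts, well, line, day_0)
    nt = _lookup_count(counts, well, line, day_t)
    if n0 <= 0:
        raise ValidationError(
            f"growth fold undefined for well {well!r}, line {line!r}: "
            f"day-{day_0} count is {n0}"
        )
    return nt / n0


def growth_table(
    counts: pd.DataFrame, day_t: int, day_0: int = 0
) -> pd.DataFrame:
    """Fold change for every (well, line) with a positive baseline count."""
    rows = []
    base = counts[counts["day"] == day_0]
    for row in base.itertuples(index=False):
        if row.line in (EXCLUDED,) or row.count <= 0:
            continue
        try:
            fold = growth_fold(counts, row.well_id, row.line, day_t, day_0)
        except (KeyError, ValidationError):
            continue
        rows.append(
            {"well_id": row.well_id, "line": row.line, "day_t": day_t, "fold": fold}
        )
    return pd.DataFrame(rows, columns=["well_id", "line", "day_t", "fold"])


def growth_false_negative_rate(
    treated_values: Sequence[float],
    reference_values: Sequence[float],
    rule: str = "3sd_above",
) -> tuple[float, float]:
    """Fraction of treated wells scored as showing no growth.

    The threshold is tau = mean(reference) + 3 sd(reference); a treated
    well at or below tau cannot be distinguished from no growth and is a
    false negative.  Works on raw counts (cross-well scoring against the
    Day-0 or Day-4 vehicle distribution) or on per-well fold changes
    (longitudinal scoring).  Returns (fraction, tau).
    """
    if rule != "3sd_above":
        raise ValidationError(f"unknown scoring rule {rule!r}")
    ref = np.asarray(reference_values, dtype=float)
    treated = np.asarray(treated_values, dtype=float)
    if ref.size < 2:
        raise ValidationError("reference sample must have at least 2 values")
    sd = float(np.std(ref, ddof=1))
    if sd == 0:
        warnings.warn(
            "reference distribution is degenerate (sd = 0); threshold equals "
            "the reference mean",
            stacklevel=2,
        )
    tau = float(np.mean(ref)) + 3.0 * sd
    return float(np.mean(treated <= tau)), tau


@dataclass(frozen=True)
class AssayQuality:
    """Z'-factor screening-quality summary.

    Z' = 1 - 3 (sigma_pos + sigma_neg) / |mu_pos - mu_neg|; values above
    0.5 indicate a separation band wide enough for screening without
    replicates.
    """

    z_prime: float
    mu_pos: float
    sigma_pos: float
    mu_neg: float
    sigma_neg: float


def z_prime(
    pos_values: Sequence[float], neg_values: Sequence[float]
) -> AssayQuality:
    """Z'-factor of a screen from positive- and negative-control wells."""
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValidationError("each control sample needs at least 2 values")
    mu_p, mu_n = float(np.mean(pos)), float(np.mean(neg))
    if mu_p == mu_n:
        raise ValidationError("Z' undefined: control means are equal")
    s_p = float(np.std(pos, ddof=1))
    s_n = float(np.std(neg, ddof=1))
    z = 1.0 - 3.0 * (s_p + s_n) / abs(mu_p - mu_n)
    return AssayQuality(z_prime=z, mu_pos=mu_p, sigma_pos=s_p, mu_neg=mu_n, sigma_neg=s_n)


def nuclear_reporter_summary(
    assigned_tables: Sequence[tuple[ObjectTable, Sequence[str]]],
    treatments: Mapping[str, str],
    reporter_channel: Channel = Channel.YFP,
) -> pd.DataFrame:
    """Per-line reporter statistics from demultiplexed nuclei.

    Per-nucleus mean reporter intensity (summed corrected intensity /
    area) is averaged within each (well, field, line) first, then
    summarized as mean +/- sd across fields per (line, treatment).
    Excluded objects are omitted; a field with no objects of a line simply
    contributes no value (missing, not zero).
    """
    field_rows = []
    for table, assignments in assigned_tables:
        if len(table) != len(assignments):
            raise ValidationError("assignments length differs from table length")
        per_field: dict[tuple[str, int, str], list[float]] = {}
        for rec, assigned in zip(table, assignments):
            if assigned in (EXCLUDED, OTHER):
                continue
            val = rec.intensity.get(reporter_channel)
            if val is None:
                continue
            key = (rec.well_id, rec.field_index, str(assigned))
            per_field.setdefault(key, []).append(val / rec.area_px)
        for (well_id, field_index, line), vals in per_field.items():
            field_rows.append(
                {
                    "well_id": well_id,
                    "field_index": field_index,
                    "line": line,
                    "treatment": treatments.get(well_id, ""),
                    "field_mean": float(np.mean(vals)),
                    "n_objects": len(vals),
                }
            )
    fields = pd.DataFrame(
        field_rows,
        columns=["well_id", "field_index", "line", "treatment", "field_mean", "n_objects"],
    )
    if fields.empty:
        return pd.DataFrame(
            columns=["line", "treatment", "mean", "sd", "n_fields"]
        )
    out = (
        fields.groupby(["line", "treatment"])["field_mean"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else math.nan,
             n_fields="size")
        .reset_index()
    )
    return out


def coculture_equivalence_test(
    measurements: pd.DataFrame,
    value_col: str = "value",
    treatment_col: str = "treatment",
    mode_col: str = "mode",
) -> tuple[float, float]:
    """Two-way ANOVA test of monoculture vs co-culture equivalence.

    Fits a fixed-effects two-way model value ~ treatment + culture-mode
    (type-II sums of squares, robust to unbalanced designs) and returns
    (F, p) for the culture-mode main effect.  A large p supports that
    bar-code-separated co-culture measurements match the independently
    plated ones across the treatment panel.
    """
    df = measurements.rename(
        columns={value_col: "value", treatment_col: "treatment", mode_col: "mode"}
    )
    for col in ("value", "treatment", "mode"):
        if col not in df.columns:
            raise ValidationError(f"measurements missing column {col!r}")
    if df["treatment"].nunique() < 2:
        raise ValidationError(
            "equivalence test needs at least two treatments; a single-treatment "
            "comparison is a plain t-test, not a panel equivalence test"
        )
    if df["mode"].nunique() != 2:
        raise ValidationError("exactly two culture modes are required")
    model = smf.ols("value ~ C(treatment) + C(mode)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    f_stat = float(table.loc["C(mode)", "F"])
    p_value = float(table.loc["C(mode)", "PR(>F)"])
    return f_stat, p_value
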