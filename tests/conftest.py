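"""Shared fixtures: small simulated plates and table builders."""

from __future__ import annotations

import numpy as np
import pytest

from nucbarcode.model import (
    Channel,
    NucleusRecord,
    ObjectTable,
    PlateLayout,
    WellSpec,
)
from nucbarcode.simulate import (
    SimulationConfig,
    default_phenotypes,
    simulate_plate_experiment,
)


def table_from_ratios(
    ratios, well_id: str = "B01", day: int = 0, field_index: int = 0
) -> ObjectTable:
    """Wrap a ratio array into an ObjectTable (em2 sum fixed at 1000)."""
    records = [
        NucleusRecord(
            object_id=i + 1,
            well_id=well_id,
            field_index=field_index,
            day=day,
            centroid=(float(i), float(i)),
            area_px=50,
            intensity={Channel.EM1: 1000.0 * r, Channel.EM2: 1000.0},
            ratio_em1_em2=float(r),
        )
        for i, r in enumerate(np.asarray(ratios, dtype=float))
    ]
    return ObjectTable(records=records)


def demux_accuracy(fields, truth, layout, params=None):
    """Run the full pipeline on a simulated plate and score the co-culture.

    Matches each measured nucleus to the nearest ground-truth object by
    centroid and returns (accuracy over assigned nuclei, calibration,
    per-category counts).
    """
    from scipy.spatial import cKDTree

    from nucbarcode import pipeline
    from nucbarcode.barcode import classify_objects

    params = params or pipeline.PipelineParams()
    tables, _ = pipeline.process_plate(fields, layout, params)
    calibration = pipeline.calibrate_plate(tables, layout, params=params)
    mixed_wells = {
        w.well_id for w in layout.sample_wells if len(w.mixture) > 1
    }
    correct = total = 0
    counts = {"other": 0, "excluded": 0, "unmatched": 0}
    for table in tables:
        if not table.records or table.records[0].well_id not in mixed_wells:
            continue
        assignments, _ = classify_objects(table, calibration)
        ft = truth[
            (truth.well_id == table.records[0].well_id)
            & (truth.field_index == table.records[0].field_index)
            & (truth.day == table.records[0].day)
        ]
        tree = cKDTree(ft[["center_row", "center_col"]].to_numpy())
        for rec, assigned in zip(table, assignments):
            dist, idx = tree.query(rec.centroid)
            row = ft.iloc[idx]
            if row.is_debris or dist > 5:
                counts["unmatched"] += 1
                continue
            if assigned == "excluded":
                counts["excluded"] += 1
                continue
            total += 1
            if assigned == row.line:
                correct += 1
            elif assigned == "other":
                counts["other"] += 1
    return correct / total, calibration, counts


@pytest.fixture(scope="session")
def three_line_layout() -> PlateLayout:
    labels = [p.label for p in default_phenotypes()]
    wells = [WellSpec("A01", "background"), WellSpec("A02", "background")]
    for i, lab in enumerate(labels):
        wells.append(WellSpec(f"B{i + 1:02d}", "sample", (lab,)))
    wells.append(WellSpec("C01", "sample", tuple(labels)))
    return PlateLayout(wells)


@pytest.fixture(scope="session")
def simulated_plate(three_line_layout):
    """One simulated 3-line plate: monocultures, one co-culture, backgrounds.

    Shared across tests; treat as read-only.
    """
    phenotypes = {p.label: p for p in default_phenotypes()}
    config = SimulationConfig(image_size=(384, 384), seed=11)
    n0 = {"B01": 700, "B02": 700, "B03": 700, "C01": 150}
    fields, truth = simulate_plate_experiment(
        three_line_layout,
        phenotypes,
        days=[0],
        config=config,
        seed=11,
        n_fields=4,
        n0_per_line=n0,
    )
    return fields, truth, config
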