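"""Tidy-CSV readers and writers for screen datasets.

Three files describe a screen:

* ``plate_map.csv`` — ``plate_id,well,content_class,gene_id,reagent_id``
* ``measurements.csv`` — ``plate_id,replicate,arm,well,cell_count,a490``
* ``standard_curve.csv`` — ``concentration_nM,absorbance``

Measurements are long format: one row per well per arm per replicate.
The T0 arm carries cell counts only; its ``a490`` field is empty (an
empty field, not 0 — zero is a legal absorbance). Canonical order is
plates sorted lexically, arms T0 < DMSO < VEM, wells A01..P24, so that
``write_dataset(read_dataset(...))`` is byte-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import plates
from .errors import PlateValidationError, SchemaError

ARMS = ("T0", "DMSO", "VEM")
TREATED_ARMS = ("DMSO", "VEM")

MEASUREMENT_COLUMNS = ["plate_id", "replicate", "arm", "well", "cell_count", "a490"]
CURVE_COLUMNS = ["concentration_nM", "absorbance"]

#: assay conditions of the screen protocol; carried as dataset metadata
DEFAULT_ASSAY_METADATA = {
    "cells_per_well": 450,
    "drug": "Vem",
    "dose_nM": 300,
    "treatment_h": 48,
    "sirna_nM": 40,
}


@dataclass
class ScreenDataset:
    """A validated screen: plate maps, well measurements, standard curve.

    All three tables are tidy pandas DataFrames in the column orders
    documented in this module.
    """

    plate_maps: pd.DataFrame
    measurements: pd.DataFrame
    standard_curve: pd.DataFrame
    metadata: dict = field(default_factory=lambda: dict(DEFAULT_ASSAY_METADATA))

    @property
    def n_replicates(self) -> int:
        return int(self.measurements["replicate"].max()) if len(self.measurements) else 0

    def validate(self) -> "ScreenDataset":
        """Check every structural invariant; raise before any computation."""
        plates.validate_plate_maps(self.plate_maps)
        self._validate_measurements()
        self._validate_curve()
        missing = set(DEFAULT_ASSAY_METADATA) - set(self.metadata)
        if missing:
            raise PlateValidationError(f"assay metadata missing keys {sorted(missing)}")
        return self

    def _validate_measurements(self) -> None:
        m = self.measurements
        missing = [c for c in MEASUREMENT_COLUMNS if c not in m.columns]
        if missing:
            raise SchemaError(f"measurements missing columns {missing}")
        if len(m) == 0:
            return
        bad_arm = set(m["arm"]) - set(ARMS)
        if bad_arm:
            raise PlateValidationError(f"unknown arm(s) {bad_arm}")
        known_plates = set(self.plate_maps["plate_id"])
        unknown = set(m["plate_id"]) - known_plates
        if unknown:
            raise PlateValidationError(f"measurements reference unknown plate(s) {sorted(unknown)}")
        valid_wells = set(plates.all_wells())
        bad_wells = set(m["well"]) - valid_wells
        if bad_wells:
            raise PlateValidationError(f"unknown well label(s) {sorted(bad_wells)[:5]}")
        if (m["cell_count"] < 0).any():
            raise PlateValidationError("negative cell_count")
        if m.loc[m["arm"] == "T0", "a490"].notna().any():
            raise PlateValidationError("T0 measurements must not carry a490")
        treated = m[m["arm"].isin(TREATED_ARMS)]
        if treated["a490"].isna().any():
            raise PlateValidationError("DMSO/VEM measurements must carry a490")
        if (treated["a490"] < 0).any():
            raise PlateValidationError("negative a490")
        # every (plate, arm) present in the same replicate set 1..R, 384 wells each
        reps = sorted(set(m["replicate"]))
        if reps != list(range(1, len(reps) + 1)):
            raise PlateValidationError(f"replicates must be 1..R, got {reps}")
        counts = m.groupby(["plate_id", "replicate", "arm"], sort=False)["well"].nunique()
        if (counts != plates.N_WELLS).any():
            bad = counts[counts != plates.N_WELLS].index[0]
            raise PlateValidationError(
                f"assay plate {bad} has {counts.loc[bad]} wells, expected {plates.N_WELLS}"
            )
        per_pa = m.groupby(["plate_id", "arm"], sort=False)["replicate"].nunique()
        if per_pa.nunique() > 1 or per_pa.iloc[0] != len(reps):
            raise PlateValidationError("each (plate, arm) must exist in exactly R replicates")

    def _validate_curve(self) -> None:
        c = self.standard_curve
        missing = [col for col in CURVE_COLUMNS if col not in c.columns]
        if missing:
            raise SchemaError(f"standard curve missing columns {missing}")
        if c["concentration_nM"].nunique() < 2:
            raise PlateValidationError("standard curve needs >=2 distinct concentrations")
        means = c.groupby("concentration_nM")["absorbance"].mean().sort_index()
        if (np.diff(means.to_numpy()) < 0).any():
            raise PlateValidationError("standard-curve absorbance must be non-decreasing")


def _canonical(ds: ScreenDataset) -> ScreenDataset:
    """Return a copy with canonical row order and dtypes for writing."""
    pm = ds.plate_maps.copy()
    pm["_w"] = pm["well"].map(plates.parse_well)
    pm = pm.sort_values(["plate_id", "_w"], kind="mergesort").drop(columns="_w")
    m = ds.measurements.copy()
    m["_a"] = m["arm"].map({a: i for i, a in enumerate(ARMS)})
    m["_w"] = m["well"].map(plates.parse_well)
    m = m.sort_values(["plate_id", "replicate", "_a", "_w"], kind="mergesort")
    m = m.drop(columns=["_a", "_w"])
    c = ds.standard_curve.sort_values(CURVE_COLUMNS, kind="mergesort")
    return ScreenDataset(
        pm.reset_index(drop=True)[plates.PLATE_MAP_COLUMNS],
        m.reset_index(drop=True)[MEASUREMENT_COLUMNS],
        c.reset_index(drop=True)[CURVE_COLUMNS],
        dict(ds.metadata),
    )


def read_dataset(
    plate_map_csv: str | os.PathLike,
    measurements_csv: str | os.PathLike,
    standard_curve_csv: str | os.PathLike,
    metadata: dict | None = None,
) -> ScreenDataset:
    """Read and validate the three-file CSV dialect."""
    pm = pd.read_csv(plate_map_csv, dtype=str, keep_default_na=False)
    missing = [c for c in plates.PLATE_MAP_COLUMNS if c not in pm.columns]
    if missing:
        raise SchemaError(f"plate map missing columns {missing}")

    m = pd.read_csv(measurements_csv, float_precision="round_trip")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in m.columns]
    if missing:
        raise SchemaError(f"measurements missing columns {missing}")
    if len(m):
        m["plate_id"] = m["plate_id"].astype(str)
        m["replicate"] = m["replicate"].astype(int)
        m["cell_count"] = m["cell_count"].astype(int)
        m["a490"] = m["a490"].astype(float)
    c = pd.read_csv(standard_curve_csv, float_precision="round_trip")
    missing = [col for col in CURVE_COLUMNS if col not in c.columns]
    if missing:
        raise SchemaError(f"standard curve missing columns {missing}")

    ds = ScreenDataset(pm, m, c, dict(metadata or DEFAULT_ASSAY_METADATA))
    return ds.validate()


def write_dataset(ds: ScreenDataset, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write the canonical three CSV files; returns the paths written."""
    ds.validate()
    ds = _canonical(ds)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "plate_map": os.path.join(out_dir, "plate_map.csv"),
        "measurements": os.path.join(out_dir, "measurements.csv"),
        "standard_curve": os.path.join(out_dir, "standard_curve.csv"),
    }
    ds.plate_maps.to_csv(paths["plate_map"], index=False)
    m = ds.measurements.copy()
    # empty field (never 0) for absent absorbance
    m["a490"] = m["a490"].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    m.to_csv(paths["measurements"], index=False)
    ds.standard_curve.to_csv(paths["standard_curve"], index=False)
    return paths
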