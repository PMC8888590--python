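"""Raw well measurements -> per-gene normalized metrics.

The pipeline per assay plate (plate x replicate x arm):

1. subtract the mean A490 of that plate's media-only background wells
   from every experimental well (negative results are kept, flagged);
2. convert corrected A490 to nM lactate by inverting a fitted linear
   standard curve;
3. divide by the well's final cell count -> lactate per cell;
4. compute dT48 = T48 - T0 count (paired by plate/replicate/well;
   negative values indicate net cell death);
5. express each metric as fold change (FC) versus the mean of the
   plate's siOTP non-targeting control wells;
6. average FCs across replicate plates per reagent per arm.

FCs are ratio-based, so per-plate offsets and scale factors cancel;
replicate averaging happens after normalization for the same reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import plates
from .errors import DegenerateStatError, PlateQCError, PlateValidationError
from .io import ScreenDataset, TREATED_ARMS

#: T48-count FC below which lactate quantitation is unreliable
LOW_COUNT_FC = 0.2

METRICS = ("fc_t48", "fc_dt48", "fc_lactate")


def subtract_background(a490, background_values):
    """Background-correct absorbances against media-only wells.

    Subtracts the mean of ``background_values`` from ``a490``; negative
    corrected values are legal (kept as-is, flag them downstream).
    """
    bg = np.asarray(background_values, dtype=float)
    if bg.size == 0:
        raise PlateQCError("plate has no media background wells")
    return np.asarray(a490, dtype=float) - bg.mean()


@dataclass(frozen=True)
class StandardCurve:
    """Fitted line absorbance = intercept + slope * concentration."""

    slope: float  # A490 per nM
    intercept: float
    r_squared: float
    slope_stderr: float

    def to_concentration(self, a490):
        """Invert the curve: corrected A490 -> nM lactate."""
        return (np.asarray(a490, dtype=float) - self.intercept) / self.slope


def fit_standard_curve(points: pd.DataFrame) -> StandardCurve:
    """Least-squares line through (concentration_nM, absorbance) points."""
    conc = points["concentration_nM"].to_numpy(dtype=float)
    absorb = points["absorbance"].to_numpy(dtype=float)
    if len(np.unique(conc)) < 2:
        raise DegenerateStatError("standard curve needs >=2 distinct concentrations")
    fit = stats.linregress(conc, absorb)
    if fit.slope <= 0:
        raise DegenerateStatError(f"non-monotone standard curve (slope {fit.slope:g})")
    return StandardCurve(fit.slope, fit.intercept, fit.rvalue**2, fit.stderr)


def lactate_per_cell(concentration_nM, cell_count):
    """nM lactate per cell; NaN where the count is zero (flag, no error)."""
    conc = np.asarray(concentration_nM, dtype=float)
    count = np.asarray(cell_count, dtype=float)
    return np.where(count > 0, conc / np.where(count > 0, count, 1.0), np.nan)


def delta_t48(t48_count, t0_count):
    """Signed change in cell number over treatment; negative = death."""
    return np.asarray(t48_count, dtype=float) - np.asarray(t0_count, dtype=float)


def fold_change_vs_plate_control(values, control_values, signed: bool = False):
    """FC of a metric versus the mean of the plate's siOTP wells.

    For signed metrics (dT48) the control mean must be positive —
    healthy non-targeting wells gain cells — otherwise the plate fails
    QC and an error is raised rather than flipping the FC sign.
    """
    ctrl = np.asarray(control_values, dtype=float)
    ctrl = ctrl[np.isfinite(ctrl)]
    if ctrl.size == 0:
        raise PlateQCError("no control wells with a finite metric")
    mean = ctrl.mean()
    if signed and mean <= 0:
        raise PlateQCError(f"control dT48 mean {mean:g} <= 0: plate fails QC")
    return np.asarray(values, dtype=float) / mean


def normalize_wells(ds: ScreenDataset, curve: StandardCurve | None = None) -> pd.DataFrame:
    """Per-well normalized metrics for every treated assay well.

    Returns one row per (plate, replicate, arm in {DMSO, VEM}, non-media
    well) with fc_t48, fc_dt48, fc_lactate and QC flags
    (neg_lactate: background-corrected A490 < 0; zero_count).
    """
    if curve is None:
        curve = fit_standard_curve(ds.standard_curve)
    m = ds.measurements.merge(ds.plate_maps, on=["plate_id", "well"], how="left")

    t0 = m.loc[m["arm"] == "T0", ["plate_id", "replicate", "well", "cell_count"]]
    t0 = t0.rename(columns={"cell_count": "t0_count"})
    w = m[m["arm"].isin(TREATED_ARMS)].copy()

    grp = ["plate_id", "replicate", "arm"]
    is_bg = w["content_class"] == plates.MEDIA_BACKGROUND
    bg = w[is_bg].groupby(grp)["a490"].agg(["mean", "size"])
    if (bg["size"] == 0).any() or len(bg) < w[grp].drop_duplicates().shape[0]:
        raise PlateQCError("assay plate without media background wells")
    w = w[~is_bg].merge(bg["mean"].rename("bg_a490"), on=grp)

    w["a490_corrected"] = w["a490"] - w["bg_a490"]
    w["neg_lactate"] = w["a490_corrected"] < 0
    w["lactate_nM"] = curve.to_concentration(w["a490_corrected"])
    w["zero_count"] = w["cell_count"] == 0
    w["lactate_per_cell"] = lactate_per_cell(w["lactate_nM"], w["cell_count"])

    w = w.merge(t0, on=["plate_id", "replicate", "well"], how="left")
    if w["t0_count"].isna().any():
        raise PlateValidationError("treated well without a matching T0 measurement")
    w["dt48"] = delta_t48(w["cell_count"], w["t0_count"])

    otp = w[w["content_class"] == plates.CONTROL_OTP]
    raw_for = {"fc_t48": "cell_count", "fc_dt48": "dt48", "fc_lactate": "lactate_per_cell"}
    for fc_col, raw_col in raw_for.items():
        ctrl_mean = otp.groupby(grp)[raw_col].mean()
        if ctrl_mean.isna().any():
            raise PlateQCError(f"no finite control values for {raw_col}")
        if fc_col == "fc_dt48" and (ctrl_mean <= 0).any():
            bad = ctrl_mean[ctrl_mean <= 0].index[0]
            raise PlateQCError(f"control dT48 mean <= 0 on assay plate {bad}: plate fails QC")
        w = w.merge(ctrl_mean.rename("_ctrl"), on=grp)
        w[fc_col] = w[raw_col] / w["_ctrl"]
        w = w.drop(columns="_ctrl")

    keep = grp + [
        "well", "content_class", "gene_id", "reagent_id",
        "cell_count", "t0_count", "dt48", "lactate_nM", "lactate_per_cell",
        "fc_t48", "fc_dt48", "fc_lactate", "neg_lactate", "zero_count",
    ]
    return w[keep]


def plate_control_stats(wells: pd.DataFrame) -> pd.DataFrame:
    """Per assay plate, per control class: mean/median/sd/n of each metric."""
    ctrl = wells[wells["content_class"].str.startswith("control_")]
    long = ctrl.melt(
        id_vars=["plate_id", "replicate", "arm", "content_class"],
        value_vars=list(METRICS),
        var_name="metric",
    )
    out = (
        long.groupby(["plate_id", "replicate", "arm", "content_class", "metric"])["value"]
        .agg(["mean", "median", "std", "count"])
        .rename(columns={"std": "sd", "count": "n"})
        .reset_index()
    )
    return out


def summarize_genes(
    ds: ScreenDataset, curve: StandardCurve | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate-averaged per-reagent summary table + control stats.

    Returns ``(gene_summary, plate_controls)``. The summary has one row
    per (gene, reagent) — controls included, tagged by content_class —
    with wide columns ``fc_<metric>_<arm>`` and per-arm low-count flags
    ``qc_low_count_<arm>`` (T48-count FC < 0.2, below which lactate
    quantitation is unreliable). Library reagents must be unique to one
    well of one plate.
    """
    wells = normalize_wells(ds, curve)

    lib = wells[wells["content_class"] == plates.LIBRARY]
    per_plate = lib.groupby(["gene_id", "reagent_id"])["plate_id"].nunique()
    if (per_plate > 1).any():
        dup = per_plate[per_plate > 1].index[0]
        raise PlateValidationError(f"library reagent {dup} appears on multiple plates")

    keys = ["content_class", "gene_id", "reagent_id"]
    avg = wells.groupby(keys + ["arm"], sort=False)[list(METRICS)].mean().reset_index()
    wide = avg.pivot(index=keys, columns="arm", values=list(METRICS))
    wide.columns = [f"{m}_{arm.lower()}" for m, arm in wide.columns]
    wide = wide.reset_index()
    for arm in TREATED_ARMS:
        wide[f"qc_low_count_{arm.lower()}"] = wide[f"fc_t48_{arm.lower()}"] < LOW_COUNT_FC
    wide = wide.sort_values(["content_class", "gene_id", "reagent_id"], ignore_index=True)
    return wide, plate_control_stats(wells)
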