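"""Duplex-deconvolution validation of primary-screen hits.

The secondary screen re-tests each hit gene with its four constituent
siRNA duplexes in individual wells. A duplex *confirms* a phenotype if
its fold change falls outside a per-plate control band — the median of
the plate's non-targeting control FCs +/- 2 sample standard deviations —
on the phenotype's side (below for suppression phenotypes). A gene is
*validated* for a phenotype when at least 2 of its 4 duplexes confirm
it; agreement of independent duplexes argues against off-target
artefacts. DMSO/drug fold-change ratios are computed per duplex as the
drug-enhancement readout (ratio > 1: stronger suppression under drug).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateStatError, PlateValidationError, SchemaError
from .io import ScreenDataset
from .normalize import METRICS, StandardCurve, normalize_wells

DUPLEXES = ("d1", "d2", "d3", "d4")
MIN_CONFIRMING_DUPLEXES = 2

#: phenotype -> (metric, arm, direction) used for confirmation.
#: All primary hit phenotypes are suppressions (direction "decrease");
#: drug enhancement is confirmed as suppression in the drug arm.
PHENOTYPES: dict[str, tuple[str, str, str]] = {
    "cell_number": ("fc_t48", "DMSO", "decrease"),
    "viability": ("fc_dt48", "DMSO", "decrease"),
    "glycolysis": ("fc_lactate", "DMSO", "decrease"),
    "enhancer_lactate": ("fc_lactate", "VEM", "decrease"),
    "enhancer_viability": ("fc_dt48", "VEM", "decrease"),
}


@dataclass(frozen=True)
class ControlBand:
    median: float
    sd: float
    lower: float
    upper: float


def control_band(control_fcs, dispersion: str = "sd") -> ControlBand:
    """Band = median(controls) +/- 2 * dispersion(controls).

    ``dispersion`` is the sample SD by default; "mad" selects the scaled
    median absolute deviation instead.
    """
    v = np.asarray(control_fcs, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        raise DegenerateStatError(f"need >=3 control wells, got {v.size}")
    med = float(np.median(v))
    if dispersion == "sd":
        s = float(np.std(v, ddof=1))
    elif dispersion == "mad":
        s = 1.4826 * float(np.median(np.abs(v - med)))
    else:
        raise SchemaError(f"unknown dispersion {dispersion!r}")
    if s == 0:
        raise DegenerateStatError("zero control dispersion: degenerate band")
    return ControlBand(med, s, med - 2 * s, med + 2 * s)


def confirm_duplex(fc: float, band: ControlBand, direction: str = "decrease") -> bool:
    """Strictly outside the band on the phenotype's side."""
    if direction == "decrease":
        return bool(fc < band.lower)
    if direction == "increase":
        return bool(fc > band.upper)
    raise SchemaError(f"unknown direction {direction!r}")


def duplex_results(
    ds: ScreenDataset,
    gene_phenotypes: Mapping[str, Sequence[str]],
    curve: StandardCurve | None = None,
    dispersion: str = "sd",
) -> pd.DataFrame:
    """Per-duplex fold changes and confirmation flags.

    ``gene_phenotypes`` maps each gene to the phenotypes its SMARTpool
    was flagged for in the primary screen; confirmation is only defined
    for those phenotypes (others are left missing). Control bands are
    computed per library plate per arm per metric from the plate's siOTP
    well FCs pooled over replicate assay plates; duplex FCs are
    replicate-averaged before banding.
    """
    unknown = {p for phs in gene_phenotypes.values() for p in phs} - set(PHENOTYPES)
    if unknown:
        raise SchemaError(f"unknown phenotype(s) {sorted(unknown)}")
    wells = normalize_wells(ds, curve)

    lib = wells[wells["gene_id"].isin(gene_phenotypes.keys())]
    keys = ["gene_id", "reagent_id", "plate_id"]
    avg = lib.groupby(keys + ["arm"], sort=False)[list(METRICS)].mean().reset_index()
    wide = avg.pivot(index=keys, columns="arm", values=list(METRICS))
    wide.columns = [f"{m}_{arm.lower()}" for m, arm in wide.columns]
    wide = wide.reset_index()

    otp = wells[wells["content_class"] == "control_OTP"]
    bands: dict[tuple[str, str, str], ControlBand] = {}
    for (plate_id, arm), grp in otp.groupby(["plate_id", "arm"]):
        for metric in METRICS:
            bands[(plate_id, arm, metric)] = control_band(grp[metric], dispersion)

    for ph, (metric, arm, direction) in PHENOTYPES.items():
        col = f"{metric}_{arm.lower()}"
        flagged = wide["gene_id"].map(lambda g, ph=ph: ph in gene_phenotypes[g])
        confirmed = [
            confirm_duplex(fc, bands[(pid, arm, metric)], direction)
            for fc, pid in zip(wide[col], wide["plate_id"])
        ]
        wide[f"confirmed_{ph}"] = pd.array(confirmed, dtype="boolean")
        wide.loc[~flagged, f"confirmed_{ph}"] = pd.NA

    for metric in METRICS:
        wide[f"ratio_{metric}"] = dmso_vem_ratio(
            wide[f"{metric}_dmso"], wide[f"{metric}_vem"]
        )
    return wide


def dmso_vem_ratio(fc_dmso, fc_vem):
    """Vehicle-arm FC over drug-arm FC; +/-inf flags a zero drug-arm FC."""
    d = np.asarray(fc_dmso, dtype=float)
    v = np.asarray(fc_vem, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(v != 0, d / np.where(v != 0, v, 1.0), np.sign(d) * np.inf)


def validate_genes(duplex_table: pd.DataFrame) -> pd.DataFrame:
    """Apply the >=2-of-4 duplex rule per gene per phenotype.

    Requires exactly 4 duplex rows per gene. Returns one row per gene
    with ``n_confirmed_<ph>`` and ``validated_<ph>`` columns (missing
    where the phenotype was not flagged for that gene) plus per-gene
    median DMSO/VEM ratios.
    """
    sizes = duplex_table.groupby("gene_id").size()
    if (sizes != len(DUPLEXES)).any():
        bad = sizes[sizes != len(DUPLEXES)].index[0]
        raise PlateValidationError(
            f"gene {bad} has {sizes.loc[bad]} duplexes, expected {len(DUPLEXES)}"
        )
    g = duplex_table.groupby("gene_id")
    out = pd.DataFrame(index=sizes.index)
    for ph in PHENOTYPES:
        col = f"confirmed_{ph}"
        if col not in duplex_table.columns:
            continue
        n_conf = g[col].sum(min_count=1)
        out[f"n_confirmed_{ph}"] = n_conf.astype("Int64")
        out[f"validated_{ph}"] = (n_conf >= MIN_CONFIRMING_DUPLEXES).mask(n_conf.isna())
    for metric in METRICS:
        col = f"ratio_{metric}"
        if col in duplex_table.columns:
            out[col + "_median"] = g[col].median()
    return out.reset_index()


def validation_rates(validated: pd.DataFrame, gene_sets: Mapping[str, Sequence[str]] | None = None
                     ) -> pd.DataFrame:
    """Percent of genes validated per phenotype, overall and per gene set.

    Rates are over the genes for which the phenotype was flagged (i.e.
    non-missing ``validated_<ph>``).
    """
    sets = {"all": list(validated["gene_id"])}
    if gene_sets:
        sets.update({k: list(v) for k, v in gene_sets.items()})
    rows = []
    for set_name, genes in sets.items():
        sub = validated[validated["gene_id"].isin(genes)]
        for ph in PHENOTYPES:
            col = f"validated_{ph}"
            if col not in sub.columns:
                continue
            flagged = sub[col].notna()
            n = int(flagged.sum())
            if n == 0:
                continue
            n_val = int(sub.loc[flagged, col].sum())
            rows.append((set_name, ph, n, n_val, 100.0 * n_val / n))
    return pd.DataFrame(
        rows, columns=["gene_set", "phenotype", "n_genes", "n_validated", "validation_rate"]
    )
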