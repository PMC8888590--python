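"""Robust z-scores, primary hit classes, and drug-enhancer binning.

Hits are called on the vehicle (DMSO) arm with screen-wide robust
z-scores computed over the library-gene population (controls excluded),
on replicate-averaged fold changes. All threshold inequalities are
strict; a gene sitting exactly on a threshold is not a hit.

The three primary hit classes and their default thresholds:

* cell-number: z(T48 count FC) < -1.5 and FC < 0.3
* viability:   z(dT48 FC) < -1.5 and FC < 0.08 (negative FCs — net cell
  death — satisfy the bound; death is the strongest viability phenotype)
* glycolysis:  z(lactate-per-cell FC) < -1.66 and FC < 0.5, subject to
  the low-count filter (T48 FC >= 0.2; lactate quantitation is
  unreliable in near-empty wells)

Drug enhancers are identified by binning each gene's DMSO-arm versus
drug-arm fold changes; the default ("methods") lactate-enhancer bin is
dT48 FC > 0.3 in both arms, DMSO lactate FC > 0.4 and drug-arm lactate
FC < 0.5 — knockdowns that leave vehicle-treated cells growing and
producing lactate but collapse lactate output under drug. An alternate
"figure1c" scheme (DMSO lactate FC < 0.5 and drug lactate FC > 0.5) is
selectable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import plates
from .errors import DegenerateStatError, SchemaError

MAD_SCALE = 1.4826  # consistency constant: scaled MAD estimates sigma for normal data


def robust_z(values, x: float) -> float:
    """Robust z-score of ``x`` against a reference population.

    z = (x - median) / (1.4826 * MAD). NaNs in ``values`` are excluded;
    at least 3 finite values and a nonzero MAD are required.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        raise DegenerateStatError(f"need >=3 finite values, got {v.size}")
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        raise DegenerateStatError("MAD = 0: degenerate population")
    return float((x - med) / (MAD_SCALE * mad))


def robust_z_scores(values) -> np.ndarray:
    """Vectorized robust z of each value against the whole vector.

    NaN inputs stay NaN and do not enter the median/MAD.
    """
    v = np.asarray(values, dtype=float)
    finite = v[np.isfinite(v)]
    if finite.size < 3:
        raise DegenerateStatError(f"need >=3 finite values, got {finite.size}")
    med = np.median(finite)
    mad = np.median(np.abs(finite - med))
    if mad == 0:
        raise DegenerateStatError("MAD = 0: degenerate population")
    return (v - med) / (MAD_SCALE * mad)


@dataclass(frozen=True)
class ThresholdConfig:
    """Hit-calling thresholds (all inequalities strict)."""

    cell_number_z_max: float = -1.5
    cell_number_fc_max: float = 0.3
    viability_z_max: float = -1.5
    viability_fc_max: float = 0.08
    glycolysis_z_max: float = -1.66
    glycolysis_fc_max: float = 0.5
    glycolysis_min_t48_fc: float = 0.2
    # "methods" lactate-enhancer bin
    enhancer_dt48_fc_min_dmso: float = 0.3
    enhancer_dt48_fc_min_vem: float = 0.3
    enhancer_lactate_fc_min_dmso: float = 0.4
    enhancer_lactate_fc_max_vem: float = 0.5
    # viability-enhancer contrast (no published threshold; package default)
    enhancer_viability_dt48_fc_min_dmso: float = 0.5
    enhancer_viability_dt48_fc_max_vem: float = 0.5


FC_COLUMNS = [
    "fc_t48_dmso", "fc_t48_vem",
    "fc_dt48_dmso", "fc_dt48_vem",
    "fc_lactate_dmso", "fc_lactate_vem",
]


def _require(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"missing metric column(s) {missing}")


def zscore_table(gene_summary: pd.DataFrame) -> pd.DataFrame:
    """Screen-wide robust z per metric per arm over library genes.

    Control rows are dropped; the population for each column is all
    library genes' replicate-averaged FCs. Returned columns are
    ``z_<metric>_<arm>`` alongside gene_id/reagent_id.

    A column with exactly zero spread (every FC identical, e.g. a
    noise-free uniform population) gets z = 0 throughout: no gene
    deviates from the population, and the hit predicates then rest on
    the FC bounds alone.
    """
    _require(gene_summary, FC_COLUMNS)
    lib = gene_summary[gene_summary["content_class"] == plates.LIBRARY].copy()
    out = lib[["gene_id", "reagent_id"]].copy()
    for col in FC_COLUMNS:
        v = lib[col].to_numpy(dtype=float)
        finite = v[np.isfinite(v)]
        if finite.size >= 3 and np.median(np.abs(finite - np.median(finite))) == 0:
            z = np.where(np.isfinite(v), 0.0, np.nan)
        else:
            z = robust_z_scores(v)
        out["z_" + col.removeprefix("fc_")] = z
    return out.reset_index(drop=True)


def call_primary_hits(
    gene_summary: pd.DataFrame,
    zscores: pd.DataFrame,
    cfg: ThresholdConfig = ThresholdConfig(),
) -> pd.DataFrame:
    """Apply the three DMSO-arm hit predicates.

    Returns one row per library reagent with boolean flags
    cell_number_hit / viability_hit / glycolysis_hit.
    """
    _require(gene_summary, FC_COLUMNS + ["qc_low_count_dmso"])
    lib = gene_summary[gene_summary["content_class"] == plates.LIBRARY]
    t = lib.merge(zscores, on=["gene_id", "reagent_id"], validate="1:1")
    out = t[["gene_id", "reagent_id"]].copy()
    out["cell_number_hit"] = (
        (t["z_t48_dmso"] < cfg.cell_number_z_max) & (t["fc_t48_dmso"] < cfg.cell_number_fc_max)
    )
    out["viability_hit"] = (
        (t["z_dt48_dmso"] < cfg.viability_z_max) & (t["fc_dt48_dmso"] < cfg.viability_fc_max)
    )
    out["glycolysis_hit"] = (
        (t["z_lactate_dmso"] < cfg.glycolysis_z_max)
        & (t["fc_lactate_dmso"] < cfg.glycolysis_fc_max)
        & (t["fc_t48_dmso"] >= cfg.glycolysis_min_t48_fc)  # low-count lactate filter
    )
    return out


def bin_enhancers(
    gene_summary: pd.DataFrame,
    cfg: ThresholdConfig = ThresholdConfig(),
    scheme: str = "methods",
) -> pd.DataFrame:
    """DMSO-vs-drug fold-change binning and enhancer flags.

    ``bin_label`` encodes each gene's (DMSO, VEM) side of the binning
    thresholds for the two readouts, 'H'/'L' per arm, e.g.
    ``dt48=HH|lact=HL`` (growing in both arms, lactate high in DMSO but
    low under drug — the lactate-enhancer bin under the default scheme).
    """
    if scheme not in ("methods", "figure1c"):
        raise SchemaError(f"unknown enhancer scheme {scheme!r}")
    _require(gene_summary, FC_COLUMNS)
    lib = gene_summary[gene_summary["content_class"] == plates.LIBRARY]
    out = lib[["gene_id", "reagent_id"]].copy()

    dt_d = lib["fc_dt48_dmso"] > cfg.enhancer_dt48_fc_min_dmso
    dt_v = lib["fc_dt48_vem"] > cfg.enhancer_dt48_fc_min_vem
    lac_d_hi = lib["fc_lactate_dmso"] > cfg.enhancer_lactate_fc_min_dmso
    lac_v_lo = lib["fc_lactate_vem"] < cfg.enhancer_lactate_fc_max_vem

    if scheme == "methods":
        out["enhancer_lactate"] = dt_d & dt_v & lac_d_hi & lac_v_lo
    else:  # figure1c: reversed lactate directions, same growth guard
        out["enhancer_lactate"] = (
            dt_d & dt_v
            & (lib["fc_lactate_dmso"] < cfg.enhancer_lactate_fc_max_vem)
            & (lib["fc_lactate_vem"] > cfg.enhancer_lactate_fc_max_vem)
        )
    out["enhancer_viability"] = (
        (lib["fc_dt48_dmso"] > cfg.enhancer_viability_dt48_fc_min_dmso)
        & (lib["fc_dt48_vem"] < cfg.enhancer_viability_dt48_fc_max_vem)
    )

    def hl(mask):
        return np.where(mask, "H", "L")

    out["bin_label"] = (
        "dt48=" + hl(dt_d) + hl(dt_v) + "|lact=" + hl(lac_d_hi) + hl(~lac_v_lo)
    )
    return out.reset_index(drop=True)


HIT_FLAGS = (
    "cell_number_hit", "viability_hit", "glycolysis_hit",
    "enhancer_lactate", "enhancer_viability",
)


def call_hits(
    gene_summary: pd.DataFrame,
    cfg: ThresholdConfig = ThresholdConfig(),
    scheme: str = "methods",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: z-scores + primary hits + enhancer bins.

    Returns ``(hit_table, zscore_table)``.
    """
    z = zscore_table(gene_summary)
    primary = call_primary_hits(gene_summary, z, cfg)
    enh = bin_enhancers(gene_summary, cfg, scheme)
    return primary.merge(enh, on=["gene_id", "reagent_id"], validate="1:1"), z


def hit_report(hit_table: pd.DataFrame) -> dict:
    """Counts per hit class and the symmetric pairwise overlap matrix."""
    flags = [f for f in HIT_FLAGS if f in hit_table.columns]
    counts = {f: int(hit_table[f].sum()) for f in flags}
    overlap = pd.DataFrame(
        {
            a: [int((hit_table[a] & hit_table[b]).sum()) for b in flags]
            for a in flags
        },
        index=flags,
    )
    return {"counts": counts, "n_genes": int(len(hit_table)), "overlap": overlap}
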