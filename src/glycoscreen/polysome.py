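"""Small follow-up computations: polysome fraction profiles,
proliferation rate, and patient-progression upregulation tabulation.

Sucrose-gradient profiles are collected as 14 fractions per sample;
fractions 3-8 contain sub-polysomal species (mRNP, 40S, 60S, 80S) and
fractions 9-14 the actively translating polysomes (four or more
ribosomes). The sub-polysome/polysome ratio rises when translation is
globally suppressed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import GlycoScreenError

N_FRACTIONS = 14
SUB_POLYSOME_RANGE = (3, 8)  # 1-based, inclusive
POLYSOME_RANGE = (9, 14)


def _profile(quantities) -> np.ndarray:
    q = np.asarray(quantities, dtype=float)
    if q.shape != (N_FRACTIONS,):
        raise GlycoScreenError(f"profile must have {N_FRACTIONS} fractions, got {q.shape}")
    if (q < 0).any():
        raise GlycoScreenError("fraction quantities must be non-negative")
    if q.sum() <= 0:
        raise GlycoScreenError("profile sums to zero")
    return q


def fraction_distribution(quantities) -> np.ndarray:
    """Percent of total signal in each of the 14 fractions (sums to 100)."""
    q = _profile(quantities)
    return 100.0 * q / q.sum()


def sub_poly_ratio(
    quantities,
    sub_range: tuple[int, int] = SUB_POLYSOME_RANGE,
    poly_range: tuple[int, int] = POLYSOME_RANGE,
) -> float:
    """Sub-polysome over polysome signal; inf when polysomes are empty.

    Ranges are 1-based inclusive fraction numbers and must be disjoint.
    """
    q = _profile(quantities)
    for lo, hi in (sub_range, poly_range):
        if not (1 <= lo <= hi <= N_FRACTIONS):
            raise GlycoScreenError(f"fraction range {lo}..{hi} outside 1..{N_FRACTIONS}")
    if not (sub_range[1] < poly_range[0] or poly_range[1] < sub_range[0]):
        raise GlycoScreenError("sub- and polysome ranges must be disjoint")
    sub = q[sub_range[0] - 1 : sub_range[1]].sum()
    poly = q[poly_range[0] - 1 : poly_range[1]].sum()
    if poly == 0:
        return float(np.inf) if sub > 0 else float(np.nan)
    return float(sub / poly)


def proliferation_rate(day5_count: float, day0_count: float, days: float = 4.0) -> float:
    """Population doublings per day: log2(day5/day0) / elapsed days.

    The 5-day assay counts span a 4-day treatment window (T0 is taken
    one day after seeding, immediately before treatment), hence the
    default 4-day denominator.
    """
    if day0_count <= 0 or day5_count <= 0:
        raise GlycoScreenError("counts must be positive")
    return float(np.log2(day5_count / day0_count) / days)


def patient_upregulation(
    expression: pd.DataFrame,
    up_threshold: float,
    percent_cutoff: float = 10.0,
) -> tuple[pd.Series, dict]:
    """Per-gene percent of patients upregulated on progression.

    ``expression`` is tidy with columns patient, gene, pre, post (paired
    pre-treatment and progression values). A patient counts as
    upregulated for a gene when post/pre > ``up_threshold`` (strict;
    the threshold is a required parameter, there is no published
    default beyond the 1.0-fold floor). Patients missing either value
    for a gene are excluded with a warning.

    Returns the per-gene percent series and a summary dict counting
    genes whose percent reaches ``percent_cutoff``.
    """
    if up_threshold <= 0:
        raise GlycoScreenError("up_threshold must be > 0")
    need = {"patient", "gene", "pre", "post"}
    if not need <= set(expression.columns):
        raise GlycoScreenError(f"expression table needs columns {sorted(need)}")
    e = expression.copy()
    bad = e["pre"].isna() | e["post"].isna()
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} patient/gene pairs with missing values",
            stacklevel=2,
        )
        e = e[~bad]
    up = e["post"] / e["pre"] > up_threshold
    percent = 100.0 * up.groupby(e["gene"]).mean()
    percent.name = "percent_upregulated"
    n_above = int((percent >= percent_cutoff).sum())
    summary = {
        "n_genes": int(percent.size),
        "n_above_cutoff": n_above,
        "percent_of_genes": 100.0 * n_above / percent.size if percent.size else float("nan"),
        "percent_cutoff": percent_cutoff,
    }
    return percent, summary
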