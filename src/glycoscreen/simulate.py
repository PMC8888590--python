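"""Synthetic dual-readout screen generator with planted effect classes.

The generator emulates the design of a genome-wide arrayed siRNA screen
with a viability readout (DAPI nuclear counts at T0 and 48 h) and a
glycolysis readout (lactate in spent medium, read as A490 through an LDH
reaction), in duplicate, across three arms (T0, 48 h DMSO, 48 h drug).
Each 384-well plate carries 16 non-targeting (siOTP), 8 death-control
(siPLK1) and 8 glycolysis-control (siPDK1) wells plus a media-only
background column; remaining wells hold one library reagent each.

Every library gene is assigned one of five effect classes whose
parameters are *target fold changes versus the non-targeting control*
for the two readouts in the two treated arms. The generator writes a
truth table alongside the dataset so every downstream stage can be
tested by parameter recovery.

Noise model: cell counts are multiplicative log-normal (median 1, CV as
configured — counts are positive and right-skewed); absorbance noise is
additive Gaussian, plus one additive offset per assay plate
(plate x replicate x arm), which per-plate background subtraction and
control normalization are expected to remove. All randomness flows from
a single ``numpy.random.default_rng(seed)`` stream, so identical seeds
give bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import plates
from .errors import GlycoScreenError
from .io import DEFAULT_ASSAY_METADATA, ScreenDataset, _canonical

NEUTRAL = "neutral"
LETHAL = "lethal"
GLYCOLYSIS_LOW = "glycolysis_low"
VEM_ENHANCER_LACTATE = "vem_enhancer_lactate"
VEM_ENHANCER_VIABILITY = "vem_enhancer_viability"


@dataclass(frozen=True)
class EffectClass:
    """Target per-arm fold changes (vs siOTP) for one planted gene class."""

    name: str
    dt48_fc_dmso: float = 1.0
    dt48_fc_vem: float = 1.0
    lactate_fc_dmso: float = 1.0
    lactate_fc_vem: float = 1.0

    def __post_init__(self) -> None:
        for v in (self.dt48_fc_dmso, self.dt48_fc_vem, self.lactate_fc_dmso, self.lactate_fc_vem):
            if not -5 < v < 5:
                raise GlycoScreenError(f"effect-class mean {v} outside (-5, 5)")


#: built-in archetypes. Lethal knockdowns lose cells over the treatment
#: window (negative change vs T0); glycolysis_low halves-to-thirds lactate
#: per cell in both arms; the drug-enhancer classes are near-neutral in
#: DMSO but strongly suppressed in the drug arm for one readout.
EFFECT_CLASSES: dict[str, EffectClass] = {
    NEUTRAL: EffectClass(NEUTRAL),
    LETHAL: EffectClass(LETHAL, dt48_fc_dmso=-0.5, dt48_fc_vem=-0.5),
    GLYCOLYSIS_LOW: EffectClass(GLYCOLYSIS_LOW, lactate_fc_dmso=0.3, lactate_fc_vem=0.3),
    VEM_ENHANCER_LACTATE: EffectClass(VEM_ENHANCER_LACTATE, lactate_fc_vem=0.25),
    VEM_ENHANCER_VIABILITY: EffectClass(VEM_ENHANCER_VIABILITY, dt48_fc_vem=0.2),
}

#: control reagents behave as fixed archetypes
CONTROL_ARCHETYPES = {
    plates.CONTROL_OTP: NEUTRAL,
    plates.CONTROL_PLK1: LETHAL,
    plates.CONTROL_PDK1: GLYCOLYSIS_LOW,
}

#: primary-screen hit class expected for each planted effect class
EXPECTED_HITS: dict[str, tuple[str, ...]] = {
    NEUTRAL: (),
    LETHAL: ("cell_number_hit", "viability_hit"),
    GLYCOLYSIS_LOW: ("glycolysis_hit",),
    VEM_ENHANCER_LACTATE: ("enhancer_lactate",),
    VEM_ENHANCER_VIABILITY: ("enhancer_viability",),
}


@dataclass(frozen=True)
class NoiseConfig:
    """Noise magnitudes; all standard deviations must be >= 0."""

    count_cv: float = 0.1  # CV of multiplicative log-normal count noise
    absorbance_sd: float = 0.01  # additive Gaussian A490 noise per well
    plate_offset_sd: float = 0.02  # additive A490 offset per assay plate
    curve_absorbance_sd: float = 0.005  # noise on standard-curve points

    def __post_init__(self) -> None:
        for v in (self.count_cv, self.absorbance_sd, self.plate_offset_sd, self.curve_absorbance_sd):
            if v < 0:
                raise GlycoScreenError("noise standard deviations must be >= 0")


@dataclass(frozen=True)
class BaselineConfig:
    """Deterministic assay baseline.

    ``t0_count`` is the neutral nuclei count at the start of treatment
    (450 cells seeded, grown to ~900 over the 48 h between seeding and
    T0 fixation). Growth factors give the neutral T48/T0 ratio per arm;
    the drug arm grows slower (sub-maximal inhibitor dose).
    ``lactate_per_cell_nM`` is the neutral true lactate concentration in
    the sampled medium per final cell.
    """

    t0_count: float = 900.0
    dmso_growth: float = 2.0
    vem_growth: float = 1.4
    lactate_per_cell_nM: float = 0.5
    background_a490: float = 0.08
    curve_slope: float = 8e-4  # A490 per nM lactate
    curve_intercept: float = 0.0
    curve_concentrations: tuple[float, ...] = (0.0, 250.0, 500.0, 1000.0, 1500.0, 2000.0)


DEFAULT_CLASS_FRACTIONS = {
    NEUTRAL: 0.85,
    LETHAL: 0.05,
    GLYCOLYSIS_LOW: 0.05,
    VEM_ENHANCER_LACTATE: 0.05,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Scale, class mix, noise and baseline of one synthetic screen.

    The desk-scale default (4 plates, duplicate) keeps tests fast; pass
    ``n_plates=58`` for a full-scale screen of the same design.
    """

    n_plates: int = 4
    n_replicates: int = 2
    class_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plates < 1:
            raise GlycoScreenError("n_plates must be >= 1")
        if self.n_replicates < 1:
            raise GlycoScreenError("n_replicates must be >= 1")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise GlycoScreenError(f"class fractions must sum to 1, got {total}")
        unknown = set(self.class_fractions) - set(EFFECT_CLASSES)
        if unknown:
            raise GlycoScreenError(f"unknown effect class(es) {unknown}")


def _class_param_frame() -> pd.DataFrame:
    rows = [
        (c.name, c.dt48_fc_dmso, c.dt48_fc_vem, c.lactate_fc_dmso, c.lactate_fc_vem)
        for c in EFFECT_CLASSES.values()
    ]
    return pd.DataFrame(
        rows,
        columns=["class_name", "dt48_fc_dmso", "dt48_fc_vem", "lactate_fc_dmso", "lactate_fc_vem"],
    )


def _lognormal_factor(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Median-1 multiplicative noise with the requested CV."""
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(sigma * rng.standard_normal(n))


def _standard_curve(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    b = cfg.baseline
    conc = np.asarray(b.curve_concentrations, dtype=float)
    absorb = b.curve_intercept + b.curve_slope * conc
    absorb = absorb + rng.normal(0.0, cfg.noise.curve_absorbance_sd, len(conc))
    return pd.DataFrame({"concentration_nM": conc, "absorbance": np.maximum(absorb, 0.0)})


def _simulate_measurements(
    cfg: SimulationConfig, well_table: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw measurements for every (plate, replicate, arm, well).

    ``well_table`` is a plate-map-like frame with a ``class_name`` column
    (NaN for media wells) giving each well's realized effect class.
    """
    b, noise = cfg.baseline, cfg.noise
    params = _class_param_frame()
    wt = well_table.merge(params, on="class_name", how="left")

    frames = []
    growth = {"DMSO": b.dmso_growth, "VEM": b.vem_growth}
    for rep in range(1, cfg.n_replicates + 1):
        for arm in ("T0", "DMSO", "VEM"):
            w = wt[["plate_id", "well", "content_class"]].copy()
            w.insert(1, "replicate", rep)
            w.insert(2, "arm", arm)
            is_media = (w["content_class"] == plates.MEDIA_BACKGROUND).to_numpy()
            n = len(w)
            if arm == "T0":
                count = b.t0_count * _lognormal_factor(rng, noise.count_cv, n)
                count[is_media] = 0.0
                w["cell_count"] = np.rint(count).astype(int)
                w["a490"] = np.nan
            else:
                f_dt = wt[f"dt48_fc_{arm.lower()}"].to_numpy(dtype=float)
                f_lac = wt[f"lactate_fc_{arm.lower()}"].to_numpy(dtype=float)
                dt_neutral = b.t0_count * (growth[arm] - 1.0)
                t48_mean = b.t0_count + np.nan_to_num(f_dt) * dt_neutral
                count = np.maximum(t48_mean, 0.0) * _lognormal_factor(rng, noise.count_cv, n)
                count[is_media] = 0.0
                count = np.rint(count).astype(int)
                # lactate produced by the cells actually present in the well
                conc = np.nan_to_num(f_lac) * b.lactate_per_cell_nM * count
                offsets = {
                    pid: rng.normal(0.0, noise.plate_offset_sd) if noise.plate_offset_sd else 0.0
                    for pid in wt["plate_id"].unique()
                }
                offset = w["plate_id"].map(offsets).to_numpy()
                a490 = (
                    b.background_a490
                    + np.where(is_media, 0.0, b.curve_intercept + b.curve_slope * conc)
                    + offset
                    + (rng.normal(0.0, noise.absorbance_sd, n) if noise.absorbance_sd else 0.0)
                )
                w["cell_count"] = count
                w["a490"] = np.maximum(a490, 0.0)
            frames.append(w.drop(columns="content_class"))
    return pd.concat(frames, ignore_index=True)


def _assemble(cfg: SimulationConfig, maps: pd.DataFrame, well_classes: pd.DataFrame,
              rng: np.random.Generator) -> ScreenDataset:
    measurements = _simulate_measurements(cfg, well_classes, rng)
    curve = _standard_curve(cfg, rng)
    ds = ScreenDataset(maps, measurements, curve, dict(DEFAULT_ASSAY_METADATA))
    return _canonical(ds.validate())


def generate_screen(cfg: SimulationConfig) -> tuple[ScreenDataset, pd.DataFrame]:
    """Simulate a primary SMARTpool screen.

    Returns the dataset and a truth table with one row per library gene:
    its effect class and the per-arm target fold changes it was drawn
    from. Controls follow their archetypes (siOTP neutral, siPLK1
    lethal, siPDK1 glycolysis-low).
    """
    rng = np.random.default_rng(cfg.seed)
    n_genes = plates.LIBRARY_WELLS_PER_PLATE * cfg.n_plates
    gene_ids = np.array([f"GENE{i:05d}" for i in range(n_genes)])
    names = list(cfg.class_fractions)
    probs = np.array([cfg.class_fractions[k] for k in names])
    classes = rng.choice(np.array(names, dtype=object), size=n_genes, p=probs)

    maps = []
    for p in range(cfg.n_plates):
        sl = slice(p * plates.LIBRARY_WELLS_PER_PLATE, (p + 1) * plates.LIBRARY_WELLS_PER_PLATE)
        maps.append(plates.default_plate_map(f"P{p + 1:02d}", list(gene_ids[sl])))
    maps = pd.concat(maps, ignore_index=True)

    truth = pd.DataFrame({"gene_id": gene_ids, "class_name": classes})
    truth = truth.merge(_class_param_frame(), on="class_name")
    truth = truth.sort_values("gene_id", ignore_index=True)

    well_classes = maps.merge(truth[["gene_id", "class_name"]], on="gene_id", how="left")
    ctrl = well_classes["content_class"].map(CONTROL_ARCHETYPES)
    well_classes["class_name"] = well_classes["class_name"].where(ctrl.isna(), ctrl)

    return _assemble(cfg, maps, well_classes, rng), truth


GENES_PER_DECONV_PLATE = plates.LIBRARY_WELLS_PER_PLATE // 4  # 84


def generate_deconv_screen(
    cfg: SimulationConfig,
    hit_genes: dict[str, str],
    concordance: float,
) -> tuple[ScreenDataset, pd.DataFrame]:
    """Simulate a duplex-deconvolution screen for the given hit genes.

    ``hit_genes`` maps gene_id to its planted effect-class name (the
    phenotype the primary screen called). Each gene occupies 4 wells
    (duplexes d1..d4) on one plate; each duplex reproduces the gene's
    effect with probability ``concordance`` and is otherwise neutral
    (off-target-style non-concordance). Plates are filled to capacity
    with neutral filler genes (``is_filler`` in the truth table), which
    should be excluded from validation-rate summaries.

    The truth table has one row per (gene, duplex) with the realized
    ``effect_bearing`` flag. ``cfg.n_plates`` is ignored; the plate
    count follows from the gene list (84 genes per plate).
    """
    if not hit_genes:
        raise GlycoScreenError("hit_genes must be nonempty")
    if not 0.0 <= concordance <= 1.0:
        raise GlycoScreenError("concordance must be in [0, 1]")
    unknown = set(hit_genes.values()) - set(EFFECT_CLASSES)
    if unknown:
        raise GlycoScreenError(f"unknown effect class(es) {unknown}")

    rng = np.random.default_rng(cfg.seed)
    genes = list(hit_genes)
    n_fill = (-len(genes)) % GENES_PER_DECONV_PLATE
    fillers = [f"FILL{i:04d}" for i in range(n_fill)]
    all_genes = genes + fillers
    gene_class = dict(hit_genes, **{g: NEUTRAL for g in fillers})

    duplexes = ["d1", "d2", "d3", "d4"]
    truth = pd.DataFrame(
        [(g, d, gene_class[g]) for g in all_genes for d in duplexes],
        columns=["gene_id", "duplex_id", "class_name"],
    )
    truth["is_filler"] = truth["gene_id"].isin(set(fillers))
    bearing = rng.random(len(truth)) < concordance
    truth["effect_bearing"] = bearing & (truth["class_name"] != NEUTRAL)
    realized = truth["class_name"].where(truth["effect_bearing"], NEUTRAL)
    truth["realized_class"] = realized

    n_plates = len(all_genes) // GENES_PER_DECONV_PLATE
    maps = []
    for p in range(n_plates):
        sl = slice(p * plates.LIBRARY_WELLS_PER_PLATE, (p + 1) * plates.LIBRARY_WELLS_PER_PLATE)
        maps.append(
            plates.default_plate_map(
                f"D{p + 1:02d}",
                list(truth["gene_id"].iloc[sl]),
                list(truth["duplex_id"].iloc[sl]),
            )
        )
    maps = pd.concat(maps, ignore_index=True)

    well_classes = maps.merge(
        truth[["gene_id", "duplex_id", "realized_class"]].rename(
            columns={"duplex_id": "reagent_id", "realized_class": "class_name"}
        ),
        on=["gene_id", "reagent_id"],
        how="left",
    )
    ctrl = well_classes["content_class"].map(CONTROL_ARCHETYPES)
    well_classes["class_name"] = well_classes["class_name"].where(ctrl.isna(), ctrl)

    sim_cfg = replace(cfg, n_plates=n_plates)
    return _assemble(sim_cfg, maps, well_classes, rng), truth


def recovery_metrics(hit_table: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Sensitivity and specificity of hit calling against planted truth.

    For each planted effect class with an expected hit flag
    (see :data:`EXPECTED_HITS`), sensitivity is the fraction of that
    class flagged with it, and specificity the fraction of all *other*
    genes not flagged with it.
    """
    t = hit_table.merge(truth[["gene_id", "class_name"]], on="gene_id", validate="1:1")
    rows = []
    for cls, flags in EXPECTED_HITS.items():
        if not flags or cls not in set(t["class_name"]):
            continue
        for flag in flags:
            if flag not in t.columns:
                continue
            pos = t["class_name"] == cls
            sens = float(t.loc[pos, flag].mean())
            spec = float((~t.loc[~pos, flag]).mean())
            rows.append((cls, flag, int(pos.sum()), sens, spec))
    return pd.DataFrame(
        rows, columns=["class_name", "hit_flag", "n_planted", "sensitivity", "specificity"]
    )


def simulate_patient_expression(
    genes: list[str],
    n_patients: int = 50,
    frac_up: dict[str, float] | None = None,
    fold: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired pre-treatment / progression expression for a gene set.

    For each gene, a planted fraction of patients (``frac_up``, default
    0.2 for every gene) shows a ``fold``-times increase on progression;
    the rest are unchanged up to mild log-normal wobble (CV 5%, well
    below a 1.5-fold calling threshold). Returns a tidy frame with
    columns patient, gene, pre, post.
    """
    rng = np.random.default_rng(seed)
    frac_up = frac_up or {g: 0.2 for g in genes}
    rows = []
    patients = [f"PT{i:02d}" for i in range(n_patients)]
    for g in genes:
        pre = rng.lognormal(mean=3.0, sigma=0.5, size=n_patients)
        n_up = int(round(frac_up.get(g, 0.0) * n_patients))
        up_idx = rng.choice(n_patients, size=n_up, replace=False)
        ratio = np.exp(rng.normal(0.0, 0.05, n_patients))
        ratio[up_idx] = fold
        for p, a, b in zip(patients, pre, pre * ratio):
            rows.append((p, g, a, b))
    return pd.DataFrame(rows, columns=["patient", "gene", "pre", "post"])
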