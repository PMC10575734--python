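"""Synthetic data generators emulating the study inputs the pipeline consumes.

Four generators cover the four input families:

* :func:`simulate_patient_cohort` — paired pre/post expression for a patient
  cohort in which a latent "true high risk" subgroup carries elevated baseline
  AGPS/UGCG, a treatment-induced increase of CD36/AGPS/UGCG, and a
  proportionally higher progression hazard;
* :func:`simulate_single_cells` — single-cell matrices with a latent CD36-high
  starved-like melanoma cell (SMC) state in which a peroxisome/UGCG program is
  retained under MAPK-inhibitor treatment;
* :func:`simulate_tumor_course` — piecewise-exponential xenograft volume
  trajectories (growth, treatment-induced shrinkage, relapse regrowth) with
  multiplicative lognormal measurement noise;
* :func:`simulate_lipidome` — lognormal lipid-class abundance tables with
  planted group effects and zero dropouts.

Every generator is a pure function of its spec (including the seed): the same
spec yields bit-identical output.  Expression noise is Gaussian on the
log-normalized scale, matching the scale all downstream statistics operate on;
raw counts are never simulated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet
from .tumor import VOLUME_CONSTANT, TumorVolumeSeries

logger = logging.getLogger("persistkit")

__all__ = [
    "RISK_GENES",
    "CohortSpec",
    "SingleCellSpec",
    "TumorCourseSpec",
    "LipidomeSpec",
    "simulate_patient_cohort",
    "simulate_single_cells",
    "simulate_tumor_course",
    "simulate_lipidome",
    "smc_gene_set",
]

#: the three transcripts entering the risk score
RISK_GENES = ("CD36", "AGPS", "UGCG")

_DEFAULT_COHORT_GENES = tuple(RISK_GENES) + tuple(f"GENE{i:03d}" for i in range(1, 51))


@dataclass
class CohortSpec:
    """Paired pre/post patient cohort with a latent high-risk subgroup.

    ``induction_effect`` (log2 units) is added to the post-treatment
    expression of the risk genes in true-high-risk patients, and
    ``baseline_effect`` to the pre- and post-treatment expression of AGPS and
    UGCG in the same patients (high-risk tumors are marked by *high or
    increased* expression, so both the baseline and the fold-change factors
    carry signal).  Progression-free survival is exponential with the hazard
    of true-high patients scaled by ``hazard_ratio``; censoring is
    administrative at the horizon where a fraction ``censor_rate`` of the
    low-hazard arm is still progression-free.
    """

    n_patients: int = 100
    genes: tuple[str, ...] = _DEFAULT_COHORT_GENES
    baseline_mean: float = 5.0
    baseline_sd: float = 0.5
    induction_effect: float = 1.5
    baseline_effect: float = 1.5
    induced_genes: tuple[str, ...] = RISK_GENES
    true_high_fraction: float = 0.5
    hazard_ratio: float = 3.0
    median_pfs_low: float = 180.0  # days; low-risk arm
    censor_rate: float = 0.2
    dataset_id: str = "cohort1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not 0 <= self.true_high_fraction <= 1:
            raise ValueError("true_high_fraction must be in [0, 1]")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        missing = set(RISK_GENES) - set(self.genes)
        if missing:
            raise ValueError(f"cohort genes must include {sorted(missing)}")


def simulate_patient_cohort(spec: CohortSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate paired pre/post expression plus an outcome table.

    Returns ``(matrix, outcomes)``; the matrix carries ``patient``,
    ``timepoint`` and ``dataset`` observation annotations, and ``outcomes``
    has one row per patient with ``pfs_days``, ``event``, ``best_response_pct``
    and the latent ``true_high`` label used by recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.genes)
    n = spec.n_patients
    patients = [f"P{i + 1:03d}" for i in range(n)]
    obs_ids = [f"{p}_{tp}" for p in patients for tp in ("pre", "relapse")]

    true_high = rng.random(n) < spec.true_high_fraction

    values = np.empty((len(genes), 2 * n), dtype=float)
    gene_index = {g: i for i, g in enumerate(genes)}
    baseline_genes = [g for g in spec.induced_genes if g != "CD36"]
    for j in range(n):
        pre = rng.normal(spec.baseline_mean, spec.baseline_sd, size=len(genes))
        post = rng.normal(spec.baseline_mean, spec.baseline_sd, size=len(genes))
        if true_high[j]:
            for g in baseline_genes:
                pre[gene_index[g]] += spec.baseline_effect
                post[gene_index[g]] += spec.baseline_effect
            for g in spec.induced_genes:
                post[gene_index[g]] += spec.induction_effect
        values[:, 2 * j] = pre
        values[:, 2 * j + 1] = post

    obs = pd.DataFrame(
        {
            "patient": np.repeat(patients, 2),
            "timepoint": ["pre", "relapse"] * n,
            "dataset": spec.dataset_id,
        },
        index=pd.Index(obs_ids, name="obs_id"),
    )
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=obs_ids), obs=obs
    )

    hazard_low = math.log(2.0) / spec.median_pfs_low
    hazards = np.where(true_high, hazard_low * spec.hazard_ratio, hazard_low)
    latent_t = rng.exponential(1.0 / hazards) if n else np.array([])
    if spec.censor_rate > 0:
        horizon = -math.log(spec.censor_rate) / hazard_low
    else:
        horizon = math.inf
    event = latent_t <= horizon
    pfs = np.minimum(latent_t, horizon)

    # best overall clinical response: high-risk patients respond poorly
    br_mean = np.where(true_high, -10.0, -55.0)
    br = np.clip(rng.normal(br_mean, 20.0), -100.0, 100.0) if n else np.array([])

    outcomes = pd.DataFrame(
        {
            "patient": patients,
            "pfs_days": pfs,
            "event": event.astype(bool) if n else pd.Series(dtype=bool),
            "best_response_pct": br,
            "true_high": true_high.astype(bool) if n else pd.Series(dtype=bool),
        }
    )
    return matrix, outcomes


_DEFAULT_STATES = {"SMC": 0.2, "pigmented": 0.35, "NCSC": 0.25, "invasive": 0.2}
_DEFAULT_PROGRAM = ("AGPS", "SCP2", "PEX1", "UGCG")


@dataclass
class SingleCellSpec:
    """Single-cell matrix with a CD36-high SMC state.

    CD36 and the SMC signature genes draw from the high component in SMC
    cells and the low component elsewhere.  ``retained_program_genes`` (the
    peroxisome/UGCG program) are expressed at ``program_mean`` everywhere
    untreated; under treatment they are decremented by ``treatment_decrement``
    in non-SMC cells only — the SMC state retains the program.
    """

    n_cells: int = 500
    state_proportions: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_STATES))
    cd36_high_mean: float = 4.0
    cd36_low_mean: float = 0.5
    cd36_sd: float = 0.5
    n_signature_genes: int = 10
    retained_program_genes: tuple[str, ...] = _DEFAULT_PROGRAM
    program_mean: float = 2.0
    treatment_decrement: float = 1.5
    n_background_genes: int = 200
    background_mean: float = 2.0
    background_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        total = sum(self.state_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state proportions sum to {total}, not 1")

    @property
    def signature_genes(self) -> tuple[str, ...]:
        return ("CD36",) + tuple(f"SMCSIG{i:02d}" for i in range(1, self.n_signature_genes + 1))


def smc_gene_set(spec: SingleCellSpec) -> GeneSet:
    """The SMC signature (CD36 plus the SMC-specific marker genes)."""
    return GeneSet(name="SMC_SIGNATURE", description="starved-like melanoma cell markers",
                   genes=spec.signature_genes)


def simulate_single_cells(
    spec: SingleCellSpec, treated: bool = False
) -> tuple[ExpressionMatrix, pd.Series]:
    """Generate a single-cell matrix and the true per-cell state labels."""
    rng = np.random.default_rng(spec.seed)
    states = list(spec.state_proportions)
    probs = np.array([spec.state_proportions[s] for s in states], dtype=float)
    labels = rng.choice(states, size=spec.n_cells, p=probs) if spec.n_cells else np.array([], dtype=object)
    is_smc = labels == "SMC"

    cell_ids = [f"cell{i + 1:04d}" for i in range(spec.n_cells)]
    sig_genes = spec.signature_genes
    bg_genes = tuple(f"BG{i:04d}" for i in range(1, spec.n_background_genes + 1))
    genes = sig_genes + spec.retained_program_genes + bg_genes

    n = spec.n_cells
    blocks = []
    sig_means = np.where(is_smc, spec.cd36_high_mean, spec.cd36_low_mean)
    blocks.append(rng.normal(sig_means, spec.cd36_sd, size=(len(sig_genes), n)))
    prog_means = np.full(n, spec.program_mean)
    if treated:
        prog_means = np.where(is_smc, spec.program_mean, spec.program_mean - spec.treatment_decrement)
    blocks.append(rng.normal(prog_means, spec.background_sd, size=(len(spec.retained_program_genes), n)))
    blocks.append(rng.normal(spec.background_mean, spec.background_sd, size=(len(bg_genes), n)))
    values = np.vstack(blocks) if n else np.empty((len(genes), 0))

    obs = pd.DataFrame(
        {"condition": "treated" if treated else "untreated"},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=list(genes), columns=cell_ids), obs=obs
    )
    return matrix, pd.Series(labels, index=cell_ids, name="state", dtype=object)


_DEFAULT_DAYS = (-4.0, -2.0, 0.0, 2.0, 4.0, 7.0, 10.0, 14.0, 17.0, 21.0, 24.0, 28.0, 31.0, 35.0)


@dataclass
class TumorCourseSpec:
    """Piecewise-exponential xenograft course, anchored at treatment start.

    Day 0 is the day dosing begins, with volume ``treatment_start_volume``
    (the 200 mm^3 enrollment convention).  Volume grows at ``growth_rate``
    per day, shrinks at ``treatment_effect`` per day while on treatment, and
    regrows at ``growth_rate`` from the animal's relapse day onward.
    Measurement noise is multiplicative lognormal with coefficient of
    variation ``noise_cv`` (volumes stay positive by construction).
    """

    n_animals: int = 8
    growth_rate: float = 0.15  # per day
    treatment_effect: float = 0.35  # per day, net shrinkage while responding
    relapse_day_mean: float = 21.0
    relapse_day_sd: float = 5.0
    noise_cv: float = 0.1
    measurement_days: tuple[float, ...] = _DEFAULT_DAYS
    treatment_start_volume: float = 200.0
    aspect_ratio: float = 1.5  # length / width for emitted caliper values
    arm: str = "treated"
    seed: int = 0

    def __post_init__(self) -> None:
        days = np.asarray(self.measurement_days, dtype=float)
        if len(days) and not np.all(np.diff(days) > 0):
            raise ValueError("measurement_days must be strictly increasing")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.treatment_start_volume <= 0:
            raise ValueError("treatment_start_volume must be > 0")


def expected_tumor_volume(spec: TumorCourseSpec, day: float, relapse_day: float) -> float:
    """Noise-free volume of the piecewise-exponential course at *day*.

    Closed form: exponential growth before day 0, exponential shrinkage from
    V0 at day 0 until ``relapse_day``, then regrowth at ``growth_rate``.
    """
    v0 = spec.treatment_start_volume
    if day <= 0:
        return v0 * math.exp(spec.growth_rate * day)
    if day <= relapse_day:
        return v0 * math.exp(-spec.treatment_effect * day)
    nadir = v0 * math.exp(-spec.treatment_effect * relapse_day)
    return nadir * math.exp(spec.growth_rate * (day - relapse_day))


def simulate_tumor_course(spec: TumorCourseSpec) -> list[TumorVolumeSeries]:
    """Generate one :class:`TumorVolumeSeries` per animal."""
    rng = np.random.default_rng(spec.seed)
    series: list[TumorVolumeSeries] = []
    days = np.asarray(spec.measurement_days, dtype=float)
    if spec.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + spec.noise_cv**2))
    else:
        sigma = 0.0
    for a in range(spec.n_animals):
        relapse = max(0.5, rng.normal(spec.relapse_day_mean, spec.relapse_day_sd))
        vols = np.array([expected_tumor_volume(spec, d, relapse) for d in days])
        if sigma > 0:
            noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=len(days)))
            vols = vols * noise
        # back out caliper values at the configured aspect ratio; the volume
        # recomputed from (L, W) equals vols exactly
        widths = np.cbrt(6.0 * vols / (VOLUME_CONSTANT * spec.aspect_ratio))
        lengths = spec.aspect_ratio * widths
        frame = pd.DataFrame(
            {"day": days, "length_mm": lengths, "width_mm": widths, "volume_mm3": vols}
        )
        series.append(
            TumorVolumeSeries(
                animal_id=f"M{a + 1:02d}",
                measurements=frame,
                arm=spec.arm,
                treatment_start_day=0.0,
                baseline_volume=float(vols[np.searchsorted(days, 0.0)]) if 0.0 in days else None,
            )
        )
    return series


_DEFAULT_CLASSES: dict[str, tuple[int, float, float]] = {
    # class -> (n_species, mean nmol/mg DNA, sd in log2 units)
    "PC": (10, 30.0, 0.4),
    "PE": (8, 15.0, 0.4),
    "PC-O": (6, 5.0, 0.4),
    "PE-O": (5, 4.0, 0.4),
    "PE-P": (6, 4.0, 0.4),
    "TG": (8, 20.0, 0.5),
    "Cer": (6, 2.0, 0.3),
    "HexCer": (4, 1.5, 0.3),
    "LacCer": (3, 0.8, 0.3),
    "DCER": (3, 0.5, 0.3),
    "SM": (6, 8.0, 0.3),
}


@dataclass
class LipidomeSpec:
    """Lognormal lipid abundance table with planted group effects.

    ``classes`` maps lipid class to ``(n_species, mean, sd)`` where the mean
    is on the nmol/mg-DNA scale and the sd is in log2 units; ``effect_map``
    adds a log2 shift to every species of a class within one group; a
    fraction ``zero_rate`` of measurements is set to exactly 0, emulating
    left-censoring at the detection limit — within each replicate column the
    *lowest* measurements drop out, which is the missingness mechanism that
    downshifted-normal imputation is built for.
    """

    classes: dict[str, tuple[int, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_CLASSES)
    )
    groups: dict[str, int] = field(
        default_factory=lambda: {"ctrl": 3, "pex3_6d": 3, "pex3_9g": 3}
    )
    effect_map: dict[tuple[str, str], float] = field(default_factory=dict)
    zero_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.zero_rate < 1:
            raise ValueError("zero_rate must be in [0, 1)")
        for group, n_rep in self.groups.items():
            if n_rep < 2 and self.zero_rate > 0:
                logger.warning(
                    "group %r has %d replicate(s); differential testing needs >= 2",
                    group, n_rep,
                )


def simulate_lipidome(spec: LipidomeSpec):
    """Generate a :class:`~persistkit.lipidomics.LipidTable` of species abundances."""
    from .lipidomics import LipidTable  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    replicate_ids: list[str] = []
    group_labels: list[str] = []
    for group, n_rep in spec.groups.items():
        for r in range(1, n_rep + 1):
            replicate_ids.append(f"{group}_r{r}")
            group_labels.append(group)

    species: list[str] = []
    rows: list[np.ndarray] = []
    carbon_grid = [(c, d) for c in range(30, 45, 2) for d in range(0, 7)]
    for cls, (n_species, mean, sd) in spec.classes.items():
        idx = rng.choice(len(carbon_grid), size=n_species, replace=False)
        for i in sorted(idx):
            c, d = carbon_grid[i]
            species.append(f"{cls} {c}:{d}")
            mu = math.log2(mean)
            log2_vals = rng.normal(mu, sd, size=len(replicate_ids))
            for j, group in enumerate(group_labels):
                shift = spec.effect_map.get((cls, group), 0.0)
                log2_vals[j] += shift
            rows.append(np.exp2(log2_vals))
    values = pd.DataFrame(np.vstack(rows) if rows else np.empty((0, len(replicate_ids))),
                          index=species, columns=replicate_ids)
    if spec.zero_rate > 0 and values.size:
        # detection-limit censoring: the lowest zero_rate fraction of each
        # replicate column reads out as exactly 0
        n_zero = int(np.floor(spec.zero_rate * len(values.index)))
        for col in values.columns:
            cutoff_idx = values[col].nsmallest(n_zero).index
            values.loc[cutoff_idx, col] = 0.0
    groups = pd.Series(group_labels, index=replicate_ids, name="group")
    return LipidTable(values=values, groups=groups)
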