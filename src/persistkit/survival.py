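"""The CD36/AGPS/UGCG risk score and survival machinery.

The risk model is rule-based.  Five inputs are collected per patient from
matched pre/post-treatment expression:

* RF1 — fold change of *CD36* after treatment,
* RF2a / RF2b — baseline *AGPS* / fold change of *AGPS*,
* RF3a / RF3b — baseline *UGCG* / fold change of *UGCG*.

Each input is z-normalized within its dataset (so cohorts profiled on
different platforms remain comparable), a sub-factor fires when its z score
exceeds the high threshold (default 0, i.e. above the within-dataset mean),
RF2/RF3 fire when either sub-factor does, and the risk score is
RF1 + RF2 + RF3 in 0..3.  Patients with score >= 2 are high risk, <= 1 low
risk.  Fold changes are post - pre when expression is log-normalized (the
default), else log2(post/pre).

Kaplan-Meier estimation and the log-rank test are delegated to lifelines;
mouse progression-free survival is derived from tumor-volume series with a
configurable progression rule (default: volume >= 1.2 x max(nadir, baseline)).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .io import ExpressionMatrix
from .scoring import pair_observations
from .tumor import TumorVolumeSeries

logger = logging.getLogger("persistkit")

__all__ = [
    "RiskProfile",
    "KMEstimate",
    "zscore_within_dataset",
    "build_risk_inputs",
    "zscore_risk_inputs",
    "assign_risk",
    "risk_profiles_from_cohort",
    "km_estimate",
    "logrank_test",
    "pfs_from_volumes",
]

_INPUT_COLUMNS = ("rf1_input", "rf2a_input", "rf2b_input", "rf3a_input", "rf3b_input")


def zscore_within_dataset(values: pd.Series, datasets: pd.Series) -> pd.Series:
    """z = (x - stratum mean) / stratum sample sd, per dataset stratum.

    Uses the n-1 denominator.  Strata of size 1 or with zero spread are
    rejected: a z score there is undefined.
    """
    values = values.astype(float)
    out = pd.Series(np.nan, index=values.index, dtype=float)
    for ds, idx in values.groupby(datasets).groups.items():
        x = values.loc[idx]
        if len(x) < 2:
            raise ValueError(f"dataset {ds!r} has a single value; z score undefined")
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError(f"dataset {ds!r} has zero spread; z score undefined")
        out.loc[idx] = (x - x.mean()) / sd
    return out


def build_risk_inputs(
    matrix: ExpressionMatrix,
    patient_key: str = "patient",
    time_key: str = "timepoint",
    dataset_key: str = "dataset",
    log_scale: bool = True,
    post_labels: tuple[str, ...] = ("relapse", "on"),
) -> pd.DataFrame:
    """Collect the five raw risk inputs per patient from a paired cohort.

    The expression scale must be declared: ``log_scale=True`` computes fold
    changes as post - pre; otherwise log2(post/pre).  When a patient has
    both on-treatment and relapse samples, *post_labels* order decides which
    is used (relapse first by default).
    """
    for gene in ("CD36", "AGPS", "UGCG"):
        if gene not in matrix.gene_ids:
            raise KeyError(f"risk gene {gene!r} not present in matrix")
    pairing = pair_observations(
        matrix.obs, patient_key=patient_key, time_key=time_key, post_labels=post_labels
    )

    def fold_change(gene: str, pre_id: str, post_id: str) -> float:
        pre = float(matrix.values.loc[gene, pre_id])
        post = float(matrix.values.loc[gene, post_id])
        if log_scale:
            return post - pre
        if pre <= 0 or post <= 0:
            raise ValueError(f"non-positive expression for {gene}; cannot take log2 ratio")
        return math.log2(post / pre)

    rows = []
    for patient, (pre_id, post_id) in sorted(pairing.items()):
        rows.append(
            {
                "patient": patient,
                "dataset": matrix.obs.loc[pre_id, dataset_key]
                if dataset_key in matrix.obs.columns
                else "all",
                "rf1_input": fold_change("CD36", pre_id, post_id),
                "rf2a_input": float(matrix.values.loc["AGPS", pre_id]),
                "rf2b_input": fold_change("AGPS", pre_id, post_id),
                "rf3a_input": float(matrix.values.loc["UGCG", pre_id]),
                "rf3b_input": fold_change("UGCG", pre_id, post_id),
            }
        )
    return pd.DataFrame(rows).set_index("patient")


def zscore_risk_inputs(inputs: pd.DataFrame) -> pd.DataFrame:
    """Add ``*_z`` columns: each input z-normalized within its dataset."""
    out = inputs.copy()
    for col in _INPUT_COLUMNS:
        out[col.replace("_input", "_z")] = zscore_within_dataset(
            inputs[col], inputs["dataset"]
        )
    return out


@dataclass
class RiskProfile:
    patient_id: str
    dataset_id: str
    rf1_z: float
    rf2a_z: float
    rf2b_z: float
    rf3a_z: float
    rf3b_z: float
    rf1: int
    rf2: int
    rf3: int
    risk_score: int
    group: str


def assign_risk(
    zscored: pd.DataFrame,
    z_high_threshold: float = 0.0,
    risk_high_min: int = 2,
    risk_low_max: int = 1,
) -> list[RiskProfile]:
    """Turn z-scored inputs into risk factors, scores, and groups.

    A sub-factor is high iff its z score exceeds ``z_high_threshold``
    (strictly); RF2 and RF3 fire when either of their sub-factors does.
    Scores between ``risk_low_max`` and ``risk_high_min`` (possible only
    with non-default thresholds) fall in an excluded intermediate group.
    """
    if not np.isfinite(z_high_threshold):
        raise ValueError("z_high_threshold must be finite")
    z_cols = [c.replace("_input", "_z") for c in _INPUT_COLUMNS]
    missing_cols = [c for c in z_cols if c not in zscored.columns]
    if missing_cols:
        raise ValueError(f"missing z-score columns: {missing_cols} (run zscore_risk_inputs)")
    profiles: list[RiskProfile] = []
    for patient, row in zscored.iterrows():
        nulls = [c for c in z_cols if pd.isna(row[c])]
        if nulls:
            raise ValueError(f"patient {patient}: missing inputs {nulls}")
        high = {c: bool(row[c] > z_high_threshold) for c in z_cols}
        rf1 = int(high["rf1_z"])
        rf2 = int(high["rf2a_z"] or high["rf2b_z"])
        rf3 = int(high["rf3a_z"] or high["rf3b_z"])
        score = rf1 + rf2 + rf3
        if score >= risk_high_min:
            group = "high"
        elif score <= risk_low_max:
            group = "low"
        else:
            group = "intermediate-excluded"
        profiles.append(
            RiskProfile(
                patient_id=str(patient),
                dataset_id=str(row.get("dataset", "all")),
                rf1_z=float(row["rf1_z"]),
                rf2a_z=float(row["rf2a_z"]),
                rf2b_z=float(row["rf2b_z"]),
                rf3a_z=float(row["rf3a_z"]),
                rf3b_z=float(row["rf3b_z"]),
                rf1=rf1,
                rf2=rf2,
                rf3=rf3,
                risk_score=score,
                group=group,
            )
        )
    return profiles


def risk_profiles_from_cohort(
    matrix: ExpressionMatrix,
    z_high_threshold: float = 0.0,
    risk_high_min: int = 2,
    risk_low_max: int = 1,
    log_scale: bool = True,
) -> pd.DataFrame:
    """End-to-end risk classification of a paired cohort, as a DataFrame."""
    inputs = build_risk_inputs(matrix, log_scale=log_scale)
    zscored = zscore_risk_inputs(inputs)
    profiles = assign_risk(
        zscored,
        z_high_threshold=z_high_threshold,
        risk_high_min=risk_high_min,
        risk_low_max=risk_low_max,
    )
    return pd.DataFrame([vars(p) for p in profiles]).set_index("patient_id")


@dataclass
class KMEstimate:
    """Product-limit survival estimate.

    ``times`` are the distinct observed times (events and censorings),
    ``survival`` the non-increasing step values S(t) at those times,
    ``at_risk`` the risk-set sizes just before each time, and
    ``censor_times`` the times at which subjects were censored.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t) with the step-function (right-continuous) convention."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    if len(records) == 0:
        raise ValueError("no survival records")
    if (records["time"] <= 0).any():
        bad = records.loc[records["time"] <= 0]
        raise ValueError(f"nonpositive survival times for {bad.index.tolist()[:5]}")
    return records


def km_estimate(records: pd.DataFrame) -> KMEstimate:
    """Kaplan-Meier product-limit estimator.

    *records* needs ``time`` and boolean ``event`` columns.  Censored
    subjects leave the risk set without a survival drop; at tied times,
    events are processed before censorings (the standard convention, as in
    lifelines).
    """
    records = _check_records(records)
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], event_observed=records["event"].astype(bool))
    table = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 else kmf.event_table
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    at_risk = table["at_risk"].to_numpy(dtype=int)
    censor_times = np.sort(
        records.loc[~records["event"].astype(bool), "time"].to_numpy(dtype=float)
    )
    return KMEstimate(times=times, survival=surv, at_risk=at_risk, censor_times=censor_times)


def logrank_test(records: pd.DataFrame, group_col: str = "group") -> tuple[float, int, float]:
    """Standard log-rank test across >= 2 groups.

    Returns ``(chi2, df, p)``.  At each distinct event time the observed
    events per group are compared with their hypergeometric expectation given
    the risk sets; the statistic is chi-square with (groups - 1) degrees of
    freedom.
    """
    records = _check_records(records)
    groups = records[group_col]
    n_groups = groups.nunique()
    if n_groups < 2:
        raise ValueError(f"log-rank needs >= 2 groups, got {n_groups}")
    if not records["event"].astype(bool).any():
        raise ValueError("log-rank needs at least one event")
    res = multivariate_logrank_test(
        records["time"], groups, records["event"].astype(bool)
    )
    return float(res.test_statistic), n_groups - 1, float(res.p_value)


def pfs_from_volumes(
    series: TumorVolumeSeries,
    progression_factor: float = 1.2,
) -> dict:
    """Progression-free survival record for one animal.

    The default rule calls progression at the first post-treatment day where
    volume >= ``progression_factor`` x max(nadir volume so far, baseline);
    otherwise the animal is censored at its last measurement.  Times are days
    since treatment start.
    """
    if progression_factor <= 0:
        raise ValueError("progression_factor must be > 0")
    v0 = series.baseline_volume
    if v0 is None or v0 <= 0:
        raise ValueError(f"animal {series.animal_id}: needs a positive baseline volume")
    post = series.post_treatment()
    if len(post) < 2:
        raise ValueError(
            f"animal {series.animal_id}: needs >= 2 post-treatment measurements, "
            f"got {len(post)}"
        )
    nadir = v0
    for row in post.itertuples():
        threshold = progression_factor * max(nadir, v0)
        if row.volume_mm3 >= threshold:
            return {
                "subject_id": series.animal_id,
                "time": float(row.day - series.treatment_start_day),
                "event": True,
                "group": series.arm,
            }
        nadir = min(nadir, float(row.volume_mm3))
    return {
        "subject_id": series.animal_id,
        "time": float(post["day"].iloc[-1] - series.treatment_start_day),
        "event": False,
        "group": series.arm,
    }
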