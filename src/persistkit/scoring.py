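"""Rank-based signature scoring and preranked gene-set enrichment.

Two rank statistics are implemented from first principles:

* **AUCell-style scoring** — per observation, genes are ranked by decreasing
  expression and the score is the area under the gene-set recovery curve
  within the top ``ceil(top_fraction * G)`` ranks, normalized by the maximal
  possible area (a set fully contained in the top ranks scores 1).  The score
  depends only on ranks, so it is invariant to any strictly monotone
  transform of a cell's expression values.

* **Preranked GSEA** — a running sum over a metric-sorted gene list: each
  gene-set hit increments by its |metric|^p weight (normalized over in-set
  genes), each miss decrements by 1/(N - |S|).  The enrichment score ES is
  the running-sum extremum by absolute value; NES divides ES by the mean |ES*|
  of same-sign gene-label permutations, and the permutation p value is
  (1 + #{same-sign |ES*| >= |ES|}) / (1 + #same-sign).

Per-patient enrichment ranks genes by the difference of normalized expression
(post minus pre) within each matched sample pair; with one pair per patient,
gene-label permutation is the only available null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io import ExpressionMatrix, GeneSet

logger = logging.getLogger("persistkit")

__all__ = [
    "SignatureScoreVector",
    "EnrichmentResult",
    "PerPatientEnrichment",
    "AssociationResult",
    "aucell_score",
    "gate_by_score",
    "gsea_preranked",
    "pair_observations",
    "per_patient_enrichment",
    "spearman_association",
]


@dataclass
class SignatureScoreVector:
    """Per-observation AUCell scores (in [0, 1]) for one gene set."""

    scores: pd.Series
    gene_set_name: str
    top_fraction: float

    def __post_init__(self) -> None:
        s = self.scores.to_numpy(dtype=float)
        if len(s) and (s.min() < -1e-12 or s.max() > 1 + 1e-12):
            raise ValueError("AUCell scores must lie in [0, 1]")


def aucell_score(
    matrix: ExpressionMatrix,
    gene_set: GeneSet,
    top_fraction: float = 0.05,
    seed: int = 0,
) -> SignatureScoreVector:
    """Area-under-the-recovery-curve signature score per observation.

    For each observation, genes are ranked by decreasing expression (ties
    broken by a seeded random permutation within tie groups — rank order on
    tied values is otherwise undefined).  The recovery curve counts
    cumulative gene-set hits over the top ``k = ceil(top_fraction * G)``
    ranks; the score is the step-curve area divided by the maximal area
    ``sum_{i=1..k} min(i, |S|)``.  Set genes absent from the matrix are
    dropped with a warning.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    present = [g for g in gene_set.genes if g in matrix.gene_ids]
    missing = sorted(set(gene_set.genes) - set(present))
    if missing:
        logger.warning(
            "gene set %s: %d gene(s) absent from matrix (e.g. %s)",
            gene_set.name, len(missing), missing[:3],
        )
    if not present:
        raise ValueError(f"no genes of set {gene_set.name!r} present in the matrix")

    n_genes = matrix.n_genes
    k = int(np.ceil(top_fraction * n_genes))
    if k < 2:
        raise ValueError(
            f"top window of {k} rank(s) is too small (G={n_genes}, "
            f"top_fraction={top_fraction})"
        )

    values = matrix.values.to_numpy(dtype=float)
    in_set = np.asarray(matrix.gene_ids.isin(present))
    n_set = int(in_set.sum())
    max_area = int(sum(min(i, n_set) for i in range(1, k + 1)))

    rng = np.random.default_rng(seed)
    tie_keys = rng.random(values.shape)
    scores = np.empty(matrix.n_obs, dtype=float)
    for j in range(matrix.n_obs):
        # decreasing expression; random key decides within tie groups
        order = np.lexsort((tie_keys[:, j], -values[:, j]))
        hit_ranks = np.flatnonzero(in_set[order]) + 1  # 1-based ranks of set genes
        top_hits = hit_ranks[hit_ranks <= k]
        # each hit at rank p contributes (k - p + 1) to the step-curve area
        scores[j] = (k - top_hits + 1).sum() / max_area
    return SignatureScoreVector(
        scores=pd.Series(scores, index=matrix.obs_ids, name=gene_set.name),
        gene_set_name=gene_set.name,
        top_fraction=top_fraction,
    )


def gate_by_score(scores: SignatureScoreVector, threshold: float) -> pd.Series:
    """Boolean labels: True iff score >= threshold (inclusive cutoff)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return (scores.scores >= threshold).rename("positive")


@dataclass
class EnrichmentResult:
    """Signed enrichment score with permutation normalization.

    ``direction`` is "increase" for positive NES (the set sits toward the top
    of the ranking) and "decrease" otherwise.
    """

    gene_set_name: str
    es: float
    nes: float
    p_value: float
    n_permutations: int

    @property
    def direction(self) -> str:
        return "increase" if self.nes > 0 else "decrease"


def _running_sum_es(order_weights: np.ndarray, in_set: np.ndarray) -> float:
    """ES of one labeled ranking: extremum of the running sum by |.|."""
    n = len(in_set)
    n_set = int(in_set.sum())
    hit_w = np.where(in_set, order_weights, 0.0)
    denom = hit_w.sum()
    # accumulate hits and misses separately: keeps the contiguous-set limits
    # (+1 / -1) exact instead of accumulating per-step rounding
    running = np.cumsum(hit_w) / denom - np.cumsum(~in_set) / (n - n_set)
    return float(running[np.argmax(np.abs(running))])


def gsea_preranked(
    ranking: pd.Series,
    gene_set: GeneSet,
    weight_exponent: float = 1.0,
    n_permutations: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Preranked gene-set enrichment with gene-label permutation null.

    *ranking* maps genes to metric values and must be sorted in decreasing
    metric order.  At ``weight_exponent=0`` the statistic has closed-form
    limits (ES = +1 / -1 for a set occupying the top / bottom |S| ranks),
    used by the exactness tests; the default exponent of 1 is the common
    public-tool convention.
    """
    metric = ranking.to_numpy(dtype=float)
    if np.any(np.diff(metric) > 0):
        raise ValueError("ranking metric must be sorted in decreasing order")
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    in_set = ranking.index.isin(gene_set.genes)
    n, n_set = len(metric), int(in_set.sum())
    if n_set < 3:
        raise ValueError(
            f"only {n_set} gene(s) of set {gene_set.name!r} present in the ranking; need >= 3"
        )
    if n_set == n:
        raise ValueError("gene set covers the entire ranking; no misses to score against")

    weights = np.abs(metric) ** weight_exponent if weight_exponent != 0 else np.ones(n)
    if weight_exponent > 0 and not np.any(weights):
        raise ValueError("all ranking metrics are zero; weighted enrichment is undefined")

    es = _running_sum_es(weights, in_set)

    rng = np.random.default_rng(seed)
    # vectorized gene-label permutations: each row is a random |S|-subset
    positions = np.argsort(rng.random((n_permutations, n)), axis=1)[:, :n_set]
    indicator = np.zeros((n_permutations, n), dtype=bool)
    np.put_along_axis(indicator, positions, True, axis=1)
    hit_w = indicator * weights
    denom = hit_w.sum(axis=1, keepdims=True)
    running = np.cumsum(hit_w, axis=1) / denom - np.cumsum(~indicator, axis=1) / (n - n_set)
    idx = np.argmax(np.abs(running), axis=1)
    es_perm = np.take_along_axis(running, idx[:, None], axis=1).ravel()

    same_sign = es_perm > 0 if es >= 0 else es_perm < 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        logger.warning("no same-sign permutation scores; NES undefined, p set to 1/(1)")
        nes = np.nan
        p = 1.0
    else:
        mean_abs = float(np.abs(es_perm[same_sign]).mean())
        nes = es / mean_abs
        p = (1 + int((np.abs(es_perm[same_sign]) >= abs(es)).sum())) / (1 + n_same)
    return EnrichmentResult(
        gene_set_name=gene_set.name, es=es, nes=nes, p_value=p,
        n_permutations=n_permutations,
    )


def pair_observations(
    obs: pd.DataFrame,
    patient_key: str = "patient",
    time_key: str = "timepoint",
    pre_label: str = "pre",
    post_labels: tuple[str, ...] = ("relapse", "on"),
) -> dict[str, tuple[str, str]]:
    """Map each patient to its (pre, post) observation ids.

    When a patient has several post-treatment samples, the first label in
    *post_labels* that is present wins (relapse preferred over on-treatment
    by default).  Patients without exactly one pre sample or without any post
    sample are reported in one error.
    """
    pairing: dict[str, tuple[str, str]] = {}
    unpaired: list[str] = []
    for patient, grp in obs.groupby(patient_key, sort=True):
        pre_ids = grp.index[grp[time_key] == pre_label]
        post_id = None
        for label in post_labels:
            cand = grp.index[grp[time_key] == label]
            if len(cand):
                post_id = cand[0]
                break
        if len(pre_ids) != 1 or post_id is None:
            unpaired.append(str(patient))
            continue
        pairing[str(patient)] = (pre_ids[0], post_id)
    if unpaired:
        raise ValueError(f"patients without a usable pre/post pair: {unpaired}")
    return pairing


@dataclass
class PerPatientEnrichment:
    """One enrichment result per patient plus the fraction with NES > 0."""

    results: dict[str, EnrichmentResult]

    @property
    def fraction_increased(self) -> float:
        nes = [r.nes for r in self.results.values()]
        return float(np.mean([x > 0 for x in nes])) if nes else np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient": p,
                    "gene_set": r.gene_set_name,
                    "es": r.es,
                    "nes": r.nes,
                    "p_value": r.p_value,
                    "direction": r.direction,
                }
                for p, r in self.results.items()
            ]
        )


def per_patient_enrichment(
    matrix: ExpressionMatrix,
    pairing: dict[str, tuple[str, str]],
    gene_set: GeneSet,
    weight_exponent: float = 1.0,
    n_permutations: int = 1000,
    seed: int = 0,
) -> PerPatientEnrichment:
    """Preranked enrichment of post-minus-pre expression change per patient."""
    results: dict[str, EnrichmentResult] = {}
    for i, (patient, (pre_id, post_id)) in enumerate(sorted(pairing.items())):
        delta = matrix.values[post_id] - matrix.values[pre_id]
        ranking = delta.sort_values(ascending=False, kind="mergesort")
        try:
            results[patient] = gsea_preranked(
                ranking, gene_set, weight_exponent=weight_exponent,
                n_permutations=n_permutations, seed=seed + i,
            )
        except ValueError as exc:
            raise ValueError(f"patient {patient}: {exc}") from exc
    return PerPatientEnrichment(results=results)


@dataclass
class AssociationResult:
    """Spearman rank correlation between two genes across observations."""

    gene_a: str
    gene_b: str
    rho: float
    p_value: float
    n: int


def spearman_association(
    matrix: ExpressionMatrix, gene_a: str, gene_b: str
) -> AssociationResult:
    """Spearman's rank-order correlation (midranks for ties, t-approximation p)."""
    for g in (gene_a, gene_b):
        if g not in matrix.gene_ids:
            raise KeyError(f"gene {g!r} not present in matrix")
    x = matrix.values.loc[gene_a].to_numpy(dtype=float)
    y = matrix.values.loc[gene_b].to_numpy(dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError(f"Spearman association needs >= 3 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero rank variance: one gene is constant across observations")
    res = scipy.stats.spearmanr(x, y)
    return AssociationResult(
        gene_a=gene_a, gene_b=gene_b,
        rho=float(res.statistic), p_value=float(res.pvalue), n=n,
    )
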