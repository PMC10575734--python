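"""Marker gating, gating concordance, and retained-expression contrasts.

Cells are called marker-positive at an inclusive normalized-expression cutoff
(CD36 >= 2.2 is the convention this mirrors).  Concordance between two
gatings — e.g. the CD36 threshold gate versus the SMC signature-score gate —
is summarized by the confusion counts, the Jaccard index on positives,
overall agreement, and Cohen's kappa.

"Retained expression" of a gene under treatment in the marker-positive
population is operationalized as a population x condition interaction in a
two-factor fixed-effects analysis of variance on the (log-normalized)
expression: a gene is retained when the treatment-induced decrease in
positives is smaller than in negatives and the interaction is significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .io import ExpressionMatrix

logger = logging.getLogger("persistkit")

__all__ = [
    "GatingResult",
    "ConcordanceReport",
    "ContrastResult",
    "gate_by_marker",
    "concordance",
    "retained_expression_contrast",
    "fraction_positive",
]


@dataclass
class GatingResult:
    """Boolean positive/negative labels from a marker-expression threshold."""

    labels: pd.Series
    marker: str
    threshold: float

    @property
    def obs_ids(self) -> pd.Index:
        return self.labels.index

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())


def gate_by_marker(
    matrix: ExpressionMatrix, gene: str, threshold: float
) -> GatingResult:
    """Label observations positive iff marker expression >= threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if gene not in matrix.gene_ids:
        raise KeyError(f"marker gene {gene!r} not present in matrix")
    labels = (matrix.values.loc[gene] >= threshold).rename("positive")
    return GatingResult(labels=labels, marker=gene, threshold=threshold)


@dataclass
class ConcordanceReport:
    both_positive: int
    a_only: int
    b_only: int
    both_negative: int

    @property
    def n(self) -> int:
        return self.both_positive + self.a_only + self.b_only + self.both_negative

    @property
    def jaccard(self) -> float:
        union = self.both_positive + self.a_only + self.b_only
        return self.both_positive / union if union else float("nan")

    @property
    def agreement(self) -> float:
        return (self.both_positive + self.both_negative) / self.n

    @property
    def cohen_kappa(self) -> float:
        n = self.n
        po = self.agreement
        p_a = (self.both_positive + self.a_only) / n
        p_b = (self.both_positive + self.b_only) / n
        pe = p_a * p_b + (1 - p_a) * (1 - p_b)
        if pe == 1.0:  # both gatings degenerate to a single class
            return 1.0 if po == 1.0 else 0.0
        return (po - pe) / (1 - pe)


def concordance(a: pd.Series | Sequence[bool], b: pd.Series | Sequence[bool]) -> ConcordanceReport:
    """Confusion counts and agreement statistics for two boolean labelings."""
    a = np.asarray(pd.Series(a), dtype=bool)
    b = np.asarray(pd.Series(b), dtype=bool)
    if len(a) != len(b):
        raise ValueError(f"label lengths differ: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("cannot compare empty labelings")
    return ConcordanceReport(
        both_positive=int(np.sum(a & b)),
        a_only=int(np.sum(a & ~b)),
        b_only=int(np.sum(~a & b)),
        both_negative=int(np.sum(~a & ~b)),
    )


@dataclass
class ContrastResult:
    """Per-gene population x condition contrast.

    ``decrease_*`` is the untreated-minus-treated mean (positive when
    treatment lowers expression); ``retained`` is True when the decrease in
    the marker-positive population is smaller than in the negatives and the
    interaction p value clears the cutoff.
    """

    gene: str
    means: dict[tuple[str, str], float]  # (population, condition) -> mean
    decrease_negatives: float
    decrease_positives: float
    interaction_p: float
    retained: bool


def _two_way_interaction_p(values: np.ndarray, pop: np.ndarray, treated: np.ndarray) -> float:
    """Interaction p from a 2x2 fixed-effects ANOVA (type II on a 2x2 design).

    With two levels per factor the interaction sum of squares has a single
    degree of freedom; the F test reduces to a contrast of the four cell
    means against the pooled within-cell variance.
    """
    cells = [values[(pop == p) & (treated == t)] for p in (False, True) for t in (False, True)]
    ns = np.array([len(c) for c in cells], dtype=float)
    means = np.array([c.mean() for c in cells])
    ss_within = sum(((c - c.mean()) ** 2).sum() for c in cells)
    df_within = int(ns.sum()) - 4
    if df_within <= 0:
        raise ValueError("not enough observations for the interaction test")
    mse = ss_within / df_within
    # interaction contrast on cell means: (m11 - m10) - (m01 - m00)
    contrast = (means[3] - means[2]) - (means[1] - means[0])
    if mse == 0:
        return 1.0 if contrast == 0 else 0.0
    var_contrast = mse * np.sum(1.0 / ns)
    f_stat = contrast**2 / var_contrast
    return float(scipy.stats.f.sf(f_stat, 1, df_within))


def retained_expression_contrast(
    matrix: ExpressionMatrix,
    gating: GatingResult,
    condition_key: str = "condition",
    genes: Sequence[str] | None = None,
    treated_label: str = "treated",
    untreated_label: str = "untreated",
    p_cutoff: float = 0.05,
) -> list[ContrastResult]:
    """Test, per gene, whether expression is retained in the positive population.

    Requires both populations in both conditions with >= 2 observations per
    stratum (variance is undefined below that); an empty or singleton stratum
    raises an error naming it.
    """
    if genes is None:
        genes = list(matrix.gene_ids)
    cond = matrix.obs[condition_key]
    pop = gating.labels.loc[matrix.obs_ids].to_numpy(dtype=bool)
    treated = (cond == treated_label).to_numpy()
    untreated = (cond == untreated_label).to_numpy()
    if not np.all(treated | untreated):
        other = sorted(set(cond) - {treated_label, untreated_label})
        raise ValueError(f"unrecognized condition labels: {other}")

    for p_flag, p_name in ((True, "positive"), (False, "negative")):
        for t_flag, t_name in ((True, treated_label), (False, untreated_label)):
            size = int(np.sum((pop == p_flag) & (treated == t_flag)))
            if size < 2:
                raise ValueError(
                    f"stratum ({p_name}, {t_name}) has {size} observation(s); need >= 2"
                )

    results: list[ContrastResult] = []
    for gene in genes:
        if gene not in matrix.gene_ids:
            raise KeyError(f"gene {gene!r} not present in matrix")
        x = matrix.values.loc[gene].to_numpy(dtype=float)
        means = {
            (pname, tname): float(x[(pop == pflag) & (treated == tflag)].mean())
            for pflag, pname in ((True, "positive"), (False, "negative"))
            for tflag, tname in ((True, treated_label), (False, untreated_label))
        }
        dec_neg = means[("negative", untreated_label)] - means[("negative", treated_label)]
        dec_pos = means[("positive", untreated_label)] - means[("positive", treated_label)]
        p_int = _two_way_interaction_p(x, pop, treated)
        results.append(
            ContrastResult(
                gene=gene,
                means=means,
                decrease_negatives=dec_neg,
                decrease_positives=dec_pos,
                interaction_p=p_int,
                retained=(dec_pos < dec_neg) and (p_int < p_cutoff),
            )
        )
    return results


def fraction_positive(
    gating: GatingResult, groups: pd.Series, confidence: float = 0.95
) -> pd.DataFrame:
    """Per-group positive fraction with an exact (Clopper-Pearson) interval."""
    groups = groups.loc[gating.obs_ids]
    if groups.isna().any():
        missing = gating.obs_ids[groups.isna()].tolist()
        raise ValueError(f"observations without a group: {missing[:5]}")
    rows = []
    for group, labels in gating.labels.groupby(groups):
        n = len(labels)
        if n == 0:
            raise ValueError(f"group {group!r} is empty")
        k = int(labels.sum())
        ci = scipy.stats.binomtest(k, n).proportion_ci(confidence, method="exact")
        rows.append(
            {
                "group": group,
                "n": n,
                "n_positive": k,
                "fraction": k / n,
                "ci_low": float(ci.low),
                "ci_high": float(ci.high),
            }
        )
    return pd.DataFrame(rows).set_index("group")
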