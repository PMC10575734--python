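"""Differential lipidomics: normalization, imputation, testing, composition.

The workflow mirrors the standard quantitative-lipidomics pipeline: species
abundances are normalized to DNA quantity (nmol lipid per mg DNA), log2
transformed, zeros (instrument dropouts) are imputed from a downshifted
normal fitted per replicate column — Normal(mean - downshift*sd,
(width*sd)^2) over that column's nonzero log2 values, with the widely used
defaults width = 0.3 and downshift = 1.8 — and species are tested across
groups with a one-way fixed-effects ANOVA followed by a post hoc pairwise
test (Tukey HSD by default, Fisher LSD as an alternative).  A species is
called increased in a comparison when its fold change is >= the cutoff
(1.5 by default) and the post hoc p value <= the cutoff (0.05), both
inclusive; decreased symmetrically at 1/fc_cutoff.  No multiple-testing
correction is applied by default (raw p values are the convention this
reproduces); Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("persistkit")

__all__ = [
    "LIPID_CLASSES",
    "LipidTable",
    "DifferentialResult",
    "parse_lipid_name",
    "normalize_to_dna",
    "log2_impute",
    "classify_change",
    "differential_species",
    "common_hits",
    "class_composition",
    "chainlength_profile",
]

#: recognized lipid-class tokens; ether (-O) and plasmalogen (-P) classes are distinct
LIPID_CLASSES = frozenset(
    {
        "PC", "PE", "PS", "PI", "PG", "PA",
        "LPC", "LPE",
        "PC-O", "PE-O", "PC-P", "PE-P",
        "TG", "DG", "MG", "CE", "FFA",
        "Cer", "DCER", "HexCer", "LacCer", "GluCer", "GalCer", "SM", "SPH",
    }
)

_NAME_RE = re.compile(r"^(?P<cls>[A-Za-z]+(?:-[OP])?)\s+(?P<c>\d+):(?P<d>\d+)$")


def parse_lipid_name(name: str) -> tuple[str, int, int]:
    """Parse a "CLASS C:D" species name into (class, carbons, double bonds)."""
    m = _NAME_RE.match(name.strip())
    if not m:
        raise ValueError(f"malformed lipid species name: {name!r}")
    cls = m.group("cls")
    if cls not in LIPID_CLASSES:
        raise ValueError(f"unknown lipid class {cls!r} in {name!r}")
    return cls, int(m.group("c")), int(m.group("d"))


@dataclass
class LipidTable:
    """Species-by-replicate abundance table with group labels.

    ``values`` is indexed by species names in the "CLASS C:D" grammar, one
    column per replicate; ``groups`` maps replicate to its sample group.
    Values are non-negative (nmol per mg DNA); exact zeros mark dropouts.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if (self.values < 0).any().any():
            raise ValueError("lipid abundances must be >= 0")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"replicates without a group label: {sorted(missing)[:5]}")
        self.groups = self.groups.loc[self.values.columns]
        for name in self.values.index:
            parse_lipid_name(name)  # fail early on unparseable species

    @property
    def species(self) -> pd.Index:
        return self.values.index

    @property
    def replicates(self) -> pd.Index:
        return self.values.columns

    def species_classes(self) -> pd.Series:
        return pd.Series(
            [parse_lipid_name(s)[0] for s in self.values.index],
            index=self.values.index, name="class",
        )


def normalize_to_dna(raw: pd.DataFrame, dna_mg: pd.Series, groups: pd.Series) -> LipidTable:
    """Divide each replicate column by its DNA mass (mg)."""
    dna_mg = dna_mg.loc[raw.columns]
    if (dna_mg <= 0).any():
        bad = dna_mg.index[dna_mg <= 0].tolist()
        raise ValueError(f"non-positive DNA quantity for replicates {bad}")
    return LipidTable(values=raw.div(dna_mg, axis=1), groups=groups)


def log2_impute(
    table: LipidTable,
    width: float = 0.3,
    downshift: float = 1.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log2 transform with downshifted-normal imputation of zeros.

    Nonzero values become log2(value); zeros are drawn from
    Normal(m - downshift*s, (width*s)^2) where m and s are the mean and sd of
    the *column's* nonzero log2 values (a column with no nonzero entries
    falls back to global statistics with a warning).  Tables without zeros
    consume no randomness.  Returns ``(log2_table, imputed_mask)``.
    """
    values = table.values
    if not (values > 0).any().any():
        raise ValueError("all lipid abundances are zero; nothing to transform")
    rng = np.random.default_rng(seed)
    arr = values.to_numpy(dtype=float)
    zero_mask = arr == 0
    log2_arr = np.where(zero_mask, np.nan, np.log2(np.where(zero_mask, 1.0, arr)))

    global_vals = log2_arr[~np.isnan(log2_arr)]
    g_mean, g_sd = float(global_vals.mean()), float(global_vals.std(ddof=1))
    out = log2_arr.copy()
    for j, col in enumerate(values.columns):
        n_zero = int(zero_mask[:, j].sum())
        if n_zero == 0:
            continue
        observed = log2_arr[~zero_mask[:, j], j]
        if len(observed) >= 2:
            m, s = float(observed.mean()), float(observed.std(ddof=1))
        else:
            logger.warning("replicate %s has <2 nonzero values; using global statistics", col)
            m, s = g_mean, g_sd
        out[zero_mask[:, j], j] = rng.normal(m - downshift * s, width * s, size=n_zero)
    log2_table = pd.DataFrame(out, index=values.index, columns=values.columns)
    mask = pd.DataFrame(zero_mask, index=values.index, columns=values.columns)
    return log2_table, mask


def classify_change(log2_fc: float, p_value: float, fc_cutoff: float, p_cutoff: float) -> str:
    """Call a species increased/decreased/unchanged with inclusive cutoffs."""
    fc = 2.0**log2_fc
    if fc >= fc_cutoff and p_value <= p_cutoff:
        return "increased"
    if fc <= 1.0 / fc_cutoff and p_value <= p_cutoff:
        return "decreased"
    return "unchanged"


@dataclass
class DifferentialResult:
    species_id: str
    comparison: str  # "group_vs_reference"
    log2_fc: float
    anova_p: float
    posthoc_p: float
    call: str
    imputation_dominated: bool = False


def _lsd_pvalues(groups: list[np.ndarray]) -> np.ndarray:
    """Fisher LSD: pairwise t tests with the pooled within-group variance."""
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / (n_total - k)
    out = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        if mse == 0:
            p = 1.0 if groups[i].mean() == groups[j].mean() else 0.0
        else:
            se = np.sqrt(mse * (1 / len(groups[i]) + 1 / len(groups[j])))
            t = (groups[i].mean() - groups[j].mean()) / se
            p = 2 * scipy.stats.t.sf(abs(t), n_total - k)
        out[i, j] = out[j, i] = p
    return out


def differential_species(
    log2_table: pd.DataFrame,
    groups: pd.Series,
    reference: str,
    fc_cutoff: float = 1.5,
    p_cutoff: float = 0.05,
    posthoc: str = "tukey",
    adjust: str = "none",
    imputed_mask: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One-way ANOVA plus post hoc calls per species, each group vs *reference*.

    Fold changes are differences of group means on the log2 scale.  With
    ``imputed_mask`` given, species imputed in at least half the replicates
    of both compared groups are flagged ``imputation_dominated``.
    ``adjust='bh'`` applies Benjamini-Hochberg to the post hoc p values
    across species, per comparison, before calling.
    """
    groups = groups.loc[log2_table.columns]
    group_names = sorted(groups.unique())
    if reference not in group_names:
        raise ValueError(f"reference group {reference!r} not among {group_names}")
    if len(group_names) < 2:
        raise ValueError("differential testing needs >= 2 groups")
    cols_by_group = {g: groups.index[groups == g] for g in group_names}
    for g, cols in cols_by_group.items():
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has {len(cols)} replicate(s); need >= 2")
        block = log2_table[cols].to_numpy(dtype=float)
        if np.allclose(block.std(axis=1, ddof=1), 0):
            logger.warning("group %r has zero variance across every species", g)
    if posthoc not in ("tukey", "lsd"):
        raise ValueError(f"unknown post hoc test {posthoc!r}")

    others = [g for g in group_names if g != reference]
    results: list[DifferentialResult] = []
    for species in log2_table.index:
        arrays = [log2_table.loc[species, cols_by_group[g]].to_numpy(dtype=float)
                  for g in group_names]
        if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
            anova_p = 1.0  # degenerate: every value identical
            pair_p = np.ones((len(arrays), len(arrays)))
        else:
            anova = scipy.stats.f_oneway(*arrays)
            anova_p = 1.0 if np.isnan(anova.pvalue) else float(anova.pvalue)
            if posthoc == "tukey":
                pair_p = scipy.stats.tukey_hsd(*arrays).pvalue
            else:
                pair_p = _lsd_pvalues(arrays)
        ref_idx = group_names.index(reference)
        ref_mean = float(arrays[ref_idx].mean())
        for g in others:
            gi = group_names.index(g)
            log2_fc = float(arrays[gi].mean()) - ref_mean
            p = float(pair_p[gi, ref_idx])
            dominated = False
            if imputed_mask is not None:
                frac_g = imputed_mask.loc[species, cols_by_group[g]].mean()
                frac_r = imputed_mask.loc[species, cols_by_group[reference]].mean()
                dominated = bool(frac_g >= 0.5 and frac_r >= 0.5)
            results.append(
                DifferentialResult(
                    species_id=species,
                    comparison=f"{g}_vs_{reference}",
                    log2_fc=log2_fc,
                    anova_p=anova_p,
                    posthoc_p=p,
                    call="",  # filled below, after optional adjustment
                    imputation_dominated=dominated,
                )
            )

    frame = pd.DataFrame([vars(r) for r in results])
    if adjust == "bh":
        for comp, idx in frame.groupby("comparison").groups.items():
            frame.loc[idx, "posthoc_p"] = multipletests(
                frame.loc[idx, "posthoc_p"], method="fdr_bh"
            )[1]
    elif adjust != "none":
        raise ValueError(f"unknown adjustment {adjust!r}")
    frame["call"] = [
        classify_change(r.log2_fc, r.posthoc_p, fc_cutoff, p_cutoff)
        for r in frame.itertuples()
    ]
    return frame


def common_hits(results: dict[str, pd.DataFrame]) -> dict:
    """Intersection report across >= 2 differential comparisons.

    For each direction, lists the species called in *all* comparisons and
    counts every region of the intersection (Venn) diagram as a mapping from
    membership pattern (tuple of booleans in comparison order) to count.
    """
    if len(results) < 2:
        raise ValueError("common_hits needs >= 2 comparisons")
    names = list(results)
    universe: set[str] = set()
    for df in results.values():
        universe |= set(df["species_id"])
    if not universe:
        raise ValueError("empty species universe")
    report: dict = {"comparisons": names}
    for direction in ("increased", "decreased"):
        called = {
            name: set(df.loc[df["call"] == direction, "species_id"])
            for name, df in results.items()
        }
        common = set.intersection(*called.values())
        regions: dict[tuple[bool, ...], int] = {}
        for species in sorted(set.union(*called.values())):
            pattern = tuple(species in called[n] for n in names)
            regions[pattern] = regions.get(pattern, 0) + 1
        report[direction] = {"common": sorted(common), "regions": regions}
    return report


def class_composition(table: LipidTable) -> pd.DataFrame:
    """Per-class concentration and percentage of total, per sample group.

    Works on the original nmol/mg-DNA scale (not log2): species are averaged
    across a group's replicates and summed within each class; percentages sum
    to 100 per group.
    """
    if table.values.empty:
        raise ValueError("empty lipid table")
    classes = table.species_classes()
    rows = []
    for group, cols in table.groups.groupby(table.groups).groups.items():
        means = table.values[list(cols)].mean(axis=1)
        totals = means.groupby(classes).sum()
        grand = totals.sum()
        for cls, conc in totals.items():
            rows.append(
                {
                    "group": group,
                    "class": cls,
                    "concentration": float(conc),
                    "percent": float(100.0 * conc / grand),
                }
            )
    return pd.DataFrame(rows)


def chainlength_profile(
    table: LipidTable,
    classes: tuple[str, ...] | str,
    log2_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Abundance grouped by carbon chain length, per group, with per-bin tests.

    Species of the filtered classes are summed per carbon count within each
    replicate; the table reports per-group mean and sd per carbon bin, plus a
    per-bin between-group p value using the pooled residual variance of the
    two-factor (carbon x group) cell-means model — the per-bin contrasts that
    accompany a two-way ANOVA.
    """
    if isinstance(classes, str):
        classes = (classes,)
    cls = table.species_classes()
    keep = cls.isin(classes)
    if not keep.any():
        raise ValueError(f"no species in classes {classes}")
    sub = table.values.loc[keep]
    carbons = pd.Series([parse_lipid_name(s)[1] for s in sub.index], index=sub.index)
    # per replicate: total abundance per carbon bin
    binned = sub.groupby(carbons).sum()  # carbon x replicate

    groups = table.groups
    group_names = sorted(groups.unique())
    cells: dict[tuple[int, str], np.ndarray] = {}
    for carbon in binned.index:
        for g in group_names:
            cells[(carbon, g)] = binned.loc[carbon, groups.index[groups == g]].to_numpy(dtype=float)
    ss_within = sum(((c - c.mean()) ** 2).sum() for c in cells.values() if len(c))
    df_within = sum(max(len(c) - 1, 0) for c in cells.values())

    rows = []
    for carbon in binned.index:
        arrays = [cells[(carbon, g)] for g in group_names]
        grand = np.concatenate(arrays).mean()
        scale = max(1.0, abs(grand))
        means_equal = all(abs(a.mean() - grand) <= 1e-10 * scale for a in arrays)
        if means_equal:
            p = 1.0  # covers the zero-variance degenerate case too
        elif df_within > 0 and ss_within > 0 and all(len(a) >= 2 for a in arrays):
            mse = ss_within / df_within
            ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
            f_stat = (ss_between / (len(arrays) - 1)) / mse
            p = float(scipy.stats.f.sf(f_stat, len(arrays) - 1, df_within))
        else:
            p = np.nan
        for g, a in zip(group_names, arrays):
            rows.append(
                {
                    "carbon": int(carbon),
                    "group": g,
                    "mean": float(a.mean()) if len(a) else np.nan,
                    "sd": float(a.std(ddof=1)) if len(a) > 1 else np.nan,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)
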