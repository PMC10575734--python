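import numpy as np
import pandas as pd
import pytest
import scipy.stats

from persistkit import synthetic
from persistkit.lipidomics import (
    LipidTable,
    chainlength_profile,
    class_composition,
    classify_change,
    common_hits,
    differential_species,
    log2_impute,
    normalize_to_dna,
    parse_lipid_name,
)


class TestParseLipidName:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("PE-P 38:4", ("PE-P", 38, 4)),
            ("HexCer 42:1", ("HexCer", 42, 1)),
            ("PC 34:2", ("PC", 34, 2)),
            ("  SM 36:1 ", ("SM", 36, 1)),
        ],
    )
    def test_valid_names(self, name, expected):
        assert parse_lipid_name(name) == expected

    @pytest.mark.parametrize("name", ["XYZ 10:0", "PC34:2", "PC 34", "PE-Q 38:4"])
    def test_invalid_names(self, name):
        with pytest.raises(ValueError):
            parse_lipid_name(name)


def _table(values, groups):
    return LipidTable(values=values, groups=pd.Series(groups, index=values.columns))


class TestNormalizeToDna:
    def test_division_by_dna_mass(self):
        raw = pd.DataFrame({"r1": [10.0], "r2": [10.0]}, index=["PC 34:2"])
        table = normalize_to_dna(raw, pd.Series({"r1": 2.0, "r2": 1.0}),
                                 pd.Series({"r1": "a", "r2": "b"}))
        assert table.values.loc["PC 34:2", "r1"] == 5.0
        assert table.values.loc["PC 34:2", "r2"] / table.values.loc["PC 34:2", "r1"] == 2.0

    def test_nonpositive_dna_rejected(self):
        raw = pd.DataFrame({"r1": [10.0]}, index=["PC 34:2"])
        with pytest.raises(ValueError, match="DNA"):
            normalize_to_dna(raw, pd.Series({"r1": 0.0}), pd.Series({"r1": "a"}))


class TestLog2Impute:
    def test_no_zeros_means_pure_log2_no_randomness(self, rng):
        vals = pd.DataFrame(rng.uniform(1, 100, (5, 4)),
                            index=[f"PC {30 + i}:0" for i in range(5)],
                            columns=list("abcd"))
        table = _table(vals, ["g1", "g1", "g2", "g2"])
        out1, mask1 = log2_impute(table, seed=1)
        out2, _ = log2_impute(table, seed=2)  # different seed, same result
        pd.testing.assert_frame_equal(out1, np.log2(vals))
        pd.testing.assert_frame_equal(out1, out2)
        assert not mask1.any().any()

    def test_seeded_imputation_reproducible(self, rng):
        vals = pd.DataFrame(rng.uniform(1, 100, (10, 3)),
                            index=[f"PC {30 + i}:0" for i in range(10)],
                            columns=list("abc"))
        vals.iloc[0, 0] = 0.0
        vals.iloc[3, 2] = 0.0
        table = _table(vals, ["g1", "g1", "g2"])
        out1, mask = log2_impute(table, seed=7)
        out2, _ = log2_impute(table, seed=7)
        pd.testing.assert_frame_equal(out1, out2)
        assert mask.to_numpy().sum() == 2
        assert out1.iloc[0, 0] < np.log2(vals.iloc[1:, 0]).mean()  # downshifted

    def test_imputed_distribution_matches_downshifted_normal(self, rng):
        # one column: 5000 observed values, 10000 zeros to impute
        n_obs, n_zero = 5000, 10000
        observed = 2.0 ** rng.normal(5.0, 1.0, n_obs)
        vals = np.concatenate([observed, np.zeros(n_zero)])
        frame = pd.DataFrame({"r1": vals},
                             index=[f"PC {i}:0" for i in range(n_obs + n_zero)])
        table = _table(frame, ["g1"])
        out, mask = log2_impute(table, seed=0)
        m = np.log2(observed).mean()
        s = np.log2(observed).std(ddof=1)
        imputed = out.loc[mask["r1"], "r1"]
        assert imputed.mean() == pytest.approx(m - 1.8 * s, abs=3 * 0.3 * s / np.sqrt(n_zero))
        assert imputed.std(ddof=1) == pytest.approx(0.3 * s, rel=0.05)

    def test_all_zero_table_rejected(self):
        vals = pd.DataFrame({"a": [0.0], "b": [0.0]}, index=["PC 34:2"])
        with pytest.raises(ValueError, match="all"):
            log2_impute(_table(vals, ["g1", "g1"]))


class TestClassifyChange:
    def test_cutoffs_are_inclusive(self):
        assert classify_change(np.log2(1.5), 0.05, 1.5, 0.05) == "increased"
        assert classify_change(-np.log2(1.5), 0.05, 1.5, 0.05) == "decreased"
        assert classify_change(np.log2(1.49), 0.05, 1.5, 0.05) == "unchanged"
        assert classify_change(np.log2(2.0), 0.051, 1.5, 0.05) == "unchanged"


class TestDifferentialSpecies:
    @staticmethod
    def _log2_table(rows, columns, index):
        return pd.DataFrame(rows, index=index, columns=columns)

    def test_identical_groups_report_p_one_and_unchanged(self):
        table = self._log2_table([[2.0] * 9], list("abcdefghi"), ["Cer 34:1"])
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3 + ["g3"] * 3, index=list("abcdefghi"))
        res = differential_species(table, groups, reference="g1")
        assert (res["anova_p"] == 1.0).all()
        assert (res["call"] == "unchanged").all()

    def test_planted_shift_recovered_with_closed_form_f(self):
        rng = np.random.default_rng(1)
        base = rng.normal(3.0, 0.1, (1, 9))
        base[0, 3:6] += 1.0  # +1 log2 in g2
        cols = list("abcdefghi")
        table = self._log2_table(base, cols, ["Cer 34:1"])
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3 + ["g3"] * 3, index=cols)
        res = differential_species(table, groups, reference="g1")
        g2 = res[res["comparison"] == "g2_vs_g1"].iloc[0]
        assert g2["call"] == "increased"
        assert g2["posthoc_p"] < 1e-4
        # ANOVA F from the textbook between/within decomposition
        arrays = [base[0, :3], base[0, 3:6], base[0, 6:9]]
        grand = np.concatenate(arrays).mean()
        ss_b = sum(3 * (a.mean() - grand) ** 2 for a in arrays)
        ss_w = sum(((a - a.mean()) ** 2).sum() for a in arrays)
        f_expected = (ss_b / 2) / (ss_w / 6)
        p_expected = scipy.stats.f.sf(f_expected, 2, 6)
        assert g2["anova_p"] == pytest.approx(p_expected, rel=1e-10)

    def test_group_swap_flips_fc_and_preserves_p(self):
        rng = np.random.default_rng(5)
        cols = list("abcdef")
        table = self._log2_table(rng.normal(2, 0.5, (4, 6)), cols,
                                 [f"PC {30 + i}:0" for i in range(4)])
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=cols)
        fwd = differential_species(table, groups, reference="g1")
        rev = differential_species(table, groups, reference="g2")
        assert np.allclose(fwd["log2_fc"], -rev["log2_fc"])
        assert np.allclose(fwd["posthoc_p"], rev["posthoc_p"])
        assert np.allclose(fwd["anova_p"], rev["anova_p"])

    def test_lsd_posthoc_alternative(self):
        rng = np.random.default_rng(2)
        cols = list("abcdef")
        base = rng.normal(2, 0.1, (1, 6))
        base[0, 3:] += 2.0
        table = self._log2_table(base, cols, ["Cer 34:1"])
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=cols)
        res = differential_species(table, groups, reference="g1", posthoc="lsd")
        assert res.iloc[0]["call"] == "increased"

    def test_too_few_replicates_rejected(self):
        table = self._log2_table([[1.0, 2.0, 3.0]], list("abc"), ["Cer 34:1"])
        groups = pd.Series(["g1", "g1", "g2"], index=list("abc"))
        with pytest.raises(ValueError, match=">= 2"):
            differential_species(table, groups, reference="g1")

    def test_imputation_dominated_flagging(self):
        cols = list("abcdef")
        table = self._log2_table([[1.0, 1.1, 0.9, 3.0, 3.1, 2.9]], cols, ["Cer 34:1"])
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=cols)
        mask = pd.DataFrame([[True, True, False, True, True, False]], index=["Cer 34:1"],
                            columns=cols)
        res = differential_species(table, groups, reference="g1", imputed_mask=mask)
        assert res.iloc[0]["imputation_dominated"]


class TestCommonHits:
    @staticmethod
    def _calls(mapping):
        return pd.DataFrame(
            [{"species_id": s, "call": c} for s, c in mapping.items()]
        )

    def test_pairwise_intersection(self):
        a = self._calls({"x": "increased", "y": "increased", "q": "unchanged"})
        b = self._calls({"y": "increased", "z": "increased", "q": "decreased"})
        rep = common_hits({"A": a, "B": b})
        assert rep["increased"]["common"] == ["y"]
        assert rep["decreased"]["common"] == []

    def test_region_counts_match_set_algebra(self):
        rng = np.random.default_rng(4)
        species = [f"PC {i}:0" for i in range(30)]
        frames = {}
        truth = {}
        for name in ("A", "B", "C"):
            calls = rng.choice(["increased", "unchanged"], size=30, p=[0.4, 0.6])
            frames[name] = pd.DataFrame({"species_id": species, "call": calls})
            truth[name] = {s for s, c in zip(species, calls) if c == "increased"}
        rep = common_hits(frames)
        regions = rep["increased"]["regions"]
        for pattern, count in regions.items():
            members = [
                s for s in species
                if tuple(s in truth[n] for n in ("A", "B", "C")) == pattern
                and any(pattern)
            ]
            assert count == len(members)
        assert set(rep["increased"]["common"]) == truth["A"] & truth["B"] & truth["C"]

    def test_needs_two_comparisons(self):
        with pytest.raises(ValueError):
            common_hits({"A": self._calls({"x": "increased"})})


class TestClassComposition:
    def test_two_classes_split(self):
        vals = pd.DataFrame({"r1": [30.0, 70.0]}, index=["PC 34:2", "TG 52:3"])
        comp = class_composition(_table(vals, ["g1"]))
        assert sorted(comp["percent"]) == pytest.approx([30.0, 70.0])

    def test_single_class_is_hundred(self):
        vals = pd.DataFrame({"r1": [5.0], "r2": [7.0]}, index=["PC 34:2"])
        comp = class_composition(_table(vals, ["g1", "g1"]))
        assert comp["percent"].tolist() == [100.0]

    def test_four_class_arithmetic_and_sum(self):
        vals = pd.DataFrame({"r1": [1.0, 2.0, 3.0, 4.0]},
                            index=["PC 34:2", "PE 36:2", "TG 52:3", "SM 36:1"])
        comp = class_composition(_table(vals, ["g1"]))
        assert sorted(comp["percent"]) == pytest.approx([10.0, 20.0, 30.0, 40.0])
        assert comp["percent"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_percentages_sum_to_hundred_per_group(self):
        spec = synthetic.LipidomeSpec(seed=12)
        table = synthetic.simulate_lipidome(spec)
        comp = class_composition(table)
        sums = comp.groupby("group")["percent"].sum()
        assert np.allclose(sums, 100.0, atol=1e-9)


class TestChainlengthProfile:
    def test_single_species_profile_is_its_group_means(self):
        vals = pd.DataFrame({"a": [2.0], "b": [4.0], "c": [6.0], "d": [8.0]},
                            index=["Cer 34:1"])
        prof = chainlength_profile(_table(vals, ["g1", "g1", "g2", "g2"]), "Cer")
        assert prof.loc[prof["group"] == "g1", "mean"].iloc[0] == 3.0
        assert prof.loc[prof["group"] == "g2", "mean"].iloc[0] == 7.0

    def test_identical_groups_flat_p(self, rng):
        vals = pd.DataFrame(
            np.tile(rng.uniform(1, 5, (4, 1)), (1, 6)),
            index=["Cer 34:1", "Cer 36:1", "Cer 40:2", "Cer 42:2"],
            columns=list("abcdef"),
        )
        prof = chainlength_profile(_table(vals, ["g1"] * 3 + ["g2"] * 3), "Cer")
        assert (prof["p_value"] == 1.0).all()

    def test_planted_bin_shift_flagged(self, rng):
        index = [f"Cer {c}:1" for c in (34, 36, 38, 40)]
        base = rng.normal(4.0, 0.1, (4, 8))
        base[2, 4:] += 3.0  # carbon-38 bin raised in group 2
        vals = pd.DataFrame(base, index=index, columns=list("abcdefgh"))
        prof = chainlength_profile(_table(vals, ["g1"] * 4 + ["g2"] * 4), "Cer")
        p_by_carbon = prof.drop_duplicates("carbon").set_index("carbon")["p_value"]
        assert p_by_carbon[38] < 1e-6
        assert (p_by_carbon.drop(38) > 0.05).all()

    def test_empty_filter_rejected(self):
        vals = pd.DataFrame({"a": [1.0], "b": [1.0]}, index=["PC 34:2"])
        with pytest.raises(ValueError, match="no species"):
            chainlength_profile(_table(vals, ["g1", "g2"]), "Cer")


class TestPipelineRecovery:
    def test_planted_cer_effect_recovered_with_low_false_calls(self):
        classes = {c: (n, m, 0.2) for c, (n, m, _) in synthetic._DEFAULT_CLASSES.items()}
        sens, fp = [], []
        for seed in range(20):
            spec = synthetic.LipidomeSpec(
                classes=classes, groups={"groupA": 3, "groupB": 3},
                effect_map={("Cer", "groupB"): 1.0}, zero_rate=0.1, seed=seed,
            )
            table = synthetic.simulate_lipidome(spec)
            log2_table, mask = log2_impute(table, seed=seed)
            diff = differential_species(log2_table, table.groups, reference="groupA")
            is_cer = diff["species_id"].str.match(r"Cer ")
            sens.append((diff.loc[is_cer, "call"] == "increased").mean())
            fp.append((diff.loc[~is_cer, "call"] != "unchanged").mean())
        assert np.mean(sens) >= 0.9
        assert np.mean(fp) <= 0.05
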