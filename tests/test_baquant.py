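"""Bile-acid quantification, classification, and differential analysis."""

import numpy as np
import pandas as pd
import pytest

from rumenba.baquant import (DEFAULT_SCHEME, EXOGENOUS_BAS,
                             MUTUAL_DIFFERENTIAL_BAS, ConcentrationMatrix,
                             DifferentialConfig, classify_bas,
                             differential_bas, dilute_concentration,
                             mutual_differentials, normalize_ba_name,
                             pool_totals, transformed_fraction)


def matrix_from(values: dict, groups: list[str]) -> ConcentrationMatrix:
    df = pd.DataFrame(values, index=[f"s{i}" for i in range(len(groups))])
    return ConcentrationMatrix(values=df,
                               groups=pd.Series(groups, index=df.index))


class TestDilution:
    def test_formula(self):
        assert dilute_concentration(100, 50, 25) == 200

    def test_identity_when_volumes_equal(self):
        assert dilute_concentration(73.5, 40, 40) == 73.5

    def test_zero_concentration(self):
        assert dilute_concentration(0, 100, 10) == 0

    def test_zero_sample_volume_rejected(self):
        with pytest.raises(ValueError):
            dilute_concentration(10, 10, 0)


class TestNames:
    @pytest.mark.parametrize("raw,canonical", [
        ("isolithocholic acid (isoLCA)", "isoLCA"),
        ("3-epideoxycholic acid (3-epiDCA)", "3-epiDCA"),
        ("HDCA", "HDCA"),
        ("hdca", "HDCA"),
        ("ω-muricholic acid (ω-MCA)", "ω-MCA"),
        ("omega-MCA", "ω-MCA"),
        ("murideoxycholic acid (MDCA)", "MDCA"),
        ("allocholic acid (alloCA)", "alloCA"),
        ("dehydrolithocholic acid (DHLCA)", "DHLCA"),
        ("glycolithocholic acid-3-sulfate (GlyLCA-3-sulfate)",
         "GlyLCA-3-sulfate"),
        ("ursodeoxycholic acid", "UDCA"),
    ])
    def test_printed_names_normalise(self, raw, canonical):
        assert normalize_ba_name(raw) == canonical

    def test_idempotence(self):
        for name in MUTUAL_DIFFERENTIAL_BAS:
            assert normalize_ba_name(normalize_ba_name(name)) == \
                normalize_ba_name(name)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize_ba_name("   ")


class TestClassification:
    @pytest.mark.parametrize("name,cls", [
        ("CDCA", "primary"), ("CA", "primary"), ("3β-CA", "primary"),
        ("GCA-3-sulfate", "primary"),
        ("HDCA", "secondary"), ("UDCA", "secondary"), ("alloCA", "secondary"),
        ("DHLCA", "unclassified"), ("6-ketoLCA", "unclassified"),
        ("UCA", "unclassified"),
        ("TCA", "unknown"),
    ])
    def test_scheme_assignment(self, name, cls):
        assert classify_bas([name])[name] == cls

    def test_scheme_sets_disjoint(self):
        assert not (DEFAULT_SCHEME.primary & DEFAULT_SCHEME.secondary)
        assert not (DEFAULT_SCHEME.primary & DEFAULT_SCHEME.unclassified)
        assert not (DEFAULT_SCHEME.secondary & DEFAULT_SCHEME.unclassified)

    def test_every_name_gets_exactly_one_class(self):
        names = MUTUAL_DIFFERENTIAL_BAS + ["TCA", "made-up-acid"]
        classes = classify_bas(names)
        assert set(classes) == set(names)
        assert set(classes.values()) <= {"primary", "secondary",
                                         "unclassified", "unknown"}


class TestPools:
    def test_worked_example(self):
        m = matrix_from({"CA": [10.0], "HDCA": [5.0], "DHLCA": [1.0]}, ["g"])
        row = pool_totals(m).iloc[0]
        assert (row.primary_total, row.secondary_total, row.total) == \
            (10.0, 5.0, 16.0)

    def test_empty_matrix_zeros(self):
        m = matrix_from({"CA": [np.nan]}, ["g"])
        row = pool_totals(m).iloc[0]
        assert row.total == 0.0

    def test_totals_match_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        names = MUTUAL_DIFFERENTIAL_BAS[:8]
        vals = {n: rng.exponential(10, 4) for n in names}
        m = matrix_from(vals, ["a"] * 4)
        out = pool_totals(m)
        classes = classify_bas(names)
        for i, sample in enumerate(m.values.index):
            p = sum(vals[n][i] for n in names if classes[n] == "primary")
            s = sum(vals[n][i] for n in names if classes[n] == "secondary")
            t = sum(vals[n][i] for n in names)
            assert out.loc[sample, "primary_total"] == pytest.approx(p)
            assert out.loc[sample, "secondary_total"] == pytest.approx(s)
            assert out.loc[sample, "total"] == pytest.approx(t)
            assert p + s <= t + 1e-12

    def test_linearity_in_concentrations(self):
        rng = np.random.default_rng(1)
        names = ["CA", "HDCA", "DHLCA", "LCA"]
        vals = {n: rng.exponential(5, 3) for n in names}
        m1 = matrix_from(vals, ["g"] * 3)
        m3 = matrix_from({n: 3 * v for n, v in vals.items()}, ["g"] * 3)
        t1 = pool_totals(m1)[["primary_total", "secondary_total", "total"]]
        t3 = pool_totals(m3)[["primary_total", "secondary_total", "total"]]
        assert np.allclose(3 * t1.to_numpy(), t3.to_numpy())


class TestTransformedFraction:
    def test_only_exogenous_gives_zero(self):
        means = pd.Series({"CA": 10.0, "HCA": 5.0})
        assert transformed_fraction(means) == 0.0

    def test_only_non_exogenous_gives_one(self):
        means = pd.Series({"UDCA": 2.0, "LCA": 3.0})
        assert transformed_fraction(means) == 1.0

    def test_always_in_unit_interval(self):
        rng = np.random.default_rng(3)
        names = list(EXOGENOUS_BAS) + ["UDCA", "LCA", "6-ketoLCA"]
        for _ in range(20):
            means = pd.Series(rng.exponential(10, len(names)), index=names)
            assert 0.0 <= transformed_fraction(means) <= 1.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            transformed_fraction(pd.Series({"CA": 0.0}))


class TestDifferential:
    def _matrix(self, rng, effect, n=6, cv=0.1, n_bas=6):
        names = [f"BA{i}" for i in range(n_bas)]
        base = {n_: 100.0 for n_ in names}
        rows = {}
        for name in names:
            mult = effect if name == "BA0" else 1.0
            control = base[name] * rng.lognormal(0, cv, n)
            treated = base[name] * mult * rng.lognormal(0, cv, n)
            rows[name] = np.concatenate([control, treated])
        return matrix_from(rows, ["control"] * n + ["treated"] * n)

    def test_planted_fivefold_effect_detected(self):
        rng = np.random.default_rng(21)
        m = self._matrix(rng, 5.0)
        out = differential_bas(m, ("control", "treated"))
        row = out[out.name == "BA0"].iloc[0]
        assert row.significant and row.direction == 1.0 and row.vip > 1.0

    def test_zero_variance_ba_flagged_non_significant(self):
        rng = np.random.default_rng(2)
        vals = {"BA0": rng.lognormal(0, 0.1, 12),
                "FLAT": np.full(12, 7.0)}
        m = matrix_from(vals, ["control"] * 6 + ["treated"] * 6)
        out = differential_bas(m, ("control", "treated"))
        flat = out[out.name == "FLAT"].iloc[0]
        assert not flat.significant and flat.degenerate and np.isnan(flat.vip)

    def test_joint_rule_never_more_permissive_than_p_rule(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            m = self._matrix(rng, 1.0)
            out = differential_bas(m, ("control", "treated"))
            assert set(out.index[out.significant]) <= \
                set(out.index[out.p < 0.05])

    def test_requires_three_samples_per_group(self):
        m = matrix_from({"BA0": [1.0, 2.0, 3.0, 4.0]},
                        ["control", "control", "treated", "treated"])
        with pytest.raises(ValueError):
            differential_bas(m, ("control", "treated"))

    def test_wilcoxon_option(self):
        rng = np.random.default_rng(31)
        m = self._matrix(rng, 6.0)
        out = differential_bas(m, ("control", "treated"),
                               DifferentialConfig(test="wilcoxon"))
        assert out[out.name == "BA0"].iloc[0].significant


class TestMutual:
    def test_simple_intersection(self):
        assert mutual_differentials({"UDCA", "HDCA"}, {"HDCA", "LCA"}) == \
            ["HDCA"]

    def test_identical_lists(self):
        lst = ["CA", "LCA", "UDCA"]
        assert mutual_differentials(lst, lst) == sorted(lst)

    def test_printed_mutual_list_consistency(self):
        # The in-vitro differential list contains the mutual list, so their
        # intersection is the 15-item mutual list itself.
        in_vitro = ["HDCA", "LCA", "6-ketoLDA", "isoHDCA", "MDCA", "UDCA",
                    "7-ketoLCA", "DHCA", "UCA", "isolithocholic acid (isoLCA)",
                    "DCA", "DHLCA", "12-ketoLCA", "alloCA", "GlyLCA-3-sulfate",
                    "3-epiDCA", "7-ketoDCA", "CDCA-3-sulfate", "12-DHCA",
                    "UDCA-3-sulfate", "HCA", "CDCA", "CA", "3β-CA", "α-MCA",
                    "β-MCA", "ω-MCA", "3-DHCA"]
        mutual = mutual_differentials(in_vitro, MUTUAL_DIFFERENTIAL_BAS)
        assert sorted(mutual) == sorted(MUTUAL_DIFFERENTIAL_BAS)
        assert len(mutual) == 15

    def test_effect_ordering(self):
        out = mutual_differentials(["a", "b", "c"], ["a", "b", "c"],
                                   effects_a={"a": 1.0, "b": -3.0, "c": 2.0})
        assert out == ["b", "c", "a"]
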