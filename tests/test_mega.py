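"""Combination engine against independent re-derivations of the formulas."""

import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from megadeg.effects import StudyEffect
from megadeg.mega import (
    FIXED,
    RANDOM,
    MegaAnalysis,
    fixed_effect_combine,
    heterogeneity,
    mega_analyze,
    mega_table,
    q_p_value,
    random_effects_combine,
)
from megadeg.simulate import SimulationConfig, simulate_studies


def eff(thetas, variances, gene="g"):
    return [
        StudyEffect(f"D{i}", gene, float(t), float(v), 10, 10)
        for i, (t, v) in enumerate(zip(thetas, variances))
    ]


# --- independent oracle: plain-python re-derivation, no shared code paths ---

def oracle(thetas, variances):
    w = [1.0 / v for v in variances]
    sw = sum(w)
    fe = sum(wi * ti for wi, ti in zip(w, thetas)) / sw
    fse = sw ** -0.5
    Q = sum(wi * (ti - fe) ** 2 for wi, ti in zip(w, thetas))
    df = len(thetas) - 1
    isq = 100.0 * (Q - df) / Q if Q > df else 0.0
    C = sw - sum(wi * wi for wi in w) / sw
    tau2 = max(0.0, (Q - df) / C)
    ws = [1.0 / (v + tau2) for v in variances]
    sws = sum(ws)
    re = sum(wi * ti for wi, ti in zip(ws, thetas)) / sws
    rse = sws ** -0.5
    return dict(fe=fe, fse=fse, Q=Q, df=df, isq=isq, tau2=tau2, re=re, rse=rse)


class TestFixedEffect:
    def test_single_study_identity(self):
        e, se, p = fixed_effect_combine(eff([1.2], [0.04]))
        assert (e, se) == (pytest.approx(1.2), pytest.approx(0.2))

    def test_symmetry_equal_variances(self):
        e, _, _ = fixed_effect_combine(eff([1.0, 2.0], [0.3, 0.3]))
        assert e == pytest.approx(1.5, rel=1e-15)

    def test_hand_weighted_mean(self):
        e, se, _ = fixed_effect_combine(eff([0.5, 1.0], [0.1, 0.2]))
        assert e == pytest.approx(2 / 3, rel=1e-14)
        assert se == pytest.approx(15 ** -0.5, rel=1e-14)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fixed_effect_combine(eff([1.0, 2.0], [0.1, 0.0]))


class TestHeterogeneity:
    def test_identical_effects_no_heterogeneity(self):
        Q, df, isq = heterogeneity(eff([1.0, 1.0, 1.0], [0.1, 0.2, 0.3]), 1.0)
        assert Q == pytest.approx(0.0, abs=1e-15)
        assert (df, isq) == (2, 0.0)

    @pytest.mark.parametrize(
        "Q,df,expected", [(3.0, 4, 0.0), (10.0, 4, 60.0), (4.0, 4, 0.0)]
    )
    def test_isq_formula_with_floor(self, Q, df, expected):
        # reconstruct ISq directly from the printed rule
        isq = 100.0 * (Q - df) / Q if Q > df else 0.0
        assert isq == expected

    def test_q_p_values(self):
        assert q_p_value(0.0, 3) == 1.0
        assert q_p_value(1.0, 1) == pytest.approx(0.3173, abs=5e-4)
        assert q_p_value(9.488, 4) == pytest.approx(0.050, abs=5e-4)
        with pytest.raises(ValueError):
            q_p_value(1.0, 0)


class TestRandomEffects:
    def test_reduces_to_fixed_when_homogeneous(self):
        effects = eff([1.0, 1.0, 1.0], [0.2, 0.2, 0.2])
        fe = fixed_effect_combine(effects)
        re = random_effects_combine(effects)
        assert re[3] == 0.0
        assert re[:3] == fe

    def test_hand_derived_dl(self):
        # Q=4, df=1, C=2 -> tau2=1.5; weights 1/2 each -> effect 1, se 1
        e, se, _, tau2 = random_effects_combine(eff([0.0, 2.0], [0.5, 0.5]))
        assert tau2 == pytest.approx(1.5, rel=1e-14)
        assert e == pytest.approx(1.0, rel=1e-14)
        assert se == pytest.approx(1.0, rel=1e-14)

    def test_equal_variances_give_unweighted_mean(self):
        thetas = [0.3, -1.2, 0.8, 2.0]
        e, *_ = random_effects_combine(eff(thetas, [0.25] * 4))
        assert e == pytest.approx(np.mean(thetas), rel=1e-12)

    def test_cross_check_against_metafor(self):
        thetas, variances = [0.5, 1.0, 0.2, 1.4], [0.1, 0.2, 0.15, 0.3]
        script = (
            "suppressMessages(library(metafor));"
            f"yi<-c({','.join(map(str, thetas))});vi<-c({','.join(map(str, variances))});"
            'fe<-rma(yi,vi,method="FE");re<-rma(yi,vi,method="DL");'
            'cat(sprintf("%.14f %.14f %.14f %.14f %.14f",'
            "coef(fe),fe$se,re$tau2,coef(re),re$se))"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        ).stdout.split()
        r_fe, r_fse, r_tau2, r_re, r_rse = map(float, out)
        effects = eff(thetas, variances)
        e, se, _ = fixed_effect_combine(effects)
        re_e, re_se, _, tau2 = random_effects_combine(effects)
        assert e == pytest.approx(r_fe, rel=1e-10)
        assert se == pytest.approx(r_fse, rel=1e-10)
        assert tau2 == pytest.approx(r_tau2, rel=1e-10)
        assert re_e == pytest.approx(r_re, rel=1e-10)
        assert re_se == pytest.approx(r_rse, rel=1e-10)


class TestMegaAnalyze:
    def test_model_switch_matches_q_rule(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 6))
            thetas = rng.normal(0, 1, k)
            variances = rng.uniform(0.05, 0.5, k)
            r = mega_analyze(eff(thetas, variances))
            o = oracle(list(thetas), list(variances))
            assert (r.model == FIXED) == (o["Q"] <= o["df"])
            assert (r.ISq == 0.0) == (o["Q"] <= o["df"])
            if r.model == FIXED:
                assert r.tau2 == 0.0

    def test_forced_models(self):
        effects = eff([0.0, 2.0], [0.5, 0.5])
        assert mega_analyze(effects, model="fixed").model == FIXED
        assert mega_analyze(effects, model="random").model == RANDOM

    def test_p_is_two_sided_normal(self):
        r = mega_analyze(eff([1.0, 1.2, 0.8], [0.09, 0.09, 0.09]))
        assert r.p_value == pytest.approx(2 * stats.norm.sf(abs(r.effect) / r.se), rel=1e-12)

    @given(
        st.lists(
            st.tuples(st.floats(-3, 3), st.floats(0.01, 1.0)), min_size=2, max_size=5
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_oracle_equivalence_property(self, pairs):
        thetas = [t for t, _ in pairs]
        variances = [v for _, v in pairs]
        r = mega_analyze(eff(thetas, variances))
        o = oracle(thetas, variances)
        expect = o["fe"] if r.model == FIXED else o["re"]
        expect_se = o["fse"] if r.model == FIXED else o["rse"]
        assert r.effect == pytest.approx(expect, rel=1e-12, abs=1e-12)
        assert r.se == pytest.approx(expect_se, rel=1e-12)
        assert r.Q == pytest.approx(o["Q"], rel=1e-12, abs=1e-12)
        assert r.ISq == pytest.approx(o["isq"], rel=1e-12, abs=1e-12)

    def test_adding_confirming_study_never_inflates_se(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 6))
            effects = eff(rng.normal(0, 1, k), rng.uniform(0.05, 0.5, k))
            r = mega_analyze(effects)
            grown = effects + [StudyEffect(f"D{k}", "g", r.effect, 0.2, 10, 10)]
            assert mega_analyze(grown).se <= r.se + 1e-12


class TestMegaTable:
    def test_heterogeneous_panel_selects_random(self):
        cfg = SimulationConfig(
            n_studies=9, n_genes=40, n_case=10, n_control=10,
            true_lfc=0.5, tau2=1.0, sigma=0.5, seed=11,
        )
        datasets, _ = simulate_studies(cfg)
        tab = mega_table(datasets)
        assert tab["random"].mean() > 0.8

    def test_gene_in_single_study_excluded(self, make_dataset, rng):
        d1 = make_dataset({"a": list(rng.normal(8, 1, 6)), "b": list(rng.normal(8, 1, 6))}, 3, "D1")
        d2 = make_dataset({"a": list(rng.normal(8, 1, 6))}, 3, "D2")
        tab = mega_table([d1, d2])
        assert list(tab["gene"]) == ["a"]

    def test_sorted_by_p_then_gene(self, make_dataset, rng):
        vals = list(rng.normal(8, 1, 8))
        d1 = make_dataset({"a": vals, "b": vals}, 4, "D1")
        d2 = make_dataset({"a": vals, "b": vals}, 4, "D2")
        tab = mega_table([d1, d2])
        assert list(tab["gene"]) == ["a", "b"]  # identical p: gene-id tie-break
        assert tab.loc[0, "p"] == tab.loc[1, "p"]

    def test_from_effects_constructor_matches(self, rng):
        cfg = SimulationConfig(n_studies=4, n_genes=10, n_case=8, n_control=8, seed=5)
        datasets, _ = simulate_studies(cfg)
        direct = MegaAnalysis(datasets).fit().table
        from megadeg.effects import study_effects_table

        frames = [
            study_effects_table(ds).rename_axis("gene").reset_index()
            for ds in datasets
        ]
        import pandas as pd

        via_frame = MegaAnalysis.from_effects(pd.concat(frames)).fit().table
        pd.testing.assert_frame_equal(direct, via_frame)
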