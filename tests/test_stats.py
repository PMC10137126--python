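import numpy as np
import pandas as pd
import pytest

from tempogate.epochs import TRIAL_COLUMNS, BehaviorTable
from tempogate.errors import (EmptyCellError, IncompleteDesignError,
                              ParameterError)
from tempogate.simulate import generate_null_measure_table
from tempogate.stats import (behavior_stats, pairwise_bonferroni,
                             rm_anova_1way, rm_anova_2way,
                             run_gated_analysis, simple_effects_tp)

from conftest import random_measure_table
from oracles import (paired_t_loop, rm_anova_1way_loop,
                     rm_anova_2way_loop)


def add_effect(table, ma=None, tp=None, delta=1.0):
    out = table.copy()
    mask = np.ones(len(out), dtype=bool)
    if ma is not None:
        mask &= out["ma"] == ma
    if tp is not None:
        mask &= out["tp"] == tp
    out.loc[mask, "value"] += delta
    return out


class TestTwoWay:
    def test_df_structure_matches_the_design(self, rng):
        table = random_measure_table(rng, n_subjects=27)
        rep = rm_anova_2way(table)
        assert rep.effects["ma"].df == (1, 26)
        assert rep.effects["tp"].df == (2, 52)
        assert rep.effects["ma x tp"].df == (2, 52)

    def test_identical_values_report_zero_f(self):
        rows = [(f"S{i}", ma, tp, "m", 1.0) for i in range(5)
                for ma in ("a", "u") for tp in ("N", "M", "V")]
        table = pd.DataFrame(rows, columns=["subject", "ma", "tp",
                                            "measure", "value"])
        rep = rm_anova_2way(table)
        for eff in rep.effects.values():
            assert eff.F == 0.0 and eff.p == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_ss_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        table = random_measure_table(rng, n_subjects=n)
        rep = rm_anova_2way(table)
        values = {(r.subject, r.ma, r.tp): r.value
                  for r in table.itertuples()}
        ref = rm_anova_2way_loop(values)
        assert rep.effects["ma"].F == pytest.approx(ref["a"][0], abs=1e-8)
        assert rep.effects["tp"].F == pytest.approx(ref["b"][0], abs=1e-8)
        assert rep.effects["ma x tp"].F == pytest.approx(ref["ab"][0],
                                                         abs=1e-8)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        table = random_measure_table(rng, n_subjects=9)
        mine = rm_anova_2way(table)
        ref = pg.rm_anova(data=table, dv="value", within=["ma", "tp"],
                          subject="subject", detailed=True)
        by_source = {row["Source"]: row for _, row in ref.iterrows()}
        assert mine.effects["ma"].F == pytest.approx(by_source["ma"]["F"])
        assert mine.effects["tp"].F == pytest.approx(by_source["tp"]["F"])
        assert mine.effects["ma x tp"].F == pytest.approx(
            by_source["ma * tp"]["F"])
        assert mine.effects["tp"].p == pytest.approx(
            by_source["tp"]["p_unc"])

    def test_missing_cell_names_subject_and_cell(self, rng):
        table = random_measure_table(rng, n_subjects=4)
        table = table[~((table["subject"] == "S02")
                        & (table["tp"] == "VTP")
                        & (table["ma"] == "attended"))]
        with pytest.raises(IncompleteDesignError, match="S02"):
            rm_anova_2way(table)

    def test_affine_rescaling_leaves_f_and_eta_unchanged(self, rng):
        table = random_measure_table(rng, n_subjects=6)
        a = rm_anova_2way(table)
        table2 = table.copy()
        table2["value"] = 3.0 * table2["value"] - 7.0
        b = rm_anova_2way(table2)
        for k in a.effects:
            assert a.effects[k].F == pytest.approx(b.effects[k].F)
            assert a.effects[k].partial_eta_sq == pytest.approx(
                b.effects[k].partial_eta_sq)
            assert 0.0 <= a.effects[k].partial_eta_sq <= 1.0

    def test_subject_constant_shift_changes_no_f(self, rng):
        table = random_measure_table(rng, n_subjects=6)
        shifted = table.copy()
        shifted.loc[shifted["subject"] == "S03", "value"] += 100.0
        a, b = rm_anova_2way(table), rm_anova_2way(shifted)
        for k in a.effects:
            assert a.effects[k].F == pytest.approx(b.effects[k].F)


class TestSimpleEffects:
    def test_matches_one_way_oracle(self, rng):
        table = random_measure_table(rng, n_subjects=6)
        rep = simple_effects_tp(table, "attended")
        sub = table[table["ma"] == "attended"]
        values = {(r.subject, r.tp): r.value for r in sub.itertuples()}
        F, d1, d2 = rm_anova_1way_loop(values)
        assert rep.effects["tp"].F == pytest.approx(F, abs=1e-8)
        assert rep.effects["tp"].df == (d1, d2)

    def test_detects_effect_only_where_programmed(self, rng):
        table = random_measure_table(rng, n_subjects=12)
        table = add_effect(table, ma="attended", tp="VTP", delta=3.0)
        att = simple_effects_tp(table, "attended")
        una = simple_effects_tp(table, "unattended")
        assert att.effects["tp"].p < 0.001
        assert una.effects["tp"].p > 0.05

    def test_single_level_factor_rejected(self, rng):
        table = random_measure_table(rng, n_subjects=4,
                                     tp_levels=("NTP",))
        with pytest.raises(ParameterError, match="levels"):
            simple_effects_tp(table, "attended")


class TestPairwise:
    def test_bonferroni_arithmetic(self, rng):
        table = random_measure_table(rng, n_subjects=20)
        contrasts = pairwise_bonferroni(table.groupby(
            ["subject", "tp"], sort=False)["value"].mean().reset_index())
        assert len(contrasts) == 3
        for c in contrasts:
            assert c.p_adj == pytest.approx(min(1.0, c.p_raw * 3))

    def test_identical_paired_samples_report_p_one(self):
        rows = [(f"S{i}", "a", tp, "m", float(i)) for i in range(5)
                for tp in ("N", "M")]
        table = pd.DataFrame(rows, columns=["subject", "ma", "tp",
                                            "measure", "value"])
        (c,) = pairwise_bonferroni(table, factor="tp")
        assert c.p_raw == 1.0 and c.p_adj == 1.0 and c.t == 0.0

    def test_paired_t_matches_textbook_formula(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        rows = [(f"S{i}", "a", "N", "m", x[i]) for i in range(12)]
        rows += [(f"S{i}", "a", "M", "m", y[i]) for i in range(12)]
        table = pd.DataFrame(rows, columns=["subject", "ma", "tp",
                                            "measure", "value"])
        (c,) = pairwise_bonferroni(table, factor="tp")
        t_ref, p_ref = paired_t_loop(x, y)
        assert c.t == pytest.approx(t_ref, abs=1e-10)
        assert c.p_raw == pytest.approx(p_ref, abs=1e-10)

    def test_unpaired_data_rejected(self, rng):
        table = random_measure_table(rng, n_subjects=4)
        table = table[~((table["subject"] == "S01")
                        & (table["tp"] == "VTP"))]
        with pytest.raises(IncompleteDesignError, match="unpaired"):
            pairwise_bonferroni(table)


class TestGated:
    def test_interaction_takes_simple_effects_branch(self, rng):
        table = random_measure_table(rng, n_subjects=12)
        table = add_effect(table, ma="attended", tp="VTP", delta=-3.0)
        rep = run_gated_analysis(table)
        assert rep.branch == "simple_effects"
        assert set(rep.simple_effects) == {"attended", "unattended"}
        assert rep.simple_effects["attended"].effects["tp"].p < 0.01
        assert rep.simple_effects["attended"].pairwise  # pairs were run

    def test_main_effect_only_takes_main_branch(self, rng):
        table = random_measure_table(rng, n_subjects=12)
        table = add_effect(table, ma="attended", delta=3.0)  # all TP alike
        rep = run_gated_analysis(table)
        assert rep.branch == "main_effects"
        assert rep.main_effects["ma"].p < 0.001

    def test_gate_keeps_null_pairwise_claims_near_alpha(self):
        rng = np.random.default_rng(99)
        hits = 0
        n_sim = 300
        for _ in range(n_sim):
            table = generate_null_measure_table(10, 15, rng)
            rep = run_gated_analysis(table)
            if rep.significant_pairwise():
                hits += 1
        rate = hits / n_sim
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert rate <= 0.05 + 2 * se


class TestBehavior:
    @staticmethod
    def frame(rt_by_tp, acc=1.0, n_subjects=6, n_trials=10, sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_subjects):
            for ma in ("attended", "unattended"):
                for tp, rt in rt_by_tp.items():
                    for t in range(n_trials):
                        rows.append((f"S{i:02d}", ma, tp, t,
                                     rng.random() < acc,
                                     rt + rng.normal(0, sd)))
        return pd.DataFrame(rows, columns=TRIAL_COLUMNS)

    def test_equal_rts_give_zero_f(self):
        bt = BehaviorTable(frame=self.frame(
            {"NTP": 0.3, "MTP": 0.3, "VTP": 0.3}))
        out = behavior_stats(bt)
        assert out["anova"][("rt_mean_s", "attended")].effects["tp"].F == 0.0

    def test_degenerate_accuracy_is_reported_not_crashed(self):
        bt = BehaviorTable(frame=self.frame(
            {"NTP": 0.3, "MTP": 0.4, "VTP": 0.5}, acc=1.0, sd=0.01))
        out = behavior_stats(bt)
        acc_rep = out["anova"][("accuracy", "attended")].effects["tp"]
        assert acc_rep.F == 0.0 and acc_rep.p == 1.0

    def test_programmed_rt_ordering_detected(self):
        bt = BehaviorTable(frame=self.frame(
            {"NTP": 0.29, "MTP": 0.44, "VTP": 0.60}, n_subjects=10,
            n_trials=20, sd=0.06, seed=3))
        out = behavior_stats(bt)
        rep = out["anova"][("rt_mean_s", "attended")]
        assert rep.effects["tp"].p < 0.001
        assert all(c.p_adj < 0.001 for c in rep.pairwise)
        means = (out["summary"].query("ma == 'attended'")
                 .groupby("tp")["rt_mean_s"].mean())
        assert means["NTP"] < means["MTP"] < means["VTP"]

    def test_empty_cell_is_an_error(self):
        frame = self.frame({"NTP": 0.3, "MTP": 0.3, "VTP": 0.3})
        frame.loc[(frame["subject"] == "S00") & (frame["tp"] == "VTP"),
                  "correct"] = False
        with pytest.raises(EmptyCellError, match="S00"):
            behavior_stats(BehaviorTable(frame=frame))
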