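import numpy as np
import pandas as pd
import pytest

from oracles import ssgsea_oracle
from tilarch.errors import ValidationError
from tilarch.genomics import (
    GeneSet,
    bh_fdr,
    de_between_risk_groups,
    mutation_risk_association,
    per_gene_survival,
    read_gmt,
    risk_correlated_genes,
    signature_group_test,
    ssgsea,
)
from tilarch.synthetic import simulate_survival_times


def _expr(rng, n_genes=50, n_samples=30, prefix="S"):
    samples = [f"{prefix}{i}" for i in range(n_samples)]
    genes = [f"G{j}" for j in range(n_genes)]
    return pd.DataFrame(rng.uniform(10, 200, size=(n_genes, n_samples)),
                        index=genes, columns=samples)


class TestRiskCorrelatedGenes:
    def test_gene_equal_to_risk_is_perfectly_correlated(self, rng):
        expr = _expr(rng, 5, 20)
        risk = pd.Series(rng.normal(size=20), index=expr.columns)
        expr.loc["G0"] = risk.to_numpy()
        out = risk_correlated_genes(expr, risk)
        assert out.loc["G0", "r"] == pytest.approx(1.0)
        assert out.loc["G0", "p"] < 1e-10 and out.loc["G0", "selected"]

    def test_exact_linear_three_samples(self):
        expr = pd.DataFrame({"S0": [1.0], "S1": [2.0], "S2": [3.0]}, index=["G0"])
        risk = pd.Series([2.0, 4.0, 6.0], index=["S0", "S1", "S2"])
        out = risk_correlated_genes(expr, risk)
        assert out.loc["G0", "r"] == pytest.approx(1.0)

    def test_residualized_gene_rarely_selected(self):
        hits = 0
        seeds = 20
        for s in range(seeds):
            r = np.random.default_rng(s)
            risk = pd.Series(r.normal(size=50),
                             index=[f"S{i}" for i in range(50)])
            g = r.normal(size=50)
            z = risk.to_numpy()
            g = g - z * (g @ z) / (z @ z)  # orthogonal to risk
            expr = pd.DataFrame([g], index=["G0"], columns=risk.index)
            out = risk_correlated_genes(expr, risk)
            hits += bool(out.loc["G0", "selected"])
        assert hits <= 0.1 * seeds

    def test_constant_gene_excluded(self, rng):
        expr = _expr(rng, 3, 20)
        expr.loc["G0"] = 7.0
        risk = pd.Series(rng.normal(size=20), index=expr.columns)
        out = risk_correlated_genes(expr, risk)
        assert "G0" not in out.index


class TestDifferentialExpression:
    def test_label_permutation_of_identical_samples_selects_nothing(self, rng):
        half = rng.uniform(10, 100, size=(40, 15))
        expr = pd.DataFrame(np.hstack([half, half]),
                            index=[f"G{j}" for j in range(40)],
                            columns=[f"S{i}" for i in range(30)])
        groups = pd.Series(["high"] * 15 + ["low"] * 15, index=expr.columns)
        out = de_between_risk_groups(expr, groups)
        assert not out["selected"].any()

    def test_planted_fourfold_genes_recovered(self):
        recovered, false_sel = [], []
        for s in range(3):
            r = np.random.default_rng(s)
            n = 30
            genes = [f"G{j}" for j in range(1000)]
            base = r.normal(50, 10, size=(1000, 2 * n)).clip(1)
            base[:10, :n] *= 4.0  # planted genes up in the high group
            expr = pd.DataFrame(base, index=genes,
                                columns=[f"S{i}" for i in range(2 * n)])
            groups = pd.Series(["high"] * n + ["low"] * n, index=expr.columns)
            out = de_between_risk_groups(expr, groups)
            sel = set(out.index[out["selected"]])
            recovered.append(len(sel & set(genes[:10])))
            false_sel.append(len(sel - set(genes[:10])))
        assert np.mean(recovered) >= 9
        assert np.mean(false_sel) <= 0.05 * (np.mean(recovered) + 1)

    def test_bh_hand_formula(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_bh_monotone_and_dominates_p(self, rng):
        p = rng.uniform(size=100)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_small_group_rejected(self, rng):
        expr = _expr(rng, 5, 4)
        groups = pd.Series(["high", "low", "low", "low"], index=expr.columns)
        with pytest.raises(ValidationError):
            de_between_risk_groups(expr, groups)


class TestSsgsea:
    def test_all_genes_set_is_normalization_fixed_point(self, rng):
        expr = _expr(rng, 20, 8)
        scores = ssgsea(expr, GeneSet("all", list(expr.index)))
        np.testing.assert_allclose(scores.to_numpy(),
                                   scores.iloc[0], rtol=1e-9)

    def test_matches_bruteforce_running_sum(self, rng):
        expr = _expr(rng, 40, 6)
        members = list(rng.choice(expr.index, 8, replace=False))
        for alpha in (0.0, 0.75, 1.0):
            scores = ssgsea(expr, GeneSet("s", members), alpha=alpha)
            for sample in expr.columns:
                expected = ssgsea_oracle(expr[sample].to_numpy(),
                                         list(expr.index), set(members), alpha)
                assert scores[sample] == pytest.approx(expected, rel=1e-9)

    def test_top_gene_alpha_zero_hand_trace(self):
        # 4 genes, set = {top gene}, alpha=0: increment 1 at the top, then
        # three decrements of 1/3 -> running sums 1, 2/3, 1/3, 0, integral 2.
        # Extremes: member at top gives +2, at bottom -2, so range is 4 and
        # the normalized activity index is 2/4 = 0.5.
        expr = pd.DataFrame({"S0": [40.0, 30.0, 20.0, 10.0]},
                            index=["A", "B", "C", "D"]).T
        score = ssgsea(expr.T, GeneSet("top", ["A"]), alpha=0.0)
        assert score["S0"] == pytest.approx(0.5)

    def test_shift_invariance_per_sample(self, rng):
        expr = _expr(rng, 30, 5)
        gs = GeneSet("s", list(rng.choice(expr.index, 6, replace=False)))
        shifted = expr + 123.0
        np.testing.assert_allclose(ssgsea(expr, gs).to_numpy(),
                                   ssgsea(shifted, gs).to_numpy(), rtol=1e-9)

    def test_absent_members_dropped_empty_set_rejected(self, rng):
        expr = _expr(rng, 10, 4)
        with pytest.raises(ValidationError):
            ssgsea(expr, GeneSet("none", ["NOPE1", "NOPE2"]))

    def test_gmt_roundtrip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("sig1\tdesc\tG1\tG2\nsig2\tdesc\tG3\n")
        sets = read_gmt(path)
        assert [s.name for s in sets] == ["sig1", "sig2"]
        assert sets[0].genes == ["G1", "G2"]


class TestSignatureGroupTest:
    def test_exact_p_for_separated_triples(self):
        activity = pd.Series([4.0, 5.0, 6.0, 1.0, 2.0, 3.0],
                             index=[f"S{i}" for i in range(6)])
        groups = pd.Series(["high"] * 3 + ["low"] * 3, index=activity.index)
        out = signature_group_test(activity, groups)
        assert out["p"] == pytest.approx(0.1)
        assert out["direction"] == 1

    def test_type_i_error_calibrated(self):
        rejections = 0
        sims = 300
        for s in range(sims):
            r = np.random.default_rng(s)
            act = pd.Series(r.normal(size=60), index=[f"S{i}" for i in range(60)])
            groups = pd.Series(["high"] * 30 + ["low"] * 30, index=act.index)
            rejections += signature_group_test(act, groups)["p"] < 0.05
        rate = rejections / sims
        band = 2.6 * np.sqrt(0.05 * 0.95 / sims)
        assert abs(rate - 0.05) < band + 0.01

    def test_power_under_two_sigma_shift(self):
        hits = 0
        sims = 40
        for s in range(sims):
            r = np.random.default_rng(s)
            hi = r.normal(2.0, 1.0, 30)
            lo = r.normal(0.0, 1.0, 30)
            act = pd.Series(np.r_[hi, lo], index=[f"S{i}" for i in range(60)])
            groups = pd.Series(["high"] * 30 + ["low"] * 30, index=act.index)
            hits += signature_group_test(act, groups)["p"] < 0.01
        assert hits >= 0.95 * sims

    def test_all_tied_warns_p_one(self):
        act = pd.Series(np.ones(8), index=[f"S{i}" for i in range(8)])
        groups = pd.Series(["high"] * 4 + ["low"] * 4, index=act.index)
        with pytest.warns(UserWarning):
            out = signature_group_test(act, groups)
        assert out["p"] == 1.0


class TestMutationAssociation:
    def _surv(self, rng, risk):
        n = len(risk)
        t, e = simulate_survival_times(risk, 0.02, 0.005, rng)
        return pd.DataFrame({"patient_id": [f"S{i}" for i in range(n)],
                             "time": t, "event": e})

    def test_independent_mutation_rarely_significant(self):
        sig = 0
        sims = 20
        for s in range(sims):
            r = np.random.default_rng(s)
            n = 60
            risk = pd.Series(r.normal(size=n), index=[f"S{i}" for i in range(n)])
            muts = pd.DataFrame([r.integers(0, 2, n)], index=["MUT0"],
                                columns=risk.index)
            out = mutation_risk_association(risk, muts, self._surv(r, np.zeros(n)))
            sig += out.loc["MUT0", "wilcoxon_p"] < 0.05
        assert sig <= 0.1 * sims + 1

    def test_protective_mutation_detected(self, rng):
        n = 90
        risk = pd.Series(np.sort(rng.normal(size=n)), index=[f"S{i}" for i in range(n)])
        mut = np.zeros(n, int)
        mut[:30] = 1  # mutation planted in the lowest-risk tertile
        muts = pd.DataFrame([mut], index=["MUT0"], columns=risk.index)
        surv = self._surv(rng, 1.2 * risk.to_numpy())
        out = mutation_risk_association(risk, muts, surv)
        assert out.loc["MUT0", "wilcoxon_p"] < 0.01
        assert out.loc["MUT0", "risk_median_mut"] < out.loc["MUT0", "risk_median_wt"]

    def test_degenerate_all_mutant_skipped(self, rng):
        n = 20
        risk = pd.Series(rng.normal(size=n), index=[f"S{i}" for i in range(n)])
        muts = pd.DataFrame([np.ones(n, int)], index=["MUT0"], columns=risk.index)
        out = mutation_risk_association(risk, muts, self._surv(rng, np.zeros(n)))
        assert len(out) == 0


class TestPerGeneSurvival:
    def _surv(self, rng, risk, n):
        t, e = simulate_survival_times(risk, 0.02, 0.005, rng)
        to, eo = simulate_survival_times(risk, 0.012, 0.005, rng)
        return pd.DataFrame({"patient_id": [f"S{i}" for i in range(n)],
                             "time": t, "event": e,
                             "os_time": to, "os_event": eo})

    def test_null_gene_p_roughly_uniform(self):
        from scipy.stats import kstest
        ps = []
        for s in range(120):
            r = np.random.default_rng(s)
            n = 40
            g = pd.Series(r.normal(size=n), index=[f"S{i}" for i in range(n)],
                          name="G0")
            ps.append(per_gene_survival(g, self._surv(r, np.zeros(n), n)).logrank_p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_risk_equal_gene_strongly_prognostic(self, rng):
        n = 200
        g = pd.Series(rng.normal(size=n), index=[f"S{i}" for i in range(n)],
                      name="G0")
        surv = self._surv(rng, 1.5 * g.to_numpy(), n)
        res = per_gene_survival(g, surv, endpoint="PFS")
        assert res.logrank_p < 0.01
        res_os = per_gene_survival(g, surv, endpoint="OS")
        assert res_os.logrank_p < 0.01

    def test_constant_gene_hits_degenerate_warning(self, rng):
        n = 20
        g = pd.Series(np.ones(n), index=[f"S{i}" for i in range(n)], name="G0")
        with pytest.warns(UserWarning, match="degenerate"):
            res = per_gene_survival(g, self._surv(rng, np.zeros(n), n))
        assert res.degenerate_split
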