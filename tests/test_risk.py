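"""Diversity, PLS-DA, imbalance detection, and risk scoring."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from microkg.model import AbundanceTable
from microkg.risk import (
    ImbalanceFlag,
    RiskConfig,
    aggregate_population,
    alpha_diversity,
    beta_diversity,
    beta_matrix,
    detect_imbalances,
    disease_risk_scores,
    disease_specific_report,
    normalize_abundance,
    plsda_discriminate,
)
from microkg.synth import CohortSpec, gen_cohort

from conftest import make_graph


def table(values, samples=None, taxa=None) -> AbundanceTable:
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{i}" for i in range(values.shape[0])]
    taxa = taxa or [f"t{j}" for j in range(values.shape[1])]
    return AbundanceTable(pd.DataFrame(values, index=samples, columns=taxa))


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

class TestDiversity:
    def test_shannon_closed_forms(self):
        assert alpha_diversity([0.25] * 4) == pytest.approx(math.log(4))
        assert alpha_diversity([1.0, 0.0]) == 0.0
        with pytest.raises(ValueError):
            alpha_diversity([0.2, 0.2])

    def test_shannon_bounds_and_maximum_at_uniform(self):
        rng = np.random.default_rng(0)
        n = 12
        for _ in range(50):
            p = rng.dirichlet(np.ones(n))
            h = alpha_diversity(p)
            assert 0 <= h <= math.log(n) + 1e-12
        assert alpha_diversity(np.full(n, 1 / n)) == pytest.approx(math.log(n))

    def test_bray_curtis_closed_forms(self):
        assert beta_diversity([0.5, 0.5, 0.0], [0.5, 0.5, 0.0]) == pytest.approx(0.0)
        assert beta_diversity([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_bray_curtis_matches_min_summation_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            p = rng.dirichlet(np.ones(8))
            q = rng.dirichlet(np.ones(8))
            expected = 1.0 - np.minimum(p, q).sum()
            assert beta_diversity(p, q) == pytest.approx(expected)

    def test_beta_matrix_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(2)
        t = table(rng.dirichlet(np.ones(6), size=5))
        m = beta_matrix(t)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 0.0)


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

class TestPLSDA:
    def make_groups(self, shift_taxon=None, shift=0.0, seed=0, n=20, p=10):
        rng = np.random.default_rng(seed)
        base = rng.dirichlet(np.ones(p) * 5, size=2 * n) + 1e-6
        taxa = [f"t{j}" for j in range(p)]
        tgt = base[:n].copy()
        if shift_taxon is not None:
            j = taxa.index(shift_taxon)
            tgt[:, j] += shift
        tgt = tgt / tgt.sum(axis=1, keepdims=True)
        ctrl = base[n:] / base[n:].sum(axis=1, keepdims=True)
        return (
            table(tgt, samples=[f"tg{i}" for i in range(n)], taxa=taxa),
            table(ctrl, samples=[f"ct{i}" for i in range(n)], taxa=taxa),
        )

    def test_planted_taxon_attains_maximal_vip(self):
        for seed in range(3):
            tgt, ctrl = self.make_groups(shift_taxon="t3", shift=0.15, seed=seed)
            out = plsda_discriminate(tgt, ctrl)
            assert out["vip"].idxmax() == "t3"

    def test_mean_squared_vip_is_one(self):
        tgt, ctrl = self.make_groups(seed=5)
        out = plsda_discriminate(tgt, ctrl)
        assert float((out["vip"] ** 2).mean()) == pytest.approx(1.0)

    def test_sample_permutation_invariance(self):
        tgt, ctrl = self.make_groups(shift_taxon="t1", shift=0.1, seed=7)
        out1 = plsda_discriminate(tgt, ctrl)
        perm = np.random.default_rng(0).permutation(len(tgt.sample_ids))
        tgt2 = AbundanceTable(tgt.data.iloc[perm])
        out2 = plsda_discriminate(tgt2, ctrl)
        assert np.allclose(out1["vip"].values, out2["vip"].values)

    def test_too_few_samples_rejected(self):
        tgt, ctrl = self.make_groups(n=20)
        small = AbundanceTable(tgt.data.iloc[:2])
        with pytest.raises(ValueError):
            plsda_discriminate(small, ctrl)


# ---------------------------------------------------------------------------
# imbalance detection
# ---------------------------------------------------------------------------

def quantile_oracle(values, q):
    """Sort-based empirical quantile with linear interpolation."""
    v = sorted(values)
    h = (len(v) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


class TestImbalances:
    def test_flags_match_sort_based_oracle_on_random_cohorts(self):
        rng = np.random.default_rng(3)
        cfg = RiskConfig()
        for _ in range(20):
            n_taxa = int(rng.integers(3, 8))
            ctrl = table(rng.dirichlet(np.ones(n_taxa), size=20))
            tgt = table(rng.dirichlet(np.ones(n_taxa), size=10))
            flags = detect_imbalances(tgt, ctrl, cfg)
            got = {(f.sample_id, f.taxon_id, f.direction) for f in flags}
            expected = set()
            for taxon in tgt.taxon_ids:
                vals = ctrl.data[taxon].values
                lo = quantile_oracle(vals, cfg.q_low)
                hi = quantile_oracle(vals, cfg.q_high)
                for sid in tgt.sample_ids:
                    obs = tgt.data.at[sid, taxon]
                    if obs > hi:
                        expected.add((sid, taxon, "high"))
                    elif obs < lo:
                        expected.add((sid, taxon, "low"))
            assert got == expected

    def test_central_sample_unflagged(self):
        ctrl = table(np.tile([0.5, 0.5], (20, 1)))
        tgt = table([[0.5, 0.5]], samples=["x"])
        assert detect_imbalances(tgt, ctrl) == []

    def test_taxon_absent_from_control_flags_high(self):
        ctrl = table([[1.0]] * 10, taxa=["t0"])
        tgt = table([[0.9, 0.1]], samples=["x"], taxa=["t0", "tNew"])
        flags = detect_imbalances(tgt, ctrl)
        assert ("x", "tNew", "high") in {
            (f.sample_id, f.taxon_id, f.direction) for f in flags
        }

    def test_widening_band_never_adds_flags(self):
        rng = np.random.default_rng(9)
        ctrl = table(rng.dirichlet(np.ones(5), size=30))
        tgt = table(rng.dirichlet(np.ones(5), size=10))
        narrow = detect_imbalances(tgt, ctrl, RiskConfig(q_low=0.1, q_high=0.9))
        wide = detect_imbalances(tgt, ctrl, RiskConfig(q_low=0.02, q_high=0.98))
        key = lambda fl: {(f.sample_id, f.taxon_id, f.direction) for f in fl}
        assert key(wide) <= key(narrow)

    def test_control_order_invariance(self):
        rng = np.random.default_rng(10)
        ctrl = table(rng.dirichlet(np.ones(4), size=25))
        tgt = table(rng.dirichlet(np.ones(4), size=5))
        f1 = detect_imbalances(tgt, ctrl)
        perm = rng.permutation(25)
        ctrl2 = AbundanceTable(ctrl.data.iloc[perm])
        f2 = detect_imbalances(tgt, ctrl2)
        assert f1 == f2


# ---------------------------------------------------------------------------
# risk scoring
# ---------------------------------------------------------------------------

def flag(sid, taxon, direction, obs=0.5, lo=0.1, hi=0.4):
    if direction == "low":
        obs, lo, hi = 0.01, 0.1, 0.4
    return ImbalanceFlag(sid, taxon, direction, obs, lo, hi)


class TestRiskScores:
    def graph(self):
        return make_graph(
            ["mP", "mN", "mC"], ["dA", "dB"],
            [("mP", "dA", 2.0), ("mN", "dA", -1.0),
             ("mP", "dB", 1.0), ("mC", "dB", 0.0)],
        )

    def test_high_flag_on_positive_association_scores_plus_one(self):
        g = make_graph(["mP"], ["dA"], [("mP", "dA", 1.0)])
        for mode in ("direction_aware", "association_only"):
            reports = disease_risk_scores(
                [flag("s1", "mP", "high")], g, RiskConfig(scoring_mode=mode)
            )
            assert reports[0].scores == {"dA": 1}

    def test_low_flag_modes_differ(self):
        g = make_graph(["mP"], ["dA"], [("mP", "dA", 1.0)])
        aware = disease_risk_scores([flag("s1", "mP", "low")], g, RiskConfig())
        literal = disease_risk_scores(
            [flag("s1", "mP", "low")], g,
            RiskConfig(scoring_mode="association_only"),
        )
        assert aware[0].scores == {"dA": -1}
        assert literal[0].scores == {"dA": 1}

    def test_contested_edges_contribute_zero(self):
        reports = disease_risk_scores([flag("s1", "mC", "high")], self.graph(),
                                      RiskConfig())
        assert reports[0].scores == {}

    def test_unresolvable_taxon_warned_and_skipped(self):
        with pytest.warns(UserWarning, match="absent from the graph"):
            reports = disease_risk_scores(
                [flag("s1", "unknown_taxon", "high")], self.graph(), RiskConfig()
            )
        assert reports[0].scores == {}

    def test_scores_match_double_loop_oracle(self):
        rng = np.random.default_rng(12)
        g = self.graph()
        directions = {
            (e.microbe_id, e.disease_id): e.direction for e in g.relation_edges
        }
        taxa = ["mP", "mN", "mC"]
        flags = [
            flag(f"s{rng.integers(4)}", taxa[rng.integers(3)],
                 "high" if rng.random() < 0.5 else "low")
            for _ in range(30)
        ]
        reports = disease_risk_scores(flags, g, RiskConfig())
        expected: dict[str, dict[str, int]] = {}
        for f in flags:  # brute-force double loop
            for (m, d), direction in directions.items():
                if m != f.taxon_id or direction == "contested":
                    continue
                fs = 1 if f.direction == "high" else -1
                a = 1 if direction == "positive" else -1
                expected.setdefault(f.sample_id, {}).setdefault(d, 0)
                expected[f.sample_id][d] += fs * a
            expected.setdefault(f.sample_id, {})
        got = {r.sample_id: r.scores for r in reports}
        assert got == expected

    def test_scoring_linearity_over_disjoint_flag_sets(self):
        g = self.graph()
        f1 = [flag("s1", "mP", "high")]
        f2 = [flag("s1", "mN", "low")]
        sep = [disease_risk_scores(f, g, RiskConfig())[0].scores for f in (f1, f2)]
        both = disease_risk_scores(f1 + f2, g, RiskConfig())[0].scores
        combined: dict[str, int] = {}
        for s in sep:
            for d, v in s.items():
                combined[d] = combined.get(d, 0) + v
        assert both == combined


class TestAggregation:
    def test_single_report_identity_and_summation(self):
        g = make_graph(["mP"], ["dA"], [("mP", "dA", 1.0)])
        r1 = disease_risk_scores([flag("s1", "mP", "high")], g, RiskConfig())
        assert aggregate_population(r1) == [("dA", 1)]
        r2 = disease_risk_scores(
            [flag("s2", "mP", "high"), flag("s2", "mP", "high")], g, RiskConfig()
        )
        # two flags in one sample is double evidence: +2, population +3
        assert aggregate_population(r1 + r2) == [("dA", 3)]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_population([])


class TestDiseaseSpecificReport:
    def test_disease_without_associates_gives_empty_report(self):
        g = make_graph(["mP"], ["dA", "dLonely"], [("mP", "dA", 1.0)])
        rng = np.random.default_rng(0)
        ctrl = table(rng.dirichlet(np.ones(3), size=20), taxa=["mP", "x", "y"])
        tgt = table(rng.dirichlet(np.ones(3), size=5), taxa=["mP", "x", "y"])
        assert disease_specific_report("dLonely", tgt, ctrl, g) == []
        with pytest.raises(KeyError):
            disease_specific_report("nope", tgt, ctrl, g)

    def test_report_is_subset_of_detected_imbalances(self):
        g = make_graph(["mP", "mN"], ["dA"],
                       [("mP", "dA", 1.0), ("mN", "dA", -1.0)])
        rng = np.random.default_rng(4)
        taxa = ["mP", "mN", "other"]
        ctrl = table(rng.dirichlet(np.ones(3), size=30), taxa=taxa)
        tgt = table(rng.dirichlet(np.ones(3), size=10), taxa=taxa)
        all_flags = {
            (f.sample_id, f.taxon_id)
            for f in detect_imbalances(tgt, ctrl, RiskConfig())
        }
        report = disease_specific_report("dA", tgt, ctrl, g)
        assert {(r["sample_id"], r["taxon_id"]) for r in report} <= all_flags
        assert all(r["taxon_id"] in ("mP", "mN") for r in report)

    def test_planted_disease_associated_imbalances_reported(self):
        g = make_graph(["m0", "m1", "m2", "m3"], ["dA"],
                       [("m0", "dA", 1.0), ("m1", "dA", 1.0), ("m2", "dA", -1.0)])
        spec = CohortSpec(
            n_taxa=8, n_target=10, n_control=40,
            taxon_ids=("m0", "m1", "m2", "m3", "t4", "t5", "t6", "t7"),
            planted_imbalances=(("m0", "high", 6.0), ("m1", "high", 6.0),
                                ("m2", "low", 6.0)),
            seed=6,
        )
        tgt, ctrl, _, _ = gen_cohort(spec, g)
        report = disease_specific_report("dA", tgt, ctrl, g)
        reported_taxa = {r["taxon_id"] for r in report}
        assert reported_taxa == {"m0", "m1", "m2"}
        interp = {(r["taxon_id"], r["interpretation"]) for r in report}
        assert ("m0", "elevated risk") in interp
        assert ("m2", "elevated risk") in interp  # low abundance of inhibitor
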