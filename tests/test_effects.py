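import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cccnet.diffexpr import OverexpressionCalls
from cccnet.effects import (
    CONFIDENCE_ALPHAS,
    DECISION_TABLE,
    INDETERMINATE,
    LigandEffectRecord,
    build_feedback_network,
    celltype_functional_enrichment,
    classify_ligand,
    classify_records,
    hg_zscore,
    is_context_sensitive,
    most_effective_dose,
    permutation_category_test,
    prediction_capacity_test,
    signed_pvalues,
)
from cccnet.lr import LRInteractionTable
from cccnet.network import build_network
from cccnet.synthetic import generate_invitro_counts


class TestClassifier:
    def test_decision_table_has_17_patterns(self):
        assert len(DECISION_TABLE) == 17

    def test_every_arrow_triple_maps_to_exactly_one_category(self):
        p_of = {1: 0.01, -1: -0.01, 0: 0.5}
        for arrows in itertools.product((-1, 0, 1), repeat=3):
            signed = tuple(p_of[a] for a in arrows)
            cat = classify_ligand(signed, alpha=0.02)
            expected = DECISION_TABLE.get(arrows, INDETERMINATE)
            assert cat == expected

    def test_all_nonsignificant_is_neutral(self):
        assert classify_ligand((0.5, -0.8, 0.9), 0.02) == "neutral"
        assert classify_ligand((0.2747, 0.2642, 0.3721), 0.05) == "neutral"

    def test_dose_dependent_reference_ligand_series(self):
        # increase of the stem-cell pool alone -> self-renewal induction
        assert classify_ligand((0.0036, 0.5, 0.5), 0.02) == "self_renewal_induction"
        # significant decrease of all three pools -> proliferation inhibition
        assert (
            classify_ligand((-0.0007, -0.0094, -0.0207), 0.05)
            == "proliferation_inhibition"
        )

    def test_arrows_only_appear_as_alpha_grows(self):
        signed = (0.015, -0.04, 0.5)
        for lo, hi in [(0.01, 0.02), (0.02, 0.05)]:
            def arrows(alpha):
                return tuple(
                    (1 if p > 0 else -1) if abs(p) <= alpha else 0 for p in signed
                )
            a_lo, a_hi = arrows(lo), arrows(hi)
            for x, y in zip(a_lo, a_hi):
                assert x == y or x == 0  # dashes can only turn into arrows

    def test_context_sensitive_flip_detected(self):
        # self-renewal at 0.01 but proliferation induction at 0.05
        assert is_context_sensitive((0.005, 0.03, 0.5))
        assert not is_context_sensitive((0.005, 0.5, 0.5))

    def test_nonstandard_alpha_warns(self, caplog):
        with caplog.at_level("WARNING", logger="cccnet.effects"):
            classify_ligand((0.5, 0.5, 0.5), alpha=0.07)
        assert "non-standard" in caplog.text


class TestMostEffectiveDose:
    def test_picks_smallest_abs_p_with_lower_dose_tiebreak(self):
        doses = {1.0: (0.3, 0.3, 0.3), 10.0: (0.004, 0.3, 0.3), 100.0: (0.004, 0.3, 0.3)}
        assert most_effective_dose(doses, alpha=0.02) == 10.0

    def test_all_null_ligand_reports_highest_dose(self):
        doses = {1.0: (0.3, 0.3, 0.3), 100.0: (0.4, 0.5, 0.6)}
        assert most_effective_dose(doses, alpha=0.02) == 100.0


class TestSignedPvalues:
    def test_null_pvalues_roughly_uniform_and_power_recovers_sign(self):
        rng = np.random.default_rng(0)
        null_p, pos_sign = [], 0
        n_power = 20
        for i in range(30):
            counts = generate_invitro_counts(
                {"LNULL": "neutral"}, seed=int(rng.integers(2**31))
            )
            null_p.extend(signed_pvalues(counts, "LNULL"))
        # |signed p| = two-sided p / 2 ~ U(0, 0.5) under the null
        ks = stats.kstest(np.abs(null_p), stats.uniform(0, 0.5).cdf)
        assert ks.pvalue > 0.01
        for i in range(n_power):
            counts = generate_invitro_counts(
                {"LUP": "self_renewal_induction"}, seed=int(rng.integers(2**31))
            )
            p = signed_pvalues(counts, "LUP")
            pos_sign += p[0] > 0
        assert pos_sign >= int(0.95 * n_power)  # planted increase recovered

    def test_zero_experiment_sd_agrees_with_plain_fixed_effect_fit(self):
        counts = generate_invitro_counts(
            {"L1": "neutral"}, experiment_sd=0.0, residual_sd=0.3, seed=1
        )
        mixed = signed_pvalues(counts, "L1")
        sub = counts[counts["condition"].isin(["BC", "L1"])]
        y = np.log(sub["n_hsc_enriched"] + 1)
        g1 = y[sub["condition"] == "L1"]
        g0 = y[sub["condition"] == "BC"]
        t = stats.ttest_ind(g1, g0)
        assert abs(mixed[0]) == pytest.approx(t.pvalue / 2, abs=0.05)

    def test_single_experiment_degrades_to_fixed_effect_with_warning(self, caplog):
        counts = generate_invitro_counts(
            {"L1": "neutral"}, n_experiments=2, seed=2
        )
        counts = counts[counts["experiment"] == "exp1"]
        with caplog.at_level("WARNING", logger="cccnet.effects"):
            p = signed_pvalues(counts, "L1")
        assert all(0 < abs(x) <= 1 for x in p)

    def test_missing_condition_rejected(self):
        counts = generate_invitro_counts({"L1": "neutral"}, seed=3)
        with pytest.raises(ValueError, match="not both present"):
            signed_pvalues(counts, "NOPE")


def test_record_classification_recovers_planted_categories():
    """Strong planted effects are recovered for most seeds end to end."""
    rng = np.random.default_rng(5)
    hits = 0
    n_runs = 10
    for _ in range(n_runs):
        counts = generate_invitro_counts(
            {"LSR": "self_renewal_induction", "LPI": "proliferation_inhibition"},
            effect_size=0.8, seed=int(rng.integers(2**31)),
        )
        recs = {r.ligand: r.category for r in classify_records(counts)}
        hits += recs["LSR"] == "self_renewal_induction"
        hits += recs["LPI"] == "proliferation_inhibition"
    assert hits >= int(0.8 * 2 * n_runs)


class TestBinomialCapacity:
    def test_reference_point_probability(self):
        res = prediction_capacity_test(33, 27, 0.5)
        assert round(res.point, 4) == 0.0001
        assert res.expectation == pytest.approx(16.5)

    def test_small_case_matches_exhaustive_enumeration(self):
        res = prediction_capacity_test(4, 4, 0.5)
        assert res.point == pytest.approx(0.0625)
        assert res.tail == pytest.approx(0.0625)

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_matches_enumeration_up_to_n12(self, n):
        for k in range(n + 1):
            res = prediction_capacity_test(n, k, 0.5)
            outcomes = list(itertools.product((0, 1), repeat=n))
            point = sum(1 for o in outcomes if sum(o) == k) / 2**n
            tail = sum(1 for o in outcomes if sum(o) >= k) / 2**n
            assert res.point == pytest.approx(point, abs=1e-12)
            assert res.tail == pytest.approx(tail, abs=1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            prediction_capacity_test(10, 11, 0.5)
        with pytest.raises(ValueError):
            prediction_capacity_test(10, 5, 1.0)


class TestHypergeometricZ:
    @staticmethod
    def enumerated_z(N, m, n, k):
        kk = np.arange(max(0, n + m - N), min(n, m) + 1)
        pmf = stats.hypergeom(N, m, n).pmf(kk)
        mean = float((kk * pmf).sum())
        var = float(((kk - mean) ** 2 * pmf).sum())
        return (k - mean) / np.sqrt(var)

    def test_mean_case_scores_zero(self):
        assert hg_zscore(10, 5, 4, 2) == pytest.approx(0.0)

    def test_complete_overlap_case_matches_enumeration(self):
        assert hg_zscore(10, 5, 4, 4) == pytest.approx(self.enumerated_z(10, 5, 4, 4))
        assert hg_zscore(10, 5, 4, 4) == pytest.approx(2.449489742783178)

    def test_agrees_with_enumeration_for_small_universes(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            N = int(rng.integers(2, 51))
            m = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(max(0, n + m - N), min(n, m) + 1))
            if m == N or n == N:
                continue  # degenerate: variance 0
            assert hg_zscore(N, m, n, k) == pytest.approx(
                self.enumerated_z(N, m, n, k), abs=1e-9
            )


def _enrichment_fixture():
    calls = OverexpressionCalls(
        ligands={"P1": {"L1", "L2"}, "P2": {"L3", "L4"}},
        receptors={"P1": {"R0"}, "P2": set()},
        fdr_threshold=0.1, min_wins=1,
    )
    lr = LRInteractionTable(pd.DataFrame({
        "ligand": ["L1", "L2", "L3", "L4"],
        "receptor": ["R0", "R0", "R0", "R0"],
    }))
    net = build_network(calls, lr, include_others=False)
    records = [
        LigandEffectRecord("L1", 100, (0.01, 0.5, 0.5), "self_renewal_induction", "intermediate"),
        LigandEffectRecord("L2", 100, (0.5, 0.5, 0.5), "neutral", "intermediate"),
        LigandEffectRecord("L3", 100, (-0.01, -0.01, -0.01), "proliferation_inhibition", "intermediate"),
        LigandEffectRecord("L4", 100, (0.03, 0.03, 0.5), INDETERMINATE, "intermediate"),
    ]
    return net, lr, records


def test_celltype_enrichment_skips_cells_without_categorized_ligands(caplog):
    net, _, records = _enrichment_fixture()
    with caplog.at_level("WARNING", logger="cccnet.effects"):
        z = celltype_functional_enrichment(net, records, target_cell="P1")
    # universe: L1, L2, L3 (L4 indeterminate); P2 produces only L3
    assert set(z.index) == {"P1", "P2"}
    assert z.loc["P2", "proliferation_inhibition"] > 0
    # P1's two ligands exclude inhibition entirely -> negative score
    assert z.loc["P1", "proliferation_inhibition"] < 0


class TestFeedbackNetwork:
    def test_receptor_mode_sums_target_receptor_levels(self):
        net, lr, records = _enrichment_fixture()
        edges = build_feedback_network(net, records, lr, {"R0": 2.5}, mode="receptor")
        row = edges[(edges["cell"] == "P1") & (edges["category"] == "self_renewal_induction")]
        assert row["weight"].item() == pytest.approx(2.5)
        # indeterminate ligand L4 contributes no edge
        assert not (
            (edges["cell"] == "P2") & (edges["category"] == INDETERMINATE)
        ).any()

    def test_frequency_mode_is_linear_in_frequency(self):
        net, lr, records = _enrichment_fixture()
        f1 = pd.Series({"P1": 0.2, "P2": 0.8})
        f2 = pd.Series({"P1": 0.4, "P2": 0.8})
        e1 = build_feedback_network(net, records, lr, {"R0": 1.0}, mode="frequency", freqs=f1)
        e2 = build_feedback_network(net, records, lr, {"R0": 1.0}, mode="frequency", freqs=f2)
        w1 = e1[e1["cell"] == "P1"]["weight"].sum()
        w2 = e2[e2["cell"] == "P1"]["weight"].sum()
        assert w2 == pytest.approx(2 * w1)

    def test_compartment_mode_scales_peripheral_cells_by_tenth(self):
        net, lr, records = _enrichment_fixture()
        f = pd.Series({"P1": 0.5, "P2": 0.5})
        freq_mode = build_feedback_network(net, records, lr, {"R0": 1.0}, mode="frequency", freqs=f)
        comp = build_feedback_network(
            net, records, lr, {"R0": 1.0}, mode="compartment", freqs=f,
            compartment_weights={"P1": 0.1, "P2": 1.0},
        )
        for cat in ("self_renewal_induction",):
            a = freq_mode[(freq_mode["cell"] == "P1") & (freq_mode["category"] == cat)]["weight"].item()
            b = comp[(comp["cell"] == "P1") & (comp["category"] == cat)]["weight"].item()
            assert b == pytest.approx(0.1 * a)

    def test_missing_frequency_rejected(self):
        net, lr, records = _enrichment_fixture()
        with pytest.raises(ValueError, match="missing frequencies"):
            build_feedback_network(
                net, records, lr, {"R0": 1.0}, mode="frequency",
                freqs=pd.Series({"P1": 1.0}),
            )


def test_permutation_category_test_detects_perfect_association():
    cats = {f"L{i}": ("alpha" if i < 5 else "beta") for i in range(10)}
    p_hit = permutation_category_test(cats, {"L0", "L1", "L2", "L3", "L4"}, "alpha",
                                      n_perm=2000, seed=0)
    assert p_hit < 0.02
    p_null = permutation_category_test(cats, {"L0", "L5"}, "alpha", n_perm=500, seed=1)
    assert p_null > 0.2
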