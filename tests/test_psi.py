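"""PSI posteriors, delta-PSI, Savage-Dickey Bayes factors, batch driver."""

import numpy as np
import pandas as pd
import pytest

from altsplice.psi import (
    PairComparison,
    ReadSupport,
    compare_all,
    compare_pair,
    comparisons_to_frame,
    estimate_psi,
    prior_diff_density_at_zero,
    psi_matrix,
)


def sup(incl, excl, sample="s", event="e1"):
    return ReadSupport(event, sample, incl, excl)


class TestEstimatePsi:
    def test_no_data_returns_prior(self):
        est = estimate_psi(sup(0, 0))
        assert est.psi_mean == 0.5
        assert (est.alpha_post, est.beta_post) == (1, 1)

    @pytest.mark.parametrize(
        "incl,excl,expected_mean",
        [(30, 10, 31 / 42), (10, 30, 11 / 42), (0, 100, 1 / 102)],
    )
    def test_conjugate_closed_form(self, incl, excl, expected_mean):
        est = estimate_psi(sup(incl, excl))
        assert est.psi_mean == pytest.approx(expected_mean, abs=1e-12)
        assert est.alpha_post == 1 + incl and est.beta_post == 1 + excl

    def test_count_swap_symmetry(self):
        a = estimate_psi(sup(17, 5))
        b = estimate_psi(sup(5, 17))
        assert a.psi_mean == pytest.approx(1 - b.psi_mean, abs=1e-12)
        assert a.ci_low == pytest.approx(1 - b.ci_high, abs=1e-9)
        assert a.ci_high == pytest.approx(1 - b.ci_low, abs=1e-9)

    def test_credible_interval_ordering(self):
        est = estimate_psi(sup(8, 3))
        assert 0 <= est.ci_low <= est.psi_mean <= est.ci_high <= 1

    def test_bad_prior_rejected(self):
        with pytest.raises(ValueError):
            estimate_psi(sup(1, 1), prior_alpha=0)
        with pytest.raises(ValueError):
            ReadSupport("e", "s", -1, 0)


class TestComparePair:
    def test_uniform_prior_density_at_zero_is_one(self):
        assert prior_diff_density_at_zero(1, 1) == pytest.approx(1.0, abs=1e-12)

    def test_no_data_gives_bayes_factor_near_one(self):
        # posterior equals the prior, so the Savage-Dickey ratio is 1 up to
        # Monte Carlo error in the density window; 10^5 draws keep that ~2%
        c = compare_pair(sup(0, 0), sup(0, 0, "n"), seed=5, n_mc=100_000)
        assert c.delta_psi == 0
        assert c.bayes_factor == pytest.approx(1.0, rel=0.15)
        assert not c.reads_ok

    def test_extreme_separation_called(self):
        # frozen from a brute-force Monte Carlo check of the conjugate means
        c = compare_pair(sup(50, 0), sup(0, 50, "n"), seed=5)
        assert c.delta_psi == pytest.approx(51 / 52 - 1 / 52, abs=1e-12)
        assert c.bayes_factor > 5
        assert c.reads_ok

    def test_identical_counts_not_called(self):
        c = compare_pair(sup(20, 20), sup(20, 20, "n"), seed=5)
        assert c.delta_psi == 0
        assert c.bayes_factor < 5

    def test_swap_negates_delta_and_keeps_bf(self):
        a = compare_pair(sup(40, 10), sup(15, 35, "n"), seed=5)
        b = compare_pair(sup(15, 35), sup(40, 10, "n"), seed=5)
        assert a.delta_psi == pytest.approx(-b.delta_psi, abs=1e-12)
        assert np.log(a.bayes_factor) == pytest.approx(
            np.log(b.bayes_factor), abs=0.35
        )

    def test_read_support_rule_is_per_sample_and_strict(self):
        # 11 reads pass (strict > 10); 10 reads in either sample fail
        assert compare_pair(sup(6, 5), sup(6, 5, "n"), seed=1).reads_ok
        assert not compare_pair(sup(5, 5), sup(6, 5, "n"), seed=1).reads_ok
        assert not compare_pair(sup(6, 5), sup(5, 5, "n"), seed=1).reads_ok

    def test_bf_monotone_in_true_separation(self):
        # deterministic count sweep at fixed depth 200
        n = 200
        bfs = []
        for shift in (0.0, 0.1, 0.2, 0.3, 0.4):
            t = sup(int(n * (0.5 + shift)), n - int(n * (0.5 + shift)))
            c = compare_pair(t, sup(n // 2, n // 2, "n"), seed=7, n_mc=50_000)
            bfs.append(c.bayes_factor)
        assert bfs == sorted(bfs)
        assert bfs[-1] > 1e3

    def test_small_n_mc_rejected(self):
        with pytest.raises(ValueError):
            compare_pair(sup(1, 1), sup(1, 1, "n"), n_mc=500, seed=1)

    def test_mismatched_events_rejected(self):
        with pytest.raises(ValueError):
            compare_pair(sup(1, 1, event="e1"), sup(1, 1, "n", event="e2"), seed=1)


def _toy_counts():
    rows = []
    for event in ("e1", "e2"):
        for sample, (i, x) in {
            "t1": (30, 10), "n1": (10, 30),
            "t2": (25, 15), "n2": (12, 28),
            "t3": (28, 12), "n3": (11, 29),
        }.items():
            rows.append((event, sample, i, x))
    rows.append(("e3", "t1", 20, 20))  # only in one sample of pair 1
    return pd.DataFrame(
        rows, columns=["event_id", "sample_id", "inclusion_reads", "exclusion_reads"]
    )


class TestCompareAll:
    PAIRS = [("p1", "t1", "n1"), ("p2", "t2", "n2"), ("p3", "t3", "n3")]

    def test_cardinality_and_skipping(self):
        out = compare_all(_toy_counts(), self.PAIRS, seed=3)
        # 2 shared events x 3 pairs; e3 lacks its normal sample everywhere
        assert len(out) == 6
        assert all(c.event_id in ("e1", "e2") for c in out)

    def test_determinism_and_order_independence(self):
        a = compare_all(_toy_counts(), self.PAIRS, seed=3)
        b = compare_all(_toy_counts(), list(reversed(self.PAIRS)), seed=3)
        key = lambda c: (c.event_id, c.pair_id)
        assert sorted(a, key=key) == sorted(b, key=key)

    def test_unknown_sample_raises(self):
        with pytest.raises(ValueError):
            compare_all(_toy_counts(), [("p1", "t1", "nope")], seed=3)

    def test_frame_columns(self):
        frame = comparisons_to_frame(compare_all(_toy_counts(), self.PAIRS, seed=3))
        assert list(frame.columns) == [
            "event_id", "pair_id", "psi_tumor", "psi_normal",
            "delta_psi", "bayes_factor", "reads_ok",
        ]


def test_psi_matrix_masks_low_support():
    counts = pd.DataFrame(
        [("e1", "s1", 30, 10), ("e1", "s2", 4, 3), ("e2", "s1", 0, 40)],
        columns=["event_id", "sample_id", "inclusion_reads", "exclusion_reads"],
    )
    mat = psi_matrix(counts)
    assert mat.loc["e1", "s1"] == pytest.approx(31 / 42)
    assert np.isnan(mat.loc["e1", "s2"])  # 7 reads fails the strict >10 rule
    assert mat.loc["e2", "s1"] == pytest.approx(1 / 42)
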