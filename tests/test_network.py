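"""Spearman edges, exact small-n P-values, bipartite network operations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from altsplice.network import (
    build_network,
    edges_frame,
    factor_subnetwork,
    select_top_targets,
    spearman_edge,
    spearman_exact_p,
    write_graphml,
    write_sif,
)


class TestSpearmanEdge:
    def test_perfect_monotone(self):
        rho, p, n = spearman_edge([1, 2, 3, 4, 5, 6], [2, 4, 6, 8, 10, 12])
        assert rho == pytest.approx(1.0)
        assert n == 6

    def test_perfect_antimonotone_small_n(self):
        rho, p, n = spearman_edge([1, 2, 3], [3, 2, 1], min_n=3)
        assert rho == pytest.approx(-1.0)

    def test_exact_two_sided_p_at_n6(self):
        # only the identity and the reversal of 720 pairings reach |rho| = 1
        rho, p, n = spearman_edge([1, 2, 3, 4, 5, 6], [2, 4, 6, 8, 10, 12])
        assert p == pytest.approx(2 / 720, abs=1e-12)

    def test_exact_p_matches_permutation_oracle(self):
        # permute one side only so the exact null enumerates n! pairings
        rng = np.random.default_rng(5)
        for _ in range(5):
            x = rng.normal(size=7)
            y = rng.normal(size=7)
            mine = spearman_exact_p(x, y)
            oracle = stats.permutation_test(
                (y,),
                lambda yp: stats.spearmanr(x, yp).statistic,
                permutation_type="pairings",
                n_resamples=np.inf,
                alternative="two-sided",
            ).pvalue
            assert mine == pytest.approx(oracle, abs=1e-9)

    def test_exact_and_asymptotic_agree_at_n9(self):
        rng = np.random.default_rng(17)
        gaps = []
        for _ in range(100):
            x = rng.normal(size=9)
            y = rng.normal(size=9)
            _, p_exact, _ = spearman_edge(x, y, method="exact")
            _, p_asym, _ = spearman_edge(x, y, method="asymptotic")
            gaps.append(abs(p_exact - p_asym))
        assert np.mean(gaps) < 0.01

    def test_missing_pairs_dropped_and_min_n_enforced(self):
        x = [1, 2, 3, 4, 5, np.nan, 7]
        y = [2, 1, 4, 3, 6, 5, np.nan]
        assert spearman_edge(x, y, min_n=6) is None  # 5 complete pairs
        assert spearman_edge(x, y, min_n=5) is not None

    def test_constant_vector_gives_no_edge(self):
        assert spearman_edge([1, 1, 1, 1, 1, 1], [1, 2, 3, 4, 5, 6]) is None

    def test_rho_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        rho1, _, _ = spearman_edge(x, y)
        rho2, _, _ = spearman_edge(np.exp(x), y**3)
        assert rho1 == pytest.approx(rho2, abs=1e-12)


def _toy_matrices(n_samples=12, seed=0):
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n_samples)]
    base = rng.normal(size=n_samples)
    expr = pd.DataFrame(
        {
            "F1": np.exp(base),
            "F2": np.exp(base + 0.05 * rng.normal(size=n_samples)),
            "G1": np.exp(rng.normal(size=n_samples)),
        },
        index=samples,
    ).T
    psi = pd.DataFrame(
        {
            "e1": stats.norm.cdf(base),
            "e2": stats.norm.cdf(base + 0.05 * rng.normal(size=n_samples)),
            "e3": stats.norm.cdf(base - 0.05 * rng.normal(size=n_samples)),
        },
        index=samples,
    ).T
    e2g = {"e1": "G1", "e2": "G1", "e3": "G2"}
    return expr, psi, e2g


class TestBuildNetwork:
    def test_cardinality_when_everything_correlates(self):
        expr, psi, e2g = _toy_matrices()
        net = build_network(["F1", "F2"], expr, psi, e2g)
        ev_edges = [
            d for _, _, d in net.edges(data=True)
            if d["edge_class"] == "factor_event"
        ]
        assert len(ev_edges) == 6  # 2 factors x 3 events, all P < 0.05

    def test_alpha_zero_gives_empty_edge_set(self):
        expr, psi, e2g = _toy_matrices()
        net = build_network(["F1", "F2"], expr, psi, e2g, alpha=0.0)
        assert net.number_of_edges() == 0

    def test_edges_monotone_in_alpha(self):
        expr, psi, e2g = _toy_matrices(seed=9)
        small = build_network(["F1", "F2"], expr, psi, e2g, alpha=0.01)
        large = build_network(["F1", "F2"], expr, psi, e2g, alpha=0.2)
        assert set(small.edges()) <= set(large.edges())

    def test_missing_factor_skipped_with_warning(self, caplog):
        expr, psi, e2g = _toy_matrices()
        with caplog.at_level("WARNING"):
            net = build_network(["F1", "NOPE"], expr, psi, e2g)
        assert "NOPE" in caplog.text
        assert "NOPE" not in net

    def test_bipartite_no_within_side_edges(self):
        expr, psi, e2g = _toy_matrices()
        net = build_network(["F1", "F2"], expr, psi, e2g)
        for u, v in net.edges():
            kinds = {net.nodes[u]["kind"], net.nodes[v]["kind"]}
            assert "factor" in kinds and kinds != {"factor"}


class TestSubnetworkAndTopTargets:
    def _network(self):
        expr, psi, e2g = _toy_matrices()
        return build_network(["F1", "F2"], expr, psi, e2g)

    def test_gene_count_bounded_by_event_count(self):
        net = self._network()
        sub, counts = factor_subnetwork(net, "F1")
        assert counts["n_event_host_genes"] <= counts["n_events"]
        assert counts["n_events"] == 3 and counts["n_event_host_genes"] == 2

    def test_unknown_factor_raises(self):
        with pytest.raises(KeyError):
            factor_subnetwork(self._network(), "nope")

    def test_strict_rho_band_and_ranking(self):
        import networkx as nx

        net = nx.Graph()
        net.add_node("F", kind="factor", bipartite=0)
        edges = {
            "perfect": (1.0, 1e-9),
            "boundary": (0.5, 1e-9),
            "strong": (-0.8, 0.001),
            "weak": (0.6, 0.04),
        }
        for name, (rho, p) in edges.items():
            net.add_node(name, kind="event", bipartite=1, gene="g")
            net.add_edge("F", name, rho=rho, p_value=p, n=30,
                         edge_class="factor_event")
        top = select_top_targets(net, "F", k=1)
        assert list(top["event_id"]) == ["strong"]  # rank by P within the band
        all_kept = select_top_targets(net, "F", k=10)
        assert set(all_kept["event_id"]) == {"strong", "weak"}

    def test_exports_round_trip(self, tmp_path):
        import networkx as nx

        net = self._network()
        sif = tmp_path / "net.sif"
        gml = tmp_path / "net.graphml"
        write_sif(net, str(sif))
        write_graphml(net, str(gml))
        assert len(sif.read_text().splitlines()) == net.number_of_edges()
        back = nx.read_graphml(str(gml))
        assert back.number_of_edges() == net.number_of_edges()


def test_frame_lists_every_edge_once():
    expr, psi, e2g = _toy_matrices()
    net = build_network(["F1", "F2"], expr, psi, e2g)
    frame = edges_frame(net)
    assert len(frame) == net.number_of_edges()
    assert set(frame["factor"]) <= {"F1", "F2"}
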