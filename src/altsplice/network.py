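"""Splicing-factor regulatory network from expression-PSI rank correlation.

Candidate regulations are scored by Spearman correlation between a splicing
factor's expression (FPKM) across samples and (a) each event's per-sample
PSI and (b) each event host gene's expression.  Edges with two-sided
P < alpha (raw, no multiple-testing correction by default) enter a bipartite
factor -> target graph.  P-values are exact (full enumeration of rank
permutations) for n <= 9 paired observations and use the t approximation
otherwise.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

MIN_N = 6
ALPHA = 0.05
RHO_BAND = (0.5, 1.0)
TOP_K = 36
EXACT_N_MAX = 9


@dataclass(frozen=True)
class NetworkEdge:
    """One candidate or retained regulation with its correlation statistics."""

    factor: str
    target: str
    edge_class: str  # "factor_event" | "factor_gene"
    rho: float
    p_value: float
    n_samples: int


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho as Pearson correlation of midranks (tie-aware)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return float("nan")
    return float((rx * ry).sum() / denom)


def spearman_exact_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided exact P by full enumeration of the n! rank pairings.

    Feasible for n <= 9 (9! = 362,880 permutations, evaluated vectorized).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n > EXACT_N_MAX:
        raise ValueError(f"exact enumeration limited to n <= {EXACT_N_MAX}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    sx = math.sqrt((rxc**2).sum())
    perms = np.array(list(itertools.permutations(ry)))
    pyc = perms - perms.mean(axis=1, keepdims=True)
    sy = np.sqrt((pyc**2).sum(axis=1))
    with np.errstate(invalid="ignore"):
        rhos = pyc @ rxc / (sx * sy)
    obs = _spearman_rho(x, y)
    # tolerance absorbs float noise so the observed pairing counts itself
    return float(np.mean(np.abs(rhos) >= abs(obs) - 1e-12))


def spearman_edge(
    x: Sequence[float],
    y: Sequence[float],
    min_n: int = MIN_N,
    method: str = "auto",
) -> Optional[tuple[float, float, int]]:
    """(rho, two-sided P, n) after dropping missing pairs, or None.

    None (no edge) when fewer than ``min_n`` complete pairs remain or either
    vector is constant (rho undefined).  ``method`` is ``auto`` (exact for
    n <= 9, asymptotic t otherwise), ``exact`` or ``asymptotic``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < min_n:
        log.debug("spearman_edge: only %d complete pairs (min %d)", n, min_n)
        return None
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None
    rho = _spearman_rho(x, y)
    use_exact = method == "exact" or (method == "auto" and n <= EXACT_N_MAX)
    if use_exact:
        p = spearman_exact_p(x, y)
    else:
        # t approximation on rho; degenerate |rho| = 1 gives P -> 0
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho * rho))
            p = 2 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p), n


def build_network(
    sf_list: Iterable[str],
    expression: pd.DataFrame,
    psi: pd.DataFrame,
    event_to_gene: Mapping[str, str],
    alpha: float = ALPHA,
    min_n: int = MIN_N,
    method: str = "auto",
) -> nx.Graph:
    """Bipartite factor -> {event, host gene} graph of P < alpha correlations.

    ``expression`` is genes x samples (FPKM), ``psi`` is events x samples;
    the two must share sample columns.  One candidate edge is tested per
    (factor, event) and per (factor, host gene of an event).  Factors absent
    from the expression matrix are skipped with a warning.
    """
    if (expression.values < 0).any():
        raise ValueError("expression matrix has negative entries")
    samples = [s for s in psi.columns if s in expression.columns]
    if not samples:
        raise ValueError("expression and PSI matrices share no samples")
    missing_map = [e for e in psi.index if e not in event_to_gene]
    if missing_map:
        raise ValueError(
            f"event->gene map misses {len(missing_map)} events, e.g. "
            f"{missing_map[:3]}"
        )

    g = nx.Graph()
    g.graph["alpha"] = alpha
    g.graph["samples"] = list(samples)
    host_genes = sorted(
        {event_to_gene[e] for e in psi.index} & set(expression.index)
    )
    for factor in sf_list:
        if factor not in expression.index:
            log.warning("factor %s absent from expression matrix, skipped", factor)
            continue
        fx = expression.loc[factor, samples].to_numpy(dtype=float)
        g.add_node(factor, bipartite=0, kind="factor")
        for event_id in psi.index:
            res = spearman_edge(
                fx, psi.loc[event_id, samples].to_numpy(dtype=float),
                min_n=min_n, method=method,
            )
            if res is None:
                continue
            rho, p, n = res
            if p < alpha:
                g.add_node(event_id, bipartite=1, kind="event",
                           gene=event_to_gene[event_id])
                g.add_edge(factor, event_id, rho=rho, p_value=p, n=n,
                           edge_class="factor_event")
        for gene in host_genes:
            if gene == factor:
                continue
            res = spearman_edge(
                fx, expression.loc[gene, samples].to_numpy(dtype=float),
                min_n=min_n, method=method,
            )
            if res is None:
                continue
            rho, p, n = res
            if p < alpha:
                g.add_node(gene, bipartite=1, kind="gene")
                g.add_edge(factor, gene, rho=rho, p_value=p, n=n,
                           edge_class="factor_gene")
    return g


def factor_subnetwork(network: nx.Graph, factor: str) -> tuple[nx.Graph, dict]:
    """Induced subgraph of one factor and its targets, with target counts.

    The distinct-gene count can be below the event count because genes may
    host several events.
    """
    if factor not in network or network.nodes[factor].get("kind") != "factor":
        raise KeyError(f"unknown factor {factor!r}")
    targets = list(network.neighbors(factor))
    sub = network.subgraph([factor] + targets).copy()
    events = [t for t in targets if network.nodes[t]["kind"] == "event"]
    direct_genes = {t for t in targets if network.nodes[t]["kind"] == "gene"}
    host_genes = {network.nodes[e].get("gene") for e in events} - {None}
    counts = {
        "n_events": len(events),
        "n_target_genes": len(direct_genes),
        "n_event_host_genes": len(host_genes),
    }
    return sub, counts


def select_top_targets(
    network: nx.Graph,
    factor: str,
    k: int = TOP_K,
    rho_band: tuple[float, float] = RHO_BAND,
) -> pd.DataFrame:
    """Top-k factor-event edges with rho_lo < |rho| < rho_hi (strict bounds).

    Sorted by ascending P, then descending |rho|, then event id; truncated
    at ``k``.  A perfectly monotone edge (|rho| = 1) is excluded by the
    strict upper bound.
    """
    sub, _ = factor_subnetwork(network, factor)
    lo, hi = rho_band
    rows = []
    for _, target, attrs in sub.edges(factor, data=True):
        if attrs["edge_class"] != "factor_event":
            continue
        if not (lo < abs(attrs["rho"]) < hi):
            continue
        rows.append(
            {
                "factor": factor,
                "event_id": target,
                "gene": sub.nodes[target].get("gene", ""),
                "rho": attrs["rho"],
                "p_value": attrs["p_value"],
                "n": attrs["n"],
            }
        )
    df = pd.DataFrame(
        rows, columns=["factor", "event_id", "gene", "rho", "p_value", "n"]
    )
    if df.empty:
        return df
    df["abs_rho"] = df["rho"].abs()
    df = df.sort_values(
        ["p_value", "abs_rho", "event_id"], ascending=[True, False, True]
    ).drop(columns="abs_rho")
    return df.head(k).reset_index(drop=True)


def edges_frame(network: nx.Graph) -> pd.DataFrame:
    rows = [
        {
            "factor": u if network.nodes[u]["kind"] == "factor" else v,
            "target": v if network.nodes[u]["kind"] == "factor" else u,
            "edge_class": d["edge_class"],
            "rho": d["rho"],
            "p_value": d["p_value"],
            "n": d["n"],
        }
        for u, v, d in network.edges(data=True)
    ]
    df = pd.DataFrame(
        rows, columns=["factor", "target", "edge_class", "rho", "p_value", "n"]
    )
    return df.sort_values(["factor", "edge_class", "target"]).reset_index(drop=True)


def write_sif(network: nx.Graph, path: str) -> None:
    """Simple-interaction format: factor <edge_class> target, one per line."""
    df = edges_frame(network)
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            fh.write(f"{row['factor']}\t{row['edge_class']}\t{row['target']}\n")


def write_graphml(network: nx.Graph, path: str) -> None:
    g = network.copy()
    g.graph.pop("samples", None)  # GraphML cannot carry list attributes
    nx.write_graphml(g, path)
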