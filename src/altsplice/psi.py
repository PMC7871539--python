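"""Bayesian percent-spliced-in (PSI) estimation and per-pair differential calls.

The model is the two-isoform special case with equal effective lengths: given
a true inclusion fraction psi, the inclusion read count among n informative
junction reads is Binomial(n, psi).  With a Beta(alpha, beta) prior the
posterior is conjugate, Beta(alpha + inclusion, beta + exclusion), so
per-sample estimates and credible intervals are closed-form.  An optional
effective-length ratio reweights the counts for users whose inclusion and
exclusion isoforms differ in informative length.

Differential splicing between a tumor/normal pair is summarized by
delta_psi = E[psi_tumor] - E[psi_normal] and a Savage-Dickey Bayes factor
against delta_psi = 0: the ratio of prior to posterior density of the PSI
difference at zero.  The prior density at zero is available in closed form
(difference of two independent Beta variates); the posterior density is
estimated from Monte Carlo draws of the two independent posteriors using a
centered histogram window.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

log = logging.getLogger(__name__)

DEFAULT_N_MC = 10_000
#: half-width of the centered window for the posterior density at zero
BF_WINDOW = 0.01
#: Bayes factors are capped here when no posterior mass falls in the window
BF_CAP = 1e6
#: strict read-support threshold: inclusion + exclusion must exceed this
MIN_READS = 10


@dataclass(frozen=True)
class ReadSupport:
    """Inclusion/exclusion junction read counts for one event in one sample."""

    event_id: str
    sample_id: str
    inclusion_reads: int
    exclusion_reads: int

    def __post_init__(self) -> None:
        if self.inclusion_reads < 0 or self.exclusion_reads < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def total(self) -> int:
        return self.inclusion_reads + self.exclusion_reads


@dataclass(frozen=True)
class PsiEstimate:
    """Beta posterior over one sample's PSI with central 95% credible bounds."""

    event_id: str
    sample_id: str
    alpha_post: float
    beta_post: float
    psi_mean: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class PairComparison:
    """Differential-splicing summary for one event in one tumor/normal pair."""

    event_id: str
    pair_id: str
    psi_tumor: float
    psi_normal: float
    delta_psi: float
    bayes_factor: float
    reads_ok: bool
    n_mc: int
    seed: int


def estimate_psi(
    support: ReadSupport,
    prior_alpha: float = 1.0,
    prior_beta: float = 1.0,
    length_ratio: float = 1.0,
) -> PsiEstimate:
    """Conjugate Beta posterior over PSI from inclusion/exclusion counts.

    ``length_ratio`` is the inclusion/exclusion effective-length ratio; the
    inclusion count is divided by it before the update (default 1 leaves the
    counts untouched).
    """
    if prior_alpha <= 0 or prior_beta <= 0:
        raise ValueError("prior parameters must be positive")
    if length_ratio <= 0:
        raise ValueError("length_ratio must be positive")
    alpha_post = prior_alpha + support.inclusion_reads / length_ratio
    beta_post = prior_beta + support.exclusion_reads
    psi_mean = alpha_post / (alpha_post + beta_post)
    ci_low, ci_high = stats.beta.ppf([0.025, 0.975], alpha_post, beta_post)
    return PsiEstimate(
        event_id=support.event_id,
        sample_id=support.sample_id,
        alpha_post=alpha_post,
        beta_post=beta_post,
        psi_mean=psi_mean,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
    )


def prior_diff_density_at_zero(prior_alpha: float, prior_beta: float) -> float:
    """Density at 0 of X - Y for X, Y iid Beta(alpha, beta).

    f(0) = integral f_Beta(t)^2 dt = B(2a-1, 2b-1) / B(a, b)^2, finite only
    for a, b > 1/2 (for the uniform prior this is exactly 1).
    """
    a, b = prior_alpha, prior_beta
    if a <= 0.5 or b <= 0.5:
        raise ValueError(
            "Savage-Dickey prior density at 0 diverges for Beta prior "
            "parameters <= 1/2"
        )
    log_f0 = special.betaln(2 * a - 1, 2 * b - 1) - 2 * special.betaln(a, b)
    return float(np.exp(log_f0))


def compare_pair(
    tumor: ReadSupport,
    normal: ReadSupport,
    prior_alpha: float = 1.0,
    prior_beta: float = 1.0,
    n_mc: int = DEFAULT_N_MC,
    seed: int = 0,
    min_reads: int = MIN_READS,
    pair_id: str = "",
    length_ratio: float = 1.0,
) -> PairComparison:
    """Posterior-mean PSI difference and Savage-Dickey Bayes factor for a pair.

    delta_psi is tumor minus normal.  reads_ok requires the strict rule
    inclusion + exclusion > ``min_reads`` in *both* samples.
    """
    if tumor.event_id != normal.event_id:
        raise ValueError(
            f"samples refer to different events: {tumor.event_id!r} vs "
            f"{normal.event_id!r}"
        )
    if n_mc < 1000:
        raise ValueError("n_mc < 1000 gives an unreliable density estimate")
    est_t = estimate_psi(tumor, prior_alpha, prior_beta, length_ratio)
    est_n = estimate_psi(normal, prior_alpha, prior_beta, length_ratio)
    delta = est_t.psi_mean - est_n.psi_mean

    prior0 = prior_diff_density_at_zero(prior_alpha, prior_beta)
    rng = np.random.default_rng(seed)
    draws_t = rng.beta(est_t.alpha_post, est_t.beta_post, size=n_mc)
    draws_n = rng.beta(est_n.alpha_post, est_n.beta_post, size=n_mc)
    in_window = np.abs(draws_t - draws_n) <= BF_WINDOW
    post0 = in_window.sum() / (n_mc * 2 * BF_WINDOW)
    bf = BF_CAP if post0 == 0 else min(prior0 / post0, BF_CAP)

    reads_ok = tumor.total > min_reads and normal.total > min_reads
    return PairComparison(
        event_id=tumor.event_id,
        pair_id=pair_id,
        psi_tumor=est_t.psi_mean,
        psi_normal=est_n.psi_mean,
        delta_psi=delta,
        bayes_factor=bf,
        reads_ok=reads_ok,
        n_mc=n_mc,
        seed=seed,
    )


def derive_seed(master_seed: int, *labels: str) -> int:
    """Deterministic sub-stream seed below 2**31 from a master seed and labels."""
    h = zlib.crc32("|".join(labels).encode())
    return (int(master_seed) * 1_000_003 + h) % (2**31 - 1)


def compare_all(
    counts: pd.DataFrame,
    pairing: Sequence[tuple[str, str, str]],
    seed: int,
    prior_alpha: float = 1.0,
    prior_beta: float = 1.0,
    n_mc: int = DEFAULT_N_MC,
    min_reads: int = MIN_READS,
) -> list[PairComparison]:
    """Run :func:`compare_pair` for every (event, pair) quantified in both samples.

    ``counts`` has columns event_id, sample_id, inclusion_reads,
    exclusion_reads.  ``pairing`` is a sequence of (pair_id, tumor_sample,
    normal_sample).  Per-comparison seeds derive deterministically from the
    master seed, the pair id and the event id, so results do not depend on
    iteration order.  Events missing from one side of a pair are skipped with
    a log message.
    """
    required = {"event_id", "sample_id", "inclusion_reads", "exclusion_reads"}
    missing_cols = required - set(counts.columns)
    if missing_cols:
        raise ValueError(f"counts table lacks columns {sorted(missing_cols)}")
    known_samples = set(counts["sample_id"].unique())
    by_sample = {
        sid: grp.set_index("event_id") for sid, grp in counts.groupby("sample_id")
    }

    out: list[PairComparison] = []
    for pair_id, tumor_sample, normal_sample in pairing:
        for sid in (tumor_sample, normal_sample):
            if sid not in known_samples:
                raise ValueError(f"unknown sample_id {sid!r} in pairing")
        tab_t = by_sample[tumor_sample]
        tab_n = by_sample[normal_sample]
        shared = tab_t.index.intersection(tab_n.index)
        skipped = len(tab_t.index.union(tab_n.index)) - len(shared)
        if skipped:
            log.info(
                "pair %s: %d events quantified in only one sample, skipped",
                pair_id,
                skipped,
            )
        for event_id in sorted(shared):
            row_t = tab_t.loc[event_id]
            row_n = tab_n.loc[event_id]
            sup_t = ReadSupport(
                event_id, tumor_sample,
                int(row_t["inclusion_reads"]), int(row_t["exclusion_reads"]),
            )
            sup_n = ReadSupport(
                event_id, normal_sample,
                int(row_n["inclusion_reads"]), int(row_n["exclusion_reads"]),
            )
            out.append(
                compare_pair(
                    sup_t,
                    sup_n,
                    prior_alpha=prior_alpha,
                    prior_beta=prior_beta,
                    n_mc=n_mc,
                    seed=derive_seed(seed, pair_id, event_id),
                    min_reads=min_reads,
                    pair_id=pair_id,
                )
            )
    return out


def comparisons_to_frame(comparisons: Iterable[PairComparison]) -> pd.DataFrame:
    """Tabulate comparisons with the documented output columns."""
    rows = [
        {
            "event_id": c.event_id,
            "pair_id": c.pair_id,
            "psi_tumor": c.psi_tumor,
            "psi_normal": c.psi_normal,
            "delta_psi": c.delta_psi,
            "bayes_factor": c.bayes_factor,
            "reads_ok": c.reads_ok,
        }
        for c in comparisons
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "pair_id",
            "psi_tumor",
            "psi_normal",
            "delta_psi",
            "bayes_factor",
            "reads_ok",
        ],
    )


def psi_matrix(
    counts: pd.DataFrame,
    prior_alpha: float = 1.0,
    prior_beta: float = 1.0,
    min_reads: Optional[int] = MIN_READS,
) -> pd.DataFrame:
    """Events x samples matrix of posterior-mean PSI.

    Entries where the sample's read support does not exceed ``min_reads``
    are left missing (NaN); pass ``min_reads=None`` to keep everything.
    """
    df = counts.copy()
    total = df["inclusion_reads"] + df["exclusion_reads"]
    psi = (prior_alpha + df["inclusion_reads"]) / (prior_alpha + prior_beta + total)
    if min_reads is not None:
        psi = psi.where(total > min_reads)
    df = df.assign(psi=psi)
    return df.pivot_table(
        index="event_id", columns="sample_id", values="psi", dropna=False
    )
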