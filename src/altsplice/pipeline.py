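"""End-to-end orchestration: PSI -> filter -> re-annotate -> overlap -> network.

Every stage reads and writes only the documented TSV/JSON formats, so the
stages are independently runnable and testable; :func:`run_all` chains them
under one configuration and one master seed (per-pair and per-stage
sub-streams derive deterministically from it) and emits a report holding
every count and percentage of the summary figures, plus a run manifest.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Mapping, Optional

import pandas as pd

from altsplice import crossdata, filters, network as netmod, psi as psimod
from altsplice import reannotation as reanno
from altsplice.events import event_signature, read_event_gff

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending record."""


@dataclass
class PipelineConfig:
    """Input paths, thresholds, seed and output directory for one run."""

    events_gff: str
    counts: str
    pairing: str
    ensembl_gtf: str
    refseq_gff: str
    alias: str
    fpkm: str
    factors: str
    outdir: str
    seed: int = 0
    bf_min: float = 5.0
    dpsi_min: float = 0.2
    min_reads: int = 10
    min_pairs: int = 3
    alpha: float = 0.05
    rho_lo: float = 0.5
    rho_hi: float = 1.0
    top_k: int = 36
    n_mc: int = psimod.DEFAULT_N_MC
    prior_alpha: float = 1.0
    prior_beta: float = 1.0

    _PATH_KEYS = (
        "events_gff",
        "counts",
        "pairing",
        "ensembl_gtf",
        "refseq_gff",
        "alias",
        "fpkm",
        "factors",
    )

    def __post_init__(self) -> None:
        for name in ("bf_min", "dpsi_min", "min_reads", "min_pairs", "alpha",
                     "rho_lo", "rho_hi", "top_k", "n_mc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            for key, value in asdict(self).items():
                fh.write(f"{key}: {value}\n")

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        raw: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, sep, value = line.partition(":")
                if not sep:
                    raise ValueError(f"malformed config line {line!r}")
                raw[key.strip()] = value.strip()
        kwargs: dict = {}
        for f in cls.__dataclass_fields__.values():
            if f.name.startswith("_") or f.name not in raw:
                continue
            value = raw[f.name]
            if f.type in ("int", int):
                kwargs[f.name] = int(value)
            elif f.type in ("float", float):
                kwargs[f.name] = float(value)
            else:
                kwargs[f.name] = value
        return cls(**kwargs)

    def check_inputs(self) -> None:
        for key in self._PATH_KEYS:
            path = getattr(self, key)
            if not os.path.exists(path):
                raise FileNotFoundError(f"input {key} not found: {path}")


def report_fractions(
    counts: Mapping[str, int], denominator_label: str
) -> pd.DataFrame:
    """Percentage of each labeled count relative to one denominator label.

    Percentages are recomputed from the counts, stored unrounded with
    1- and 2-decimal display roundings (half away from zero) alongside.
    """
    if denominator_label not in counts:
        raise KeyError(f"denominator label {denominator_label!r} not in counts")
    denom = counts[denominator_label]
    if denom <= 0:
        raise ValueError("zero or negative denominator")
    rows = []
    for label, count in counts.items():
        pct = filters.percentage(count, denom)
        rows.append(
            {
                "label": label,
                "count": count,
                "percent": pct,
                "percent_1dp": filters.round_half_away(pct, 1),
                "percent_2dp": filters.round_half_away(pct, 2),
            }
        )
    return pd.DataFrame(rows).set_index("label")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        wrapper.__name__ = fn.__name__
        return wrapper

    return deco


@_stage("psi")
def _run_psi(config: PipelineConfig, counts: pd.DataFrame, pairing: pd.DataFrame):
    pairs = list(
        pairing[["pair_id", "tumor_sample", "normal_sample"]].itertuples(
            index=False, name=None
        )
    )
    comparisons = psimod.compare_all(
        counts,
        pairs,
        seed=config.seed,
        prior_alpha=config.prior_alpha,
        prior_beta=config.prior_beta,
        n_mc=config.n_mc,
        min_reads=config.min_reads,
    )
    return comparisons


@_stage("filter")
def _run_filter(config: PipelineConfig, comparisons, event_types):
    matrix = filters.build_call_matrix(
        comparisons, bf_min=config.bf_min, dpsi_min=config.dpsi_min
    )
    retained = filters.trend_and_recurrence_filter(matrix, config.min_pairs)
    report = filters.tally(matrix, event_types, retained)
    return matrix, retained, report


@_stage("reannotate")
def _run_reannotate(config: PipelineConfig, events):
    alias = reanno.read_alias_table(config.alias)
    ens = reanno.build_index(config.ensembl_gtf, "ensembl_gtf")
    ref = reanno.build_index(config.refseq_gff, "refseq_gff", alias_table=alias)
    results = reanno.validate_all(events, ens, ref)
    return results, reanno.partition_by_support(results)


@_stage("overlap")
def _run_overlap(matrix, retained, cl_matrix, events):
    tissue_records = [
        crossdata.TrendRecord(
            event_key=event_signature(events[eid]),
            dataset="tissue",
            delta_psi=float(matrix.events.loc[eid, "median_delta_psi"]),
            event_type=events[eid].event_type,
        )
        for eid in retained
    ]
    cl_sig = cl_matrix.retained_ids(min_pairs=1)
    external_records = [
        crossdata.TrendRecord(
            event_key=event_signature(events[eid]),
            dataset="cell_line",
            delta_psi=float(cl_matrix.events.loc[eid, "median_delta_psi"]),
            event_type=events[eid].event_type,
        )
        for eid in cl_sig
    ]
    table, per_type = crossdata.overlap_and_judge(tissue_records, external_records)
    return table, per_type, cl_sig


@_stage("network")
def _run_network(config: PipelineConfig, counts, tissue_samples, network_events,
                 events):
    fpkm = pd.read_csv(config.fpkm, sep="\t", index_col=0)
    sf_list = pd.read_csv(config.factors, sep="\t")["factor"].tolist()
    psi_all = psimod.psi_matrix(
        counts,
        prior_alpha=config.prior_alpha,
        prior_beta=config.prior_beta,
        min_reads=config.min_reads,
    )
    keep = [e for e in network_events if e in psi_all.index]
    psi_tab = psi_all.loc[keep, [s for s in tissue_samples if s in psi_all.columns]]
    event_to_gene = {eid: events[eid].host_gene or "" for eid in keep}
    net = netmod.build_network(
        sf_list, fpkm, psi_tab, event_to_gene, alpha=config.alpha
    )
    return net


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the summary report."""
    config.check_inputs()
    os.makedirs(config.outdir, exist_ok=True)

    events = read_event_gff(config.events_gff)
    counts = pd.read_csv(config.counts, sep="\t")
    pairing = pd.read_csv(config.pairing, sep="\t")
    if "dataset" not in pairing.columns:
        pairing["dataset"] = "tissue"
    tissue_pairing = pairing[pairing["dataset"] == "tissue"]
    cl_pairing = pairing[pairing["dataset"] == "cell_line"]
    tissue_samples = sorted(
        set(tissue_pairing["tumor_sample"]) | set(tissue_pairing["normal_sample"])
    )
    event_types = {ev.event_id: ev.event_type for ev in events}

    comparisons = _run_psi(config, counts, pairing)
    tissue_pair_ids = set(tissue_pairing["pair_id"])
    tissue_cmp = [c for c in comparisons if c.pair_id in tissue_pair_ids]
    cl_cmp = [c for c in comparisons if c.pair_id not in tissue_pair_ids]
    psimod.comparisons_to_frame(comparisons).to_csv(
        os.path.join(config.outdir, "comparisons.tsv"), sep="\t", index=False
    )

    matrix, retained, tally_report = _run_filter(config, tissue_cmp, event_types)
    filters.retained_events_frame(matrix, retained, event_types).to_csv(
        os.path.join(config.outdir, "retained.tsv"), sep="\t"
    )
    with open(os.path.join(config.outdir, "tally.json"), "w") as fh:
        json.dump(tally_report.to_dict(), fh, indent=1, sort_keys=True)

    retained_events = [events[eid] for eid in retained]
    results, support = _run_reannotate(config, retained_events)
    reanno.results_to_frame(results).to_csv(
        os.path.join(config.outdir, "reannotation.tsv"), sep="\t", index=False
    )
    coding_counts = {"coding": 0, "noncoding": 0, "unassessed": 0}
    for r in results:
        coding_counts[r.coding_status] += 1
    summary = {
        "support": support,
        "coding": coding_counts,
        "validated_total": support["support"]["both"]
        + support["support"]["ensembl_only"]
        + support["support"]["refseq_only"],
    }
    with open(os.path.join(config.outdir, "reannotation_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)

    overlap_counts: dict = {}
    if len(cl_pairing):
        cl_matrix = filters.build_call_matrix(
            cl_cmp, bf_min=config.bf_min, dpsi_min=config.dpsi_min
        )
        overlap_table, overlap_per_type, cl_sig = _run_overlap(
            matrix, retained, cl_matrix, events
        )
        overlap_table.to_csv(
            os.path.join(config.outdir, "overlap.tsv"), sep="\t", index=False
        )
        in_both = int(overlap_table["in_both"].sum())
        same_trend = int(overlap_table["same_trend"].sum(skipna=True))
        overlap_counts = {
            "cell_line_significant": len(cl_sig),
            "in_both": in_both,
            "same_trend": same_trend,
            "per_type": overlap_per_type.to_dict(orient="records"),
        }

    validated_ids = [r.event_id for r in results if r.support_class != "neither"]
    net = _run_network(config, counts, tissue_samples, validated_ids, events)
    netmod.edges_frame(net).to_csv(
        os.path.join(config.outdir, "network_edges.tsv"), sep="\t", index=False
    )
    netmod.write_sif(net, os.path.join(config.outdir, "network.sif"))
    netmod.write_graphml(net, os.path.join(config.outdir, "network.graphml"))
    edge_classes = [d["edge_class"] for _, _, d in net.edges(data=True)]

    report = {
        "detected_events": len(events),
        "compared_events": int(matrix.events.shape[0]),
        "significant_events": tally_report.significant_events,
        "significant_incidences": tally_report.significant_incidences,
        "pct_significant": filters.percentage(
            tally_report.significant_events, len(events)
        ),
        "retained_events": len(retained),
        "per_type": tally_report.per_type.reset_index().to_dict(orient="records"),
        "reannotation": summary,
        "overlap": overlap_counts,
        "network": {
            "n_factors": sum(
                1 for n, d in net.nodes(data=True) if d.get("kind") == "factor"
            ),
            "factor_event_edges": edge_classes.count("factor_event"),
            "factor_gene_edges": edge_classes.count("factor_gene"),
        },
    }
    with open(os.path.join(config.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "stage_rows": {
            "comparisons": len(comparisons),
            "tissue_comparisons": len(tissue_cmp),
            "cell_line_comparisons": len(cl_cmp),
            "retained": len(retained),
            "reannotated": len(results),
            "network_edges": len(edge_classes),
        },
    }
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return report
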