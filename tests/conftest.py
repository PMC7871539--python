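import pytest

from altsplice import synthetic
from altsplice.pipeline import PipelineConfig, run_all


@pytest.fixture(scope="session")
def tiny_fixture(tmp_path_factory):
    """Small synthetic study: 8 events/type, 8 tissue pairs + cell line."""
    outdir = tmp_path_factory.mktemp("fixture")
    events, truth, genes = synthetic.generate_annotation(
        seed=11, events_per_type=8, n_pairs=8, outdir=str(outdir)
    )
    synthetic.simulate_expression(truth, n_factors=3, outdir=str(outdir))
    synthetic.simulate_counts(truth, coverage=100, outdir=str(outdir))
    truth.to_json(str(outdir / "truth.json"))
    return {"dir": outdir, "events": events, "truth": truth, "genes": genes}


def make_config(fixture_dir, outdir, seed=11, **overrides) -> PipelineConfig:
    d = str(fixture_dir)
    kwargs = dict(
        events_gff=f"{d}/events.gff3",
        counts=f"{d}/counts.tsv",
        pairing=f"{d}/pairing.tsv",
        ensembl_gtf=f"{d}/ensembl.gtf",
        refseq_gff=f"{d}/refseq.gff3",
        alias=f"{d}/alias.tsv",
        fpkm=f"{d}/fpkm.tsv",
        factors=f"{d}/factors.tsv",
        outdir=str(outdir),
        seed=seed,
    )
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)


@pytest.fixture(scope="session")
def tiny_run(tiny_fixture, tmp_path_factory):
    """One full pipeline run on the tiny fixture, shared across tests."""
    outdir = tmp_path_factory.mktemp("run")
    config = make_config(tiny_fixture["dir"], outdir)
    report = run_all(config)
    return {"report": report, "outdir": outdir, "config": config, **tiny_fixture}
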