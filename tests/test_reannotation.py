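"""Transcript indexes and validity criteria (i)-(v) on planted fixtures."""

import pytest

from altsplice.events import ASEvent, GenomicInterval
from altsplice.reannotation import (
    SourceVerdict,
    TranscriptIndex,
    TranscriptModel,
    ValidationResult,
    build_index,
    classify_coding,
    partition_by_support,
    read_alias_table,
    validate_all,
    validate_event,
)
from altsplice.synthetic import generate_annotation, write_annotation_files

E = lambda s, e, strand="+", chrom="chr1": GenomicInterval(chrom, s, e, strand)


def make_index(*chains, biotype="protein_coding", strand="+", chrom="chr1"):
    idx = TranscriptIndex(source="test")
    for i, chain in enumerate(chains):
        exons = tuple(E(s, e, strand, chrom) for s, e in chain)
        idx.add(
            TranscriptModel(
                transcript_id=f"T{i + 1}",
                gene_id="G1",
                gene_symbol="G1",
                biotype=biotype,
                chrom=chrom,
                strand=strand,
                exon_chain=exons,
            )
        )
    return idx


SE_EVENT = ASEvent(
    "se", "SE", (E(100, 200), E(500, 600), E(900, 1000))
)
RI_EVENT = ASEvent("ri", "RI", (E(100, 200), E(500, 600)))
MXE_EVENT = ASEvent(
    "mxe", "MXE", (E(100, 200), E(500, 600), E(900, 1000), E(1300, 1400))
)


class TestCriteria:
    def test_se_valid_when_three_exons_share_a_transcript(self):
        # exons 2-4 of a longer chain still satisfy criterion (i)
        idx = make_index([(10, 50), (100, 200), (500, 600), (900, 1000)])
        v = validate_event(SE_EVENT, idx)
        assert (v.verdict, v.criterion) == ("valid", "i")
        assert v.matched_transcripts == ("T1",)

    def test_se_invalid_on_one_bp_boundary_shift(self):
        idx = make_index([(101, 200), (500, 600), (900, 1000)])
        assert validate_event(SE_EVENT, idx).verdict == "invalid"

    def test_ri_requires_no_exon_between_flanks(self):
        valid_idx = make_index([(100, 200), (500, 600)])
        invalid_idx = make_index([(100, 200), (300, 350), (500, 600)])
        assert validate_event(RI_EVENT, valid_idx).verdict == "valid"
        assert validate_event(RI_EVENT, valid_idx).criterion == "ii"
        assert validate_event(RI_EVENT, invalid_idx).verdict == "invalid"

    def test_mxe_needs_both_isoforms_and_no_four_exon_transcript(self):
        both = make_index(
            [(100, 200), (500, 600), (1300, 1400)],
            [(100, 200), (900, 1000), (1300, 1400)],
        )
        v = validate_event(MXE_EVENT, both)
        assert (v.verdict, v.criterion) == ("valid", "iii")
        assert set(v.matched_transcripts) == {"T1", "T2"}

        one_isoform = make_index([(100, 200), (500, 600), (1300, 1400)])
        assert validate_event(MXE_EVENT, one_isoform).verdict == "invalid"

        with_all_four = make_index(
            [(100, 200), (500, 600), (1300, 1400)],
            [(100, 200), (900, 1000), (1300, 1400)],
            [(100, 200), (500, 600), (900, 1000), (1300, 1400)],
        )
        assert validate_event(MXE_EVENT, with_all_four).verdict == "invalid"

    @pytest.mark.parametrize("matched_form", ["long", "short"])
    def test_alt_splice_site_accepts_either_variable_form(self, matched_form):
        event = ASEvent(
            "a5", "A5SS", (E(100, 260), E(500, 600)),
            alt_boundaries=(200, 260), alt_side="end",
        )
        chain = [(100, 260), (500, 600)] if matched_form == "long" else [
            (100, 200), (500, 600)
        ]
        idx = make_index(chain)
        v = validate_event(event, idx)
        assert (v.verdict, v.criterion) == ("valid", "v")

    def test_alt_splice_site_rejects_exon_between(self):
        event = ASEvent(
            "a5", "A5SS", (E(100, 260), E(500, 600)),
            alt_boundaries=(200, 260), alt_side="end",
        )
        idx = make_index([(100, 260), (300, 340), (500, 600)])
        assert validate_event(event, idx).verdict == "invalid"

    def test_uncovered_chromosome_is_unmatched_not_error(self):
        idx = make_index([(100, 200)], chrom="chr9")
        assert validate_event(SE_EVENT, idx).verdict == "unmatched"

    def test_wrong_strand_never_matches(self):
        idx = make_index(
            [(100, 200), (500, 600), (900, 1000)], strand="-"
        )
        assert validate_event(SE_EVENT, idx).verdict == "unmatched"


@pytest.fixture(scope="module")
def planted(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("anno")
    events, truth, genes = generate_annotation(
        seed=29,
        events_per_type=10,
        invalid_fraction=0.4,
        single_source_fraction=0.2,
        n_pairs=2,
        outdir=str(outdir),
    )
    ens = build_index(str(outdir / "ensembl.gtf"), "ensembl_gtf")
    alias = read_alias_table(str(outdir / "alias.tsv"))
    ref = build_index(str(outdir / "refseq.gff3"), "refseq_gff", alias)
    results = validate_all(list(events), ens, ref)
    return truth, {r.event_id: r for r in results}


class TestPlantedFixtures:
    """Generator-built annotations: every planted verdict must reproduce."""

    def test_all_planted_verdicts_reproduce(self, planted):
        truth, results = planted
        defects_seen = set()
        for eid, t in truth.events.items():
            r = results[eid]
            expected_ens = (
                "valid" if t.valid_ensembl
                else ("unmatched" if not t.in_ensembl else "invalid")
            )
            expected_ref = (
                "valid" if t.valid_refseq
                else ("unmatched" if not t.in_refseq else "invalid")
            )
            assert r.ensembl.verdict == expected_ens, (eid, t.invalid_reason)
            assert r.refseq.verdict == expected_ref, (eid, t.invalid_reason)
            if t.invalid_reason:
                defects_seen.add(t.invalid_reason)
        assert defects_seen == {
            "boundary_shift", "intervening_exon", "four_exon_mxe"
        }

    def test_coding_status_matches_planted_biotypes(self, planted):
        truth, results = planted
        for eid, t in truth.events.items():
            r = results[eid]
            if r.support_class == "neither":
                assert r.coding_status == "unassessed"
            else:
                assert r.coding_status == ("coding" if t.coding else "noncoding")

    def test_single_source_events_populate_partitions(self, planted):
        truth, results = planted
        part = partition_by_support(results.values())["support"]
        assert part["ensembl_only"] >= 1 and part["refseq_only"] >= 1


class TestIndexConstruction:
    def test_refseq_accessions_translated_through_alias(self, tmp_path):
        _, _, genes = generate_annotation(
            seed=3, events_per_type=2, invalid_fraction=0, n_pairs=2
        )
        paths = write_annotation_files(genes, str(tmp_path))
        alias = read_alias_table(paths["alias"])
        idx = build_index(paths["refseq"], "refseq_gff", alias)
        chroms = {t.chrom for t in idx.transcripts.values()}
        assert chroms and all(c.startswith("chrS") for c in chroms)

    def test_refseq_without_alias_raises(self, tmp_path):
        _, _, genes = generate_annotation(
            seed=3, events_per_type=2, invalid_fraction=0, n_pairs=2
        )
        paths = write_annotation_files(genes, str(tmp_path))
        with pytest.raises(ValueError, match="alias"):
            build_index(paths["refseq"], "refseq_gff", alias_table=None)

    def test_gtf_round_trip_chain_count(self, tmp_path):
        _, _, genes = generate_annotation(
            seed=3, events_per_type=2, invalid_fraction=0, n_pairs=2
        )
        paths = write_annotation_files(genes, str(tmp_path))
        idx = build_index(paths["ensembl"], "ensembl_gtf")
        expected = sum(
            len(g.transcripts) for g in genes if "ensembl" in g.sources
        )
        assert len(idx) == expected


class TestClassifyAndPartition:
    def _result(self, ens, ref):
        return ValidationResult(
            "e", "SE",
            SourceVerdict(ens, "i", ("T1",) if ens == "valid" else ()),
            SourceVerdict(ref, "i", ("T2",) if ref == "valid" else ()),
        )

    def test_one_protein_coding_transcript_suffices(self):
        idx_pc = make_index([(1, 10)], biotype="protein_coding")
        idx_nc = make_index([(1, 10)], biotype="lincRNA")
        r = self._result("valid", "valid")
        # matched T1 in ensembl (coding), T2 unknown in refseq index -> rename
        idx_nc2 = TranscriptIndex(source="refseq")
        idx_nc2.add(
            TranscriptModel("T2", "G", "G", "lincRNA", "chr1", "+",
                            (E(1, 10),))
        )
        assert classify_coding(r.ensembl, r.refseq, idx_pc, idx_nc2) == "coding"
        idx_nc1 = TranscriptIndex(source="ensembl")
        idx_nc1.add(
            TranscriptModel("T1", "G", "G", "lincRNA", "chr1", "+", (E(1, 10),))
        )
        assert classify_coding(r.ensembl, r.refseq, idx_nc1, idx_nc2) == "noncoding"

    def test_unassessed_iff_no_support(self):
        r = self._result("invalid", "unmatched")
        assert classify_coding(r.ensembl, r.refseq, None, None) == "unassessed"
        assert r.support_class == "neither"

    def test_partition_set_algebra(self):
        results = [
            self._result("valid", "valid"),    # both
            self._result("valid", "invalid"),  # ensembl only
            self._result("invalid", "valid"),  # refseq only
            self._result("invalid", "invalid"),
        ]
        part = partition_by_support(results)
        assert part["support"] == {
            "both": 1, "ensembl_only": 1, "refseq_only": 1, "neither": 1,
        }
        assert sum(part["support"].values()) == part["total"] == 4

    def test_published_mxe_attrition_fraction(self):
        # 62 significant MXE events before re-annotation, 6 surviving
        assert round(100 * 6 / 62, 1) == 9.7
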