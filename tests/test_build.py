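"""Genome scanning and synonym-table construction."""

import gzip
import io

import pytest
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from syngenes.build import (
    BuildError,
    BuildReport,
    RawExtraction,
    accumulate,
    build_from_files,
    scan_genome,
)
from syngenes.store import SynonymEntry, SynonymTable


def make_record(features, accession="TEST00001"):
    length = 60 * (len(features) + 1)
    record = SeqRecord(
        Seq("ACGT" * (length // 4)),
        id=accession,
        name=accession,
        description="constructed test record",
        annotations={"molecule_type": "DNA"},
    )
    record.features = [
        SeqFeature(FeatureLocation(i * 60, (i + 1) * 60), type=kind, qualifiers=quals)
        for i, (kind, quals) in enumerate(features)
    ]
    return record


def write_genbank(path, records):
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "genbank")
    return path


@pytest.fixture()
def canonical_map():
    return SynonymTable(
        [
            SynonymEntry("COX1", "COI", "mt", "Mitochondrial Complex IV"),
            SynonymEntry("cytochrome oxidase subunit I", "COI", "mt"),
            SynonymEntry("CYTB", "CYTB", "mt", "Mitochondrial Complex III"),
            SynonymEntry("cytochrome b", "CYTB", "mt"),
            SynonymEntry("16S ribosomal RNA", "16S", "mt", "rRNA"),
            SynonymEntry("D-loop", "Control Region", "mt", "Control Region"),
            SynonymEntry("control region", "Control Region", "mt"),
        ]
    )


class TestScan:
    def test_cds_harvested_trna_ignored(self):
        record = make_record(
            [
                ("CDS", {"gene": ["COX1"],
                         "product": ["cytochrome c oxidase subunit I"]}),
                ("tRNA", {"gene": ["trnF"], "product": ["tRNA-Phe"]}),
            ]
        )
        out = scan_genome(record)
        assert len(out) == 1
        assert out[0].gene == "COX1"
        assert out[0].product == "cytochrome c oxidase subunit I"
        assert out[0].kind == "CDS"
        assert out[0].accession == "TEST00001"

    def test_rrna_harvested(self):
        record = make_record([("rRNA", {"product": ["16S ribosomal RNA"]})])
        (extraction,) = scan_genome(record)
        assert extraction.kind == "rRNA" and extraction.gene is None

    def test_no_target_features_gives_empty_list(self):
        record = make_record(
            [("tRNA", {"gene": ["trnK"]}), ("source", {"organism": ["x"]})]
        )
        assert scan_genome(record) == []

    def test_dloop_and_control_region_misc_feature_harvested(self):
        record = make_record(
            [
                ("D-loop", {"note": ["control region of the mitochondrion"]}),
                ("misc_feature", {"note": ["putative control region"]}),
                ("misc_feature", {"note": ["repeat unit"]}),
            ]
        )
        out = scan_genome(record)
        assert [x.kind for x in out] == ["control_region", "control_region"]

    def test_order_follows_feature_order(self):
        record = make_record(
            [
                ("CDS", {"gene": ["CYTB"], "product": ["cytochrome b"]}),
                ("rRNA", {"product": ["16S ribosomal RNA"]}),
                ("CDS", {"gene": ["COX1"],
                         "product": ["cytochrome oxidase subunit I"]}),
            ]
        )
        assert [x.gene for x in scan_genome(record)] == ["CYTB", None, "COX1"]

    def test_extraction_requires_some_name(self):
        with pytest.raises(ValueError):
            RawExtraction(None, None, "CDS")
        with pytest.raises(ValueError):
            RawExtraction("COI", "x", "gene")


class TestAccumulate:
    def test_known_product_is_skipped(self, canonical_map):
        draft = SynonymTable()
        draft.add(SynonymEntry("cytochrome b", "CYTB", "mt"))
        report = BuildReport()
        delta = accumulate(
            draft,
            RawExtraction(None, "cytochrome b", "CDS"),
            canonical_map,
            "mt",
            report,
        )
        assert delta is False
        assert report.duplicates_skipped == 1 and len(draft) == 1

    def test_new_product_inserted_under_resolved_symbol(self, canonical_map):
        draft = SynonymTable()
        report = BuildReport()
        delta = accumulate(
            draft,
            RawExtraction("COX1", "cytochrome oxidase subunit I", "CDS"),
            canonical_map,
            "mt",
            report,
        )
        assert delta is True
        assert draft.lookup("cytochrome oxidase subunit I", "mt") == "COI"
        # the gene qualifier spelling is recorded too
        assert draft.lookup("COX1", "mt") == "COI"
        assert report.new_entries == 1 and report.gene_variants_added == 1

    def test_unresolvable_extraction_goes_to_unmapped(self, canonical_map):
        draft = SynonymTable()
        report = BuildReport()
        extraction = RawExtraction("xyz9", "completely unknown protein", "CDS")
        assert not accumulate(draft, extraction, canonical_map, "mt", report)
        assert len(draft) == 0
        assert report.unmapped == [extraction]

    def test_conflicting_resolution_recorded_draft_unchanged(self, canonical_map):
        draft = SynonymTable()
        draft.add(SynonymEntry("16S ribosomal RNA", "16S", "mt"))
        report = BuildReport()
        conflicting = RawExtraction("CYTB", "16S ribosomal RNA", "CDS", "ACC1")
        assert not accumulate(draft, conflicting, canonical_map, "mt", report)
        assert len(report.conflicts) == 1
        assert draft.lookup("16S ribosomal RNA", "mt") == "16S"


class TestBuildFromFiles:
    def small_corpus(self, tmp_path, canonical_map, n_products=4):
        # one genome: 3 CDS with distinct resolvable products + 1 rRNA
        features = [
            ("CDS", {"gene": ["COX1"], "product": ["cytochrome oxidase subunit I"]}),
            ("CDS", {"gene": ["CYTB"], "product": ["cytochrome b"]}),
            ("CDS", {"gene": ["COX1"], "product": ["COX1 protein"]}),
            ("rRNA", {"product": ["16S ribosomal RNA"]}),
        ]
        record = make_record(features, accession="CORPUS001")
        return write_genbank(tmp_path / "one.gb", [record])

    def test_counts_on_constructed_corpus(self, tmp_path, canonical_map):
        path = self.small_corpus(tmp_path, canonical_map)
        draft, report = build_from_files([path], "mt", canonical_map)
        assert report.genomes_scanned == 1
        assert report.features_seen == 4
        assert report.new_entries == 4
        assert report.duplicates_skipped == 0
        assert report.new_entries + report.duplicates_skipped == (
            report.features_seen - len(report.unmapped) - len(report.conflicts)
        )
        # draft growth is fully accounted for
        assert len(draft) == report.new_entries + report.gene_variants_added

    def test_duplicated_corpus_is_idempotent(self, tmp_path, canonical_map):
        path = self.small_corpus(tmp_path, canonical_map)
        draft1, report1 = build_from_files([path], "mt", canonical_map)
        draft2, report2 = build_from_files([path, path], "mt", canonical_map)
        assert draft2.as_mapping() == draft1.as_mapping()
        assert report2.duplicates_skipped == (
            report1.duplicates_skipped + report1.features_seen
        )
        assert report2.new_entries == report1.new_entries

    def test_monotonic_growth_when_adding_genomes(self, tmp_path, canonical_map):
        path1 = self.small_corpus(tmp_path, canonical_map)
        extra = make_record(
            [("CDS", {"gene": ["CYTB"], "product": ["cytochrome b apoenzyme x"]})],
            accession="CORPUS002",
        )
        path2 = write_genbank(tmp_path / "two.gb", [extra])
        draft1, _ = build_from_files([path1], "mt", canonical_map)
        draft12, _ = build_from_files([path1, path2], "mt", canonical_map)
        map1, map12 = draft1.as_mapping(), draft12.as_mapping()
        assert set(map1).issubset(set(map12))
        assert all(map12[k] == v for k, v in map1.items())

    def test_gzip_input_accepted(self, tmp_path, canonical_map):
        path = self.small_corpus(tmp_path, canonical_map)
        gz = tmp_path / "one.gb.gz"
        gz.write_bytes(gzip.compress(path.read_bytes()))
        draft_gz, _ = build_from_files([gz], "mt", canonical_map)
        draft, _ = build_from_files([path], "mt", canonical_map)
        assert draft_gz.as_mapping() == draft.as_mapping()

    def test_unreadable_path_names_the_file(self, canonical_map, tmp_path):
        with pytest.raises(BuildError, match="nope.gb"):
            build_from_files([tmp_path / "nope.gb"], "mt", canonical_map)

    def test_bad_record_aborts_unless_skip_bad(self, tmp_path, canonical_map):
        bad = tmp_path / "bad.gb"
        bad.write_text("LOCUS       broken\nthis is not a genbank record\n//\n")
        with pytest.raises(BuildError):
            build_from_files([bad], "mt", canonical_map)
        draft, report = build_from_files([bad], "mt", canonical_map, skip_bad=True)
        assert len(draft) == 0

    def test_brute_force_equivalence(self, tmp_path, canonical_map):
        """The folded build equals a one-pass 'unique normalized product
        names, each with its resolved canonical' oracle."""
        from syngenes.normalize import canonicalize_text

        path = self.small_corpus(tmp_path, canonical_map)
        draft, _ = build_from_files([path, path], "mt", canonical_map)

        expected = {}
        with open(path) as fh:
            records = list(SeqIO.parse(fh, "genbank"))
        for record in records * 2:
            for x in scan_genome(record):
                short = canonical_map.lookup(x.gene or "", "mt") or (
                    canonical_map.lookup(x.product or "", "mt")
                )
                if short is None:
                    continue
                for name in (x.primary_name, x.gene):
                    if name is not None:
                        expected.setdefault(canonicalize_text(name), short)
        assert draft.as_mapping("mt") == expected
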