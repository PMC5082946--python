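"""Strand-specific counting rules against SAM fixtures and a brute-force oracle."""

import random
from collections import defaultdict

import numpy as np
import pandas as pd
import pysam
import pytest

from dualrna.annotations import Annotation, FeatureAnnotation
from dualrna.counting import (
    CountingError,
    FeatureIndex,
    StrandedCountTable,
    assign_mate,
    collapse_pair,
    count_sample,
    is_perfect,
    remove_rrna,
    transcribed_strand,
)
from dualrna.simulate import emit_sam_fixture
from tests.conftest import micro_config


def brute_force_recount(sam_path, ann):
    """Independent recount: enumerate records, apply the rules from scratch.

    Deliberately implemented without FeatureIndex/assign_mate so it can
    serve as an oracle for count_sample.
    """
    full = ann.with_intergenic() if not any(
        f.feature_class == "intergenic" for f in ann.features
    ) else ann
    by_qname = defaultdict(list)
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as fh:
        for r in fh.fetch(until_eof=True):
            if r.is_secondary or r.is_supplementary or r.is_unmapped:
                continue
            by_qname[r.query_name].append(r)
    counts = defaultdict(int)
    for reads in by_qname.values():
        keys = set()
        for r in reads:
            # perfect = all-M cigar and NM == 0
            if any(op != 0 for op, _ in r.cigartuples):
                continue
            try:
                if r.get_tag("NM") != 0:
                    continue
            except KeyError:
                continue
            # dUTP: mate 1 carries transcript strand
            rs = "-" if r.is_reverse else "+"
            ts = rs if (r.is_read1 or not r.is_paired) else ("-" if rs == "+" else "+")
            for f in full.features:
                if f.replicon != r.reference_name:
                    continue
                if r.reference_start < f.end and r.reference_end > f.start:
                    if f.strand == "both":
                        orient = "sense" if ts == "+" else "antisense"
                    else:
                        orient = "sense" if ts == f.strand else "antisense"
                    keys.add((f.feature_id, orient))
        for k in keys:
            counts[k] += 1
    return dict(counts)


@pytest.fixture()
def fixture_requests(toy_annotation):
    return {
        ("geneA", "sense"): 5,
        ("geneA", "antisense"): 2,
        ("geneB", "sense"): 3,
        ("geneP", "sense"): 4,
        ("trnaX", "sense"): 1,
    }


class TestIsPerfect:
    @staticmethod
    def _read(cigar, nm, header):
        a = pysam.AlignedSegment(header)
        a.query_name = "r1"
        a.flag = 0x1 | 0x40
        a.reference_id = 0
        a.reference_start = 10
        a.cigarstring = cigar
        a.query_sequence = "A" * sum(
            ln for op, ln in a.cigartuples if op in (0, 1, 4)
        )
        if nm is not None:
            a.set_tag("NM", nm)
        return a

    @pytest.fixture()
    def header(self):
        return pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr", "LN": 10000}]}
        )

    def test_full_length_exact_match_is_perfect(self, header):
        assert is_perfect(self._read("40M", 0, header))

    def test_one_mismatch_is_not_perfect(self, header):
        assert not is_perfect(self._read("40M", 1, header))

    def test_soft_clip_is_not_perfect(self, header):
        # 39M1S: not full length even with NM 0
        assert not is_perfect(self._read("39M1S", 0, header))

    def test_indel_is_not_perfect(self, header):
        assert not is_perfect(self._read("20M1I19M", 1, header))

    def test_missing_nm_tag_raises(self, header):
        with pytest.raises(KeyError):
            is_perfect(self._read("40M", None, header))


class TestStrandAssignment:
    def _mate(self, toy_annotation, pos, flag, replicon="host_chr"):
        header = pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6"},
                "SQ": [
                    {"SN": n, "LN": l}
                    for n, l in sorted(toy_annotation.replicon_lengths.items())
                ],
            }
        )
        a = pysam.AlignedSegment(header)
        a.query_name = "t"
        a.flag = flag
        a.reference_id = header.get_tid(replicon)
        a.reference_start = pos
        a.cigarstring = "40M"
        a.query_sequence = "A" * 40
        a.set_tag("NM", 0)
        return a

    def test_mate1_forward_in_plus_orf_is_sense(self, toy_annotation):
        idx = FeatureIndex(toy_annotation)
        read = self._mate(toy_annotation, 500, 0x1 | 0x40)  # mate1 forward
        assert assign_mate(read, idx) == {("geneA", "sense")}

    def test_mate1_reverse_in_plus_orf_is_antisense(self, toy_annotation):
        idx = FeatureIndex(toy_annotation)
        read = self._mate(toy_annotation, 500, 0x1 | 0x40 | 0x10)
        assert assign_mate(read, idx) == {("geneA", "antisense")}

    def test_mate2_strand_is_complemented(self, toy_annotation):
        idx = FeatureIndex(toy_annotation)
        # mate2 reverse => transcript on + => sense for a + feature
        read = self._mate(toy_annotation, 500, 0x1 | 0x80 | 0x10)
        assert assign_mate(read, idx) == {("geneA", "sense")}
        assert transcribed_strand(read) == "+"

    def test_opposite_library_dialect_flips_orientation(self, toy_annotation):
        idx = FeatureIndex(toy_annotation)
        read = self._mate(toy_annotation, 500, 0x1 | 0x40)
        assert assign_mate(read, idx, mate1_is_transcript=False) == {
            ("geneA", "antisense")
        }

    def test_read_straddling_orf_boundary_hits_both_features(self, toy_annotation):
        idx = FeatureIndex(toy_annotation)
        read = self._mate(toy_annotation, 1080, 0x1 | 0x40)  # geneA ends at 1100
        hits = assign_mate(read, idx)
        ids = {fid for fid, _ in hits}
        assert "geneA" in ids and len(ids) == 2  # also the intergenic gap
        # exhaustive coordinate check
        for f in idx.ann.features:
            overlaps = f.replicon == "host_chr" and 1080 < f.end and 1120 > f.start
            assert (f.feature_id in ids) == overlaps


class TestCollapsePair:
    def test_both_mates_same_feature_count_once(self):
        hits = {("A", "sense")}
        assert collapse_pair(hits, hits) == {("A", "sense"): 1}

    def test_mates_in_different_features_count_each(self):
        out = collapse_pair({("A", "sense")}, {("B", "sense")})
        assert out == {("A", "sense"): 1, ("B", "sense"): 1}

    def test_single_perfect_mate_still_counts(self):
        assert collapse_pair({("A", "sense")}, set()) == {("A", "sense"): 1}


class TestCountSample:
    def test_round_trip_recovers_requested_counts(self, toy_annotation,
                                                  fixture_requests, tmp_path):
        sam = tmp_path / "s.sam"
        emit_sam_fixture(toy_annotation, fixture_requests, str(sam), seed=1)
        col, log = count_sample(str(sam), toy_annotation)
        for key, expected in fixture_requests.items():
            assert col.loc[key] == expected, key
        # nothing else hit
        assert col.sum() == sum(fixture_requests.values())
        assert log.templates_retained == sum(fixture_requests.values())

    def test_empty_sam_gives_all_zero_column(self, toy_annotation, tmp_path):
        sam = tmp_path / "empty.sam"
        emit_sam_fixture(toy_annotation, {}, str(sam))
        col, log = count_sample(str(sam), toy_annotation)
        assert col.sum() == 0
        assert log.templates_seen == 0

    def test_imperfect_pairs_are_discarded(self, toy_annotation, tmp_path):
        sam = tmp_path / "imp.sam"
        emit_sam_fixture(toy_annotation, {}, str(sam), n_imperfect_pairs=10, seed=2)
        col, log = count_sample(str(sam), toy_annotation)
        assert col.sum() == 0
        assert log.discarded_imperfect == 10

    def test_cross_feature_pair_counts_once_for_each(self, toy_annotation, tmp_path):
        sam = tmp_path / "cross.sam"
        emit_sam_fixture(
            toy_annotation, {}, str(sam),
            cross_pairs=[("geneA", "geneP", "sense")], seed=3,
        )
        col, _ = count_sample(str(sam), toy_annotation)
        assert col.loc[("geneA", "sense")] == 1
        assert col.xs("geneP", level="feature_id").sum() == 1

    def test_header_replicon_mismatch_rejected(self, toy_annotation, tmp_path):
        other = Annotation(
            [FeatureAnnotation("x", "host", "other_chr", 0, 500, "+", "ORF")],
            {"other_chr": 1000},
        )
        sam = tmp_path / "o.sam"
        emit_sam_fixture(other, {("x", "sense"): 1}, str(sam))
        with pytest.raises(CountingError, match="replicon"):
            count_sample(str(sam), toy_annotation)

    def test_record_order_does_not_matter(self, toy_annotation, fixture_requests,
                                          tmp_path):
        sam = tmp_path / "s.sam"
        emit_sam_fixture(toy_annotation, fixture_requests, str(sam), seed=4,
                         n_imperfect_pairs=3)
        lines = sam.read_text().splitlines()
        header = [l for l in lines if l.startswith("@")]
        body = [l for l in lines if not l.startswith("@")]
        random.Random(0).shuffle(body)
        shuffled = tmp_path / "shuf.sam"
        shuffled.write_text("\n".join(header + body) + "\n")
        col1, _ = count_sample(str(sam), toy_annotation)
        col2, _ = count_sample(str(shuffled), toy_annotation)
        assert col1.equals(col2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle_on_random_fixtures(self, seed, tmp_path):
        rng = np.random.default_rng(seed)
        cfg = micro_config(seed=seed, n_host_genes=6, n_phage_genes=3)
        from dualrna.simulate import generate_annotations

        ann = generate_annotations(cfg)
        orfs = [f for f in ann.features if f.feature_class == "ORF"]
        requests = {}
        for f in orfs:
            for orient in ("sense", "antisense"):
                n = int(rng.integers(0, 20))
                if n:
                    requests[(f.feature_id, orient)] = n
        cross = [
            (orfs[i].feature_id, orfs[i + 1].feature_id, "sense")
            for i in range(0, len(orfs) - 1, 3)
        ]
        sam = tmp_path / f"r{seed}.sam"
        emit_sam_fixture(ann, requests, str(sam), seed=seed,
                         n_imperfect_pairs=int(rng.integers(0, 15)),
                         cross_pairs=cross)
        col, _ = count_sample(str(sam), ann)
        oracle = brute_force_recount(str(sam), ann)
        got = {k: int(v) for k, v in col.items() if v > 0}
        assert got == oracle


class TestRemoveRrna:
    def _table(self, toy_annotation, data):
        idx = pd.MultiIndex.from_tuples(
            list(data), names=["feature_id", "orientation"]
        )
        counts = pd.DataFrame({"s1": list(data.values())}, index=idx)
        samples = pd.DataFrame(
            {"time_h": [0.5], "light": ["light"], "infected": ["infected"],
             "replicate": [1]},
            index=pd.Index(["s1"], name="sample_id"),
        )
        return StrandedCountTable(counts=counts, samples=samples)

    def test_rrna_rows_dropped_others_unchanged(self, toy_annotation):
        table = self._table(
            toy_annotation,
            {("rrna16S", "sense"): 1000, ("geneA", "sense"): 10,
             ("geneB", "sense"): 20},
        )
        out, frac = remove_rrna(table, toy_annotation)
        assert list(out.counts.index.get_level_values("feature_id")) == [
            "geneA", "geneB"
        ]
        assert out.counts["s1"].tolist() == [10, 20]
        assert frac["s1"] == pytest.approx(1000 / 1030)

    def test_removed_fraction_reported(self, toy_annotation):
        # a sample that is 14% rRNA reports removed fraction 0.14
        table = self._table(
            toy_annotation, {("rrna16S", "sense"): 14, ("geneA", "sense"): 86}
        )
        _, frac = remove_rrna(table, toy_annotation)
        assert frac["s1"] == pytest.approx(0.14)

    def test_no_rrna_rows_is_a_noop(self, toy_annotation):
        table = self._table(toy_annotation, {("geneA", "sense"): 10})
        out, frac = remove_rrna(table, toy_annotation)
        assert out.counts.equals(table.counts)
        assert frac["s1"] == 0.0
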