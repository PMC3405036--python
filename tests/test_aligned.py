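import numpy as np
import pytest

from primereval.aligned import (AlignedDatabase, AlignedRecord,
                                AlignmentError, WindowError,
                                build_reference_map, depth_profile,
                                map_window, read_aligned_fasta,
                                window_denominator, write_aligned_fasta,
                                write_metadata)
from primereval.synth import SyntheticConfig, generate


def make_db(rows, ref_id=None):
    """rows: list of (id, aligned_seq[, group, envs]) tuples."""
    records = []
    for row in rows:
        rid, seq = row[0], row[1]
        group = row[2] if len(row) > 2 else "other"
        envs = frozenset(row[3]) if len(row) > 3 else frozenset()
        records.append(AlignedRecord(id=rid, aligned_seq=seq,
                                     group_label=group, env_labels=envs))
    ref_id = ref_id or rows[0][0]
    ref = next(r for r in records if r.id == ref_id)
    return AlignedDatabase(records=records,
                           refmap=build_reference_map(ref_id, ref.aligned_seq))


class TestReadWrite:
    def test_round_trip(self, tmp_path, planted):
        db, manifest = planted
        fa = tmp_path / "db.fasta"
        meta = tmp_path / "meta.tsv"
        write_aligned_fasta(db, fa)
        write_metadata(db, meta)
        back = read_aligned_fasta(fa, meta, reference_id="REF")
        assert len(back) == len(db)
        for orig, rec in zip(db.records, back.records):
            assert rec.id == orig.id
            assert rec.aligned_seq == orig.aligned_seq
            assert rec.group_label == orig.group_label
            assert rec.env_labels == orig.env_labels
        # manifest labels round-trip
        for man_rec, rec in zip(manifest.records, back.records):
            assert man_rec["group"] == rec.group_label
            assert man_rec["envs"] == rec.env_labels

    def test_three_records_with_reference(self, tmp_path):
        fa = tmp_path / "x.fasta"
        fa.write_text(">REF\nACGTACGT\n>a\nAC--ACGT\n>b\n--GTAC--\n")
        db = read_aligned_fasta(fa, reference_id="REF")
        assert len(db) == 3
        assert db.refmap.reference_length == 8

    def test_ragged_alignment_rejected(self, tmp_path):
        fa = tmp_path / "x.fasta"
        fa.write_text(">REF\nACGTACGT\n>a\nACGT\n")
        with pytest.raises(AlignmentError, match="ragged"):
            read_aligned_fasta(fa, reference_id="REF")

    def test_missing_reference_rejected(self, tmp_path):
        fa = tmp_path / "x.fasta"
        fa.write_text(">a\nACGT\n")
        with pytest.raises(AlignmentError, match="not in alignment"):
            read_aligned_fasta(fa, reference_id="REF")

    def test_dot_gaps_and_lowercase_accepted(self):
        rec = AlignedRecord(id="a", aligned_seq="ac.t-g")
        assert rec.aligned_seq == "AC-T-G"

    def test_all_gap_record_rejected(self):
        with pytest.raises(AlignmentError, match="all gaps"):
            AlignedRecord(id="a", aligned_seq="--..--")


class TestDepthProfile:
    def test_flat_for_identical_full_length(self):
        db = make_db([("REF", "ACGTACGTAC")] +
                     [(f"r{i}", "ACGTACGTAC") for i in range(49)])
        assert (depth_profile(db) == 50).all()

    def test_gap_does_not_increment(self):
        db = make_db([("REF", "ACGT"), ("a", "A-GT"), ("b", "AC-T")])
        assert list(depth_profile(db)) == [3, 2, 2, 3]

    def test_matches_manifest_interval_stabbing(self, fig1):
        db, manifest = fig1
        prof = depth_profile(db)
        for pos in range(1, manifest.ref_length + 1, 13):
            assert prof[pos - 1] == manifest.expected_depth(pos), pos

    def test_sum_equals_total_reference_column_characters(self, planted):
        db, _ = planted
        nt = db.nucleotide_matrix()
        cols = db.refmap.refpos_to_column
        assert depth_profile(db).sum() == nt[:, cols].sum()

    def test_insertion_columns_invisible(self, registry):
        base = dict(n_records=40, seed=3, ref_length=300, span="uniform")
        db_plain, _ = generate(SyntheticConfig(**base))
        db_ins, _ = generate(SyntheticConfig(
            **base, insertion_columns=((100, 4), (200, 2)),
            insertion_fill_fraction=0.5))
        assert db_ins.alignment_length == db_plain.alignment_length + 6
        assert (depth_profile(db_ins) == depth_profile(db_plain)).all()


class TestWindowDenominator:
    def test_full_length_records(self):
        db = make_db([("REF", "ACGTACGTAC")] +
                     [(f"r{i}", "ACGTACGTAC") for i in range(9)])
        assert window_denominator(db, (2, 9)) == 10

    def test_span_containment(self):
        ref = "A" * 400
        frag = "-" * 99 + "C" * 201 + "-" * 100  # covers positions 100-300
        db = make_db([("REF", ref), ("frag", frag)])
        assert window_denominator(db, (115, 131)) == 2
        assert window_denominator(db, (310, 390)) == 1  # only REF

    def test_internal_gaps_still_count(self):
        db = make_db([("REF", "ACGTACGTAC"), ("a", "AC--ACGTAC")])
        # endpoints rule: gaps at 3-4 are a deletion, not absence
        assert window_denominator(db, (2, 6)) == 2
        assert window_denominator(db, (2, 6), require_full=True) == 1

    def test_matches_manifest(self, fig1):
        db, manifest = fig1
        for window in [(115, 131), (457, 473), (19, 35), (388, 413)]:
            expected = sum(
                1 for r in manifest.records
                if r["span"][0] <= window[0] and r["span"][1] >= window[1])
            assert window_denominator(db, window) == expected

    def test_monotone_under_window_inclusion(self, fig1):
        db, _ = fig1
        rng = np.random.default_rng(0)
        L = db.refmap.reference_length
        for _ in range(25):
            s = int(rng.integers(1, L - 50))
            e = int(rng.integers(s + 10, min(s + 200, L)))
            grow_s, grow_e = max(1, s - 20), min(L, e + 20)
            assert window_denominator(db, (s, e)) >= \
                window_denominator(db, (grow_s, grow_e))

    def test_window_outside_reference_rejected(self, planted):
        db, _ = planted
        with pytest.raises(WindowError):
            window_denominator(db, (590, 700))


class TestMapWindow:
    def test_identity_for_ungapped_reference(self):
        refmap = build_reference_map("REF", "ACGTACGTAC")
        assert map_window(refmap, (3, 7)) == (2, 6)  # 0-based columns

    def test_offset_by_insertion_column(self):
        # one insertion column before reference position 10
        aligned = "ACGTACGTA" + "-" + "CGTACGTACGT"
        refmap = build_reference_map("REF", aligned)
        assert map_window(refmap, (10, 20)) == (10, 20)
        assert map_window(refmap, (1, 9)) == (0, 8)

    def test_beyond_reference_rejected(self):
        refmap = build_reference_map("REF", "ACGTACGT")
        with pytest.raises(WindowError, match="cannot be represented"):
            map_window(refmap, (5, 12))

    def test_round_trip_property(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            chars = list("ACGT" * 30)
            for pos in rng.choice(len(chars), size=15, replace=False):
                chars[pos] = "-"
            aligned = "".join(chars)
            refmap = build_reference_map("REF", aligned)
            L = refmap.reference_length
            s = int(rng.integers(1, L))
            e = int(rng.integers(s, L + 1))
            c0, c1 = map_window(refmap, (s, e))
            assert refmap.column_to_refpos[c0] == s
            assert refmap.column_to_refpos[c1] == e
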