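import numpy as np
import pytest

from primereval.aligned import AlignedDatabase, AlignedRecord, \
    build_reference_map
from primereval.iupac import reverse_complement_seq
from primereval.matching import char_match, scan, scan_oracle
from primereval.registry import validate_primer
from primereval.synth import PrimerPlant, SyntheticConfig, generate

from conftest import random_degenerate


def single_record_db(seq, rid="REF"):
    rec = AlignedRecord(id=rid, aligned_seq=seq)
    return AlignedDatabase(records=[rec],
                           refmap=build_reference_map(rid, rec.aligned_seq))


def random_db(rng, n_records, length=150):
    rows = []
    ref = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
    rows.append(AlignedRecord(id="REF", aligned_seq=ref))
    for i in range(n_records - 1):
        seq = list("ACGT"[j] for j in rng.integers(0, 4, size=length))
        # sprinkle gaps and ambiguity codes on the target side
        for pos in rng.choice(length, size=length // 10, replace=False):
            seq[pos] = "-"
        for pos in rng.choice(length, size=3, replace=False):
            if seq[pos] != "-":
                seq[pos] = "RYSWKMN"[rng.integers(7)]
        rows.append(AlignedRecord(id=f"r{i}", aligned_seq="".join(seq)))
    return AlignedDatabase(
        records=rows, refmap=build_reference_map("REF", ref))


class TestCharMatch:
    @pytest.mark.parametrize("p,t,expected", [
        ("R", "A", True),
        ("Y", "G", False),
        ("I", "C", True),   # universal base
        ("N", "R", True),
        ("A", "A", True),
        ("A", "C", False),
    ])
    def test_intersection(self, p, t, expected):
        assert char_match(p, t) is expected

    def test_gap_never_matches(self):
        assert char_match("N", "-") is False

    def test_strict_policy(self):
        # ambiguous target not contained in pattern set -> mismatch
        assert char_match("R", "N", policy="strict") is False
        assert char_match("N", "R", policy="strict") is True
        assert char_match("R", "N", policy="intersection") is True

    def test_unknown_characters_rejected(self):
        with pytest.raises(ValueError):
            char_match("P", "A")
        with pytest.raises(ValueError):
            char_match("A", "Z")


class TestScan:
    def test_planted_fraction(self, registry):
        """10 records, 7 with an exact site -> 7 hit sequences at k=0."""
        cfg = SyntheticConfig(
            n_records=10, seed=1, ref_length=600, span="full",
            plants=[PrimerPlant(registry.primer("F2"), {1: 0.3})])
        db, _ = generate(cfg)
        res = scan(db, registry.primer("F2"), k=0)
        assert res.hit_sequences == 7

    def test_double_site_counts_two_events(self):
        site = "TGCGATCCAAAAGCTGA"  # one expansion of F2 (I read as any)
        spacer = "TTTTTTTTTT"
        db = single_record_db(site + spacer + site)
        p = validate_primer("F2", "TGYGAYCCIAAIGCIGA", orientation="forward")
        res = scan(db, p, k=0, window=None)
        assert res.hit_events == 2
        assert res.hit_sequences == 1

    def test_monotone_in_k(self, fig1, registry):
        db, _ = fig1
        for name in ("Nh21F", "F2", "nifH3", "polF"):
            p = registry.primer(name)
            events = [scan(db, p, k=k).hit_events for k in (0, 1, 2)]
            assert events == sorted(events)

    def test_window_confinement_only_adds_events_when_lifted(self, fig1,
                                                             registry):
        db, _ = fig1
        p = registry.primer("F2")
        assert scan(db, p, k=1, window=None).hit_events >= \
            scan(db, p, k=1).hit_events

    def test_empty_database(self):
        db = AlignedDatabase(records=[],
                             refmap=build_reference_map("REF", "ACGTACGT"))
        p = validate_primer("p", "ACGTACGT")
        assert scan(db, p, k=0, window=None).hit_events == 0

    def test_exact_substring_single_event(self):
        db = single_record_db("GGGGACGTACGTTTTT")
        p = validate_primer("p", "ACGTACGT")
        assert scan(db, p, k=0, window=None).hit_events == 1

    def test_longer_than_records_warns(self):
        db = single_record_db("ACGT")
        p = validate_primer("p", "ACGTACGTACGT")
        with pytest.warns(UserWarning, match="longer than every record"):
            res = scan(db, p, k=0, window=None)
        assert res.hit_events == 0

    def test_nonstandard_primer_refused(self, registry):
        db = single_record_db("ACGTACGTACGT")
        with pytest.raises(ValueError, match="non-IUPAC"):
            scan(db, registry.primer("PicenoF44"), k=0)


class TestOracleEquivalence:
    def test_randomized_instances(self):
        """scan == scan_oracle on random dbs x random degenerate primers."""
        rng = np.random.default_rng(42)
        db = random_db(rng, 60)
        for i in range(10):
            seq = random_degenerate(rng, int(rng.integers(12, 22)))
            orientation = "forward" if rng.random() < 0.5 else "reverse"
            p = validate_primer(f"p{i}", seq, orientation=orientation)
            for k in (0, 1, 2):
                a = scan(db, p, k=k, window=None)
                b = scan_oracle(db, p, k=k, window=None)
                key = lambda r: sorted(
                    (h.record_index, h.start_index, h.mismatches)
                    for h in r.hits)
                assert key(a) == key(b), (seq, orientation, k)

    def test_windowed_equivalence(self, fig1, registry):
        db, _ = fig1
        for name in ("F2", "R6", "nifH3"):
            p = registry.primer(name)
            for k in (0, 1):
                a = scan(db, p, k=k)
                b = scan_oracle(db, p, k=k)
                assert a.hit_events == b.hit_events
                assert a.hit_sequences == b.hit_sequences


class TestInvariances:
    def test_strand_symmetry(self):
        """Scanning rc(p) against a record equals scanning p against the
        record's reverse complement."""
        rng = np.random.default_rng(5)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=120))
        p = validate_primer("p", random_degenerate(rng, 15))
        rc_p = validate_primer("p_rc", reverse_complement_seq(p.sequence))
        db_fwd = single_record_db(seq)
        db_rev = single_record_db(reverse_complement_seq(seq))
        a = scan(db_fwd, rc_p, k=1, window=None)
        b = scan(db_rev, p, k=1, window=None)
        assert a.hit_events == b.hit_events

    def test_gap_insertion_invariance(self):
        """Hits are unchanged by inserting gap columns (ungapped matching)."""
        rng = np.random.default_rng(6)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=100))
        p = validate_primer("p", random_degenerate(rng, 14))
        plain = single_record_db(seq)
        gapped_chars = list(seq)
        for pos in sorted(rng.choice(100, size=12, replace=False),
                          reverse=True):
            gapped_chars.insert(pos, "-")
        gapped = single_record_db("".join(gapped_chars))
        for k in (0, 1, 2):
            a = scan(plain, p, k=k, window=None)
            b = scan(gapped, p, k=k, window=None)
            assert [h.matched for h in a.hits] == [h.matched for h in b.hits]

    def test_reverse_primer_scanned_as_rc(self, registry):
        """A reverse primer hits where its reverse complement appears."""
        p = registry.primer("R6")  # TCIGGIGARATGATGGC
        sense_site = reverse_complement_seq(p.sequence).replace("I", "A") \
            .replace("R", "G").replace("Y", "C").replace("N", "A")
        db = single_record_db("TTTT" + sense_site + "TTTT")
        res = scan(db, p, k=0, window=None)
        assert res.hit_events >= 1
        assert res.hits[0].strand == "-"
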