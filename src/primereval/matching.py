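"""Mismatch-tolerant degenerate pattern scanning against aligned databases.

Matching is Hamming-style against the gap-stripped (ungapped) sequence of
each record: gaps are skipped, no indels are tolerated within a hit.
Reverse-orientation primers are scanned as their reverse complement against
the sense strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .aligned import AlignedDatabase
from .iupac import MATCH_SETS, pattern_mask_array, target_mask_array
from .registry import Primer, expand, reverse_complement_seq

#: how ambiguous target-side characters are treated
AMBIGUITY_POLICIES = ("intersection", "strict")


def char_match(pattern_char: str, target_char: str,
               policy: str = "intersection") -> bool:
    """True iff the primer character can pair with the target character.

    ``intersection`` (default): base sets overlap; an ambiguous database
    base *could* be the primer's base.  ``strict``: the target's base set
    must be fully contained in the pattern's (an ambiguous target base that
    might mismatch counts as a mismatch).  Gaps never match.
    """
    if target_char in "-.":
        return False
    p = MATCH_SETS.get(pattern_char.upper())
    t = MATCH_SETS.get(target_char.upper())
    if p is None:
        raise ValueError(f"unknown pattern character {pattern_char!r}")
    if t is None:
        raise ValueError(f"unknown target character {target_char!r}")
    if policy == "strict":
        return t <= p
    return bool(p & t)


@dataclass(frozen=True)
class Hit:
    record_index: int
    record_id: str
    start_index: int          # 0-based index into the ungapped sequence
    ref_start: int            # 1-based reference position (0 if insertion)
    ref_end: int
    strand: str
    mismatches: int
    matched: str


@dataclass
class MatchResult:
    primer_name: str
    k: int
    hit_events: int
    hit_sequences: int
    hits: list[Hit] = field(default_factory=list)
    scanned_window: Optional[tuple[int, int]] = None

    def events_per_record(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for h in self.hits:
            out[h.record_index] = out.get(h.record_index, 0) + 1
        return out


# ---------------------------------------------------------------------------
# per-record scan caches
# ---------------------------------------------------------------------------

def _record_arrays(db: AlignedDatabase, idx: int):
    """(ungapped string, target bitmask array, refpos per ungapped index)."""
    key = ("rec", idx)
    if key not in db._cache:
        rec = db.records[idx]
        seq = rec.ungapped
        codes = np.frombuffer(rec.aligned_seq.encode("ascii"), dtype=np.uint8)
        nongap = codes != ord("-")
        cols = np.flatnonzero(nongap)
        refpos = db.refmap.column_to_refpos[cols]
        db._cache[key] = (seq, target_mask_array(seq), refpos)
    return db._cache[key]


def _pattern_for_scan(primer: Primer) -> str:
    if primer.nonstandard:
        raise ValueError(
            f"{primer.name}: contains non-IUPAC characters; "
            "excluded from matching")
    if primer.orientation == "reverse":
        return reverse_complement_seq(primer.sequence)
    return primer.sequence


def _mismatch_counts(tmask: np.ndarray, pmask: np.ndarray,
                     starts: np.ndarray, policy: str) -> np.ndarray:
    """Mismatch count of the pattern placed at each candidate start."""
    m = len(pmask)
    if policy == "strict":
        # mismatch when the target set is not contained in the pattern set
        fail = lambda t, p: ((t & ~p) != 0) | (t == 0)
    else:
        fail = lambda t, p: (t & p) == 0
    if len(starts) > 4 and len(starts) == len(tmask) - m + 1:
        # dense scan: one vectorized sliding-window pass
        windows = sliding_window_view(tmask, m)
        return fail(windows, pmask).sum(axis=1).astype(int)
    out = np.empty(len(starts), dtype=int)
    for j, s in enumerate(starts):
        out[j] = int(fail(tmask[s:s + m], pmask).sum())
    return out


def scan(db: AlignedDatabase, primer: Primer, k: int = 0,
         window="auto", tolerance: int = 0,
         policy: str = "intersection") -> MatchResult:
    """Scan every record for primer sites with at most ``k`` mismatches.

    ``window`` — "auto": confine hit starts to the primer's own binding
    window (the per-primer coverage convention); None: scan the whole
    alignment; or an explicit (start, end) reference interval.  With a
    window, a hit must start at a position whose reference coordinate lies
    within ``tolerance`` of the window start (default exactly at it).
    """
    if policy not in AMBIGUITY_POLICIES:
        raise ValueError(f"unknown ambiguity policy {policy!r}")
    if window == "auto":
        window = primer.binding_window
    cache_key = ("scan", primer.name, primer.sequence, primer.orientation,
                 k, tuple(window) if window else None, tolerance, policy)
    if cache_key in db._cache:
        return db._cache[cache_key]
    pattern = _pattern_for_scan(primer)
    pmask = pattern_mask_array(pattern)
    m = len(pmask)
    strand = "+" if primer.orientation == "forward" else "-"

    hits: list[Hit] = []
    any_scannable = False
    for idx, rec in enumerate(db.records):
        seq, tmask, refpos = _record_arrays(db, idx)
        if len(seq) < m:
            continue
        any_scannable = True
        if window is None:
            starts = np.arange(len(seq) - m + 1)
        else:
            lo, hi = window[0] - tolerance, window[0] + tolerance
            starts = np.flatnonzero(
                (refpos >= max(lo, 1)) & (refpos <= hi))
            starts = starts[starts + m <= len(seq)]
        if len(starts) == 0:
            continue
        mm = _mismatch_counts(tmask, pmask, starts, policy)
        for s, c in zip(starts[mm <= k], mm[mm <= k]):
            s = int(s)
            hits.append(Hit(
                record_index=idx, record_id=rec.id, start_index=s,
                ref_start=int(refpos[s]), ref_end=int(refpos[s + m - 1]),
                strand=strand, mismatches=int(c),
                matched=seq[s:s + m]))
    if not any_scannable and len(db.records):
        warnings.warn(
            f"{primer.name}: primer longer than every record; zero hits")
    result = MatchResult(
        primer_name=primer.name, k=k,
        hit_events=len(hits),
        hit_sequences=len({h.record_index for h in hits}),
        hits=hits,
        scanned_window=tuple(window) if window else None)
    db._cache[cache_key] = result
    return result


def write_hit_report(result: MatchResult, path, policy: str = "intersection",
                     extra_meta: dict = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# primer={result.primer_name} k={result.k} "
                 f"ambiguity_policy={policy}\n")
        for key, val in (extra_meta or {}).items():
            fh.write(f"# {key}={val}\n")
        fh.write("record_id\tref_start\tref_end\tstrand\tmismatches\tmatched\n")
        for h in result.hits:
            fh.write(f"{h.record_id}\t{h.ref_start}\t{h.ref_end}\t"
                     f"{h.strand}\t{h.mismatches}\t{h.matched}\n")


# ---------------------------------------------------------------------------
# brute-force oracle (tests only): full expansion + per-expansion Hamming
# ---------------------------------------------------------------------------

_ORACLE_BASES = "ACGTI"
_MEMBER = np.zeros((256, len(_ORACLE_BASES)), dtype=bool)
for _tc, _tset in MATCH_SETS.items():
    for _bi, _b in enumerate(_ORACLE_BASES):
        ok = _tset & MATCH_SETS[_b] if _b != "I" else _tset
        _MEMBER[ord(_tc), _bi] = bool(ok)


def scan_oracle(db: AlignedDatabase, primer: Primer, k: int = 0,
                window="auto", tolerance: int = 0,
                cap: int = 65_536) -> MatchResult:
    """Same contract as :func:`scan`, implemented by expanding the primer
    into its concrete oligos and sliding each one independently.

    Deliberately shares no scanning machinery with :func:`scan`; used as the
    independent correctness oracle in the test suite.
    """
    if window == "auto":
        window = primer.binding_window
    pattern = _pattern_for_scan(primer)
    expansions = sorted(expand(pattern, cap=cap))
    m = len(pattern)
    exp_idx = np.array(
        [[_ORACLE_BASES.index(c) for c in e] for e in expansions], dtype=int)
    strand = "+" if primer.orientation == "forward" else "-"

    hits: list[Hit] = []
    for idx, rec in enumerate(db.records):
        # recompute ungapped sequence and reference positions from scratch
        seq_chars, refpos = [], []
        pos = 0
        for col, c in enumerate(rec.aligned_seq):
            rp = int(db.refmap.column_to_refpos[col])
            if c != "-":
                seq_chars.append(c)
                refpos.append(rp)
        seq = "".join(seq_chars)
        if len(seq) < m:
            continue
        codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        allowed = _MEMBER[codes]                      # (L, 5)
        sw = sliding_window_view(allowed, m, axis=0)  # (L-m+1, 5, m)
        jj = np.arange(m)
        # per expansion: matches at each start
        best = None
        for row in exp_idx:
            okmat = sw[:, row, jj]                    # (L-m+1, m)
            mm = m - okmat.sum(axis=1)
            best = mm if best is None else np.minimum(best, mm)
        for s in np.flatnonzero(best <= k):
            s = int(s)
            if window is not None:
                rp = refpos[s]
                if not (window[0] - tolerance <= rp <= window[0] + tolerance
                        and rp > 0):
                    continue
            hits.append(Hit(
                record_index=idx, record_id=rec.id, start_index=s,
                ref_start=refpos[s], ref_end=refpos[s + m - 1],
                strand=strand, mismatches=int(best[s]),
                matched=seq[s:s + m]))
    return MatchResult(
        primer_name=primer.name, k=k,
        hit_events=len(hits),
        hit_sequences=len({h.record_index for h in hits}),
        hits=hits,
        scanned_window=tuple(window) if window else None)
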