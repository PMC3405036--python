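"""In-silico PCR for primer pairs: amplicon prediction and pair coverage.

Pair coverage counts *records* yielding at least one amplicon (the pair
tables contain no >100% values), over the records with nucleotide
representation in BOTH primer windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .aligned import AlignedDatabase, AlignedRecord, WindowError, \
    build_reference_map, window_span_mask
from .coverage import CoverageCell
from .matching import scan
from .registry import Primer, PrimerPair, expected_length


@dataclass(frozen=True)
class AmpliconPrediction:
    record_id: str
    fwd_start: int      # reference coordinate of the forward 5' end
    rev_end: int        # reference coordinate of the reverse 5' end
    length: int         # inclusive span in reference coordinates
    template_length: int  # ungapped template-relative product length
    fwd_mismatches: int
    rev_mismatches: int


def _as_database(record: AlignedRecord | AlignedDatabase) -> AlignedDatabase:
    if isinstance(record, AlignedDatabase):
        return record
    refmap = build_reference_map(record.id, record.aligned_seq)
    return AlignedDatabase(records=[record], refmap=refmap)


def find_amplicons(record, fwd: Primer, rev: Primer, k: int = 0,
                   max_length: Optional[int] = None,
                   policy: str = "intersection") -> list[AmpliconPrediction]:
    """All correctly oriented (forward hit, reverse hit) products on a record.

    ``record`` may be a single AlignedRecord (gapped or not; the record's
    own coordinates are then the reference frame) or a one-record database.
    Both primers are scanned over the whole template; the forward site must
    lie strictly 5' of the reverse site, and the product must not exceed
    ``max_length`` when given.
    """
    db = _as_database(record)
    if fwd.orientation != "forward" or rev.orientation != "reverse":
        raise ValueError("find_amplicons expects a forward and a reverse primer")
    fhits = scan(db, fwd, k=k, window=None, policy=policy).hits
    rhits = scan(db, rev, k=k, window=None, policy=policy).hits
    out = []
    for fh in fhits:
        for rh in rhits:
            if rh.start_index <= fh.start_index:
                continue  # reverse site must be 3' of the forward site
            tmpl_len = rh.start_index + len(rev.sequence) - fh.start_index
            if tmpl_len <= 0:
                continue
            if max_length is not None and tmpl_len > max_length:
                continue
            out.append(AmpliconPrediction(
                record_id=fh.record_id,
                fwd_start=fh.ref_start, rev_end=rh.ref_end,
                length=rh.ref_end - fh.ref_start + 1
                if rh.ref_end and fh.ref_start else tmpl_len,
                template_length=tmpl_len,
                fwd_mismatches=fh.mismatches,
                rev_mismatches=rh.mismatches))
    return out


def pair_coverage(db: AlignedDatabase, pair: PrimerPair, k: int = 0,
                  stratum: str = "all", policy: str = "intersection",
                  require_full: bool = False) -> CoverageCell:
    """Coverage of a primer pair at mismatch budget ``k`` within a stratum.

    Numerator: records with a window-confined hit for both primers.
    Denominator: records spanning both binding windows.  Either window
    unmappable (or absent) yields an NA cell.
    """
    fwd, rev = pair.forward, pair.reverse
    if (fwd.binding_window is None or rev.binding_window is None
            or fwd.nonstandard or rev.nonstandard):
        return CoverageCell(pair.name, stratum, k, 0, 0)
    try:
        span_f = window_span_mask(db, fwd.binding_window, require_full)
        span_r = window_span_mask(db, rev.binding_window, require_full)
    except WindowError:
        return CoverageCell(pair.name, stratum, k, 0, 0)
    smask = np.zeros(len(db.records), dtype=bool)
    smask[db.subset_indices(stratum)] = True
    denom = int((smask & span_f & span_r).sum())

    fseqs = {h.record_index for h in scan(db, fwd, k=k, policy=policy).hits}
    rseqs = {h.record_index for h in scan(db, rev, k=k, policy=policy).hits}
    num = sum(1 for i in (fseqs & rseqs) if smask[i])
    return CoverageCell(pair.name, stratum, k, num, denom)


def evaluate_pairs(db: AlignedDatabase, pairs: Sequence[PrimerPair],
                   k: int = 0,
                   groups: Sequence[str] = ("Pr", "Cy", "III", "IA",
                                            "Fr", "Pb", "Ep", "IV"),
                   environments: Sequence[str] = ("Soil", "Mat", "Sea"),
                   policy: str = "intersection") -> pd.DataFrame:
    """One row per pair: pos, expected length, and coverage per stratum."""
    known = db.groups | db.environments
    rows = []
    for pair in pairs:
        row: dict = {"pair": pair.name}
        if pair.amplicon_window:
            row["pos"] = f"{pair.amplicon_window[0]}-{pair.amplicon_window[1]}"
            row["length"] = expected_length(pair)
        else:
            row["pos"] = pd.NA
            row["length"] = pd.NA
        strata = ["all"] + [s for s in list(groups) + list(environments)]
        for s in strata:
            if s != "all" and s not in known:
                row["all" if s == "all" else s] = pd.NA
                continue
            cell = pair_coverage(db, pair, k=k, stratum=s, policy=policy)
            val = cell.percent
            row["all" if s == "all" else s] = val if val is not None else pd.NA
        rows.append(row)
    return pd.DataFrame(rows)


def amplicon_table(predictions: Sequence[AmpliconPrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"record_id": a.record_id, "fwd_start": a.fwd_start,
          "rev_end": a.rev_end, "length": a.length,
          "template_length": a.template_length,
          "fwd_mm": a.fwd_mismatches, "rev_mm": a.rev_mismatches}
         for a in predictions],
        columns=["record_id", "fwd_start", "rev_end", "length",
                 "template_length", "fwd_mm", "rev_mm"])
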