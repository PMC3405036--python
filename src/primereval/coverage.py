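"""Depth-normalized coverage percentages, stratified by phylogenetic group
and environment.

Coverage = hit events within the primer's binding window divided by the
number of records with nucleotide representation spanning that window, as a
half-up-rounded integer percent.  A zero denominator yields NA (distinct
from a zero numerator over a positive denominator, which is 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .aligned import AlignedDatabase, WindowError, window_span_mask
from .matching import MatchResult, scan
from .registry import Primer, Registry, degeneracy

DEFAULT_GROUP_ORDER = ("Pr", "Cy", "III", "IA", "Fr", "Pb", "Ep", "IV")
DEFAULT_ENV_ORDER = ("Soil", "Mat", "Sea")


def round_half_up(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CoverageCell:
    primer_name: str
    stratum: str
    k: int
    numerator: int
    denominator: int

    @property
    def percent(self) -> Optional[int]:
        if self.denominator == 0:
            return None  # NA
        return round_half_up(100.0 * self.numerator / self.denominator)


def _stratum_mask(db: AlignedDatabase, stratum: str) -> np.ndarray:
    mask = np.zeros(len(db.records), dtype=bool)
    mask[db.subset_indices(stratum)] = True
    return mask


def coverage_from_result(db: AlignedDatabase, result: MatchResult,
                         window: tuple[int, int], stratum: str = "all",
                         multi_hit: str = "events",
                         require_full: bool = False) -> CoverageCell:
    """Build a CoverageCell from an existing scan result."""
    smask = _stratum_mask(db, stratum)
    span = window_span_mask(db, window, require_full)
    denom = int((smask & span).sum())
    if multi_hit == "events":
        num = sum(n for i, n in result.events_per_record().items() if smask[i])
    elif multi_hit == "sequences":
        num = len({h.record_index for h in result.hits if smask[h.record_index]})
    else:
        raise ValueError(f"multi_hit must be events|sequences, got {multi_hit!r}")
    return CoverageCell(primer_name=result.primer_name, stratum=stratum,
                        k=result.k, numerator=num, denominator=denom)


def primer_coverage(db: AlignedDatabase, primer: Primer, k: int = 0,
                    stratum: str = "all", multi_hit: str = "events",
                    policy: str = "intersection",
                    require_full: bool = False) -> CoverageCell:
    """Coverage of one primer at one mismatch budget within one stratum."""
    if primer.binding_window is None:
        return CoverageCell(primer.name, stratum, k, 0, 0)  # NA
    result = scan(db, primer, k=k, policy=policy)
    return coverage_from_result(db, result, primer.binding_window, stratum,
                                multi_hit, require_full)


def evaluate_registry(db: AlignedDatabase, primers: Sequence[Primer],
                      k_list: Sequence[int] = (0, 1, 2),
                      groups: Sequence[str] = DEFAULT_GROUP_ORDER,
                      environments: Sequence[str] = DEFAULT_ENV_ORDER,
                      stratum_k: int = 0,
                      multi_hit: str = "events",
                      policy: str = "intersection",
                      tm_ranges: Optional[dict] = None) -> pd.DataFrame:
    """One row per primer, mirroring the survey-table layout.

    Columns: name, pos, degeneracy, tm, percent at each k over all records,
    percent at ``stratum_k`` per group and per environment.  NA cells are
    pandas NA.  Row order is registry order.
    """
    known = db.groups | db.environments
    rows = []
    for p in primers:
        row: dict = {"name": p.name}
        if p.binding_window:
            row["pos"] = f"{p.binding_window[0]}-{p.binding_window[1]}"
        else:
            row["pos"] = pd.NA
        row["degeneracy"] = pd.NA if p.nonstandard else degeneracy(p)
        if tm_ranges and p.name in tm_ranges:
            row["tm"] = tm_ranges[p.name]
        else:
            row["tm"] = pd.NA
        usable = not p.nonstandard and p.binding_window is not None
        if usable:
            try:
                results = {k: scan(db, p, k=k, policy=policy)
                           for k in sorted(set(k_list) | {stratum_k})}
            except WindowError:
                usable = False
        for k in k_list:
            row[f"k{k}"] = _pct(db, p, results.get(k), multi_hit) \
                if usable else pd.NA
        for s in list(groups) + list(environments):
            if usable and s in known:
                row[s] = _pct(db, p, results[stratum_k], multi_hit, s)
            else:
                row[s] = pd.NA
        rows.append(row)
    return pd.DataFrame(rows)


def _pct(db, primer, result, multi_hit, stratum="all"):
    try:
        cell = coverage_from_result(db, result, primer.binding_window,
                                    stratum, multi_hit)
    except WindowError:
        return pd.NA  # window not representable on this reference
    return cell.percent if cell.percent is not None else pd.NA


def summarize_thresholds(table: pd.DataFrame,
                         thresholds: tuple = (90, 50, 10),
                         column: str = "k0") -> dict[str, int]:
    """Counts of primers at/above, below, and at/below the three thresholds."""
    hi, mid, lo = thresholds
    vals = pd.to_numeric(table[column], errors="coerce").dropna()
    return {
        f">={hi}": int((vals >= hi).sum()),
        f"<{mid}": int((vals < mid).sum()),
        f"<={lo}": int((vals <= lo).sum()),
    }


def write_coverage_table(table: pd.DataFrame, path,
                         metadata: Optional[dict] = None) -> None:
    """TSV with '#'-prefixed metadata header lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}={val}\n")
        table.to_csv(fh, sep="\t", index=False, na_rep="NA")
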