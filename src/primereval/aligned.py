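"""Aligned marker-gene databases: reading, reference-coordinate mapping,
positional depth profiles and window denominators.

All user-facing coordinates are 1-based inclusive positions on the
designated reference sequence; alignment columns are internal 0-based and
never exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .iupac import GAP_CHARS, target_mask_array

KNOWN_GROUPS = ("Pr", "Cy", "III", "IA", "Fr", "Pb", "Ep", "IV", "other")
KNOWN_ENVS = ("Soil", "Mat", "Sea", "other")


class AlignmentError(ValueError):
    pass


class WindowError(ValueError):
    """A requested window cannot be represented on the reference."""


@dataclass
class AlignedRecord:
    id: str
    aligned_seq: str
    group_label: str = "other"
    env_labels: frozenset = frozenset()

    def __post_init__(self):
        self.aligned_seq = self.aligned_seq.upper().replace(".", "-")
        if not any(c not in GAP_CHARS for c in self.aligned_seq):
            raise AlignmentError(f"{self.id}: record is all gaps")

    @property
    def ungapped(self) -> str:
        return self.aligned_seq.replace("-", "")


@dataclass
class ReferenceMap:
    """Bidirectional mapping between alignment columns and reference positions."""

    reference_id: str
    #: per alignment column: 1-based reference position, or 0 for insertion columns
    column_to_refpos: np.ndarray
    #: index r-1 -> alignment column of reference position r
    refpos_to_column: np.ndarray

    @property
    def reference_length(self) -> int:
        return len(self.refpos_to_column)

    def column_of(self, refpos: int) -> int:
        if not 1 <= refpos <= self.reference_length:
            raise WindowError(
                f"reference position {refpos} outside 1..{self.reference_length}"
                " (binding position cannot be represented on this reference)")
        return int(self.refpos_to_column[refpos - 1])


def map_window(refmap: ReferenceMap, window: tuple[int, int]) -> tuple[int, int]:
    """Map a 1-based inclusive reference window to alignment columns."""
    s, e = window
    if s > e:
        raise WindowError(f"window {s}-{e} out of order")
    return refmap.column_of(s), refmap.column_of(e)


@dataclass
class AlignedDatabase:
    records: list[AlignedRecord]
    refmap: ReferenceMap

    # lazily built scan caches (see matching module)
    _cache: dict = field(default_factory=dict, repr=False)

    def __len__(self):
        return len(self.records)

    def __post_init__(self):
        lengths = {len(r.aligned_seq) for r in self.records}
        if len(lengths) > 1:
            raise AlignmentError(
                f"ragged alignment: row lengths {sorted(lengths)}")
        if self.records and len(self.refmap.column_to_refpos) not in lengths:
            raise AlignmentError("reference map length does not match alignment")

    @property
    def alignment_length(self) -> int:
        return len(self.refmap.column_to_refpos)

    @property
    def groups(self) -> set[str]:
        return {r.group_label for r in self.records}

    @property
    def environments(self) -> set[str]:
        out = set()
        for r in self.records:
            out |= r.env_labels
        return out

    def subset_indices(self, stratum: str) -> np.ndarray:
        """Record indices belonging to a stratum ('all', a group, or an env)."""
        if stratum == "all":
            return np.arange(len(self.records))
        groups = self.groups
        envs = self.environments
        if stratum in groups:
            sel = [i for i, r in enumerate(self.records)
                   if r.group_label == stratum]
        elif stratum in envs:
            sel = [i for i, r in enumerate(self.records)
                   if stratum in r.env_labels]
        else:
            known = sorted(groups | envs)
            raise KeyError(
                f"unknown stratum {stratum!r}; known strata: all, {known}")
        return np.asarray(sel, dtype=int)

    # --- matrices used by profiling/matching -------------------------------
    def char_matrix(self) -> np.ndarray:
        """(n_records, n_columns) uint8 matrix of ASCII codes."""
        if "chars" not in self._cache:
            if not self.records:
                self._cache["chars"] = np.zeros(
                    (0, self.alignment_length), dtype=np.uint8)
            else:
                buf = "".join(r.aligned_seq for r in self.records)
                self._cache["chars"] = np.frombuffer(
                    buf.encode("ascii"), dtype=np.uint8
                ).reshape(len(self.records), -1)
        return self._cache["chars"]

    def nucleotide_matrix(self) -> np.ndarray:
        """Boolean matrix: True where a record has a nucleotide (not a gap)."""
        if "nt" not in self._cache:
            self._cache["nt"] = target_mask_array_matrix(self.char_matrix())
        return self._cache["nt"]


def target_mask_array_matrix(chars: np.ndarray) -> np.ndarray:
    from .iupac import TARGET_MASKS
    return TARGET_MASKS[chars] != 0


def build_reference_map(reference_id: str, aligned_ref: str) -> ReferenceMap:
    aligned_ref = aligned_ref.upper().replace(".", "-")
    codes = np.frombuffer(aligned_ref.encode("ascii"), dtype=np.uint8)
    is_base = ~np.isin(codes, [ord("-")])
    col_to_ref = np.where(is_base, np.cumsum(is_base), 0).astype(np.int64)
    ref_to_col = np.flatnonzero(is_base).astype(np.int64)
    if len(ref_to_col) == 0:
        raise AlignmentError(f"reference {reference_id!r} has no nucleotides")
    return ReferenceMap(reference_id=reference_id,
                        column_to_refpos=col_to_ref,
                        refpos_to_column=ref_to_col)


def read_metadata(path) -> dict[str, tuple[str, frozenset]]:
    """Read the metadata TSV: id, group, semicolon-separated environments."""
    meta = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["id", "group", "environments"]:
            raise AlignmentError(
                f"metadata header must be id/group/environments, got {header}")
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            rid, group = fields[0], fields[1] or "other"
            envs = frozenset(e for e in fields[2].split(";") if e) \
                if len(fields) > 2 else frozenset()
            meta[rid] = (group, envs)
    return meta


def read_aligned_fasta(path, metadata_path=None,
                       reference_id: str = None) -> AlignedDatabase:
    """Read an aligned FASTA plus optional metadata into an AlignedDatabase.

    Gap dialects '-' and '.' and lowercase bases are accepted.  Records
    missing from the metadata table get group label "other" and no
    environment labels.  The reference record must be present; it defines
    the 1-based coordinate system and is itself part of the database.
    """
    if reference_id is None:
        raise AlignmentError("reference_id is required")
    meta = read_metadata(metadata_path) if metadata_path else {}
    records = []
    ref_row = None
    for rec in SeqIO.parse(str(path), "fasta"):
        group, envs = meta.get(rec.id, ("other", frozenset()))
        ar = AlignedRecord(id=rec.id, aligned_seq=str(rec.seq),
                           group_label=group, env_labels=envs)
        records.append(ar)
        if rec.id == reference_id:
            ref_row = ar.aligned_seq
    if ref_row is None:
        raise AlignmentError(f"reference {reference_id!r} not in alignment")
    refmap = build_reference_map(reference_id, ref_row)
    return AlignedDatabase(records=records, refmap=refmap)


def write_aligned_fasta(db: AlignedDatabase, path) -> None:
    recs = [SeqRecord(Seq(r.aligned_seq), id=r.id, description="")
            for r in db.records]
    SeqIO.write(recs, str(path), "fasta")


def write_metadata(db: AlignedDatabase, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tgroup\tenvironments\n")
        for r in db.records:
            fh.write(f"{r.id}\t{r.group_label}\t"
                     f"{';'.join(sorted(r.env_labels))}\n")


def depth_profile(db: AlignedDatabase) -> np.ndarray:
    """Per reference position, the count of records with a nucleotide there.

    Columns that are insertions relative to the reference are excluded, so
    the profile lives entirely in reference coordinates (index 0 is
    reference position 1).
    """
    nt = db.nucleotide_matrix()
    ref_cols = db.refmap.refpos_to_column
    return nt[:, ref_cols].sum(axis=0).astype(int)


def write_depth_profile(profile: np.ndarray, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ref_position\tdepth\n")
        for pos, d in enumerate(profile, start=1):
            fh.write(f"{pos}\t{int(d)}\n")


def window_denominator(db: AlignedDatabase, window: tuple[int, int],
                       indices: Optional[np.ndarray] = None,
                       require_full: bool = False) -> int:
    """Number of records with nucleotide representation spanning ``window``.

    Default rule: nucleotides at both the first and last reference position
    of the window (internal alignment gaps are deletions and still count as
    representation).  ``require_full=True`` demands a nucleotide at every
    reference position of the window.
    """
    return int(window_span_mask(db, window, require_full)[
        indices if indices is not None else slice(None)].sum())


def window_span_mask(db: AlignedDatabase, window: tuple[int, int],
                     require_full: bool = False) -> np.ndarray:
    """Boolean per-record mask of the spanning rule for ``window``."""
    key = ("span", window, require_full)
    if key not in db._cache:
        c0, c1 = map_window(db.refmap, window)
        nt = db.nucleotide_matrix()
        if require_full:
            cols = db.refmap.refpos_to_column[window[0] - 1:window[1]]
            mask = nt[:, cols].all(axis=1)
        else:
            mask = nt[:, c0] & nt[:, c1]
        db._cache[key] = mask
    return db._cache[key]
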