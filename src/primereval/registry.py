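"""Degenerate primer registry: domain types, degeneracy arithmetic and the
packaged primer/pair fixtures.

The packaged fixtures transcribe the published nifH primer survey tables
verbatim, including rows the survey itself flags as probably erroneous;
those carry a ``flagged`` annotation instead of being silently corrected.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from itertools import product
from math import prod
from pathlib import Path
from typing import Iterator, Optional

from .iupac import DEGENERACY_SETS, PRIMER_ALPHABET, reverse_complement_seq


class PrimerValidationError(ValueError):
    """Raised when a raw primer record fails validation."""


class DegeneracyCapError(ValueError):
    """Raised when an expansion would exceed the configured cap."""


DEFAULT_EXPANSION_CAP = 65_536


@dataclass(frozen=True)
class Primer:
    """A named degenerate oligonucleotide, 5'->3'.

    ``orientation`` is the strand of the written sequence relative to the
    sense strand of the reference: ``forward`` primers read along it,
    ``reverse`` primers are its reverse complement.
    """

    name: str
    sequence: str
    orientation: str = "forward"
    binding_window: Optional[tuple[int, int]] = None  # 1-based inclusive
    target_group: str = "universal"
    citation: str = ""
    flagged: str = ""
    deg_printed: Optional[int] = None
    tm_printed: str = ""
    nonstandard: bool = False  # contains non-IUPAC characters (P/K bases)

    def __post_init__(self):
        if self.orientation not in ("forward", "reverse"):
            raise PrimerValidationError(
                f"{self.name}: orientation must be forward|reverse, "
                f"got {self.orientation!r}")
        if self.binding_window is not None:
            s, e = self.binding_window
            if s > e:
                raise PrimerValidationError(
                    f"{self.name}: binding window {s}-{e} not normalized")

    def __len__(self) -> int:
        return len(self.sequence)


def validate_primer(name: str, sequence: str, **kwargs) -> Primer:
    """Validate a raw name/sequence record and return a :class:`Primer`.

    The sequence is uppercased; characters outside the degenerate DNA
    alphabet {A,C,G,T,R,Y,S,W,K,M,B,D,H,V,N,I} are rejected with the
    1-based offending position named in the error.
    """
    if not name:
        raise PrimerValidationError("primer name must be non-empty")
    seq = (sequence or "").upper()
    if not seq:
        raise PrimerValidationError(f"{name}: empty sequence")
    for i, c in enumerate(seq, start=1):
        if c not in PRIMER_ALPHABET:
            raise PrimerValidationError(
                f"{name}: illegal character {c!r} at position {i}")
    return Primer(name=name, sequence=seq, **kwargs)


def degeneracy(primer: Primer | str) -> int:
    """Number of concrete oligonucleotides the primer comprises.

    Product over positions of the IUPAC multiplicity; inosine contributes 1
    because it is a single synthesized base.
    """
    seq = primer.sequence if isinstance(primer, Primer) else primer.upper()
    try:
        return prod(len(DEGENERACY_SETS[c]) for c in seq)
    except KeyError as exc:
        raise PrimerValidationError(
            f"non-IUPAC character {exc.args[0]!r} in {seq!r}") from None


def expand(primer: Primer | str, cap: int = DEFAULT_EXPANSION_CAP) -> set[str]:
    """Set of concrete oligos over {A,C,G,T,I} represented by the primer.

    Refuses to expand past ``cap`` (default 65,536) to prevent
    combinatorial blowup; inosine positions are retained as ``I``.
    """
    seq = primer.sequence if isinstance(primer, Primer) else primer.upper()
    d = degeneracy(seq)
    if d > cap:
        raise DegeneracyCapError(
            f"degeneracy {d} exceeds expansion cap {cap}")
    choices = [sorted(DEGENERACY_SETS[c]) for c in seq]
    return {"".join(t) for t in product(*choices)}


def reverse_complement(primer: Primer) -> Primer:
    """Per-character IUPAC complement followed by reversal.

    Orientation is swapped; applying twice returns the original primer.
    """
    return replace(
        primer,
        sequence=reverse_complement_seq(primer.sequence),
        orientation="reverse" if primer.orientation == "forward" else "forward",
    )


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer combination with its reference amplicon."""

    name: str
    forward: Primer
    reverse: Primer
    amplicon_window: Optional[tuple[int, int]] = None
    flagged: str = ""
    len_printed: Optional[int] = None

    @property
    def expected_length(self) -> int:
        return expected_length(self)


def expected_length(pair: PrimerPair) -> int:
    """Inclusive reference-coordinate span of the predicted amplicon."""
    if pair.amplicon_window is None:
        raise ValueError(f"{pair.name}: no amplicon window")
    s, e = pair.amplicon_window
    if s > e:
        raise ValueError(f"{pair.name}: amplicon window {s}-{e} out of order")
    return e - s + 1


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

_PRIMER_COLUMNS = ["name", "sequence", "orientation", "pos_start", "pos_end",
                   "target_group", "reference", "flagged", "deg_printed",
                   "tm_printed"]
_PAIR_COLUMNS = ["pair_name", "fwd_name", "rev_name", "pos_start", "pos_end",
                 "length", "flagged"]


def _data_path(filename: str):
    return resources.files("primereval").joinpath("data").joinpath(filename)


def _is_standard(seq: str) -> bool:
    return all(c in PRIMER_ALPHABET for c in seq.upper())


def load_primers(path=None) -> list[Primer]:
    """Load a primer TSV (packaged fixture layout) into Primer objects.

    Rows containing non-IUPAC characters (the P/K-base primers) are kept
    verbatim with ``nonstandard=True`` and are excluded from degeneracy,
    expansion, matching and thermodynamics by their consumers.
    """
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_PRIMER_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise PrimerValidationError(
                f"primer table missing columns: {sorted(missing)}")
        primers = []
        for row in reader:
            window = None
            if row["pos_start"] and row["pos_end"]:
                window = (int(row["pos_start"]), int(row["pos_end"]))
            deg_printed = int(row["deg_printed"]) if row["deg_printed"] else None
            common = dict(
                orientation=row["orientation"],
                binding_window=window,
                target_group=row["target_group"],
                citation=row["reference"],
                flagged=row["flagged"],
                deg_printed=deg_printed,
                tm_printed=row["tm_printed"],
            )
            seq = row["sequence"].upper()
            if _is_standard(seq):
                primers.append(validate_primer(row["name"], seq, **common))
            else:
                primers.append(Primer(name=row["name"], sequence=seq,
                                      nonstandard=True, **common))
    return primers


def load_pairs(path, primers: list[Primer]) -> list[PrimerPair]:
    """Load a pair TSV, resolving member names against ``primers``."""
    by_name = {p.name: p for p in primers}
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_PAIR_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise PrimerValidationError(
                f"pair table missing columns: {sorted(missing)}")
        pairs = []
        for row in reader:
            try:
                fwd = by_name[row["fwd_name"]]
                rev = by_name[row["rev_name"]]
            except KeyError as exc:
                raise PrimerValidationError(
                    f"{row['pair_name']}: unknown primer {exc.args[0]!r}"
                ) from None
            window = None
            if row["pos_start"] and row["pos_end"]:
                window = (int(row["pos_start"]), int(row["pos_end"]))
            pairs.append(PrimerPair(
                name=row["pair_name"], forward=fwd, reverse=rev,
                amplicon_window=window, flagged=row["flagged"],
                len_printed=int(row["length"]) if row["length"] else None))
    return pairs


@dataclass
class Registry:
    """The packaged registry: all primers and pairs from the survey tables."""

    universal: list[Primer] = field(default_factory=list)
    group_specific: list[Primer] = field(default_factory=list)
    universal_pairs: list[PrimerPair] = field(default_factory=list)
    group_pairs: list[PrimerPair] = field(default_factory=list)

    @property
    def primers(self) -> list[Primer]:
        return self.universal + self.group_specific

    @property
    def pairs(self) -> list[PrimerPair]:
        return self.universal_pairs + self.group_pairs

    def primer(self, name: str) -> Primer:
        for p in self.primers:
            if p.name == name:
                return p
        raise KeyError(name)

    def pair(self, name: str) -> PrimerPair:
        for p in self.pairs:
            if p.name == name:
                return p
        raise KeyError(name)


def load_registry(directory: Optional[Path] = None) -> Registry:
    """Load the packaged registry (or an identically laid-out directory)."""
    def p(fn):
        return Path(directory) / fn if directory else _data_path(fn)

    universal = load_primers(p("primers_universal.tsv"))
    group = load_primers(p("primers_group_specific.tsv"))
    all_primers = universal + group
    return Registry(
        universal=universal,
        group_specific=group,
        universal_pairs=load_pairs(p("pairs_universal.tsv"), all_primers),
        group_pairs=load_pairs(p("pairs_group_specific.tsv"), all_primers),
    )
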