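"""Synthetic aligned databases with exact ground truth.

Records are fragments of a mutated reference.  Primer binding sites are
stamped onto the reference so every window-spanning fragment matches at 0
mismatches unless a mismatch quota says otherwise; quotas are applied with
largest-remainder rounding so manifest-specified coverage fractions are
recovered *exactly* by the evaluation pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from .aligned import AlignedDatabase, AlignedRecord, ReferenceMap, \
    build_reference_map
from .iupac import MATCH_SETS, reverse_complement_seq
from .matching import scan
from .registry import Primer

_BASES = "ACGT"


class SyntheticConfigError(ValueError):
    """Contradictory generator constraints (never silently compromised)."""


@dataclass(frozen=True)
class PrimerPlant:
    """A primer whose window-spanning records get controlled mismatches.

    ``mismatch_fractions`` maps an exact mismatch count to the fraction of
    window-spanning records that receive it (remaining records get 0).
    """
    primer: Primer
    mismatch_fractions: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.primer.binding_window is None:
            raise SyntheticConfigError(
                f"{self.primer.name}: cannot plant a primer with no window")
        total = sum(self.mismatch_fractions.values())
        if total > 1.0 + 1e-9:
            raise SyntheticConfigError(
                f"{self.primer.name}: mismatch fractions sum to {total} > 1")
        for m, f in self.mismatch_fractions.items():
            if m < 1 or not 0.0 <= f <= 1.0:
                raise SyntheticConfigError(
                    f"{self.primer.name}: bad fraction {f} for count {m}")


@dataclass
class SyntheticConfig:
    n_records: int = 100
    seed: int = 0
    ref_length: int = 900
    reference_id: str = "REF"
    plants: Sequence[PrimerPlant] = ()
    group_proportions: dict = field(default_factory=dict)
    env_fractions: dict = field(default_factory=dict)
    span: str = "amplicon_like"          # or "uniform" or "full"
    core: tuple[int, int] = (115, 476)
    core_fraction: float = 0.7           # fraction of amplicon-like spans on the core
    min_span: int = 60
    dip_positions: Sequence[int] = ()
    dip_keep_fraction: float = 0.05
    insertion_columns: Sequence[tuple[int, int]] = ()  # (after_refpos, width)
    insertion_fill_fraction: float = 0.3

    def __post_init__(self):
        if self.n_records < 1:
            raise SyntheticConfigError("n_records must be >= 1")
        if sum(self.group_proportions.values()) > 1.0 + 1e-9:
            raise SyntheticConfigError("group proportions sum to > 1")


@dataclass
class SyntheticManifest:
    """Ground truth for a generated database."""
    seed: int
    ref_length: int
    reference_id: str
    reference_seq: str
    records: list        # dicts: id, span, group, envs, planted, dip_gaps
    dip_positions: list
    insertion_columns: list
    planted_primers: list  # primer names

    def spans(self) -> list[tuple[int, int]]:
        return [tuple(r["span"]) for r in self.records]

    def expected_depth(self, refpos: int) -> int:
        """Interval-stabbing depth at a reference position (dips included)."""
        n = 0
        for r in self.records:
            s, e = r["span"]
            if s <= refpos <= e and refpos not in r["dip_gaps"]:
                n += 1
        return n

    def expected_coverage_percent(self, primer_name: str, k: int) -> int:
        """Manifest-derived coverage percent for a planted primer."""
        from .coverage import round_half_up
        window = self._window(primer_name)
        span_recs = [r for r in self.records
                     if r["span"][0] <= window[0] and r["span"][1] >= window[1]]
        if not span_recs:
            raise ZeroDivisionError("no spanning records")
        hit = sum(1 for r in span_recs
                  if r["planted"].get(primer_name, 0) <= k)
        return round_half_up(100.0 * hit / len(span_recs))

    _windows: dict = field(default_factory=dict)

    def _window(self, primer_name: str) -> tuple[int, int]:
        return self._windows[primer_name]

    def to_yaml(self, path) -> None:
        data = {
            "seed": self.seed,
            "ref_length": self.ref_length,
            "reference_id": self.reference_id,
            "reference_seq": self.reference_seq,
            "dip_positions": list(self.dip_positions),
            "insertion_columns": [list(c) for c in self.insertion_columns],
            "planted_primers": list(self.planted_primers),
            "windows": {k: list(v) for k, v in self._windows.items()},
            "records": [
                {"id": r["id"], "span": list(r["span"]), "group": r["group"],
                 "envs": sorted(r["envs"]),
                 "planted": dict(r["planted"]),
                 "dip_gaps": sorted(r["dip_gaps"])}
                for r in self.records],
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticManifest":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        m = cls(seed=d["seed"], ref_length=d["ref_length"],
                reference_id=d["reference_id"],
                reference_seq=d["reference_seq"],
                records=[{**r, "span": tuple(r["span"]),
                          "envs": frozenset(r["envs"]),
                          "dip_gaps": set(r["dip_gaps"])}
                         for r in d["records"]],
                dip_positions=d["dip_positions"],
                insertion_columns=[tuple(c) for c in d["insertion_columns"]],
                planted_primers=d["planted_primers"])
        m._windows = {k: tuple(v) for k, v in d["windows"].items()}
        return m


def largest_remainder(fractions: dict, n: int) -> dict:
    """Integer apportionment of n items by largest remainder.

    Keys are processed in sorted order for determinism; fractions may sum
    to < 1 (the remainder is unallocated).
    """
    keys = sorted(fractions)
    exact = {k: fractions[k] * n for k in keys}
    base = {k: int(exact[k]) for k in keys}
    left = int(round(sum(exact[k] for k in keys))) - sum(base.values())
    order = sorted(keys, key=lambda k: (-(exact[k] - base[k]), k))
    for k in order[:left]:
        base[k] += 1
    return base


def _sense_constraint(primer: Primer) -> tuple[int, list[frozenset]]:
    """(window start, per-position allowed base sets on the sense strand)."""
    seq = primer.sequence if primer.orientation == "forward" \
        else reverse_complement_seq(primer.sequence)
    return primer.binding_window[0], [MATCH_SETS[c] for c in seq]


def _stamp_reference(rng, cfg: SyntheticConfig) -> str:
    """Random reference constrained to match every planted primer exactly."""
    allowed = [frozenset(_BASES)] * cfg.ref_length
    for plant in cfg.plants:
        start, sets = _sense_constraint(plant.primer)
        if start < 1 or start - 1 + len(sets) > cfg.ref_length:
            raise SyntheticConfigError(
                f"{plant.primer.name}: window outside reference")
        for off, s in enumerate(sets):
            i = start - 1 + off
            inter = allowed[i] & s
            if not inter:
                raise SyntheticConfigError(
                    f"conflicting primer constraints at reference position "
                    f"{i + 1}")
            allowed[i] = inter
    for attempt in range(50):
        ref = "".join(
            sorted(allowed[i])[rng.integers(len(allowed[i]))]
            for i in range(cfg.ref_length))
        if not _off_window_sites(ref, cfg):
            return ref
    raise SyntheticConfigError(
        "could not generate a reference without off-window primer sites")


def _off_window_sites(ref: str, cfg: SyntheticConfig) -> bool:
    """True if any planted primer matches the reference outside its window."""
    db = _plain_db(ref, cfg.reference_id)
    for plant in cfg.plants:
        res = scan(db, plant.primer, k=0, window=None)
        for h in res.hits:
            if h.ref_start != plant.primer.binding_window[0]:
                return True
    return False


def _plain_db(seq: str, rid: str) -> AlignedDatabase:
    rec = AlignedRecord(id=rid, aligned_seq=seq)
    return AlignedDatabase(records=[rec],
                           refmap=build_reference_map(rid, seq))


def _sample_span(rng, cfg: SyntheticConfig) -> tuple[int, int]:
    L = cfg.ref_length
    if cfg.span == "full":
        return 1, L
    if cfg.span == "uniform":
        while True:
            a = int(rng.integers(1, L + 1))
            b = int(rng.integers(1, L + 1))
            s, e = min(a, b), max(a, b)
            if e - s + 1 >= cfg.min_span:
                return s, e
    if cfg.span != "amplicon_like":
        raise SyntheticConfigError(f"unknown span mode {cfg.span!r}")
    cs, ce = cfg.core
    u = rng.random()
    if u < cfg.core_fraction:
        # amplicon-like: cover the core, with modest jitter outwards
        s = max(1, cs - int(rng.integers(0, 15)))
        e = min(L, ce + int(rng.integers(0, 15)))
        return s, e
    if u < cfg.core_fraction + 0.1:
        return 1, L  # full-length (genome-derived)
    # partial fragment overlapping one end of the core
    if rng.random() < 0.5:
        s = max(1, cs - int(rng.integers(0, 40)))
        e = min(L, s + cfg.min_span + int(rng.integers(0, (ce - cs))))
    else:
        e = min(L, ce + int(rng.integers(0, 40)))
        s = max(1, e - cfg.min_span - int(rng.integers(0, (ce - cs))))
    return min(s, e), max(s, e)


def _plant_positions(plant: PrimerPlant, cfg: SyntheticConfig,
                     ref: str) -> list[tuple[int, frozenset]]:
    """Window positions eligible for a planted mismatch, with the sense-
    strand base sets they must *avoid*."""
    start, sets = _sense_constraint(plant.primer)
    others = []
    for other in cfg.plants:
        if other is not plant:
            w = other.primer.binding_window
            others.append(range(w[0], w[1] + 1))
    eligible = []
    for off, s in enumerate(sets):
        pos = start + off
        if len(s) == 4:
            continue  # N/I position: every base matches, cannot mismatch
        if any(pos in r for r in others):
            raise SyntheticConfigError(
                f"{plant.primer.name}: window overlaps another planted "
                f"primer's window at position {pos}")
        if pos in cfg.dip_positions:
            continue
        eligible.append((pos, s))
    return eligible


def generate(cfg: SyntheticConfig
             ) -> tuple[AlignedDatabase, SyntheticManifest]:
    """Generate an aligned database plus its ground-truth manifest.

    Deterministic for a fixed config (seed included); rerunning yields
    byte-identical FASTA and manifest output.
    """
    rng = np.random.default_rng(cfg.seed)
    ref = _stamp_reference(rng, cfg)

    # record 0 is the reference itself: full-length, defines coordinates
    spans = [_sample_span(rng, cfg) for _ in range(cfg.n_records)]
    spans[0] = (1, cfg.ref_length)

    # group labels by largest remainder, shuffled deterministically
    quotas = largest_remainder(cfg.group_proportions, cfg.n_records)
    labels = []
    for g in sorted(quotas):
        labels += [g] * quotas[g]
    labels += ["other"] * (cfg.n_records - len(labels))
    labels = [str(x) for x in np.array(labels)[rng.permutation(cfg.n_records)]]

    # environment labels: independent largest-remainder per label
    env_sets = [set() for _ in range(cfg.n_records)]
    for env in sorted(cfg.env_fractions):
        quota = largest_remainder({env: cfg.env_fractions[env]},
                                  cfg.n_records)[env]
        chosen = rng.permutation(cfg.n_records)[:quota]
        for i in chosen:
            env_sets[int(i)].add(env)

    # per-record mutable base arrays over the record's span
    seqs = [list(ref[s - 1:e]) for s, e in spans]
    planted: list[dict] = [dict() for _ in range(cfg.n_records)]

    # mismatch quotas per planted primer
    for plant in cfg.plants:
        w = plant.primer.binding_window
        spanning = [i for i, (s, e) in enumerate(spans)
                    if s <= w[0] and e >= w[1]]
        mm_quotas = largest_remainder(plant.mismatch_fractions, len(spanning))
        order = list(np.array(spanning)[rng.permutation(len(spanning))])
        eligible = _plant_positions(plant, cfg, ref)
        cursor = 0
        for m in sorted(mm_quotas):
            if mm_quotas[m] and len(eligible) < m:
                raise SyntheticConfigError(
                    f"{plant.primer.name}: cannot plant {m} mismatches; "
                    f"only {len(eligible)} eligible window positions")
            for _ in range(mm_quotas[m]):
                i = order[cursor]
                cursor += 1
                pos_choice = rng.permutation(len(eligible))[:m]
                for j in pos_choice:
                    pos, allowed_set = eligible[int(j)]
                    bad = sorted(set(_BASES) - allowed_set)
                    newbase = bad[rng.integers(len(bad))]
                    seqs[i][pos - spans[i][0]] = newbase
                planted[i][plant.primer.name] = m

    # dips: records spanning a dip position get a gap there, except an
    # exact largest-remainder quota of keepers.  The reference row is
    # exempt: a gap there would delete the position from the coordinate
    # system itself.
    dip_gaps: list[set] = [set() for _ in range(cfg.n_records)]
    for dpos in cfg.dip_positions:
        covering = [i for i, (s, e) in enumerate(spans)
                    if s <= dpos <= e and i != 0]
        keep = largest_remainder({"keep": cfg.dip_keep_fraction},
                                 len(covering)).get("keep", 0)
        order = list(np.array(covering)[rng.permutation(len(covering))]) \
            if covering else []
        for i in order[keep:]:
            dip_gaps[int(i)].add(dpos)

    # build alignment columns: reference positions + insertion blocks
    inserts = sorted(cfg.insertion_columns)
    for after, width in inserts:
        if not 0 <= after <= cfg.ref_length or width < 1:
            raise SyntheticConfigError(
                f"bad insertion column specification ({after}, {width})")

    def build_row(span, seq_list, gaps, carry_insert, rng_row):
        s, e = span
        row = []
        it = iter(inserts)
        nxt = next(it, None)
        while nxt is not None and nxt[0] == 0:  # insertions before position 1
            row.extend("-" * nxt[1])
            nxt = next(it, None)
        for pos in range(1, cfg.ref_length + 1):
            if s <= pos <= e and pos not in gaps:
                row.append(seq_list[pos - s])
            else:
                row.append("-")
            while nxt is not None and nxt[0] == pos:
                width = nxt[1]
                if carry_insert and s <= pos < e:
                    row.extend(_BASES[rng_row.integers(4)]
                               for _ in range(width))
                else:
                    row.extend("-" * width)
                nxt = next(it, None)
        return "".join(row)

    # insertion columns are gaps in the reference row by construction
    carry = rng.random(cfg.n_records) < cfg.insertion_fill_fraction
    carry[0] = False
    records = []
    man_records = []
    for i in range(cfg.n_records):
        rid = cfg.reference_id if i == 0 else f"SYN{i:05d}"
        row_rng = np.random.default_rng(cfg.seed + 1000 + i)
        records.append(AlignedRecord(
            id=rid,
            aligned_seq=build_row(spans[i], seqs[i], dip_gaps[i],
                                  bool(carry[i]) and bool(inserts), row_rng),
            group_label=labels[i],
            env_labels=frozenset(env_sets[i])))
        man_records.append({
            "id": rid, "span": spans[i], "group": labels[i],
            "envs": frozenset(env_sets[i]), "planted": planted[i],
            "dip_gaps": dip_gaps[i]})

    refmap = build_reference_map(cfg.reference_id, records[0].aligned_seq)
    db = AlignedDatabase(records=records, refmap=refmap)
    manifest = SyntheticManifest(
        seed=cfg.seed, ref_length=cfg.ref_length,
        reference_id=cfg.reference_id, reference_seq=ref,
        records=man_records,
        dip_positions=list(cfg.dip_positions),
        insertion_columns=[tuple(c) for c in inserts],
        planted_primers=[p.primer.name for p in cfg.plants])
    manifest._windows = {p.primer.name: p.primer.binding_window
                         for p in cfg.plants}
    return db, manifest


def fig1_fixture(n_records: int = 300, seed: int = 42
                 ) -> tuple[AlignedDatabase, SyntheticManifest]:
    """A packaged small database with the canonical depth-profile shape:
    deep over the central core, shallow at the termini, with engineered
    dips at positions 199 and 350 and insertion columns after 250."""
    from .registry import load_registry
    reg = load_registry()
    plants = [
        PrimerPlant(reg.primer("Nh21F"), {1: 0.10}),
        PrimerPlant(reg.primer("F2"), {1: 0.05, 2: 0.05}),
        PrimerPlant(reg.primer("R6"), {1: 0.08}),
        PrimerPlant(reg.primer("DVV"), {1: 0.15}),
        PrimerPlant(reg.primer("nifH3"), {1: 0.10, 2: 0.10}),
    ]
    cfg = SyntheticConfig(
        n_records=n_records, seed=seed, ref_length=900,
        plants=plants,
        group_proportions={"Pr": 0.35, "Cy": 0.15, "III": 0.15, "IA": 0.1,
                           "Fr": 0.1, "Pb": 0.05, "Ep": 0.05, "IV": 0.05},
        env_fractions={"Soil": 0.4, "Mat": 0.2, "Sea": 0.3},
        span="amplicon_like", core=(115, 476),
        dip_positions=(199, 350), dip_keep_fraction=0.05,
        insertion_columns=((250, 3),), insertion_fill_fraction=0.3)
    return generate(cfg)
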