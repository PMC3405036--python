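"""Run configuration and the full-evaluation report bundle."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .aligned import AlignedDatabase, depth_profile, read_aligned_fasta, \
    write_depth_profile
from .coverage import evaluate_registry, write_coverage_table
from .pairpcr import evaluate_pairs
from .registry import Registry, load_registry
from .thermo import TmConditions, tm_range

log = logging.getLogger("primereval")


@dataclass
class RunConfig:
    """All policy choices for a full evaluation run.

    Every default equals the documented table-reproducing behavior:
    events-based multi-hit counting, intersection ambiguity handling,
    half-up integer rounding, group/environment strata at 0 mismatches.
    """

    db_fasta: Optional[str] = None
    metadata: Optional[str] = None
    reference_id: str = "REF"
    mismatches: Sequence[int] = (0, 1, 2)
    strata: Sequence[str] = ("groups", "environments")
    multi_hit: str = "events"          # events | sequences
    ambiguity_policy: str = "intersection"  # intersection | strict
    rounding: str = "half_up"
    tm: TmConditions = field(default_factory=TmConditions)
    seed: int = 0
    out_dir: str = "primereval_out"

    def config_hash(self) -> str:
        fields = asdict(self)
        fields.pop("out_dir")  # analysis identity, not output placement
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def metadata_header(self) -> dict:
        return {
            "version": __version__,
            "config_hash": self.config_hash(),
            "multi_hit": self.multi_hit,
            "ambiguity_policy": self.ambiguity_policy,
            "rounding": self.rounding,
            "mismatches": ",".join(map(str, self.mismatches)),
            "seed": self.seed,
        }


def write_primer_map(registry_primers, path) -> pd.DataFrame:
    """Per-primer reference windows, sorted by start then name.

    Primers without a mappable window are skipped with a warning.
    """
    rows = []
    for p in registry_primers:
        if p.binding_window is None:
            log.warning("%s: no binding window; skipped from primer map",
                        p.name)
            continue
        rows.append({"name": p.name, "ref_start": p.binding_window[0],
                     "ref_end": p.binding_window[1],
                     "orientation": p.orientation})
    table = pd.DataFrame(
        rows, columns=["name", "ref_start", "ref_end", "orientation"])
    table = table.sort_values(["ref_start", "name"], kind="mergesort")
    table.to_csv(path, sep="\t", index=False)
    return table


def _tm_column(primers, cond: TmConditions) -> dict:
    out = {}
    for p in primers:
        if p.nonstandard:
            continue
        try:
            r = tm_range(p, cond)
        except Exception:  # length < 8 or other parameterization gap
            continue
        if r.tm_min == r.tm_max:
            out[p.name] = f"{r.tm_min:.1f}"
        else:
            out[p.name] = f"{r.tm_min:.1f}-{r.tm_max:.1f}"
    return out


def run_full_evaluation(config: RunConfig,
                        db: Optional[AlignedDatabase] = None,
                        registry: Optional[Registry] = None) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns a dict of output paths.  Any stage error propagates with the
    stage name; partially written outputs are removed.
    """
    t_start = time.time()
    unknown = set(config.strata) - {"groups", "environments"}
    if unknown:
        raise KeyError(
            f"unknown strata {sorted(unknown)}; "
            "known: ['groups', 'environments']")
    if config.multi_hit not in ("events", "sequences"):
        raise ValueError(f"unknown multi_hit policy {config.multi_hit!r}")
    registry = registry or load_registry()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    meta = config.metadata_header()

    def stage(name, fn):
        t0 = time.time()
        try:
            result = fn()
        except Exception as exc:
            for p in written:
                p.unlink(missing_ok=True)
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        log.info("stage %s done in %.2fs", name, time.time() - t0)
        return result

    if db is None:
        if not config.db_fasta:
            raise ValueError("no database given: set db_fasta or pass db")
        db = stage("read", lambda: read_aligned_fasta(
            config.db_fasta, config.metadata, config.reference_id))

    paths = {}

    def emit(key, filename, writer):
        path = out / filename
        stage(key, lambda: writer(path))
        written.append(path)
        paths[key] = str(path)

    tm_cols = stage("thermo", lambda: _tm_column(registry.primers, config.tm))

    groups = sorted(g for g in db.groups if g != "other") \
        if "groups" in config.strata else []
    envs = sorted(e for e in db.environments if e != "other") \
        if "environments" in config.strata else []

    def cov_writer(primers):
        def write(path):
            table = evaluate_registry(
                db, primers, k_list=tuple(config.mismatches),
                groups=groups, environments=envs,
                multi_hit=config.multi_hit,
                policy=config.ambiguity_policy, tm_ranges=tm_cols)
            write_coverage_table(table, path, meta)
        return write

    def pair_writer(pairs):
        def write(path):
            table = evaluate_pairs(db, pairs, k=0, groups=groups,
                                   environments=envs,
                                   policy=config.ambiguity_policy)
            write_coverage_table(table, path, meta)
        return write

    emit("universal", "coverage_universal.tsv",
         cov_writer(registry.universal))
    emit("group_specific", "coverage_group_specific.tsv",
         cov_writer(registry.group_specific))
    emit("pairs_universal", "pairs_universal.tsv",
         pair_writer(registry.universal_pairs))
    emit("pairs_group_specific", "pairs_group_specific.tsv",
         pair_writer(registry.group_pairs))
    emit("depth", "depth_profile.tsv",
         lambda path: write_depth_profile(depth_profile(db), path))
    emit("primer_map", "primer_map.tsv",
         lambda path: write_primer_map(registry.primers, path))

    log.info("full evaluation finished in %.2fs", time.time() - t_start)

    def write_log(path):
        # no timestamps here: identical configs must yield identical bytes
        with open(path, "w", encoding="utf-8") as fh:
            for k, v in meta.items():
                fh.write(f"{k}={v}\n")
            fh.write(f"n_records={len(db)}\n")
    emit("runlog", "run_log.txt", write_log)
    return paths
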