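"""Nearest-neighbor melting temperatures and min-max ranges for degenerate
primers.

Duplex stability is summed from a unified nearest-neighbor parameter table
(shipped as a data file, swappable) with initiation terms and the oligo
concentration term.  Divalent cations are folded into a monovalent
equivalent (Na_eq = Na + 120*sqrt(Mg_free), in mM) and applied as an
entropy correction; an Owczarzy-style reciprocal-temperature correction is
available as an alternative.  Default conditions: 0.25 uM oligo, 50 mM
Na+, 1.5 mM Mg++, 0 mM dNTPs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from .iupac import DEGENERACY_SETS
from .registry import (DEFAULT_EXPANSION_CAP, Primer, degeneracy, expand)

R_GAS = 1.9872  # cal / (mol K)

SALT_METHODS = ("monovalent_equivalent", "owczarzy")


@dataclass(frozen=True)
class TmConditions:
    oligo_conc: float = 0.25e-6   # molar, total strand concentration
    na: float = 0.050             # molar monovalent cation
    mg: float = 1.5e-3            # molar divalent cation
    dntp: float = 0.0             # molar dNTPs
    salt_method: str = "monovalent_equivalent"

    def __post_init__(self):
        for name in ("oligo_conc", "na", "mg", "dntp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.salt_method not in SALT_METHODS:
            raise ValueError(f"salt_method must be one of {SALT_METHODS}")

    @property
    def free_mg(self) -> float:
        """Mg not sequestered by dNTPs (association constant 3e4 /M)."""
        if self.dntp <= 0:
            return self.mg
        ka = 3.0e4
        b = ka * self.dntp - ka * self.mg + 1.0
        return (-b + math.sqrt(b * b + 4.0 * ka * self.mg)) / (2.0 * ka)

    @property
    def monovalent_equivalent(self) -> float:
        """Effective monovalent concentration (molar)."""
        return self.na + 120.0 * math.sqrt(self.free_mg * 1000.0) / 1000.0


DEFAULT_CONDITIONS = TmConditions()


@dataclass(frozen=True)
class TmRange:
    primer_name: str
    tm_min: float
    tm_max: float
    n_evaluated: int


class ThermoError(ValueError):
    pass


@lru_cache(maxsize=None)
def _load_nn_table() -> dict:
    """Stack -> (dH kcal/mol, dS cal/mol/K), plus initiation terms."""
    table = {}
    for fn in ("nn_unified.tsv", "nn_inosine.tsv"):
        path = resources.files("primereval").joinpath("data").joinpath(fn)
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                if line.startswith("#") or line.startswith("stack"):
                    continue
                key, dh, ds = line.split()
                table[key] = (float(dh), float(ds))
    return table


def _init_terms(base: str, table: dict) -> tuple[float, float]:
    if base in "GC":
        return table["init_GC"]
    if base in "AT":
        return table["init_AT"]
    if base == "I":
        return table["init_I"]
    raise ThermoError(f"cannot assign initiation term for base {base!r}")


def _sum_params(oligo: str, table: dict) -> tuple[float, float]:
    dh, ds = 0.0, 0.0
    for term in (_init_terms(oligo[0], table), _init_terms(oligo[-1], table)):
        dh += term[0]
        ds += term[1]
    for i in range(len(oligo) - 1):
        stack = oligo[i:i + 2]
        try:
            h, s = table[stack]
        except KeyError:
            raise ThermoError(
                f"unparameterized dinucleotide stack {stack!r}") from None
        dh += h
        ds += s
    return dh, ds


def _gc_fraction(oligo: str) -> float:
    return sum(c in "GC" for c in oligo) / len(oligo)


def _owczarzy_inverse_tm_term(fgc: float, n_bp: int,
                              cond: TmConditions) -> float:
    """Additive 1/Tm correction for mixed monovalent/divalent cations."""
    mon, mg = cond.na, cond.free_mg
    if mon == 0 and mg == 0:
        return 0.0
    a, b, c, d = 3.92e-5, -9.11e-6, 6.26e-5, 1.42e-5
    e, f, g = -4.82e-4, 5.25e-4, 8.31e-5
    if mon > 0:
        r = math.sqrt(mg) / mon
        if r < 0.22:
            return ((4.29 * fgc - 3.95) * 1e-5 * math.log(mon)
                    + 9.40e-6 * math.log(mon) ** 2)
        if r < 6.0:
            ln_mon = math.log(mon)
            a = 3.92e-5 * (0.843 - 0.352 * math.sqrt(mon) * ln_mon)
            d = 1.42e-5 * (1.279 - 4.03e-3 * ln_mon - 8.03e-3 * ln_mon ** 2)
            g = 8.31e-5 * (0.486 - 0.258 * ln_mon + 5.25e-3 * ln_mon ** 3)
    ln_mg = math.log(mg)
    return (a + b * ln_mg + fgc * (c + d * ln_mg)
            + (1.0 / (2.0 * (n_bp - 1)))
            * (e + f * ln_mg + g * ln_mg ** 2))


def nn_tm(oligo: str, cond: TmConditions = DEFAULT_CONDITIONS) -> float:
    """Melting temperature (deg C) of a concrete A/C/G/T/I oligo."""
    oligo = (oligo or "").upper()
    if len(oligo) < 8:
        raise ThermoError(
            f"oligo too short for nearest-neighbor Tm (length {len(oligo)} < 8)")
    bad = set(oligo) - set("ACGTI")
    if bad:
        raise ThermoError(f"non-concrete characters in oligo: {sorted(bad)}")
    table = _load_nn_table()
    dh, ds = _sum_params(oligo, table)
    conc = R_GAS * math.log(cond.oligo_conc / 4.0)
    if cond.salt_method == "monovalent_equivalent":
        ds += 0.368 * (len(oligo) - 1) * math.log(cond.monovalent_equivalent)
        return 1000.0 * dh / (ds + conc) - 273.15
    tm_1m = 1000.0 * dh / (ds + conc)
    inv = 1.0 / tm_1m + _owczarzy_inverse_tm_term(
        _gc_fraction(oligo), len(oligo), cond)
    return 1.0 / inv - 273.15


def tm_range(primer: Primer, cond: TmConditions = DEFAULT_CONDITIONS,
             cap: int = DEFAULT_EXPANSION_CAP,
             method: str = "auto") -> TmRange:
    """Min and max Tm over all expansions of a degenerate primer.

    ``enumerate``: exhaustive (refused above ``cap``); ``dp``: exact
    optimum without enumeration via Dinkelbach fractional programming over
    a base-choice DP (valid because nearest-neighbor contributions are
    position-local); ``auto``: enumerate under the cap, else dp.
    """
    if primer.nonstandard:
        raise ThermoError(
            f"{primer.name}: non-IUPAC bases; melting temperature undefined")
    d = degeneracy(primer)
    if method == "auto":
        method = "enumerate" if d <= cap else "dp"
    if method == "enumerate":
        oligos = expand(primer, cap=cap)
        tms = [nn_tm(o, cond) for o in oligos]
        return TmRange(primer.name, min(tms), max(tms), len(tms))
    if method != "dp":
        raise ValueError(f"unknown method {method!r}")
    # minimizing 1/Tm yields the Tm maximum, and vice versa
    lo = _dp_extreme(primer.sequence, cond, minimize=False)
    hi = _dp_extreme(primer.sequence, cond, minimize=True)
    return TmRange(primer.name, lo, hi, d)


# ---------------------------------------------------------------------------
# exact min/max without enumeration
#
# Under the monovalent-equivalent correction
#     Tm = 1000 dH / (dS + salt + conc)
# with dH and dS additive over stacks, so max/min Tm over expansions is a
# linear-fractional program solved exactly by Dinkelbach iteration over a
# per-position base-choice DP.  Under the Owczarzy correction the 1/Tm term
# depends additionally on the GC count, which is handled by constraining
# the DP to each feasible GC count in turn.
# ---------------------------------------------------------------------------


def _dp_extreme(sequence: str, cond: TmConditions, minimize: bool) -> float:
    table = _load_nn_table()
    n = len(sequence)
    choice_sets = [sorted(DEGENERACY_SETS[c]) for c in sequence]
    conc = R_GAS * math.log(cond.oligo_conc / 4.0)
    if cond.salt_method == "monovalent_equivalent":
        const = conc + 0.368 * (n - 1) * math.log(cond.monovalent_equivalent)
        inv = _dinkelbach(choice_sets, table, const, None, minimize)
        return 1.0 / inv - 273.15
    best_inv = None
    for g in _feasible_gc_counts(choice_sets):
        salt = _owczarzy_inverse_tm_term(g / n, n, cond)
        inv = _dinkelbach(choice_sets, table, conc, g, minimize) + salt
        if best_inv is None:
            best_inv = inv
        best_inv = min(best_inv, inv) if minimize else max(best_inv, inv)
    return 1.0 / best_inv - 273.15


def _feasible_gc_counts(choice_sets) -> range:
    lo = sum(1 for s in choice_sets if set(s) <= set("GC"))
    hi = sum(1 for s in choice_sets if set(s) & set("GC"))
    return range(lo, hi + 1)


def _dinkelbach(choice_sets, table, const_entropy, gc_target, minimize,
                tol=1e-13, max_iter=60):
    """Optimum of (dS + const)/(1000 dH) over expansions, optionally
    constrained to a fixed GC count.

    Both numerator and denominator are negative for any stable duplex;
    rewritten as P/Q with P = -(dS + const) > 0, Q = -1000 dH > 0.
    Minimizing this ratio minimizes 1/Tm (maximizes Tm).  Note the caller
    passes ``minimize`` for the *1/Tm* sense.
    """
    sign = 1.0 if minimize else -1.0

    def solve(lam):
        """Optimize sign*(P - lam*Q) over paths; returns best (v, P, Q)."""
        n = len(choice_sets)
        state: dict = {}
        for b in choice_sets[0]:
            ih, is_ = _init_terms(b, table)
            p, q = -is_, -1000.0 * ih
            g = 1 if b in "GC" else 0
            v = sign * (p - lam * q)
            cur = state.get((b, g))
            if cur is None or v < cur[0]:
                state[(b, g)] = (v, p, q)
        for i in range(1, n):
            nxt: dict = {}
            last = i == n - 1
            for (b, g), (v, p, q) in state.items():
                for b2 in choice_sets[i]:
                    h, s = table[b + b2]
                    p2, q2 = p - s, q - 1000.0 * h
                    g2 = g + (1 if b2 in "GC" else 0)
                    if gc_target is not None and g2 > gc_target:
                        continue
                    if last:
                        ih, is_ = _init_terms(b2, table)
                        p2, q2 = p2 - is_, q2 - 1000.0 * ih
                    v2 = sign * (p2 - lam * q2)
                    cur = nxt.get((b2, g2))
                    if cur is None or v2 < cur[0]:
                        nxt[(b2, g2)] = (v2, p2, q2)
            state = nxt
        finals = [vpq for (b, g), vpq in state.items()
                  if gc_target is None or g == gc_target]
        if not finals:
            raise ThermoError("no expansion with the requested GC count")
        # adding the constant entropy shifts every path's P equally
        v, p, q = min(finals)
        p -= const_entropy
        return sign * (p - lam * q), p, q

    _, p, q = solve(0.0)
    lam = p / q
    for _ in range(max_iter):
        _, p, q = solve(lam)
        new_lam = p / q
        if abs(new_lam - lam) < tol:
            break
        lam = new_lam
    return lam
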