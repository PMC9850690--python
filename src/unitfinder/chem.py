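"""Element tables, valence-aware formula enumeration and DBE validation.

A candidate repeat unit is modelled as a multiset of atoms where every atom
carries an explicit valence state.  The placeholder element ``X`` (mass 0,
valence 1) marks the bonds that connect the unit to its molecular scaffold.
Chemical plausibility is decided by a double-bond-equivalent (DBE) criterion
restricted to reject under- and over-bonded compositions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ElementSpec",
    "ValencedComposition",
    "ValidationResult",
    "LibraryCapExceeded",
    "UnknownElementError",
    "MONOISOTOPIC_MASS",
    "DEFAULT_ELEMENT_ORDER",
    "default_element_table",
    "compute_dbe",
    "validate_formula",
    "monoisotopic_mass",
    "enumerate_formulas",
    "enumerate_table",
    "formula_string",
    "parse_formula",
    "write_library",
    "read_library",
]

# Monoisotopic masses of the most abundant isotope (Da); X is a massless
# placeholder marking connection points, so it must not shift unit masses.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "S": 31.9720711744,
    "O": 15.9949146196,
    "N": 14.0030740044,
    "P": 30.9737619984,
    "F": 18.9984031627,
    "Cl": 34.968852682,
    "Br": 78.9183376,
    "Si": 27.976926535,
    "X": 0.0,
}

DEFAULT_ELEMENT_ORDER = ("C", "H", "S", "O", "N", "P", "F", "Cl", "Br", "Si", "X")

#: Default per-element valence states and count limits used for library
#: generation: (valences, count_min, count_max).
_DEFAULT_TABLE: dict[str, tuple[tuple[int, ...], int, int]] = {
    "C": ((4,), 0, 10),
    "H": ((1,), 0, 20),
    "S": ((2, 4, 6), 0, 4),
    "O": ((2,), 0, 4),
    "N": ((3,), 0, 2),
    "P": ((3, 5), 0, 2),
    "F": ((1,), 0, 4),
    "Cl": ((1,), 0, 2),
    "Br": ((1,), 0, 2),
    "Si": ((4,), 0, 1),
    "X": ((1,), 1, 2),
}

DEFAULT_GRID_CAP = 20_000_000


class LibraryCapExceeded(RuntimeError):
    """Raised when the enumeration grid exceeds the configured cap."""


class UnknownElementError(KeyError):
    """Raised for an element symbol without a known monoisotopic mass."""


@dataclass(frozen=True)
class ElementSpec:
    """An element with its allowed valence states and count range."""

    symbol: str
    monoisotopic_mass: float
    valences: tuple[int, ...]
    count_min: int = 0
    count_max: int = 0

    def __post_init__(self) -> None:
        if not self.valences:
            raise ValueError(f"{self.symbol}: valences must be non-empty")
        if any(v < 1 for v in self.valences):
            raise ValueError(f"{self.symbol}: every valence must be >= 1")
        if self.count_min < 0 or self.count_min > self.count_max:
            raise ValueError(
                f"{self.symbol}: need 0 <= count_min <= count_max, "
                f"got [{self.count_min}, {self.count_max}]"
            )
        object.__setattr__(self, "valences", tuple(sorted(set(self.valences))))

    @property
    def monovalent(self) -> bool:
        return all(v == 1 for v in self.valences)

    @property
    def polyvalent(self) -> bool:
        return all(v >= 2 for v in self.valences)


def default_element_table() -> list[ElementSpec]:
    """The 11-element table (C, H, S, O, N, P, F, Cl, Br, Si, X) with the
    default valence states and count limits used for library generation."""
    return [
        ElementSpec(sym, MONOISOTOPIC_MASS[sym], vals, lo, hi)
        for sym, (vals, lo, hi) in _DEFAULT_TABLE.items()
    ]


class ValencedComposition(Mapping[tuple[str, int], int]):
    """Counts of atoms keyed by (element symbol, valence state).

    Absent keys mean zero atoms; present counts are >= 1.  Hashable and
    immutable so compositions can be deduplicated and used as dict keys.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[tuple[str, int], int]):
        cleaned = {}
        for (sym, val), n in counts.items():
            if n < 0:
                raise ValueError(f"negative count for {sym} (valence {val})")
            if n > 0:
                cleaned[(str(sym), int(val))] = int(n)
        self._counts = dict(sorted(cleaned.items()))

    def __getitem__(self, key: tuple[str, int]) -> int:
        return self._counts[key]

    def __iter__(self):
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    def __eq__(self, other) -> bool:
        if isinstance(other, ValencedComposition):
            return self._counts == other._counts
        return NotImplemented

    def __repr__(self) -> str:
        inner = ", ".join(f"{s}(v{v})x{n}" for (s, v), n in self._counts.items())
        return f"ValencedComposition({inner})"

    def collapsed(self) -> dict[str, int]:
        """Plain elemental composition, summing over valence states."""
        out: dict[str, int] = {}
        for (sym, _), n in self._counts.items():
            out[sym] = out.get(sym, 0) + n
        return out

    def merge(self, other: "ValencedComposition") -> "ValencedComposition":
        counts = dict(self._counts)
        for key, n in other.items():
            counts[key] = counts.get(key, 0) + n
        return ValencedComposition(counts)


@dataclass(frozen=True)
class ValidationResult:
    """Outcome of the valence-based formula check."""

    valid: bool
    dbe: Fraction
    reason: str | None = None


def compute_dbe(vc: ValencedComposition) -> Fraction:
    """Double-bond equivalents: (1/2) * sum E_i (nu_i - 2) + 1.

    May be negative or half-integral; such values mark implausible formulas.
    """
    total = sum(n * (val - 2) for (_, val), n in vc.items())
    return Fraction(total, 2) + 1


def validate_formula(vc: ValencedComposition) -> ValidationResult:
    """Decide chemical plausibility of a valenced composition.

    Uses a saturation balance restricted by the number of polyvalent atoms P
    (atoms with valence >= 2):

    * P = 0: rejected — a bridging unit of only valence-1 atoms cannot bond
      into a scaffold.
    * P = 1: the single polyvalent atom's valence must exactly equal the
      number of monovalent atoms (rejects e.g. NX).
    * P > 1: the DBE must be a non-negative integer.

    The ``dbe`` field always carries the plain DBE value.
    """
    dbe = compute_dbe(vc)
    p_count = sum(n for (_, val), n in vc.items() if val >= 2)
    m_count = sum(n for (_, val), n in vc.items() if val == 1)
    if p_count == 0:
        return ValidationResult(False, dbe, "no polyvalent atom")
    if p_count == 1:
        poly_valence_sum = sum(n * val for (_, val), n in vc.items() if val >= 2)
        if poly_valence_sum != m_count:
            return ValidationResult(False, dbe, "saturation-rule violated")
        return ValidationResult(True, dbe)
    if dbe.denominator != 1:
        return ValidationResult(False, dbe, "non-integer DBE")
    if dbe < 0:
        return ValidationResult(False, dbe, "negative DBE")
    return ValidationResult(True, dbe)


def monoisotopic_mass(vc: ValencedComposition | Mapping[str, int]) -> float:
    """Monoisotopic mass in Da; X contributes exactly 0."""
    if isinstance(vc, ValencedComposition):
        counts = vc.collapsed()
    else:
        counts = dict(vc)
    total = 0.0
    for sym, n in counts.items():
        try:
            total += n * MONOISOTOPIC_MASS[sym]
        except KeyError:
            raise UnknownElementError(sym) from None
    return total


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------


def _fast_eligible(elements: Sequence[ElementSpec]) -> bool:
    # The vectorised path needs each element to be purely mono- or polyvalent
    # and multi-valence sets to form a step-2 range (e.g. {2,4,6} or {3,5}),
    # so that attainable valence sums are exactly "parity + interval".
    for e in elements:
        if not (e.monovalent or e.polyvalent):
            return False
        vs = e.valences
        if any(b - a != 2 for a, b in zip(vs, vs[1:])):
            return False
    return True


def _grid_columns(elements: Sequence[ElementSpec], cap: int) -> dict[str, np.ndarray]:
    sizes = [e.count_max - e.count_min + 1 for e in elements]
    total = math.prod(sizes)
    if total > cap:
        raise LibraryCapExceeded(
            f"enumeration grid has {total} points, exceeding the cap of {cap}; "
            "tighten the per-element count limits or raise the cap"
        )
    ranges = [
        np.arange(e.count_min, e.count_max + 1, dtype=np.int16) for e in elements
    ]
    mesh = np.meshgrid(*ranges, indexing="ij")
    return {e.symbol: m.reshape(-1) for e, m in zip(elements, mesh)}


def enumerate_table(
    elements: Sequence[ElementSpec] | None = None,
    cap: int = DEFAULT_GRID_CAP,
) -> pd.DataFrame:
    """Enumerate all valid compositions as a DataFrame (fast, vectorised).

    Columns: one int count per element symbol, plus ``mass`` (Da) and ``dbe``
    (int, for a witness valence assignment of minimal total valence).  One row
    per collapsed elemental composition; a row is kept when at least one
    valence-state assignment validates.
    """
    if elements is None:
        elements = default_element_table()
    _check_table(elements)
    if not _fast_eligible(elements):
        return _table_from_compositions(enumerate_formulas(elements, cap=cap))

    cols = _grid_columns(elements, cap)
    mono = [e for e in elements if e.monovalent]
    poly = [e for e in elements if not e.monovalent]

    n_rows = len(next(iter(cols.values()))) if cols else 0
    m_count = np.zeros(n_rows, dtype=np.int64)
    for e in mono:
        m_count += cols[e.symbol]
    p_count = np.zeros(n_rows, dtype=np.int64)
    s2_min = np.zeros(n_rows, dtype=np.int64)
    s2_max = np.zeros(n_rows, dtype=np.int64)
    for e in poly:
        c = cols[e.symbol].astype(np.int64)
        p_count += c
        s2_min += c * min(e.valences)
        s2_max += c * max(e.valences)

    bound = 2 * p_count + m_count - 2
    parity_ok = (s2_min - m_count) % 2 == 0
    valid_multi = (p_count >= 2) & parity_ok & (s2_max >= bound)

    valid_single = np.zeros(n_rows, dtype=bool)
    single = p_count == 1
    for e in poly:
        in_set = np.isin(m_count, np.asarray(e.valences, dtype=np.int64))
        valid_single |= single & (cols[e.symbol] == 1) & in_set

    valid = valid_multi | valid_single
    # Witness valence sum: smallest attainable total >= bound (same parity
    # throughout the attainable range); for P=1 this lands exactly on M.
    s2_wit = np.maximum(s2_min, bound)
    dbe = np.where(valid, (s2_wit - bound) // 2, 0)

    out: dict[str, np.ndarray] = {}
    for e in elements:
        out[e.symbol] = cols[e.symbol][valid].astype(np.int16)
    mass = np.zeros(int(valid.sum()), dtype=np.float64)
    for e in elements:
        mass += out[e.symbol].astype(np.float64) * e.monoisotopic_mass

    df = pd.DataFrame(out)
    df["mass"] = mass
    df["dbe"] = dbe[valid].astype(np.int64)

    # Spread the witness excess over multi-valence elements so valence-state
    # witness columns are reconstructible (used by enumerate_formulas).
    multi = [e for e in poly if len(e.valences) > 1]
    if multi:
        delta = (s2_wit - s2_min)[valid]
        for e in multi:
            c = out[e.symbol].astype(np.int64)
            span = max(e.valences) - min(e.valences)
            capacity = c * span
            take = np.minimum(delta, capacity)
            delta = delta - take
            df[f"_take_{e.symbol}"] = take
    return df.reset_index(drop=True)


def _check_table(elements: Sequence[ElementSpec]) -> None:
    seen = set()
    for e in elements:
        if e.symbol in seen:
            raise ValueError(f"duplicate element {e.symbol}")
        seen.add(e.symbol)
        if e.symbol not in MONOISOTOPIC_MASS and e.monoisotopic_mass is None:
            raise UnknownElementError(e.symbol)


def _witness_from_row(elements: Sequence[ElementSpec], row) -> ValencedComposition:
    counts: dict[tuple[str, int], int] = {}
    for e in elements:
        n = int(row[e.symbol])
        if n == 0:
            continue
        if len(e.valences) == 1:
            counts[(e.symbol, e.valences[0])] = n
            continue
        take = int(row[f"_take_{e.symbol}"])
        vmin, vmax = min(e.valences), max(e.valences)
        span = vmax - vmin
        n_top = take // span if span else 0
        rem = take - n_top * span
        if n_top:
            counts[(e.symbol, vmax)] = n_top
        if rem:
            counts[(e.symbol, vmin + rem)] = counts.get((e.symbol, vmin + rem), 0) + 1
        base = n - n_top - (1 if rem else 0)
        if base:
            counts[(e.symbol, vmin)] = counts.get((e.symbol, vmin), 0) + base
    return ValencedComposition(counts)


def enumerate_formulas(
    elements: Sequence[ElementSpec] | None = None,
    cap: int = DEFAULT_GRID_CAP,
) -> list[ValencedComposition]:
    """All valid compositions within the table's count limits.

    Every valence state of a multi-valence element is iterated independently,
    so mixed valence-state combinations occur.  Output is deduplicated by
    collapsed elemental composition (one record kept, valid under at least one
    valence assignment) and ordered deterministically by the element order of
    the table.
    """
    if elements is None:
        elements = default_element_table()
    _check_table(elements)
    if _fast_eligible(elements):
        df = enumerate_table(elements, cap=cap)
        return [_witness_from_row(elements, row) for _, row in df.iterrows()]
    return _enumerate_bruteforce(elements, cap)


def _enumerate_bruteforce(
    elements: Sequence[ElementSpec], cap: int
) -> list[ValencedComposition]:
    # Honest per-valence-state iteration; used for unusual valence tables.
    per_element: list[list[tuple[tuple[tuple[str, int], int], ...]]] = []
    grid_total = 1
    for e in elements:
        splits = []
        state_ranges = [range(0, e.count_max + 1)] * len(e.valences)
        for combo in itertools.product(*state_ranges):
            if e.count_min <= sum(combo) <= e.count_max:
                splits.append(
                    tuple(
                        ((e.symbol, v), n)
                        for v, n in zip(e.valences, combo)
                        if n > 0
                    )
                )
        per_element.append(splits)
        grid_total *= len(splits)
        if grid_total > cap:
            raise LibraryCapExceeded(
                f"enumeration grid exceeds the cap of {cap}; tighten limits"
            )

    seen: set[tuple[tuple[str, int], ...]] = set()
    out: list[ValencedComposition] = []
    for assignment in itertools.product(*per_element):
        counts: dict[tuple[str, int], int] = {}
        for split in assignment:
            for key, n in split:
                counts[key] = counts.get(key, 0) + n
        vc = ValencedComposition(counts)
        if not vc:
            continue
        key = tuple(sorted(vc.collapsed().items()))
        if key in seen:
            continue
        if validate_formula(vc).valid:
            seen.add(key)
            out.append(vc)
    return out


def _table_from_compositions(vcs: Iterable[ValencedComposition]) -> pd.DataFrame:
    rows = []
    symbols: list[str] = []
    for vc in vcs:
        coll = vc.collapsed()
        for s in coll:
            if s not in symbols:
                symbols.append(s)
        rows.append((coll, validate_formula(vc).dbe))
    data = {s: [int(coll.get(s, 0)) for coll, _ in rows] for s in symbols}
    df = pd.DataFrame(data, dtype=np.int16)
    df["mass"] = [monoisotopic_mass(coll) for coll, _ in rows]
    df["dbe"] = [int(d) for _, d in rows]
    return df


# ---------------------------------------------------------------------------
# Formula strings and library files
# ---------------------------------------------------------------------------


def formula_string(composition: Mapping[str, int]) -> str:
    """Hill-like display form: C, H, then other elements alphabetically,
    X always last; counts of one are omitted."""
    comp = {s: n for s, n in composition.items() if n > 0}
    order = [s for s in ("C", "H") if s in comp]
    order += sorted(s for s in comp if s not in ("C", "H", "X"))
    if "X" in comp:
        order.append("X")
    return "".join(f"{s}{comp[s] if comp[s] > 1 else ''}" for s in order)


def parse_formula(text: str) -> dict[str, int]:
    """Parse an element+count token string like ``C2H4OX2`` (1s optional)."""
    import re

    text = text.strip()
    if not text:
        raise ValueError("empty formula")
    out: dict[str, int] = {}
    pos = 0
    for m in re.finditer(r"([A-Z][a-z]?)(\d*)", text):
        if m.start() != pos or not m.group(1):
            break
        if m.group(0) == "":
            break
        sym = m.group(1)
        n = int(m.group(2)) if m.group(2) else 1
        out[sym] = out.get(sym, 0) + n
        pos = m.end()
        if pos == len(text):
            break
    if pos != len(text) or not out:
        raise ValueError(f"unparseable formula: {text!r}")
    unknown = [s for s in out if s not in MONOISOTOPIC_MASS]
    if unknown:
        raise UnknownElementError(", ".join(unknown))
    return out


def write_library(df: pd.DataFrame, path, header_lines: Sequence[str] = ()) -> None:
    """Write a library table as delimited text: formula, exact mass (7
    decimals), DBE.  ``header_lines`` are prefixed as ``#`` comments."""
    element_cols = [c for c in df.columns if c in MONOISOTOPIC_MASS]
    formulas = [
        formula_string({s: int(row[s]) for s in element_cols})
        for _, row in df.iterrows()
    ]
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("formula,exact_mass,dbe\n")
        for formula, mass, dbe in zip(formulas, df["mass"], df["dbe"]):
            fh.write(f"{formula},{mass:.7f},{int(dbe)}\n")


def read_library(path) -> pd.DataFrame:
    """Read a library file back into the element-column table form."""
    df = pd.read_csv(path, comment="#")
    comps = [parse_formula(f) for f in df["formula"]]
    symbols: list[str] = []
    for c in comps:
        for s in c:
            if s not in symbols:
                symbols.append(s)
    out = pd.DataFrame({s: [c.get(s, 0) for c in comps] for s in symbols}, dtype=np.int16)
    out["mass"] = df["exact_mass"].astype(float)
    out["dbe"] = df["dbe"].astype(int)
    return out
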