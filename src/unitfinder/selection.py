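"""Screening of the formula library down to candidate changing units.

Filters: per-element count ceilings, elemental ratios relative to carbon,
a unit-mass window and a DBE ceiling.  Every filter can be disabled
individually.  In untargeted runs the upper mass bound is additionally
capped at max(m/z) divided by the minimum desired number of repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import chem
from .peaklist import PeakList

__all__ = [
    "RATIO_ELEMENTS",
    "SelectionCriteria",
    "UnitCandidate",
    "default_criteria",
    "select_units",
    "auto_criteria",
    "filter_table",
    "candidates_from_table",
]

#: Elements with a default "per carbon" ratio bound, in reporting order.
RATIO_ELEMENTS = ("H", "N", "O", "P", "S", "F", "Cl", "Br", "Si")

_DEFAULT_RATIOS: dict[str, tuple[float, float]] = {
    "H": (0.3, 4.0),
    "N": (0.0, 1.3),
    "O": (0.0, 1.2),
    "P": (0.0, 0.3),
    "S": (0.0, 0.8),
    "F": (0.0, 1.5),
    "Cl": (0.0, 0.8),
    "Br": (0.0, 0.8),
    "Si": (0.0, 0.5),
}


@dataclass(frozen=True)
class UnitCandidate:
    """A collapsed elemental composition that can act as a repeat unit."""

    composition: tuple[tuple[str, int], ...]
    exact_mass: float
    dbe: int
    formula_string: str = ""

    def __post_init__(self) -> None:
        if self.exact_mass <= 0:
            raise ValueError("exact_mass must be positive")
        if self.dbe < 0:
            raise ValueError("dbe must be non-negative")
        if not self.formula_string:
            object.__setattr__(
                self, "formula_string", chem.formula_string(dict(self.composition))
            )

    @classmethod
    def from_composition(
        cls, composition: Mapping[str, int], dbe: int = 0
    ) -> "UnitCandidate":
        comp = tuple(sorted((s, int(n)) for s, n in composition.items() if n > 0))
        return cls(comp, chem.monoisotopic_mass(dict(comp)), dbe)

    @classmethod
    def from_formula(cls, text: str, dbe: int | None = None) -> "UnitCandidate":
        """Build from an element+count token string like ``C2H4O``.

        If ``dbe`` is omitted it is computed with each element's lowest
        default valence state.
        """
        comp = chem.parse_formula(text)
        if dbe is None:
            counts = {
                (sym, chem._DEFAULT_TABLE[sym][0][0]): n
                for sym, n in comp.items()
                if sym in chem._DEFAULT_TABLE
            }
            val = chem.compute_dbe(chem.ValencedComposition(counts))
            dbe = max(0, int(val)) if val.denominator == 1 else 0
        return cls.from_composition(comp, dbe=dbe)

    def count(self, symbol: str) -> int:
        return dict(self.composition).get(symbol, 0)


@dataclass(frozen=True)
class SelectionCriteria:
    """Chemical screening rules for candidate units.

    ``ratio_bounds`` maps an element symbol to its (lo, hi) bound relative to
    carbon; a ``None`` value disables that single ratio.  All bounds are
    inclusive.
    """

    element_max: Mapping[str, int] = field(default_factory=dict)
    ratio_bounds: Mapping[str, tuple[float, float] | None] = field(
        default_factory=dict
    )
    mass_min: float = 14.0
    mass_max: float = 200.0
    dbe_max: int | None = 40
    filter_elements: bool = True
    filter_ratios: bool = True
    filter_mass: bool = True
    filter_dbe: bool = True

    def __post_init__(self) -> None:
        if self.mass_min < 0 or self.mass_min > self.mass_max:
            raise ValueError("need 0 <= mass_min <= mass_max")
        for sym, bound in self.ratio_bounds.items():
            if bound is not None and bound[0] > bound[1]:
                raise ValueError(f"ratio bound for {sym} has lo > hi")

    def disabled(self) -> "SelectionCriteria":
        """Copy with every filter switched off."""
        return replace(
            self,
            filter_elements=False,
            filter_ratios=False,
            filter_mass=False,
            filter_dbe=False,
        )


def default_criteria() -> SelectionCriteria:
    """Default screen: the printed per-carbon ratio bounds
    (0.3 <= H/C <= 4.0 ... 0 <= Si/C <= 0.5), unit-mass window 14-200 Da,
    the default element count ceilings and a generous DBE ceiling of 40."""
    element_max = {
        sym: hi for sym, (_, _, hi) in chem._DEFAULT_TABLE.items()
    }
    return SelectionCriteria(
        element_max=element_max,
        ratio_bounds=dict(_DEFAULT_RATIOS),
        mass_min=14.0,
        mass_max=200.0,
        dbe_max=40,
    )


def _ratio_denominator(comp: Mapping[str, int]) -> int:
    # X marks bonds into the (carbon) scaffold, so it joins the denominator;
    # this keeps fully substituted small units such as CF2X2 admissible
    # under the printed per-carbon bounds.
    return comp.get("C", 0) + comp.get("X", 0)


def _passes(comp: Mapping[str, int], mass: float, dbe: int, c: SelectionCriteria) -> bool:
    if c.filter_mass and not (c.mass_min <= mass <= c.mass_max):
        return False
    if c.filter_dbe and c.dbe_max is not None and dbe > c.dbe_max:
        return False
    if c.filter_elements:
        for sym, hi in c.element_max.items():
            if comp.get(sym, 0) > hi:
                return False
    if c.filter_ratios:
        denom = _ratio_denominator(comp)
        if denom > 0:
            for sym, bound in c.ratio_bounds.items():
                if bound is None:
                    continue
                count = comp.get(sym, 0)
                if count == 0:
                    continue  # absent element: ratio constraint is vacuous
                ratio = count / denom
                if not (bound[0] <= ratio <= bound[1]):
                    return False
    return True


def select_units(
    library: Sequence[UnitCandidate], criteria: SelectionCriteria
) -> list[UnitCandidate]:
    """Retain candidates satisfying all enabled filters, sorted by mass.

    Ratio filters pass vacuously when the composition has no carbon and no X
    (nothing to divide by), and a single ratio is skipped when its numerator
    element is absent (a hydrogen bound should not reject CF2).
    """
    kept = [
        u
        for u in library
        if _passes(dict(u.composition), u.exact_mass, u.dbe, criteria)
    ]
    return sorted(kept, key=lambda u: (u.exact_mass, u.formula_string))


def auto_criteria(
    peaks: PeakList,
    min_repetitions: int = 3,
    base: SelectionCriteria | None = None,
) -> SelectionCriteria:
    """Untargeted auto-derivation: cap the maximum unit mass at the largest
    m/z in the dataset divided by the minimum desired number of repetitions
    (never loosening the configured window)."""
    if len(peaks) == 0:
        raise ValueError("empty peak list")
    if min_repetitions < 1:
        raise ValueError("min_repetitions must be >= 1")
    if base is None:
        base = default_criteria()
    cap = float(peaks.mz[-1]) / min_repetitions
    return replace(base, mass_max=min(base.mass_max, cap))


# ---------------------------------------------------------------------------
# Vectorised variants operating on the enumerate_table DataFrame
# ---------------------------------------------------------------------------


def filter_table(df: pd.DataFrame, criteria: SelectionCriteria) -> pd.DataFrame:
    """Apply the same screen to a library table (element-count columns)."""
    n = len(df)
    keep = np.ones(n, dtype=bool)
    mass = df["mass"].to_numpy()
    dbe = df["dbe"].to_numpy()
    if criteria.filter_mass:
        keep &= (mass >= criteria.mass_min) & (mass <= criteria.mass_max)
    if criteria.filter_dbe and criteria.dbe_max is not None:
        keep &= dbe <= criteria.dbe_max
    if criteria.filter_elements:
        for sym, hi in criteria.element_max.items():
            if sym in df.columns:
                keep &= df[sym].to_numpy() <= hi
    if criteria.filter_ratios:
        carbon = df["C"].to_numpy() if "C" in df.columns else np.zeros(n)
        x = df["X"].to_numpy() if "X" in df.columns else np.zeros(n)
        denom = carbon.astype(np.float64) + x.astype(np.float64)
        has_denom = denom > 0
        for sym, bound in criteria.ratio_bounds.items():
            if bound is None or sym not in df.columns:
                continue
            count = df[sym].to_numpy().astype(np.float64)
            applies = has_denom & (count > 0)
            ratio = count / np.where(has_denom, denom, 1.0)
            keep &= ~applies | ((ratio >= bound[0]) & (ratio <= bound[1]))
    out = df.loc[keep]
    return out.sort_values("mass", kind="mergesort").reset_index(drop=True)


def candidates_from_table(df: pd.DataFrame) -> list[UnitCandidate]:
    """Materialise a table's rows as UnitCandidate objects."""
    element_cols = [c for c in df.columns if c in chem.MONOISOTOPIC_MASS]
    out = []
    for _, row in df.iterrows():
        comp = {s: int(row[s]) for s in element_cols if row[s] > 0}
        mass_total = float(row["mass"])
        if mass_total <= 0:
            continue  # pure-X placeholder rows cannot be searched by mass
        out.append(
            UnitCandidate(
                tuple(sorted(comp.items())), mass_total, int(row["dbe"])
            )
        )
    return out
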