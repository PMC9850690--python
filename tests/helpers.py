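"""Shared test utilities: independent brute-force oracles and strategies."""

from __future__ import annotations

import itertools

from unitfinder.chem import (
    ElementSpec,
    MONOISOTOPIC_MASS,
    ValencedComposition,
    validate_formula,
)


def brute_force_enumerate(elements) -> set[tuple[tuple[str, int], ...]]:
    """Exhaustive nested-loop enumeration oracle.

    Walks every per-valence-state count grid point, applies validate_formula,
    and returns the set of collapsed compositions that validate under at
    least one valence assignment.  Deliberately naive — independent of the
    library's vectorised enumeration path.
    """
    per_element: list[list[dict[tuple[str, int], int]]] = []
    for e in elements:
        options = []
        state_ranges = [range(0, e.count_max + 1)] * len(e.valences)
        for combo in itertools.product(*state_ranges):
            if e.count_min <= sum(combo) <= e.count_max:
                options.append(
                    {
                        (e.symbol, v): n
                        for v, n in zip(e.valences, combo)
                        if n > 0
                    }
                )
        per_element.append(options)

    valid: set[tuple[tuple[str, int], ...]] = set()
    for assignment in itertools.product(*per_element):
        counts: dict[tuple[str, int], int] = {}
        for part in assignment:
            for key, n in part.items():
                counts[key] = counts.get(key, 0) + n
        if not counts:
            continue
        vc = ValencedComposition(counts)
        if validate_formula(vc).valid:
            valid.add(tuple(sorted(vc.collapsed().items())))
    return valid


def make_element(symbol, valences, lo, hi) -> ElementSpec:
    return ElementSpec(symbol, MONOISOTOPIC_MASS[symbol], tuple(valences), lo, hi)


def collapsed_set(vcs) -> set[tuple[tuple[str, int], ...]]:
    return {tuple(sorted(vc.collapsed().items())) for vc in vcs}
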