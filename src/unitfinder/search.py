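"""Repeat-unit detection: local chain search and global difference search.

Two complementary detectors decide whether a candidate unit of mass ``u``
repeats in a spectrum:

* **local search** walks ladders inside the spectrum: a chain opens at peak
  ``p`` when a peak matches ``p + u`` (within the selection error) and is
  extended with theoretical sums ``p + n*u`` (within the loop error) until
  ``n`` reaches the required number of steps ``m``.
* **global search** builds the multiset of all pairwise m/z differences and
  requires every multiple ``k*u`` (k = 1..m) to match some difference; no
  constraint is placed on where in the spectrum the matches occur.

Tolerances are absolute Da by default (``error_unit="ppm"`` switches both to
parts-per-million of the target mass).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .peaklist import PeakList
from .selection import SelectionCriteria, UnitCandidate, auto_criteria, select_units

__all__ = [
    "SearchConfig",
    "DifferenceMultiset",
    "ChainEvidence",
    "DifferenceMatch",
    "UnitHit",
    "local_search",
    "pairwise_differences",
    "global_search",
    "find_units",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchConfig:
    """Parameters shared by both detectors.

    ``selection_error`` bounds the first match of a candidate, ``loop_error``
    the chained/multiplied matches; ``m`` is the required repetition count.
    """

    selection_error: float = 0.0025
    loop_error: float = 0.0025
    m: int = 3
    algorithm: Literal["local", "global"] = "global"
    mode: Literal["targeted", "untargeted"] = "untargeted"
    min_repetitions: int = 3
    error_unit: Literal["da", "ppm"] = "da"
    strict_multiples: bool = True

    def __post_init__(self) -> None:
        if self.selection_error <= 0 or self.loop_error <= 0:
            raise ValueError("errors must be positive")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.min_repetitions < 1:
            raise ValueError("min_repetitions must be >= 1")

    def tolerance(self, step: int, target: float) -> float:
        """Absolute tolerance for step ``n`` (1 = first match) at ``target`` Da."""
        err = self.selection_error if step == 1 else self.loop_error
        if self.error_unit == "ppm":
            return err * 1e-6 * target
        return err


@dataclass(frozen=True)
class ChainEvidence:
    """One complete local chain: the starting m/z and the matched peak m/z
    for each of the m steps."""

    start_mz: float
    matched_mz: tuple[float, ...]


@dataclass(frozen=True)
class DifferenceMatch:
    """A pairwise difference matching multiple k of the unit mass."""

    multiple: int
    difference: float
    low_index: int
    high_index: int


@dataclass(frozen=True)
class UnitHit:
    candidate: UnitCandidate
    count: int
    evidence: tuple = ()
    algorithm: str = ""
    m: int = 0

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass
class DifferenceMultiset:
    """All positive pairwise m/z differences, sorted, with provenance."""

    values: np.ndarray
    low_index: np.ndarray
    high_index: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


def pairwise_differences(peaks: PeakList) -> DifferenceMultiset:
    """Every unordered peak pair contributes one positive difference."""
    n = len(peaks)
    if n < 2:
        raise ValueError("need at least 2 peaks")
    i, j = np.triu_indices(n, k=1)
    diffs = peaks.mz[j] - peaks.mz[i]
    order = np.argsort(diffs, kind="mergesort")
    return DifferenceMultiset(diffs[order], i[order], j[order])


def _nearest_indices(sorted_arr: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Index of the nearest element in ``sorted_arr`` for each target."""
    pos = np.searchsorted(sorted_arr, targets)
    lo = np.clip(pos - 1, 0, len(sorted_arr) - 1)
    hi = np.clip(pos, 0, len(sorted_arr) - 1)
    pick_hi = np.abs(sorted_arr[hi] - targets) < np.abs(sorted_arr[lo] - targets)
    return np.where(pick_hi, hi, lo)


def local_search(
    peaks: PeakList,
    candidates: Sequence[UnitCandidate],
    cfg: SearchConfig,
) -> list[UnitHit]:
    """Chain detector: report a candidate iff at least one peak starts a
    complete chain of m unit additions; count = number of distinct starting
    peaks with a complete chain."""
    if len(peaks) == 0:
        raise ValueError("empty peak list")
    mz = peaks.mz
    steps = np.arange(1, cfg.m + 1, dtype=np.float64)
    hits: list[UnitHit] = []
    for cand in candidates:
        u = cand.exact_mass
        targets = mz[:, None] + u * steps[None, :]  # theoretical sums
        idx = _nearest_indices(mz, targets.reshape(-1)).reshape(targets.shape)
        matched_mz = mz[idx]
        tol = np.array(
            [cfg.tolerance(int(s), 0.0) for s in steps]
        )
        if cfg.error_unit == "ppm":
            tol = np.stack(
                [cfg.tolerance(int(s), 1.0) * targets[:, k] for k, s in enumerate(steps)],
                axis=1,
            )
        ok = np.abs(matched_mz - targets) <= tol
        complete = ok.all(axis=1)
        starts = np.nonzero(complete)[0]
        if len(starts) == 0:
            continue
        evidence = tuple(
            ChainEvidence(float(mz[s]), tuple(float(v) for v in matched_mz[s]))
            for s in starts
        )
        hits.append(
            UnitHit(cand, int(len(starts)), evidence, algorithm="local", m=cfg.m)
        )
    return hits


def global_search(
    peaks: PeakList,
    candidates: Sequence[UnitCandidate],
    cfg: SearchConfig,
    diffs: DifferenceMultiset | None = None,
) -> list[UnitHit]:
    """Difference detector: report a candidate iff every multiple k*u
    (k = 1..m) matches some pairwise difference; count = total number of
    matching differences over all k.

    With ``strict_multiples=False`` a candidate is instead reported when its
    first multiple matches and at least one higher multiple does too.
    """
    if len(peaks) < 2:
        raise ValueError("need at least 2 peaks")
    if diffs is None:
        diffs = pairwise_differences(peaks)
    values = diffs.values
    hits: list[UnitHit] = []
    for cand in candidates:
        u = cand.exact_mass
        matches: list[DifferenceMatch] = []
        per_multiple_ok: list[bool] = []
        for k in range(1, cfg.m + 1):
            target = k * u
            tol = cfg.tolerance(k, target)
            lo = np.searchsorted(values, target - tol, side="left")
            hi = np.searchsorted(values, target + tol, side="right")
            per_multiple_ok.append(hi > lo)
            for idx in range(lo, hi):
                matches.append(
                    DifferenceMatch(
                        k,
                        float(values[idx]),
                        int(diffs.low_index[idx]),
                        int(diffs.high_index[idx]),
                    )
                )
        if cfg.strict_multiples:
            reported = all(per_multiple_ok)
        else:
            reported = per_multiple_ok[0] and (
                cfg.m == 1 or any(per_multiple_ok[1:])
            )
        if reported and matches:
            hits.append(
                UnitHit(
                    cand, len(matches), tuple(matches), algorithm="global", m=cfg.m
                )
            )
    return hits


def find_units(
    peaks: PeakList,
    cfg: SearchConfig | None = None,
    criteria: SelectionCriteria | None = None,
    library: Sequence[UnitCandidate] | None = None,
) -> list[UnitHit]:
    """Full workflow: screen the library to candidate units, run the chosen
    detector and return hits sorted by count (descending) then mass.

    In untargeted mode the screen is auto-derived from the data (max unit
    mass = max m/z / min_repetitions) and the global detector is used.  When
    no library is given, one is enumerated from the default element table.
    """
    if cfg is None:
        cfg = SearchConfig()
    if library is None:
        from . import chem, selection

        t0 = time.monotonic()
        table = chem.enumerate_table()
        pre = criteria if criteria is not None else selection.default_criteria()
        table = selection.filter_table(table, pre)
        library = selection.candidates_from_table(table)
        logger.info(
            "enumerated default library: %d candidates in %.1f s",
            len(library),
            time.monotonic() - t0,
        )

    if cfg.mode == "untargeted":
        crit = auto_criteria(peaks, cfg.min_repetitions, base=criteria)
        algorithm = "global"
    else:
        from .selection import default_criteria

        crit = criteria if criteria is not None else default_criteria()
        algorithm = cfg.algorithm

    candidates = select_units(list(library), crit)
    if not candidates:
        logger.warning("no candidate units survive selection; nothing to search")
        return []
    logger.info(
        "searching %d candidate units with %s algorithm (m=%d)",
        len(candidates),
        algorithm,
        cfg.m,
    )
    if algorithm == "local":
        hits = local_search(peaks, candidates, cfg)
    else:
        hits = global_search(peaks, candidates, cfg)
    return sorted(hits, key=lambda h: (-h.count, h.candidate.exact_mass))
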