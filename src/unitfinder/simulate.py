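"""Deterministic synthetic HRMS peak lists with planted homologous series.

Each planted series is an arithmetic ladder scaffold + k*unit_mass with a
monotone-decaying intensity envelope, optional truncated-normal mass jitter
and either sequential or sparse presence.  Uniform noise peaks are kept away
from planted positions so recall tests remain deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .peaklist import PeakList
from .selection import UnitCandidate

__all__ = ["SeriesSpec", "generate_spectrum", "planted_positions", "write_manifest"]


@dataclass(frozen=True)
class SeriesSpec:
    """One planted homologous series."""

    unit: UnitCandidate
    scaffold_mass: float
    n_min: int = 0
    n_max: int = 8
    base_intensity: float = 1000.0
    decay: float = 0.85
    jitter_sd: float = 0.0
    presence: Literal["sequential", "sparse"] = "sequential"
    keep_fraction: float = 0.6
    keep_indices: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_min < 0 or self.n_min > self.n_max:
            raise ValueError("need 0 <= n_min <= n_max")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if not (0 < self.decay <= 1):
            raise ValueError("decay must be in (0, 1]")

    def ladder(self) -> np.ndarray:
        """Exact (jitter-free) m/z positions of the full ladder."""
        ks = np.arange(self.n_min, self.n_max + 1)
        return self.scaffold_mass + ks * self.unit.exact_mass


def planted_positions(series: Sequence[SeriesSpec]) -> np.ndarray:
    """Exact positions of every planted ladder member (all series pooled)."""
    if not series:
        return np.empty(0)
    return np.concatenate([s.ladder() for s in series])


def _truncated_normal(rng: np.random.Generator, sd: float, size: int) -> np.ndarray:
    # jitter truncated at +/- 3 sd so tolerance guarantees stay testable
    if sd == 0:
        return np.zeros(size)
    draws = rng.normal(0.0, sd, size=size)
    bad = np.abs(draws) > 3 * sd
    while bad.any():
        draws[bad] = rng.normal(0.0, sd, size=int(bad.sum()))
        bad = np.abs(draws) > 3 * sd
    return draws


def generate_spectrum(
    series: Sequence[SeriesSpec],
    n_noise: int = 0,
    mz_range: tuple[float, float] = (50.0, 1000.0),
    seed: int = 0,
    noise_intensity: tuple[float, float] = (1.0, 100.0),
    noise_exclusion: float = 0.005,
) -> PeakList:
    """Emit a reproducible peak list with the planted series plus noise.

    Noise peaks are rejected if they fall within ``noise_exclusion`` Da of
    any exact planted position.  Duplicate m/z values are merged.
    """
    lo, hi = mz_range
    if not (0 < lo < hi):
        raise ValueError("invalid mz_range")
    rng = np.random.default_rng(seed)
    mzs: list[float] = []
    intens: list[float] = []
    for s in series:
        ks = np.arange(s.n_min, s.n_max + 1)
        if s.presence == "sparse":
            if s.keep_indices is not None:
                keep = np.array(
                    [k in set(s.keep_indices) for k in range(len(ks))]
                )
            else:
                keep = rng.random(len(ks)) < s.keep_fraction
                if not keep.any():
                    keep[0] = True
            ks = ks[keep]
        positions = s.scaffold_mass + ks * s.unit.exact_mass
        positions = positions + _truncated_normal(rng, s.jitter_sd, len(positions))
        envelope = s.base_intensity * s.decay ** (ks - s.n_min)
        mzs.extend(positions.tolist())
        intens.extend(envelope.tolist())

    exact = planted_positions(series)
    accepted = 0
    while accepted < n_noise:
        draw = rng.uniform(lo, hi)
        if len(exact) and np.min(np.abs(exact - draw)) < noise_exclusion:
            continue
        mzs.append(float(draw))
        intens.append(float(rng.uniform(*noise_intensity)))
        accepted += 1

    if not mzs:
        raise ValueError("nothing to generate: no series and no noise")
    return PeakList.from_unsorted(
        np.array(mzs), np.array(intens), metadata=f"synthetic seed={seed}"
    )


def write_manifest(
    series: Sequence[SeriesSpec], path: str | Path, seed: int, n_noise: int
) -> None:
    """Record the planted ground truth as JSON for downstream scoring."""
    payload = {
        "seed": seed,
        "n_noise": n_noise,
        "series": [
            {
                "unit": s.unit.formula_string,
                "unit_mass": s.unit.exact_mass,
                "scaffold_mass": s.scaffold_mass,
                "n_min": s.n_min,
                "n_max": s.n_max,
                "jitter_sd": s.jitter_sd,
                "presence": s.presence,
                "keep_indices": list(s.keep_indices) if s.keep_indices else None,
            }
            for s in series
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
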