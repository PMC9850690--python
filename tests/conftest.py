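import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from unitfinder import chem, selection, simulate
from unitfinder.peaklist import PeakList
from unitfinder.selection import UnitCandidate

from helpers import make_element

PEG = UnitCandidate.from_formula("C2H4O")  # 44.0262 Da
PPG = UnitCandidate.from_formula("C3H6O")  # 58.0419 Da
CF2 = UnitCandidate.from_formula("CF2")  # 49.9968 Da


@pytest.fixture(scope="session")
def peg_unit() -> UnitCandidate:
    return PEG


@pytest.fixture(scope="session")
def chofx_table():
    """Restricted C/H/O/F/X element table: small but containing the three
    polymer repeat units used throughout the evaluation tests."""
    return [
        make_element("C", (4,), 0, 4),
        make_element("H", (1,), 0, 10),
        make_element("O", (2,), 0, 2),
        make_element("F", (1,), 0, 3),
        make_element("X", (1,), 1, 2),
    ]


@pytest.fixture(scope="session")
def chofx_candidates(chofx_table):
    table = chem.enumerate_table(chofx_table)
    table = selection.filter_table(table, selection.default_criteria())
    return selection.candidates_from_table(table)


@pytest.fixture()
def peg_ladder() -> PeakList:
    """Exact arithmetic C2H4O ladder: 100 + k*u, k = 0..4."""
    mz = 100.0 + np.arange(5) * PEG.exact_mass
    return PeakList(mz, np.full(5, 100.0))


def make_mixture(seed: int = 11, jitter_sd: float = 0.0003):
    """Synthetic stand-in for the swab/plasma evaluation mixture: sequential
    C2H4O and C3H6O ladders, a sparse CF2 pattern and noise."""
    series = [
        simulate.SeriesSpec(PEG, scaffold_mass=150.0, n_min=0, n_max=6,
                            jitter_sd=jitter_sd),
        simulate.SeriesSpec(PPG, scaffold_mass=201.0, n_min=0, n_max=6,
                            jitter_sd=jitter_sd),
        simulate.SeriesSpec(CF2, scaffold_mass=351.0, n_min=0, n_max=6,
                            jitter_sd=jitter_sd, presence="sparse",
                            keep_indices=(0, 1, 3, 6)),
    ]
    peaks = simulate.generate_spectrum(
        series, n_noise=40, mz_range=(60.0, 900.0), seed=seed
    )
    return peaks, series


@pytest.fixture()
def mixture_peaks():
    peaks, _ = make_mixture()
    return peaks
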