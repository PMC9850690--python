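"""Kendrick mass defect transformation for a chosen repeat unit.

Rescales accurate m/z values so members of a homologous series built on the
unit share a common mass defect: KM = mz * nominal(unit) / exact(unit) and
KMD = nominal(KM) - KM, with nominal mass taken as round-to-nearest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO

import numpy as np

from .peaklist import PeakList
from .selection import UnitCandidate

__all__ = ["KendrickTable", "kendrick_transform", "write_kendrick_table"]


@dataclass
class KendrickTable:
    """Per-peak Kendrick coordinates for one stated unit."""

    mz: np.ndarray
    kendrick_mass: np.ndarray
    kendrick_mass_defect: np.ndarray
    unit_formula: str
    unit_exact_mass: float
    unit_nominal_mass: int


def kendrick_transform(peaks: PeakList, unit: UnitCandidate) -> KendrickTable:
    """Transform a peak list into Kendrick coordinates for ``unit``."""
    exact = float(unit.exact_mass)
    if exact <= 0:
        raise ValueError("unit exact mass must be positive")
    nominal = int(np.rint(exact))
    if nominal <= 0:
        raise ValueError("unit nominal mass rounds to zero")
    km = peaks.mz * (nominal / exact)
    kmd = np.rint(km) - km
    return KendrickTable(
        mz=peaks.mz.copy(),
        kendrick_mass=km,
        kendrick_mass_defect=kmd,
        unit_formula=unit.formula_string,
        unit_exact_mass=exact,
        unit_nominal_mass=nominal,
    )


def write_kendrick_table(table: KendrickTable, dest: str | Path | IO[str]) -> None:
    """Export as CSV: mz, kendrick_mass, kendrick_mass_defect."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            write_kendrick_table(table, fh)
        return
    dest.write(
        f"# unit={table.unit_formula} exact_mass={table.unit_exact_mass:.7f} "
        f"nominal_mass={table.unit_nominal_mass}\n"
    )
    dest.write("mz,kendrick_mass,kendrick_mass_defect\n")
    for mz, km, kmd in zip(
        table.mz, table.kendrick_mass, table.kendrick_mass_defect
    ):
        dest.write(f"{mz:.6f},{km:.6f},{kmd:.6f}\n")
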