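"""Peak-list ingestion, export and the two data-reduction filters."""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO

import numpy as np

__all__ = [
    "PeakList",
    "PeakListError",
    "read_peaklist",
    "write_peaklist",
    "filter_top_n",
    "filter_intensity",
]

_SPLIT = re.compile(r"[,\t;]|\s+")


class PeakListError(ValueError):
    """Unparseable or invalid peak-list data."""


@dataclass
class PeakList:
    """m/z values (Da, strictly ascending) with parallel intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    metadata: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise PeakListError("mz and intensity must be 1-D")
        if len(self.mz) != len(self.intensity):
            raise PeakListError("mz and intensity lengths differ")
        if len(self.mz) and not np.all(np.diff(self.mz) > 0):
            raise PeakListError("mz must be strictly increasing")
        if np.any(self.intensity < 0):
            raise PeakListError("negative intensity")

    def __len__(self) -> int:
        return len(self.mz)

    @classmethod
    def from_unsorted(
        cls, mz, intensity, metadata: str = ""
    ) -> "PeakList":
        """Sort by m/z and merge exact-duplicate m/z rows by summing."""
        mz = np.asarray(mz, dtype=np.float64)
        intensity = np.asarray(intensity, dtype=np.float64)
        order = np.argsort(mz, kind="mergesort")
        mz, intensity = mz[order], intensity[order]
        if len(mz):
            uniq, inverse = np.unique(mz, return_inverse=True)
            summed = np.zeros(len(uniq))
            np.add.at(summed, inverse, intensity)
            mz, intensity = uniq, summed
        return cls(mz, intensity, metadata)


def _coerce_row(cells: list[str], lineno: int) -> tuple[float, float]:
    try:
        mz, inten = float(cells[0]), float(cells[1])
    except ValueError:
        raise PeakListError(f"non-numeric cell on line {lineno}") from None
    if inten < 0:
        raise PeakListError(f"negative intensity on line {lineno}")
    return mz, inten


def read_peaklist(source: str | Path | IO[str], metadata: str = "") -> PeakList:
    """Read a two-column (m/z, intensity) delimited text peak list.

    Comma, tab, semicolon and whitespace dialects are accepted; a single
    header row is auto-detected and skipped; duplicate m/z rows are merged by
    summing their intensities.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_peaklist(fh, metadata=metadata or str(source))
    mzs: list[float] = []
    intens: list[float] = []
    first_data_row = True
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cells = [c for c in _SPLIT.split(line) if c != ""]
        if len(cells) < 2:
            raise PeakListError(f"line {lineno}: expected two columns")
        if first_data_row:
            first_data_row = False
            try:
                float(cells[0]), float(cells[1])
            except ValueError:
                continue  # header row
        mz, inten = _coerce_row(cells[:2], lineno)
        mzs.append(mz)
        intens.append(inten)
    if not mzs:
        raise PeakListError("no parsable rows")
    return PeakList.from_unsorted(mzs, intens, metadata=metadata)


def write_peaklist(peaks: PeakList, dest: str | Path | IO[str], decimals: int = 6) -> None:
    """Write as CSV with a header row; m/z printed at ``decimals`` places."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            write_peaklist(peaks, fh, decimals=decimals)
        return
    dest.write("mz,intensity\n")
    for mz, inten in zip(peaks.mz, peaks.intensity):
        dest.write(f"{mz:.{decimals}f},{inten:g}\n")


def filter_top_n(peaks: PeakList, x: int) -> PeakList:
    """Keep the min(x, N) most intense peaks; ties go to the lower m/z."""
    if x < 1:
        raise ValueError("x must be >= 1")
    if x >= len(peaks):
        return PeakList(peaks.mz.copy(), peaks.intensity.copy(), peaks.metadata)
    order = np.lexsort((peaks.mz, -peaks.intensity))[:x]
    keep = np.sort(order)
    return PeakList(peaks.mz[keep], peaks.intensity[keep], peaks.metadata)


def filter_intensity(peaks: PeakList, i_percent: float) -> PeakList:
    """Keep peaks whose intensity, normalised to the base peak, is at least
    ``i_percent`` percent.  The base peak always survives."""
    if len(peaks) == 0:
        raise PeakListError("empty peak list")
    if not (0 < i_percent <= 100):
        raise ValueError("i_percent must be in (0, 100]")
    top = peaks.intensity.max()
    if top <= 0:
        raise PeakListError("all intensities are zero")
    keep = 100.0 * peaks.intensity / top >= i_percent
    return PeakList(peaks.mz[keep], peaks.intensity[keep], peaks.metadata)
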