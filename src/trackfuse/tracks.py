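"""Genomic signal-track containers and BED/bedGraph input/output.

Tracks are sequences of fixed-width genomic bins carrying a numeric value:
read depth for coverage tracks, a probability in [0, 1] for the
probability tracks produced by the cMBF transform and the integrator.
Coordinates follow the BED convention: 0-based, half-open intervals.
Chromosome order is the order of first appearance in the source; no
karyotype sorting is imposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicBin",
    "Track",
    "CoverageTrack",
    "ProbabilityTrack",
    "BackgroundTrack",
    "TrackParseError",
    "TrackValidationError",
    "read_coverage_bed",
    "read_probability_bed",
    "write_bed",
    "write_bedgraph",
    "rebin",
]

_COLUMNS = ["chrom", "start", "end", "value"]
_HEADER_PREFIXES = ("track", "browser", "#")


class TrackParseError(ValueError):
    """A BED line could not be parsed; the message names the line number."""


class TrackValidationError(ValueError):
    """A track violates a structural invariant (overlap, range, order)."""


@dataclass(frozen=True)
class GenomicBin:
    """One genomic interval with a value (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    value: float

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise TrackValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if not np.isfinite(self.value) or self.value < 0:
            raise TrackValidationError(
                f"invalid value {self.value!r} at {self.chrom}:{self.start}"
            )


@dataclass
class Track:
    """Sorted, non-overlapping fixed-width bins across one or more chromosomes.

    ``data`` holds columns (chrom, start, end, value); bins are ordered by
    chromosome first-appearance then start. ``bin_size`` is the modal bin
    width; the final bin of a chromosome may be shorter (coverage tools emit
    short tail bins at chromosome ends).
    """

    data: pd.DataFrame
    bin_size: int
    chrom_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        if not self.chrom_order:
            self.chrom_order = list(dict.fromkeys(self.data["chrom"]))
        self._validate()

    # -- invariants ---------------------------------------------------------

    def _validate(self) -> None:
        df = self.data
        if len(df) == 0:
            return
        values = df["value"].to_numpy()
        if not np.all(np.isfinite(values)):
            raise TrackValidationError("non-finite values in track")
        if (values < 0).any():
            raise TrackValidationError("negative values in track")
        if (df["start"].to_numpy() < 0).any():
            raise TrackValidationError("negative start coordinate")
        if (df["end"].to_numpy() <= df["start"].to_numpy()).any():
            raise TrackValidationError("bin with end <= start")
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if len(starts) > 1 and (starts[1:] < ends[:-1]).any():
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise TrackValidationError(
                    f"overlapping bins on {chrom} near position {starts[i + 1]}"
                )

    # -- accessors ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    def __iter__(self) -> Iterator[GenomicBin]:
        for row in self.data.itertuples(index=False):
            yield GenomicBin(row.chrom, int(row.start), int(row.end), float(row.value))

    @property
    def bins(self) -> list[GenomicBin]:
        return list(self)

    @property
    def values(self) -> np.ndarray:
        return self.data["value"].to_numpy(dtype=float)

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.data.loc[self.data["chrom"] == chrom, "value"].to_numpy(dtype=float)

    def with_values(self, values: np.ndarray, cls: type | None = None) -> "Track":
        """Return a track of class ``cls`` with the same bins but new values."""
        cls = cls or type(self)
        df = self.data.copy()
        df["value"] = np.asarray(values, dtype=float)
        return cls(df, self.bin_size, list(self.chrom_order))


class CoverageTrack(Track):
    """Track of non-negative read depths (the vector R = [r_i])."""


class ProbabilityTrack(Track):
    """Track whose values are probabilities of true signal, in [0, 1]."""

    def _validate(self) -> None:
        super()._validate()
        if len(self.data) and (self.data["value"].to_numpy() > 1.0).any():
            raise TrackValidationError(
                "probability track contains values > 1 "
                "(did you pass raw coverage instead of cMBF output?)"
            )


class BackgroundTrack(Track):
    """Per-bin background-noise estimates n_i; strictly positive by construction."""

    def _validate(self) -> None:
        super()._validate()
        if len(self.data) and (self.data["value"].to_numpy() <= 0).any():
            raise TrackValidationError("background estimates must be > 0")


# -- reading ---------------------------------------------------------------


def _parse_bed_lines(path: Path) -> pd.DataFrame:
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(_HEADER_PREFIXES):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise TrackParseError(
                    f"{path}:{lineno}: expected >= 4 fields, got {len(fields)}"
                )
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError:
                raise TrackParseError(
                    f"{path}:{lineno}: coordinates must be integers"
                ) from None
            try:
                value = float(fields[3])
            except ValueError:
                raise TrackParseError(
                    f"{path}:{lineno}: value field is not numeric"
                ) from None
            if start < 0:
                raise TrackParseError(f"{path}:{lineno}: negative start coordinate")
            if end <= start:
                raise TrackParseError(f"{path}:{lineno}: end must exceed start")
            if not np.isfinite(value) or value < 0:
                raise TrackParseError(f"{path}:{lineno}: value must be a finite non-negative number")
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            values.append(value)
    return pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": ends, "value": values}
    )


def _modal_width(df: pd.DataFrame) -> int:
    if len(df) == 0:
        return 1
    widths = (df["end"] - df["start"]).to_numpy()
    vals, counts = np.unique(widths, return_counts=True)
    return int(vals[np.argmax(counts)])


def _read_bed_as(path: str | Path, cls: type) -> Track:
    path = Path(path)
    df = _parse_bed_lines(path)
    chrom_order = list(dict.fromkeys(df["chrom"])) if len(df) else []
    # restore per-chromosome start order if the file was unsorted
    for chrom in chrom_order:
        sub = df.loc[df["chrom"] == chrom, "start"]
        if not sub.is_monotonic_increasing:
            logger.info("input %s: sorting bins on %s by start", path, chrom)
            order = np.concatenate(
                [df.index[df["chrom"] == c][np.argsort(df.loc[df["chrom"] == c, "start"], kind="stable")]
                 for c in chrom_order]
            )
            df = df.loc[order]
            break
    return cls(df.reset_index(drop=True), _modal_width(df))


def read_coverage_bed(path: str | Path) -> CoverageTrack:
    """Read a 4-column coverage BED file (chrom, start, end, depth).

    Lines beginning with ``track``, ``browser`` or ``#`` are skipped.
    Bins are re-sorted per chromosome if the file is unsorted (logged);
    overlapping bins raise :class:`TrackValidationError`. The bin size is
    inferred as the modal interval width.
    """
    return _read_bed_as(path, CoverageTrack)


def read_probability_bed(path: str | Path) -> ProbabilityTrack:
    """Read a 4-column BED of probabilities (e.g. a cMBF track)."""
    return _read_bed_as(path, ProbabilityTrack)


# -- writing ---------------------------------------------------------------


def write_bed(track: Track, path: str | Path, precision: int = 6) -> None:
    """Write a track as tab-delimited 4-column BED, values to ``precision`` decimals.

    Round-trips through :func:`read_coverage_bed` up to 10**-precision.
    """
    with open(path, "w") as fh:
        for row in track.data.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{row.value:.{precision}f}\n"
            )


def write_bedgraph(
    track: Track,
    path: str | Path,
    track_name: str = "trackfuse",
    merge: bool = True,
    precision: int = 6,
) -> None:
    """Write a bedGraph file with a standard track header.

    With ``merge`` on, runs of contiguous bins whose formatted values are
    equal collapse into single records (run-length merge), the form genome
    browsers expect for constant stretches.
    """
    with open(path, "w") as fh:
        fh.write(f"track type=bedGraph name={track_name}\n")
        prev = None  # [chrom, start, end, formatted value]
        for row in track.data.itertuples(index=False):
            fmt = f"{row.value:.{precision}f}"
            if (
                merge
                and prev is not None
                and prev[0] == row.chrom
                and prev[2] == row.start
                and prev[3] == fmt
            ):
                prev[2] = int(row.end)
                continue
            if prev is not None:
                fh.write(f"{prev[0]}\t{prev[1]}\t{prev[2]}\t{prev[3]}\n")
            prev = [row.chrom, int(row.start), int(row.end), fmt]
        if prev is not None:
            fh.write(f"{prev[0]}\t{prev[1]}\t{prev[2]}\t{prev[3]}\n")


# -- rebinning -------------------------------------------------------------


def rebin(track: CoverageTrack, new_bin_size: int) -> CoverageTrack:
    """Coarsen a track to a larger bin size by averaging constituent bins.

    ``new_bin_size`` must be a positive multiple of the current bin size.
    Each output bin's value is the mean of the input bins it covers; a
    partial trailing group keeps the mean of its available bins, so the
    genomic extent of every chromosome is preserved.
    """
    if new_bin_size <= 0 or new_bin_size % track.bin_size != 0:
        raise ValueError(
            f"new_bin_size {new_bin_size} is not a positive multiple of "
            f"bin_size {track.bin_size}"
        )
    factor = new_bin_size // track.bin_size
    if factor == 1:
        return CoverageTrack(track.data.copy(), track.bin_size, list(track.chrom_order))
    frames = []
    for chrom in track.chrom_order:
        sub = track.data[track.data["chrom"] == chrom].reset_index(drop=True)
        group = np.arange(len(sub)) // factor
        agg = sub.groupby(group).agg(
            start=("start", "first"), end=("end", "last"), value=("value", "mean")
        )
        agg.insert(0, "chrom", chrom)
        frames.append(agg)
    df = pd.concat(frames, ignore_index=True) if frames else track.data.iloc[0:0]
    return CoverageTrack(df, new_bin_size, list(track.chrom_order))
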