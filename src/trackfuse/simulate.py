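"""Synthetic coverage tracks with known signal and background structure.

The generator emulates the regime the windowed-median background estimator
is built for: a genome-wide background depth (constant, or Poisson read
counts) with sparse rectangular enrichment regions ("peaks") added on top.
Sparsity is enforced — total peak width must stay under half the
chromosome — because the median only reflects background when true signal
is a minority of every window. Tracks are deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import CoverageTrack

__all__ = ["SyntheticTrackSpec", "generate_track", "generate_replicates"]

NOISE_MODELS = ("constant", "poisson")


@dataclass(frozen=True)
class SyntheticTrackSpec:
    """Recipe for one synthetic chromosome of binned coverage.

    peaks are (start_bp, width_bp, height) triples; a bin belongs to a peak
    when its start coordinate falls inside [start_bp, start_bp + width_bp).
    """

    chrom_length_bp: int
    bin_size: int = 10
    background_rate: float = 5.0
    noise_model: str = "constant"
    peaks: tuple = ()
    seed: int = 0
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.chrom_length_bp <= 0 or self.bin_size <= 0:
            raise ValueError("chrom_length_bp and bin_size must be positive")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {NOISE_MODELS}")
        total_width = 0
        prev_end = None
        for start, width, height in sorted(self.peaks):
            if width <= 0 or height < 0:
                raise ValueError("peak widths must be > 0 and heights >= 0")
            if start < 0 or start + width > self.chrom_length_bp:
                raise ValueError(
                    f"peak ({start}, {width}) extends outside the chromosome"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(f"overlapping peaks at {start}")
            prev_end = start + width
            total_width += width
        if total_width >= 0.5 * self.chrom_length_bp:
            raise ValueError(
                "total peak width must stay below 50% of the chromosome: the "
                "windowed-median background estimate assumes sparse signal"
            )


def _bin_grid(spec: SyntheticTrackSpec) -> tuple[np.ndarray, np.ndarray]:
    starts = np.arange(0, spec.chrom_length_bp, spec.bin_size, dtype=np.int64)
    ends = np.minimum(starts + spec.bin_size, spec.chrom_length_bp)
    return starts, ends


def _peak_height_per_bin(spec: SyntheticTrackSpec, starts: np.ndarray) -> np.ndarray:
    height = np.zeros(len(starts), dtype=float)
    for p_start, p_width, p_height in spec.peaks:
        height[(starts >= p_start) & (starts < p_start + p_width)] += p_height
    return height


def generate_track(spec: SyntheticTrackSpec) -> CoverageTrack:
    """Materialize one synthetic coverage track from its spec.

    Constant noise yields exactly ``background_rate`` outside peaks and
    ``background_rate + height`` inside; the Poisson model draws each bin's
    background depth from Poisson(background_rate) and adds the peak height.
    Deterministic for a fixed ``spec.seed``.
    """
    starts, ends = _bin_grid(spec)
    height = _peak_height_per_bin(spec, starts)
    if spec.noise_model == "constant":
        values = np.full(len(starts), spec.background_rate, dtype=float) + height
    else:
        rng = np.random.default_rng(spec.seed)
        values = rng.poisson(spec.background_rate, size=len(starts)).astype(float) + height
    df = pd.DataFrame(
        {"chrom": spec.chrom, "start": starts, "end": ends, "value": values}
    )
    return CoverageTrack(df, spec.bin_size, [spec.chrom])


def generate_replicates(
    spec: SyntheticTrackSpec, n_reps: int, seeds: list[int]
) -> list[CoverageTrack]:
    """Replicate tracks: shared peak structure, independent noise per seed.

    Emulates multiple replicates of the same experiment — the true signal
    (peak locations and heights) is common, the background draws are not.
    Duplicate seeds trigger a warning since they defeat independence.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if len(seeds) != n_reps:
        raise ValueError(f"need exactly {n_reps} seeds, got {len(seeds)}")
    if len(set(seeds)) != len(seeds):
        warnings.warn("duplicate seeds: replicates will share noise draws", stacklevel=2)
    return [
        generate_track(
            SyntheticTrackSpec(
                chrom_length_bp=spec.chrom_length_bp,
                bin_size=spec.bin_size,
                background_rate=spec.background_rate,
                noise_model=spec.noise_model,
                peaks=spec.peaks,
                seed=s,
                chrom=spec.chrom,
            )
        )
        for s in seeds
    ]
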