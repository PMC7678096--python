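"""Integration of probability tracks by per-position joint probability.

Treating each input track's value p_k,i as an independent probability of
true signal at position i, the integrated value is the joint probability
P_i = prod_k p_k,i. Multiplication is commutative and associative, so
multi-track integration reduces to sequential pairwise products and the
result does not depend on input order. The product shrinks mid-range
background probabilities much faster than near-1 peak probabilities, which
is what sharpens signal relative to noise across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import CoverageTrack, ProbabilityTrack
from .background import CalculatorConfig
from .cmbf import calculate_track

__all__ = [
    "MISSING_POLICIES",
    "AlignmentError",
    "IntegrationPlan",
    "integrate_pair",
    "integrate_many",
    "integrate_coverage",
]

MISSING_POLICIES = ("error", "treat-as-zero", "intersect")


class AlignmentError(ValueError):
    """Input tracks are not on a compatible bin grid."""


@dataclass
class IntegrationPlan:
    """An ordered list of probability tracks and a policy for ragged bins."""

    inputs: list[ProbabilityTrack]
    missing_policy: str = "error"

    def __post_init__(self) -> None:
        if len(self.inputs) < 2:
            raise ValueError("integration requires at least 2 input tracks")
        if self.missing_policy not in MISSING_POLICIES:
            raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")

    def run(self) -> ProbabilityTrack:
        return integrate_many(self.inputs, self.missing_policy)


def _check_grid(a: ProbabilityTrack, b: ProbabilityTrack) -> None:
    if len(a) == 0 or len(b) == 0:
        return
    if a.bin_size != b.bin_size:
        raise AlignmentError(
            f"bin sizes differ ({a.bin_size} vs {b.bin_size}); rebin the "
            "coarser-compatible track before integrating"
        )
    offs_a = set(np.unique(a.data["start"].to_numpy() % a.bin_size))
    offs_b = set(np.unique(b.data["start"].to_numpy() % b.bin_size))
    if offs_a != offs_b:
        raise AlignmentError(
            "bin boundaries are shifted between tracks (same bin size, "
            "different start offsets); rebin onto a common grid"
        )


def integrate_pair(
    a: ProbabilityTrack, b: ProbabilityTrack, missing_policy: str = "error"
) -> ProbabilityTrack:
    """Joint probability of two aligned probability tracks: P_i = p_a,i * p_b,i.

    Bins are matched on identical (chrom, start, end). Bins present in only
    one track are handled by ``missing_policy``: ``error`` aborts naming the
    first offending bin, ``treat-as-zero`` emits P_i = 0 there, and
    ``intersect`` drops them. Misaligned grids (same region, different bin
    boundaries) raise :class:`AlignmentError`.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")
    _check_grid(a, b)
    merged = a.data.merge(
        b.data, on=["chrom", "start", "end"], how="outer", indicator=True,
        suffixes=("_a", "_b"),
    )
    unmatched = merged["_merge"] != "both"
    if unmatched.any():
        if missing_policy == "error":
            row = merged.loc[unmatched].iloc[0]
            raise AlignmentError(
                f"bin {row.chrom}:{int(row.start)}-{int(row.end)} is present "
                "in only one track (missing_policy='error'); use "
                "'treat-as-zero' or 'intersect' for ragged inputs"
            )
        if missing_policy == "intersect":
            merged = merged[~unmatched]
    prod = merged["value_a"].fillna(0.0).to_numpy() * merged["value_b"].fillna(0.0).to_numpy()
    if missing_policy == "treat-as-zero":
        prod[merged["_merge"].to_numpy() != "both"] = 0.0
    out = merged[["chrom", "start", "end"]].copy()
    out["value"] = prod
    chrom_order = list(dict.fromkeys([*a.chrom_order, *b.chrom_order]))
    out["__c"] = pd.Categorical(out["chrom"], categories=chrom_order, ordered=True)
    out = out.sort_values(["__c", "start"], kind="stable").drop(columns="__c")
    bin_size = a.bin_size if len(a) else b.bin_size
    return ProbabilityTrack(out.reset_index(drop=True), bin_size, chrom_order)


def integrate_many(
    tracks: list[ProbabilityTrack], missing_policy: str = "error"
) -> ProbabilityTrack:
    """Fold :func:`integrate_pair` over two or more tracks.

    Because per-bin multiplication is commutative and associative, the
    result is independent of input order (up to the last ulp for chains of
    three or more floating-point products).
    """
    if len(tracks) < 2:
        raise ValueError("integrate_many requires at least 2 tracks")
    acc = tracks[0]
    for t in tracks[1:]:
        acc = integrate_pair(acc, t, missing_policy)
    return acc


def integrate_coverage(
    tracks: list[CoverageTrack],
    config: CalculatorConfig | None = None,
    missing_policy: str = "error",
) -> ProbabilityTrack:
    """Full pipeline convenience: cMBF-transform each coverage track, then integrate."""
    if len(tracks) < 2:
        raise ValueError("integrate_coverage requires at least 2 tracks")
    sizes = {t.bin_size for t in tracks if len(t)}
    if len(sizes) > 1:
        raise ValueError(
            f"coverage tracks have mixed bin sizes {sorted(sizes)}; rebin "
            "to a common size first"
        )
    probs = [calculate_track(t, config).probability_track for t in tracks]
    return integrate_many(probs, missing_policy)
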