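"""Differential RNA-structure screen between two groups of replicates.

Given normalized DMS reactivity profiles for biological replicates of two
strains, the screen computes per-nucleotide dissimilarity scores — the
mean absolute reactivity difference over replicate pairs drawn within a
strain (d_within) and across strains (d_between) — and their difference
Δd = d_between − d_within.  Contiguous runs of nucleotides where
between-strain variation exceeds within-strain variation (Δd > 0) become
candidate regions; each is tested with a one-sided Wilcoxon signed-rank
test pairing d_between with d_within, p-values are Benjamini–Hochberg
adjusted within the comparison, and a region is called significant when
it is at least 5 nt long with p < 0.05, q < 0.1 and mean Δd > 0.01.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .reactivity import MASK_OK, ReactivityProfile

__all__ = [
    "GroupedProfiles",
    "DissimilarityTracks",
    "RegionCall",
    "dissimilarity_tracks",
    "candidate_regions",
    "test_region",
    "adjust_fdr",
    "call_significant",
    "run_screen",
    "regions_to_frame",
    "regions_to_bed",
]

MIN_REGION_LEN = 5
P_THRESHOLD = 0.05
Q_THRESHOLD = 0.1
DELTA_D_THRESHOLD = 0.01


@dataclass
class GroupedProfiles:
    """Replicate reactivity profiles for two (or more) groups.

    All profiles must share the transcript and position set; the
    per-position mask used by the screen is the intersection of the
    replicate masks (a position must be usable in every replicate).
    """

    groups: dict[str, list[ReactivityProfile]]

    def __post_init__(self) -> None:
        profiles = [p for reps in self.groups.values() for p in reps]
        if not profiles:
            raise ValueError("no profiles supplied")
        ref = profiles[0]
        for p in profiles[1:]:
            if p.transcript_id != ref.transcript_id:
                raise ValueError("profiles span multiple transcripts")
            if not np.array_equal(p.positions, ref.positions):
                raise ValueError("profiles have differing position sets")

    @property
    def transcript_id(self) -> str:
        return next(iter(self.groups.values()))[0].transcript_id

    @property
    def positions(self) -> np.ndarray:
        return next(iter(self.groups.values()))[0].positions

    def common_ok(self) -> np.ndarray:
        """Positions unmasked (and finite) in every replicate of every group."""
        ok = None
        for reps in self.groups.values():
            for p in reps:
                values = p.normalized if p.normalized is not None else p.raw
                this = (p.mask == MASK_OK) & np.isfinite(values)
                ok = this if ok is None else (ok & this)
        return ok

    def value_matrix(self, group: str) -> np.ndarray:
        """(n_replicates, n_positions) matrix of normalized reactivities."""
        reps = self.groups[group]
        return np.vstack(
            [p.normalized if p.normalized is not None else p.raw for p in reps]
        )


@dataclass
class DissimilarityTracks:
    """Per-nucleotide within/between dissimilarities on unmasked positions."""

    transcript_id: str
    positions: np.ndarray  # all transcript positions
    ok: np.ndarray  # boolean: positions where tracks are defined
    d_within: np.ndarray  # NaN where not ok
    d_between: np.ndarray

    @property
    def delta_d(self) -> np.ndarray:
        return self.d_between - self.d_within


@dataclass
class RegionCall:
    """A candidate or tested differential region (1-based inclusive)."""

    transcript_id: str
    start: int
    end: int
    mean_delta_d: float
    p_value: float = np.nan
    q_value: float = np.nan
    significant: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def dissimilarity_tracks(grouped: GroupedProfiles) -> DissimilarityTracks:
    """Mean absolute pairwise reactivity differences, within and between groups."""
    names = list(grouped.groups)
    if len(names) != 2:
        raise ValueError(f"screen requires exactly 2 groups, got {len(names)}")
    for name in names:
        if len(grouped.groups[name]) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 replicates")

    ok = grouped.common_ok()
    if not ok.any():
        raise ValueError("no common unmasked positions across replicates")
    a = grouped.value_matrix(names[0])
    b = grouped.value_matrix(names[1])

    within_pairs = [
        np.abs(m[i] - m[j])
        for m in (a, b)
        for i, j in itertools.combinations(range(m.shape[0]), 2)
    ]
    between_pairs = [
        np.abs(a[i] - b[j])
        for i in range(a.shape[0])
        for j in range(b.shape[0])
    ]
    d_within = np.mean(within_pairs, axis=0)
    d_between = np.mean(between_pairs, axis=0)
    d_within[~ok] = np.nan
    d_between[~ok] = np.nan
    return DissimilarityTracks(
        transcript_id=grouped.transcript_id,
        positions=grouped.positions,
        ok=ok,
        d_within=d_within,
        d_between=d_between,
    )


def candidate_regions(
    tracks: DissimilarityTracks, min_len: int = MIN_REGION_LEN
) -> list[RegionCall]:
    """Maximal runs of consecutive unmasked nucleotides with Δd > 0.

    Runs are split at masked gaps and at gaps in the position coordinate;
    only runs of at least ``min_len`` nucleotides are kept.
    """
    dd = tracks.delta_d
    eligible = tracks.ok & np.isfinite(dd) & (dd > 0)
    regions: list[RegionCall] = []
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        return regions
    pos = tracks.positions
    # break runs where array indices or transcript positions are non-consecutive
    breaks = np.flatnonzero((np.diff(idx) != 1) | (np.diff(pos[idx]) != 1)) + 1
    for run in np.split(idx, breaks):
        if run.size >= min_len:
            regions.append(
                RegionCall(
                    transcript_id=tracks.transcript_id,
                    start=int(pos[run[0]]),
                    end=int(pos[run[-1]]),
                    mean_delta_d=float(np.mean(dd[run])),
                )
            )
    return regions


def test_region(region: RegionCall, tracks: DissimilarityTracks) -> float:
    """One-sided Wilcoxon signed-rank p for d_between > d_within in a region.

    Zero paired differences are dropped (Wilcoxon convention).  The exact
    null distribution is used for up to 25 informative pairs; beyond that
    a normal approximation with continuity correction.
    """
    sel = (
        (tracks.positions >= region.start)
        & (tracks.positions <= region.end)
        & tracks.ok
    )
    diffs = tracks.d_between[sel] - tracks.d_within[sel]
    diffs = diffs[np.isfinite(diffs) & (diffs != 0)]
    n = diffs.size
    if n == 0:
        return 1.0
    has_ties = np.unique(np.abs(diffs)).size < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        diffs, alternative="greater", method=method, correction=True
    )
    return float(res.pvalue)


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_significant(regions: list[RegionCall]) -> list[RegionCall]:
    """Flag regions meeting all published thresholds; sort by coordinates."""
    for r in regions:
        r.significant = bool(
            r.length >= MIN_REGION_LEN
            and r.p_value < P_THRESHOLD
            and r.q_value < Q_THRESHOLD
            and r.mean_delta_d > DELTA_D_THRESHOLD
        )
    return sorted(regions, key=lambda r: (r.transcript_id, r.start))


def run_screen(
    grouped: GroupedProfiles, min_len: int = MIN_REGION_LEN
) -> tuple[list[RegionCall], DissimilarityTracks]:
    """Full screen for one two-group comparison of one transcript.

    FDR adjustment is applied across the candidate regions of this
    comparison only (each pairwise comparison of conditions is adjusted
    separately).
    """
    tracks = dissimilarity_tracks(grouped)
    regions = candidate_regions(tracks, min_len=min_len)
    if regions:
        p = np.array([test_region(r, tracks) for r in regions])
        q = adjust_fdr(p)
        for r, pi, qi in zip(regions, p, q):
            r.p_value = float(pi)
            r.q_value = float(qi)
    return call_significant(regions), tracks


def regions_to_frame(regions: list[RegionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript": [r.transcript_id for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "length": [r.length for r in regions],
            "mean_dd": [round(r.mean_delta_d, 6) for r in regions],
            "p": [round(r.p_value, 6) for r in regions],
            "q": [round(r.q_value, 6) for r in regions],
            "significant": [r.significant for r in regions],
        }
    )


def regions_to_bed(regions: list[RegionCall]) -> pd.DataFrame:
    """BED6 rows (0-based half-open) for the called regions."""
    return pd.DataFrame(
        {
            "chrom": [r.transcript_id for r in regions],
            "start": [r.start - 1 for r in regions],
            "end": [r.end for r in regions],
            "name": [f"region_{i + 1}" for i in range(len(regions))],
            "score": [round(1000 * min(1.0, r.mean_delta_d * 10)) for r in regions],
            "strand": ["+"] * len(regions),
        }
    )
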