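"""Per-nucleotide DMS reactivity from mutational-profiling count tables.

DMS methylates unpaired adenosines and cytosines in vivo; a processive
reverse transcriptase converts each methylation into a mutation in the
cDNA, so the per-nucleotide mutation rate in a DMS-treated sample, after
background correction against an untreated control, measures base
accessibility.  This module turns paired treated/untreated count tables
into background-corrected reactivities

    r_k = max( ((X+_k/C+_k - X-_k/C-_k) / (1 - X-_k/C-_k)), 0 )

where ``X`` is the mutation count and ``C`` the coverage at nucleotide
``k``, and scales them with the standard 2-8% normalization: guanines and
uracils (which DMS does not probe at the Watson-Crick face) are masked,
the top 2% of the remaining reactivities are excluded as outliers, and
the profile is divided by the mean of the next 8%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MapCountTable",
    "ReactivityProfile",
    "MASK_OK",
    "MASK_GU",
    "MASK_LOW_COVERAGE",
    "MASK_INVALID",
    "compute_raw_reactivity",
    "normalize_2_8",
    "read_count_table",
    "write_count_table",
    "write_profile",
    "read_profile",
]

# mask codes
MASK_OK = "ok"
MASK_GU = "GU_masked"
MASK_LOW_COVERAGE = "low_coverage"
MASK_INVALID = "invalid"

DEFAULT_MIN_COVERAGE = 1000

_GU = frozenset("GUT")


@dataclass
class MapCountTable:
    """Mutation counts and coverages for one sample of one transcript.

    ``channel`` is "+" for the DMS-treated sample and "-" for the
    untreated control.  Positions are 1-based and strictly increasing.
    """

    transcript_id: str
    sequence: str
    positions: np.ndarray
    mut_count: np.ndarray
    coverage: np.ndarray
    channel: str
    replicate_id: str = "rep1"
    group_id: str = "group1"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.mut_count = np.asarray(self.mut_count, dtype=np.int64)
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        n = len(self.sequence)
        if not (len(self.positions) == len(self.mut_count) == len(self.coverage) == n):
            raise ValueError(
                f"length mismatch: sequence {n}, positions {len(self.positions)}, "
                f"counts {len(self.mut_count)}, coverage {len(self.coverage)}"
            )
        if n and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.mut_count < 0) or np.any(self.coverage < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(self.mut_count > self.coverage):
            bad = int(self.positions[np.argmax(self.mut_count > self.coverage)])
            raise ValueError(f"mutation count exceeds coverage at position {bad}")
        if self.channel not in ("+", "-"):
            raise ValueError(f"channel must be '+' or '-', got {self.channel!r}")
        self.sequence = self.sequence.upper()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MapCountTable):
            return NotImplemented
        return (
            self.transcript_id == other.transcript_id
            and self.sequence == other.sequence
            and self.channel == other.channel
            and self.replicate_id == other.replicate_id
            and self.group_id == other.group_id
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.mut_count, other.mut_count)
            and np.array_equal(self.coverage, other.coverage)
        )


@dataclass
class ReactivityProfile:
    """Raw and normalized reactivities with per-position mask flags."""

    transcript_id: str
    sequence: str
    positions: np.ndarray
    raw: np.ndarray
    mask: np.ndarray  # array of mask-code strings
    normalized: np.ndarray | None = None
    replicate_id: str = "rep1"
    group_id: str = "group1"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.raw = np.asarray(self.raw, dtype=float)
        self.mask = np.asarray(self.mask, dtype=object)
        if self.normalized is not None:
            self.normalized = np.asarray(self.normalized, dtype=float)

    @property
    def ok(self) -> np.ndarray:
        """Boolean array: positions usable for normalization/comparison."""
        return self.mask == MASK_OK


def compute_raw_reactivity(
    treated: MapCountTable,
    untreated: MapCountTable,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> ReactivityProfile:
    """Background-corrected raw reactivity per nucleotide.

    Positions where either channel has coverage below ``min_coverage``
    (or zero) are flagged ``low_coverage`` and carry NaN; G/U(T)
    positions are flagged ``GU_masked``; positions where the untreated
    mutation rate is 1 are flagged ``invalid``.  Negative background-
    corrected rates are clamped to zero.
    """
    if treated.channel != "+" or untreated.channel != "-":
        raise ValueError("expected a treated '+' and an untreated '-' table")
    if treated.transcript_id != untreated.transcript_id:
        raise ValueError("transcript mismatch between channels")
    if not np.array_equal(treated.positions, untreated.positions):
        raise ValueError("position sets differ between channels")
    if treated.sequence != untreated.sequence:
        raise ValueError("sequences differ between channels")

    n = len(treated.sequence)
    raw = np.full(n, np.nan)
    mask = np.array([MASK_OK] * n, dtype=object)

    is_gu = np.fromiter((b in _GU for b in treated.sequence), dtype=bool, count=n)
    mask[is_gu] = MASK_GU

    low = (treated.coverage < max(min_coverage, 1)) | (
        untreated.coverage < max(min_coverage, 1)
    )
    mask[low & ~is_gu] = MASK_LOW_COVERAGE

    evaluable = ~low
    with np.errstate(divide="ignore", invalid="ignore"):
        rp = np.where(evaluable, treated.mut_count / np.maximum(treated.coverage, 1), np.nan)
        rm = np.where(evaluable, untreated.mut_count / np.maximum(untreated.coverage, 1), np.nan)
        denom = 1.0 - rm
        r = np.maximum((rp - rm) / denom, 0.0)

    saturated = evaluable & (rm >= 1.0)
    mask[saturated & ~is_gu] = MASK_INVALID
    r[saturated] = np.nan
    # reactivity is evaluated everywhere it is defined, including G/U
    # positions (masking applies downstream, at normalization)
    raw[evaluable & ~saturated] = r[evaluable & ~saturated]

    return ReactivityProfile(
        transcript_id=treated.transcript_id,
        sequence=treated.sequence,
        positions=treated.positions.copy(),
        raw=raw,
        mask=mask,
        replicate_id=treated.replicate_id,
        group_id=treated.group_id,
    )


def two_eight_normalizer(values: np.ndarray) -> float:
    """The 2-8% normalization factor of a vector of reactivities.

    Sort descending; exclude the top ``ceil(0.02 n)`` values as
    outliers; return the mean of the next ``ceil(0.08 n)`` values.
    Ties are broken by position order (stable sort).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = v.size
    if n < 10:
        raise ValueError(f"need at least 10 unmasked values to normalize, got {n}")
    order = np.argsort(-v, kind="stable")
    n_excl = math.ceil(0.02 * n)
    n_norm = math.ceil(0.08 * n)
    window = v[order[n_excl : n_excl + n_norm]]
    norm = float(window.mean())
    if norm <= 0:
        raise ValueError(
            f"non-positive 2-8% normalizer ({norm}); profile has no dynamic range"
        )
    return norm


def normalize_2_8(profile: ReactivityProfile) -> ReactivityProfile:
    """Scale a raw profile by its 2-8% normalizer.

    Only unmasked (``ok``) positions enter the normalizer and receive a
    normalized value; masked positions carry NaN.
    """
    ok = profile.ok & np.isfinite(profile.raw)
    norm = two_eight_normalizer(profile.raw[ok])
    normalized = np.full(profile.raw.shape, np.nan)
    normalized[ok] = profile.raw[ok] / norm
    return replace(profile, normalized=normalized)


# ---------------------------------------------------------------------------
# I/O: tab-delimited count tables and SHAPE-style .map profiles

_COUNT_COLUMNS = ["transcript", "pos", "base", "mut_count", "coverage"]


def write_count_table(table: MapCountTable, path) -> None:
    df = pd.DataFrame(
        {
            "transcript": table.transcript_id,
            "pos": table.positions,
            "base": list(table.sequence),
            "mut_count": table.mut_count,
            "coverage": table.coverage,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_count_table(
    path, channel: str = "+", replicate_id: str = "rep1", group_id: str = "group1"
) -> MapCountTable:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty count table") from None
    missing = [c for c in _COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: count table has no rows")
    bad = df.index[df["mut_count"] > df["coverage"]]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ValueError(f"{path}: mut_count > coverage at line {int(bad[0]) + 2}")
    transcripts = df["transcript"].unique()
    if len(transcripts) != 1:
        raise ValueError(f"{path}: expected one transcript, found {list(transcripts)}")
    return MapCountTable(
        transcript_id=str(transcripts[0]),
        sequence="".join(df["base"].astype(str)),
        positions=df["pos"].to_numpy(),
        mut_count=df["mut_count"].to_numpy(),
        coverage=df["coverage"].to_numpy(),
        channel=channel,
        replicate_id=replicate_id,
        group_id=group_id,
    )


def write_profile(profile: ReactivityProfile, path) -> None:
    """Write a normalized profile in 4-column SHAPE/.map layout.

    Columns: position, normalized reactivity (-999 where masked), a
    stderr placeholder of 0, and base.
    """
    values = profile.normalized if profile.normalized is not None else profile.raw
    out = np.where(np.isfinite(values), values, -999.0)
    df = pd.DataFrame(
        {
            "pos": profile.positions,
            "reactivity": np.round(out, 6),
            "stderr": 0.0,
            "base": list(profile.sequence),
        }
    )
    df.to_csv(path, sep="\t", index=False, header=False)


def read_profile(
    path, transcript_id: str = "", replicate_id: str = "rep1", group_id: str = "group1"
) -> ReactivityProfile:
    df = pd.read_csv(path, sep="\t", header=None, names=["pos", "reactivity", "stderr", "base"])
    if len(df) == 0:
        raise ValueError(f"{path}: empty profile")
    values = df["reactivity"].to_numpy(dtype=float)
    masked = values <= -998.0
    values = np.where(masked, np.nan, values)
    seq = "".join(df["base"].astype(str))
    mask = np.array(
        [
            MASK_GU if b in _GU else (MASK_INVALID if m else MASK_OK)
            for b, m in zip(seq, masked)
        ],
        dtype=object,
    )
    return ReactivityProfile(
        transcript_id=transcript_id or str(path),
        sequence=seq,
        positions=df["pos"].to_numpy(),
        raw=values,
        mask=mask,
        normalized=values,
        replicate_id=replicate_id,
        group_id=group_id,
    )
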