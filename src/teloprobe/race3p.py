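"""3' RACE read classification: templated end position and poly(A) tail.

Yeast telomerase RNA (TLC1) exists as a minor long polyadenylated
precursor and an abundant ~1157-nt mature form lacking a tail.  3' RACE
reads, trimmed of adapters and ligated linker, consist of a templated
stretch matching the reference followed by zero or more non-templated
adenosines.  Each read is assigned the 1-based reference position of its
last templated nucleotide and a tail-length bin (0, 1, 2-5, 6-10, >10
adenosines); templated/tail ambiguity — a trailing A that also matches
the reference — is resolved greedily in favor of templated, the standard
3' RACE convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TailCall",
    "EndDistribution",
    "Reference3p",
    "tail_bin",
    "end_bin",
    "classify_read",
    "classify_reads",
    "tabulate_ends",
    "long_to_mature_ratio",
    "TAIL_BINS",
    "END_BINS",
    "MATURE_END",
    "DEFAULT_MIN_ANCHOR",
]

TAIL_BINS = ["0", "1", "2-5", "6-10", ">10"]
END_BINS = ["1154", "1155", "1156", "1157", "1158", ">=1159", "other"]
MATURE_END = 1157
DEFAULT_MIN_ANCHOR = 15


@dataclass(frozen=True)
class TailCall:
    """One read's templated 3' end and non-templated poly(A) tail."""

    read_id: str
    end_position: int  # 1-based position of last templated nucleotide
    tail_length: int

    @property
    def tail_bin(self) -> str:
        return tail_bin(self.tail_length)

    @property
    def end_bin(self) -> str:
        return end_bin(self.end_position)


@dataclass(frozen=True)
class Reference3p:
    """A reference sequence with a coordinate offset.

    ``offset`` is the 1-based transcript position of ``sequence[0]``, so
    a reference may cover just the 3' region of interest.
    """

    transcript_id: str
    sequence: str
    offset: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper().replace("U", "T"))

    def position_of_index(self, i: int) -> int:
        return self.offset + i

    @property
    def last_position(self) -> int:
        return self.offset + len(self.sequence) - 1


def tail_bin(tail_length: int) -> str:
    if tail_length < 0:
        raise ValueError("tail length must be nonnegative")
    if tail_length == 0:
        return "0"
    if tail_length == 1:
        return "1"
    if tail_length <= 5:
        return "2-5"
    if tail_length <= 10:
        return "6-10"
    return ">10"


def end_bin(end_position: int) -> str:
    if end_position < 1154:
        return "other"
    if end_position >= 1159:
        return ">=1159"
    return str(end_position)


def classify_read(
    read: str,
    reference: Reference3p,
    linker: str | None = None,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    max_mismatches: int = 0,
    read_id: str = "read",
) -> TailCall | None:
    """Classify one sense-strand read; ``None`` if unclassifiable.

    The linker, if given, is stripped from the read 3' end by exact
    suffix match.  The templated stretch is the longest read prefix
    matching the reference, allowing up to ``max_mismatches`` scattered
    mismatches; the stretch always ends on a matching base, so the end
    call itself is exact.  Remaining trailing residues must all be A to
    count as a poly(A) tail.
    """
    read = read.upper().replace("U", "T")
    if linker:
        linker = linker.upper().replace("U", "T")
        if read.endswith(linker):
            read = read[: -len(linker)]
    ref = reference.sequence
    n = min(len(read), len(ref))
    if n == 0:
        return None

    # greedy extension of the templated prefix
    mismatches = 0
    last_match = -1  # index into read of last matching position
    for i in range(n):
        if read[i] == ref[i]:
            last_match = i
        else:
            mismatches += 1
            if mismatches > max_mismatches:
                break
    templated_len = last_match + 1
    if templated_len < min_anchor:
        return None
    tail = read[templated_len:]
    if tail and set(tail) != {"A"}:
        return None
    return TailCall(
        read_id=read_id,
        end_position=reference.position_of_index(templated_len - 1),
        tail_length=len(tail),
    )


def classify_reads(
    reads,
    reference: Reference3p,
    linker: str | None = None,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    max_mismatches: int = 0,
) -> tuple[list[TailCall], int]:
    """Classify (read_id, sequence) pairs; returns calls and the unclassified count."""
    calls: list[TailCall] = []
    unclassified = 0
    for read_id, seq in reads:
        call = classify_read(
            seq,
            reference,
            linker=linker,
            min_anchor=min_anchor,
            max_mismatches=max_mismatches,
            read_id=read_id,
        )
        if call is None:
            unclassified += 1
        else:
            calls.append(call)
    return calls, unclassified


@dataclass
class EndDistribution:
    """Read counts cross-tabulated by 3' end bin and poly(A) tail bin."""

    counts: pd.DataFrame  # index END_BINS, columns TAIL_BINS
    total_reads: int

    @property
    def fractions(self) -> pd.DataFrame:
        if self.total_reads == 0:
            return self.counts.astype(float)
        return self.counts / self.total_reads


def tabulate_ends(calls: list[TailCall]) -> EndDistribution:
    """Count matrix over (end bin x tail bin); ends <1154 pool into 'other'."""
    counts = pd.DataFrame(0, index=pd.Index(END_BINS, name="end"), columns=pd.Index(TAIL_BINS, name="tail"))
    for call in calls:
        counts.loc[call.end_bin, call.tail_bin] += 1
    return EndDistribution(counts=counts, total_reads=len(calls))


def long_to_mature_ratio(
    dist_or_calls, mature_end: int = MATURE_END
) -> float:
    """Ratio of precursor-like to mature reads.

    A read counts as precursor when it carries any poly(A) tail or ends
    3' of the mature end; mature reads end at or before ``mature_end``
    with no tail.  Returns NaN (reported, not raised) when no mature
    reads exist.
    """
    if isinstance(dist_or_calls, EndDistribution):
        raise TypeError(
            "long_to_mature_ratio needs per-read calls (end pooling in the "
            "distribution loses the precursor/mature split)"
        )
    calls: list[TailCall] = list(dist_or_calls)
    precursor = sum(1 for c in calls if c.tail_length > 0 or c.end_position > mature_end)
    mature = sum(1 for c in calls if c.end_position <= mature_end and c.tail_length == 0)
    if mature == 0:
        return float("nan")
    return precursor / mature


def calls_to_frame(calls: list[TailCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [c.read_id for c in calls],
            "end_position": [c.end_position for c in calls],
            "tail_length": [c.tail_length for c in calls],
            "end_bin": [c.end_bin for c in calls],
            "tail_bin": [c.tail_bin for c in calls],
        }
    )
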