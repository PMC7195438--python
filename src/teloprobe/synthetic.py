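"""Ground-truth-labeled synthetic inputs for every pipeline stage.

Three generators emulate the three data modalities the pipeline consumes:

* mutational-profiling count tables — per-nucleotide binomial mutation
  counts at structure-dependent rates, with Poisson coverage, replicate-
  level rate dispersion and optional strain-specific regions where the
  pairing state flips;
* three-channel 3D fluorescence stacks — Gaussian-PSF spots planted in
  nucleolar / nucleoplasmic / cytoplasmic compartments of ellipsoidal
  cells over Poisson background;
* 3' RACE reads — reference prefixes ending at defined transcript
  positions followed by non-templated poly(A) runs of defined lengths.

Every generator is deterministic given its config (same seed, same
bytes) and returns the exact planted truth alongside the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .race3p import Reference3p, TailCall, end_bin, tail_bin
from .reactivity import MapCountTable

__all__ = [
    "MapSimConfig",
    "FishSimConfig",
    "RaceSimConfig",
    "simulate_map_counts",
    "simulate_fish_stack",
    "simulate_race_reads",
    "DEFAULT_LINKER",
    "write_fastq",
    "write_fasta",
]

# 17-nt fixed linker appended 3' of the poly(A) tail when requested
DEFAULT_LINKER = "CTGTAGGCACCATCAAT"


# ---------------------------------------------------------------------------
# DMS-MaPseq count tables


@dataclass
class MapSimConfig:
    """Conditions for the mutational-profiling generator.

    Rates are per-read mutation probabilities.  ``diff_regions`` lists
    (start, end, group_id) intervals (1-based inclusive) where the
    pairing state of every A/C nucleotide is flipped in that group only.
    ``replicate_sigma`` is the log-normal sigma of the per-replicate
    multiplicative rate factor that models biological replicate
    variability.
    """

    transcript_length: int = 300
    n_replicates_per_group: int = 3
    coverage_mean: float = 10_000.0
    unpaired_rate: float = 0.05
    paired_rate: float = 0.01
    background_rate: float = 0.002
    diff_regions: tuple = ()
    gc_sequence_fraction: float = 0.4
    group_ids: tuple = ("WT", "pop")
    paired_fraction: float = 0.5
    replicate_sigma: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("unpaired_rate", "paired_rate", "background_rate",
                     "gc_sequence_fraction", "paired_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.background_rate < self.paired_rate < self.unpaired_rate:
            raise ValueError("need background_rate < paired_rate < unpaired_rate")
        if self.transcript_length < 1 or self.n_replicates_per_group < 1:
            raise ValueError("transcript_length and replicate count must be >= 1")
        spans = []
        for start, end, group in self.diff_regions:
            if not (1 <= start <= end <= self.transcript_length):
                raise ValueError(f"diff region ({start},{end}) outside transcript")
            if group not in self.group_ids:
                raise ValueError(f"unknown group {group!r} in diff_regions")
            spans.append((start, end))
        spans.sort()
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("overlapping diff_regions")


def simulate_map_counts(config: MapSimConfig):
    """Generate count tables for every group/replicate/channel.

    Returns ``(tables, truth)`` where ``tables`` is a flat list of
    :class:`MapCountTable` and ``truth`` a dict with the sequence, the
    per-group boolean unpaired-state arrays, and the boolean mask of
    nucleotides whose state differs between groups.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.transcript_length

    n_gu = int(round(config.gc_sequence_fraction * n))
    bases = np.array(["A", "C"])[rng.integers(0, 2, size=n)]
    gu_idx = rng.choice(n, size=n_gu, replace=False)
    bases[gu_idx] = np.array(["G", "T"])[rng.integers(0, 2, size=n_gu)]
    sequence = "".join(bases)
    is_ac = ~np.isin(np.arange(n), gu_idx)

    base_unpaired = rng.random(n) > config.paired_fraction
    unpaired = {g: base_unpaired.copy() for g in config.group_ids}
    for start, end, group in config.diff_regions:
        sel = (np.arange(1, n + 1) >= start) & (np.arange(1, n + 1) <= end) & is_ac
        unpaired[group][sel] = ~unpaired[group][sel]

    group_arrays = [unpaired[g] for g in config.group_ids]
    differs = np.zeros(n, dtype=bool)
    for arr in group_arrays[1:]:
        differs |= arr != group_arrays[0]

    positions = np.arange(1, n + 1)
    tables: list[MapCountTable] = []
    for group in config.group_ids:
        treated_rate = np.where(unpaired[group], config.unpaired_rate, config.paired_rate)
        treated_rate = np.where(is_ac, treated_rate, config.background_rate)
        for rep in range(1, config.n_replicates_per_group + 1):
            factor = rng.lognormal(0.0, config.replicate_sigma) if config.replicate_sigma > 0 else 1.0
            for channel, rate in (("+", treated_rate * factor),
                                  ("-", np.full(n, config.background_rate) * factor)):
                rate = np.clip(rate, 0.0, 1.0)
                coverage = np.maximum(rng.poisson(config.coverage_mean, size=n), 1)
                muts = rng.binomial(coverage, rate)
                tables.append(
                    MapCountTable(
                        transcript_id="synthetic_rna",
                        sequence=sequence,
                        positions=positions,
                        mut_count=muts,
                        coverage=coverage,
                        channel=channel,
                        replicate_id=f"{group}_rep{rep}",
                        group_id=group,
                    )
                )
    truth = {
        "sequence": sequence,
        "unpaired": unpaired,
        "differential": differs,
        "positions": positions,
    }
    return tables, truth


# ---------------------------------------------------------------------------
# smFISH stacks


@dataclass
class FishSimConfig:
    """Conditions for the 3-channel smFISH stack generator.

    ``spots_per_compartment`` is (nucleolus, nucleoplasm, cytoplasm)
    counts planted per cell.  The PSF is a 3D Gaussian, isotropic in xy
    with a 2x elongation along z (widefield approximation).  Planted
    spots keep a pairwise distance of at least ``min_spot_separation``
    (default 4 PSF sigmas, in z-compressed coordinates matching the PSF
    anisotropy) so that each planted molecule is an optically resolvable
    object with well-defined ground truth.
    """

    stack_shape: tuple = (32, 96, 96)  # (z, y, x) voxels
    n_cells: int = 2
    spots_per_compartment: tuple = (1, 2, 2)
    psf_sigma: float = 1.3
    spot_amplitude: float = 300.0
    background_lambda: float = 2.0
    compartment_fill: float = 60.0
    min_voxel_object: int = 10
    min_spot_separation: float | None = None  # default 4 * psf_sigma
    seed: int = 0

    def validate(self) -> None:
        if len(self.stack_shape) != 3 or any(s < 8 for s in self.stack_shape):
            raise ValueError("stack_shape must be a (z, y, x) triple, each >= 8")
        if self.n_cells < 1:
            raise ValueError("need at least one cell")
        if any(c < 0 for c in self.spots_per_compartment):
            raise ValueError("spot counts must be nonnegative")
        if self.psf_sigma <= 0 or self.spot_amplitude < 0 or self.background_lambda < 0:
            raise ValueError("psf_sigma must be > 0; intensities nonnegative")


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((zz - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((xx - center[2]) / radii[2]) ** 2
    ) <= 1.0


def gaussian_spot(shape, center, amplitude, sigma_xy, sigma_z, radius_factor=4.0):
    """Render one 3D Gaussian into a zero array (window-limited)."""
    out = np.zeros(shape, dtype=float)
    rz = int(np.ceil(radius_factor * sigma_z))
    rxy = int(np.ceil(radius_factor * sigma_xy))
    z0, y0, x0 = center
    zs = slice(max(0, int(z0) - rz), min(shape[0], int(z0) + rz + 1))
    ys = slice(max(0, int(y0) - rxy), min(shape[1], int(y0) + rxy + 1))
    xs = slice(max(0, int(x0) - rxy), min(shape[2], int(x0) + rxy + 1))
    zz, yy, xx = np.meshgrid(
        np.arange(zs.start, zs.stop),
        np.arange(ys.start, ys.stop),
        np.arange(xs.start, xs.stop),
        indexing="ij",
    )
    out[zs, ys, xs] = amplitude * np.exp(
        -((zz - z0) ** 2) / (2 * sigma_z**2)
        - ((yy - y0) ** 2) / (2 * sigma_xy**2)
        - ((xx - x0) ** 2) / (2 * sigma_xy**2)
    )
    return out


def simulate_fish_stack(config: FishSimConfig):
    """Generate one 3-channel stack plus exact masks and planted spots.

    Returns ``(channels, truth)``; ``channels`` maps cy3/cy5/dapi to 3D
    float arrays, ``truth`` holds labeled cell/nucleus/nucleolus masks
    and a DataFrame of planted spots (cell, compartment, z, y, x,
    amplitude).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.stack_shape)
    nz, ny, nx = shape

    cells = np.zeros(shape, dtype=np.int32)
    nuclei = np.zeros(shape, dtype=np.int32)
    nucleoli = np.zeros(shape, dtype=np.int32)

    # lay cells out on a horizontal grid; reject configs that cannot fit
    n_cols = int(np.ceil(np.sqrt(config.n_cells)))
    n_rows = int(np.ceil(config.n_cells / n_cols))
    cell_rx = nx / (2 * n_cols) - 2
    cell_ry = ny / (2 * n_rows) - 2
    cell_rz = nz / 2 - 2
    if min(cell_rx, cell_ry, cell_rz) < 3:
        raise ValueError("stack too small for the requested cell count")
    for cid in range(1, config.n_cells + 1):
        row, col = divmod(cid - 1, n_cols)
        center = (
            nz / 2,
            (2 * row + 1) * ny / (2 * n_rows),
            (2 * col + 1) * nx / (2 * n_cols),
        )
        cell = _ellipsoid_mask(shape, center, (cell_rz, cell_ry, cell_rx))
        nucleus = _ellipsoid_mask(
            shape,
            (center[0], center[1], center[2] - 0.25 * cell_rx),
            (0.55 * cell_rz, 0.55 * cell_ry, 0.55 * cell_rx),
        )
        nucleolus = _ellipsoid_mask(
            shape,
            (center[0], center[1], center[2] - 0.45 * cell_rx),
            (0.28 * cell_rz, 0.28 * cell_ry, 0.28 * cell_rx),
        )
        nucleus &= cell
        nucleolus &= nucleus
        cells[cell] = cid
        nuclei[nucleus] = cid
        nucleoli[nucleolus] = cid

    compartment_of = {
        "NO": nucleoli > 0,
        "NP": (nuclei > 0) & (nucleoli == 0),
        "CYT": (cells > 0) & (nuclei == 0),
    }

    spots = []
    cy3 = np.zeros(shape, dtype=float)
    sigma_xy = config.psf_sigma
    sigma_z = 2.0 * config.psf_sigma
    min_sep = (
        config.min_spot_separation
        if config.min_spot_separation is not None
        else 4.0 * config.psf_sigma
    )
    placed: list[np.ndarray] = []

    def far_enough(center):
        # z compressed by the PSF elongation so separation is in PSF units
        scaled = np.array([center[0] / 2.0, center[1], center[2]])
        return all(np.linalg.norm(scaled - p) >= min_sep for p in placed)

    for cid in range(1, config.n_cells + 1):
        for comp, count in zip(("NO", "NP", "CYT"), config.spots_per_compartment):
            voxels = np.argwhere(compartment_of[comp] & (cells == cid))
            if count > 0 and len(voxels) < count:
                raise ValueError(
                    f"cell {cid}: {count} spots requested for {comp} but the "
                    f"compartment has only {len(voxels)} voxels"
                )
            for _ in range(count):
                for _attempt in range(200):
                    vz, vy, vx = voxels[rng.integers(len(voxels))]
                    center = (
                        vz + rng.uniform(-0.4, 0.4),
                        vy + rng.uniform(-0.4, 0.4),
                        vx + rng.uniform(-0.4, 0.4),
                    )
                    if far_enough(center):
                        break
                else:
                    raise ValueError(
                        f"cell {cid}: cannot place {count} resolvable spots in "
                        f"{comp} (min separation {min_sep:.1f} voxels)"
                    )
                placed.append(np.array([center[0] / 2.0, center[1], center[2]]))
                cy3 += gaussian_spot(shape, center, config.spot_amplitude, sigma_xy, sigma_z)
                spots.append(
                    {"cell": cid, "compartment": comp, "z": center[0],
                     "y": center[1], "x": center[2], "amplitude": config.spot_amplitude}
                )

    fill = config.compartment_fill
    cy5 = (nucleoli > 0) * fill
    dapi = (nuclei > 0) * fill
    lam = config.background_lambda
    if lam > 0:
        cy3 = cy3 + rng.poisson(lam, size=shape)
        cy5 = cy5 + rng.poisson(lam, size=shape)
        dapi = dapi + rng.poisson(lam, size=shape)

    channels = {"cy3": cy3.astype(float), "cy5": cy5.astype(float), "dapi": dapi.astype(float)}
    truth = {
        "cells": cells,
        "nuclei": nuclei,
        "nucleoli": nucleoli,
        "spots": pd.DataFrame(spots, columns=["cell", "compartment", "z", "y", "x", "amplitude"]),
    }
    return channels, truth


# ---------------------------------------------------------------------------
# 3' RACE reads


def make_race_reference(seed: int = 0, offset: int = 1040, length: int = 140) -> Reference3p:
    """A TLC1-like 3'-region reference for simulation.

    Random sequence with the 3'-end window (transcript positions
    1150-1170) kept free of adenosines so that planted poly(A) tails are
    never templated and ground truth is unambiguous.
    """
    rng = np.random.default_rng(seed)
    seq = np.array(list("ACGT"))[rng.integers(0, 4, size=length)]
    window = np.array(list("CGT"))[rng.integers(0, 3, size=length)]
    idx = np.arange(offset, offset + length)
    in_window = (idx >= 1150) & (idx <= 1170)
    seq[in_window] = window[in_window]
    return Reference3p(transcript_id="TLC1_synthetic", sequence="".join(seq), offset=offset)


@dataclass
class RaceSimConfig:
    """Conditions for the 3' RACE read generator.

    ``end_position_weights`` maps templated 3'-end transcript positions
    to sampling probabilities; ``tail_length_distribution`` likewise for
    non-templated poly(A) lengths.  Reads are emitted 5'->3' on the
    sense strand, pre-trimmed by default (``append_linker`` adds the
    linker back).
    """

    reference: Reference3p = field(default_factory=make_race_reference)
    end_position_weights: dict = field(
        default_factory=lambda: {1156: 0.1, 1157: 0.75, 1158: 0.05, 1159: 0.1}
    )
    tail_length_distribution: dict = field(
        default_factory=lambda: {0: 0.8, 1: 0.05, 3: 0.05, 8: 0.05, 14: 0.05}
    )
    n_reads: int = 1000
    linker: str = DEFAULT_LINKER
    append_linker: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("end_position_weights", "tail_length_distribution"):
            probs = np.array(list(getattr(self, name).values()), dtype=float)
            if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
                raise ValueError(f"{name} must be nonnegative and sum to 1")
        for pos in self.end_position_weights:
            if pos < self.reference.offset or pos > self.reference.last_position:
                raise ValueError(f"end position {pos} outside reference")
        if any(t < 0 for t in self.tail_length_distribution):
            raise ValueError("tail lengths must be nonnegative")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")


def simulate_race_reads(config: RaceSimConfig):
    """Generate reads and their exact ground-truth calls.

    Returns ``(records, truth)``: ``records`` is a list of
    (read_id, sequence) pairs and ``truth`` a list of
    :class:`TailCall` with the planted end position and tail length.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ends = np.array(list(config.end_position_weights), dtype=int)
    end_p = np.array(list(config.end_position_weights.values()), dtype=float)
    tails = np.array(list(config.tail_length_distribution), dtype=int)
    tail_p = np.array(list(config.tail_length_distribution.values()), dtype=float)

    chosen_ends = rng.choice(ends, size=config.n_reads, p=end_p / end_p.sum())
    chosen_tails = rng.choice(tails, size=config.n_reads, p=tail_p / tail_p.sum())

    records = []
    truth = []
    ref = config.reference
    for i, (end, tail) in enumerate(zip(chosen_ends, chosen_tails)):
        prefix = ref.sequence[: end - ref.offset + 1]
        seq = prefix + "A" * int(tail)
        if config.append_linker:
            seq += config.linker
        read_id = f"race_{i:06d}"
        records.append((read_id, seq))
        truth.append(TailCall(read_id=read_id, end_position=int(end), tail_length=int(tail)))
    return records, truth


# ---------------------------------------------------------------------------
# plain-text writers


def write_fastq(records, path, quality_char: str = "I") -> None:
    """Write (id, sequence) pairs as Phred+33 FASTQ with constant quality."""
    with open(path, "w") as fh:
        for read_id, seq in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_fasta(reference: Reference3p, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{reference.transcript_id} offset={reference.offset}\n")
        seq = reference.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
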