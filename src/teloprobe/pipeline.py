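"""Stage orchestration, manifests, and small shared statistics utilities.

The pipeline runs simulate -> reactivity -> diffscan (and, on request,
the FISH and RACE stages) from a single seeded configuration, writing
plain-text outputs plus a JSON manifest recording inputs, parameters,
seed and output checksums so any run can be reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diffscan import GroupedProfiles, regions_to_bed, regions_to_frame, run_screen
from .fishquant import (
    classify_spots,
    clean_detect,
    compare_strains,
    segment_compartments,
    spots_to_frame,
    summarize_cells,
)
from .race3p import Reference3p, calls_to_frame, classify_reads, long_to_mature_ratio, tabulate_ends
from .reactivity import compute_raw_reactivity, normalize_2_8, write_count_table, write_profile
from .synthetic import (
    FishSimConfig,
    MapSimConfig,
    RaceSimConfig,
    simulate_fish_stack,
    simulate_map_counts,
    simulate_race_reads,
    write_fasta,
    write_fastq,
)

__all__ = ["RunConfig", "ddct_fold_change", "run_pipeline"]

STAGES = ("simulate", "reactivity", "diffscan", "fish", "race")


@dataclass
class RunConfig:
    """Configuration for an end-to-end synthetic run."""

    out_dir: str = "teloprobe_run"
    stages: tuple = ("simulate", "reactivity", "diffscan")
    seed: int = 0
    min_coverage: int = 1000
    min_region_len: int = 5
    map_sim: MapSimConfig = field(default_factory=MapSimConfig)
    fish_sim: FishSimConfig = field(default_factory=FishSimConfig)
    race_sim: RaceSimConfig = field(default_factory=RaceSimConfig)
    fish_min_intensity: float = 30.0
    fish_psf_sigma: float = 1.3
    min_voxel_object: int = 10

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.min_coverage < 0 or self.min_region_len < 1:
            raise ValueError("thresholds must be positive")


def ddct_fold_change(records: pd.DataFrame, calibrator: str) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    ``records`` needs columns ``sample``, ``target_ct``, ``reference_ct``
    (one row per replicate).  dCt = Ct_target - Ct_reference per
    replicate; ddCt subtracts the calibrator's mean dCt; fold = 2^-ddCt.
    Returns per-sample mean fold change and its SD over replicates.
    """
    required = {"sample", "target_ct", "reference_ct"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if records[["target_ct", "reference_ct"]].isna().any().any():
        bad = records.loc[records[["target_ct", "reference_ct"]].isna().any(axis=1), "sample"]
        raise ValueError(f"missing Ct values for sample(s): {sorted(set(bad))}")
    if calibrator not in set(records["sample"]):
        raise ValueError(f"calibrator sample {calibrator!r} not present")

    df = records.copy()
    df["dct"] = df["target_ct"] - df["reference_ct"]
    calibrator_dct = df.loc[df["sample"] == calibrator, "dct"].mean()
    df["ddct"] = df["dct"] - calibrator_dct
    df["fold"] = 2.0 ** (-df["ddct"])
    out = (
        df.groupby("sample", sort=False)["fold"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "fold_mean", "std": "fold_sd", "count": "n_replicates"})
    )
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _derive_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in dependency order; returns the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": {
            "min_coverage": config.min_coverage,
            "min_region_len": config.min_region_len,
            "fish_min_intensity": config.fish_min_intensity,
            "fish_psf_sigma": config.fish_psf_sigma,
            "min_voxel_object": config.min_voxel_object,
            "map_sim": asdict(config.map_sim),
            "fish_sim": asdict(config.fish_sim),
            "race_sim": {
                **{k: v for k, v in asdict(config.race_sim).items() if k != "reference"},
                "reference": config.race_sim.reference.transcript_id,
            },
        },
        "outputs": {},
    }

    want = set(config.stages)
    tables = profiles = None

    if want & {"simulate", "reactivity", "diffscan"}:
        map_cfg = MapSimConfig(**{**asdict(config.map_sim), "seed": _derive_seed(config.seed, "map")})
        tables, _truth = simulate_map_counts(map_cfg)
        if "simulate" in want:
            for t in tables:
                path = out / f"counts_{t.group_id}_{t.replicate_id}_{'plus' if t.channel == '+' else 'minus'}.tsv"
                write_count_table(t, path)
                manifest["outputs"][path.name] = _sha256(path)

    if want & {"reactivity", "diffscan"}:
        by_sample: dict[tuple, dict] = {}
        for t in tables:
            by_sample.setdefault((t.group_id, t.replicate_id), {})[t.channel] = t
        profiles = {}
        for (group, rep), channels in sorted(by_sample.items()):
            prof = normalize_2_8(
                compute_raw_reactivity(channels["+"], channels["-"], min_coverage=config.min_coverage)
            )
            profiles.setdefault(group, []).append(prof)
            if "reactivity" in want:
                path = out / f"reactivity_{group}_{rep}.map"
                write_profile(prof, path)
                manifest["outputs"][path.name] = _sha256(path)

    if "diffscan" in want:
        regions, _tracks = run_screen(
            GroupedProfiles(groups=profiles), min_len=config.min_region_len
        )
        frame = regions_to_frame(regions)
        path = out / "regions.tsv"
        frame.to_csv(path, sep="\t", index=False)
        manifest["outputs"][path.name] = _sha256(path)
        bed = regions_to_bed([r for r in regions if r.significant])
        path = out / "regions.bed"
        bed.to_csv(path, sep="\t", index=False, header=False)
        manifest["outputs"][path.name] = _sha256(path)

    if "fish" in want:
        fish_cfg = FishSimConfig(**{**asdict(config.fish_sim), "seed": _derive_seed(config.seed, "fish")})
        channels, truth = simulate_fish_stack(fish_cfg)
        masks = segment_compartments(
            channels, truth["cells"], min_voxel_object=config.min_voxel_object
        )
        spots = clean_detect(
            channels["cy3"], masks, config.fish_min_intensity, psf_sigma=config.fish_psf_sigma
        )
        spots, discarded = classify_spots(spots, masks)
        stats_list = summarize_cells(spots, masks)
        path = out / "fish_spots.csv"
        spots_to_frame(spots).to_csv(path, index=False)
        manifest["outputs"][path.name] = _sha256(path)
        cell_rows = pd.DataFrame(
            {
                "cell": [s.cell_id for s in stats_list],
                "total": [s.total for s in stats_list],
                **{
                    f"n_{c}": [s.counts[c] for s in stats_list]
                    for c in ("NO", "NP", "CYT")
                },
            }
        )
        path = out / "fish_cells.csv"
        cell_rows.to_csv(path, index=False)
        manifest["outputs"][path.name] = _sha256(path)
        manifest["fish_discarded_spots"] = discarded

    if "race" in want:
        race_cfg = RaceSimConfig(
            **{
                **{k: v for k, v in asdict(config.race_sim).items() if k != "reference"},
                "reference": config.race_sim.reference,
                "seed": _derive_seed(config.seed, "race"),
            }
        )
        records, _truth = simulate_race_reads(race_cfg)
        write_fastq(records, out / "race_reads.fastq")
        write_fasta(race_cfg.reference, out / "race_reference.fasta")
        calls, unclassified = classify_reads(records, race_cfg.reference)
        dist = tabulate_ends(calls)
        path = out / "race_calls.tsv"
        calls_to_frame(calls).to_csv(path, sep="\t", index=False)
        manifest["outputs"][path.name] = _sha256(path)
        path = out / "race_matrix.csv"
        dist.counts.to_csv(path)
        manifest["outputs"][path.name] = _sha256(path)
        ratio = long_to_mature_ratio(calls)
        summary = {
            "total_reads": len(records),
            "classified": len(calls),
            "unclassified": unclassified,
            "long_to_mature_ratio": None if np.isnan(ratio) else ratio,
        }
        path = out / "race_summary.json"
        path.write_text(json.dumps(summary, indent=2))
        manifest["outputs"][path.name] = _sha256(path)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
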