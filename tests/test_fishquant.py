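"""Segmentation, CLEAN detection, compartment classification, strain comparison."""

import numpy as np
import pytest
from scipy import stats as sps

from teloprobe.fishquant import (
    CompartmentMasks,
    Spot,
    classify_spot,
    classify_spots,
    clean_detect,
    compare_strains,
    segment_compartments,
    summarize_cells,
)
from teloprobe.synthetic import FishSimConfig, gaussian_spot, simulate_fish_stack


def truth_masks(truth):
    return CompartmentMasks(
        cells=truth["cells"], nuclei=truth["nuclei"], nucleoli=truth["nucleoli"]
    )


def match_spots(found, truth_df, tol=1.0):
    """Greedy nearest matching; returns per-truth-spot distances."""
    remaining = list(found)
    dists = []
    for _, row in truth_df.iterrows():
        if not remaining:
            dists.append(np.inf)
            continue
        t = np.array([row.z, row.y, row.x])
        d = [np.linalg.norm(t - np.array(s.centroid)) for s in remaining]
        i = int(np.argmin(d))
        dists.append(d[i])
        remaining.pop(i)
    return np.array(dists)


class TestSegmentation:
    def test_noise_free_masks_recovered_exactly(self):
        channels, truth = simulate_fish_stack(
            FishSimConfig(seed=1, background_lambda=0.0, spots_per_compartment=(0, 0, 0))
        )
        masks = segment_compartments(channels, truth["cells"], threshold_method=1.0)
        np.testing.assert_array_equal(masks.nuclei, truth["nuclei"])
        np.testing.assert_array_equal(masks.nucleoli, truth["nucleoli"])

    def test_small_objects_removed(self):
        shape = (16, 32, 32)
        dapi = np.zeros(shape)
        dapi[4:6, 4:6, 4:6] = 100.0  # 8-voxel speck
        dapi[8:13, 10:20, 10:20] = 100.0  # 500-voxel nucleus
        cells = np.ones(shape, dtype=np.int32)
        masks = segment_compartments(
            {"dapi": dapi, "cy5": np.zeros(shape)}, cells, threshold_method=50.0
        )
        assert not masks.nuclei[4:6, 4:6, 4:6].any()
        assert masks.nuclei[8:13, 10:20, 10:20].all()

    def test_flat_channel_warns_and_is_empty(self):
        shape = (16, 32, 32)
        with pytest.warns(UserWarning, match="flat|empty"):
            masks = segment_compartments(
                {"dapi": np.zeros(shape), "cy5": np.zeros(shape)},
                np.ones(shape, dtype=np.int32),
            )
        assert not masks.nuclei.any() and not masks.nucleoli.any()


class TestCleanDetect:
    def test_blank_cell_yields_no_spots(self):
        channels, truth = simulate_fish_stack(
            FishSimConfig(seed=2, spots_per_compartment=(0, 0, 0), background_lambda=2.0)
        )
        spots = clean_detect(channels["cy3"], truth_masks(truth), 30.0)
        assert spots == []

    def test_single_spot_recovered_within_one_voxel(self):
        cfg = FishSimConfig(
            seed=3, n_cells=1, spots_per_compartment=(0, 0, 1),
            spot_amplitude=300.0, background_lambda=2.0,
        )
        channels, truth = simulate_fish_stack(cfg)
        spots = clean_detect(channels["cy3"], truth_masks(truth), 30.0)
        assert len(spots) == 1
        assert match_spots(spots, truth["spots"]).max() <= 1.0

    def test_well_separated_pair_resolved(self):
        """Two spots 4 PSF sigmas apart are each recovered once."""
        shape = (24, 48, 48)
        sigma = 1.3
        cy3 = (
            gaussian_spot(shape, (12, 24, 20), 200.0, sigma, 2 * sigma)
            + gaussian_spot(shape, (12, 24, 20 + 4 * sigma), 200.0, sigma, 2 * sigma)
        )
        cells = np.ones(shape, dtype=np.int32)
        masks = CompartmentMasks(cells, np.zeros_like(cells), np.zeros_like(cells))
        spots = clean_detect(cy3, masks, 20.0, psf_sigma=sigma)
        assert len(spots) == 2
        xs = sorted(s.x for s in spots)
        assert xs[0] == pytest.approx(20, abs=1.0)
        assert xs[1] == pytest.approx(20 + 4 * sigma, abs=1.0)

    def test_flux_conserved_and_residual_monotone(self):
        """Noise-free input: fitted flux + residual equals the input within 1%,
        and the residual maximum never increases across iterations."""
        cfg = FishSimConfig(
            seed=4, n_cells=2, spots_per_compartment=(1, 1, 2),
            background_lambda=0.0, spot_amplitude=250.0,
        )
        channels, truth = simulate_fish_stack(cfg)
        cy3 = channels["cy3"]
        trace: list = []
        spots = clean_detect(cy3, truth_masks(truth), 25.0, trace=trace)
        total_flux = sum(s.integrated_intensity for s in spots)
        # reconstruct the final residual from the recorded fit parameters
        residual = cy3.copy()
        for s in spots:
            residual -= gaussian_spot(cy3.shape, s.centroid, s.amplitude, s.sigma_xy, s.sigma_z)
        assert total_flux + residual.sum() == pytest.approx(cy3.sum(), rel=1e-6)
        assert abs(residual.sum()) <= 0.01 * cy3.sum()  # fits captured the flux
        for cell_trace in trace:
            assert all(a >= b - 1e-9 for a, b in zip(cell_trace, cell_trace[1:]))

    def test_requires_positive_threshold(self):
        masks = CompartmentMasks(*(np.zeros((8, 8, 8), dtype=np.int32),) * 3)
        with pytest.raises(ValueError):
            clean_detect(np.zeros((8, 8, 8)), masks, 0.0)


class TestClassification:
    def make_masks(self):
        shape = (8, 16, 16)
        cells = np.zeros(shape, dtype=np.int32)
        nuclei = np.zeros(shape, dtype=np.int32)
        nucleoli = np.zeros(shape, dtype=np.int32)
        cells[:, :, :8] = 1
        nuclei[2:6, 4:12, 1:6] = 1
        nucleoli[3:5, 6:10, 2:4] = 1
        return CompartmentMasks(cells, nuclei, nucleoli)

    def spot_at(self, z, y, x):
        return Spot(cell_id=1, z=z, y=y, x=x, amplitude=1, sigma_xy=1, sigma_z=2,
                    integrated_intensity=1)

    def test_precedence_no_np_cyt(self):
        masks = self.make_masks()
        assert classify_spot(self.spot_at(4, 8, 3), masks) == "NO"
        assert classify_spot(self.spot_at(4, 8, 5), masks) == "NP"
        assert classify_spot(self.spot_at(4, 8, 7), masks) == "CYT"
        assert classify_spot(self.spot_at(4, 8, 12), masks) is None

    def test_outside_cell_spots_discarded_and_counted(self):
        masks = self.make_masks()
        spots = [self.spot_at(4, 8, 3), self.spot_at(4, 8, 12)]
        kept, discarded = classify_spots(spots, masks)
        assert len(kept) == 1 and discarded == 1

    def test_planted_compartments_recovered_exactly(self):
        """Noise-free masks: every planted spot classifies to its planted label."""
        channels, truth = simulate_fish_stack(
            FishSimConfig(seed=5, n_cells=3, spots_per_compartment=(2, 3, 4))
        )
        masks = truth_masks(truth)
        for _, row in truth["spots"].iterrows():
            spot = Spot(cell_id=int(row.cell), z=row.z, y=row.y, x=row.x,
                        amplitude=1, sigma_xy=1, sigma_z=2, integrated_intensity=1)
            assert classify_spot(spot, masks) == row.compartment


class TestCellStats:
    def test_fractions(self):
        masks = CompartmentMasks(
            cells=np.ones((4, 4, 4), dtype=np.int32),
            nuclei=np.zeros((4, 4, 4), dtype=np.int32),
            nucleoli=np.zeros((4, 4, 4), dtype=np.int32),
        )
        spots = []
        for comp, n in (("NO", 1), ("NP", 2), ("CYT", 1)):
            for _ in range(n):
                s = Spot(cell_id=1, z=1, y=1, x=1, amplitude=1, sigma_xy=1,
                         sigma_z=2, integrated_intensity=1, compartment=comp)
                spots.append(s)
        (cell,) = summarize_cells(spots, masks)
        assert cell.total == 4
        assert cell.fractions == {"NO": 0.25, "NP": 0.5, "CYT": 0.25}
        assert sum(cell.fractions.values()) == pytest.approx(1.0)

    def test_zero_spot_cell_excluded_from_fraction_stats(self):
        cells = np.zeros((4, 4, 8), dtype=np.int32)
        cells[:, :, :4] = 1
        cells[:, :, 4:] = 2
        masks = CompartmentMasks(cells, np.zeros_like(cells), np.zeros_like(cells))
        s = Spot(cell_id=1, z=1, y=1, x=1, amplitude=1, sigma_xy=1, sigma_z=2,
                 integrated_intensity=1, compartment="CYT")
        stats_list = summarize_cells([s], masks)
        assert [c.total for c in stats_list] == [1, 0]
        assert stats_list[1].fractions is None


class TestCompareStrains:
    def stats_from_totals(self, totals):
        out = []
        for i, t in enumerate(totals):
            counts = {"NO": 0, "NP": 0, "CYT": t}
            fr = {"NO": 0.0, "NP": 0.0, "CYT": 1.0} if t else None
            out.append(type("S", (), {"total": t, "counts": counts, "fractions": fr,
                                      "cell_id": i})())
        return out

    def test_ks_examples(self):
        identical = compare_strains(
            self.stats_from_totals([1, 2, 3]), self.stats_from_totals([1, 2, 3])
        )
        assert identical["spots_per_cell"]["D"] == 0.0
        disjoint = compare_strains(
            self.stats_from_totals([1, 2, 3]), self.stats_from_totals([4, 5, 6])
        )
        assert disjoint["spots_per_cell"]["D"] == 1.0
        shifted = compare_strains(
            self.stats_from_totals([1, 2, 3, 4]), self.stats_from_totals([2, 3, 4, 5])
        )
        # brute-force ECDF oracle on the pooled support
        x, y = [1, 2, 3, 4], [2, 3, 4, 5]
        d_oracle = max(
            abs(np.mean([v <= s for v in x]) - np.mean([v <= s for v in y]))
            for s in x + y
        )
        assert d_oracle == 0.25
        assert shifted["spots_per_cell"]["D"] == pytest.approx(0.25)
        # cross-check p against scipy on raw arrays
        assert shifted["spots_per_cell"]["p"] == pytest.approx(
            sps.ks_2samp([1, 2, 3, 4], [2, 3, 4, 5]).pvalue
        )

    def test_requires_two_cells_per_strain(self):
        with pytest.raises(ValueError):
            compare_strains(self.stats_from_totals([1]), self.stats_from_totals([1, 2]))
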