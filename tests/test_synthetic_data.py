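"""Generator contracts: composition bookkeeping, planted truth, determinism."""

from __future__ import annotations

import math

import numpy as np
import pytest

import pipnano as pn
from pipnano import synthetic_data as sd
from pipnano.fluorescence_analysis import PolarizedIntensities


class TestFluidBilayer:
    def test_composition_bookkeeping(self, fluid_bilayer):
        frame, _ = fluid_bilayer
        census = frame.census()
        assert census["PIP2_160"] == 90
        assert census["POPC"] == 810
        leaf = frame.leaflet.astype(str)
        assert (leaf == "upper").sum() == 450
        assert (leaf == "lower").sum() == 450

    def test_zero_disorder_chains_parallel_to_normal(self):
        frame, _ = sd.build_fluid_bilayer(n_lipids=64, chain_disorder=0.0, seed=3)
        for sp in ("POPC", "PIP2_160"):
            lipids = np.flatnonzero(frame.species.astype(str) == sp)
            if len(lipids) == 0:
                continue
            top = frame.topology[sp]
            for ci in range(len(top.chains)):
                beads = top.chains[ci]
                pos = np.stack(
                    [frame.positions_by_bead(lipids, b) for b in beads], axis=1
                )
                bonds = np.diff(pos, axis=1)
                assert np.allclose(bonds[:, :, :2], 0.0, atol=1e-12)

    def test_full_disorder_first_bond_isotropic(self):
        """At chain_disorder=1 bond directions are isotropic: S ~ 0 within
        3 standard errors over ~10^4 chains (Monte-Carlo oracle)."""
        frame, _ = sd.build_fluid_bilayer(
            n_lipids=6000, pip2_fraction=0.0, chain_disorder=1.0, seed=4
        )
        prof = pn.order_profile(frame, "POPC", chain=0)
        assert abs(prof.s_values[0]) < 3 * prof.standard_errors[0]

    def test_seed_determinism_and_sensitivity(self):
        a1, _ = sd.build_fluid_bilayer(n_lipids=100, seed=9)
        a2, _ = sd.build_fluid_bilayer(n_lipids=100, seed=9)
        b, _ = sd.build_fluid_bilayer(n_lipids=100, seed=10)
        assert np.array_equal(a1.positions, a2.positions)
        assert not np.array_equal(a1.positions, b.positions)

    def test_rejects_odd_count_and_overlapping_lattice(self):
        with pytest.raises(ValueError, match="even"):
            sd.build_fluid_bilayer(n_lipids=901)
        with pytest.raises(ValueError, match="overlap"):
            sd.build_fluid_bilayer(n_lipids=100, area_per_lipid=0.1)


class TestPlantClusters:
    def test_single_cluster_limit(self):
        frame, _ = sd.build_fluid_bilayer(n_lipids=900, pip2_fraction=0.1, seed=1)
        out, truth = sd.plant_clusters(frame, [90], seed=2)
        assert len(truth.planted_partition) == 1
        assert len(truth.planted_partition[0]) == 90

    def test_monomer_limit(self):
        frame, _ = sd.build_fluid_bilayer(n_lipids=900, pip2_fraction=0.1, seed=1)
        out, truth = sd.plant_clusters(frame, [1] * 90, min_gap=1.0, seed=2)
        assert len(truth.planted_partition) == 90
        assert all(len(c) == 1 for c in truth.planted_partition)

    def test_partition_covers_exactly_the_pip2_lipids(self, clustered_bilayer):
        frame, truth = clustered_bilayer
        covered = set().union(*truth.planted_partition)
        assert covered == set(int(l) for l in frame.lipids_matching("PIP2"))

    def test_size_mismatch_rejected(self, fluid_bilayer):
        frame, _ = fluid_bilayer
        with pytest.raises(ValueError, match="sum"):
            sd.plant_clusters(frame, [10, 10], seed=0)

    def test_packing_error_when_box_too_small(self):
        frame, _ = sd.build_fluid_bilayer(n_lipids=64, pip2_fraction=0.5, seed=0)
        with pytest.raises(ValueError, match="too small"):
            sd.plant_clusters(frame, [8, 8, 8, 8], min_gap=6.0, seed=1)


class TestGelPatch:
    def test_planted_height_offset(self, gel_patch_frame):
        frame, truth = gel_patch_frame
        gel = np.array(sorted(truth.gel_membership))
        upper = np.flatnonzero(frame.leaflet.astype(str) == "upper")
        fluid = np.array([l for l in upper if int(l) not in truth.gel_membership])
        zg = frame.positions_by_bead(gel, "PO4")[:, 2].mean()
        zf = frame.positions_by_bead(fluid, "PO4")[:, 2].mean()
        assert zg - zf == pytest.approx(1.0, abs=0.05)

    def test_membership_recorded(self, gel_patch_frame):
        frame, truth = gel_patch_frame
        assert truth.gel_chain_count == 127
        assert len(truth.gel_membership) == math.ceil(127 / 2)

    def test_huge_spacing_gives_no_hexagonal_chains(self):
        frame, _ = sd.build_fluid_bilayer(n_lipids=512, seed=5)
        out, _ = sd.build_gel_patch(frame, 19, lattice_spacing=2.0, seed=6)
        res = pn.hexagonality(out, leaflet="upper")
        assert res.n_chains_hexagonal == 0

    def test_invalid_spacing_rejected(self, fluid_bilayer):
        frame, _ = fluid_bilayer
        with pytest.raises(ValueError, match="spacing"):
            sd.build_gel_patch(frame, 19, lattice_spacing=0.0)


class TestUndulatedBilayer:
    def test_flat_limit(self):
        frame, truth = sd.build_undulated_bilayer(
            n_lipids=128, amplitude=0.0, wavelength=5.0, seed=0
        )
        x = np.linspace(0, frame.box.Lx, 50)
        assert np.allclose(truth.analytic_curvature(x), 0.0)

    def test_crest_closed_form(self):
        _, truth = sd.build_undulated_bilayer(
            n_lipids=2048, amplitude=1.0, wavelength=25.0, seed=1
        )
        k = 2 * math.pi / truth.wavelength
        x_crest = (math.pi / 2) / k  # sin = 1, cos = 0
        want = -1.0 * k * k / 2.0
        assert truth.analytic_curvature(np.array([x_crest]))[0] == pytest.approx(
            want, rel=1e-12
        )
        assert want == pytest.approx(-0.0316, abs=5e-5)

    def test_analytic_field_integrates_to_zero_over_period(self):
        _, truth = sd.build_undulated_bilayer(
            n_lipids=2048, amplitude=1.0, wavelength=25.0, seed=1
        )
        x = np.linspace(0.0, truth.wavelength, 20001)
        integral = np.trapezoid(truth.analytic_curvature(x), x)
        assert integral == pytest.approx(0.0, abs=1e-12)

    def test_amplitude_bound_enforced(self):
        with pytest.raises(ValueError, match="quarter"):
            sd.build_undulated_bilayer(amplitude=4.0, wavelength=25.0, box_z=13.0)


class TestAsymmetricBilayer:
    def test_pip2_only_in_lower_leaflet(self):
        frame, truth = sd.build_asymmetric_bilayer(
            n_lipids=900, pip2_fraction=0.1, seed=2
        )
        pip2 = frame.lipids_matching("PIP2")
        assert len(pip2) == 45  # 10% of the 450-lipid lower leaflet
        assert all(str(frame.leaflet[l]) == "lower" for l in pip2)

    def test_leaflet_areas_balanced_within_one_percent(self):
        _, truth = sd.build_asymmetric_bilayer(
            n_lipids=900, pip2_fraction=0.1, pip2_area_per_lipid=0.70, seed=3
        )
        assert truth.extras["area_mismatch"] < 0.01


class TestSimulateDecay:
    def test_noiseless_single_exponential_log_linear(self):
        hist, _ = sd.simulate_decay([1.0], [5.0], n_photons=1e6, noise=False)
        t, c = hist.times, hist.counts
        slope = np.polyfit(t, np.log(c), 1)[0]
        assert slope == pytest.approx(-1.0 / 5.0, rel=1e-9)

    def test_seed_determinism(self):
        h1, _ = sd.simulate_decay([0.6, 0.4], [1, 10], n_photons=1e5, seed=7)
        h2, _ = sd.simulate_decay([0.6, 0.4], [1, 10], n_photons=1e5, seed=7)
        h3, _ = sd.simulate_decay([0.6, 0.4], [1, 10], n_photons=1e5, seed=8)
        assert np.array_equal(h1.counts, h2.counts)
        assert not np.array_equal(h1.counts, h3.counts)

    def test_poisson_dispersion(self):
        """Mean/variance ratio of repeated channel draws ~ 1 (Poisson)."""
        draws = []
        for s in range(40):
            h, _ = sd.simulate_decay(
                [0.6, 0.4], [1, 10], n_photons=1e6, n_channels=256,
                channel_width=0.2, seed=s,
            )
            draws.append(h.counts)
        draws = np.array(draws)
        mean = draws.mean(axis=0)
        var = draws.var(axis=0, ddof=1)
        busy = mean > 100
        ratio = var[busy] / mean[busy]
        assert abs(ratio.mean() - 1.0) < 0.15

    def test_total_counts_near_photon_budget(self):
        h, _ = sd.simulate_decay([0.6, 0.4], [1, 10], n_photons=1e6, seed=0)
        assert h.counts.sum() == pytest.approx(1e6, rel=0.01)

    def test_truncation_flag(self):
        with pytest.warns(UserWarning, match="truncated"):
            h, _ = sd.simulate_decay(
                [1.0], [10.0], n_channels=100, channel_width=0.1, seed=0
            )
        assert h.truncated

    def test_invalid_amplitudes_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sd.simulate_decay([0.5, 0.4], [1, 10])


class TestSimulatePolarized:
    def test_isotropic_limit(self):
        I = sd.simulate_polarized_intensities(0.0, 1e6, G=1.0)
        assert I.IVV == pytest.approx(I.IVH)

    def test_fully_polarized_limit(self):
        I = sd.simulate_polarized_intensities(1.0, 1e6, G=1.0)
        assert I.IVH == 0.0

    def test_ihv_ihh_ratio_is_g(self):
        I = sd.simulate_polarized_intensities(0.2, 1e6, G=1.37)
        assert I.IHV / I.IHH == pytest.approx(1.37)

    def test_out_of_range_r_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_polarized_intensities(1.2, 1e6)


class TestSimulateThermalProfile:
    def test_midpoint_by_symmetry(self):
        profile, _ = sd.simulate_thermal_profile(
            r_low=0.06, r_high=0.28, tm=45.0, width=2.0,
            temperatures=[25, 35, 44, 45, 46, 55, 65], noise_sd=0.0, seed=0,
        )
        i = list(profile.temperatures).index(45.0)
        assert profile.anisotropies[i] == pytest.approx((0.06 + 0.28) / 2)

    def test_high_temperature_asymptote(self):
        profile, _ = sd.simulate_thermal_profile(
            r_low=0.06, r_high=0.28, tm=45.0, width=2.0,
            temperatures=np.arange(60.0, 121.0, 10.0), noise_sd=0.0, seed=0,
        )
        assert profile.anisotropies[-1] == pytest.approx(0.06, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="6"):
            sd.simulate_thermal_profile(temperatures=[30, 40, 50], seed=0)
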