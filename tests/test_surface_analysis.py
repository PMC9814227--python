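"""Height fields, mean curvature, thickness maps, leaflet registration."""

from __future__ import annotations

import math

import numpy as np
import pytest

import pipnano as pn
from pipnano import synthetic_data as sd
from pipnano.surface_analysis import (
    HeightField,
    _bin_mean_z,
    build_height_field,
    mean_curvature_field,
    registration_coefficient,
    thickness_map,
)
from conftest import averaged_height_field


def _uniform_field(values, spacing=1.0):
    values = np.asarray(values, dtype=float)
    nx, ny = values.shape
    return HeightField(
        values=values,
        mask=np.ones_like(values, dtype=bool),
        spacing_x=spacing,
        spacing_y=spacing,
        Lx=nx * spacing,
        Ly=ny * spacing,
    )


class TestHeightField:
    def test_flat_leaflet_height(self, fluid_bilayer):
        frame, _ = fluid_bilayer
        hf = build_height_field(frame, "upper", spacing=2.0)
        z_ref = frame.positions_by_bead(
            np.flatnonzero(frame.leaflet.astype(str) == "upper"), "PO4"
        )[:, 2].mean()
        assert np.allclose(hf.values[hf.mask], z_ref, atol=0.2)

    def test_undulated_field_tracks_planted_surface(self):
        frame, truth = sd.build_undulated_bilayer(
            n_lipids=2048, amplitude=1.0, wavelength=25.0, seed=21
        )
        hf = build_height_field(frame, "upper", spacing=1.0)
        x, _ = hf.cell_centers()
        k = 2 * math.pi / truth.wavelength
        sine = np.broadcast_to(np.sin(k * x)[:, None], hf.shape)
        z0 = np.nanmean(hf.values[hf.mask] - sine[hf.mask])
        rms = np.sqrt(
            np.mean((hf.values[hf.mask] - z0 - sine[hf.mask]) ** 2)
        )
        assert rms < 0.1  # bead jitter at default density

    def test_degenerate_single_cell_grid(self, fluid_bilayer):
        frame, _ = fluid_bilayer
        hf = build_height_field(frame, "lower", spacing=2 * frame.box.Lx)
        assert hf.shape == (1, 1)
        z_ref = frame.positions_by_bead(
            np.flatnonzero(frame.leaflet.astype(str) == "lower"), "PO4"
        )[:, 2].mean()
        assert hf.values[0, 0] == pytest.approx(z_ref, abs=1e-9)

    def test_oversampling_warns(self, fluid_bilayer):
        frame, _ = fluid_bilayer
        with pytest.warns(UserWarning, match="oversamples"):
            build_height_field(frame, "upper", spacing=0.1)


class TestMeanCurvature:
    def test_flat_field_zero(self):
        hf = _uniform_field(np.full((12, 12), 7.0))
        cf = mean_curvature_field(hf, fit_radius=2.5)
        assert np.all(np.abs(cf.values[cf.mask]) < 1e-8)

    def test_tilted_plane_zero_away_from_seam(self):
        """The full first-fundamental-form correction keeps any plane at
        H = 0; evaluated away from the periodic seam where the plane is
        discontinuous."""
        n = 24
        x = (np.arange(n) + 0.5) * 1.0
        vals = 0.35 * x[:, None] + 0.21 * x[None, :] + 2.0
        hf = _uniform_field(vals)
        cf = mean_curvature_field(hf, fit_radius=2.5)
        interior = cf.values[4 : n - 4, 4 : n - 4]
        assert np.all(np.abs(interior) < 1e-6)

    def test_undulation_crest_matches_analytic_value(self):
        """Crest curvature of the planted A=1, L=25 nm sinusoid (frame-
        averaged surface) within 5% of -A k^2 / 2 = -0.0316 /nm."""
        hf, truth = averaged_height_field(range(12))
        cf = mean_curvature_field(hf, fit_radius=2.5)
        k = 2 * math.pi / truth.wavelength
        x_crest = (math.pi / 2) / k
        x, _ = cf.cell_centers()
        sel = (
            np.abs(((x - x_crest + truth.wavelength / 2) % truth.wavelength)
                   - truth.wavelength / 2) < 0.55
        )
        got = np.nanmean(cf.values[sel][cf.mask[sel]])
        want = truth.analytic_curvature(np.array([x_crest]))[0]
        assert want == pytest.approx(-0.0316, abs=5e-5)
        assert got == pytest.approx(want, rel=0.05)

    def test_sphere_cap_closed_form(self):
        """Bead shell on a sphere of R = 10 nm: H = 1/R = 0.1 /nm at the
        cap (upward-opening cap, positive H in this convention)."""
        R, Lbox = 10.0, 12.0
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, Lbox, size=(4000, 2))
        d = xy - Lbox / 2
        r2 = d[:, 0] ** 2 + d[:, 1] ** 2
        keep = r2 < 16.0
        pos = np.column_stack([xy[keep], 5.0 + r2[keep] / (2 * R)])
        nx = ny = 12
        vals, mask = _bin_mean_z(pos, Lbox, Lbox, nx, ny)
        hf = HeightField(
            values=vals, mask=mask, spacing_x=Lbox / nx, spacing_y=Lbox / ny,
            Lx=Lbox, Ly=Lbox,
        )
        cf = mean_curvature_field(hf, fit_radius=2.0)
        x, y = cf.cell_centers()
        sel = [
            cf.values[i, j]
            for i in range(nx)
            for j in range(ny)
            if cf.mask[i, j]
            and (x[i] - Lbox / 2) ** 2 + (y[j] - Lbox / 2) ** 2 < 4.0
        ]
        assert np.mean(sel) == pytest.approx(0.1, rel=0.05)

    def test_z_translation_invariance_and_reflection_antisymmetry(self):
        hf, _ = averaged_height_field(range(3))
        cf = mean_curvature_field(hf, fit_radius=2.5)
        up = HeightField(
            values=hf.values + 11.0, mask=hf.mask, spacing_x=hf.spacing_x,
            spacing_y=hf.spacing_y, Lx=hf.Lx, Ly=hf.Ly,
        )
        cf_up = mean_curvature_field(up, fit_radius=2.5)
        assert np.allclose(cf_up.values[cf.mask], cf.values[cf.mask], atol=1e-9)
        flipped = HeightField(
            values=-hf.values, mask=hf.mask, spacing_x=hf.spacing_x,
            spacing_y=hf.spacing_y, Lx=hf.Lx, Ly=hf.Ly,
        )
        cf_fl = mean_curvature_field(flipped, fit_radius=2.5)
        assert np.allclose(cf_fl.values[cf.mask], -cf.values[cf.mask], atol=1e-9)


class TestThickness:
    def test_flat_symmetric_bilayer_constant(self, fluid_bilayer):
        frame, _ = fluid_bilayer
        tm = thickness_map(frame, spacing=2.0)
        v = tm.field.values[tm.field.mask]
        assert v.std() < 0.1
        up = tm.species_mean_heights.query("leaflet == 'upper'")["mean_z"].mean()
        lo = tm.species_mean_heights.query("leaflet == 'lower'")["mean_z"].mean()
        assert v.mean() == pytest.approx(up - lo, abs=0.05)

    def test_planted_gel_offset_recovered(self, gel_patch_frame):
        frame, truth = gel_patch_frame
        tm = thickness_map(frame, spacing=2.0)
        c = np.array([frame.box.Lx / 2, frame.box.Ly / 2])
        x, y = tm.field.cell_centers()
        patch, background = [], []
        r_patch = truth.extras["patch_radius"]
        for i in range(len(x)):
            for j in range(len(y)):
                if not tm.field.mask[i, j]:
                    continue
                r = math.hypot(x[i] - c[0], y[j] - c[1])
                if r < 0.7 * r_patch:
                    patch.append(tm.field.values[i, j])
                elif r > r_patch + 2.0:
                    background.append(tm.field.values[i, j])
        assert np.mean(patch) - np.mean(background) == pytest.approx(1.0, abs=0.1)

    def test_symmetric_undulation_cancels(self):
        frame, _ = sd.build_undulated_bilayer(
            n_lipids=2048, amplitude=1.5, wavelength=25.0, seed=31
        )
        tm = thickness_map(frame, spacing=2.0)
        v = tm.field.values[tm.field.mask]
        assert v.std() < 0.1  # undulation-thickness decoupling


def _mirror_pip2_across_leaflets(frame):
    """Move each lower-leaflet PI(4,5)P2 lipid to an upper one's xy."""
    out = frame.copy()
    pip2 = out.lipids_matching("PIP2")
    upper = [l for l in pip2 if str(out.leaflet[l]) == "upper"]
    lower = [l for l in pip2 if str(out.leaflet[l]) == "lower"]
    for lu, ll in zip(upper, lower):
        target = out.bead_position(int(lu), "PO4")[:2]
        anchor = out.bead_position(int(ll), "PO4")[:2]
        beads = out.beads_of_lipid(int(ll))
        out.positions[beads, :2] += target - anchor
    return out


class TestRegistration:
    def test_identical_patterns_fully_registered(self, clustered_bilayer):
        frame, _ = clustered_bilayer
        mirrored = _mirror_pip2_across_leaflets(frame)
        res = registration_coefficient(mirrored, "PIP2", spacing=2.0)
        assert res.coefficient == pytest.approx(1.0, abs=1e-12)

    def test_complementary_patterns_anti_registered(self, clustered_bilayer):
        frame, _ = clustered_bilayer
        out = frame.copy()
        rng = np.random.default_rng(5)
        pip2 = out.lipids_matching("PIP2")
        for l in pip2:
            beads = out.beads_of_lipid(int(l))
            cur = out.bead_position(int(l), "PO4")[0]
            if str(out.leaflet[l]) == "upper":
                new_x = rng.uniform(0.5, out.box.Lx / 2 - 0.5)
            else:
                new_x = rng.uniform(out.box.Lx / 2 + 0.5, out.box.Lx - 0.5)
            out.positions[beads, 0] += new_x - cur
        res = registration_coefficient(out, "PIP2", spacing=2.0)
        assert res.coefficient < 0

    def test_independent_patterns_null_distribution(self):
        """50 independently seeded frames: mean coefficient ~ 0 within
        3 standard deviations of the mean."""
        coeffs = []
        for seed in range(50):
            frame, _ = sd.build_fluid_bilayer(
                n_lipids=400, pip2_fraction=0.1, seed=2000 + seed
            )
            coeffs.append(
                registration_coefficient(frame, "PIP2", spacing=2.0).coefficient
            )
        coeffs = np.array(coeffs)
        assert abs(coeffs.mean()) < 3 * coeffs.std(ddof=1) / math.sqrt(len(coeffs))

    def test_symmetric_under_leaflet_exchange(self, clustered_bilayer):
        frame, _ = clustered_bilayer
        res = registration_coefficient(frame, "PIP2", spacing=2.0)
        flipped = frame.copy()
        mid = frame.box.Lz / 2
        flipped.positions[:, 2] = 2 * mid - flipped.positions[:, 2]
        flipped.leaflet = np.where(
            frame.leaflet.astype(str) == "upper", "lower", "upper"
        ).astype(object)
        res_fl = registration_coefficient(flipped, "PIP2", spacing=2.0)
        assert res_fl.coefficient == pytest.approx(res.coefficient, abs=1e-12)

    def test_joint_translation_invariance(self, clustered_bilayer):
        frame, _ = clustered_bilayer
        res = registration_coefficient(frame, "PIP2", spacing=2.0)
        moved = frame.copy()
        # translate by whole grid cells so binning shifts rigidly
        moved.positions[:, :2] += np.array([4.0, 6.0])
        res_mv = registration_coefficient(moved, "PIP2", spacing=2.0)
        assert res_mv.coefficient == pytest.approx(res.coefficient, abs=1e-9)

    def test_one_leaflet_system_rejected(self):
        frame, _ = sd.build_asymmetric_bilayer(n_lipids=400, seed=1)
        with pytest.raises(ValueError, match="one-leaflet"):
            registration_coefficient(frame, "PIP2")
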