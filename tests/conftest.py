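"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import pipnano as pn
from pipnano import synthetic_data as sd


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_force_min_image(p, q, box, in_plane=False):
    """Minimum distance over explicit enumeration of the 27 periodic images."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    L = np.array([box.Lx, box.Ly, box.Lz])
    best = np.inf
    for ix in (-1, 0, 1):
        for iy in (-1, 0, 1):
            for iz in (-1, 0, 1):
                shift = np.array([ix, iy, iz]) * L
                d = q + shift - p
                if in_plane:
                    d = d[:2]
                best = min(best, float(np.linalg.norm(d)))
    return best


def brute_force_clusters(frame, species="PIP2", cutoff=0.6,
                         bead_selection="headgroup", in_plane=True):
    """O(N^2) union-find over all selected bead pairs and periodic images.

    Written independently of the production path: explicit image
    enumeration, no KD-tree.
    """
    lipids = [int(l) for l in frame.lipids_matching(species)]
    bead_pos: list[np.ndarray] = []
    bead_owner: list[int] = []
    for k, lipid in enumerate(lipids):
        sp = str(frame.species[lipid])
        top = frame.topology[sp]
        names = (
            set(top.contact_beads)
            if bead_selection == "headgroup"
            else set(top.all_beads)
        )
        for b in frame.beads_of_lipid(lipid):
            if str(frame.bead_names[b]) in names:
                bead_pos.append(frame.positions[b])
                bead_owner.append(k)
    parent = list(range(len(lipids)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(len(bead_pos)):
        for j in range(i + 1, len(bead_pos)):
            oi, oj = bead_owner[i], bead_owner[j]
            if oi == oj:
                continue
            d = brute_force_min_image(
                bead_pos[i], bead_pos[j], frame.box, in_plane=in_plane
            )
            if d <= cutoff:
                ra, rb = find(oi), find(oj)
                if ra != rb:
                    parent[rb] = ra
    groups: dict[int, set[int]] = {}
    for k, lipid in enumerate(lipids):
        groups.setdefault(find(k), set()).add(lipid)
    return set(frozenset(g) for g in groups.values())


def straighten_chains(frame, lipids):
    """Rebuild the chains of the given lipids fully extended along z."""
    for lipid in lipids:
        lipid = int(lipid)
        top = frame.topology[str(frame.species[lipid])]
        sign = -1.0 if str(frame.leaflet[lipid]) == "upper" else 1.0
        for chain in top.chains:
            p0 = frame.bead_position(lipid, chain[0])
            for k, bead in enumerate(chain[1:], start=1):
                idx = np.flatnonzero(
                    (frame.lipid_index == lipid) & (frame.bead_names == bead)
                )[0]
                frame.positions[idx] = p0 + np.array([0.0, 0.0, sign * 0.47 * k])
    return frame


def averaged_height_field(seeds, amplitude=1.0, wavelength=25.0,
                          n_lipids=2048, leaflet="upper", spacing=1.0):
    """Height field averaged over independently seeded undulated frames.

    Mirrors how surfaces are averaged over trajectory frames before
    curvature estimation; the planted undulation is common to all frames.
    """
    from pipnano.surface_analysis import HeightField

    hfs = []
    truth = None
    for s in seeds:
        frame, truth = sd.build_undulated_bilayer(
            n_lipids=n_lipids, amplitude=amplitude, wavelength=wavelength, seed=s
        )
        hfs.append(pn.build_height_field(frame, leaflet, spacing=spacing))
    values = np.mean([h.values for h in hfs], axis=0)
    mask = np.all([h.mask for h in hfs], axis=0)
    hf = HeightField(
        values=values,
        mask=mask,
        spacing_x=hfs[0].spacing_x,
        spacing_y=hfs[0].spacing_y,
        Lx=hfs[0].Lx,
        Ly=hfs[0].Ly,
    )
    return hf, truth


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def fluid_bilayer():
    """Medium fluid bilayer, 10% PI(4,5)P2, default disorder."""
    frame, truth = sd.build_fluid_bilayer(
        n_lipids=900, pip2_fraction=0.1, seed=42
    )
    return frame, truth


@pytest.fixture(scope="session")
def clustered_bilayer():
    """Bilayer with planted clusters of sizes [30, 25, 20, 15]."""
    frame, _ = sd.build_fluid_bilayer(n_lipids=900, pip2_fraction=0.1, seed=7)
    return sd.plant_clusters(
        frame, [30, 25, 20, 15], intra_spacing=0.45, min_gap=1.5, seed=8
    )


@pytest.fixture(scope="session")
def gel_patch_frame():
    """512-lipid bilayer with a planted 127-chain hexagonal gel patch."""
    frame, _ = sd.build_fluid_bilayer(n_lipids=512, seed=5)
    return sd.build_gel_patch(
        frame, 127, lattice_spacing=0.48, thickness_increase=1.0, seed=6
    )
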