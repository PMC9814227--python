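"""Synthetic membrane configurations and fluorescence data with ground truth.

These generators emulate the statistical structure of the study systems —
POPC bilayers doped with PI(4,5)P2, cation-induced PI(4,5)P2 clusters,
hexagonally packed gel patches, undulating and asymmetric bilayers, TCSPC
photon histograms and anisotropy thermal scans — while planting exactly
known ground truth (cluster partitions, gel membership, analytic curvature,
decay components, melting midpoints) so every analysis stage can be tested
end to end without molecular dynamics or instruments.

The generators plant structure; they do not simulate it.  Chains are
geometric bead strings (0.47 nm bonds) whose orientational statistics are
controlled by a single ``chain_disorder`` dial: each successive bond's polar
cosine is drawn uniformly from ``[1 - 2*d, 1]``, giving exactly straight
chains at ``d = 0`` and isotropic bonds (first-bond order parameter 0) at
``d = 1``.  Every stochastic generator takes a seed and is reproducible
bit for bit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .membrane_model import (
    Box,
    DEFAULT_TOPOLOGIES,
    Frame,
    LipidTopology,
)
from .fluorescence_analysis import DecayHistogram, ThermalProfile

__all__ = [
    "GroundTruth",
    "build_fluid_bilayer",
    "plant_clusters",
    "build_gel_patch",
    "build_undulated_bilayer",
    "build_asymmetric_bilayer",
    "simulate_decay",
    "simulate_polarized_intensities",
    "simulate_thermal_profile",
    "expected_first_bond_s",
]

#: Martini-like bond length between consecutive chain beads (nm).
BOND_LENGTH = 0.47
#: Default fluid area per lipid (nm^2), POPC-like.
DEFAULT_APL = 0.64
#: Default gel lattice spacing per acyl chain (nm).
GEL_SPACING = 0.48


@dataclass
class GroundTruth:
    """Planted truth recorded by a generator.

    Only the fields relevant to the generator that produced it are set.
    """

    seed: int
    planted_partition: list[frozenset[int]] | None = None
    gel_membership: frozenset[int] | None = None
    gel_chain_count: int | None = None
    analytic_curvature: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None
    amplitude: float | None = None
    wavelength: float | None = None
    planted_decay: tuple[tuple[float, ...], tuple[float, ...]] | None = None
    planted_tm: float | None = None
    extras: dict = field(default_factory=dict)


def expected_first_bond_s(chain_disorder: float) -> float:
    """Closed-form first-bond order parameter implied by ``chain_disorder``.

    With bond polar cosine uniform on [1-2d, 1], <cos^2> = (1 + b + b^2)/3
    for b = 1-2d, so S = (3<cos^2> - 1)/2 = (b + b^2)/2.
    """
    b = 1.0 - 2.0 * chain_disorder
    return (b + b * b) / 2.0


# ---------------------------------------------------------------------------
# bilayer construction helpers
# ---------------------------------------------------------------------------

# Headgroup bead stacks: per-species vertical offsets (nm) above the PO4
# plane (positive = away from the bilayer midplane) and small lateral
# offsets.  Lateral offsets are kept below 0.05 nm so that headgroup-bead
# contact distances track the lipid lattice spacing closely.
_HEAD_STACKS: dict[str, list[tuple[str, float, float, float]]] = {}


def _head_stack(topology: LipidTopology) -> list[tuple[str, float, float, float]]:
    """(bead, dx, dy, dz) layout of non-chain beads relative to the PO4 site."""
    key = topology.species
    if key in _HEAD_STACKS:
        return _HEAD_STACKS[key]
    stack: list[tuple[str, float, float, float]] = []
    # headgroup beads stacked above PO4
    for k, bead in enumerate(topology.headgroup_beads):
        dx = 0.04 * math.cos(2.1 * k)
        dy = 0.04 * math.sin(2.1 * k)
        stack.append((bead, dx, dy, 0.30 + 0.12 * k))
    stack.append((topology.phosphodiester_bead, 0.0, 0.0, 0.0))
    # glycerol region below PO4
    if topology.anchor_bead not in {b for b, *_ in stack}:
        stack.append((topology.anchor_bead, 0.03, 0.0, -0.30))
    if "GL2" not in {b for b, *_ in stack} and topology.anchor_bead == "GL1":
        stack.append(("GL2", -0.03, 0.04, -0.35))
    _HEAD_STACKS[key] = stack
    return stack


def _max_chain_len(topology: LipidTopology) -> int:
    return max(len(c) for c in topology.chains)


def _grow_chain(
    rng: np.random.Generator,
    start: np.ndarray,
    n_beads: int,
    sign: float,
    disorder: float,
) -> np.ndarray:
    """Build a chain of beads descending toward the midplane.

    ``sign`` is -1 for the upper leaflet (chains grow toward -z) and +1 for
    the lower.  At ``disorder = 0`` every bond is exactly along the leaflet
    inward normal.
    """
    pos = np.empty((n_beads, 3))
    pos[0] = start
    for k in range(1, n_beads):
        if disorder <= 0:
            d = np.array([0.0, 0.0, sign])
        else:
            c = 1.0 - 2.0 * disorder * rng.random()  # cos(theta) ~ U[1-2d, 1]
            phi = rng.uniform(0.0, 2.0 * math.pi)
            s = math.sqrt(max(0.0, 1.0 - c * c))
            d = np.array([s * math.cos(phi), s * math.sin(phi), sign * c])
        pos[k] = pos[k - 1] + BOND_LENGTH * d
    return pos


def _leaflet_sites(
    rng: np.random.Generator, n: int, Lx: float, Ly: float, jitter: float
) -> np.ndarray:
    """n jittered sites on a square lattice tiling an Lx x Ly box."""
    n_side_x = int(math.ceil(math.sqrt(n * Lx / Ly)))
    n_side_y = int(math.ceil(n / n_side_x))
    sx, sy = Lx / n_side_x, Ly / n_side_y
    gx, gy = np.meshgrid(np.arange(n_side_x), np.arange(n_side_y), indexing="ij")
    sites = np.column_stack(
        [(gx.ravel() + 0.5) * sx, (gy.ravel() + 0.5) * sy]
    )[:n]
    sites += rng.normal(scale=jitter, size=sites.shape)
    return sites


def _assemble_frame(
    rng: np.random.Generator,
    box: Box,
    leaflet_plan: list[tuple[str, np.ndarray, str]],
    topology: dict[str, LipidTopology],
    chain_disorder: float,
    z_jitter: float = 0.05,
) -> Frame:
    """Build a Frame from (species, xy-site, leaflet) lipid plans.

    The PO4 plane of each leaflet is placed so the longest chain in the
    composition fits between the headgroup region and the midplane.
    """
    max_chain = max(
        _max_chain_len(topology[sp]) for sp, _, _ in leaflet_plan
    )
    half_height = 0.6 + BOND_LENGTH * (max_chain - 1) + 0.3
    z_mid = box.Lz / 2.0

    positions: list[np.ndarray] = []
    bead_names: list[str] = []
    lipid_index: list[int] = []
    species: list[str] = []
    leaflets: list[str] = []

    for lipid_id, (sp, site, leaflet) in enumerate(leaflet_plan):
        top = topology[sp]
        sign = -1.0 if leaflet == "upper" else 1.0  # chain growth direction
        z_po4 = z_mid - sign * half_height + rng.normal(scale=z_jitter)
        species.append(sp)
        leaflets.append(leaflet)
        for bead, dx, dy, dz in _head_stack(top):
            positions.append(
                np.array([site[0] + dx, site[1] + dy, z_po4 - sign * dz])
            )
            bead_names.append(bead)
            lipid_index.append(lipid_id)
        for ci, chain in enumerate(top.chains):
            start = np.array(
                [
                    site[0] + (0.12 if ci == 0 else -0.12),
                    site[1] + 0.05 * (ci - 0.5),
                    z_po4 + sign * 0.6,
                ]
            )
            chain_pos = _grow_chain(rng, start, len(chain), sign, chain_disorder)
            for bead, p in zip(chain, chain_pos):
                positions.append(p)
                bead_names.append(bead)
                lipid_index.append(lipid_id)

    return Frame(
        box=box,
        positions=np.array(positions),
        bead_names=np.array(bead_names, dtype=object),
        lipid_index=np.array(lipid_index, dtype=int),
        species=np.array(species, dtype=object),
        topology=topology,
        leaflet=np.array(leaflets, dtype=object),
    )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def build_fluid_bilayer(
    n_lipids: int = 900,
    pip2_fraction: float = 0.1,
    area_per_lipid: float = DEFAULT_APL,
    chain_disorder: float = 0.25,
    box_z: float = 13.0,
    seed: int = 0,
    pip2_species: str = "PIP2_160",
    site_jitter_fraction: float = 0.08,
    topology: dict[str, LipidTopology] | None = None,
) -> tuple[Frame, GroundTruth]:
    """Symmetric fluid POPC/PI(4,5)P2 bilayer on jittered lattices.

    Two mirrored leaflets of ``n_lipids/2`` lipids each are laid out on
    square lattices at the given area per lipid; species are assigned at
    random with exactly ``round(n_lipids * pip2_fraction)`` PI(4,5)P2
    lipids split evenly between leaflets, mutually dispersed (no planted
    clusters).  Chains are grown bead by bead toward the midplane with
    angular noise set by ``chain_disorder``.
    """
    if n_lipids % 2:
        raise ValueError("n_lipids must be even (two equal leaflets)")
    if not 0.0 <= pip2_fraction <= 1.0:
        raise ValueError("pip2_fraction must lie in [0, 1]")
    if area_per_lipid < 0.3:
        raise ValueError(
            f"area per lipid {area_per_lipid} nm^2 too small: lattice would overlap"
        )
    topology = dict(topology or DEFAULT_TOPOLOGIES)
    rng = np.random.default_rng(seed)

    n_leaf = n_lipids // 2
    L = math.sqrt(n_leaf * area_per_lipid)
    box = Box(L, L, box_z)
    spacing = math.sqrt(area_per_lipid)
    jitter = site_jitter_fraction * spacing

    n_pip2 = round(n_lipids * pip2_fraction)
    n_pip2_upper = n_pip2 // 2
    plan: list[tuple[str, np.ndarray, str]] = []
    for leaflet, n_p in (("upper", n_pip2_upper), ("lower", n_pip2 - n_pip2_upper)):
        sites = _leaflet_sites(rng, n_leaf, L, L, jitter)
        labels = np.array(
            [pip2_species] * n_p + ["POPC"] * (n_leaf - n_p), dtype=object
        )
        rng.shuffle(labels)
        plan.extend((str(sp), site, leaflet) for sp, site in zip(labels, sites))

    frame = _assemble_frame(rng, box, plan, topology, chain_disorder)
    truth = GroundTruth(
        seed=seed,
        extras={
            "pip2_species": pip2_species,
            "chain_disorder": chain_disorder,
            "expected_first_bond_s": expected_first_bond_s(chain_disorder),
            "area_per_lipid": area_per_lipid,
        },
    )
    return frame, truth


def _disk_sites(n: int, spacing: float) -> np.ndarray:
    """The n triangular-lattice points closest to the origin (compact disk)."""
    if n == 1:
        return np.zeros((1, 2))
    # generous lattice patch, then keep the n nearest sites
    m = int(math.ceil(math.sqrt(n))) + 3
    pts = []
    for i in range(-m, m + 1):
        for j in range(-m, m + 1):
            x = spacing * (i + 0.5 * j)
            y = spacing * (math.sqrt(3) / 2.0) * j
            pts.append((x * x + y * y, x, y))
    pts.sort()
    return np.array([(x, y) for _, x, y in pts[:n]])


def plant_clusters(
    frame: Frame,
    cluster_sizes: Sequence[int],
    intra_spacing: float = 0.45,
    min_gap: float = 1.5,
    seed: int = 0,
    species: str = "PIP2",
    max_tries: int = 20000,
) -> tuple[Frame, GroundTruth]:
    """Relocate the frame's PI(4,5)P2 lipids into compact disk clusters.

    Cluster members sit on a triangular lattice of pitch ``intra_spacing``;
    disks are separated edge to edge by at least ``min_gap``.  The planted
    partition (one lipid-index set per disk) is recorded and is exactly
    recoverable by cluster detection at any cutoff between the intra-cluster
    spacing and the gap.
    """
    out = frame.copy()
    lipids = out.lipids_matching(species)
    sizes = [int(s) for s in cluster_sizes]
    if any(s < 1 for s in sizes):
        raise ValueError("cluster sizes must be positive")
    if sum(sizes) != len(lipids):
        raise ValueError(
            f"cluster sizes sum to {sum(sizes)} but frame has {len(lipids)} "
            f"{species} lipids"
        )
    rng = np.random.default_rng(seed)
    box = out.box

    disks = [_disk_sites(s, intra_spacing) for s in sizes]
    radii = [float(np.max(np.linalg.norm(d, axis=1))) if len(d) > 1 else 0.0 for d in disks]

    centers: list[np.ndarray] = []
    for ci, r_new in enumerate(radii):
        placed = False
        for _ in range(max_tries):
            c = rng.uniform([0.0, 0.0], [box.Lx, box.Ly])
            ok = True
            for cj, r_old in zip(centers, radii):
                d = c - cj
                d -= np.array([box.Lx, box.Ly]) * np.round(d / [box.Lx, box.Ly])
                if float(np.hypot(*d)) < r_new + r_old + min_gap:
                    ok = False
                    break
            if ok:
                centers.append(c)
                placed = True
                break
        if not placed:
            raise ValueError(
                f"box {box.Lx:.1f}x{box.Ly:.1f} nm too small to place "
                f"{len(sizes)} clusters with min_gap={min_gap} nm"
            )

    # assign lipids to clusters and rigidly translate them in-plane
    order = rng.permutation(lipids)
    partition: list[frozenset[int]] = []
    pos = 0
    for disk, center in zip(disks, centers):
        members = order[pos : pos + len(disk)]
        pos += len(disk)
        partition.append(frozenset(int(m) for m in members))
        for site, lipid in zip(disk, members):
            sp = str(out.species[lipid])
            anchor = out.bead_position(lipid, out.topology[sp].phosphodiester_bead)
            shift = np.array([center[0] + site[0] - anchor[0],
                              center[1] + site[1] - anchor[1], 0.0])
            beads = out.beads_of_lipid(int(lipid))
            out.positions[beads] += shift

    truth = GroundTruth(seed=seed, planted_partition=partition)
    return out, truth


def build_gel_patch(
    frame: Frame,
    patch_chain_count: int,
    lattice_spacing: float = GEL_SPACING,
    thickness_increase: float = 1.0,
    seed: int = 0,
    leaflet: str = "upper",
    clear_margin: float = 0.8,
) -> tuple[Frame, GroundTruth]:
    """Plant a contiguous hexagonally packed gel patch of straight chains.

    ``patch_chain_count`` chain sites are taken as the compact triangular-
    lattice disk of pitch ``lattice_spacing`` centred in the box.  Whole
    lipids of the chosen leaflet are recruited (two chains each, on adjacent
    sites); their chains are rebuilt fully extended and the entire lipid is
    raised by ``thickness_increase`` nm, emulating the height offset of a
    gel phase over the fluid background.  Fluid lipids of the same leaflet
    whose chains would intrude within ``clear_margin`` of the patch are
    relocated outside it.
    """
    if lattice_spacing <= 0:
        raise ValueError("lattice spacing must be positive")
    if patch_chain_count < 1:
        raise ValueError("patch must contain at least one chain")
    out = frame.copy()
    rng = np.random.default_rng(seed)
    box = out.box
    center = np.array([box.Lx / 2.0, box.Ly / 2.0])

    sites = _disk_sites(patch_chain_count, lattice_spacing) + center
    patch_radius = float(
        np.max(np.linalg.norm(sites - center, axis=1))
    ) if patch_chain_count > 1 else 0.0
    if patch_radius * 2 + 2 * clear_margin > min(box.Lx, box.Ly):
        raise ValueError("gel patch does not fit in the box")

    leaf_lipids = np.flatnonzero(out.leaflet.astype(str) == leaflet)
    if len(leaf_lipids) == 0:
        raise ValueError(f"no lipids in leaflet {leaflet!r}")
    n_gel_lipids = math.ceil(patch_chain_count / 2)
    if n_gel_lipids > len(leaf_lipids):
        raise ValueError("not enough lipids in leaflet to build the patch")

    # recruit the lipids nearest the patch centre (minimum image)
    anchors = np.empty((len(leaf_lipids), 2))
    for k, lipid in enumerate(leaf_lipids):
        sp = str(out.species[lipid])
        anchors[k] = out.bead_position(int(lipid), out.topology[sp].phosphodiester_bead)[:2]
    d = anchors - center
    d -= np.array([box.Lx, box.Ly]) * np.round(d / [box.Lx, box.Ly])
    nearest = leaf_lipids[np.argsort(np.hypot(d[:, 0], d[:, 1]))]
    gel_lipids = [int(l) for l in nearest[:n_gel_lipids]]

    sign = -1.0 if leaflet == "upper" else 1.0
    z_mid = box.Lz / 2.0

    site_iter = iter(range(patch_chain_count))
    parked = center + np.array([patch_radius + clear_margin + 2.0, 0.0])
    for lipid in gel_lipids:
        sp = str(out.species[lipid])
        top = out.topology[sp]
        max_chain = _max_chain_len(top)
        half_height = 0.6 + BOND_LENGTH * (max_chain - 1) + 0.3
        z_po4 = z_mid - sign * half_height + sign * 0  # deterministic plane
        chain_sites: list[np.ndarray] = []
        for _ in top.chains:
            try:
                chain_sites.append(sites[next(site_iter)])
            except StopIteration:
                chain_sites.append(parked)  # odd leftover chain, far from patch
        head_site = np.mean(chain_sites, axis=0)
        beads = out.beads_of_lipid(lipid)
        # rebuild the whole lipid deterministically: straight vertical chains
        by_name = {str(out.bead_names[b]): b for b in beads}
        for bead, dx, dy, dz in _head_stack(top):
            if bead in by_name:
                out.positions[by_name[bead]] = np.array(
                    [head_site[0] + dx, head_site[1] + dy, z_po4 - sign * dz]
                )
        for ci, chain in enumerate(top.chains):
            site = chain_sites[ci] if ci < len(chain_sites) else parked
            for k, bead in enumerate(chain):
                if bead in by_name:
                    out.positions[by_name[bead]] = np.array(
                        [site[0], site[1], z_po4 + sign * (0.6 + BOND_LENGTH * k)]
                    )
        out.positions[beads, 2] += thickness_increase

    # push intruding fluid chains of the same leaflet out of the patch area
    keepout = patch_radius + clear_margin
    gel_set = set(gel_lipids)
    for lipid in leaf_lipids:
        lipid = int(lipid)
        if lipid in gel_set:
            continue
        beads = out.beads_of_lipid(lipid)
        xy = out.positions[beads, :2]
        d = xy - center
        d -= np.array([box.Lx, box.Ly]) * np.round(d / [box.Lx, box.Ly])
        if np.min(np.hypot(d[:, 0], d[:, 1])) < keepout + 0.2:
            for _ in range(1000):
                c = rng.uniform([0.0, 0.0], [box.Lx, box.Ly])
                dc = c - center
                dc -= np.array([box.Lx, box.Ly]) * np.round(dc / [box.Lx, box.Ly])
                if np.hypot(*dc) > keepout + 1.8:
                    break
            else:
                raise ValueError("cannot relocate fluid lipids outside gel patch")
            anchor = out.positions[beads, :2].mean(axis=0)
            out.positions[beads, :2] += c - anchor

    truth = GroundTruth(
        seed=seed,
        gel_membership=frozenset(gel_lipids),
        gel_chain_count=patch_chain_count,
        extras={
            "lattice_spacing": lattice_spacing,
            "thickness_increase": thickness_increase,
            "leaflet": leaflet,
            "patch_radius": patch_radius,
        },
    )
    return out, truth


def build_undulated_bilayer(
    n_lipids: int = 900,
    amplitude: float = 1.0,
    wavelength: float = 25.0,
    pip2_fraction: float = 0.1,
    area_per_lipid: float = DEFAULT_APL,
    chain_disorder: float = 0.25,
    box_z: float = 13.0,
    seed: int = 0,
    **kwargs,
) -> tuple[Frame, GroundTruth]:
    """Bilayer with a planted sinusoidal undulation of analytic curvature.

    Both leaflets are displaced by ``z -> z + A sin(2 pi x / L)``.  So that
    the undulation is periodic at exactly the requested wavelength, the box
    edge is set to an integer number of wavelengths and the area per lipid
    adjusted by the (few-permille) amount needed to fit ``n_lipids/2``
    sites.  The recorded analytic mean-curvature field is::

        H(x) = -A k^2 sin(kx) / (2 (1 + (A k cos(kx))^2)^(3/2)),  k = 2 pi / L

    i.e. the standard upward-normal Monge convention in which a crest (a
    local bump toward +z) has negative H and a trough positive H.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if amplitude >= box_z / 4.0:
        raise ValueError("amplitude must be below a quarter of the box height")
    target_L = math.sqrt((n_lipids // 2) * area_per_lipid)
    if wavelength > target_L * 1.5:
        raise ValueError("wavelength must not exceed the box edge")
    n_waves = max(1, round(target_L / wavelength))
    Lx = n_waves * wavelength
    frame, truth = build_fluid_bilayer(
        n_lipids=n_lipids,
        pip2_fraction=pip2_fraction,
        area_per_lipid=Lx * Lx / (n_lipids // 2),
        chain_disorder=chain_disorder,
        box_z=box_z,
        seed=seed,
        **kwargs,
    )
    L_eff = wavelength
    k = 2.0 * math.pi / L_eff
    frame.positions[:, 2] += amplitude * np.sin(k * frame.positions[:, 0])

    A = amplitude

    def H(x: np.ndarray, y: np.ndarray | None = None) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        num = -A * k * k * np.sin(k * x)
        den = 2.0 * (1.0 + (A * k * np.cos(k * x)) ** 2) ** 1.5
        return num / den

    truth.analytic_curvature = H
    truth.amplitude = A
    truth.wavelength = L_eff
    return frame, truth


def build_asymmetric_bilayer(
    n_lipids: int = 900,
    pip2_fraction: float = 0.1,
    area_per_lipid: float = DEFAULT_APL,
    pip2_area_per_lipid: float = 0.70,
    chain_disorder: float = 0.25,
    box_z: float = 13.0,
    seed: int = 0,
    pip2_species: str = "PIP2_160",
    site_jitter_fraction: float = 0.08,
    topology: dict[str, LipidTopology] | None = None,
) -> tuple[Frame, GroundTruth]:
    """Asymmetric bilayer: PI(4,5)P2 in the lower leaflet only.

    The lower leaflet holds ``n_lipids/2`` lipids at ``pip2_fraction``
    PI(4,5)P2; the upper leaflet is pure POPC with its lipid count adjusted
    so the two leaflet areas (per-species area-per-lipid times count) match,
    avoiding planted tension.
    """
    if n_lipids % 2:
        raise ValueError("n_lipids must be even")
    if not 0.0 <= pip2_fraction <= 1.0:
        raise ValueError("pip2_fraction must lie in [0, 1]")
    topology = dict(topology or DEFAULT_TOPOLOGIES)
    rng = np.random.default_rng(seed)

    n_lower = n_lipids // 2
    n_pip2 = round(n_lower * pip2_fraction)
    lower_area = (n_lower - n_pip2) * area_per_lipid + n_pip2 * pip2_area_per_lipid
    n_upper = round(lower_area / area_per_lipid)
    L = math.sqrt(lower_area)
    box = Box(L, L, box_z)
    jitter = site_jitter_fraction * math.sqrt(area_per_lipid)

    plan: list[tuple[str, np.ndarray, str]] = []
    upper_sites = _leaflet_sites(rng, n_upper, L, L, jitter)
    plan.extend(("POPC", s, "upper") for s in upper_sites)
    lower_sites = _leaflet_sites(rng, n_lower, L, L, jitter)
    labels = np.array(
        [pip2_species] * n_pip2 + ["POPC"] * (n_lower - n_pip2), dtype=object
    )
    rng.shuffle(labels)
    plan.extend((str(sp), s, "lower") for sp, s in zip(labels, lower_sites))

    frame = _assemble_frame(rng, box, plan, topology, chain_disorder)
    upper_area = n_upper * area_per_lipid
    truth = GroundTruth(
        seed=seed,
        extras={
            "n_upper": n_upper,
            "n_lower": n_lower,
            "n_pip2_lower": n_pip2,
            "upper_area": upper_area,
            "lower_area": lower_area,
            "area_mismatch": abs(upper_area - lower_area) / lower_area,
        },
    )
    return frame, truth


# ---------------------------------------------------------------------------
# fluorescence data generators
# ---------------------------------------------------------------------------


def simulate_decay(
    alphas: Sequence[float],
    taus: Sequence[float],
    n_photons: float = 1e6,
    n_channels: int = 4096,
    channel_width: float = 0.0122,
    seed: int = 0,
    noise: bool = True,
) -> tuple[DecayHistogram, GroundTruth]:
    """Synthetic TCSPC histogram for a sum-of-exponentials decay.

    Expected counts per channel are proportional to the channel integral of
    ``i(t) = sum alpha_i exp(-t/tau_i)`` normalized over the acquisition
    window, times ``n_photons``; with ``noise=True`` each channel is drawn
    Poisson (total counts ~ n_photons).  With ``noise=False`` the exact
    expected counts are returned (diagnostic mode).  A window shorter than
    three times the longest lifetime sets the histogram's ``truncated``
    flag and emits a warning.
    """
    a = np.asarray(alphas, dtype=float)
    t = np.asarray(taus, dtype=float)
    if len(a) != len(t) or len(a) == 0:
        raise ValueError("alphas and taus must have equal nonzero length")
    if abs(a.sum() - 1.0) > 1e-9:
        raise ValueError("alphas must sum to 1")
    if np.any(t <= 0):
        raise ValueError("lifetimes must be positive")
    window = n_channels * channel_width
    truncated = window < 3.0 * t.max()
    if truncated:
        warnings.warn(
            f"acquisition window {window:.3g} ns < 3x the longest lifetime "
            f"{t.max():.3g} ns; decay is truncated",
            stacklevel=2,
        )

    t0 = np.arange(n_channels) * channel_width
    q = np.zeros(n_channels)
    for ai, ti in zip(a, t):
        q += ai * ti * (np.exp(-t0 / ti) - np.exp(-(t0 + channel_width) / ti))
    expected = n_photons * q / q.sum()

    if noise:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    hist = DecayHistogram(
        channel_width=channel_width, counts=counts, truncated=truncated
    )
    truth = GroundTruth(
        seed=seed, planted_decay=(tuple(a.tolist()), tuple(t.tolist()))
    )
    return hist, truth


def simulate_polarized_intensities(
    r_true: float, total_intensity: float = 1e6, G: float = 1.0
):
    """Polarized intensities whose anisotropy is exactly ``r_true``.

    Inverts ``r = (IVV - G*IVH)/(IVV + 2*G*IVH)`` at the given total
    intensity ``IVV + 2*G*IVH``; the horizontal-excitation pair satisfies
    ``IHV/IHH = G``.
    """
    from .fluorescence_analysis import PolarizedIntensities

    if not -0.5 <= r_true <= 1.0:
        raise ValueError("r_true must lie in [-0.5, 1.0]")
    if G <= 0:
        raise ValueError("G must be positive")
    if total_intensity <= 0:
        raise ValueError("total intensity must be positive")
    ivv = total_intensity * (1.0 + 2.0 * r_true) / 3.0
    ivh = total_intensity * (1.0 - r_true) / (3.0 * G)
    ihh = total_intensity / 4.0
    return PolarizedIntensities(IVV=ivv, IVH=ivh, IHV=G * ihh, IHH=ihh)


def simulate_thermal_profile(
    r_low: float = 0.06,
    r_high: float = 0.28,
    tm: float = 45.0,
    width: float = 2.0,
    temperatures: Sequence[float] | None = None,
    noise_sd: float = 0.002,
    seed: int = 0,
) -> tuple[ThermalProfile, GroundTruth]:
    """Sigmoidal anisotropy thermal scan with a planted midpoint.

    ``r(T) = r_low + (r_high - r_low)/(1 + exp((T - Tm)/width))`` plus
    Gaussian noise; the planted Tm is recorded.  Defaults emulate a
    gel-to-fluid melting profile with a 45 degC midpoint sampled every
    2 degC.
    """
    if r_high <= r_low:
        raise ValueError("r_high must exceed r_low")
    if width <= 0:
        raise ValueError("width must be positive")
    if temperatures is None:
        temperatures = np.arange(25.0, 66.0, 2.0)
    T = np.asarray(temperatures, dtype=float)
    if len(T) < 6:
        raise ValueError("need at least 6 temperature points")
    rng = np.random.default_rng(seed)
    r = r_low + (r_high - r_low) / (1.0 + np.exp((T - tm) / width))
    if noise_sd > 0:
        r = r + rng.normal(scale=noise_sd, size=r.shape)
    profile = ThermalProfile(temperatures=T, anisotropies=r)
    truth = GroundTruth(seed=seed, planted_tm=tm)
    return profile, truth
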