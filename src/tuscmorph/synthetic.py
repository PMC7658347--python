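"""Synthetic two-spoke assemblies and noisy maps with known ground truth.

The generator emulates, at toy scale, a Y-shaped two-spoke γ-tubulin small
complex: each spoke is three rigid blocks (GRIP1, GRIP2, γ-body) of ideal
poly-alanine α-helices, and a conformational transition tilts the second
spoke's GRIP2+γ block toward the first spoke by a known angle — the kind of
rigid inter-segment motion the segment-wise comparison pipeline is built to
measure.  Because the applied transform is known exactly, expected
per-segment displacements are available analytically, so every pipeline
stage can be verified without downloading any deposited structure or map.

All randomness (coordinate noise, map noise, sequence mutations) flows from
the seed in the parameter object; identical parameters give bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .densitymaps import DensityMap, SimulationParams, simulate_density
from .structures import Atom, AtomSubset, Chain, Residue, SegmentSpec, Structure
from .superpose import RigidTransform

__all__ = ["ToySpokeParams", "ToyPair", "make_toy_pair", "make_toy_map", "ideal_helix_ca"]

#: Ideal α-helix geometry: rise per residue and twist, Cα radius.
HELIX_RISE = 1.5  # Å
HELIX_TWIST_DEG = 100.0
HELIX_RADIUS = 2.3  # Å

STANDARD_AA_POOL = [
    "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE", "LEU",
    "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]

SEGMENT_NAMES = [
    "Spc97-GRIP1", "Spc97-GRIP2", "gamma-Spc97",
    "Spc98-GRIP1", "Spc98-GRIP2", "gamma-Spc98",
]

#: Anchor = the whole first spoke, mirroring re-anchoring on the Spc97 spoke.
ANCHOR_SEGMENTS = ["Spc97-GRIP1", "Spc97-GRIP2", "gamma-Spc97"]


@dataclass
class ToySpokeParams:
    n_helices_per_domain: int = 3
    helix_length: int = 20  # residues per helix
    tilt_angle: float = 15.0  # degrees, spoke-2 GRIP2+γ block between states
    coordinate_noise_sigma: float = 0.0  # Å, i.i.d. per coordinate, second state only
    mutation_fraction: float = 0.0  # fraction of residues renamed in the second state
    spread_angle: float = 20.0  # degrees each spoke leans away from vertical
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tilt_angle <= 60.0:
            raise ValueError("tilt_angle must be within [0, 60] degrees")
        if self.coordinate_noise_sigma < 0:
            raise ValueError("coordinate_noise_sigma must be >= 0")
        if not 0.0 <= self.mutation_fraction <= 1.0:
            raise ValueError("mutation_fraction must be in [0, 1]")
        if self.n_helices_per_domain < 1 or self.helix_length < 4:
            raise ValueError("need >= 1 helix of >= 4 residues per domain")


@dataclass
class ToyPair:
    state_open: Structure
    state_closed: Structure
    ground_truth: dict[str, RigidTransform]
    expected_rmsd: dict[str, float]
    params: ToySpokeParams
    segment_ranges: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def segment_specs(self, atom_subset: AtomSubset = AtomSubset.CA_ONLY) -> list[tuple[SegmentSpec, SegmentSpec]]:
        out = []
        for name in SEGMENT_NAMES:
            chain, lo, hi = self.segment_ranges[name]
            spec = SegmentSpec(name, [(chain, lo, hi)], atom_subset)
            out.append((spec, spec))
        return out

    def spec(self, name: str, atom_subset: AtomSubset = AtomSubset.CA_ONLY) -> SegmentSpec:
        chain, lo, hi = self.segment_ranges[name]
        return SegmentSpec(name, [(chain, lo, hi)], atom_subset)

    @property
    def anchor(self) -> list[str]:
        return list(ANCHOR_SEGMENTS)


def ideal_helix_ca(n_res: int, start: np.ndarray = None) -> np.ndarray:
    """Cα trace of an ideal α-helix along +z (rise 1.5 Å, twist 100°)."""
    i = np.arange(n_res)
    theta = np.radians(HELIX_TWIST_DEG) * i
    xyz = np.stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * i],
        axis=1,
    )
    if start is not None:
        xyz = xyz + np.asarray(start, dtype=float)
    return xyz


def _block_ca(p: ToySpokeParams) -> np.ndarray:
    """One rigid block: n parallel ideal helices, centred in x/y."""
    cols = []
    for h in range(p.n_helices_per_domain):
        offset = np.array([8.0 * h, 4.0 * (h % 2), 0.0])
        cols.append(ideal_helix_ca(p.helix_length, offset))
    block = np.vstack(cols)
    block[:, :2] -= block[:, :2].mean(axis=0)
    return block


def _rot_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _make_chain(chain_id: str, coords: np.ndarray, names: list[str], start_resnum: int = 1) -> Chain:
    residues = [
        Residue(
            name=names[i],
            seq_number=start_resnum + i,
            atoms=[Atom("CA", "C", coords[i].copy())],
        )
        for i in range(len(coords))
    ]
    return Chain(chain_id, residues)


def make_toy_pair(p: ToySpokeParams) -> ToyPair:
    """Build two conformational states of a toy two-spoke assembly.

    State 'open' is the reference geometry; state 'closed' applies a rigid
    tilt of the second spoke's GRIP2+γ block about the spoke-2 GRIP1/GRIP2
    junction (axis normal to the two-spoke plane, rotating the block toward
    spoke 1), then adds seeded Gaussian coordinate noise.  The returned
    ground truth carries the exact per-segment transforms and the expected
    per-segment Cα RMSD obtained by applying those transforms directly.
    """
    rng = np.random.default_rng(p.seed)
    block = _block_ca(p)
    block_h = p.helix_length * HELIX_RISE
    gap = 6.0
    levels = {"GRIP1": 0.0, "GRIP2": block_h + gap, "gamma": 2 * (block_h + gap)}

    spokes = {
        "Spc97": {"lean": -p.spread_angle, "base": np.array([-8.0, 0.0, 0.0])},
        "Spc98": {"lean": +p.spread_angle, "base": np.array([+8.0, 0.0, 0.0])},
    }

    def place(spoke: str, level: float) -> np.ndarray:
        r = _rot_y(spokes[spoke]["lean"])
        return block @ r.T + spokes[spoke]["base"] + r @ np.array([0.0, 0.0, level])

    # open-state coordinates per segment
    open_coords = {
        "Spc97-GRIP1": place("Spc97", levels["GRIP1"]),
        "Spc97-GRIP2": place("Spc97", levels["GRIP2"]),
        "gamma-Spc97": place("Spc97", levels["gamma"]),
        "Spc98-GRIP1": place("Spc98", levels["GRIP1"]),
        "Spc98-GRIP2": place("Spc98", levels["GRIP2"]),
        "gamma-Spc98": place("Spc98", levels["gamma"]),
    }

    # ground-truth tilt of spoke-2 GRIP2+γ about the GRIP1/GRIP2 junction;
    # negative rotation about y leans the block back toward spoke 1
    r98 = _rot_y(spokes["Spc98"]["lean"])
    pivot = spokes["Spc98"]["base"] + r98 @ np.array([0.0, 0.0, levels["GRIP2"]])
    rot = _rot_y(-p.tilt_angle)
    tilt = RigidTransform(rot, pivot - rot @ pivot)
    identity = RigidTransform.identity()
    ground_truth = {
        name: (tilt if name in ("Spc98-GRIP2", "gamma-Spc98") else identity)
        for name in SEGMENT_NAMES
    }

    closed_coords = {name: ground_truth[name].apply(c) for name, c in open_coords.items()}
    expected_rmsd = {
        name: float(np.sqrt(np.mean(np.sum((closed_coords[name] - open_coords[name]) ** 2, axis=1))))
        for name in SEGMENT_NAMES
    }
    if p.coordinate_noise_sigma > 0:
        closed_coords = {
            name: c + rng.normal(0.0, p.coordinate_noise_sigma, size=c.shape)
            for name, c in closed_coords.items()
        }

    # chains: A = Spc97 GRIP1+GRIP2, B = γ(Spc97), C = Spc98 GRIP1+GRIP2, D = γ(Spc98)
    n_block = len(block)
    layout = [
        ("A", ["Spc97-GRIP1", "Spc97-GRIP2"]),
        ("B", ["gamma-Spc97"]),
        ("C", ["Spc98-GRIP1", "Spc98-GRIP2"]),
        ("D", ["gamma-Spc98"]),
    ]
    names_open = ["ALA"] * n_block
    segment_ranges: dict[str, tuple[str, int, int]] = {}

    def build(coords_by_seg: dict[str, np.ndarray], mutate: bool, label: str) -> Structure:
        chains = []
        for chain_id, segs in layout:
            resnum = 1
            chain_res: list[Residue] = []
            for seg in segs:
                coords = coords_by_seg[seg]
                names = list(names_open)
                if mutate and p.mutation_fraction > 0:
                    n_mut = int(round(p.mutation_fraction * n_block))
                    idx = rng.choice(n_block, size=n_mut, replace=False)
                    for i in idx:
                        names[i] = STANDARD_AA_POOL[rng.integers(len(STANDARD_AA_POOL))]
                segment_ranges[seg] = (chain_id, resnum, resnum + n_block - 1)
                for i in range(n_block):
                    chain_res.append(
                        Residue(names[i], resnum + i, atoms=[Atom("CA", "C", coords[i].copy())])
                    )
                resnum += n_block
            chains.append(Chain(chain_id, chain_res))
        return Structure(label, chains)

    state_open = build(open_coords, mutate=False, label="toy-open")
    state_closed = build(closed_coords, mutate=True, label="toy-closed")
    return ToyPair(
        state_open=state_open,
        state_closed=state_closed,
        ground_truth=ground_truth,
        expected_rmsd=expected_rmsd,
        params=p,
        segment_ranges=segment_ranges,
    )


def make_toy_map(
    s: Structure,
    resolution: float,
    voxel: float,
    noise_sigma: float = 0.0,
    seed: int = 0,
    params: SimulationParams | None = None,
) -> DensityMap:
    """Simulate a density map from a structure and add seeded voxel noise."""
    p = params or SimulationParams(resolution=resolution)
    m = simulate_density(s, p, voxel)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        m = DensityMap(
            m.values + rng.normal(0.0, noise_sigma, size=m.values.shape),
            m.voxel_size,
            m.origin.copy(),
        )
    return m
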