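"""Synthetic fixtures with known ground truth for every pipeline stage.

Three families of generators:

* planted-correlation bead trajectories -- each chain is a line of
  C-alpha-labelled beads; residues in the same "block" share a latent 1-D
  fluctuation, so the correlation matrix and the contact adjacency are both
  known in closed form;
* toy membrane slabs -- pseudo-lipid lattices (P / choline N / tail carbons,
  POPC atom naming) around a Tyr-like probe at a controlled depth, with
  zero-jitter ground-truth interaction counts computed by construction;
* synthetic electrophysiology -- tail-current sweep families from a
  Boltzmann open probability and G-V points from the Horrigan-Aldrich
  model, with Gaussian noise and known underlying parameters.

Every generator is deterministic under a fixed seed and can write its ground
truth to a JSON sidecar.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .ephys import GVCurve, SweepProtocol, SweepRecording, boltzmann
from .hamodel import HAParameters, ha_po, ha_v_half
from .traj import Topology, Trajectory

__all__ = [
    "PlantedSpec",
    "ToyMembraneSpec",
    "gen_corr_traj",
    "gen_membrane_toy",
    "gen_current_traces",
    "gen_ha_gv",
]


# ---------------------------------------------------------------------------
# planted-correlation trajectories
# ---------------------------------------------------------------------------

@dataclass
class PlantedSpec:
    """Planted block-correlation trajectory specification.

    Chains are straight bead strings along x, spaced ``chain_gap`` apart in
    y, one bead per residue every ``spacing`` A. Bead i moves as

        r_i(t) = r_i0 + a_i * s_g(i)(t) * u_hat + eps_i(t)

    with one latent Gaussian series s_g per block (sd ``latent_sd``), shared
    displacement direction u_hat = z (perpendicular to the chain axis so the
    planted contacts are minimally disturbed), and isotropic private noise of
    TOTAL 3-D standard deviation ``noise_sd`` (per-axis sd noise_sd/sqrt(3)).
    With that convention the correlation of same-block pairs is exactly

        C_ij = a_i a_j s^2 / sqrt((a_i^2 s^2 + n_i^2)(a_j^2 s^2 + n_j^2)),

    s = latent_sd, n_i = noise_sd, and 0 for pairs in different blocks.
    Contacts are planted geometrically: sequence-adjacent beads sit within
    ``spacing`` <= cutoff, and chains are separated by more than the cutoff.
    """

    n_chains: int = 1
    n_residues: int = 20
    blocks: list[list[tuple[str, int]]] = field(default_factory=list)
    amplitude: float = 1.0
    latent_sd: float = 0.5
    noise_sd: float = 0.3
    spacing: float = 3.8
    chain_gap: float = 20.0
    n_frames: int = 1000
    dt_ns: float = 0.05
    seed: int = 0

    def chain_ids(self) -> list[str]:
        return [chr(ord("A") + c) for c in range(self.n_chains)]

    def node_ids(self) -> list[tuple[str, int]]:
        return [(c, r) for c in self.chain_ids() for r in range(1, self.n_residues + 1)]

    def default_blocks(self) -> list[list[tuple[str, int]]]:
        if self.blocks:
            return self.blocks
        # one block per chain half
        out = []
        half = self.n_residues // 2
        for c in self.chain_ids():
            out.append([(c, r) for r in range(1, half + 1)])
            out.append([(c, r) for r in range(half + 1, self.n_residues + 1)])
        return out


def planted_correlation(spec: PlantedSpec) -> np.ndarray:
    """Closed-form correlation matrix implied by the planted spec."""
    nodes = spec.node_ids()
    block_of = {}
    for b, members in enumerate(spec.default_blocks()):
        for node in members:
            block_of[node] = b
    n = len(nodes)
    a, s2, n2 = spec.amplitude, spec.latent_sd ** 2, spec.noise_sd ** 2
    same = a * a * s2 / (a * a * s2 + n2)
    C = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if block_of.get(nodes[i]) is not None and \
               block_of.get(nodes[i]) == block_of.get(nodes[j]):
                C[i, j] = C[j, i] = same
    return C


def planted_adjacency(spec: PlantedSpec, cutoff: float = 4.5
                      ) -> set[tuple[tuple[str, int], tuple[str, int]]]:
    """Residue pairs whose rest-position distance is within ``cutoff``."""
    nodes = spec.node_ids()
    pos = {node: _rest_position(spec, node) for node in nodes}
    out = set()
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            if np.linalg.norm(pos[a] - pos[b]) <= cutoff:
                out.add((a, b))
    return out


def _rest_position(spec: PlantedSpec, node: tuple[str, int]) -> np.ndarray:
    chain_index = spec.chain_ids().index(node[0])
    return np.array([(node[1] - 1) * spec.spacing, chain_index * spec.chain_gap, 0.0])


def gen_corr_traj(spec: PlantedSpec) -> tuple[Trajectory, np.ndarray,
                                              set[tuple[tuple[str, int], tuple[str, int]]]]:
    """Bead trajectory with planted block correlations.

    Returns (trajectory, analytic correlation matrix, planted adjacency).
    Bit-reproducible under ``spec.seed``.
    """
    if spec.latent_sd <= 0 and spec.noise_sd <= 0:
        raise ValueError("spec has zero total variance")
    rng = np.random.default_rng(spec.seed)
    nodes = spec.node_ids()
    blocks = spec.default_blocks()
    block_of = {}
    for b, members in enumerate(blocks):
        for node in members:
            if node in block_of:
                raise ValueError(f"residue {node} assigned to two blocks")
            block_of[node] = b
    n = len(nodes)
    rest = np.stack([_rest_position(spec, node) for node in nodes])
    latent = rng.normal(0.0, spec.latent_sd, size=(spec.n_frames, len(blocks)))
    noise = rng.normal(0.0, spec.noise_sd / np.sqrt(3.0),
                       size=(spec.n_frames, n, 3))
    u_hat = np.array([0.0, 0.0, 1.0])
    coords = rest[None, :, :] + noise
    for i, node in enumerate(nodes):
        b = block_of.get(node)
        if b is not None:
            coords[:, i, :] += spec.amplitude * latent[:, [b]] * u_hat[None, :]
    top = Topology(
        atom_name=["CA"] * n,
        element=["C"] * n,
        residue_id=[r for (_c, r) in nodes],
        residue_name=["GLY"] * n,
        chain_id=[c for (c, _r) in nodes],
        segment_class=["protein"] * n,
        mass=[12.011] * n)
    span = max(200.0, spec.n_residues * spec.spacing + 50.0,
               spec.n_chains * spec.chain_gap + 50.0)
    box = np.full((spec.n_frames, 3), span)
    time = np.arange(spec.n_frames) * spec.dt_ns
    traj = Trajectory(top, coords, box, time)
    return traj, planted_correlation(spec), planted_adjacency(spec)


# ---------------------------------------------------------------------------
# toy membrane around a Tyr-like probe
# ---------------------------------------------------------------------------

@dataclass
class ToyMembraneSpec:
    """Pseudo-lipid slab around a Tyr-like probe.

    A square ``nx x ny`` lattice of pseudo-POPC lipids per leaflet: P at
    ``interface_z``, choline N 1.5 A above it (toward water), and
    ``tail_carbons`` evenly spaced tail C atoms below it (toward the
    membrane center at z = 0). The probe is a Tyr-like sidechain (6-carbon
    ring + OH + HH) whose ring center sits at depth ``probe_z``. Waters fill
    the region beyond the headgroups. ``jitter_sd`` adds isotropic Gaussian
    displacement to lipid and water atoms (never the probe), seeded.
    """

    nx: int = 4
    ny: int = 4
    lattice_const: float = 8.0
    interface_z: float = 18.0
    tail_carbons: int = 4
    probe_z: float = 16.0
    probe_xy: tuple[float, float] | None = None  # default: box center
    jitter_sd: float = 0.0
    n_waters: int = 20
    n_frames: int = 1
    seed: int = 0

    def box_xy(self) -> float:
        return max(self.nx, self.ny) * self.lattice_const


#: ideal Tyr ring geometry: hexagon of radius 1.39 A in the xy plane
_RING_NAMES = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]


def _tyr_probe(center: np.ndarray) -> tuple[list[str], list[str], np.ndarray]:
    angles = np.deg2rad(np.arange(0, 360, 60))
    ring = center + 1.39 * np.column_stack(
        [np.cos(angles), np.sin(angles), np.zeros(6)])
    # hydroxyl on CZ, pointing up (+z, toward headgroups/water)
    oh = ring[3] + np.array([0.0, 0.0, 1.36])
    hh = oh + np.array([0.0, 0.0, 0.97])
    names = _RING_NAMES + ["OH", "HH"]
    elements = ["C"] * 6 + ["O", "H"]
    return names, elements, np.vstack([ring, oh, hh])


def gen_membrane_toy(spec: ToyMembraneSpec) -> tuple[Trajectory, dict]:
    """Toy membrane/probe trajectory plus zero-jitter ground-truth counts.

    Ground truth (computed from the as-built geometry with plain distance
    arithmetic, before jitter): n_pication, n_cc, n_hbond_distance (pairs
    passing the 3.0 A donor-acceptor distance; the angle criterion depends on
    the O-H orientation and is left to the analysis), and lipid proximity.
    """
    L = spec.box_xy()
    if not (0.0 <= spec.probe_z <= spec.interface_z + 10.0):
        raise ValueError(f"probe depth z={spec.probe_z} outside the box slab")
    rng = np.random.default_rng(spec.seed)
    names: list[str] = []
    elements: list[str] = []
    resids: list[int] = []
    resnames: list[str] = []
    chains: list[str] = []
    segclass: list[str] = []
    coords0: list[np.ndarray] = []

    xy = spec.probe_xy if spec.probe_xy is not None else (L / 2.0, L / 2.0)
    probe_center = np.array([xy[0], xy[1], spec.probe_z])
    pnames, pelems, pxyz = _tyr_probe(probe_center)
    for nm, el, xyz in zip(pnames, pelems, pxyz):
        names.append(nm); elements.append(el); resids.append(1)
        resnames.append("TYR"); chains.append("A"); segclass.append("protein")
        coords0.append(xyz)

    rid = 0
    for leaf in (+1, -1):
        for ix in range(spec.nx):
            for iy in range(spec.ny):
                rid += 1
                x = (ix + 0.5) * spec.lattice_const
                y = (iy + 0.5) * spec.lattice_const
                z_p = leaf * spec.interface_z
                lipid_atoms = [("P", "P", np.array([x, y, z_p])),
                               ("N", "N", np.array([x, y, z_p + leaf * 1.5]))]
                for t in range(spec.tail_carbons):
                    z_t = z_p - leaf * (3.0 + 3.0 * t)
                    lipid_atoms.append((f"C2{t+2}", "C", np.array([x + 1.0, y, z_t])))
                for nm, el, xyz in lipid_atoms:
                    names.append(nm); elements.append(el); resids.append(rid)
                    resnames.append("POPC"); chains.append("L"); segclass.append("lipid")
                    coords0.append(xyz)

    for w in range(spec.n_waters):
        names.append("OH2"); elements.append("O"); resids.append(w + 1)
        resnames.append("TIP3"); chains.append("W"); segclass.append("water")
        coords0.append(np.array([rng.uniform(0, L), rng.uniform(0, L),
                                 rng.uniform(spec.interface_z + 5.0,
                                             spec.interface_z + 15.0)]))

    coords0 = np.stack(coords0)
    n_atoms = len(names)
    top = Topology(names, elements, resids, resnames, chains, segclass,
                   [{"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                     "P": 30.974}[e] for e in elements])

    frames = np.repeat(coords0[None, :, :], spec.n_frames, axis=0)
    if spec.jitter_sd > 0:
        movable = np.asarray([s != "protein" for s in segclass])
        frames[:, movable, :] += rng.normal(
            0.0, spec.jitter_sd, size=(spec.n_frames, movable.sum(), 3))
    box = np.full((spec.n_frames, 3),
                  [L, L, 2.0 * (spec.interface_z + 20.0)])
    traj = Trajectory(top, frames, box, np.arange(spec.n_frames) * 0.05)

    # ground truth at zero jitter, by direct construction geometry
    ring_centroid = pxyz[:6].mean(axis=0)
    oh_pos = pxyz[6]
    is_lipid = np.asarray([s == "lipid" for s in segclass])
    n_pos = np.stack([c for c, nm, lp in zip(coords0, names, is_lipid) if lp and nm == "N"])
    p_pos = np.stack([c for c, nm, lp in zip(coords0, names, is_lipid) if lp and nm == "P"])
    tail_list = [c for c, lp, el in zip(coords0, is_lipid, elements)
                 if lp and el == "C"]
    tail_pos = np.stack(tail_list) if tail_list else np.zeros((0, 3))
    truth = {
        "n_pication": int(np.sum(np.linalg.norm(n_pos - ring_centroid, axis=1) <= 5.0)),
        "n_cc": int(sum(np.sum(np.linalg.norm(tail_pos - rc, axis=1) <= 4.5)
                        for rc in pxyz[:6])),
        "n_hbond_distance": int(
            np.sum(np.linalg.norm(np.vstack([n_pos, p_pos]) - oh_pos, axis=1) <= 3.0)),
        "probe_z": spec.probe_z,
        "interface_z": spec.interface_z,
    }
    return traj, truth


# ---------------------------------------------------------------------------
# synthetic electrophysiology
# ---------------------------------------------------------------------------

def default_protocol() -> SweepProtocol:
    """Step family emulating a BK activation protocol: hold -50 mV, test
    pulses -30..250 mV in 20 mV increments, tail at -80 mV."""
    return SweepProtocol(holding_mV=-50.0,
                         test_voltages_mV=np.arange(-30.0, 250.0 + 1, 20.0),
                         tail_mV=-80.0, pulse_start_ms=5.0, pulse_end_ms=25.0)


def gen_current_traces(V05: float, b: float, Gmax: float = 1000.0,
                       protocol: SweepProtocol | None = None,
                       noise_sd: float = 0.0, seed: int = 0,
                       dt_ms: float = 0.1, tail_len_ms: float = 10.0
                       ) -> tuple[SweepRecording, dict]:
    """Synthetic tail-current sweep family from a Boltzmann open probability.

    During the test pulse the current is Gmax*Po(V)*s_pulse; after
    repolarization the tail current is Gmax*Po(V)*s_tail (instantaneous
    plateau, no deactivation decay, so the mean over any tail window equals
    the amplitude). Gaussian noise of sd ``noise_sd`` (pA) is added to every
    sample. Returns the recording and a ground-truth dict.
    """
    if b <= 0:
        raise ValueError("slope factor b must be positive")
    proto = protocol or default_protocol()
    rng = np.random.default_rng(seed)
    t_end = proto.pulse_end_ms + tail_len_ms
    t = np.arange(0.0, t_end + dt_ms / 2, dt_ms)
    po = boltzmann(proto.test_voltages_mV, V05, b)
    # unit driving-force scale during pulse and tail; amplitude ~ conductance
    cur = np.zeros((len(po), len(t)))
    pulse = (t >= proto.pulse_start_ms) & (t < proto.pulse_end_ms)
    tail = t >= proto.pulse_end_ms
    for i, p in enumerate(po):
        cur[i, pulse] = Gmax * p
        cur[i, tail] = Gmax * p * 0.8  # fixed tail driving-force ratio
    if noise_sd > 0:
        cur = cur + rng.normal(0.0, noise_sd, size=cur.shape)
    rec = SweepRecording(t, cur, proto)
    truth = {"V05": V05, "b": b, "Gmax": Gmax, "tail_scale": 0.8,
             "noise_sd": noise_sd, "seed": seed}
    return rec, truth


def gen_ha_gv(p: HAParameters, Ca: float, V_grid: np.ndarray,
              noise_sd: float = 0.0, seed: int = 0) -> tuple[GVCurve, dict]:
    """G-V points from the Horrigan-Aldrich model, normalized to the grid
    maximum, with additive Gaussian noise; ground-truth V0.5 from the exact
    equal-partition solution."""
    V_grid = np.asarray(V_grid, dtype=float)
    rng = np.random.default_rng(seed)
    po = ha_po(V_grid, Ca, p)
    y = po / po.max()
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    v05 = ha_v_half(Ca, p)
    if not (V_grid.min() <= v05 <= V_grid.max()):
        warnings.warn(f"voltage grid [{V_grid.min()}, {V_grid.max()}] does not span "
                      f"the model midpoint {v05:.1f} mV", stacklevel=2)
    curve = GVCurve(V_grid, y, mode="conductance")
    truth = {"V05": v05, "Ca": Ca, "noise_sd": noise_sd, "seed": seed}
    return curve, truth


def write_ground_truth(truth: dict, path: str) -> None:
    """JSON sidecar for any generator's ground truth."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=float)
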