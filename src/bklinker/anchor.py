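"""Aromatic sidechain--membrane interface interaction metrics.

Quantifies how a Tyr-like sidechain anchors at the lipid headgroup--water
interface: hydrogen bonds from the hydroxyl to headgroup acceptors, pi-cation
contacts between the aromatic ring centroid and choline nitrogens,
hydrophobic carbon-carbon contacts with lipid tails, and the solvent
accessible surface area buried by lipid tails. Also provides residue contact
probability maps, pore water counting, and replica aggregation (mean +/- SEM
across independent simulations).

All distance criteria are inclusive at the cutoff ("no greater than").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .sasa import VDW_RADII, shrake_rupley
from .traj import DegenerateSelectionError, Selection, Trajectory, minimum_image

__all__ = [
    "InteractionCriteria",
    "MembraneFrame",
    "AnchorProfile",
    "count_hbonds",
    "count_pi_cation",
    "count_cc_contacts",
    "lipid_burial_sasa",
    "contact_probability_map",
    "pore_water_count",
    "aggregate_replicas",
    "membrane_frames",
]


@dataclass
class InteractionCriteria:
    """Geometric cutoffs for the anchoring metrics (all inclusive).

    cc_cutoff : A, ring-carbon to tail-carbon hydrophobic contact.
    pication_cutoff : A, ring centroid to choline N.
    hbond_da_cutoff : A, donor--acceptor heavy-atom distance.
    hbond_dha_min : degrees, donor-H-acceptor angle lower bound.
    contactmap_cutoff : A, heavy-atom residue contact map.
    sasa_probe : A, solvent probe radius.
    """

    cc_cutoff: float = 4.5
    pication_cutoff: float = 5.0
    hbond_da_cutoff: float = 3.0
    hbond_dha_min: float = 150.0
    contactmap_cutoff: float = 5.0
    sasa_probe: float = 1.4

    def __post_init__(self) -> None:
        for name in ("cc_cutoff", "pication_cutoff", "hbond_da_cutoff",
                     "contactmap_cutoff", "sasa_probe"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.hbond_dha_min <= 180.0):
            raise ValueError("hbond_dha_min must lie in (0, 180]")


@dataclass
class MembraneFrame:
    """Per-frame membrane geometry from lipid phosphorus z coordinates."""

    center_z: float
    upper_interface_z: float
    lower_interface_z: float
    leaflet: dict  # (chain, resid) -> "upper" | "lower"

    def __post_init__(self) -> None:
        if not (self.lower_interface_z <= self.center_z <= self.upper_interface_z):
            raise ValueError("membrane center must lie between the leaflet interfaces")


def membrane_frames(traj: Trajectory, phosphorus_sel: Selection | None = None
                    ) -> list[MembraneFrame]:
    """Membrane center and leaflet interfaces per frame.

    The center is the mean lipid phosphorus z; each lipid is assigned to the
    upper or lower leaflet by the sign of its phosphorus z relative to the
    center, and each interface plane is that leaflet's mean phosphorus z.
    """
    sel = phosphorus_sel if phosphorus_sel is not None else Selection(
        atom_names=["P"], segment_class="lipid")
    idx = sel.indices(traj.topology)
    if len(idx) == 0:
        raise DegenerateSelectionError("no lipid phosphorus atoms selected")
    top = traj.topology
    keys = [(top.chain_id[i], int(top.residue_id[i])) for i in idx]
    out = []
    for f in range(traj.n_frames):
        z = traj.coords[f][idx, 2]
        center = float(z.mean())
        upper = z >= center
        leaflet = {k: ("upper" if u else "lower") for k, u in zip(keys, upper)}
        uz = float(z[upper].mean()) if upper.any() else center
        lz = float(z[~upper].mean()) if (~upper).any() else center
        out.append(MembraneFrame(center, uz, lz, leaflet))
    return out


@dataclass
class AnchorProfile:
    """Per-frame anchoring metrics for one replica, or replica-aggregated
    means with standard errors (SEM across replicas, never across frames)."""

    n_hbond: np.ndarray | None = None
    n_pication: np.ndarray | None = None
    n_cc: np.ndarray | None = None
    burial_sasa: np.ndarray | None = None
    mean: dict = field(default_factory=dict)
    sem: dict = field(default_factory=dict)
    n_replicas: int | None = None

    METRICS = ("n_hbond", "n_pication", "n_cc", "burial_sasa")

    def to_frame(self, time_ns: np.ndarray | None = None) -> pd.DataFrame:
        data = {}
        if time_ns is not None:
            data["time_ns"] = time_ns
        for m in self.METRICS:
            v = getattr(self, m)
            if v is not None:
                data[m] = v
        return pd.DataFrame(data)

    def summary_frame(self) -> pd.DataFrame:
        rows = [{"metric": m, "mean": self.mean.get(m), "sem": self.sem.get(m),
                 "n": self.n_replicas} for m in self.METRICS if m in self.mean]
        return pd.DataFrame(rows)


def _frames_or_default(traj: Trajectory, frames) -> np.ndarray:
    if frames is None:
        return np.arange(traj.n_frames)
    return np.asarray(frames, dtype=int)


def _resolve_hydrogens(traj: Trajectory, donor_idx: np.ndarray,
                       bond_cutoff: float = 1.25) -> dict[int, np.ndarray]:
    """Hydrogens covalently attached to each donor heavy atom, resolved
    geometrically (same residue, within ``bond_cutoff`` A in frame 0)."""
    top = traj.topology
    out: dict[int, np.ndarray] = {}
    x0 = traj.coords[0]
    for d in donor_idx:
        res_atoms = top.atoms_of_residue(top.chain_id[d], int(top.residue_id[d]))
        hyd = [i for i in res_atoms if top.element[i] == "H"
               and np.linalg.norm(x0[i] - x0[d]) <= bond_cutoff]
        if not hyd:
            raise DegenerateSelectionError(
                f"donor atom {top.chain_id[d]}:{top.residue_id[d]}:{top.atom_name[d]} "
                "has no attached hydrogen")
        out[int(d)] = np.asarray(hyd)
    return out


def count_hbonds(traj: Trajectory, donor_sel: Selection, acceptor_sel: Selection,
                 criteria: InteractionCriteria | None = None,
                 frames=None) -> np.ndarray:
    """Per-frame hydrogen-bond count between donor hydroxyls and acceptors.

    A bond requires donor--acceptor distance <= ``hbond_da_cutoff`` and
    donor-H-acceptor angle >= ``hbond_dha_min`` for at least one donor
    hydrogen. Hydrogens are resolved from the topology geometrically.
    """
    c = criteria or InteractionCriteria()
    donors = donor_sel.indices(traj.topology)
    acceptors = acceptor_sel.indices(traj.topology)
    if len(donors) == 0 or len(acceptors) == 0:
        raise DegenerateSelectionError("empty donor or acceptor selection")
    hydro = _resolve_hydrogens(traj, donors)
    frames = _frames_or_default(traj, frames)
    counts = np.zeros(len(frames), dtype=int)
    cos_min = np.cos(np.deg2rad(c.hbond_dha_min))
    for k, f in enumerate(frames):
        x = traj.coords[f]
        n = 0
        for d in donors:
            da = x[acceptors] - x[d]
            dist = np.linalg.norm(da, axis=1)
            close = dist <= c.hbond_da_cutoff
            for a_local in np.flatnonzero(close):
                a = acceptors[a_local]
                ok = False
                for h in hydro[int(d)]:
                    hd = x[d] - x[h]
                    ha = x[a] - x[h]
                    cosang = np.dot(hd, ha) / (np.linalg.norm(hd) * np.linalg.norm(ha))
                    # angle >= min  <=>  cos(angle) <= cos(min)
                    if cosang <= cos_min + 1e-12:
                        ok = True
                        break
                n += ok
        counts[k] = n
    return counts


def _ring_groups(traj: Trajectory, ring_sel: Selection) -> list[np.ndarray]:
    top = traj.topology
    idx = ring_sel.indices(traj.topology)
    groups: dict[tuple[str, int], list[int]] = {}
    for i in idx:
        groups.setdefault((top.chain_id[i], int(top.residue_id[i])), []).append(i)
    out = []
    for key, atoms in sorted(groups.items()):
        if len(atoms) != 6:
            raise DegenerateSelectionError(
                f"ring of residue {key} resolves to {len(atoms)} atoms, expected 6")
        if any(top.element[i] != "C" for i in atoms):
            raise DegenerateSelectionError(f"ring of residue {key} contains non-carbon atoms")
        out.append(np.asarray(atoms))
    if not out:
        raise DegenerateSelectionError("ring selection resolves to no residue")
    return out


def count_pi_cation(traj: Trajectory, ring_sel: Selection, cation_sel: Selection,
                    criteria: InteractionCriteria | None = None,
                    frames=None) -> np.ndarray:
    """Per-frame count of choline N atoms within ``pication_cutoff`` of the
    mass-weighted aromatic ring centroid (6 ring carbons, so equal-weight)."""
    c = criteria or InteractionCriteria()
    rings = _ring_groups(traj, ring_sel)
    cations = cation_sel.indices(traj.topology)
    frames = _frames_or_default(traj, frames)
    masses = traj.topology.mass
    counts = np.zeros(len(frames), dtype=int)
    for k, f in enumerate(frames):
        x = traj.coords[f]
        n = 0
        for ring in rings:
            w = masses[ring] / masses[ring].sum()
            centroid = (x[ring] * w[:, None]).sum(axis=0)
            d = np.linalg.norm(x[cations] - centroid, axis=1)
            n += int(np.sum(d <= c.pication_cutoff))
        counts[k] = n
    return counts


def count_cc_contacts(traj: Trajectory, ring_sel: Selection, tail_sel: Selection,
                      criteria: InteractionCriteria | None = None,
                      frames=None) -> np.ndarray:
    """Per-frame count of hydrophobic C-C contacts (pairs <= ``cc_cutoff``)
    between aromatic ring carbons and lipid tail carbons."""
    c = criteria or InteractionCriteria()
    top = traj.topology
    ring = ring_sel.indices(top)
    tails = tail_sel.indices(top)
    for name, idx in (("ring", ring), ("tail", tails)):
        bad = [i for i in idx if top.element[i] != "C"]
        if bad:
            raise DegenerateSelectionError(
                f"{name} selection contains non-carbon atom "
                f"{top.chain_id[bad[0]]}:{top.residue_id[bad[0]]}:{top.atom_name[bad[0]]}")
    if len(ring) == 0 or len(tails) == 0:
        raise DegenerateSelectionError("empty carbon selection")
    frames = _frames_or_default(traj, frames)
    counts = np.zeros(len(frames), dtype=int)
    for k, f in enumerate(frames):
        x = traj.coords[f]
        tree = cKDTree(x[tails])
        hits = tree.query_ball_point(x[ring], c.cc_cutoff)
        counts[k] = sum(len(h) for h in hits)
    return counts


def lipid_burial_sasa(traj: Trajectory, sidechain_sel: Selection,
                      lipid_tail_sel: Selection,
                      criteria: InteractionCriteria | None = None,
                      context_sel: Selection | None = None,
                      frames=None, n_points: int = 960) -> np.ndarray:
    """Per-frame SASA (A^2) of the sidechain buried by lipid tail atoms.

    burial = SASA(sidechain | protein context) - SASA(sidechain | context +
    lipid tails), clipped at zero. The context defaults to all protein atoms.
    """
    c = criteria or InteractionCriteria()
    top = traj.topology
    side = sidechain_sel.indices(top)
    tails = lipid_tail_sel.indices(top)
    if len(side) == 0:
        raise DegenerateSelectionError("empty sidechain selection")
    if set(side) & set(tails):
        raise DegenerateSelectionError("sidechain and lipid selections overlap")
    ctx_sel = context_sel if context_sel is not None else Selection(segment_class="protein")
    ctx = ctx_sel.indices(top)
    ctx = np.unique(np.concatenate([ctx, side]))
    frames = _frames_or_default(traj, frames)
    radii_ctx = np.asarray([VDW_RADII.get(top.element[i], VDW_RADII["X"]) for i in ctx])
    both = np.concatenate([ctx, tails])
    radii_both = np.asarray([VDW_RADII.get(top.element[i], VDW_RADII["X"]) for i in both])
    side_in_ctx = np.isin(ctx, side)
    side_in_both = np.isin(both, side)
    out = np.zeros(len(frames))
    for k, f in enumerate(frames):
        x = traj.coords[f]
        s_free = shrake_rupley(x[ctx], radii_ctx, probe=c.sasa_probe,
                               n_points=n_points)[side_in_ctx].sum()
        s_lip = shrake_rupley(x[both], radii_both, probe=c.sasa_probe,
                              n_points=n_points)[side_in_both].sum()
        out[k] = max(0.0, s_free - s_lip)
    return out


def contact_probability_map(traj: Trajectory, sel_a: Selection, sel_b: Selection,
                            cutoff: float = 5.0, frames=None,
                            pbc: bool = False) -> pd.DataFrame:
    """Residue x residue contact probability over a frame window.

    P = fraction of frames in which the minimal heavy-atom distance between
    the residue pair is <= cutoff. Rows are sel_a residues, columns sel_b.
    """
    frames = _frames_or_default(traj, frames)
    if len(frames) == 0:
        raise ValueError("empty frame window")
    top = traj.topology
    heavy = top.heavy_mask

    def residues_of(sel: Selection) -> list[tuple[str, int]]:
        idx = sel.indices(top)
        keys: list[tuple[str, int]] = []
        for i in idx:
            key = (top.chain_id[i], int(top.residue_id[i]))
            if key not in keys:
                keys.append(key)
        return keys

    res_a = residues_of(sel_a)
    res_b = residues_of(sel_b)
    atoms = {}
    for key in set(res_a) | set(res_b):
        aa = top.atoms_of_residue(*key)
        aa = aa[heavy[aa]]
        if len(aa) == 0:
            raise DegenerateSelectionError(f"residue {key} has no heavy atom")
        atoms[key] = aa
    P = np.zeros((len(res_a), len(res_b)))
    for f in frames:
        x = traj.coords[f]
        for i, ka in enumerate(res_a):
            xa = x[atoms[ka]]
            for j, kb in enumerate(res_b):
                if ka == kb:
                    P[i, j] += 1.0
                    continue
                diff = xa[:, None, :] - x[atoms[kb]][None, :, :]
                if pbc:
                    diff = minimum_image(diff, traj.box[f])
                if np.min(np.sum(diff ** 2, axis=2)) <= cutoff ** 2:
                    P[i, j] += 1.0
    P /= len(frames)
    labels_a = [f"{c}:{r}" for c, r in res_a]
    labels_b = [f"{c}:{r}" for c, r in res_b]
    return pd.DataFrame(P, index=labels_a, columns=labels_b)


def pore_water_count(traj: Trajectory, upper_sel: Selection, lower_sel: Selection,
                     radius: float = 10.0, frames=None) -> np.ndarray:
    """Per-frame count of water oxygens inside the pore cylinder.

    The cylinder axis is z; its end planes are the mean C-alpha z of the two
    residue-ring selections (upper above lower), and its axis passes through
    the mean x,y of both rings. This cylinder parameterization stands in for
    earlier hydration criteria not restated here; outputs should be read as
    such.
    """
    top = traj.topology
    upper = upper_sel.indices(top)
    lower = lower_sel.indices(top)
    if len(upper) == 0 or len(lower) == 0:
        raise DegenerateSelectionError("empty plane selection")
    wat_o = [i for i in Selection(segment_class="water").indices(top)
             if top.element[i] == "O"]
    wat_o = np.asarray(wat_o, dtype=int)
    frames = _frames_or_default(traj, frames)
    counts = np.zeros(len(frames), dtype=int)
    for k, f in enumerate(frames):
        x = traj.coords[f]
        z_up = float(x[upper, 2].mean())
        z_lo = float(x[lower, 2].mean())
        if z_up < z_lo:
            raise ValueError(
                f"inverted pore planes: upper z {z_up:.2f} < lower z {z_lo:.2f}")
        axis_xy = np.concatenate([x[upper, :2], x[lower, :2]]).mean(axis=0)
        if len(wat_o) == 0:
            counts[k] = 0
            continue
        w = x[wat_o]
        inside_z = (w[:, 2] >= z_lo) & (w[:, 2] <= z_up)
        r2 = np.sum((w[:, :2] - axis_xy) ** 2, axis=1)
        counts[k] = int(np.sum(inside_z & (r2 <= radius ** 2)))
    return counts


def aggregate_replicas(profiles: list[AnchorProfile],
                       window: slice | np.ndarray | None = None) -> AnchorProfile:
    """Replica mean +/- SEM of time-averaged anchoring metrics.

    Each replica is first time-averaged over ``window`` frames; the SEM is
    the standard deviation of the replica means over sqrt(n_replicas). A
    single replica yields the mean with SEM flagged as NaN (undefined), never
    fabricated.
    """
    if not profiles:
        raise ValueError("no replicas given")
    out = AnchorProfile(n_replicas=len(profiles))
    single = len(profiles) == 1
    if single:
        warnings.warn("single replica: SEM is undefined and reported as NaN",
                      stacklevel=2)
    for metric in AnchorProfile.METRICS:
        series = [getattr(p, metric) for p in profiles]
        if any(s is None for s in series):
            continue
        means = []
        for s in series:
            s = np.asarray(s, dtype=float)
            if window is not None:
                s = s[window]
            means.append(float(s.mean()))
        means = np.asarray(means)
        out.mean[metric] = float(means.mean())
        out.sem[metric] = (float("nan") if single
                           else float(means.std(ddof=1) / np.sqrt(len(means))))
    return out
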