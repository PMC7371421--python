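"""Trajectory container, standard-format I/O and basic structural observables.

Coordinates are stored in Angstrom, time in nanoseconds, and residue
numbering is taken verbatim from the input files (hSlo1 author numbering,
e.g. R329--K343 for the C-linker). Only orthorhombic periodic boxes are
supported; triclinic input raises :class:`UnsupportedFormatError`.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Topology",
    "Trajectory",
    "Selection",
    "FormatError",
    "UnsupportedFormatError",
    "DegenerateSelectionError",
    "load_trajectory",
    "write_trajectory",
    "superpose",
    "kabsch_rotation",
    "rmsd_series",
    "rmsf_per_residue",
    "end_to_end_distance",
    "min_heavy_distance",
]

# resname -> segment class heuristics (CHARMM / PDB conventions)
_WATER_RESNAMES = {"TIP3", "TIP3P", "HOH", "WAT", "SOL", "TIP4", "SPC"}
_ION_RESNAMES = {"K", "POT", "CL", "CLA", "NA", "SOD", "CA", "CAL", "MG", "ZN", "CS"}
_LIPID_RESNAMES = {"POPC", "POPE", "POPS", "POPG", "DPPC", "DOPC", "DMPC", "CHL1", "PLIP"}

_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974, "S": 32.06, "K": 39.098}


class FormatError(ValueError):
    """Raised for malformed or inconsistent structure/trajectory input."""


class UnsupportedFormatError(FormatError):
    """Raised for input this package deliberately does not handle (e.g. triclinic boxes)."""


class DegenerateSelectionError(ValueError):
    """Raised when a selection cannot support the requested geometry operation."""


def _guess_element(name: str) -> str:
    name = name.strip()
    if not name:
        return "X"
    # strip leading digits (e.g. "1HB")
    stripped = name.lstrip("0123456789")
    if not stripped:
        return "X"
    first = stripped[0].upper()
    if first == "H":
        return "H"
    return first


def classify_segment(resname: str) -> str:
    resname = resname.strip().upper()
    if resname in _WATER_RESNAMES:
        return "water"
    if resname in _ION_RESNAMES:
        return "ion"
    if resname in _LIPID_RESNAMES:
        return "lipid"
    return "protein"


@dataclass
class Topology:
    """Per-atom labelling arrays; all arrays have equal length.

    ``(chain_id, residue_id, atom_name)`` must be unique. Heavy atoms are
    exactly those with element != 'H'.
    """

    atom_name: np.ndarray
    element: np.ndarray
    residue_id: np.ndarray
    residue_name: np.ndarray
    chain_id: np.ndarray
    segment_class: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        arrays = [self.atom_name, self.element, self.residue_id, self.residue_name,
                  self.chain_id, self.segment_class, self.mass]
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        self.element = np.asarray(self.element, dtype=object)
        self.residue_id = np.asarray(self.residue_id, dtype=int)
        self.residue_name = np.asarray(self.residue_name, dtype=object)
        self.chain_id = np.asarray(self.chain_id, dtype=object)
        self.segment_class = np.asarray(self.segment_class, dtype=object)
        self.mass = np.asarray(self.mass, dtype=float)
        lengths = {len(a) for a in arrays}
        if len(lengths) != 1:
            raise FormatError(f"per-atom arrays have unequal lengths: {sorted(lengths)}")
        keys = list(zip(self.chain_id, self.residue_id, self.atom_name))
        if len(set(keys)) != len(keys):
            seen: set = set()
            dup = next(k for k in keys if k in seen or seen.add(k))  # type: ignore[func-returns-value]
            raise FormatError(f"duplicate (chain, residue, atom) key: {dup}")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.asarray([e != "H" for e in self.element], dtype=bool)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Ordered unique (chain_id, residue_id) keys, in atom order."""
        keys: list[tuple[str, int]] = []
        seen: set = set()
        for c, r in zip(self.chain_id, self.residue_id):
            if (c, r) not in seen:
                seen.add((c, r))
                keys.append((c, r))
        return keys

    def atoms_of_residue(self, chain_id: str, residue_id: int) -> np.ndarray:
        mask = (self.chain_id == chain_id) & (self.residue_id == int(residue_id))
        return np.flatnonzero(mask)


@dataclass
class Selection:
    """Declarative atom predicate; resolves to an ascending atom-index list.

    All fields are optional and combined with AND. ``residue_ids`` may be a
    ``range`` or any iterable of ints.
    """

    chain_id: str | None = None
    residue_ids: Iterable[int] | None = None
    residue_names: Iterable[str] | None = None
    atom_names: Iterable[str] | None = None
    segment_class: str | None = None

    def indices(self, top: Topology) -> np.ndarray:
        mask = np.ones(top.n_atoms, dtype=bool)
        if self.chain_id is not None:
            mask &= top.chain_id == self.chain_id
        if self.residue_ids is not None:
            rid = set(int(r) for r in self.residue_ids)
            mask &= np.asarray([int(r) in rid for r in top.residue_id])
        if self.residue_names is not None:
            names = {str(n) for n in self.residue_names}
            mask &= np.asarray([n in names for n in top.residue_name])
        if self.atom_names is not None:
            names = {str(n) for n in self.atom_names}
            mask &= np.asarray([n in names for n in top.atom_name])
        if self.segment_class is not None:
            mask &= top.segment_class == self.segment_class
        return np.flatnonzero(mask)


#: default superposition fit selection: protein C-alpha atoms
CA_PROTEIN = Selection(atom_names=["CA"], segment_class="protein")


@dataclass
class Trajectory:
    """Frames x atoms x 3 coordinates (A) bound to a labelled topology."""

    topology: Topology
    coords: np.ndarray          # (n_frames, n_atoms, 3), Angstrom
    box: np.ndarray             # (n_frames, 3) orthorhombic lengths, Angstrom
    time: np.ndarray            # (n_frames,), ns

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError(f"coords must be (frames, atoms, 3); got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise FormatError("trajectory must have at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise FormatError(
                f"atom-count mismatch: coordinates have {self.coords.shape[1]} atoms, "
                f"topology has {self.topology.n_atoms}")
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("non-finite coordinates")
        self.box = np.asarray(self.box, dtype=float)
        if self.box.shape != (self.n_frames, 3):
            raise FormatError(f"box must be (frames, 3); got {self.box.shape}")
        if np.any(self.box <= 0):
            raise FormatError("box lengths must be positive")
        self.time = np.asarray(self.time, dtype=float)
        if self.time.shape != (self.n_frames,):
            raise FormatError("time must be per-frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame_window(self, t_start: float | None = None, t_end: float | None = None) -> np.ndarray:
        """Frame indices with time in [t_start, t_end] (ns); None = unbounded."""
        mask = np.ones(self.n_frames, dtype=bool)
        if t_start is not None:
            mask &= self.time >= t_start
        if t_end is not None:
            mask &= self.time <= t_end
        return np.flatnonzero(mask)

    def last_window(self, duration_ns: float = 150.0) -> np.ndarray:
        """Frames of the final ``duration_ns``; whole trajectory (with a warning)
        when it is shorter than that."""
        span = self.time[-1] - self.time[0]
        if span < duration_ns:
            warnings.warn(
                f"trajectory spans {span:.3g} ns < requested {duration_ns:.3g} ns window; "
                "using all frames", stacklevel=2)
            return np.arange(self.n_frames)
        return self.frame_window(t_start=self.time[-1] - duration_ns)

    def with_coords(self, coords: np.ndarray) -> "Trajectory":
        return Trajectory(self.topology, coords, self.box.copy(), self.time.copy())


def _topology_from_universe(u) -> Topology:
    atoms = u.atoms
    names = [a.name for a in atoms]
    try:
        elements = [str(e) if str(e) else _guess_element(n)
                    for e, n in zip(atoms.elements, names)]
    except Exception:
        elements = [_guess_element(n) for n in names]
    elements = [e.capitalize() if len(e) > 1 else e.upper() for e in elements]
    resids = [a.resid for a in atoms]
    resnames = [a.resname for a in atoms]
    chains: list[str] = []
    for a in atoms:
        cid = ""
        if hasattr(a, "chainID") and str(getattr(a, "chainID", "")).strip():
            cid = str(a.chainID).strip()
        elif str(getattr(a, "segid", "")).strip():
            cid = str(a.segid).strip()
        chains.append(cid or "A")
    seg = [classify_segment(r) for r in resnames]
    try:
        masses = [float(m) for m in atoms.masses]
    except Exception:
        masses = [_MASSES.get(e, 12.0) for e in elements]
    return Topology(names, elements, resids, resnames, chains, seg, masses)


def load_trajectory(structure_path: str, trajectory_path: str | None = None,
                    dt_ns: float | None = None) -> Trajectory:
    """Read a PDB/PSF topology and optional DCD/XTC trajectory.

    With no trajectory file the PDB coordinates give a single-frame
    Trajectory.  ``dt_ns`` overrides the per-frame time step when the file
    carries no (or bogus) time information.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if trajectory_path is None:
            u = mda.Universe(structure_path)
        else:
            try:
                u = mda.Universe(structure_path, trajectory_path)
            except ValueError as exc:
                raise FormatError(f"failed to bind trajectory to topology: {exc}") from exc
    top = _topology_from_universe(u)
    coords, boxes, times = [], [], []
    for i, ts in enumerate(u.trajectory):
        try:
            xyz = ts.positions.copy()
        except Exception as exc:  # pragma: no cover - corrupt frame path
            raise FormatError(f"unreadable frame {i}: {exc}") from exc
        if ts.dimensions is not None and np.all(np.asarray(ts.dimensions)[:3] > 0):
            dims = np.asarray(ts.dimensions, dtype=float)
            if not np.allclose(dims[3:], 90.0, atol=1e-3):
                raise UnsupportedFormatError(
                    f"triclinic box (angles {dims[3:]}) not supported; orthorhombic only")
            boxes.append(dims[:3])
        else:
            boxes.append(np.full(3, 1e6))  # effectively non-periodic
        coords.append(xyz)
        if dt_ns is not None:
            times.append(i * dt_ns)
        else:
            t_ps = float(getattr(ts, "time", 0.0) or 0.0)
            times.append(t_ps / 1000.0)
    coords = np.asarray(coords, dtype=float)
    if coords.shape[1] != top.n_atoms:
        raise FormatError(
            f"atom-count mismatch: trajectory has {coords.shape[1]} atoms, "
            f"structure has {top.n_atoms}")
    return Trajectory(top, coords, np.asarray(boxes), np.asarray(times))


def write_trajectory(traj: Trajectory, structure_path: str,
                     trajectory_path: str | None = None) -> None:
    """Write a PDB snapshot (frame 0) and optionally a DCD/XTC trajectory."""
    import MDAnalysis as mda

    top = traj.topology
    n = top.n_atoms
    resindex = {}
    res_of_atom = []
    for c, r in zip(top.chain_id, top.residue_id):
        res_of_atom.append(resindex.setdefault((c, r), len(resindex)))
    n_res = len(resindex)
    res_keys = [None] * n_res
    for k, i in resindex.items():
        res_keys[i] = k
    seg_of_res = {}
    for (c, _r), i in resindex.items():
        seg_of_res[i] = c
    segids = sorted(set(seg_of_res.values()))
    seg_index = {s: i for i, s in enumerate(segids)}
    u = mda.Universe.empty(
        n_atoms=n, n_residues=n_res, n_segments=len(segids),
        atom_resindex=np.asarray(res_of_atom),
        residue_segindex=np.asarray([seg_index[seg_of_res[i]] for i in range(n_res)]),
        trajectory=True)
    u.add_TopologyAttr("names", list(top.atom_name))
    u.add_TopologyAttr("elements", list(top.element))
    u.add_TopologyAttr("resids", [int(r) for (_c, r) in res_keys])
    first_atom_of_res = {}
    for ai, ri in enumerate(res_of_atom):
        first_atom_of_res.setdefault(ri, ai)
    u.add_TopologyAttr("resnames", [str(top.residue_name[first_atom_of_res[i]])
                                    for i in range(n_res)])
    u.add_TopologyAttr("segids", segids)
    u.add_TopologyAttr("chainIDs", [str(c)[:1] for c in top.chain_id])
    u.add_TopologyAttr("masses", list(top.mass))
    u.atoms.positions = traj.coords[0]
    u.dimensions = np.concatenate([traj.box[0], [90.0, 90.0, 90.0]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(structure_path)
        if trajectory_path is not None:
            with mda.Writer(trajectory_path, n_atoms=n) as w:
                for f in range(traj.n_frames):
                    u.atoms.positions = traj.coords[f]
                    u.dimensions = np.concatenate([traj.box[f], [90.0] * 3])
                    u.trajectory.ts.time = traj.time[f] * 1000.0  # ps
                    w.write(u.atoms)


# ---------------------------------------------------------------------------
# superposition and observables
# ---------------------------------------------------------------------------

def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal least-squares rotation R and centroids (mob_c, ref_c).

    ``R @ (x - mob_c) + ref_c`` maps mobile onto reference. Standard
    SVD solution with reflection correction.
    """
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    H = (mobile - mob_c).T @ (reference - ref_c)
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, mob_c, ref_c


def _check_fit_atoms(x: np.ndarray) -> None:
    if x.shape[0] < 3:
        raise DegenerateSelectionError(f"superposition needs >= 3 atoms, got {x.shape[0]}")
    centered = x - x.mean(axis=0)
    # collinear <=> rank of the centered coordinates < 2
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise DegenerateSelectionError("superposition selection is collinear")


def superpose(traj: Trajectory, reference_frame: int = 0,
              sel: Selection | None = None) -> Trajectory:
    """Rigid-body fit every frame onto ``reference_frame`` over ``sel`` atoms.

    Defaults to protein C-alphas. Returns a new Trajectory; idempotent.
    """
    sel = sel if sel is not None else CA_PROTEIN
    idx = sel.indices(traj.topology)
    ref = traj.coords[reference_frame][idx]
    _check_fit_atoms(ref)
    out = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        R, mob_c, ref_c = kabsch_rotation(traj.coords[f][idx], ref)
        out[f] = (traj.coords[f] - mob_c) @ R.T + ref_c
    return traj.with_coords(out)


def rmsd_series(traj: Trajectory, reference: Trajectory, reference_frame: int = 0,
                sel: Selection | None = None, fit_sel: Selection | None = None
                ) -> np.ndarray:
    """Per-frame RMSD (A) of ``sel`` atoms after least-squares fit on ``fit_sel``."""
    sel = sel if sel is not None else CA_PROTEIN
    fit_sel = fit_sel if fit_sel is not None else sel
    idx = sel.indices(traj.topology)
    fidx = fit_sel.indices(traj.topology)
    ridx = sel.indices(reference.topology)
    rfidx = fit_sel.indices(reference.topology)
    if len(idx) != len(ridx):
        raise FormatError(
            f"selection resolves to {len(idx)} atoms in trajectory but {len(ridx)} in reference")
    if len(idx) == 0:
        raise DegenerateSelectionError("empty selection")
    ref_fit = reference.coords[reference_frame][rfidx]
    ref_meas = reference.coords[reference_frame][ridx]
    _check_fit_atoms(ref_fit)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        R, mob_c, ref_c = kabsch_rotation(traj.coords[f][fidx], ref_fit)
        moved = (traj.coords[f][idx] - mob_c) @ R.T + ref_c
        out[f] = np.sqrt(np.mean(np.sum((moved - ref_meas) ** 2, axis=1)))
    return out


def rmsf_per_residue(traj: Trajectory, sel: Selection | None = None
                     ) -> tuple[list[tuple[str, int]], np.ndarray, list[tuple[str, int]]]:
    """Per-residue RMSF (A) about the time-mean position.

    ``sel`` should pick one representative atom per residue (default C-alpha);
    assumes the trajectory is already superposed. Returns (residue_keys,
    rmsf_values, skipped_residues) where skipped residues had no matching atom.
    """
    sel = sel if sel is not None else CA_PROTEIN
    idx = sel.indices(traj.topology)
    top = traj.topology
    by_res: dict[tuple[str, int], int] = {}
    for i in idx:
        key = (top.chain_id[i], int(top.residue_id[i]))
        if key in by_res:
            raise FormatError(f"selection picks more than one atom for residue {key}")
        by_res[key] = i
    all_keys = [k for k in top.residue_keys()
                if top.segment_class[top.atoms_of_residue(*k)[0]] == "protein"]
    skipped = [k for k in all_keys if k not in by_res]
    keys = [k for k in all_keys if k in by_res]
    if not keys:
        raise DegenerateSelectionError("selection matches no residue")
    sub = traj.coords[:, [by_res[k] for k in keys], :]
    disp = sub - sub.mean(axis=0, keepdims=True)
    rmsf = np.sqrt(np.mean(np.sum(disp ** 2, axis=2), axis=0))
    return keys, rmsf, skipped


def end_to_end_distance(traj: Trajectory, chain_id: str,
                        res_start: int = 329, res_end: int = 343) -> np.ndarray:
    """Per-frame C-alpha--C-alpha distance (A) between two residues of a chain.

    Defaults to the hSlo1 C-linker termini R329 and K343.
    """
    top = traj.topology
    out_idx = []
    for rid in (res_start, res_end):
        atoms = top.atoms_of_residue(chain_id, rid)
        ca = [i for i in atoms if top.atom_name[i] == "CA"]
        if not ca:
            raise DegenerateSelectionError(
                f"residue {chain_id}:{rid} has no CA atom")
        out_idx.append(ca[0])
    d = traj.coords[:, out_idx[0], :] - traj.coords[:, out_idx[1], :]
    return np.linalg.norm(d, axis=1)


def minimum_image(diff: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the orthorhombic minimum image."""
    return diff - box * np.round(diff / box)


def min_heavy_distance(traj: Trajectory, frame: int,
                       residue_a: tuple[str, int], residue_b: tuple[str, int],
                       pbc: bool = False) -> float:
    """Minimum heavy-atom pair distance (A) between two residues in one frame."""
    top = traj.topology
    heavy = top.heavy_mask
    pairs = []
    for res in (residue_a, residue_b):
        atoms = top.atoms_of_residue(*res)
        atoms = atoms[heavy[atoms]]
        if len(atoms) == 0:
            raise DegenerateSelectionError(f"residue {res} has no heavy atom")
        pairs.append(atoms)
    xa = traj.coords[frame][pairs[0]]
    xb = traj.coords[frame][pairs[1]]
    diff = xa[:, None, :] - xb[None, :, :]
    if pbc:
        diff = minimum_image(diff, traj.box[frame])
    return float(np.sqrt(np.sum(diff ** 2, axis=2)).min())
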