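"""Structure/trajectory readers, system registry and physical constants.

Unit conventions used throughout the package: coordinates in Angstrom, times
in picoseconds, energies in kcal/mol, angles in degrees, temperatures in
Kelvin.  Base pairs are numbered 1..N along the Watson strand 5'->3'; the
Crick partner of bp *i* carries the same bp number.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda


class FormatError(RuntimeError):
    """Unreadable or malformed input file."""


class ConfigurationError(ValueError):
    """Inconsistent configuration (roles, ranges, missing metadata)."""


# ---------------------------------------------------------------------------
# Physical constants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants in the package's internal units.

    ``k_B`` is in kcal/mol/K so that ``k_B * T_ref`` is the familiar thermal
    energy 0.596 kcal/mol at 300 K.  ``hbar_SI`` is kept in SI (J*s) because
    it only enters the Schlitter formula through a dimensionless prefactor
    assembled in :mod:`dnamech.entropy_analysis`.
    """

    k_B: float = 1.987204259e-3        # kcal/mol/K
    T_ref: float = 300.0               # K
    hbar_SI: float = 1.054571817e-34   # J*s
    k_B_SI: float = 1.380649e-23       # J/K
    amu_SI: float = 1.66053906660e-27  # kg
    e_euler: float = math.e
    N_A: float = 6.02214076e23         # 1/mol
    k_coulomb: float = 332.0637        # kcal*A/mol/e^2

    def __post_init__(self) -> None:
        vals = [self.k_B, self.T_ref, self.hbar_SI, self.k_B_SI,
                self.amu_SI, self.e_euler, self.N_A, self.k_coulomb]
        if any(v <= 0 for v in vals):
            raise ValueError("physical constants must be strictly positive")

    @property
    def kT_ref(self) -> float:
        """Thermal energy k_B*T_ref, ~0.596 kcal/mol at 300 K."""
        return self.k_B * self.T_ref


CONSTANTS = PhysicalConstants()


# ---------------------------------------------------------------------------
# System registry
# ---------------------------------------------------------------------------

METHYLATION_STATES = ("WT", "ME")
BOUND_STATES = ("naked", "CEBPB", "E2F1DP1", "both")


@dataclass(frozen=True, order=True)
class SystemLabel:
    """One of the eight methylation x binding-state systems of the study."""

    methylation: str
    bound_state: str

    def __post_init__(self) -> None:
        if self.methylation not in METHYLATION_STATES:
            raise ConfigurationError(
                f"methylation must be one of {METHYLATION_STATES}, "
                f"got {self.methylation!r}")
        if self.bound_state not in BOUND_STATES:
            raise ConfigurationError(
                f"bound_state must be one of {BOUND_STATES}, "
                f"got {self.bound_state!r}")

    @property
    def name(self) -> str:
        return f"{self.methylation}_{self.bound_state}"

    @property
    def has_cebpb(self) -> bool:
        return self.bound_state in ("CEBPB", "both")

    @property
    def has_e2f1dp1(self) -> bool:
        return self.bound_state in ("E2F1DP1", "both")


def enumerate_systems(
    methylations: Sequence[str] = METHYLATION_STATES,
    bound_states: Sequence[str] = BOUND_STATES,
) -> list[SystemLabel]:
    """Enumerate study systems in stable (methylation-major) order.

    The default yields the eight WT/ME x {naked, CEBPB, E2F1DP1, both}
    systems simulated in the study.
    """
    return [SystemLabel(m, b) for m in methylations for b in bound_states]


# ---------------------------------------------------------------------------
# Trajectory handle
# ---------------------------------------------------------------------------

#: chain-role vocabulary.  Protein chains may carry a suffix after a colon,
#: e.g. "protein:CEBPB1".
ROLE_DNA_WATSON = "dna_watson"
ROLE_DNA_CRICK = "dna_crick"
ROLE_PROTEIN = "protein"
ROLE_ION = "ion"

_STANDARD_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "K": 39.098, "CL": 35.45, "NA": 22.990, "MG": 24.305,
}


def _element_from_name(name: str, resname: str = "") -> str:
    name = name.strip()
    if resname.upper() in ("K", "K+", "POT"):
        return "K"
    if resname.upper() in ("CL", "CL-", "CLA"):
        return "CL"
    if not name:
        return "C"
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    return name[0].upper()


def _mass_from_name(name: str, resname: str = "") -> float:
    return _STANDARD_MASSES.get(_element_from_name(name, resname), 12.011)


class TrajectoryHandle:
    """A loaded topology + coordinate trajectory with assigned chain roles.

    Wraps an :class:`MDAnalysis.Universe` (or plain coordinate arrays) and
    records which chain plays which role (DNA Watson / DNA Crick strand,
    protein monomers, ions).  Frames already discarded as equilibration are
    tracked so that trimming is idempotent.
    """

    def __init__(
        self,
        universe: "mda.Universe",
        roles: Mapping[str, str],
        timestep: float | None = None,
        _frame_offset: int = 0,
        _trim_ps: float = 0.0,
    ) -> None:
        self.universe = universe
        self.roles = dict(roles)
        self._frame_offset = int(_frame_offset)
        self._trim_ps = float(_trim_ps)

        chain_ids = set(self.chain_ids())
        for cid in self.roles:
            if cid not in chain_ids:
                raise ConfigurationError(
                    f"role assigned to absent chain {cid!r}; "
                    f"available chains: {sorted(chain_ids)}")

        if timestep is not None:
            self.timestep = float(timestep)
        else:
            dt = getattr(universe.trajectory, "dt", None)
            if dt is None or dt <= 0:
                raise ConfigurationError(
                    "trajectory carries no timestep metadata; pass timestep=")
            self.timestep = float(dt)

        if self.n_frames < 1:
            raise FormatError("trajectory has no frames")

        masses = self.atoms_masses()
        if np.any(masses <= 0):
            raise FormatError("every atom must have a positive mass")

        self._validate_dna()

    # -- construction --------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        coordinates: np.ndarray,
        names: Sequence[str],
        resnames: Sequence[str],
        resids: Sequence[int],
        chain_ids: Sequence[str],
        roles: Mapping[str, str],
        timestep: float,
        masses: Sequence[float] | None = None,
    ) -> "TrajectoryHandle":
        """Build an in-memory handle from raw per-frame coordinates.

        ``coordinates`` has shape (n_frames, n_atoms, 3) in Angstrom;
        residue metadata is per-atom.
        """
        coordinates = np.asarray(coordinates, dtype=float)
        if coordinates.ndim != 3 or coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        n_atoms = coordinates.shape[1]
        names = list(names)
        resnames = list(resnames)
        resids = [int(r) for r in resids]
        chain_ids = list(chain_ids)
        if not (len(names) == len(resnames) == len(resids)
                == len(chain_ids) == n_atoms):
            raise ValueError("per-atom metadata length mismatch")

        # one residue entry per unique (chain, resid)
        res_keys: list[tuple[str, int]] = []
        atom_resindex = np.empty(n_atoms, dtype=int)
        for i, key in enumerate(zip(chain_ids, resids)):
            if not res_keys or res_keys[-1] != key:
                res_keys.append(key)
            atom_resindex[i] = len(res_keys) - 1
        seg_ids: list[str] = []
        res_segindex = np.empty(len(res_keys), dtype=int)
        for j, (cid, _) in enumerate(res_keys):
            if not seg_ids or seg_ids[-1] != cid:
                seg_ids.append(cid)
            res_segindex[j] = len(seg_ids) - 1

        u = mda.Universe.empty(
            n_atoms, n_residues=len(res_keys), n_segments=len(seg_ids),
            atom_resindex=atom_resindex, residue_segindex=res_segindex,
            trajectory=True,
        )
        first_atom_of_res = [int(np.flatnonzero(atom_resindex == j)[0])
                             for j in range(len(res_keys))]
        u.add_TopologyAttr("names", names)
        u.add_TopologyAttr("resnames", [resnames[i] for i in first_atom_of_res])
        u.add_TopologyAttr("resids", [r for _, r in res_keys])
        u.add_TopologyAttr("segids", seg_ids)
        u.add_TopologyAttr("chainIDs", chain_ids)
        if masses is None:
            masses = [_mass_from_name(n, rn) for n, rn in zip(names, resnames)]
        u.add_TopologyAttr("masses", list(masses))
        u.load_new(coordinates.astype(np.float32), format="memory", dt=timestep)
        handle = cls(u, roles, timestep=timestep)
        # MDAnalysis stores positions as float32; keep the float64 originals
        # so that rebuild -> re-measure round trips retain full precision.
        handle._coords64 = coordinates
        return handle

    # -- metadata ------------------------------------------------------

    def chain_ids(self) -> list[str]:
        atoms = self.universe.atoms
        if hasattr(atoms, "chainIDs"):
            seen: list[str] = []
            for cid in atoms.chainIDs:
                if cid not in seen:
                    seen.append(cid)
            return seen
        return list(dict.fromkeys(s.segid for s in self.universe.segments))

    def _chain_selection(self, chain_id: str) -> "mda.AtomGroup":
        atoms = self.universe.atoms
        if hasattr(atoms, "chainIDs"):
            return atoms[atoms.chainIDs == chain_id]
        return atoms[atoms.segids == chain_id]

    def atoms_with_role(self, role_prefix: str) -> "mda.AtomGroup":
        groups = [self._chain_selection(cid)
                  for cid, role in self.roles.items()
                  if role == role_prefix or role.startswith(role_prefix + ":")]
        if not groups:
            return self.universe.atoms[[]]
        out = groups[0]
        for g in groups[1:]:
            out = out + g
        return out

    @property
    def n_frames(self) -> int:
        return len(self.universe.trajectory) - self._frame_offset

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps, relative to the original trajectory start."""
        idx = np.arange(self._frame_offset,
                        self._frame_offset + self.n_frames)
        return idx * self.timestep

    @property
    def duration(self) -> float:
        return len(self.universe.trajectory) * self.timestep

    def atoms_names(self) -> np.ndarray:
        return np.asarray(self.universe.atoms.names)

    def atoms_resnames(self) -> np.ndarray:
        return np.asarray(self.universe.atoms.resnames)

    def atoms_masses(self) -> np.ndarray:
        return np.asarray(self.universe.atoms.masses, dtype=float)

    # -- coordinates ---------------------------------------------------

    _coords64: np.ndarray | None = None

    def coordinates(self, frame: int, atoms: "mda.AtomGroup | None" = None) -> np.ndarray:
        if frame < 0 or frame >= self.n_frames:
            raise IndexError(f"frame {frame} out of range 0..{self.n_frames - 1}")
        if self._coords64 is not None:
            idx = (atoms.indices if atoms is not None
                   else slice(None))
            return np.array(self._coords64[frame + self._frame_offset, idx, :])
        self.universe.trajectory[frame + self._frame_offset]
        group = atoms if atoms is not None else self.universe.atoms
        return group.positions.astype(float).copy()

    def iter_coordinates(self, atoms: "mda.AtomGroup | None" = None) -> Iterable[np.ndarray]:
        for i in range(self.n_frames):
            yield self.coordinates(i, atoms)

    def coordinate_array(self, atoms: "mda.AtomGroup | None" = None) -> np.ndarray:
        """All frames as one (n_frames, n_atoms, 3) array."""
        group = atoms if atoms is not None else self.universe.atoms
        out = np.empty((self.n_frames, len(group), 3))
        for i in range(self.n_frames):
            out[i] = self.coordinates(i, group)
        return out

    # -- DNA structure -------------------------------------------------

    def dna_residues(self, strand: str) -> "mda.ResidueGroup":
        role = ROLE_DNA_WATSON if strand.lower().startswith("w") else ROLE_DNA_CRICK
        group = self.atoms_with_role(role)
        return group.residues

    def _validate_dna(self) -> None:
        w = self.dna_residues("watson")
        c = self.dna_residues("crick")
        if len(w) == 0 and len(c) == 0:
            return
        if len(w) != len(c):
            raise ConfigurationError(
                f"DNA strands have unequal residue counts: {len(w)} vs {len(c)}")
        dna_resnames = {"DA", "DT", "DG", "DC", "5MC", "DA5", "DT5", "DG5",
                        "DC5", "DA3", "DT3", "DG3", "DC3", "A", "T", "G", "C"}
        for res in list(w) + list(c):
            if res.resname.upper() not in dna_resnames:
                raise ConfigurationError(
                    f"chain assigned a DNA role contains non-DNA residue "
                    f"{res.resname!r} (resid {res.resid})")

    @property
    def n_bp(self) -> int:
        return len(self.dna_residues("watson"))

    # -- trimming & export ---------------------------------------------

    def trim_equilibration(self, discard: float) -> "TrajectoryHandle":
        """Drop the first ``discard`` ps as equilibration (idempotent)."""
        if discard < 0:
            raise ValueError("discard must be non-negative")
        if discard <= self._trim_ps:
            return self._copy()
        total = len(self.universe.trajectory)
        skip = int(math.floor(discard / self.timestep))
        if skip >= total:
            raise ValueError(
                f"discarding {discard} ps removes all {total} frames")
        new = TrajectoryHandle(
            self.universe, self.roles, timestep=self.timestep,
            _frame_offset=skip, _trim_ps=discard)
        return self._carry_extras(new)

    def _copy(self) -> "TrajectoryHandle":
        new = TrajectoryHandle(
            self.universe, self.roles, timestep=self.timestep,
            _frame_offset=self._frame_offset, _trim_ps=self._trim_ps)
        return self._carry_extras(new)

    def _carry_extras(self, new: "TrajectoryHandle") -> "TrajectoryHandle":
        for attr in ("_coords64", "contact_truth", "atom_index"):
            if getattr(self, attr, None) is not None:
                setattr(new, attr, getattr(self, attr))
        return new

    def write_pdb(self, path: str | Path) -> None:
        """Write the (trimmed) trajectory as a multi-model PDB."""
        atoms = self.universe.atoms
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with mda.Writer(str(path), multiframe=True, n_atoms=len(atoms)) as w:
                for i in range(self.n_frames):
                    self.universe.trajectory[i + self._frame_offset]
                    w.write(atoms)


def trim_equilibration(traj: TrajectoryHandle, discard: float) -> TrajectoryHandle:
    """Functional form of :meth:`TrajectoryHandle.trim_equilibration`."""
    return traj.trim_equilibration(discard)


def load_system(
    topology_path: str | Path,
    trajectory_path: str | Path | None = None,
    roles: Mapping[str, str] | None = None,
    timestep: float | None = None,
) -> TrajectoryHandle:
    """Load a topology (PDB/GRO) plus optional trajectory (XTC/DCD/PDB).

    ``roles`` maps chain identifiers to chain roles ("dna_watson",
    "dna_crick", "protein[:name]", "ion").  Chains without a role are kept
    but ignored by the role-based analyses.
    """
    topology_path = Path(topology_path)
    if not topology_path.exists():
        raise FormatError(f"topology file not found: {topology_path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if trajectory_path is None:
                u = mda.Universe(str(topology_path))
            else:
                trajectory_path = Path(trajectory_path)
                if not trajectory_path.exists():
                    raise FormatError(f"trajectory file not found: {trajectory_path}")
                u = mda.Universe(str(topology_path), str(trajectory_path))
    except FormatError:
        raise
    except Exception as exc:  # MDAnalysis raises a zoo of parse errors
        raise FormatError(f"cannot read {topology_path}: {exc}") from exc
    if not hasattr(u.atoms, "masses"):
        u.add_TopologyAttr("masses", [
            _mass_from_name(n, rn)
            for n, rn in zip(u.atoms.names, u.atoms.resnames)])
    else:
        m = np.asarray(u.atoms.masses)
        if np.any(m <= 0):
            fixed = [mi if mi > 0 else _mass_from_name(n, rn)
                     for mi, n, rn in zip(m, u.atoms.names, u.atoms.resnames)]
            u.atoms.masses = fixed
    return TrajectoryHandle(u, roles or {}, timestep=timestep)


# ---------------------------------------------------------------------------
# Atom force-field parameters (charge / LJ)
# ---------------------------------------------------------------------------

@dataclass
class AtomParams:
    """Per-atom nonbonded parameters assigned to a topology."""

    charge: np.ndarray   # e
    sigma: np.ndarray    # Angstrom
    epsilon: np.ndarray  # kcal/mol

    def __post_init__(self) -> None:
        self.charge = np.asarray(self.charge, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if np.any(self.sigma <= 0):
            raise ValueError("LJ sigma must be > 0 for every atom")
        if np.any(self.epsilon < 0):
            raise ValueError("LJ epsilon must be >= 0 for every atom")


class AtomParamTable:
    """Lookup (residue name, atom name) -> (charge, sigma, epsilon).

    Plain-text format, one entry per line::

        atom_name residue charge sigma epsilon

    ``residue`` may be ``*`` to match any residue.
    """

    def __init__(self, entries: Mapping[tuple[str, str], tuple[float, float, float]]):
        self.entries = dict(entries)

    @classmethod
    def read(cls, path: str | Path) -> "AtomParamTable":
        entries: dict[tuple[str, str], tuple[float, float, float]] = {}
        for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 5:
                raise FormatError(
                    f"{path}:{ln}: expected 'atom residue charge sigma epsilon'")
            name, res = parts[0], parts[1]
            try:
                q, s, e = (float(x) for x in parts[2:])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-numeric parameter") from exc
            entries[(res.upper(), name.upper())] = (q, s, e)
        return cls(entries)

    def write(self, path: str | Path) -> None:
        lines = ["# atom residue charge sigma epsilon"]
        for (res, name), (q, s, e) in sorted(self.entries.items()):
            lines.append(f"{name} {res} {q:.6f} {s:.6f} {e:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")

    def assign(self, handle: TrajectoryHandle) -> AtomParams:
        names = handle.atoms_names()
        resnames = handle.atoms_resnames()
        q = np.empty(len(names))
        s = np.empty(len(names))
        e = np.empty(len(names))
        for i, (name, res) in enumerate(zip(names, resnames)):
            key = (res.upper(), name.upper())
            wild = ("*", name.upper())
            if key in self.entries:
                q[i], s[i], e[i] = self.entries[key]
            elif wild in self.entries:
                q[i], s[i], e[i] = self.entries[wild]
            else:
                raise ConfigurationError(
                    f"no nonbonded parameters for atom {name!r} in residue {res!r}")
        return AtomParams(q, s, e)
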