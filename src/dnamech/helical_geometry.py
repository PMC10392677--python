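"""Base-pair frames, helical parameters, grooves and backbone torsions.

The rigid-body parameter convention is the mid-frame (CEHS-style)
decomposition used by the standard DNA analysis programs: for two frames
(R1, o1) and (R2, o2) the relative rotation is factored as

    R1^T R2 = Rz(omega/2 - phi) Ry(Gamma) Rz(omega/2 + phi)

where ``omega`` is the twist-like angle, ``Gamma = hypot(roll, tilt)`` the
bend magnitude and ``phi = atan2(tilt, roll)`` its phase; translations are
read in the mid-frame.  Base-pair frames follow the standard reference
frame: x points into the major groove, y toward the Watson backbone, z along
the helix 5'->3' of the Watson strand.  The inverse (compose) direction uses
exactly the same factorisation, which makes build -> measure an identity up
to floating-point error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, UnivariateSpline

from .core_io import ConfigurationError, FormatError, TrajectoryHandle

STEP_PARAM_NAMES = ("shift", "slide", "rise", "tilt", "roll", "twist")
BP_PARAM_NAMES = ("shear", "stretch", "stagger", "buckle", "propeller",
                  "opening", "xdisp", "ydisp")
GROOVE_PARAM_NAMES = ("major_width", "major_depth",
                      "minor_width", "minor_depth")
TORSION_NAMES = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi")

#: radial van der Waals correction subtracted from cross-strand phosphate
#: spline distances to convert them into groove widths (Angstrom).
GROOVE_WIDTH_OFFSET = 5.8

_FLIP = np.diag([1.0, -1.0, -1.0])


# ---------------------------------------------------------------------------
# Rotation helpers (vectorised over leading axes; angles in degrees)
# ---------------------------------------------------------------------------

def _rotz(angle_deg: np.ndarray) -> np.ndarray:
    a = np.deg2rad(np.asarray(angle_deg, dtype=float))
    c, s = np.cos(a), np.sin(a)
    out = np.zeros(a.shape + (3, 3))
    out[..., 0, 0] = c
    out[..., 0, 1] = -s
    out[..., 1, 0] = s
    out[..., 1, 1] = c
    out[..., 2, 2] = 1.0
    return out


def _roty(angle_deg: np.ndarray) -> np.ndarray:
    a = np.deg2rad(np.asarray(angle_deg, dtype=float))
    c, s = np.cos(a), np.sin(a)
    out = np.zeros(a.shape + (3, 3))
    out[..., 0, 0] = c
    out[..., 0, 2] = s
    out[..., 2, 0] = -s
    out[..., 2, 2] = c
    out[..., 1, 1] = 1.0
    return out


def _wrap_deg(angle: np.ndarray) -> np.ndarray:
    """Wrap angles to (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    return wrapped


def cehs_decompose(R1: np.ndarray, o1: np.ndarray,
                   R2: np.ndarray, o2: np.ndarray):
    """Mid-frame decomposition of the transform from frame 1 to frame 2.

    Returns ``(params, Rm, om)`` where ``params[..., :]`` is
    (dx, dy, dz, x-rotation, y-rotation, z-rotation) in Angstrom/degrees —
    i.e. (shift, slide, rise, tilt, roll, twist) for a step or
    (shear, stretch, stagger, buckle, propeller, opening) for a base pair —
    and (Rm, om) is the mid frame.
    """
    R1 = np.asarray(R1, dtype=float)
    R2 = np.asarray(R2, dtype=float)
    o1 = np.asarray(o1, dtype=float)
    o2 = np.asarray(o2, dtype=float)
    A = np.swapaxes(R1, -1, -2) @ R2

    cosG = np.clip(A[..., 2, 2], -1.0, 1.0)
    gamma_mag = np.degrees(np.arccos(cosG))
    sinG = np.sqrt(np.maximum(0.0, 1.0 - cosG ** 2))
    degenerate = sinG < 1e-10

    alpha = np.degrees(np.arctan2(A[..., 1, 2], A[..., 0, 2]))
    gamma = np.degrees(np.arctan2(A[..., 2, 1], -A[..., 2, 0]))
    # alpha, gamma are principal values; their sum/difference must be
    # range-reduced together, otherwise the bend phase aliases by 180 deg.
    omega_raw = alpha + gamma
    phi = (gamma - alpha) / 2.0
    out_of_range = (omega_raw > 180.0) | (omega_raw <= -180.0)
    omega = _wrap_deg(omega_raw)
    phi = np.where(out_of_range, phi + 180.0, phi)
    phi = _wrap_deg(phi)

    # pure-twist limit: A ~ Rz(omega), bend phase undefined -> zero bend
    omega_deg_plain = np.degrees(np.arctan2(A[..., 1, 0], A[..., 0, 0]))
    omega = np.where(degenerate, omega_deg_plain, omega)
    phi = np.where(degenerate, 0.0, phi)
    gamma_mag = np.where(degenerate, 0.0, gamma_mag)

    roll = gamma_mag * np.cos(np.deg2rad(phi))
    tilt = gamma_mag * np.sin(np.deg2rad(phi))

    Rm = R1 @ _rotz(omega / 2.0 - phi) @ _roty(gamma_mag / 2.0) @ _rotz(phi)
    disp = o2 - o1
    t = np.einsum("...ji,...j->...i", Rm, disp)
    om = 0.5 * (o1 + o2)

    params = np.stack([t[..., 0], t[..., 1], t[..., 2], tilt, roll, omega],
                      axis=-1)
    return params, Rm, om


def cehs_compose(R1: np.ndarray, o1: np.ndarray, params: np.ndarray):
    """Inverse of :func:`cehs_decompose`: apply parameters to frame 1."""
    params = np.asarray(params, dtype=float)
    tilt, roll, omega = params[..., 3], params[..., 4], params[..., 5]
    gamma_mag = np.hypot(roll, tilt)
    phi = np.degrees(np.arctan2(tilt, roll))
    phi = np.where(gamma_mag < 1e-12, 0.0, phi)

    R2 = R1 @ _rotz(omega / 2.0 - phi) @ _roty(gamma_mag) @ _rotz(omega / 2.0 + phi)
    Rm = R1 @ _rotz(omega / 2.0 - phi) @ _roty(gamma_mag / 2.0) @ _rotz(phi)
    o2 = o1 + np.einsum("...ij,...j->...i", Rm, params[..., :3])
    return R2, o2, Rm


def bp_frames_from_params(params: np.ndarray, Rm: np.ndarray, om: np.ndarray):
    """Split a mid frame into the two constituent frames.

    Returns ``(R1, o1, R2, o2)`` such that ``cehs_decompose(R1,o1,R2,o2)``
    recovers ``params`` and ``(Rm, om)``.  For a base pair, frame 1 is the
    flipped Crick base frame and frame 2 the Watson base frame.
    """
    params = np.asarray(params, dtype=float)
    tilt, roll, omega = params[..., 3], params[..., 4], params[..., 5]
    gamma_mag = np.hypot(roll, tilt)
    phi = np.degrees(np.arctan2(tilt, roll))
    phi = np.where(gamma_mag < 1e-12, 0.0, phi)

    R2 = Rm @ _rotz(-phi) @ _roty(gamma_mag / 2.0) @ _rotz(omega / 2.0 + phi)
    R1 = Rm @ _rotz(-phi) @ _roty(-gamma_mag / 2.0) @ _rotz(phi - omega / 2.0)
    shift_vec = np.einsum("...ij,...j->...i", Rm, params[..., :3])
    o2 = om + 0.5 * shift_vec
    o1 = om - 0.5 * shift_vec
    return R1, o1, R2, o2


# ---------------------------------------------------------------------------
# Idealised base geometries (standard reference frame, z = 0 plane)
# ---------------------------------------------------------------------------
# Ring + exocyclic heavy atoms of the four bases plus 5-methylcytosine, in
# the base's own standard frame.  Values follow the standard-reference-frame
# layout (origin near the WC edge midpoint, y toward the backbone); they are
# the package's pinned idealised geometry for fitting and rebuilding.

BASE_GEOMETRY: dict[str, dict[str, tuple[float, float]]] = {
    "A": {
        "N9": (-1.291, 4.498), "C8": (0.024, 4.897), "N7": (0.877, 3.902),
        "C5": (0.071, 2.771), "C6": (0.369, 1.398), "N6": (1.611, 0.909),
        "N1": (-0.668, 0.532), "C2": (-1.912, 1.023), "N3": (-2.320, 2.290),
        "C4": (-1.267, 3.124), "C1'": (-2.479, 5.346),
    },
    "G": {
        "N9": (-1.289, 4.551), "C8": (0.023, 4.962), "N7": (0.870, 3.969),
        "C5": (0.071, 2.833), "C6": (0.424, 1.460), "O6": (1.554, 0.955),
        "N1": (-0.700, 0.641), "C2": (-1.999, 1.087), "N2": (-2.949, 0.139),
        "N3": (-2.342, 2.364), "C4": (-1.265, 3.177), "C1'": (-2.477, 5.399),
    },
    "C": {
        "N1": (-1.285, 4.542), "C2": (-1.472, 3.158), "O2": (-2.628, 2.709),
        "N3": (-0.391, 2.344), "C4": (0.837, 2.868), "N4": (1.875, 2.027),
        "C5": (1.056, 4.275), "C6": (-0.023, 5.068), "C1'": (-2.477, 5.402),
    },
    "T": {
        "N1": (-1.284, 4.500), "C2": (-1.462, 3.135), "O2": (-2.562, 2.608),
        "N3": (-0.298, 2.407), "C4": (0.994, 2.897), "O4": (1.944, 2.119),
        "C5": (1.106, 4.338), "C7": (2.466, 4.961), "C6": (-0.024, 5.057),
        "C1'": (-2.481, 5.354),
    },
}
BASE_GEOMETRY["5MC"] = dict(BASE_GEOMETRY["C"], C5M=(2.420, 4.962))

#: atoms used for least-squares frame fitting (ring atoms only)
BASE_RING_ATOMS: dict[str, tuple[str, ...]] = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "T": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "5MC": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

#: crude backbone-atom positions in the base frame; enough to define the
#: standard torsions on rebuilt duplexes (not crystallographic geometry).
BACKBONE_LOCAL: dict[str, tuple[float, float, float]] = {
    "P": (-3.00, 8.50, 0.00),
    "O5'": (-3.60, 8.05, 0.75),
    "C5'": (-4.35, 7.25, 0.15),
    "C4'": (-4.25, 6.10, -0.75),
    "O4'": (-3.40, 5.30, -0.05),
    "C3'": (-3.75, 6.15, -2.15),
    "O3'": (-3.55, 7.35, -2.80),
}

_RESNAME_TO_BASE = {
    "DA": "A", "DA5": "A", "DA3": "A", "A": "A",
    "DT": "T", "DT5": "T", "DT3": "T", "T": "T",
    "DG": "G", "DG5": "G", "DG3": "G", "G": "G",
    "DC": "C", "DC5": "C", "DC3": "C", "C": "C",
    "5MC": "5MC", "5CM": "5MC", "DCM": "5MC",
}

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def base_letter(resname: str) -> str | None:
    return _RESNAME_TO_BASE.get(resname.upper())


def standard_base_coords(base: str, atom_names: Sequence[str]) -> np.ndarray:
    geo = BASE_GEOMETRY[base]
    return np.array([[geo[a][0], geo[a][1], 0.0] for a in atom_names])


# ---------------------------------------------------------------------------
# Frame fitting
# ---------------------------------------------------------------------------

def _kabsch(standard: np.ndarray, observed: np.ndarray):
    """Proper rotation R and origin o such that observed ~ standard @ R.T + o.

    ``standard`` (n,3) are idealised coordinates in the base frame,
    ``observed`` (..., n, 3) lab coordinates.  Vectorised over leading axes.
    """
    obs = np.asarray(observed, dtype=float)
    std = np.asarray(standard, dtype=float)
    c_obs = obs.mean(axis=-2)
    c_std = std.mean(axis=0)
    H = np.einsum("...ni,nj->...ij", obs - c_obs[..., None, :], std - c_std)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.zeros(U.shape)
    D[..., 0, 0] = 1.0
    D[..., 1, 1] = 1.0
    D[..., 2, 2] = d
    R = U @ D @ Vt
    origin = c_obs - np.einsum("...ij,j->...i", R, c_std)
    return R, origin


@dataclass
class BasePairFrames:
    """Fitted base and base-pair frames for every frame of a trajectory.

    ``watson_R``/``crick_R`` are the per-base frames (each base in its own
    5'->3' convention); ``bp_R``/``bp_o`` the averaged, re-orthonormalised
    base-pair frames.  ``valid`` marks base pairs whose both bases could be
    fitted.  Array shapes: rotations (n_frames, n_bp, 3, 3), origins
    (n_frames, n_bp, 3).
    """

    watson_R: np.ndarray
    watson_o: np.ndarray
    crick_R: np.ndarray
    crick_o: np.ndarray
    bp_R: np.ndarray
    bp_o: np.ndarray
    intra_params: np.ndarray      # (n_frames, n_bp, 6)
    valid: np.ndarray             # (n_bp,) bool
    sequence: str
    failures: list[str] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.bp_R.shape[0]

    @property
    def n_bp(self) -> int:
        return self.bp_R.shape[1]


def fit_base_pair_frames(traj: TrajectoryHandle,
                         check_handedness: bool = True) -> BasePairFrames:
    """Least-squares fit of every base to its idealised geometry.

    The bp frame is the CEHS mid frame of the Watson base frame and the
    flipped Crick base frame; intra-bp parameters fall out of the same
    decomposition.  Residues with missing ring atoms are recorded in
    ``failures`` and the bp flagged invalid.
    """
    watson = traj.dna_residues("watson")
    crick = traj.dna_residues("crick")
    if len(watson) < 2:
        raise ConfigurationError("need at least 2 base pairs")
    n_bp = len(watson)
    n_frames = traj.n_frames

    # Crick residues pair with Watson residues in reverse order along the
    # chain; both handles index by bp number so we align by position: the
    # Crick strand runs antiparallel, so bp i pairs Watson[i] with
    # Crick[n_bp - 1 - i] when the Crick chain is stored 5'->3'.
    crick_list = list(crick)
    crick_by_bp = crick_list[::-1]

    seq_letters = []
    per_bp_atoms: list[tuple[np.ndarray | None, np.ndarray | None,
                             np.ndarray | None, np.ndarray | None]] = []
    failures: list[str] = []
    valid = np.ones(n_bp, dtype=bool)
    for i in range(n_bp):
        wres = watson[i]
        cres = crick_by_bp[i]
        wbase = base_letter(wres.resname)
        cbase = base_letter(cres.resname)
        if wbase is None or cbase is None:
            failures.append(f"bp {i + 1}: unknown residue "
                            f"{wres.resname}/{cres.resname}")
            valid[i] = False
            per_bp_atoms.append((None, None, None, None))
            seq_letters.append("N")
            continue
        seq_letters.append("C" if wbase == "5MC" else wbase)
        entry = []
        ok = True
        for res, base in ((wres, wbase), (cres, cbase)):
            names = BASE_RING_ATOMS[base]
            sel = {a.name: a.index for a in res.atoms}
            if not all(n in sel for n in names):
                missing = [n for n in names if n not in sel]
                failures.append(
                    f"bp {i + 1} residue {res.resname}{res.resid}: "
                    f"missing ring atoms {missing}")
                ok = False
                break
            idx = np.array([sel[n] for n in names])
            entry.append((standard_base_coords(base, names), idx))
        if not ok:
            valid[i] = False
            per_bp_atoms.append((None, None, None, None))
        else:
            per_bp_atoms.append((entry[0][0], entry[0][1],
                                 entry[1][0], entry[1][1]))

    coords = traj.coordinate_array()

    watson_R = np.full((n_frames, n_bp, 3, 3), np.nan)
    watson_o = np.full((n_frames, n_bp, 3), np.nan)
    crick_R = np.full((n_frames, n_bp, 3, 3), np.nan)
    crick_o = np.full((n_frames, n_bp, 3), np.nan)

    for i in range(n_bp):
        wstd, widx, cstd, cidx = per_bp_atoms[i]
        if wstd is None:
            continue
        Rw, ow = _kabsch(wstd, coords[:, widx, :])
        Rc, oc = _kabsch(cstd, coords[:, cidx, :])
        watson_R[:, i] = Rw
        watson_o[:, i] = ow
        crick_R[:, i] = Rc
        crick_o[:, i] = oc

    crick_flipped = crick_R @ _FLIP
    intra, bp_R, bp_o = cehs_decompose(crick_flipped, crick_o,
                                       watson_R, watson_o)

    frames = BasePairFrames(
        watson_R=watson_R, watson_o=watson_o,
        crick_R=crick_R, crick_o=crick_o,
        bp_R=bp_R, bp_o=bp_o, intra_params=intra,
        valid=valid, sequence="".join(seq_letters), failures=failures)

    if check_handedness:
        good = np.flatnonzero(valid[:-1] & valid[1:])
        if good.size:
            step, _, _ = cehs_decompose(
                bp_R[0, good], bp_o[0, good],
                bp_R[0, good + 1], bp_o[0, good + 1])
            # mirrored input flips either the twist sign or the alignment
            # of base normals with the 5'->3' strand direction (rise < 0)
            if (np.nanmedian(step[..., 5]) < 0
                    or np.nanmedian(step[..., 2]) < 0):
                raise FormatError(
                    "duplex appears left-handed or mirrored: "
                    "right-handedness violation")
    return frames


# ---------------------------------------------------------------------------
# Helical axis
# ---------------------------------------------------------------------------

def helical_axis(bp_o: np.ndarray, smoothing: float = 1.0) -> np.ndarray:
    """Smoothed curve through bp origins, sampled at each bp level.

    ``bp_o`` is (n_frames, n_bp, 3); a cubic smoothing spline is fitted per
    frame and coordinate with smoothing factor ``smoothing`` (Angstrom^2 per
    bp of allowed residual).  Returns an array of the same shape.
    """
    n_frames, n_bp, _ = bp_o.shape
    u = np.arange(n_bp, dtype=float)
    out = np.empty_like(bp_o)
    s = smoothing * n_bp
    for f in range(n_frames):
        for k in range(3):
            y = bp_o[f, :, k]
            if np.any(~np.isfinite(y)):
                m = np.isfinite(y)
                if m.sum() < 4:
                    out[f, :, k] = np.nan
                    continue
                spl = UnivariateSpline(u[m], y[m], k=3, s=smoothing * m.sum())
                out[f, :, k] = spl(u)
            else:
                spl = UnivariateSpline(u, y, k=3, s=s)
                out[f, :, k] = spl(u)
    return out


# ---------------------------------------------------------------------------
# Helical parameter ensemble
# ---------------------------------------------------------------------------

@dataclass
class HelicalEnsemble:
    """Time-indexed helical/groove/torsion parameters for one system.

    ``step_params``: (n_frames, n_bp - 1, 6) in :data:`STEP_PARAM_NAMES`
    order; ``bp_params``: (n_frames, n_bp, 8) in :data:`BP_PARAM_NAMES`
    order; ``grooves``: (n_frames, n_bp, 4) in :data:`GROOVE_PARAM_NAMES`
    order (NaN where undefined, e.g. near termini); ``torsions``:
    (n_frames, 2, n_bp, 7) per strand (0 Watson, 1 Crick) or None;
    ``bii_state``: boolean BII flag of matching shape or None.
    """

    sequence: str
    times: np.ndarray
    step_params: np.ndarray
    bp_params: np.ndarray
    grooves: np.ndarray | None = None
    torsions: np.ndarray | None = None
    bii_state: np.ndarray | None = None
    methylation: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        n_bp = len(self.sequence)
        if self.bp_params.shape[1] != n_bp:
            raise ValueError("bp_params inconsistent with sequence length")
        if self.step_params.shape[1] != n_bp - 1:
            raise ValueError("step_params inconsistent with sequence length")
        if self.step_params.shape[0] != self.bp_params.shape[0]:
            raise ValueError("frame count mismatch")

    @property
    def n_frames(self) -> int:
        return self.bp_params.shape[0]

    @property
    def n_bp(self) -> int:
        return len(self.sequence)

    def series(self, parameter: str) -> np.ndarray:
        """Per-position time series, shape (n_frames, n_positions).

        Step parameters are indexed by step (1..n_bp-1), bp and groove
        parameters by bp (1..n_bp).
        """
        if parameter in STEP_PARAM_NAMES:
            return self.step_params[:, :, STEP_PARAM_NAMES.index(parameter)]
        if parameter in BP_PARAM_NAMES:
            return self.bp_params[:, :, BP_PARAM_NAMES.index(parameter)]
        if parameter in GROOVE_PARAM_NAMES:
            if self.grooves is None:
                raise KeyError("ensemble carries no groove parameters")
            return self.grooves[:, :, GROOVE_PARAM_NAMES.index(parameter)]
        raise KeyError(f"unknown parameter {parameter!r}")

    def mean_profile(self, parameter: str) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.series(parameter), axis=0)

    # -- tidy CSV interchange ------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: frame, index (1-based bp/step), parameter, value."""
        blocks = []
        for names, arr in ((STEP_PARAM_NAMES, self.step_params),
                           (BP_PARAM_NAMES, self.bp_params),
                           (GROOVE_PARAM_NAMES, self.grooves)):
            if arr is None:
                continue
            n_frames, n_pos, n_par = arr.shape
            frame_idx = np.repeat(np.arange(n_frames), n_pos * n_par)
            pos_idx = np.tile(np.repeat(np.arange(1, n_pos + 1), n_par), n_frames)
            par_idx = np.tile(np.array(names), n_frames * n_pos)
            blocks.append(pd.DataFrame({
                "frame": frame_idx, "index": pos_idx,
                "parameter": par_idx, "value": arr.reshape(-1)}))
        return pd.concat(blocks, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sequence: str,
                   times: np.ndarray | None = None) -> "HelicalEnsemble":
        n_bp = len(sequence)
        frames = np.sort(df["frame"].unique())
        n_frames = len(frames)
        frame_pos = {f: i for i, f in enumerate(frames)}
        step = np.full((n_frames, n_bp - 1, 6), np.nan)
        bp = np.full((n_frames, n_bp, 8), np.nan)
        groove = np.full((n_frames, n_bp, 4), np.nan)
        has_groove = False
        for names, arr, width in ((STEP_PARAM_NAMES, step, n_bp - 1),
                                  (BP_PARAM_NAMES, bp, n_bp),
                                  (GROOVE_PARAM_NAMES, groove, n_bp)):
            sub = df[df["parameter"].isin(names)]
            if sub.empty:
                continue
            if names is GROOVE_PARAM_NAMES:
                has_groove = True
            fi = sub["frame"].map(frame_pos).to_numpy()
            pi = sub["index"].to_numpy(dtype=int) - 1
            ki = sub["parameter"].map({n: k for k, n in enumerate(names)}).to_numpy()
            arr[fi, pi, ki] = sub["value"].to_numpy(dtype=float)
        if times is None:
            times = frames.astype(float)
        return cls(sequence=sequence, times=np.asarray(times, dtype=float),
                   step_params=step, bp_params=bp,
                   grooves=groove if has_groove else None)

    @classmethod
    def from_csv(cls, path: str | Path, sequence: str) -> "HelicalEnsemble":
        return cls.from_frame(pd.read_csv(path), sequence)


def compute_parameters(frames: BasePairFrames,
                       times: np.ndarray | None = None,
                       axis_smoothing: float = 1.0) -> HelicalEnsemble:
    """Derive the 12 helical parameters (+ axis displacement) from frames."""
    n_frames, n_bp = frames.n_frames, frames.n_bp
    step, _, _ = cehs_decompose(
        frames.bp_R[:, :-1], frames.bp_o[:, :-1],
        frames.bp_R[:, 1:], frames.bp_o[:, 1:])

    bp = np.full((n_frames, n_bp, 8), np.nan)
    bp[:, :, :6] = frames.intra_params

    axis = helical_axis(frames.bp_o, smoothing=axis_smoothing)
    rel = frames.bp_o - axis
    bp[:, :, 6] = np.einsum("fbi,fbi->fb", rel, frames.bp_R[..., :, 0])
    bp[:, :, 7] = np.einsum("fbi,fbi->fb", rel, frames.bp_R[..., :, 1])
    # terminal bp excluded from axis-derived quantities
    bp[:, 0, 6:] = np.nan
    bp[:, -1, 6:] = np.nan

    if times is None:
        times = np.arange(n_frames, dtype=float)
    return HelicalEnsemble(
        sequence=frames.sequence, times=np.asarray(times, dtype=float),
        step_params=step, bp_params=bp)


# ---------------------------------------------------------------------------
# Groove geometry
# ---------------------------------------------------------------------------

def compute_grooves(traj: TrajectoryHandle,
                    frames: BasePairFrames | None = None,
                    width_offset: float = GROOVE_WIDTH_OFFSET,
                    axis_smoothing: float = 1.0,
                    samples_per_step: int = 12) -> np.ndarray:
    """Major/minor groove widths and depths per bp level.

    Widths: cubic splines are threaded through the phosphate positions of
    each strand; for every interior bp level the minimal cross-strand spline
    distance is found separately on the major- and minor-groove side (side
    classified by the sign of the connector midpoint along the bp frame's
    x-axis, which points into the major groove) and reduced by
    ``width_offset`` (phosphate van der Waals).  Depths: distance from the
    connector midpoint to the helical axis at that level.  Returns
    (n_frames, n_bp, 4) in :data:`GROOVE_PARAM_NAMES` order with NaN where
    undefined (termini, missing phosphates).
    """
    if frames is None:
        frames = fit_base_pair_frames(traj)
    n_frames, n_bp = frames.n_frames, frames.n_bp

    watson = traj.dna_residues("watson")
    crick_by_bp = list(traj.dna_residues("crick"))[::-1]

    def p_indices(residues) -> tuple[np.ndarray, np.ndarray]:
        idx, levels = [], []
        for i, res in enumerate(residues):
            sel = {a.name: a.index for a in res.atoms}
            if "P" in sel:
                idx.append(sel["P"])
                levels.append(i)
        return np.array(idx, dtype=int), np.array(levels, dtype=float)

    w_idx, w_lvl = p_indices(watson)
    c_idx, c_lvl = p_indices(crick_by_bp)
    out = np.full((n_frames, n_bp, 4), np.nan)
    if len(w_idx) < 4 or len(c_idx) < 4:
        warnings.warn("fewer than 4 phosphates per strand: grooves undefined")
        return out

    coords = traj.coordinate_array()
    axis = helical_axis(frames.bp_o, smoothing=axis_smoothing)

    t_dense = np.linspace(c_lvl[0], c_lvl[-1],
                          int((c_lvl[-1] - c_lvl[0]) * samples_per_step) + 1)
    interior = range(1, n_bp - 1)
    for f in range(n_frames):
        wp = coords[f, w_idx, :]
        cp = coords[f, c_idx, :]
        w_spl = CubicSpline(w_lvl, wp, axis=0)
        c_spl = CubicSpline(c_lvl, cp, axis=0)
        c_dense = c_spl(t_dense)
        for i in interior:
            if not frames.valid[i] or not (w_lvl[0] <= i <= w_lvl[-1]):
                continue
            wi = w_spl(float(i))
            d = np.linalg.norm(c_dense - wi, axis=1)
            mid = 0.5 * (c_dense + wi)
            side = np.einsum("nj,j->n", mid - frames.bp_o[f, i],
                             frames.bp_R[f, i, :, 0])
            for g, mask in ((0, side >= 0), (2, side < 0)):
                if not mask.any():
                    continue
                j = np.argmin(np.where(mask, d, np.inf))
                out[f, i, g] = d[j] - width_offset
                out[f, i, g + 1] = np.linalg.norm(mid[j] - axis[f, i])
    return out


# ---------------------------------------------------------------------------
# Backbone torsions and BI/BII classification
# ---------------------------------------------------------------------------

def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> np.ndarray:
    """Signed dihedral angle (IUPAC convention) in degrees, vectorised."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.einsum("...i,...i->...", b0, b1)[..., None] * b1
    w = b2 - np.einsum("...i,...i->...", b2, b1)[..., None] * b1
    x = np.einsum("...i,...i->...", v, w)
    y = np.einsum("...i,...i->...", np.cross(b1, v), w)
    return np.degrees(np.arctan2(y, x))


_TORSION_ATOMS = {
    # name: (quadruplet, residue offsets)
    "alpha": (("O3'", "P", "O5'", "C5'"), (-1, 0, 0, 0)),
    "beta": (("P", "O5'", "C5'", "C4'"), (0, 0, 0, 0)),
    "gamma": (("O5'", "C5'", "C4'", "C3'"), (0, 0, 0, 0)),
    "delta": (("C5'", "C4'", "C3'", "O3'"), (0, 0, 0, 0)),
    "epsilon": (("C4'", "C3'", "O3'", "P"), (0, 0, 0, 1)),
    "zeta": (("C3'", "O3'", "P", "O5'"), (0, 0, 1, 1)),
}


def compute_torsions(traj: TrajectoryHandle) -> tuple[np.ndarray, np.ndarray]:
    """Backbone torsions alpha..zeta plus chi, and the BI/BII state.

    Returns ``(angles, bii)``: ``angles`` is (n_frames, 2, n_bp, 7) in
    :data:`TORSION_NAMES` order (strand 0 Watson, 1 Crick, both indexed by
    bp number); ``bii`` a boolean array (True = BII) defined where epsilon
    and zeta are defined.  Angles whose atoms are missing are NaN.
    """
    coords = traj.coordinate_array()
    n_frames = coords.shape[0]
    strands = [list(traj.dna_residues("watson")),
               list(traj.dna_residues("crick"))[::-1]]
    n_bp = len(strands[0])
    angles = np.full((n_frames, 2, n_bp, 7), np.nan)

    for s, residues in enumerate(strands):
        atom_of = []
        for res in residues:
            atom_of.append({a.name: a.index for a in res.atoms})
        # chain order for torsion neighbours: Watson residues run 5'->3'
        # with bp number; Crick residues run 5'->3' against bp number.
        order = list(range(n_bp)) if s == 0 else list(range(n_bp - 1, -1, -1))
        pos_in_chain = {b: k for k, b in enumerate(order)}
        for b in range(n_bp):
            k = pos_in_chain[b]
            for t, name in enumerate(TORSION_NAMES[:6]):
                quad, offs = _TORSION_ATOMS[name]
                idx = []
                ok = True
                for a, off in zip(quad, offs):
                    kk = k + off
                    if kk < 0 or kk >= n_bp:
                        ok = False
                        break
                    amap = atom_of[order[kk]]
                    if a not in amap:
                        ok = False
                        break
                    idx.append(amap[a])
                if ok:
                    p = coords[:, idx, :]
                    angles[:, s, b, t] = dihedral(p[:, 0], p[:, 1],
                                                  p[:, 2], p[:, 3])
            # chi: O4'-C1'-N9-C4 (purine) or O4'-C1'-N1-C2 (pyrimidine)
            amap = atom_of[b]
            base = base_letter(strands[s][b].resname)
            if base is None:
                continue
            quad = (("O4'", "C1'", "N9", "C4") if base in ("A", "G")
                    else ("O4'", "C1'", "N1", "C2"))
            if all(a in amap for a in quad):
                idx = [amap[a] for a in quad]
                p = coords[:, idx, :]
                angles[:, s, b, 6] = dihedral(p[:, 0], p[:, 1], p[:, 2], p[:, 3])

    eps = angles[..., TORSION_NAMES.index("epsilon")]
    zet = angles[..., TORSION_NAMES.index("zeta")]
    diff = _wrap_deg(eps - zet)
    bii = diff >= 0
    return angles, bii


def classify_bi_bii(epsilon: np.ndarray, zeta: np.ndarray) -> np.ndarray:
    """BI/BII state from the wrapped epsilon - zeta difference.

    Returns an array of "BI"/"BII" strings: BI where (epsilon - zeta)
    wrapped to (-180, 180] is negative, BII otherwise.
    """
    diff = _wrap_deg(np.asarray(epsilon, dtype=float)
                     - np.asarray(zeta, dtype=float))
    return np.where(diff < 0, "BI", "BII")
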