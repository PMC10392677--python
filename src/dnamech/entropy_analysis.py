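"""Schlitter upper-bound configurational entropies over trajectory windows.

For a selection of atoms with diagonal mass matrix M and Cartesian
covariance sigma (after removing overall translation, optionally also
rotation), Schlitter's formula bounds the configurational entropy:

    S' = (k_B / 2) ln det[ 1 + (k_B T e^2 / hbar^2) M^(1/2) sigma M^(1/2) ]

Reported as T*S' in kcal/mol at T = 300 K.  Window statistics follow the
convention of evaluating the full post-equilibration trajectory plus its
last 75% and last 50%, with the spread over the three windows as the
uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import CONSTANTS, TrajectoryHandle

WINDOW_FRACTIONS = {"full": 1.0, "last_75": 0.75, "last_50": 0.5}

#: eigenvalue floor on M^(1/2) sigma M^(1/2) for ln det stability
EIGENVALUE_FLOOR = 1e-12


def schlitter_prefactor(temperature: float = CONSTANTS.T_ref) -> float:
    """Dimensionless k_B T e^2 / hbar^2 per (amu * A^2)."""
    c = CONSTANTS
    return (c.k_B_SI * temperature * c.e_euler ** 2
            * c.amu_SI * 1e-20 / c.hbar_SI ** 2)


def _remove_rigid_body(coords: np.ndarray, masses: np.ndarray,
                       remove: str) -> np.ndarray:
    """Per-frame mass-weighted centering, optionally least-squares
    superposition (translation + rotation) onto the mean structure."""
    w = masses / masses.sum()
    centred = coords - np.einsum("fak,a->fk", coords, w)[:, None, :]
    if remove == "translation":
        return centred
    if remove != "trans_rot":
        raise ValueError("remove must be 'translation' or 'trans_rot'")
    ref = centred[0]
    for _ in range(2):
        aligned = np.empty_like(centred)
        for f in range(centred.shape[0]):
            H = np.einsum("ai,a,aj->ij", centred[f], w, ref)
            U, _, Vt = np.linalg.svd(H)
            d = np.sign(np.linalg.det(U @ Vt))
            R = (U * np.array([1.0, 1.0, d])) @ Vt
            aligned[f] = centred[f] @ R
        ref = aligned.mean(axis=0)
        centred = aligned
    return centred


def schlitter_entropy_from_covariance(
        covariance: np.ndarray, masses: np.ndarray,
        temperature: float = CONSTANTS.T_ref) -> float:
    """T*S' (kcal/mol) from a 3N x 3N Cartesian covariance in A^2."""
    m3 = np.repeat(np.asarray(masses, dtype=float), 3)
    sqrt_m = np.sqrt(m3)
    A = schlitter_prefactor(temperature) * (sqrt_m[:, None] * covariance
                                            * sqrt_m[None, :])
    lam = np.linalg.eigvalsh(0.5 * (A + A.T))
    lam = np.maximum(lam, EIGENVALUE_FLOOR)
    s = 0.5 * CONSTANTS.k_B * np.sum(np.log1p(lam))
    return float(temperature * s)


def schlitter_entropy(traj: TrajectoryHandle,
                      selection: np.ndarray,
                      window: tuple[int, int] | None = None,
                      remove: str = "translation",
                      temperature: float = CONSTANTS.T_ref) -> float:
    """T*S' (kcal/mol) for the atoms in ``selection`` (universe indices).

    ``window`` is a (start, stop) frame range of the (trimmed) trajectory;
    None means all frames.  Translation is always removed per frame;
    ``remove='trans_rot'`` additionally superposes each frame onto the mean
    structure.
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty atom selection")
    start, stop = window if window is not None else (0, traj.n_frames)
    n_w = stop - start
    if n_w < 2:
        raise ValueError("window must contain at least 2 frames")
    masses = traj.atoms_masses()[selection]
    if n_w < 3 * selection.size:
        import warnings
        warnings.warn(
            f"window of {n_w} frames underdetermines the covariance of "
            f"{selection.size} atoms; entropy may be ill-conditioned")
    coords = np.empty((n_w, selection.size, 3))
    for k, f in enumerate(range(start, stop)):
        coords[k] = traj.coordinates(f)[selection]
    centred = _remove_rigid_body(coords, masses, remove)
    flat = centred.reshape(n_w, -1)
    cov = np.cov(flat, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    return schlitter_entropy_from_covariance(cov, masses, temperature)


# ---------------------------------------------------------------------------
# Selections and window reports
# ---------------------------------------------------------------------------

def p_atom_selection(traj: TrajectoryHandle,
                     bp_range: tuple[int, int] | None = None) -> np.ndarray:
    """Universe indices of backbone P atoms, optionally restricted to a
    1-based inclusive bp range (both strands)."""
    idx = []
    for strand in ("watson", "crick"):
        residues = list(traj.dna_residues(strand))
        if strand == "crick":
            residues = residues[::-1]     # bp order
        for i, res in enumerate(residues, start=1):
            if bp_range is not None and not bp_range[0] <= i <= bp_range[1]:
                continue
            for a in res.atoms:
                if a.name == "P":
                    idx.append(a.index)
    return np.array(sorted(idx), dtype=int)


@dataclass
class EntropyReport:
    """TS per selection per window, with window spread as uncertainty."""

    rows: pd.DataFrame   # selection, window, n_frames, TS

    def mean_sd(self, selection: str) -> tuple[float, float]:
        sub = self.rows[self.rows["selection"] == selection]["TS"]
        return float(sub.mean()), float(sub.std(ddof=1))

    def write_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def entropy_windows(traj: TrajectoryHandle,
                    selections: Mapping[str, np.ndarray],
                    fractions: Mapping[str, float] = WINDOW_FRACTIONS,
                    remove: str = "translation",
                    temperature: float = CONSTANTS.T_ref) -> EntropyReport:
    """TS for the full / last-75% / last-50% windows of each selection."""
    n = traj.n_frames
    rows = []
    for label, sel in selections.items():
        for wname, frac in fractions.items():
            start = n - int(round(frac * n))
            ts = schlitter_entropy(traj, sel, window=(start, n),
                                   remove=remove, temperature=temperature)
            rows.append({"selection": label, "window": wname,
                         "n_frames": n - start, "TS": ts})
    return EntropyReport(rows=pd.DataFrame(rows))
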