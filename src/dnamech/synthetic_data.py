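"""Synthetic ensembles with known ground truth for every pipeline input.

The generator emulates the study's model system: a 49-bp promoter duplex
carrying an E2F1-DP1 response element (TTTCCCGC, bp 7-14) and a
non-canonical CEBPB element (TTACACTA, bp 27-34), with six methylcytosines
in the ME state (four single marks in the E2F1-DP1 site and linker, one
double CpG mark in the CEBPB 3'-flank).  Helical-parameter dynamics are
stationary Gaussian AR(1) series with tetranucleotide-dependent means and
covariances; methylation shifts CpG-step means (twist down, roll up);
CEBPB binding injects lagged long-distance couplings along the
linker in the WT state (lost upon methylation).  Coordinates, pseudo-protein
contact scripts, K+/Cl- ion clouds at 150 mM and genomic interval fixtures
are all rebuilt from these ensembles so that downstream analyses can be
checked against planted truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .core_io import CONSTANTS, SystemLabel, TrajectoryHandle
from .helical_geometry import (
    BACKBONE_LOCAL, BASE_GEOMETRY, COMPLEMENT, GROOVE_PARAM_NAMES,
    STEP_PARAM_NAMES, BP_PARAM_NAMES, HelicalEnsemble, _FLIP,
    bp_frames_from_params, cehs_compose,
)

#: default Watson-strand sequence (49 bp).  RE layout: E2F1-DP1 TTTCCCGC at
#: bp 7-14, CEBPB TTACACTA at bp 27-34; CpG steps at 12, 14, 20, 24, 35.
DEFAULT_SEQUENCE = "ATGGTATTTCCCGCGATATCGGACGGTTACACTACGATTAGTATGATTA"

#: six methylcytosines of the ME systems: four single marks (Watson C of a
#: CpG) in the E2F1-DP1 site and linker, one double mark (both strands) at
#: the CpG in the CEBPB 3'-flank.
DEFAULT_METHYLATION = ((12, "W"), (14, "W"), (20, "W"), (24, "W"),
                       (35, "W"), (36, "C"))

E2F1DP1_RE = (7, 14)
CEBPB_RE = (27, 34)

# -- sequence-dependent equilibrium values ---------------------------------
# (twist, roll, slide) by central dinucleotide; remaining step means are
# sequence independent.  Values are B-DNA-like averages.
_DINUC_STEP = {
    "AA": (35.3, 0.7, -0.2), "AT": (31.2, 1.1, -0.6), "TA": (36.3, 3.3, 0.1),
    "GG": (33.6, 3.6, -0.2), "GC": (38.4, 0.7, 0.4), "CG": (31.1, 5.4, 0.6),
    "CA": (34.3, 4.7, 0.1), "AC": (31.8, 0.7, -0.1), "AG": (32.3, 3.3, -0.2),
    "GA": (37.6, 1.9, 0.0),
}
_SOFT_STEPS = {"TA", "CA", "TG", "CG"}

_INTRA_MEAN = np.array([0.0, 0.0, 0.1, 0.5, -11.0, 0.6])
_INTRA_SD = np.array([0.25, 0.12, 0.35, 6.5, 7.5, 3.5])
_STEP_SD = np.array([0.45, 0.40, 0.25, 3.5, 5.5, 5.0])

_GROOVE_MEAN = np.array([11.7, 10.0, 5.7, 9.6])
_GROOVE_SD = np.array([0.6, 0.4, 0.5, 0.4])

#: methylation-induced shifts of CpG step means (twist down, roll up)
ME_TWIST_SHIFT = -2.5   # deg
ME_ROLL_SHIFT = +3.0    # deg


def _dinuc_key(a: str, b: str) -> str:
    d = a + b
    if d in _DINUC_STEP:
        return d
    # read the step on the complementary strand
    return COMPLEMENT[b] + COMPLEMENT[a]


def _base_correlation() -> np.ndarray:
    """Within-position correlation of the 12-vector [intra(6), step(6)]."""
    c = np.eye(12)
    pairs = {(11, 10): -0.35,   # twist-roll
             (11, 7): 0.45,     # twist-slide
             (10, 8): -0.40,    # roll-rise
             (4, 10): 0.20}     # propeller-roll
    for (i, j), r in pairs.items():
        c[i, j] = c[j, i] = r
    return c

_BASE_CORR = _base_correlation()


@dataclass(frozen=True)
class Coupling:
    """Injected lagged cross-position correlation (ground truth)."""
    source_param: str
    source_pos: int     # 1-based bp or step index
    target_param: str
    target_pos: int
    lag: int            # frames (target follows source by `lag`)
    rho: float

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError("|rho| must be < 1")
        if self.lag < 0:
            raise ValueError("lag must be >= 0")


@dataclass(frozen=True)
class IonSite:
    """A groove-bound ion population at a bp level."""
    bp: int
    groove: str = "major"     # "major" | "minor"
    radius: float = 9.0       # Angstrom from the axis
    radial_sigma: float = 0.35
    occupancy: float = 0.4

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be within [0, 1]")


@dataclass(frozen=True)
class IonModel:
    molarity: float = 0.15        # mol/L bulk KCl
    sites: tuple[IonSite, ...] = ()
    box_padding: float = 10.0     # Angstrom around the duplex


@dataclass(frozen=True)
class ContactScriptEntry:
    """A scripted pseudo-protein contact with known per-frame truth."""
    chain: str
    resname: str
    resid: int
    atom: str                   # contacting protein atom
    target_bp: int
    target_strand: str          # "W" | "C"
    target_atom: str
    kind: str                   # "hbond" | "hydrophobic" | "backbone"
    occupancy: float = 1.0
    distance: float = 2.9       # contact distance when formed (Angstrom)

    def __post_init__(self) -> None:
        if self.kind not in ("hbond", "hydrophobic", "backbone"):
            raise ValueError(f"unknown contact kind {self.kind!r}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be within [0, 1]")


@dataclass(frozen=True)
class MeanShift:
    """Additive offset on a parameter mean at given 1-based positions."""
    param: str
    positions: tuple[int, ...]
    delta: float


@dataclass(frozen=True)
class MeanOverride:
    param: str
    positions: tuple[int, ...]
    value: float


@dataclass(frozen=True)
class VarianceScale:
    """Multiplies the SD of a parameter (or all) over a position range."""
    positions: tuple[int, ...]
    factor: float
    param: str | None = None    # None = all 12 helical parameters


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for one synthetic system (the ground truth)."""

    sequence: str = DEFAULT_SEQUENCE
    methylation_marks: tuple[tuple[int, str], ...] = ()
    n_frames: int = 2000
    timestep: float = 1.0           # ps
    seed: int = 0
    ar1_tau: float = 20.0           # AR(1) autocorrelation time, frames
    mean_shifts: tuple[MeanShift, ...] = ()
    mean_overrides: tuple[MeanOverride, ...] = ()
    variance_scales: tuple[VarianceScale, ...] = ()
    couplings: tuple[Coupling, ...] = ()
    ions: IonModel = IonModel()
    contacts: tuple[ContactScriptEntry, ...] = ()
    me_twist_shift: float = ME_TWIST_SHIFT
    me_roll_shift: float = ME_ROLL_SHIFT
    covariance_scale: float = 1.0   # 0 -> deterministic means

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if set(seq) - set("ACGT"):
            raise ValueError("sequence must be an ACGT string")
        object.__setattr__(self, "sequence", seq)
        for bp, strand in self.methylation_marks:
            if strand not in ("W", "C"):
                raise ValueError("strand must be 'W' or 'C'")
            if strand == "W":
                if not (1 <= bp < len(seq)) or seq[bp - 1] != "C" or seq[bp] != "G":
                    raise ValueError(
                        f"Watson mark at bp {bp} is not the C of a CpG")
            else:
                if not (1 < bp <= len(seq)) or seq[bp - 1] != "G" or seq[bp - 2] != "C":
                    raise ValueError(
                        f"Crick mark at bp {bp} is not the C of a CpG")

    @property
    def n_bp(self) -> int:
        return len(self.sequence)

    def me_cpg_steps(self) -> tuple[int, ...]:
        """1-based step indices of methylated CpG steps."""
        steps = set()
        for bp, strand in self.methylation_marks:
            steps.add(bp if strand == "W" else bp - 1)
        return tuple(sorted(steps))

    def replace(self, **kw) -> "SyntheticSpec":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# Ground-truth moments
# ---------------------------------------------------------------------------

def equilibrium_means(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(intra_mean (n_bp, 6), step_mean (n_steps, 6), groove_mean (n_bp, 4))."""
    n_bp = spec.n_bp
    seq = spec.sequence
    intra = np.tile(_INTRA_MEAN, (n_bp, 1))
    step = np.zeros((n_bp - 1, 6))
    for j in range(n_bp - 1):
        tw, ro, sl = _DINUC_STEP[_dinuc_key(seq[j], seq[j + 1])]
        step[j] = [0.0, sl, 3.32, 0.0, ro, tw]
    for s in spec.me_cpg_steps():
        step[s - 1, STEP_PARAM_NAMES.index("twist")] += spec.me_twist_shift
        step[s - 1, STEP_PARAM_NAMES.index("roll")] += spec.me_roll_shift
    groove = np.tile(_GROOVE_MEAN, (n_bp, 1))

    def _apply(param, positions, value, additive):
        if param in STEP_PARAM_NAMES:
            arr, k, n = step, STEP_PARAM_NAMES.index(param), n_bp - 1
        elif param in BP_PARAM_NAMES[:6]:
            arr, k, n = intra, BP_PARAM_NAMES.index(param), n_bp
        elif param in GROOVE_PARAM_NAMES:
            arr, k, n = groove, GROOVE_PARAM_NAMES.index(param), n_bp
        else:
            raise KeyError(f"unknown parameter {param!r}")
        for p in positions:
            if not 1 <= p <= n:
                raise ValueError(f"position {p} out of range for {param}")
            arr[p - 1, k] = arr[p - 1, k] + value if additive else value

    for ms in spec.mean_shifts:
        _apply(ms.param, ms.positions, ms.delta, additive=True)
    for mo in spec.mean_overrides:
        _apply(mo.param, mo.positions, mo.value, additive=False)
    return intra, step, groove


def equilibrium_sds(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(intra_sd (n_bp, 6), step_sd (n_steps, 6), groove_sd (n_bp, 4))."""
    n_bp = spec.n_bp
    seq = spec.sequence
    intra = np.tile(_INTRA_SD, (n_bp, 1))
    step = np.tile(_STEP_SD, (n_bp - 1, 1))
    for j in range(n_bp - 1):
        if seq[j] + seq[j + 1] in _SOFT_STEPS:
            step[j] *= 1.2
    groove = np.tile(_GROOVE_SD, (n_bp, 1))
    for vs in spec.variance_scales:
        params = ([vs.param] if vs.param is not None
                  else list(STEP_PARAM_NAMES) + list(BP_PARAM_NAMES[:6]))
        for param in params:
            if param in STEP_PARAM_NAMES:
                arr, k = step, STEP_PARAM_NAMES.index(param)
            elif param in BP_PARAM_NAMES[:6]:
                arr, k = intra, BP_PARAM_NAMES.index(param)
            elif param in GROOVE_PARAM_NAMES:
                arr, k = groove, GROOVE_PARAM_NAMES.index(param)
            else:
                raise KeyError(f"unknown parameter {param!r}")
            for p in vs.positions:
                arr[p - 1, k] *= vs.factor
    scale = np.sqrt(spec.covariance_scale) if spec.covariance_scale > 0 else 0.0
    return intra * scale, step * scale, groove * scale


def position_covariance(spec: SyntheticSpec, step_index: int) -> np.ndarray:
    """Ground-truth 12x12 covariance of [intra(bp j+1), step(j)] (1-based j)."""
    intra_sd, step_sd, _ = equilibrium_sds(spec)
    sd = np.concatenate([intra_sd[step_index], step_sd[step_index - 1]])
    return np.outer(sd, sd) * _BASE_CORR


# ---------------------------------------------------------------------------
# Helical ensemble generation
# ---------------------------------------------------------------------------

def _ar1_series(rng: np.random.Generator, cov: np.ndarray, n: int,
                phi: float, burn: int) -> np.ndarray:
    """Stationary Gaussian AR(1) with marginal covariance ``cov``.

    Returns (n + burn, d); the caller discards the first ``burn`` rows.
    """
    d = cov.shape[0]
    if not np.any(cov):
        return np.zeros((n + burn, d))
    # symmetrise before Cholesky to be safe against rounding
    L = np.linalg.cholesky(0.5 * (cov + cov.T))
    eps = rng.standard_normal((n + burn, d))
    w = eps @ L.T
    w[1:] *= np.sqrt(1.0 - phi ** 2)
    return lfilter([1.0], [1.0, -phi], w, axis=0)


def generate_helical_ensemble(spec: SyntheticSpec) -> HelicalEnsemble:
    """Draw the per-position helical + groove parameter time series.

    Per step j (1-based), the 12-vector [intra params of bp j+1, step
    params of step j] follows a stationary Gaussian AR(1) with the
    ground-truth mean and covariance; bp 1's intra parameters and the
    groove series are generated the same way.  Injected couplings then mix
    a standardized, lag-shifted copy of the source series into the target
    so that the planted lagged Pearson correlation is exact in expectation.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n_bp, n = spec.n_bp, spec.n_frames
    phi = float(np.exp(-1.0 / spec.ar1_tau))
    max_lag = max([c.lag for c in spec.couplings], default=0)
    burn = int(max(10 * spec.ar1_tau, max_lag + 1))

    intra_mean, step_mean, groove_mean = equilibrium_means(spec)
    intra_sd, step_sd, groove_sd = equilibrium_sds(spec)

    bp_params = np.full((n + burn, n_bp, 8), np.nan)
    step_params = np.empty((n + burn, n_bp - 1, 6))
    grooves = np.full((n + burn, n_bp, 4), np.nan)

    # bp 1 intra params (not attached to any incoming step)
    cov0 = np.diag(intra_sd[0] ** 2)
    bp_params[:, 0, :6] = intra_mean[0] + _ar1_series(rng, cov0, n, phi, burn)

    for j in range(1, n_bp):      # step j (1-based), bp j+1 intra
        cov = position_covariance(spec, j)
        series = _ar1_series(rng, cov, n, phi, burn)
        bp_params[:, j, :6] = intra_mean[j] + series[:, :6]
        step_params[:, j - 1, :] = step_mean[j - 1] + series[:, 6:]

    for i in range(1, n_bp - 1):  # grooves undefined at termini
        cov = np.diag(groove_sd[i] ** 2)
        grooves[:, i, :] = groove_mean[i] + _ar1_series(rng, cov, n, phi, burn)

    def _series_ref(param: str, pos: int):
        if param in STEP_PARAM_NAMES:
            return step_params, pos - 1, STEP_PARAM_NAMES.index(param), \
                step_mean[pos - 1, STEP_PARAM_NAMES.index(param)], \
                step_sd[pos - 1, STEP_PARAM_NAMES.index(param)]
        if param in BP_PARAM_NAMES[:6]:
            k = BP_PARAM_NAMES.index(param)
            return bp_params, pos - 1, k, intra_mean[pos - 1, k], intra_sd[pos - 1, k]
        if param in GROOVE_PARAM_NAMES:
            k = GROOVE_PARAM_NAMES.index(param)
            return grooves, pos - 1, k, groove_mean[pos - 1, k], groove_sd[pos - 1, k]
        raise KeyError(f"unknown parameter {param!r}")

    for c in spec.couplings:
        s_arr, s_pos, s_k, s_mu, s_sd = _series_ref(c.source_param, c.source_pos)
        t_arr, t_pos, t_k, t_mu, t_sd = _series_ref(c.target_param, c.target_pos)
        if s_sd <= 0 or t_sd <= 0:
            continue
        z = (s_arr[:, s_pos, s_k] - s_mu) / s_sd
        z_lagged = np.empty_like(z)
        if c.lag:
            z_lagged[c.lag:] = z[:-c.lag]
            z_lagged[:c.lag] = z[0]
        else:
            z_lagged[:] = z
        resid = t_arr[:, t_pos, t_k] - t_mu
        t_arr[:, t_pos, t_k] = (t_mu + c.rho * t_sd * z_lagged
                                + np.sqrt(1.0 - c.rho ** 2) * resid)

    times = np.arange(n, dtype=float) * spec.timestep
    return HelicalEnsemble(
        sequence=spec.sequence, times=times,
        step_params=step_params[burn:],
        bp_params=bp_params[burn:],
        grooves=grooves[burn:],
        methylation=tuple(spec.methylation_marks))


# ---------------------------------------------------------------------------
# Coordinate building
# ---------------------------------------------------------------------------

_P_LOCAL = np.array(BACKBONE_LOCAL["P"])


def _me_lookup(marks: Sequence[tuple[int, str]]) -> set[tuple[int, str]]:
    return {(bp, strand) for bp, strand in marks}


def build_coordinates(ensemble: HelicalEnsemble,
                      spec: SyntheticSpec | None = None,
                      include_backbone: bool = True,
                      max_frames: int | None = None) -> TrajectoryHandle:
    """Rebuild an atomic duplex trajectory from helical parameters.

    Base atoms are placed on idealised base geometries composed through the
    per-frame bp and step transforms (the exact inverse of the parameter
    measurement); phosphate/backbone atoms sit at fixed positions in each
    base frame.  If ``spec`` carries a contact script or an ion model,
    pseudo-protein atoms and K+/Cl- ions are added with known per-frame
    ground truth.
    """
    n_frames = ensemble.n_frames if max_frames is None \
        else min(ensemble.n_frames, max_frames)
    n_bp = ensemble.n_bp
    seq = ensemble.sequence
    marks = _me_lookup(ensemble.methylation)
    rng = np.random.default_rng(0 if spec is None else spec.seed + 1)

    step = ensemble.step_params[:n_frames]
    intra = ensemble.bp_params[:n_frames, :, :6]

    # chain bp frames
    bp_R = np.empty((n_frames, n_bp, 3, 3))
    bp_o = np.zeros((n_frames, n_bp, 3))
    bp_R[:, 0] = np.eye(3)
    for j in range(n_bp - 1):
        R2, o2, _ = cehs_compose(bp_R[:, j], bp_o[:, j], step[:, j])
        bp_R[:, j + 1] = R2
        bp_o[:, j + 1] = o2

    crick_flip_R, crick_o, watson_R, watson_o = bp_frames_from_params(
        intra, bp_R, bp_o)
    crick_R = crick_flip_R @ _FLIP

    names: list[str] = []
    resnames: list[str] = []
    resids: list[int] = []
    chains: list[str] = []
    blocks: list[np.ndarray] = []   # each (n_frames, n_atoms_block, 3)
    atom_index: dict[tuple[int, str, str], int] = {}

    def _place_residue(bp: int, strand: str, chain: str) -> None:
        letter = seq[bp - 1] if strand == "W" else COMPLEMENT[seq[bp - 1]]
        resname = "5MC" if (bp, strand) in marks else "D" + letter
        base_key = "5MC" if resname == "5MC" else letter
        local = {a: (x, y, 0.0) for a, (x, y) in BASE_GEOMETRY[base_key].items()}
        if include_backbone:
            local.update({a: xyz for a, xyz in BACKBONE_LOCAL.items()})
        atom_names = list(local)
        L = np.array([local[a] for a in atom_names])      # (m, 3)
        R = watson_R[:, bp - 1] if strand == "W" else crick_R[:, bp - 1]
        o = watson_o[:, bp - 1] if strand == "W" else crick_o[:, bp - 1]
        pos = np.einsum("fij,mj->fmi", R, L) + o[:, None, :]
        for k, a in enumerate(atom_names):
            atom_index[(bp, strand, a)] = len(names) + k
        names.extend(atom_names)
        resnames.extend([resname] * len(atom_names))
        resids.extend([bp] * len(atom_names))
        chains.extend([chain] * len(atom_names))
        blocks.append(pos)

    for bp in range(1, n_bp + 1):
        _place_residue(bp, "W", "A")
    for bp in range(n_bp, 0, -1):   # Crick chain stored 5'->3'
        _place_residue(bp, "C", "B")

    roles = {"A": "dna_watson", "B": "dna_crick"}
    contact_truth: dict[int, np.ndarray] = {}

    if spec is not None and spec.contacts:
        for idx, entry in enumerate(spec.contacts):
            key = (entry.target_bp, entry.target_strand, entry.target_atom)
            if key not in atom_index:
                raise ValueError(f"contact target atom {key} not in duplex")
            sub = np.random.default_rng(spec.seed * 1000003 + 17 * idx + 3)
            active = sub.random(n_frames) < entry.occupancy
            contact_truth[idx] = active
            # stack target positions & radial direction
            t_idx = atom_index[key]
            target = blocks_positions(blocks, t_idx)[:n_frames]
            origin = bp_o[:, entry.target_bp - 1]
            u = target - origin
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            dist = np.where(active, entry.distance, 8.5)
            pos = target + u * dist[:, None]
            res_atoms = [(entry.atom, pos)]
            if entry.kind == "hbond":
                hpos = target + u * (dist - 1.0)[:, None]
                res_atoms.append(("H" + entry.atom[-2:], hpos))
            for aname, apos in res_atoms:
                names.append(aname)
                resnames.append(entry.resname)
                resids.append(entry.resid)
                chains.append(entry.chain)
                blocks.append(apos[:, None, :])
            if entry.chain not in roles:
                roles[entry.chain] = f"protein:{entry.chain}"

    if spec is not None and spec.ions is not None and spec.ions.molarity > 0:
        ion = spec.ions
        # fixed box from the duplex extent in frame 0
        dna = np.concatenate([b[0] for b in blocks], axis=0)
        lo = dna.min(axis=0) - ion.box_padding
        hi = dna.max(axis=0) + ion.box_padding
        volume_L = float(np.prod(hi - lo)) * 1e-27
        n_bulk = int(round(ion.molarity * CONSTANTS.N_A * volume_L))
        for species, count in (("K", n_bulk), ("CL", n_bulk)):
            if count == 0:
                continue
            pos = lo + rng.random((n_frames, count, 3)) * (hi - lo)
            if species == "K":
                for s_idx, site in enumerate(ion.sites):
                    if s_idx >= count:
                        break
                    sub = np.random.default_rng(spec.seed * 999983 + s_idx)
                    active = sub.random(n_frames) < site.occupancy
                    r = site.radius + sub.normal(0, site.radial_sigma, n_frames)
                    ang = np.deg2rad(sub.uniform(-50, 50, n_frames))
                    sign = 1.0 if site.groove == "major" else -1.0
                    x_hat = bp_R[:, site.bp - 1, :, 0] * sign
                    y_hat = bp_R[:, site.bp - 1, :, 1]
                    bound = (bp_o[:, site.bp - 1]
                             + (np.cos(ang) * r)[:, None] * x_hat
                             + (np.sin(ang) * r)[:, None] * y_hat)
                    pos[:, s_idx, :] = np.where(active[:, None], bound,
                                                pos[:, s_idx, :])
            for k in range(count):
                names.append(species)
                resnames.append(species)
                resids.append(k + 1)
                chains.append("I" if species == "K" else "J")
            blocks.append(pos)
        roles["I"] = "ion"
        roles["J"] = "ion"

    coords = np.concatenate(blocks, axis=1)
    handle = TrajectoryHandle.from_arrays(
        coords, names, resnames, resids, chains, roles,
        timestep=float(ensemble.times[1] - ensemble.times[0])
        if len(ensemble.times) > 1 else 1.0)
    handle.contact_truth = contact_truth      # planted per-frame activity
    handle.atom_index = atom_index
    return handle


def blocks_positions(blocks: list[np.ndarray], flat_index: int) -> np.ndarray:
    """Position time series of the atom at a flat index across blocks."""
    off = 0
    for b in blocks:
        if flat_index < off + b.shape[1]:
            return b[:, flat_index - off, :]
        off += b.shape[1]
    raise IndexError(flat_index)


# ---------------------------------------------------------------------------
# Default force-field-style parameter table for built systems
# ---------------------------------------------------------------------------

_ELEMENT_NB = {
    # element: (sigma A, epsilon kcal/mol)
    "H": (1.10, 0.016), "C": (3.40, 0.086), "N": (3.25, 0.170),
    "O": (2.96, 0.210), "P": (3.74, 0.200), "K": (3.04, 0.100),
    "CL": (4.40, 0.100), "S": (3.56, 0.250),
}
_ELEMENT_CHARGE = {"H": 0.30, "C": 0.10, "N": -0.40, "O": -0.45,
                   "P": -1.00, "K": 1.00, "CL": -1.00, "S": -0.10}


def default_atom_params(handle: TrajectoryHandle):
    """Plausible per-atom charges and LJ parameters for built systems.

    A stand-in parameter set keyed by element, sufficient for the
    short-range Coulomb/LJ machinery; not a force field.
    """
    from .core_io import AtomParamTable, _element_from_name
    entries: dict[tuple[str, str], tuple[float, float, float]] = {}
    for name, res in zip(handle.atoms_names(), handle.atoms_resnames()):
        key = (res.upper(), name.upper())
        if key in entries:
            continue
        el = _element_from_name(name, res)
        s, e = _ELEMENT_NB.get(el, (3.4, 0.1))
        q = _ELEMENT_CHARGE.get(el, 0.0)
        entries[key] = (q, s, e)
    return AtomParamTable(entries)


# ---------------------------------------------------------------------------
# Per-system study specs (the eight WT/ME x binding-state conditions)
# ---------------------------------------------------------------------------

#: long-distance coupling chain induced by CEBPB binding in the WT state:
#: from the middle of the CEBPB element (bp 32) over the linker (bp 21-23,
#: then 19-20) into the E2F1-DP1 element (bp 10-14).
WT_CEBPB_COUPLINGS = (
    Coupling("shift", 32, "shift", 21, 0, 0.25),
    Coupling("shift", 32, "shift", 22, 0, 0.25),
    Coupling("shift", 32, "shift", 23, 0, 0.22),
    Coupling("shift", 22, "shift", 19, 0, 0.22),
    Coupling("shift", 22, "shift", 20, 0, 0.25),
    Coupling("shift", 20, "major_width", 12, 0, 0.22),
    Coupling("shift", 20, "shift", 11, 0, 0.20),
)

#: last three steps of the E2F1-DP1 element where WT and ME systems show
#: opposite shift signs when the dimer is bound
RE_3PRIME_STEPS = (12, 13, 14)


def default_system_spec(label: SystemLabel, n_frames: int = 2000,
                        seed: int = 0, timestep: float = 1.0) -> SyntheticSpec:
    """Synthetic recipe emulating one of the eight study systems.

    Encodes the study's qualitative effect signs: methylation lowers twist
    and raises roll at CpG steps and narrows linker shift distributions;
    E2F1-DP1-bound WT vs ME systems have opposite mean shift at the RE
    3'-steps; CEBPB binding rigidifies its own site (and mildly the
    E2F1-DP1 site), perturbs the linker, and in the WT state injects the
    long-distance coupling chain (absent upon methylation); protein binding
    scripts the corresponding specific contacts; methylation pulls
    major-groove K+ closer to the axis.
    """
    me = label.methylation == "ME"
    marks = DEFAULT_METHYLATION if me else ()
    shifts: list[MeanShift] = []
    scales: list[VarianceScale] = []
    couplings: tuple[Coupling, ...] = ()
    contacts: list[ContactScriptEntry] = []
    sites: list[IonSite] = []

    linker = tuple(range(16, 27))
    e2f_site = tuple(range(6, 16))
    cebpb_site = tuple(range(26, 36))

    if me:
        # narrowed linker shift distributions upon methylation
        scales.append(VarianceScale(linker, 0.85, "shift"))
    if label.has_e2f1dp1:
        # opposite shift sign at the RE 3'-steps; the displacement from the
        # relaxed state is larger on methylated DNA (binding costs more,
        # with an extra slide rearrangement across the RE 3'-half)
        shifts.append(MeanShift("shift", RE_3PRIME_STEPS,
                                -0.55 if me else +0.40))
        scales.append(VarianceScale(e2f_site, 0.96))
        if me:
            shifts.append(MeanShift("slide", (10, 11, 12, 13, 14), +0.5))
            # DP1 Arg167-type contact turns from H-bonding the Crick
            # guanines into hydrophobic packing with the 5-methyl group
            contacts.append(ContactScriptEntry(
                "D", "ARG", 167, "CB", 12, "W", "C5M", "hydrophobic",
                occupancy=0.80, distance=3.8))
            contacts.append(ContactScriptEntry(
                "D", "ARG", 167, "NH1", 11, "C", "O6", "hbond",
                occupancy=0.15))
        else:
            contacts.append(ContactScriptEntry(
                "D", "ARG", 167, "NH1", 11, "C", "O6", "hbond",
                occupancy=0.85))
        contacts.append(ContactScriptEntry(
            "D", "ARG", 168, "NH1", 12, "W", "P", "backbone",
            occupancy=0.60, distance=3.0))
        contacts.append(ContactScriptEntry(
            "D", "TYR", 170, "CD1", 9, "W", "C7", "hydrophobic",
            occupancy=0.70 if (label.bound_state == "both" and not me) else 0.30,
            distance=3.9))
    if label.has_cebpb:
        # induced conformational changes in the linker (twist/shift/slide)
        # plus mild rigidification of both sites
        linker_steps = tuple(range(16, 26))
        shifts.append(MeanShift("twist", linker_steps, 3.0))
        shifts.append(MeanShift("shift", linker_steps, 0.6))
        shifts.append(MeanShift("slide", linker_steps, 0.4))
        scales.append(VarianceScale(cebpb_site, 0.96))
        scales.append(VarianceScale(e2f_site, 0.95))
        if not me:
            couplings = WT_CEBPB_COUPLINGS
            if label.bound_state == "both":
                couplings = tuple(
                    dataclasses.replace(c, rho=min(c.rho + 0.04, 0.9))
                    for c in couplings)
        contacts.append(ContactScriptEntry(
            "E", "ARG", 289, "NH2", 31, "W", "N7", "hbond", occupancy=0.80))
        contacts.append(ContactScriptEntry(
            "E", "ALA", 284, "CB", 28, "W", "C7", "hydrophobic",
            occupancy=0.65, distance=3.9))

    # K+ population in the major groove of the E2F1-DP1 element;
    # methylation pulls it ~0.8 A closer to the helical axis
    sites.append(IonSite(bp=12, groove="major",
                         radius=8.2 if me else 9.0,
                         occupancy=0.5 if me else 0.4))

    return SyntheticSpec(
        sequence=DEFAULT_SEQUENCE,
        methylation_marks=marks,
        n_frames=n_frames,
        seed=seed * 8 + (0 if not me else 4) + BOUND_OFFSET[label.bound_state],
        timestep=timestep,
        mean_shifts=tuple(shifts),
        variance_scales=tuple(scales),
        couplings=couplings,
        contacts=tuple(contacts),
        ions=IonModel(sites=tuple(sites)),
    )


BOUND_OFFSET = {"naked": 0, "CEBPB": 1, "E2F1DP1": 2, "both": 3}


# ---------------------------------------------------------------------------
# Genomic interval fixtures
# ---------------------------------------------------------------------------

def generate_intervals(out_dir: str | Path,
                       n_promoters: int = 10,
                       n_qualifying: int = 3,
                       window: int = 200,
                       seed: int = 0) -> dict:
    """Write TSS, two peak tracks and a methylation track as BED files.

    Exactly ``n_qualifying`` promoters have peaks from both factor tracks
    within ``window`` bp of the TSS; the rest miss on one or both tracks.
    Returns the ground truth (file paths and qualifying TSS positions).
    """
    from .region_finder import GenomicInterval, write_bed
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tss, peaks1, peaks2, meth = [], [], [], []
    qualifying = []
    pos = 100_000
    for i in range(n_promoters):
        pos += int(rng.integers(5_000, 10_000))
        t = GenomicInterval("chr19", pos, pos, strand="+")
        tss.append(t)
        qualifies = i < n_qualifying
        near = int(rng.integers(10, max(11, window - 60)))
        far = window + 150 + int(rng.integers(0, 200))
        d1 = near if qualifies else (near if i % 3 == 0 else far)
        d2 = near if qualifies else far
        peaks1.append(GenomicInterval("chr19", pos + d1, pos + d1 + 40))
        peaks2.append(GenomicInterval("chr19", pos - d2 - 40, pos - d2))
        if qualifies:
            qualifying.append(pos)
            for k in range(3):
                m = pos + 20 + 15 * k
                meth.append(GenomicInterval("chr19", m, m + 1,
                                            score=float(rng.integers(40, 95))))
    paths = {
        "tss": out / "tss.bed", "peaks1": out / "peaks_factor1.bed",
        "peaks2": out / "peaks_factor2.bed", "methylation": out / "methylation.bed",
    }
    write_bed(tss, paths["tss"])
    write_bed(peaks1, paths["peaks1"])
    write_bed(peaks2, paths["peaks2"])
    write_bed(meth, paths["methylation"], scores=True)
    return {"paths": paths, "qualifying_tss": qualifying,
            "window": window, "n_promoters": n_promoters}


#: genomic coordinates of the studied 49-bp hypermethylated promoter region
NDUFA13_REGION = ("chr19", 19_626_898, 19_626_946)


def ndufa13_region_fixture(out_dir: str | Path) -> dict:
    """Interval fixture around the studied promoter region.

    The 49-bp region sits 130 bp upstream of the TSS; 14 CpG methylation
    sites lie within the 500-bp promoter window, six of them (four single,
    one double CpG mark) inside the region, matching the synthetic duplex's
    methylation layout.
    """
    from .region_finder import GenomicInterval, write_bed
    chrom, start, end = NDUFA13_REGION
    tss_pos = end + 130 + 1
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # six in-region marks at the Watson/Crick methylcytosine positions of
    # the model duplex (bp offsets 12, 14, 20, 24, 35, 36)
    in_region = [start + off - 1 for off in (12, 14, 20, 24, 35, 36)]
    downstream = [end + d for d in (20, 45, 70, 95)]      # closer to TSS
    upstream = [start - d for d in (30, 60, 90, 120)]     # further away
    sites = sorted(in_region + downstream + upstream)
    meth = [GenomicInterval(chrom, p, p, score=75.0) for p in sites]

    tss = [GenomicInterval(chrom, tss_pos, tss_pos, strand="+")]
    region = GenomicInterval(chrom, start, end)
    paths = {"tss": out / "tss.bed", "methylation": out / "methylation.bed"}
    write_bed(tss, paths["tss"])
    write_bed(meth, paths["methylation"], scores=True)
    return {"region": region, "tss": tss_pos, "n_sites_window": len(sites),
            "in_region_sites": in_region, "paths": paths}
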