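"""Tetranucleotide-dependent harmonic DNA deformation energy with
conformational substates and nearest-neighbour substate coupling.

Each step position carries a 12-vector x = [6 intra-bp parameters of the
step's 3' base pair, 6 step parameters].  Per tetranucleotide context the
thermal ensemble is modelled as a mixture of Gaussian substates; substate s
contributes a harmonic well

    e_s(x) = 1/2 (x - x0_s)^T F_s (x - x0_s) + c_s,   F_s = k_B T Sigma_s^-1

with a weight-derived offset c_s = -k_B T ln(w_s / w_max) >= 0 so that the
most populated substate's minimum defines the zero of energy.  Adjacent
positions couple through an Ising-like bond energy J(s_i, s_{i+1}) derived
from the log odds ratio of observed neighbour substate co-occurrence
(shifted to be >= 0, zero for independent neighbours).  The deformation
energy of a configuration is the minimum over substate assignments of the
sum of wells plus bonds; with a single substate and no coupling the model
reduces to the plain sequence-dependent harmonic approximation, whose
thermal average is (12/2) k_B T per bp by equipartition (~4 kcal/mol*bp
at 300 K).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

from .core_io import CONSTANTS
from .helical_geometry import HelicalEnsemble

N_DOF = 12

MECHANISM_INDUCED_FIT = "induced_fit"
MECHANISM_CONFORMATIONAL_SELECTION = "conformational_selection"
MECHANISM_MIXED = "mixed"


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass
class Substate:
    weight: float
    x0: np.ndarray            # (12,) equilibrium values
    F: np.ndarray             # (12, 12) stiffness, kcal/mol per unit^2
    covariance: np.ndarray    # (12, 12) fitted covariance (for sampling)
    offset: float             # kcal/mol, >= 0


@dataclass
class ContextModel:
    context: str
    substates: list[Substate]

    @property
    def n_substates(self) -> int:
        return len(self.substates)


@dataclass
class DeformationModel:
    """Fitted substate-coupled harmonic model, keyed by sequence context."""

    contexts: dict[str, ContextModel]
    coupling: dict[tuple[str, str], np.ndarray]   # (ctx_i, ctx_i+1) -> J matrix
    temperature: float = CONSTANTS.T_ref

    @property
    def kT(self) -> float:
        return CONSTANTS.k_B * self.temperature

    def context_for(self, key: str) -> ContextModel:
        if key in self.contexts:
            return self.contexts[key]
        raise KeyError(f"no model for context {key!r}")

    # -- serialization -------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        obj = {
            "temperature": self.temperature,
            "contexts": {
                key: [{
                    "weight": s.weight,
                    "x0": s.x0.tolist(),
                    "F": s.F.reshape(-1).tolist(),
                    "covariance": s.covariance.reshape(-1).tolist(),
                    "offset": s.offset,
                } for s in cm.substates]
                for key, cm in self.contexts.items()
            },
            "coupling": [
                {"a": a, "b": b, "J": J.reshape(-1).tolist(),
                 "shape": list(J.shape)}
                for (a, b), J in self.coupling.items()
            ],
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "DeformationModel":
        obj = json.loads(Path(path).read_text())
        contexts = {}
        for key, subs in obj["contexts"].items():
            states = [Substate(
                weight=s["weight"],
                x0=np.array(s["x0"]),
                F=np.array(s["F"]).reshape(N_DOF, N_DOF),
                covariance=np.array(s["covariance"]).reshape(N_DOF, N_DOF),
                offset=s["offset"]) for s in subs]
            contexts[key] = ContextModel(key, states)
        coupling = {
            (c["a"], c["b"]): np.array(c["J"]).reshape(c["shape"])
            for c in obj["coupling"]}
        return cls(contexts=contexts, coupling=coupling,
                   temperature=obj["temperature"])


@dataclass
class DeformationProfile:
    """Per-frame deformation energies for one bp region."""

    region: tuple[int, int]
    label: str
    energies: np.ndarray          # (n_frames,) kcal/mol, total over region
    n_bp: int

    def __post_init__(self) -> None:
        if np.any(self.energies < -1e-9):
            raise ValueError("deformation energies must be >= 0")

    @property
    def mean(self) -> float:
        return float(np.mean(self.energies))

    @property
    def sd(self) -> float:
        return float(np.std(self.energies, ddof=1))

    @property
    def se(self) -> float:
        return self.sd / np.sqrt(len(self.energies))

    @property
    def mean_per_bp(self) -> float:
        return self.mean / self.n_bp

    @property
    def sd_per_bp(self) -> float:
        return self.sd / self.n_bp

    @property
    def se_per_bp(self) -> float:
        return self.se / self.n_bp


# ---------------------------------------------------------------------------
# Context bookkeeping
# ---------------------------------------------------------------------------

def annotated_sequence(ensemble: HelicalEnsemble) -> str:
    """Watson sequence with methylation folded in: the C of a Watson mark
    becomes 'M', the G whose Crick partner is methylated becomes 'm'."""
    seq = list(ensemble.sequence)
    for bp, strand in ensemble.methylation:
        seq[bp - 1] = "M" if strand == "W" else "m"
    return "".join(seq)


def step_contexts(sequence: str) -> list[str]:
    """Context key per step (0-based step s joins bp s+1, s+2 1-based).

    Interior steps use the tetranucleotide (bases s-1..s+2, 0-based);
    terminal steps fall back to the trinucleotide then dinucleotide context,
    with a prefix recording the fallback level.
    """
    n_steps = len(sequence) - 1
    out = []
    for s in range(n_steps):
        if 1 <= s <= n_steps - 2:
            out.append(sequence[s - 1:s + 3])
        elif s == 0 and n_steps >= 2:
            out.append("tri:" + sequence[0:3])
        else:
            out.append("tri:" + sequence[s - 1:s + 2] if s >= 1
                       else "di:" + sequence[s:s + 2])
    return out


def step_vectors(ensemble: HelicalEnsemble) -> np.ndarray:
    """(n_frames, n_steps, 12) arrays [intra of 3' bp, step params]."""
    return np.concatenate(
        [ensemble.bp_params[:, 1:, :6], ensemble.step_params], axis=2)


def region_steps(bp_range: tuple[int, int], n_bp: int) -> np.ndarray:
    """0-based step-vector indices for a 1-based inclusive bp range.

    Base pair i is represented by the step arriving at it (step i-1), so a
    region a..b maps to steps a-2..b-2 (0-based) and contains exactly
    b - a + 1 vectors.
    """
    a, b = bp_range
    if not (2 <= a <= b <= n_bp):
        raise ValueError(f"bp range {bp_range} outside 2..{n_bp}")
    return np.arange(a - 2, b - 1)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_model(ensemble: HelicalEnsemble, n_substates: int = 2,
              temperature: float = CONSTANTS.T_ref,
              min_frames: int = 500,
              random_state: int = 0) -> DeformationModel:
    """Estimate substate means, stiffnesses and couplings from an ensemble.

    Per context, a Gaussian mixture with ``n_substates`` components is fit
    to the pooled 12-vectors; stiffness matrices are k_B T times the
    inverse component covariances.  Couplings come from neighbour substate
    co-occurrence odds ratios (Laplace-smoothed), shifted so the ground
    bond energy is zero.  Contexts observed on fewer than ``min_frames``
    samples fall back to pooling every position that shares the central
    dinucleotide.
    """
    kT = CONSTANTS.k_B * temperature
    X = step_vectors(ensemble)
    n_frames, n_steps, _ = X.shape
    contexts = step_contexts(annotated_sequence(ensemble))

    by_ctx: dict[str, list[int]] = {}
    for s, c in enumerate(contexts):
        by_ctx.setdefault(c, []).append(s)

    def central_dinuc(ctx: str) -> str:
        core = ctx.split(":")[-1]
        mid = (len(core) - 2) // 2
        return core[mid:mid + 2]

    fitted: dict[str, ContextModel] = {}
    for ctx, positions in by_ctx.items():
        data = X[:, positions, :].reshape(-1, N_DOF)
        if data.shape[0] < min_frames:
            pool = [s for s, c in enumerate(contexts)
                    if central_dinuc(c) == central_dinuc(ctx)]
            warnings.warn(
                f"context {ctx!r}: only {data.shape[0]} samples; pooling "
                f"{len(pool)} positions sharing the central dinucleotide")
            data = X[:, pool, :].reshape(-1, N_DOF)
        fitted[ctx] = _fit_context(ctx, data, n_substates, kT, random_state)

    # neighbour substate co-occurrence -> coupling matrices
    assign = np.empty((n_frames, n_steps), dtype=int)
    for s in range(n_steps):
        assign[:, s] = _well_energies(fitted[contexts[s]], X[:, s, :]).argmin(axis=1)
    coupling: dict[tuple[str, str], np.ndarray] = {}
    pair_counts: dict[tuple[str, str], np.ndarray] = {}
    for s in range(n_steps - 1):
        a, b = contexts[s], contexts[s + 1]
        na, nb = fitted[a].n_substates, fitted[b].n_substates
        counts = pair_counts.setdefault((a, b), np.zeros((na, nb)))
        np.add.at(counts, (assign[:, s], assign[:, s + 1]), 1.0)
    for (a, b), counts in pair_counts.items():
        counts = counts + 0.5                      # Laplace smoothing
        total = counts.sum()
        pa = counts.sum(axis=1) / total
        pb = counts.sum(axis=0) / total
        J = -kT * np.log(counts / total / np.outer(pa, pb))
        coupling[(a, b)] = J - J.min()             # ground bond = 0
    return DeformationModel(contexts=fitted, coupling=coupling,
                            temperature=temperature)


def _fit_context(ctx: str, data: np.ndarray, n_substates: int,
                 kT: float, random_state: int) -> ContextModel:
    if n_substates == 1:
        mu = data.mean(axis=0)
        cov = np.cov(data, rowvar=False)
        weights, means, covs = np.array([1.0]), mu[None], cov[None]
    else:
        gm = GaussianMixture(n_components=n_substates, covariance_type="full",
                             random_state=random_state, reg_covar=1e-6,
                             n_init=1, max_iter=200)
        gm.fit(data)
        order = np.argsort(-gm.weights_)
        weights = gm.weights_[order]
        means = gm.means_[order]
        covs = gm.covariances_[order]
    w_max = weights.max()
    substates = []
    for w, mu, cov in zip(weights, means, covs):
        F = kT * np.linalg.inv(cov)
        F = 0.5 * (F + F.T)
        substates.append(Substate(
            weight=float(w), x0=mu.copy(), F=F, covariance=cov.copy(),
            offset=float(-kT * np.log(max(w, 1e-12) / w_max))))
    return ContextModel(ctx, substates)


def _well_energies(cm: ContextModel, x: np.ndarray) -> np.ndarray:
    """e_s(x) for every substate; x is (n, 12) -> (n, S)."""
    out = np.empty((x.shape[0], cm.n_substates))
    for k, s in enumerate(cm.substates):
        d = x - s.x0
        out[:, k] = 0.5 * np.einsum("ni,ij,nj->n", d, s.F, d) + s.offset
    return out


# ---------------------------------------------------------------------------
# Energy evaluation
# ---------------------------------------------------------------------------

def evaluate_frames(model: DeformationModel, vectors: np.ndarray,
                    contexts: Sequence[str],
                    step_indices: np.ndarray,
                    n_sweeps: int = 3) -> np.ndarray:
    """Deformation energy per frame over the chosen step vectors.

    ``vectors``: (n_frames, n_steps, 12) for the whole molecule;
    ``step_indices``: the 0-based steps to include.  Substates are chosen
    per frame by a greedy sweep: positions are initialised at their minimal
    well, then refined left-to-right against the coupling to both
    neighbours until the assignment stops changing (ties break toward the
    lower substate index).
    """
    idx = np.asarray(step_indices)
    n_frames = vectors.shape[0]
    wells = []          # per position: (n_frames, S)
    Js = []             # per bond within the region: J matrix or None
    for k, s in enumerate(idx):
        wells.append(_well_energies(model.context_for(contexts[s]),
                                    vectors[:, s, :]))
        if k + 1 < len(idx) and idx[k + 1] == s + 1:
            Js.append(model.coupling.get((contexts[s], contexts[s + 1])))
        elif k + 1 < len(idx):
            Js.append(None)

    assign = [w.argmin(axis=1) for w in wells]
    for _ in range(n_sweeps):
        changed = False
        for k in range(len(idx)):
            cost = wells[k].copy()
            if k > 0 and Js[k - 1] is not None:
                cost += Js[k - 1][assign[k - 1], :]
            if k < len(idx) - 1 and Js[k] is not None:
                cost += Js[k][:, assign[k + 1]].T
            new = cost.argmin(axis=1)
            if np.any(new != assign[k]):
                changed = True
            assign[k] = new
        if not changed:
            break

    total = np.zeros(n_frames)
    for k in range(len(idx)):
        total += wells[k][np.arange(n_frames), assign[k]]
        if k < len(idx) - 1 and Js[k] is not None:
            total += Js[k][assign[k], assign[k + 1]]
    return total


def energy(model: DeformationModel, ensemble: HelicalEnsemble,
           bp_range: tuple[int, int]) -> np.ndarray:
    """Per-frame deformation energy (kcal/mol) over a 1-based bp range."""
    X = step_vectors(ensemble)
    contexts = step_contexts(annotated_sequence(ensemble))
    idx = region_steps(bp_range, ensemble.n_bp)
    return evaluate_frames(model, X, contexts, idx)


def profile_regions(model: DeformationModel, ensemble: HelicalEnsemble,
                    regions: Mapping[str, tuple[int, int]]) -> dict[str, DeformationProfile]:
    """Deformation profiles for named (possibly overlapping) bp regions."""
    X = step_vectors(ensemble)
    contexts = step_contexts(annotated_sequence(ensemble))
    out = {}
    for label, (a, b) in regions.items():
        idx = region_steps((a, b), ensemble.n_bp)
        e = evaluate_frames(model, X, contexts, idx)
        out[label] = DeformationProfile(region=(a, b), label=label,
                                        energies=e, n_bp=b - a + 1)
    return out


def classify_mechanism(e_bound: float, e_naked: float) -> str:
    """Binding-mechanism trichotomy from per-bp deformation energies.

    A two-fold or larger increase of the bound-DNA deformation energy over
    naked DNA indicates induced fit; no increase indicates conformational
    selection (the bound conformation is thermally accessible); anything in
    between indicates coexisting mechanisms.
    """
    if e_bound < 0 or e_naked < 0:
        raise ValueError("deformation energies must be >= 0")
    if e_bound >= 2.0 * e_naked:
        return MECHANISM_INDUCED_FIT
    if e_bound <= e_naked:
        return MECHANISM_CONFORMATIONAL_SELECTION
    return MECHANISM_MIXED


# ---------------------------------------------------------------------------
# Boltzmann sampling
# ---------------------------------------------------------------------------

def sample_boltzmann(model: DeformationModel, contexts: Sequence[str],
                     n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Draw (n_samples, n_steps, 12) configurations from the model.

    Each position draws a substate by weight and then a Gaussian from that
    substate's covariance.  For a single-substate model this is exactly the
    model's Boltzmann distribution at its fitting temperature; with several
    substates it is the mixture approximation (bond couplings are not
    resampled).
    """
    n_steps = len(contexts)
    out = np.empty((n_samples, n_steps, N_DOF))
    for s, key in enumerate(contexts):
        cm = model.context_for(key)
        weights = np.array([st.weight for st in cm.substates])
        weights = weights / weights.sum()
        choice = rng.choice(len(weights), size=n_samples, p=weights)
        for k, st in enumerate(cm.substates):
            m = choice == k
            if m.any():
                out[m, s, :] = rng.multivariate_normal(
                    st.x0, st.covariance, size=int(m.sum()),
                    method="cholesky")
    return out


def thermal_energy_per_bp(model: DeformationModel, ensemble: HelicalEnsemble,
                          bp_range: tuple[int, int], n_samples: int,
                          rng: np.random.Generator) -> float:
    """Mean deformation energy per bp of model-sampled configurations."""
    contexts = step_contexts(annotated_sequence(ensemble))
    idx = region_steps(bp_range, ensemble.n_bp)
    region_ctx = [contexts[s] for s in idx]
    draws = sample_boltzmann(model, region_ctx, n_samples, rng)
    e = evaluate_frames(model, draws, region_ctx, np.arange(len(idx)))
    return float(e.mean() / (bp_range[1] - bp_range[0] + 1))
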