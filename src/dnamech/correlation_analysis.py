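"""Long-distance (lagged) correlation maps between per-position series.

For parameters p, q and lag tau (frames), the map holds the Pearson
correlation of x_p at position i with x_q at position j shifted tau frames
later, over all overlapping frames.  Translational helical parameters
(shift, slide, rise, x-displacement) and groove parameters (widths,
depths) are the study's default choices; any per-position series of a
:class:`~dnamech.helical_geometry.HelicalEnsemble` can be mapped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .helical_geometry import HelicalEnsemble

TRANSLATIONAL_PARAMS = ("shift", "slide", "rise", "xdisp")
GROOVE_PARAMS = ("major_width", "major_depth", "minor_width", "minor_depth")


@dataclass
class CorrelationMap:
    param_p: str
    param_q: str
    lag: int
    matrix: np.ndarray        # (n_pos_p, n_pos_q), NaN where undefined
    n_frames: int             # overlapping frames used

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix).to_csv(path, sep="\t", index=True)


def _standardize(x: np.ndarray) -> np.ndarray:
    """Column-standardise; constant or NaN-containing columns become NaN
    (undefined, flagged rather than zeroed)."""
    x = np.asarray(x, dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    bad = ~np.isfinite(mean) | ~np.isfinite(sd) | (sd <= 0)
    out = np.empty_like(x)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (x - mean) / sd
    out[:, bad] = np.nan
    return out


def lagged_correlation(ensemble: HelicalEnsemble, p: str, q: str,
                       lags: Sequence[int] = (0,)) -> dict[int, CorrelationMap]:
    """Pearson maps r[i][j](tau) = corr(x_p,i(t), x_q,j(t + tau)).

    Requires the series length to exceed max(lags) + 100 frames.
    """
    X = ensemble.series(p)
    Y = ensemble.series(q)
    n = X.shape[0]
    max_lag = max(lags)
    if n <= max_lag + 100:
        raise ValueError(
            f"series length {n} too short for max lag {max_lag}")
    out = {}
    for lag in lags:
        A = _standardize(X[:n - lag] if lag else X)
        B = _standardize(Y[lag:] if lag else Y)
        m = A.shape[0]
        bad_a = np.isnan(A).any(axis=0)
        bad_b = np.isnan(B).any(axis=0)
        Af = np.where(np.isnan(A), 0.0, A)
        Bf = np.where(np.isnan(B), 0.0, B)
        mat = (Af.T @ Bf) / (m - 1)
        mat[bad_a, :] = np.nan
        mat[:, bad_b] = np.nan
        out[lag] = CorrelationMap(param_p=p, param_q=q, lag=lag,
                                  matrix=mat, n_frames=m)
    return out


@dataclass
class CorrelationHit:
    pos_p: int     # 1-based position index
    pos_q: int
    r: float


def map_summary(cmap: CorrelationMap, threshold: float = 0.2,
                min_separation: int = 5) -> list[CorrelationHit]:
    """Long-distance cells with |r| >= threshold and |i - j| >= separation,
    sorted by descending |r|."""
    hits = []
    mat = cmap.matrix
    for i in range(mat.shape[0]):
        for j in range(mat.shape[1]):
            r = mat[i, j]
            if np.isfinite(r) and abs(r) >= threshold \
                    and abs(i - j) >= min_separation:
                hits.append(CorrelationHit(pos_p=i + 1, pos_q=j + 1, r=float(r)))
    hits.sort(key=lambda h: -abs(h.r))
    return hits


def lag_sweep_peak(ensemble: HelicalEnsemble, p: str, i: int, q: str, j: int,
                   lags: Sequence[int]) -> tuple[int, float]:
    """(argmax lag, correlation) of |r_ij(tau)| over a lag grid.

    Positions are 1-based.
    """
    maps = lagged_correlation(ensemble, p, q, lags=lags)
    best_lag, best_r = None, 0.0
    for lag, cmap in maps.items():
        r = cmap.matrix[i - 1, j - 1]
        if np.isfinite(r) and abs(r) >= abs(best_r):
            best_lag, best_r = lag, float(r)
    return best_lag, best_r
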