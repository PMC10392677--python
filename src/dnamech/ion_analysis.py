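"""Curvilinear-coordinate ion statistics around the DNA helical axis.

Each ion observation is mapped to the nearest point of the smoothed
helical axis, giving a level D (bp index), a radial distance R (A,
measured perpendicular to the local axis tangent) and an azimuth A (deg,
measured from the bp frame's major-groove x-axis toward the Watson-backbone
y-axis).  Groove molarities divide sector counts by the analytic
curvilinear sector volume; by construction a uniform bulk cloud returns
its bulk molarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import CONSTANTS, TrajectoryHandle
from .helical_geometry import BasePairFrames, helical_axis

#: default groove sectors (degrees around the bp-frame major-groove axis)
MAJOR_SECTOR = (-60.0, 60.0)
MINOR_SECTOR = (120.0, 240.0)      # i.e. |A| >= 120 on the minor side


@dataclass
class IonDensity:
    """Binned (level, radius, azimuth) ion observations."""

    species: str
    counts: np.ndarray          # (n_bp, n_r, n_a)
    bulk_count: int             # beyond r_max
    n_frames: int
    n_ions: int
    r_edges: np.ndarray
    a_edges: np.ndarray         # degrees, spanning (-180, 180]
    level_spacing: np.ndarray   # (n_bp,) mean axis arc length per level, A

    @property
    def total_observations(self) -> int:
        return int(self.counts.sum()) + self.bulk_count


def ion_histogram(traj: TrajectoryHandle, frames: BasePairFrames,
                  species: str = "K", r_max: float = 25.0,
                  r_bin: float = 0.5, a_bin: float = 10.0,
                  axis_smoothing: float = 1.0) -> IonDensity:
    """Histogram ion positions in curvilinear helicoidal coordinates.

    Ions farther than ``r_max`` from the axis (or off the axis ends) count
    as bulk.
    """
    ions = traj.atoms_with_role("ion")
    sel = ions[np.asarray(ions.resnames) == species]
    if len(sel) == 0:
        raise ValueError(f"no ion atoms of species {species!r}")
    n_frames = traj.n_frames
    n_bp = frames.n_bp
    axis = helical_axis(frames.bp_o, smoothing=axis_smoothing)

    r_edges = np.arange(0.0, r_max + r_bin, r_bin)
    a_edges = np.arange(-180.0, 180.0 + a_bin, a_bin)
    counts = np.zeros((n_bp, len(r_edges) - 1, len(a_edges) - 1))
    bulk = 0

    spacing = np.linalg.norm(np.diff(axis, axis=1), axis=2).mean(axis=0)
    level_spacing = np.empty(n_bp)
    level_spacing[1:-1] = 0.5 * (spacing[:-1] + spacing[1:])
    level_spacing[0] = spacing[0]
    level_spacing[-1] = spacing[-1]

    for f in range(n_frames):
        pos = traj.coordinates(f, sel)
        d2 = ((pos[:, None, :] - axis[f][None, :, :]) ** 2).sum(axis=2)
        level = d2.argmin(axis=1)
        v = pos - axis[f][level]
        z_hat = frames.bp_R[f, level, :, 2]
        x_hat = frames.bp_R[f, level, :, 0]
        y_hat = frames.bp_R[f, level, :, 1]
        v_perp = v - np.einsum("ni,ni->n", v, z_hat)[:, None] * z_hat
        r = np.linalg.norm(v_perp, axis=1)
        ang = np.degrees(np.arctan2(np.einsum("ni,ni->n", v_perp, y_hat),
                                    np.einsum("ni,ni->n", v_perp, x_hat)))
        ok = r < r_max
        bulk += int((~ok).sum())
        ri = np.clip((r[ok] / r_bin).astype(int), 0, len(r_edges) - 2)
        ai = np.clip(((ang[ok] + 180.0) / a_bin).astype(int),
                     0, len(a_edges) - 2)
        np.add.at(counts, (level[ok], ri, ai), 1.0)

    return IonDensity(species=species, counts=counts, bulk_count=bulk,
                      n_frames=n_frames, n_ions=len(sel),
                      r_edges=r_edges, a_edges=a_edges,
                      level_spacing=level_spacing)


def _sector_mask(a_centres: np.ndarray, sector: tuple[float, float]) -> np.ndarray:
    lo, hi = sector
    a = np.mod(a_centres - lo, 360.0)
    width = np.mod(hi - lo, 360.0)
    if width == 0:
        width = 360.0
    return a < width


def groove_molarity(density: IonDensity,
                    r_range: tuple[float, float] = (2.0, 10.25),
                    sectors: dict[str, tuple[float, float]] | None = None,
                    ) -> pd.DataFrame:
    """Per-bp groove molarity (mol/L) from the binned density.

    molarity = counts / (n_frames * N_A * V_sector), with the sector
    volume from the curvilinear bin geometry
    V = delta_z * (theta/2) * (r_out^2 - r_in^2).
    """
    if sectors is None:
        sectors = {"major": MAJOR_SECTOR, "minor": MINOR_SECTOR}
    r_centres = 0.5 * (density.r_edges[:-1] + density.r_edges[1:])
    a_centres = 0.5 * (density.a_edges[:-1] + density.a_edges[1:])
    r_mask = (r_centres >= r_range[0]) & (r_centres < r_range[1])
    if not r_mask.any():
        raise ValueError("radial range selects no bins")
    # analytic volume from the edges of the bins actually included
    r_lo = density.r_edges[:-1][r_mask][0]
    r_hi = density.r_edges[1:][r_mask][-1]
    rows = []
    for name, sector in sectors.items():
        a_mask = _sector_mask(a_centres, sector)
        theta = np.deg2rad(np.mod(sector[1] - sector[0], 360.0) or 360.0)
        counts = density.counts[:, r_mask][:, :, a_mask].sum(axis=(1, 2))
        for i in range(density.counts.shape[0]):
            v_a3 = density.level_spacing[i] * 0.5 * theta * (r_hi ** 2 - r_lo ** 2)
            if v_a3 <= 0:
                molarity = np.nan
            else:
                v_litre = v_a3 * 1e-27
                molarity = counts[i] / (density.n_frames * CONSTANTS.N_A * v_litre)
            rows.append({"bp": i + 1, "groove": name,
                         "count": counts[i], "molarity": molarity})
    return pd.DataFrame(rows)


def radial_profile(density: IonDensity,
                   sector: tuple[float, float] = MAJOR_SECTOR,
                   bp_range: tuple[int, int] | None = None) -> pd.DataFrame:
    """Counts vs radius within a groove sector (optionally bp-restricted)."""
    a_centres = 0.5 * (density.a_edges[:-1] + density.a_edges[1:])
    a_mask = _sector_mask(a_centres, sector)
    counts = density.counts[:, :, a_mask].sum(axis=2)
    if bp_range is not None:
        counts = counts[bp_range[0] - 1:bp_range[1]]
    prof = counts.sum(axis=0)
    r_centres = 0.5 * (density.r_edges[:-1] + density.r_edges[1:])
    return pd.DataFrame({"r": r_centres, "count": prof})


def radial_mode(density: IonDensity,
                sector: tuple[float, float] = MAJOR_SECTOR,
                bp_range: tuple[int, int] | None = None) -> float:
    """Radius of the most populated radial bin within a sector."""
    prof = radial_profile(density, sector, bp_range)
    return float(prof["r"][prof["count"].idxmax()])
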