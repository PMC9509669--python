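"""Niche-dynamics quantification in a gridded, kernel-smoothed PCA space.

The two-entity comparison (an ancestral "native" entity vs. a derived
"introduced" one — e.g. a wild progenitor vs. its cultivated crop) follows
the COUE scheme: occurrences of both entities are projected onto the first
two principal components of the climate predictors, their densities are
kernel-smoothed on a bounded 100 × 100 grid, corrected for the availability
of environments, and the occupied cells are partitioned into

* stability  (S) — cells occupied by both entities,
* unfilling  (U) — cells occupied only by the native entity,
* expansion  (E) — cells occupied only by the introduced entity.

From the occupied-cell counts, niche breadths BN = U + S (native) and
BI = E + S (introduced) give the breadth ratio BR = BI / BN and Sørensen's
similarity SI = 2S / (BN + BI).  The niche-conservatism hypothesis is
rejected when BR > 1 and SI < 0.5.

Normalization convention: E and S are reported as fractions of the
introduced breadth BI (so E + S = 1) and U as a fraction of the native
breadth BN, while BN, BI, BR and SI are computed on raw occupied-cell
counts. This is the only convention under which breadth ratios far above 1
can coexist with expansion/stability fractions that sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .predictors import SampleMatrix

DEFAULT_RESOLUTION = 100
#: truncation radius of the Gaussian kernel, in bandwidths; beyond it the
#: kernel is exactly zero, so "positive density" delimits a bounded region
KERNEL_TRUNCATION = 4.0


@dataclass
class EnvSpace:
    """A fitted two-dimensional environmental ordination space."""

    basis: np.ndarray            # (2, p) loading vectors for PC1, PC2
    explained: np.ndarray        # variance fraction per axis
    center: np.ndarray           # column means of the calibration data
    scale: np.ndarray            # column standard deviations
    columns: list[str]
    bounds: np.ndarray           # (2, 2): [[min1, max1], [min2, max2]]
    resolution: int = DEFAULT_RESOLUTION

    @property
    def loadings_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"PC1": self.basis[0], "PC2": self.basis[1]}, index=self.columns
        )

    def project(self, matrix: SampleMatrix, clamp: bool = True) -> np.ndarray:
        """Project a sample matrix into (n, 2) axis scores, clamped to bounds."""
        x = matrix.values[self.columns].to_numpy(dtype=float)
        z = (x - self.center) / self.scale
        scores = z @ self.basis.T
        if clamp:
            scores = np.clip(scores, self.bounds[:, 0], self.bounds[:, 1])
        return scores

    def grid_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center coordinates along each axis."""
        axes = []
        for j in range(2):
            lo, hi = self.bounds[j]
            edges = np.linspace(lo, hi, self.resolution + 1)
            axes.append(0.5 * (edges[:-1] + edges[1:]))
        return axes[0], axes[1]


def fit_env_pca(
    background: SampleMatrix,
    resolution: int = DEFAULT_RESOLUTION,
    bounds_margin: float = 0.1,
) -> EnvSpace:
    """Correlation-matrix PCA of the background environments, keeping two axes.

    Columns are z-scored before the eigendecomposition, so each predictor
    contributes equal variance. Sign convention: on each axis the loading of
    largest magnitude is made positive. Grid bounds are the score range of
    the calibration data extended by ``bounds_margin`` on each side.
    """
    if resolution < 10:
        raise ValueError("resolution must be at least 10")
    x = background.to_numpy()
    if x.shape[0] < 3:
        raise ValueError("need at least 3 background rows to fit the space")
    center = x.mean(axis=0)
    scale = x.std(axis=0, ddof=1)
    nonconstant = scale > 0
    if nonconstant.sum() < 2:
        raise ValueError("background is degenerate: fewer than 2 varying predictors")
    scale = np.where(nonconstant, scale, 1.0)
    z = (x - center) / scale
    if np.linalg.matrix_rank(z, tol=1e-10) < 2:
        raise ValueError("background has rank < 2; cannot build a 2-D space")
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(z)
    basis = pca.components_.copy()
    for j in range(2):
        dominant = np.argmax(np.abs(basis[j]))
        if basis[j, dominant] < 0:
            basis[j] = -basis[j]
            scores[:, j] = -scores[:, j]
    lo = scores.min(axis=0)
    hi = scores.max(axis=0)
    pad = (hi - lo) * bounds_margin
    bounds = np.column_stack([lo - pad, hi + pad])
    return EnvSpace(
        basis=basis,
        explained=pca.explained_variance_ratio_.copy(),
        center=center,
        scale=scale,
        columns=list(background.columns),
        bounds=bounds,
        resolution=resolution,
    )


def top_loadings(space: EnvSpace, axis: int, k: int) -> list[str]:
    """Predictors ranked by |loading| on axis 1 or 2; ties broken alphabetically."""
    if axis not in (1, 2):
        raise ValueError("axis must be 1 or 2")
    load = np.abs(space.basis[axis - 1])
    order = sorted(zip(space.columns, load), key=lambda t: (-t[1], t[0]))
    return [name for name, _ in order[: max(0, k)]]


@dataclass
class DensityGrid:
    """Kernel-smoothed occurrence density on the environment-space grid."""

    occ_density: np.ndarray       # normalized to total mass 1
    env_density: np.ndarray       # background availability, mass 1
    corrected: np.ndarray         # occupancy density after availability correction
    occupied: np.ndarray          # boolean occupancy per grid cell
    bandwidth: np.ndarray         # per-axis kernel bandwidth used

    @property
    def occupied_cells(self) -> set[tuple[int, int]]:
        return {tuple(ix) for ix in np.argwhere(self.occupied)}


def _silverman_bandwidth(scores: np.ndarray) -> np.ndarray:
    # 2-D reference rule: h_j = sigma_j * n^(-1/6)
    n = scores.shape[0]
    sd = scores.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1e-12)
    return sd * n ** (-1.0 / 6.0)


def _truncated_kde_1d(points: np.ndarray, centers: np.ndarray, h: float) -> np.ndarray:
    """(n_points, n_centers) Gaussian kernel weights, zero beyond the truncation radius."""
    d = (centers[None, :] - points[:, None]) / h
    k = np.exp(-0.5 * d * d)
    k[np.abs(d) > KERNEL_TRUNCATION] = 0.0
    return k


def _kde_on_grid(scores: np.ndarray, ax1: np.ndarray, ax2: np.ndarray, h: np.ndarray) -> np.ndarray:
    # separable axis-aligned Gaussian product kernel
    k1 = _truncated_kde_1d(scores[:, 0], ax1, h[0])
    k2 = _truncated_kde_1d(scores[:, 1], ax2, h[1])
    return k1.T @ k2  # (res1, res2), indexed [i1, i2]


def density_grid(
    scores: np.ndarray,
    background_scores: np.ndarray,
    space: EnvSpace,
    bandwidth: str | float | np.ndarray = "silverman",
    threshold_quantile: float = 0.0,
    threshold_mode: str = "value",
) -> DensityGrid:
    """Availability-corrected kernel density of occurrences in environment space.

    The occurrence and background scores are smoothed with a truncated
    Gaussian product kernel on the space's grid, each normalized to unit
    mass. The corrected occupancy density divides occurrence density by
    background availability (cells with zero availability are excluded).

    Occupancy thresholding (``threshold_mode``):

    * ``"value"`` (default): occupied cells are those whose corrected
      density exceeds the ``threshold_quantile`` quantile of its positive
      values; quantile 0 keeps every positive cell.
    * ``"mass"``: occupied cells form the smallest highest-density region
      holding at least 1 − ``threshold_quantile`` of the corrected mass.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("scores must be (n, 2)")
    if scores.shape[0] < 5:
        raise ValueError("need at least 5 occurrence scores for a density estimate")
    if not 0.0 <= threshold_quantile < 1.0:
        raise ValueError("threshold_quantile must be in [0, 1)")
    if threshold_mode not in ("value", "mass"):
        raise ValueError("threshold_mode must be 'value' or 'mass'")

    if isinstance(bandwidth, str):
        if bandwidth != "silverman":
            raise ValueError(f"unknown bandwidth rule {bandwidth!r}")
        h = _silverman_bandwidth(scores)
    else:
        h = np.broadcast_to(np.asarray(bandwidth, dtype=float), (2,)).copy()
    if np.any(h <= 0):
        raise ValueError("bandwidth must be positive")

    ax1, ax2 = space.grid_axes()
    occ = _kde_on_grid(scores, ax1, ax2, h)
    env = _kde_on_grid(np.asarray(background_scores, dtype=float), ax1, ax2,
                       _silverman_bandwidth(np.asarray(background_scores, dtype=float)))
    occ_sum = occ.sum()
    env_sum = env.sum()
    if occ_sum <= 0 or env_sum <= 0:
        raise ValueError("density is identically zero on the grid; check bounds")
    occ /= occ_sum
    env /= env_sum

    corrected = np.zeros_like(occ)
    avail = env > 0
    corrected[avail] = occ[avail] / env[avail]
    total = corrected.sum()
    if total > 0:
        corrected = corrected / total

    if threshold_mode == "value":
        pos = corrected[corrected > 0]
        if pos.size == 0:
            occupied = np.zeros_like(corrected, dtype=bool)
        elif threshold_quantile == 0.0:
            occupied = corrected > 0
        else:
            thr = np.quantile(pos, threshold_quantile)
            occupied = corrected > thr
    else:  # mass
        flat = corrected.ravel()
        order = np.argsort(flat)[::-1]
        cum = np.cumsum(flat[order])
        target = 1.0 - threshold_quantile
        n_keep = int(np.searchsorted(cum, target) + 1)
        n_keep = min(n_keep, int((flat > 0).sum()))
        occupied = np.zeros(flat.size, dtype=bool)
        occupied[order[:n_keep]] = True
        occupied = occupied.reshape(corrected.shape)

    return DensityGrid(occ, env, corrected, occupied, h)


@dataclass
class NicheIndices:
    """COUE partition counts and the derived breadth/similarity indices."""

    E_frac: float          # expansion fraction of introduced breadth
    S_frac_intro: float    # stability fraction of introduced breadth
    U_frac: float          # unfilling fraction of native breadth
    S_cells: int
    U_cells: int
    E_cells: int
    BN: int                # native breadth, occupied-cell count
    BI: int                # introduced breadth, occupied-cell count
    BR: float              # BI / BN
    SI: float              # 2S / (BN + BI)

    def as_dict(self) -> dict:
        return {
            "E": self.E_frac, "S": self.S_frac_intro, "U": self.U_frac,
            "S_cells": self.S_cells, "U_cells": self.U_cells, "E_cells": self.E_cells,
            "BN": self.BN, "BI": self.BI, "BR": self.BR, "SI": self.SI,
        }


def indices_from_sets(native_cells: set, intro_cells: set) -> NicheIndices:
    """COUE indices from two occupied-cell sets (the set-arithmetic core)."""
    s = len(native_cells & intro_cells)
    u = len(native_cells - intro_cells)
    e = len(intro_cells - native_cells)
    bn = u + s
    bi = e + s
    if bn == 0:
        raise ZeroDivisionError("native breadth is zero; BR and U are undefined")
    return NicheIndices(
        E_frac=e / bi if bi else 0.0,
        S_frac_intro=s / bi if bi else 0.0,
        U_frac=u / bn,
        S_cells=s, U_cells=u, E_cells=e,
        BN=bn, BI=bi,
        BR=bi / bn,
        SI=2.0 * s / (bn + bi),
    )


def niche_indices(native: DensityGrid, intro: DensityGrid) -> NicheIndices:
    """Partition two occupancy grids into S/U/E and derive BN, BI, BR, SI."""
    if native.occupied.shape != intro.occupied.shape:
        raise ValueError("grids are not on the same environment space")
    nat = native.occupied
    intr = intro.occupied
    s = int(np.sum(nat & intr))
    u = int(np.sum(nat & ~intr))
    e = int(np.sum(~nat & intr))
    bn = u + s
    bi = e + s
    if bn == 0:
        raise ZeroDivisionError("native breadth is zero; BR and U are undefined")
    return NicheIndices(
        E_frac=e / bi if bi else 0.0,
        S_frac_intro=s / bi if bi else 0.0,
        U_frac=u / bn,
        S_cells=s, U_cells=u, E_cells=e,
        BN=bn, BI=bi,
        BR=bi / bn,
        SI=2.0 * s / (bn + bi),
    )


def conservatism_verdict(idx: NicheIndices) -> str:
    """``"not_conserved"`` iff BR > 1 and SI < 0.5, else ``"conserved"``."""
    return "not_conserved" if (idx.BR > 1.0 and idx.SI < 0.5) else "conserved"


def sorensen_from_triple(e: float, s: float, u: float) -> float:
    """Sørensen similarity from a breadth-normalized (E, S, U) triple.

    Applies BN = U + S, BI = E + S and SI = 2S/(BN + BI) directly on the
    normalized scale; useful for checking the internal consistency of
    reported expansion/stability/unfilling triples.
    """
    bn = u + s
    bi = e + s
    if bn + bi == 0:
        raise ZeroDivisionError("both breadths are zero")
    return 2.0 * s / (bn + bi)
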