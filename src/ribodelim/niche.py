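"""Realized-niche analysis of metabarcoding time series.

The Outlying Mean Index (OMI) of a taxon is the squared distance between
its abundance-weighted mean position in (range-standardized, centered)
environmental space and the average sampled conditions; tolerance is the
weighted variance of sample positions projected on the marginality
direction, and the residual tolerance the remaining per-taxon inertia.
Eigenanalysis of the taxon-weighted marginality cross-product gives niche
axes shared by all taxa.  Realized niches on the first two axes are
abundance-weighted Gaussian kernel densities on a common grid, compared
pairwise with Schoener's D overlap statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .phenotypes import range_standardize


@dataclass
class OMIResult:
    taxa: list[str]
    marginality: np.ndarray       # taxa x descriptors
    omi: np.ndarray               # squared marginality norm
    tolerance: np.ndarray
    residual_tolerance: np.ndarray
    inertia: np.ndarray
    weights: np.ndarray           # taxon share of total abundance
    axes: np.ndarray              # descriptors x axes (unit eigenvectors)
    eigenvalues: np.ndarray
    sample_scores: np.ndarray     # samples x axes
    descriptor_names: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "taxon": self.taxa, "omi": self.omi, "tolerance": self.tolerance,
            "residual_tolerance": self.residual_tolerance, "inertia": self.inertia,
            "weight": self.weights,
        })


@dataclass
class KernelNiche:
    """Gridded abundance-weighted density on the first two niche axes."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    density: np.ndarray  # (gx, gy) cell masses summing to 1

    def __post_init__(self) -> None:
        d = np.asarray(self.density, dtype=float)
        if np.any(d < 0):
            raise ValueError("density must be non-negative")
        s = d.sum()
        if not np.isfinite(s) or s <= 0:
            raise ValueError("density must have positive total mass")
        self.density = d / s

    def same_grid(self, other: "KernelNiche") -> bool:
        return (self.density.shape == other.density.shape
                and np.allclose(self.grid_x, other.grid_x)
                and np.allclose(self.grid_y, other.grid_y))


def filter_unique_sequences(counts: pd.DataFrame, min_libraries: int = 2) -> pd.DataFrame:
    """Drop taxa observed in fewer than ``min_libraries`` samples."""
    present = (counts > 0).sum(axis=0)
    kept = counts.loc[:, present >= min_libraries]
    if kept.shape[1] == 0:
        warnings.warn("no taxa survive the library-occurrence filter")
    return kept


def hellinger(counts: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: sqrt of within-sample relative abundance."""
    x = counts.to_numpy(dtype=float)
    row_sums = x.sum(axis=1)
    if (row_sums == 0).any():
        raise ValueError("all-zero sample row: Hellinger transform undefined")
    return pd.DataFrame(np.sqrt(x / row_sums[:, None]),
                        index=counts.index, columns=counts.columns)


def omi_analysis(y: pd.DataFrame, x: pd.DataFrame) -> OMIResult:
    """Outlying Mean Index analysis of a community table against descriptors.

    ``y``: samples x taxa abundances (typically Hellinger transformed);
    ``x``: samples x descriptors.  Descriptors are range-standardized to
    [0, 1] and centered on the uniform sample mean, so the origin is the
    average sampled condition.  Taxa with zero total are excluded with a
    warning.
    """
    if list(y.index) != list(x.index):
        raise ValueError("community and environment tables must share sample order")
    xs = range_standardize(x).to_numpy(dtype=float)
    xc = xs - xs.mean(axis=0)

    totals = y.sum(axis=0)
    dead = totals[totals <= 0].index.tolist()
    if dead:
        warnings.warn(f"excluding taxa with zero total abundance: {dead}")
        y = y.drop(columns=dead)
        totals = totals.drop(dead)

    taxa = list(y.columns)
    q = y.to_numpy(dtype=float) / totals.to_numpy(dtype=float)  # samples x taxa profiles
    m = q.T @ xc                                                # taxa x descriptors
    omi = np.einsum("td,td->t", m, m)
    inertia = q.T @ np.einsum("id,id->i", xc, xc)

    tol = np.zeros(len(taxa))
    for t in range(len(taxa)):
        norm = np.sqrt(omi[t])
        if norm > 0:
            proj = xc @ (m[t] / norm)
            tol[t] = float(q[:, t] @ (proj - norm) ** 2)
        else:  # no marginality direction: all inertia is residual
            tol[t] = 0.0
    residual = inertia - omi - tol

    w = totals.to_numpy(dtype=float) / float(totals.sum())
    cross = m.T @ np.diag(w) @ m
    evals, evecs = np.linalg.eigh((cross + cross.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    scores = xc @ evecs

    return OMIResult(taxa, m, omi, tol, residual, inertia, w, evecs, evals,
                     scores, list(x.columns))


def _silverman_bandwidth(values: np.ndarray, weights: np.ndarray) -> float:
    w = weights / weights.sum()
    mu = float(w @ values)
    var = float(w @ (values - mu) ** 2)
    n_eff = float(weights.sum() ** 2 / np.sum(weights ** 2))
    sd = np.sqrt(var)
    if sd == 0:
        sd = max(abs(mu), 1.0) * 1e-3  # degenerate spread: nominal width
    return sd * n_eff ** (-1.0 / 6.0)  # Silverman's rule in two dimensions


def niche_grid(sample_scores: np.ndarray, g: int = 100,
               margin: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Shared evaluation grid spanning the sample cloud plus a margin."""
    s = np.asarray(sample_scores, dtype=float)[:, :2]
    lo, hi = s.min(axis=0), s.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    lo, hi = lo - margin * span, hi + margin * span
    return np.linspace(lo[0], hi[0], g), np.linspace(lo[1], hi[1], g)


def kernel_niche(sample_scores: np.ndarray, weights: np.ndarray,
                 grid: tuple[np.ndarray, np.ndarray] | None = None,
                 g: int = 100) -> KernelNiche:
    """Abundance-weighted Gaussian product-kernel density on the niche plane.

    Per-axis bandwidths follow Silverman's rule on the weighted samples;
    cell masses are normalized to sum to one, so uniformly rescaling the
    weights leaves the niche unchanged.
    """
    s = np.asarray(sample_scores, dtype=float)[:, :2]
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if w.sum() <= 0:
        raise ValueError("weights must have positive total")
    if grid is None:
        grid = niche_grid(s, g=g)
    gx, gy = grid
    hx = _silverman_bandwidth(s[:, 0], w)
    hy = _silverman_bandwidth(s[:, 1], w)
    kx = np.exp(-0.5 * ((gx[:, None] - s[None, :, 0]) / hx) ** 2)  # gx x n
    ky = np.exp(-0.5 * ((gy[:, None] - s[None, :, 1]) / hy) ** 2)  # gy x n
    density = np.einsum("in,n,jn->ij", kx, w, ky)
    return KernelNiche(gx, gy, density)


def schoener_d(a: KernelNiche, b: KernelNiche) -> float:
    """Schoener's niche overlap D = 1 - 0.5 * sum |p_a - p_b| in [0, 1]."""
    if not a.same_grid(b):
        raise ValueError("niches must share the same grid")
    return float(1.0 - 0.5 * np.abs(a.density - b.density).sum())


def overlap_matrix(niches: dict[str, KernelNiche]) -> tuple[pd.DataFrame, list[str]]:
    """All-pairs Schoener D plus an average-linkage leaf order for heatmaps."""
    taxa = list(niches)
    if len(taxa) < 2:
        raise ValueError("need at least two niches")
    n = len(taxa)
    d = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = schoener_d(niches[taxa[i]], niches[taxa[j]])
    frame = pd.DataFrame(d, index=taxa, columns=taxa)
    dissim = squareform(np.clip(1.0 - d, 0.0, None), checks=False)
    order = [taxa[i] for i in leaves_list(linkage(dissim, method="average"))]
    return frame, order
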