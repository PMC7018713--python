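"""Phenotype comparisons and ordination of strains.

Ribotypes are compared on flow-cytometry characters, genome size, operon
copies and host range: pairwise two-sided Mann-Whitney tests on log(x+1)
data with Holm adjustment, then a principal coordinate analysis of
Bray-Curtis distances computed from range-standardized phenotypes combined
with raw binary infection columns, with environmental-style descriptor
fitting (envfit) onto the first two axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dist import DistanceMatrix


@dataclass
class OrdinationResult:
    ids: list[str]
    scores: np.ndarray            # samples x axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray       # positive eigenvalues, descending
    negative_inertia_fraction: float


@dataclass
class EnvfitResult:
    r2: float
    direction: np.ndarray  # unit vector in ordination space
    p: float
    n_perm: int


def pairwise_group_tests(values: dict[str, np.ndarray], alpha: float = 0.01,
                         adjust: str = "holm") -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney tests on log(x+1)-transformed data.

    Returns a long-format table with raw and Holm-adjusted p-values for
    every pair of groups with at least one observation each; empty groups
    are skipped.  The rank test is invariant to the monotone log transform;
    it is applied for consistency with the reported analyses.
    """
    groups = {g: np.log1p(np.asarray(v, dtype=float)) for g, v in values.items()
              if len(v) > 0}
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least two non-empty groups")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided",
                                     method="asymptotic")
            rows.append({"group_a": a, "group_b": b, "u": float(res.statistic),
                         "p_raw": float(res.pvalue)})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"], method=adjust)[1]
    out["significant"] = out["p_adj"] < alpha
    return out


def range_standardize(df: pd.DataFrame) -> pd.DataFrame:
    """Column-wise (x - min)/(max - min) scaling into [0, 1]."""
    out = {}
    for col in df.columns:
        x = df[col].to_numpy(dtype=float)
        span = x.max() - x.min()
        if span == 0:
            raise ValueError(f"column {col!r} is constant; range standardization undefined")
        out[col] = (x - x.min()) / span
    return pd.DataFrame(out, index=df.index)


def bray_curtis(df: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between rows of a non-negative matrix."""
    x = df.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("Bray-Curtis needs non-negative entries")
    if (x.sum(axis=1) == 0).any():
        raise ValueError("all-zero row: Bray-Curtis undefined")
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        num = np.abs(x[i] - x[i + 1:]).sum(axis=1)
        den = (x[i] + x[i + 1:]).sum(axis=1)
        d[i, i + 1:] = num / den
    d = d + d.T
    return DistanceMatrix([str(i) for i in df.index], d)


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinate analysis (classical metric scaling).

    Gower double-centering of -D^2/2, eigendecomposition, scores scaled by
    the square root of each positive eigenvalue.  Negative eigenvalues are
    dropped; their share of total absolute inertia is reported.
    """
    n = len(d.ids)
    a = -0.5 * d.values ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10 * max(1.0, abs(evals[0]))
    neg_frac = float(np.abs(evals[~pos & (evals < 0)]).sum() / np.abs(evals).sum()) if np.abs(evals).sum() else 0.0
    evals_pos = evals[pos]
    scores = evecs[:, pos] * np.sqrt(evals_pos)
    if n_axes is not None:
        scores = scores[:, :n_axes]
        evals_pos = evals_pos[:n_axes]
    return OrdinationResult(list(d.ids), scores, evals_pos, neg_frac)


def envfit(scores: np.ndarray, descriptor: np.ndarray, n_perm: int = 999,
           seed: int | None = None) -> EnvfitResult:
    """Fit one descriptor onto the first two ordination axes.

    Least squares of the centered descriptor on the centered axes; R^2 is
    the explained fraction of descriptor variance, the direction the unit
    coefficient vector, and significance the permutation fraction of fits
    with R^2 at least as large (vegan-style ``(hits + 1)/(n_perm + 1)``).
    """
    x = np.asarray(scores, dtype=float)[:, :2]
    y = np.asarray(descriptor, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant descriptor")
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    tss = float(yc @ yc)
    pinv = np.linalg.pinv(xc)

    def fit_r2(vec):
        beta = pinv @ vec
        resid = vec - xc @ beta
        return 1.0 - float(resid @ resid) / tss, beta

    r2, beta = fit_r2(yc)
    norm = np.linalg.norm(beta)
    direction = beta / norm if norm > 0 else beta
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm_r2, _ = fit_r2(rng.permutation(yc))
        if perm_r2 >= r2:
            hits += 1
    return EnvfitResult(r2, direction, (hits + 1) / (n_perm + 1), n_perm)


def envfit_table(scores: np.ndarray, descriptors: pd.DataFrame, n_perm: int = 999,
                 seed: int | None = None) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for col in descriptors.columns:
        y = descriptors[col].to_numpy(dtype=float)
        if np.ptp(y) == 0:  # constant descriptor carries no direction
            rows.append({"descriptor": col, "r2": np.nan, "p": np.nan,
                         "dir1": np.nan, "dir2": np.nan})
            continue
        res = envfit(scores, y, n_perm, seed=int(rng.integers(2**31 - 1)))
        rows.append({"descriptor": col, "r2": res.r2, "p": res.p,
                     "dir1": res.direction[0], "dir2": res.direction[1]})
    return pd.DataFrame(rows)


def phenotype_descriptor_matrix(phenotypes: pd.DataFrame,
                                host_matrix: pd.DataFrame) -> pd.DataFrame:
    """Descriptor matrix for the strain ordination.

    Continuous phenotypic characters are range-standardized to [0, 1];
    binary infection columns are appended unstandardized.
    """
    std = range_standardize(phenotypes)
    hosts = host_matrix.loc[std.index]
    if not hosts.isin([0, 1]).all().all():
        raise ValueError("host matrix must be binary")
    return pd.concat([std, hosts], axis=1)
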