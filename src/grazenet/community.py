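"""Community-level statistics: rarefaction, alpha diversity, Bray-Curtis,
and permutation-based PERMANOVA.

These are the standard whole-community analyses run alongside the
per-ASV interaction-strength estimation: subsample libraries to a fixed
depth (default 6215 reads, the smallest library in the reference
design), compare richness and Shannon diversity, and test treatment
effects on community composition with a one-way PERMANOVA on
Bray-Curtis dissimilarities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "rarefy",
    "richness",
    "shannon",
    "bray_curtis",
    "permanova",
    "pairwise_permanova",
    "PermanovaResult",
]

DEFAULT_RAREFACTION_DEPTH = 6215


def rarefy(counts: pd.DataFrame, depth: int = DEFAULT_RAREFACTION_DEPTH,
           seed: int = 0) -> pd.DataFrame:
    """Subsample every sample without replacement to exactly `depth` reads.

    Samples with fewer than `depth` reads are dropped with a warning;
    an error is raised if none remain. Seeded and reproducible.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    arr = counts.to_numpy(dtype=np.int64)
    totals = arr.sum(axis=1)
    keep = totals >= depth
    if not keep.any():
        raise ValueError(f"all samples are below rarefaction depth {depth}")
    if not keep.all():
        dropped = list(counts.index[~keep])
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below depth {depth}: {dropped}",
            stacklevel=2,
        )
    out = np.empty((int(keep.sum()), arr.shape[1]), dtype=np.int64)
    for r, i in enumerate(np.flatnonzero(keep)):
        if totals[i] == depth:
            out[r] = arr[i]
        else:
            out[r] = rng.multivariate_hypergeometric(arr[i], depth)
    return pd.DataFrame(out, index=counts.index[keep], columns=counts.columns)


def richness(counts: pd.DataFrame) -> pd.Series:
    """Observed ASV richness (count of taxa with count > 0) per sample."""
    arr = counts.to_numpy()
    return pd.Series((arr > 0).sum(axis=1), index=counts.index, name="richness")


def shannon(counts: pd.DataFrame) -> pd.Series:
    """Shannon diversity H = -sum p ln p (natural log) per sample.

    All-zero samples get NaN (H undefined on an empty composition).
    """
    arr = counts.to_numpy(dtype=float)
    totals = arr.sum(axis=1)
    out = np.full(arr.shape[0], np.nan)
    for i in range(arr.shape[0]):
        if totals[i] <= 0:
            continue
        p = arr[i] / totals[i]
        p = p[p > 0]
        out[i] = float(-(p * np.log(p)).sum())
    return pd.Series(out, index=counts.index, name="shannon")


def bray_curtis(counts: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities, BC(x,y) = sum|x-y| / sum(x+y).

    Returns a symmetric sample x sample DataFrame with zero diagonal.
    A pair of all-zero samples has an undefined dissimilarity (NaN,
    reported with a warning).
    """
    if counts.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    arr = counts.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(arr, metric="braycurtis"))
    np.fill_diagonal(d, 0.0)
    if np.isnan(d).any():
        warnings.warn("undefined Bray-Curtis entries (pairs of all-zero samples)",
                      stacklevel=2)
    return pd.DataFrame(d, index=counts.index, columns=counts.index)


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int
    seed: int
    group_sizes: dict

    def __repr__(self) -> str:  # compact, result-object style
        return (
            f"PermanovaResult(pseudo_F={self.pseudo_f:.4f}, R2={self.r2:.4f}, "
            f"p={self.p_value:.4g}, permutations={self.n_permutations})"
        )


def _ss_partition(d2: np.ndarray, codes: np.ndarray, k: int, n: int):
    """Total and within-group sums of squares from squared distances."""
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss_total, ss_within


def permanova(distances: pd.DataFrame, groups, n_permutations: int = 9999,
              seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA (pseudo-F over a distance matrix).

    The among/within partition follows the direct sum-of-squares
    formulation on squared dissimilarities; the p-value is
    (1 + #{F_perm >= F_obs}) / (n_permutations + 1) over seeded label
    permutations.
    """
    d = distances.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    labels = pd.Series(list(groups))
    if len(labels) != d.shape[0]:
        raise ValueError("group labels do not match distance matrix size")
    codes, uniques = pd.factorize(labels)
    k = len(uniques)
    if k < 2:
        raise ValueError("need >= 2 groups")
    sizes = pd.Series(codes).value_counts()
    if (sizes < 2).any():
        small = [str(uniques[i]) for i in sizes[sizes < 2].index]
        raise ValueError(f"group(s) with fewer than 2 samples: {small}")
    n = d.shape[0]
    d2 = d**2

    def pseudo_f(c):
        ss_total, ss_within = _ss_partition(d2, c, k, n)
        ss_among = ss_total - ss_within
        if ss_within == 0.0:  # groups internally identical
            return np.inf, ss_among / ss_total
        return (ss_among / (k - 1)) / (ss_within / (n - k)), ss_among / ss_total

    f_obs, r2 = pseudo_f(codes)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        f_p, _ = pseudo_f(perm)
        if f_p >= f_obs:
            exceed += 1
    p = (1.0 + exceed) / (n_permutations + 1.0)
    return PermanovaResult(
        pseudo_f=float(f_obs), r2=float(r2), p_value=float(p),
        n_permutations=n_permutations, seed=seed,
        group_sizes={str(uniques[i]): int(sizes[i]) for i in range(k)},
    )


def pairwise_permanova(distances: pd.DataFrame, groups, n_permutations: int = 9999,
                       seed: int = 0) -> pd.DataFrame:
    """All pairwise group contrasts with Benjamini-Hochberg adjustment."""
    from statsmodels.stats.multitest import multipletests

    labels = pd.Series(list(groups), index=distances.index)
    uniq = list(pd.unique(labels))
    rows = []
    for a in range(len(uniq) - 1):
        for b in range(a + 1, len(uniq)):
            mask = labels.isin([uniq[a], uniq[b]]).to_numpy()
            sub = distances.loc[mask, mask]
            res = permanova(sub, labels[mask], n_permutations, seed)
            rows.append((uniq[a], uniq[b], res.pseudo_f, res.r2, res.p_value))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "pseudo_f", "r2", "p_value"])
    if len(out):
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
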