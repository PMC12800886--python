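"""Nestedness metrics for (weighted) bipartite interaction matrices.

A bipartite matrix is nested when the partners of specialists form
subsets of the partners of generalists, i.e. presences pack into one
corner once rows and columns are sorted by marginal totals. This module
implements, from their primary definitions, the metrics used to
characterise grazer x ASV networks:

* :func:`nodf` — paired overlap and decreasing fill, binary, 0-100
  (``variant="sorted"`` is the fill-sorted NODF2 dialect);
* :func:`weighted_nodf` — the weighted extension (cells of the poorer
  row must carry strictly smaller positive weights), computed after
  sorting by marginal totals;
* :func:`wnoda` — weighted nestedness by overlap and decreasing
  abundance: the same pairwise term but ranked directly by marginal
  totals, with no sorting requirement;
* :func:`wine` — weighted-interaction nestedness estimator: mean
  weighted distance of links to the packed corner, normalised between
  its random and maximally packed calibrations;
* :func:`matrix_temperature` — Atmar-Patterson temperature (0 nested,
  100 disordered) minimised over row/column orders by seeded simulated
  annealing;
* :func:`discrepancy` — number of presences that must move to reach the
  perfectly packed matrix with the same row fills (``variant=
  "fill_sorted"`` is the discrepancy2 dialect).

Exact tie rules and constants are recorded in ``docs/metrics_reference.md``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

__all__ = [
    "nodf",
    "weighted_nodf",
    "wnoda",
    "wine",
    "WineResult",
    "matrix_temperature",
    "discrepancy",
    "compute_metrics",
]


def _as_matrix(mat) -> np.ndarray:
    arr = np.asarray(getattr(mat, "to_numpy", lambda: mat)(), dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    return arr


def _check_nondegenerate(arr: np.ndarray, name: str) -> None:
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError(f"{name}: need >= 2 rows and >= 2 columns, got {arr.shape}")
    if not (arr > 0).any():
        raise ValueError(f"{name}: matrix has no presences")


# ---------------------------------------------------------------------------
# NODF family
# ---------------------------------------------------------------------------


def _pair_scores(mat: np.ndarray, fills: np.ndarray, weighted: bool) -> float:
    """Sum of paired nestedness terms over positional pairs i<j.

    A pair contributes 0 unless the later row/column has strictly
    smaller fill; otherwise it contributes 100 x the fraction of the
    poorer margin's links that overlap the richer one (binary) or are
    strictly dominated by it (weighted).
    """
    n = mat.shape[0]
    total = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            if fills[j] >= fills[i] or fills[j] == 0:
                continue
            if weighted:
                k = np.count_nonzero((mat[j] > 0) & (mat[j] < mat[i]))
            else:
                k = np.count_nonzero((mat[j] > 0) & (mat[i] > 0))
            total += 100.0 * k / fills[j]
    return total


def _nodf_engine(arr: np.ndarray, weighted: bool, sort: bool) -> float:
    def order(a):
        fills = np.count_nonzero(a, axis=1)
        totals = a.sum(axis=1)
        key = sorted(range(a.shape[0]), key=lambda i: (-fills[i], -totals[i]))
        return a[np.array(key)]

    score = 0.0
    n_pairs = 0
    for axis_mat in (arr, arr.T):
        m = order(axis_mat) if sort else axis_mat
        fills = np.count_nonzero(m, axis=1)
        score += _pair_scores(m, fills, weighted)
        n = m.shape[0]
        n_pairs += n * (n - 1) // 2
    return score / n_pairs


def nodf(mat, variant: str = "sorted") -> float:
    """Binary NODF in [0, 100].

    ``variant="as_is"`` scores the matrix in its given order;
    ``variant="sorted"`` (the NODF2 dialect) first sorts rows and
    columns by decreasing fill (ties keep original order).
    """
    if variant not in ("as_is", "sorted"):
        raise ValueError(f"unknown variant {variant!r}")
    arr = (_as_matrix(mat) > 0).astype(float)
    _check_nondegenerate(arr, "nodf")
    return _nodf_engine(arr, weighted=False, sort=(variant == "sorted"))


def weighted_nodf(mat) -> float:
    """Weighted NODF in [0, 100].

    Rows and columns are sorted by decreasing fill (ties by decreasing
    marginal total); a pair contributes only under strictly decreasing
    fill, and the poorer member scores the fraction of its links whose
    weight is strictly below the richer member's weight in the same
    column — equal-weight overlaps score zero.
    """
    arr = _as_matrix(mat)
    if (arr < 0).any():
        raise ValueError("weighted_nodf: negative weights")
    _check_nondegenerate(arr, "weighted_nodf")
    return _nodf_engine(arr, weighted=True, sort=True)


def wnoda(mat) -> float:
    """Weighted nestedness by overlap and decreasing abundance, in [0, 100].

    Pairs are ranked by their marginal totals directly (no positional
    sorting requirement): for each unordered pair, the member with the
    smaller total is the "poorer" one and scores the fraction of its
    links strictly dominated by the richer member; ties in totals score 0.
    """
    arr = _as_matrix(mat)
    if (arr < 0).any():
        raise ValueError("wnoda: negative weights")
    _check_nondegenerate(arr, "wnoda")

    def margin(m):
        totals = m.sum(axis=1)
        fills = np.count_nonzero(m, axis=1)
        n = m.shape[0]
        s = 0.0
        for i in range(n - 1):
            for j in range(i + 1, n):
                if totals[i] == totals[j]:
                    continue
                g, p = (i, j) if totals[i] > totals[j] else (j, i)
                if fills[p] == 0:
                    continue
                k = np.count_nonzero((m[p] > 0) & (m[p] < m[g]))
                s += 100.0 * k / fills[p]
        return s, n * (n - 1) // 2

    sr, nr = margin(arr)
    sc, nc = margin(arr.T)
    return (sr + sc) / (nr + nc)


# ---------------------------------------------------------------------------
# WINE
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WineResult:
    """Weighted-interaction nestedness estimator.

    ``d_w`` is the weight-averaged Euclidean distance of links to the
    packed corner of the totals-sorted matrix; ``d_rnd`` its expectation
    under random link placement; ``d_pack`` its value when the same
    weights are packed as tightly as possible (heaviest nearest the
    corner). ``eta = (d_rnd - d_w)/(d_rnd - d_pack)`` is ~1 for maximal
    nestedness, ~0 for random structure, negative for anti-nested
    matrices; it is None when the calibration is degenerate.
    """

    d_w: float
    d_rnd: float
    d_pack: float
    eta: float | None

    @property
    def statistic(self) -> float:
        return self.eta if self.eta is not None else self.d_w


def _canonical_order(arr: np.ndarray, n_iter: int = 4) -> np.ndarray:
    """Sort rows/cols by decreasing totals, ties by content (permutation-stable)."""
    m = arr.copy()
    for _ in range(n_iter):
        rk = [(-m[i].sum(), tuple(-m[i])) for i in range(m.shape[0])]
        m = m[np.array(sorted(range(m.shape[0]), key=lambda i: rk[i]))]
        ck = [(-m[:, j].sum(), tuple(-m[:, j])) for j in range(m.shape[1])]
        m = m[:, np.array(sorted(range(m.shape[1]), key=lambda j: ck[j]))]
    return m


def wine(mat) -> WineResult:
    """Weighted-interaction nestedness estimator of a non-negative matrix."""
    arr = _as_matrix(mat)
    if (arr < 0).any():
        raise ValueError("wine: negative weights")
    if not (arr > 0).any():
        raise ValueError("wine: matrix has no links")
    m = _canonical_order(arr)
    r, c = m.shape
    ii, jj = np.meshgrid(np.arange(r), np.arange(c), indexing="ij")
    dist = np.sqrt(ii.astype(float) ** 2 + jj.astype(float) ** 2)
    links = m > 0
    w = m[links]
    d = dist[links]
    wsum = w.sum()
    d_w = float((w * d).sum() / wsum)
    d_rnd = float(dist.mean())
    # maximal packing: heaviest weights on the cells closest to the corner
    order_d = np.sort(dist.ravel())[: w.size]
    order_w = np.sort(w)[::-1]
    d_pack = float((order_w * order_d).sum() / wsum)
    denom = d_rnd - d_pack
    eta = None if abs(denom) < 1e-12 else float((d_rnd - d_w) / denom)
    return WineResult(d_w=d_w, d_rnd=d_rnd, d_pack=d_pack, eta=eta)


# ---------------------------------------------------------------------------
# Matrix temperature
# ---------------------------------------------------------------------------

#: Atmar-Patterson normalisation: maximal mean unexpectedness.
_T_NORM = 0.04145


def _isocline_p(fill: float) -> float:
    """Superellipse exponent whose filled area x^p + y^p < 1 equals `fill`."""

    def area(p):
        return np.exp(2.0 * gammaln(1.0 + 1.0 / p) - gammaln(1.0 + 2.0 / p))

    return brentq(lambda lp: area(np.exp(lp)) - fill, -8.0, 8.0, xtol=1e-10)


def _unexpectedness_grid(r: int, c: int, fill: float):
    """Per-cell u values (if unexpected) and the filled-side mask.

    Cell (i, j) sits at normalised position x=(j+.5)/c, y=(i+.5)/r from
    the packed top-left corner. The isocline of perfect nestedness at
    this fill is x^p + y^p = 1; a cell is unexpected when it is a
    presence outside the filled side or an absence inside it, and its
    contribution is (d/D)^2 where d is the distance to the isocline
    along the cell's (1,1) diagonal and D that diagonal's full length.
    """
    y = (np.arange(r) + 0.5)[:, None] / r
    x = (np.arange(c) + 0.5)[None, :] / c
    x = np.broadcast_to(x, (r, c)).copy()
    y = np.broadcast_to(y, (r, c)).copy()
    p = np.exp(_isocline_p(fill))
    inside = x**p + y**p < 1.0
    # solve (x+t)^p + (y+t)^p = 1 for t by bisection (monotone in t)
    t_lo = -np.minimum(x, y)
    t_hi = np.minimum(1.0 - x, 1.0 - y)
    lo, hi = t_lo.copy(), t_hi.copy()
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        f = (x + mid) ** p + (y + mid) ** p - 1.0
        lo = np.where(f < 0, mid, lo)
        hi = np.where(f < 0, hi, mid)
    t_star = 0.5 * (lo + hi)
    # clamp: the diagonal may not cross the isocline inside the square
    t_star = np.clip(t_star, t_lo, t_hi)
    d = np.abs(t_star)
    big_d = t_hi - t_lo
    u = (d / np.where(big_d > 0, big_d, 1.0)) ** 2
    return u, inside


def _temperature_of(order_rows, order_cols, B, u, inside):
    m = B[np.ix_(order_rows, order_cols)]
    unexpected = np.where(m > 0, ~inside, inside)
    return float((u * unexpected).sum())


def matrix_temperature(mat, budget: int = 20000, seed: int = 0,
                       return_order: bool = False):
    """Atmar-Patterson matrix temperature in [0, 100].

    Rows and columns are reordered to minimise the summed unexpectedness
    (fill-sort warm start, then simulated annealing over row/column
    swaps with `budget` proposals, seeded); the minimised sum is scaled
    by 100 / (0.04145 * r * c) and clamped to [0, 100]. 0 = perfectly
    nested, 100 = maximally disordered.
    """
    B = (_as_matrix(mat) > 0).astype(float)
    _check_nondegenerate(B, "matrix_temperature")
    r, c = B.shape
    fill = B.sum() / (r * c)
    if fill >= 1.0:
        return (0.0, np.arange(r), np.arange(c)) if return_order else 0.0
    u, inside = _unexpectedness_grid(r, c, fill)

    rng = np.random.default_rng(seed)
    rows = np.argsort(-B.sum(axis=1), kind="stable")
    cols = np.argsort(-B.sum(axis=0), kind="stable")
    cur = _temperature_of(rows, cols, B, u, inside)
    best, best_rows, best_cols = cur, rows.copy(), cols.copy()

    t0, t1 = 0.5, 1e-4
    for k in range(budget):
        temp = t0 * (t1 / t0) ** (k / max(budget - 1, 1))
        if rng.random() < 0.5 and r > 1:
            i, j = rng.choice(r, size=2, replace=False)
            rows[i], rows[j] = rows[j], rows[i]
            cand = _temperature_of(rows, cols, B, u, inside)
            if cand <= cur or rng.random() < np.exp((cur - cand) / temp):
                cur = cand
            else:
                rows[i], rows[j] = rows[j], rows[i]
        elif c > 1:
            i, j = rng.choice(c, size=2, replace=False)
            cols[i], cols[j] = cols[j], cols[i]
            cand = _temperature_of(rows, cols, B, u, inside)
            if cand <= cur or rng.random() < np.exp((cur - cand) / temp):
                cur = cand
            else:
                cols[i], cols[j] = cols[j], cols[i]
        if cur < best:
            best, best_rows, best_cols = cur, rows.copy(), cols.copy()

    t = min(100.0, 100.0 * best / (_T_NORM * r * c))
    if return_order:
        return t, best_rows, best_cols
    return t


# ---------------------------------------------------------------------------
# Discrepancy
# ---------------------------------------------------------------------------


def discrepancy(mat, variant: str = "fill_sorted") -> int:
    """Presences that must move to pack each row into its leading columns.

    With columns in a fixed order (``variant="fixed_order"`` keeps the
    given order; ``"fill_sorted"``, the discrepancy2 dialect, first
    sorts columns by decreasing totals, ties by original index), a row
    with k presences should occupy the first k columns; the discrepancy
    is the total number of presences falling outside those positions,
    i.e. the minimum number of moves to perfect nestedness with row
    fills conserved.
    """
    if variant not in ("fixed_order", "fill_sorted"):
        raise ValueError(f"unknown variant {variant!r}")
    B = (_as_matrix(mat) > 0).astype(int)
    if variant == "fill_sorted":
        B = B[:, np.argsort(-B.sum(axis=0), kind="stable")]
    total = 0
    for row in B:
        k = int(row.sum())
        total += k - int(row[:k].sum())
    return total


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


def compute_metrics(network, budget: int = 20000, seed: int = 0) -> dict:
    """Full metric report for one bipartite network, with provenance.

    Binary metrics (NODF, temperature, discrepancy) consume the
    binarised matrix; weighted metrics (weighted NODF, WNODA, WINE) the
    |DI| weights. Degenerate networks yield None values with a note.
    """
    from .networks import BipartiteNetwork, binarize
    from .specialization import h2_prime

    if isinstance(network, BipartiteNetwork):
        w = network.weights
        label = {"mode": network.mode, "sign": network.sign}
    else:
        import pandas as pd

        w = pd.DataFrame(network)
        label = {}
    arr = w.to_numpy(dtype=float)
    b = binarize(w).to_numpy()
    report = {
        "network": label,
        "shape": list(arr.shape),
        "n_edges": int((arr > 0).sum()),
        "fill": float((arr > 0).mean()) if arr.size else float("nan"),
        "options": {
            "binary_input": "binarized significant-edge matrix",
            "weighted_input": "|DI| of significant edges",
            "temperature_budget": budget,
            "seed": seed,
            "sorting_ties": "original index",
        },
        "metrics": {},
    }
    degenerate = arr.shape[0] < 2 or arr.shape[1] < 2 or not (arr > 0).any()
    if degenerate:
        report["metrics"] = {k: None for k in (
            "nodf", "nodf2", "weighted_nodf", "wnoda", "wine_eta", "wine_raw",
            "temperature", "discrepancy", "discrepancy2", "h2_prime")}
        report["note"] = "degenerate matrix; metrics undefined"
        return report
    wres = wine(arr)
    spec = h2_prime(arr)
    report["metrics"] = {
        "nodf": nodf(b, "as_is"),
        "nodf2": nodf(b, "sorted"),
        "weighted_nodf": weighted_nodf(arr),
        "wnoda": wnoda(arr),
        "wine_raw": wres.d_w,
        "wine_eta": wres.eta,
        "temperature": matrix_temperature(b, budget=budget, seed=seed),
        "discrepancy": discrepancy(b, "fixed_order"),
        "discrepancy2": discrepancy(b, "fill_sorted"),
        "h2_prime": spec.h2_prime,
    }
    return report
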