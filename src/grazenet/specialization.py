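"""Network-level (H2') and species-level (d') specialization indices.

The Shannon entropy of the joint interaction-frequency distribution,
H2 = -sum p_ij ln p_ij, measures how evenly interactions are spread
over grazer-ASV combinations. Its extremes given the marginal totals —
H2_max (interactions as even as the marginals allow) and H2_min
(interactions packed into as few cells as possible) — standardise it to

    H2' = (H2_max - H2) / (H2_max - H2_min)  in [0, 1],

0 meaning fully generalised (each grazer uses partners in proportion to
their availability) and 1 fully specialised (exclusive partners).

d' applies the same idea per species: d_i is the Kullback-Leibler
divergence of species i's interaction distribution from overall partner
availability, standardised by its maximum ln(W / A_i).

The extremal-entropy search follows the integer "interaction
frequency" formulation: continuous weights are scaled to a fixed total
(default 1000) and rounded, and H2_min/H2_max are found by greedy
construction plus steepest 2x2-swap refinement over matrices with the
same integer marginals. Exhaustive enumeration (used as a test oracle)
confirms the heuristic on small totals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpecializationReport", "h2_prime", "d_prime"]


def _xlogx(a: np.ndarray) -> np.ndarray:
    out = np.zeros_like(a, dtype=float)
    pos = a > 0
    out[pos] = a[pos] * np.log(a[pos])
    return out


def _entropy(m: np.ndarray) -> float:
    """Shannon entropy of m / m.sum()."""
    t = m.sum()
    if t <= 0:
        raise ValueError("matrix total must be positive")
    return float(np.log(t) - _xlogx(m.astype(float)).sum() / t)


def _integerize(arr: np.ndarray, precision: int) -> np.ndarray:
    w = arr.sum()
    if w <= 0:
        raise ValueError("matrix total must be positive")
    m = np.rint(arr * (precision / w)).astype(int)
    if m.sum() == 0:
        # all weights below half a unit; keep the largest cell
        m = np.zeros_like(m)
        m[np.unravel_index(np.argmax(arr), arr.shape)] = 1
    return m


# -- extremal-entropy search under fixed integer marginals -----------------


def _greedy_min_entropy(r: np.ndarray, c: np.ndarray,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Pack the largest feasible cells first (minimises entropy greedily).

    With `rng`, ties and near-ties are broken at random, giving diverse
    starting points for the multi-start refinement: the minimum-entropy
    landscape has local optima that 2x2 moves alone cannot escape.
    """
    rrem, crem = r.copy(), c.copy()
    m = np.zeros((r.size, c.size), dtype=int)
    while rrem.sum() > 0:
        cand = np.minimum.outer(rrem, crem)
        if cand.max() == 0:
            break
        if rng is None:
            i, j = np.unravel_index(np.argmax(cand), cand.shape)
        else:
            flat = cand.ravel().astype(float)
            top = flat >= 0.5 * flat.max()
            probs = np.where(top, flat**2, 0.0)
            pick = rng.choice(flat.size, p=probs / probs.sum())
            i, j = np.unravel_index(pick, cand.shape)
        amount = cand[i, j]
        m[i, j] += amount
        rrem[i] -= amount
        crem[j] -= amount
    return m


def _proportional_fill(r: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Integer matrix close to the independence expectation r_i c_j / W."""
    w = r.sum()
    exp = np.outer(r, c) / w
    m = np.floor(exp).astype(int)
    rrem = r - m.sum(axis=1)
    crem = c - m.sum(axis=0)
    frac = exp - m
    # largest-remainder repair restricted to deficient rows/columns
    while rrem.sum() > 0:
        mask = np.outer(rrem > 0, crem > 0)
        if not mask.any():
            break
        masked = np.where(mask, frac, -1.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        m[i, j] += 1
        rrem[i] -= 1
        crem[j] -= 1
        frac[i, j] = max(frac[i, j] - 1.0, 0.0)
    return m


def _best_move(m: np.ndarray, maximize_S: bool):
    """Best 2x2 swap move; returns (step, (i, j, k, l)) or None.

    The move shifts `step` units: m[i,j] += step, m[k,l] += step,
    m[i,l] -= step, m[k,j] -= step, conserving all marginals.
    ``maximize_S=True`` (minimal entropy) evaluates the *full* feasible
    shift per direction — S = sum a ln a is convex along a move, so its
    maximum over the segment sits at an endpoint; ``False`` (maximal
    entropy) evaluates unit steps, which steepest descent on a convex
    objective accepts until the interior optimum is reached.
    """
    a = m.astype(float)
    n, mm = m.shape
    if maximize_S:
        # step[i,j,k,l] = min(m[i,l], m[k,j]); nan where no shift possible
        step = np.minimum(a[:, None, None, :], a.T[None, :, :, None])
        with np.errstate(invalid="ignore"):
            step = np.where(step >= 1, step, np.nan)
        add_ij = _xlogx(a[:, :, None, None] + step) - _xlogx(
            np.broadcast_to(a[:, :, None, None], step.shape))
        add_kl = _xlogx(a[None, None, :, :] + step) - _xlogx(
            np.broadcast_to(a[None, None, :, :], step.shape))
        rem_il = _xlogx(a[:, None, None, :] - step) - _xlogx(
            np.broadcast_to(a[:, None, None, :], step.shape))
        rem_kj = _xlogx(a.T[None, :, :, None] - step) - _xlogx(
            np.broadcast_to(a.T[None, :, :, None], step.shape))
        delta = add_ij + add_kl + rem_il + rem_kj
    else:
        gain = _xlogx(a + 1) - _xlogx(a)
        with np.errstate(invalid="ignore"):
            loss = np.where(m > 0, _xlogx(np.maximum(a - 1, 0)) - _xlogx(a), np.nan)
        # delta[i, j, k, l] = gain[i,j] + gain[k,l] + loss[i,l] + loss[k,j]
        delta = (
            gain[:, :, None, None]
            + gain[None, None, :, :]
            + loss[:, None, None, :]
            + loss.T[None, :, :, None]
        )
        delta = -delta  # we select the largest entropy *increase*
    ii = np.arange(n)
    jj = np.arange(mm)
    delta[ii, :, ii, :] = np.nan  # i == k is a no-op
    delta[:, jj, :, jj] = np.nan  # j == l is a no-op
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            flat = np.nanmax(delta)
        except ValueError:
            return None
        if not np.isfinite(flat) or flat <= 1e-12:
            return None
        idx = np.unravel_index(np.nanargmax(delta), delta.shape)
    i, j, k, l = idx
    step = int(min(m[i, l], m[k, j])) if maximize_S else 1
    return step, idx


def _refine(m: np.ndarray, maximize_S: bool, max_steps: int = 200000) -> np.ndarray:
    m = m.copy()
    for _ in range(max_steps):
        best = _best_move(m, maximize_S)
        if best is None:
            break
        step, (i, j, k, l) = best
        m[i, j] += step
        m[k, l] += step
        m[i, l] -= step
        m[k, j] -= step
    return m


@dataclass
class SpecializationReport:
    """H2 and its extremes under fixed marginals, plus per-row d / d'."""

    h2: float
    h2_min: float
    h2_max: float
    h2_prime: float | None
    d: pd.Series | None = None
    d_prime: pd.Series | None = None
    options: dict = field(default_factory=dict)


def h2_prime(mat, precision: int = 1000, n_restarts: int = 60) -> SpecializationReport:
    """Network-level specialization H2' of a non-negative weight matrix.

    Weights are scaled to ``precision`` total units and rounded; H2 and
    its extremes are computed on that integer matrix so that all three
    share one marginal constraint. The H2_min search uses `n_restarts`
    randomized greedy starts (internally seeded: the function is
    deterministic). H2' is None (undefined) when H2_max == H2_min
    (e.g. a single occupied cell).
    """
    if isinstance(mat, pd.DataFrame):
        arr = mat.to_numpy(dtype=float)
        index = mat.index
    else:
        arr = np.asarray(mat, dtype=float)
        index = pd.RangeIndex(arr.shape[0])
    if (arr < 0).any():
        raise ValueError("h2_prime: negative weights")
    m = _integerize(arr, precision)
    r, c = m.sum(axis=1), m.sum(axis=0)
    h2 = _entropy(m)

    cand_max = [_refine(_proportional_fill(r, c), maximize_S=False), _refine(m, False)]
    cand_min = [_refine(_greedy_min_entropy(r, c), maximize_S=True), _refine(m, True)]
    rng = np.random.default_rng(12345)  # fixed stream: h2_prime is deterministic
    for _ in range(n_restarts):
        cand_min.append(_refine(_greedy_min_entropy(r, c, rng), maximize_S=True))
    h2_max = max(max(_entropy(x) for x in cand_max), h2)
    h2_min = min(min(_entropy(x) for x in cand_min), h2)

    if h2_max - h2_min < 1e-12:
        h2p = None
    else:
        h2p = float(np.clip((h2_max - h2) / (h2_max - h2_min), 0.0, 1.0))
    dd, ddp = _d_series(arr, index)
    return SpecializationReport(
        h2=h2, h2_min=h2_min, h2_max=h2_max, h2_prime=h2p,
        d=dd, d_prime=ddp, options={"precision": precision},
    )


def _d_series(arr: np.ndarray, index) -> tuple[pd.Series, pd.Series]:
    w = arr.sum()
    q = arr.sum(axis=0) / w  # partner availability
    d_vals, dp_vals = [], []
    for i in range(arr.shape[0]):
        ai = arr[i].sum()
        if ai == 0:
            d_vals.append(np.nan)
            dp_vals.append(np.nan)
            continue
        p = arr[i] / ai
        pos = p > 0
        d = float(np.sum(p[pos] * np.log(p[pos] / q[pos])))
        dmax = float(np.log(w / ai))
        d_vals.append(d)
        if dmax <= 0:
            dp_vals.append(np.nan)  # the row is the whole network
        else:
            dp_vals.append(float(np.clip(d / dmax, 0.0, 1.0)))
    return pd.Series(d_vals, index=index, name="d"), pd.Series(
        dp_vals, index=index, name="d_prime"
    )


def d_prime(mat, margin: str = "rows") -> pd.DataFrame:
    """Species-level specialization d and d' for one margin.

    d_i is the KL divergence of species i's interaction distribution
    from partner availability (the opposite margin's totals); d' = d /
    ln(W / A_i), clipped to [0, 1]. Rows (columns) with no interactions
    get NaN. The continuous lower bound d_min = 0 is used: with
    continuous weights a species can always match availability exactly.
    """
    if margin not in ("rows", "columns"):
        raise ValueError("margin must be 'rows' or 'columns'")
    if isinstance(mat, pd.DataFrame):
        df = mat if margin == "rows" else mat.T
        arr, index = df.to_numpy(dtype=float), df.index
    else:
        arr = np.asarray(mat, dtype=float)
        if margin == "columns":
            arr = arr.T
        index = pd.RangeIndex(arr.shape[0])
    if (arr < 0).any():
        raise ValueError("d_prime: negative weights")
    if arr.sum() <= 0:
        raise ValueError("d_prime: matrix total must be positive")
    d, dp = _d_series(arr, index)
    return pd.DataFrame({"d": d, "d_prime": dp})
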