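"""Compositional treatment of amplicon count tables.

Sequencing counts carry no information about absolute abundance: each
sample is a composition, defined only up to its total. Before comparing
samples we therefore (1) replace zeros with a uniform pseudocount and
close rows to proportions, and (2) apply the centered log-ratio (clr)
transformation, which expresses every taxon relative to the geometric
mean of its own sample and thereby removes the arbitrary sequencing
depth.

The clr of a strictly positive composition x is

    clr_i(x) = ln( x_i / g(x) ),   g(x) = (prod_j x_j)^(1/p)

so each clr row sums to zero, and multiplying a sample by any positive
constant leaves its clr unchanged (scale invariance). The perturbation
property — clr(x * p) - clr(x) = clr-contrast of p — is what makes clr
differences between treatment and control a well-defined effect scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["replace_zeros", "clr_transform", "clr_from_counts"]


def _as_frame(x) -> pd.DataFrame:
    if isinstance(x, pd.DataFrame):
        return x
    return pd.DataFrame(np.asarray(x, dtype=float))


def replace_zeros(counts, pseudocount: float = 1.0) -> pd.DataFrame:
    """Add a uniform pseudocount to every count and close rows to proportions.

    Parameters
    ----------
    counts : DataFrame or array, samples x ASVs
        Non-negative counts.
    pseudocount : float
        Strictly positive value added to every cell before closure.
        The default of 1 is a deliberately simple, reproducible choice;
        it is configurable because clr-based effect estimates for rare
        taxa are sensitive to it.

    Returns
    -------
    DataFrame of strictly positive proportions; each row sums to 1.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
    df = _as_frame(counts)
    arr = df.to_numpy(dtype=float)
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"negative count at sample {df.index[i]!r}, ASV {df.columns[j]!r}"
        )
    zero_rows = np.flatnonzero(arr.sum(axis=1) == 0)
    if zero_rows.size:
        names = [repr(df.index[i]) for i in zero_rows]
        raise ValueError(f"all-zero sample row(s): {', '.join(names)}")
    arr = arr + pseudocount
    arr /= arr.sum(axis=1, keepdims=True)
    return pd.DataFrame(arr, index=df.index, columns=df.columns)


def clr_transform(proportions) -> pd.DataFrame:
    """Centered log-ratio transform of strictly positive compositions.

    Each row of the result sums to zero (up to floating point).
    """
    df = _as_frame(proportions)
    arr = df.to_numpy(dtype=float)
    if (arr <= 0).any():
        i, j = np.argwhere(arr <= 0)[0]
        raise ValueError(
            f"non-positive entry at sample {df.index[i]!r}, ASV {df.columns[j]!r}; "
            "apply replace_zeros first"
        )
    logx = np.log(arr)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=df.index, columns=df.columns)


def clr_from_counts(counts, pseudocount: float = 1.0) -> pd.DataFrame:
    """Convenience composition: ``clr_transform(replace_zeros(counts))``."""
    return clr_transform(replace_zeros(counts, pseudocount))
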