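"""Per-capita interaction strength estimation via the Dynamic Index.

The Dynamic Index (DI) measures the per-capita, per-time effect of an
interactor on a target's abundance:

    DI = ln(N / D) / (Y * t)

where N is the target's (relative) abundance with the interactor
present, D its abundance in interactor-free controls, Y the interactor
abundance (1 grazer per aquarium here) and t the duration (one
experimental period). DI > 0 means the grazer raises the target's
relative abundance; DI < 0 that it depresses it.

Two spaces are supported for count data:

* ``clr_difference`` (default): DI = (mean clr_N - mean clr_D)/(Y t).
  The clr difference equals ln(N/D) for the depth-free part of the
  composition and is always well defined, whereas raw clr values can be
  negative, making ln(N/D) on clr values ill-posed.
* ``relative_ratio``: literal ln of the ratio of group-mean proportions
  (pseudocounted), for fidelity to the classical formula.

The experimental design identifies grazer effects in two observable
contrasts — grazing treatments vs control (total effect = trophic +
non-trophic) and mucus treatments vs control (non-trophic effect) — and
obtains the trophic effect by subtraction. Uncertainty comes from a
percentile bootstrap over replicates, resampling treatment and control
groups independently; the trophic CI is formed from the paired
bootstrap distribution total - non_trophic, sharing the control
resamples so that the subtraction is coherent draw by draw. An edge is
"significant" when its (1 - alpha) CI excludes zero; no multiple-testing
correction is applied by default (an optional Benjamini-Hochberg flag
is provided).

The statsmodels-style entry point is :class:`DynamicIndexModel`, whose
``fit()`` returns an :class:`InteractionResults` carrying the effect
table, bootstrap distributions and a ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .compositional import clr_from_counts, replace_zeros

__all__ = [
    "dynamic_index",
    "DynamicIndexModel",
    "InteractionResults",
    "estimate_effects",
    "decompose_trophic",
]

MODES = ("total", "non_trophic", "trophic")

EFFECT_COLUMNS = [
    "grazer",
    "target",
    "mode",
    "di_mean",
    "ci_low",
    "ci_high",
    "n_boot",
    "alpha",
    "significant",
]


def dynamic_index(n, d, grazer_abundance: float = 1.0, duration: float = 1.0,
                  space: str = "relative_ratio"):
    """Dynamic Index DI = ln(N/D)/(Y t) (or a clr difference scaled by 1/(Y t)).

    Parameters
    ----------
    n, d : float or array
        Target abundance with (n) and without (d) the interactor. In
        ``relative_ratio`` space both must be strictly positive; in
        ``clr_difference`` space they are clr values (any reals) and the
        result is (n - d)/(Y t).
    grazer_abundance : float
        Y, the number of interactors (> 0).
    duration : float
        t, the experiment duration (> 0).
    """
    yt = grazer_abundance * duration
    if yt <= 0:
        raise ValueError("grazer_abundance * duration must be > 0")
    n = np.asarray(n, dtype=float)
    d = np.asarray(d, dtype=float)
    if space == "relative_ratio":
        if (n <= 0).any() or (d <= 0).any():
            raise ValueError("N and D must be > 0 in relative_ratio space")
        out = np.log(n / d) / yt
    elif space == "clr_difference":
        out = (n - d) / yt
    else:
        raise ValueError(f"unknown DI space: {space!r}")
    return out.item() if out.ndim == 0 else out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (for the optional FDR flag)."""
    from statsmodels.stats.multitest import multipletests

    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class InteractionResults:
    """Fitted per-capita effects with bootstrap uncertainty.

    Attributes
    ----------
    effects : DataFrame
        One row per (grazer, target, mode) with columns
        grazer, target, mode, di_mean, ci_low, ci_high, n_boot, alpha,
        significant.
    boot : dict
        mode -> DataFrame-compatible ndarray of bootstrap draws with
        shape (n_boot, n_pairs) aligned to ``pair_index[mode]``;
        retained so trophic decomposition and downstream contrasts stay
        paired by draw.
    config : dict
        Echo of estimation settings (space, pseudocount, alpha, seed, ...).
    """

    effects: pd.DataFrame
    boot: dict = field(default_factory=dict, repr=False)
    pair_index: dict = field(default_factory=dict, repr=False)
    config: dict = field(default_factory=dict)

    def mode(self, mode: str) -> pd.DataFrame:
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}")
        return self.effects[self.effects["mode"] == mode].reset_index(drop=True)

    @property
    def significant(self) -> pd.DataFrame:
        return self.effects[self.effects["significant"]].reset_index(drop=True)

    def networks(self, taxonomy: pd.DataFrame | None = None):
        """Signed bipartite grazer x ASV networks from significant effects."""
        from .networks import build_networks

        return build_networks(self.effects, taxonomy=taxonomy)

    def summary(self) -> str:
        """Plain-text summary in the spirit of statsmodels results."""
        cfg = self.config
        eff = self.effects
        lines = [
            "Dynamic Index interaction-strength estimates",
            "=" * 60,
            f"DI space:       {cfg.get('di_space')}",
            f"alpha:          {cfg.get('alpha')}   n_boot: {cfg.get('n_boot')}"
            f"   seed: {cfg.get('seed')}",
            f"Y (grazers):    {cfg.get('grazer_abundance')}   t: {cfg.get('duration')}",
            f"pairs per mode: {len(eff) // max(len(MODES), 1)}",
            "-" * 60,
            f"{'mode':<12}{'n sig':>7}{'n pos':>7}{'n neg':>7}"
            f"{'max |DI|':>12}",
        ]
        for mode in MODES:
            sub = eff[eff["mode"] == mode]
            sig = sub[sub["significant"]]
            lines.append(
                f"{mode:<12}{len(sig):>7}{(sig['di_mean'] > 0).sum():>7}"
                f"{(sig['di_mean'] < 0).sum():>7}"
                f"{sub['di_mean'].abs().max():>12.4f}"
            )
        lines.append("=" * 60)
        return "\n".join(lines)


class DynamicIndexModel:
    """Estimate grazer per-capita effects on every ASV from a count table.

    Parameters
    ----------
    counts : DataFrame, samples x ASVs
        Non-negative integer counts.
    metadata : DataFrame indexed by sample id
        Columns ``treatment_class`` in {control, grazing, mucus},
        ``grazer`` (label, empty/NaN for controls), ``replicate``.
    pseudocount : float
        Uniform pseudocount used before closure / clr.
    di_space : {"clr_difference", "relative_ratio"}
    alpha : float
        CI level for the significance rule (CI excludes 0).
    n_boot : int
        Bootstrap draws (>= 99).
    grazer_abundance, duration : float
        Y and t of the Dynamic Index.
    rarefy_depth : int, optional
        If given, subsample every sample to this depth first (off by
        default).
    fdr : bool
        If True, apply a Benjamini-Hochberg correction across pairs
        within each mode when flagging significance (off by default).
    seed : int
        Seed for the bootstrap (and rarefaction) streams.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        metadata: pd.DataFrame,
        *,
        pseudocount: float = 1.0,
        di_space: str = "clr_difference",
        alpha: float = 0.05,
        n_boot: int = 9999,
        grazer_abundance: float = 1.0,
        duration: float = 1.0,
        rarefy_depth: int | None = None,
        fdr: bool = False,
        seed: int = 0,
    ):
        if not (0.0 < alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if n_boot < 99:
            raise ValueError("n_boot must be >= 99")
        if di_space not in ("clr_difference", "relative_ratio"):
            raise ValueError(f"unknown di_space {di_space!r}")
        self.counts = counts
        self.metadata = _check_metadata(counts, metadata)
        self.pseudocount = float(pseudocount)
        self.di_space = di_space
        self.alpha = float(alpha)
        self.n_boot = int(n_boot)
        self.grazer_abundance = float(grazer_abundance)
        self.duration = float(duration)
        self.rarefy_depth = rarefy_depth
        self.fdr = bool(fdr)
        self.seed = int(seed)

    # -- fitting -----------------------------------------------------------

    def fit(self) -> InteractionResults:
        counts = self.counts
        if self.rarefy_depth is not None:
            from .community import rarefy

            counts = rarefy(counts, self.rarefy_depth, seed=self.seed)
        meta = self.metadata.loc[counts.index]

        if self.di_space == "clr_difference":
            values = clr_from_counts(counts, self.pseudocount).to_numpy()
        else:
            values = replace_zeros(counts, self.pseudocount).to_numpy()

        ctrl_idx = np.flatnonzero((meta["treatment_class"] == "control").to_numpy())
        if ctrl_idx.size == 0:
            raise ValueError("no control samples: effect estimation needs controls")
        grazers = sorted(
            meta.loc[meta["treatment_class"] != "control", "grazer"].dropna().unique()
        )
        asvs = list(counts.columns)
        yt = self.grazer_abundance * self.duration

        rng = np.random.default_rng(self.seed)
        rows = []
        boot = {m: [] for m in MODES}
        pair_index = {m: [] for m in MODES}

        for g in grazers:
            graz_idx = np.flatnonzero(
                ((meta["treatment_class"] == "grazing") & (meta["grazer"] == g)).to_numpy()
            )
            muc_idx = np.flatnonzero(
                ((meta["treatment_class"] == "mucus") & (meta["grazer"] == g)).to_numpy()
            )
            # one control resample stream per grazer, shared between the
            # total and non-trophic contrasts so the trophic difference
            # is paired by draw.
            ctrl_draws = rng.integers(0, ctrl_idx.size, size=(self.n_boot, ctrl_idx.size))
            point, dists = {}, {}
            for mode, idx in (("total", graz_idx), ("non_trophic", muc_idx)):
                if idx.size == 0:
                    continue  # design without this treatment class
                point[mode], dists[mode] = self._contrast(
                    values, idx, ctrl_idx, ctrl_draws, yt, rng, g, mode
                )
            if "total" in point and "non_trophic" in point:
                point["trophic"] = point["total"] - point["non_trophic"]
                if dists["total"] is not None and dists["non_trophic"] is not None:
                    dists["trophic"] = dists["total"] - dists["non_trophic"]
                else:
                    dists["trophic"] = None
            elif len(point) == 1:
                warnings.warn(
                    f"grazer {g!r}: only one treatment class present; "
                    "trophic decomposition unavailable",
                    stacklevel=2,
                )

            for mode in (m for m in MODES if m in point):
                est, dist = point[mode], dists[mode]
                lo, hi = self._ci(dist)
                for j, asv in enumerate(asvs):
                    rows.append((g, asv, mode, est[j],
                                 lo[j] if lo is not None else np.nan,
                                 hi[j] if hi is not None else np.nan))
                if dist is not None:
                    boot[mode].append(dist)
                pair_index[mode].extend((g, a) for a in asvs)

        eff = pd.DataFrame(
            rows, columns=["grazer", "target", "mode", "di_mean", "ci_low", "ci_high"]
        )
        eff["n_boot"] = self.n_boot
        eff["alpha"] = self.alpha
        sig = (eff["ci_low"] > 0) | (eff["ci_high"] < 0)
        sig &= eff["ci_low"].notna()
        if self.fdr:
            sig = self._fdr_flag(eff, boot)
        eff["significant"] = sig.to_numpy() if hasattr(sig, "to_numpy") else sig

        boot_arr = {
            m: np.concatenate(v, axis=1) if v else np.empty((self.n_boot, 0))
            for m, v in boot.items()
        }
        cfg = dict(
            di_space=self.di_space,
            pseudocount=self.pseudocount,
            alpha=self.alpha,
            n_boot=self.n_boot,
            grazer_abundance=self.grazer_abundance,
            duration=self.duration,
            rarefy_depth=self.rarefy_depth,
            fdr=self.fdr,
            seed=self.seed,
        )
        return InteractionResults(
            effects=eff, boot=boot_arr, pair_index=pair_index, config=cfg
        )

    # -- internals ---------------------------------------------------------

    def _contrast(self, values, treat_idx, ctrl_idx, ctrl_draws, yt, rng, g, mode):
        """Point estimate and bootstrap distribution of one treatment-vs-control DI."""
        if treat_idx.size == 0:
            raise ValueError(f"no {mode!r} samples for grazer {g!r}")
        point = self._group_di(values, treat_idx, ctrl_idx, yt)
        if treat_idx.size < 2 or ctrl_idx.size < 2:
            warnings.warn(
                f"grazer {g!r} mode {mode!r}: <2 replicates in a group; "
                "bootstrap CI unavailable",
                stacklevel=3,
            )
            return point, None
        tr_draws = rng.integers(0, treat_idx.size, size=(self.n_boot, treat_idx.size))
        dist = np.empty((self.n_boot, values.shape[1]))
        tvals = values[treat_idx]
        cvals = values[ctrl_idx]
        for b in range(self.n_boot):
            dist[b] = self._mean_di(
                tvals[tr_draws[b]], cvals[ctrl_draws[b]], yt
            )
        return point, dist

    def _group_di(self, values, treat_idx, ctrl_idx, yt):
        return self._mean_di(values[treat_idx], values[ctrl_idx], yt)

    def _mean_di(self, tvals, cvals, yt):
        tmean = tvals.mean(axis=0)
        cmean = cvals.mean(axis=0)
        if self.di_space == "clr_difference":
            return (tmean - cmean) / yt
        return np.log(tmean / cmean) / yt

    def _ci(self, dist):
        if dist is None:
            return None, None
        q = 100.0 * np.array([self.alpha / 2.0, 1.0 - self.alpha / 2.0])
        lo, hi = np.percentile(dist, q, axis=0)
        return lo, hi

    def _fdr_flag(self, eff, boot):
        """BH-adjusted significance from bootstrap two-sided 'p-values'."""
        sig = np.zeros(len(eff), dtype=bool)
        for mode in MODES:
            mask = (eff["mode"] == mode).to_numpy()
            dists = boot[mode]
            if not dists:
                continue
            dist = np.concatenate(dists, axis=1)
            frac = (dist > 0).mean(axis=0)
            p = 2.0 * np.minimum(frac, 1.0 - frac)
            p = np.clip(p, 1.0 / (self.n_boot + 1), 1.0)
            sig[mask] = _bh_adjust(p) < self.alpha
        return pd.Series(sig)


def _check_metadata(counts: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    meta = metadata.copy()
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    missing = [s for s in counts.index if s not in meta.index]
    if missing:
        raise ValueError(f"metadata missing counted sample(s): {missing}")
    meta = meta.loc[counts.index]
    bad = set(meta["treatment_class"]) - {"control", "grazing", "mucus"}
    if bad:
        raise ValueError(f"unknown treatment_class value(s): {sorted(bad)}")
    grazer = meta.get("grazer")
    is_ctrl = meta["treatment_class"] == "control"
    has_grazer = grazer.notna() & (grazer.astype(str).str.len() > 0)
    if (is_ctrl & has_grazer).any():
        bad_ids = list(meta.index[is_ctrl & has_grazer])
        raise ValueError(f"control sample(s) with a grazer label: {bad_ids}")
    if (~is_ctrl & ~has_grazer).any():
        bad_ids = list(meta.index[~is_ctrl & ~has_grazer])
        raise ValueError(f"grazing/mucus sample(s) without grazer: {bad_ids}")
    meta.loc[is_ctrl, "grazer"] = None
    return meta


# -- functional facade over the model ------------------------------------


def estimate_effects(counts, metadata, mode: str = "total", **kwargs) -> pd.DataFrame:
    """One-mode effect table ('total' or 'non_trophic') against controls."""
    if mode not in ("total", "non_trophic"):
        raise ValueError("mode must be 'total' or 'non_trophic'")
    res = DynamicIndexModel(counts, metadata, **kwargs).fit()
    out = res.mode(mode)
    if out.empty:
        raise ValueError(f"no {mode!r} contrasts estimable from this design")
    return out


def decompose_trophic(total: pd.DataFrame, nti: pd.DataFrame,
                      boot_total: np.ndarray | None = None,
                      boot_nti: np.ndarray | None = None,
                      alpha: float | None = None) -> pd.DataFrame:
    """Trophic = total - non_trophic, with a paired-bootstrap CI when
    the two bootstrap distributions (aligned draw by draw) are supplied.

    Raises if the two tables do not cover the same (grazer, target) pairs.
    """
    key = ["grazer", "target"]
    t = total.set_index(key).sort_index()
    m = nti.set_index(key).sort_index()
    only_t = t.index.difference(m.index)
    only_m = m.index.difference(t.index)
    if len(only_t) or len(only_m):
        raise ValueError(
            "domain mismatch between total and non_trophic tables; "
            f"missing from non_trophic: {list(only_t)}; "
            f"missing from total: {list(only_m)}"
        )
    if alpha is None:
        alpha = float(t["alpha"].iloc[0])
    out = pd.DataFrame(index=t.index)
    out["mode"] = "trophic"
    out["di_mean"] = t["di_mean"] - m["di_mean"]
    if boot_total is not None and boot_nti is not None:
        if boot_total.shape != boot_nti.shape:
            raise ValueError("bootstrap distributions have different shapes")
        dist = boot_total - boot_nti
        q = 100.0 * np.array([alpha / 2.0, 1.0 - alpha / 2.0])
        lo, hi = np.percentile(dist, q, axis=0)
        out["ci_low"], out["ci_high"] = lo, hi
        out["n_boot"] = dist.shape[0]
    else:
        out["ci_low"] = np.nan
        out["ci_high"] = np.nan
        out["n_boot"] = 0
    out["alpha"] = alpha
    out["significant"] = (out["ci_low"] > 0) | (out["ci_high"] < 0)
    out.loc[out["ci_low"].isna(), "significant"] = False
    return out.reset_index()[EFFECT_COLUMNS]
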