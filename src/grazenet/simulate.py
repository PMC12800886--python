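"""Synthetic grazer-exclusion amplicon experiments with known ground truth.

The generator emulates a laboratory design in which rock-coupon biofilms
are exposed to one of five mollusk grazer species either directly
(grazing treatments: consumption plus pedal-mucus contact) or through a
mesh cage that admits only the pedal mucus (mucus treatments), alongside
grazer-free controls. The default design is 1 control group (13
replicates) + 5 grazing treatments (13 replicates each) + 5 mucus
treatments (10 replicates each) = 128 experimental units, sequenced to
library sizes around 6215 reads.

Ground truth is a pair of per-(grazer, ASV) log-effects:

* ``delta_nti`` — the non-trophic (mucus-mediated) effect, expressed in
  mucus samples;
* ``delta_ti`` — the trophic (consumptive) effect, never observed alone;
  grazing samples express ``delta_total = delta_ti + delta_nti``.

Effects act multiplicatively on an ASV's expected relative abundance
(log-linear), so the clr-difference Dynamic Index is the natural
estimand. Baseline abundances are log-normal (the heavy-tailed
rank-abundance profile typical of biofilm communities); replicate-level
log-normal noise models aquarium-to-aquarium variation; counts are drawn
multinomially (optionally Dirichlet-multinomial) at a negative-binomial
library size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_GRAZERS",
    "SimulationConfig",
    "TruthTable",
    "SimulatedExperiment",
    "simulate_experiment",
    "truth_networks",
]

#: The five model grazer species (one chiton, four gastropods).
DEFAULT_GRAZERS = (
    "C_granosus",
    "E_peruviana",
    "F_crassa",
    "S_araucana",
    "S_lessonii",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated grazer-exclusion experiment.

    Defaults reproduce the reference design: 11 treatment groups, 128
    samples, library sizes centred on 6215 reads.
    """

    n_asv: int = 150
    grazer_names: Sequence[str] = DEFAULT_GRAZERS
    reps_control: int = 13
    reps_grazing: int = 13
    reps_mucus: int = 10
    depth_mean: float = 6215.0
    #: negative-binomial size parameter for library depth; larger = tighter.
    depth_dispersion: float = 30.0
    #: (mean, sd) of baseline ASV log-abundances.
    base_log_mean_sd: tuple[float, float] = (0.0, 1.5)
    #: fraction of (grazer, ASV) pairs with a nonzero effect, per mode.
    effect_sparsity: float = 0.10
    #: SD of nonzero log-effects.
    effect_sd: float = 1.0
    #: SD of per-replicate, per-ASV log-normal noise.
    noise_sd: float = 0.30
    #: Dirichlet concentration scale; None = pure multinomial sampling.
    overdispersion: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_asv < 2:
            raise ValueError("n_asv must be >= 2")
        if len(self.grazer_names) < 1:
            raise ValueError("at least one grazer required")
        if len(set(self.grazer_names)) != len(self.grazer_names):
            raise ValueError("grazer names must be unique")
        for name, v in (
            ("reps_control", self.reps_control),
            ("reps_grazing", self.reps_grazing),
            ("reps_mucus", self.reps_mucus),
        ):
            if v < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")
        if not (0.0 <= self.effect_sparsity <= 1.0):
            raise ValueError("effect_sparsity must be in [0, 1]")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise ValueError("overdispersion must be positive or None")

    @property
    def n_samples(self) -> int:
        g = len(self.grazer_names)
        return self.reps_control + g * (self.reps_grazing + self.reps_mucus)


@dataclass
class TruthTable:
    """True log-effects per (grazer, ASV); ``delta_total = delta_ti + delta_nti``."""

    delta_ti: pd.DataFrame  # grazers x ASVs
    delta_nti: pd.DataFrame

    @property
    def delta_total(self) -> pd.DataFrame:
        return self.delta_ti + self.delta_nti

    @property
    def grazers(self) -> list:
        return list(self.delta_ti.index)

    @property
    def asv_ids(self) -> list:
        return list(self.delta_ti.columns)


@dataclass
class SimulatedExperiment:
    counts: pd.DataFrame  # samples x ASVs, integer
    metadata: pd.DataFrame  # sample_id index; treatment_class, grazer, replicate
    truth: TruthTable
    config: SimulationConfig
    seed: int
    flags: dict = field(default_factory=dict)

    def config_dict(self) -> dict:
        d = asdict(self.config)
        d["grazer_names"] = list(d["grazer_names"])
        d["base_log_mean_sd"] = list(d["base_log_mean_sd"])
        return d


def _draw_truth(config: SimulationConfig, rng: np.random.Generator) -> TruthTable:
    g = len(config.grazer_names)
    shape = (g, config.n_asv)
    asvs = [f"ASV{i + 1:04d}" for i in range(config.n_asv)]

    def one(rng):
        mask = rng.random(shape) < config.effect_sparsity
        vals = rng.normal(0.0, config.effect_sd, size=shape)
        return pd.DataFrame(
            np.where(mask, vals, 0.0), index=list(config.grazer_names), columns=asvs
        )

    return TruthTable(delta_ti=one(rng), delta_nti=one(rng))


def simulate_experiment(
    config: SimulationConfig | None = None,
    truth: TruthTable | None = None,
    **overrides,
) -> SimulatedExperiment:
    """Simulate one full experiment; byte-identical for identical seeds.

    Parameters
    ----------
    config : SimulationConfig, optional
        Full configuration; keyword overrides may be given instead.
    truth : TruthTable, optional
        Explicit ground-truth effects (e.g. fixed ±1 deltas for recovery
        studies). When omitted, sparse normal effects are drawn from the
        config's sparsity/SD settings.
    """
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = SimulationConfig(**{**asdict(config), **overrides})
    config.validate()
    rng = np.random.default_rng(config.seed)

    if truth is None:
        truth = _draw_truth(config, rng)
    else:
        # keep the rng stream aligned whether or not truth is supplied
        _ = _draw_truth(config, rng)
        if list(truth.delta_ti.index) != list(config.grazer_names):
            raise ValueError("truth grazers do not match config.grazer_names")
        if truth.delta_ti.shape[1] != config.n_asv:
            raise ValueError("truth ASV dimension does not match config.n_asv")

    asvs = list(truth.delta_ti.columns)
    mu, sd = config.base_log_mean_sd
    base_log = rng.normal(mu, sd, size=config.n_asv)

    rows = []  # (sample_id, class, grazer, replicate, log-mean vector)
    for r in range(config.reps_control):
        rows.append((f"control_r{r + 1:02d}", "control", None, r + 1, base_log))
    total = truth.delta_total.to_numpy()
    nti = truth.delta_nti.to_numpy()
    for gi, g in enumerate(config.grazer_names):
        for r in range(config.reps_grazing):
            rows.append(
                (f"{g}_grazing_r{r + 1:02d}", "grazing", g, r + 1, base_log + total[gi])
            )
        for r in range(config.reps_mucus):
            rows.append(
                (f"{g}_mucus_r{r + 1:02d}", "mucus", g, r + 1, base_log + nti[gi])
            )

    n = len(rows)
    log_means = np.stack([r[4] for r in rows])
    log_means = log_means + rng.normal(0.0, config.noise_sd, size=log_means.shape)
    props = np.exp(log_means - log_means.max(axis=1, keepdims=True))
    props /= props.sum(axis=1, keepdims=True)  # compositional closure

    # library sizes: negative binomial around depth_mean
    size = config.depth_dispersion
    p = size / (size + config.depth_mean)
    depths = np.maximum(rng.negative_binomial(size, p, size=n), 1)

    counts = np.empty((n, config.n_asv), dtype=np.int64)
    for i in range(n):
        pvec = props[i]
        if config.overdispersion is not None:
            pvec = rng.dirichlet(config.overdispersion * pvec)
        counts[i] = rng.multinomial(depths[i], pvec)

    sample_ids = [r[0] for r in rows]
    counts_df = pd.DataFrame(counts, index=sample_ids, columns=asvs)
    counts_df.index.name = "sample_id"
    meta = pd.DataFrame(
        {
            "treatment_class": [r[1] for r in rows],
            "grazer": [r[2] for r in rows],
            "replicate": [r[3] for r in rows],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    flags = {}
    if min(config.reps_control, config.reps_grazing, config.reps_mucus) < 2:
        flags["insufficient_replication_for_bootstrap"] = True
    return SimulatedExperiment(
        counts=counts_df, metadata=meta, truth=truth, config=config,
        seed=config.seed, flags=flags,
    )


def truth_networks(truth: TruthTable, threshold: float = 0.0) -> dict:
    """True edge sets for scoring estimated networks.

    Returns a dict keyed by ``(mode, sign)`` with mode in
    ``{"trophic", "non_trophic"}`` and sign in ``{"positive", "negative"}``;
    each value is a frozenset of (grazer, asv_id) pairs with
    ``|delta| > threshold`` and the matching sign.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out = {}
    for mode, df in (("trophic", truth.delta_ti), ("non_trophic", truth.delta_nti)):
        arr = df.to_numpy()
        for sign, keep in (
            ("positive", arr > threshold),
            ("negative", arr < -threshold),
        ):
            gi, ai = np.nonzero(keep)
            out[(mode, sign)] = frozenset(
                (df.index[i], df.columns[j]) for i, j in zip(gi, ai)
            )
    return out
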