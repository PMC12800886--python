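import numpy as np
import pandas as pd
import pytest

import grazenet as g
from grazenet.interaction import decompose_trophic, dynamic_index

from conftest import GRAZERS


class TestDynamicIndex:
    @pytest.mark.parametrize(
        "n, d, y, t, expected",
        [
            (10.0, 10.0, 1, 1, 0.0),                      # identity
            (np.e * 3.0, 3.0, 1, 1, 1.0),                 # ln e
            (54.0, 99.9, 1, 1, np.log(54.0 / 99.9)),      # grazed vs control cover
            (54.0, 99.9, 2, 1, np.log(54.0 / 99.9) / 2),  # linear in 1/Y
        ],
    )
    def test_point_values(self, n, d, y, t, expected):
        assert dynamic_index(n, d, y, t) == pytest.approx(expected, abs=1e-12)

    def test_cover_example_magnitude(self):
        # per-capita effect of the chiton on biofilm cover, from mean
        # cover 54% (grazed) vs 99.9% (control) over 24 h with Y = 1
        assert dynamic_index(54.0, 99.9) == pytest.approx(-0.6152, abs=5e-4)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        n, d = rng.uniform(0.1, 10, size=2)
        assert dynamic_index(n, d) == pytest.approx(-dynamic_index(d, n), abs=1e-12)

    def test_scaling_in_inverse_yt(self):
        base = dynamic_index(7.0, 2.0, 1.0, 1.0)
        assert dynamic_index(7.0, 2.0, 4.0, 1.0) == pytest.approx(base / 4)
        assert dynamic_index(7.0, 2.0, 2.0, 3.0) == pytest.approx(base / 6)

    def test_clr_space_accepts_negatives(self):
        assert dynamic_index(-1.2, 0.3, space="clr_difference") == pytest.approx(-1.5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dynamic_index(0.0, 1.0)
        with pytest.raises(ValueError):
            dynamic_index(1.0, 1.0, grazer_abundance=0.0)


def _copied_data_experiment():
    """Treatment replicates identical to control replicates."""
    rng = np.random.default_rng(4)
    base = rng.integers(0, 200, size=(4, 12))
    counts = pd.DataFrame(
        np.vstack([base, base]),
        index=[f"c{i}" for i in range(4)] + [f"t{i}" for i in range(4)],
        columns=[f"ASV{j}" for j in range(12)],
    )
    meta = pd.DataFrame(
        {
            "treatment_class": ["control"] * 4 + ["grazing"] * 4,
            "grazer": [None] * 4 + ["G"] * 4,
            "replicate": [1, 2, 3, 4] * 2,
        },
        index=counts.index,
    )
    return counts, meta


class TestEstimateEffects:
    def test_copied_data_gives_zero_nonsignificant(self):
        counts, meta = _copied_data_experiment()
        # mucus class absent: estimate only the total mode via the facade
        eff = g.estimate_effects(counts, meta, mode="total", n_boot=199, seed=0)
        np.testing.assert_allclose(eff["di_mean"], 0.0, atol=1e-12)
        assert not eff["significant"].any()

    def test_depth_invariance_in_clr_space(self):
        # rescaling each sample's library leaves clr-space DI unchanged
        # (closure removes depth; tiny pseudocount isolates the property)
        counts, meta = _copied_data_experiment()
        counts = counts + 1  # strictly positive so scaling is exact
        factors = np.random.default_rng(2).integers(1, 6, size=len(counts))
        scaled = counts.mul(factors, axis=0)
        eff1 = g.estimate_effects(counts, meta, mode="total", n_boot=199,
                                  seed=1, pseudocount=1e-9)
        eff2 = g.estimate_effects(scaled, meta, mode="total", n_boot=199,
                                  seed=1, pseudocount=1e-9)
        np.testing.assert_allclose(eff2["di_mean"], eff1["di_mean"], atol=1e-6)

    def test_missing_control_raises(self):
        counts, meta = _copied_data_experiment()
        meta["treatment_class"] = "grazing"
        meta["grazer"] = "G"
        with pytest.raises(ValueError, match="control"):
            g.estimate_effects(counts, meta, n_boot=199)

    def test_single_replicate_warns_with_nan_ci(self):
        counts, meta = _copied_data_experiment()
        counts = counts.drop(index=["t1", "t2", "t3"])
        meta = meta.drop(index=["t1", "t2", "t3"])
        with pytest.warns(UserWarning, match="replicates"):
            eff = g.estimate_effects(counts, meta, mode="total", n_boot=199)
        assert eff["ci_low"].isna().all()
        assert not eff["significant"].any()

    def test_recovery_within_quarter_and_significant(self, recovery_fit):
        exp, res = recovery_fit
        for mode, tdf in (
            ("total", exp.truth.delta_total),
            ("non_trophic", exp.truth.delta_nti),
            ("trophic", exp.truth.delta_ti),
        ):
            sub = res.mode(mode).set_index(["grazer", "target"])
            tr = tdf.stack()
            tr.index.names = ["grazer", "target"]
            affected = tr[tr.abs() > 0.5]
            est = sub.loc[affected.index, "di_mean"]
            err = est - affected
            assert abs(err.mean()) < 0.25
            # most clearly affected pairs are detected
            assert sub.loc[affected.index, "significant"].mean() > 0.8

    def test_null_significant_rate_near_alpha(self, null_fit):
        _, res = null_fit
        for mode in ("total", "non_trophic"):
            rate = res.mode(mode)["significant"].mean()
            assert 0.02 <= rate <= 0.10, f"{mode}: {rate}"

    def test_ci_brackets_point_estimate(self, recovery_fit):
        _, res = recovery_fit
        eff = res.effects.dropna(subset=["ci_low"])
        assert (eff["ci_low"] <= eff["di_mean"] + 1e-9).all()
        assert (eff["di_mean"] <= eff["ci_high"] + 1e-9).all()

    def test_determinism_given_seed(self, small_experiment):
        exp = small_experiment
        r1 = g.DynamicIndexModel(exp.counts, exp.metadata, n_boot=199, seed=5).fit()
        r2 = g.DynamicIndexModel(exp.counts, exp.metadata, n_boot=199, seed=5).fit()
        pd.testing.assert_frame_equal(r1.effects, r2.effects)


class TestDecomposition:
    def test_additivity_exact(self, recovery_fit):
        _, res = recovery_fit
        key = ["grazer", "target"]
        tot = res.mode("total").set_index(key)["di_mean"]
        nti = res.mode("non_trophic").set_index(key)["di_mean"]
        tro = res.mode("trophic").set_index(key)["di_mean"]
        np.testing.assert_array_equal(tro.to_numpy(), (tot - nti).to_numpy())

    def test_point_subtraction(self):
        tot = pd.DataFrame(
            {"grazer": ["G"], "target": ["a"], "mode": "total", "di_mean": [0.8],
             "ci_low": [0.1], "ci_high": [1.5], "n_boot": 99, "alpha": 0.05,
             "significant": [True]}
        )
        nti = tot.assign(mode="non_trophic", di_mean=[0.3])
        out = decompose_trophic(tot, nti)
        assert out["di_mean"].iloc[0] == pytest.approx(0.5)
        assert not out["significant"].iloc[0]  # no bootstrap given -> undecidable

    def test_identical_tables_give_zero(self):
        tot = pd.DataFrame(
            {"grazer": ["G", "G"], "target": ["a", "b"], "mode": "total",
             "di_mean": [0.8, -0.2], "ci_low": [0.1, -0.5], "ci_high": [1.5, 0.1],
             "n_boot": 99, "alpha": 0.05, "significant": [True, False]}
        )
        boot = np.random.default_rng(0).normal(size=(99, 2))
        out = decompose_trophic(tot, tot.assign(mode="non_trophic"), boot, boot)
        np.testing.assert_allclose(out["di_mean"], 0.0)
        assert not out["significant"].any()

    def test_domain_mismatch_raises(self):
        tot = pd.DataFrame(
            {"grazer": ["G"], "target": ["a"], "mode": "total", "di_mean": [0.8],
             "ci_low": [0.1], "ci_high": [1.5], "n_boot": 99, "alpha": 0.05,
             "significant": [True]}
        )
        nti = tot.assign(target=["b"], mode="non_trophic")
        with pytest.raises(ValueError, match="mismatch"):
            decompose_trophic(tot, nti)

    def test_recovered_trophic_with_opposed_nti(self):
        # delta_ti = +1, delta_nti = -0.5 on one ASV
        from conftest import zero_truth

        truth = zero_truth(40)
        truth.delta_ti.iloc[0, 0] = 1.0
        truth.delta_nti.iloc[0, 0] = -0.5
        exp = g.simulate_experiment(
            g.SimulationConfig(n_asv=40, seed=13), truth=truth
        )
        res = g.DynamicIndexModel(exp.counts, exp.metadata, n_boot=499, seed=2).fit()
        tro = res.mode("trophic").set_index(["grazer", "target"])
        est = tro.loc[(GRAZERS[0], truth.delta_ti.columns[0])]
        assert 0.75 <= est["di_mean"] <= 1.25
        assert est["significant"]
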