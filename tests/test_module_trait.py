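"""Eigengene-trait association, q-values, permutation and bootstrap inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tbvnet._stats import correlation_pvalue, zdiff_population
from tbvnet.coexpression import compute_module_eigengenes
from tbvnet.module_trait import (
    PermutationSpec,
    bootstrap_ci,
    group_difference_permutation,
    module_trait_correlation,
    permutation_module_pvalue,
    storey_qvalues,
    subnetwork_association,
)
from tbvnet.preprocessing import age_adjust_trait
from tbvnet.synthetic import SyntheticConfig, generate_two_group_study

from conftest import make_samples, small_config


class TestCorrelationTest:
    def test_printed_correlation_pvalue(self):
        """r = 0.74 at n = 25: Student asymptotic p within 2x of the reported
        2.7e-5 (the test statistic itself gives ~2.4e-5)."""
        p = correlation_pvalue(0.74, 25)
        assert 2.7e-5 / 2 <= p <= 2.7e-5 * 2

    def test_identity_gives_r_one(self, study, network_run):
        me = network_run["me"]
        samples = study.samples.copy()
        samples["tbv_residual_cc"] = me.me.iloc[0].loc[samples["sample_id"]].to_numpy()
        rec = module_trait_correlation(me, samples, "all")
        assert rec.iloc[0]["r"] == pytest.approx(1.0)
        assert rec.iloc[0]["p"] == pytest.approx(0.0, abs=1e-30)

    def test_antisymmetry(self, study, network_run):
        me = network_run["me"]
        rec = module_trait_correlation(me, study.samples, "all")
        flipped = study.samples.copy()
        flipped["tbv_residual_cc"] = -flipped["tbv_residual_cc"]
        rec2 = module_trait_correlation(me, flipped, "all")
        assert np.allclose(rec["r"].to_numpy(), -rec2["r"].to_numpy())

    def test_constant_trait_raises(self, network_run, study):
        samples = study.samples.copy()
        samples["tbv_residual_cc"] = 0.0
        with pytest.raises(ValueError):
            module_trait_correlation(network_run["me"], samples, "all")


class TestStoreyQ:
    def test_all_ones_stay_one(self):
        assert np.allclose(storey_qvalues([1.0] * 30), 1.0)

    def test_signal_block_detected_and_bounded_by_bh(self):
        p = np.array([0.001] * 10 + list(np.linspace(0.5, 1.0, 90)))
        q = storey_qvalues(p)
        assert (q[:10] < 0.05).all()
        from statsmodels.stats.multitest import multipletests

        bh = multipletests(p, method="fdr_bh")[1]
        assert (q <= bh + 1e-12).all()  # pi0 <= 1

    def test_empty_input(self):
        assert storey_qvalues([]).size == 0

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, pvals):
        q = storey_qvalues(pvals)
        assert (q >= 0).all() and (q <= 1).all()
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


@pytest.fixture(scope="module")
def perm_setup():
    bundle = generate_two_group_study(
        small_config(
            seed=21,
            n_genes=250,
            module_specs=((30, 0.7),),
            trait_coupling={"M1": {"control": 0.8, "case": 0.8}},
            hub_fraction_coupled={"control": 1.0, "case": 1.0},
        )
    )
    samples = age_adjust_trait(bundle.samples, method="linear")
    return bundle, samples


class TestPermutationModule:

    def test_strong_signal_gives_floor_pvalue(self, perm_setup):
        bundle, samples = perm_setup
        res = permutation_module_pvalue(
            bundle.expression, bundle.truth.planted_partition, samples,
            PermutationSpec(n_perm=199, seed=1), "all",
        )
        # the observed association beats every null draw: p = 0/(n+1)
        assert res.iloc[0]["perm_p"] == 0.0

    def test_seed_reproducibility(self, perm_setup):
        bundle, samples = perm_setup
        kwargs = dict(spec=PermutationSpec(n_perm=99, seed=7), group="all")
        a = permutation_module_pvalue(
            bundle.expression, bundle.truth.planted_partition, samples, **kwargs)
        b = permutation_module_pvalue(
            bundle.expression, bundle.truth.planted_partition, samples, **kwargs)
        pd.testing.assert_frame_equal(a, b)

    def test_null_pvalues_roughly_uniform(self):
        """Trait-independent data with an unstructured module label: the
        scrambling null is exchangeable and p is uniform."""
        ps = []
        for seed in range(50):
            bundle = generate_two_group_study(
                small_config(seed=seed, n_genes=60, module_specs=((15, 0.0),),
                             trait_coupling={}, n_samples_per_group=(15, 15))
            )
            samples = age_adjust_trait(bundle.samples, method="linear")
            res = permutation_module_pvalue(
                bundle.expression, bundle.truth.planted_partition, samples,
                PermutationSpec(n_perm=199, seed=seed), "all",
            )
            ps.append(res.iloc[0]["perm_p"])
        frac = np.mean(np.asarray(ps) < 0.05)
        assert 0.01 <= frac <= 0.12

    def test_zero_perms_raises(self):
        with pytest.raises(ValueError):
            PermutationSpec(n_perm=0)


class TestGroupDifference:
    def test_identical_groups_give_zero(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=30)
        t = 0.5 * v + rng.normal(size=30)
        trait = np.concatenate([t, t])
        samples = make_samples(trait, groups=["case"] * 30 + ["control"] * 30)
        values = pd.Series(np.concatenate([v, v]), index=samples["sample_id"])
        res = group_difference_permutation(values, samples, PermutationSpec(n_perm=99, seed=3))
        assert res["z_diff_obs"] == pytest.approx(0.0, abs=1e-12)
        assert res["perm_p"] > 0.5

    def test_swapping_groups_flips_sign(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=60)
        t = rng.normal(size=60) + np.r_[0.8 * v[:30], np.zeros(30)]
        samples = make_samples(t, groups=["case"] * 30 + ["control"] * 30)
        values = pd.Series(v, index=samples["sample_id"])
        res1 = group_difference_permutation(values, samples, PermutationSpec(n_perm=9, seed=0))
        swapped = samples.copy()
        swapped["group"] = swapped["group"].map({"case": "control", "control": "case"})
        res2 = group_difference_permutation(values, swapped, PermutationSpec(n_perm=9, seed=0))
        assert res1["z_diff_obs"] == pytest.approx(-res2["z_diff_obs"])

    def test_power_against_planted_difference(self):
        """Coupling 0.6 vs 0.0 at n=50/group is detected most of the time."""
        hits = 0
        n_sims = 25
        for seed in range(n_sims):
            bundle = generate_two_group_study(
                small_config(
                    seed=seed, n_genes=40, module_specs=((30, 0.7),),
                    trait_coupling={"M1": {"control": 0.6, "case": 0.0}},
                    n_samples_per_group=(50, 50),
                )
            )
            samples = age_adjust_trait(bundle.samples, method="linear")
            me = compute_module_eigengenes(bundle.expression, bundle.truth.planted_partition)
            res = group_difference_permutation(
                me.me.loc["M1"], samples, PermutationSpec(n_perm=199, seed=seed)
            )
            hits += res["perm_p"] < 0.05
        assert hits >= int(0.8 * n_sims)


class TestBootstrap:
    def test_degenerate_duplicate_vector(self):
        rng = np.random.default_rng(5)
        t = rng.normal(size=20)
        samples = make_samples(t)
        samples["tbv_residual_cc"] = t  # exact copy, r = 1 in every resample
        values = pd.Series(t, index=samples["sample_id"])
        lo, hi = bootstrap_ci(values, samples, n_boot=200, seed=0)
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_coverage_of_true_correlation(self):
        hits = 0
        rng = np.random.default_rng(6)
        for _ in range(50):
            v = rng.normal(size=100)
            t = 0.5 * v + np.sqrt(1 - 0.25) * rng.normal(size=100)
            samples = make_samples(t)
            values = pd.Series(v, index=samples["sample_id"])
            lo, hi = bootstrap_ci(values, samples, n_boot=400, seed=1)
            hits += lo <= 0.5 <= hi
        assert hits >= 45

    def test_seed_determinism(self, study, network_run):
        me = network_run["me"].me.iloc[0]
        a = bootstrap_ci(me, study.samples, n_boot=200, seed=9, group="control")
        b = bootstrap_ci(me, study.samples, n_boot=200, seed=9, group="control")
        assert a == b


class TestSubnetwork:
    def test_singleton_set_equals_gene_significance(self, study):
        from tbvnet.gene_metrics import gene_significance

        gene = study.expression.index[0]
        res = subnetwork_association([gene], study.expression, study.samples,
                                     PermutationSpec(n_perm=9, seed=0))
        gs = gene_significance(study.expression.loc[[gene]], study.samples, "all")
        assert res["association"]["all"]["r"] == pytest.approx(gs["gs"].iloc[0], abs=1e-10)

    def test_module_average_close_to_eigengene(self):
        deltas = []
        for seed in range(3):
            bundle = generate_two_group_study(
                small_config(seed=seed, n_genes=60, module_specs=((40, 0.7),),
                             trait_coupling={"M1": {"control": 0.5, "case": 0.5}})
            )
            samples = age_adjust_trait(bundle.samples, method="linear")
            genes = list(bundle.truth.planted_partition.index[
                bundle.truth.planted_partition == "M1"])
            res = subnetwork_association(genes, bundle.expression, samples,
                                         PermutationSpec(n_perm=9, seed=0))
            me = compute_module_eigengenes(bundle.expression, bundle.truth.planted_partition)
            rec = module_trait_correlation(me, samples, "all")
            deltas.append(abs(res["association"]["all"]["r"] - rec.iloc[0]["r"]))
        assert max(deltas) <= 0.15

    def test_missing_genes_raise(self, study):
        with pytest.raises(ValueError, match="missing"):
            subnetwork_association(["NOPE1", "NOPE2"], study.expression, study.samples)


def test_zdiff_population_values():
    assert zdiff_population(0.64, 0.42, 253, 253) == pytest.approx(3.47, abs=0.01)
    assert zdiff_population(0.74, -0.34, 25, 25) == pytest.approx(4.33, abs=0.01)
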