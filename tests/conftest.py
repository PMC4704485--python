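"""Shared fixtures: small synthetic studies with known planted structure."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from tbvnet.preprocessing import age_adjust_trait
from tbvnet.synthetic import SyntheticConfig, generate_two_group_study


def small_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A fast four-module study: 2 coupled modules, 75+75 samples."""
    base = dict(
        n_genes=300,
        n_samples_per_group=(75, 75),
        module_specs=((50, 0.7), (40, 0.6), (40, 0.5)),
        trait_coupling={
            "M1": {"control": 0.6, "case": 0.2},
            "M3": {"control": 0.0, "case": 0.5},
        },
        seed=seed,
    )
    if "module_specs" in overrides and "trait_coupling" not in overrides:
        base["trait_coupling"] = {}
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def study():
    """One fixed small study with residuals already computed."""
    bundle = generate_two_group_study(small_config(seed=11))
    bundle.samples = age_adjust_trait(bundle.samples, method="linear")
    return bundle


@pytest.fixture(scope="session")
def network_run(study):
    """Adjacency, TOM, detected partition, and eigengenes for the study."""
    from tbvnet.coexpression import (
        NetworkParams,
        build_adjacency,
        compute_module_eigengenes,
        compute_tom,
        detect_modules,
        select_soft_power,
    )

    params = NetworkParams(min_module_size=30)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        power, fit = select_soft_power(study.expression, params)
    adjacency = build_adjacency(study.expression, power)
    tom = compute_tom(adjacency)
    partition = detect_modules(tom, params, expr=study.expression)
    me_set = compute_module_eigengenes(study.expression, partition)
    return {
        "params": params,
        "power": power,
        "fit": fit,
        "adjacency": adjacency,
        "tom": tom,
        "partition": partition,
        "me": me_set,
    }


def make_samples(trait: np.ndarray, groups=None, ages=None) -> pd.DataFrame:
    """Minimal sample table around a given residualized trait vector."""
    n = len(trait)
    trait = np.asarray(trait, dtype=float)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:04d}" for i in range(n)],
            "group": groups if groups is not None else ["case"] * (n // 2) + ["control"] * (n - n // 2),
            "age_years": ages if ages is not None else np.full(n, 2.5),
            "tbv_cc": 1100 + trait,
            "tbv_residual_cc": trait - trait.mean(),
            "replicate_of": pd.array([pd.NA] * n, dtype="string"),
        }
    )
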