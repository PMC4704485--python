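"""Synthetic two-group expression studies with planted co-expression modules.

The generator emulates a blood leukocyte microarray study of toddlers in two
diagnostic groups (``case``/``control``) whose trait of interest is total
brain volume (TBV, cc).  Each planted module m follows a single-factor block
model: gene i in module m is

    x_i = rho_i * f_m + sqrt(1 - rho_i**2) * eps_i

with a shared latent factor ``f_m ~ N(0,1)`` per sample and per-gene
factor correlations ``rho_i`` calibrated so the expected pairwise
within-module correlation equals the requested ``within_cor``
(``rho_i rho_j`` averages to ``within_cor`` when ``rho = sqrt(within_cor)``
up to a mild hub gradient).  The gradient in ``rho`` creates a well-defined
hub/peripheral ordering inside every module.

The trait is built from realized expression, not from the detected
eigengenes, so module detection and trait association stay independently
testable: per group the trait couples to a *coupled gene subset* of each
coupled module.  ``hub_fraction_coupled`` controls what fraction of that
subset is drawn from the top of the connectivity order (hubs, which couple
through their full expression and hence through the shared factor) versus
the bottom (peripheral genes, which couple through their idiosyncratic
components).  This is the mechanism that lets one group carry its trait
signal in hubs and the other in the periphery.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "StudyBundle",
    "generate_expression",
    "generate_trait",
    "generate_two_group_study",
]

GROUPS = ("case", "control")

#: Default planted modules (size, within-module correlation).  The first is
#: a 253-gene module emulating the cell-cycle module of the motivating study
#: design; the remainder give a spread of sizes and tightnesses.
DEFAULT_MODULE_SPECS: tuple[tuple[int, float], ...] = (
    (253, 0.60),
    (500, 0.50),
    (400, 0.50),
    (300, 0.45),
    (200, 0.45),
    (150, 0.40),
    (100, 0.40),
    (60, 0.40),
)

#: Default eigengene-trait couplings per module and group.  M1 (the
#: cell-cycle-like module) couples strongly in controls and weakly in cases;
#: M3 couples in cases only (a cell-adhesion-like pattern).
DEFAULT_TRAIT_COUPLING: Mapping[str, Mapping[str, float]] = {
    "M1": {"control": 0.60, "case": 0.25},
    "M3": {"control": 0.0, "case": 0.45},
}


def _default_coupling() -> dict:
    return {m: dict(g) for m, g in DEFAULT_TRAIT_COUPLING.items()}


@dataclass
class SyntheticConfig:
    """Configuration of a synthetic two-group study.

    Defaults mirror the emulated study design: ~12,208 gene probes, 87 case
    and 55 control male toddlers aged 1-4 years, log-intensity expression
    around mean 8 / sd 1, and a normally distributed trait (TBV, cc) with a
    smooth age trend.
    """

    n_genes: int = 12208
    n_samples_per_group: tuple[int, int] = (87, 55)  # (case, control)
    module_specs: Sequence[tuple[int, float]] = DEFAULT_MODULE_SPECS
    trait_coupling: Mapping[str, Mapping[str, float]] = field(default_factory=_default_coupling)
    #: fraction of the coupled gene subset drawn from the top of the
    #: connectivity order, per group; the remainder comes from the bottom.
    hub_fraction_coupled: Mapping[str, float] = field(
        default_factory=lambda: {"control": 1.0, "case": 0.2}
    )
    #: fraction of each coupled module's genes that carry trait coupling.
    coupled_fraction: float = 0.3
    noise_sd: float = 1.0
    base_mean: float = 8.0  # log-intensity location; arbitrary documented constant
    age_range: tuple[float, float] = (1.0, 4.0)
    #: smooth trait~age trend: ("linear", slope_cc_per_year) or a callable age->cc.
    age_effect: tuple[str, float] | Callable[[np.ndarray], np.ndarray] = ("linear", 50.0)
    trait_mean: float = 1100.0  # cc, toddler-range TBV
    trait_sd: float = 60.0  # cc, residual spread around the age trend
    missing_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        n_case, n_control = self.n_samples_per_group
        if n_case < 2 or n_control < 2:
            raise ValueError(
                f"each group needs at least 2 samples, got {self.n_samples_per_group}"
            )
        sizes = [int(s) for s, _ in self.module_specs]
        if any(s < 2 for s in sizes):
            raise ValueError("module sizes must be >= 2")
        if sum(sizes) > self.n_genes:
            raise ValueError(
                f"module sizes sum to {sum(sizes)} > n_genes={self.n_genes}"
            )
        for _, c in self.module_specs:
            if not 0.0 <= c < 1.0:
                raise ValueError(f"within_cor must be in [0, 1), got {c}")
        labels = self.module_labels()
        for mod, per_group in self.trait_coupling.items():
            if mod not in labels:
                raise ValueError(f"trait_coupling refers to unknown module {mod!r}")
            for g, c in per_group.items():
                if g not in GROUPS:
                    raise ValueError(f"unknown group {g!r}")
                if not abs(c) < 1.0:
                    raise ValueError(f"coupling magnitudes must be < 1, got {c}")
        for g in GROUPS:
            tot = sum(per.get(g, 0.0) ** 2 for per in self.trait_coupling.values())
            if tot >= 1.0:
                raise ValueError(f"sum of squared couplings for {g!r} is {tot:.3f} >= 1")
        for g, f in self.hub_fraction_coupled.items():
            if g not in GROUPS or not 0.0 <= f <= 1.0:
                raise ValueError("hub_fraction_coupled must map groups to [0, 1]")
        if not 0.0 < self.coupled_fraction <= 1.0:
            raise ValueError("coupled_fraction must be in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.missing_frac < 1.0:
            raise ValueError("missing_frac must be in [0, 1)")

    def module_labels(self) -> list[str]:
        return [f"M{i + 1}" for i in range(len(self.module_specs))]

    def age_effect_fn(self) -> Callable[[np.ndarray], np.ndarray]:
        if callable(self.age_effect):
            return self.age_effect
        kind, param = self.age_effect
        mid = 0.5 * (self.age_range[0] + self.age_range[1])
        if kind == "linear":
            return lambda age: param * (np.asarray(age, dtype=float) - mid)
        raise ValueError(f"unknown age_effect kind {kind!r}")


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic study.

    ``planted_partition`` maps every gene to its module label ("noise" for
    unplanted genes), ``planted_eigensignals`` holds the latent factor of
    each module per sample, ``loadings`` the per-gene factor correlation
    (the connectivity order within a module), and ``realized_couplings``
    the realized factor-trait correlation per module and group (filled by
    :func:`generate_trait`).
    """

    planted_partition: pd.Series
    planted_eigensignals: pd.DataFrame  # modules x samples
    loadings: pd.Series
    realized_couplings: dict = field(default_factory=dict)
    coupled_genes: dict = field(default_factory=dict)  # group -> module -> [genes]

    def to_json(self) -> str:
        payload = {
            "planted_partition": self.planted_partition.to_dict(),
            "planted_eigensignals": {
                m: self.planted_eigensignals.loc[m].tolist()
                for m in self.planted_eigensignals.index
            },
            "sample_ids": self.planted_eigensignals.columns.tolist(),
            "loadings": self.loadings.to_dict(),
            "realized_couplings": self.realized_couplings,
            "coupled_genes": self.coupled_genes,
        }
        return json.dumps(payload, indent=1)


@dataclass
class StudyBundle:
    expression: pd.DataFrame
    samples: pd.DataFrame
    truth: SyntheticTruth
    config: SyntheticConfig


def _sample_ids(config: SyntheticConfig) -> tuple[list[str], np.ndarray]:
    n_case, n_control = config.n_samples_per_group
    ids = [f"S{i + 1:04d}" for i in range(n_case + n_control)]
    groups = np.array(["case"] * n_case + ["control"] * n_control)
    return ids, groups


def generate_expression(config: SyntheticConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a genes x samples log-intensity matrix with planted modules.

    Returns the expression matrix and the ground truth.  Bit-identical under
    a fixed seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    sample_ids, _ = _sample_ids(config)
    n = len(sample_ids)
    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    labels = config.module_labels()

    factors = rng.standard_normal((len(labels), n))
    values = np.empty((config.n_genes, n))
    partition = np.full(config.n_genes, "noise", dtype=object)
    loadings = np.zeros(config.n_genes)

    pos = 0
    for (size, within_cor), label, f in zip(config.module_specs, labels, factors):
        # hub gradient: per-gene factor correlation rho_i around sqrt(within_cor)
        base = np.sqrt(within_cor)
        rho = np.clip(base * np.linspace(1.1, 0.9, size), 0.0, 0.995)
        eps = rng.standard_normal((size, n))
        block = rho[:, None] * f[None, :] + np.sqrt(1.0 - rho[:, None] ** 2) * eps
        values[pos : pos + size] = block
        partition[pos : pos + size] = label
        loadings[pos : pos + size] = rho
        pos += size
    values[pos:] = rng.standard_normal((config.n_genes - pos, n))

    # per-gene location jitter and scale heterogeneity (log-intensity realism;
    # correlations are scale-invariant so calibration is unaffected)
    gene_means = config.base_mean + 0.25 * rng.standard_normal(config.n_genes)
    gene_scales = config.noise_sd * np.exp(0.15 * rng.standard_normal(config.n_genes))
    values = gene_means[:, None] + gene_scales[:, None] * values

    if config.missing_frac > 0:
        mask = rng.random(values.shape) < config.missing_frac
        values[mask] = np.nan

    expr = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    expr.index.name = "gene_id"
    truth = SyntheticTruth(
        planted_partition=pd.Series(partition, index=gene_ids, name="module"),
        planted_eigensignals=pd.DataFrame(factors, index=labels, columns=sample_ids),
        loadings=pd.Series(loadings, index=gene_ids, name="loading"),
    )
    return expr, truth


def generate_trait(
    config: SyntheticConfig,
    truth: SyntheticTruth,
    expr: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Generate the sample table with group labels, ages, and the trait.

    trait = trait_mean + age_effect(age) + trait_sd * (coupled signal + noise).
    Per group and coupled module the signal mixes two parts in proportion
    to the hub fraction: hub picks couple through their full (standardized)
    expression, which is close to the shared module factor, while
    peripheral picks couple through their idiosyncratic components
    (expression minus the factor part), so that trait relevance genuinely
    sits in the module periphery instead of leaking through the shared
    factor.  When ``expr`` is None the latent factors themselves carry the
    coupling (hub selectivity is then unavailable).  Realized factor-trait
    correlations are recorded in ``truth.realized_couplings``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    sample_ids, groups = _sample_ids(config)
    n = len(sample_ids)
    ages = rng.uniform(config.age_range[0], config.age_range[1], n)

    signals: dict[str, np.ndarray] = {}
    for mod in config.trait_coupling:
        if expr is not None:
            genes = truth.planted_partition.index[truth.planted_partition == mod]
            # hub selection happens per group below; cache standardized rows
            vals = expr.loc[genes, sample_ids].to_numpy(dtype=float)
            mu = vals.mean(axis=1, keepdims=True)
            sd = vals.std(axis=1, keepdims=True)
            signals[mod] = (vals - mu) / np.where(sd == 0, 1.0, sd)
        else:
            signals[mod] = None  # couple to the factor directly

    z_noise = rng.standard_normal(n)
    trait = np.zeros(n)
    for g in GROUPS:
        sel = groups == g
        couplings = {
            mod: per.get(g, 0.0)
            for mod, per in config.trait_coupling.items()
            if per.get(g, 0.0) != 0.0
        }
        total = np.zeros(sel.sum())
        c2 = 0.0
        for mod, c in couplings.items():
            genes = truth.planted_partition.index[truth.planted_partition == mod]
            if expr is not None:
                hub_frac = config.hub_fraction_coupled.get(g, 1.0)
                order = truth.loadings.loc[genes].sort_values(ascending=False).index
                n_coupled = max(2, int(round(config.coupled_fraction * len(order))))
                n_hub = int(round(hub_frac * n_coupled))
                hub_picks = list(order[:n_hub])
                peri_picks = list(order[::-1][: n_coupled - n_hub])
                truth.coupled_genes.setdefault(g, {})[mod] = hub_picks + peri_picks
                rows = signals[mod]
                gene_pos = {gn: i for i, gn in enumerate(genes)}
                f = truth.planted_eigensignals.loc[mod].to_numpy()
                fz = (f - f.mean()) / f.std()
                parts = []
                if hub_picks:
                    hub_vec = rows[[gene_pos[gn] for gn in hub_picks]].mean(axis=0)
                    parts.append((n_hub / n_coupled, hub_vec))
                if peri_picks:
                    # idiosyncratic components: remove the factor's share
                    idx = [gene_pos[gn] for gn in peri_picks]
                    rho = truth.loadings.loc[peri_picks].to_numpy()[:, None]
                    uniq = (rows[idx] - rho * fz[None, :]) / np.sqrt(1.0 - rho**2)
                    parts.append((1.0 - n_hub / n_coupled, uniq.mean(axis=0)))
                m_vec = np.zeros(n)
                for w, vec in parts:
                    m_vec += w * (vec - vec.mean()) / vec.std()
            else:
                m_vec = truth.planted_eigensignals.loc[mod].to_numpy()
            v = m_vec[sel]
            v = (v - v.mean()) / v.std()
            total += c * v
            c2 += c * c
        total += np.sqrt(max(0.0, 1.0 - c2)) * (
            (z_noise[sel] - z_noise[sel].mean()) / z_noise[sel].std()
        )
        trait[sel] = total

    age_fn = config.age_effect_fn()
    tbv = config.trait_mean + age_fn(ages) + config.trait_sd * trait

    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": groups,
            "age_years": ages,
            "tbv_cc": tbv,
            "tbv_residual_cc": np.nan,
            "replicate_of": pd.array([pd.NA] * n, dtype="string"),
        }
    )

    for mod in truth.planted_eigensignals.index:
        f = truth.planted_eigensignals.loc[mod].to_numpy()
        rec = {}
        for g in GROUPS:
            sel = groups == g
            rec[g] = float(np.corrcoef(f[sel], trait[sel])[0, 1])
        truth.realized_couplings[mod] = rec
    return samples


def generate_two_group_study(
    config: SyntheticConfig, out_dir: str | Path | None = None
) -> StudyBundle:
    """Generate expression + samples + truth; optionally write fixture files.

    Files (written when ``out_dir`` is given): ``expression.tsv`` (gene x
    sample TSV, first column gene_id), ``samples.csv``, ``truth.json``.
    """
    expr, truth = generate_expression(config)
    samples = generate_trait(config, truth, expr)
    bundle = StudyBundle(expression=expr, samples=samples, truth=truth, config=config)
    if out_dir is not None:
        out = Path(out_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
            from . import io as _io

            _io.write_expression(expr, out / "expression.tsv")
            _io.write_samples(samples, out / "samples.csv")
            (out / "truth.json").write_text(truth.to_json())
            cfg = dataclasses.asdict(config)
            cfg["module_specs"] = [list(t) for t in config.module_specs]
            if not callable(config.age_effect):
                cfg["age_effect"] = list(config.age_effect)
            else:  # pragma: no cover - callables are not serializable
                cfg["age_effect"] = "<callable>"
            cfg["n_samples_per_group"] = list(config.n_samples_per_group)
            cfg["hub_fraction_coupled"] = dict(config.hub_fraction_coupled)
            cfg["trait_coupling"] = {m: dict(v) for m, v in config.trait_coupling.items()}
            (out / "config.json").write_text(json.dumps(cfg, indent=1))
        except OSError as exc:  # pragma: no cover - environment dependent
            raise OSError(f"failed writing study files under {out}: {exc}") from exc
    return bundle
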