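"""End-to-end orchestration: preprocessing -> network -> association ->
gene metrics -> subgroup analysis -> (optional) preservation & enrichment.

A single global seed fans out to per-stage seeds through a spawning seed
sequence; every statistical output table is written as TSV/JSON next to a
machine-readable run manifest.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from . import __version__
from .coexpression import (
    NetworkParams,
    UNASSIGNED,
    build_adjacency,
    compute_module_eigengenes,
    compute_tom,
    detect_modules,
    select_soft_power,
)
from .enrichment import DEFAULT_BACKGROUND, hypergeometric_enrichment
from .gene_metrics import (
    contingency_odds_ratio,
    gene_significance,
    gs_gc_analysis,
    intramodular_connectivity,
    map_hubs_to_ppi,
    rank_and_overlap,
)
from .module_trait import (
    PermutationSpec,
    bootstrap_ci,
    group_difference_permutation,
    module_trait_correlation,
    permutation_module_pvalue,
    storey_qvalues,
)
from .preprocessing import age_adjust_trait, collapse_replicates, filter_genes
from .preservation import module_preservation
from .subgroup import classify_gene_relevance
from .synthetic import SyntheticConfig, generate_two_group_study

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    out_dir: str | Path = "tbvnet_run"
    expression_path: str | Path | None = None
    samples_path: str | Path | None = None
    synthetic: SyntheticConfig | None = None  # used when no input paths given
    network: NetworkParams = field(default_factory=NetworkParams)
    n_perm: int = 1000
    n_boot: int = 1000
    top_k: int = 30
    max_missing_frac: float = 0.5
    variance_alpha: float = 0.05
    age_method: str = "spline"
    age_df: int = 4
    run_filter: bool = True
    run_preservation: bool = False
    gmt_path: str | Path | None = None
    ppi_path: str | Path | None = None
    enrichment_background: int = DEFAULT_BACKGROUND
    seed: int = 0

    def __post_init__(self) -> None:
        have_files = self.expression_path is not None and self.samples_path is not None
        if not have_files and self.synthetic is None:
            self.synthetic = SyntheticConfig(
                n_genes=2000,
                n_samples_per_group=(60, 60),
                module_specs=((120, 0.6), (100, 0.5), (80, 0.5), (60, 0.45)),
                seed=self.seed,
            )
        if self.n_perm < 1 or self.n_boot < 1:
            raise ValueError("n_perm and n_boot must be >= 1")


def _stage_seeds(seed: int, n: int = 16) -> list[int]:
    """Deterministic per-stage seeds below 2**31 derived from the global seed."""
    ss = np.random.SeedSequence(int(seed))
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and write the result bundle to ``out_dir``.

    Returns the manifest dictionary (also written as ``manifest.json``).
    Stage failures abort with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "package_version": __version__,
        "seed": int(config.seed),
        "stage_seeds": seeds,
        "parameters": {
            "n_perm": config.n_perm,
            "n_boot": config.n_boot,
            "top_k": config.top_k,
            "network": dataclasses.asdict(config.network),
        },
        "stages": {},
        "outputs": [],
    }

    def _write(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["outputs"].append(name)

    stage = "load"
    try:
        if config.expression_path is not None:
            expr, samples = _io.load_study(config.expression_path, config.samples_path)
        else:
            bundle = generate_two_group_study(config.synthetic, out_dir=out / "synthetic")
            expr, samples = bundle.expression, bundle.samples
            manifest["outputs"] += [
                "synthetic/expression.tsv", "synthetic/samples.csv", "synthetic/truth.json",
            ]
        manifest["stages"][stage] = {"n_genes": int(expr.shape[0]), "n_samples": int(expr.shape[1])}

        stage = "preprocessing"
        if samples["replicate_of"].notna().any():
            expr, samples = collapse_replicates(expr, samples, policy="average")
        if config.run_filter:
            expr = filter_genes(expr, config.max_missing_frac, config.variance_alpha)
        expr = expr.dropna(axis=0)  # network stages require complete rows
        samples = age_adjust_trait(samples, method=config.age_method, df=config.age_df)
        _write("expression_filtered.tsv", lambda p: _io.write_expression(expr, p))
        _write("samples_adjusted.csv", lambda p: _io.write_samples(samples, p))
        manifest["stages"][stage] = {
            "n_genes_after_filter": int(expr.shape[0]),
            "age_adjustment": samples.attrs.get("age_adjustment", {}),
        }

        stage = "coexpression"
        power, fit = select_soft_power(expr, config.network)
        adjacency = build_adjacency(expr, power)
        tom = compute_tom(adjacency)
        partition = detect_modules(tom, config.network, expr=expr)
        me_set = compute_module_eigengenes(expr, partition)
        _write("scale_free_fit.tsv", lambda p: fit.to_csv(p, sep="\t", index=False))
        _write("partition.tsv", lambda p: _io.write_partition(partition, p))
        _write("eigengenes.tsv", lambda p: _io.write_eigengenes(me_set.me, p))
        manifest["stages"][stage] = {
            "power": int(power),
            "n_modules": int(len(me_set.modules)),
            "n_unassigned": int((partition == UNASSIGNED).sum()),
        }

        stage = "module_trait"
        spec = PermutationSpec(n_perm=config.n_perm, seed=seeds[1])
        if not me_set.modules:
            warnings.warn("no modules detected; association stages skipped", stacklevel=2)
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
            manifest["outputs"].append("manifest.json")
            return manifest
        assoc_frames = []
        for grp in ("all", "case", "control"):
            assoc = module_trait_correlation(me_set, samples, grp)
            assoc["q"] = storey_qvalues(assoc["p"].to_numpy())
            cis = [
                bootstrap_ci(me_set.me.loc[m], samples, config.n_boot, seeds[2], grp)
                for m in assoc["module"]
            ]
            assoc["ci_low"] = [c[0] for c in cis]
            assoc["ci_high"] = [c[1] for c in cis]
            assoc_frames.append(assoc)
        assoc_all = pd.concat(assoc_frames, ignore_index=True)
        perm = permutation_module_pvalue(expr, partition, samples, spec, "all")
        assoc_all = assoc_all.merge(
            perm[["module", "perm_p"]], on="module", how="left"
        )
        diffs = {
            m: group_difference_permutation(me_set.me.loc[m], samples, spec)
            for m in me_set.modules
        }
        _write("associations.tsv", lambda p: assoc_all.to_csv(p, sep="\t", index=False))
        _write(
            "group_differences.json",
            lambda p: p.write_text(json.dumps(diffs, indent=1, default=float)),
        )
        manifest["stages"][stage] = {"n_modules_tested": len(me_set.modules)}

        stage = "gene_metrics"
        gs_case = gene_significance(expr, samples, "case")
        gs_control = gene_significance(expr, samples, "control")
        gc = intramodular_connectivity(adjacency, partition)
        metrics = pd.DataFrame(
            {
                "module": partition,
                "gs_case": gs_case["gs"],
                "gs_case_p": gs_case["gs_p"],
                "gs_control": gs_control["gs"],
                "gs_control_p": gs_control["gs_p"],
                "gc": gc["gc"],
                "gc_comparable": gc["comparable"],
            }
        )
        gsgc = {}
        contingency = {}
        focus_modules = [
            m for m in me_set.modules
            if (partition == m).sum() >= max(4, config.top_k)
        ]
        for m in focus_modules:
            genes = partition.index[partition == m]
            gsgc[m] = gs_gc_analysis(gs_case["gs"], gs_control["gs"], gc["gc"], genes)
            k = min(config.top_k, len(genes))
            hubs = rank_and_overlap(
                gc.loc[genes, "gc"], gc.loc[genes, "gc"], k=k, absolute=False
            ).top_case  # hub set is group-independent (combined network GC)
            top_gs = {
                "case": rank_and_overlap(
                    gs_case.loc[genes, "gs"], gs_control.loc[genes, "gs"], k=k
                ).top_case,
                "control": rank_and_overlap(
                    gs_case.loc[genes, "gs"], gs_control.loc[genes, "gs"], k=k
                ).top_control,
            }
            a = len(set(hubs) & set(top_gs["control"]))
            c = len(set(hubs) & set(top_gs["case"]))
            orr = contingency_odds_ratio([[a, k - a], [c, k - c]])
            contingency[m] = {
                "hub_top_gs_control": a,
                "hub_top_gs_case": c,
                "k": k,
                "odds_ratio": orr.or_value,
                "ci_low": orr.ci_low,
                "ci_high": orr.ci_high,
                "fisher_p": orr.fisher_p,
                "haldane_corrected": orr.corrected,
            }
        _write("gene_metrics.tsv", lambda p: metrics.to_csv(p, sep="\t", index_label="gene"))
        _write(
            "gs_gc.json",
            lambda p: p.write_text(json.dumps(gsgc, indent=1, default=float)),
        )
        _write(
            "hub_contingency.json",
            lambda p: p.write_text(json.dumps(contingency, indent=1, default=float)),
        )
        manifest["stages"][stage] = {"modules_analyzed": focus_modules}

        stage = "subgroup"
        subgroup_results = {}
        if focus_modules:
            focal = focus_modules[0]
            genes = partition.index[partition == focal]
            k = min(config.top_k, len(genes))
            hubs = rank_and_overlap(
                gc.loc[genes, "gc"], gc.loc[genes, "gc"], k=k, absolute=False
            ).top_case
            if config.ppi_path is not None:
                edges = _io.read_edge_list(config.ppi_path)
                mapped = map_hubs_to_ppi(hubs, edges)
                hub_list = mapped.index.tolist() or hubs
                manifest["stages"].setdefault("ppi", {})["n_mapped"] = len(mapped)
            else:
                hub_list = hubs
                manifest["stages"].setdefault("ppi", {})["note"] = "no PPI edge list; mapping skipped"
            frames = {}
            for grp in ("case", "control"):
                try:
                    rec = classify_gene_relevance(
                        hub_list, expr, samples, grp, candidates=list(genes)
                    )
                except ValueError as exc:
                    warnings.warn(f"subgroup analysis skipped for {grp}: {exc}", stacklevel=2)
                    continue
                frames[grp] = rec
                subgroup_results[grp] = {
                    "retained_small": int((rec["status_small"] == "retained").sum()),
                    "retained_big": int((rec["status_big"] == "retained").sum()),
                    "n_hubs": int(rec["in_hub_list"].sum()),
                    "n_gained": int(rec["gained"].sum()),
                }
            if frames:
                combined = pd.concat(frames, names=["group", "gene"])
                _write(
                    "subgroup_status.tsv",
                    lambda p: combined.to_csv(p, sep="\t"),
                )
            if len(subgroup_results) == 2:
                nh_c = subgroup_results["control"]["n_hubs"]
                nh_a = subgroup_results["case"]["n_hubs"]
                for side in ("small", "big"):
                    rc = subgroup_results["control"][f"retained_{side}"]
                    ra = subgroup_results["case"][f"retained_{side}"]
                    orr = contingency_odds_ratio([[rc, nh_c - rc], [ra, nh_a - ra]])
                    subgroup_results[f"odds_ratio_{side}"] = {
                        "or": orr.or_value,
                        "ci_low": orr.ci_low,
                        "ci_high": orr.ci_high,
                        "fisher_p": orr.fisher_p,
                    }
            _write(
                "subgroup_summary.json",
                lambda p: p.write_text(json.dumps(subgroup_results, indent=1, default=float)),
            )
        manifest["stages"][stage] = {"done": bool(subgroup_results)}

        if config.run_preservation:
            stage = "preservation"
            case_ids = samples.loc[samples["group"] == "case", "sample_id"].tolist()
            ctrl_ids = samples.loc[samples["group"] == "control", "sample_id"].tolist()
            pres = module_preservation(
                expr[ctrl_ids], expr[case_ids], partition,
                power=power, n_perm=200, seed=seeds[3],
            )
            _write("preservation.tsv", lambda p: pres.to_csv(p, sep="\t"))
            manifest["stages"][stage] = {
                "bands": pres["band"].value_counts().to_dict()
            }

        if config.gmt_path is not None:
            stage = "enrichment"
            sets = _io.read_gmt(config.gmt_path)
            frames = []
            for m in me_set.modules:
                res = hypergeometric_enrichment(
                    partition.index[partition == m], sets, config.enrichment_background
                )
                res.insert(0, "module", m)
                frames.append(res)
            enr = pd.concat(frames, ignore_index=True)
            _write("enrichment.tsv", lambda p: enr.to_csv(p, sep="\t", index=False))
            manifest["stages"][stage] = {"n_sets": len(sets)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    manifest["outputs"].append("manifest.json")
    return manifest
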