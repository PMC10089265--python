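"""End-to-end pipeline: simulate/ingest → qPCR quantification → community
statistics → co-occurrence networks and keystones → driver importance →
spatial interpolation, emitting a machine-readable JSON report.

A single global seed deterministically derives one child seed per stage
(via numpy SeedSequence spawning, in a fixed stage order), so any stage can
be re-run in isolation and identical config+seed gives identical reports.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import community, drivers, network, qmec, spatial, synth
from .io import Dataset, FeatureTable, load_dataset, write_dataset, write_network
from .panel import FUNCTIONAL_CATEGORIES

_STAGES = ("synth", "community", "network", "drivers", "spatial")


class StageError(RuntimeError):
    """Wraps a failure with the stage name and a remediation hint."""

    def __init__(self, stage: str, original: Exception, hint: str = ""):
        self.stage = stage
        msg = f"pipeline stage '{stage}' failed: {original}"
        if hint:
            msg += f" — {hint}"
        super().__init__(msg)


def derive_stage_seeds(seed: int) -> dict[str, int]:
    """Fixed-order SeedSequence spawn; each stage seed is < 2**31."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(_STAGES, children)
    }


class ReportSchema(BaseModel):
    """Bundled schema the pipeline report must validate against."""

    model_config = ConfigDict(extra="forbid")

    seed: int
    stage_seeds: dict[str, int]
    parameters: dict[str, Any]
    design: dict[str, Any]
    qmec: dict[str, Any]
    community: dict[str, Any]
    networks: dict[str, Any]
    keystones: dict[str, Any]
    drivers: dict[str, Any]
    spatial: dict[str, Any]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="index"))
    if obj is None or isinstance(obj, (bool, int, float, str)):
        return obj
    if dataclasses.is_dataclass(obj):
        return _jsonable(dataclasses.asdict(obj))
    return str(obj)


def run_pipeline(
    cfg: dict,
    seed: int,
    out_dir: str | Path | None = None,
    dataset: Dataset | None = None,
    truth: synth.SyntheticTruth | None = None,
) -> dict:
    """Execute the full analysis and return (and optionally write) the report.

    ``cfg`` mirrors the YAML run-config: an optional ``simulate`` block
    (generator parameters), or an ``inputs`` path to an on-disk dataset,
    plus optional per-stage parameter blocks (``community``, ``network``,
    ``drivers``, ``spatial``).
    """
    seeds = derive_stage_seeds(seed)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # ---------------- data stage ----------------
    try:
        if dataset is None:
            if "inputs" in cfg:
                dataset = load_dataset(cfg["inputs"])
            else:
                sim_params = dict(cfg.get("simulate", {}))
                sim_params.setdefault("seed", seeds["synth"])
                scfg = synth.SynthConfig(**sim_params)
                dataset, truth = synth.generate_dataset(scfg)
        dataset.metadata.check_paired_design()
    except Exception as exc:  # noqa: BLE001
        raise StageError("synth", exc, "check the simulate block or input directory") from exc

    groups = dataset.metadata.groups
    report: dict[str, Any] = {
        "seed": seed,
        "stage_seeds": seeds,
        "parameters": _jsonable(
            {k: v for k, v in cfg.items() if k not in ("inputs",)}
        ),
        "design": {
            "n_samples": len(dataset.metadata.sample_ids),
            "n_sites": int(dataset.metadata.data["site_id"].nunique()),
            "groups": sorted(groups.unique().tolist()),
            "n_otus": dataset.otus.shape[1],
        },
    }
    if truth is not None:
        report["design"]["planted_keystones"] = truth.keystones

    # ---------------- qmec stage ----------------
    try:
        quant = qmec.quantify(dataset.ct, dataset.panel, dataset.abs_16s)
        categories = qmec.aggregate_categories(quant, dataset.panel)
        gene_table = FeatureTable(quant.absolute, kind="gene", units="copies_per_gram")
        report["qmec"] = {
            "n_assays_quantified": quant.absolute.shape[1],
            "detected_fraction": float(quant.detected.to_numpy().mean()),
            "category_totals_mean": categories.mean(axis=0).to_dict(),
            "flagged_samples": quant.flagged_samples,
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("qmec", exc, "check the CT table and panel definition") from exc

    # ---------------- community stage ----------------
    try:
        comm_cfg = cfg.get("community", {})
        rarefied = community.rarefy(
            dataset.otus, depth=comm_cfg.get("rarefaction_depth"), seed=seeds["community"]
        )
        alpha = community.alpha_diversity(rarefied)
        dm = community.bray_curtis(rarefied)
        ord_res = community.pcoa(dm)
        ano = community.anosim(
            dm,
            groups.reindex(dm.index),
            n_permutations=comm_cfg.get("anosim_permutations", 999),
            seed=seeds["community"],
        )
        kw_phylum = community.kruskal_wallis_screen(
            rarefied, groups.reindex(dm.index), dataset.taxonomy, rank="phylum", top_n=10
        )
        kw_family = community.kruskal_wallis_screen(
            rarefied, groups.reindex(dm.index), dataset.taxonomy, rank="family", top_n=20
        )
        report["community"] = {
            "rarefaction_depth": int(rarefied.data.sum(axis=1).iloc[0]),
            "alpha_mean_by_group": alpha.groupby(groups.reindex(alpha.index)).mean().to_dict(),
            "anosim": {"R": ano.R, "p_value": ano.p_value, "n_permutations": ano.n_permutations},
            "pcoa_proportion_explained": ord_res.proportion_explained[:2].tolist(),
            "kw_phylum_significant": kw_phylum.index[kw_phylum["p_value"] < 0.05].tolist(),
            "kw_family_significant": kw_family.index[kw_family["p_value"] < 0.05].tolist(),
        }
        if out is not None:
            alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
            ord_res.coordinates.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
    except Exception as exc:  # noqa: BLE001
        raise StageError("community", exc, "check OTU counts are integers") from exc

    # ---------------- network stage ----------------
    try:
        net_cfg = cfg.get("network", {})
        fmen_cfg = network.NetworkConfig(
            prevalence_min=net_cfg.get("prevalence_min", 0.8),
            r_min=net_cfg.get("r_min_fmen", 0.6),
            alpha=net_cfg.get("alpha", 0.05),
            p_adjust=net_cfg.get("p_adjust", "bh_fdr"),
        )
        gene_cfg = dataclasses.replace(fmen_cfg, r_min=net_cfg.get("r_min_genenet", 0.8))
        k = net_cfg.get("k_keystones", 5)
        report["networks"] = {}
        report["keystones"] = {}
        nets: dict[str, Any] = {}
        for grp in sorted(groups.unique()):
            samples = groups.index[groups == grp]
            otus_g = dataset.otus.subset_samples(samples)
            genes_g = gene_table.subset_samples(samples)
            fmen = network.build_network(otus_g, genes_g, cfg=fmen_cfg)
            genenet = network.build_network(None, genes_g, cfg=gene_cfg)
            nets[grp] = fmen
            report["networks"][grp] = {
                "fmen": network.topology(fmen).to_dict(),
                "genenet": network.topology(genenet).to_dict()
                if genenet.number_of_edges() > 0
                else {"n_nodes": genenet.number_of_nodes(), "n_edges": 0},
            }
            ks = network.keystone_table(fmen, dataset.taxonomy, k=k)
            report["keystones"][grp] = _jsonable(ks)
            if out is not None:
                write_network(fmen, out / f"fmen_{grp}.graphml")
                write_network(genenet, out / f"genenet_{grp}.graphml")
                ks.to_csv(out / f"keystones_{grp}.tsv", sep="\t")
    except Exception as exc:  # noqa: BLE001
        raise StageError("network", exc, "prevalence threshold may be too strict") from exc

    # ---------------- drivers stage ----------------
    try:
        drv_cfg = cfg.get("drivers", {})
        report["drivers"] = {}
        for grp in sorted(groups.unique()):
            samples = groups.index[groups == grp]
            ks_ids = list(report["keystones"][grp].keys())
            ks_counts = dataset.otus.relative_abundance().subset_samples(samples)
            ks_table = FeatureTable(
                ks_counts.data[ks_ids].clip(lower=1e-12), kind="otu", units="relative"
            )
            response = np.log(gene_table.subset_samples(samples).data.sum(axis=1))
            predictors = pd.concat(
                [
                    drivers.average_standardized_abundance(ks_table).rename("keystones"),
                    dataset.metadata.edaphic().loc[samples],
                ],
                axis=1,
            )
            imp = drivers.importance(
                predictors,
                response,
                method=drv_cfg.get("method", "rf_permutation"),
                n_trees=drv_cfg.get("n_trees", 200),
                n_perm=drv_cfg.get("n_perm", 49),
                seed=seeds["drivers"],
            )
            reg = drivers.keystone_gene_regression(
                ks_table,
                gene_table.subset_samples(samples).data.sum(axis=1),
                zero_policy="pseudocount",
            )
            rda_res = drivers.rda(
                np.log(gene_table.subset_samples(samples).data.clip(lower=1e-12)),
                dataset.metadata.edaphic().loc[samples],
                n_perm=drv_cfg.get("rda_permutations", 199),
                seed=seeds["drivers"],
            )
            report["drivers"][grp] = {
                "importance": _jsonable(imp.summary()),
                "importance_method": imp.method,
                "keystone_gene_regression": _jsonable(reg),
                "rda": {
                    "proportion_constrained": rda_res.proportion_constrained,
                    "f_statistic": rda_res.f_statistic,
                    "p_value": rda_res.p_value,
                },
            }
    except Exception as exc:  # noqa: BLE001
        raise StageError("drivers", exc, "check keystone and edaphic inputs") from exc

    # ---------------- spatial stage ----------------
    try:
        spa_cfg = cfg.get("spatial", {})
        coords = dataset.metadata.data[["lon", "lat"]]
        report["spatial"] = {}
        for grp in sorted(groups.unique()):
            samples = groups.index[groups == grp]
            pts = pd.concat([coords.loc[samples], categories.loc[samples]], axis=1)
            contrast = spatial.north_south_contrast(
                pts, value_cols=list(FUNCTIONAL_CATEGORIES)
            )
            fields = {}
            for cat in FUNCTIONAL_CATEGORIES:
                fld = spatial.idw(
                    pts, cat,
                    power=spa_cfg.get("power", 2.0),
                    grid_size=tuple(spa_cfg.get("grid_size", (100, 100))),
                )
                fields[cat] = {
                    "min": float(fld.values.min()),
                    "max": float(fld.values.max()),
                    "mean": float(fld.values.mean()),
                }
                if out is not None:
                    fld.to_ascii_grid(out / f"idw_{grp}_{cat}.asc")
            report["spatial"][grp] = {
                "north_south_contrast": _jsonable(contrast),
                "fields": fields,
            }
    except Exception as exc:  # noqa: BLE001
        raise StageError("spatial", exc, "check coordinates in metadata") from exc

    report = _jsonable(report)
    ReportSchema.model_validate(report)
    if out is not None:
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        if truth is not None:
            truth.to_json(out / "truth.json")
        if dataset is not None and "inputs" not in cfg:
            write_dataset(dataset, out / "dataset")
    return report


def load_run_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("run config must be a YAML mapping")
    return cfg
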