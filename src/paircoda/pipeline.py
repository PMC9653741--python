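"""End-to-end orchestration of the paired-cohort compositional analysis.

The pipeline runs: optional contaminant removal -> per-rank aggregation ->
rarefied alpha diversity (with a stool-vs-biopsy rank-sum comparison) ->
paired stool/biopsy comparison (stratified PERMANOVA with a Shannon
covariate, reproducibility-refined sample-type balance, ilr-shift
correction, cross-validated AUC) -> per-factor PERMANOVA screening with
batch and Shannon correction -> nearest balances for the factors that
pass the beta-diversity gate -> cooperatives per sample type and batch ->
component-wise per-taxon analysis. Every stage writes plain-text results
and the run manifest records all seeds and filtering decisions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coda, diversity, io, networks, stats
from .balances import reproducible_balance, sample_type_auc
from .design import AssociationDesign
from .io import CountTable

logger = logging.getLogger(__name__)

_ALLOWED_KEYS = None  # populated after PipelineConfig definition


@dataclasses.dataclass
class PipelineConfig:
    """All knobs of :func:`run_pipeline`; also loadable from YAML."""

    counts_path: str | None = None
    metadata_path: str | None = None
    output_dir: str = "paircoda_results"
    # simulation fallback when no input paths are given
    simulate: bool = False
    n_patients: int = 50
    n_taxa: int = 150
    # preprocessing
    pseudocount: float = 0.5
    rarefaction_depth: int | None = None
    ranks: tuple[str, ...] = ("species", "genus", "family", "order", "class", "phylum")
    # nearest balance
    nb_iterations: int = 500
    nb_subsample_fraction: float = 0.5
    nb_threshold: float = 0.80
    # PERMANOVA
    n_permutations: int = 999
    factors: tuple[str, ...] = ("location", "n_lesions", "size", "nice", "pathway")
    gate_fdr: float = 0.05
    # AUC
    auc_iterations: int = 100
    auc_inner_iterations: int = 25
    # cooperatives
    coop_min_count: int = 10
    coop_min_samples: int = 10
    coop_n_subsamples: int = 10
    coop_n_lambda: int = 10
    coop_lambda_min_ratio: float = 0.2
    run_cooperatives: bool = True
    run_componentwise: bool = True
    componentwise_depth: int = 2442
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("ranks", "factors"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if not 0 < self.nb_subsample_fraction < 1:
            raise ValueError("nb_subsample_fraction must be in (0, 1)")
        if not 0 <= self.nb_threshold <= 1:
            raise ValueError("nb_threshold must be in [0, 1]")
        if self.n_permutations < 1 or self.nb_iterations < 1:
            raise ValueError("iteration counts must be positive")
        bad = [r for r in self.ranks if r not in io.RANKS]
        if bad:
            raise ValueError(f"unknown ranks: {bad}")


def _seed_for(base: int, label: str) -> int:
    """Stable per-stage seed derived from the base seed and a stage label."""
    h = np.frombuffer(label.encode(), dtype=np.uint8).sum()
    return int(np.random.SeedSequence([base, int(h)]).generate_state(1)[0])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a manifest of produced artifacts."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}, "seeds": {}}

    # ------------------------------------------------------------------ load
    if config.counts_path and config.metadata_path:
        table = io.read_count_table(config.counts_path)
        metadata = io.read_metadata(config.metadata_path)
    elif config.simulate:
        from .simulate import default_truth, generate_cohort

        truth = default_truth(n_taxa=config.n_taxa, seed=config.seed)
        table, metadata, truth = generate_cohort(config.n_patients, truth)
        io.write_count_table(table, out / "simulated_counts.tsv")
        io.write_metadata(metadata, out / "simulated_metadata.tsv")
        truth.to_json(out / "simulated_truth.json")
    else:
        raise ValueError("either input paths or simulate=true required")
    metadata = io.aggregate_metadata(metadata)
    io.validate_metadata(metadata, table)
    manifest["stages"]["load"] = {
        "n_taxa": len(table.taxa),
        "n_samples": len(table.samples),
    }

    # ----------------------------------------------------------- aggregation
    tables = {"asv": table}
    for rank in config.ranks:
        tables[rank] = coda.aggregate_to_rank(table, rank)
    species = tables.get("species", table)

    # -------------------------------------------------------------- diversity
    seed = _seed_for(config.seed, "rarefy")
    manifest["seeds"]["rarefy"] = seed
    depth = config.rarefaction_depth or int(species.sample_totals().min())
    rarefied = diversity.rarefy(species, depth=depth, seed=seed)
    alpha = diversity.alpha_diversity(rarefied)
    diversity.write_alpha_diversity(alpha, out / "alpha_diversity.tsv")
    manifest["stages"]["diversity"] = {"depth": depth, "n_samples": len(alpha)}

    meta_alpha = alpha.merge(metadata, on="sample_id")
    from scipy.stats import ranksums

    wilcoxon = {}
    for index in ("shannon", "chao1"):
        stool = meta_alpha.loc[meta_alpha["sample_type"] == "stool", index]
        biopsy = meta_alpha.loc[meta_alpha["sample_type"] == "biopsy", index]
        stat, p = ranksums(stool, biopsy)
        wilcoxon[index] = {"statistic": float(stat), "p": float(p)}
    _write_json(wilcoxon, out / "alpha_sample_type_wilcoxon.json")

    # shared metadata with Shannon covariate
    meta_full = metadata.merge(alpha[["sample_id", "shannon"]], on="sample_id", how="inner")

    # ----------------------------------------------- stool/biopsy comparison
    comp_species = coda.zero_replace(species, config.pseudocount)
    dist = coda.aitchison_distance(comp_species)
    coda.write_distance_matrix(dist, out / "aitchison_species.tsv")

    paired_design = AssociationDesign(
        factor="sample_type",
        covariates=("shannon",),
        random_group="patient_id",
        strata="patient_id",
    )
    seed = _seed_for(config.seed, "permanova_type")
    manifest["seeds"]["permanova_type"] = seed
    type_perm = stats.permanova(
        dist, meta_full, paired_design, n_perm=config.n_permutations, seed=seed,
        level="species",
    )
    _write_json(type_perm.to_dict(), out / "permanova_sample_type.json")

    seed = _seed_for(config.seed, "nb_type")
    manifest["seeds"]["nb_type"] = seed
    type_fit = reproducible_balance(
        species, meta_full,
        AssociationDesign(factor="sample_type", random_group="patient_id"),
        n_iter=config.nb_iterations,
        subsample_fraction=config.nb_subsample_fraction,
        threshold=config.nb_threshold,
        seed=seed,
        pseudocount=config.pseudocount,
    )
    type_fit.to_json(out / "balance_sample_type.json")
    type_fit.to_table().to_csv(out / "balance_sample_type.tsv", sep="\t", index=False)

    # correction
    meta_idx = metadata.set_index("sample_id")
    stool_ids = [s for s in comp_species.index if meta_idx.loc[s, "sample_type"] == "stool"]
    biopsy_ids = [s for s in comp_species.index if meta_idx.loc[s, "sample_type"] == "biopsy"]
    corrected = coda.sample_type_correction(
        comp_species.loc[stool_ids], comp_species.loc[biopsy_ids]
    )
    corrected.to_csv(out / "stool_corrected.tsv", sep="\t")

    seed = _seed_for(config.seed, "auc")
    manifest["seeds"]["auc"] = seed
    auc_mean, auc_sd, _ = sample_type_auc(
        species, meta_full,
        n_iter=config.auc_iterations,
        inner_iter=config.auc_inner_iterations,
        seed=seed,
        pseudocount=config.pseudocount,
    )
    _write_json({"mean_auc": auc_mean, "sd_auc": auc_sd,
                 "n_iterations": config.auc_iterations}, out / "sample_type_auc.json")
    manifest["stages"]["sample_type"] = {
        "permanova_p": type_perm.p_value,
        "permanova_r2": type_perm.r2,
        "auc": auc_mean,
    }

    # ------------------------------------------------------- factor screening
    screen_rows = []
    available_factors = [f for f in config.factors if f in metadata.columns]
    for sample_type in ("stool", "biopsy"):
        ids = stool_ids if sample_type == "stool" else biopsy_ids
        sub_meta = meta_full[meta_full["sample_id"].isin(ids)]
        for rank in config.ranks:
            sub = tables[rank].subset_samples(ids)
            comp = coda.zero_replace(sub, config.pseudocount)
            sub_dist = coda.aitchison_distance(comp)
            for factor in available_factors:
                usable = sub_meta.dropna(subset=[factor])
                if usable[factor].nunique() < 2:
                    continue
                d = sub_dist.loc[usable["sample_id"], usable["sample_id"]]
                design = AssociationDesign(
                    factor=factor, covariates=("shannon",)
                )
                if usable["batch"].nunique() > 1:
                    design = AssociationDesign(
                        factor=factor, covariates=("shannon", "batch")
                    )
                seed = _seed_for(config.seed, f"screen_{sample_type}_{rank}_{factor}")
                try:
                    res = stats.permanova(
                        d, usable, design, n_perm=config.n_permutations,
                        seed=seed, level=rank,
                    )
                except ValueError as exc:
                    logger.info("screen skipped (%s/%s/%s): %s", sample_type, rank, factor, exc)
                    continue
                screen_rows.append(
                    {"sample_type": sample_type, "rank": rank, "factor": factor,
                     "r2": res.r2, "pseudo_f": res.pseudo_f, "p": res.p_value}
                )
    screen = pd.DataFrame(screen_rows)
    if len(screen):
        # BH family: factor x rank grid within each sample type
        screen["q"] = np.nan
        for sample_type, idx in screen.groupby("sample_type").groups.items():
            screen.loc[idx, "q"] = stats.bh_adjust(screen.loc[idx, "p"].to_numpy())
    screen.to_csv(out / "permanova_screen.tsv", sep="\t", index=False)
    manifest["stages"]["screen"] = {"n_tests": len(screen)}

    # ------------------------------------------------- gated nearest balances
    gated = (
        screen[screen["q"] < config.gate_fdr] if len(screen) else screen
    )
    balance_results = {}
    for _, row in gated.iterrows():
        key = f"{row['sample_type']}_{row['rank']}_{row['factor']}"
        ids = stool_ids if row["sample_type"] == "stool" else biopsy_ids
        sub_meta = meta_full[meta_full["sample_id"].isin(ids)].dropna(subset=[row["factor"]])
        sub = tables[row["rank"]].subset_samples(sub_meta["sample_id"].tolist())
        seed = _seed_for(config.seed, f"nb_{key}")
        manifest["seeds"][f"nb_{key}"] = seed
        design = AssociationDesign(factor=row["factor"])
        try:
            fit = reproducible_balance(
                sub, sub_meta, design,
                n_iter=config.nb_iterations,
                subsample_fraction=config.nb_subsample_fraction,
                threshold=config.nb_threshold,
                seed=seed,
                pseudocount=config.pseudocount,
            )
        except ValueError as exc:
            logger.warning("nearest balance failed for %s: %s", key, exc)
            continue
        fit.to_json(out / f"balance_{key}.json")
        balance_results[key] = fit.balance.to_dict()
    manifest["stages"]["balances"] = {"gated": sorted(balance_results)}

    # ------------------------------------------------------------ cooperatives
    coop_summary = {}
    if config.run_cooperatives:
        for sample_type in ("stool", "biopsy"):
            ids = stool_ids if sample_type == "stool" else biopsy_ids
            for batch in sorted(metadata["batch"].dropna().unique()):
                stratum_ids = [
                    s for s in ids if meta_idx.loc[s, "batch"] == batch
                ]
                if len(stratum_ids) < 10:
                    logger.info("cooperatives: stratum %s/%s too small", sample_type, batch)
                    continue
                sub = species.subset_samples(stratum_ids)
                try:
                    filtered = networks.prevalence_filter(
                        sub, config.coop_min_count, config.coop_min_samples
                    )
                except ValueError as exc:
                    logger.info("cooperatives skipped (%s/%s): %s", sample_type, batch, exc)
                    continue
                seed = _seed_for(config.seed, f"net_{sample_type}_{batch}")
                manifest["seeds"][f"net_{sample_type}_{batch}"] = seed
                try:
                    net = networks.mb_network(
                        filtered,
                        n_subsamples=config.coop_n_subsamples,
                        n_lambda=config.coop_n_lambda,
                        lambda_min_ratio=config.coop_lambda_min_ratio,
                        seed=seed,
                        pseudocount=config.pseudocount,
                    )
                except ValueError as exc:
                    logger.info("network skipped (%s/%s): %s", sample_type, batch, exc)
                    continue
                net.to_tsv(out / f"network_{sample_type}_{batch}.tsv")
                clusters = networks.louvain_clusters(net, seed=seed)
                clusters = [c for c in clusters if len(c) < len(filtered.taxa)]
                coops = networks.cooperative_association(
                    filtered, clusters,
                    meta_full[meta_full["sample_id"].isin(stratum_ids)],
                    factors=list(available_factors),
                    pseudocount=config.pseudocount,
                )
                networks.cooperatives_to_json(
                    coops, out / f"cooperatives_{sample_type}_{batch}.json"
                )
                coop_summary[f"{sample_type}_{batch}"] = {
                    "n_edges": net.n_edges,
                    "n_clusters": len(clusters),
                    "n_tests": len(coops),
                }
    manifest["stages"]["cooperatives"] = coop_summary

    # ---------------------------------------------------------- componentwise
    if config.run_componentwise:
        cw_rows = []
        for sample_type in ("stool", "biopsy"):
            ids = stool_ids if sample_type == "stool" else biopsy_ids
            sub_meta = meta_full[meta_full["sample_id"].isin(ids)]
            sub = species.subset_samples(sub_meta["sample_id"].tolist())
            for factor in available_factors:
                usable = sub_meta.dropna(subset=[factor])
                if usable[factor].nunique() < 2:
                    continue
                seed = _seed_for(config.seed, f"cw_{sample_type}_{factor}")
                design = AssociationDesign(factor=factor, random_group="batch")
                try:
                    res = stats.componentwise(
                        sub.subset_samples(usable["sample_id"].tolist()),
                        usable, design,
                        depth=config.componentwise_depth, seed=seed,
                    )
                except ValueError as exc:
                    logger.info("componentwise skipped (%s/%s): %s", sample_type, factor, exc)
                    continue
                res.insert(0, "sample_type", sample_type)
                cw_rows.append(res)
        if cw_rows:
            pd.concat(cw_rows, ignore_index=True).to_csv(
                out / "componentwise.tsv", sep="\t", index=False
            )
        manifest["stages"]["componentwise"] = {"n_blocks": len(cw_rows)}

    _write_json(manifest, out / "run_manifest.json")
    return manifest


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
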