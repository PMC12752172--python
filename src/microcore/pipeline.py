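"""End-to-end orchestration: filter -> diversity -> ordination -> tests ->
assembly -> core -> association models, with provenance and determinism.

A single global seed is fanned out to every stochastic stage through a
fixed per-stage key, so adding or reordering stages never silently changes
another stage's draws.  The resolved configuration is echoed into the
output directory; re-running from it reproduces every numeric output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .containers import CountTable, Phylogeny, SampleMetadata, TaxonomyTable
from .preprocess import filter_dataset, DEFAULT_CONTAMINANTS
from .simulate import SimulationConfig, simulate_dataset
from .diversity import alpha_diversity_table, bray_curtis, pcoa, rarefy, unweighted_unifrac
from .permutation import permanova, stepwise_dbrda_select
from .assembly import beta_nti, fit_sloan_neutral
from .core import core_overlap, neutral_overlay, occupancy_models
from .design import build_design
from .gllvm import directional_associations, fit_gllvm
from .codalasso import fit_coda_lasso

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs", "stage_seed"]

# fixed stage keys: reordering stages must not change another stage's stream
_STAGE_KEYS = {
    "simulate": 11,
    "rarefy": 23,
    "permanova": 37,
    "stepwise": 41,
    "bnti": 53,
    "gllvm": 67,
    "codalasso": 71,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    ss = np.random.SeedSequence([int(global_seed), _STAGE_KEYS[stage]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class PipelineConfig:
    """Resolved settings for a full pipeline run.

    Leave the input paths unset to run on a freshly simulated dataset
    (written into the output directory for provenance).
    """

    # inputs (None -> simulate)
    otu_table: str | None = None
    metadata: str | None = None
    tree: str | None = None
    taxonomy: str | None = None
    # simulation fallback
    sim_n_taxa: int = 300
    sim_n_samples: int = 116
    # filtering
    min_reads: int = 5000
    exclude: list[str] = field(default_factory=lambda: list(DEFAULT_CONTAMINANTS))
    drop_unassigned: bool = True
    unassigned_mode: str = "all"
    # diversity
    rarefaction_depth: int | None = None
    distances: list[str] = field(default_factory=lambda: ["bray_curtis", "unifrac"])
    # permanova / stepwise RDA
    permanova_terms: list[str] = field(
        default_factory=lambda: ["farm_id", "texture", "amendment", "Ca", "LOI"]
    )
    n_perm: int = 999
    rda_candidates: list[str] = field(default_factory=list)
    alpha_enter: float = 0.05
    alpha_drop: float = 0.10
    n_perm_rda: int = 199
    # assembly
    bnti_nulls: int = 199
    bnti_max_samples: int = 40
    sloan_ci: float = 0.95
    # core microbiome
    core_model_var: str = "amendment"
    core_group_var: str = "farm_id"
    core_delta: float = 0.02
    core_prevalence: float = 1.0
    # association models
    gllvm_covariates: list[str] = field(
        default_factory=lambda: ["farm_id", "crop_year_2", "amendment", "LOI", "Ca"]
    )
    gllvm_family: str = "nb"
    gllvm_latent: int = 2
    codalasso_response: str = "LOI"
    codalasso_subset: str = "amended"  # all | amended | none
    codalasso_mixing: float = 1.0
    codalasso_folds: int = 5
    # run control
    outdir: str = "microcore_out"
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def validate_inputs(
    table: CountTable,
    meta: SampleMetadata | None = None,
    tree: Phylogeny | None = None,
    taxonomy: TaxonomyTable | None = None,
) -> dict:
    """Report-only consistency check across the four inputs."""
    report: dict = {}
    if meta is not None:
        report["samples_missing_metadata"] = [
            s for s in table.sample_ids if s not in set(meta.sample_ids)
        ]
    if tree is not None:
        tips = set(tree.tip_names)
        report["otus_missing_from_tree"] = [o for o in table.otu_ids if o not in tips]
    if taxonomy is not None:
        tax = set(taxonomy.otu_ids)
        report["otus_missing_from_taxonomy"] = [o for o in table.otu_ids if o not in tax]
    report["zero_count_otus"] = [
        o for o, t in zip(table.otu_ids, table.counts.sum(axis=1)) if t == 0
    ]
    report["zero_count_samples"] = [
        s for s, t in zip(table.sample_ids, table.counts.sum(axis=0)) if t == 0
    ]
    return {k: v for k, v in report.items() if v}


def _load_or_simulate(config: PipelineConfig, outdir: Path):
    if config.otu_table is None:
        sim = SimulationConfig(
            n_taxa=config.sim_n_taxa,
            n_samples=config.sim_n_samples,
            seed=stage_seed(config.seed, "simulate"),
        )
        ds = simulate_dataset(sim)
        ds.write(outdir / "simulated_input")
        return ds.table, ds.metadata, ds.tree, ds.taxonomy
    table = mio.read_count_table(config.otu_table)
    meta = mio.read_metadata(config.metadata) if config.metadata else None
    tree = mio.read_tree(config.tree) if config.tree else None
    taxonomy = mio.read_taxonomy(config.taxonomy) if config.taxonomy else None
    return table, meta, tree, taxonomy


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis sequence; returns a summary dictionary.

    Writes all stage outputs (TSV/JSON), the resolved config and a run log
    into ``config.outdir``.  Any stage failure aborts with the stage named
    in the raised error.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("microcore")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {"seed": config.seed}
    config.to_yaml(outdir / "config_resolved.yaml")

    stage = "load"
    try:
        table, meta, tree, taxonomy = _load_or_simulate(config, outdir)
        if meta is None:
            raise ValueError("metadata required for the full pipeline")
        consistency = validate_inputs(table, meta, tree, taxonomy)
        (outdir / "input_validation.json").write_text(json.dumps(consistency, indent=2))
        missing = consistency.get("samples_missing_metadata", [])
        if missing:
            logger.warning("dropping %d samples without metadata", len(missing))
            table = table.select_samples([s for s in table.sample_ids if s not in set(missing)])

        stage = "filter"
        table = filter_dataset(
            table,
            taxonomy,
            min_reads=config.min_reads,
            exclude=tuple(config.exclude),
            drop_unassigned=config.drop_unassigned,
            unassigned_mode=config.unassigned_mode,
        )
        nonzero = [o for o, t in zip(table.otu_ids, table.counts.sum(axis=1)) if t > 0]
        table = table.select_otus(nonzero)
        meta = meta.subset(table.sample_ids)
        mio.write_count_table(table, outdir / "otu_table_filtered.tsv")
        summary["n_samples"], summary["n_otus"] = table.n_samples, table.n_otus

        stage = "alpha_diversity"
        rare = rarefy(table, depth=config.rarefaction_depth, seed=stage_seed(config.seed, "rarefy"))
        alpha = alpha_diversity_table(rare)
        alpha.rename_axis("sample_id").to_csv(outdir / "alpha_diversity.tsv", sep="\t")
        summary["mean_shannon"] = float(alpha["shannon"].mean())
        summary["mean_chao1"] = float(alpha["chao1"].mean())

        stage = "beta_diversity"
        dms = {}
        if "bray_curtis" in config.distances:
            dms["bray_curtis"] = bray_curtis(table)
        if "unifrac" in config.distances:
            if tree is None:
                raise ValueError("tree required for UniFrac")
            dms["unifrac"] = unweighted_unifrac(table, tree)
        for name, dm in dms.items():
            mio.write_distance_matrix(dm, outdir / f"distance_{name}.tsv")
            ordn = pcoa(dm)
            ordn.to_frame().rename_axis("sample_id").to_csv(
                outdir / f"pcoa_{name}.tsv", sep="\t"
            )
            (outdir / f"pcoa_{name}_eigen.json").write_text(
                json.dumps(
                    {
                        "eigenvalues": ordn.eigenvalues.tolist(),
                        "proportion_explained": ordn.proportion_explained.tolist(),
                        "correction": ordn.correction,
                    }
                )
            )

        stage = "permanova"
        primary = dms.get("bray_curtis") or next(iter(dms.values()))
        perm = permanova(
            primary,
            meta,
            config.permanova_terms,
            n_perm=config.n_perm,
            seed=stage_seed(config.seed, "permanova"),
        )
        perm.table.rename_axis("term").to_csv(outdir / "permanova.tsv", sep="\t")
        summary["permanova_r2"] = {
            t: float(perm.table.at[t, "R2"]) for t in config.permanova_terms
        }

        if config.rda_candidates:
            stage = "stepwise_rda"
            sel = stepwise_dbrda_select(
                primary,
                meta,
                config.rda_candidates,
                alpha_enter=config.alpha_enter,
                alpha_drop=config.alpha_drop,
                n_perm=config.n_perm_rda,
                seed=stage_seed(config.seed, "stepwise"),
            )
            (outdir / "stepwise_rda.json").write_text(
                json.dumps({"selected": sel.selected, "trace": sel.trace}, default=str, indent=2)
            )
            summary["rda_selected"] = sel.selected

        stage = "bnti"
        if tree is not None:
            bt = table
            if bt.n_samples > config.bnti_max_samples:
                rng = np.random.default_rng(stage_seed(config.seed, "bnti"))
                keep = sorted(
                    rng.choice(bt.n_samples, size=config.bnti_max_samples, replace=False)
                )
                bt = bt.select_samples([bt.sample_ids[i] for i in keep])
            bnti = beta_nti(
                bt, tree, n_null=config.bnti_nulls, seed=stage_seed(config.seed, "bnti")
            )
            bnti.bnti.rename_axis("sample_id").to_csv(outdir / "bnti.tsv", sep="\t")
            pair_vals = bnti.pair_values()
            summary["bnti_mean"] = float(np.nanmean(pair_vals))
            summary["bnti_frac_deterministic"] = float(np.nanmean(np.abs(pair_vals) > 2))

        stage = "sloan"
        sloan = fit_sloan_neutral(table, ci_level=config.sloan_ci)
        sloan.per_otu.rename_axis("otu_id").to_csv(outdir / "sloan_per_otu.tsv", sep="\t")
        summary["sloan_m"] = sloan.m_hat
        summary["sloan_r2"] = sloan.r_squared
        summary["sloan_partition"] = {
            k: int(v) for k, v in sloan.partition_counts().items()
        }

        stage = "core"
        cores = occupancy_models(
            table,
            meta,
            model_var=config.core_model_var,
            group_var=config.core_group_var,
            delta=config.core_delta,
        )
        pooled = cores["all"]
        pooled.per_otu_table().rename_axis("otu_id").to_csv(
            outdir / "core_pooled.tsv", sep="\t"
        )
        summary["core_size"] = len(pooled.core)
        summary["core_min_occupancy"] = pooled.min_core_occupancy
        overlay = neutral_overlay(pooled, sloan)
        summary["core_partition"] = overlay.value_counts().to_dict()
        if len(cores) > 2:
            stage = "core_overlap"
            ov = core_overlap(cores, prevalence_filter=config.core_prevalence)
            (outdir / "core_overlap.json").write_text(
                json.dumps(
                    {
                        "venn": ov.venn,
                        "pairwise_sharing_pct": {f"{a}|{b}": v for (a, b), v in ov.pairwise.items()},
                        "total_sharing_pct": ov.total_sharing,
                    },
                    indent=2,
                )
            )
            summary["core_total_sharing_pct"] = ov.total_sharing

        stage = "gllvm"
        usable = [c for c in config.gllvm_covariates if c in meta.data.columns]
        design = build_design(meta, usable)
        fit = fit_gllvm(
            table,
            design,
            family=config.gllvm_family,
            n_latent=config.gllvm_latent,
            seed=stage_seed(config.seed, "gllvm"),
        )
        fit.coefficient_table().to_csv(outdir / "gllvm_coefficients.tsv", sep="\t", index=False)
        direction = directional_associations(fit)
        direction.rename_axis("taxon").to_csv(outdir / "gllvm_directions.tsv", sep="\t")
        summary["gllvm_converged"] = fit.converged
        summary["gllvm_n_directional"] = int((direction != "none").to_numpy().sum())

        stage = "codalasso"
        if config.codalasso_subset == "amended":
            samples = [
                s for s in table.sample_ids if meta.data.at[s, "amendment"] != "None"
            ]
        elif config.codalasso_subset == "none":
            samples = [
                s for s in table.sample_ids if meta.data.at[s, "amendment"] == "None"
            ]
        else:
            samples = table.sample_ids
        sub = table.select_samples(samples)
        nonzero = [o for o, t in zip(sub.otu_ids, sub.counts.sum(axis=1)) if t > 0]
        sub = sub.select_otus(nonzero)
        yresp = meta.data.loc[samples, config.codalasso_response].astype(float)
        coda = fit_coda_lasso(
            sub,
            yresp,
            response_name=config.codalasso_response,
            mixing=config.codalasso_mixing,
            cv_folds=min(config.codalasso_folds, len(samples)),
            seed=stage_seed(config.seed, "codalasso"),
        )
        coda.coefficients.rename_axis("otu_id").to_csv(outdir / "codalasso_coefficients.tsv", sep="\t")
        summary["codalasso_n_selected"] = int((coda.coefficients != 0).sum())
        summary["codalasso_lambda"] = coda.lambda_chosen

        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
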