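"""Synthetic soil-community generator with known ground truth.

Emulates the statistical structure of an agricultural 16S survey: a
lognormal metacommunity sampled into local communities under Sloan-type
neutral immigration, overlaid with deterministic environmental filtering
tied to continuous soil covariates (calcium, loss on ignition) and
optionally confined to a phylogenetic clade.  The sampling design mirrors
a multi-farm survey: 14 farms, four organic-amendment groups with two rare
levels (digestate and slurry), four soil textures, and library sizes in
the 5,079-41,827 read range.

Every draw is driven by a single seed; ``(config, seed)`` reproduces the
dataset exactly, and the injected truth (migration rate, effect taxa and
sizes, metacommunity proportions) is recorded for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import CountTable, Phylogeny, SampleMetadata, TaxonomyTable, RANKS
from . import io as mio

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_tree",
    "simulate_metacommunity",
    "simulate_neutral_counts",
    "apply_environmental_filter",
    "simulate_metadata",
    "simulate_dataset",
]

AMENDMENT_LEVELS = ("None", "FYM", "Digestate", "Slurry")
TEXTURE_LEVELS = ("sandy_loam", "sandy_silt_loam", "silty_clay_loam", "clay_loam")


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a synthetic community survey.

    Defaults reproduce the survey's design: 116 samples over 14 farms,
    amendment frequencies None 0.55 / FYM 0.38 / Digestate 0.035 /
    Slurry 0.035, and per-sample depths uniform on [5079, 41827].  The
    taxon count is held at a few hundred so the full analysis stack runs
    at desk scale.
    """

    n_taxa: int = 300
    n_samples: int = 116
    n_farms: int = 14
    amendment_freqs: dict[str, float] = field(
        default_factory=lambda: {"None": 0.55, "FYM": 0.38, "Digestate": 0.035, "Slurry": 0.035}
    )
    log_mean: float = 0.0
    log_sd: float = 1.5
    m_true: float = 0.1
    depth_range: tuple[int, int] = (5079, 41827)
    n_effect_taxa: int = 20
    effect_size: float = 1.0
    effect_covariates: tuple[str, ...] = ("Ca", "LOI")
    phylo_signal: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2 or self.n_samples < 1 or self.n_farms < 1:
            raise ValueError("n_taxa, n_samples and n_farms must be positive (n_taxa >= 2)")
        if self.m_true <= 0:
            raise ValueError("m_true must be positive")
        freqs = np.array(list(self.amendment_freqs.values()))
        if np.any(freqs < 0) or np.any(freqs > 1) or not np.isclose(freqs.sum(), 1.0):
            raise ValueError("amendment frequencies must be probabilities summing to 1")
        if self.depth_range[0] < 1 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("invalid depth range")


@dataclass
class SyntheticDataset:
    """A simulated survey plus the truth used to generate it."""

    table: CountTable
    metadata: SampleMetadata
    tree: Phylogeny
    taxonomy: TaxonomyTable
    truth: dict

    def write(self, outdir: str | Path) -> None:
        """Write otu_table.tsv, metadata.tsv, tree.nwk, taxonomy.tsv, truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mio.write_count_table(self.table, outdir / "otu_table.tsv")
        mio.write_metadata(self.metadata, outdir / "metadata.tsv")
        mio.write_tree(self.tree, outdir / "tree.nwk")
        mio.write_taxonomy(self.taxonomy, outdir / "taxonomy.tsv")
        truth = dict(self.truth)
        truth["effects"] = {
            t: {c: float(v) for c, v in row.items()}
            for t, row in self.truth["effects"].items()
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2))


def simulate_tree(n_tips: int, seed: int = 0, rate: float = 1.0) -> Phylogeny:
    """Simulate a Yule (pure-birth) topology with exponential branch lengths.

    Tips are labelled ``OTU_1 .. OTU_n``.  Branch lengths are iid
    Exponential(rate); the tree is rooted and generally not ultrametric.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)
    # Yule growth: split a uniformly chosen active lineage until n_tips.
    nodes = [TreeNode(name="OTU_1"), TreeNode(name="OTU_2")]
    root = TreeNode(children=list(nodes))
    for k in range(3, n_tips + 1):
        i = rng.integers(len(nodes))
        tip = nodes[i]
        left = TreeNode(name=tip.name)
        right = TreeNode(name=f"OTU_{k}")
        tip.name = None
        tip.extend([left, right])
        nodes[i] = left
        nodes.append(right)
    for node in root.traverse(include_self=False):
        node.length = float(rng.exponential(1.0 / rate))
    return Phylogeny(root)


def simulate_metacommunity(
    n_taxa: int, log_mean: float = 0.0, log_sd: float = 1.5, seed: int = 0
) -> np.ndarray:
    """Lognormal metacommunity relative abundances, normalised to sum 1."""
    if log_sd <= 0:
        raise ValueError("log_sd must be positive")
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(mean=log_mean, sigma=log_sd, size=n_taxa)
    return raw / raw.sum()


def simulate_neutral_counts(
    meta: np.ndarray,
    m: float,
    depths: np.ndarray,
    seed: int = 0,
    sample_ids: list[str] | None = None,
    otu_ids: list[str] | None = None,
) -> CountTable:
    """Sample local communities under the Sloan neutral immigration model.

    For sample j with depth ``N_j``, local relative abundances are drawn
    from a Dirichlet with concentration ``N_j * m * p`` — giving each taxon
    the Beta(N_j m p_i, N_j m (1-p_i)) marginal of the neutral model — and
    counts follow a Multinomial(N_j, local proportions).

    ``meta`` may be a vector of metacommunity proportions (shared across
    samples) or a (taxa x samples) matrix of per-sample source proportions
    (e.g. after environmental filtering).
    """
    if m <= 0:
        raise ValueError("migration parameter m must be positive")
    meta = np.asarray(meta, dtype=float)
    depths = np.asarray(depths, dtype=np.int64)
    if np.any(depths < 1):
        raise ValueError("depths must be >= 1")
    n_samples = len(depths)
    if meta.ndim == 1:
        meta = np.repeat(meta[:, None], n_samples, axis=1)
    if meta.shape[1] != n_samples:
        raise ValueError("proportion matrix columns must match depths")
    n_taxa = meta.shape[0]
    rng = np.random.default_rng(seed)
    counts = np.zeros((n_taxa, n_samples), dtype=np.int64)
    for j in range(n_samples):
        alpha = depths[j] * m * meta[:, j]
        # Gamma-normalisation form of the Dirichlet; tiny concentrations can
        # underflow to zero, which simply means the taxon failed to immigrate.
        gam = rng.gamma(np.maximum(alpha, 1e-300))
        total = gam.sum()
        local = gam / total if total > 0 else meta[:, j]
        counts[:, j] = rng.multinomial(depths[j], local / local.sum())
    otu_ids = otu_ids or [f"OTU_{i + 1}" for i in range(n_taxa)]
    sample_ids = sample_ids or [f"S{j + 1:03d}" for j in range(n_samples)]
    return CountTable(counts, otu_ids, sample_ids)


def apply_environmental_filter(
    meta: np.ndarray,
    metadata: SampleMetadata,
    effects: pd.DataFrame,
    otu_ids: list[str] | None = None,
) -> np.ndarray:
    """Deterministic selection: tilt metacommunity proportions per sample.

    For sample j: ``p_ij ∝ p_i * exp(sum_k effects_ik * z_jk)`` with z the
    standardised continuous covariates named by the effect columns;
    proportions are renormalised per sample.  Taxa absent from ``effects``
    have zero effect.  Returns a (taxa x samples) matrix.
    """
    meta = np.asarray(meta, dtype=float)
    n_taxa = meta.shape[0]
    otu_ids = otu_ids or [f"OTU_{i + 1}" for i in range(n_taxa)]
    z = np.zeros((len(metadata.sample_ids), len(effects.columns)))
    for k, cov in enumerate(effects.columns):
        vals = metadata.data[cov].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite values in covariate {cov!r}")
        sd = vals.std()
        z[:, k] = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
    eff = np.zeros((n_taxa, len(effects.columns)))
    idx = {o: i for i, o in enumerate(otu_ids)}
    for otu, row in effects.iterrows():
        if otu not in idx:
            raise ValueError(f"effect taxon {otu!r} not among OTU ids")
        eff[idx[otu]] = row.to_numpy(dtype=float)
    tilt = np.exp(eff @ z.T)  # taxa x samples
    p = meta[:, None] * tilt
    return p / p.sum(axis=0)


def simulate_metadata(config: SimulationConfig, rng: np.random.Generator) -> SampleMetadata:
    """Draw the survey design and soil chemistry for each sample.

    Amendment levels follow the configured frequencies (digestate and
    slurry rare); soil chemistry is normal with group-specific shifts —
    higher LOI under digestate/slurry, higher calcium in silty clay loam —
    mirroring the qualitative covariate structure of amended arable soils.
    """
    n = config.n_samples
    sample_ids = [f"S{j + 1:03d}" for j in range(n)]
    levels = list(config.amendment_freqs)
    freqs = np.array([config.amendment_freqs[a] for a in levels])
    amendment = rng.choice(levels, size=n, p=freqs)
    texture = rng.choice(TEXTURE_LEVELS, size=n)
    farm = rng.choice([f"F{k + 1:02d}" for k in range(config.n_farms)], size=n)
    crops = ("WW", "WOSR", "SPOT", "WPOT", "SPEAS", "Fallow")

    loi = rng.normal(6.0, 1.2, size=n) + 3.0 * np.isin(amendment, ["Digestate", "Slurry"])
    ca = rng.normal(2000.0, 350.0, size=n) + 800.0 * (texture == "silty_clay_loam")
    data = pd.DataFrame(
        {
            "farm_id": farm,
            "texture": texture,
            "amendment": amendment,
            "crop_year_1": rng.choice(crops, size=n),
            "crop_year_2": rng.choice(crops, size=n),
            "crop_year_3": rng.choice(crops, size=n),
            "crop_year_4": rng.choice(crops, size=n),
            "rotation": rng.choice(["combinable_only", "combinable_roots"], size=n),
            "straw": rng.choice(["yes", "no"], size=n),
            "cultivation": rng.choice(["plough", "min_till"], size=n),
            "nematicide": rng.choice(["yes", "no"], size=n),
            "pH": np.round(rng.normal(6.5, 0.5, size=n), 2),
            "P": np.round(rng.normal(50.0, 15.0, size=n), 1),
            "K": np.round(rng.normal(150.0, 40.0, size=n), 1),
            "Mg": np.round(rng.normal(120.0, 30.0, size=n), 1),
            "Ca": np.round(ca, 1),
            "Na": np.round(rng.normal(20.0, 6.0, size=n), 1),
            "LOI": np.round(loi, 2),
        },
        index=sample_ids,
    )
    lv = {
        "amendment": tuple(["None"] + [a for a in levels if a != "None"]),
        "texture": TEXTURE_LEVELS,
    }
    return SampleMetadata(data, lv)


def _pick_effect_clade(tree: Phylogeny, target: int) -> list[str]:
    """Internal node whose tip set is closest in size to ``target``."""
    best, best_gap = None, None
    for node in tree.tree.non_tips(include_self=False):
        tips = [t.name for t in node.tips()]
        gap = abs(len(tips) - target)
        if best_gap is None or gap < best_gap:
            best, best_gap = tips, gap
    return best if best is not None else tree.tip_names[:target]


def _dummy_taxonomy(tree: Phylogeny, n_phyla: int = 8, rng: np.random.Generator | None = None) -> TaxonomyTable:
    """Dummy lineages: phyla follow the tree's ladder order so related tips share clades."""
    tips = tree.tip_names
    n = len(tips)
    rows = {}
    for i, otu in enumerate(tips):
        ph = f"Phylum_{i * n_phyla // n + 1}"
        rows[otu] = {
            "domain": "Bacteria",
            "phylum": ph,
            "class": f"{ph}_c",
            "order": f"{ph}_o",
            "family": f"Family_{i // 10 + 1}",
            "genus": f"Genus_{i + 1}",
        }
    df = pd.DataFrame.from_dict(rows, orient="index").loc[:, list(RANKS)]
    return TaxonomyTable(df)


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Compose tree, metacommunity, metadata, filtering and neutral sampling.

    With ``n_effect_taxa = 0`` the dataset is purely neutral: every sample
    draws from the same metacommunity, so downstream selection tests see
    only stochastic structure.
    """
    config = config or SimulationConfig()
    master = np.random.default_rng(config.seed)
    # independent child streams so one stage's draws never shift another's
    seeds = master.integers(0, 2**31 - 1, size=6)

    tree = simulate_tree(config.n_taxa, seed=int(seeds[0]))
    meta_p = simulate_metacommunity(config.n_taxa, config.log_mean, config.log_sd, seed=int(seeds[1]))
    metadata = simulate_metadata(config, np.random.default_rng(int(seeds[2])))

    otu_ids = [f"OTU_{i + 1}" for i in range(config.n_taxa)]
    if config.n_effect_taxa > 0:
        if config.phylo_signal:
            chosen = _pick_effect_clade(tree, config.n_effect_taxa)[: config.n_effect_taxa]
        else:
            rng_e = np.random.default_rng(int(seeds[3]))
            chosen = list(rng_e.choice(otu_ids, size=config.n_effect_taxa, replace=False))
        effects = pd.DataFrame(
            config.effect_size,
            index=chosen,
            columns=list(config.effect_covariates),
        )
    else:
        effects = pd.DataFrame(columns=list(config.effect_covariates))

    if len(effects):
        p_matrix = apply_environmental_filter(meta_p, metadata, effects, otu_ids=otu_ids)
    else:
        p_matrix = np.repeat(meta_p[:, None], config.n_samples, axis=1)

    rng_d = np.random.default_rng(int(seeds[4]))
    depths = rng_d.integers(config.depth_range[0], config.depth_range[1] + 1, size=config.n_samples)
    table = simulate_neutral_counts(
        p_matrix,
        config.m_true,
        depths,
        seed=int(seeds[5]),
        sample_ids=metadata.sample_ids,
        otu_ids=otu_ids,
    )
    taxonomy = _dummy_taxonomy(tree)
    truth = {
        "seed": config.seed,
        "m_true": config.m_true,
        "effect_taxa": list(effects.index),
        "effects": {t: effects.loc[t].to_dict() for t in effects.index},
        "metacommunity": meta_p.tolist(),
    }
    return SyntheticDataset(table, metadata, tree, taxonomy, truth)
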