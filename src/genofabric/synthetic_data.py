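"""Synthetic two-color microarray experiments with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: several phenotypes profiled with a small number of biological
replicas, each transcript probed redundantly by 1-13 spots, multiplicative
log-normal biological noise with gene-specific coefficient of variation,
spot-specific technical bias shared across samples, additive background,
randomly corrupted spots, planted fold-changes between phenotypes, and
planted replicate-level coordination modules (synergistic when loadings
share a sign, antagonistic otherwise). Every stochastic element derives
from a single seed, so the emitted spot tables are byte-identical across
runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .io_formats import SpotTable

__all__ = [
    "PlantedFold",
    "CoordinationModule",
    "DesignConfig",
    "GroundTruth",
    "default_config",
    "generate_experiment",
    "config_from_yaml",
    "config_to_yaml",
]


@dataclass(frozen=True)
class PlantedFold:
    """A planted expression-ratio for one gene (1-based index) in one phenotype.

    ``fold`` is a signed ratio with |fold| >= 1: +f multiplies the baseline
    level by f, -f divides it by f (down-regulation).
    """

    gene: int
    phenotype: str
    fold: float


@dataclass(frozen=True)
class CoordinationModule:
    """A group of genes sharing a per-replica latent factor.

    ``loadings`` are +1/-1 per gene; same-sign pairs are synergistic by
    construction, opposite-sign pairs antagonistic. ``latent_sd`` scales
    the latent factor on the log-expression scale.
    """

    genes: tuple[int, ...]
    loadings: tuple[int, ...]
    latent_sd: float = 1.0


_DEFAULT_REDUNDANCY = {1: 0.70, 2: 0.12, 3: 0.06, 4: 0.04, 5: 0.03, 6: 0.02, 8: 0.02, 13: 0.01}


@dataclass
class DesignConfig:
    """Full specification of a simulated experiment."""

    n_genes: int = 200
    phenotypes: tuple[str, ...] = ("MRLp", "MRLlpr", "Fn14ko")
    n_replicas: int = 4
    redundancy_dist: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_REDUNDANCY)
    )
    base_level_log_mean: float = math.log(1000.0)
    base_level_log_sd: float = 1.0
    bio_cv_range: tuple[float, float] = (0.02, 0.40)
    spot_bias_sd: float = 0.10
    bg_level: float = 50.0
    corrupted_rate: float = 0.01
    planted_folds: tuple[PlantedFold, ...] = ()
    coordination_modules: tuple[CoordinationModule, ...] = ()
    seed: int = 17

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_replicas < 2:
            raise ValueError("n_replicas must be >= 2")
        probs = np.array(list(self.redundancy_dist.values()), dtype=float)
        if (probs < 0).any() or (probs > 1).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("redundancy_dist must be a probability distribution")
        if any(r < 1 or r > 13 for r in self.redundancy_dist):
            raise ValueError("redundancy values must lie in 1..13")
        if not 0.0 <= self.corrupted_rate <= 1.0:
            raise ValueError("corrupted_rate must lie in [0, 1]")
        lo, hi = self.bio_cv_range
        if not 0.0 <= lo <= hi:
            raise ValueError("bio_cv_range must be an ordered non-negative interval")
        for pf in self.planted_folds:
            if not 1 <= pf.gene <= self.n_genes:
                raise ValueError(f"planted gene {pf.gene} not in 1..{self.n_genes}")
            if pf.phenotype not in self.phenotypes:
                raise ValueError(f"planted phenotype {pf.phenotype!r} unknown")
            if abs(pf.fold) < 1.0:
                raise ValueError("planted |fold| must be >= 1")
        seen: set[tuple[int, str]] = set()
        for pf in self.planted_folds:
            key = (pf.gene, pf.phenotype)
            if key in seen:
                raise ValueError(f"gene {pf.gene} planted twice in {pf.phenotype}")
            seen.add(key)
        for mod in self.coordination_modules:
            if len(mod.genes) != len(mod.loadings):
                raise ValueError("module genes and loadings differ in length")
            if any(not 1 <= g <= self.n_genes for g in mod.genes):
                raise ValueError("module gene index out of range")
            if any(l not in (-1, 1) for l in mod.loadings):
                raise ValueError("module loadings must be +1 or -1")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    genes: list[str]
    #: multiplicative factor applied to each gene's baseline per phenotype
    phenotype_factors: pd.DataFrame
    #: per-gene module id (-1 = none) and loading (0 = none)
    modules: pd.DataFrame
    #: per-gene biological coefficient of variation
    true_cv: pd.Series
    #: (array_id, spot_id) pairs flagged corrupted
    corrupted: list[tuple[str, str]]
    #: genes overlapping both a planted fold and a module
    overlap_notes: list[str]

    def true_fold(self, gene: str, phen_p: str, phen_q: str) -> float:
        """Signed expression ratio of P vs Q, in the |x| >= 1 convention."""
        fp = self.phenotype_factors.loc[gene, phen_p]
        fq = self.phenotype_factors.loc[gene, phen_q]
        ratio = fp / fq
        return ratio if ratio >= 1.0 else -1.0 / ratio


def default_config(scale: str = "tiny") -> DesignConfig:
    """Canonical configurations: ``tiny`` (200 genes, seconds to run) or
    ``study_like`` (~17,000 genes, the profiled-chip order of magnitude).
    Both use 3 phenotypes x 4 biological replicas."""
    if scale == "tiny":
        cfg = DesignConfig(n_genes=200)
    elif scale == "study_like":
        cfg = DesignConfig(n_genes=17000)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    cfg.validate()
    return cfg


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def generate_experiment(config: DesignConfig) -> tuple[list[SpotTable], GroundTruth]:
    """Simulate raw spot tables (one per sample) plus ground truth.

    Foreground of gene i, spot k, replica xi in phenotype P is
    ``bg_level + L_i * F_{i,P} * exp(b_{i,k}) * exp(eps_{i,xi,P} + lambda_i * z_{xi,P,m})``
    with L_i the log-normal baseline, F the planted fold factor, b the
    spot-specific technical bias, eps the gene-CV-matched biological noise
    and z the module latent replicate factor.
    """
    config.validate()
    n, n_rep = config.n_genes, config.n_replicas
    phens = list(config.phenotypes)
    genes = _gene_names(n)

    (
        rng_red,
        rng_level,
        rng_cv,
        rng_bias,
        rng_noise,
        rng_latent,
        rng_bg,
        rng_corrupt,
    ) = np.random.default_rng(config.seed).spawn(8)

    r_values = np.array(sorted(config.redundancy_dist), dtype=int)
    r_probs = np.array([config.redundancy_dist[r] for r in r_values], dtype=float)
    R = rng_red.choice(r_values, size=n, p=r_probs / r_probs.sum())

    L = np.exp(
        rng_level.normal(config.base_level_log_mean, config.base_level_log_sd, size=n)
    )
    cv = rng_cv.uniform(*config.bio_cv_range, size=n)
    sigma = np.sqrt(np.log1p(cv**2))  # log-sd matching the target CV

    # planted fold factors per (gene, phenotype); 1 if none planted
    F = pd.DataFrame(1.0, index=genes, columns=phens)
    for pf in config.planted_folds:
        factor = pf.fold if pf.fold > 0 else 1.0 / abs(pf.fold)
        F.loc[genes[pf.gene - 1], pf.phenotype] = factor

    # module membership
    module_id = np.full(n, -1, dtype=int)
    loading = np.zeros(n)
    overlap_notes: list[str] = []
    planted_set = {pf.gene for pf in config.planted_folds}
    for m, mod in enumerate(config.coordination_modules):
        for g, l in zip(mod.genes, mod.loadings):
            module_id[g - 1] = m
            loading[g - 1] = l * mod.latent_sd
            if g in planted_set:
                overlap_notes.append(
                    f"gene {genes[g - 1]} carries both a planted fold and module {m}"
                )

    # per-gene-spot technical bias, shared across samples
    total_spots = int(R.sum())
    spot_gene = np.repeat(np.arange(n), R)
    bias = rng_bias.normal(0.0, config.spot_bias_sd, size=total_spots)
    spot_ids = [
        f"{genes[g]}_s{k + 1}"
        for g in range(n)
        for k in range(int(R[g]))
    ]

    # biological noise and module latents, per phenotype x replica
    eps = rng_noise.normal(size=(len(phens), n_rep, n)) * sigma  # (P, xi, i)
    n_mod = len(config.coordination_modules)
    z = rng_latent.normal(size=(len(phens), n_rep, max(n_mod, 1)))

    tables: list[SpotTable] = []
    corrupted: list[tuple[str, str]] = []
    exp_bias = np.exp(bias)
    for p_idx, phen in enumerate(phens):
        base_p = L * F[phen].to_numpy()  # (n,)
        for xi in range(n_rep):
            log_bio = eps[p_idx, xi].copy()
            in_mod = module_id >= 0
            if n_mod and in_mod.any():
                log_bio[in_mod] += loading[in_mod] * z[p_idx, xi, module_id[in_mod]]
            signal = base_p[spot_gene] * np.exp(log_bio)[spot_gene] * exp_bias
            bg = config.bg_level * np.clip(
                1.0 + rng_bg.normal(0.0, 0.02, size=total_spots), 0.0, None
            )
            fg = config.bg_level + signal
            sample = f"{phen}.{xi + 1}"
            flags = np.where(
                rng_corrupt.random(total_spots) < config.corrupted_rate,
                "corrupted",
                "ok",
            )
            df = pd.DataFrame(
                {
                    "spot_id": spot_ids,
                    "gene": [genes[g] for g in spot_gene],
                    "sample": sample,
                    "fg": fg,
                    "bg": bg,
                    "flag": flags,
                }
            )
            table = SpotTable(array_id=sample, data=df)
            tables.append(table)
            for sid in df.loc[df["flag"] == "corrupted", "spot_id"]:
                corrupted.append((sample, sid))

    truth = GroundTruth(
        genes=genes,
        phenotype_factors=F,
        modules=pd.DataFrame(
            {"gene": genes, "module": module_id, "loading": loading}
        ).set_index("gene"),
        true_cv=pd.Series(cv, index=genes, name="true_cv"),
        corrupted=corrupted,
        overlap_notes=overlap_notes,
    )
    return tables, truth


# ---------------------------------------------------------------------------
# config (de)serialization for the CLI

def config_to_yaml(config: DesignConfig, path: str) -> None:
    d = {
        "n_genes": config.n_genes,
        "phenotypes": list(config.phenotypes),
        "n_replicas": config.n_replicas,
        "redundancy_dist": {int(k): float(v) for k, v in config.redundancy_dist.items()},
        "base_level_log_mean": config.base_level_log_mean,
        "base_level_log_sd": config.base_level_log_sd,
        "bio_cv_range": list(config.bio_cv_range),
        "spot_bias_sd": config.spot_bias_sd,
        "bg_level": config.bg_level,
        "corrupted_rate": config.corrupted_rate,
        "planted_folds": [
            {"gene": pf.gene, "phenotype": pf.phenotype, "fold": pf.fold}
            for pf in config.planted_folds
        ],
        "coordination_modules": [
            {
                "genes": list(m.genes),
                "loadings": list(m.loadings),
                "latent_sd": m.latent_sd,
            }
            for m in config.coordination_modules
        ],
        "seed": config.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def config_from_yaml(path: str) -> DesignConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    cfg = DesignConfig(
        n_genes=d.get("n_genes", 200),
        phenotypes=tuple(d.get("phenotypes", ("MRLp", "MRLlpr", "Fn14ko"))),
        n_replicas=d.get("n_replicas", 4),
        redundancy_dist={
            int(k): float(v)
            for k, v in d.get("redundancy_dist", _DEFAULT_REDUNDANCY).items()
        },
        base_level_log_mean=d.get("base_level_log_mean", math.log(1000.0)),
        base_level_log_sd=d.get("base_level_log_sd", 1.0),
        bio_cv_range=tuple(d.get("bio_cv_range", (0.02, 0.40))),
        spot_bias_sd=d.get("spot_bias_sd", 0.10),
        bg_level=d.get("bg_level", 50.0),
        corrupted_rate=d.get("corrupted_rate", 0.01),
        planted_folds=tuple(
            PlantedFold(**pf) for pf in d.get("planted_folds", [])
        ),
        coordination_modules=tuple(
            CoordinationModule(
                genes=tuple(m["genes"]),
                loadings=tuple(m["loadings"]),
                latent_sd=m.get("latent_sd", 1.0),
            )
            for m in d.get("coordination_modules", [])
        ),
        seed=d.get("seed", 17),
    )
    cfg.validate()
    return cfg


def with_seed(config: DesignConfig, seed: int) -> DesignConfig:
    return replace(config, seed=seed)
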