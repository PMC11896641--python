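"""Synthetic grouped ASV tables with known ground truth.

The generator emulates the product of an amplicon workflow after
denoising: one count table per habitat, with a small number of sample
groups (stand ages), a handful of replicates per group, and uneven
library sizes in the few-times-10^4 read range. Counts follow a
Dirichlet-multinomial: each group has a mean composition built from
log-normal base abundances (optionally shifted on designated "effect"
features), each sample draws its composition from a Dirichlet around the
group mean, and reads are a multinomial draw at a log-normally
distributed depth. Inter-taxon association is planted as latent
per-sample log-abundance factors shared by blocks of features, which
induces positive rank correlation within a block after the compositional
and counting distortions that real inference has to survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["SimulationConfig", "GroundTruth", "generate_community",
           "generate_stability_contrast"]

#: stand ages of the emulated survey design, used when n_groups == 4
_DEFAULT_AGES = ("12", "22", "30", "40")


class ConfigError(ValueError):
    """Raised for an infeasible simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the community generator.

    Attributes
    ----------
    n_features, n_groups, replicates_per_group
        Table geometry; defaults mirror a 4-age x 5-replicate survey.
    depth_mean, depth_sd
        Mean and SD of the log-normal library-size distribution (reads).
    base_logmean_sd
        SD of the log base abundances; 1.5 gives the few-dominant /
        long-tail shape typical of amplicon communities.
    effect_features, effect_logfold
        Number of taxa whose log abundance is shifted between groups and
        the full shift applied to the last group (intermediate groups get
        a proportional fraction, i.e. a monotone age gradient).
    dispersion
        Base Dirichlet concentration; per-sample compositions are drawn
        from Dirichlet(concentration x group mean). Larger = tighter
        replicates. Divided by the per-group ``dispersion_multipliers``.
    correlation_blocks
        Sequence of ``(block_size, loading)`` pairs; each block shares a
        standard-normal latent factor scaled by ``loading`` on the log
        scale.
    dispersion_multipliers
        Per-group positive multipliers on the variance (concentration is
        divided by them); ``None`` means all ones.
    """

    n_features: int = 200
    n_groups: int = 4
    replicates_per_group: int = 5
    depth_mean: float = 30_000.0
    depth_sd: float = 3_000.0
    base_logmean_sd: float = 1.5
    effect_features: int = 20
    effect_logfold: float = 1.0
    dispersion: float = 500.0
    correlation_blocks: tuple[tuple[int, float], ...] = ()
    dispersion_multipliers: tuple[float, ...] | None = None
    habitat: str = "soil"
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_features, self.n_groups, self.replicates_per_group) < 1:
            raise ConfigError("n_features, n_groups and replicates_per_group must be >= 1")
        if self.depth_mean <= 0 or self.depth_sd < 0:
            raise ConfigError("depth_mean must be > 0 and depth_sd >= 0")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be > 0")
        if not 0 <= self.effect_features <= self.n_features:
            raise ConfigError(
                f"effect_features={self.effect_features} exceeds n_features={self.n_features}"
            )
        sizes = [s for s, _ in self.correlation_blocks]
        if any(s < 1 for s in sizes):
            raise ConfigError("correlation block sizes must be >= 1")
        if sum(sizes) > self.n_features:
            raise ConfigError("correlation blocks overlap: total block size exceeds n_features")
        if self.dispersion_multipliers is not None:
            if len(self.dispersion_multipliers) != self.n_groups:
                raise ConfigError("need one dispersion multiplier per group")
            if any(m <= 0 for m in self.dispersion_multipliers):
                raise ConfigError("dispersion multipliers must be positive")


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery checks."""

    group_names: list[str]
    mean_vectors: pd.DataFrame          # groups x features, rows sum to 1
    effect_features: list[str]
    block_membership: pd.Series         # feature -> block index, -1 = none
    dispersion_multipliers: np.ndarray  # per group
    concentrations: np.ndarray          # per group
    seed: int


def _softmax(log_abund: np.ndarray) -> np.ndarray:
    z = np.exp(log_abund - log_abund.max())
    return z / z.sum()


def _group_names(cfg: SimulationConfig) -> list[str]:
    if cfg.n_groups == len(_DEFAULT_AGES):
        return list(_DEFAULT_AGES)
    return [f"G{g + 1}" for g in range(cfg.n_groups)]


def generate_community(cfg: SimulationConfig):
    """Draw one grouped count table.

    Returns
    -------
    (table, metadata, truth)
        ``table`` — features x samples integer DataFrame; ``metadata`` —
        frame indexed by sample id with habitat / stand_age / plot;
        ``truth`` — :class:`GroundTruth`. Byte-identical given the same
        config (the seed lives in the config).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    p, g, k = cfg.n_features, cfg.n_groups, cfg.replicates_per_group
    features = [f"ASV{i + 1:04d}" for i in range(p)]
    groups = _group_names(cfg)
    mult = np.asarray(cfg.dispersion_multipliers if cfg.dispersion_multipliers is not None
                      else [1.0] * g, dtype=float)
    conc = cfg.dispersion / mult

    base_log = rng.normal(0.0, cfg.base_logmean_sd, size=p)

    # features are partitioned: correlation blocks first, effect features
    # drawn from the remainder so the two plantings never overlap
    perm = rng.permutation(p)
    block_membership = np.full(p, -1)
    pos = 0
    loadings = []
    for b, (size, loading) in enumerate(cfg.correlation_blocks):
        block_membership[perm[pos:pos + size]] = b
        loadings.append(loading)
        pos += size
    free = perm[pos:]
    if cfg.effect_features > len(free):
        raise ConfigError("not enough non-block features to host the effect features")
    effect_idx = np.sort(free[: cfg.effect_features])

    # per-group mean compositions: monotone shift gradient across groups
    shifts = np.linspace(0.0, 1.0, g) * cfg.effect_logfold if g > 1 else np.zeros(1)
    mean_vectors = np.empty((g, p))
    for gi in range(g):
        lm = base_log.copy()
        lm[effect_idx] += shifts[gi]
        mean_vectors[gi] = _softmax(lm)

    # library sizes: log-normal with the requested mean/SD
    n_samples = g * k
    if cfg.depth_sd == 0:
        depths = np.full(n_samples, int(round(cfg.depth_mean)))
    else:
        sigma2 = np.log1p((cfg.depth_sd / cfg.depth_mean) ** 2)
        mu = np.log(cfg.depth_mean) - sigma2 / 2
        depths = np.maximum(1, np.round(rng.lognormal(mu, np.sqrt(sigma2), n_samples))).astype(int)

    counts = np.empty((p, n_samples), dtype=np.int64)
    sample_ids, meta_rows = [], []
    s = 0
    for gi, group in enumerate(groups):
        lm_g = base_log.copy()
        lm_g[effect_idx] += shifts[gi]
        for r in range(k):
            lm = lm_g.copy()
            for b, loading in enumerate(loadings):
                lm[block_membership == b] += loading * rng.normal()
            alpha = conc[gi] * _softmax(lm)
            prop = rng.dirichlet(alpha)
            counts[:, s] = rng.multinomial(depths[s], prop)
            sid = f"{cfg.habitat}_age{group}_r{r + 1}"
            sample_ids.append(sid)
            meta_rows.append({"sample_id": sid, "habitat": cfg.habitat,
                              "stand_age": group, "plot": f"P{r + 1}"})
            s += 1

    table = pd.DataFrame(counts, index=pd.Index(features, name="feature_id"),
                         columns=sample_ids)
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = GroundTruth(
        group_names=groups,
        mean_vectors=pd.DataFrame(mean_vectors, index=groups, columns=features),
        effect_features=[features[i] for i in effect_idx],
        block_membership=pd.Series(block_membership, index=features, name="block"),
        dispersion_multipliers=mult,
        concentrations=conc,
        seed=cfg.seed,
    )
    return table, metadata, truth


def generate_stability_contrast(cfg: SimulationConfig, dispersion_multipliers):
    """Groups differing only in within-group dispersion.

    Composition effects are switched off so the contrast between groups
    is purely the Dirichlet concentration (divided by each group's
    multiplier); group ``i`` gets ``dispersion / multipliers[i]``.
    """
    mult = tuple(float(m) for m in dispersion_multipliers)
    if any(m <= 0 for m in mult):
        raise ConfigError("dispersion multipliers must be positive")
    cfg = replace(cfg, n_groups=len(mult), dispersion_multipliers=mult,
                  effect_logfold=0.0, effect_features=0)
    return generate_community(cfg)
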