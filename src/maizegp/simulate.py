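"""Synthetic genotype and phenotype generator for an inbred maize panel.

The generator emulates the structure of a tropical maize diversity panel:
fully homozygous inbred lines drawn from two subpopulations (default
83 + 175 = 258 lines), ~10 chromosomes with block-wise linkage
disequilibrium, and three flowering traits scored in several environments —
female flowering (FF) and male flowering (MF) with a strong genetic
correlation, and the anthesis–silking interval (ASI) defined record-wise as
MF − FF, whose low heritability emerges from the FF/MF difference rather
than being imposed.

Population structure follows the Balding–Nichols model: each marker has an
ancestral frequency p and subpopulation frequencies drawn from
Beta(p(1−F)/F, (1−p)(1−F)/F) at divergence F (Fst).  Within a chromosome,
haplotypes follow a Gaussian-copula AR(1) process whose latent correlation
between adjacent markers is exp(−d/L) for spacing d and block length L, so
marginal allele frequencies are preserved exactly while pairwise LD decays
with physical distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .panel import GenotypePanel, validate_phenotypes

DEFAULT_H2 = {"FF": 0.72, "MF": 0.66, "ASI": 0.29}


@dataclass
class TraitConfig:
    """Genetic architecture of the simulated flowering traits.

    ``target_h2`` is the narrow-sense heritability of each primary trait on a
    single-plot basis within one environment (genetic variance over genetic +
    residual variance); ASI's heritability is emergent from the MF − FF
    difference, so its entry is informational only.  ``gxe_variance_share``
    is var(G×E)/(var(G) + var(G×E)) within an environment.
    """

    trait_names: tuple[str, ...] = ("FF", "MF", "ASI")
    target_h2: dict = field(default_factory=lambda: dict(DEFAULT_H2))
    genetic_correlation: float = 0.85
    n_qtl: int = 150
    env_means: dict | None = None
    gxe_variance_share: float = 0.2
    asi_is_difference: bool = True
    genetic_sd: float = 3.0
    base_means: dict = field(default_factory=lambda: {"FF": 67.0, "MF": 65.0})
    replicate_sd: float = 0.3
    block_sd: float = 0.3

    def __post_init__(self) -> None:
        if not -1.0 <= self.genetic_correlation <= 1.0:
            raise ValueError("genetic correlation must be in [-1, 1]")
        for trait, h2 in self.target_h2.items():
            if not 0.0 < h2 <= 1.0:
                raise ValueError(f"h2 for {trait} must be in (0, 1]")
        if not 0.0 <= self.gxe_variance_share < 1.0:
            raise ValueError("gxe_variance_share must be in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth stored alongside every simulated phenotype set."""

    qtl_indices: np.ndarray
    qtl_effects: dict  # trait -> effects (main), (trait, env) -> per-env effects
    genetic_values: dict  # (trait, env) -> per-line true genetic value
    variance_components: dict  # (trait, env) -> {"var_g", "var_e", "h2_realized"}
    line_ids: list[str]

    def to_json(self) -> str:
        payload = {
            "qtl_indices": self.qtl_indices.tolist(),
            "qtl_effects": {str(k): np.asarray(v).tolist() for k, v in self.qtl_effects.items()},
            "genetic_values": {f"{t}|{e}": v.tolist() for (t, e), v in self.genetic_values.items()},
            "variance_components": {f"{t}|{e}": v for (t, e), v in self.variance_components.items()},
            "line_ids": self.line_ids,
        }
        return json.dumps(payload, indent=1)


def simulate_genotypes(
    n_lines: int = 258,
    n_markers: int = 3000,
    n_chromosomes: int = 10,
    subpop_proportions: tuple[float, ...] = (83 / 258, 175 / 258),
    fst: float = 0.1,
    ld_block_length_bp: float = 50_000.0,
    missing_rate: float = 0.0,
    seed: int | None = None,
    mean_spacing_bp: int = 3_300,
) -> GenotypePanel:
    """Simulate a homozygous inbred panel with block-wise LD and structure.

    Parameters mirror the panel being emulated: 258 lines in two
    subpopulations of 83 and 175, ten chromosomes, markers spaced a few kb
    apart.  Dosages are 0/2 before missing-data injection.
    """
    if seed is None:
        raise ValueError("a seed is required")
    if n_lines < 2 or n_markers < 1 or n_chromosomes < 1:
        raise ValueError("non-positive dimensions")
    props = np.asarray(subpop_proportions, dtype=float)
    if props.ndim != 1 or props.size < 1 or np.any(props <= 0) or abs(props.sum() - 1.0) > 1e-8:
        raise ValueError("subpopulation proportions must be positive and sum to 1")
    if not 0.0 <= fst <= 0.5:
        raise ValueError("fst must be in [0, 0.5]")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")

    rng = np.random.default_rng(seed)
    # subpopulation sizes: largest-remainder rounding so they sum to n_lines
    sizes = np.floor(props * n_lines).astype(int)
    while sizes.sum() < n_lines:
        sizes[np.argmax(props * n_lines - sizes)] += 1
    subpop = np.repeat([f"pop{i + 1}" for i in range(sizes.size)], sizes)

    # marker map: chromosomes of near-equal marker counts, positions by
    # cumulative random spacing (strictly increasing by construction)
    per_chrom = np.full(n_chromosomes, n_markers // n_chromosomes)
    per_chrom[: n_markers % n_chromosomes] += 1
    chromosome, position = [], []
    for c, m in enumerate(per_chrom):
        gaps = rng.integers(1, 2 * mean_spacing_bp, size=m)
        pos = np.cumsum(gaps)
        chromosome.extend([f"chr{c + 1}"] * m)
        position.extend(pos.tolist())
    chromosome = np.asarray(chromosome, dtype=object)
    position = np.asarray(position, dtype=np.int64)

    # Balding–Nichols subpopulation frequencies
    p_anc = rng.uniform(0.1, 0.9, size=n_markers)
    freqs = np.empty((sizes.size, n_markers))
    if fst > 0:
        a = p_anc * (1 - fst) / fst
        b = (1 - p_anc) * (1 - fst) / fst
        for s in range(sizes.size):
            freqs[s] = np.clip(rng.beta(a, b), 0.01, 0.99)
    else:
        freqs[:] = p_anc

    # one haplotype per inbred line: latent Gaussian AR(1) along each
    # chromosome, thresholded at Phi^{-1}(p) to preserve marginal frequency
    dosage = np.empty((n_lines, n_markers))
    for c in range(n_chromosomes):
        idx = np.flatnonzero(chromosome == f"chr{c + 1}")
        m = idx.size
        z = np.empty((n_lines, m))
        z[:, 0] = rng.standard_normal(n_lines)
        gaps = np.diff(position[idx]).astype(float)
        if ld_block_length_bp > 0:
            rho = np.exp(-gaps / float(ld_block_length_bp))
        else:
            rho = np.zeros_like(gaps)
        for j in range(1, m):
            e = rng.standard_normal(n_lines)
            z[:, j] = rho[j - 1] * z[:, j - 1] + np.sqrt(1 - rho[j - 1] ** 2) * e
        start = 0
        for s, size in enumerate(sizes):
            thresh = norm.ppf(freqs[s, idx])
            allele = (z[start : start + size] < thresh[None, :]).astype(float)
            dosage[start : start + size][:, idx] = 2.0 * allele
            start += size

    if missing_rate > 0:
        mask = rng.random(dosage.shape) < missing_rate
        dosage[mask] = np.nan

    width = max(3, len(str(n_lines)))
    line_ids = [f"L{i + 1:0{width}d}" for i in range(n_lines)]
    marker_ids = [f"M{j + 1:05d}" for j in range(n_markers)]
    return GenotypePanel(
        line_ids=line_ids,
        marker_ids=marker_ids,
        chromosome=chromosome,
        position_bp=position,
        dosage=dosage,
        subpopulation=subpop.tolist(),
    )


def simulate_phenotypes(
    panel: GenotypePanel,
    trait_config: TraitConfig | None = None,
    environments: tuple[str, ...] = ("ENV1", "ENV2", "ENV3", "ENV4"),
    seed: int | None = None,
    n_replicates: int = 3,
    n_blocks: int = 4,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate multi-environment flowering phenotypes on a genotyped panel.

    FF and MF QTL effects are drawn from a bivariate normal with the
    configured genetic correlation at a shared QTL set (pleiotropy).  G×E is
    generated by per-environment perturbations of the QTL effects, scaled so
    that within an environment var(G×E)/(var(G)+var(G×E)) equals
    ``gxe_variance_share``.  Residual noise is scaled against the realized
    per-environment genetic variance so plot-level h² matches its target up
    to sampling error.  ASI records are emitted as MF − FF of the same
    line/environment/replicate.
    """
    if seed is None:
        raise ValueError("a seed is required")
    cfg = trait_config or TraitConfig()
    if len(environments) < 1:
        raise ValueError("at least one environment required")
    if np.isnan(panel.dosage).any():
        raise ValueError("panel has missing dosages; impute or simulate with missing_rate=0")
    if cfg.n_qtl > panel.n_markers:
        raise ValueError("n_qtl exceeds number of markers")

    rng = np.random.default_rng(seed)
    n = panel.n_lines
    primary = [t for t in cfg.trait_names if t != "ASI" or not cfg.asi_is_difference]

    qtl = np.sort(rng.choice(panel.n_markers, size=cfg.n_qtl, replace=False))
    W = panel.dosage[:, qtl] - panel.dosage[:, qtl].mean(axis=0)

    # bivariate-normal effects at shared QTL for the two primary traits
    r = cfg.genetic_correlation
    cov = np.array([[1.0, r], [r, 1.0]])
    eff = rng.multivariate_normal(np.zeros(2), cov, size=cfg.n_qtl)
    effects = {}
    for k, trait in enumerate(primary[:2]):
        effects[trait] = eff[:, k]
    for trait in primary[2:]:
        effects[trait] = rng.standard_normal(cfg.n_qtl)

    env_means = cfg.env_means or {
        env: float(off) for env, off in zip(environments, np.linspace(-2.0, 2.0, len(environments)))
    }

    # G x E perturbations for the two primary traits share the genetic
    # correlation (flowering-time G x E is itself correlated across traits);
    # without this, per-environment deviations would dilute the configured
    # within-environment correlation
    delta_draws: dict = {}
    if cfg.gxe_variance_share > 0:
        for env in environments:
            pair = rng.multivariate_normal(np.zeros(2), cov, size=cfg.n_qtl)
            for k, trait in enumerate(primary[:2]):
                delta_draws[(trait, env)] = pair[:, k]
            for trait in primary[2:]:
                delta_draws[(trait, env)] = rng.standard_normal(cfg.n_qtl)

    genetic_values: dict = {}
    var_comp: dict = {}
    env_effects: dict = {}
    resid_sd: dict = {}
    for trait in primary:
        g_main = W @ effects[trait]
        sd = g_main.std()
        scale = cfg.genetic_sd / sd if sd > 0 else 0.0
        g_main = g_main * scale
        effects[trait] = effects[trait] * scale
        s = cfg.gxe_variance_share
        for env in environments:
            if s > 0:
                delta_eff = delta_draws[(trait, env)]
                delta = W @ delta_eff
                dsd = delta.std()
                target_sd = cfg.genetic_sd * np.sqrt(s / (1 - s))
                k = target_sd / dsd if dsd > 0 else 0.0
                delta = delta * k
                env_effects[(trait, env)] = effects[trait] + delta_eff * k
            else:
                delta = np.zeros(n)
                env_effects[(trait, env)] = effects[trait]
            g_env = g_main + delta
            genetic_values[(trait, env)] = g_env
            h2 = cfg.target_h2.get(trait, 0.5)
            var_g = g_env.var()
            var_e = var_g * (1 - h2) / h2 if h2 < 1.0 else 0.0
            resid_sd[(trait, env)] = np.sqrt(var_e)
            var_comp[(trait, env)] = {
                "var_g": float(var_g),
                "var_e": float(var_e),
                "h2_realized": float(var_g / (var_g + var_e)) if var_g + var_e > 0 else np.nan,
            }

    # design effects shared across traits within an env/replicate
    noiseless = all(cfg.target_h2.get(t, 0.5) >= 1.0 for t in primary)
    rep_sd = 0.0 if noiseless else cfg.replicate_sd
    blk_sd = 0.0 if noiseless else cfg.block_sd
    rep_eff = {
        (t, e, rep): rng.normal(0.0, rep_sd) if rep_sd > 0 else 0.0
        for t in primary
        for e in environments
        for rep in range(1, n_replicates + 1)
    }
    blk_eff = {
        (t, e, rep, b): rng.normal(0.0, blk_sd) if blk_sd > 0 else 0.0
        for t in primary
        for e in environments
        for rep in range(1, n_replicates + 1)
        for b in range(1, n_blocks + 1)
    }

    rows = []
    for env in environments:
        for rep in range(1, n_replicates + 1):
            # lines rotate through blocks across replicates
            blocks = (np.arange(n) + rep) % n_blocks + 1
            values = {}
            for trait in primary:
                mu = cfg.base_means.get(trait, 0.0) + env_means.get(env, 0.0)
                eps_sd = resid_sd[(trait, env)]
                eps = rng.normal(0.0, eps_sd, size=n) if eps_sd > 0 else np.zeros(n)
                vals = (
                    mu
                    + genetic_values[(trait, env)]
                    + rep_eff[(trait, env, rep)]
                    + np.array([blk_eff[(trait, env, rep, b)] for b in blocks])
                    + eps
                )
                values[trait] = vals
            for i, line in enumerate(panel.line_ids):
                for trait in primary:
                    rows.append((line, env, rep, int(blocks[i]), trait, values[trait][i]))
                if cfg.asi_is_difference and "ASI" in cfg.trait_names:
                    rows.append(
                        (line, env, rep, int(blocks[i]), "ASI", values["MF"][i] - values["FF"][i])
                    )

    records = pd.DataFrame(rows, columns=["line", "environment", "replicate", "block", "trait", "value"])
    records = validate_phenotypes(records)

    if cfg.asi_is_difference and "ASI" in cfg.trait_names and {"FF", "MF"} <= set(primary):
        for env in environments:
            g_asi = genetic_values[("MF", env)] - genetic_values[("FF", env)]
            genetic_values[("ASI", env)] = g_asi
            var_g = g_asi.var()
            var_e = var_comp[("FF", env)]["var_e"] + var_comp[("MF", env)]["var_e"]
            var_comp[("ASI", env)] = {
                "var_g": float(var_g),
                "var_e": float(var_e),
                "h2_realized": float(var_g / (var_g + var_e)) if var_g + var_e > 0 else np.nan,
            }

    truth = SimTruth(
        qtl_indices=qtl,
        qtl_effects={**effects, **{f"{t}|{e}": v for (t, e), v in env_effects.items()}},
        genetic_values=genetic_values,
        variance_components=var_comp,
        line_ids=list(panel.line_ids),
    )
    return records, truth


def mask_dosages(
    panel: GenotypePanel, mask_rate: float, seed: int | None = None
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Mask a random fraction of observed dosage cells for imputation tests.

    Returns the masked panel and an index table (line_idx, marker_idx,
    true_dosage) of the cells that were set to missing.
    """
    if not 0.0 <= mask_rate < 1.0:
        raise ValueError("mask_rate must be in [0, 1)")
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)
    masked = panel.copy()
    observed = ~np.isnan(masked.dosage)
    hit = (rng.random(masked.dosage.shape) < mask_rate) & observed
    li, mi = np.nonzero(hit)
    index = pd.DataFrame(
        {"line_idx": li, "marker_idx": mi, "true_dosage": masked.dosage[li, mi]}
    )
    masked.dosage[li, mi] = np.nan
    return masked, index
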