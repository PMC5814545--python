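"""Synthetic open-pollinated progeny-trial data with known ground truth.

Emulates the structure of a multi-site OP family test: a set of maternal
parents, each producing nominally half-sib offspring by wind pollination
from a finite pollen pool, offspring planted one-per-position in a
randomized complete block design over several sites, genotyped at
independent biallelic SNPs and phenotyped for a quantitative trait composed
of additive, dominance, additive-by-additive, genotype-by-site and block
effects plus residual noise.

Two features of real OP trials drive the downstream science and are
parameters here:

* ``full_sib_excess`` — the probability that an offspring reuses the
  previous sib's sire, creating hidden full-sibs inside nominal half-sib
  families (the violation of the half-sib assumption that inflates
  pedigree-based additive variance);
* genotype-by-site interaction — generated from *independent site-specific
  marker effects*, so the interaction covariance between two trees is the
  genomic kernel when they share a site and zero otherwise, mirroring the
  axe/dxe terms of the fitted models.

Each variance component is rescaled after simulation so that its realized
sample variance across individuals equals the requested value exactly,
making parameter-recovery tests sharp at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimDataset",
    "DEFAULT_VAR_COMPONENTS",
    "simulate_population",
    "simulate_phenotypes",
    "mask_genotypes",
]

# Trait composition used by default: the variance fractions follow the full
# (additive + dominance + epistasis + GxE) height decomposition of a
# multi-site interior spruce OP trial, normalized to a total of 1.
DEFAULT_VAR_COMPONENTS: dict[str, float] = {
    "additive": 0.2438,
    "dominance": 0.1946,
    "axa": 0.0,
    "axe": 0.2814,
    "dxe": 0.0454,
    "block": 0.0207,
    "residual": 0.2141,
}

_COMPONENT_KEYS = tuple(DEFAULT_VAR_COMPONENTS)


@dataclass
class SimConfig:
    """Generating parameters for one synthetic OP progeny trial."""

    n_families: int = 25
    offspring_per_family: int = 40
    n_markers: int = 30_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    pollen_pool_size: int = 100
    full_sib_excess: float = 0.25
    n_sites: int = 3
    n_blocks_per_site: int = 4
    var_components: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VAR_COMPONENTS)
    )
    n_causal: int = 300
    missing_rate: float = 0.0
    seed: int = 1234
    memory_guard_cells: int = 200_000_000

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ValueError("maf_range must satisfy 0 < low <= high < 1")
        unknown = set(self.var_components) - set(_COMPONENT_KEYS)
        if unknown:
            raise ValueError(f"unknown variance components: {sorted(unknown)}")
        for key, val in self.var_components.items():
            if val < 0:
                raise ValueError(f"variance component {key!r} is negative")
        for key in _COMPONENT_KEYS:
            self.var_components.setdefault(key, 0.0)
        if self.n_causal > self.n_markers:
            raise ValueError("n_causal cannot exceed n_markers")
        if self.pollen_pool_size < 1:
            raise ValueError("pollen_pool_size must be >= 1")
        if not 0 <= self.full_sib_excess <= 1:
            raise ValueError("full_sib_excess must lie in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")

    @property
    def n_offspring(self) -> int:
        return self.n_families * self.offspring_per_family


@dataclass
class SimTruth:
    """Ground truth recorded by the generator for recovery tests."""

    marker_effects: pd.DataFrame  # columns: additive, dominance (per marker)
    realized_var: dict[str, float]
    true_bv: pd.Series  # per-individual additive genetic value
    sire_assignments: pd.Series  # offspring -> pollen-pool founder id


@dataclass
class SimDataset:
    genotypes: GenotypeMatrix
    pedigree: pd.DataFrame  # individual, family, sire (recorded as unknown)
    phenotypes: pd.DataFrame  # individual, family, site, block, trait
    truth: SimTruth
    config: SimConfig


def _gamete(codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one gamete (haplotype) per row from unphased genotype codes."""
    het = codes == 1
    allele = (codes == 2).astype(np.int8)
    allele[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return allele


def simulate_population(config: SimConfig) -> SimDataset:
    """Generate a complete OP progeny-trial dataset.

    Founders (maternal parents and the pollen pool) receive Hardy-Weinberg
    genotypes at frequencies drawn uniformly from ``maf_range``. Each
    offspring receives one gamete from its family's mother and one from a
    sire drawn uniformly from the pollen pool — except that with probability
    ``full_sib_excess`` it reuses the previous sib's sire, creating a
    half-sib/full-sib mixture. Deterministic given ``config.seed``.
    """
    cells = config.n_offspring * config.n_markers
    if cells > config.memory_guard_cells:
        raise ValueError(
            f"requested {cells:.2e} genotype cells exceeds the memory guard "
            f"({config.memory_guard_cells:.2e}); reduce the problem size or "
            "raise memory_guard_cells"
        )
    rng = np.random.default_rng(config.seed)
    p = rng.uniform(config.maf_range[0], config.maf_range[1], config.n_markers)

    mothers = rng.binomial(2, p, size=(config.n_families, config.n_markers)).astype(
        np.int8
    )
    pool = rng.binomial(
        2, p, size=(config.pollen_pool_size, config.n_markers)
    ).astype(np.int8)
    sire_ids = [f"P{i + 1:03d}" for i in range(config.pollen_pool_size)]

    offspring = np.empty((config.n_offspring, config.n_markers), dtype=np.int8)
    individual_ids: list[str] = []
    families: list[str] = []
    sires: list[str] = []
    row = 0
    for f in range(config.n_families):
        fam_id = f"F{f + 1:02d}"
        prev_sire = None
        for j in range(config.offspring_per_family):
            if prev_sire is not None and rng.random() < config.full_sib_excess:
                sire = prev_sire
            else:
                sire = int(rng.integers(config.pollen_pool_size))
            prev_sire = sire
            mat = _gamete(mothers[f], rng)
            pat = _gamete(pool[sire], rng)
            offspring[row] = mat + pat
            individual_ids.append(f"{fam_id}_O{j + 1:03d}")
            families.append(fam_id)
            sires.append(sire_ids[sire])
            row += 1

    marker_ids = [f"M{j + 1:05d}" for j in range(config.n_markers)]
    genotypes = GenotypeMatrix(individual_ids, marker_ids, offspring.astype(float))

    pedigree = pd.DataFrame(
        {"individual": individual_ids, "family": families, "sire": "unknown"}
    )

    # field layout: each family spread round-robin across all site x block
    # cells (single-tree plots), so families are replicated everywhere
    cells_list = [
        (f"S{s + 1}", f"B{b + 1}")
        for s in range(config.n_sites)
        for b in range(config.n_blocks_per_site)
    ]
    design_rows = []
    for f in range(config.n_families):
        for j in range(config.offspring_per_family):
            site, block = cells_list[(j + f) % len(cells_list)]
            design_rows.append(
                {
                    "individual": individual_ids[f * config.offspring_per_family + j],
                    "family": families[f * config.offspring_per_family + j],
                    "site": site,
                    "block": block,
                }
            )
    design = pd.DataFrame(design_rows)

    phenotypes, truth = simulate_phenotypes(genotypes, design, config, rng=rng)
    truth.sire_assignments = pd.Series(
        sires, index=individual_ids, name="sire"
    )

    if config.missing_rate > 0:
        genotypes = mask_genotypes(
            genotypes, config.missing_rate,
            seed=int(rng.integers(2**31 - 1)),
        )

    return SimDataset(
        genotypes=genotypes,
        pedigree=pedigree,
        phenotypes=phenotypes,
        truth=truth,
        config=config,
    )


def _rescale(values: np.ndarray, target: float, what: str) -> np.ndarray:
    """Center a component and scale its sample variance to ``target``."""
    if target == 0:
        return np.zeros_like(values)
    centered = values - values.mean()
    sv = centered.var(ddof=1)
    if sv <= 0:
        raise ValueError(f"cannot rescale degenerate {what} component")
    return centered * np.sqrt(target / sv)


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    design: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Generate trait values on top of genotypes and a field design.

    trait = site mean + block(site) + additive + dominance + a-by-a
          + site-specific additive deviation (axe) + site-specific dominance
          deviation (dxe) + residual,
    with every component centered and rescaled so its realized variance
    equals the requested value.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    vc = {k: config.var_components.get(k, 0.0) for k in _COMPONENT_KEYS}
    if sum(vc.values()) <= 0:
        raise ValueError("total requested variance is zero")
    design = design.reset_index(drop=True)
    if set(design["individual"]) != set(genotypes.individual_ids):
        raise ValueError("design and genotype individuals differ")
    order = {v: i for i, v in enumerate(genotypes.individual_ids)}
    design = design.iloc[
        design["individual"].map(order).argsort(kind="stable")
    ].reset_index(drop=True)

    M = genotypes.codes
    if np.isnan(M).any():
        raise ValueError("phenotype simulation requires complete genotypes")
    n, m = M.shape
    p = M.mean(axis=0) / 2.0
    q = 1.0 - p

    causal = rng.choice(m, size=config.n_causal, replace=False)
    Zc = M[:, causal] - 2.0 * p[causal]
    # orthogonal dominance coding at the causal loci
    Wc = np.where(
        M[:, causal] == 1,
        2.0 * p[causal] * q[causal],
        np.where(M[:, causal] == 0, -2.0 * p[causal] ** 2, -2.0 * q[causal] ** 2),
    )

    add_eff = rng.standard_normal(config.n_causal)
    dom_eff = rng.standard_normal(config.n_causal)

    g_add = _rescale(Zc @ add_eff, vc["additive"], "additive")
    g_dom = _rescale(Wc @ dom_eff, vc["dominance"], "dominance")

    # additive-by-additive: products of centered codes over random causal pairs
    pair_idx = rng.permutation(config.n_causal)
    half = config.n_causal // 2
    pairs = (pair_idx[:half], pair_idx[half: 2 * half])
    axa_eff = rng.standard_normal(half)
    g_axa = _rescale((Zc[:, pairs[0]] * Zc[:, pairs[1]]) @ axa_eff,
                     vc["axa"], "axa")

    sites = design["site"].to_numpy()
    site_levels = sorted(set(sites))
    g_axe = np.zeros(n)
    g_dxe = np.zeros(n)
    for s in site_levels:
        mask = sites == s
        g_axe[mask] = Zc[mask] @ rng.standard_normal(config.n_causal)
        g_dxe[mask] = Wc[mask] @ rng.standard_normal(config.n_causal)
    g_axe = _rescale(g_axe, vc["axe"], "axe")
    g_dxe = _rescale(g_dxe, vc["dxe"], "dxe")

    blocks = (design["site"].astype(str) + "//" + design["block"].astype(str)).to_numpy()
    block_levels = sorted(set(blocks))
    block_draw = dict(zip(block_levels, rng.standard_normal(len(block_levels))))
    g_block = _rescale(
        np.array([block_draw[b] for b in blocks]), vc["block"], "block"
    )

    resid = _rescale(rng.standard_normal(n), vc["residual"], "residual")

    site_means = dict(
        zip(site_levels, rng.normal(0.0, 0.5, size=len(site_levels)))
    )
    mu = np.array([site_means[s] for s in sites])

    trait = mu + g_block + g_add + g_dom + g_axa + g_axe + g_dxe + resid

    phenotypes = design.copy()
    phenotypes["trait"] = trait

    effects = pd.DataFrame(
        {"additive": 0.0, "dominance": 0.0},
        index=[genotypes.marker_ids[j] for j in range(m)],
    )
    # record the rescaled per-marker effects actually used
    add_scale = (
        np.sqrt(vc["additive"] / np.var(Zc @ add_eff - (Zc @ add_eff).mean(), ddof=1))
        if vc["additive"] > 0
        else 0.0
    )
    dom_scale = (
        np.sqrt(vc["dominance"] / np.var(Wc @ dom_eff - (Wc @ dom_eff).mean(), ddof=1))
        if vc["dominance"] > 0
        else 0.0
    )
    effects.iloc[causal, 0] = add_eff * add_scale
    effects.iloc[causal, 1] = dom_eff * dom_scale

    realized = {
        "additive": float(np.var(g_add, ddof=1)) if vc["additive"] else 0.0,
        "dominance": float(np.var(g_dom, ddof=1)) if vc["dominance"] else 0.0,
        "axa": float(np.var(g_axa, ddof=1)) if vc["axa"] else 0.0,
        "axe": float(np.var(g_axe, ddof=1)) if vc["axe"] else 0.0,
        "dxe": float(np.var(g_dxe, ddof=1)) if vc["dxe"] else 0.0,
        "block": float(np.var(g_block, ddof=1)) if vc["block"] else 0.0,
        "residual": float(np.var(resid, ddof=1)) if vc["residual"] else 0.0,
    }
    truth = SimTruth(
        marker_effects=effects,
        realized_var=realized,
        true_bv=pd.Series(g_add, index=genotypes.individual_ids, name="true_bv"),
        sire_assignments=pd.Series(dtype=object),
    )
    return phenotypes, truth


def mask_genotypes(
    genotypes: GenotypeMatrix, missing_rate: float, seed: int
) -> GenotypeMatrix:
    """Set entries missing independently with the given probability."""
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    out = genotypes.copy()
    if missing_rate == 0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(out.codes.shape) < missing_rate
    out.codes[mask] = np.nan
    return out
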