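"""Synthetic multi-environment trial (MET) phenotype generation.

Generates long-format progeny-trial phenotypes under the same linear model
the analysis side fits,

    y_ijkt = mu_t + E_jt + R_k(j)t + G_it + GE_ijt + eps_ijkt,

where ``t`` indexes traits, ``j`` environments, ``k`` blocks within
environment and ``i`` genotypes.  Genotype effects ``G`` are multivariate
Gaussian across traits with a configurable genetic correlation matrix;
interaction (``GE``) and residual effects are independent Gaussians per
trait.  Environment and block effects are fixed shifts.

A registry of presets encodes the published per-trait variance partitions
(phenotypic variance, heritability, interaction proportion, genotypic CV)
for three poplar F1 families and their joint set, evaluated in a
two-spacing trial with three complete blocks, so that downstream fitting,
genetic-parameter and selection-index code can be exercised on data with
known truth at realistic scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical trait order: plant height, petiole length, leaf area, leaf
#: circumference, leaf length, leaf width, stomatal density, stomatal length.
TRAITS = ["H", "PL", "LA", "LC", "LL", "LW", "SD", "SL"]

#: Progeny counts of the three F1 families and their concatenation.
FAMILY_SIZES = {"1-XYxN139": 172, "1-XYxN188": 169, "ZL-3xN188": 232, "joint": 573}

# Per family x trait: (phenotypic variance, h2 = genotypic proportion,
# geir2 = interaction proportion, CVg %).  The genotypic CV pins the trait
# mean via mu = 100*sqrt(h2*phen_var)/CVg.
TABLE2_PRESETS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "1-XYxN139": {
        "H": (2.26, 0.175, 0.117, 7.88),
        "PL": (74.0, 0.277, 0.0178, 10.3),
        "LA": (326.0, 0.209, 0.0271, 12.4),
        "LC": (54.7, 0.046, 0.0595, 4.43),
        "LL": (1.90, 0.195, 0.00265, 5.92),
        "LW": (1.81, 0.152, 0.0308, 5.53),
        "SD": (25.7, 0.0203, 0.304, 3.18),
        "SL": (12.0, 0.0631, 0.0, 4.12),
    },
    "1-XYxN188": {
        "H": (2.45, 0.241, 0.0643, 9.87),
        "PL": (184.0, 0.556, 3.48e-09, 18.2),
        "LA": (476.0, 0.29, 0.0, 16.7),
        "LC": (51.7, 0.248, 3.48e-16, 9.60),
        "LL": (3.18, 0.307, 5.81e-10, 9.10),
        "LW": (2.54, 0.313, 0.0, 9.13),
        "SD": (26.8, 0.333, 0.0, 14.9),
        "SL": (12.2, 0.0933, 0.0214, 5.27),
    },
    "ZL-3xN188": {
        "H": (2.42, 0.0881, 0.095, 5.52),
        "PL": (83.1, 0.383, 0.00494, 12.2),
        "LA": (315.0, 0.145, 0.0036, 9.41),
        "LC": (41.0, 0.189, 0.0639, 7.26),
        "LL": (2.13, 0.23, 0.0129, 6.53),
        "LW": (1.62, 0.143, 0.0383, 4.88),
        "SD": (22.9, 0.148, 0.0, 7.92),
        "SL": (9.52, 0.033, 0.0398, 2.62),
    },
    "joint": {
        "H": (2.67, 0.157, 0.0739, 8.01),
        "PL": (136.0, 0.515, 0.0193, 17.3),
        "LA": (393.0, 0.187, 0.0484, 12.3),
        "LC": (54.4, 0.0977, 0.141, 6.18),
        "LL": (2.55, 0.227, 0.0423, 7.15),
        "LW": (2.10, 0.178, 0.0572, 6.29),
        "SD": (27.1, 0.221, 0.0767, 11.1),
        "SL": (11.7, 0.0772, 0.0119, 4.54),
    },
}

# Block structure of the default genetic correlation matrix: the five leaf
# traits form a tightly correlated block, height correlates mildly and
# positively with everything, and the two stomatal traits oppose each other
# and (weakly) the leaf block.
_LEAF = ["PL", "LA", "LC", "LL", "LW"]


def default_genetic_correlation(traits: list[str] | None = None) -> pd.DataFrame:
    """Genetic correlation matrix with the reported sign structure.

    Positive within the leaf-morphology block, mildly positive between
    height and the other traits, negative between stomatal density and
    stomatal length and between stomata and leaf traits.
    """
    traits = list(traits) if traits is not None else list(TRAITS)
    p = len(traits)
    r = np.eye(p)

    def _set(a: str, b: str, val: float) -> None:
        if a in traits and b in traits:
            ia, ib = traits.index(a), traits.index(b)
            r[ia, ib] = r[ib, ia] = val

    for i, a in enumerate(_LEAF):
        for b in _LEAF[i + 1:]:
            _set(a, b, 0.70)
    for t in _LEAF:
        _set("H", t, 0.30)
        _set("SD", t, -0.25)
        _set("SL", t, -0.15)
    _set("H", "SD", 0.25)
    _set("H", "SL", 0.20)
    _set("SD", "SL", -0.50)
    return pd.DataFrame(r, index=traits, columns=traits)


@dataclass
class METDesign:
    """Layout of a balanced multi-environment trial.

    ``n_genotypes`` genotypes, each present in every environment and every
    complete block before any attrition; ``family_labels`` optionally maps
    genotype id -> family id.
    """

    n_genotypes: int
    environments: list[str] = field(default_factory=lambda: ["E1", "E2"])
    n_blocks: int = 3
    family_labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.n_genotypes < 2:
            raise ValueError("need at least 2 genotypes")
        if len(self.environments) < 1:
            raise ValueError("need at least 1 environment")
        if self.n_blocks < 1:
            raise ValueError("need at least 1 block per environment")

    @property
    def n_env(self) -> int:
        return len(self.environments)

    def genotype_ids(self) -> list[str]:
        width = len(str(self.n_genotypes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genotypes)]


@dataclass
class SimulationConfig:
    """Full parameterization of one synthetic MET data set.

    Variances are per trait and in squared trait units; ``genetic_correlation``
    applies to the genotype main effects only.  ``env_effects`` (e x p) and
    ``block_effects`` (e*b x p) are fixed shifts added to the trait mean.
    """

    design: METDesign
    trait_names: list[str]
    trait_means: np.ndarray
    sigma2_g: np.ndarray
    sigma2_ge: np.ndarray
    sigma2_e: np.ndarray
    genetic_correlation: pd.DataFrame | np.ndarray | None = None
    env_effects: np.ndarray | None = None
    block_effects: np.ndarray | None = None
    attrition_rate: float = 0.0
    min_obs_per_cell: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        p = len(self.trait_names)
        self.trait_means = np.asarray(self.trait_means, dtype=float)
        self.sigma2_g = np.asarray(self.sigma2_g, dtype=float)
        self.sigma2_ge = np.asarray(self.sigma2_ge, dtype=float)
        self.sigma2_e = np.asarray(self.sigma2_e, dtype=float)
        for name in ("trait_means", "sigma2_g", "sigma2_ge", "sigma2_e"):
            if getattr(self, name).shape != (p,):
                raise ValueError(f"{name} must have length {p} (one per trait)")
        for name in ("sigma2_g", "sigma2_ge", "sigma2_e"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} contains a negative variance")
        if self.genetic_correlation is None:
            corr = np.eye(p)
        else:
            corr = np.asarray(self.genetic_correlation, dtype=float)
        if corr.shape != (p, p):
            raise ValueError(f"genetic_correlation must be {p}x{p}")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ValueError("genetic_correlation must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ValueError("genetic_correlation must have unit diagonal")
        eigvals = np.linalg.eigvalsh(corr)
        if eigvals.min() < -1e-10:
            raise ValueError(
                "genetic_correlation is not positive semidefinite "
                f"(min eigenvalue {eigvals.min():.3e})"
            )
        self._corr = corr
        e, b = self.design.n_env, self.design.n_blocks
        if self.env_effects is None:
            self.env_effects = np.zeros((e, p))
        self.env_effects = np.asarray(self.env_effects, dtype=float)
        if self.env_effects.shape != (e, p):
            raise ValueError(f"env_effects must be {e}x{p}")
        if self.block_effects is None:
            self.block_effects = np.zeros((e * b, p))
        self.block_effects = np.asarray(self.block_effects, dtype=float)
        if self.block_effects.shape != (e * b, p):
            raise ValueError(f"block_effects must be {e * b}x{p}")
        if not 0.0 <= self.attrition_rate < 1.0:
            raise ValueError("attrition_rate must be in [0, 1)")


def _psd_factor(corr: np.ndarray) -> np.ndarray:
    """Square-root factor of a PSD correlation matrix (eigen clip at 0)."""
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def simulate_met(config: SimulationConfig, return_effects: bool = False):
    """Generate a balanced long-format phenotype table.

    One observation per genotype x environment x block x trait.  Bit-identical
    under the same ``config.seed``.  If ``config.attrition_rate`` > 0 the
    balanced table is thinned with :func:`apply_attrition` (same seed stream).

    Returns the tidy table with columns ``genotype, family, environment,
    block, trait, value``; with ``return_effects=True`` also a dict holding
    the simulated true genotype and interaction effect matrices.
    """
    rng = np.random.default_rng(config.seed)
    design = config.design
    g, e, b, p = design.n_genotypes, design.n_env, design.n_blocks, len(config.trait_names)

    sd_g = np.sqrt(config.sigma2_g)
    factor = _psd_factor(config._corr)
    G = rng.standard_normal((g, p)) @ factor.T * sd_g  # g x p, Cov = D corr D
    GE = rng.standard_normal((g, e, p)) * np.sqrt(config.sigma2_ge)
    eps = rng.standard_normal((g, e, b, p)) * np.sqrt(config.sigma2_e)

    base = (
        config.trait_means[None, None, None, :]
        + config.env_effects[None, :, None, :]
        + config.block_effects.reshape(e, b, p)[None, :, :, :]
        + G[:, None, None, :]
        + GE[:, :, None, :]
        + eps
    )  # g x e x b x p

    geno_ids = design.genotype_ids()
    fam = design.family_labels or {}
    idx = pd.MultiIndex.from_product(
        [geno_ids, design.environments, [f"B{k + 1}" for k in range(b)], config.trait_names],
        names=["genotype", "environment", "block", "trait"],
    )
    table = idx.to_frame(index=False)
    table["value"] = base.reshape(-1)
    table.insert(1, "family", table["genotype"].map(lambda gid: fam.get(gid, "F1")))

    if config.attrition_rate > 0:
        table = apply_attrition(
            table, config.attrition_rate, config.min_obs_per_cell,
            seed=int(rng.integers(2**31 - 1)),
        )
    if return_effects:
        truth = {
            "G": pd.DataFrame(G, index=geno_ids, columns=config.trait_names),
            "GE": GE,
        }
        return table, truth
    return table


def apply_attrition(
    table: pd.DataFrame, rate: float, min_obs_per_cell: int, seed: int
) -> pd.DataFrame:
    """Bernoulli-thin observations, never emptying a genotype x env cell.

    Each record is dropped independently with probability ``rate`` unless the
    drop would leave fewer than ``min_obs_per_cell`` observations in that
    record's genotype x environment cell (per trait).  Deterministic under
    ``seed``; records are visited in input order with one uniform draw each.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("attrition rate must be in [0, 1)")
    if min_obs_per_cell < 0:
        raise ValueError("min_obs_per_cell must be non-negative")
    if rate == 0.0:
        return table.copy()

    counts = table.groupby(["genotype", "environment", "trait"], observed=True).size()
    if (counts < min_obs_per_cell).any():
        raise ValueError(
            "min_obs_per_cell exceeds the observations available in some "
            "genotype x environment cell"
        )
    rng = np.random.default_rng(seed)
    u = rng.random(len(table))
    cell_key = pd.MultiIndex.from_frame(table[["genotype", "environment", "trait"]])
    remaining = counts.to_dict()
    keep = np.ones(len(table), dtype=bool)
    for pos, (key, drop) in enumerate(zip(cell_key, u < rate)):
        if drop and remaining[key] > min_obs_per_cell:
            keep[pos] = False
            remaining[key] -= 1
    return table.loc[keep].reset_index(drop=True)


def preset_variances(family: str, trait: str) -> dict[str, float]:
    """Variance components and mean implied by a published preset row.

    Returns ``sigma2_g``, ``sigma2_ge``, ``sigma2_e`` (phenotypic variance
    split by the published proportions) and ``mu`` recovered from the
    genotypic CV.
    """
    phen_var, h2, geir2, cvg = TABLE2_PRESETS[family][trait]
    s2g = h2 * phen_var
    s2ge = geir2 * phen_var
    s2e = max(phen_var - s2g - s2ge, 0.0)
    mu = 100.0 * np.sqrt(s2g) / cvg
    return {"sigma2_g": s2g, "sigma2_ge": s2ge, "sigma2_e": s2e, "mu": mu,
            "phenotypic_variance": phen_var}


def preset_config(
    family: str = "joint",
    n_genotypes: int | None = None,
    traits: list[str] | None = None,
    seed: int = 0,
    attrition_rate: float = 0.15,
    env_effect_scale: float = 0.5,
    block_effect_scale: float = 0.4,
) -> SimulationConfig:
    """Simulation configuration emulating one published family unit.

    Trait means, variance partitions and scale come from the preset registry;
    the genetic correlation uses :func:`default_genetic_correlation`.  Fixed
    environment shifts are +/- ``env_effect_scale``/2 phenotypic SDs (denser
    spacing depresses leaf traits and raises stomatal density); block shifts
    are drawn once, Gaussian with ``block_effect_scale`` phenotypic SDs.
    Default attrition (15%, floor of one observation per genotype x
    environment cell) leaves most genotypes with 2-6 surviving observations
    per trait, mirroring the survival range of the field trial.
    """
    traits = list(traits) if traits is not None else list(TRAITS)
    if n_genotypes is None:
        n_genotypes = FAMILY_SIZES[family]
    design = METDesign(n_genotypes=n_genotypes)
    pv = {t: preset_variances(family, t) for t in traits}
    sd_p = np.array([np.sqrt(pv[t]["phenotypic_variance"]) for t in traits])
    # E1 (dense spacing) lowers leaf/height traits and raises stomatal density.
    direction = np.array([-1.0 if t != "SD" else +1.0 for t in traits])
    env_effects = np.vstack([
        +0.5 * env_effect_scale * sd_p * direction,
        -0.5 * env_effect_scale * sd_p * direction,
    ])
    rng = np.random.default_rng(seed + 1_000_003)
    block_effects = rng.standard_normal((design.n_env * design.n_blocks, len(traits)))
    block_effects *= block_effect_scale * sd_p
    return SimulationConfig(
        design=design,
        trait_names=traits,
        trait_means=np.array([pv[t]["mu"] for t in traits]),
        sigma2_g=np.array([pv[t]["sigma2_g"] for t in traits]),
        sigma2_ge=np.array([pv[t]["sigma2_ge"] for t in traits]),
        sigma2_e=np.array([pv[t]["sigma2_e"] for t in traits]),
        genetic_correlation=default_genetic_correlation(traits).to_numpy(),
        env_effects=env_effects,
        block_effects=block_effects,
        attrition_rate=attrition_rate,
        min_obs_per_cell=1,
        seed=seed,
    )


#: Genotype-id prefixes of the three crosses, as used in progeny labels.
FAMILY_PREFIXES = {"1-XYxN139": "C2", "1-XYxN188": "C4", "ZL-3xN188": "E4"}


def simulate_study(
    seed: int = 0,
    n_genotypes: dict[str, int] | None = None,
    attrition_rate: float = 0.15,
) -> pd.DataFrame:
    """Simulate the full three-family two-spacing progeny trial.

    Each family is generated from its own preset (its published variance
    partition) and the tables are concatenated with family labels and
    family-prefixed genotype ids, giving one tidy table whose joint set of
    genotypes matches the pooled analysis unit.
    """
    sizes = {f: FAMILY_SIZES[f] for f in FAMILY_PREFIXES}
    if n_genotypes:
        sizes.update(n_genotypes)
    tables = []
    root = np.random.default_rng(seed)
    for fam, prefix in FAMILY_PREFIXES.items():
        cfg = preset_config(
            family=fam, n_genotypes=sizes[fam],
            seed=int(root.integers(2**31 - 1)),
            attrition_rate=attrition_rate,
        )
        t = simulate_met(cfg)
        t["genotype"] = prefix + "-" + t["genotype"].str.lstrip("G")
        t["family"] = fam
        tables.append(t)
    return pd.concat(tables, ignore_index=True)


def write_phenotypes(table: pd.DataFrame, path) -> None:
    """Write a tidy phenotype CSV (UTF-8, '.' decimal separator)."""
    table.to_csv(path, index=False)
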