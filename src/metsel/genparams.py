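"""Broad-sense genetic parameters from MET variance components.

For each trait the REML components (sigma2_g, sigma2_ge, sigma2_e) yield:

* h2      = sigma2_g  / (sigma2_g + sigma2_ge + sigma2_e)   broad-sense heritability
* geir2   = sigma2_ge / (sigma2_g + sigma2_ge + sigma2_e)   GEI determination
* h2mg    = sigma2_g / (sigma2_g + sigma2_ge/e + sigma2_e/(e*b))
            heritability on the genotype-mean basis across e environments
            and b blocks
* accuracy = sqrt(h2mg)                                      selection accuracy
* rge, CVg, CVr and their ratio.

The genotype-environment correlation ``rge`` deserves a note.  Two
definitions circulate: sigma2_g/(sigma2_g + sigma2_ge), and
sigma2_ge/(sigma2_ge + sigma2_e).  Published parameter tables for this kind
of trial are consistent only with the latter (which is also what the
upstream R tooling reports), so it is the default here; the former is
available as ``definition="genotypic"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixedmodel import VarianceComponents

__all__ = [
    "GeneticParameterSet",
    "compute_genetic_parameters",
    "parameters_from_proportions",
    "summarize_variance_proportions",
]

_PARAM_ORDER = [
    "phenotypic_variance", "heritability", "geir2", "h2mg", "accuracy",
    "rge", "cvg", "cvr", "cv_ratio",
]


@dataclass
class GeneticParameterSet:
    phenotypic_variance: float
    heritability: float
    geir2: float
    h2mg: float
    accuracy: float
    rge: float
    cvg: float
    cvr: float
    cv_ratio: float
    degenerate: bool = False

    def to_series(self, name: str | None = None) -> pd.Series:
        return pd.Series({k: getattr(self, k) for k in _PARAM_ORDER}, name=name)


def compute_genetic_parameters(
    vc: VarianceComponents, definition: str = "interaction"
) -> GeneticParameterSet:
    """Genetic-parameter bundle for one trait.

    ``definition`` selects the rge formula: ``"interaction"`` (default,
    sigma2_ge/(sigma2_ge + sigma2_e), consistent with published tables) or
    ``"genotypic"`` (sigma2_g/(sigma2_g + sigma2_ge)).

    All-zero variance components return zeros with ``degenerate=True``;
    a zero grand mean makes the CVs undefined and raises.
    """
    s2g, s2ge, s2e = vc.sigma2_g, vc.sigma2_ge, vc.sigma2_e
    e, b, mu = vc.n_env, vc.n_blocks, vc.grand_mean
    if min(s2g, s2ge, s2e) < 0:
        raise ValueError("variance components must be non-negative")
    phen = s2g + s2ge + s2e
    if phen == 0.0:
        return GeneticParameterSet(0, 0, 0, 0, 0, 0, 0, 0, 0, degenerate=True)
    if mu == 0.0:
        raise ValueError("grand mean is zero: coefficients of variation undefined")

    h2 = s2g / phen
    geir2 = s2ge / phen
    denom_mg = s2g + s2ge / e + s2e / (e * b)
    h2mg = s2g / denom_mg if denom_mg > 0 else 0.0
    accuracy = float(np.sqrt(h2mg))
    if definition == "interaction":
        rge = s2ge / (s2ge + s2e) if (s2ge + s2e) > 0 else 0.0
    elif definition == "genotypic":
        rge = s2g / (s2g + s2ge) if (s2g + s2ge) > 0 else 0.0
    else:
        raise ValueError(f"unknown rge definition {definition!r}")
    cvg = 100.0 * np.sqrt(s2g) / abs(mu)
    cvr = 100.0 * np.sqrt(s2e) / abs(mu)
    cv_ratio = cvg / cvr if cvr > 0 else np.inf
    return GeneticParameterSet(
        phenotypic_variance=phen, heritability=h2, geir2=geir2, h2mg=h2mg,
        accuracy=accuracy, rge=rge, cvg=float(cvg), cvr=float(cvr),
        cv_ratio=float(cv_ratio),
    )


def parameters_from_proportions(
    h2: float, geir2: float, n_env: int, n_blocks: int,
    phenotypic_variance: float = 1.0, grand_mean: float = 1.0,
    definition: str = "interaction",
) -> GeneticParameterSet:
    """Parameters recomputed from printed (h2, geir2) proportions.

    Convenience for arithmetic-consistency checks against published tables:
    proportions are turned back into variance components on an arbitrary
    scale (h2mg, accuracy and rge are scale-invariant).
    """
    if h2 < 0 or geir2 < 0 or h2 + geir2 > 1 + 1e-12:
        raise ValueError("h2 and geir2 must be non-negative with h2 + geir2 <= 1")
    vc = VarianceComponents(
        sigma2_g=h2 * phenotypic_variance,
        sigma2_ge=geir2 * phenotypic_variance,
        sigma2_e=max(1.0 - h2 - geir2, 0.0) * phenotypic_variance,
        grand_mean=grand_mean, n_env=n_env, n_blocks=n_blocks,
    )
    return compute_genetic_parameters(vc, definition=definition)


def summarize_variance_proportions(
    params: dict[str, GeneticParameterSet]
) -> pd.DataFrame:
    """Stacked variance proportions (GEN, GEN x ENV, residual) per trait.

    Rows ordered by trait name order of the input mapping; the three
    proportions sum to one by construction.
    """
    rows = {}
    for trait, ps in params.items():
        resid = 1.0 - ps.heritability - ps.geir2 if not ps.degenerate else 0.0
        rows[trait] = {"GEN": ps.heritability, "GEN x ENV": ps.geir2,
                       "residual": resid}
    return pd.DataFrame(rows).T[["GEN", "GEN x ENV", "residual"]]


def genetic_parameter_table(
    params: dict[str, GeneticParameterSet], traits: list[str] | None = None
) -> pd.DataFrame:
    """Published-style table: rows = parameters, columns = traits."""
    traits = traits or list(params)
    return pd.DataFrame({t: params[t].to_series() for t in traits})
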