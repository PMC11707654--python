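import numpy as np
import pandas as pd
import pytest

from metsel.simdata import METDesign, SimulationConfig, simulate_met


def make_config(g=60, e=2, b=3, s2g=0.4, s2ge=0.26, s2e=1.6, mu=10.0,
                seed=0, **kws) -> SimulationConfig:
    env_effects = None
    if e == 2:
        env_effects = np.array([[1.0], [-1.0]])
    return SimulationConfig(
        design=METDesign(g, environments=[f"E{j+1}" for j in range(e)], n_blocks=b),
        trait_names=["T"], trait_means=[mu],
        sigma2_g=[s2g], sigma2_ge=[s2ge], sigma2_e=[s2e],
        env_effects=env_effects, seed=seed, **kws)


@pytest.fixture
def balanced_table() -> pd.DataFrame:
    """Balanced single-trait MET: 60 genotypes x 2 environments x 3 blocks."""
    return simulate_met(make_config(seed=42))


def anova_oracle(table: pd.DataFrame, trait: str = "T") -> dict:
    """Closed-form balanced-ANOVA moment estimators, written independently
    of the package internals (pandas groupby arithmetic only):
    s2e = MSE, s2ge = (MS_GE - MSE)/b, s2g = (MS_G - MS_GE)/(b*e)."""
    sub = table[table.trait == trait]
    g = sub.genotype.nunique()
    e = sub.environment.nunique()
    b = sub.block.nunique()
    grand = sub.value.mean()
    gm = sub.groupby("genotype").value.mean()
    em = sub.groupby("environment").value.mean()
    cm = sub.groupby(["genotype", "environment"]).value.mean()
    ebm = sub.groupby(["environment", "block"]).value.mean()

    ms_g = e * b * ((gm - grand) ** 2).sum() / (g - 1)
    inter = cm - gm.reindex(cm.index, level=0) - em.reindex(cm.index, level=1) + grand
    ms_ge = b * (inter ** 2).sum() / ((g - 1) * (e - 1))
    resid = (sub.set_index(["genotype", "environment"]).value
             - cm.reindex(pd.MultiIndex.from_frame(sub[["genotype", "environment"]]))
             .to_numpy())
    blk_dev = (ebm - em.reindex(ebm.index, level=0)).reindex(
        pd.MultiIndex.from_frame(sub[["environment", "block"]])).to_numpy()
    rr = sub.value.to_numpy() - cm.reindex(
        pd.MultiIndex.from_frame(sub[["genotype", "environment"]])).to_numpy() - blk_dev
    mse = (rr ** 2).sum() / (len(sub) - g * e - e * (b - 1))
    return {
        "sigma2_e": mse,
        "sigma2_ge": (ms_ge - mse) / b,
        "sigma2_g": (ms_g - ms_ge) / (b * e),
        "ms_g": ms_g, "ms_ge": ms_ge, "mse": mse,
    }
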