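"""Shared fixtures: small synthetic OP trials reused across test modules."""

import warnings

import numpy as np
import pandas as pd
import pytest

import opvardec as ov


def make_trial(**overrides):
    """Simulate a small OP trial and prepare standardized data + kernels."""
    params = dict(
        n_families=15,
        offspring_per_family=20,
        n_markers=1500,
        pollen_pool_size=80,
        full_sib_excess=0.25,
        n_causal=200,
        missing_rate=0.0,
        seed=20_24,
    )
    params.update(overrides)
    cfg = ov.SimConfig(**params)
    ds = ov.simulate_population(cfg)
    y_std, site_stats = ov.standardize_phenotypes(ds.phenotypes, "trait")
    data = ds.phenotypes.copy()
    data["trait_std"] = y_std
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        kernels = ov.standard_kernels(ds.genotypes, ds.pedigree)
    return {"dataset": ds, "data": data, "kernels": kernels,
            "site_stats": site_stats, "config": cfg}


@pytest.fixture(scope="session")
def trial():
    """Default small trial: 15 families x 20 offspring, 1500 markers."""
    return make_trial()


@pytest.fixture(scope="session")
def trial_fits(trial):
    """ABLUP and GBLUP-A fits on the default small trial."""
    fits = {}
    for name in ("ABLUP", "GBLUP-A"):
        spec = ov.model_spec(name, trial["kernels"], trait="trait_std")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fits[name] = ov.reml_fit(spec, trial["data"])
    return fits


@pytest.fixture(scope="session")
def hwe_panel():
    """Unrelated individuals in Hardy-Weinberg proportions, many markers."""
    rng = np.random.default_rng(91)
    n, m = 150, 10_000
    p = rng.uniform(0.1, 0.5, m)
    codes = rng.binomial(2, p, size=(n, m)).astype(float)
    return ov.GenotypeMatrix(
        [f"i{i}" for i in range(n)], [f"m{j}" for j in range(m)], codes
    )


def toy_genotypes(codes, prefix="i"):
    codes = np.asarray(codes, dtype=float)
    return ov.GenotypeMatrix(
        [f"{prefix}{k}" for k in range(codes.shape[0])],
        [f"m{j}" for j in range(codes.shape[1])],
        codes,
    )


def fake_fit(components, residual, name="fake", ses=None, trait="trait_std"):
    """Construct a REMLFit carrying given variance components (for report
    arithmetic on printed values)."""
    ses = ses or {}
    spec = ov.ModelSpec(
        name, trait,
        [ov.RandomTerm(lab, None, "individual") for lab in components],
    )
    labels = list(components) + ["residual"]
    comps = {
        lab: ov.lmm.VarianceComponent(val, ses.get(lab, 0.0), pinned=(val == 0))
        for lab, val in components.items()
    }
    return ov.REMLFit(
        spec=spec,
        components=comps,
        residual=ov.lmm.VarianceComponent(residual, ses.get("residual", 0.0)),
        fixed_effects=pd.DataFrame({"estimate": [0.0], "se": [0.0]},
                                   index=["intercept"]),
        loglik=0.0,
        loglik_trace=[0.0],
        converged=True,
        n_iter=1,
        n_obs=0,
        vcov=pd.DataFrame(np.zeros((len(labels),) * 2), index=labels,
                          columns=labels),
    )
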