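"""Variance reporting, heritabilities and cross-validated prediction.

Derived quantities
------------------
* percentage of total variance per component (total includes block and
  residual, so the percentages sum to 100);
* narrow-sense heritability h2 = sigma2_a / sigma2_p, with the phenotypic
  variance sigma2_p the sum of every component *except* block(site);
* broad-sense heritability H2 = (sum of genetic components) / sigma2_p,
  defined only when nonadditive genetic terms are in the model;
* model fit R2 (percent) = 100 - residual percentage;
* combined G-by-E percentage = axe% + dxe%.

Cross-validation
----------------
k-fold with two folding schemes: ``random`` (individuals partitioned at
random, so relatives bridge training and validation) and ``family``
(entire maternal families held out together, removing relatedness between
training and validation). Predictability is the Pearson correlation between
cross-validated predicted breeding values (PBV-CV) and the (standardized)
phenotype; prediction accuracy is the Pearson correlation between PBV-CV
and the breeding values estimated from the full data (EBV-all). Metric SEs
are the standard deviation of the replicate means over sqrt(replicates).

A pedigree model under family folding predicts every held-out individual at
the overall model mean (zero relatedness to training), so its PBV-CV vector
is constant and the metrics are reported as undefined (NA), not numeric.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import ModelSpec, REMLFit, REMLOptions, predict_masked, reml_fit

__all__ = [
    "VarianceReport",
    "CVConfig",
    "CVResult",
    "variance_report",
    "gxe_percent",
    "additive_shrinkage_ratio",
    "make_folds",
    "cross_validate",
    "pairwise_accuracy",
]

_GENETIC = ("a", "d", "axa", "dxd", "axd")
_NONADDITIVE = ("d", "axa", "dxd", "axd")
_GXE = ("axe", "dxe")
_BLOCK = "r(s)"


@dataclass
class VarianceReport:
    table: pd.DataFrame  # index component; columns estimate, se, percent
    h2: tuple[float, float]  # (estimate, se)
    H2: tuple[float, float] | None
    r2_percent: float

    @property
    def percents(self) -> pd.Series:
        return self.table["percent"]


def variance_report(fit: REMLFit) -> VarianceReport:
    """Summarize a fit as component percentages, h2, H2 and R2."""
    labels = list(fit.components) + ["residual"]
    est = np.array(
        [fit.components[k].estimate for k in fit.components]
        + [fit.residual.estimate]
    )
    se = np.array(
        [fit.components[k].se for k in fit.components] + [fit.residual.se]
    )
    total = est.sum()
    if total <= 0:
        raise ValueError("total variance is zero; nothing to report")
    percent = 100.0 * est / total
    table = pd.DataFrame(
        {"estimate": est, "se": se, "percent": percent}, index=labels
    )

    # phenotypic variance excludes the design (block) component
    pheno_idx = [k for k in labels if k != _BLOCK]
    sigma_p = float(table.loc[pheno_idx, "estimate"].sum())
    sigma_a = float(table.loc["a", "estimate"]) if "a" in labels else 0.0
    h2 = sigma_a / sigma_p

    # delta-method SE of the ratio using the AI covariance of the components
    vcov = fit.vcov.reindex(index=labels, columns=labels).fillna(0.0).to_numpy()
    grad = np.zeros(len(labels))
    for i, lab in enumerate(labels):
        if lab == _BLOCK:
            continue
        grad[i] = -sigma_a / sigma_p**2
        if lab == "a":
            grad[i] += 1.0 / sigma_p
    h2_se = float(np.sqrt(max(grad @ vcov @ grad, 0.0)))

    H2: tuple[float, float] | None = None
    if any(k in labels for k in _NONADDITIVE):
        genetic = [k for k in _GENETIC if k in labels]
        sigma_g = float(table.loc[genetic, "estimate"].sum())
        gradH = np.zeros(len(labels))
        for i, lab in enumerate(labels):
            if lab == _BLOCK:
                continue
            gradH[i] = -sigma_g / sigma_p**2
            if lab in genetic:
                gradH[i] += 1.0 / sigma_p
        H2 = (
            sigma_g / sigma_p,
            float(np.sqrt(max(gradH @ vcov @ gradH, 0.0))),
        )

    r2 = 100.0 - float(table.loc["residual", "percent"])
    return VarianceReport(table=table, h2=(h2, h2_se), H2=H2, r2_percent=r2)


def gxe_percent(report: VarianceReport) -> float:
    """Total genotype-by-environment share: axe% + dxe%."""
    return float(
        sum(report.table.loc[k, "percent"] for k in _GXE if k in report.table.index)
    )


def additive_shrinkage_ratio(fit_ref: REMLFit, fit_alt: REMLFit) -> float:
    """100 x sigma2_a(alt) / sigma2_a(ref), e.g. GBLUP-A relative to ABLUP."""
    ref = fit_ref.components["a"]
    if ref.pinned or ref.estimate <= 0:
        raise ValueError("reference additive variance is at the floor; ratio undefined")
    return 100.0 * fit_alt.components["a"].estimate / ref.estimate


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVConfig:
    k: int = 10
    replicates: int = 5
    scheme: str = "random"  # 'random' | 'family'
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.scheme not in ("random", "family"):
            raise ValueError(f"unknown folding scheme {self.scheme!r}")


def make_folds(
    individuals: pd.Series | list,
    families: pd.Series | list,
    config: CVConfig,
) -> list[np.ndarray]:
    """Fold assignment per individual for each replicate.

    Random folding partitions individuals into k near-equal folds; family
    folding shuffles the families and deals them round-robin to folds, so no
    family ever spans folds. Deterministic per (seed, replicate).
    """
    individuals = np.asarray(individuals, dtype=object)
    families = np.asarray(families, dtype=object)
    n = len(individuals)
    if config.scheme == "family":
        n_fam = len(pd.unique(families))
        if n_fam < config.k:
            raise ValueError(
                f"family folding needs >= {config.k} families, got {n_fam}"
            )
    out = []
    for rep in range(config.replicates):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, rep]))
        assign = np.empty(n, dtype=int)
        if config.scheme == "random":
            perm = rng.permutation(n)
            for fold, chunk in enumerate(np.array_split(perm, config.k)):
                assign[chunk] = fold
        else:
            fams = pd.unique(families)
            shuffled = rng.permutation(fams)
            fam_fold = {
                fam: i % config.k for i, fam in enumerate(shuffled)
            }
            assign = np.array([fam_fold[f] for f in families], dtype=int)
        out.append(assign)
    return out


@dataclass
class CVResult:
    model: str
    scheme: str
    pbv_cv: pd.DataFrame  # individuals x replicates
    predictability: tuple[float, float]  # mean, se over replicates (NaN if NA)
    accuracy: tuple[float, float]
    per_replicate: pd.DataFrame  # columns predictability, accuracy
    ebv_all: pd.Series
    undefined_reason: str | None = None


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) < 1e-12 or np.std(b) < 1e-12:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def cross_validate(
    spec: ModelSpec,
    data: pd.DataFrame,
    config: CVConfig,
    reestimate: bool = True,
    full_fit: REMLFit | None = None,
    options: REMLOptions | None = None,
) -> CVResult:
    """k-fold cross-validated breeding-value prediction.

    Each fold's phenotypes are masked and the model refit on the remaining
    records (variance components re-estimated unless ``reestimate=False``,
    in which case the full-data estimates are reused and only the BLUP
    system is re-solved). PBV-CV collects, per replicate, each individual's
    predicted additive BV from the fold in which it was held out.
    """
    if full_fit is None:
        full_fit = reml_fit(spec, data, options=options, compute_sep=False)
    ebv_all = full_fit.blup["a"].reindex(
        data["individual"].astype(str)
    )
    folds = make_folds(
        data["individual"].astype(str), data["family"].astype(str), config
    )
    y_std = data[spec.trait].astype(float).to_numpy()
    ids = data["individual"].astype(str).to_numpy()

    fixed = full_fit.variance_estimates if not reestimate else None
    pbv = pd.DataFrame(
        np.nan, index=ids, columns=[f"rep{r + 1}" for r in range(config.replicates)]
    )
    rows = []
    for rep, assign in enumerate(folds):
        for fold in range(config.k):
            val = assign == fold
            if not val.any():
                continue
            masked = data.copy()
            masked.loc[masked.index[val], spec.trait] = np.nan
            pred, _ = predict_masked(
                spec, masked, options=options, fix_components=fixed
            )
            pbv.iloc[val, rep] = pred.reindex(ids[val]).to_numpy()
        col = pbv.iloc[:, rep].to_numpy()
        rows.append(
            {
                "predictability": _safe_corr(col, y_std),
                "accuracy": _safe_corr(col, ebv_all.to_numpy()),
            }
        )
    per_rep = pd.DataFrame(rows, index=pbv.columns)

    reason = None
    if per_rep.isna().any().any():
        reason = (
            "predicted breeding values are constant within a replicate "
            "(no kernel relatedness between training and validation); the "
            "prediction equals the overall model mean"
        )

    def mean_se(col: pd.Series) -> tuple[float, float]:
        if col.isna().any():
            return (float("nan"), float("nan"))
        return (
            float(col.mean()),
            float(col.std(ddof=1) / math.sqrt(len(col))) if len(col) > 1 else 0.0,
        )

    return CVResult(
        model=spec.name,
        scheme=config.scheme,
        pbv_cv=pbv,
        predictability=mean_se(per_rep["predictability"]),
        accuracy=mean_se(per_rep["accuracy"]),
        per_replicate=per_rep,
        ebv_all=pd.Series(ebv_all.to_numpy(), index=ids, name="ebv_all"),
        undefined_reason=reason,
    )


def pairwise_accuracy(results: dict[str, CVResult]) -> pd.DataFrame:
    """Model-by-model accuracy table.

    Cell (i, j) is the Pearson correlation between model i's PBV-CV and
    model j's EBV-all, averaged over replicates; the diagonal is each
    model's own prediction accuracy.
    """
    names = list(results)
    table = pd.DataFrame(np.nan, index=names, columns=names)
    for i in names:
        ri = results[i]
        for j in names:
            ej = results[j].ebv_all.reindex(ri.pbv_cv.index).to_numpy()
            cors = [
                _safe_corr(ri.pbv_cv[c].to_numpy(), ej) for c in ri.pbv_cv.columns
            ]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                table.loc[i, j] = float(np.nanmean(cors)) if not all(
                    np.isnan(c) for c in cors
                ) else float("nan")
    return table
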