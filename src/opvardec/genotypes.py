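"""SNP genotype matrix container, quality filtering and EM imputation.

Genotypes are coded as counts of the alternative allele (0, 1, 2); missing
calls are NaN. After imputation entries may be fractional but stay in [0, 2].
The QC pipeline mirrors common GBS practice for open-pollinated progeny
trials: retain the individuals with the least missing data, drop markers with
too much missingness, then impute the remainder with an
expectation-maximization algorithm on the marker covariance (so imputed calls
borrow information from correlated markers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = [
    "GenotypeMatrix",
    "MarkerStats",
    "ImputationLog",
    "read_genotypes",
    "write_genotypes",
    "filter_individuals_by_missingness",
    "filter_markers_by_missingness",
    "allele_frequencies",
    "em_impute",
    "mean_impute",
]


@dataclass
class GenotypeMatrix:
    """Individuals x markers matrix of alternative-allele counts.

    ``codes`` is a float array; missing entries are NaN. Identifiers are
    unique and ordered; row/column order is meaningful and preserved by all
    filters.
    """

    individual_ids: list[str]
    marker_ids: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.individual_ids), len(self.marker_ids)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.marker_ids)} markers"
            )
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")
        finite = self.codes[~np.isnan(self.codes)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("genotype codes must lie in [0, 2] (or NaN)")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.codes)

    def is_complete(self) -> bool:
        return not np.isnan(self.codes).any()

    def individual_missing_rates(self) -> np.ndarray:
        return self.missing_mask.mean(axis=1)

    def marker_missing_rates(self) -> np.ndarray:
        return self.missing_mask.mean(axis=0)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.individual_ids), list(self.marker_ids), self.codes.copy()
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.codes, index=self.individual_ids, columns=self.marker_ids
        )


class MarkerStats(NamedTuple):
    marker_id: str
    missing_rate: float
    p: float


@dataclass
class ImputationLog:
    method: str
    n_imputed: int
    n_iter: int = 0
    final_change: float = float("nan")
    converged: bool = True
    loglik_trace: list[float] = field(default_factory=list)


_NA_TOKENS = {"NA", "NaN", "nan", "", "na", "N/A"}


def read_genotypes(path, dialect: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from delimited text.

    ``dialect`` is one of ``tsv`` / ``csv`` (first column = individual id,
    header row = marker ids) or ``plink-raw`` (whitespace-delimited PLINK
    ``.raw``-style layout with FID IID PAT MAT SEX PHENOTYPE lead columns).
    """
    if dialect in ("tsv", "csv"):
        sep = "\t" if dialect == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                         keep_default_na=False)
        ind_ids = [str(i) for i in df.index]
        marker_ids = [str(c) for c in df.columns]
        raw = df.to_numpy()
    elif dialect in ("plink-raw", "plink-raw-like"):
        df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
        lead = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        missing_cols = [c for c in lead if c not in df.columns]
        if missing_cols:
            raise ValueError(f"plink-raw file lacks columns {missing_cols}")
        ind_ids = [str(i) for i in df["IID"]]
        marker_ids = [c for c in df.columns if c not in lead]
        raw = df[marker_ids].to_numpy()
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    codes = np.empty(raw.shape, dtype=float)
    for j in range(raw.shape[1]):
        col = raw[:, j]
        for i, tok in enumerate(col):
            tok = tok.strip()
            if tok in _NA_TOKENS:
                codes[i, j] = np.nan
                continue
            try:
                val = float(tok)
            except ValueError:
                raise ValueError(
                    f"invalid genotype token {tok!r} at individual "
                    f"{ind_ids[i]!r}, marker {marker_ids[j]!r}"
                ) from None
            if not 0.0 <= val <= 2.0:
                raise ValueError(
                    f"genotype value {val} out of [0, 2] at individual "
                    f"{ind_ids[i]!r}, marker {marker_ids[j]!r}"
                )
            codes[i, j] = val
    return GenotypeMatrix(ind_ids, marker_ids, codes)


def write_genotypes(matrix: GenotypeMatrix, path, dialect: str = "tsv") -> None:
    """Write a genotype matrix as delimited text; missing entries become NA.

    Integer-valued codes are written without a decimal point so that
    ``read_genotypes(write_genotypes(x)) == x`` holds bit-for-bit.
    """
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"unsupported output dialect {dialect!r}")
    sep = "\t" if dialect == "tsv" else ","

    def fmt(v: float) -> str:
        if np.isnan(v):
            return "NA"
        if float(v).is_integer():
            return str(int(v))
        return repr(float(v))

    with open(path, "w") as fh:
        fh.write("id" + sep + sep.join(matrix.marker_ids) + "\n")
        for i, ind in enumerate(matrix.individual_ids):
            row = matrix.codes[i]
            fh.write(ind + sep + sep.join(fmt(v) for v in row) + "\n")


def filter_individuals_by_missingness(g: GenotypeMatrix, keep_n: int) -> GenotypeMatrix:
    """Retain the ``keep_n`` individuals with the lowest missing rate.

    Ties are broken by input order and the original order is preserved among
    the survivors (stable selection).
    """
    if not 1 <= keep_n <= g.n_individuals:
        raise ValueError(f"keep_n must be in [1, {g.n_individuals}], got {keep_n}")
    rates = g.individual_missing_rates()
    order = np.argsort(rates, kind="stable")[:keep_n]
    keep = np.sort(order)
    return GenotypeMatrix(
        [g.individual_ids[i] for i in keep],
        list(g.marker_ids),
        g.codes[keep, :].copy(),
    )


def filter_markers_by_missingness(
    g: GenotypeMatrix, max_missing: float = 0.30
) -> GenotypeMatrix:
    """Keep markers whose missing rate is strictly below ``max_missing``."""
    if not 0 < max_missing <= 1:
        raise ValueError(f"max_missing must be in (0, 1], got {max_missing}")
    n = g.n_individuals
    counts = g.missing_mask.sum(axis=0)
    # strict "<" on the exact fraction; guard float noise at the boundary
    rates = counts / n
    keep = (rates < max_missing) & ~np.isclose(rates, max_missing)
    if not keep.any():
        raise ValueError(
            f"no markers survive the {max_missing:.0%} missingness filter; "
            "raise the threshold"
        )
    idx = np.flatnonzero(keep)
    return GenotypeMatrix(
        list(g.individual_ids),
        [g.marker_ids[j] for j in idx],
        g.codes[:, idx].copy(),
    )


def allele_frequencies(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker alternative-allele frequency and missing rate.

    ``p`` is computed from non-missing calls only: sum of codes divided by
    twice the number of observed calls. Returns a DataFrame indexed by marker
    with columns ``p`` and ``missing_rate``.
    """
    obs = ~g.missing_mask
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        bad = [g.marker_ids[j] for j in np.flatnonzero(n_obs == 0)]
        raise ValueError(f"markers with no observed calls: {bad[:5]}")
    sums = np.nansum(g.codes, axis=0)
    p = sums / (2.0 * n_obs)
    return pd.DataFrame(
        {"p": p, "missing_rate": g.marker_missing_rates()}, index=g.marker_ids
    )


def marker_stats(g: GenotypeMatrix) -> list[MarkerStats]:
    freqs = allele_frequencies(g)
    return [
        MarkerStats(m, float(freqs.loc[m, "missing_rate"]), float(freqs.loc[m, "p"]))
        for m in g.marker_ids
    ]


def mean_impute(g: GenotypeMatrix) -> tuple[GenotypeMatrix, ImputationLog]:
    """Replace each missing call by its marker mean (2 * p-hat)."""
    out = g.copy()
    mask = out.missing_mask
    if mask.any():
        means = np.nanmean(out.codes, axis=0)
        idx = np.where(mask)
        out.codes[idx] = means[idx[1]]
    return out, ImputationLog(method="mean", n_imputed=int(mask.sum()))


def em_impute(
    g: GenotypeMatrix,
    max_iter: int = 100,
    tol: float = 1e-4,
    ridge: float = 0.0,
) -> tuple[GenotypeMatrix, ImputationLog]:
    """Impute missing genotypes with a multivariate-normal EM algorithm.

    Individuals are treated as i.i.d. draws from N(mu, Sigma) over markers;
    the marker mean vector and marker-by-marker covariance are re-estimated
    each iteration, so imputed calls exploit correlation (LD) between
    markers. Observed entries are never altered. Iteration stops when the
    largest absolute change in an imputed value drops below ``tol`` or after
    ``max_iter`` iterations. Imputed values are clamped to [0, 2] on output.

    The observed-data log-likelihood is tracked per iteration (monotone
    non-decreasing for the exact EM, i.e. ``ridge=0``). A positive ``ridge``
    adds a diagonal stabiliser to Sigma for p >= n panels at the cost of
    exact monotonicity.

    Cost is cubic in the number of markers per distinct missingness pattern;
    intended for the filtered, desk-scale marker panels used here.
    """
    for dim, rates in (("individual", g.individual_missing_rates()),
                       ("marker", g.marker_missing_rates())):
        if (rates >= 1.0).any():
            raise ValueError(f"every {dim} needs at least one observed call")

    out = g.copy()
    mask = out.missing_mask
    n_missing = int(mask.sum())
    if n_missing == 0:
        return out, ImputationLog(method="em", n_imputed=0, n_iter=0,
                                  final_change=0.0)

    X = out.codes
    n, p = X.shape
    col_means = np.nanmean(X, axis=0)
    fill = np.where(mask, col_means[None, :], X)

    # group rows by missingness pattern to reuse factorizations
    patterns: dict[bytes, list[int]] = {}
    for i in range(n):
        patterns.setdefault(mask[i].tobytes(), []).append(i)

    loglik_trace: list[float] = []
    final_change = np.inf
    converged = False
    n_iter = 0
    # accumulated conditional covariance from the previous E-step; the exact
    # M-step is Sigma = (1/n) [ sum (xhat_i - mu)(xhat_i - mu)' + sum C_i ]
    cond_cov = np.zeros((p, p))
    # sticky stabiliser: raised (once) if Sigma turns out singular, e.g. for
    # perfectly collinear markers, then applied consistently so the EM stays
    # (near-)monotone for the stabilised model
    auto_ridge = ridge
    for n_iter in range(1, max_iter + 1):
        mu = fill.mean(axis=0)
        centered = fill - mu
        sigma = centered.T @ centered / n + cond_cov / n
        while True:
            try:
                linalg.cho_factor(sigma + auto_ridge * np.eye(p), lower=True)
                break
            except linalg.LinAlgError:
                auto_ridge = max(auto_ridge * 10, 1e-10 * np.trace(sigma) / p)
        if auto_ridge > 0:
            sigma = sigma + auto_ridge * np.eye(p)

        new_fill = fill.copy()
        cond_cov_acc = np.zeros((p, p))
        loglik = 0.0
        for key, rows in patterns.items():
            miss = np.frombuffer(key, dtype=bool)
            obs = ~miss
            xo = fill[rows][:, obs]
            s_oo = sigma[np.ix_(obs, obs)]
            cf = linalg.cho_factor(s_oo, lower=True)
            resid = xo - mu[obs]
            solved = linalg.cho_solve(cf, resid.T)  # (n_obs, len(rows))
            logdet = 2.0 * np.log(np.diag(cf[0])).sum()
            quad = np.einsum("ij,ji->i", resid, solved)
            loglik += -0.5 * (
                len(rows) * (obs.sum() * np.log(2 * np.pi) + logdet) + quad.sum()
            )
            if miss.any():
                s_mo = sigma[np.ix_(miss, obs)]
                imputed = mu[miss] + (s_mo @ solved).T
                new_fill[np.ix_(rows, miss)] = imputed
                # conditional covariance, shared by all rows with this pattern
                cond = sigma[np.ix_(miss, miss)] - s_mo @ linalg.cho_solve(cf, s_mo.T)
                block = np.zeros((p, p))
                block[np.ix_(miss, miss)] = cond * len(rows)
                cond_cov_acc += block
        loglik_trace.append(float(loglik))

        final_change = float(np.max(np.abs(new_fill[mask] - fill[mask])))
        fill = new_fill
        cond_cov = cond_cov_acc
        if final_change < tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"EM imputation did not converge in {max_iter} iterations "
            f"(last max change {final_change:.3g})",
            RuntimeWarning,
        )

    out.codes[mask] = np.clip(fill[mask], 0.0, 2.0)
    return out, ImputationLog(
        method="em",
        n_imputed=n_missing,
        n_iter=n_iter,
        final_change=final_change,
        converged=converged,
        loglik_trace=loglik_trace,
    )
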