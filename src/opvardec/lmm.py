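"""Multi-environment linear mixed models over relationship kernels.

Fits models of the form

    y = X beta + sum_k Z_k u_k + e,   u_k ~ N(0, K_k sigma2_k),  e ~ N(0, I sigma2_e)

by restricted maximum likelihood, where the K_k are arbitrary positive
(semi-)definite kernels: the pedigree numerator matrix, genomic additive and
dominance matrices, their Hadamard epistatic products, genotype-by-site
interaction kernels and the block-within-site design kernel. The four named
model specs are

* ``ABLUP``      — a (pedigree A), axe, r(s)
* ``GBLUP-A``    — a (G_add), axe, r(s)
* ``GBLUP-AD``   — + d (G_dom), dxe
* ``GBLUP-ADE``  — + axa, dxd, axd (Hadamard kernels)

Phenotypes are standardized within site before modeling (heterogeneous
variance across environments), fixed effects are the overall mean and site,
and blocks are random, nested within site.

A note on the G-by-E terms: each tree grows at exactly one site, so a
genotype-by-site effect with an *identity* covariance over trees would be
indistinguishable from the residual. The axe/dxe terms here therefore carry
the covariance K ∘ S — the genetic kernel restricted to pairs at the same
site (equivalently I_sites ⊗ K on the observed layout) — which is the
block-diagonal G×E structure that makes sigma2_axe estimable from the
relatedness contrast between same-site and cross-site relatives. Passing
``kernel=None`` in a RandomTerm still gives the literal identity covariance.

Estimation is average-information REML with expectation-maximization
fallback steps and a variance floor; components pinned at the floor are
reported as 0 with SE 0 (the boundary convention used by standard REML
software). Standard errors come from the inverse average-information matrix
at convergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .kinship import RelationshipMatrix

__all__ = [
    "RandomTerm",
    "ModelSpec",
    "VarianceComponent",
    "REMLFit",
    "REMLOptions",
    "MODEL_NAMES",
    "model_spec",
    "standardize_phenotypes",
    "reml_fit",
    "blup_and_sep",
    "predict_masked",
]

MODEL_NAMES = ("ABLUP", "GBLUP-A", "GBLUP-AD", "GBLUP-ADE")


@dataclass
class RandomTerm:
    """One random effect: a label, a kernel and how levels map to data.

    grouping:
      * ``individual`` — one level per kernel id (or per individual if the
        kernel is None); covariance K.
      * ``individual_within_site`` — one level per individual; covariance
        K ∘ same-site indicator (identity within the term if kernel is None).
      * ``block_within_site`` — one level per (site, block) cell; identity
        covariance.
    """

    label: str
    kernel: RelationshipMatrix | None = None
    grouping: str = "individual"

    def __post_init__(self) -> None:
        if self.grouping not in (
            "individual",
            "individual_within_site",
            "block_within_site",
        ):
            raise ValueError(f"unknown grouping {self.grouping!r}")


@dataclass
class ModelSpec:
    name: str
    trait: str
    random_terms: list[RandomTerm]
    fixed_terms: tuple[str, ...] = ("intercept", "site")

    def __post_init__(self) -> None:
        labels = [t.label for t in self.random_terms]
        if len(set(labels)) != len(labels):
            raise ValueError("random term labels must be unique")


def model_spec(
    name: str, kernels: dict[str, RelationshipMatrix], trait: str = "trait"
) -> ModelSpec:
    """Construct one of the four canonical model specifications."""
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    gen = kernels["A"] if name == "ABLUP" else kernels["G_add"]
    terms = [RandomTerm("a", gen, "individual")]
    if name in ("GBLUP-AD", "GBLUP-ADE"):
        terms.append(RandomTerm("d", kernels["G_dom"], "individual"))
    if name == "GBLUP-ADE":
        terms.append(RandomTerm("axa", kernels["AxA"], "individual"))
        terms.append(RandomTerm("dxd", kernels["DxD"], "individual"))
        terms.append(RandomTerm("axd", kernels["AxD"], "individual"))
    terms.append(RandomTerm("axe", gen, "individual_within_site"))
    if name in ("GBLUP-AD", "GBLUP-ADE"):
        terms.append(RandomTerm("dxe", kernels["G_dom"], "individual_within_site"))
    terms.append(RandomTerm("r(s)", None, "block_within_site"))
    return ModelSpec(name=name, trait=trait, random_terms=terms)


def standardize_phenotypes(
    phenotypes: pd.DataFrame, trait: str, site_col: str = "site"
) -> tuple[pd.Series, pd.DataFrame]:
    """Z-score the trait within each site.

    Returns the standardized series (aligned to the input index; missing
    values stay missing) and per-site (mean, sd, n) statistics for
    back-transformation.
    """
    y = phenotypes[trait].astype(float)
    out = pd.Series(np.nan, index=phenotypes.index, name=f"{trait}_std")
    stats = []
    for site, idx in phenotypes.groupby(site_col).groups.items():
        vals = y.loc[idx]
        obs = vals.dropna()
        if len(obs) < 2:
            raise ValueError(f"site {site!r} has fewer than 2 phenotyped trees")
        mu, sd = float(obs.mean()), float(obs.std(ddof=1))
        if sd == 0:
            raise ValueError(f"site {site!r} has zero phenotypic variance")
        out.loc[idx] = (vals - mu) / sd
        stats.append({"site": site, "mean": mu, "sd": sd, "n": len(obs)})
    return out, pd.DataFrame(stats).set_index("site")


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


@dataclass
class _TermDesign:
    label: str
    level_ids: list
    K: np.ndarray        # n_levels x n_levels covariance among levels
    Z: np.ndarray        # n_obs x n_levels incidence
    Q: np.ndarray        # Z K Z', n_obs x n_obs

    @property
    def q(self) -> int:
        return len(self.level_ids)


def _build_designs(
    spec: ModelSpec, data: pd.DataFrame, obs: np.ndarray
) -> list[_TermDesign]:
    ind = data["individual"].astype(str).to_numpy()
    if len(set(ind)) != len(ind):
        raise ValueError("data must contain one row per individual")
    site = data["site"].astype(str).to_numpy()
    obs_ind = ind[obs]
    designs = []
    for term in spec.random_terms:
        if term.grouping == "block_within_site":
            cells = (site + "//" + data["block"].astype(str).to_numpy())
            level_ids = sorted(set(cells))
            pos = {c: i for i, c in enumerate(level_ids)}
            Z = np.zeros((obs.sum(), len(level_ids)))
            Z[np.arange(obs.sum()), [pos[c] for c in cells[obs]]] = 1.0
            K = np.eye(len(level_ids))
        else:
            if term.kernel is not None:
                level_ids = list(term.kernel.individual_ids)
                missing = set(ind) - set(level_ids)
                if missing:
                    raise ValueError(
                        f"kernel for term {term.label!r} lacks individuals "
                        f"{sorted(missing)[:5]}"
                    )
                K = term.kernel.values
            else:
                level_ids = list(ind)
                K = np.eye(len(level_ids))
            if term.grouping == "individual_within_site":
                # restrict the kernel to same-site pairs; levels keep the
                # kernel's id universe, sites taken from the design table
                site_of = dict(zip(ind, site))
                lv_site = np.array([site_of.get(i, "__unplaced__") for i in level_ids])
                same = lv_site[:, None] == lv_site[None, :]
                same &= lv_site[:, None] != "__unplaced__"
                K = np.where(same, K, 0.0)
                np.fill_diagonal(K, np.diag(term.kernel.values if term.kernel
                                            is not None else K))
            pos = {v: i for i, v in enumerate(level_ids)}
            Z = np.zeros((obs.sum(), len(level_ids)))
            Z[np.arange(obs.sum()), [pos[i] for i in obs_ind]] = 1.0
        Q = Z @ K @ Z.T
        designs.append(_TermDesign(term.label, level_ids, K, Z, Q))
    return designs


def _fixed_design(data: pd.DataFrame, obs: np.ndarray) -> tuple[np.ndarray, list[str]]:
    site = pd.Categorical(data["site"].astype(str).to_numpy()[obs])
    cols = [np.ones(obs.sum())]
    names = ["intercept"]
    for lev in site.categories[1:]:
        cols.append((site == lev).astype(float))
        names.append(f"site[{lev}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design matrix is singular")
    return X, names


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------


@dataclass
class REMLOptions:
    max_iter: int = 200
    tol_loglik: float = 1e-8
    tol_param: float = 1e-6
    floor_frac: float = 1e-8
    verbose: bool = False


@dataclass
class VarianceComponent:
    estimate: float
    se: float
    pinned: bool = False


@dataclass
class REMLFit:
    spec: ModelSpec
    components: dict[str, VarianceComponent]
    residual: VarianceComponent
    fixed_effects: pd.DataFrame
    loglik: float
    loglik_trace: list[float]
    converged: bool
    n_iter: int
    n_obs: int
    vcov: pd.DataFrame
    blup: dict[str, pd.Series] = field(default_factory=dict)
    sep: dict[str, pd.Series] = field(default_factory=dict)
    # internals for blup_and_sep / diagnostics
    _designs: list[_TermDesign] | None = field(default=None, repr=False)
    _P: np.ndarray | None = field(default=None, repr=False)
    _Py: np.ndarray | None = field(default=None, repr=False)
    _obs_ids: list[str] | None = field(default=None, repr=False)

    @property
    def variance_estimates(self) -> dict[str, float]:
        out = {k: v.estimate for k, v in self.components.items()}
        out["residual"] = self.residual.estimate
        return out


class _LikEval:
    def __init__(self, ll, P, Py, beta, beta_cov):
        self.ll, self.P, self.Py, self.beta, self.beta_cov = ll, P, Py, beta, beta_cov


def _evaluate(theta: np.ndarray, Qs: list[np.ndarray], y, X) -> _LikEval:
    n = len(y)
    V = theta[-1] * np.eye(n)
    for t, Q in zip(theta[:-1], Qs):
        V += t * Q
    jitter = 0.0
    for _ in range(4):
        try:
            cf = linalg.cho_factor(V + jitter * np.eye(n), lower=True)
            break
        except linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-10 * np.trace(V) / n)
    else:  # pragma: no cover - pathological
        raise linalg.LinAlgError("V not positive definite")
    logdetV = 2.0 * np.log(np.diag(cf[0])).sum()
    Vinv = linalg.cho_solve(cf, np.eye(n))
    W = Vinv @ X
    C = X.T @ W
    cC = linalg.cho_factor(C, lower=True)
    logdetC = 2.0 * np.log(np.diag(cC[0])).sum()
    beta = linalg.cho_solve(cC, W.T @ y)
    beta_cov = linalg.cho_solve(cC, np.eye(C.shape[0]))
    P = Vinv - W @ linalg.cho_solve(cC, W.T)
    P = 0.5 * (P + P.T)
    Py = P @ y
    ll = -0.5 * (logdetV + logdetC + float(y @ Py))
    return _LikEval(ll, P, Py, beta, beta_cov)


def reml_log_likelihood(
    theta: Sequence[float], Qs: list[np.ndarray], y: np.ndarray, X: np.ndarray
) -> float:
    """REML log-likelihood at a given set of variances (terms..., residual)."""
    return _evaluate(np.asarray(theta, dtype=float), Qs, y, X).ll


def _aireml(
    y: np.ndarray,
    X: np.ndarray,
    Qs: list[np.ndarray],
    q_levels: list[int],
    opts: REMLOptions,
    theta0: np.ndarray | None = None,
):
    n = len(y)
    K = len(Qs)
    vary = float(np.var(y, ddof=1)) if n > 1 else 0.0
    floor = opts.floor_frac * vary
    theta = (
        np.asarray(theta0, dtype=float)
        if theta0 is not None
        else np.full(K + 1, vary / (K + 1))
    )
    theta = np.maximum(theta, floor)
    pinned = np.zeros(K + 1, dtype=bool)
    QsI = Qs + [np.eye(n)]
    qlev = list(q_levels) + [n]

    state = _evaluate(theta, Qs, y, X)
    trace = [state.ll]
    converged = False
    n_iter = 0

    def stats(st):
        trPQ = np.array([np.sum(st.P * Q) for Q in QsI])
        T = np.column_stack([Q @ st.Py for Q in QsI])
        yPQPy = st.Py @ T
        return trPQ, T, yPQPy

    at_floor = lambda t: t <= floor * (1 + 1e-9)  # noqa: E731
    for n_iter in range(1, opts.max_iter + 1):
        trPQ, T, yPQPy = stats(state)
        score = -0.5 * (trPQ - yPQPy)
        # a component stays in the update set unless it sits at the floor
        # with the likelihood pushing it further down (boundary condition)
        free = ~at_floor(theta) | (score > 0)
        idx = np.flatnonzero(free)

        accepted = None
        if len(idx):
            PT = state.P @ T[:, idx]
            AI = 0.5 * (T[:, idx].T @ PT)
            ridge = 1e-8 * max(np.trace(AI) / len(idx), 1e-300)
            try:
                delta = linalg.solve(
                    AI + ridge * np.eye(len(idx)), score[idx], assume_a="pos"
                )
            except linalg.LinAlgError:
                delta = None
            if delta is not None:
                # average-information step with deep step halving: the AI
                # matrix can be nearly singular along kernel ridges
                step = 1.0
                for _ in range(12):
                    cand = theta.copy()
                    cand[idx] = theta[idx] + step * delta
                    cand = np.maximum(cand, floor)
                    st = _evaluate(cand, Qs, y, X)
                    if st.ll >= state.ll - 1e-10:
                        accepted = (cand, st)
                        break
                    step *= 0.5
            if accepted is None:
                # EM-flavoured gradient fallback; the quadratic factor is
                # bounded below so boundary components with positive score
                # can re-enter the interior (plain EM is multiplicative and
                # would leave them stranded at the floor)
                base = np.maximum(theta, 1e-4 * vary)
                scale = 1.0
                for _ in range(8):
                    cand = theta.copy()
                    for k in idx:
                        cand[k] = theta[k] + scale * base[k] ** 2 * (
                            yPQPy[k] - trPQ[k]
                        ) / qlev[k]
                    cand = np.maximum(cand, floor)
                    st = _evaluate(cand, Qs, y, X)
                    if st.ll >= state.ll - 1e-10:
                        accepted = (cand, st)
                        break
                    scale *= 0.5
        if accepted is None:
            # no ascent direction found: numerically stalled at the optimum
            converged = True
            break

        new_theta, new_state = accepted
        dll = new_state.ll - state.ll
        dpar = np.max(np.abs(new_theta - theta)) / max(vary, 1e-300)
        theta, state = new_theta, new_state
        trace.append(state.ll)
        if opts.verbose:  # pragma: no cover
            print(f"iter {n_iter}: ll={state.ll:.6f} theta={theta}")
        if abs(dll) < opts.tol_loglik and dpar < opts.tol_param:
            converged = True
            break
    pinned = at_floor(theta)

    # standard errors from the inverse AI matrix over free parameters
    trPQ, T, yPQPy = stats(state)
    free = ~pinned
    idx = np.flatnonzero(free)
    se = np.zeros(K + 1)
    vcov = np.zeros((K + 1, K + 1))
    if len(idx):
        PT = state.P @ T[:, idx]
        AI = 0.5 * (T[:, idx].T @ PT)
        try:
            cov_free = linalg.inv(AI)
        except linalg.LinAlgError:
            cov_free = np.linalg.pinv(AI)
        se[idx] = np.sqrt(np.maximum(np.diag(cov_free), 0.0))
        vcov[np.ix_(idx, idx)] = cov_free
    est = np.where(pinned, 0.0, theta)
    return {
        "theta": est,
        "theta_internal": theta,
        "se": se,
        "vcov": vcov,
        "pinned": pinned,
        "loglik": state.ll,
        "trace": trace,
        "converged": converged,
        "n_iter": n_iter,
        "state": state,
        "floor": floor,
    }


def reml_fit(
    spec: ModelSpec,
    data: pd.DataFrame,
    options: REMLOptions | None = None,
    fix_components: dict[str, float] | None = None,
    compute_blups: bool = True,
    compute_sep: bool = True,
) -> REMLFit:
    """Fit a mixed model by AI-REML.

    ``data`` must hold one row per individual with columns ``individual``,
    ``site``, ``block`` and the trait named by ``spec.trait``; rows with a
    missing trait value are excluded from the likelihood (their breeding
    values are still predicted through the kernels). ``fix_components`` skips
    estimation and solves the model at the given variances (keys are term
    labels plus ``residual``), which is used to speed up cross-validation.
    """
    opts = options or REMLOptions()
    y_all = data[spec.trait].astype(float).to_numpy()
    obs = ~np.isnan(y_all)
    if obs.sum() == 0:
        raise ValueError("all phenotypes are missing")
    y = y_all[obs]
    X, fixed_names = _fixed_design(data, obs)
    if obs.sum() <= X.shape[1]:
        raise ValueError("fewer observations than fixed effects")
    designs = _build_designs(spec, data, obs)
    Qs = [d.Q for d in designs]
    labels = [d.label for d in designs]

    if float(np.var(y)) < 1e-300 or np.allclose(y, y[0]):
        # degenerate constant response: every component at the floor
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        comps = {lab: VarianceComponent(0.0, 0.0, pinned=True) for lab in labels}
        fit = REMLFit(
            spec=spec,
            components=comps,
            residual=VarianceComponent(0.0, 0.0, pinned=True),
            fixed_effects=pd.DataFrame(
                {"estimate": beta, "se": np.nan}, index=fixed_names
            ),
            loglik=float("nan"),
            loglik_trace=[],
            converged=True,
            n_iter=0,
            n_obs=int(obs.sum()),
            vcov=pd.DataFrame(
                np.zeros((len(labels) + 1,) * 2),
                index=labels + ["residual"],
                columns=labels + ["residual"],
            ),
            _designs=designs,
            _obs_ids=list(data["individual"].astype(str).to_numpy()[obs]),
        )
        for d in designs:
            fit.blup[d.label] = pd.Series(0.0, index=d.level_ids)
            fit.sep[d.label] = pd.Series(0.0, index=d.level_ids)
        return fit

    if fix_components is not None:
        theta = np.array(
            [fix_components[lab] for lab in labels] + [fix_components["residual"]]
        )
        state = _evaluate(theta, Qs, y, X)
        res = {
            "theta": theta,
            "theta_internal": theta,
            "se": np.full(len(theta), np.nan),
            "vcov": np.full((len(theta),) * 2, np.nan),
            "pinned": theta <= 0,
            "loglik": state.ll,
            "trace": [state.ll],
            "converged": True,
            "n_iter": 0,
            "state": state,
            "floor": 0.0,
        }
    else:
        res = _aireml(y, X, Qs, [d.q for d in designs], opts)
        if not res["converged"]:
            warnings.warn(
                f"REML did not converge in {opts.max_iter} iterations "
                f"for model {spec.name}",
                RuntimeWarning,
            )

    theta, se, pinned = res["theta"], res["se"], res["pinned"]
    comps = {
        lab: VarianceComponent(float(theta[k]), float(se[k]) if not pinned[k] else 0.0,
                               bool(pinned[k]))
        for k, lab in enumerate(labels)
    }
    residual = VarianceComponent(
        float(theta[-1]), float(se[-1]) if not pinned[-1] else 0.0, bool(pinned[-1])
    )
    state = res["state"]
    fixed = pd.DataFrame(
        {
            "estimate": state.beta,
            "se": np.sqrt(np.maximum(np.diag(state.beta_cov), 0.0)),
        },
        index=fixed_names,
    )
    all_labels = labels + ["residual"]
    fit = REMLFit(
        spec=spec,
        components=comps,
        residual=residual,
        fixed_effects=fixed,
        loglik=res["loglik"],
        loglik_trace=res["trace"],
        converged=res["converged"],
        n_iter=res["n_iter"],
        n_obs=int(obs.sum()),
        vcov=pd.DataFrame(res["vcov"], index=all_labels, columns=all_labels),
        _designs=designs,
        _P=state.P,
        _Py=state.Py,
        _obs_ids=list(data["individual"].astype(str)[obs]),
    )
    if compute_blups:
        blup_and_sep(fit, compute_sep=compute_sep)
    return fit


def blup_and_sep(fit: REMLFit, compute_sep: bool = True) -> REMLFit:
    """Solve the BLUPs (and prediction SEs) at the REML estimates.

    For each random term, u_hat = sigma2 K Z' P y and the prediction error
    variance is PEV = sigma2 K - sigma2^2 K Z' P Z K; SEP_i is the square
    root of its diagonal. Both follow directly from the mixed-model
    equations; individuals without records obtain predictions through the
    kernel. Terms pinned at the variance floor give u_hat = 0 and SEP = 0.
    """
    if fit._designs is None or fit._P is None:
        raise ValueError("fit does not carry solver internals")
    for d, lab in zip(fit._designs, list(fit.components)):
        sigma2 = fit.components[lab].estimate
        B = d.Z @ d.K  # n_obs x n_levels
        u = sigma2 * (B.T @ fit._Py)
        fit.blup[lab] = pd.Series(u, index=d.level_ids, name=lab)
        if compute_sep:
            PB = fit._P @ B
            pev = sigma2 * np.diag(d.K) - sigma2**2 * np.einsum(
                "ij,ij->j", B, PB
            )
            fit.sep[lab] = pd.Series(
                np.sqrt(np.clip(pev, 0.0, None)), index=d.level_ids, name=lab
            )
    return fit


def predict_masked(
    spec: ModelSpec,
    data: pd.DataFrame,
    options: REMLOptions | None = None,
    fix_components: dict[str, float] | None = None,
) -> tuple[pd.Series, REMLFit]:
    """Predict additive breeding values for phenotype-masked individuals.

    ``data`` rows with a missing trait are treated as the validation set:
    the model is (re)fit on the observed rows and the masked individuals'
    BVs flow through the relationship kernel. Under a pedigree kernel with
    zero relatedness to the training set the prediction is exactly 0 (the
    overall model mean on the standardized scale).

    Returns (predicted BVs for the masked individuals, the fit).
    """
    y = data[spec.trait].astype(float)
    masked = data.loc[y.isna(), "individual"].astype(str).tolist()
    if y.notna().sum() == 0:
        raise ValueError("all phenotypes are masked; nothing to train on")
    fit = reml_fit(
        spec, data, options=options, fix_components=fix_components,
        compute_blups=True, compute_sep=False,
    )
    bv = fit.blup["a"]
    pred = bv.reindex(masked)
    if pred.isna().any():
        missing = pred.index[pred.isna()].tolist()
        raise ValueError(f"masked individuals absent from kernel: {missing[:5]}")
    return pred, fit
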