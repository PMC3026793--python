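"""Binomial logistic mixed models with participant-level random effects.

The fitter follows the lme4 recipe at nAGQ = 1: for fixed variance
parameters theta (random-effect standard deviations), a penalized
iteratively reweighted least squares (joint Newton over fixed effects and
random-effect modes) finds the conditional mode, and the Laplace
approximation of the marginal log-likelihood

    l(theta) = loglik(beta, b-hat) - 1/2 sum_i b_i' S^-1 b_i
               - 1/2 sum_i log det(I + S Z_i' W_i Z_i)

is maximized over theta by a deterministic bounded search. Random effects
are a per-participant intercept and, optionally, an independent
trial-type slope (diagonal covariance). Observations with identical
covariates within a participant are aggregated to binomial counts first,
which makes desk-scale refits (e.g. thousands of leave-one-out folds)
cheap without changing the likelihood.

Nested fits are compared with likelihood-ratio tests against the
chi-square reference. Bayesian posterior summaries (mode and 95% highest
posterior density interval) for selected coefficients come from a seeded
adaptive random-walk Metropolis sampler over (beta, log sigma) using the
Laplace-integrated likelihood, with the study's priors: independent
normals with variance 1e10 on fixed effects and an inverse Wishart with
one degree of freedom (equivalently inverse gamma) on the random-effect
variance, scaled by the response variance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, roots_hermitenorm
from scipy.stats import chi2, gaussian_kde, invgamma

__all__ = [
    "ModelSpec",
    "FittedModel",
    "LRTestResult",
    "PosteriorSummary",
    "fit_glmm",
    "lr_test",
    "posterior_summary",
    "predict_expected",
    "hpdi",
]

#: Reference levels for treatment coding; the first sorted level otherwise.
DEFAULT_REFERENCE: Mapping[str, str] = {
    "group": "control",
    "trial_type": "distractor",
    "rotation": "frontal",
    "gender": "female",
}

_GRAD_TOL = 1e-6  # PIRLS convergence: max |gradient| of the penalized loglik
_THETA_MAX = 8.0  # search bound for random-effect standard deviations


@dataclass(frozen=True)
class ModelSpec:
    """Structure of a binomial logit GLMM.

    ``fixed`` lists main effects by column name and interactions as
    ``"a:b"``; an intercept is always included. Every interaction must be
    accompanied by its main effects. Random terms reference the
    participant grouping only: an intercept and optionally one slope
    (``random_slope`` names a column, e.g. ``"trial_type"``).
    """

    response: str = "correct"
    fixed: tuple[str, ...] = ("age_c", "trial_type", "rotation")
    random_intercept: bool = True
    random_slope: str | None = None
    group_col: str = "participant_id"
    reference: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_REFERENCE))

    def __post_init__(self):
        for term in self.fixed:
            for part in term.split(":"):
                if ":" in term and part not in self.fixed:
                    raise ValueError(f"interaction {term!r} lacks main effect {part!r}")
        if self.random_slope is not None and not self.random_intercept:
            raise ValueError("a random slope requires the random intercept")

    @property
    def n_random(self) -> int:
        return int(self.random_intercept) + int(self.random_slope is not None)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fixed"] = list(self.fixed)
        d["reference"] = dict(self.reference)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        d["fixed"] = tuple(d["fixed"])
        return cls(**d)


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def _encode_column(data: pd.DataFrame, col: str, reference: Mapping[str, str], levels: dict):
    """Treatment-code one column: numeric passes through, categorical dummies."""
    v = data[col]
    if pd.api.types.is_numeric_dtype(v) and not isinstance(v.dtype, pd.CategoricalDtype):
        return [(col, v.to_numpy(dtype=float))]
    lv = levels.get(col)
    if lv is None:
        lv = sorted(map(str, v.unique()))
        ref = reference.get(col)
        if ref is not None and ref in lv:
            lv = [ref] + [x for x in lv if x != ref]
        levels[col] = lv
    vals = v.astype(str).to_numpy()
    unknown = set(vals) - set(lv)
    if unknown:
        raise ValueError(f"unknown level(s) {sorted(unknown)} in column {col!r}")
    return [(f"{col}[{l}]", (vals == l).astype(float)) for l in lv[1:]]


def build_design(
    data: pd.DataFrame, spec: ModelSpec, levels: dict | None = None
) -> tuple[np.ndarray, list[str], dict]:
    """Fixed-effect design matrix (intercept first) with treatment coding.

    ``levels`` (categorical level orders) from a previous call makes the
    encoding of new data consistent with the fit.
    """
    levels = {} if levels is None else dict(levels)
    cols: list[tuple[str, np.ndarray]] = [("(Intercept)", np.ones(len(data)))]
    for term in spec.fixed:
        parts = term.split(":")
        missing = [p for p in parts if p not in data.columns]
        if missing:
            raise ValueError(f"data lack covariate(s) {missing} for term {term!r}")
        encoded = [_encode_column(data, p, spec.reference, levels) for p in parts]
        out = encoded[0]
        for nxt in encoded[1:]:
            out = [(f"{n1}:{n2}", v1 * v2) for n1, v1 in out for n2, v2 in nxt]
        cols.extend(out)
    names = [n for n, _ in cols]
    X = np.column_stack([v for _, v in cols]) if cols else np.empty((len(data), 0))
    return X, names, levels


def _random_design(data: pd.DataFrame, spec: ModelSpec, levels: dict) -> np.ndarray | None:
    """Per-row random-effect covariate rows U (n x q), or None when q = 0."""
    q = spec.n_random
    if q == 0:
        return None
    U = [np.ones(len(data))]
    if spec.random_slope is not None:
        enc = _encode_column(data, spec.random_slope, spec.reference, levels)
        if len(enc) != 1:
            raise ValueError("random slope must encode to a single column")
        U.append(enc[0][1])
    return np.column_stack(U)


def _aggregate(X: np.ndarray, U: np.ndarray | None, gidx: np.ndarray, y: np.ndarray):
    """Collapse rows with identical (participant, covariates) to binomial counts."""
    key_cols = [gidx[:, None], X] + ([U] if U is not None else [])
    key = np.hstack([np.asarray(c, dtype=float) for c in key_cols])
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    succ = np.bincount(inv, weights=y, minlength=len(uniq))
    tot = np.bincount(inv, minlength=len(uniq)).astype(float)
    ga = uniq[:, 0].astype(int)
    Xa = uniq[:, 1 : 1 + X.shape[1]]
    Ua = uniq[:, 1 + X.shape[1] :] if U is not None else None
    return Xa, Ua, ga, succ, tot


# ---------------------------------------------------------------------------
# fitted model container
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    spec: ModelSpec
    coef: pd.Series  # fixed effects on the logit scale
    coef_se: pd.Series
    random_sd: dict[str, float]
    log_likelihood: float
    converged: bool
    n_obs: int
    n_groups: int
    levels: dict  # categorical level orders, for consistent prediction
    ranef: pd.Series | None = None  # conditional modes (intercept component)
    numeric_range: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return len(self.coef) + len(self.random_sd)

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "coefficients": self.coef.to_dict(),
            "coef_se": self.coef_se.to_dict(),
            "random_sd": dict(self.random_sd),
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
        }


@dataclass(frozen=True)
class LRTestResult:
    D: float  # deviance difference 2 * (ll_alt - ll_null)
    df: int
    p: float


@dataclass(frozen=True)
class PosteriorSummary:
    coefficient: str
    posterior_mode: float
    hpdi_low: float
    hpdi_high: float
    n_samples: int
    seed: int
    rhat: float


# ---------------------------------------------------------------------------
# PIRLS / Laplace machinery
# ---------------------------------------------------------------------------

def _loglik_terms(eta, succ, tot):
    # sum y*eta - m*log(1+e^eta), numerically stable
    return float(np.sum(succ * eta - tot * np.logaddexp(0.0, eta)))


class _Problem:
    """Aggregated data plus PIRLS solver state for one model/data pair."""

    def __init__(self, Xa, Ua, ga, succ, tot, q):
        self.X, self.U, self.g, self.y, self.m = Xa, Ua, ga, succ, tot
        self.q = q
        self.p = Xa.shape[1]
        self.n_groups = int(ga.max()) + 1 if len(ga) else 0
        # the response is Bernoulli at the trial level, so the aggregated
        # binomial kernel IS the trial log-likelihood (no C(m,y) constants)
        self.const = 0.0

    def eta(self, beta, b):
        e = self.X @ beta
        if self.q:
            e = e + np.einsum("ij,ij->i", self.U, b[self.g])
        return e

    def penalized(self, beta, b, sig_inv_diag):
        ll = _loglik_terms(self.eta(beta, b), self.y, self.m)
        pen = 0.5 * float(np.sum(b**2 * sig_inv_diag)) if self.q else 0.0
        return ll - pen

    def pirls(self, sigmas, beta, b, fit_beta=True, max_iter=80):
        """Joint Newton over (beta, b); returns (beta, b, converged, cov_beta, logdet_term).

        ``sigmas``: length-q array of random sds. With ``fit_beta=False``
        only the random-effect modes are updated (used by the MCMC
        integrated likelihood).
        """
        q, p = self.q, self.p
        if q:
            sig_inv = np.where(np.asarray(sigmas) > 0, 1.0 / np.maximum(np.asarray(sigmas), 1e-12) ** 2, 1e12)
        else:
            sig_inv = np.zeros(0)
        obj = self.penalized(beta, b, sig_inv)
        S_last = None
        Dmat = None
        for _ in range(max_iter):
            eta = self.eta(beta, b)
            mu = expit(eta)
            w = self.m * mu * (1 - mu) + 1e-12
            r = self.y - self.m * mu
            gbeta = self.X.T @ r if fit_beta else None
            if q:
                gb = np.zeros((self.n_groups, q))
                np.add.at(gb, self.g, self.U * r[:, None])
                gb -= b * sig_inv
                # per-group blocks D_i = U' W U + Sigma^-1
                Dmat = np.zeros((self.n_groups, q, q))
                wU = self.U * w[:, None]
                for a in range(q):
                    for c in range(q):
                        np.add.at(Dmat[:, a, c], self.g, wU[:, a] * self.U[:, c])
                Dmat[:, np.arange(q), np.arange(q)] += sig_inv
                Dinv = np.linalg.inv(Dmat)
                if fit_beta:
                    # B_i = X' W U per group (p x q)
                    B = np.zeros((self.n_groups, p, q))
                    wX = self.X * w[:, None]
                    for a in range(p):
                        for c in range(q):
                            np.add.at(B[:, a, c], self.g, wX[:, a] * self.U[:, c])
                    A = self.X.T @ wX
                    S = A - np.einsum("gac,gcd,gbd->ab", B, Dinv, B)
                    rhs = gbeta - np.einsum("gac,gc->a", B, np.einsum("gab,gb->ga", Dinv, gb))
                    dbeta = np.linalg.solve(S, rhs)
                    db = np.einsum("gab,gb->ga", Dinv, gb - np.einsum("gba,b->ga", B, dbeta))
                    S_last = S
                else:
                    dbeta = np.zeros(p)
                    db = np.einsum("gab,gb->ga", Dinv, gb)
                gnorm = max(
                    float(np.max(np.abs(gbeta))) if fit_beta else 0.0,
                    float(np.max(np.abs(gb))) if self.n_groups else 0.0,
                )
            else:
                A = self.X.T @ (self.X * w[:, None])
                dbeta = np.linalg.solve(A, gbeta)
                db = None
                S_last = A
                gnorm = float(np.max(np.abs(gbeta)))
            if gnorm < _GRAD_TOL:
                break
            # step halving on the penalized objective
            step = 1.0
            for _ in range(30):
                nb = beta + step * dbeta
                nbb = b + step * db if q else b
                nobj = self.penalized(nb, nbb, sig_inv)
                if nobj >= obj - 1e-12:
                    break
                step *= 0.5
            beta, b, obj = nb, nbb, nobj
        converged = gnorm < 1e-4
        # Laplace log-det correction: sum_i log det(I + Sigma U'WU)
        logdet = 0.0
        if q and Dmat is not None:
            C = Dmat.copy()  # U'WU + Sigma^-1 at the mode
            C[:, np.arange(q), np.arange(q)] -= sig_inv
            sig2 = np.asarray(sigmas, dtype=float) ** 2
            M = np.eye(q)[None] + sig2[None, :, None] * C  # I + Sigma U'WU
            _, ld = np.linalg.slogdet(M)
            logdet = float(np.sum(ld))
        return beta, b, converged, S_last, logdet, sig_inv

    def laplace_loglik(self, sigmas, beta, b, fit_beta=True):
        beta, b, conv, S, logdet, sig_inv = self.pirls(sigmas, beta, b, fit_beta=fit_beta)
        ll = self.penalized(beta, b, sig_inv) + self.const - 0.5 * logdet
        return ll, beta, b, conv, S


def _prepare(data: pd.DataFrame, spec: ModelSpec, levels=None):
    if spec.group_col not in data.columns:
        raise ValueError(f"data lack grouping column {spec.group_col!r}")
    X, names, levels = build_design(data, spec, levels)
    U = _random_design(data, spec, levels)
    groups = pd.Categorical(data[spec.group_col].astype(str))
    gidx = groups.codes.astype(int)
    y = data[spec.response].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("response must be binary 0/1 at the trial level")
    Xa, Ua, ga, succ, tot = _aggregate(X, U, gidx, y)
    prob = _Problem(Xa, Ua, ga, succ, tot, spec.n_random)
    return prob, names, levels, list(groups.categories)


def fit_glmm(
    spec: ModelSpec,
    data: pd.DataFrame,
    start_sigma: float = 0.5,
    warm: FittedModel | None = None,
    refit_variance: bool = True,
) -> FittedModel:
    """Maximum (Laplace-approximated) likelihood fit of a binomial GLMM.

    Deterministic: fixed starting values and a bounded deterministic
    search over the variance parameters, so refitting identical data
    reproduces identical estimates. ``warm`` seeds the optimizer from a
    previous fit (same spec) — with ``refit_variance=False`` the variance
    parameters are frozen at the warm fit's values and only the fixed
    effects are re-estimated, the mode used for leave-one-out refits.

    Raises no exception on non-convergence; the ``converged`` flag is set
    instead. Quasi-complete separation shows up as huge coefficients and a
    failed convergence flag.
    """
    prob, names, levels, groups = _prepare(data, spec)
    if prob.n_groups < 2 and spec.n_random > 0:
        raise ValueError("a mixed model needs at least 2 participants")
    q = spec.n_random
    p = prob.p

    beta0 = np.zeros(p)
    if warm is not None and list(warm.coef.index) == names:
        beta0 = warm.coef.to_numpy().copy()
    state = {"beta": beta0, "b": np.zeros((prob.n_groups, q)) if q else np.zeros((0, 0))}

    if q == 0:
        ll, beta, b, conv, S = prob.laplace_loglik(np.zeros(0), state["beta"], state["b"])
        sigmas = np.zeros(0)
    else:
        warm_sig = None
        if warm is not None and warm.random_sd:
            warm_sig = np.array(list(warm.random_sd.values()))

        def neg(sig_arr):
            sig_arr = np.abs(np.asarray(sig_arr, dtype=float))
            ll, bta, bb, conv, _ = prob.laplace_loglik(sig_arr, state["beta"], state["b"])
            state["beta"], state["b"] = bta, bb
            return -ll

        if warm is not None and not refit_variance and warm_sig is not None:
            sigmas = warm_sig
        elif q == 1:
            s0 = float(warm_sig[0]) if warm_sig is not None else start_sigma
            res = optimize.minimize_scalar(
                lambda s: neg([s]), bounds=(0.0, _THETA_MAX), method="bounded",
                options={"xatol": 1e-6},
            )
            sigmas = np.array([abs(res.x)])
        else:
            x0 = warm_sig if warm_sig is not None else np.full(q, start_sigma)
            res = optimize.minimize(
                neg, x0, method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400},
            )
            sigmas = np.abs(res.x)
        ll, beta, b, conv, S = prob.laplace_loglik(sigmas, state["beta"], state["b"])

    try:
        cov = np.linalg.inv(S)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        conv = False
    if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 30:
        conv = False  # separation or divergence

    sd_names = []
    if spec.random_intercept:
        sd_names.append("participant")
    if spec.random_slope is not None:
        sd_names.append(f"participant:{spec.random_slope}")
    ranef = None
    if q:
        ranef = pd.Series(b[:, 0], index=pd.Index(groups, name=spec.group_col), name="u0")
    numeric_range = {}
    for term in spec.fixed:
        for part in term.split(":"):
            if part in data.columns and pd.api.types.is_numeric_dtype(data[part]):
                col = data[part].to_numpy(dtype=float)
                numeric_range[part] = (float(np.min(col)), float(np.max(col)))
    return FittedModel(
        spec=spec,
        coef=pd.Series(beta, index=names),
        coef_se=pd.Series(se, index=names),
        random_sd={n: float(s) for n, s in zip(sd_names, sigmas)},
        log_likelihood=float(ll),
        converged=bool(conv),
        n_obs=int(prob.m.sum()),
        n_groups=prob.n_groups,
        levels=levels,
        ranef=ranef,
        numeric_range=numeric_range,
    )


# ---------------------------------------------------------------------------
# likelihood-ratio tests
# ---------------------------------------------------------------------------

def lr_test(null_fit: FittedModel, alt_fit: FittedModel) -> LRTestResult:
    """Chi-square likelihood-ratio test of nested fits on the same data."""
    if null_fit.n_obs != alt_fit.n_obs:
        raise ValueError("fits compare different numbers of observations")
    if not set(null_fit.coef.index) <= set(alt_fit.coef.index):
        raise ValueError("null model fixed effects are not nested in the alternative")
    df = alt_fit.n_params - null_fit.n_params
    if df < 0:
        raise ValueError("alternative model has fewer parameters than the null")
    D = 2.0 * (alt_fit.log_likelihood - null_fit.log_likelihood)
    if D < -1e-3:  # beyond optimizer tolerance: the fits cannot be nested
        raise ValueError(f"negative deviance difference {D:.3g}: fits are not properly nested")
    D = max(D, 0.0)
    p = 1.0 if df == 0 else float(chi2.sf(D, df))
    return LRTestResult(D=D, df=df, p=p)


# ---------------------------------------------------------------------------
# Bayesian posterior summaries
# ---------------------------------------------------------------------------

def hpdi(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the samples."""
    x = np.sort(np.asarray(samples))
    n = len(x)
    k = max(1, int(np.ceil(mass * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k])


def _kde_mode(samples: np.ndarray) -> float:
    kde = gaussian_kde(samples)
    grid = np.linspace(samples.min(), samples.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def _split_rhat(chains: np.ndarray) -> float:
    """Gelman-Rubin split-R-hat over (n_chains, n_draws) for one parameter."""
    n = chains.shape[1] // 2
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    m, n = halves.shape
    cm = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean()
    B = n * cm.var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W)) if W > 0 else np.inf


def posterior_summary(
    spec: ModelSpec,
    data: pd.DataFrame,
    coefficients: Sequence[str] | None = None,
    n_samples: int = 4000,
    n_chains: int = 4,
    burn: int = 1500,
    seed: int = 0,
    rhat_threshold: float = 1.05,
    prior_fixed_var: float = 1e10,
    check_convergence: bool = True,
) -> dict[str, PosteriorSummary]:
    """Posterior mode and 95% HPDI per coefficient.

    Adaptive random-walk Metropolis over (beta, log sigma), target the
    Laplace-integrated likelihood plus priors: N(0, ``prior_fixed_var``)
    on each fixed effect and inverse Wishart (df = 1, scale = response
    variance) on each random-effect variance. Proposal scales adapt
    during burn-in only. Identical seeds give identical summaries.
    """
    prob, names, levels, _ = _prepare(data, spec)
    q = spec.n_random
    mle = fit_glmm(spec, data)
    y = data[spec.response].to_numpy(dtype=float)
    iw_scale = float(np.var(y))  # inverse Wishart scale: unconditional response variance

    ndim = prob.p + q
    b_state = [np.zeros((prob.n_groups, q)) if q else np.zeros((0, 0)) for _ in range(n_chains)]

    def logpost(x, ci):
        beta = x[: prob.p]
        lp = -0.5 * np.sum(beta**2) / prior_fixed_var
        if q:
            logsig = x[prob.p :]
            sig = np.exp(logsig)
            sig2 = sig**2
            # inverse gamma(nu/2, scale/2) with nu=1 on sigma^2, Jacobian to log sigma
            lp += float(np.sum(invgamma.logpdf(sig2, 0.5, scale=iw_scale / 2) + np.log(2 * sig2)))
            ll, _, bb, _, _ = prob.laplace_loglik(sig, beta, b_state[ci], fit_beta=False)
            b_state[ci] = bb
        else:
            ll = prob.laplace_loglik(np.zeros(0), beta, b_state[ci])[0]
        return ll + lp

    rng = np.random.default_rng([int(seed), 977])
    x0 = np.concatenate([
        mle.coef.to_numpy(),
        np.log(np.maximum(list(mle.random_sd.values()), 0.05)) if q else np.zeros(0),
    ])
    scales0 = np.concatenate([
        np.maximum(mle.coef_se.to_numpy(), 0.02) if np.all(np.isfinite(mle.coef_se)) else np.full(prob.p, 0.1),
        np.full(q, 0.25),
    ])

    total = burn + int(np.ceil(n_samples / n_chains))
    draws = np.empty((n_chains, total - burn, ndim))
    for ci in range(n_chains):
        x = x0 + 0.1 * scales0 * rng.standard_normal(ndim)
        lp = logpost(x, ci)
        scales = scales0.copy()
        acc_win = np.zeros(ndim)
        for it in range(total):
            # Metropolis-within-Gibbs: one component per sub-step
            for j in range(ndim):
                prop = x.copy()
                prop[j] += scales[j] * rng.standard_normal()
                lpp = logpost(prop, ci)
                if np.log(rng.random()) < lpp - lp:
                    x, lp = prop, lpp
                    acc_win[j] += 1
            if it < burn and (it + 1) % 50 == 0:  # adapt during burn-in only
                rate = acc_win / 50
                scales *= np.exp(np.clip(rate - 0.44, -0.5, 0.5))
                acc_win[:] = 0
            if it >= burn:
                draws[ci, it - burn] = x
    flat = draws.reshape(-1, ndim)

    rhats = {names[j]: _split_rhat(draws[:, :, j]) for j in range(prob.p)}
    bad = {k: v for k, v in rhats.items() if v > rhat_threshold}
    if bad and check_convergence:
        raise RuntimeError(f"MCMC failed convergence diagnostics (split R-hat): {bad}")

    wanted = list(coefficients) if coefficients is not None else names
    out = {}
    for name in wanted:
        j = names.index(name)
        s = flat[:, j]
        lo, hi = hpdi(s, 0.95)
        out[name] = PosteriorSummary(
            coefficient=name,
            posterior_mode=_kde_mode(s),
            hpdi_low=lo,
            hpdi_high=hi,
            n_samples=len(s),
            seed=seed,
            rhat=rhats[name],
        )
    return out


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_expected(
    model: FittedModel,
    covariates: pd.DataFrame,
    marginalization: str = "quadrature",
    n_quad: int = 31,
) -> np.ndarray:
    """Expected correct-response probability at new covariates.

    ``marginalization="quadrature"`` integrates over the random effects
    with Gauss-Hermite quadrature (the performance a new participant with
    those covariates is expected to show); ``"conditional"`` evaluates at
    random effects equal to zero.
    """
    spec = model.spec
    X, names, levels = build_design(covariates, spec, model.levels)
    if names != list(model.coef.index):
        raise ValueError("covariates produce a design incompatible with the fitted model")
    eta = X @ model.coef.to_numpy()
    sigmas = np.array(list(model.random_sd.values()))
    q = len(sigmas)
    if marginalization == "conditional" or q == 0 or np.all(sigmas == 0):
        return expit(eta)
    if marginalization != "quadrature":
        raise ValueError(f"unknown marginalization {marginalization!r}")
    nodes, weights = roots_hermitenorm(n_quad)
    weights = weights / weights.sum()
    U = _random_design(covariates, spec, dict(model.levels))
    if q == 1:
        grid = eta[:, None] + sigmas[0] * U[:, 0][:, None] * nodes[None, :]
        return expit(grid) @ weights
    # q == 2: tensor-product quadrature over (intercept, slope)
    out = np.zeros(len(eta))
    for w0, x0_ in zip(weights, nodes):
        shift0 = sigmas[0] * U[:, 0] * x0_
        grid = (eta + shift0)[:, None] + sigmas[1] * U[:, 1][:, None] * nodes[None, :]
        out += w0 * (expit(grid) @ weights)
    return out
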