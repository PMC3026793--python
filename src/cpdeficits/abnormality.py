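"""Single-case abnormality scores from control-referenced mixed models.

The procedure, per test:

1. Fit the control nullmodel (binomial GLMM) on control observations only.
2. Residual of each case = observed performance minus the performance a
   control with the same covariates is expected to show under that model.
3. Residuals of the controls themselves come from individualized
   leave-one-out (LOO) control models: the fixed effects are re-estimated
   with that control excluded, so control residual variance is an honest
   cross-validation estimate rather than an optimistic in-sample one.
4. All residuals are z-standardized by the control residual mean and sd.
5. Category scores average the member-test z-scores per participant and
   are re-standardized against the controls.
6. A deficit is called when the score falls below the one-sided 5% cutoff
   of a t distribution with n_controls - 1 degrees of freedom
   (single-case modified t-test: t = z / sqrt((n+1)/n)).

Residuals live on the empirical-logit scale by default: near-ceiling
binomial proportions are left-skewed on the response scale, which
inflates the lower-tail false-positive rate of the t-based deficit call;
on the logit scale the participant-level deviations are approximately
normal (random intercept plus delta-method binomial noise) and the test
holds its nominal level. ``scale="response"`` (plain proportions) is
available for comparison.

Sign convention: worse-than-expected performance is negative everywhere.
Externally supplied z-scores whose raw direction is flipped (e.g.
reaction times, where larger is worse) must be negated at ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, roots_hermitenorm
from scipy.stats import t as t_dist

from . import glmm as _glmm
from .glmm import FittedModel, ModelSpec, fit_glmm, predict_expected

__all__ = [
    "Residual",
    "DeficitCall",
    "CategoryMap",
    "default_category_map",
    "observed_performance",
    "case_residuals",
    "loo_control_residuals",
    "standardize",
    "build_ztable",
    "ingest_external_z",
    "aggregate_scores",
    "crawford_deficit_test",
    "deficit_table",
]


@dataclass(frozen=True)
class Residual:
    participant_id: str
    test_id: str
    observed: float
    expected: float

    @property
    def residual(self) -> float:
        return self.observed - self.expected


@dataclass(frozen=True)
class DeficitCall:
    participant_id: str
    column: str
    t_statistic: float
    df: int
    p: float
    is_deficit: bool


@dataclass(frozen=True)
class CategoryMap:
    """Test-to-category assignment and aggregate-column definitions.

    ``tests`` maps each separate test column to a
    (category, stimulus-class) pair with category in {perceptual,
    associative, mnestic} and stimulus class in {faces, shoes};
    ``aggregates`` defines each summary column as a set of member tests.
    """

    tests: dict[str, tuple[str, str]]
    aggregates: dict[str, tuple[str, ...]]

    def validate(self) -> None:
        for test, (cat, stim) in self.tests.items():
            if cat not in ("perceptual", "associative", "mnestic"):
                raise ValueError(f"unknown category {cat!r} for test {test!r}")
            if stim not in ("faces", "shoes"):
                raise ValueError(f"unknown stimulus class {stim!r} for test {test!r}")
        for agg, members in self.aggregates.items():
            if len(members) == 0:
                raise ValueError(f"aggregate {agg!r} defined over zero columns")
            unknown = set(members) - set(self.tests)
            if unknown:
                raise ValueError(f"aggregate {agg!r} references unknown tests {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {
            "tests": {k: list(v) for k, v in self.tests.items()},
            "aggregates": {k: list(v) for k, v in self.aggregates.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CategoryMap":
        return cls(
            tests={k: tuple(v) for k, v in d["tests"].items()},
            aggregates={k: tuple(v) for k, v in d["aggregates"].items()},
        )


def default_category_map() -> CategoryMap:
    """Default battery layout.

    Perceptual: reaction time and presentation-time thresholds; associative:
    rotated-view and restricted-time generalization; mnestic: one-year
    recognition and famous-face recall. Category summaries aggregate the
    face tests (the subtype definitions are face-centric); ``faces_total``,
    ``shoes_total`` and ``overall`` aggregate by stimulus class. The text
    of study reports rarely enumerates this membership, so it is
    configurable rather than hard-wired.
    """
    tests = {
        "rt_faces": ("perceptual", "faces"),
        "pt80_faces": ("perceptual", "faces"),
        "rotation_faces": ("associative", "faces"),
        "learn_faces": ("associative", "faces"),
        "test_faces": ("associative", "faces"),
        "faces_longterm": ("mnestic", "faces"),
        "bfft": ("mnestic", "faces"),
        "rt_shoes": ("perceptual", "shoes"),
        "pt80_shoes": ("perceptual", "shoes"),
        "rotation_shoes": ("associative", "shoes"),
        "shoes_longterm": ("mnestic", "shoes"),
    }
    faces = tuple(t for t, (_, s) in tests.items() if s == "faces")
    shoes = tuple(t for t, (_, s) in tests.items() if s == "shoes")
    aggregates = {
        "perceptual": tuple(t for t, (c, s) in tests.items() if c == "perceptual" and s == "faces"),
        "associative": tuple(t for t, (c, s) in tests.items() if c == "associative" and s == "faces"),
        "mnestic": tuple(t for t, (c, s) in tests.items() if c == "mnestic" and s == "faces"),
        "faces_total": faces,
        "shoes_total": shoes,
        "overall": faces + shoes,
    }
    return CategoryMap(tests=tests, aggregates=aggregates)


# ---------------------------------------------------------------------------
# residuals
# ---------------------------------------------------------------------------

def _elogit(succ: np.ndarray, tot: np.ndarray) -> np.ndarray:
    return np.log((succ + 0.5) / (tot - succ + 0.5))


def observed_performance(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Per-participant successes, trials and observed proportion."""
    g = data.groupby(spec.group_col, sort=True)[spec.response]
    out = pd.DataFrame({"successes": g.sum(), "trials": g.count()})
    out["observed"] = out["successes"] / out["trials"]
    return out


def _participant_residuals(model: FittedModel, data: pd.DataFrame, scale: str) -> pd.DataFrame:
    """Observed-minus-expected per participant, on the requested scale.

    Expected performance averages the model's per-trial probabilities
    over the participant's own trial covariates, so the comparison is a
    control with identical covariates facing the same trial schedule.
    On the response scale the expectation marginalizes over the random
    effects (the mean proportion a new control would show), which makes
    null residuals average exactly zero. On the logit scale the
    expectation is conditional on zero random effects (the typical
    control's linear predictor), so a participant's residual estimates
    their own random effect plus noise and is approximately normal.
    """
    spec = model.spec
    obs = observed_performance(data, spec)
    marginalization = "quadrature" if scale == "response" else "conditional"
    pred = predict_expected(model, data, marginalization=marginalization)
    exp = pd.Series(pred, index=data[spec.group_col].to_numpy()).groupby(level=0).mean()
    exp = exp.reindex(obs.index)
    if scale == "response":
        observed = obs["observed"]
        expected = exp
    elif scale == "logit":
        tot = obs["trials"].to_numpy()
        observed = pd.Series(_elogit(obs["successes"].to_numpy(), tot), index=obs.index)
        # same Haldane correction on the expected counts, so performing
        # exactly as predicted yields a residual of exactly zero
        expected = pd.Series(_elogit(exp.to_numpy() * tot, tot), index=obs.index)
    else:
        raise ValueError(f"unknown residual scale {scale!r}")
    out = pd.DataFrame(
        {
            "observed": observed,
            "expected": expected,
            "residual": observed - expected,
        }
    )
    out.index.name = "participant_id"
    return out


def case_residuals(
    control_model: FittedModel, case_data: pd.DataFrame, scale: str = "logit"
) -> pd.DataFrame:
    """Residuals of case participants under the control model.

    Covariates outside the control model's support (e.g. a case older
    than every control) are extrapolated, not refused; a ``flagged``
    column marks them.
    """
    res = _participant_residuals(control_model, case_data, scale)
    # flag participants whose numeric covariates extrapolate beyond the
    # control model's training range (computed, not refused)
    spec = control_model.spec
    flagged = pd.Series(False, index=res.index)
    for col, (lo, hi) in control_model.numeric_range.items():
        if col in case_data.columns:
            v = case_data.groupby(spec.group_col)[col].agg(["min", "max"])
            out_of_range = (v["min"] < lo) | (v["max"] > hi)
            flagged |= out_of_range.reindex(flagged.index).fillna(False)
    res["flagged"] = flagged
    return res


def loo_control_residuals(
    spec: ModelSpec,
    control_data: pd.DataFrame,
    scale: str = "logit",
    refit_variance: bool = False,
    full_fit: FittedModel | None = None,
) -> tuple[pd.DataFrame, FittedModel]:
    """Leave-one-out residual for every control, plus the full control fit.

    For control i the fixed effects are re-estimated on all controls
    except i (one fit per fold, warm-started from the full fit; variance
    parameters follow the full fit unless ``refit_variance``), and i's
    residual is computed under that individualized model. Any fold that
    fails to converge is reported in the ``converged`` column.
    """
    ids = pd.unique(control_data[spec.group_col])
    if len(ids) < 3:
        raise ValueError("leave-one-out residuals need at least 3 controls")
    full = full_fit if full_fit is not None else fit_glmm(spec, control_data)
    if refit_variance:
        rows = []
        for pid in ids:
            mask = control_data[spec.group_col] == pid
            fold_fit = fit_glmm(spec, control_data[~mask], warm=full, refit_variance=True)
            r = _participant_residuals(fold_fit, control_data[mask], scale)
            rows.append(
                {
                    "participant_id": pid,
                    "observed": r["observed"].iloc[0],
                    "expected": r["expected"].iloc[0],
                    "residual": r["residual"].iloc[0],
                    "converged": fold_fit.converged,
                }
            )
        return pd.DataFrame(rows).set_index("participant_id"), full
    return _loo_beta_refits(spec, control_data, full, scale), full


def _marginal_cell_prob(eta: np.ndarray, U: np.ndarray | None, sigmas: np.ndarray, n_quad: int = 31) -> np.ndarray:
    """Random-effect-marginal success probability per aggregated cell."""
    q = len(sigmas)
    if q == 0 or np.all(sigmas == 0):
        return expit(eta)
    nodes, weights = roots_hermitenorm(n_quad)
    weights = weights / weights.sum()
    if q == 1:
        return expit(eta[:, None] + sigmas[0] * U[:, 0][:, None] * nodes[None, :]) @ weights
    out = np.zeros(len(eta))
    for w0, x0 in zip(weights, nodes):
        shifted = eta + sigmas[0] * U[:, 0] * x0
        out += w0 * (expit(shifted[:, None] + sigmas[1] * U[:, 1][:, None] * nodes[None, :]) @ weights)
    return out


def _loo_beta_refits(
    spec: ModelSpec, control_data: pd.DataFrame, full: FittedModel, scale: str
) -> pd.DataFrame:
    """Array-level leave-one-out fixed-effect refits (variance held fixed).

    The aggregated binomial problem is built once; each fold masks one
    participant's cells and reruns the penalized Newton solver
    warm-started from the full fit, which is algebraically the same
    refit as dropping the rows from the raw table.
    """
    prob, names, levels, groups = _glmm._prepare(control_data, spec)
    q = spec.n_random
    sigmas = np.array(list(full.random_sd.values())) if q else np.zeros(0)
    beta_full = full.coef.to_numpy()
    _, b_full, *_ = prob.pirls(sigmas, beta_full.copy(), np.zeros((prob.n_groups, q)) if q else np.zeros((0, 0)))
    rows = []
    for gi, pid in enumerate(groups):
        keep = prob.g != gi
        sub = _glmm._Problem(
            prob.X[keep], prob.U[keep] if q else None, prob.g[keep], prob.y[keep], prob.m[keep], q
        )
        sub.n_groups = prob.n_groups  # dropped participant keeps an (empty) slot
        beta, b, conv, *_ = sub.pirls(sigmas, beta_full.copy(), b_full.copy())
        cells = prob.g == gi
        eta = prob.X[cells] @ beta
        if scale == "response":
            p_cell = _marginal_cell_prob(eta, prob.U[cells] if q else None, sigmas)
        else:
            p_cell = expit(eta)  # conditional at zero random effects
        m = prob.m[cells]
        expected_prop = float(np.sum(p_cell * m) / m.sum())
        succ, tot = float(prob.y[cells].sum()), float(m.sum())
        if scale == "response":
            observed, expected = succ / tot, expected_prop
        elif scale == "logit":
            observed = float(np.log((succ + 0.5) / (tot - succ + 0.5)))
            em = expected_prop * tot
            expected = float(np.log((em + 0.5) / (tot - em + 0.5)))
        else:
            raise ValueError(f"unknown residual scale {scale!r}")
        rows.append(
            {
                "participant_id": pid,
                "observed": observed,
                "expected": expected,
                "residual": observed - expected,
                "converged": bool(conv),
            }
        )
    return pd.DataFrame(rows).set_index("participant_id")


# ---------------------------------------------------------------------------
# standardization and aggregation
# ---------------------------------------------------------------------------

def standardize(control_residuals: pd.Series, all_residuals: pd.Series) -> pd.Series:
    """z = (r - mean of control residuals) / sd of control residuals."""
    ctl = control_residuals.dropna()
    mu = float(ctl.mean())
    sd = float(ctl.std(ddof=1))
    if not np.isfinite(sd) or sd <= 0:
        raise ValueError("control residuals have zero variance; z-scores undefined")
    return (all_residuals - mu) / sd


def build_ztable(columns: dict[str, pd.Series], participants: pd.Index | None = None) -> pd.DataFrame:
    """Assemble per-test z-score series into a participants x tests table.

    Missing cells are NaN — explicitly distinct from a zero score.
    """
    table = pd.DataFrame(columns)
    if participants is not None:
        table = table.reindex(participants)
    table.index.name = "participant_id"
    return table


def ingest_external_z(
    scores: pd.DataFrame,
    control_ids: pd.Index | list,
    higher_is_better: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Ingest externally standardized z-score columns.

    Direction-flipped measures (``higher_is_better[col] = False``, e.g.
    reaction times) are negated so that negative always means worse.
    Each column is then re-standardized against the ingested control
    rows, so control mean 0 / sd 1 holds in this table too.
    """
    df = scores.set_index("participant_id") if "participant_id" in scores.columns else scores.copy()
    df = df.select_dtypes(include=[np.number])
    out = {}
    for col in df.columns:
        v = df[col].astype(float)
        if higher_is_better is not None and not higher_is_better.get(col, True):
            v = -v
        out[col] = standardize(v.loc[v.index.intersection(pd.Index(control_ids))], v)
    return pd.DataFrame(out)


def aggregate_scores(
    ztable: pd.DataFrame, category_map: CategoryMap, control_ids: pd.Index | list
) -> pd.DataFrame:
    """Append aggregate columns: mean of available member z-scores,
    re-standardized against the control distribution of that mean.

    Participants missing every member stay missing; at least one
    available member is enough to receive a summary score.
    """
    category_map.validate()
    out = ztable.copy()
    control_ids = pd.Index(control_ids)
    for agg, members in category_map.aggregates.items():
        present = [m for m in members if m in ztable.columns]
        if not present:
            raise ValueError(f"aggregate {agg!r}: none of its member columns are in the table")
        mean = ztable[present].mean(axis=1, skipna=True)  # NaN only if all members missing
        out[agg] = standardize(mean.loc[control_ids.intersection(mean.index)], mean)
    return out


# ---------------------------------------------------------------------------
# deficit calls
# ---------------------------------------------------------------------------

def crawford_deficit_test(z: float, n_controls: int, alpha: float = 0.05) -> DeficitCall:
    """Single-case modified t-test of one z-score against n controls.

    t = z / sqrt((n+1)/n) with df = n - 1; one-sided lower tail — only
    worse-than-control performance counts as a deficit.
    """
    if n_controls < 2:
        raise ValueError("the deficit test needs at least 2 controls")
    if np.isnan(z):
        return DeficitCall("", "", np.nan, n_controls - 1, np.nan, False)
    t = float(z) / np.sqrt((n_controls + 1) / n_controls)
    p = float(t_dist.cdf(t, n_controls - 1))
    return DeficitCall("", "", t, n_controls - 1, p, bool(p < alpha))


def deficit_table(
    ztable: pd.DataFrame, control_ids: pd.Index | list, alpha: float = 0.05
) -> pd.DataFrame:
    """Deficit calls for every cell of a z-score table (long format).

    The normative sample size per column is the number of controls with a
    non-missing score in that column.
    """
    control_ids = pd.Index(control_ids)
    rows = []
    for col in ztable.columns:
        n_ctl = int(ztable.loc[ztable.index.intersection(control_ids), col].notna().sum())
        for pid, z in ztable[col].items():
            if pd.isna(z):
                rows.append(
                    {"participant_id": pid, "column": col, "t": np.nan, "df": n_ctl - 1,
                     "p": np.nan, "is_deficit": False, "is_missing": True}
                )
                continue
            call = crawford_deficit_test(float(z), n_ctl, alpha)
            rows.append(
                {"participant_id": pid, "column": col, "t": call.t_statistic, "df": call.df,
                 "p": call.p, "is_deficit": call.is_deficit, "is_missing": False}
            )
    return pd.DataFrame(rows)
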