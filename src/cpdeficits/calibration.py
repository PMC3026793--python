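"""Operating-characteristic simulations of the analysis pipeline.

Everything here regenerates data from the synthetic cohort model and
measures the behaviour of the downstream statistics:

- false-positive rate of the single-case deficit call on held-out
  control-like participants under the null generative model;
- type-I error and null distribution of the likelihood-ratio test for a
  spurious group effect;
- bias of the recovered group coefficient at the study's design size;
- recovery of planted phenotypic subtypes by the clustering stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import abnormality, glmm, subtyping
from .synthetic import GenerativeConfig, StudyDesign, planted_subtype_cohort, simulate_experiment, generate_participants

__all__ = [
    "attach_covariates",
    "deficit_false_positive_rate",
    "lr_null_simulation",
    "beta_cp_recovery",
    "subtype_recovery",
]

NULL_SPEC = glmm.ModelSpec(
    response="correct",
    fixed=("age_c", "trial_type", "rotation"),
    random_intercept=True,
)

MAIN_SPEC = glmm.ModelSpec(
    response="correct",
    fixed=("age_c", "trial_type", "rotation", "group"),
    random_intercept=True,
)

FULL_SPEC = glmm.ModelSpec(
    response="correct",
    fixed=("age_c", "trial_type", "rotation", "group", "group:trial_type", "group:rotation"),
    random_intercept=True,
)


def attach_covariates(trials: pd.DataFrame, participants: pd.DataFrame) -> pd.DataFrame:
    """Merge participant covariates into a trial table for model fitting."""
    keep = [
        c
        for c in ("participant_id", "group", "age", "age_c", "gender", "tv_band", "print_band")
        if c in participants.columns
    ]
    return trials.merge(participants[keep], on="participant_id", how="left")


def deficit_false_positive_rate(
    n_replicates: int = 2000,
    n_controls: int = 25,
    seed: int = 0,
    config: GenerativeConfig | None = None,
    design: StudyDesign | None = None,
    scale: str = "logit",
) -> dict:
    """Fraction of held-out null participants flagged as deficient.

    Each replicate simulates ``n_controls`` + 1 participants from the
    null generative model (all group effects zero), runs the full
    abnormality pipeline — control nullmodel fit, leave-one-out control
    residuals, z-standardization, single-case t-test at the 5% one-sided
    cutoff — on the held-out participant, and records the deficit flag.
    Nominal rate: 0.05.
    """
    base = (config or GenerativeConfig()).replace(
        n_controls=n_controls + 1, n_cp=0, beta_cp=0.0, beta_cp_trial=0.0, beta_cp_rotation=0.0
    )
    design = design or StudyDesign()
    flags = 0
    used = 0
    for rep in range(n_replicates):
        rep_seed = (seed * 1_000_003 + rep) % (2**31)
        participants = generate_participants(base, seed=rep_seed)
        trials = simulate_experiment(participants, design, base, seed=rep_seed)
        data = attach_covariates(trials, participants)
        ids = participants["participant_id"].tolist()
        ctl_ids, case_id = ids[:-1], ids[-1]
        ctl = data[data["participant_id"].isin(ctl_ids)]
        case = data[data["participant_id"] == case_id]
        loo, full = abnormality.loo_control_residuals(NULL_SPEC, ctl, scale=scale)
        case_res = abnormality.case_residuals(full, case, scale=scale)
        z = abnormality.standardize(loo["residual"], case_res["residual"])
        call = abnormality.crawford_deficit_test(float(z.iloc[0]), n_controls)
        flags += int(call.is_deficit)
        used += 1
    return {"rate": flags / used, "n_replicates": used, "n_controls": n_controls, "nominal": 0.05}


def lr_null_simulation(
    n_replicates: int = 500,
    seed: int = 0,
    config: GenerativeConfig | None = None,
    design: StudyDesign | None = None,
) -> pd.DataFrame:
    """Null distribution of the LR test for a spurious group main effect.

    Cohorts are simulated with all group effects zero; for each, the
    nullmodel and the main-effect model are fitted and compared. Under
    the null, D is approximately chi-square with 1 df.

    The default cohort (150 + 150 participants, 40 trials each) is sized
    so the asymptotic chi-square reference is valid and the check
    measures the implementation rather than the approximation: for a
    between-participant effect the relevant sample size is the number of
    participants, and at small cohorts the chi-square reference is
    mildly anti-conservative (p-values a little too small) — rerun with
    a study-sized ``config`` to see that caveat directly.
    """
    base = (config or GenerativeConfig(n_controls=150, n_cp=150)).replace(
        beta_cp=0.0, beta_cp_trial=0.0, beta_cp_rotation=0.0
    )
    design = design or StudyDesign(repetitions_per_part=1)
    rows = []
    for rep in range(n_replicates):
        rep_seed = (seed * 2_000_003 + rep) % (2**31)
        participants = generate_participants(base, seed=rep_seed)
        trials = simulate_experiment(participants, design, base, seed=rep_seed)
        data = attach_covariates(trials, participants)
        null_fit = glmm.fit_glmm(NULL_SPEC, data)
        alt_fit = glmm.fit_glmm(MAIN_SPEC, data, warm=None)
        res = glmm.lr_test(null_fit, alt_fit)
        rows.append({"D": res.D, "df": res.df, "p": res.p})
    return pd.DataFrame(rows)


def beta_cp_recovery(
    n_replicates: int = 100,
    seed: int = 0,
    config: GenerativeConfig | None = None,
    design: StudyDesign | None = None,
) -> dict:
    """Bias of the estimated group coefficient at the study design size.

    Cohorts of 25 controls and 13 CPs with the default group effects
    (beta_CP = -1.04 plus the trial-type and rotation interactions) are
    simulated and refitted with the matching full interaction model;
    reports the mean group[CP] estimate and its bias on the logit scale.
    """
    base = config or GenerativeConfig()
    design = design or StudyDesign()
    est = []
    for rep in range(n_replicates):
        rep_seed = (seed * 3_000_017 + rep) % (2**31)
        participants = generate_participants(base, seed=rep_seed)
        trials = simulate_experiment(participants, design, base, seed=rep_seed)
        data = attach_covariates(trials, participants)
        fit = glmm.fit_glmm(FULL_SPEC, data)
        est.append(fit.coef["group[CP]"])
    est = np.asarray(est)
    return {
        "mean_estimate": float(est.mean()),
        "true": base.beta_cp,
        "bias": float(est.mean() - base.beta_cp),
        "sd": float(est.std(ddof=1)),
        "n_replicates": n_replicates,
    }


def _adjusted_rand(a: np.ndarray, b: np.ndarray) -> float:
    """Adjusted Rand index between two label vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = len(a)
    cats_a, ia = np.unique(a, return_inverse=True)
    cats_b, ib = np.unique(b, return_inverse=True)
    table = np.zeros((len(cats_a), len(cats_b)))
    np.add.at(table, (ia, ib), 1)
    comb = lambda x: x * (x - 1) / 2.0
    sum_ij = comb(table).sum()
    sum_a = comb(table.sum(axis=1)).sum()
    sum_b = comb(table.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb(n)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def subtype_recovery(
    n_replicates: int = 100,
    n_per_type: int = 5,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> dict:
    """Recovery of three planted deficit archetypes by complete linkage.

    For each replicate a summary z-score cohort with planted archetypes
    is generated, all participants are clustered, the CP rows' labels at
    a k = 3 cut (of the CP-only subtree relabelling) are compared to the
    planted partition by adjusted Rand index. Reports the fraction of
    replicates with agreement > 0.8.
    """
    hits = 0
    aris = []
    for rep in range(n_replicates):
        table, truth = planted_subtype_cohort(
            n_per_type=n_per_type, noise_sd=noise_sd, seed=(seed * 4_000_037 + rep) % (2**31)
        )
        cps = truth[truth != "control"].index
        dist = subtyping.pairwise_distance(table.loc[cps])
        dend = subtyping.complete_linkage(dist)
        labels = subtyping.cut_clusters(dend, 3)
        ari = _adjusted_rand(labels.loc[cps].to_numpy(), truth.loc[cps].to_numpy())
        aris.append(ari)
        hits += ari > 0.8
    return {
        "fraction_recovered": hits / n_replicates,
        "mean_ari": float(np.mean(aris)),
        "n_replicates": n_replicates,
    }
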