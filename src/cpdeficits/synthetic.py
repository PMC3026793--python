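"""Synthetic case-control cohorts for long-term recognition-memory studies.

Generates participants (controls and congenital prosopagnosics, CPs),
balanced trial schedules for the one-year recognition experiments, and
trial-level binary responses under a logistic mixed model, so that every
downstream analysis stage can be exercised without access to the private
participant data such studies rest on.

The generative model for a recognition trial is

    correct ~ Bernoulli(logit^-1(eta)),
    eta = b0 + beta_age * age_c + beta_trial * target + beta_rot * rotated
          + CP * (beta_cp + beta_cp_trial * target + beta_cp_rot * rotated)
          + u0_i + u1_i * target,

with participant random effects u0_i ~ N(0, sigma_intercept^2) and an
optional random trial-type slope u1_i ~ N(0, sigma_trial_slope^2).
``age_c`` is age centered at 40 years and scaled to decades.

Famous-face free recall (BFFT) uses a separate logistic model with
age, gender, TV and print media-consumption bands, group, and
group x media interactions.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

__all__ = [
    "GenerativeConfig",
    "StudyDesign",
    "EXTERNAL_TESTS",
    "shoes_config",
    "generate_participants",
    "generate_trial_schedule",
    "simulate_responses",
    "simulate_experiment",
    "simulate_bfft",
    "generate_external_scores",
    "score_questionnaire",
    "planted_subtype_cohort",
    "substream",
]

#: External short-term tests ingested as precomputed z-score columns.
EXTERNAL_TESTS = (
    "rt_faces",
    "pt80_faces",
    "rotation_faces",
    "learn_faces",
    "test_faces",
    "rt_shoes",
    "pt80_shoes",
    "rotation_shoes",
)

# fixed integer tags for deterministic per-stage substreams of the master seed
_STREAM_TAGS = {
    "participants": 11,
    "schedule": 23,
    "responses": 37,
    "bfft": 41,
    "external": 53,
    "questionnaire": 61,
    "planted": 71,
}


def substream(seed: int, stage: str, extra: int = 0) -> np.random.Generator:
    """Deterministic child generator for a named pipeline stage.

    A single master ``seed`` reproduces every table; distinct stages (and
    per-participant ``extra`` offsets) get independent streams.
    """
    return np.random.default_rng([int(seed), _STREAM_TAGS[stage], int(extra)])


@dataclass(frozen=True)
class StudyDesign:
    """Schedule contract of a long-term recognition experiment.

    Two parts; each part presents every stimulus ``repetitions_per_part``
    times in randomized order (default 8 x (4 targets + 16 distractors) =
    160 presentations per part). The first part shows rotated views, the
    second frontal views. Target trials carry one of four illumination
    labels, exactly one of which matches the familiarization condition.
    """

    n_targets: int = 4
    n_distractors: int = 16
    repetitions_per_part: int = 8
    parts: tuple[str, ...] = ("rotated", "frontal")
    illumination_levels: tuple[str, ...] = ("familiar", "novel1", "novel2", "novel3")

    @property
    def n_stimuli(self) -> int:
        return self.n_targets + self.n_distractors

    @property
    def presentations_per_part(self) -> int:
        return self.repetitions_per_part * self.n_stimuli

    def validate(self) -> None:
        if self.n_targets < 1 or self.n_distractors < 1 or self.repetitions_per_part < 1:
            raise ValueError("stimulus and repetition counts must be >= 1")
        if len(self.parts) == 0:
            raise ValueError("design needs at least one part")


@dataclass(frozen=True)
class GenerativeConfig:
    """All parameters of the synthetic cohort, on the logit scale.

    Defaults encode the study conditions: 25 controls vs 13 CPs, ages
    truncated-normal 37.3 +/- 17.9 on [18, 80], and group effects taken
    from the reported posterior estimates (beta_CP = -1.04,
    beta_CP*trial = -1.63, beta_CP*rotation = 0.31; BFFT beta_CP = -0.67,
    beta_CP*TV = -0.12, beta_CP*print = -0.30).
    """

    # cohort
    n_controls: int = 25
    n_cp: int = 13
    age_mean: float = 37.3
    age_sd: float = 17.9
    age_min: float = 18.0
    age_max: float = 80.0
    p_male: float = 0.5
    band_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    # recognition experiment fixed effects (logit scale)
    intercept: float = 3.0
    beta_age: float = -0.2  # per decade, age centered at 40
    beta_trial: float = -0.3  # target trials vs distractor trials
    beta_rotation: float = -0.6  # rotated part vs frontal part
    beta_cp: float = -1.04
    beta_cp_trial: float = -1.63
    beta_cp_rotation: float = 0.31

    # random effects
    sigma_intercept: float = 0.7
    sigma_trial_slope: float = 0.0

    # BFFT (famous-face free recall) fixed effects; media bands centered at 2.5
    n_bfft_items: int = 40
    bfft_intercept: float = 0.9
    bfft_beta_age: float = -0.3
    bfft_beta_gender: float = 0.2  # male vs female
    bfft_beta_tv: float = 0.15
    bfft_beta_print: float = 0.30
    bfft_beta_cp: float = -0.67
    bfft_beta_cp_tv: float = -0.12
    bfft_beta_cp_print: float = -0.30
    bfft_sigma_intercept: float = 0.7

    # questionnaire totals (15 items, 1..5 each => total in [15, 75])
    q_control_mean: float = 22.0
    q_control_sd: float = 5.0
    q_cp_mean: float = 50.0
    q_cp_sd: float = 10.0
    q_ability_rho: float = -0.55  # copula correlation of CP total with latent ability

    seed: int = 0

    def validate(self) -> None:
        if self.n_controls < 0 or self.n_cp < 0 or self.n_controls + self.n_cp < 1:
            raise ValueError("cohort sizes must be nonnegative and sum to >= 1")
        if self.sigma_intercept < 0 or self.sigma_trial_slope < 0 or self.bfft_sigma_intercept < 0:
            raise ValueError("random-effect standard deviations must be >= 0")
        if not (self.age_min < self.age_max):
            raise ValueError("age_min must be below age_max")
        if abs(sum(self.band_probs) - 1.0) > 1e-9 or len(self.band_probs) != 4:
            raise ValueError("band_probs must be 4 probabilities summing to 1")

    def replace(self, **kw) -> "GenerativeConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band_probs"] = list(self.band_probs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeConfig":
        d = dict(d)
        if "band_probs" in d:
            d["band_probs"] = tuple(d["band_probs"])
        return cls(**d)


def shoes_config(base: GenerativeConfig | None = None) -> GenerativeConfig:
    """Preset for the intra-class object (sneaker) recognition experiment.

    Lower baseline accuracy, a weaker group effect (beta_CP = -0.40 as
    reported), no group x condition interactions, and a nonzero random
    trial-type slope (the trial-type effect varied across participants in
    the object experiment and was modelled as an additional random effect).
    """
    base = base or GenerativeConfig()
    return base.replace(
        intercept=1.6,
        beta_cp=-0.40,
        beta_cp_trial=0.0,
        beta_cp_rotation=0.0,
        sigma_trial_slope=0.5,
    )


# ---------------------------------------------------------------------------
# participants
# ---------------------------------------------------------------------------

def score_questionnaire(ratings: Sequence[int]) -> int:
    """Total score of the 15 scored screening-questionnaire items.

    Each item is rated 1-5 (larger = more self-reported difficulty), so the
    total ranges from 15 to 75. Dummy items must be excluded by the caller.
    """
    ratings = list(ratings)
    if len(ratings) != 15:
        raise ValueError(f"expected exactly 15 scored ratings, got {len(ratings)}")
    total = 0
    for r in ratings:
        if r != int(r) or not (1 <= int(r) <= 5):
            raise ValueError(f"rating {r!r} outside the 1..5 scale")
        total += int(r)
    return total


def _truncated_ages(config: GenerativeConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Ages from a normal truncated to [age_min, age_max].

    The location parameter is adjusted so the truncated distribution's
    mean equals ``age_mean`` (plain truncation at these settings would
    shift the mean up by ~4 years).
    """
    lo, hi, sd = config.age_min, config.age_max, config.age_sd

    def trunc_mean(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return truncnorm.mean(a, b, loc=loc, scale=sd)

    loc = brentq(lambda m: trunc_mean(m) - config.age_mean, lo - 3 * sd, hi + 3 * sd, xtol=1e-8)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return truncnorm.rvs(a, b, loc=loc, scale=sd, size=n, random_state=rng)


def _ratings_from_total(total: int, rng: np.random.Generator) -> np.ndarray:
    """Random 15-item composition of ``total`` with each item in 1..5."""
    rem = int(total) - 15
    slots = np.repeat(np.arange(15), 4)  # each item can absorb 4 extra points
    take = rng.permutation(slots)[:rem]
    return 1 + np.bincount(take, minlength=15)


def generate_participants(config: GenerativeConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw the participant table: covariates plus latent abilities.

    Latent columns (``u0``, ``u_trial``, ``u0_bfft``) exist only in
    simulated cohorts; ingested data never need them. Questionnaire totals
    of CPs correlate negatively (Gaussian copula, ``q_ability_rho``) with
    the participant's latent recognition ability so that self-assessment
    tracks the simulated deficit.
    """
    config.validate()
    if config.n_controls + config.n_cp < 1:
        raise ValueError("empty cohort")
    seed = config.seed if seed is None else seed
    rng = substream(seed, "participants")
    qrng = substream(seed, "questionnaire")

    n = config.n_controls + config.n_cp
    group = np.array(["control"] * config.n_controls + ["CP"] * config.n_cp)
    ids = [f"C{i + 1:02d}" for i in range(config.n_controls)] + [
        f"P{i + 1:02d}" for i in range(config.n_cp)
    ]

    age = _truncated_ages(config, n, rng)
    gender = np.where(rng.random(n) < config.p_male, "male", "female")
    tv_band = rng.choice([1, 2, 3, 4], size=n, p=config.band_probs)
    print_band = rng.choice([1, 2, 3, 4], size=n, p=config.band_probs)

    u0 = rng.normal(0.0, config.sigma_intercept, size=n)
    u_trial = rng.normal(0.0, config.sigma_trial_slope, size=n) if config.sigma_trial_slope > 0 else np.zeros(n)
    u0_bfft = rng.normal(0.0, config.bfft_sigma_intercept, size=n)

    # questionnaire totals: copula-correlated with latent ability for CPs
    is_cp = group == "CP"
    ability_z = u0 / config.sigma_intercept if config.sigma_intercept > 0 else np.zeros(n)
    eps = qrng.normal(size=n)
    rho = config.q_ability_rho
    # CP totals correlate rho with latent ability (rho < 0: higher ability,
    # lower self-reported difficulty); control totals are independent noise.
    z_cp = rho * ability_z + np.sqrt(max(0.0, 1 - rho**2)) * eps
    z_total = np.where(is_cp, z_cp, eps)
    mean = np.where(is_cp, config.q_cp_mean, config.q_control_mean)
    sd = np.where(is_cp, config.q_cp_sd, config.q_control_sd)
    totals = np.clip(np.rint(mean + sd * z_total), 15, 75).astype(int)
    ratings = np.vstack([_ratings_from_total(t, qrng) for t in totals])

    df = pd.DataFrame(
        {
            "participant_id": ids,
            "group": group,
            "age": age,
            "gender": gender,
            "tv_band": tv_band,
            "print_band": print_band,
            "questionnaire_total": totals,
            "u0": u0,
            "u_trial": u_trial,
            "u0_bfft": u0_bfft,
        }
    )
    df["age_c"] = (df["age"] - 40.0) / 10.0
    for k in range(15):
        df[f"q{k + 1:02d}"] = ratings[:, k]
    assert (df["questionnaire_total"] == ratings.sum(axis=1)).all()
    return df


# ---------------------------------------------------------------------------
# trial schedules and responses
# ---------------------------------------------------------------------------

def generate_trial_schedule(design: StudyDesign, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Randomized presentation schedule for one participant (no responses).

    Each part is an unconstrained random permutation in which every
    stimulus occurs exactly ``repetitions_per_part`` times. Rotation is a
    part-level condition (part 1 rotated, part 2 frontal). The repetitions
    of each target within a part cycle through the illumination levels in
    a balanced way; distractors carry the base illumination label.
    """
    design.validate()
    rng = seed if isinstance(seed, np.random.Generator) else substream(int(seed), "schedule")

    targets = [f"t{i + 1}" for i in range(design.n_targets)]
    distractors = [f"d{i + 1}" for i in range(design.n_distractors)]
    n_illum = len(design.illumination_levels)

    parts = []
    for part_idx, rotation in enumerate(design.parts, start=1):
        stim = np.array((targets + distractors) * design.repetitions_per_part)
        order = rng.permutation(len(stim))
        stim = stim[order]
        trial_type = np.where(np.char.startswith(stim, "t"), "target", "distractor")
        # balanced illumination across the repetitions of each target
        illum = np.full(len(stim), "base", dtype=object)
        for t in targets:
            pos = np.flatnonzero(stim == t)
            cycle = np.tile(design.illumination_levels, len(pos) // n_illum + 1)[: len(pos)]
            illum[pos] = rng.permutation(cycle)
        parts.append(
            pd.DataFrame(
                {
                    "part": part_idx,
                    "trial_index": np.arange(1, len(stim) + 1),
                    "stimulus_id": stim,
                    "trial_type": trial_type,
                    "rotation": rotation,
                    "illumination": illum,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def _linear_predictor(participants: pd.DataFrame, trials: pd.DataFrame, config: GenerativeConfig) -> np.ndarray:
    required = {"age_c", "group", "u0", "u_trial"}
    missing = required - set(participants.columns)
    if missing:
        raise ValueError(f"participants table lacks columns {sorted(missing)}")
    p = participants.set_index("participant_id").loc[trials["participant_id"]]
    cp = (p["group"].to_numpy() == "CP").astype(float)
    target = (trials["trial_type"].to_numpy() == "target").astype(float)
    rotated = (trials["rotation"].to_numpy() == "rotated").astype(float)
    eta = (
        config.intercept
        + config.beta_age * p["age_c"].to_numpy()
        + config.beta_trial * target
        + config.beta_rotation * rotated
        + cp * (config.beta_cp + config.beta_cp_trial * target + config.beta_cp_rotation * rotated)
        + p["u0"].to_numpy()
        + p["u_trial"].to_numpy() * target
    )
    return eta


def simulate_responses(
    participants: pd.DataFrame,
    schedule: pd.DataFrame,
    config: GenerativeConfig,
    experiment: str = "faces_longterm",
    seed: int | None = None,
) -> pd.DataFrame:
    """Attach Bernoulli responses to a schedule for every participant.

    ``schedule`` may already carry a ``participant_id`` column (one row per
    participant-trial); otherwise the same schedule is replicated for each
    participant. Correct-response probability is the inverse logit of the
    linear predictor (fixed effects plus the participant's latent effects);
    given the latents, trials are independent.
    """
    seed = config.seed if seed is None else seed
    if "participant_id" not in schedule.columns:
        reps = []
        for pid in participants["participant_id"]:
            s = schedule.copy()
            s.insert(0, "participant_id", pid)
            reps.append(s)
        trials = pd.concat(reps, ignore_index=True)
    else:
        trials = schedule.copy()
    trials.insert(1, "experiment", experiment)

    eta = _linear_predictor(participants, trials, config)
    # crc32, not hash(): Python string hashing is randomized per process
    rng = substream(seed, "responses", extra=zlib.crc32(experiment.encode()) % (2**31))
    correct = (rng.random(len(trials)) < expit(eta)).astype(int)
    is_target = trials["trial_type"].to_numpy() == "target"
    response = np.where(
        is_target == correct.astype(bool), "target", "nontarget"
    )
    trials["response"] = response
    trials["correct"] = correct
    return trials


def simulate_experiment(
    participants: pd.DataFrame,
    design: StudyDesign,
    config: GenerativeConfig,
    experiment: str = "faces_longterm",
    seed: int | None = None,
) -> pd.DataFrame:
    """Full experiment: per-participant randomized schedules plus responses."""
    seed = config.seed if seed is None else seed
    schedules = []
    for k, pid in enumerate(participants["participant_id"]):
        s = generate_trial_schedule(design, substream(seed, "schedule", extra=k))
        s.insert(0, "participant_id", pid)
        schedules.append(s)
    schedule = pd.concat(schedules, ignore_index=True)
    return simulate_responses(participants, schedule, config, experiment, seed=seed)


def simulate_bfft(
    participants: pd.DataFrame,
    n_items: int | None = None,
    config: GenerativeConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-item famous-face free-recall outcomes.

    Logit-linear in age, gender, TV band, print band, group and
    group x media interactions, plus a participant random intercept.
    Media bands enter centered at 2.5 so the intercept refers to a
    mid-consumption participant.
    """
    config = config or GenerativeConfig()
    n_items = config.n_bfft_items if n_items is None else n_items
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    for col in ("tv_band", "print_band"):
        bands = participants[col].to_numpy()
        if ((bands < 1) | (bands > 4)).any():
            raise ValueError(f"{col} outside the 1..4 range")
    seed = config.seed if seed is None else seed

    p = participants
    cp = (p["group"].to_numpy() == "CP").astype(float)
    male = (p["gender"].to_numpy() == "male").astype(float)
    tv = p["tv_band"].to_numpy().astype(float) - 2.5
    pr = p["print_band"].to_numpy().astype(float) - 2.5
    eta = (
        config.bfft_intercept
        + config.bfft_beta_age * p["age_c"].to_numpy()
        + config.bfft_beta_gender * male
        + config.bfft_beta_tv * tv
        + config.bfft_beta_print * pr
        + cp * (config.bfft_beta_cp + config.bfft_beta_cp_tv * tv + config.bfft_beta_cp_print * pr)
        + p["u0_bfft"].to_numpy()
    )
    prob = expit(eta)
    rng = substream(seed, "bfft")
    rows = []
    for i, pid in enumerate(p["participant_id"]):
        recalled = (rng.random(n_items) < prob[i]).astype(int)
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "item_id": [f"item{j + 1:02d}" for j in range(n_items)],
                    "recalled": recalled,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# external short-term test scores and planted subtype profiles
# ---------------------------------------------------------------------------

# Archetype shifts (z units) on the eight external short-term tests. The three
# phenotypic subtypes mirror apperceptive (perceptual deficits cascading into
# association), amnestic-only (normal short-term performance), and
# face+object profiles; a fourth "diffuse" pattern has mild deficits.
_ARCHETYPE_EXTERNAL = {
    "apperceptive": dict(
        rt_faces=-3.0, pt80_faces=-3.0, rotation_faces=-2.5, learn_faces=-2.0, test_faces=-2.0
    ),
    "amnestic": {},
    "face_object": dict(
        rt_faces=-2.5, pt80_faces=-2.5, rotation_faces=-1.5, learn_faces=-1.0,
        test_faces=-1.0, rt_shoes=-2.5, pt80_shoes=-2.5, rotation_shoes=-1.5,
    ),
    "diffuse": {t: -0.8 for t in EXTERNAL_TESTS},
}
_ARCHETYPE_PROBS = {"apperceptive": 4 / 15, "amnestic": 4 / 15, "face_object": 3 / 15, "diffuse": 4 / 15}


def generate_external_scores(
    participants: pd.DataFrame,
    seed: int = 0,
    noise_sd: float = 0.7,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Precomputed z-score columns for the eight short-term tests.

    Controls are standard normal per column; each CP draws a phenotypic
    archetype and receives the archetype's shifts plus noise. Optionally a
    fraction of cells is set missing (NaN), emulating incomplete test
    batteries.
    """
    rng = substream(seed, "external")
    n = len(participants)
    is_cp = participants["group"].to_numpy() == "CP"
    z = rng.normal(size=(n, len(EXTERNAL_TESTS)))
    names = list(_ARCHETYPE_PROBS)
    probs = np.array([_ARCHETYPE_PROBS[k] for k in names])
    archetypes = np.where(is_cp, rng.choice(names, size=n, p=probs), "none")
    for i in range(n):
        if is_cp[i]:
            shift = _ARCHETYPE_EXTERNAL[archetypes[i]]
            z[i] = noise_sd * z[i] + np.array([shift.get(t, 0.0) for t in EXTERNAL_TESTS])
    if missing_rate > 0:
        mask = rng.random(z.shape) < missing_rate
        z[mask] = np.nan
    out = pd.DataFrame(z, columns=list(EXTERNAL_TESTS))
    out.insert(0, "participant_id", participants["participant_id"].to_numpy())
    out["archetype"] = archetypes
    return out


# Planted archetype means over the six summary columns used for clustering.
_PLANTED_COLUMNS = ("perceptual", "associative", "mnestic", "faces_total", "shoes_total", "overall")
_PLANTED_MEANS = {
    "apperceptive": (-3.0, -3.0, -3.0, -3.5, 0.0, -3.0),
    "amnestic": (0.0, 0.0, -4.0, -1.5, 0.0, -1.0),
    "face_object": (-3.0, -1.5, -1.5, -2.0, -3.0, -3.0),
}


def planted_subtype_cohort(
    n_per_type: int = 5,
    n_controls: int = 25,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Summary z-score table with three planted CP deficit archetypes.

    Controls are standard normal on every summary column; each archetype's
    CPs scatter around the archetype mean profile with within-archetype
    noise ``noise_sd``. Returns the table and the true archetype labels
    (controls labelled ``control``) for clustering-recovery checks.
    """
    rng = substream(seed, "planted")
    rows, labels, ids = [], [], []
    for i in range(n_controls):
        rows.append(rng.normal(size=len(_PLANTED_COLUMNS)))
        labels.append("control")
        ids.append(f"C{i + 1:02d}")
    k = 0
    for name, mu in _PLANTED_MEANS.items():
        for _ in range(n_per_type):
            rows.append(np.array(mu) + rng.normal(0.0, noise_sd, size=len(mu)))
            labels.append(name)
            k += 1
            ids.append(f"P{k:02d}")
    table = pd.DataFrame(rows, columns=list(_PLANTED_COLUMNS), index=pd.Index(ids, name="participant_id"))
    return table, pd.Series(labels, index=table.index, name="archetype")
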