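"""Signal-detection scoring of recognition trial tables.

Per participant and experiment: hit / miss / false-alarm / correct-rejection
counts, the overall error rate (misses + false alarms over all trials), and
the bias-free sensitivity d' = PHI^-1(H) - PHI^-1(F). Hit or false-alarm
rates of exactly 0 or 1 make the normal quantile infinite, so extreme rates
are adjusted before the transform; the default rule replaces 0 by 1/(2N)
and 1 by 1 - 1/(2N), a log-linear (+0.5 to all four counts) alternative is
selectable.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import norm

__all__ = ["ConfusionCounts", "DPrime", "confusion_counts", "error_rate", "dprime", "sdt_table"]


@dataclass(frozen=True)
class ConfusionCounts:
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    @property
    def n_target_trials(self) -> int:
        return self.hits + self.misses

    @property
    def n_distractor_trials(self) -> int:
        return self.false_alarms + self.correct_rejections

    @property
    def n_trials(self) -> int:
        return self.n_target_trials + self.n_distractor_trials


@dataclass(frozen=True)
class DPrime:
    value: float
    hit_rate_used: float
    fa_rate_used: float
    correction_applied: bool


def confusion_counts(
    trials: pd.DataFrame, participant_id: str | None = None, experiment: str | None = None
) -> ConfusionCounts:
    """Tabulate one participant's trials into the four response classes."""
    t = trials
    if participant_id is not None:
        t = t[t["participant_id"] == participant_id]
    if experiment is not None and "experiment" in t.columns:
        t = t[t["experiment"] == experiment]
    if len(t) == 0:
        raise ValueError(f"no trials found for participant={participant_id!r}, experiment={experiment!r}")
    target = t["trial_type"].to_numpy() == "target"
    correct = t["correct"].to_numpy().astype(bool)
    return ConfusionCounts(
        hits=int((target & correct).sum()),
        misses=int((target & ~correct).sum()),
        false_alarms=int((~target & ~correct).sum()),
        correct_rejections=int((~target & correct).sum()),
    )


def error_rate(counts: ConfusionCounts) -> float:
    """(misses + false alarms) / total trials."""
    if counts.n_trials == 0:
        raise ValueError("error rate undefined for zero trials")
    return (counts.misses + counts.false_alarms) / counts.n_trials


def _adjusted_rates(counts: ConfusionCounts, correction: str) -> tuple[float, float, bool]:
    nt, nd = counts.n_target_trials, counts.n_distractor_trials
    if correction == "loglinear":
        return (counts.hits + 0.5) / (nt + 1), (counts.false_alarms + 0.5) / (nd + 1), True
    if correction != "half":
        raise ValueError(f"unknown correction rule {correction!r}")
    h, f = counts.hits / nt, counts.false_alarms / nd
    applied = False
    if h == 0.0:
        h, applied = 1 / (2 * nt), True
    elif h == 1.0:
        h, applied = 1 - 1 / (2 * nt), True
    if f == 0.0:
        f, applied = 1 / (2 * nd), True
    elif f == 1.0:
        f, applied = 1 - 1 / (2 * nd), True
    return h, f, applied


def dprime(counts: ConfusionCounts, correction: str = "half") -> DPrime:
    """Sensitivity d' from hit and false-alarm rates.

    ``correction``: ``"half"`` (default) nudges only extreme rates by the
    1/(2N) rule; ``"loglinear"`` adds 0.5 to every count unconditionally.
    """
    if counts.n_target_trials == 0 or counts.n_distractor_trials == 0:
        raise ValueError("d' needs at least one target and one distractor trial")
    h, f, applied = _adjusted_rates(counts, correction)
    return DPrime(
        value=float(norm.ppf(h) - norm.ppf(f)),
        hit_rate_used=h,
        fa_rate_used=f,
        correction_applied=applied,
    )


def sdt_table(trials: pd.DataFrame, correction: str = "half", by_part: bool = False) -> pd.DataFrame:
    """Signal-detection summary per participant and experiment.

    Pools the two experiment parts by default (participant-level d'); with
    ``by_part`` each part gets its own row.
    """
    keys = ["participant_id"]
    if "experiment" in trials.columns:
        keys.append("experiment")
    if by_part:
        keys.append("part")
    rows = []
    for key, t in trials.groupby(keys, sort=True):
        c = confusion_counts(t)
        d = dprime(c, correction)
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            dict(zip(keys, key))
            | {
                "hits": c.hits,
                "misses": c.misses,
                "false_alarms": c.false_alarms,
                "correct_rejections": c.correct_rejections,
                "error_rate": error_rate(c),
                "dprime": d.value,
            }
        )
    return pd.DataFrame(rows)
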