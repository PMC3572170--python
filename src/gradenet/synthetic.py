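"""Synthetic cohort generator with an optional planted contagion effect.

The real study population — one high-school junior class surveyed about
its friendships, with official GPA records at two timepoints one year
apart — is IRB-restricted, so every pipeline stage runs on generated
cohorts that emulate its stated features: roughly 158 students, three
nested tiers of directed self-reported ties with nobody friendless, a
negatively skewed GPA distribution near the top of a 0-100 scale, and
an overall upward GPA drift across the year.

Contagion is planted in GPA space, not rank space: each student's
second-year GPA moves toward their friends' first-year average with
coefficient ``contagion_delta``.  The analysis pipeline must then
detect the effect *through* the rank transform, which is the honest
end-to-end exercise.  ``contagion_delta = 0`` gives exact null cohorts
for calibration experiments.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TextIO

import numpy as np

from .ranking import GpaTable
from .survey import SurveyResponse

#: Contagion coefficient used by the suite's strong-effect experiments.
STRONG_CONTAGION_DELTA = 0.5

# Homophily kernel bandwidth, in GPA points.
_HOMOPHILY_BW = 5.0


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; the defaults are the study conditions emulated.

    ``gpa_shape`` are Beta shape parameters (a, b) for GPA/100 at the
    first timepoint; the default (8, 2) gives sample skewness around
    -0.8 with mass near the top of the scale.  ``drift`` is the maximum
    upward GPA shift over the year, attenuated linearly toward the top
    of the scale so the shift is order-preserving and never overshoots
    100.  ``out_degree_means`` are per-student Poisson means of the
    *exclusive* tier out-degrees; the friend tier is clipped to at least
    1 so no student is friendless.  ``homophily`` in [0, 1] biases
    best-friend choices toward classmates with similar GPA.
    """

    n_students: int = 158
    out_degree_means: tuple[float, float, float] = (45.0, 7.0, 2.5)  # acq, friend, best
    gpa_shape: tuple[float, float] = (8.0, 2.0)
    drift: float = 5.0
    contagion_delta: float = 0.0
    noise_sd: float = 3.0
    homophily: float = 0.5
    related_fraction: float = 0.02
    incomplete_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.n_students
        if n < 3:
            raise ValueError("need at least 3 students")
        if any(m < 0 or m > n - 1 for m in self.out_degree_means):
            raise ValueError("out-degree means must lie in [0, n-1]")
        if sum(self.out_degree_means) > n - 1:
            raise ValueError("summed tier out-degree means exceed n-1; degree config infeasible")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.homophily <= 1:
            raise ValueError("homophily must lie in [0, 1]")
        if not 0 <= self.incomplete_count <= n:
            raise ValueError("incomplete_count must lie in [0, n_students]")
        a, b = self.gpa_shape
        if a <= 0 or b <= 0:
            raise ValueError("gpa_shape parameters must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_degree_means"] = list(self.out_degree_means)
        d["gpa_shape"] = list(self.gpa_shape)
        return d


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[SurveyResponse], GpaTable, GpaTable]:
    """Generate survey responses and two-timepoint GPA tables.

    Returns ``(responses, gpa_t0, gpa_t1)``.  Exclusive tier neighbor
    sets are disjoint by construction (best friends drawn first, with
    homophily bias, then friends, then acquaintances); all remaining
    classmates are rated "unknown" except a small "related" fraction.
    ``incomplete_count`` responses each have one rating row deleted —
    the minimal violation of completeness.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_students
    width = max(3, len(str(n - 1)))
    ids = [f"S{i:0{width}d}" for i in range(n)]

    a, b = config.gpa_shape
    gpa0 = 100.0 * rng.beta(a, b, size=n)

    mean_acq, mean_friend, mean_best = config.out_degree_means
    k_best = rng.poisson(mean_best, size=n).clip(0, n - 2)
    k_friend = np.maximum(1, rng.poisson(mean_friend, size=n))
    k_friend = np.minimum(k_friend, n - 1 - k_best)
    k_acq = rng.poisson(mean_acq, size=n)
    k_acq = np.minimum(k_acq, n - 1 - k_best - k_friend)

    best_sets: list[np.ndarray] = []
    friend_sets: list[np.ndarray] = []
    acq_sets: list[np.ndarray] = []
    all_idx = np.arange(n)
    for u in range(n):
        others = np.delete(all_idx, u)
        if k_best[u] > 0:
            w = np.exp(-config.homophily * np.abs(gpa0[others] - gpa0[u]) / _HOMOPHILY_BW)
            w /= w.sum()
            best = rng.choice(others, size=k_best[u], replace=False, p=w)
        else:
            best = np.empty(0, dtype=int)
        pool = np.setdiff1d(others, best, assume_unique=True)
        friends = rng.choice(pool, size=k_friend[u], replace=False)
        pool2 = np.setdiff1d(pool, friends, assume_unique=True)
        acq = rng.choice(pool2, size=k_acq[u], replace=False)
        best_sets.append(best)
        friend_sets.append(friends)
        acq_sets.append(acq)

    friend_mean_gpa = np.array([gpa0[f].mean() for f in friend_sets])
    shift = config.drift * (100.0 - gpa0) / 100.0
    gpa1 = (
        gpa0
        + shift
        + config.contagion_delta * (friend_mean_gpa - gpa0)
        + rng.normal(0.0, config.noise_sd, size=n)
    )
    gpa1 = np.clip(gpa1, 0.0, 100.0)

    responses: list[SurveyResponse] = []
    for u in range(n):
        ratings: dict[str, str] = {}
        for v in best_sets[u]:
            ratings[ids[v]] = "best_friend"
        for v in friend_sets[u]:
            ratings[ids[v]] = "friend"
        for v in acq_sets[u]:
            ratings[ids[v]] = "acquaintance"
        rated = set(best_sets[u]) | set(friend_sets[u]) | set(acq_sets[u])
        rest = [v for v in range(n) if v != u and v not in rated]
        related = rng.random(len(rest)) < config.related_fraction
        for v, is_rel in zip(rest, related):
            ratings[ids[v]] = "related" if is_rel else "unknown"
        responses.append(SurveyResponse(ids[u], ratings, complete=True))

    if config.incomplete_count:
        who = rng.choice(n, size=config.incomplete_count, replace=False)
        for u in who:
            r = responses[u]
            targets = sorted(r.ratings)
            drop = targets[int(rng.integers(len(targets)))]
            del r.ratings[drop]
            responses[u] = SurveyResponse(r.respondent_id, r.ratings, complete=False)

    t0 = GpaTable("t0", {ids[i]: float(gpa0[i]) for i in range(n)})
    t1 = GpaTable("t1", {ids[i]: float(gpa1[i]) for i in range(n)})
    return responses, t0, t1


def generate_null_cohort(
    config: CohortConfig,
) -> tuple[list[SurveyResponse], GpaTable, GpaTable]:
    """A cohort with the contagion coefficient forced to zero."""
    return generate_cohort(replace(config, contagion_delta=0.0))


def write_survey_csv(responses: list[SurveyResponse], stream: TextIO) -> None:
    """Emit the survey CSV dialect the pipeline consumes."""
    stream.write("respondent_id,target_id,relation\n")
    for r in responses:
        for target, rel in sorted(r.ratings.items()):
            stream.write(f"{r.respondent_id},{target},{rel}\n")


def write_roster_csv(gpa_t0: GpaTable, gpa_t1: GpaTable, stream: TextIO) -> None:
    """Emit the roster CSV (``student_id,gpa_t0,gpa_t1``)."""
    stream.write("student_id,gpa_t0,gpa_t1\n")
    for sid in sorted(gpa_t0.values):
        stream.write(f"{sid},{gpa_t0.values[sid]:.6f},{gpa_t1.values[sid]:.6f}\n")
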