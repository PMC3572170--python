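"""Class rankings, academic progress, and social-environment statistics.

Raw GPA distributions in this setting are heavily left-skewed (most of
the class sits near the top of the scale) and drift upward between
timepoints, so all analysis runs on order statistics.  A student's
*academic ranking* g is the cohort size minus their GPA position, so
larger g means higher standing and a tie-free cohort gets exactly
{0, 1, ..., N-1}.  *Academic progress* y is the change in g between the
two timepoints one year apart.

The *social environment statistic* x_i of student u at tier i is the
difference, in rank units, between u's self-reported tier-i neighbors'
average standing and u's own standing: positive x means the student's
friends outrank them.  The phrase "neighbors' average GPA" admits two
readings, both implemented:

``mean_neighbor_rank`` (default)
    x_u = mean(g over out-neighbors) - g_u.  Stays entirely in rank
    units, like g and y.
``rank_of_mean_gpa``
    Average the neighbors' raw GPAs first, place that mean on the class
    ranking scale (classmates with lower GPA counted fully, ties counted
    half, the student excluded), then subtract g_u.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

TIE_POLICIES = ("average", "dense", "random")
X_MODES = ("mean_neighbor_rank", "rank_of_mean_gpa")
UNDEFINED_POLICIES = ("exclude", "zero")


@dataclass
class GpaTable:
    """GPA of every student at one timepoint, on the school's 0-100 scale."""

    timepoint: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        for sid, v in self.values.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite GPA for {sid!r}: {v!r}")
            if v < 0:
                raise ValueError(f"negative GPA for {sid!r}: {v!r}")


@dataclass
class RankingTable:
    """Class rankings g at one timepoint; higher rank = higher GPA."""

    timepoint: str
    n: int
    rank: dict[str, float]
    tie_policy: str


@dataclass
class EnvironmentScores:
    """Per-student environment statistics x (by tier) and progress y.

    ``x`` maps ``(student_id, tier)`` to the environment score;
    ``undefined`` records (student, tier) pairs with no out-neighbors at
    that tier, whose handling is governed by ``undefined_policy``
    ("exclude": absent from ``x``; "zero": present with x = 0).
    """

    x: dict[tuple[str, str], float]
    y: dict[str, float]
    mode: str
    undefined_policy: str
    undefined: set[tuple[str, str]] = field(default_factory=set)


def read_roster(stream: TextIO | Iterable[str]) -> tuple[GpaTable, GpaTable]:
    """Parse a roster CSV (``student_id,gpa_t0,gpa_t1``) into two GPA tables."""
    reader = csv.reader(iter(stream))
    try:
        header = next(reader)
    except StopIteration:
        raise ValueError("empty roster CSV") from None
    expected = ["student_id", "gpa_t0", "gpa_t1"]
    if [h.strip().lower() for h in header] != expected:
        raise ValueError(f"bad roster header {header!r}; expected {','.join(expected)}")
    t0: dict[str, float] = {}
    t1: dict[str, float] = {}
    for lineno, row in enumerate(reader, start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != 3:
            raise ValueError(f"line {lineno}: expected 3 fields, got {len(row)}")
        sid = row[0].strip()
        if sid in t0:
            raise ValueError(f"line {lineno}: duplicate student {sid!r}")
        try:
            t0[sid] = float(row[1])
            t1[sid] = float(row[2])
        except ValueError:
            raise ValueError(f"line {lineno}: non-numeric GPA in {row!r}") from None
    return GpaTable("t0", t0), GpaTable("t1", t1)


def gpa_to_ranking(
    gpas: GpaTable,
    tie_policy: str = "average",
    rng: np.random.Generator | None = None,
) -> RankingTable:
    """Transform a GPA table into class rankings.

    Position 1 is the highest GPA and ranking = N - position, so the
    best student has rank N-1 and the worst rank 0.  Under the
    "average" policy tied students share the mean of the rankings they
    would span; "dense" collapses ties onto consecutive integers;
    "random" breaks ties uniformly at random (requires ``rng``).
    """
    if tie_policy not in TIE_POLICIES:
        raise ValueError(f"unknown tie_policy {tie_policy!r}; expected one of {TIE_POLICIES}")
    ids = list(gpas.values)
    vals = np.array([gpas.values[s] for s in ids], dtype=float)
    n = len(ids)
    if n < 2:
        raise ValueError("ranking requires at least 2 students")
    if tie_policy == "average":
        g = rankdata(vals, method="average") - 1.0
    elif tie_policy == "dense":
        g = rankdata(vals, method="dense") - 1.0
    else:
        if rng is None:
            raise ValueError("tie_policy 'random' requires an rng")
        order = np.lexsort((rng.random(n), vals))  # ascending GPA, random ties
        g = np.empty(n)
        g[order] = np.arange(n, dtype=float)
    return RankingTable(
        timepoint=gpas.timepoint,
        n=n,
        rank={s: float(r) for s, r in zip(ids, g)},
        tie_policy=tie_policy,
    )


def academic_progress(
    rank_t0: RankingTable, rank_t1: RankingTable
) -> dict[str, float]:
    """Per-student progress y = rank_t1 - rank_t0 over identical cohorts."""
    c0, c1 = set(rank_t0.rank), set(rank_t1.rank)
    if c0 != c1:
        diff = sorted(c0 ^ c1)
        raise ValueError(f"cohort mismatch between timepoints; symmetric difference: {diff}")
    return {s: rank_t1.rank[s] - rank_t0.rank[s] for s in rank_t0.rank}


def _rank_of_mean_gpa(mean_gpa: float, own_id: str, gpas: GpaTable) -> float:
    """Place a GPA value on the class ranking scale, excluding ``own_id``.

    Classmates strictly below the value count fully, exact ties count
    half — the continuous analogue of the average-tie rank transform.
    """
    below = 0.0
    for sid, v in gpas.values.items():
        if sid == own_id:
            continue
        if v < mean_gpa:
            below += 1.0
        elif v == mean_gpa:
            below += 0.5
    return below


def tier_environment(
    net,
    gpas_t0: GpaTable | None,
    rank_t0: RankingTable,
    mode: str = "mean_neighbor_rank",
) -> dict[str, float]:
    """Environment score x for every node of one tier network.

    Neighbors of u are the targets of u's outgoing (self-reported)
    edges.  Nodes with no out-neighbors are simply absent from the
    result; the caller decides how to treat them.
    """
    if mode not in X_MODES:
        raise ValueError(f"unknown x mode {mode!r}; expected one of {X_MODES}")
    if mode == "rank_of_mean_gpa" and gpas_t0 is None:
        raise ValueError("mode 'rank_of_mean_gpa' requires the t0 GPA table")
    missing = [u for u in net.nodes if u not in rank_t0.rank]
    if missing:
        raise ValueError(f"network nodes outside the ranking cohort: {missing}")
    out: dict[str, float] = {}
    for u, nbrs in net.out_neighbors().items():
        if not nbrs:
            continue
        if mode == "mean_neighbor_rank":
            x = float(np.mean([rank_t0.rank[v] for v in nbrs])) - rank_t0.rank[u]
        else:
            m = float(np.mean([gpas_t0.values[v] for v in nbrs]))
            x = _rank_of_mean_gpa(m, u, gpas_t0) - rank_t0.rank[u]
        out[u] = x
    return out


def environment_scores(
    nets: Mapping[str, "TierNetwork"],
    gpas_t0: GpaTable | None,
    rank_t0: RankingTable,
    y: Mapping[str, float],
    mode: str = "mean_neighbor_rank",
    undefined_policy: str = "zero",
) -> EnvironmentScores:
    """Assemble the full environment-score table over one or more tiers.

    ``nets`` maps tier labels to networks built from the same retained
    cohort.  x is always computed from timepoint-0 quantities only.
    """
    if undefined_policy not in UNDEFINED_POLICIES:
        raise ValueError(
            f"unknown undefined_policy {undefined_policy!r}; expected one of {UNDEFINED_POLICIES}"
        )
    x: dict[tuple[str, str], float] = {}
    undefined: set[tuple[str, str]] = set()
    for tier, net in nets.items():
        per = tier_environment(net, gpas_t0, rank_t0, mode=mode)
        for u in net.nodes:
            if u in per:
                x[(u, tier)] = per[u]
            else:
                undefined.add((u, tier))
                if undefined_policy == "zero":
                    x[(u, tier)] = 0.0
    if undefined and undefined_policy == "zero":
        logger.warning(
            "%d (student, tier) pairs had no out-neighbors; x set to 0", len(undefined)
        )
    return EnvironmentScores(
        x=x, y=dict(y), mode=mode, undefined_policy=undefined_policy, undefined=undefined
    )


def _tier_column(tier: str) -> str:
    for stem, col in (
        ("acquaintance", "x_acquaintance"),
        ("friend", "x_friend"),
        ("best", "x_best_friend"),
    ):
        if tier.startswith(stem):
            return col
    raise ValueError(f"cannot map tier {tier!r} onto a predictor column")


def scores_frame(scores: EnvironmentScores, g: RankingTable) -> pd.DataFrame:
    """Tabulate g, the per-tier x columns and y, one row per student.

    Rows are indexed by student id, ordered by id.  (student, tier)
    pairs excluded under the "exclude" policy appear as NaN.
    """
    tiers = sorted({t for _, t in scores.x} | {t for _, t in scores.undefined})
    students = sorted(scores.y)
    data: dict[str, list[float]] = {"g": [g.rank[s] for s in students]}
    for tier in tiers:
        col = _tier_column(tier)
        data[col] = [scores.x.get((s, tier), np.nan) for s in students]
    data["y"] = [scores.y[s] for s in students]
    return pd.DataFrame(data, index=pd.Index(students, name="student_id"))
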