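"""Out-degree-preserving network randomization and the permutation test.

The environment score x and progress y are inherently positively
correlated: a student with high-GPA friends tends to sit low in the
class and has more room to rise.  The null model therefore keeps each
student's number of outgoing friendship nominations fixed — preserving
reporting propensity — while reassigning the targets uniformly at
random among the other students, destroying any real social structure.
Recomputing x on each randomized network and correlating it with the
*unchanged* y yields the null distribution of Pearson's r; the observed
r is compared against it with an add-one empirical p-value, so the test
can never report p = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .inference import pearson_r
from .ranking import GpaTable, RankingTable, tier_environment
from .survey import TierNetwork

logger = logging.getLogger(__name__)


@dataclass
class EnvironmentRecomputer:
    """Recompute x from an arbitrary network with fixed mode/policy.

    Passed to :func:`null_distribution` so each randomized replicate
    uses exactly the same x definition as the observed analysis.
    Instances of this class enable a vectorized rewiring path; any other
    callable ``TierNetwork -> {student: x}`` is run per replicate.
    """

    rank_t0: RankingTable
    mode: str = "mean_neighbor_rank"
    gpas_t0: GpaTable | None = None

    def __call__(self, net: TierNetwork) -> dict[str, float]:
        return tier_environment(net, self.gpas_t0, self.rank_t0, mode=self.mode)


@dataclass
class PermutationResult:
    """Observed r, its randomized-network null distribution and summary.

    ``null_rs`` has one entry per replicate; replicates whose x series
    degenerated to a constant are recorded as NaN and excluded from the
    p-value and summary.  ``summary`` is (min, Q1, median, Q3, max) of
    the valid null values — the box-whisker view of the null.
    """

    observed_r: float
    null_rs: np.ndarray
    n_reps: int
    empirical_p: float
    alternative: str
    summary: tuple[float, float, float, float, float]
    seed: int | None
    n_missing: int = 0

    @property
    def observed_exceeds_null_max(self) -> bool:
        return bool(self.observed_r > np.nanmax(self.null_rs))

    def to_dict(self) -> dict:
        return {
            "observed_r": self.observed_r,
            "n_reps": self.n_reps,
            "empirical_p": self.empirical_p,
            "alternative": self.alternative,
            "summary": {
                k: v
                for k, v in zip(("min", "q1", "median", "q3", "max"), self.summary)
            },
            "seed": self.seed,
            "n_missing": self.n_missing,
            "observed_exceeds_null_max": self.observed_exceeds_null_max,
            "null_rs": [None if np.isnan(v) else float(v) for v in self.null_rs],
        }


def _as_rng(rng) -> tuple[np.random.Generator, int | None]:
    if isinstance(rng, np.random.Generator):
        return rng, None
    seed = int(rng)
    return np.random.default_rng(seed), seed


def _sample_targets(u: int, k: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """k distinct targets for node u, uniform over the other n-1 nodes."""
    idx = rng.choice(n - 1, size=k, replace=False)
    return idx + (idx >= u)


def randomize_out_degree_preserving(
    net: TierNetwork, rng
) -> TierNetwork:
    """Rewire a network keeping every node's out-degree fixed.

    Each node's new targets are drawn uniformly without replacement from
    the other n-1 nodes: no self-loops, no duplicate edges, in-degrees
    unconstrained.  A node already pointing at everyone else keeps a
    forced (unchanged up to order) neighborhood.
    """
    gen, _ = _as_rng(rng)
    nodes = list(net.nodes)
    n = len(nodes)
    if n < 2:
        raise ValueError("rewiring requires at least 2 nodes")
    deg = net.out_degrees()
    edges: list[tuple[str, str]] = []
    for u_idx, u in enumerate(nodes):
        k = deg[u]
        if k > n - 1:
            raise ValueError(f"node {u!r} has out-degree {k} > n-1 = {n - 1}")
        if k == 0:
            continue
        if k == n - 1:
            logger.debug("node %r has full out-degree; neighborhood forced", u)
        targets = _sample_targets(u_idx, k, n, gen)
        edges.extend((u, nodes[t]) for t in targets)
    return TierNetwork(tier=net.tier, mode=net.mode, nodes=net.nodes, edges=tuple(edges))


def empirical_p(
    observed_r: float, null_rs: Sequence[float], alternative: str = "greater"
) -> float:
    """Add-one empirical p-value of the observed statistic.

    greater: p = (1 + #{null >= observed}) / (m + 1); two_sided doubles
    the smaller one-sided p, capped at 1.  NaN entries (missing
    replicates) are ignored.
    """
    arr = np.asarray(null_rs, dtype=float)
    arr = arr[~np.isnan(arr)]
    m = len(arr)
    if m == 0:
        raise ValueError("empty null distribution")
    p_greater = (1 + int(np.sum(arr >= observed_r))) / (m + 1)
    if alternative == "greater":
        return p_greater
    if alternative == "two_sided":
        p_less = (1 + int(np.sum(arr <= observed_r))) / (m + 1)
        return min(1.0, 2.0 * min(p_greater, p_less))
    raise ValueError(f"unknown alternative {alternative!r}")


def summarize_null(null_rs: Sequence[float]) -> tuple[float, float, float, float, float]:
    """(min, Q1, median, Q3, max) with linearly interpolated quartiles."""
    arr = np.asarray(null_rs, dtype=float)
    arr = arr[~np.isnan(arr)]
    if len(arr) == 0:
        raise ValueError("empty null distribution")
    q = np.percentile(arr, [0, 25, 50, 75, 100], method="linear")
    return tuple(float(v) for v in q)  # type: ignore[return-value]


def _aligned_pearson(
    x: Mapping[str, float], y: Mapping[str, float]
) -> float:
    students = sorted(set(x) & set(y))
    xv = np.array([x[s] for s in students])
    yv = np.array([y[s] for s in students])
    return pearson_r(xv, yv).r


def _fast_null_rs(
    net: TierNetwork,
    recomputer: EnvironmentRecomputer,
    y: Mapping[str, float],
    n_reps: int,
    gen: np.random.Generator,
) -> np.ndarray:
    """Vectorized rewiring + x recomputation + correlation, one r per rep.

    Each replicate draws an independent uniform permutation of the other
    n-1 nodes per student (via argsort of i.i.d. uniforms) and takes the
    first k_u entries — exactly uniform sampling without replacement.
    """
    nodes = list(net.nodes)
    n = len(nodes)
    ranks = np.array([recomputer.rank_t0.rank[u] for u in nodes])
    deg = net.out_degrees()
    k = np.array([deg[u] for u in nodes])
    yv = np.array([y[u] for u in nodes])
    mask = k > 0
    if mask.sum() < 3:
        raise ValueError("fewer than 3 students with out-neighbors")
    yv_m = yv[mask]
    if np.ptp(yv_m) == 0:
        raise ValueError("progress y is constant; correlation undefined")
    rows = np.arange(n)
    k_m = k[mask]
    if recomputer.mode == "rank_of_mean_gpa":
        gpas = np.array([recomputer.gpas_t0.values[u] for u in nodes])
        cohort = np.array(sorted(recomputer.gpas_t0.values.values()))
    out = np.empty(n_reps)
    for rep in range(n_reps):
        order = np.argsort(gen.random((n, n - 1)), axis=1)
        mapped = order + (order >= rows[:, None])
        if recomputer.mode == "mean_neighbor_rank":
            cs = np.cumsum(ranks[mapped], axis=1)
            xm = cs[rows[mask], k_m - 1] / k_m
            x = xm - ranks[mask]
        else:
            cs = np.cumsum(gpas[mapped], axis=1)
            m_u = cs[rows[mask], k_m - 1] / k_m
            below = np.searchsorted(cohort, m_u, side="left").astype(float)
            ties = np.searchsorted(cohort, m_u, side="right") - below
            own = gpas[mask]
            below -= own < m_u
            ties -= own == m_u
            x = below + 0.5 * ties - ranks[mask]
        if np.ptp(x) == 0:
            out[rep] = np.nan
            continue
        xc = x - x.mean()
        yc = yv_m - yv_m.mean()
        out[rep] = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    return out


def null_distribution(
    net: TierNetwork,
    scores_builder: Callable[[TierNetwork], Mapping[str, float]],
    y: Mapping[str, float],
    n_reps: int,
    rng,
    alternative: str = "greater",
) -> PermutationResult:
    """Permutation test of the x/y correlation under network rewiring.

    ``scores_builder`` recomputes every student's x from a network; it
    is applied once to the real network (observed r) and once per
    rewired replicate.  y and the rankings are never permuted.  A
    replicate whose x series is constant is recorded as missing; more
    than 10% missing raises.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    gen, seed = _as_rng(rng)
    missing_y = [u for u in net.nodes if u not in y]
    if missing_y:
        raise ValueError(f"students without progress values: {missing_y}")
    observed_x = scores_builder(net)
    observed = _aligned_pearson(observed_x, y)

    if isinstance(scores_builder, EnvironmentRecomputer):
        null_rs = _fast_null_rs(net, scores_builder, y, n_reps, gen)
    else:
        null_rs = np.empty(n_reps)
        for rep in range(n_reps):
            rewired = randomize_out_degree_preserving(net, gen)
            x = scores_builder(rewired)
            try:
                null_rs[rep] = _aligned_pearson(x, y)
            except ValueError:
                logger.warning("replicate %d degenerate (constant series); recorded missing", rep)
                null_rs[rep] = np.nan

    n_missing = int(np.isnan(null_rs).sum())
    if n_missing > 0.1 * n_reps:
        raise ValueError(
            f"{n_missing}/{n_reps} replicates degenerate; null distribution unusable"
        )
    if n_missing:
        logger.warning("%d/%d replicates recorded missing", n_missing, n_reps)
    return PermutationResult(
        observed_r=observed,
        null_rs=null_rs,
        n_reps=n_reps,
        empirical_p=empirical_p(observed, null_rs, alternative),
        alternative=alternative,
        summary=summarize_null(null_rs),
        seed=seed,
        n_missing=n_missing,
    )
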