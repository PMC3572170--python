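"""Sociometric survey ingestion and tiered friendship-network construction.

A sociometric survey hands every respondent the full class roster and asks
them to rate each classmate as a best/close friend, a friend, an
acquaintance, someone unknown, or a relative.  The first three levels
define three nested directed networks over the cohort: an edge ``(u, v)``
means *u reported the relation about v*, so ties are self-reported and
deliberately left unreciprocated.

Networks can be built *cumulatively* (a tier plus all stronger tiers —
the nesting used for whole-network metrics) or *exclusively* (exactly one
tier — the disjoint neighbor sets used as separate regression
predictors).  ``unknown`` and ``related`` ratings are kept in the data
model for round-trip fidelity but never produce edges.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

#: The five admissible relation levels, strongest friendship first.
RELATION_LEVELS = ("best_friend", "friend", "acquaintance", "unknown", "related")

#: Strength of each edge-producing relation (larger = stronger tie).
_STRENGTH = {"acquaintance": 1, "friend": 2, "best_friend": 3}

#: Cumulative tier labels -> minimum relation strength included.
CUMULATIVE_TIERS = {"acquaintance_plus": 1, "friend_plus": 2, "best_only": 3}

#: Exclusive tier labels -> the single relation included.
EXCLUSIVE_TIERS = {
    "acquaintance_only": "acquaintance",
    "friend_only": "friend",
    "best_only": "best_friend",
}


class SurveyParseError(ValueError):
    """Malformed survey CSV (bad header, unknown relation string...)."""


class SurveyValidationError(ValueError):
    """Structurally valid CSV that violates survey semantics."""


@dataclass
class SurveyResponse:
    """One respondent's relation rating of every other roster member.

    ``complete`` is True iff the respondent rated every roster member
    other than themselves exactly once.
    """

    respondent_id: str
    ratings: dict[str, str]
    complete: bool

    def __post_init__(self) -> None:
        if self.respondent_id in self.ratings:
            raise SurveyValidationError(
                f"respondent {self.respondent_id!r} rated themselves"
            )
        for target, rel in self.ratings.items():
            if rel not in RELATION_LEVELS:
                raise SurveyValidationError(
                    f"unknown relation {rel!r} for {self.respondent_id!r} -> {target!r}"
                )


@dataclass
class TierNetwork:
    """A directed friendship network at one tier level.

    ``edges`` are ordered ``(source, target)`` pairs: the source reported
    the relation about the target.  No self-loops, no duplicates, all
    endpoints in ``nodes``.
    """

    tier: str
    mode: str
    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        seen: set[tuple[str, str]] = set()
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop at {u!r}")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge ({u!r}, {v!r}) has endpoint outside nodes")
            if (u, v) in seen:
                raise ValueError(f"duplicate edge ({u!r}, {v!r})")
            seen.add((u, v))

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.edges)

    def out_neighbors(self) -> dict[str, tuple[str, ...]]:
        """Targets of each node's outgoing edges, in edge order."""
        nbrs: dict[str, list[str]] = {u: [] for u in self.nodes}
        for u, v in self.edges:
            nbrs[u].append(v)
        return {u: tuple(vs) for u, vs in nbrs.items()}

    def out_degrees(self) -> dict[str, int]:
        deg = {u: 0 for u in self.nodes}
        for u, _ in self.edges:
            deg[u] += 1
        return deg

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass
class NetworkMetrics:
    """Whole-network summary statistics of one tier network.

    ``out_ccdf``/``in_ccdf`` are complementary cumulative degree
    distributions: element ``k`` is the fraction of nodes with degree
    >= ``k``, reported at every integer from 0 to the maximum degree.
    """

    density: float
    transitivity: float
    avg_clustering: float
    out_ccdf: tuple[float, ...]
    in_ccdf: tuple[float, ...]
    n_components: int
    n_isolated: int

    def to_dict(self) -> dict:
        return {
            "density": self.density,
            "transitivity": self.transitivity,
            "avg_clustering": self.avg_clustering,
            "out_ccdf": list(self.out_ccdf),
            "in_ccdf": list(self.in_ccdf),
            "n_components": self.n_components,
            "n_isolated": self.n_isolated,
        }


def read_survey(
    stream: TextIO | Iterable[str], roster: Sequence[str]
) -> list[SurveyResponse]:
    """Parse a survey CSV into one :class:`SurveyResponse` per respondent.

    The CSV must have header ``respondent_id,target_id,relation``;
    relation strings are matched case-insensitively against the five
    levels.  A respondent is complete iff every non-self roster member
    has exactly one rating row; a duplicated rating for the same target
    is a validation error, not a silent overwrite.
    """
    roster_set = set(roster)
    if len(roster_set) != len(roster):
        raise SurveyValidationError("roster contains duplicate student ids")
    reader = csv.reader(iter(stream))
    try:
        header = next(reader)
    except StopIteration:
        raise SurveyParseError("empty survey CSV") from None
    expected = ["respondent_id", "target_id", "relation"]
    if [h.strip().lower() for h in header] != expected:
        raise SurveyParseError(
            f"bad header {header!r}; expected {','.join(expected)}"
        )

    ratings: dict[str, dict[str, str]] = {}
    for lineno, row in enumerate(reader, start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != 3:
            raise SurveyParseError(f"line {lineno}: expected 3 fields, got {len(row)}")
        resp, target, relation = (f.strip() for f in row)
        rel = relation.lower()
        if rel not in RELATION_LEVELS:
            raise SurveyParseError(
                f"line {lineno}: unknown relation {relation!r} "
                f"(expected one of {', '.join(RELATION_LEVELS)})"
            )
        if resp == target:
            raise SurveyValidationError(f"line {lineno}: respondent {resp!r} rated self")
        if resp not in roster_set:
            raise SurveyValidationError(f"line {lineno}: respondent {resp!r} not on roster")
        if target not in roster_set:
            raise SurveyValidationError(f"line {lineno}: target {target!r} not on roster")
        per = ratings.setdefault(resp, {})
        if target in per:
            raise SurveyValidationError(
                f"line {lineno}: duplicate rating {resp!r} -> {target!r}"
            )
        per[target] = rel

    responses = []
    for resp, per in ratings.items():
        complete = set(per) == roster_set - {resp}
        responses.append(SurveyResponse(resp, per, complete))
    return responses


def filter_complete(responses: Iterable[SurveyResponse]) -> list[SurveyResponse]:
    """Keep only complete responses, preserving order.

    Edges pointing at excluded respondents are *not* removed here;
    network construction restricts to the retained node set.
    """
    return [r for r in responses if r.complete]


def build_tier_network(
    responses: Sequence[SurveyResponse], tier: str, mode: str = "cumulative"
) -> TierNetwork:
    """Build the directed network at one tier from complete responses.

    Cumulative mode includes the tier and all stronger tiers
    (``acquaintance_plus`` ⊇ ``friend_plus`` ⊇ ``best_only``); exclusive
    mode includes exactly one relation level.  Ratings naming students
    outside the retained cohort are dropped with a logged warning.
    """
    if mode == "cumulative":
        if tier not in CUMULATIVE_TIERS:
            raise ValueError(
                f"unknown cumulative tier {tier!r}; "
                f"expected one of {', '.join(CUMULATIVE_TIERS)}"
            )
        min_strength = CUMULATIVE_TIERS[tier]
        accepted = {rel for rel, s in _STRENGTH.items() if s >= min_strength}
    elif mode == "exclusive":
        if tier not in EXCLUSIVE_TIERS:
            raise ValueError(
                f"unknown exclusive tier {tier!r}; "
                f"expected one of {', '.join(EXCLUSIVE_TIERS)}"
            )
        accepted = {EXCLUSIVE_TIERS[tier]}
    else:
        raise ValueError(f"mode must be 'cumulative' or 'exclusive', got {mode!r}")

    incomplete = [r.respondent_id for r in responses if not r.complete]
    if incomplete:
        raise SurveyValidationError(
            f"networks are built from complete responses only; "
            f"incomplete: {incomplete}"
        )

    nodes = tuple(r.respondent_id for r in responses)
    node_set = set(nodes)
    edges: list[tuple[str, str]] = []
    n_dropped = 0
    for r in responses:
        for target, rel in r.ratings.items():
            if rel in accepted:
                if target in node_set:
                    edges.append((r.respondent_id, target))
                else:
                    n_dropped += 1
    if n_dropped:
        logger.warning(
            "dropped %d %s-tier ratings naming students outside the retained cohort",
            n_dropped,
            tier,
        )
    return TierNetwork(tier=tier, mode=mode, nodes=nodes, edges=tuple(edges))


def _ccdf(degrees: Sequence[int]) -> tuple[float, ...]:
    """P(degree >= k) for k = 0..max(degree)."""
    deg = np.asarray(degrees, dtype=int)
    n = len(deg)
    kmax = int(deg.max())
    counts = np.bincount(deg, minlength=kmax + 1)
    # survival at k = fraction with degree >= k
    surv = counts[::-1].cumsum()[::-1] / n
    return tuple(float(v) for v in surv)


def directed_transitivity(net: TierNetwork) -> float:
    """Fraction of directed two-paths i->j->k (i != k) closed by an edge i->k.

    The standard directed generalization of the triangle ratio; a
    complete digraph scores 1, a pure directed cycle scores 0.  Returns
    0 when the network has no two-paths.
    """
    a = nx.to_numpy_array(net.to_networkx(), nodelist=list(net.nodes))
    a2 = a @ a
    paths = a2.sum() - np.trace(a2)
    if paths == 0:
        return 0.0
    closed = (a2 * a).sum()
    return float(closed / paths)


def network_metrics(net: TierNetwork) -> NetworkMetrics:
    """Compute the whole-network metrics of one tier.

    Density and transitivity use the directed edges; average clustering
    is computed after symmetrizing every edge (``{u,v}`` exists if either
    direction was reported).  Components and isolates are counted on the
    undirected view.
    """
    g = net.to_networkx()
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("density is undefined for a network with fewer than 2 nodes")
    density = g.number_of_edges() / (n * (n - 1))
    und = g.to_undirected()
    return NetworkMetrics(
        density=float(density),
        transitivity=directed_transitivity(net),
        avg_clustering=float(nx.average_clustering(und)),
        out_ccdf=_ccdf([d for _, d in g.out_degree()]),
        in_ccdf=_ccdf([d for _, d in g.in_degree()]),
        n_components=nx.number_connected_components(und),
        n_isolated=sum(1 for _, d in und.degree() if d == 0),
    )


def write_edgelist_tsv(net: TierNetwork, stream: TextIO) -> None:
    """Write ``source<TAB>target<TAB>tier`` rows (no header)."""
    for u, v in net.edges:
        stream.write(f"{u}\t{v}\t{net.tier}\n")
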