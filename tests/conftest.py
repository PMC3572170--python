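"""Shared fixtures: tiny hand-built surveys and synthetic cohort helpers."""

from __future__ import annotations

import io

import numpy as np
import pytest

from gradenet.ranking import GpaTable, gpa_to_ranking
from gradenet.survey import SurveyResponse, TierNetwork


@pytest.fixture
def three_student_survey() -> str:
    """Smallest full survey: 3 students, 6 rating rows, all complete."""
    return (
        "respondent_id,target_id,relation\n"
        "A,B,best_friend\n"
        "A,C,friend\n"
        "B,A,friend\n"
        "B,C,acquaintance\n"
        "C,A,unknown\n"
        "C,B,related\n"
    )


def make_responses(ratings: dict[str, dict[str, str]]) -> list[SurveyResponse]:
    """Build complete SurveyResponse objects from a nested rating dict."""
    roster = set(ratings)
    out = []
    for resp, per in ratings.items():
        full = dict(per)
        for other in roster - {resp}:
            full.setdefault(other, "unknown")
        out.append(SurveyResponse(resp, full, complete=True))
    return out


@pytest.fixture
def five_node_responses() -> list[SurveyResponse]:
    """Hand-listed 5-node toy survey used for edge-set enumeration."""
    return make_responses(
        {
            "A": {"B": "best_friend", "C": "friend", "D": "acquaintance"},
            "B": {"A": "friend", "E": "best_friend"},
            "C": {"A": "acquaintance", "B": "related"},
            "D": {"E": "friend"},
            "E": {"A": "acquaintance", "D": "best_friend"},
        }
    )


def random_network(rng: np.random.Generator, n: int, p: float = 0.4) -> TierNetwork:
    """Erdős–Rényi-style random directed network on n nodes."""
    nodes = tuple(f"N{i}" for i in range(n))
    edges = tuple(
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < p
    )
    return TierNetwork(tier="friend_only", mode="exclusive", nodes=nodes, edges=edges)


def ranking_from_gpas(gpas: dict[str, float], timepoint: str = "t0"):
    return gpa_to_ranking(GpaTable(timepoint, gpas))
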