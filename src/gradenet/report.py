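"""End-to-end analysis runs and machine-readable reports.

Ties the stages together: survey ingestion -> completeness filter ->
tier networks and their metrics -> rankings, progress and environment
scores -> progress regression with sequential ANOVA -> permutation test
of the friend-environment/progress correlation.  Every run writes a
manifest recording all policy choices and the seed, so a report bundle
is reproducible byte-for-byte from its manifest and inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .inference import (
    SequentialAnovaTable,
    fit_progress_model,
    pearson_r,
    sequential_anova,
    significance_stars,
)
from .permutation import EnvironmentRecomputer, PermutationResult, null_distribution
from .ranking import (
    GpaTable,
    academic_progress,
    environment_scores,
    gpa_to_ranking,
    read_roster,
    scores_frame,
)
from .survey import (
    CUMULATIVE_TIERS,
    EXCLUSIVE_TIERS,
    build_tier_network,
    filter_complete,
    network_metrics,
    read_survey,
)
from .synthetic import CohortConfig, generate_cohort, write_roster_csv, write_survey_csv

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one end-to-end run.

    Exactly one of (``survey`` + ``roster`` paths) or ``simulate`` must
    be active; in simulate mode ``cohort`` supplies the generator
    settings and the generated inputs are written alongside the reports.
    """

    survey: Path | None = None
    roster: Path | None = None
    simulate: bool = False
    cohort: CohortConfig | None = None
    x_mode: str = "mean_neighbor_rank"
    tier_mode: str = "exclusive"
    tie_policy: str = "average"
    undefined_policy: str = "zero"
    n_reps: int = 500
    alternative: str = "greater"
    seed: int = 0
    out_dir: Path = Path("gradenet_out")

    def __post_init__(self) -> None:
        has_paths = self.survey is not None and self.roster is not None
        if has_paths == self.simulate:
            raise ValueError("exactly one of (survey+roster paths, simulate) must be active")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


def _fmt(x: float) -> float:
    """Round to 6 significant digits for report serialization."""
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return x
    return float(f"{x:.6g}")


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _load_inputs(config: RunConfig):
    if config.simulate:
        cohort = config.cohort or CohortConfig(seed=config.seed)
        responses, gpa0, gpa1 = generate_cohort(cohort)
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "survey.csv", "w") as fh:
            write_survey_csv(responses, fh)
        with open(out / "roster.csv", "w") as fh:
            write_roster_csv(gpa0, gpa1, fh)
        return responses, gpa0, gpa1, cohort
    with open(config.roster) as fh:
        gpa0, gpa1 = read_roster(fh)
    roster_ids = list(gpa0.values)
    with open(config.survey) as fh:
        responses = read_survey(fh, roster_ids)
    return responses, gpa0, gpa1, None


def _restrict(gpas: GpaTable, ids: set[str]) -> GpaTable:
    return GpaTable(gpas.timepoint, {s: v for s, v in gpas.values.items() if s in ids})


def _pipeline(config: RunConfig):
    """Shared front half: inputs -> retained cohort -> scores frame."""
    responses, gpa0, gpa1, cohort_cfg = _load_inputs(config)
    retained = filter_complete(responses)
    if len(retained) < 3:
        raise ValueError(f"only {len(retained)} complete responses; cannot analyze")
    ids = {r.respondent_id for r in retained}
    missing_gpa = ids - set(gpa0.values) | ids - set(gpa1.values)
    if missing_gpa:
        raise ValueError(f"retained respondents without GPA records: {sorted(missing_gpa)}")
    gpa0_r = _restrict(gpa0, ids)
    gpa1_r = _restrict(gpa1, ids)

    rank0 = gpa_to_ranking(gpa0_r, tie_policy=config.tie_policy)
    rank1 = gpa_to_ranking(gpa1_r, tie_policy=config.tie_policy)
    y = academic_progress(rank0, rank1)

    tiers = EXCLUSIVE_TIERS if config.tier_mode == "exclusive" else CUMULATIVE_TIERS
    x_nets = {
        t: build_tier_network(retained, t, mode=config.tier_mode) for t in tiers
    }
    scores = environment_scores(
        x_nets,
        gpa0_r,
        rank0,
        y,
        mode=config.x_mode,
        undefined_policy=config.undefined_policy,
    )
    return {
        "responses": responses,
        "retained": retained,
        "gpa0": gpa0_r,
        "gpa1": gpa1_r,
        "rank0": rank0,
        "rank1": rank1,
        "y": y,
        "x_nets": x_nets,
        "scores": scores,
        "cohort_cfg": cohort_cfg,
    }


def _manifest(config: RunConfig, state, extra: dict) -> dict:
    m = {
        "seed": config.seed,
        "x_mode": config.x_mode,
        "tier_mode": config.tier_mode,
        "tie_policy": config.tie_policy,
        "undefined_policy": config.undefined_policy,
        "n_responses": len(state["responses"]),
        "n_retained": len(state["retained"]),
        "simulate": config.simulate,
    }
    if state["cohort_cfg"] is not None:
        m["cohort_config"] = state["cohort_cfg"].to_dict()
    else:
        m["survey"] = str(config.survey)
        m["roster"] = str(config.roster)
    m.update(extra)
    return m


def anova_tsv(table: SequentialAnovaTable) -> str:
    """Render the sequential ANOVA as a TSV with significance stars."""
    lines = ["term\tDF\tSS\tMS\tF\tp\tsig"]
    for r in table.rows:
        lines.append(
            f"{r.term}\t{r.df}\t{_fmt(r.ss)}\t{_fmt(r.ms)}\t{_fmt(r.f)}\t{_fmt(r.p)}"
            f"\t{significance_stars(r.p)}"
        )
    lines.append(
        f"Error\t{table.error_df}\t{_fmt(table.error_ss)}\t{_fmt(table.error_ms)}\t\t\t"
    )
    lines.append(f"Total\t{table.total_df}\t{_fmt(table.total_ss)}\t\t\t\t")
    return "\n".join(lines) + "\n"


def run_analyze(config: RunConfig) -> dict:
    """Full descriptive + regression analysis; writes the report bundle.

    Writes per-tier network metrics JSON (cumulative tiers, matching
    the whole-network view), the per-student scores TSV, the ANOVA TSV,
    and a manifest.  Returns the bundle as a dict.
    """
    state = _pipeline(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    metric_nets = {
        t: build_tier_network(state["retained"], t, mode="cumulative")
        for t in CUMULATIVE_TIERS
    }
    metrics = {t: network_metrics(net).to_dict() for t, net in metric_nets.items()}
    for t in metrics:
        for k in ("density", "transitivity", "avg_clustering"):
            metrics[t][k] = _fmt(metrics[t][k])
    _json_dump(metrics, out / "metrics.json")

    frame = scores_frame(state["scores"], state["rank0"])
    frame.round(6).to_csv(out / "scores.tsv", sep="\t")

    fit = fit_progress_model(frame)
    table = sequential_anova(frame)
    (out / "anova.tsv").write_text(anova_tsv(table))
    (out / "equation.txt").write_text(fit.equation() + "\n")

    manifest = _manifest(
        config,
        state,
        {
            "outputs": ["metrics.json", "scores.tsv", "anova.tsv", "equation.txt"],
            "equation": fit.equation(),
        },
    )
    _json_dump(manifest, out / "manifest.json")
    return {
        "metrics": metrics,
        "scores": frame,
        "fit": fit,
        "anova": table,
        "manifest": manifest,
    }


def run_permtest(config: RunConfig) -> PermutationResult:
    """Permutation test of r(x_friend, y) under out-degree-preserving rewiring.

    Only the friend-tier network is rewired; y and the rankings are
    never permuted.  Writes permutation.json (including the full null
    distribution, for re-plotting) and a manifest.
    """
    state = _pipeline(config)
    friend_tier = "friend_only" if config.tier_mode == "exclusive" else "friend_plus"
    net = state["x_nets"][friend_tier]
    recomputer = EnvironmentRecomputer(
        rank_t0=state["rank0"], mode=config.x_mode, gpas_t0=state["gpa0"]
    )
    result = null_distribution(
        net,
        recomputer,
        state["y"],
        n_reps=config.n_reps,
        rng=config.seed,
        alternative=config.alternative,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = result.to_dict()
    payload["observed_r"] = _fmt(payload["observed_r"])
    payload["empirical_p"] = _fmt(payload["empirical_p"])
    payload["summary"] = {k: _fmt(v) for k, v in payload["summary"].items()}
    payload["null_rs"] = [None if v is None else _fmt(v) for v in payload["null_rs"]]
    payload["rewired_tier"] = friend_tier
    _json_dump(payload, out / "permutation.json")
    manifest = _manifest(
        config,
        state,
        {"outputs": ["permutation.json"], "n_reps": config.n_reps, "alternative": config.alternative},
    )
    _json_dump(manifest, out / "manifest.json")
    return result


def quick_test(own_gpa: float, friend_gpas: list[float]) -> str:
    """Predict the direction of a student's progress from friends' GPAs.

    The back-of-the-envelope screen: compare the self-reported friends'
    average GPA with the student's own.  Higher -> "up", lower ->
    "down", equal -> "flat".
    """
    if not friend_gpas:
        raise ValueError("need at least one friend GPA")
    mean = float(np.mean(friend_gpas))
    if mean > own_gpa:
        return "up"
    if mean < own_gpa:
        return "down"
    return "flat"
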