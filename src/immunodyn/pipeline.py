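"""End-to-end orchestration: cohort table in, result directory out.

For each participant the pipeline builds the analysis grid, assembles a
system snapshot per instant, factorizes it, solves for the minimum-norm
unknowns, name-tags the singular vectors, applies the activity thresholds,
and accumulates the normalized Quad occurrence counts.  Cohorts are then
averaged, differenced, ranked, and exported as tables and flow diagrams,
with a machine-readable manifest recording versions, thresholds, stopping
policy and quality checks.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .activity import Thresholds, participant_quads
from .aggregate import average_cohort, diff_cohorts, export_flow, top_doublets
from .assembly import assemble_participant
from .knowledge import (default_ruleset, enumerate_relationships,
                        load_ruleset, validate_model)
from .panel import build_grid, default_panel, load_cohort, load_panel
from .svd import StopPolicy

__all__ = ["RunConfig", "run_pipeline"]


def _pkg_version() -> str:
    from immunodyn import __version__
    return __version__

log = logging.getLogger("immunodyn")


@dataclass
class RunConfig:
    """All knobs of one reproducible pipeline run."""

    cohort_path: str
    out_dir: str
    panel_path: str | None = None
    ruleset_path: str | None = None
    points_per_interval: int = 6
    weekend_policy: str = "exclude"
    policy: StopPolicy = field(default_factory=StopPolicy)
    thresholds: Thresholds = field(default_factory=Thresholds)
    rank_tol: float = 1e-12
    quality_checks: bool = True
    export_flows: bool = True
    cohort_pair: tuple[str, str] = ("cancer", "healthy")
    top_n_doublets: int = 10

    def validate_paths(self) -> None:
        for p in (self.cohort_path, self.panel_path, self.ruleset_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _round2(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f":
            out[c] = out[c].round(2)
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis; returns the populated results directory."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    panel = (load_panel(config.panel_path) if config.panel_path
             else default_panel())
    ruleset = (load_ruleset(config.ruleset_path) if config.ruleset_path
               else default_ruleset())
    km = enumerate_relationships(panel, ruleset)
    report = validate_model(km)
    series = load_cohort(config.cohort_path, panel)
    log.info("loaded %d participants; knowledge model: %d relationships",
             len(series), len(km))

    quads_by_cohort: dict[str, list[pd.DataFrame]] = {}
    manifest: dict = {
        "version": _pkg_version(),
        "knowledge_model": {
            "total_relationships": report.total,
            "distinct_triples": report.n_distinct_triples,
            "per_type": report.per_type_counts,
        },
        "policy": asdict(config.policy),
        "thresholds": asdict(config.thresholds),
        "grid": {"points_per_interval": config.points_per_interval,
                 "weekend_policy": config.weekend_policy},
        "participants": [],
        "all_quality_checks_passed": True,
    }

    for s in series:
        t0 = _time.time()
        grid = build_grid(s, config.points_per_interval,
                          config.weekend_policy)
        snaps = assemble_participant(grid, km)
        try:
            if config.quality_checks:
                quads, checks = participant_quads(
                    snaps, config.policy, config.thresholds,
                    config.rank_tol, collect_checks=True)
                ok = all(c.passed for c in checks)
                manifest["all_quality_checks_passed"] &= ok
            else:
                quads = participant_quads(snaps, config.policy,
                                          config.thresholds, config.rank_tol)
                checks, ok = [], None
        except Exception as exc:
            raise RuntimeError(
                f"pipeline failed for participant {s.participant_id}: {exc}"
            ) from exc
        quads.insert(0, "participant", s.participant_id)
        quads.insert(1, "cohort", s.cohort)
        quads_by_cohort.setdefault(s.cohort, []).append(quads)
        manifest["participants"].append({
            "id": s.participant_id, "cohort": s.cohort,
            "grid_points": len(grid), "active_quads": int(len(quads)),
            "quality_checks_passed": ok,
            "seconds": round(_time.time() - t0, 3),
        })
        log.info("participant %s: %d grid points, %d active quads (%.1fs)",
                 s.participant_id, len(grid), len(quads),
                 _time.time() - t0)

    all_quads = pd.concat(
        [q for qs in quads_by_cohort.values() for q in qs],
        ignore_index=True)
    _round2(all_quads).to_csv(out / "quads.csv", index=False)

    means = {c: average_cohort([q.drop(columns=["participant", "cohort"])
                                for q in qs])
             for c, qs in quads_by_cohort.items()}
    for c, m in means.items():
        _round2(m).to_csv(out / f"mean_quads_{c}.csv", index=False)

    a, b = config.cohort_pair
    if a in means and b in means:
        cmp = diff_cohorts(means[a], means[b])
        _round2(cmp.diff).to_csv(out / f"diff_{a}_minus_{b}.csv", index=False)
        top = top_doublets(cmp, n=config.top_n_doublets)
        _round2(top).to_csv(out / "top_doublets.csv", index=False)
        if config.export_flows:
            for c, m in means.items():
                export_flow(m, out / f"flow_{c}.dot")
            export_flow(cmp, out / f"flow_{a}_minus_{b}.dot")
    elif config.export_flows:
        for c, m in means.items():
            export_flow(m, out / f"flow_{c}.dot")

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out
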