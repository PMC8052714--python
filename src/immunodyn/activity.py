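"""Occurrence counting: from singular vectors to Quad activity tables.

At every analysis instant the factorization yields 50 left singular vectors
(LSVs, the columns of U) and their right singular vector rows (RSVs, the
rows of Vt, one component per Knowledge-Model relationship).  Each LSV is
name-tagged with the biomarker dominating it; a five-dimensional record
(time, LSV tag, target, source, modulator) is declared *active* when

* the relationship's solved unknown is nonzero (``|a_j| > zero_tol``),
* the tagged LSV carries the relationship's target (``|U[row(T), l]| >=
  lsv_threshold``), and
* the relationship's RSV component is non-negligible within its row
  (``|Vt[l, j]| >= rsv_threshold * max_j' |Vt[l, j']|``).

Counting the instants at which a (modulator, source, target, LSV-tag) Quad
is active over the test period, then normalizing by the grid size x 100,
gives the normalized Occurrence Count in [0, 100] — the basis of every
downstream view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .knowledge import KnowledgeModel
from .panel import Panel
from .svd import SVDFactors, SolutionVector

__all__ = [
    "Thresholds",
    "LSVTagging",
    "QuintRecord",
    "tag_lsvs",
    "score_activity",
    "active_mask",
    "count_occurrences",
    "normalize_counts",
    "participant_quads",
]

QUAD_KEY = ["modulator", "source", "target", "lsv"]


@dataclass(frozen=True)
class Thresholds:
    """Response-threshold rules for declaring relationship activity.

    lsv_threshold
        absolute minimum |U| component for an LSV to carry a target.
    rsv_threshold
        minimum RSV magnitude relative to the row maximum.
    zero_tol_rel
        |a_j| below ``zero_tol_rel * max|a|`` counts as a zero unknown.
    Each conjunct of the activity rule can be disabled for sensitivity
    analysis by setting its threshold to 0.
    """

    lsv_threshold: float = 0.10
    rsv_threshold: float = 0.05
    zero_tol_rel: float = 1e-12

    def __post_init__(self) -> None:
        if min(self.lsv_threshold, self.rsv_threshold,
               self.zero_tol_rel) < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class LSVTagging:
    """Bijective assignment of LSV columns to biomarker names."""

    assignment: np.ndarray          # lsv index -> biomarker row index
    ambiguity_log: list[tuple[int, float, float]] = field(
        default_factory=list)   # (lsv, top, second) with ratio within 5%

    def names(self, panel: Panel) -> list[str]:
        return [panel.names[i] for i in self.assignment]


def tag_lsvs(U: np.ndarray, panel: Panel,
             ambiguity_ratio: float = 0.05) -> LSVTagging:
    """Greedy unique name-tagging of LSVs by dominant |U| component.

    All (biomarker, LSV) pairs are ranked by |U| descending; pairs whose
    biomarker and LSV are both unassigned are taken until the assignment is
    bijective.  Ties break by panel order, then LSV index.  Pairs whose
    top-two competing magnitudes lie within ``ambiguity_ratio`` are logged.
    """
    U = np.asarray(U, dtype=float)
    n = len(panel)
    if U.shape != (n, n):
        raise ValueError(f"U must be square over the panel ({n}); "
                         f"got {U.shape}")
    mag = np.abs(U)
    bio, lsv = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    # sort by magnitude desc, then biomarker asc, then lsv asc
    order = np.lexsort((lsv.ravel(), bio.ravel(), -mag.ravel()))
    assignment = np.full(n, -1, dtype=np.int64)
    bio_used = np.zeros(n, dtype=bool)
    assigned = 0
    for idx in order:
        b = idx // n
        l = idx % n
        if bio_used[b] or assignment[l] >= 0:
            continue
        assignment[l] = b
        bio_used[b] = True
        assigned += 1
        if assigned == n:
            break
    log: list[tuple[int, float, float]] = []
    for l in range(n):
        col = np.sort(mag[:, l])[::-1]
        if col.size > 1 and col[0] > 0:
            if (col[0] - col[1]) <= ambiguity_ratio * col[0]:
                log.append((l, float(col[0]), float(col[1])))
    return LSVTagging(assignment=assignment, ambiguity_log=log)


def active_mask(factors: SVDFactors, solution: SolutionVector,
                km: KnowledgeModel, thr: Thresholds) -> np.ndarray:
    """Boolean (n_lsv, n_relationships) activity matrix for one instant.

    Duplicate system-matrix columns (the same (M, S, T) triple enumerated
    by two Knowledge-Model types) are merged by logical OR so a Quad can
    never be counted twice at one time point.
    """
    U, Vt = factors.U, factors.Vt
    amax = float(np.max(np.abs(solution.a))) if solution.a.size else 0.0
    a_ok = np.abs(solution.a) > thr.zero_tol_rel * amax
    row_max = np.max(np.abs(Vt), axis=1, keepdims=True)
    rsv_ok = np.abs(Vt) >= thr.rsv_threshold * row_max
    lsv_ok = np.abs(U[km.target_idx, :]).T >= thr.lsv_threshold
    mask = rsv_ok & lsv_ok & a_ok[None, :]
    for cols in km.duplicate_triples.values():
        merged = mask[:, cols].any(axis=1)
        for c in cols:
            mask[:, c] = merged
    return mask


@dataclass(frozen=True)
class QuintRecord:
    """One active 5-D record: (time, lsv_tag, target, source, modulator)."""

    time: float
    lsv_tag: str
    target: str
    source: str
    modulator: str
    value: float    # |RSV component|
    active: bool


def score_activity(factors: SVDFactors, solution: SolutionVector,
                   tagging: LSVTagging, km: KnowledgeModel,
                   thr: Thresholds, time: float) -> list[QuintRecord]:
    """Materialize the active quint records of one analysis instant."""
    if factors.U.shape[0] != len(km.panel):
        raise ValueError("factors do not match the knowledge model panel")
    mask = active_mask(factors, solution, km, thr)
    names = km.panel.names
    out = []
    for l, j in zip(*np.nonzero(mask)):
        r = km.relationships[j]
        out.append(QuintRecord(
            time=time, lsv_tag=names[tagging.assignment[l]],
            target=r.target, source=r.source, modulator=r.modulator,
            value=float(abs(factors.Vt[l, j])), active=True))
    return out


def count_occurrences(quints: list[QuintRecord]) -> pd.DataFrame:
    """Raw occurrence counts per Quad: distinct active times per key."""
    if not quints:
        return pd.DataFrame(columns=QUAD_KEY + ["raw_count"])
    df = pd.DataFrame([{
        "modulator": q.modulator, "source": q.source, "target": q.target,
        "lsv": q.lsv_tag, "time": q.time} for q in quints if q.active])
    counts = (df.drop_duplicates(QUAD_KEY + ["time"])
                .groupby(QUAD_KEY, sort=True).size()
                .rename("raw_count").reset_index())
    return counts


def normalize_counts(counts: pd.DataFrame, max_count: int) -> pd.DataFrame:
    """Add ``normalized = 100 * raw / max_count`` (full precision).

    Presentation rounding to 2 decimals happens only at export.
    """
    if max_count < 1:
        raise ValueError("max_count must be >= 1")
    if len(counts) and (counts["raw_count"] > max_count).any():
        raise ValueError("raw_count exceeds max_count")
    out = counts.copy()
    out["normalized"] = 100.0 * out["raw_count"] / max_count
    return out


def participant_quads(snapshots, policy=None, thr: Thresholds | None = None,
                      rank_tol: float = 1e-12,
                      collect_checks: bool = False):
    """Run factorize -> solve -> tag -> count over a snapshot sequence.

    The heavy path: activity is accumulated in a dense (biomarker, column)
    integer array in tag space (the Quad key uses the tag *name*, so counts
    agree across instants even as LSV column order changes).  Returns a
    normalized quad table; with ``collect_checks`` also the per-instant
    `QualityReport` list.
    """
    from .svd import StopPolicy, pseudo_solve, quality_check, svd_factorize

    if policy is None:
        policy = StopPolicy()
    thr = thr or Thresholds()
    counts = None
    km = None
    n_times = 0
    checks = []
    for snap in snapshots:
        km = snap.km
        factors = svd_factorize(snap.K, policy,
                                compute_recon=collect_checks)
        sol = pseudo_solve(factors, snap.dxdt, rank_tol=rank_tol)
        if collect_checks:
            checks.append(quality_check(factors, sol, snap.K, snap.dxdt))
        tagging = tag_lsvs(factors.U, km.panel)
        mask = active_mask(factors, sol, km, thr)
        if counts is None:
            counts = np.zeros((len(km.panel), len(km)), dtype=np.int32)
        counts[tagging.assignment] += mask
        n_times += 1
    if counts is None:
        raise ValueError("no snapshots supplied")
    # one representative column per (M, S, T): merged duplicates carry
    # identical counts, so dropping the others loses nothing
    rep = np.ones(len(km), dtype=bool)
    for cols in km.duplicate_triples.values():
        for c in cols[1:]:
            rep[c] = False
    tag_idx, col_idx = np.nonzero(counts * rep[None, :])
    names = km.panel.names
    quads = pd.DataFrame({
        "modulator": [km.relationships[j].modulator for j in col_idx],
        "source": [km.relationships[j].source for j in col_idx],
        "target": [km.relationships[j].target for j in col_idx],
        "lsv": [names[i] for i in tag_idx],
        "raw_count": counts[tag_idx, col_idx],
    }).sort_values(QUAD_KEY, kind="stable").reset_index(drop=True)
    quads = normalize_counts(quads, n_times)
    if collect_checks:
        return quads, checks
    return quads
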