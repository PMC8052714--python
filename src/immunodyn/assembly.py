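"""Per-instant system characterization matrix K and rate vector dx/dt.

Each biomarker's rate of change is the algebraic sum of its candidate
relationship terms (a Kolmogorov-Gabor polynomial truncated at the bi-linear
term):

    dx_T/dt = sum_j a_j * c_j(x),   c_j = x_source(j)            (linear)
                                    c_j = x_mod(j) * x_source(j) (bi-linear)

Stacking one equation per panel biomarker gives ``dx/dt = K a`` where K has
one row per target biomarker and one column per Knowledge-Model relationship.
Column j has a single potentially-nonzero entry, in the row of its target,
equal to ``c_j(x)``; with strictly positive concentrations every column is
nonzero, so K carries exactly as many nonzero entries as the model has
relationships.  Because the columns are single-entry, the rows of K are
mutually orthogonal — the structural fact behind the closed-form SVD limit
used in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np

from .knowledge import KnowledgeModel, Relationship
from .panel import GridPoint, ParticipantGrid

__all__ = ["SystemSnapshot", "column_value", "column_values",
           "build_snapshot", "assemble_participant"]


@dataclass
class SystemSnapshot:
    """K and dx/dt fully quantified by one participant at one instant."""

    participant_id: str
    time: float
    K: np.ndarray       # (n_biomarkers, n_relationships)
    dxdt: np.ndarray    # (n_biomarkers,)
    km: KnowledgeModel

    @property
    def nnz(self) -> int:
        return int(np.count_nonzero(self.K))


def column_value(rel: Relationship, x: Mapping[str, float]) -> float:
    """Evaluate one relationship's regressor at concentrations ``x``."""
    try:
        v = x[rel.source]
        if rel.kind == "bilinear":
            v = v * x[rel.modulator]
    except KeyError as exc:
        raise KeyError(f"biomarker {exc} absent from concentration vector")
    return float(v)


def column_values(km: KnowledgeModel, x: np.ndarray) -> np.ndarray:
    """Vectorized regressor values for every relationship (panel-ordered x)."""
    x = np.asarray(x, dtype=float)
    vals = x[km.source_idx].copy()
    bil = ~km.is_linear
    vals[bil] *= x[km.modulator_idx[bil]]
    return vals


def build_snapshot(
    grid_point: GridPoint, km: KnowledgeModel,
    participant_id: str = "",
) -> SystemSnapshot:
    """Assemble K and dx/dt for one grid point."""
    n = len(km.panel)
    vals = column_values(km, grid_point.x)
    K = np.zeros((n, len(km)))
    K[km.target_idx, np.arange(len(km))] = vals
    return SystemSnapshot(participant_id, grid_point.time, K,
                          np.asarray(grid_point.dxdt, dtype=float), km)


def assemble_participant(
    grid: ParticipantGrid, km: KnowledgeModel
) -> Iterator[SystemSnapshot]:
    """One snapshot per grid point, in time order (lazily generated).

    A dense 50 x 28,605 matrix is ~11 MB; the full 48-point sequence is
    generated lazily so pipelines can factor and discard each snapshot.
    """
    for gp in grid.grid_points:
        yield build_snapshot(gp, km, grid.participant_id)
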