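"""Biomarker panel, cohort time series, and the interpolated analysis grid.

A panel is an ordered list of named biomarkers, each a cytokine (plasma
concentration) or an immune-cell phenotype (relative concentration among
PBMCs).  Panel order is canonical: it fixes the row order of every system
matrix so that singular-vector components stay comparable across time points
and participants.

Blood draws happen on weekdays over two weeks (days 0-4 and 7-11).  Between
consecutive draws the concentration trace is linearly interpolated, which
makes the rate of change piecewise constant; the analysis grid places a fixed
number of strictly interior points inside each retained inter-draw interval
(weekend-spanning gaps are dropped by default), yielding 8 intervals x 6
points = 48 analysis instants on the standard schedule.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BiomarkerClass",
    "Biomarker",
    "Panel",
    "ParticipantSeries",
    "GridPoint",
    "ParticipantGrid",
    "default_panel",
    "load_panel",
    "load_cohort",
    "write_cohort",
    "build_grid",
]


class BiomarkerClass(str, enum.Enum):
    CELL = "cell"
    CYTOKINE = "cytokine"


@dataclass(frozen=True)
class Biomarker:
    """A measured immune analyte: a cytokine or a cell phenotype."""

    name: str
    klass: BiomarkerClass

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("biomarker name must be non-empty")
        object.__setattr__(self, "klass", BiomarkerClass(self.klass))


# The 35 plasma cytokines and 15 PBMC cell phenotypes of the default study
# panel, in canonical order (cytokines first, then cells).
DEFAULT_CYTOKINES: tuple[str, ...] = (
    "EGF", "EOTAXIN", "FGF-2", "FLT-3L", "FRACTALKINE", "G-CSF", "GM-CSF",
    "IFNa2", "IFNg", "IL-10", "IL-12p40", "IL-12p70", "IL-13", "IL-15",
    "IL-17A", "IL-1a", "IL-1b", "IL-1ra", "IL-2", "IL-3", "IL-4", "IL-5",
    "IL-6", "IL-7", "IL-8", "IL-9", "IP-10", "MCP-1", "MCP-3", "MIP-1a",
    "MIP-1b", "TGFa", "TNFa", "TNFb", "VEGF",
)
DEFAULT_CELLS: tuple[str, ...] = (
    "CD11c+", "CD11c/CD14+", "CD11c/CD86+", "CD11c/HLA-DR+", "CD123/HLA-DR+",
    "CD14/CD197+", "CD16/CD56+", "CD3+", "CD3/CD4+", "CD3/CD62L+",
    "CD3/CD69+", "CD3/CD8+", "CD4/CD294+", "CD4/TIM3+", "CD56+",
)


class Panel:
    """An ordered, duplicate-free collection of biomarkers.

    The order is canonical and stable: it defines matrix row order for the
    whole pipeline.
    """

    def __init__(self, biomarkers: Iterable[Biomarker]):
        self.biomarkers: tuple[Biomarker, ...] = tuple(biomarkers)
        if not self.biomarkers:
            raise ValueError("empty panel")
        names = [b.name for b in self.biomarkers]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate biomarker name(s): {dupes}")
        self._index = {b.name: i for i, b in enumerate(self.biomarkers)}

    def __len__(self) -> int:
        return len(self.biomarkers)

    def __iter__(self):
        return iter(self.biomarkers)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def index(self, name: str) -> int:
        return self._index[name]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.biomarkers)

    @property
    def cytokines(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.biomarkers
                     if b.klass is BiomarkerClass.CYTOKINE)

    @property
    def cells(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.biomarkers
                     if b.klass is BiomarkerClass.CELL)

    def count(self, klass: BiomarkerClass | str) -> int:
        klass = BiomarkerClass(klass)
        return sum(1 for b in self.biomarkers if b.klass is klass)

    def klass_of(self, name: str) -> BiomarkerClass:
        return self.biomarkers[self._index[name]].klass

    def __eq__(self, other) -> bool:
        return isinstance(other, Panel) and self.biomarkers == other.biomarkers

    def __repr__(self) -> str:
        return (f"Panel({len(self)} biomarkers: "
                f"{self.count(BiomarkerClass.CYTOKINE)} cytokines, "
                f"{self.count(BiomarkerClass.CELL)} cells)")


def default_panel() -> Panel:
    """The built-in 50-biomarker study panel (35 cytokines + 15 cells)."""
    return Panel(
        [Biomarker(n, BiomarkerClass.CYTOKINE) for n in DEFAULT_CYTOKINES]
        + [Biomarker(n, BiomarkerClass.CELL) for n in DEFAULT_CELLS]
    )


def load_panel(source: str | Path | pd.DataFrame) -> Panel:
    """Load a panel from a delimited table with columns ``name, klass``."""
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source)
    missing = {"name", "klass"} - set(df.columns)
    if missing:
        raise ValueError(f"panel table missing column(s): {sorted(missing)}")
    if df.empty:
        raise ValueError("empty panel")
    try:
        return Panel(Biomarker(str(r.name), str(r.klass))
                     for r in df.itertuples(index=False))
    except ValueError as exc:
        raise ValueError(f"invalid panel table: {exc}") from exc


@dataclass
class ParticipantSeries:
    """One participant's raw draw-day concentration record.

    ``values`` has shape (n_biomarkers, n_draws) in panel order; cytokines are
    plasma concentrations (pg/mL-like), cells relative concentrations.
    """

    participant_id: str
    cohort: str
    panel: Panel
    draw_times: np.ndarray  # days, strictly increasing
    values: np.ndarray      # (n_biomarkers, n_draws), finite, >= 0

    def __post_init__(self) -> None:
        self.draw_times = np.asarray(self.draw_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.draw_times.ndim != 1 or self.draw_times.size < 2:
            raise ValueError(
                f"participant {self.participant_id}: need at least 2 draws")
        if np.any(np.diff(self.draw_times) <= 0):
            raise ValueError(
                f"participant {self.participant_id}: draw times not "
                "strictly increasing")
        if self.values.shape != (len(self.panel), self.draw_times.size):
            raise ValueError(
                f"participant {self.participant_id}: values shape "
                f"{self.values.shape} != ({len(self.panel)}, "
                f"{self.draw_times.size})")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(
                f"participant {self.participant_id}: non-finite value")
        if np.any(self.values < 0):
            bio, draw = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"participant {self.participant_id}: negative value for "
                f"biomarker {self.panel.names[bio]!r} at day "
                f"{self.draw_times[draw]:g}")


@dataclass(frozen=True)
class GridPoint:
    interval_index: int
    time: float
    x: np.ndarray      # concentrations, panel order
    dxdt: np.ndarray   # rates (concentration / day), panel order


@dataclass
class ParticipantGrid:
    """The interpolated analysis grid for one participant."""

    participant_id: str
    cohort: str
    panel: Panel
    grid_points: list[GridPoint]

    def __len__(self) -> int:
        return len(self.grid_points)

    @property
    def times(self) -> np.ndarray:
        return np.array([g.time for g in self.grid_points])


#: Default draw schedule: weekdays of a two-week study period.
STANDARD_SCHEDULE: tuple[float, ...] = (0, 1, 2, 3, 4, 7, 8, 9, 10, 11)


def build_grid(
    series: ParticipantSeries,
    points_per_interval: int = 6,
    weekend_policy: str = "exclude",
    max_gap_days: float = 2.5,
) -> ParticipantGrid:
    """Place equally spaced interior analysis points inside each interval.

    For each retained interval ``[t_i, t_i+1]`` the grid holds
    ``points_per_interval`` points at ``t_i + j*(t_i+1 - t_i)/(p+1)`` for
    ``j = 1..p`` — strictly interior, so no grid time coincides with a draw
    (where the piecewise-linear slope is undefined).  ``x`` is the linear
    interpolant of the bounding draws and ``dxdt`` the constant interval
    slope.

    With ``weekend_policy="exclude"`` intervals longer than ``max_gap_days``
    are dropped; on the standard weekday schedule this removes the Fri-Mon
    gap, leaving 8 intervals and hence ``8 * points_per_interval`` points.
    """
    if points_per_interval < 1:
        raise ValueError("points_per_interval must be >= 1")
    if weekend_policy not in ("exclude", "include"):
        raise ValueError(f"unknown weekend_policy {weekend_policy!r}")
    t = series.draw_times
    v = series.values
    points: list[GridPoint] = []
    kept = 0
    for i in range(t.size - 1):
        dt = t[i + 1] - t[i]
        if weekend_policy == "exclude" and dt > max_gap_days:
            continue
        dxdt = (v[:, i + 1] - v[:, i]) / dt
        for j in range(1, points_per_interval + 1):
            frac = j / (points_per_interval + 1)
            tau = t[i] + frac * dt
            x = v[:, i] + frac * (v[:, i + 1] - v[:, i])
            points.append(GridPoint(kept, float(tau), x, dxdt))
        kept += 1
    return ParticipantGrid(series.participant_id, series.cohort,
                           series.panel, points)


_COHORT_COLUMNS = ("participant", "cohort", "biomarker", "day", "value")


def load_cohort(
    source: str | Path | pd.DataFrame, panel: Panel
) -> list[ParticipantSeries]:
    """Read a long-format cohort table into per-participant series.

    The table must carry columns ``participant, cohort, biomarker, day,
    value``; every participant must supply a value for every panel biomarker
    at every one of their draw days.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        # round_trip parsing: loading a written cohort is bit-exact
        df = pd.read_csv(source, float_precision="round_trip")
    missing = set(_COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing column(s): {sorted(missing)}")
    unknown = set(df["biomarker"].unique()) - set(panel.names)
    if unknown:
        raise ValueError(f"unknown biomarker name(s): {sorted(unknown)}")
    out: list[ParticipantSeries] = []
    for pid, sub in df.groupby("participant", sort=True):
        cohorts = sub["cohort"].unique()
        if len(cohorts) != 1:
            raise ValueError(f"participant {pid}: inconsistent cohort labels")
        days = np.sort(sub["day"].unique())
        wide = sub.pivot_table(index="biomarker", columns="day",
                               values="value", aggfunc="first")
        if wide.isna().any().any() or set(wide.index) != set(panel.names):
            missing_bio = sorted(set(panel.names) - set(wide.index))
            if missing_bio:
                raise ValueError(
                    f"participant {pid}: missing biomarker(s) "
                    f"{missing_bio[:3]}...")
            bad = np.argwhere(wide.isna().values)[0]
            raise ValueError(
                f"participant {pid}: missing value for biomarker "
                f"{wide.index[bad[0]]!r} at day {wide.columns[bad[1]]:g}")
        values = wide.reindex(panel.names).loc[:, days].to_numpy(dtype=float)
        neg = np.argwhere(values < 0)
        if neg.size:
            b, d = neg[0]
            raise ValueError(
                f"participant {pid}: negative value for biomarker "
                f"{panel.names[b]!r} at day {days[d]:g}")
        out.append(ParticipantSeries(str(pid), str(cohorts[0]), panel,
                                     days, values))
    return out


def write_cohort(
    series: Sequence[ParticipantSeries], path: str | Path
) -> pd.DataFrame:
    """Write series back to the long-format dialect read by `load_cohort`."""
    frames = []
    for s in series:
        n_bio, n_draw = s.values.shape
        frames.append(pd.DataFrame({
            "participant": np.repeat(s.participant_id, n_bio * n_draw),
            "cohort": np.repeat(s.cohort, n_bio * n_draw),
            "biomarker": np.repeat(list(s.panel.names), n_draw),
            "day": np.tile(s.draw_times, n_bio),
            "value": s.values.ravel(),
        }))
    df = pd.concat(frames, ignore_index=True)
    # %.17g round-trips every IEEE double exactly
    df.to_csv(path, index=False, float_format="%.17g")
    return df
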