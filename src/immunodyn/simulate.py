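"""Seeded synthetic cohorts emulating the serial blood-draw study design.

The clinical data behind the method is restricted, so synthetic cohorts
stand in for it.  Two generators are provided:

``sinusoid``
    Each biomarker oscillates around a positive baseline,
    ``baseline * (1 + amplitude * sin(2 pi t / period + phase)) + noise``,
    with per-participant phases and periods drawn from the seeded
    generator.  This emulates the highly dynamic, fluctuating oscillations
    seen in real draws, with cytokine scales (pg/mL-like, spanning orders
    of magnitude) and cell scales (relative concentrations) deliberately
    disparate.  It makes no claim about real interaction structure.

``glv``
    Ground-truth mode: trajectories are integrated (explicit Euler) from a
    known sparse coefficient vector over Knowledge-Model relationships,
    ``dx_T/dt = sum_j a_j x_M(j) x_S(j)`` (linear terms ``a_j x_S(j)``).
    Recovering the sparse truth is *not* expected — with 50 equations and
    28,605 unknowns the minimum-norm solution spreads weight — but the
    simulated rates let end-to-end consistency (``K a* = dx/dt``) be tested
    exactly.

Cohort sizes default to the study design: 14 cancer, 27 healthy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assembly import column_values
from .knowledge import KnowledgeModel
from .panel import Panel, STANDARD_SCHEDULE, default_panel

__all__ = ["SimulationSpec", "simulate_sinusoid_cohort",
           "simulate_glv_cohort", "default_baselines"]


def default_baselines(panel: Panel, rng: np.random.Generator) -> np.ndarray:
    """Positive baselines: cytokines log-uniform 1-500 (pg/mL-like),
    cells uniform 0.5-40 (relative concentration)."""
    base = np.empty(len(panel))
    for i, b in enumerate(panel.biomarkers):
        if b.klass.value == "cytokine":
            base[i] = 10.0 ** rng.uniform(0.0, np.log10(500.0))
        else:
            base[i] = rng.uniform(0.5, 40.0)
    return base


@dataclass
class SimulationSpec:
    """Study-condition parameters for a synthetic cohort.

    The defaults are the study conditions assumed throughout: two cohorts
    (14 cancer / 27 healthy), the two-week weekday draw schedule, 20%
    oscillation amplitude with 2-7 day periods, and 5% measurement noise.
    """

    panel: Panel = field(default_factory=default_panel)
    cohort_sizes: dict[str, int] = field(
        default_factory=lambda: {"cancer": 14, "healthy": 27})
    draw_days: tuple[float, ...] = STANDARD_SCHEDULE
    seed: int = 0
    mode: str = "sinusoid"
    amplitude: float = 0.2        # fraction of baseline
    period_range: tuple[float, float] = (2.0, 7.0)   # days
    noise_sd: float = 0.05        # fraction of baseline
    # glv mode
    coefficients: dict[int, float] | None = None   # relationship idx -> a_j
    initial: np.ndarray | None = None
    step: float = 0.01            # Euler step, days
    divergence_cap: float = 1e9

    def __post_init__(self) -> None:
        if self.mode not in ("sinusoid", "glv"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be >= 0")
        if not (0 < self.period_range[0] <= self.period_range[1]):
            raise ValueError("invalid period range")
        if len(self.draw_days) < 2:
            raise ValueError("need at least two draw days")
        if self.step <= 0:
            raise ValueError("step must be positive")


def _long_frame(panel, pid, cohort, days, values):
    n_bio, n_draw = values.shape
    return pd.DataFrame({
        "participant": np.repeat(pid, n_bio * n_draw),
        "cohort": np.repeat(cohort, n_bio * n_draw),
        "biomarker": np.repeat(list(panel.names), n_draw),
        "day": np.tile(np.asarray(days, dtype=float), n_bio),
        "value": values.ravel(),
    })


def simulate_sinusoid_cohort(spec: SimulationSpec) -> pd.DataFrame:
    """Generate a cohort table in the long-format dialect of the loaders.

    Identical specs (including seed) produce byte-identical tables: the
    generator is an integer-state PCG64 stream and participants are drawn
    in a fixed order.
    """
    rng = np.random.default_rng(spec.seed)
    panel = spec.panel
    days = np.asarray(spec.draw_days, dtype=float)
    frames = []
    clipped = 0
    for cohort in sorted(spec.cohort_sizes):
        baselines = default_baselines(panel, rng)
        for k in range(spec.cohort_sizes[cohort]):
            pid = f"{cohort}-{k + 1:02d}"
            period = rng.uniform(*spec.period_range, size=len(panel))
            phase = rng.uniform(0, 2 * np.pi, size=len(panel))
            t = days[None, :]
            vals = baselines[:, None] * (
                1.0 + spec.amplitude * np.sin(
                    2 * np.pi * t / period[:, None] + phase[:, None]))
            vals = vals + rng.normal(
                0.0, 1.0, size=vals.shape) * (spec.noise_sd
                                              * baselines[:, None])
            neg = vals < 0
            clipped += int(neg.sum())
            vals[neg] = 0.0
            frames.append(_long_frame(panel, pid, cohort, days, vals))
    if clipped:
        warnings.warn(f"{clipped} simulated values clipped at 0")
    return pd.concat(frames, ignore_index=True)


def simulate_glv_cohort(
    spec: SimulationSpec, km: KnowledgeModel
) -> tuple[pd.DataFrame, np.ndarray]:
    """Integrate generalized Lotka-Volterra dynamics from known coefficients.

    Returns the cohort table (one trajectory per participant, all sharing
    the ground-truth coefficients but with per-participant jittered initial
    states) and the dense ground-truth vector ``a*`` over relationships.
    """
    if spec.coefficients is None:
        raise ValueError("glv mode requires a coefficients mapping")
    rng = np.random.default_rng(spec.seed)
    panel = spec.panel
    a_star = np.zeros(len(km))
    for j, c in spec.coefficients.items():
        a_star[int(j)] = float(c)
    x0 = (np.asarray(spec.initial, dtype=float) if spec.initial is not None
          else default_baselines(panel, rng))
    if np.any(x0 < 0):
        raise ValueError("initial concentrations must be >= 0")
    days = np.asarray(spec.draw_days, dtype=float)
    frames = []
    for cohort in sorted(spec.cohort_sizes):
        for k in range(spec.cohort_sizes[cohort]):
            pid = f"{cohort}-{k + 1:02d}"
            x = x0 * rng.uniform(0.9, 1.1, size=x0.shape)
            t = float(days[0])
            out = np.empty((len(panel), days.size))
            d = 0
            if np.isclose(t, days[0]):
                out[:, 0] = x
                d = 1
            step = 0
            while d < days.size:
                rates = np.zeros(len(panel))
                np.add.at(rates, km.target_idx,
                          a_star * column_values(km, x))
                x = np.clip(x + spec.step * rates, 0.0, None)
                t += spec.step
                step += 1
                if np.any(np.abs(x) > spec.divergence_cap):
                    raise FloatingPointError(
                        f"gLV trajectory diverged at step {step} "
                        f"(t={t:.3f} d) for participant {pid}")
                while d < days.size and t >= days[d] - spec.step / 2:
                    out[:, d] = x
                    d += 1
            frames.append(_long_frame(panel, pid, cohort, days, out))
    return pd.concat(frames, ignore_index=True), a_star
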