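"""Generative simulator of asynchronously cycling cell populations under
nucleotide-analogue (EdU) labeling experiments.

The model is the classical deterministic-cycle picture behind cumulative
labeling and percentage-of-labeled-mitoses (PLM) experiments: a fraction
``gf`` of cells (the growth fraction) cycles through G1 -> S -> G2 -> M with
per-phase durations, the remainder is quiescent.  At steady state the
position of each cycling cell within its own cycle is uniformly distributed,
so the expected fraction of cells occupying a phase equals that phase's
duration divided by the total cycle length.  This uniform-occupancy premise
is exactly what makes the cumulative labeling index rise linearly to a
plateau, and it is the premise of the estimators in :mod:`cmzcycle.kinetics`.

Three experiment designs are supported:

``pulse``
    EdU available for a finite window; cells in S during the window are
    labeled.
``cumulative``
    EdU constantly available from t=0; every cell that enters (or is in)
    S-phase after t=0 becomes labeled, so the labeling index climbs to the
    growth fraction.
``plm``
    Same continuous labeling, but the scored quantity of interest is the
    fraction of mitotic (PH3+) cells that are EdU+, whose half-rise time
    estimates the G2 duration.

Time is continuous and label acquisition is resolved analytically per cell
(first entry into S relative to the label window); there is no fixed-step
integration and hence no step-size artifacts.  Division wraps a cell from M
back to G1 keeping the census constant — all downstream estimators consume
fractions, not absolute growth.  The EdU label is binary and persistent;
dilution over divisions is ignored, which is adequate for experiment
horizons of at most a couple of cycle lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CycleParams",
    "CellState",
    "ExperimentDesign",
    "LabelingObservation",
    "Population",
    "init_population",
    "simulate_experiment",
    "observations_to_frame",
    "frame_to_observations",
    "PRESETS",
]

Phase = Literal["G1", "S", "G2", "M", "quiescent"]

#: canonical column order of observation tables (TSV header)
OBS_COLUMNS = ("time_h", "replicate", "n_scored", "n_edu_pos", "n_ph3_pos", "n_double_pos")


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{name}: {msg}")


@dataclass(frozen=True)
class CycleParams:
    """Generative truth for a cycling population.

    Parameters
    ----------
    gf:
        Growth fraction — the proportion of cycling cells within the scored
        population, in [0, 1].
    t_g1, t_s, t_g2, t_m:
        Mean durations of G1, S, G2 and M in hours, each > 0.  The total
        cycle length is ``t_c = t_g1 + t_s + t_g2 + t_m``.
    cv:
        Coefficient of variation of per-cell phase durations (lognormal,
        drawn once per cell per phase); 0 means every cell has exactly the
        nominal durations.  Capped at 0.5.
    n_cells:
        Population size per simulated replicate.
    """

    gf: float = 1.0
    t_g1: float = 12.5
    t_s: float = 4.0
    t_g2: float = 2.5
    t_m: float = 1.0
    cv: float = 0.0
    n_cells: int = 10_000

    def __post_init__(self) -> None:
        _require(0.0 <= self.gf <= 1.0, "gf", f"must be in [0, 1], got {self.gf}")
        for name in ("t_g1", "t_s", "t_g2", "t_m"):
            v = getattr(self, name)
            _require(math.isfinite(v) and v > 0, name, f"must be a finite duration > 0 h, got {v}")
        _require(0.0 <= self.cv <= 0.5, "cv", f"must be in [0, 0.5], got {self.cv}")
        _require(int(self.n_cells) == self.n_cells and self.n_cells >= 1,
                 "n_cells", f"must be a positive integer, got {self.n_cells}")

    @property
    def t_c(self) -> float:
        """Total cycle length in hours."""
        return self.t_g1 + self.t_s + self.t_g2 + self.t_m


@dataclass(frozen=True)
class CellState:
    """Snapshot of a single cell (scalar view into a :class:`Population`)."""

    cycling: bool
    cycle_position: float  # hours from G1 start, in [0, own t_c); 0 for quiescent
    phase: Phase
    edu_labeled: bool


@dataclass(frozen=True)
class ExperimentDesign:
    """A labeling-experiment design.

    ``observation_times`` are hours of EdU exposure (measured from
    ``label_start``, which defines t=0).  ``label_duration`` is the EdU
    availability window; it is treated as unbounded for ``cumulative`` and
    ``plm`` modes regardless of the value given.
    """

    mode: Literal["pulse", "cumulative", "plm"]
    observation_times: tuple[float, ...]
    n_replicates: int = 5
    cells_scored_per_replicate: int = 50
    label_start: float = 0.0
    label_duration: float = math.inf
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.mode in ("pulse", "cumulative", "plm"), "mode",
                 f"must be one of pulse/cumulative/plm, got {self.mode!r}")
        times = tuple(float(t) for t in self.observation_times)
        _require(len(times) > 0, "observation_times", "must not be empty")
        _require(all(t >= 0 for t in times), "observation_times",
                 "must all be >= 0 (hours since label start)")
        _require(all(b > a for a, b in zip(times, times[1:])),
                 "observation_times", "must be strictly increasing")
        object.__setattr__(self, "observation_times", times)
        _require(self.n_replicates >= 1, "n_replicates", "must be >= 1")
        _require(self.cells_scored_per_replicate >= 1,
                 "cells_scored_per_replicate", "must be >= 1")
        if self.mode == "pulse":
            _require(math.isfinite(self.label_duration) and self.label_duration > 0,
                     "label_duration", "pulse mode needs a finite window > 0 h")

    @property
    def effective_label_duration(self) -> float:
        return self.label_duration if self.mode == "pulse" else math.inf


@dataclass(frozen=True)
class LabelingObservation:
    """Scored counts for one replicate at one EdU exposure time."""

    time: float
    replicate: int
    n_scored: int
    n_edu_pos: int
    n_ph3_pos: int
    n_double_pos: int

    def __post_init__(self) -> None:
        _require(self.n_scored > 0, "n_scored", "must be > 0")
        _require(0 <= self.n_edu_pos <= self.n_scored, "n_edu_pos",
                 f"must satisfy 0 <= n_edu_pos <= n_scored, got {self.n_edu_pos}/{self.n_scored}")
        _require(0 <= self.n_ph3_pos <= self.n_scored, "n_ph3_pos",
                 f"must satisfy 0 <= n_ph3_pos <= n_scored, got {self.n_ph3_pos}/{self.n_scored}")
        _require(0 <= self.n_double_pos <= self.n_ph3_pos, "n_double_pos",
                 "must satisfy 0 <= n_double_pos <= n_ph3_pos")


class Population:
    """Vectorized collection of :class:`CellState` at steady state.

    Cycling cells carry per-cell phase durations (lognormal around the
    nominal means when ``cv > 0``) and a cycle position drawn uniformly on
    [0, own cycle length) — the steady-state asynchronous configuration.
    Quiescent cells never enter S or M and are never labeled.

    Indexing returns :class:`CellState` snapshots at time 0.
    """

    def __init__(self, params: CycleParams, rng: np.random.Generator) -> None:
        self.params = params
        n = int(params.n_cells)
        n_cycling = int(round(params.gf * n))
        self.cycling = np.zeros(n, dtype=bool)
        self.cycling[:n_cycling] = True

        nominal = np.array([params.t_g1, params.t_s, params.t_g2, params.t_m])
        if params.cv > 0:
            sigma2 = math.log1p(params.cv ** 2)
            mu = np.log(nominal) - sigma2 / 2.0
            self.durations = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=(n, 4))
        else:
            self.durations = np.broadcast_to(nominal, (n, 4)).copy()
        # phase boundaries within each cell's own cycle
        self.bounds = np.cumsum(self.durations, axis=1)  # [end G1, end S, end G2, t_c]
        self.t_c = self.bounds[:, 3]
        self.position0 = rng.uniform(0.0, self.t_c)
        self.position0[~self.cycling] = 0.0

    def __len__(self) -> int:
        return int(self.params.n_cells)

    def position_at(self, t: float) -> np.ndarray:
        """Cycle position of every cell at time ``t`` hours (wrapping M -> G1)."""
        return np.where(self.cycling, (self.position0 + t) % self.t_c, 0.0)

    def phase_index_at(self, t: float) -> np.ndarray:
        """0=G1, 1=S, 2=G2, 3=M, -1=quiescent."""
        pos = self.position_at(t)
        idx = np.sum(pos[:, None] >= self.bounds[:, :3], axis=1)
        return np.where(self.cycling, idx, -1)

    def labeled_by(self, t: float, label_duration: float = math.inf) -> np.ndarray:
        """Whether each cell has overlapped S-phase during the label window.

        The label is available over [0, ``label_duration``] and the cell is
        observed at ``t``; a cell is EdU+ iff it was in S at some moment of
        [0, min(t, label_duration)].  Resolved analytically from the waiting
        time to the next S entry at t=0 (0 if already in S).
        """
        g1_end = self.bounds[:, 0]
        s_end = self.bounds[:, 1]
        p0 = self.position0
        wait = np.where(
            p0 < g1_end, g1_end - p0,
            np.where(p0 < s_end, 0.0, self.t_c - p0 + g1_end),
        )
        window = min(t, label_duration)
        return self.cycling & (wait <= window)

    def __getitem__(self, i: int) -> CellState:
        phase_i = int(self.phase_index_at(0.0)[i])
        phase: Phase = ("G1", "S", "G2", "M")[phase_i] if phase_i >= 0 else "quiescent"
        return CellState(
            cycling=bool(self.cycling[i]),
            cycle_position=float(self.position0[i]),
            phase=phase,
            edu_labeled=False,
        )

    def __iter__(self) -> Iterator[CellState]:
        return (self[i] for i in range(len(self)))


def init_population(params: CycleParams, seed: int) -> Population:
    """Draw a steady-state asynchronous population, deterministically.

    Exactly ``round(gf * n_cells)`` cells cycle; each cycling cell's position
    is uniform on [0, its own cycle length).  A uniform position distribution
    (rather than the exponentially decaying age distribution of an expanding
    population) is used because the linear-rise cumulative-labeling model
    presumes uniform phase occupancy.
    """
    return Population(params, np.random.default_rng(seed))


def _simulate_replicate(params: CycleParams, design: ExperimentDesign,
                        replicate: int, rng: np.random.Generator) -> list[LabelingObservation]:
    pop = Population(params, rng)
    n = len(pop)
    k = design.cells_scored_per_replicate
    _require(k <= n, "cells_scored_per_replicate",
             f"cannot score {k} cells from a population of {n}")
    out = []
    window = design.effective_label_duration
    for t in design.observation_times:
        labeled = pop.labeled_by(t, window)
        mitotic = pop.phase_index_at(t) == 3
        idx = rng.choice(n, size=k, replace=False)
        n_edu = int(labeled[idx].sum())
        n_ph3 = int(mitotic[idx].sum())
        n_double = int((labeled[idx] & mitotic[idx]).sum())
        out.append(LabelingObservation(time=t, replicate=replicate, n_scored=k,
                                       n_edu_pos=n_edu, n_ph3_pos=n_ph3,
                                       n_double_pos=n_double))
    return out


def simulate_experiment(params: CycleParams, design: ExperimentDesign) -> list[LabelingObservation]:
    """Simulate a labeling experiment; one independent population per replicate.

    Each replicate (a "retina") gets its own population and its own RNG
    stream derived deterministically from ``design.seed``, so counts are
    independent across replicates yet bit-reproducible.  At every
    observation time ``cells_scored_per_replicate`` cells are sampled
    without replacement and tallied: EdU+ (S-phase overlap with the label
    window), PH3+ (in M at sampling time), and double-positive.
    """
    obs: list[LabelingObservation] = []
    for r in range(design.n_replicates):
        rng = np.random.default_rng([int(design.seed), r])
        obs.extend(_simulate_replicate(params, design, r, rng))
    return obs


def observations_to_frame(obs: Sequence[LabelingObservation]) -> pd.DataFrame:
    """Observation list -> canonical table (columns ``OBS_COLUMNS``)."""
    return pd.DataFrame(
        [(o.time, o.replicate, o.n_scored, o.n_edu_pos, o.n_ph3_pos, o.n_double_pos)
         for o in obs],
        columns=list(OBS_COLUMNS),
    )


def frame_to_observations(df: pd.DataFrame) -> list[LabelingObservation]:
    """Canonical table -> observation list (validates every row)."""
    return [
        LabelingObservation(time=float(r.time_h), replicate=int(r.replicate),
                            n_scored=int(r.n_scored), n_edu_pos=int(r.n_edu_pos),
                            n_ph3_pos=int(r.n_ph3_pos), n_double_pos=int(r.n_double_pos))
        for r in df.itertuples(index=False)
    ]


# Configuration presets for the two experimental conditions of interest.
# The G2 durations (2.5 h control vs 4.5 h knockdown) reflect the reported
# doubling of G2 length upon Yap knockdown in the frog ciliary marginal
# zone; the knockdown preset also lengthens G1 and shortens S, matching the
# reported direction of the total-cycle and S-phase changes.  These are
# configuration defaults for simulation studies, not measured claims.
PRESETS: dict[str, CycleParams] = {
    "control": CycleParams(gf=0.8, t_g1=12.5, t_s=4.0, t_g2=2.5, t_m=1.0),
    "yap_morphant": CycleParams(gf=0.8, t_g1=16.5, t_s=2.0, t_g2=4.5, t_m=1.0),
}

# Observation-time layouts for parameter-recovery studies at realistic
# scoring depth (replicate means of ~50 scored cells).  The cumulative
# layout follows optimal-design reasoning for the quantities of interest: a
# cluster of short exposures pins the intercept LI_0 directly, one long
# pre-plateau exposure gives the slope its lever arm, and two post-plateau
# points measure the growth fraction; the PLM layout brackets the expected
# half-rise (G2 + M/2 for the control preset) densely and includes clear
# pre- and post-rise anchors.
DESIGN_PRESETS: dict[str, ExperimentDesign] = {
    "cumulative_recovery": ExperimentDesign(
        mode="cumulative", observation_times=(0.5, 0.75, 1.0, 1.25, 14.0, 24.0, 32.0),
        n_replicates=5, cells_scored_per_replicate=50),
    "plm_recovery": ExperimentDesign(
        mode="plm", observation_times=(0.5, 1.5, 2.5, 3.0, 3.5, 4.5, 6.0),
        n_replicates=5, cells_scored_per_replicate=50),
}
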