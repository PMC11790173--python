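"""Reverse estimation of pattern-formation timing and wavelength.

The reverse method rests on one premise: at the moment a Turing pattern
stops being produced, its motifs are equally spaced, so the ratio of motif
counts along two body distances equals the ratio of those distances' lengths
at that moment.  Given (i) motif counts along several distances on the adult
and (ii) the developmental trajectory of each distance's length relative to
a reference distance (the head), each distance votes for the developmental
stage at which its relative length matched its motif-count ratio.  If the
votes converge, that stage dates the end of pattern production, and dividing
the absolute distance length at that stage by the motif count gives the
natural wavelength of the pattern at formation.

Counts made on patterns that kept growing after formation are biased low:
at equilibrium after growth the simulated motif count falls short of the
proportional expectation c*S by a reproducible margin (the "delta", about
15%).  ``apply_rosette_correction`` applies the resulting +15% (+/-5%)
correction, and ``delta_calibration`` re-measures the margin by simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import (
    GrowthSchedule,
    ReactionParams,
    SimulationConfig,
    growth_duration,
    run_simulation,
)
from .metrics import count_motifs

__all__ = [
    "CorrectedCount",
    "DistanceTrajectory",
    "MotifCountSet",
    "TimingEstimate",
    "TimingResults",
    "ReverseTimingModel",
    "ProportionalityFit",
    "DeltaScenario",
    "DeltaReport",
    "apply_rosette_correction",
    "formation_relative_size",
    "estimate_timing",
    "expected_motif_count",
    "delta_calibration",
]

#: Motif-count correction in the presence of rosettes: +15%, +/-5%.
ROSETTE_CORRECTION = 1.15
ROSETTE_CORRECTION_BAND = (1.10, 1.20)


@dataclass(frozen=True)
class CorrectedCount:
    value: float
    band: tuple[float, float]


def apply_rosette_correction(count: float, rosettes_present: bool) -> CorrectedCount:
    """Correct a motif count for the growth deficit when rosettes are present.

    Rosettes signal that the pattern kept growing after formation, so the
    raw count underestimates the proportional expectation; the correction is
    +15% with a +/-5 percentage-point uncertainty band.  Counts are kept as
    reals; rounding is left to reporting.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    if not rosettes_present:
        return CorrectedCount(float(count), (float(count), float(count)))
    lo, hi = ROSETTE_CORRECTION_BAND
    return CorrectedCount(count * ROSETTE_CORRECTION, (count * lo, count * hi))


@dataclass(frozen=True)
class DistanceTrajectory:
    """Absolute length of one body distance across developmental stages."""

    distance_id: str
    stages: tuple[float, ...]
    lengths: tuple[float, ...]

    def __post_init__(self):
        if len(self.stages) != len(self.lengths):
            raise ValueError("stages and lengths must align")
        if len(self.stages) < 2:
            raise ValueError("need at least two stages")
        if any(s2 <= s1 for s1, s2 in zip(self.stages, self.stages[1:])):
            raise ValueError("stages must be strictly increasing")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("lengths must be positive")

    def length_at(self, stage: float) -> float:
        return float(np.interp(stage, self.stages, self.lengths))


@dataclass(frozen=True)
class MotifCountSet:
    """Adult motif counts along each distance.

    ``generation`` 1 counts a rosette as one motif (dating the first
    generation of dots); 2 counts its sub-motifs (dating the second).
    ``rosettes`` flags the distances whose counts need the +15% correction.
    """

    counts: Mapping[str, float]
    reference: str = "head"
    generation: int = 1
    rosettes: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.reference not in self.counts:
            raise ValueError(f"reference distance {self.reference!r} has no count")
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("motif counts must be >= 1")
        object.__setattr__(self, "rosettes", frozenset(self.rosettes))

    def corrected(self, distance_id: str) -> CorrectedCount:
        return apply_rosette_correction(self.counts[distance_id], distance_id in self.rosettes)


def formation_relative_size(counts: MotifCountSet, distance_id: str) -> float:
    """Relative size (vs the reference) the distance must have had at pattern
    formation: corrected count ratio, because equal wavelength at formation
    makes length ratios equal count ratios."""
    if distance_id not in counts.counts:
        raise ValueError(f"no count for distance {distance_id!r}")
    return counts.corrected(distance_id).value / counts.corrected(counts.reference).value


def _invert_trajectory(stages: np.ndarray, rel: np.ndarray, target: float) -> tuple[float, bool]:
    """Earliest stage where the (piecewise-linear) relative size crosses the
    target; returns (stage, extrapolated)."""
    if target < rel.min() or target > rel.max():
        # outside the observed range: clamp to the nearest end, flagged
        return (float(stages[np.argmin(rel)]) if target < rel.min()
                else float(stages[np.argmax(rel)])), True
    for k in range(len(stages) - 1):
        r0, r1 = rel[k], rel[k + 1]
        if (r0 - target) * (r1 - target) <= 0:
            if r0 == r1:
                return float(stages[k]), False
            frac = (target - r0) / (r1 - r0)
            return float(stages[k] + frac * (stages[k + 1] - stages[k])), False
    return float(stages[-1]), True  # unreachable for continuous data


@dataclass(frozen=True)
class TimingEstimate:
    """Per-distance formation-stage and wavelength estimates."""

    table: pd.DataFrame
    consensus_stage: float
    stage_iqr: float
    consensus_wavelength: float

    def __str__(self):  # pragma: no cover - convenience
        return self.table.to_string(index=False)


def estimate_timing(
    trajectories: Sequence[DistanceTrajectory],
    counts: MotifCountSet,
) -> TimingEstimate:
    """Estimate the stage at which the pattern formed, one vote per distance.

    For each non-reference distance the estimated stage is where the
    distance's relative length (linear interpolation between measured
    stages) equals its formation ratio.  Dispersion across distances is the
    interquartile range; the per-distance wavelength is the absolute length
    at the estimated stage divided by the corrected count, and the consensus
    wavelength is their median.  Formation ratios outside the observed
    trajectory range are flagged ``extrapolated`` rather than silently
    clipped.
    """
    by_id = {t.distance_id: t for t in trajectories}
    if counts.reference not in by_id:
        raise ValueError(f"no trajectory for reference {counts.reference!r}")
    others = [t for t in trajectories if t.distance_id != counts.reference
              and t.distance_id in counts.counts]
    if len(others) < 2:
        raise ValueError("need at least two non-reference distances with counts")
    ref = by_id[counts.reference]

    rows = []
    for traj in others:
        stages = np.array(traj.stages)
        rel = np.array([traj.length_at(s) / ref.length_at(s) for s in stages])
        target = formation_relative_size(counts, traj.distance_id)
        stage, extrapolated = _invert_trajectory(stages, rel, target)
        wavelength = traj.length_at(stage) / counts.corrected(traj.distance_id).value
        rows.append(
            dict(distance_id=traj.distance_id, formation_ratio=target,
                 stage=stage, extrapolated=extrapolated, wavelength=wavelength)
        )
    table = pd.DataFrame(rows)
    stages = table["stage"].to_numpy()
    q75, q25 = np.percentile(stages, [75, 25])
    return TimingEstimate(
        table=table,
        consensus_stage=float(np.median(stages)),
        stage_iqr=float(q75 - q25),
        consensus_wavelength=float(table["wavelength"].median()),
    )


class ReverseTimingModel:
    """Model-style interface around :func:`estimate_timing`.

    Parameters
    ----------
    trajectories
        Per-distance absolute lengths over developmental stages.
    counts
        Adult motif counts (with rosette flags) along the same distances.
    """

    def __init__(self, trajectories: Sequence[DistanceTrajectory], counts: MotifCountSet):
        self.trajectories = list(trajectories)
        self.counts = counts

    @classmethod
    def from_frames(cls, trajectories: pd.DataFrame, counts: pd.DataFrame,
                    reference: str = "head", generation: int = 1) -> "ReverseTimingModel":
        """Build from tidy tables.

        ``trajectories``: columns distance_id, stage, length.
        ``counts``: columns distance_id, count and optionally rosettes (bool).
        """
        trajs = []
        for did, grp in trajectories.groupby("distance_id", sort=False):
            grp = grp.sort_values("stage")
            trajs.append(DistanceTrajectory(str(did), tuple(grp["stage"]), tuple(grp["length"])))
        rosettes = frozenset(
            str(r.distance_id) for r in counts.itertuples()
            if getattr(r, "rosettes", False)
        )
        count_set = MotifCountSet(
            counts=dict(zip(counts["distance_id"].astype(str), counts["count"].astype(float))),
            reference=reference, generation=generation, rosettes=rosettes,
        )
        return cls(trajs, count_set)

    def fit(self) -> "TimingResults":
        return TimingResults(self, estimate_timing(self.trajectories, self.counts))


class TimingResults:
    """Fitted reverse-timing estimates with a readable summary."""

    def __init__(self, model: ReverseTimingModel, estimate: TimingEstimate):
        self.model = model
        self.estimate = estimate

    @property
    def table(self) -> pd.DataFrame:
        return self.estimate.table

    @property
    def consensus_stage(self) -> float:
        return self.estimate.consensus_stage

    @property
    def consensus_wavelength(self) -> float:
        return self.estimate.consensus_wavelength

    @property
    def stage_iqr(self) -> float:
        return self.estimate.stage_iqr

    def summary(self) -> str:
        e = self.estimate
        lines = [
            "Reverse timing estimate",
            "=======================",
            e.table.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
            "",
            f"consensus stage      : {e.consensus_stage:.4g}",
            f"stage IQR            : {e.stage_iqr:.4g}",
            f"consensus wavelength : {e.consensus_wavelength:.4g}",
            f"reference distance   : {self.model.counts.reference}",
            f"motif generation     : {self.model.counts.generation}",
        ]
        if e.table["extrapolated"].any():
            bad = ", ".join(e.table.loc[e.table.extrapolated, "distance_id"])
            lines.append(f"extrapolated distances: {bad}")
        return "\n".join(lines)


@dataclass(frozen=True)
class ProportionalityFit:
    """Through-origin fit N(S) = c*S of motif count vs tissue size."""

    slope: float
    sizes: tuple[float, ...]
    counts: tuple[float, ...]
    relative_residuals: tuple[float, ...]

    def predict(self, size: float) -> float:
        return self.slope * size


def expected_motif_count(table: Iterable[tuple[float, float]] | pd.DataFrame) -> ProportionalityFit:
    """Least-squares through-origin fit of motif count against tissue size."""
    if isinstance(table, pd.DataFrame):
        pairs = list(zip(table["size"].astype(float), table["count"].astype(float)))
    else:
        pairs = [(float(s), float(n)) for s, n in table]
    if len(pairs) < 2:
        raise ValueError("need counts at >= 2 tissue sizes")
    sizes = np.array([p[0] for p in pairs])
    counts = np.array([p[1] for p in pairs])
    slope = float((sizes * counts).sum() / (sizes**2).sum())
    resid = (counts - slope * sizes) / (slope * sizes)
    return ProportionalityFit(slope, tuple(sizes), tuple(counts), tuple(float(r) for r in resid))


# ---------------------------------------------------------------------------
# Delta calibration
# ---------------------------------------------------------------------------

#: The published calibration grid: growth rates and final surface multiples.
CALIBRATION_RATES = (0.01, 0.02, 0.05, 0.1, 0.2)
CALIBRATION_MAX_SIZES = (1 / 0.4, 1 / 0.25, 1 / 0.185)


@dataclass(frozen=True)
class DeltaScenario:
    g: float
    max_surface: float
    growth_end_iteration: int
    n_iter: int
    counts_start: tuple[int, ...]
    counts_end: tuple[int, ...]
    counts_final: tuple[int, ...]
    deltas_end: tuple[float, ...]
    deltas_final: tuple[float, ...]
    formed_growth_patterns: bool

    @property
    def mean_delta_end(self) -> float:
        return float(np.mean(self.deltas_end))

    @property
    def mean_delta_final(self) -> float:
        return float(np.mean(self.deltas_final))


@dataclass(frozen=True)
class DeltaReport:
    """Motif-count deficits across the (growth rate x final size) grid.

    ``delta`` is 100*(c*S - N)/(c*S): the percentage by which the observed
    motif count falls short of the proportional expectation.  Scenarios in
    which the motif count did not increase during growth are flagged (growth
    too fast to produce growth patterns) and excluded from the recommended
    correction.
    """

    baseline: ProportionalityFit
    scenarios: tuple[DeltaScenario, ...]
    recommended_correction: float
    correction_spread: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                g=s.g, max_surface=round(s.max_surface, 3),
                delta_end=s.mean_delta_end, delta_final=s.mean_delta_final,
                formed_growth_patterns=s.formed_growth_patterns,
            )
            for s in self.scenarios
        )

    def summary(self) -> str:
        lines = [
            "Delta calibration",
            "=================",
            f"baseline slope c = {self.baseline.slope:.3f} motifs per unit surface",
            self.to_frame().to_string(index=False, float_format=lambda v: f"{v:.2f}"),
            "",
            f"recommended correction: +{self.recommended_correction:.1f}% "
            f"(spread {self.correction_spread[0]:.1f}-{self.correction_spread[1]:.1f}%)",
        ]
        return "\n".join(lines)


def _scenario_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def delta_calibration(
    rates: Sequence[float] = CALIBRATION_RATES,
    max_sizes: Sequence[float] = CALIBRATION_MAX_SIZES,
    reps: int = 3,
    seed: int = 0,
    reaction: ReactionParams | None = None,
    shape: tuple[int, int] = (128, 128),
    t_start: int = 10_000,
    initial_condition: str = "random_noise",
    relax_iterations: int = 25_000,
    min_iterations: int = 45_000,
    baseline_iterations: int = 30_000,
    noise_tolerance: float | None = None,
) -> DeltaReport:
    """Measure the motif-count deficit induced by growth.

    The proportional baseline c is fitted from no-growth runs at effective
    sizes {1} plus the final sizes (diffusion multiplier d = 1/S).  Each
    (rate, size) scenario is then simulated through growth and a relaxation
    tail, and the deficit versus c*S is reported at the end of growth and at
    the final (equilibrated) state, averaged over ``reps`` seeded replicates.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    reaction = reaction or ReactionParams(s=6.0, r=30.0)
    seeds = _scenario_seeds(seed, reps)

    # ---- no-growth proportionality baseline (d scaled as 1/S) ----
    baseline_sizes = sorted({1.0, *max_sizes})
    pairs = []
    for size in baseline_sizes:
        for sd in seeds:
            cfg = SimulationConfig(
                reaction=ReactionParams(
                    s=reaction.s, r=reaction.r, d=reaction.d / size, dt=reaction.dt),
                growth=GrowthSchedule(g=0.0),
                shape=shape, initial_condition=initial_condition,
                n_iter=baseline_iterations, snapshot_interval=baseline_iterations,
                seed=sd,
            )
            hist = run_simulation(cfg)
            pairs.append((size, count_motifs(hist.b_snapshots[-1], noise_tolerance)))
    baseline = expected_motif_count(pairs)

    scenarios = []
    for g in rates:
        for size in max_sizes:
            n_growth = growth_duration(g, size, reaction.dt)
            growth_end = t_start + n_growth
            n_iter = max(min_iterations, growth_end + relax_iterations)
            cs, ce, cf, de, df = [], [], [], [], []
            for sd in seeds:
                cfg = SimulationConfig(
                    reaction=reaction,
                    growth=GrowthSchedule(g=g, t_start=t_start, max_surface=size),
                    shape=shape, initial_condition=initial_condition,
                    n_iter=n_iter, snapshot_interval=250, seed=sd,
                )
                hist = run_simulation(cfg)
                n0 = count_motifs(hist.b_snapshots[hist.index_at(t_start)], noise_tolerance)
                ne = count_motifs(hist.b_snapshots[hist.index_at(growth_end)], noise_tolerance)
                nf = count_motifs(hist.b_snapshots[-1], noise_tolerance)
                expected = baseline.predict(size)
                cs.append(n0)
                ce.append(ne)
                cf.append(nf)
                de.append(100.0 * (expected - ne) / expected)
                df.append(100.0 * (expected - nf) / expected)
            formed = bool(np.median(np.array(ce) - np.array(cs)) > 0)
            scenarios.append(DeltaScenario(
                g=g, max_surface=size, growth_end_iteration=growth_end, n_iter=n_iter,
                counts_start=tuple(cs), counts_end=tuple(ce), counts_final=tuple(cf),
                deltas_end=tuple(de), deltas_final=tuple(df),
                formed_growth_patterns=formed,
            ))

    formed = [s for s in scenarios if s.formed_growth_patterns] or scenarios
    finals = [s.mean_delta_final for s in formed]
    return DeltaReport(
        baseline=baseline,
        scenarios=tuple(scenarios),
        recommended_correction=float(np.mean(finals)),
        correction_spread=(float(np.min(finals)), float(np.max(finals))),
    )
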