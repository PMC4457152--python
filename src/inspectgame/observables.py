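"""Stationarity detection, phase classification, parameter sweeps and
pairwise invasion experiments.

A *phase* at a parameter point is the set of strategies surviving in the
stationary state.  Stationarity is declared when the time-averaged
strategy fractions stop drifting between consecutive windows.  Phase
transitions along a parameter axis are the points where the surviving
set changes; their location is reported as the midpoint between adjacent
grid values (no bisection refinement).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

from .core_model import PayoffParams, Strategy, get_variant, strategy_labels
from .dynamics import SimulationConfig, TimeSeries, run_simulation
from .lattice import half_blocks

__all__ = [
    "Stationarity",
    "is_stationary",
    "PhasePoint",
    "PhaseDiagram",
    "classify_point",
    "sweep",
    "pairwise_invasion",
    "stationary_fraction",
]

#: Time-averaged fraction below which a strategy is treated as extinct
#: (finite-lattice noise floor at L ~ 100-200), on top of a hard
#: zero-count check.
EPS_EXTINCT = 1e-3

#: Default stationarity window (MCS) and absolute tolerance on the
#: drift of per-strategy window means.
STAT_WINDOW = 100.0
STAT_TOL = 0.01

#: Length (MCS) of the final averaging window for stationary fractions.
AVG_WINDOW = 200.0


class Stationarity(NamedTuple):
    """``stationary`` is None when the series is too short to decide
    (inconclusive, distinct from a definite "not stationary").

    ``onset_mcs`` is the first sampled time at which the two-window
    criterion holds (the *detection* time); ``reached_mcs`` is the start
    of the stationary stretch that detection demonstrates, i.e. the
    detection time minus the two comparison windows (clipped at the
    start of the series).  A series that is constant from the beginning
    has ``reached_mcs`` equal to its first sample time.
    """

    stationary: bool | None
    onset_mcs: float | None
    reached_mcs: float | None = None


def is_stationary(
    ts: TimeSeries, window: float = STAT_WINDOW, tol: float = STAT_TOL
) -> Stationarity:
    """Check whether the fractions became time-independent.

    The criterion holds at time t when, for every strategy, the mean
    fractions over the two consecutive non-overlapping windows
    (t - 2w, t - w] and (t - w, t] differ by at most ``tol``.  The onset
    is the first sampled t at which it holds; the criterion is a trailing
    detector, so the state itself is stationary from about t - 2w on.
    """
    t = ts.mcs
    if t[-1] - t[0] < 2 * window:
        return Stationarity(None, None, None)
    for k in range(len(t)):
        tk = t[k]
        if tk - t[0] < 2 * window:
            continue
        recent = (t > tk - window) & (t <= tk)
        earlier = (t > tk - 2 * window) & (t <= tk - window)
        if not recent.any() or not earlier.any():
            continue
        drift = np.abs(
            ts.fractions[recent].mean(axis=0) - ts.fractions[earlier].mean(axis=0)
        ).max()
        if drift <= tol:
            onset = float(tk)
            return Stationarity(True, onset, max(float(t[0]), onset - 2 * window))
    return Stationarity(False, None, None)


@dataclass(frozen=True)
class PhasePoint:
    """Classification of one parameter point."""

    params: PayoffParams
    variant_name: str
    surviving: frozenset[Strategy]
    fractions: dict[Strategy, float]
    n_replicates: int
    n_agree: int  # replicates whose surviving set matches the majority
    onset_mcs: float | None  # median stationarity onset of agreeing replicates
    unresolved: bool = False

    @property
    def label(self) -> str:
        return strategy_labels(self.surviving) if self.surviving else "-"


@dataclass
class PhaseDiagram:
    """Ordered scan along one parameter axis."""

    axis: str
    values: np.ndarray
    points: list[PhasePoint]
    transitions: list[tuple[float, str, str]] = field(default_factory=list)

    @property
    def phase_sequence(self) -> list[str]:
        """Ordered distinct phase labels along the axis (unresolved
        points excluded)."""
        seq: list[str] = []
        for p in self.points:
            if p.unresolved:
                continue
            if not seq or seq[-1] != p.label:
                seq.append(p.label)
        return seq

    @property
    def has_unresolved(self) -> bool:
        return any(p.unresolved for p in self.points)

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for v, p in zip(self.values, self.points):
            row = {
                self.axis: v,
                "alpha": p.params.alpha,
                "beta": p.params.beta,
                "gamma": p.params.gamma,
                "phase": p.label,
                "unresolved": p.unresolved,
                "n_agree": p.n_agree,
                "n_replicates": p.n_replicates,
                "onset_mcs": p.onset_mcs,
            }
            for s, f in sorted(p.fractions.items()):
                row[f"f_{s.name}"] = f
            rows.append(row)
        return pd.DataFrame(rows)

    def summary_json(self) -> str:
        return json.dumps(
            {
                "axis": self.axis,
                "values": [float(v) for v in self.values],
                "phase_sequence": self.phase_sequence,
                "transitions": [
                    {"at": at, "from": a, "to": b} for at, a, b in self.transitions
                ],
                "unresolved_points": [
                    float(v)
                    for v, p in zip(self.values, self.points)
                    if p.unresolved
                ],
            },
            indent=2,
        )


def _replicate_summary(
    config: SimulationConfig,
    seed: int,
    eps_extinct: float,
    window: float,
    tol: float,
):
    ts = run_simulation(config.with_seed(seed))
    stat = is_stationary(ts, window, tol)
    avg_start = max(ts.mcs[0], ts.mcs[-1] - AVG_WINDOW)
    means = ts.window_mean(avg_start)
    final_counts = ts.final_state.counts()
    surviving = frozenset(
        s
        for i, s in enumerate(config.variant.strategies)
        if final_counts[i] > 0 and means[i] > eps_extinct
    )
    return surviving, means, stat


def classify_point(
    config: SimulationConfig,
    replicates: int | None = None,
    eps_extinct: float = EPS_EXTINCT,
    window: float = STAT_WINDOW,
    tol: float = STAT_TOL,
) -> PhasePoint:
    """Classify one parameter point by the majority surviving set.

    Runs ``replicates`` independent simulations (replicate r uses seed
    ``config.seed + r``); a strategy survives a replicate when its final
    site count is positive and its time-averaged stationary fraction
    exceeds ``eps_extinct``.  The point's surviving set is the majority
    vote; a tie escalates the replicate count once (2x) before the point
    is flagged unresolved.  A point is also unresolved when no replicate
    reaches the stationarity criterion within the MCS budget.
    """
    n = replicates if replicates is not None else config.replicates

    def gather(nrep):
        return [
            _replicate_summary(config, config.seed + r, eps_extinct, window, tol)
            for r in range(nrep)
        ]

    results = gather(n)

    def tally(res):
        votes: dict[frozenset, int] = {}
        for surv, _, _ in res:
            votes[surv] = votes.get(surv, 0) + 1
        best = max(votes.values())
        winners = [s for s, c in votes.items() if c == best]
        return winners, best

    winners, best = tally(results)
    if len(winners) > 1:  # tie: escalate once
        results = gather(2 * n)
        n = 2 * n
        winners, best = tally(results)

    unresolved = len(winners) > 1
    majority = winners[0] if not unresolved else frozenset()
    if not any(stat.stationary for _, _, stat in results):
        unresolved = True

    agreeing = [r for r in results if r[0] == majority] if not unresolved else []
    variant = config.variant
    if agreeing:
        mean_frac = np.mean([m for _, m, _ in agreeing], axis=0)
        fractions = {s: float(mean_frac[i]) for i, s in enumerate(variant.strategies)}
        onsets = [st.onset_mcs for _, _, st in agreeing if st.onset_mcs is not None]
        onset = float(np.median(onsets)) if onsets else None
    else:
        fractions = {}
        onset = None

    return PhasePoint(
        params=config.params,
        variant_name=variant.name,
        surviving=majority,
        fractions=fractions,
        n_replicates=n,
        n_agree=best if not unresolved else 0,
        onset_mcs=onset,
        unresolved=unresolved,
    )


def sweep(
    axis: str,
    values: Sequence[float],
    base_config: SimulationConfig,
    replicates: int | None = None,
    eps_extinct: float = EPS_EXTINCT,
    progress: bool = False,
) -> PhaseDiagram:
    """Classify every grid value of one payoff parameter.

    ``axis`` is one of ``alpha``, ``beta``, ``gamma``.  The grid must be
    strictly increasing with at least 2 points.  Transitions are the
    midpoints between consecutive resolved points with differing
    surviving sets; gaps at unresolved points are excluded from the
    count.
    """
    if axis not in ("alpha", "beta", "gamma"):
        raise ValueError(f"axis must be a payoff parameter, got {axis!r}")
    values = np.asarray(values, dtype=float)
    if len(values) < 2 or not np.all(np.diff(values) > 0):
        raise ValueError("grid must be strictly increasing with >= 2 points")

    points = []
    for v in values:
        cfg = replace(base_config, params=replace(base_config.params, **{axis: float(v)}))
        pt = classify_point(cfg, replicates, eps_extinct)
        points.append(pt)
        if progress:
            print(f"  {axis}={v:g}: {pt.label}{' (unresolved)' if pt.unresolved else ''}")

    transitions = []
    for (v0, p0), (v1, p1) in zip(
        zip(values[:-1], points[:-1]), zip(values[1:], points[1:])
    ):
        if p0.unresolved or p1.unresolved:
            continue
        if p0.surviving != p1.surviving:
            transitions.append((float((v0 + v1) / 2), p0.label, p1.label))
    return PhaseDiagram(axis, values, points, transitions)


def pairwise_invasion(
    s_a: Strategy,
    s_b: Strategy,
    params: PayoffParams,
    variant: str = "five_strategy",
    L: int = 60,
    K: float = 0.5,
    max_mcs: int = 3000,
    replicates: int = 5,
    seed: int = 0,
    eps_extinct: float = EPS_EXTINCT,
) -> str:
    """Head-to-head competition started from two half-lattice blocks.

    The initial state contains only the two strategies, so interface
    motion decides the outcome.  Returns ``"a_wins"``, ``"b_wins"``,
    ``"coexistence"`` or ``"inconclusive"``.
    """
    v = get_variant(variant)
    if s_a not in v or s_b not in v:
        raise ValueError(f"strategies must belong to variant {v.name!r}")
    config = SimulationConfig(
        variant=v,
        params=params,
        L=L,
        max_mcs=max_mcs,
        sample_every=10,
        seed=seed,
        initial=half_blocks(s_a, s_b),
    )
    point = classify_point(config, replicates, eps_extinct)
    if point.unresolved:
        return "inconclusive"
    if point.surviving == {s_a}:
        return "a_wins"
    if point.surviving == {s_b}:
        return "b_wins"
    if point.surviving == {s_a, s_b}:
        return "coexistence"
    return "inconclusive"


def stationary_fraction(
    config: SimulationConfig,
    strategy: Strategy,
    replicates: int | None = None,
    avg_window: float = AVG_WINDOW,
) -> tuple[float, float]:
    """Mean stationary fraction of one strategy, with its standard error.

    Each replicate contributes the time average of the strategy's
    fraction over the final ``avg_window`` MCS; the mean and the
    standard error are taken across replicates.  Returns (0.0, 0.0)
    when the strategy is extinct in every replicate.
    """
    n = replicates if replicates is not None else config.replicates
    idx = config.variant.index[strategy]
    vals = []
    for r in range(n):
        ts = run_simulation(config.with_seed(config.seed + r))
        avg_start = max(ts.mcs[0], ts.mcs[-1] - avg_window)
        vals.append(float(ts.window_mean(avg_start)[idx]))
    vals = np.asarray(vals)
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return mean, se
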