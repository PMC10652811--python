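"""Multistage (Erlang-stage) linear ODE model of cell-cycle progression.

Each cell-cycle phase — G0–G1, S, G2–M — is subdivided into ``m`` memoryless
subphases so that phase durations are Erlang(m) distributed rather than
exponential. The population state is the vector of cell counts per subphase,

    X = (G1_1 .. G1_m, S_1 .. S_m, M_1 .. M_m),

and evolves as the linear system dX/dt = A·X where A encodes progression
through the chain: within-G1 steps at rate ``lambda_alpha``, the final
G1_m → S_1 exit at the drug-dependent rate ``lambda_g1s`` (the only rate
affected by treatment), S steps at ``lambda_beta``, G2–M steps at
``lambda_gamma``, and division at the end of G2–M returning two daughter
cells to G1_1. There is no carrying capacity and no death compartment:
untreated populations grow exponentially at the Perron eigenvalue of A.

All rates are per day; time is in days throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._linalg import expm_batch

__all__ = [
    "CellCycleParams",
    "SubphaseState",
    "PhaseTrajectory",
    "build_rate_matrix",
    "simulate_constant",
    "simulate_timevarying",
    "aggregate_phases",
    "initial_state",
    "growth_rate",
    "stationary_distribution",
]

DEFAULT_STEP = 0.05  # day; midpoint-frozen propagation step


@dataclass(frozen=True)
class CellCycleParams:
    """Subphase count and per-subphase progression rates (1/day).

    ``lambda_alpha`` drives the first m−1 within-G1 steps; the G1→S exit
    rate is supplied per call (it depends on drug concentrations). For
    m = 1 ``lambda_alpha`` does not enter the dynamics at all.
    Per-subphase rates are used raw — no internal rescaling by m; if a
    caller wants phase durations held fixed across m it must scale the
    rates itself.
    """

    m: int
    lambda_alpha: float
    lambda_beta: float
    lambda_gamma: float

    def __post_init__(self) -> None:
        if not (isinstance(self.m, (int, np.integer)) and self.m >= 1):
            raise ValueError(f"m must be a positive integer, got {self.m!r}")
        for name in ("lambda_alpha", "lambda_beta", "lambda_gamma"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive and finite, got {v!r}")

    @property
    def n_states(self) -> int:
        return 3 * self.m


@dataclass
class SubphaseState:
    """Counts per subphase (length 3m, ordered G1_1..G1_m, S_1..S_m, M_1..M_m)."""

    counts: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or self.counts.size % 3 != 0:
            raise ValueError("counts must be a 1-D vector of length 3m")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class PhaseTrajectory:
    """Phase-aggregated counts over time (G1, S, G2M and their total)."""

    times: np.ndarray
    g1: np.ndarray
    s: np.ndarray
    g2m: np.ndarray
    total: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("times", "g1", "s", "g2m"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.total is None:
            self.total = self.g1 + self.s + self.g2m
        else:
            self.total = np.asarray(self.total, dtype=float)

    def to_frame(self):
        """Tidy long-format table: time_days, phase (G1|S|G2M|total), count."""
        import pandas as pd

        blocks = []
        for phase, arr in (("G1", self.g1), ("S", self.s), ("G2M", self.g2m), ("total", self.total)):
            blocks.append(pd.DataFrame({"time_days": self.times, "phase": phase, "count": arr}))
        return pd.concat(blocks, ignore_index=True)


def build_rate_matrix(params: CellCycleParams, lambda_g1s: float) -> np.ndarray:
    """Rate matrix A of the 3m-state chain, dX/dt = A·X.

    ``lambda_g1s`` is the (possibly drug-suppressed) G1_m → S_1 exit rate.
    Division at the M_m exit feeds 2 cells back into G1_1, so the M_m
    column sums to +lambda_gamma (net production) and every other column
    sums to zero.
    """
    if not (np.isfinite(lambda_g1s) and lambda_g1s >= 0):
        raise ValueError(f"lambda_g1s must be non-negative and finite, got {lambda_g1s!r}")
    m = params.m
    n = 3 * m
    a = np.zeros((n, n))
    la, lb, lg = params.lambda_alpha, params.lambda_beta, params.lambda_gamma
    # G1 chain: internal steps at lambda_alpha, exit at lambda_g1s
    for i in range(m - 1):
        a[i, i] -= la
        a[i + 1, i] += la
    a[m - 1, m - 1] -= lambda_g1s
    a[m, m - 1] += lambda_g1s
    # S chain: all steps (incl. S_m -> M_1) at lambda_beta
    for i in range(m):
        a[m + i, m + i] -= lb
        a[m + i + 1, m + i] += lb
    # G2-M chain: steps at lambda_gamma; exit of M_m divides into 2 × G1_1
    for i in range(m - 1):
        a[2 * m + i, 2 * m + i] -= lg
        a[2 * m + i + 1, 2 * m + i] += lg
    a[n - 1, n - 1] -= lg
    a[0, n - 1] += 2.0 * lg
    return a


def _clip_counts(x: np.ndarray) -> np.ndarray:
    # expm of a Metzler matrix is nonnegative; clip numerical dust only
    return np.where(x < 0, 0.0, x)


def simulate_constant(
    params: CellCycleParams,
    state0: SubphaseState,
    lambda_g1s: float,
    times: np.ndarray,
) -> list[SubphaseState]:
    """Propagate the chain under a constant G1→S rate.

    Uses the closed form X(t) = expm(A·(t−t0))·X0; exact for this linear
    constant-coefficient system up to floating-point error.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return []
    if not np.all(np.diff(times) >= 0):
        raise ValueError("times must be non-decreasing")
    if abs(times[0] - state0.time) > 1e-12:
        raise ValueError("times[0] must equal state0.time")
    a = build_rate_matrix(params, lambda_g1s)
    dts = times - state0.time
    props = expm_batch(a[None, :, :] * dts[:, None, None])
    out = []
    for t, p in zip(times, props):
        out.append(SubphaseState(_clip_counts(p @ state0.counts), time=float(t)))
    return out


def simulate_timevarying(
    params: CellCycleParams,
    state0: SubphaseState,
    lambda_g1s_fn,
    times: np.ndarray,
    step: float = DEFAULT_STEP,
) -> list[SubphaseState]:
    """Propagate under a time-varying G1→S rate by midpoint freezing.

    The horizon is cut into segments of at most ``step`` days (requested
    output times always fall on segment boundaries); within each segment
    the rate is frozen at its midpoint value and the state advanced with
    the segment's matrix exponential. Second-order accurate in ``step``
    and unconditionally stable/nonnegative on this Metzler system.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return []
    if not np.all(np.diff(times) >= 0):
        raise ValueError("times must be non-decreasing")
    if abs(times[0] - state0.time) > 1e-12:
        raise ValueError("times[0] must equal state0.time")
    t0, t1 = float(times[0]), float(times[-1])
    # segment grid: uniform steps unioned with the requested output times
    n_seg = max(1, int(np.ceil((t1 - t0) / step - 1e-9)))
    grid = np.union1d(t0 + (t1 - t0) * np.arange(n_seg + 1) / n_seg, times)
    mids = 0.5 * (grid[:-1] + grid[1:])
    rates = np.asarray([lambda_g1s_fn(t) for t in mids], dtype=float)
    if not np.all(np.isfinite(rates)) or (rates < 0).any():
        raise ValueError("lambda_g1s_fn returned a negative or non-finite rate")
    a0 = build_rate_matrix(params, 0.0)
    b = build_rate_matrix(params, 1.0) - a0  # unit G1->S exit block
    dts = np.diff(grid)
    mats = (a0[None] + rates[:, None, None] * b[None]) * dts[:, None, None]
    props = expm_batch(mats)
    out = []
    x = state0.counts.copy()
    want = {round(t, 12) for t in times}
    if round(t0, 12) in want:
        out.append(SubphaseState(x.copy(), time=t0))
    for tnext, p in zip(grid[1:], props):
        x = _clip_counts(p @ x)
        if round(float(tnext), 12) in want:
            out.append(SubphaseState(x.copy(), time=float(tnext)))
    return out


def aggregate_phases(states, m: int) -> PhaseTrajectory:
    """Sum subphases 1..m into per-phase counts; total is preserved."""
    times = np.array([s.time for s in states], dtype=float)
    counts = np.array([s.counts for s in states], dtype=float)
    if counts.size and counts.shape[1] != 3 * m:
        raise ValueError("state length does not match 3m")
    g1 = counts[:, :m].sum(axis=1)
    s_ = counts[:, m : 2 * m].sum(axis=1)
    g2m = counts[:, 2 * m :].sum(axis=1)
    return PhaseTrajectory(times=times, g1=g1, s=s_, g2m=g2m)


def growth_rate(params: CellCycleParams, lambda_g1s: float) -> float:
    """Asymptotic exponential growth rate: the Perron eigenvalue of A (1/day)."""
    a = build_rate_matrix(params, lambda_g1s)
    return float(np.max(np.linalg.eigvals(a).real))


def stationary_distribution(params: CellCycleParams, lambda_g1s: float) -> np.ndarray:
    """Stable subphase proportions: normalised dominant right eigenvector of A."""
    a = build_rate_matrix(params, lambda_g1s)
    w, v = np.linalg.eig(a)
    vec = v[:, np.argmax(w.real)].real
    vec = np.abs(vec)  # Perron vector of a Metzler matrix is sign-definite
    return vec / vec.sum()


def initial_state(
    total: float,
    mode: str,
    params: CellCycleParams,
    lambda_g1s: float,
) -> SubphaseState:
    """Initial population of ``total`` cells.

    ``synchronized`` places all cells in G1_1 (serum-starvation release);
    ``stationary`` distributes them along the dominant right eigenvector of
    A, the proportions an exponentially growing culture settles into.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    n = params.n_states
    if mode == "synchronized":
        x = np.zeros(n)
        x[0] = total
    elif mode == "stationary":
        x = total * stationary_distribution(params, lambda_g1s)
    else:
        raise ValueError(f"unknown initial-state mode {mode!r}")
    return SubphaseState(x, time=0.0)
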