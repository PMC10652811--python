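"""Synthetic in vitro assay generator.

Emulates the two plate-based experimental designs that parameterize the
model, so the full pipeline (generation → inference → trial simulation)
is testable end to end:

* a 5-day *drug synergy* assay: live-cell counts per well, days 0–5, over
  a 5×5 dose matrix (palbociclib 0/12.5/25/50/100 nmol/L × fulvestrant
  0/0.65/1.3/2.6/5.2 nmol/L), 3 replicates, 2000–3000 cells seeded per
  well, cells initially in exponential (stationary-distribution) growth;
* a 4-day *cell-cycle* assay: per-phase (G0–G1, S, G2–M) counts, days
  0–4, for single-drug ladders F1–F4 / P1–P4 and matched combinations,
  500 cells/well seeded in a synchronized (G1_1) state after serum
  starvation, with ~10% of cells left phase-unassigned by the readout.

Observation noise is multiplicative log-normal on counts (counts span
orders of magnitude and measured uncertainty behaves multiplicatively);
the inference module's likelihood uses the same observation model, so
parameter recovery from these tables is well-posed by construction.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from .cellcycle import (
    CellCycleParams,
    aggregate_phases,
    initial_state,
    simulate_constant,
)
from .response import InteractionParams, g1s_rate

__all__ = [
    "GroundTruth",
    "SynergyAssayConfig",
    "CellCycleAssayConfig",
    "ASSAY_COLUMNS",
    "generate_synergy",
    "generate_cellcycle",
    "noise_free_totals",
    "noise_free_phases",
    "default_truth",
    "PROFILES",
]

#: canonical tidy column order of an assay table
ASSAY_COLUMNS = ["assay", "cell_line", "dose_F", "dose_P", "day", "replicate", "phase", "count"]


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters of one cell-line profile."""

    label: str
    cell_cycle: CellCycleParams
    interaction: InteractionParams
    day0_synergy: float = 2000.0  # seeded cells/well, synergy assay
    day0_cellcycle: float = 500.0  # seeded cells/well, cell-cycle assay
    sigma_synergy: float = 0.10  # log-scale s.d. of count noise
    sigma_cellcycle: float = 0.20
    unassigned_fraction: float = 0.10

    def __post_init__(self) -> None:
        for name in ("day0_synergy", "day0_cellcycle"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("sigma_synergy", "sigma_cellcycle"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 <= self.unassigned_fraction < 0.5):
            raise ValueError("unassigned_fraction must lie in [0, 0.5)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        d["cell_cycle"] = CellCycleParams(**d["cell_cycle"])
        d["interaction"] = InteractionParams(**d["interaction"])
        return cls(**d)


@dataclass(frozen=True)
class SynergyAssayConfig:
    """5×5 dose-matrix growth assay layout (doses nmol/L, days 0–5)."""

    doses_P: tuple = (0.0, 12.5, 25.0, 50.0, 100.0)
    doses_F: tuple = (0.0, 0.65, 1.3, 2.6, 5.2)
    days: tuple = (0, 1, 2, 3, 4, 5)
    replicates: int = 3


@dataclass(frozen=True)
class CellCycleAssayConfig:
    """Phase-resolved assay layout: single-drug ladders + matched combos."""

    levels_F: tuple = (1.25, 2.5, 5.0, 10.0)
    levels_P: tuple = (12.5, 25.0, 50.0, 100.0)
    include_control: bool = True
    include_combos: bool = True
    days: tuple = (0, 1, 2, 3, 4)
    replicates: int = 3

    def conditions(self) -> list[tuple[float, float]]:
        conds = []
        if self.include_control:
            conds.append((0.0, 0.0))
        conds += [(f, 0.0) for f in self.levels_F]
        conds += [(0.0, p) for p in self.levels_P]
        if self.include_combos:
            conds += list(zip(self.levels_F, self.levels_P))
        return conds


def noise_free_totals(truth: GroundTruth, d_f: float, d_p: float, days) -> np.ndarray:
    """Noise-free expected total counts per day for one synergy well."""
    lam = g1s_rate(d_f, d_p, truth.interaction)
    lam0 = truth.interaction.lambda_ctrl
    x0 = initial_state(truth.day0_synergy, "stationary", truth.cell_cycle, lam0)
    states = simulate_constant(truth.cell_cycle, x0, lam, np.asarray(days, dtype=float))
    return np.array([s.total for s in states])


def noise_free_phases(truth: GroundTruth, d_f: float, d_p: float, days) -> np.ndarray:
    """Noise-free expected (G1, S, G2M) counts per day for one cell-cycle well."""
    lam = g1s_rate(d_f, d_p, truth.interaction)
    x0 = initial_state(truth.day0_cellcycle, "synchronized", truth.cell_cycle, lam)
    states = simulate_constant(truth.cell_cycle, x0, lam, np.asarray(days, dtype=float))
    traj = aggregate_phases(states, truth.cell_cycle.m)
    return np.column_stack([traj.g1, traj.s, traj.g2m])


def generate_synergy(
    truth: GroundTruth, config: SynergyAssayConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Synthetic 5-day synergy assay table (phase = 'total' rows only).

    Wells start at the stationary phase distribution of the untreated
    chain (cells were growing in full media before treatment); treatment
    is applied from day 0, day-0 counts are pre-treatment. Each
    observation is multiplied by exp(sigma·z) noise, i.i.d. given seed.
    """
    config = config or SynergyAssayConfig()
    rng = np.random.default_rng(seed)
    days = np.asarray(config.days, dtype=float)
    rows = []
    for d_f in config.doses_F:
        for d_p in config.doses_P:
            expected = noise_free_totals(truth, d_f, d_p, days)
            for rep in range(1, config.replicates + 1):
                noise = np.exp(truth.sigma_synergy * rng.standard_normal(days.size))
                for day, cnt in zip(config.days, expected * noise):
                    rows.append(("synergy", truth.label, d_f, d_p, int(day), rep, "total", cnt))
    return pd.DataFrame(rows, columns=ASSAY_COLUMNS)


def generate_cellcycle(
    truth: GroundTruth, config: CellCycleAssayConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Synthetic 4-day phase-resolved assay table.

    Wells start synchronized (all cells in G1_1, emulating release from
    serum starvation). A binomial ``unassigned_fraction`` of each phase's
    (rounded) count is thinned uniformly into an 'unassigned' row before
    log-normal noise is applied to the assigned phase counts.
    """
    config = config or CellCycleAssayConfig()
    rng = np.random.default_rng(seed)
    days = np.asarray(config.days, dtype=float)
    u = truth.unassigned_fraction
    rows = []
    for d_f, d_p in config.conditions():
        expected = noise_free_phases(truth, d_f, d_p, days)  # (n_days, 3)
        for rep in range(1, config.replicates + 1):
            for i, day in enumerate(config.days):
                phase_counts = expected[i]
                removed = np.array(
                    [rng.binomial(int(round(c)), u) if u > 0 else 0 for c in phase_counts],
                    dtype=float,
                )
                kept = np.maximum(phase_counts - removed, 0.0)
                noise = np.exp(truth.sigma_cellcycle * rng.standard_normal(3))
                for phase, cnt in zip(("G1", "S", "G2M"), kept * noise):
                    rows.append(
                        ("cellcycle", truth.label, d_f, d_p, int(day), rep, phase, cnt)
                    )
                rows.append(
                    ("cellcycle", truth.label, d_f, d_p, int(day), rep, "unassigned", float(removed.sum()))
                )
    return pd.DataFrame(rows, columns=ASSAY_COLUMNS)


# ---------------------------------------------------------------------------
# Documented cell-line fixtures
# ---------------------------------------------------------------------------

def _minus_dox() -> GroundTruth:
    # Wild-type-ER-like line: m=8 stages; extremely fulvestrant-sensitive
    # (half-max dose orders of magnitude below palbociclib's); mild synergy.
    # Rates chosen for a ~1.2-day doubling time; lambda_ctrl and the shallow
    # fulvestrant slope are calibrated so the operational day-5 IC50s land
    # near 58 (palbociclib) and 0.2 (fulvestrant) nmol/L while the G1-S
    # TR50s equal the half-max doses exactly.
    return GroundTruth(
        label="sensitive_minusDOX",
        cell_cycle=CellCycleParams(m=8, lambda_alpha=13.0, lambda_beta=22.0, lambda_gamma=31.0),
        interaction=InteractionParams(
            C_F=1.47e-5, C_P=7.7, h_F=0.32, h_P=1.5, a_FP=-0.113, lambda_ctrl=52.0
        ),
        day0_synergy=2000.0,
    )


def _plus_dox() -> GroundTruth:
    # ESR1-mutant-like line: m=2 stages; relative fulvestrant resistance
    # (half-max dose in the nmol/L range); comparable palbociclib response.
    # Calibrated analogously: day-5 IC50s near 41 / 5 nmol/L.
    return GroundTruth(
        label="sensitive_plusDOX",
        cell_cycle=CellCycleParams(m=2, lambda_alpha=2.0, lambda_beta=5.6, lambda_gamma=7.9),
        interaction=InteractionParams(
            C_F=1.49, C_P=18.0, h_F=1.1, h_P=1.5, a_FP=-0.1, lambda_ctrl=10.0
        ),
        day0_synergy=3000.0,
    )


def _palbo_resistant() -> GroundTruth:
    # Palbociclib-resistant variant of the wild-type-ER-like line:
    # half-max palbociclib dose scaled 10x.
    base = _minus_dox()
    return replace(
        base, label="palbo_resistant", interaction=base.interaction.with_scaled_C_P(10.0)
    )


def _recovery_small() -> GroundTruth:
    # Reduced inference fixture: short chain (cheap 6-state linear algebra),
    # clearly negative interaction, rates deliberately distinct so the chain
    # matrix is diagonalizable. Used for parameter-recovery and
    # model-selection experiments at desk scale.
    return GroundTruth(
        label="recovery_small",
        cell_cycle=CellCycleParams(m=2, lambda_alpha=2.0, lambda_beta=5.6, lambda_gamma=7.9),
        interaction=InteractionParams(
            C_F=1.49, C_P=18.0, h_F=1.1, h_P=1.5, a_FP=-0.113, lambda_ctrl=10.0
        ),
        day0_synergy=3000.0,
    )


PROFILES = {
    "sensitive_minusDOX": _minus_dox,
    "sensitive_plusDOX": _plus_dox,
    "palbo_resistant": _palbo_resistant,
    "recovery_small": _recovery_small,
}


def default_truth(profile: str) -> GroundTruth:
    """Documented ground-truth fixture for a named cell-line profile."""
    try:
        return PROFILES[profile]()
    except KeyError:
        raise ValueError(
            f"unknown profile {profile!r}; known: {sorted(PROFILES)}"
        ) from None
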