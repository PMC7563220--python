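"""Particle-swarm search over per-channel drive amplitudes and phases.

The treatment-planning objective is THQ of the combined field on the
detailed benchmark model.  The swarm searches a box of n amplitudes in
[0, 1] and n−1 free phases (channel 0 is gauge-fixed to phase 0 — THQ is
invariant under a global phase, so one phase is redundant).  Global-best
PSO with inertia damping; amplitudes reflect off the box walls, phases
wrap circularly.  The all-equal-weights drive is injected as one initial
particle so the optimizer can never end below that trivial baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dosimetry import DriveSettings, HOTSPOT_FRACTION, hotspot_mean
from .fdtd import ChannelFieldSet, MaterialGrids

__all__ = ["SwarmConfig", "OptimizationResult", "SarContext", "optimize_drive"]


@dataclass(frozen=True)
class SwarmConfig:
    """PSO hyperparameters (a published reference set does not exist for
    clinical planning tools; these are conventional constriction-style
    values)."""

    particles: int = 40
    iterations: int = 150
    inertia: float = 0.72
    inertia_decay: float = 0.995
    cognitive: float = 1.49
    social: float = 1.49
    seed: int = 0
    amp_bounds: tuple[float, float] = (0.0, 1.0)
    gauge_channel: int = 0

    def __post_init__(self) -> None:
        if self.particles <= 0 or self.iterations <= 0:
            raise ValueError("particles and iterations must be positive")
        if not np.isfinite([self.inertia, self.cognitive, self.social]).all():
            raise ValueError("coefficients must be finite")
        if not self.amp_bounds[0] <= self.amp_bounds[1]:
            raise ValueError("amplitude bounds must be ordered")
        # equal bounds pin the amplitudes and search phases only


@dataclass
class SarContext:
    """Pre-extracted per-voxel data for fast repeated THQ evaluation.

    ``e_htv``/``e_healthy`` are (n_channels, n_voxels, n_components)
    complex matrices of the unit-drive fields restricted to the HTV and
    healthy masks; ``q_*`` are the matching σ/(2ρ) factors.
    """

    e_htv: np.ndarray
    e_healthy: np.ndarray
    q_htv: np.ndarray
    q_healthy: np.ndarray
    fraction: float = HOTSPOT_FRACTION

    @classmethod
    def from_materials(
        cls,
        fields: ChannelFieldSet,
        materials: MaterialGrids,
        fraction: float = HOTSPOT_FRACTION,
    ) -> "SarContext":
        fields.validate_against(materials)
        if materials.htv_mask is None:
            raise ValueError("materials lack an HTV mask")
        htv = materials.htv_mask
        healthy = materials.body_mask & ~htv
        if not htv.any():
            raise ValueError("HTV mask is empty")
        with np.errstate(divide="ignore", invalid="ignore"):
            q = materials.sigma / (2.0 * materials.rho)
        q[materials.rho <= 0] = 0.0
        return cls(
            e_htv=fields.fields[:, htv, :],
            e_healthy=fields.fields[:, healthy, :],
            q_htv=q[htv],
            q_healthy=q[healthy],
            fraction=fraction,
        )

    def thq(self, weights: np.ndarray) -> float:
        """THQ of the combined field under complex channel weights."""
        et = np.tensordot(weights, self.e_htv, axes=(0, 0))
        sar_t = self.q_htv * np.sum(np.abs(et) ** 2, axis=-1)
        eh = np.tensordot(weights, self.e_healthy, axes=(0, 0))
        sar_h = self.q_healthy * np.sum(np.abs(eh) ** 2, axis=-1)
        den = hotspot_mean(sar_h, np.ones(sar_h.shape, bool), self.fraction)
        if den == 0.0:
            return 0.0
        return float(sar_t.mean()) / den


@dataclass
class OptimizationResult:
    drive: DriveSettings
    thq: float
    trace: np.ndarray  # global-best THQ per iteration
    amplitudes: np.ndarray
    phases: np.ndarray  # phase[gauge_channel] == 0


def _decode(x: np.ndarray, n: int, gauge: int) -> np.ndarray:
    amps = x[:n]
    phases = np.insert(x[n:], gauge, 0.0)
    return amps * np.exp(1j * phases)


def optimize_drive(
    fields: ChannelFieldSet,
    materials: MaterialGrids,
    config: SwarmConfig,
    fraction: float = HOTSPOT_FRACTION,
) -> OptimizationResult:
    """Maximize THQ over per-channel amplitudes and phases.

    Deterministic given ``config.seed``.  Raises if the best drive found
    has all-zero amplitude (optimization failure).
    """
    ctx = SarContext.from_materials(fields, materials, fraction)
    n = fields.n_channels
    gauge = config.gauge_channel
    if not (0 <= gauge < n):
        raise ValueError("gauge_channel out of range")
    dim = n + (n - 1)
    lo, hi = config.amp_bounds
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(config.seed)))

    pos = np.empty((config.particles, dim))
    pos[:, :n] = rng.uniform(lo, hi, size=(config.particles, n))
    pos[:, n:] = rng.uniform(0.0, 2 * np.pi, size=(config.particles, n - 1))
    # the all-equal-weights baseline is always particle 0
    pos[0, :n] = hi
    pos[0, n:] = 0.0
    vel = np.zeros_like(pos)
    vel[:, :n] = rng.uniform(-0.1, 0.1, size=(config.particles, n)) * (hi - lo)
    vel[:, n:] = rng.uniform(-0.1, 0.1, size=(config.particles, n - 1)) * 2 * np.pi

    def objective(x: np.ndarray) -> float:
        w = _decode(x, n, gauge)
        if np.all(w == 0):
            return 0.0
        return ctx.thq(w)

    pbest = pos.copy()
    pbest_val = np.array([objective(p) for p in pos])
    g = int(np.argmax(pbest_val))
    gbest = pbest[g].copy()
    gbest_val = float(pbest_val[g])

    trace = np.empty(config.iterations)
    w_inertia = config.inertia
    for it in range(config.iterations):
        r1 = rng.random((config.particles, dim))
        r2 = rng.random((config.particles, dim))
        # circular distance for the phase block keeps pulls short-way-round
        d_p = pbest - pos
        d_g = gbest[None, :] - pos
        d_p[:, n:] = (d_p[:, n:] + np.pi) % (2 * np.pi) - np.pi
        d_g[:, n:] = (d_g[:, n:] + np.pi) % (2 * np.pi) - np.pi
        vel = (
            w_inertia * vel
            + config.cognitive * r1 * d_p
            + config.social * r2 * d_g
        )
        pos = pos + vel
        # reflect amplitudes at the box walls
        a = pos[:, :n]
        over = a > hi
        under = a < lo
        a[over] = 2 * hi - a[over]
        a[under] = 2 * lo - a[under]
        np.clip(a, lo, hi, out=a)
        vel[:, :n][over | under] *= -1.0
        # wrap phases
        pos[:, n:] %= 2 * np.pi

        vals = np.array([objective(p) for p in pos])
        improved = vals > pbest_val
        pbest[improved] = pos[improved]
        pbest_val[improved] = vals[improved]
        g = int(np.argmax(pbest_val))
        if pbest_val[g] > gbest_val:
            gbest_val = float(pbest_val[g])
            gbest = pbest[g].copy()
        trace[it] = gbest_val
        w_inertia *= config.inertia_decay

    amps = gbest[:n].copy()
    phases = np.insert(gbest[n:], gauge, 0.0)
    if np.all(amps == 0.0) or gbest_val <= 0.0:
        raise RuntimeError(
            f"optimization failure: best drive has no power (trace tail "
            f"{trace[-5:].tolist()})"
        )
    drive = DriveSettings.from_amp_phase(amps, phases)
    return OptimizationResult(
        drive=drive, thq=gbest_val, trace=trace, amplitudes=amps, phases=phases
    )
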