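"""1D membrane-grid simulation: growth and gene expression per quadrant
coupled by HSL diffusion along the row.

A row of 1 mm quadrants (default 24, genotype boundary between quadrants 12
and 13, 1-based left-to-right) hosts the well model locally; 3OC6HSL and
3OC12HSL diffuse along the row by an explicit discrete Laplacian with
no-flux outer boundaries.  Three source modes mirror the solid-culture
assays:

- "uniform": HSLs present in the substrate at fixed ambient concentrations;
- "spotted": fixed-concentration source nodes one quadrant beyond each row
  end (3OC6HSL on the left, 3OC12HSL on the right) feeding opposed gradients;
- "senders": quadrant genotypes synthesize HSLs under arabinose induction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import CircuitParams, Condition, NoiseModel
from .kinetics import GENOTYPES, NSTATE, initial_state, state_derivative

__all__ = ["GridSpec", "MembraneSeries", "default_membrane_schedule",
           "simulate_membrane", "sender_grid"]


def default_membrane_schedule(t_end: float = 3000.0, step: float = 30.0) -> np.ndarray:
    return np.arange(0.0, t_end + step / 2, step)


@dataclass(frozen=True)
class GridSpec:
    """Geometry and genotype layout of one membrane row (1-based indices)."""

    n_quadrants: int = 24
    quadrant_mm: float = 1.0
    genotypes: tuple[str, ...] = ()
    boundary_index: int = 12

    def __post_init__(self) -> None:
        if self.n_quadrants < 2:
            raise ValueError("need at least two quadrants")
        if not 1 <= self.boundary_index < self.n_quadrants:
            raise ValueError("boundary_index must satisfy 1 <= b < n_quadrants")
        if not self.genotypes:
            object.__setattr__(self, "genotypes",
                               ("and_full",) * self.n_quadrants)
        if len(self.genotypes) != self.n_quadrants:
            raise ValueError("one genotype tag per quadrant required")
        for g in self.genotypes:
            if g not in GENOTYPES:
                raise KeyError(f"unknown genotype tag {g!r}")

    @property
    def positions(self) -> np.ndarray:
        return np.arange(1, self.n_quadrants + 1)


def sender_grid(n_quadrants: int = 24, boundary_index: int = 12,
                left: str = "sender_luxI", right: str = "sender_lasI") -> GridSpec:
    """Two adjacent sender populations with the genotype boundary between
    quadrants ``boundary_index`` and ``boundary_index + 1``."""
    genos = (left,) * boundary_index + (right,) * (n_quadrants - boundary_index)
    return GridSpec(n_quadrants=n_quadrants, genotypes=genos,
                    boundary_index=boundary_index)


@dataclass
class MembraneSeries:
    """Quadrant-resolved fields over time.

    hsl_fields and channels map names to arrays of shape (ntimes, n_quadrants).
    """

    grid: GridSpec
    times: np.ndarray
    hsl_fields: dict[str, np.ndarray]
    channels: dict[str, np.ndarray]
    od: np.ndarray
    diffusion: dict[str, float]
    hsl_decay: float
    meta: dict = field(default_factory=dict)

    def at_time(self, t: float) -> int:
        """Index of the recorded timepoint closest to t (minutes)."""
        return int(np.argmin(np.abs(self.times - t)))


def _diffuse(c: np.ndarray, lam: float, left_clamp: float | None,
             right_clamp: float | None) -> np.ndarray:
    """One explicit-Euler Laplacian step; no-flux ends unless clamped by a
    fixed-concentration virtual node just beyond that end."""
    left = c[0] if left_clamp is None else left_clamp
    right = c[-1] if right_clamp is None else right_clamp
    padded = np.concatenate(([left], c, [right]))
    # (left + right) - 2c grouping keeps mirror symmetry exact in floats
    return c + lam * ((padded[:-2] + padded[2:]) - 2.0 * c)


def simulate_membrane(params: CircuitParams, grid: GridSpec, mode: str,
                      cond: Condition | None = None,
                      schedule: np.ndarray | None = None,
                      seed: int | None = None, noise: bool = False,
                      dt: float = 1.0,
                      init_c6: np.ndarray | None = None,
                      init_c12: np.ndarray | None = None,
                      spot_c6: float = 500.0, spot_c12: float = 200.0,
                      decay: float | None = None) -> MembraneSeries:
    """Simulate one membrane row.

    cond supplies ambient inducers: uniform HSL concentrations in "uniform"
    mode, arabinose for the sender genotypes in "senders" mode.  The explicit
    diffusion step must satisfy the CFL condition D*dt/dx^2 <= 0.5.
    """
    if mode not in ("uniform", "spotted", "senders"):
        raise ValueError(f"unknown mode {mode!r}")
    cond = cond or Condition()
    if schedule is None:
        schedule = default_membrane_schedule()
    schedule = np.asarray(schedule, dtype=float)
    n = grid.n_quadrants
    dx2 = grid.quadrant_mm ** 2
    k_decay = params.hsl_decay if decay is None else decay
    lam = {h: params.hsl_diffusion[h] * dt / dx2 for h in ("c6", "c12")}
    if any(v > 0.5 for v in lam.values()):
        raise ValueError("unstable diffusion step: D*dt/dx^2 exceeds 0.5")

    c6 = np.full(n, cond.c6 if mode == "uniform" else 0.0)
    c12 = np.full(n, cond.c12 if mode == "uniform" else 0.0)
    if init_c6 is not None:
        c6 = np.asarray(init_c6, dtype=float).copy()
    if init_c12 is not None:
        c12 = np.asarray(init_c12, dtype=float).copy()
    if c6.shape != (n,) or c12.shape != (n,):
        raise ValueError("initial fields must have one value per quadrant")

    clamp6 = (spot_c6, None) if mode == "spotted" else (None, None)
    clamp12 = (None, spot_c12) if mode == "spotted" else (None, None)

    # group quadrants by genotype for vectorized local kinetics
    geno_idx = {g: np.array([i for i, q in enumerate(grid.genotypes) if q == g])
                for g in set(grid.genotypes)}
    state = np.zeros((NSTATE, n))
    sender_sign = np.zeros(n)   # +1 -> synthesizes c6, set per genotype
    sender_c12 = np.zeros(n)
    for g, idx in geno_idx.items():
        state[:, idx] = initial_state(params, g, len(idx))
        if GENOTYPES[g].sender == "luxI":
            sender_sign[idx] = 1.0
        elif GENOTYPES[g].sender == "lasI":
            sender_c12[idx] = 1.0

    t_end = float(schedule[-1])
    nsteps = int(round(t_end / dt))
    rec_steps = np.round(schedule / dt).astype(int)
    if np.any(np.abs(rec_steps * dt - schedule) > 1e-9):
        raise ValueError("schedule times must align with the integrator step")
    rec = dict(zip(rec_steps.tolist(), range(len(schedule))))

    traj = np.empty((len(schedule), NSTATE, n))
    f6 = np.empty((len(schedule), n))
    f12 = np.empty((len(schedule), n))

    def record(step, s):
        if step in rec:
            i = rec[step]
            traj[i] = s
            f6[i] = c6
            f12[i] = c12

    record(0, state)
    ara = np.full(n, cond.arabinose if mode == "senders" else 0.0)
    for step in range(1, nsteps + 1):
        # local kinetics (RK4) with the current HSL fields
        for g, idx in geno_idx.items():
            loc = {"iptg": np.zeros(len(idx)), "arabinose": ara[idx],
                   "c6": c6[idx], "c12": c12[idx]}
            s = state[:, idx]
            gt = GENOTYPES[g]
            k1 = state_derivative(params, gt, loc, s)
            k2 = state_derivative(params, gt, loc, s + 0.5 * dt * k1)
            k3 = state_derivative(params, gt, loc, s + 0.5 * dt * k2)
            k4 = state_derivative(params, gt, loc, s + dt * k3)
            state[:, idx] = np.maximum(s + (dt / 6) * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)
        # HSL production by senders, decay, diffusion
        if mode == "senders":
            prod = params.sender_k_syn * state[9] * state[0] * dt
            c6 = c6 + prod * sender_sign
            c12 = c12 + prod * sender_c12
        if k_decay > 0:
            c6 = c6 * (1.0 - k_decay * dt)
            c12 = c12 * (1.0 - k_decay * dt)
        c6 = _diffuse(c6, lam["c6"], *clamp6)
        c12 = _diffuse(c12, lam["c12"], *clamp12)
        record(step, state)

    rng = np.random.default_rng(seed)
    nm = params.noise if noise else NoiseModel.off()
    N = traj[:, 0, :]
    channels = {}
    for ch, m_idx in (("CFP", 4), ("YFP", 6), ("RFP", 8)):
        sig = params.gains[ch] * traj[:, m_idx, :] * N
        cv = nm.cv.get(ch, 0.0)
        if cv > 0:
            sg = np.sqrt(np.log1p(cv ** 2))
            sig = sig * rng.lognormal(-0.5 * sg ** 2, sg, size=sig.shape)
        sd = nm.read_sd.get(ch, 0.0)
        if sd > 0:
            sig = sig + rng.normal(0.0, sd, size=sig.shape)
        channels[ch] = sig + params.blanks.get(ch, 0.0)

    return MembraneSeries(
        grid=grid, times=schedule.copy(), hsl_fields={"c6": f6, "c12": f12},
        channels=channels, od=N.copy(),
        diffusion=dict(params.hsl_diffusion), hsl_decay=k_decay,
        meta={"mode": mode, "seed": seed, "noise": noise,
              "condition": cond.as_dict(),
              "spots": {"c6": spot_c6, "c12": spot_c12} if mode == "spotted" else None},
    )
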