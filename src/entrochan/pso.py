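"""Binary channel selection by particle swarm optimization.

Particles move in a continuous box ``X in [-10, 10]^D`` with velocities
clamped to ``[-4, 4]``; a position is decoded into a 0/1 channel mask by
thresholding the sigmoid ``S(x) = 1 / (1 + exp(-x))`` at 0.5 (equivalently,
channel j is selected iff x_j > 0).  A mask's fitness is the mean ten-fold
cross-validated KNN accuracy computed on the two entropy columns of each
selected channel; the empty mask scores 0 by convention, which keeps
deselection pressure on.

By default the fold partition is drawn once per run from the PSO seed and
held fixed, making fitness a deterministic function of the mask (so the
global-best trace is exactly monotone and memoization by bit-pattern is
sound).  ``refold_per_eval=True`` re-randomizes folds at every evaluation
instead.  Inertia stays at 1 with no damping; the position clamp bounds the
swarm.  Optional linear inertia decay and stagnation-patience stopping are
available but off by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classify import KNNConfig, cross_validate, fold_partition
from .features import FeatureTable

__all__ = ["PSOConfig", "ChannelMask", "PSOTrace", "binarize", "fitness",
           "update_swarm", "pso_select", "SwarmState"]


@dataclass(frozen=True)
class PSOConfig:
    """Swarm hyper-parameters (defaults are the study profile)."""

    n_particles: int = 50
    t_max: int = 100
    c1: float = 1.49445
    c2: float = 1.49445
    inertia: float = 1.0
    x_bounds: tuple[float, float] = (-10.0, 10.0)
    v_bounds: tuple[float, float] = (-4.0, 4.0)
    select_threshold: float = 0.5
    seed: int = 0
    inertia_decay_to: float | None = None  # linear decay target, off by default
    patience: int | None = None  # stagnation stopping, off by default
    refold_per_eval: bool = False

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("need at least one particle")
        if self.t_max < 0:
            raise ValueError("t_max must be >= 0")
        if self.x_bounds[0] >= self.x_bounds[1] or self.v_bounds[0] >= self.v_bounds[1]:
            raise ValueError("bounds must be well-ordered")
        if not 0 < self.select_threshold < 1:
            raise ValueError("select_threshold must lie in (0, 1)")


@dataclass
class ChannelMask:
    """A 0/1 channel choice keyed by name, with its fitness if evaluated."""

    channels: tuple[str, ...]
    bits: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.shape != (len(self.channels),):
            raise ValueError("bits/channels length mismatch")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("mask bits must be 0/1")

    @property
    def selected(self) -> tuple[str, ...]:
        return tuple(c for c, b in zip(self.channels, self.bits) if b)

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())

    def key(self) -> bytes:
        return self.bits.tobytes()

    def to_dict(self) -> dict:
        return {
            "channels": list(self.channels),
            "bits": self.bits.tolist(),
            "selected": list(self.selected),
            "fitness": self.fitness,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelMask":
        return cls(tuple(d["channels"]), np.array(d["bits"]), d.get("fitness"))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def from_json(cls, path) -> "ChannelMask":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class PSOTrace:
    """Per-iteration global best (fitness and mask) and evaluation count."""

    best_fitness: list[float] = field(default_factory=list)
    best_mask: list[np.ndarray] = field(default_factory=list)
    n_evaluations: int = 0


@dataclass
class SwarmState:
    x: np.ndarray  # (n_particles, D) positions
    v: np.ndarray  # velocities
    pbest_x: np.ndarray
    pbest_f: np.ndarray
    gbest_x: np.ndarray
    gbest_f: float
    gbest_bits: np.ndarray
    rng: np.random.Generator


def binarize(position: np.ndarray, channels: tuple[str, ...],
             threshold: float = 0.5) -> ChannelMask:
    """Decode a continuous position into a channel mask.

    Channel j is selected iff ``1 / (1 + exp(-x_j)) > threshold`` — strict,
    so at threshold 0.5 a position of exactly 0 is *not* selected.
    """
    position = np.asarray(position, dtype=float)
    if not np.isfinite(position).all():
        raise ValueError("position contains non-finite values")
    weights = 1.0 / (1.0 + np.exp(-position))
    return ChannelMask(channels, (weights > threshold).astype(np.uint8))


def fitness(mask: ChannelMask, table: FeatureTable,
            knn_cfg: KNNConfig = KNNConfig(), folds: int = 10,
            partition: list[np.ndarray] | None = None) -> float:
    """Mean 10-fold CV accuracy on the selected channels' entropy columns.

    The empty mask scores 0.0 by convention.
    """
    if tuple(mask.channels) != tuple(table.channels):
        raise ValueError("mask is not keyed to the table's channels")
    if mask.n_selected == 0:
        return 0.0
    sub = table.select_channels(mask.selected)
    return cross_validate(sub, knn_cfg, folds=folds, partition=partition).mean_accuracy


def update_swarm(state: SwarmState, cfg: PSOConfig,
                 inertia: float | None = None) -> SwarmState:
    """One velocity/position update with fresh per-dimension r1, r2.

    ``V <- w V + c1 r1 (P_i - X) + c2 r2 (P_g - X)``, then ``X <- X + V``;
    both are clamped to their boxes component-wise.
    """
    w = cfg.inertia if inertia is None else inertia
    shape = state.x.shape
    r1 = state.rng.uniform(0.0, 1.0, size=shape)
    r2 = state.rng.uniform(0.0, 1.0, size=shape)
    v = (w * state.v
         + cfg.c1 * r1 * (state.pbest_x - state.x)
         + cfg.c2 * r2 * (state.gbest_x - state.x))
    np.clip(v, cfg.v_bounds[0], cfg.v_bounds[1], out=v)
    x = state.x + v
    np.clip(x, cfg.x_bounds[0], cfg.x_bounds[1], out=x)
    state.v = v
    state.x = x
    return state


def pso_select(table: FeatureTable, cfg: PSOConfig = PSOConfig(),
               knn_cfg: KNNConfig = KNNConfig(),
               folds: int = 10) -> tuple[ChannelMask, PSOTrace]:
    """Run the swarm and return the best-ever mask with its fitness.

    Fully reproducible from ``cfg.seed``; fitness evaluations are memoized
    by mask bit-pattern, and equal-fitness incumbents are kept (strict
    improvement only).
    """
    channels = table.channels
    d = len(channels)
    rng = np.random.default_rng(cfg.seed)
    fold_seed = int(rng.integers(0, 2**31 - 1))
    partition = (None if cfg.refold_per_eval
                 else fold_partition(table.n_epochs, folds, fold_seed))

    cache: dict[bytes, float] = {}
    trace = PSOTrace()

    def evaluate(position: np.ndarray) -> tuple[float, np.ndarray]:
        mask = binarize(position, channels, cfg.select_threshold)
        key = mask.key()
        if key in cache:
            return cache[key], mask.bits
        part = (fold_partition(table.n_epochs, folds,
                               int(rng.integers(0, 2**31 - 1)))
                if cfg.refold_per_eval else partition)
        f = fitness(mask, table, knn_cfg, folds=folds, partition=part)
        cache[key] = f
        trace.n_evaluations += 1
        return f, mask.bits

    x = rng.uniform(cfg.x_bounds[0], cfg.x_bounds[1], size=(cfg.n_particles, d))
    v = rng.uniform(cfg.v_bounds[0], cfg.v_bounds[1], size=(cfg.n_particles, d))
    f0 = np.empty(cfg.n_particles)
    bits0 = []
    for i in range(cfg.n_particles):
        f0[i], b = evaluate(x[i])
        bits0.append(b)
    g = int(np.argmax(f0))
    state = SwarmState(
        x=x, v=v, pbest_x=x.copy(), pbest_f=f0.copy(),
        gbest_x=x[g].copy(), gbest_f=float(f0[g]), gbest_bits=bits0[g].copy(),
        rng=rng,
    )
    trace.best_fitness.append(state.gbest_f)
    trace.best_mask.append(state.gbest_bits.copy())

    stagnant = 0
    for t in range(cfg.t_max):
        if cfg.inertia_decay_to is not None and cfg.t_max > 1:
            w = cfg.inertia + (cfg.inertia_decay_to - cfg.inertia) * t / (cfg.t_max - 1)
        else:
            w = cfg.inertia
        update_swarm(state, cfg, inertia=w)
        improved = False
        for i in range(cfg.n_particles):
            f, b = evaluate(state.x[i])
            if f > state.pbest_f[i]:
                state.pbest_f[i] = f
                state.pbest_x[i] = state.x[i].copy()
            if f > state.gbest_f:
                state.gbest_f = float(f)
                state.gbest_x = state.x[i].copy()
                state.gbest_bits = b.copy()
                improved = True
        trace.best_fitness.append(state.gbest_f)
        trace.best_mask.append(state.gbest_bits.copy())
        stagnant = 0 if improved else stagnant + 1
        if cfg.patience is not None and stagnant >= cfg.patience:
            break

    best = ChannelMask(channels, state.gbest_bits, fitness=state.gbest_f)
    return best, trace
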