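"""Metropolis Monte Carlo sampler for tethered hard-cylinder chains.

The sampler realizes the coarse-grained GQ-multimer model: hard-core
excluded volume between all cylinder pairs, an infinite-square-well tether
(rim-to-rim, range L_max) on consecutive pairs, and a finite square well of
depth u0 (range delta, acting on the facing base centers) that rewards
stacked junctions.  The control parameter is the dimensionless effective
temperature T* = kB*T/u0; at T* = +inf the attraction is switched off and
every constraint-respecting move is accepted, which samples the
beads-on-a-string reference ensemble.

Randomness comes from the NumPy legacy MT19937 generator seeded inside the
compiled kernel, so a run is bit-reproducible from its seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from . import _kernels as _k
from .geometry import (
    DEFAULT_HEIGHT,
    DEFAULT_RADIUS,
    ChainConfiguration,
    InteractionParams,
)

__all__ = [
    "MCSettings",
    "SimulationEnsemble",
    "build_initial_chain",
    "total_energy",
    "run_mc",
    "simulate",
    "calibrate_delta",
]


@dataclass(frozen=True)
class MCSettings:
    """Sampler settings.

    ``sweeps`` counts attempted sweeps (n single-unit trial moves each);
    snapshots are recorded every ``snapshot_stride`` sweeps once
    ``equilibration_sweeps`` have passed.  Default step sizes give a
    30-50% acceptance rate for the default geometry at T* ~ 0.2.
    """

    sweeps: int = 200_000
    equilibration_sweeps: int = 20_000
    max_translation: float = 0.3
    max_rotation: float = 20.0
    seed: int = 0
    snapshot_stride: int = 10
    n_units: int | None = None

    def __post_init__(self):
        if not (self.sweeps > self.equilibration_sweeps >= 0):
            raise ValueError("need sweeps > equilibration_sweeps >= 0")
        if self.snapshot_stride < 1:
            raise ValueError("snapshot_stride must be >= 1")
        if not (self.max_translation > 0 and self.max_rotation > 0):
            raise ValueError("step sizes must be positive")
        if not (0 <= self.seed < 2**32):
            raise ValueError("seed must fit in 32 bits")


@dataclass
class SimulationEnsemble:
    """Sampled configurations plus per-junction bond geometry.

    ``junction_distances[t, j]`` is the facing base-center distance of
    junction j in snapshot t; the boolean bond matrix is derived from it by
    comparison with the stacking range, so ensembles sampled without
    attraction can still be interrogated for "would-be-bonded" geometry.
    """

    positions: np.ndarray  # (S, n, 3)
    axes: np.ndarray  # (S, n, 3)
    junction_distances: np.ndarray  # (S, n-1)
    base_signs: np.ndarray  # (n-1, 2)
    params: InteractionParams
    settings: MCSettings
    acceptance_rate: float

    @property
    def n_units(self) -> int:
        return self.positions.shape[1]

    @property
    def n_snapshots(self) -> int:
        return self.positions.shape[0]

    @property
    def bond_matrix(self) -> np.ndarray:
        """Boolean (S, n-1) matrix: junction within the stacking well range."""
        return self.junction_distances <= self.params.delta

    def snapshot(self, t: int) -> ChainConfiguration:
        return ChainConfiguration(self.positions[t], self.axes[t],
                                  self.params_radius, self.params_height,
                                  self.base_signs)

    # radius/height travel with the ensemble; stored at save time
    params_radius: float = DEFAULT_RADIUS
    params_height: float = DEFAULT_HEIGHT

    def junction_angles(self) -> np.ndarray:
        """(S, n-1) angles between consecutive axes, degrees."""
        cosb = np.einsum("tij,tij->ti", self.axes[:, :-1, :], self.axes[:, 1:, :])
        return np.degrees(np.arccos(np.clip(cosb, -1.0, 1.0)))

    def save(self, path) -> None:
        """Persist to a structured .npz container (plus JSON metadata)."""
        meta = {
            "params": {k: (None if isinstance(v, float) and math.isinf(v) else v)
                       for k, v in asdict(self.params).items()},
            "T_star_infinite": math.isinf(self.params.T_star),
            "settings": asdict(self.settings),
            "acceptance_rate": self.acceptance_rate,
            "radius": self.params_radius,
            "height": self.params_height,
        }
        np.savez_compressed(
            path,
            positions=self.positions,
            axes=self.axes,
            junction_distances=self.junction_distances,
            base_signs=self.base_signs,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path) -> "SimulationEnsemble":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"].tobytes()).decode())
            p = meta["params"]
            if meta["T_star_infinite"]:
                p["T_star"] = math.inf
            params = InteractionParams(**p)
            settings = MCSettings(**meta["settings"])
            ens = cls(z["positions"], z["axes"], z["junction_distances"],
                      z["base_signs"], params, settings,
                      meta["acceptance_rate"])
            ens.params_radius = meta["radius"]
            ens.params_height = meta["height"]
        return ens


def build_initial_chain(n: int, radius: float = DEFAULT_RADIUS,
                        height: float = DEFAULT_HEIGHT,
                        mode: str = "stacked",
                        params: InteractionParams | None = None) -> ChainConfiguration:
    """Valid starting configuration: a coaxial column.

    ``stacked``: facing base centers coincide (every junction bonded).
    ``extended``: collinear with each tether stretched to ~0.9 L_max
    (no junction bonded for any delta < 0.9 L_max).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or InteractionParams()
    if mode == "stacked":
        gap = 0.0
    elif mode == "extended":
        gap = 0.9 * params.L_max
        if gap <= 0:
            raise ValueError("cannot build an extended chain with L_max <= 0")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    z = (height + gap) * np.arange(n)
    positions = np.column_stack([np.zeros(n), np.zeros(n), z])
    axes = np.tile([0.0, 0.0, 1.0], (n, 1))
    signs = np.tile([1, -1], (max(n - 1, 0), 1)).astype(np.int64)
    return ChainConfiguration(positions, axes, radius, height, base_signs=signs)


def total_energy(config: ChainConfiguration, params: InteractionParams) -> float:
    """Chain energy in units of u0: -(number of active stacking bonds).

    Returns ``math.inf`` for configurations violating the hard-core or
    tether constraints.
    """
    if not config.is_valid(params):
        return math.inf
    bonds = sum(config.junction_base_distance(j) <= params.delta
                for j in range(config.n_units - 1))
    return -float(bonds) * params.u0


def run_mc(initial: ChainConfiguration, params: InteractionParams,
           settings: MCSettings) -> SimulationEnsemble:
    """Metropolis sampling from ``initial``; see module docstring for the move set."""
    if settings.n_units is not None and settings.n_units != initial.n_units:
        raise ValueError("settings.n_units does not match the initial chain")
    if initial.n_units < 1:
        raise ValueError("empty chain")
    if not initial.is_valid(params):
        raise ValueError("initial configuration violates hard constraints")
    pos = initial.positions.copy()
    ax = initial.axes.copy()
    sgn = initial.base_signs.astype(np.float64)
    if sgn.size == 0:
        sgn = np.zeros((0, 2))
    snap_pos, snap_ax, snap_jd, accepted, tried = _k._run_mc(
        pos, ax, np.ascontiguousarray(sgn[:, 0]), np.ascontiguousarray(sgn[:, 1]),
        initial.radius, initial.height, params.delta, params.L_max,
        params.beta, settings.sweeps, settings.equilibration_sweeps,
        settings.snapshot_stride, settings.max_translation,
        math.radians(settings.max_rotation), settings.seed)
    ens = SimulationEnsemble(snap_pos, snap_ax, snap_jd,
                             initial.base_signs.copy(), params, settings,
                             accepted / max(tried, 1))
    ens.params_radius = initial.radius
    ens.params_height = initial.height
    return ens


def simulate(n_units: int, params: InteractionParams | None = None,
             settings: MCSettings | None = None,
             radius: float = DEFAULT_RADIUS, height: float = DEFAULT_HEIGHT,
             initial_mode: str = "stacked") -> SimulationEnsemble:
    """Convenience wrapper: build an initial chain and sample it."""
    params = params or InteractionParams()
    settings = settings or MCSettings()
    initial = build_initial_chain(n_units, radius, height, initial_mode, params)
    return run_mc(initial, params, settings)


def calibrate_delta(target_rate: float, params: InteractionParams | None = None,
                    radius: float = DEFAULT_RADIUS, height: float = DEFAULT_HEIGHT,
                    sweeps: int = 2_000_000, equilibration: int = 50_000,
                    seed: int = 12345) -> float:
    """Calibrate the stacking-well range against a chance-bonding anchor.

    Samples a free dimer (attraction off) and returns the well range delta
    such that a fraction ``target_rate`` of the sampled junction geometries
    would count as bonded, i.e. the ``target_rate`` quantile of the facing
    base-center distance distribution.  This is how the shipped default
    ``DEFAULT_DELTA`` was obtained; it does not depend on delta itself,
    only on the cylinder dimensions and the tether length.
    """
    if not 0 < target_rate < 1:
        raise ValueError("target_rate must be in (0, 1)")
    base = params or InteractionParams()
    free = InteractionParams(u0=base.u0, delta=base.delta, L_max=base.L_max,
                             T_star=math.inf)
    settings = MCSettings(sweeps=sweeps, equilibration_sweeps=equilibration,
                          snapshot_stride=1, seed=seed)
    ens = simulate(2, free, settings, radius, height)
    d = np.sort(ens.junction_distances[:, 0])
    return float(np.quantile(d, target_rate))
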