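"""Discrete-time 1D lattice simulation of two-sided SMC loop extruders.

Loop extruders (condensin I, condensin II, cohesin) are two-legged motors on a
lattice of genomic sites of size ``sigma`` kb.  Each extruder occupies two
sites; after loading at a pair of adjacent free sites, each leg independently
steps outward with probability ``p`` per timestep of ``tau0`` seconds, giving a
macroscopic loop-growth velocity ``v = 2 * p * sigma / tau0``.  A leg stops
when the destination site is occupied by another leg or is a lattice boundary,
and a CTCF-respecting species (cohesin) stalls permanently, with probability
``q_stall``, upon stepping onto a convergently oriented CTCF site.  Extruders
unload stochastically with mean residence time ``tau_res`` and are reloaded to
keep each species at its (possibly time-varying) target abundance
``N = L * sigma / d``.

Update order within one timestep: unload, load, translocate; extruders are
translocated in a fresh random permutation each step.  Blocked steps are lost
(no retry within the tick).  The lattice is linear: boundaries block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LatticeConfig",
    "ExtruderSpecies",
    "CTCFSite",
    "Extruder",
    "ExtruderState",
    "ExtrusionTrajectory",
    "step_extrusion",
    "run_extrusion",
    "measure_extension_velocity",
    "quench_loops",
    "ctcf_sites_from_bed",
]


@dataclass(frozen=True)
class LatticeConfig:
    """Lattice geometry and clock. ``sigma`` in kb, ``tau0`` in seconds."""

    L: int = 61_600
    sigma: float = 0.5
    tau0: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError(f"lattice needs at least 2 sites, got L={self.L}")
        if self.sigma <= 0 or self.tau0 <= 0:
            raise ValueError("sigma and tau0 must be positive")


@dataclass(frozen=True)
class ExtruderSpecies:
    """One extruder species.

    ``tau_res``: mean residence time (s).  ``d_target``: mean genomic
    separation between extruders (kb); the target abundance on a lattice is
    ``N = L * sigma / d_target``.  ``p``: per-leg step probability per tick.
    """

    name: str
    tau_res: float
    d_target: float | None
    p: float = 0.25
    respects_ctcf: bool = False
    q_stall: float = 0.5

    def __post_init__(self) -> None:
        if self.tau_res <= 0:
            raise ValueError("tau_res must be positive")
        if self.d_target is not None and self.d_target <= 0:
            raise ValueError("d_target must be positive (or None for target 0)")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")
        if not 0.0 <= self.q_stall <= 1.0:
            raise ValueError("q_stall must be in [0, 1]")

    def target_count(self, config: LatticeConfig) -> int:
        if self.d_target is None:
            return 0
        return int(round(config.L * config.sigma / self.d_target))

    def unload_probability(self, config: LatticeConfig) -> float:
        # exact per-step probability for exponential residence at rate 1/tau_res
        return 1.0 - math.exp(-config.tau0 / self.tau_res)


@dataclass(frozen=True)
class CTCFSite:
    """CTCF motif on the lattice.  Orientation "+" stalls legs translocating in
    the decreasing-index direction, "-" stalls increasing-index legs
    (convergent-capture convention)."""

    site_index: int
    orientation: str

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-"):
            raise ValueError(f"orientation must be '+' or '-', got {self.orientation!r}")
        if self.site_index < 0:
            raise ValueError("site_index must be non-negative")


@dataclass
class Extruder:
    uid: int
    species: int  # index into the species table
    left: int
    right: int
    left_stalled: bool = False
    right_stalled: bool = False
    loaded_at: int = 0  # timestep of loading

    @property
    def loop_size(self) -> int:
        return self.right - self.left + 1


class ExtruderState:
    """All bound extruders plus the site occupancy map.

    Invariants (checked by :meth:`validate`): ``left < right`` for every
    extruder, no two legs share a site, and every occupied site maps back to
    exactly one leg.
    """

    def __init__(self, config: LatticeConfig, species_table: list[ExtruderSpecies]):
        self.config = config
        self.species_table = list(species_table)
        self.extruders: dict[int, Extruder] = {}
        # occupancy[site] = uid of the extruder whose leg sits there, -1 if free
        self.occupancy = np.full(config.L, -1, dtype=np.int64)
        self.time = 0
        self._next_uid = 0
        self.unload_log: list[tuple[int, int, int]] = []  # (uid, loaded_at, unloaded_at)
        self.quenched = False

    # -- bookkeeping -----------------------------------------------------
    def _add(self, species: int, left: int, right: int) -> Extruder:
        ex = Extruder(self._next_uid, species, left, right, loaded_at=self.time)
        self._next_uid += 1
        if self.occupancy[left] != -1 or self.occupancy[right] != -1:
            raise RuntimeError("loading onto occupied sites")
        self.occupancy[left] = ex.uid
        self.occupancy[right] = ex.uid
        self.extruders[ex.uid] = ex
        return ex

    def _remove(self, uid: int) -> None:
        ex = self.extruders.pop(uid)
        self.occupancy[ex.left] = -1
        self.occupancy[ex.right] = -1
        self.unload_log.append((uid, ex.loaded_at, self.time))

    def count_by_species(self) -> np.ndarray:
        counts = np.zeros(len(self.species_table), dtype=np.int64)
        for ex in self.extruders.values():
            counts[ex.species] += 1
        return counts

    def loop_sizes(self) -> np.ndarray:
        return np.array([ex.loop_size for ex in self.extruders.values()], dtype=np.int64)

    def validate(self) -> None:
        occ = np.full(self.config.L, -1, dtype=np.int64)
        for ex in self.extruders.values():
            if not 0 <= ex.left < ex.right < self.config.L:
                raise AssertionError(f"bad legs {ex.left},{ex.right} for uid {ex.uid}")
            for leg in (ex.left, ex.right):
                if occ[leg] != -1:
                    raise AssertionError(f"site {leg} doubly occupied")
                occ[leg] = ex.uid
        if not np.array_equal(occ, self.occupancy):
            raise AssertionError("occupancy map out of sync with extruder records")


@dataclass
class ExtrusionTrajectory:
    """Time-ordered snapshots of leg positions, one table per sampled frame."""

    config: LatticeConfig
    species_table: list[ExtruderSpecies]
    frames: list[dict]  # {"time": int, "uid","species","left","right","left_stalled","right_stalled" arrays}
    stride: int
    seed: int | None = None
    unload_log: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [f["time"] for f in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.frames:
            n = len(f["uid"])
            rows.append(
                pd.DataFrame(
                    {
                        "frame": np.full(n, f["time"], dtype=np.int64),
                        "extruder_id": f["uid"],
                        "species": [self.species_table[s].name for s in f["species"]],
                        "left_site": f["left"],
                        "right_site": f["right"],
                        "left_stalled": f["left_stalled"],
                        "right_stalled": f["right_stalled"],
                    }
                )
            )
        if not rows:
            return pd.DataFrame(
                columns=["frame", "extruder_id", "species", "left_site", "right_site", "left_stalled", "right_stalled"]
            )
        return pd.concat(rows, ignore_index=True)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _snapshot(state: ExtruderState) -> dict:
    exs = sorted(state.extruders.values(), key=lambda e: e.uid)
    return {
        "time": state.time,
        "uid": np.array([e.uid for e in exs], dtype=np.int64),
        "species": np.array([e.species for e in exs], dtype=np.int64),
        "left": np.array([e.left for e in exs], dtype=np.int64),
        "right": np.array([e.right for e in exs], dtype=np.int64),
        "left_stalled": np.array([e.left_stalled for e in exs], dtype=bool),
        "right_stalled": np.array([e.right_stalled for e in exs], dtype=bool),
    }


def _ctcf_stall_arrays(config: LatticeConfig, ctcf: list[CTCFSite]) -> tuple[np.ndarray, np.ndarray]:
    """Per-site stall masks for legs moving left (decreasing index) and right."""
    stall_left = np.zeros(config.L, dtype=bool)
    stall_right = np.zeros(config.L, dtype=bool)
    for site in ctcf:
        if site.site_index >= config.L:
            raise ValueError(f"CTCF site {site.site_index} outside lattice of length {config.L}")
        if site.orientation == "+":
            stall_left[site.site_index] = True
        else:
            stall_right[site.site_index] = True
    return stall_left, stall_right


def _load_extruders(state: ExtruderState, targets: np.ndarray, rng: np.random.Generator) -> None:
    """Top species up to their targets at uniformly drawn adjacent free pairs."""
    counts = state.count_by_species()
    L = state.config.L
    for s_idx, target in enumerate(targets):
        deficit = int(target) - int(counts[s_idx])
        for _ in range(deficit):
            placed = False
            for _attempt in range(100):
                i = int(rng.integers(0, L - 1))
                if state.occupancy[i] == -1 and state.occupancy[i + 1] == -1:
                    state._add(s_idx, i, i + 1)
                    placed = True
                    break
            if not placed:  # fall back to a scan for any free adjacent pair
                free = state.occupancy == -1
                pairs = np.flatnonzero(free[:-1] & free[1:])
                if len(pairs) == 0:
                    raise RuntimeError(
                        f"cannot load species {state.species_table[s_idx].name}: "
                        f"no free adjacent site pair on the lattice"
                    )
                i = int(rng.choice(pairs))
                state._add(s_idx, i, i + 1)


def _unload_to_target(state: ExtruderState, targets: np.ndarray, rng: np.random.Generator) -> None:
    """When a schedule lowers a target, unload uniformly random extruders."""
    counts = state.count_by_species()
    for s_idx, target in enumerate(targets):
        excess = int(counts[s_idx]) - int(target)
        if excess <= 0:
            continue
        uids = [uid for uid, ex in state.extruders.items() if ex.species == s_idx]
        for uid in rng.choice(np.array(uids), size=excess, replace=False):
            state._remove(int(uid))


def step_extrusion(
    state: ExtruderState,
    targets: np.ndarray | None,
    stall_left: np.ndarray,
    stall_right: np.ndarray,
    rng: np.random.Generator,
) -> ExtruderState:
    """Advance the lattice by one timestep (in place; returns ``state``).

    Order: stochastic unloading, loading to target abundances, then per-leg
    translocation in a random permutation of extruders.
    """
    if state.quenched:
        state.time += 1
        return state
    config = state.config
    if targets is None:
        targets = np.array([sp.target_count(config) for sp in state.species_table])

    # 1. stochastic unloading
    unload_p = np.array([sp.unload_probability(config) for sp in state.species_table])
    for uid in list(state.extruders.keys()):
        ex = state.extruders[uid]
        if rng.random() < unload_p[ex.species]:
            state._remove(uid)

    # schedule-driven abundance drops, then loading up to target
    _unload_to_target(state, targets, rng)
    _load_extruders(state, targets, rng)

    # 3. translocation, random extruder order; legs step outward independently
    uids = np.array(sorted(state.extruders.keys()), dtype=np.int64)
    rng.shuffle(uids)
    occ = state.occupancy
    for uid in uids:
        ex = state.extruders[int(uid)]
        sp = state.species_table[ex.species]
        # left leg moves toward decreasing index
        if not ex.left_stalled and rng.random() < sp.p:
            dest = ex.left - 1
            if dest >= 0 and occ[dest] == -1:
                if sp.respects_ctcf and stall_left[dest] and rng.random() < sp.q_stall:
                    occ[ex.left] = -1
                    ex.left = dest
                    occ[dest] = ex.uid
                    ex.left_stalled = True
                else:
                    occ[ex.left] = -1
                    ex.left = dest
                    occ[dest] = ex.uid
        # right leg moves toward increasing index
        if not ex.right_stalled and rng.random() < sp.p:
            dest = ex.right + 1
            if dest < config.L and occ[dest] == -1:
                if sp.respects_ctcf and stall_right[dest] and rng.random() < sp.q_stall:
                    occ[ex.right] = -1
                    ex.right = dest
                    occ[dest] = ex.uid
                    ex.right_stalled = True
                else:
                    occ[ex.right] = -1
                    ex.right = dest
                    occ[dest] = ex.uid

    state.time += 1
    return state


def run_extrusion(
    config: LatticeConfig,
    species_table: list[ExtruderSpecies],
    ctcf: list[CTCFSite] | None,
    n_steps: int,
    target_schedule=None,
    stride: int = 1,
    rng: np.random.Generator | None = None,
    initial_state: ExtruderState | None = None,
) -> ExtrusionTrajectory:
    """Run the lattice for ``n_steps`` timesteps, sampling every ``stride``.

    ``target_schedule``: optional callable ``step -> array of per-species
    target counts`` (floats allowed; fractional targets are resolved by
    stochastic rounding).  Without a schedule, targets are the species'
    ``target_count``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    state = initial_state if initial_state is not None else ExtruderState(config, species_table)
    stall_left, stall_right = _ctcf_stall_arrays(config, ctcf or [])
    frames: list[dict] = []
    base_targets = np.array([sp.target_count(config) for sp in species_table], dtype=float)
    for _ in range(n_steps):
        if target_schedule is not None:
            raw = np.asarray(target_schedule(state.time), dtype=float)
            if raw.shape != (len(species_table),):
                raise ValueError("target_schedule must return one target per species")
            frac, whole = np.modf(raw)
            targets = whole.astype(int) + (rng.random(len(raw)) < frac).astype(int)
        else:
            targets = base_targets.astype(int)
        step_extrusion(state, targets, stall_left, stall_right, rng)
        if state.time % stride == 0:
            frames.append(_snapshot(state))
    traj = ExtrusionTrajectory(
        config, list(species_table), frames, stride, seed=config.seed, unload_log=list(state.unload_log)
    )
    traj.final_state = state  # type: ignore[attr-defined]
    return traj


def measure_extension_velocity(trajectory: ExtrusionTrajectory) -> float:
    """Mean loop-growth velocity (kb/s) over unobstructed growth episodes.

    Considers per-extruder loop-size increments between consecutive frames in
    which the extruder is present, unstalled on both legs and away from the
    lattice boundaries.  Blocking by *other* extruders is not detectable from
    the frames alone; feed trajectories of sparse or single extruders.
    """
    if not trajectory.frames:
        raise ValueError("empty trajectory")
    config = trajectory.config
    growth_sites = 0
    growth_steps = 0
    prev: dict[int, tuple[int, int, int]] = {}
    for f in trajectory.frames:
        cur: dict[int, tuple[int, int, int]] = {}
        clear = (
            ~f["left_stalled"]
            & ~f["right_stalled"]
            & (f["left"] > 0)
            & (f["right"] < config.L - 1)
        )
        for uid, left, right, ok in zip(f["uid"], f["left"], f["right"], clear):
            if ok:
                cur[int(uid)] = (int(left), int(right), f["time"])
        for uid, (left, right, t) in cur.items():
            if uid in prev:
                pl, pr, pt = prev[uid]
                growth_sites += (pl - left) + (right - pr)
                growth_steps += t - pt
        prev = cur
    if growth_steps == 0:
        raise ValueError("no unobstructed growth episodes in trajectory")
    return (growth_sites / growth_steps) * config.sigma / config.tau0


def quench_loops(state: ExtruderState) -> list[tuple[int, int]]:
    """Freeze the current loop configuration: an immutable (left, right) list.

    Marks the state as quenched so subsequent extrusion steps are no-ops.
    """
    state.quenched = True
    return sorted((ex.left, ex.right) for ex in state.extruders.values())


def ctcf_sites_from_bed(path, config: LatticeConfig, offset_bp: int = 0) -> list[CTCFSite]:
    """Read CTCF sites from a BED file (orientation in the strand column).

    Interval midpoints are mapped to lattice sites at ``sigma`` kb per site,
    after subtracting ``offset_bp``. 0-based half-open coordinates.
    """
    from .io import read_bed

    bed = read_bed(path)
    sites = []
    site_bp = config.sigma * 1000.0
    for _, row in bed.iterrows():
        mid = (row["start"] + row["end"]) / 2.0 - offset_bp
        idx = int(mid // site_bp)
        if 0 <= idx < config.L:
            sites.append(CTCFSite(idx, row.get("strand", "+")))
    return sites
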