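"""The M-to-G1 transition protocol and steady-state parameter sweeps.

The canonical schedule couples extruder species, confinement geometry,
volumetric density, homotypic affinities and CTCF activation to a
minutes-based clock (0.5 s per extrusion step, 540 polymer steps per
extrusion step at full calibration):

* t < 15 min (prometaphase arrest): condensin I (tau_res = 3 min,
  d = 35 kb) and condensin II (1 h, 140 kb) extrude inside a 4:1 cylinder at
  density 0.65 with the chain ends tethered to the cylinder ends.
* 15-17 min: condensin I transiently rises to d = 27 kb, then ramps to zero
  over 17-20 min.
* 25-30 min: the cylinder height halves while the radius grows, lowering the
  density to 0.45.
* t = 30 min: condensin II is removed; CTCF stall sites and the A/B
  compartment affinity (eps_B = 0.05) switch on; cohesin (10 min residence)
  starts loading, rising linearly to d = 100 kb by t = 245 min; the cylinder
  crosses over to a sphere at density 0.25 during 30-35 min, releasing the
  tethers.
* Collection windows: PM [0,10), AT [20,30), EG1 [55,65), MG1 [115,125),
  LG1 [235,245) minutes.

A desk-scale factor ``scale`` multiplies times (residence times, event
times, windows); extruder separations stay in literal kb by default so the
extrusion activity 2v/d that controls microcompartment disruption matches
the full-scale protocol.  Chain length is set by the monomer typing passed
in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .extrusion import (
    CTCFSite,
    ExtruderSpecies,
    ExtruderState,
    LatticeConfig,
    _ctcf_stall_arrays,
    quench_loops,
    run_extrusion,
    step_extrusion,
)
from .mapstats import ContactMap, contact_map_from_trajectory, sim_window_strength
from .polymer import (
    ConfinementSpec,
    MonomerTyping,
    PolymerSim,
    PolymerSystem,
    PotentialParams,
    Trajectory3D,
    init_conformation,
)

__all__ = [
    "TransitionSchedule",
    "SweepSpec",
    "build_m2g1_schedule",
    "run_transition",
    "run_steady_state",
    "transition_window_strengths",
    "multiway_cluster_sizes",
]

WINDOWS = {"PM": (0.0, 10.0), "AT": (20.0, 30.0), "EG1": (55.0, 65.0), "MG1": (115.0, 125.0), "LG1": (235.0, 245.0)}


@dataclass
class TransitionSchedule:
    """Canonical M-to-G1 event clock (all times in full-scale protocol minutes, all
    separations in kb); query methods interpolate ramps linearly."""

    # condensin I
    tau_ci_min: float = 3.0
    d_ci_kb: float = 35.0
    d_ci_burst_kb: float = 27.0
    ci_burst_start: float = 15.0
    ci_burst_end: float = 17.0
    ci_removed: float = 20.0
    # condensin II
    tau_cii_min: float = 60.0
    d_cii_kb: float = 140.0
    cii_removed: float = 30.0
    # cohesin
    tau_coh_min: float = 10.0
    d_coh_kb: float = 100.0
    coh_start: float = 30.0
    coh_full: float = 245.0
    # densities and confinement
    rho_pm: float = 0.65
    rho_at: float = 0.45
    rho_g1: float = 0.25
    at_ramp: tuple = (25.0, 30.0)
    crossover: tuple = (30.0, 35.0)
    aspect: float = 4.0
    # affinities
    eps_c: float = 0.9
    eps_b: float = 0.05
    ab_on: float = 30.0
    ctcf_on: float = 30.0
    q_stall: float = 0.5
    # equilibration and clock constants
    equil_1d_steps: int = 36_000
    equil_3d_min: float = 300.0
    tau0: float = 0.5
    steps_per_extrusion: int = 540
    t_end: float = 245.0
    windows: dict = field(default_factory=lambda: dict(WINDOWS))

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.windows.items():
            if not (0.0 <= lo < hi <= self.t_end):
                raise ValueError(f"window {name} [{lo},{hi}) outside [0, {self.t_end}]")
        for rho in (self.rho_pm, self.rho_at, self.rho_g1):
            if not 0.0 < rho < 1.0:
                raise ValueError(f"density {rho} outside (0, 1)")

    # -- queries (t in protocol minutes; t < 0 = PM arrest / equilibration) ----
    def density(self, t: float) -> float:
        r0, r1 = self.at_ramp
        c0, c1 = self.crossover
        if t < r0:
            return self.rho_pm
        if t < r1:
            return self.rho_pm + (self.rho_at - self.rho_pm) * (t - r0) / (r1 - r0)
        if t < c0:
            return self.rho_at
        if t < c1:
            return self.rho_at + (self.rho_g1 - self.rho_at) * (t - c0) / (c1 - c0)
        return self.rho_g1

    def linear_density(self, t: float, species: str) -> float:
        """Extruders per kb (1/d) for one species at protocol-time t."""
        if species == "condensinI":
            if t < self.ci_burst_start:
                return 1.0 / self.d_ci_kb
            if t < self.ci_burst_end:
                f = (t - self.ci_burst_start) / (self.ci_burst_end - self.ci_burst_start)
                return 1.0 / self.d_ci_kb + f * (1.0 / self.d_ci_burst_kb - 1.0 / self.d_ci_kb)
            if t < self.ci_removed:
                f = (t - self.ci_burst_end) / (self.ci_removed - self.ci_burst_end)
                return (1.0 - f) / self.d_ci_burst_kb
            return 0.0
        if species == "condensinII":
            return 1.0 / self.d_cii_kb if t < self.cii_removed else 0.0
        if species == "cohesin":
            if t < self.coh_start:
                return 0.0
            f = min((t - self.coh_start) / (self.coh_full - self.coh_start), 1.0)
            return f / self.d_coh_kb
        raise KeyError(f"unknown species {species!r}")

    def species_present(self, t: float) -> set[str]:
        return {
            s
            for s in ("condensinI", "condensinII", "cohesin")
            if self.linear_density(t, s) > 0
        }

    def eps(self, t: float) -> dict:
        return {"A": 0.0, "B": self.eps_b if t >= self.ab_on else 0.0, "C": self.eps_c}

    def ctcf_active(self, t: float) -> bool:
        return t >= self.ctcf_on

    def confinement(self, t: float, n_monomers: int, a: float = 1.0) -> dict:
        """Wall geometry at protocol-time t: cylinder radius/height/stiffness
        fraction and sphere radius/stiffness fraction (for the crossover)."""
        mono_vol = 4.0 / 3.0 * np.pi * (a / 2.0) ** 3
        r0, r1 = self.at_ramp
        c0, c1 = self.crossover
        spec0 = ConfinementSpec("cylinder", self.rho_pm, self.aspect)
        cr0, ch0 = spec0.cylinder_radius_height(n_monomers, a)
        if t < r0:
            return {"cyl_r": cr0, "cyl_h": ch0, "cyl_frac": 1.0, "sphere_R": 0.0, "sphere_frac": 0.0, "tether_frac": 1.0}
        h_end = ch0 / 2.0
        if t < r1:  # height halves; radius set by the ramping density
            f = (t - r0) / (r1 - r0)
            h = ch0 + (h_end - ch0) * f
            vol = n_monomers * mono_vol / self.density(t)
            r = np.sqrt(vol / (np.pi * h))
            return {"cyl_r": r, "cyl_h": h, "cyl_frac": 1.0, "sphere_R": 0.0, "sphere_frac": 0.0, "tether_frac": 1.0}
        vol_at = n_monomers * mono_vol / self.rho_at
        r_at = np.sqrt(vol_at / (np.pi * h_end))
        sphere_R = ConfinementSpec("sphere", self.rho_g1).sphere_radius(n_monomers, a)
        if t < c0:
            return {"cyl_r": r_at, "cyl_h": h_end, "cyl_frac": 1.0, "sphere_R": sphere_R, "sphere_frac": 0.0, "tether_frac": 1.0}
        if t < c1:  # crossover: old wall ramps down, new wall ramps up, tethers release
            f = (t - c0) / (c1 - c0)
            return {"cyl_r": r_at, "cyl_h": h_end, "cyl_frac": 1.0 - f, "sphere_R": sphere_R, "sphere_frac": f, "tether_frac": 1.0 - f}
        return {"cyl_r": r_at, "cyl_h": h_end, "cyl_frac": 0.0, "sphere_R": sphere_R, "sphere_frac": 1.0, "tether_frac": 0.0}

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionSchedule":
        d = dict(d)
        d["windows"] = {k: tuple(v) for k, v in d["windows"].items()}
        for key in ("at_ramp", "crossover"):
            d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        """Declarative config-file form of the schedule."""
        import yaml

        d = self.to_dict()
        d["windows"] = {k: list(v) for k, v in d["windows"].items()}
        d["at_ramp"], d["crossover"] = list(d["at_ramp"]), list(d["crossover"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "TransitionSchedule":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_m2g1_schedule(overrides: dict | None = None) -> TransitionSchedule:
    """The canonical M-to-G1 schedule, with optional field overrides
    (e.g. ``{"ci_removed": 28.0}`` delays condensin I removal into AT)."""
    overrides = overrides or {}
    valid = set(TransitionSchedule.__dataclass_fields__)
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(f"unknown schedule parameters: {sorted(unknown)}")
    return TransitionSchedule(**overrides)


@dataclass
class TransitionResult:
    """Per-window 3D trajectories plus the full parameter log."""

    windows: dict  # name -> Trajectory3D
    typing: MonomerTyping
    schedule: TransitionSchedule
    scale: float
    seed: int
    parameter_log: pd.DataFrame = None
    ctcf_sites: list = field(default_factory=list)


def _species_table(
    schedule: TransitionSchedule, scale: float, p: float, d_scale: float
) -> list[ExtruderSpecies]:
    """Desk-scaled species table: residence times scale with the clock, and
    separations scale by ``d_scale`` (1 = literal kb, preserving the full-scale
    extrusion activity 2v/d)."""
    return [
        ExtruderSpecies("condensinI", schedule.tau_ci_min * 60 * scale, schedule.d_ci_kb * d_scale, p=p),
        ExtruderSpecies("condensinII", schedule.tau_cii_min * 60 * scale, schedule.d_cii_kb * d_scale, p=p),
        ExtruderSpecies(
            "cohesin", schedule.tau_coh_min * 60 * scale, schedule.d_coh_kb * d_scale,
            p=p, respects_ctcf=True, q_stall=schedule.q_stall,
        ),
    ]


def run_transition(
    schedule: TransitionSchedule,
    typing: MonomerTyping,
    seed: int = 0,
    scale: float = 1.0,
    ctcf_sites: list[CTCFSite] | None = None,
    steps_per_extrusion: int | None = None,
    sample_stride: int = 2,
    p_step: float = 0.5,
    dt: float = 0.02,
    log_every: int = 20,
    scale_separations: bool = False,
) -> TransitionResult:
    """Execute equilibration and the event clock; returns frames grouped by
    collection window plus the parameter log.

    ``scale`` in (0, 1] multiplies all times (residence times, event clock,
    windows); the lattice length is ``len(typing)``.  Genomic separations
    stay in literal kb by default, preserving the extrusion activity 2v/d
    that controls microcompartment disruption (``scale_separations=True``
    scales them too).  ``sample_stride``: extrusion steps between collected
    frames inside windows.
    """
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = len(typing)
    config = LatticeConfig(L=n, sigma=0.5, tau0=schedule.tau0, seed=seed)
    d_scale = scale if scale_separations else 1.0
    species = _species_table(schedule, scale, p_step, d_scale)
    sigma_kb = config.sigma
    spe = schedule.steps_per_extrusion if steps_per_extrusion is None else steps_per_extrusion

    ctcf_sites = ctcf_sites or []
    stall_none = _ctcf_stall_arrays(config, [])
    stall_active = _ctcf_stall_arrays(config, ctcf_sites)

    def targets_at(t_protocol: float) -> np.ndarray:
        # linear density is per full-scale kb; with separations scaled by d_scale
        # the target over an n*sigma-kb lattice is linear_density/d_scale * n*sigma
        raw = np.array(
            [schedule.linear_density(t_protocol, sp.name) / d_scale * n * sigma_kb for sp in species]
        )
        frac, whole = np.modf(raw)
        return whole.astype(int) + (rng.random(len(raw)) < frac).astype(int)

    # --- 1D pre-equilibration at PM parameters -----------------------------
    state = ExtruderState(config, species)
    n_1d = max(int(round(schedule.equil_1d_steps * scale)), 10)
    for _ in range(n_1d):
        step_extrusion(state, targets_at(0.0), *stall_none, rng)

    # --- 3D setup in the PM cylinder ---------------------------------------
    conf0 = ConfinementSpec("cylinder", schedule.rho_pm, schedule.aspect, tethered=True)
    coords = init_conformation(n, conf0, seed=seed)
    system = PolymerSystem(
        coords, typing,
        potential=PotentialParams(eps={"A": 0.0, "B": 0.0, "C": schedule.eps_c}),
        confinement=conf0, dt=dt,
    )
    sim = PolymerSim(system, seed=seed)
    wall_k = conf0.wall_k

    minutes_per_step = schedule.tau0 / 60.0 / scale  # protocol minutes per extrusion step
    t_equil_steps = max(int(round(schedule.equil_3d_min * scale * 60 / schedule.tau0)), 10)
    t_main_steps = int(round(schedule.t_end * scale * 60 / schedule.tau0))

    window_frames: dict[str, list] = {w: [] for w in schedule.windows}
    window_times: dict[str, list] = {w: [] for w in schedule.windows}
    log_rows = []
    eps_on = False
    ctcf_now = False

    def apply_walls(t_protocol: float) -> None:
        geo = schedule.confinement(t_protocol, n)
        sim.set_cylinder(geo["cyl_r"], geo["cyl_h"], wall_k * geo["cyl_frac"])
        sim.set_sphere(geo["sphere_R"], wall_k * geo["sphere_frac"])
        if geo["tether_frac"] > 0:
            sim.set_tethers(
                np.array([0, n - 1]),
                np.array([[0.0, 0.0, -geo["cyl_h"] / 2], [0.0, 0.0, geo["cyl_h"] / 2]]),
                k=wall_k * geo["tether_frac"],
            )
        else:
            sim.clear_tethers()

    total_steps = t_equil_steps + t_main_steps
    for step_i in range(total_steps):
        t_protocol = (step_i - t_equil_steps) * minutes_per_step
        if not ctcf_now and schedule.ctcf_active(t_protocol):
            ctcf_now = True
        if not eps_on and t_protocol >= schedule.ab_on:
            sim.set_eps(schedule.eps(t_protocol))
            eps_on = True
        stall = stall_active if ctcf_now else stall_none
        step_extrusion(state, targets_at(min(t_protocol, schedule.t_end)), *stall, rng)
        bridges = np.array(
            [[ex.left, ex.right] for ex in state.extruders.values()], dtype=np.int64
        ).reshape(-1, 2)
        sim.set_bridges(bridges)
        apply_walls(t_protocol)
        sim.run_block(spe)
        if step_i % log_every == 0:
            counts = state.count_by_species()
            log_rows.append(
                {
                    "t_protocol_min": t_protocol,
                    "density": schedule.density(t_protocol),
                    "condensinI": counts[0],
                    "condensinII": counts[1],
                    "cohesin": counts[2],
                    "eps_B": schedule.eps(t_protocol)["B"],
                    "ctcf_active": ctcf_now,
                }
            )
        if t_protocol >= 0:
            for wname, (lo, hi) in schedule.windows.items():
                if lo <= t_protocol < hi and (step_i - t_equil_steps) % sample_stride == 0:
                    window_frames[wname].append(system.coords.copy())
                    window_times[wname].append(system.time)

    windows = {}
    for wname in schedule.windows:
        if not window_frames[wname]:
            raise RuntimeError(f"window {wname} collected zero frames (sample_stride too large?)")
        windows[wname] = Trajectory3D(
            np.array(window_frames[wname]), np.array(window_times[wname]), typing,
            meta={"window": wname, "seed": seed, "scale": scale},
        )
    return TransitionResult(
        windows=windows, typing=typing, schedule=schedule, scale=scale, seed=seed,
        parameter_log=pd.DataFrame(log_rows), ctcf_sites=list(ctcf_sites),
    )


# ----------------------------------------------------------------------------
# window metrics


def _pair_list(bins: np.ndarray, min_sep: int, max_sep: int | None) -> list[tuple[int, int]]:
    pairs = []
    for ai in range(len(bins)):
        for aj in range(ai + 1, len(bins)):
            sep = abs(int(bins[aj]) - int(bins[ai]))
            if sep >= min_sep and (max_sep is None or sep <= max_sep):
                pairs.append((int(bins[ai]), int(bins[aj])))
    return pairs


def window_map(trajectory: Trajectory3D, bin_monomers: int = 4, contact_radius: float = 1.5) -> ContactMap:
    """Desk-scale window map.  The contact radius defaults to the attraction
    range (1.5 a, physically bound contacts) rather than the full-scale
    4-monomer capture radius: at desk chain lengths the densest containers
    are only a few monomer diameters across, and a 4 a radius saturates the
    map."""
    return contact_map_from_trajectory(trajectory, contact_radius=contact_radius, bin_monomers=bin_monomers)


def cc_pair_strength(
    cmap: ContactMap,
    typing: MonomerTyping,
    bin_monomers: int = 4,
    min_sep_bins: int = 4,
    max_sep_bins: int | None = None,
) -> float:
    """Mean relative (distance-scaled) 6-kb window strength over all C-anchor
    pairs at usable separations; NaN if no usable pair."""
    anchors = typing.c_anchor_monomers() // bin_monomers
    pairs = _pair_list(np.unique(anchors), min_sep_bins, max_sep_bins)
    vals = []
    for pair in pairs:
        try:
            vals.append(sim_window_strength(cmap, pair, window_kb=6.0, relative=True))
        except ValueError:
            continue
    return float(np.nanmean(vals)) if vals else float("nan")


def ctcf_pair_strength(
    cmap: ContactMap,
    ctcf_sites: list[CTCFSite],
    bin_monomers: int = 4,
    min_sep_bins: int = 4,
) -> float:
    """Mean relative strength over convergent CTCF site pairs."""
    # convergent pair: left anchor stalls left-moving legs ("+"), right anchor
    # stalls right-moving legs ("-")
    left_anchors = sorted(s.site_index for s in ctcf_sites if s.orientation == "+")
    right_anchors = sorted(s.site_index for s in ctcf_sites if s.orientation == "-")
    pairs = []
    for u in left_anchors:
        for v in right_anchors:
            if v > u and (v - u) // bin_monomers >= min_sep_bins:
                pairs.append((u // bin_monomers, v // bin_monomers))
    vals = []
    for pair in pairs:
        try:
            vals.append(sim_window_strength(cmap, pair, window_kb=6.0, relative=True))
        except ValueError:
            continue
    return float(np.nanmean(vals)) if vals else float("nan")


def transition_window_strengths(results: list[TransitionResult], bin_monomers: int = 4) -> pd.DataFrame:
    """Per-window mean C-C and CTCF-CTCF relative strengths, frames pooled
    across seeds before map construction."""
    first = results[0]
    rows = []
    for wname in first.schedule.windows:
        frames = np.concatenate([r.windows[wname].frames for r in results])
        times = np.arange(1, len(frames) + 1)
        traj = Trajectory3D(frames, times, first.typing)
        cmap = window_map(traj, bin_monomers)
        rows.append(
            {
                "window": wname,
                "cc_strength": cc_pair_strength(cmap, first.typing, bin_monomers),
                "ctcf_strength": ctcf_pair_strength(cmap, first.ctcf_sites, bin_monomers),
            }
        )
    return pd.DataFrame(rows)


def multiway_cluster_sizes(
    trajectory: Trajectory3D,
    typing: MonomerTyping,
    radius: float = 2.0,
    a: float = 1.0,
) -> np.ndarray:
    """Sizes of spatial clusters of C-type anchors per frame.

    Anchors within ``radius * a`` of each other are linked; cluster = connected
    component with >= 2 anchors (an isolated anchor underlies no focal
    contact).  Returns the concatenated cluster sizes over frames.
    """
    anchors = typing.c_anchor_monomers()
    sizes = []
    for frame in trajectory.frames:
        pts = frame[anchors]
        m = len(pts)
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        adj = d2 <= (radius * a) ** 2
        seen = np.zeros(m, dtype=bool)
        for i in range(m):
            if seen[i]:
                continue
            stack, comp = [i], 0
            seen[i] = True
            while stack:
                u = stack.pop()
                comp += 1
                for v in np.flatnonzero(adj[u] & ~seen):
                    seen[v] = True
                    stack.append(v)
            if comp >= 2:
                sizes.append(comp)
    return np.array(sizes, dtype=int)


# ----------------------------------------------------------------------------
# steady-state sweeps


@dataclass
class SweepSpec:
    """Steady-state parameter sweep at desk scale.

    ``grid``: parameter name -> values; supported names: ``eps_c``, ``rho``,
    ``tau_res_s``, ``d_kb``, ``p``.  Unswept parameters take the fixed
    defaults (one extruder species, no CTCF, spherical confinement).
    """

    grid: dict
    eps_c: float = 0.9
    rho: float = 0.25
    tau_res_s: float = 150.0
    d_kb: float = 100.0
    p: float = 0.5
    replicates: int = 5
    equil_1d_steps: int = 1000
    equil_blocks: int = 400
    collect_blocks: int = 400
    steps_per_block: int = 50
    sample_stride: int = 5
    quenched: bool = False
    scale_note: str = "desk"

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.grid:
            raise ValueError("grid must be non-empty")
        known = {"eps_c", "rho", "tau_res_s", "d_kb", "p"}
        unknown = set(self.grid) - known
        if unknown:
            raise ValueError(f"unknown sweep parameters: {sorted(unknown)}")

    def points(self) -> list[dict]:
        from itertools import product

        keys = sorted(self.grid)
        return [dict(zip(keys, combo)) for combo in product(*(self.grid[k] for k in keys))]


def _check_equilibrated(rg_series: np.ndarray) -> bool:
    """Plateau check: relative change of the windowed mean Rg < 2% over the
    last third of equilibration."""
    third = max(len(rg_series) // 3, 1)
    a, b = rg_series[-2 * third : -third], rg_series[-third:]
    if len(a) == 0 or len(b) == 0:
        return True
    ma, mb = float(np.mean(a)), float(np.mean(b))
    return abs(mb - ma) / max(abs(ma), 1e-12) < 0.02


def run_steady_state(
    sweep: SweepSpec,
    typing: MonomerTyping,
    seeds: list[int] | None = None,
    dt: float = 0.005,
) -> pd.DataFrame:
    """One equilibrated coupled run per grid point per replicate; returns a
    summary table with the mean relative C-C window strength per run.

    With ``sweep.quenched`` the 1D simulation is equilibrated, loops are
    frozen, and the 3D run uses the static bridges.
    """
    seeds = list(range(sweep.replicates)) if seeds is None else list(seeds)
    n = len(typing)
    rows = []
    for point in sweep.points():
        par = {k: getattr(sweep, k) for k in ("eps_c", "rho", "tau_res_s", "d_kb", "p")}
        par.update(point)
        for seed in seeds:
            rows.append(
                _steady_state_run(sweep, typing, par, seed, dt)
            )
    return pd.DataFrame(rows)


def _steady_state_run(sweep: SweepSpec, typing: MonomerTyping, par: dict, seed: int, dt: float) -> dict:
    n = len(typing)
    rng = np.random.default_rng(seed)
    config = LatticeConfig(L=n, sigma=0.5, tau0=0.5, seed=seed)
    species = [ExtruderSpecies("generic", par["tau_res_s"], par["d_kb"], p=par["p"])]
    # 1D equilibration
    traj1d = run_extrusion(config, species, None, sweep.equil_1d_steps, stride=sweep.equil_1d_steps, rng=rng)
    state = traj1d.final_state
    static_loops = None
    if sweep.quenched:
        static_loops = quench_loops(state)
    conf = ConfinementSpec("sphere", par["rho"])
    coords = init_conformation(n, conf, seed=seed)
    system = PolymerSystem(
        coords, typing,
        potential=PotentialParams(eps={"A": 0.0, "B": 0.0, "C": par["eps_c"]}),
        confinement=conf, dt=dt,
    )
    sim = PolymerSim(system, seed=seed)
    stall = _ctcf_stall_arrays(config, [])
    rg_log = []
    frames, times = [], []
    for b in range(sweep.equil_blocks + sweep.collect_blocks):
        if static_loops is None:
            step_extrusion(state, None, *stall, rng)
            bridges = np.array(
                [[ex.left, ex.right] for ex in state.extruders.values()], dtype=np.int64
            ).reshape(-1, 2)
        else:
            bridges = np.asarray(static_loops, dtype=np.int64).reshape(-1, 2)
        sim.set_bridges(bridges)
        sim.run_block(sweep.steps_per_block)
        if b < sweep.equil_blocks:
            if b % 10 == 0:
                com = system.coords.mean(0)
                rg_log.append(float(np.sqrt(((system.coords - com) ** 2).sum(1).mean())))
        elif (b - sweep.equil_blocks) % sweep.sample_stride == 0:
            frames.append(system.coords.copy())
            times.append(system.time)
    equilibrated = _check_equilibrated(np.array(rg_log))
    if not equilibrated:
        warnings.warn(f"run at {par} seed={seed}: Rg not plateaued; flagged unequilibrated")
    traj = Trajectory3D(np.array(frames), np.array(times), typing, meta={"seed": seed, **par})
    cmap = window_map(traj)
    cc = cc_pair_strength(cmap, typing)
    out = {**par, "seed": seed, "cc_strength": cc, "equilibrated": equilibrated,
           "quenched": sweep.quenched, "n_frames": len(frames), "scale_note": sweep.scale_note}
    return out
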