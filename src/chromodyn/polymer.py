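"""Overdamped Langevin dynamics of a typed bead-spring chromatin polymer.

The chain is a block copolymer of A/B/C monomers (B = inactive chromatin,
C = microcompartment anchors such as CRE sites) connected by harmonic springs.
Non-bonded monomers interact through a smooth square-well pair potential: a
soft repulsive core of height ``E_repel`` for ``r < a`` (``a`` = monomer
diameter, physically ~25 nm ~ 0.5 kb) and, for homotypic pairs, an attractive
well of depth ``eps_i`` on ``a <= r <= a* = 1.5 a``; the potential and its
first derivative vanish at both branch points and the potential is truncated
to zero beyond ``a*``.  Loop extruders enter as harmonic bridge bonds between
the monomers their legs occupy (one lattice site = one monomer).

Confinement to a sphere or a 4:1 cylinder is imposed by a one-sided harmonic
wall whose radius is set by the prescribed volumetric density
``rho = N * (4/3) pi (a/2)^3 / V_container``.

Everything is in reduced units: ``a = 1``, ``k_B T = 1``, monomer mass 1.
Integration uses the underdamped BAOAB Langevin splitting at a low collision
rate, which samples the narrow attraction well accurately at practical
timesteps (the configurational bias of BAOAB is O(dt^2) with a small
constant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "PotentialParams",
    "MonomerTyping",
    "ConfinementSpec",
    "PolymerSystem",
    "Trajectory3D",
    "PolymerSim",
    "pair_potential",
    "pair_force",
    "init_conformation",
    "run_polymer",
    "summarize_conformation",
]

TYPE_CODES = {"A": 0, "B": 1, "C": 2}
A0 = np.sqrt(6.0 / 7.0)
E0 = 46_656.0 / 823_543.0  # = (6/7)^6 / 7


@dataclass(frozen=True)
class PotentialParams:
    """Pair-potential constants (energies in k_B T, lengths in units of a)."""

    e_repel: float = 3.0
    a: float = 1.0
    eps: dict = field(default_factory=lambda: {"A": 0.0, "B": 0.05, "C": 0.9})

    @property
    def a_star(self) -> float:
        return 1.5 * self.a

    def eps_matrix(self) -> np.ndarray:
        """3x3 homotypic affinity matrix (heterotypic entries zero)."""
        m = np.zeros((3, 3))
        for label, code in TYPE_CODES.items():
            m[code, code] = self.eps.get(label, 0.0)
        return m


def pair_potential(r, eps_i, params: PotentialParams | None = None):
    """Smooth square-well pair energy U(r) in k_B T.  Vectorized over ``r``.

    ``eps_i`` is the homotypic affinity of the pair (0 for heterotypic or
    A-type pairs).
    """
    params = params or PotentialParams()
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be non-negative")
    a, a_star, e_rep = params.a, params.a_star, params.e_repel
    out = np.zeros_like(r)
    core = r < a
    x = A0 * r[core] / a
    out[core] = e_rep * (1.0 + (x**2 - 1.0) * x**12 / E0)
    well = (r >= a) & (r <= a_star)
    c = (a + a_star) / 2.0
    w = (a_star - a) / 2.0
    y = (r[well] - c) / w * A0
    out[well] = -eps_i * ((y**2 - 1.0) * y**12 / E0 + 1.0)
    return out if out.ndim else float(out)


def pair_force(r, eps_i, params: PotentialParams | None = None):
    """Radial force magnitude -dU/dr (positive = repulsive)."""
    params = params or PotentialParams()
    r = np.asarray(r, dtype=float)
    a, a_star, e_rep = params.a, params.a_star, params.e_repel
    out = np.zeros_like(r)
    core = r < a
    x = A0 * r[core] / a
    out[core] = -e_rep / E0 * (14.0 * x**13 - 12.0 * x**11) * (A0 / a)
    well = (r >= a) & (r <= a_star)
    c = (a + a_star) / 2.0
    w = (a_star - a) / 2.0
    y = (r[well] - c) / w * A0
    out[well] = eps_i / E0 * (14.0 * y**13 - 12.0 * y**11) * (A0 / w)
    return out if out.ndim else float(out)


@dataclass
class MonomerTyping:
    """Per-monomer A/B/C labels plus layout metadata (locus copies, spacers,
    C-block anchor positions)."""

    codes: np.ndarray  # int8, values in {0: A, 1: B, 2: C}
    layout: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 1:
            raise ValueError("codes must be a 1D sequence")
        if not np.all((self.codes >= 0) & (self.codes <= 2)):
            raise ValueError("codes must be 0 (A), 1 (B) or 2 (C)")

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def labels(self) -> np.ndarray:
        lut = np.array(["A", "B", "C"])
        return lut[self.codes]

    @classmethod
    def from_labels(cls, labels, layout=None) -> "MonomerTyping":
        codes = np.array([TYPE_CODES[t] for t in labels], dtype=np.int8)
        return cls(codes, layout or {})

    def c_anchor_monomers(self) -> np.ndarray:
        """Center monomer of each contiguous C block."""
        is_c = self.codes == 2
        padded = np.concatenate([[False], is_c, [False]])
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])
        return ((starts + ends - 1) // 2).astype(np.int64)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"index": np.arange(len(self)), "type": self.labels}).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class ConfinementSpec:
    """Sphere or 4:1 cylinder at prescribed volumetric density ``rho_chr``.

    The container volume is ``N * (4/3) pi (a/2)^3 / rho_chr``; for the sphere
    this gives radius ``R = (a/2) (N / rho)^(1/3)`` and for the cylinder
    (height = aspect * diameter) radius ``r = (a/2) (N / (1.5 * aspect * rho))^(1/3)``.
    """

    shape: str = "sphere"  # sphere | cylinder | none
    rho_chr: float = 0.25
    aspect: float = 4.0
    wall_k: float = 10.0
    tethered: bool = False

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "cylinder", "none"):
            raise ValueError(f"unknown confinement shape {self.shape!r}")
        if self.shape != "none" and not 0.0 < self.rho_chr < 1.0:
            raise ValueError("rho_chr must be in (0, 1)")

    def sphere_radius(self, n_monomers: int, a: float = 1.0) -> float:
        return (a / 2.0) * (n_monomers / self.rho_chr) ** (1.0 / 3.0)

    def cylinder_radius_height(self, n_monomers: int, a: float = 1.0) -> tuple[float, float]:
        # V = pi r^2 h with h = 2 * aspect * r  ->  r^3 = N (a/2)^3 (4/3) / (2 aspect rho)
        r = (a / 2.0) * (2.0 * n_monomers / (3.0 * self.aspect * self.rho_chr)) ** (1.0 / 3.0)
        return r, 2.0 * self.aspect * r


@dataclass
class PolymerSystem:
    """Full 3D simulation state: coordinates, typing, bonds, potentials."""

    coords: np.ndarray
    typing: MonomerTyping
    potential: PotentialParams = field(default_factory=PotentialParams)
    confinement: ConfinementSpec = field(default_factory=ConfinementSpec)
    bridges: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=np.int64))
    bond_k: float = 30.0
    bond_r0: float = 1.0
    dt: float = 0.02
    gamma: float = 0.1
    time: int = 0

    def __post_init__(self) -> None:
        self.coords = np.ascontiguousarray(self.coords, dtype=np.float64)
        if self.coords.shape != (len(self.typing), 3):
            raise ValueError("coords must be (n_monomers, 3) matching typing length")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        self.bridges = np.asarray(self.bridges, dtype=np.int64).reshape(-1, 2)
        if len(self.bridges) and np.any(self.bridges[:, 0] == self.bridges[:, 1]):
            raise ValueError("bridge bonds must connect distinct monomers")

    @property
    def n_monomers(self) -> int:
        return len(self.typing)

    def chain_bonds(self) -> np.ndarray:
        n = self.n_monomers
        return np.column_stack([np.arange(n - 1), np.arange(1, n)]).astype(np.int64)


@dataclass
class Trajectory3D:
    """Sampled coordinate frames with timestamps in polymer steps."""

    frames: np.ndarray  # (n_frames, n_monomers, 3)
    times: np.ndarray  # polymer steps, strictly increasing
    typing: MonomerTyping
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        if len(self.times) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def minutes(self, tau0: float = 0.5, steps_per_extrusion: int = 540) -> np.ndarray:
        return self.times / steps_per_extrusion * tau0 / 60.0


# ----------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _seed_numba(seed):  # numba keeps its own RNG state
    np.random.seed(seed)


@njit(cache=True)
def _compute_forces(
    pos, codes, eps_mat, e_rep, a, a_star, bonds, bond_k, bond_r0,
    sphere_R, sphere_k, cyl_r, cyl_h, cyl_k,
    tether_idx, tether_pts, tether_k, forces,
):
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    a0 = 0.9258200997725514  # sqrt(6/7)
    e0 = 46656.0 / 823543.0
    cut = a_star
    cut2 = cut * cut
    c = (a + a_star) * 0.5
    w = (a_star - a) * 0.5
    # linked-cell neighbor search (cell edge = cutoff)
    xmin, ymin, zmin = pos[0, 0], pos[0, 1], pos[0, 2]
    xmax, ymax, zmax = xmin, ymin, zmin
    for i in range(1, n):
        if pos[i, 0] < xmin:
            xmin = pos[i, 0]
        elif pos[i, 0] > xmax:
            xmax = pos[i, 0]
        if pos[i, 1] < ymin:
            ymin = pos[i, 1]
        elif pos[i, 1] > ymax:
            ymax = pos[i, 1]
        if pos[i, 2] < zmin:
            zmin = pos[i, 2]
        elif pos[i, 2] > zmax:
            zmax = pos[i, 2]
    span = (xmax - xmin) + (ymax - ymin) + (zmax - zmin)
    if not np.isfinite(span):
        return  # exploding coordinates; caller raises on the NaN check
    # grid cells no smaller than the cutoff; cap the grid so degenerate
    # geometries cannot blow up the allocation (larger cells stay correct)
    nmax = 64
    nx = min(max(int((xmax - xmin) / cut) + 1, 1), nmax)
    ny = min(max(int((ymax - ymin) / cut) + 1, 1), nmax)
    nz = min(max(int((zmax - zmin) / cut) + 1, 1), nmax)
    ncell = nx * ny * nz
    head = np.full(ncell, -1, dtype=np.int64)
    nxt = np.empty(n, dtype=np.int64)
    cix = np.empty(n, dtype=np.int64)
    ciy = np.empty(n, dtype=np.int64)
    ciz = np.empty(n, dtype=np.int64)
    ex = max(cut, (xmax - xmin) / nx + 1e-12)
    ey = max(cut, (ymax - ymin) / ny + 1e-12)
    ez = max(cut, (zmax - zmin) / nz + 1e-12)
    for i in range(n):
        gx = min(int((pos[i, 0] - xmin) / ex), nx - 1)
        gy = min(int((pos[i, 1] - ymin) / ey), ny - 1)
        gz = min(int((pos[i, 2] - zmin) / ez), nz - 1)
        cix[i], ciy[i], ciz[i] = gx, gy, gz
        cell = (gx * ny + gy) * nz + gz
        nxt[i] = head[cell]
        head[cell] = i
    for i in range(n):
        xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
        ci = codes[i]
        for ox in range(-1, 2):
            gx = cix[i] + ox
            if gx < 0 or gx >= nx:
                continue
            for oy in range(-1, 2):
                gy = ciy[i] + oy
                if gy < 0 or gy >= ny:
                    continue
                for oz in range(-1, 2):
                    gz = ciz[i] + oz
                    if gz < 0 or gz >= nz:
                        continue
                    j = head[(gx * ny + gy) * nz + gz]
                    while j != -1:
                        if j <= i:
                            j = nxt[j]
                            continue
                        dx = xi - pos[j, 0]
                        dy = yi - pos[j, 1]
                        dz = zi - pos[j, 2]
                        r2 = dx * dx + dy * dy + dz * dz
                        if r2 >= cut2 or r2 < 1e-12:
                            j = nxt[j]
                            continue
                        r = np.sqrt(r2)
                        if r < a:
                            x = a0 * r / a
                            x11 = x ** 11
                            fmag = -e_rep / e0 * (14.0 * x * x * x11 - 12.0 * x11) * (a0 / a)
                        else:
                            eps = eps_mat[ci, codes[j]]
                            if eps == 0.0:
                                j = nxt[j]
                                continue
                            y = (r - c) / w * a0
                            y11 = y ** 11
                            fmag = eps / e0 * (14.0 * y * y * y11 - 12.0 * y11) * (a0 / w)
                        fx = fmag * dx / r
                        fy = fmag * dy / r
                        fz = fmag * dz / r
                        forces[i, 0] += fx
                        forces[i, 1] += fy
                        forces[i, 2] += fz
                        forces[j, 0] -= fx
                        forces[j, 1] -= fy
                        forces[j, 2] -= fz
                        j = nxt[j]
    # harmonic bonds (chain + extruder bridges)
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        fmag = -bond_k * (r - bond_r0)
        fx = fmag * dx / r
        fy = fmag * dy / r
        fz = fmag * dz / r
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    # one-sided harmonic walls
    if sphere_k > 0.0:
        for i in range(n):
            r = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
            if r > sphere_R and r > 1e-12:
                fmag = -sphere_k * (r - sphere_R)
                forces[i, 0] += fmag * pos[i, 0] / r
                forces[i, 1] += fmag * pos[i, 1] / r
                forces[i, 2] += fmag * pos[i, 2] / r
    if cyl_k > 0.0:
        half_h = cyl_h * 0.5
        for i in range(n):
            rad = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2)
            if rad > cyl_r and rad > 1e-12:
                fmag = -cyl_k * (rad - cyl_r)
                forces[i, 0] += fmag * pos[i, 0] / rad
                forces[i, 1] += fmag * pos[i, 1] / rad
            if pos[i, 2] > half_h:
                forces[i, 2] += -cyl_k * (pos[i, 2] - half_h)
            elif pos[i, 2] < -half_h:
                forces[i, 2] += -cyl_k * (pos[i, 2] + half_h)
    # tethers
    for t in range(tether_idx.shape[0]):
        i = tether_idx[t]
        for dcomp in range(3):
            forces[i, dcomp] += -tether_k * (pos[i, dcomp] - tether_pts[t, dcomp])


@njit(cache=True)
def _langevin_block(
    pos, codes, eps_mat, e_rep, a, a_star, bonds, bond_k, bond_r0,
    sphere_R, sphere_k, cyl_r, cyl_h, cyl_k,
    tether_idx, tether_pts, tether_k,
    n_steps, dt, gamma, vel, forces,
):
    """Underdamped BAOAB Langevin step (unit mass, kT = 1):
    B half-kick, A half-drift, O Ornstein-Uhlenbeck velocity refresh,
    A half-drift, B half-kick; one force evaluation per step."""
    n = pos.shape[0]
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(1.0 - c1 * c1)
    _compute_forces(
        pos, codes, eps_mat, e_rep, a, a_star, bonds, bond_k, bond_r0,
        sphere_R, sphere_k, cyl_r, cyl_h, cyl_k,
        tether_idx, tether_pts, tether_k, forces,
    )
    for _s in range(n_steps):
        noise = np.random.standard_normal((n, 3))
        for i in range(n):
            for d in range(3):
                vel[i, d] += 0.5 * dt * forces[i, d]
                pos[i, d] += 0.5 * dt * vel[i, d]
                vel[i, d] = c1 * vel[i, d] + c2 * noise[i, d]
                pos[i, d] += 0.5 * dt * vel[i, d]
        _compute_forces(
            pos, codes, eps_mat, e_rep, a, a_star, bonds, bond_k, bond_r0,
            sphere_R, sphere_k, cyl_r, cyl_h, cyl_k,
            tether_idx, tether_pts, tether_k, forces,
        )
        for i in range(n):
            for d in range(3):
                vel[i, d] += 0.5 * dt * forces[i, d]


def compute_forces(system: PolymerSystem) -> np.ndarray:
    """All forces at the current coordinates (used by tests against finite
    differences of the total energy)."""
    sim = PolymerSim(system, seed=0)
    forces = np.zeros_like(system.coords)
    _compute_forces(
        system.coords, sim._codes, sim._eps_mat, system.potential.e_repel,
        system.potential.a, system.potential.a_star, sim._bonds,
        system.bond_k, system.bond_r0,
        sim._sphere_R, sim._sphere_k, sim._cyl_r, sim._cyl_h, sim._cyl_k,
        sim._tether_idx, sim._tether_pts, sim._tether_k, forces,
    )
    return forces


def total_energy(system: PolymerSystem) -> float:
    """Total potential energy (pairwise + bonds + walls + tethers), numpy."""
    pos = system.coords
    p = system.potential
    eps_mat = p.eps_matrix()
    codes = system.typing.codes
    n = len(pos)
    diff = pos[:, None, :] - pos[None, :, :]
    r = np.sqrt((diff**2).sum(-1))
    iu = np.triu_indices(n, k=1)
    rr = r[iu]
    eps_pair = eps_mat[codes[iu[0]], codes[iu[1]]]
    e = float(np.sum(pair_potential(rr, 0.0, p) * (rr < p.a)))
    well = (rr >= p.a) & (rr <= p.a_star)
    if well.any():
        e += float(np.sum(pair_potential(rr[well], 1.0, p) * eps_pair[well]))
    bonds = np.vstack([system.chain_bonds(), system.bridges])
    bl = np.linalg.norm(pos[bonds[:, 0]] - pos[bonds[:, 1]], axis=1)
    e += float(0.5 * system.bond_k * np.sum((bl - system.bond_r0) ** 2))
    sim = PolymerSim(system, seed=0)
    if sim._sphere_k > 0:
        rad = np.linalg.norm(pos, axis=1)
        e += float(0.5 * sim._sphere_k * np.sum(np.maximum(rad - sim._sphere_R, 0.0) ** 2))
    if sim._cyl_k > 0:
        rad = np.linalg.norm(pos[:, :2], axis=1)
        e += float(0.5 * sim._cyl_k * np.sum(np.maximum(rad - sim._cyl_r, 0.0) ** 2))
        over = np.maximum(np.abs(pos[:, 2]) - sim._cyl_h / 2.0, 0.0)
        e += float(0.5 * sim._cyl_k * np.sum(over**2))
    if sim._tether_k > 0 and len(sim._tether_idx):
        d = pos[sim._tether_idx] - sim._tether_pts
        e += float(0.5 * sim._tether_k * np.sum(d**2))
    return e


class PolymerSim:
    """Mutable driver around a :class:`PolymerSystem`: lets a protocol change
    bridges, affinities and walls between Langevin blocks."""

    def __init__(self, system: PolymerSystem, seed: int):
        self.system = system
        self._codes = np.ascontiguousarray(system.typing.codes)
        self._eps_mat = system.potential.eps_matrix()
        self._forces = np.zeros_like(system.coords)
        self._vel = None  # Maxwell-Boltzmann initialized on first block
        self._tether_idx = np.zeros(0, dtype=np.int64)
        self._tether_pts = np.zeros((0, 3))
        self._tether_k = 0.0
        self.set_bridges(system.bridges)
        self._init_walls()
        self.seed = int(seed) % (2**31)
        _seed_numba(self.seed)

    def _init_walls(self) -> None:
        conf = self.system.confinement
        n = self.system.n_monomers
        a = self.system.potential.a
        self._sphere_R = self._sphere_k = 0.0
        self._cyl_r = self._cyl_h = self._cyl_k = 0.0
        if conf.shape == "sphere":
            self._sphere_R = conf.sphere_radius(n, a)
            self._sphere_k = conf.wall_k
        elif conf.shape == "cylinder":
            self._cyl_r, self._cyl_h = conf.cylinder_radius_height(n, a)
            self._cyl_k = conf.wall_k
            if conf.tethered:
                self.set_tethers(
                    np.array([0, n - 1]),
                    np.array([[0.0, 0.0, -self._cyl_h / 2], [0.0, 0.0, self._cyl_h / 2]]),
                    k=conf.wall_k,
                )

    def set_bridges(self, bridges) -> None:
        bridges = np.asarray(bridges, dtype=np.int64).reshape(-1, 2)
        self.system.bridges = bridges
        self._bonds = np.ascontiguousarray(
            np.vstack([self.system.chain_bonds(), bridges])
        )

    def set_eps(self, eps: dict) -> None:
        pot = self.system.potential
        self.system.potential = PotentialParams(pot.e_repel, pot.a, dict(eps))
        self._eps_mat = self.system.potential.eps_matrix()

    def set_sphere(self, R: float, k: float) -> None:
        self._sphere_R, self._sphere_k = float(R), float(k)

    def set_cylinder(self, r: float, h: float, k: float) -> None:
        self._cyl_r, self._cyl_h, self._cyl_k = float(r), float(h), float(k)

    def set_tethers(self, idx, points, k: float) -> None:
        self._tether_idx = np.ascontiguousarray(idx, dtype=np.int64)
        self._tether_pts = np.ascontiguousarray(points, dtype=np.float64).reshape(-1, 3)
        self._tether_k = float(k)

    def clear_tethers(self) -> None:
        self._tether_idx = np.zeros(0, dtype=np.int64)
        self._tether_pts = np.zeros((0, 3))
        self._tether_k = 0.0

    def run_block(self, n_steps: int) -> None:
        sys_ = self.system
        if self._vel is None:
            _seed_numba(self.seed)
            self._vel = np.random.default_rng(self.seed).standard_normal(
                sys_.coords.shape
            )
        _langevin_block(
            sys_.coords, self._codes, self._eps_mat, sys_.potential.e_repel,
            sys_.potential.a, sys_.potential.a_star, self._bonds,
            sys_.bond_k, sys_.bond_r0,
            self._sphere_R, self._sphere_k, self._cyl_r, self._cyl_h, self._cyl_k,
            self._tether_idx, self._tether_pts, self._tether_k,
            n_steps, sys_.dt, sys_.gamma, self._vel, self._forces,
        )
        sys_.time += n_steps
        if not np.all(np.isfinite(sys_.coords)):
            raise RuntimeError(
                f"non-finite coordinates after {sys_.time} polymer steps "
                "(timestep too large or overlapping bridges?)"
            )


def init_conformation(
    n_monomers: int,
    confinement: ConfinementSpec,
    seed: int,
    a: float = 1.0,
) -> np.ndarray:
    """Random-walk initial conformation with unit bonds folded into the
    container (steps proposing positions outside the walls are redrawn, with a
    bias toward the center after repeated failures)."""
    if confinement.shape != "none" and confinement.rho_chr >= 1.0:
        raise ValueError("container too small: rho_chr must be < 1")
    rng = np.random.default_rng(seed)
    if confinement.shape == "sphere":
        R = confinement.sphere_radius(n_monomers, a)
        inside = lambda p: np.dot(p, p) <= (0.95 * R) ** 2
        start = np.zeros(3)
    elif confinement.shape == "cylinder":
        r, h = confinement.cylinder_radius_height(n_monomers, a)
        inside = lambda p: (p[0] ** 2 + p[1] ** 2 <= (0.95 * r) ** 2) and (abs(p[2]) <= 0.48 * h)
        start = np.array([0.0, 0.0, -0.45 * h])
    else:
        inside = lambda p: True
        start = np.zeros(3)
    coords = np.empty((n_monomers, 3))
    coords[0] = start
    if confinement.shape == "cylinder":
        # march along the axis so the chain spans the cylinder end to end
        drift = np.array([0.0, 0.0, 0.9 * h / max(n_monomers - 1, 1)])
    else:
        drift = np.zeros(3)
    for i in range(1, n_monomers):
        for _ in range(200):
            step = rng.standard_normal(3)
            step = step / np.linalg.norm(step) * a
            cand = coords[i - 1] + step + drift
            if inside(cand):
                break
        else:
            cand = coords[i - 1] + (start - coords[i - 1]) * 0.1
        coords[i] = cand
    return coords


def run_polymer(
    system: PolymerSystem,
    extruder_source=None,
    n_blocks: int = 100,
    steps_per_block: int = 540,
    seed: int = 0,
    sample_every: int = 1,
) -> Trajectory3D:
    """Alternate Langevin blocks with extruder-bridge updates.

    ``extruder_source`` may be an :class:`~chromodyn.extrusion.ExtrusionTrajectory`
    (frames consumed one per block; lattice site i = monomer i), a static list
    of (left, right) loops, or None.
    """
    from .extrusion import ExtrusionTrajectory

    frames_1d = None
    if isinstance(extruder_source, ExtrusionTrajectory):
        frames_1d = extruder_source.frames
        if extruder_source.config.L != system.n_monomers:
            raise ValueError(
                f"lattice length {extruder_source.config.L} != polymer length {system.n_monomers}"
            )
        if len(frames_1d) < n_blocks:
            raise ValueError("extrusion trajectory shorter than requested block count")
    elif extruder_source is not None:
        system.bridges = np.asarray(list(extruder_source), dtype=np.int64).reshape(-1, 2)

    sim = PolymerSim(system, seed=seed)
    out_frames, out_times = [], []
    for b in range(n_blocks):
        if frames_1d is not None:
            f = frames_1d[b]
            sim.set_bridges(np.column_stack([f["left"], f["right"]]))
        sim.run_block(steps_per_block)
        if (b + 1) % sample_every == 0:
            out_frames.append(system.coords.copy())
            out_times.append(system.time)
    return Trajectory3D(
        np.array(out_frames),
        np.array(out_times),
        system.typing,
        meta={"seed": seed, "steps_per_block": steps_per_block, "dt": system.dt, "gamma": system.gamma},
    )


def summarize_conformation(trajectory: Trajectory3D, region=None, confinement: ConfinementSpec | None = None, a: float = 1.0, tol: float = 0.5) -> dict:
    """Per-frame radius of gyration of ``region`` (slice or index array), plus
    wall-violation counts and an inside-container density check."""
    if trajectory.n_frames == 0:
        raise ValueError("empty trajectory")
    if region is None:
        region = slice(None)
    sub = trajectory.frames[:, region, :]
    if sub.shape[1] == 0:
        raise ValueError("empty region")
    com = sub.mean(axis=1, keepdims=True)
    rg = np.sqrt(((sub - com) ** 2).sum(axis=2).mean(axis=1))
    out = {"rg": rg}
    if confinement is not None and confinement.shape != "none":
        pos = trajectory.frames
        n = pos.shape[1]
        if confinement.shape == "sphere":
            R = confinement.sphere_radius(n, a)
            rad = np.linalg.norm(pos, axis=2)
            out["wall_violations"] = int(np.sum(rad > R + tol))
            vol = 4.0 / 3.0 * np.pi * R**3
        else:
            r, h = confinement.cylinder_radius_height(n, a)
            rad = np.linalg.norm(pos[:, :, :2], axis=2)
            out["wall_violations"] = int(np.sum((rad > r + tol) | (np.abs(pos[:, :, 2]) > h / 2 + tol)))
            vol = np.pi * r**2 * h
        mono_vol = 4.0 / 3.0 * np.pi * (a / 2.0) ** 3
        out["density"] = n * mono_vol / vol
    return out
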