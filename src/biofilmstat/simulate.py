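"""Agent-based mechanical model of early biofilm microcolony growth.

Cells are growing, dividing rod-shaped particles (spherocylinders) on a flat
substrate at z = 0. Their positional and orientational dynamics are
overdamped: velocity is force over drag, with drag anisotropic between motion
along and transverse to the cell axis (the extracellular matrix polymer
network suppresses transverse motion), and rotational drag scaling with the
cube of cell length. Cells interact through

* short-range steric repulsion — a Hertzian-type force of magnitude
  ``k_rep * (r_rep - delta)**1.5`` acting when the surface separation delta
  falls below the repulsion range ``r_rep`` (the range models the soft matrix
  envelope around each cell, so the force already acts at small positive
  separations);
* matrix-protein mediated cell–cell attraction — a pull of magnitude
  ``f_att * (1 - (delta - r_rep)/r_att)`` in the shell
  ``r_rep <= delta < r_rep + r_att``, saturating at ``f_att`` for
  ``delta < r_rep`` so the total pair force is continuous and a mechanical
  equilibrium separation exists where adhesion balances repulsion;
* cell–surface interaction applied per cell endpoint: Hertzian repulsion from
  the substrate plus a short-range surface attraction of the same saturating
  form, anchoring the colony at a resting height slightly inside contact.

Both force laws are exact negative gradients of piecewise-smooth pair
potentials, which the test suite verifies by finite differences. Cells
elongate exponentially at rate ``growth_rate`` and divide into two end-to-end
daughters when they exceed a per-cell division threshold drawn from a
lognormal around ``division_length``.

Randomness (founder orientation, division thresholds, division tilts) comes
from a single seeded ``numpy.random.Generator``; draws are consumed in a
fixed documented order, so a run is bit-reproducible given (params, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy.spatial import cKDTree

from .cells import BiofilmSample, SampleMetadata
from .geometry import pair_separation

__all__ = ["SimParams", "SimState", "pair_interaction", "surface_interaction", "step", "grow_and_divide", "run"]


@dataclass(frozen=True)
class SimParams:
    """Full parameter set of the mechanical model.

    The four scanned parameters are ``division_length``, ``repulsion_range``,
    ``attraction_range`` and ``attraction_strength``; the remaining values are
    package defaults chosen to give a stable, surface-attached colony at desk
    scale (they are not a published calibration).
    """

    # scanned
    division_length: float = 3.0  # um, mean pole-to-pole length at division
    repulsion_range: float = 0.2  # um
    attraction_range: float = 0.4  # um
    attraction_strength: float = 1.0  # force units
    # fixed mechanics
    repulsion_stiffness: float = 100.0  # force / um^1.5
    width: float = 0.8  # um
    growth_rate: float = math.log(2.0) / 0.5  # 1/h  (30-min doubling)
    surface_attraction: float = 2.0  # force units
    surface_range: float = 0.2  # um
    drag_parallel: float = 1.0  # force * h / um^2 (per unit length)
    friction_anisotropy: float = 5.0  # zeta_perp / zeta_par >= 1
    rotational_drag: float = 5.0  # force * h / um^4 (per length^3)
    # integration and stochasticity
    dt: float = 0.01  # h
    division_noise: float = 0.1  # lognormal sigma on the division threshold
    orientation_noise: float = 0.05  # rad tilt at division
    n_target: int = 2000
    seed: int = 0
    max_steps: int = 200_000

    def __post_init__(self) -> None:
        if self.division_length <= self.width:
            raise ValueError("division_length must exceed cell width")
        if self.friction_anisotropy < 1.0:
            raise ValueError("friction anisotropy zeta_perp/zeta_par must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in ("repulsion_range", "attraction_range", "attraction_strength",
                     "repulsion_stiffness", "surface_attraction", "surface_range"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict[str, Any]:
        from dataclasses import asdict

        return asdict(self)


@dataclass
class SimState:
    """Mutable simulation state: per-cell arrays plus time and RNG."""

    positions: np.ndarray  # (n, 3)
    orientations: np.ndarray  # (n, 3) unit directors
    lengths: np.ndarray  # (n,)
    thresholds: np.ndarray  # (n,) per-cell division lengths
    time: float
    rng: np.random.Generator
    next_id: int
    ids: np.ndarray

    @property
    def n(self) -> int:
        return len(self.lengths)


def _founder_state(params: SimParams) -> SimState:
    rng = np.random.default_rng(params.seed)
    theta = rng.uniform(0.0, 2.0 * np.pi)  # draw 1: founder in-plane orientation
    ori = np.array([[np.cos(theta), np.sin(theta), 0.0]])
    length = max(params.width, params.division_length / 2.0)
    thr = params.division_length * math.exp(
        params.division_noise * rng.standard_normal()
    )  # draw 2: founder division threshold
    return SimState(
        positions=np.array([[0.0, 0.0, params.width / 2.0]]),
        orientations=ori,
        lengths=np.array([length]),
        thresholds=np.array([thr]),
        time=0.0,
        rng=rng,
        next_id=1,
        ids=np.array([0]),
    )


def _candidate_pairs(state: SimState, params: SimParams) -> np.ndarray:
    """Centroid pairs possibly within interaction reach (spatial-index cull)."""
    reach = float(state.lengths.max()) + params.repulsion_range + params.attraction_range
    tree = cKDTree(state.positions)
    return tree.query_pairs(reach, output_type="ndarray")


def _pair_force_magnitude(delta: np.ndarray, params: SimParams) -> np.ndarray:
    """Signed force along the contact normal on cell A (positive = repulsion).

    Repulsion: ``k_rep * (r_rep - delta)**1.5`` for delta < r_rep. Attraction:
    ``-f_att * (1 - (delta - r_rep)/r_att)`` in the shell, saturated at
    ``-f_att`` below r_rep; the sum is continuous in delta and balances at an
    equilibrium separation ``r_rep - (f_att/k_rep)**(2/3)``.
    """
    r_rep, r_att = params.repulsion_range, params.attraction_range
    mag = np.zeros_like(delta)
    rep = delta < r_rep
    mag[rep] = params.repulsion_stiffness * np.power(r_rep - delta[rep], 1.5)
    if r_att > 0 and params.attraction_strength > 0:
        shell = delta < r_rep + r_att
        frac = np.clip((delta - r_rep) / r_att, 0.0, 1.0)
        mag[shell] -= params.attraction_strength * (1.0 - frac[shell])
    return mag


def pair_interaction(
    pos_a: np.ndarray,
    ori_a: np.ndarray,
    len_a: float,
    pos_b: np.ndarray,
    ori_b: np.ndarray,
    len_b: float,
    params: SimParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Force and torque on a single cell pair: ``(F_A, tau_A, F_B, tau_B)``.

    Forces act along the contact normal at the contact points, so the pair is
    momentum-free (F_A = -F_B) but exerts torques about each centroid.
    """
    delta, normal, s, t, _ = pair_separation(
        pos_a[None], ori_a[None], np.array([len_a]),
        pos_b[None], ori_b[None], np.array([len_b]),
        params.width,
    )
    mag = _pair_force_magnitude(delta, params)
    f_a = (mag[:, None] * normal)[0]
    tau_a = np.cross(s[0] * ori_a, f_a)
    tau_b = np.cross(t[0] * ori_b, -f_a)
    return f_a, tau_a, -f_a, tau_b


def pair_potential(delta: float, params: SimParams) -> float:
    """Pair potential whose negative delta-gradient is the pair force law.

    Continuous and piecewise C^1; zero beyond ``r_rep + r_att``.
    """
    r_rep, r_att = params.repulsion_range, params.attraction_range
    f_att = params.attraction_strength
    u = 0.0
    if delta < r_rep:
        u += 0.4 * params.repulsion_stiffness * (r_rep - delta) ** 2.5
        if r_att > 0 and f_att > 0:
            u += f_att * (delta - r_rep) - 0.5 * f_att * r_att
    elif r_att > 0 and f_att > 0 and delta < r_rep + r_att:
        u += -0.5 * f_att * r_att * (1.0 - (delta - r_rep) / r_att) ** 2
    return u


def _surface_force_z(h: np.ndarray, params: SimParams) -> np.ndarray:
    """Vertical force on an endpoint sphere at height h (positive = upward).

    Hertzian push-off below contact (h < w/2) plus surface attraction of
    magnitude ``f_surf * (1 - (h - w/2)/r_surf)`` in the shell, saturated at
    ``f_surf`` below contact; continuous, with resting height
    ``w/2 - (f_surf/k_rep)**(2/3)`` for a horizontal cell.
    """
    r0 = params.width / 2.0
    fz = np.zeros_like(h)
    below = h < r0
    fz[below] = params.repulsion_stiffness * np.power(r0 - h[below], 1.5)
    if params.surface_range > 0 and params.surface_attraction > 0:
        shell = h < r0 + params.surface_range
        frac = np.clip((h - r0) / params.surface_range, 0.0, 1.0)
        fz[shell] -= params.surface_attraction * (1.0 - frac[shell])
    return fz


def surface_potential(h: float, params: SimParams) -> float:
    """Endpoint–substrate potential matching :func:`_surface_force_z`."""
    r0 = params.width / 2.0
    r_s = params.surface_range
    f_s = params.surface_attraction
    u = 0.0
    if h < r0:
        u += 0.4 * params.repulsion_stiffness * (r0 - h) ** 2.5
        if r_s > 0 and f_s > 0:
            u += f_s * (h - r0) - 0.5 * f_s * r_s
    elif r_s > 0 and f_s > 0 and h < r0 + r_s:
        u += -0.5 * f_s * r_s * (1.0 - (h - r0) / r_s) ** 2
    return u


def surface_interaction(
    pos: np.ndarray, ori: np.ndarray, length: float, params: SimParams
) -> tuple[np.ndarray, np.ndarray]:
    """Force and torque on one cell from the substrate (both endpoints)."""
    e = max(length - params.width, 0.0) / 2.0
    force = np.zeros(3)
    torque = np.zeros(3)
    for sgn in (1.0, -1.0):
        arm = sgn * e * ori
        h = np.array([pos[2] + arm[2]])
        fz = _surface_force_z(h, params)[0]
        f = np.array([0.0, 0.0, fz])
        force += f
        torque += np.cross(arm, f)
    return force, torque


def _net_forces(state: SimState, params: SimParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Total force and torque on every cell; also returns the net pair force."""
    n = state.n
    force = np.zeros((n, 3))
    torque = np.zeros((n, 3))

    if n > 1:
        pairs = _candidate_pairs(state, params)
        if len(pairs):
            i, j = pairs[:, 0], pairs[:, 1]
            delta, normal, s, t, _ = pair_separation(
                state.positions[i], state.orientations[i], state.lengths[i],
                state.positions[j], state.orientations[j], state.lengths[j],
                params.width,
            )
            mag = _pair_force_magnitude(delta, params)
            active = mag != 0.0
            if active.any():
                i, j = i[active], j[active]
                f = mag[active, None] * normal[active]
                np.add.at(force, i, f)
                np.add.at(force, j, -f)
                tau_i = np.cross(s[active, None] * state.orientations[i], f)
                tau_j = np.cross(t[active, None] * state.orientations[j], -f)
                np.add.at(torque, i, tau_i)
                np.add.at(torque, j, tau_j)
    net_pair = force.sum(axis=0).copy()

    # substrate forces per endpoint
    e = np.maximum(state.lengths - params.width, 0.0)[:, None] / 2.0
    for sgn in (1.0, -1.0):
        arm = sgn * e * state.orientations
        h = state.positions[:, 2] + arm[:, 2]
        fz = _surface_force_z(h, params)
        f = np.zeros((n, 3))
        f[:, 2] = fz
        force += f
        torque += np.cross(arm, f)
    return force, torque, net_pair


def mobility(
    force: np.ndarray,
    torque: np.ndarray,
    orientations: np.ndarray,
    lengths: np.ndarray,
    params: SimParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Overdamped velocities from forces: anisotropic drag along/across the axis.

    Translational drag is ``zeta * L`` with the transverse channel a factor
    ``zeta_perp/zeta_par`` stiffer; rotational drag is ``zeta_rot * L^3``, and
    only the torque component transverse to the axis reorients the rod.
    """
    zeta_par = params.drag_parallel * lengths
    zeta_perp = params.friction_anisotropy * zeta_par
    f_par = np.einsum("ij,ij->i", force, orientations)[:, None] * orientations
    f_perp = force - f_par
    vel = f_par / zeta_par[:, None] + f_perp / zeta_perp[:, None]
    omega = torque / (params.rotational_drag * lengths[:, None] ** 3)
    omega = omega - np.einsum("ij,ij->i", omega, orientations)[:, None] * orientations
    return vel, omega


def step(state: SimState, params: SimParams) -> SimState:
    """One overdamped explicit-Euler update (in place; returns the state).

    Net force is split along/transverse to the cell axis and divided by the
    corresponding drag (``zeta * L``); torque drives rotation against
    ``zeta_rot * L^3``. A stability guard subdivides the timestep whenever the
    largest displacement would exceed a tenth of the cell width.
    """
    remaining = params.dt
    guard = params.width / 10.0
    while remaining > 1e-15:
        force, torque, _ = _net_forces(state, params)
        if not np.all(np.isfinite(force)):
            bad = int(state.ids[np.flatnonzero(~np.isfinite(force).all(axis=1))[0]])
            raise FloatingPointError(f"non-finite force on cell {bad}")
        ori = state.orientations
        vel, omega = mobility(force, torque, ori, state.lengths, params)

        speed = float(np.max(np.linalg.norm(vel, axis=1))) if state.n else 0.0
        dt_sub = remaining
        if speed * dt_sub > guard:
            dt_sub = guard / speed
        state.positions = state.positions + vel * dt_sub
        new_ori = ori + np.cross(omega, ori) * dt_sub
        state.orientations = new_ori / np.linalg.norm(new_ori, axis=1, keepdims=True)
        state.time += dt_sub
        remaining -= dt_sub
    return state


def _perturb_orientation(ori: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Small random tilt: add a transverse Gaussian kick and renormalize."""
    kick = sigma * rng.standard_normal(3)
    kick -= np.dot(kick, ori) * ori
    out = ori + kick
    return out / np.linalg.norm(out)


def grow_and_divide(state: SimState, params: SimParams) -> SimState:
    """Exponential elongation plus division into end-to-end daughters.

    Every cell's length is multiplied by ``exp(growth_rate * dt)``. A cell
    whose length reaches its division threshold splits into two daughters of
    half the mother's length, centred a quarter length either side of the
    mother centroid along its axis; each daughter gets a small random tilt
    and a freshly drawn division threshold.
    """
    state.lengths = state.lengths * math.exp(params.growth_rate * params.dt)
    dividing = np.flatnonzero(state.lengths >= state.thresholds)
    for idx in dividing:  # cell order fixes the RNG draw order
        mother_pos = state.positions[idx].copy()
        mother_ori = state.orientations[idx].copy()
        mother_len = float(state.lengths[idx])
        d_len = max(params.width, mother_len / 2.0)
        offsets = (mother_len / 4.0) * mother_ori
        # daughter A replaces the mother's slot (keeps its id); B is appended
        for slot, sgn in ((idx, 1.0), (None, -1.0)):
            pos = mother_pos + sgn * offsets
            pos[2] = max(pos[2], params.width / 2.0 * 1e-6)  # substrate handled by forces
            ori = _perturb_orientation(mother_ori, params.orientation_noise, state.rng)
            thr = params.division_length * math.exp(params.division_noise * state.rng.standard_normal())
            if slot is not None:
                state.positions[slot] = pos
                state.orientations[slot] = ori
                state.lengths[slot] = d_len
                state.thresholds[slot] = thr
            else:
                state.positions = np.vstack([state.positions, pos])
                state.orientations = np.vstack([state.orientations, ori])
                state.lengths = np.append(state.lengths, d_len)
                state.thresholds = np.append(state.thresholds, thr)
                state.ids = np.append(state.ids, state.next_id)
                state.next_id += 1
    return state


def _state_to_sample(state: SimState, params: SimParams) -> BiofilmSample:
    positions = state.positions.copy()
    positions[:, 2] = np.maximum(positions[:, 2], 0.0)
    meta = SampleMetadata(
        group="simulation",
        condition="",
        replicate=str(params.seed),
        provenance="simulation",
        params=params.to_dict(),
    )
    return BiofilmSample.from_arrays(
        positions=positions,
        orientations=state.orientations.copy(),
        lengths=np.maximum(state.lengths, params.width),
        widths=np.full(state.n, params.width),
        metadata=meta,
        ids=state.ids.copy(),
    )


def run(params: SimParams) -> BiofilmSample:
    """Grow a colony from one founder cell to ``n_target`` cells.

    Alternates the mechanical step and growth/division until the cell count
    reaches the target; raises ``RuntimeError`` if ``max_steps`` updates do
    not get there (parameter blow-up safeguard).
    """
    if params.n_target < 1:
        raise ValueError("n_target must be >= 1")
    state = _founder_state(params)
    if params.n_target == 1:
        return _state_to_sample(state, params)
    for _ in range(params.max_steps):
        step(state, params)
        grow_and_divide(state, params)
        if state.n >= params.n_target:
            return _state_to_sample(state, params)
    raise RuntimeError(f"simulation did not reach {params.n_target} cells in {params.max_steps} steps")


def with_params(params: SimParams, **kwargs: Any) -> SimParams:
    """Convenience: a copy of ``params`` with fields replaced."""
    return replace(params, **kwargs)
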