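"""Deterministic (ODE) and stochastic (Gillespie SSA) simulation.

The stochastic path is the direct method: exponential waiting times from the
total propensity, reaction choice proportional to individual propensities.
The jump process is recorded by piecewise-constant sampling on a uniform
grid.  A mid-run change of rate constants (the external-Pi switch
experiment) is handled exactly by rescaling the pending unit-exponential
waiting time at the switch instant, so a "switch" to identical constants
reproduces the unswitched trajectory bit for bit.

The deterministic path translates the network to dx/dt = S v(x) with
mass-action fluxes v and integrates with a stiff-capable SciPy solver.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from .crn import COPIES_PER_UM, CRNModel, ScalingFactors

__all__ = [
    "Trajectory",
    "PerturbationSchedule",
    "ode_rhs",
    "simulate_ode",
    "steady_state",
    "simulate_ssa",
    "run_with_perturbation",
    "write_trajectory",
]


@dataclass
class Trajectory:
    """Time grid x state matrix from one simulation run.

    ``states`` holds integer copy numbers for SSA runs and concentrations
    (uM) for ODE runs; rows follow ``times``, columns follow ``species``.
    """

    times: np.ndarray
    states: np.ndarray
    species: list
    kind: str  # "ssa" | "ode"
    model_id: str = ""
    seed: int | None = None
    condition: ScalingFactors | None = None
    grid_dt: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != self.states.shape[0]:
            raise ValueError("times and states row count disagree")
        if np.any(np.diff(self.times) <= 0) and len(self.times) > 1:
            raise ValueError("times must be strictly increasing")

    def get(self, species: str) -> np.ndarray:
        return self.states[:, self.species.index(species)]


@dataclass(frozen=True)
class PerturbationSchedule:
    """A single step change of fc at ``t_switch`` seconds."""

    t_switch: float
    fc_before: float
    fc_after: float

    def __post_init__(self):
        if self.t_switch <= 0:
            raise ValueError("t_switch must be > 0")


# -- deterministic ---------------------------------------------------------

def ode_rhs(model: CRNModel):
    """Return f(t, x) computing dx/dt (uM/s) for concentration vector x.

    Mass-action fluxes: k, k[A], k[A][B] or k[A]^2 by reaction order; the
    derivative is the stoichiometric matrix times the flux vector, so every
    conserved sum has derivative identically zero.
    """
    S = model.stoichiometry_matrix().astype(float)
    n_rxn = len(model.reactions)
    ks = np.array([r.rate_constant for r in model.reactions])
    # reactant index layout: ia, ib = -1 when absent; homo flag for 2A
    ia = np.full(n_rxn, -1, dtype=np.int64)
    ib = np.full(n_rxn, -1, dtype=np.int64)
    for j, rxn in enumerate(model.reactions):
        items = list(rxn.reactants.items())
        if rxn.order >= 1:
            ia[j] = model.index(items[0][0])
        if rxn.order == 2:
            if len(items) == 1:
                ib[j] = ia[j]
            else:
                ib[j] = model.index(items[1][0])

    def rhs(t, x):
        v = ks.copy()
        mask1 = ia >= 0
        v[mask1] *= x[ia[mask1]]
        mask2 = ib >= 0
        v[mask2] *= x[ib[mask2]]
        return S @ v

    return rhs


def simulate_ode(
    model: CRNModel,
    initial: np.ndarray | None = None,
    t_end: float = 16200.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    grid_dt: float = 1.0,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the deterministic model on a uniform grid.

    ``initial`` is a concentration vector in uM (defaults to the model's
    initial concentrations).  ``t_end = 0`` returns just the initial state.
    """
    x0 = (
        model.initial_concentrations()
        if initial is None
        else np.asarray(initial, dtype=float)
    )
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    if t_end == 0:
        return Trajectory(
            np.array([0.0]), x0[None, :].copy(), model.species_names,
            "ode", model.model_id, grid_dt=grid_dt,
        )
    times = np.arange(0.0, t_end + 0.5 * grid_dt, grid_dt)
    if times[-1] > t_end:
        times = times[:-1]
    if times[-1] < t_end:
        times = np.append(times, t_end)
    sol = solve_ivp(
        ode_rhs(model), (0.0, t_end), x0, method=method,
        t_eval=times, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"ODE integration failed at t={sol.t[-1] if len(sol.t) else 0.0}: "
            f"{sol.message}"
        )
    return Trajectory(
        sol.t, sol.y.T.copy(), model.species_names, "ode",
        model.model_id, grid_dt=grid_dt,
    )


def steady_state(
    model: CRNModel,
    t_probe: float = 16200.0,
    tol: float = 1e-4,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Deterministic state (uM) at ``t_probe`` seconds.

    Emits a warning if the largest |dx/dt| component at the probe time
    exceeds *tol* (equilibrium not yet reached).
    """
    x0 = model.initial_concentrations()
    sol = solve_ivp(
        ode_rhs(model), (0.0, t_probe), x0, method="LSODA",
        rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    x = sol.y[:, -1]
    resid = float(np.max(np.abs(ode_rhs(model)(t_probe, x))))
    if resid > tol:
        warnings.warn(
            f"{model.model_id}: |dx/dt| = {resid:.3g} > {tol:.3g} at "
            f"t = {t_probe} s; equilibrium may not be reached",
            stacklevel=2,
        )
    return x


# -- stochastic ------------------------------------------------------------

def _ssa_arrays(model: CRNModel):
    """Stochastic propensity constants plus index/update arrays."""
    scale = COPIES_PER_UM * model.volume
    n_rxn = len(model.reactions)
    c = np.zeros(n_rxn)
    ia = np.full(n_rxn, -1, dtype=np.int64)
    ib = np.full(n_rxn, -1, dtype=np.int64)
    homo = np.zeros(n_rxn, dtype=np.bool_)
    for j, rxn in enumerate(model.reactions):
        k = rxn.rate_constant
        items = list(rxn.reactants.items())
        if rxn.order == 0:
            c[j] = k * scale
        elif rxn.order == 1:
            c[j] = k
            ia[j] = model.index(items[0][0])
        else:
            if len(items) == 1:  # 2A
                c[j] = 2.0 * k / scale
                ia[j] = model.index(items[0][0])
                homo[j] = True
            else:
                c[j] = k / scale
                ia[j] = model.index(items[0][0])
                ib[j] = model.index(items[1][0])
    S = model.stoichiometry_matrix()  # species x reactions
    update = S.T.copy()  # reactions x species
    return c, ia, ib, homo, update


@njit(cache=True)
def _ssa_core(x0, c1, c2, t_switch, ia, ib, homo, update, grid, seed):
    np.random.seed(seed)
    n_rxn = c1.shape[0]
    n_sp = x0.shape[0]
    n_grid = grid.shape[0]
    out = np.zeros((n_grid, n_sp), dtype=np.int64)
    x = x0.copy()
    a = np.zeros(n_rxn)
    t = grid[0]
    gi = 0
    switched = t >= t_switch
    c = c2 if switched else c1

    def _props(x, c, a):
        a0 = 0.0
        for j in range(n_rxn):
            if ia[j] < 0:
                a[j] = c[j]
            elif homo[j]:
                a[j] = c[j] * x[ia[j]] * (x[ia[j]] - 1) * 0.5
            elif ib[j] < 0:
                a[j] = c[j] * x[ia[j]]
            else:
                a[j] = c[j] * x[ia[j]] * x[ib[j]]
            a0 += a[j]
        return a0

    a0 = _props(x, c, a)
    while gi < n_grid:
        if a0 <= 0.0:
            t_next = np.inf
        else:
            t_next = t + np.random.exponential(1.0 / a0)
        if not switched and t_next >= t_switch:
            # exact rescaling of the pending unit-exponential across the switch
            a0_old = a0
            residual = (t_next - t_switch) * a0_old if a0_old > 0.0 else 0.0
            switched = True
            c = c2
            a0 = _props(x, c, a)
            t = t_switch
            if a0 > 0.0:
                if a0_old <= 0.0:
                    residual = np.random.exponential(1.0)
                t_next = t + residual / a0
            else:
                t_next = np.inf
        # record all grid points strictly before the next jump
        while gi < n_grid and grid[gi] < t_next:
            for i in range(n_sp):
                out[gi, i] = x[i]
            gi += 1
        if gi >= n_grid:
            break
        if t_next == np.inf:
            continue  # unreachable: grid exhausted above when absorbing
        # choose reaction
        r = np.random.random() * a0
        acc = 0.0
        j = n_rxn - 1  # fallback guards float roundoff in the partial sums
        for jj in range(n_rxn):
            acc += a[jj]
            if r < acc:
                j = jj
                break
        for i in range(n_sp):
            x[i] += update[j, i]
        t = t_next
        a0 = _props(x, c, a)
    return out


def simulate_ssa(
    model: CRNModel,
    initial_counts: np.ndarray | None = None,
    t_end: float = 1000.0,
    seed: int = 0,
    grid_dt: float = 1.0,
    condition: ScalingFactors | None = None,
    _model_after: CRNModel | None = None,
    _t_switch: float = np.inf,
) -> Trajectory:
    """Exact SSA run recorded on a uniform grid of spacing ``grid_dt``.

    The recorded value at each grid time is the state at the latest jump at
    or before that time.  If all propensities vanish the remaining grid is
    padded with the absorbing state.  Identical (model, initial, seed, grid)
    give identical trajectories.
    """
    x0 = (
        model.initial_counts()
        if initial_counts is None
        else np.asarray(initial_counts, dtype=np.int64)
    )
    if np.any(x0 < 0):
        raise ValueError("initial counts must be non-negative")
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    grid = np.arange(0.0, t_end + 0.5 * grid_dt, grid_dt)
    if grid[-1] > t_end + 1e-12:
        grid = grid[:-1]
    c1, ia, ib, homo, update = _ssa_arrays(model)
    if _model_after is not None:
        c2, ia2, ib2, homo2, _ = _ssa_arrays(_model_after)
        if not (
            np.array_equal(ia, ia2)
            and np.array_equal(ib, ib2)
            and np.array_equal(homo, homo2)
        ):
            raise ValueError("switch models must share one reaction structure")
    else:
        c2 = c1
    states = _ssa_core(
        x0, c1, c2, float(_t_switch), ia, ib, homo, update, grid,
        np.int64(seed),
    )
    return Trajectory(
        grid, states, model.species_names, "ssa", model.model_id,
        seed=seed, condition=condition, grid_dt=grid_dt,
    )


def run_with_perturbation(
    model: CRNModel,
    schedule: PerturbationSchedule,
    bf: float = 1.0,
    uf: float = 1.0,
    t_end: float = 14000.0,
    seed: int = 0,
    initial_counts: np.ndarray | None = None,
    grid_dt: float = 1.0,
) -> Trajectory:
    """SSA run whose fc steps from ``fc_before`` to ``fc_after`` at t_switch.

    The state is continuous across the switch; only the fc-tagged rate
    constants change.  With ``fc_before == fc_after`` the trajectory is
    identical to an unperturbed run with the same seed.
    """
    from .crn import apply_scaling

    if not schedule.t_switch < t_end:
        raise ValueError("t_switch must lie inside (0, t_end)")
    before = apply_scaling(model, ScalingFactors(schedule.fc_before, bf, uf))
    after = apply_scaling(model, ScalingFactors(schedule.fc_after, bf, uf))
    traj = simulate_ssa(
        before,
        initial_counts=initial_counts,
        t_end=t_end,
        seed=seed,
        grid_dt=grid_dt,
        condition=ScalingFactors(schedule.fc_before, bf, uf),
        _model_after=after,
        _t_switch=schedule.t_switch,
    )
    return traj


# -- output ----------------------------------------------------------------

def write_trajectory(traj: Trajectory, csv_path, manifest_path=None) -> None:
    """CSV with header ``time,<species...>`` plus a JSON metadata sidecar."""
    import pandas as pd

    df = pd.DataFrame(traj.states, columns=traj.species)
    df.insert(0, "time", traj.times)
    df.to_csv(csv_path, index=False)
    if manifest_path is not None:
        cond = traj.condition
        meta = {
            "model_id": traj.model_id,
            "kind": traj.kind,
            "seed": traj.seed,
            "grid_dt": traj.grid_dt,
            "condition": None
            if cond is None
            else {"fc": cond.fc, "bf": cond.bf, "uf": cond.uf},
        }
        with open(manifest_path, "w") as fh:
            json.dump(meta, fh, indent=1)
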