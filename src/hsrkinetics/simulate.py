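"""Time integration of the heat shock response circuit.

Integrates the six-species ODE system under piecewise-constant protocols,
with packaged scenarios for each simulated experiment: sustained heat
shock with or without rapamycin, temperature sweeps, day-to-day
variability ensembles, Sis1 depletion, feedback deletion, and
pulse/recovery regimes. Also houses an independent fixed-step
Runge–Kutta reference integrator used as a numerical oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    BASELINE,
    HSP70_DFBL,
    RAPAMYCIN,
    SIS1_DEPLETION,
    SPECIES,
    Condition,
    DomainError,
    KineticParameters,
    ModelState,
    Protocol,
    apply_condition,
    effective_rates,
    hill_activation,
    logger,
    rhs_array,
    temperature_condition,
)

# Solver tolerances: rate constants span five orders of magnitude
# (k1=320 vs kd=0.0025), so the system is stiff and integrated with a
# stiff-capable adaptive method at tight tolerances. 1e-10/1e-12 keeps
# protocol-refinement differences below 1e-9 relative at negligible cost.
RTOL = 1e-10
ATOL = 1e-12
#: States may undershoot zero by at most this much (solver tolerance slack).
NEGATIVITY_TOL = 1e-9

#: Default mapping from heat shock temperature (°C) to folding-rate
#: multiplier. 39°C is the reference shock (multiplier 1); hotter shocks
#: slow folding further. Entries are a declared convention (the circuit
#: fixes only the monotone-decreasing direction) and are user-editable.
TEMPERATURE_TABLE: dict[float, float] = {
    35.0: 1.6,
    37.0: 1.3,
    39.0: 1.0,
    41.0: 0.8,
}

#: Folding-rate multiplier representing recovery at permissive
#: temperature in pulse/recovery protocols (folding faster than at 39°C).
RECOVERY_KDUP_FACTOR = 1.5

SCENARIO_NAMES = (
    "baseline_hs",
    "rapamycin_hs",
    "temperature_sweep",
    "variability_ensemble",
    "sis1_depletion",
    "hsp70_dFBL",
    "pulse_recovery",
)


class IntegrationError(RuntimeError):
    """The ODE solver failed or produced an invalid trajectory."""


# ---------------------------------------------------------------------------
# Trajectories and ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trajectory:
    """Solution of the model on a time grid.

    ``states`` is an (n_times, 6) array in the order of
    :data:`~hsrkinetics.model.SPECIES`; ``condition_names`` records which
    condition was active at each output time; ``metadata`` carries the
    resolved configuration of the run that produced it.
    """

    times: np.ndarray
    states: np.ndarray
    condition_names: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        states = np.asarray(self.states, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)
        if states.shape != (times.size, len(SPECIES)):
            raise DomainError(
                f"states shape {states.shape} does not match "
                f"({times.size}, {len(SPECIES)})"
            )
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise DomainError("times must be strictly increasing")

    def species(self, name: str) -> np.ndarray:
        if name not in SPECIES:
            raise DomainError(f"unknown species {name!r}; valid: {SPECIES}")
        return self.states[:, SPECIES.index(name)]

    @property
    def yfp(self) -> np.ndarray:
        return self.species("yfp")

    @property
    def hsf(self) -> np.ndarray:
        return self.species("hsf")

    def state_at(self, index: int) -> ModelState:
        return ModelState.from_array(self.states[index])

    def to_frame(self, scenario: str = "", replicate: int = 0) -> pd.DataFrame:
        """Tidy long-format table (scenario, replicate, time_min, species, value)."""
        frames = []
        for j, name in enumerate(SPECIES):
            frames.append(
                pd.DataFrame(
                    {
                        "scenario": scenario,
                        "replicate": replicate,
                        "time_min": self.times,
                        "species": name,
                        "value": self.states[:, j],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class Ensemble:
    """Trajectories generated under random k_up multipliers from one seed."""

    trajectories: tuple[Trajectory, ...]
    draws: np.ndarray
    seed: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        draws = np.asarray(self.draws, dtype=float)
        object.__setattr__(self, "draws", draws)
        object.__setattr__(self, "trajectories", tuple(self.trajectories))
        if len(self.trajectories) != draws.size:
            raise DomainError("one draw per trajectory required")

    def __len__(self) -> int:
        return len(self.trajectories)

    def to_frame(self, scenario: str = "") -> pd.DataFrame:
        return pd.concat(
            [t.to_frame(scenario=scenario, replicate=i) for i, t in enumerate(self.trajectories)],
            ignore_index=True,
        )


def write_run(path_prefix, obj, scenario: str, config: dict) -> tuple[str, str]:
    """Write a trajectory/ensemble as tidy CSV plus a JSON sidecar with the
    resolved configuration. Returns (csv_path, sidecar_path)."""
    csv_path = f"{path_prefix}.csv"
    sidecar_path = f"{path_prefix}.json"
    frame = obj.to_frame(scenario=scenario)
    frame.to_csv(csv_path, index=False)
    with open(sidecar_path, "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return csv_path, sidecar_path


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def integrate(
    params: KineticParameters,
    init: ModelState,
    protocol: Protocol,
    output_times: np.ndarray,
) -> Trajectory:
    """Solve the circuit ODEs over a protocol.

    Integration restarts at every segment boundary with that segment's
    condition applied to ``params``. The solution is checked after the
    fact: total Hsf1 must be conserved to 1e-6 relative, the YFP reporter
    must be non-decreasing (it has no loss term), and no species may fall
    below ``-NEGATIVITY_TOL``. Tiny solver undershoots are clamped to 0.
    """
    output_times = np.atleast_1d(np.asarray(output_times, dtype=float))
    if output_times.size == 0:
        raise DomainError("output_times must be non-empty")
    if np.any(np.diff(output_times) <= 0):
        raise DomainError("output_times must be strictly increasing")
    init.validate_nonnegative()
    t0, t1 = output_times[0], output_times[-1]
    if t0 < 0 or t1 > protocol.t_end:
        raise DomainError(
            f"output times [{t0}, {t1}] not covered by protocol span [0, {protocol.t_end}]"
        )

    out_states = np.empty((output_times.size, len(SPECIES)))
    written = np.zeros(output_times.size, dtype=bool)
    cond_names: list[str] = [""] * output_times.size

    y = init.as_array()
    for seg in protocol:
        seg_params = apply_condition(params, seg.condition)
        # Output points at the segment start take the incoming state (the
        # condition switches instantaneously; concentrations are continuous).
        at_start = np.flatnonzero((output_times == seg.t_start) & ~written)
        for i in at_start:
            out_states[i] = y
            cond_names[i] = seg.condition.name
            written[i] = True
        inside = np.flatnonzero(
            (output_times > seg.t_start) & (output_times <= seg.t_end) & ~written
        )
        t_eval = output_times[inside]
        # Always integrate to the segment end to carry the state forward.
        targets = np.unique(np.concatenate([t_eval, [seg.t_end]]))
        sol = solve_ivp(
            lambda t, yv: rhs_array(yv, seg_params),
            (seg.t_start, seg.t_end),
            y,
            method="LSODA",
            rtol=RTOL,
            atol=ATOL,
            t_eval=targets,
        )
        if not sol.success:
            raise IntegrationError(
                f"solver failed in segment [{seg.t_start}, {seg.t_end}] "
                f"(condition {seg.condition.name!r}): {sol.message}"
            )
        if not np.all(np.isfinite(sol.y)):
            raise IntegrationError(
                f"non-finite state in segment [{seg.t_start}, {seg.t_end}]"
            )
        produced = {t: sol.y[:, k] for k, t in enumerate(sol.t)}
        y = produced[seg.t_end]
        for i in inside:
            out_states[i] = produced[output_times[i]]
            cond_names[i] = seg.condition.name
            written[i] = True
        if seg.t_end >= t1 and written.all():
            break

    if not written.all():
        missing = output_times[~written]
        raise IntegrationError(f"internal error: output times not produced: {missing}")

    if np.min(out_states) < -NEGATIVITY_TOL:
        worst = float(np.min(out_states))
        raise IntegrationError(f"species fell below tolerance: min value {worst}")
    out_states = np.clip(out_states, 0.0, None)

    total_hsf0 = init.hsf + init.hsp_hsf
    total_hsf = out_states[:, SPECIES.index("hsf")] + out_states[:, SPECIES.index("hsp_hsf")]
    if total_hsf0 > 0:
        drift = np.max(np.abs(total_hsf - total_hsf0)) / total_hsf0
        if drift > 1e-6:
            raise IntegrationError(f"total Hsf1 drifted by {drift:.3e} relative (> 1e-6)")
    yfp = out_states[:, SPECIES.index("yfp")]
    if np.any(np.diff(yfp) < -1e-9):
        raise IntegrationError("YFP decreased along the trajectory")

    return Trajectory(
        times=output_times,
        states=out_states,
        condition_names=tuple(cond_names),
    )


def default_grid(t_end: float = 240.0, dt: float = 0.5) -> np.ndarray:
    return np.arange(0.0, t_end + dt / 2, dt)


# ---------------------------------------------------------------------------
# Independent fixed-step reference integrator (numerical oracle)
# ---------------------------------------------------------------------------

#: Default oracle step (min). The fastest local mode of the system is the
#: Hsp70·Hsf1 binding relaxation, rate ≈ k1·(hsp+hsf)+k2 ≈ 4e3 min⁻¹ at
#: the published initial state; the classical 4th-order scheme is stable
#: only for step·rate ≲ 2.785, requiring dt ≲ 7e-4 min. 5e-4 sits inside
#: the stability region with margin and converges at 4th order.
ORACLE_DT = 5e-4
_RK4_STABILITY_BOUND = 2.785


def _fastest_rate(y, p: KineticParameters) -> float:
    """Crude upper bound on the fastest local relaxation rate (min⁻¹)."""
    hsp, hsf, up = y[0], y[1], y[2]
    return max(
        p.k1 * (hsp + hsf) + p.k2,
        p.k3 * (hsp + up) + p.k4 + p.k5,
        p.k_dup,
    )


def fixed_step_reference(
    params: KineticParameters,
    init: ModelState,
    t_end: float,
    dt: float = ORACLE_DT,
    check_stability: bool = True,
) -> Trajectory:
    """Classical 4th-order fixed-step integration, written independently
    of :func:`~hsrkinetics.model.rhs_array` from the model equations.

    Serves as a numerical oracle for the adaptive solver. Raises
    :class:`IntegrationError` when the requested step lies outside the
    scheme's stability region for the initial state (for the published
    parameters any dt ≳ 7e-4 min is unstable and would silently produce
    a plausible-looking but wrong trajectory).
    """
    p = effective_rates(params)
    k_up, k_dup = p.k_up, p.k_dup
    k1, k2, k3, k4, k5 = p.k1, p.k2, p.k3, p.k4, p.k5
    beta, kd, n = p.beta, p.kd, p.n
    feedback = p.hsp_feedback_enabled
    kd_n = kd**n

    def deriv(y):
        hsp, hsf, up, chf, cup, yfp = y
        hf = max(hsf, 0.0)
        hill = beta * hf**n / (kd_n + hf**n)
        d_hsp = k2 * chf - k1 * hsp * hsf + (k4 + k5) * cup - k3 * hsp * up
        if feedback:
            d_hsp += hill
        return np.array(
            [
                d_hsp,
                k2 * chf - k1 * hsp * hsf,
                k_up - k_dup * up + k4 * cup - k3 * hsp * up,
                k1 * hsp * hsf - k2 * chf,
                k3 * hsp * up - (k4 + k5) * cup,
                hill,
            ]
        )

    y = init.as_array()
    if check_stability:
        rate = _fastest_rate(y, p)
        if dt * rate > _RK4_STABILITY_BOUND:
            raise IntegrationError(
                f"fixed-step oracle unstable: dt*rate = {dt * rate:.2f} exceeds the "
                f"4th-order stability bound {_RK4_STABILITY_BOUND} "
                f"(fastest local rate ≈ {rate:.0f} min⁻¹); use dt <= "
                f"{_RK4_STABILITY_BOUND / rate:.1e}"
            )
    n_steps = int(round(t_end / dt))
    times = [0.0]
    states = [y.copy()]
    t = 0.0
    for i in range(n_steps):
        s1 = deriv(y)
        s2 = deriv(y + 0.5 * dt * s1)
        s3 = deriv(y + 0.5 * dt * s2)
        s4 = deriv(y + dt * s3)
        y = y + (dt / 6.0) * (s1 + 2.0 * s2 + 2.0 * s3 + s4)
        t = (i + 1) * dt
        if not np.all(np.isfinite(y)):
            raise IntegrationError(f"fixed-step oracle diverged at t={t}")
    times.append(t_end)
    states.append(y)
    return Trajectory(
        times=np.array(times),
        states=np.array(states),
        condition_names=("baseline",) * 2,
        metadata={"method": "rk4_fixed_step", "dt": dt},
    )


# ---------------------------------------------------------------------------
# Scenario runners
# ---------------------------------------------------------------------------

def temperature_sweep(
    params: KineticParameters,
    scales,
    labels=None,
    init: ModelState | None = None,
    t_end: float = 240.0,
    output_times: np.ndarray | None = None,
) -> list[Trajectory]:
    """One heat-shock trajectory per folding-rate multiplier.

    ``scales`` multiply ``k_dup``; by convention 1.0 is the 39°C
    reference and smaller scales represent hotter shocks. ``labels``
    (e.g. temperatures in °C) are recorded in each trajectory's metadata.
    """
    scales = list(scales)
    if labels is None:
        labels = [None] * len(scales)
    labels = list(labels)
    if len(labels) != len(scales):
        raise DomainError(
            f"labels ({len(labels)}) and scales ({len(scales)}) must have the same length"
        )
    init = init or ModelState()
    if output_times is None:
        output_times = default_grid(t_end)
    out = []
    for scale, label in zip(scales, labels):
        cond = temperature_condition(scale)
        traj = integrate(params, init, Protocol.constant(cond, output_times[-1]), output_times)
        traj = replace(traj, metadata={"k_dup_scale": scale, "label": label})
        out.append(traj)
    return out


def variability_ensemble(
    params: KineticParameters,
    init: ModelState,
    protocol: Protocol,
    n: int,
    fraction: float = 0.2,
    seed: int = 0,
    output_times: np.ndarray | None = None,
) -> Ensemble:
    """Day-to-day variability: k_up varied uniformly by ±``fraction``.

    Each replicate draws one multiplier from [1−fraction, 1+fraction]
    applied to the translation source at t=0, modeling differences in the
    cells' metabolic state (and hence basal translation rate) between
    experiments. Deterministic for a given seed.
    """
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    if not (0 <= fraction < 1):
        raise DomainError(f"fraction must be in [0, 1), got {fraction}")
    if output_times is None:
        output_times = default_grid(protocol.t_end)
    rng = np.random.default_rng(seed)
    draws = rng.uniform(1.0 - fraction, 1.0 + fraction, size=n)
    trajectories = []
    for mult in draws:
        p_i = replace(params, k_up=params.k_up * mult)
        trajectories.append(integrate(p_i, init, protocol, output_times))
    return Ensemble(
        trajectories=tuple(trajectories),
        draws=draws,
        seed=seed,
        metadata={"fraction": fraction, "n": n},
    )


def pulse_recovery_protocol(
    pulse_min: float = 30.0,
    recovery_min: float = 120.0,
    n_pulses: int = 1,
    recovery_factor: float = RECOVERY_KDUP_FACTOR,
    final_recovery: bool = True,
) -> Protocol:
    """Alternating heat-shock and recovery segments.

    Heat segments run the baseline (shock) condition; recovery segments
    scale ``k_dup`` up by ``recovery_factor`` to represent return to
    permissive temperature. Extension plumbing — supports pulse/recovery
    regimes at the simulation level.
    """
    recovery = temperature_condition(recovery_factor)
    segs = []
    t = 0.0
    for i in range(n_pulses):
        segs.append((t, t + pulse_min, BASELINE))
        t += pulse_min
        if i < n_pulses - 1 or final_recovery:
            segs.append((t, t + recovery_min, recovery))
            t += recovery_min
    return Protocol.from_segments(segs)


def run_scenario(
    name: str,
    params: KineticParameters | None = None,
    init: ModelState | None = None,
    t_end: float = 240.0,
    output_times: np.ndarray | None = None,
    seed: int = 0,
    **overrides,
):
    """Dispatch a packaged scenario by name.

    Scenarios (all starting from the published initial state unless
    overridden):

    - ``baseline_hs`` — sustained 39°C heat shock, published parameters.
    - ``rapamycin_hs`` — heat shock with the translation source reduced
      40% (rapamycin pretreatment).
    - ``temperature_sweep`` — one run per folding-rate multiplier
      (override ``scales``/``labels``; defaults from TEMPERATURE_TABLE).
    - ``variability_ensemble`` — ±20% uniform k_up draws (override ``n``,
      ``fraction``); returns an :class:`Ensemble`.
    - ``sis1_depletion`` — Sis1 reduced to ``sis1_level`` (default 0.1,
      i.e. 10× the effective Hsp70·Hsf1 dissociation rate) at basal
      temperature (no folding-rate change).
    - ``hsp70_dFBL`` — heat shock with Hsf1-induced Hsp70 synthesis
      removed.
    - ``pulse_recovery`` — 30-min shock then recovery at permissive
      temperature (override ``pulse_min``, ``recovery_min``,
      ``n_pulses``, ``recovery_factor``).

    Returns a :class:`Trajectory` (or :class:`Ensemble`) whose
    ``metadata`` records the resolved configuration.
    """
    if name not in SCENARIO_NAMES:
        raise DomainError(f"unknown scenario {name!r}; valid: {SCENARIO_NAMES}")
    params = params or KineticParameters()
    init = init or ModelState()
    if output_times is None:
        output_times = default_grid(t_end)
    t_end = float(output_times[-1])
    config = {"scenario": name, "t_end": t_end, "seed": seed, **overrides}

    if name == "temperature_sweep":
        scales = overrides.pop("scales", None)
        labels = overrides.pop("labels", None)
        if scales is None:
            labels = sorted(TEMPERATURE_TABLE)
            scales = [TEMPERATURE_TABLE[k] for k in labels]
        return temperature_sweep(params, scales, labels, init, output_times=output_times)

    if name == "variability_ensemble":
        n = int(overrides.pop("n", 18))
        fraction = float(overrides.pop("fraction", 0.2))
        protocol = Protocol.constant(BASELINE, t_end)
        ens = variability_ensemble(
            params, init, protocol, n=n, fraction=fraction, seed=seed,
            output_times=output_times,
        )
        ens.metadata.update(config)
        return ens

    if name == "pulse_recovery":
        protocol = pulse_recovery_protocol(
            pulse_min=float(overrides.pop("pulse_min", 30.0)),
            recovery_min=float(overrides.pop("recovery_min", 120.0)),
            n_pulses=int(overrides.pop("n_pulses", 1)),
            recovery_factor=float(overrides.pop("recovery_factor", RECOVERY_KDUP_FACTOR)),
        )
        grid = output_times[output_times <= protocol.t_end]
        traj = integrate(params, init, protocol, grid)
        config["protocol"] = protocol.to_dict()
        return replace(traj, metadata=config)

    condition = {
        "baseline_hs": BASELINE,
        "rapamycin_hs": RAPAMYCIN,
        "hsp70_dFBL": HSP70_DFBL,
    }.get(name)
    if name == "sis1_depletion":
        level = float(overrides.pop("sis1_level", SIS1_DEPLETION.sis1_level))
        condition = Condition(name="sis1_depletion", sis1_level=level)
    if overrides:
        raise DomainError(f"unknown overrides for scenario {name!r}: {sorted(overrides)}")
    protocol = Protocol.constant(condition, t_end)
    traj = integrate(params, init, protocol, output_times)
    config["condition"] = condition.to_dict()
    logger.info("scenario %s: %d output times, condition %s", name, output_times.size, condition.name)
    return replace(traj, metadata=config)


# ---------------------------------------------------------------------------
# Regime diagnostics
# ---------------------------------------------------------------------------

def hill_regime_report(trajectory: Trajectory, params: KineticParameters) -> dict:
    """Where the trajectory sits on the Hill curve.

    With the published parameters, basal free Hsf1
    (≈ k2·[HSP·Hsf1]/(k1·[HSP]) ≈ 0.23 a.u.) exceeds the half-saturation
    constant kd = 0.0025 a.u. by ~100-fold, so the Hill activation runs
    near its ceiling β throughout a simulation. In that regime the
    reporter rises almost linearly at rate β and perturbations to the
    translation source or to Sis1 change its output direction but only
    marginally in magnitude. This report makes that explicit so scenario
    comparisons are interpreted correctly.

    Returns a dict with the min/max free-Hsf1-to-kd ratio over the
    trajectory, the min/max Hill occupancy (activation as a fraction of
    β), and a ``saturated`` flag (min occupancy > 0.99 over times after
    the first output).
    """
    p = effective_rates(params)
    hsf = trajectory.hsf
    occ = np.array([hill_activation(max(h, 0.0), p.beta, p.kd, p.n) / p.beta for h in hsf])
    # Ignore the initial instant: the published initial state has hsf=0
    # and relaxes onto the binding quasi-equilibrium within milliseconds.
    occ_after = occ[1:] if occ.size > 1 else occ
    hsf_after = hsf[1:] if hsf.size > 1 else hsf
    return {
        "hsf_over_kd_min": float(np.min(hsf_after) / p.kd),
        "hsf_over_kd_max": float(np.max(hsf_after) / p.kd),
        "hill_occupancy_min": float(np.min(occ_after)),
        "hill_occupancy_max": float(np.max(occ_after)),
        "saturated": bool(np.min(occ_after) > 0.99),
    }
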