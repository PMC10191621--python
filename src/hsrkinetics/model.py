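"""Core kinetic model of the Hsp70–Hsf1 heat shock response feedback circuit.

The model tracks four protein species — the chaperone Hsp70 ("hsp"), the
transcription factor Hsf1 ("hsf"), unfolded newly synthesized protein
("up"), and an ectopic HSE-YFP reporter ("yfp") — and two complexes
(Hsp70·Hsf1 and Hsp70·UP). Translation feeds a constant source of unfolded
protein (``k_up``) which folds spontaneously at rate ``k_dup``; heat shock
is represented as a reduction of that folding rate, so unfolded protein
accumulates and titrates Hsp70 away from Hsf1. Free Hsf1 drives synthesis
of Hsp70 (the negative feedback loop) and of the YFP reporter through a
shared Hill function.

All concentrations are in arbitrary units (a.u.) and time is in minutes.
The J-domain co-chaperone Sis1 is not an explicit species: it enters as a
dimensionless scalar that inversely scales the Hsp70·Hsf1 dissociation
rate (Sis1 stabilizes the repressive complex, so depleting it accelerates
dissociation).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterator, Sequence

import numpy as np
import yaml

logger = logging.getLogger("hsrkinetics")

#: Names of the six state variables, in canonical order.
SPECIES = ("hsp", "hsf", "up", "hsp_hsf", "hsp_up", "yfp")

#: Condition names with packaged parameter mappings.
CONDITION_NAMES = (
    "baseline",
    "rapamycin",
    "temperature",
    "sis1_depletion",
    "hsp70_dFBL",
    "custom",
)


class DomainError(ValueError):
    """A model precondition was violated (negative rate, bad state, ...)."""


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of the feedback circuit.

    Defaults are the published nominal values describing the onset of a
    39°C heat shock.

    Parameters
    ----------
    k_up:
        Zeroth-order source of unfolded newly synthesized protein
        (a.u.·min⁻¹). Scales with the rate of ongoing translation.
    k_dup:
        Spontaneous folding (maturation) rate of unfolded protein (min⁻¹).
        Heat shock lowers it; recovery raises it.
    k1, k2:
        Hsp70·Hsf1 association (min⁻¹·a.u.⁻¹) and dissociation (min⁻¹).
    k3, k4:
        Hsp70·UP association (min⁻¹·a.u.⁻¹) and dissociation (min⁻¹).
    k5:
        Hsp70-mediated degradation/folding of bound UP (min⁻¹); drains the
        Hsp70·UP complex and releases free Hsp70.
    beta, n, kd:
        Hill function of free Hsf1 driving synthesis of Hsp70 and YFP:
        maximal rate (min⁻¹), Hill coefficient, half-saturation (a.u.).
    sis1_level:
        Dimensionless Sis1 abundance (basal = 1). The effective Hsp70·Hsf1
        dissociation rate is ``k2 / sis1_level``.
    hsp_feedback_enabled:
        If False, the Hill synthesis term is removed from d[HSP]/dt (the
        Hsp70∆FBL strain); it always remains in d[YFP]/dt.
    couple_k4_to_sis1:
        Off by default. If True, Sis1 also scales the Hsp70·UP
        dissociation rate (``k4 / sis1_level``), reflecting its secondary
        role in strengthening Hsp70–client binding.
    """

    k_up: float = 1.0
    k_dup: float = 0.35
    k1: float = 320.0
    k2: float = 0.7
    k3: float = 112.0
    k4: float = 0.1
    k5: float = 0.15
    beta: float = 0.1
    n: int = 3
    kd: float = 0.0025
    sis1_level: float = 1.0
    hsp_feedback_enabled: bool = True
    couple_k4_to_sis1: bool = False

    _RATE_FIELDS = ("k_up", "k_dup", "k1", "k2", "k3", "k4", "k5", "beta", "kd")

    def __post_init__(self) -> None:
        for name in self._RATE_FIELDS:
            value = getattr(self, name)
            if not (value > 0 and math.isfinite(value)):
                raise DomainError(f"parameter {name} must be strictly positive, got {value!r}")
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise DomainError(f"Hill coefficient n must be a positive integer, got {self.n!r}")
        if not (self.sis1_level > 0 and math.isfinite(self.sis1_level)):
            raise DomainError(f"sis1_level must be > 0, got {self.sis1_level!r}")

    def to_dict(self) -> dict:
        """Flat mapping using the published symbol names."""
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, mapping: dict) -> "KineticParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise DomainError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_file(cls, path) -> "KineticParameters":
        """Read parameters from a flat JSON or YAML mapping."""
        with open(path) as fh:
            text = fh.read()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(data, dict):
            raise DomainError(f"parameter file {path} must contain a flat mapping")
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def effective_rates(params: KineticParameters) -> KineticParameters:
    """Resolve Sis1 coupling into effective dissociation rates.

    Sis1 substantiates Hsp70–client binding, so dissociation rates scale
    inversely with its level: ``k2_eff = k2 / sis1_level`` (and
    ``k4_eff = k4 / sis1_level`` only when ``couple_k4_to_sis1`` is set).
    The returned copy has ``sis1_level`` reset to 1 so the scaling is not
    applied twice.
    """
    if not params.sis1_level > 0:
        raise DomainError(f"sis1_level must be > 0, got {params.sis1_level!r}")
    s = params.sis1_level
    if s == 1.0:
        return params
    k4 = params.k4 / s if params.couple_k4_to_sis1 else params.k4
    return replace(params, k2=params.k2 / s, k4=k4, sis1_level=1.0)


# ---------------------------------------------------------------------------
# State
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelState:
    """Concentrations (a.u.) of the six species at one instant.

    Defaults are the published initial values at the onset of heat shock:
    nearly all Hsf1 is sequestered in the Hsp70·Hsf1 complex, and no
    unfolded protein has yet accumulated.
    """

    hsp: float = 12.0
    hsf: float = 0.0
    up: float = 0.0
    hsp_hsf: float = 1250.0
    hsp_up: float = 0.0
    yfp: float = 1.0

    def __post_init__(self) -> None:
        for name in SPECIES:
            value = getattr(self, name)
            if not math.isfinite(value):
                raise DomainError(f"state field {name} must be finite, got {value!r}")

    def validate_nonnegative(self, tol: float = 0.0) -> None:
        for name in SPECIES:
            if getattr(self, name) < -tol:
                raise DomainError(f"state field {name} is negative: {getattr(self, name)!r}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "ModelState":
        if len(values) != len(SPECIES):
            raise DomainError(f"expected {len(SPECIES)} values, got {len(values)}")
        return cls(**dict(zip(SPECIES, map(float, values))))

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in SPECIES}


def conserved_totals(state: ModelState) -> tuple[float, float, float]:
    """Bookkeeping totals implied by the reaction structure.

    Returns ``(total_hsf, total_hsp, total_up)`` where total Hsf1 counts
    free and complexed Hsf1, total Hsp70 counts free and both complexes,
    and total UP counts free and chaperone-bound unfolded protein. Total
    Hsf1 is exactly conserved by the equations; total Hsp70 changes only
    through Hill-driven synthesis; total UP through synthesis, folding and
    degradation.
    """
    total_hsf = state.hsf + state.hsp_hsf
    total_hsp = state.hsp + state.hsp_hsf + state.hsp_up
    total_up = state.up + state.hsp_up
    return (total_hsf, total_hsp, total_up)


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

def hill_activation(hsf: float, beta: float, kd: float, n: int) -> float:
    """Hill-type synthesis rate driven by free Hsf1.

    ``beta * hsf**n / (kd**n + hsf**n)`` — sigmoidal in ``hsf``, bounded
    in ``[0, beta)``, half-maximal at ``hsf == kd``.
    """
    if hsf < 0:
        raise DomainError(f"hsf must be non-negative, got {hsf!r}")
    if not (beta > 0 and kd > 0):
        raise DomainError("beta and kd must be strictly positive")
    if n < 1:
        raise DomainError(f"Hill coefficient must be >= 1, got {n!r}")
    if hsf == 0.0:
        return 0.0
    # Evaluate in ratio form, choosing the ratio <= 1 to avoid overflow
    # at either extreme of hsf/kd.
    if hsf >= kd:
        return beta / (1.0 + (kd / hsf) ** n)
    x = (hsf / kd) ** n
    return beta * x / (1.0 + x)


def rhs(state: ModelState, params: KineticParameters) -> ModelState:
    """Time derivative of the model state (a.u.·min⁻¹ per field).

    Mass-action kinetics for the two binding equilibria, a constant
    translation source feeding UP, spontaneous folding draining it, and
    the shared Hill term synthesizing Hsp70 (when feedback is enabled)
    and YFP. The sum ``hsf + hsp_hsf`` has identically zero derivative.
    """
    state.validate_nonnegative(tol=0.0)
    d = rhs_array(state.as_array(), params)
    return ModelState.from_array(d)


def rhs_array(y: np.ndarray, params: KineticParameters) -> np.ndarray:
    """Vector form of :func:`rhs` for use inside ODE solvers.

    Does not validate non-negativity: adaptive solvers probe slightly
    negative states and the expressions remain well defined there.
    """
    p = effective_rates(params)
    hsp, hsf, up, hsp_hsf, hsp_up, yfp = y
    hill = hill_activation(max(hsf, 0.0), p.beta, p.kd, p.n)
    bind_hsf = p.k1 * hsp * hsf
    unbind_hsf = p.k2 * hsp_hsf
    bind_up = p.k3 * hsp * up
    unbind_up = p.k4 * hsp_up
    clear_up = p.k5 * hsp_up

    d_hsp = unbind_hsf - bind_hsf + unbind_up + clear_up - bind_up
    if p.hsp_feedback_enabled:
        d_hsp += hill
    d_hsf = unbind_hsf - bind_hsf
    d_up = p.k_up - p.k_dup * up + unbind_up - bind_up
    d_hsp_hsf = bind_hsf - unbind_hsf
    d_hsp_up = bind_up - unbind_up - clear_up
    d_yfp = hill
    return np.array([d_hsp, d_hsf, d_up, d_hsp_hsf, d_hsp_up, d_yfp])


# ---------------------------------------------------------------------------
# Conditions and protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Condition:
    """A named experimental condition expressed as parameter modifiers."""

    name: str = "baseline"
    k_up_scale: float = 1.0
    k_dup_scale: float = 1.0
    sis1_level: float = 1.0
    hsp_feedback_enabled: bool = True

    def __post_init__(self) -> None:
        if self.name not in CONDITION_NAMES:
            raise DomainError(
                f"unknown condition name {self.name!r}; valid: {CONDITION_NAMES}"
            )
        for attr in ("k_up_scale", "k_dup_scale", "sis1_level"):
            if not getattr(self, attr) > 0:
                raise DomainError(f"{attr} must be > 0, got {getattr(self, attr)!r}")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: Identity condition: unmodified published parameters (39°C heat shock onset).
BASELINE = Condition(name="baseline")

#: Rapamycin pretreatment: TORC1 inhibition removes ~40% of newly
#: synthesized proteins, modeled as a 40% reduction of the translation source.
RAPAMYCIN = Condition(name="rapamycin", k_up_scale=0.6)

#: Nuclear Sis1 depletion (anchor-away), destabilizing the Hsp70·Hsf1
#: complex: sis1_level 0.1 means a 10-fold increase of the effective k2.
SIS1_DEPLETION = Condition(name="sis1_depletion", sis1_level=0.1)

#: Hsp70∆FBL strain: Hsp70 expression decoupled from Hsf1 — no Hill
#: synthesis term in d[HSP]/dt; the HSE-YFP reporter is retained.
HSP70_DFBL = Condition(name="hsp70_dFBL", hsp_feedback_enabled=False)


def temperature_condition(k_dup_scale: float) -> Condition:
    """Heat shock at a non-reference temperature: folding rate scaled by
    ``k_dup_scale`` (smaller scale = hotter shock = slower folding)."""
    return Condition(name="temperature", k_dup_scale=k_dup_scale)


def apply_condition(params: KineticParameters, condition: Condition) -> KineticParameters:
    """Map a named condition onto a parameter set.

    Scales the translation source and folding rate, overrides the Sis1
    level, and sets the feedback flag. Raises on non-positive scales (via
    the Condition/parameter validators).
    """
    return replace(
        params,
        k_up=params.k_up * condition.k_up_scale,
        k_dup=params.k_dup * condition.k_dup_scale,
        sis1_level=condition.sis1_level,
        hsp_feedback_enabled=condition.hsp_feedback_enabled,
    )


@dataclass(frozen=True)
class ProtocolSegment:
    t_start: float
    t_end: float
    condition: Condition

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise DomainError(
                f"segment must have t_end > t_start, got [{self.t_start}, {self.t_end}]"
            )


@dataclass(frozen=True)
class Protocol:
    """A piecewise-constant schedule of conditions over the horizon.

    Segments must start at t=0, be contiguous and non-overlapping. This
    supports pulse/recovery regimes (heat shock, return to permissive
    temperature, second shock, ...) as well as plain constant-condition
    runs.
    """

    segments: tuple[ProtocolSegment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise DomainError("protocol needs at least one segment")
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        if segs[0].t_start != 0.0:
            raise DomainError(f"protocol must start at t=0, got {segs[0].t_start}")
        for a, b in zip(segs, segs[1:]):
            if a.t_end != b.t_start:
                raise DomainError(
                    f"segments must be contiguous: [{a.t_start},{a.t_end}] then "
                    f"[{b.t_start},{b.t_end}]"
                )

    @property
    def t_end(self) -> float:
        return self.segments[-1].t_end

    def condition_at(self, t: float) -> Condition:
        """Condition active at time ``t`` (right-open segments; the final
        segment includes its endpoint)."""
        for seg in self.segments:
            if seg.t_start <= t < seg.t_end:
                return seg.condition
        if t == self.t_end:
            return self.segments[-1].condition
        raise DomainError(f"time {t} outside protocol span [0, {self.t_end}]")

    def __iter__(self) -> Iterator[ProtocolSegment]:
        return iter(self.segments)

    @classmethod
    def constant(cls, condition: Condition, t_end: float) -> "Protocol":
        return cls(segments=(ProtocolSegment(0.0, float(t_end), condition),))

    @classmethod
    def from_segments(cls, spec: Sequence[tuple[float, float, Condition]]) -> "Protocol":
        return cls(segments=tuple(ProtocolSegment(float(a), float(b), c) for a, b, c in spec))

    def to_dict(self) -> dict:
        return {
            "segments": [
                {"t_start": s.t_start, "t_end": s.t_end, "condition": s.condition.to_dict()}
                for s in self.segments
            ]
        }
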