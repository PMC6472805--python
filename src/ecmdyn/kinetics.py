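"""Stochastic force-sensitive crosslink kinetics.

Crosslinks are slip bonds: the unbinding rate grows exponentially with the
tensile force they carry (Bell's model), k_u = k_u0·exp(λF/(k_B T)), and each
bound crosslink unbinds independently per step with probability
1 − exp(−k_u·Δt).  Only positive (stretching) forces feed the kinetics.
Optionally, an unbound crosslink whose attachment loci have drifted back
within reach may rebind; it reattaches at the current geometry with zero
strain, so rebinding can never inject elastic energy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import KineticParams
from .network import FiberNetwork

__all__ = [
    "unbind_rate",
    "unbind_probability",
    "apply_unbinding",
    "apply_rebinding",
    "UnbindEvent",
]


@dataclass
class UnbindEvent:
    time: float
    crosslink: int
    tension: float
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))


def unbind_rate(force, params: KineticParams):
    """Bell-model unbinding rate k_u0·exp(λF/(k_B T)) in 1/s.

    ``force`` must already be clamped to >= 0 by the caller (compressed
    bonds carry zero kinetic force).  Monotone non-decreasing in force.
    The exponent is clamped at ``params.exponent_cap`` to guard overflow,
    with a warning the first time the cap engages.
    """
    force = np.asarray(force, dtype=float)
    if np.any(force < 0):
        raise ValueError("unbind_rate expects non-negative forces")
    expo = params.lam * force / params.kbt
    if np.any(expo > params.exponent_cap):
        warnings.warn(
            "Bell exponent clamped at "
            f"{params.exponent_cap:.0f} (force beyond the resolved kinetic range)",
            RuntimeWarning,
            stacklevel=2,
        )
        expo = np.minimum(expo, params.exponent_cap)
    return params.k_u0 * np.exp(expo)


def unbind_probability(k_u, dt: float):
    """Per-step unbinding probability 1 − exp(−k_u·Δt), in [0, 1]."""
    k_u = np.asarray(k_u, dtype=float)
    if np.any(k_u < 0) or dt < 0:
        raise ValueError("rate and dt must be >= 0")
    return -np.expm1(-k_u * dt)


def apply_unbinding(
    net: FiberNetwork,
    params: KineticParams,
    rng: np.random.Generator,
    time: float = 0.0,
    event_log: list | None = None,
):
    """Stochastically unbind crosslinks at their current cached tensions.

    Tensions must have been refreshed this step (``crosslink_forces``).  One
    uniform draw is consumed per crosslink in index order regardless of bound
    state, which keeps event sequences reproducible across model variants for
    a fixed seed.  Returns the indices that unbound this step.
    """
    n = net.n_crosslinks
    if n == 0:
        return np.empty(0, dtype=np.intp)
    u = rng.random(n)
    rates = unbind_rate(np.maximum(net.cl_tension, 0.0), params)
    p = unbind_probability(rates, params.dt)
    events = np.flatnonzero(net.cl_bound & (u < p))
    if len(events):
        net.cl_bound[events] = False
        if event_log is not None:
            xa, xb = net.crosslink_points()
            mid = 0.5 * (xa[events] + xb[events])
            for idx, pos in zip(events, mid):
                event_log.append(UnbindEvent(time, int(idx), float(net.cl_tension[idx]), pos))
    return events


def apply_rebinding(
    net: FiberNetwork,
    params: KineticParams,
    rng: np.random.Generator,
):
    """Rebind unbound crosslinks whose attachment loci are within reach.

    Rebinding probability per step is 1 − exp(−rebind_rate·Δt); a rebound
    crosslink resumes force transmission at the current attachment-point
    separation with zero initial strain (its rest length is reset to the
    current geometry).  Crosslinks are never created or destroyed, only
    flipped between bound and unbound.  Returns the rebound indices.
    """
    n = net.n_crosslinks
    if n == 0 or params.rebind_rate <= 0:
        if n:
            rng.random(n)  # keep the stream aligned with the rebinding variant
        return np.empty(0, dtype=np.intp)
    u = rng.random(n)
    xa, xb = net.crosslink_points()
    sep = np.linalg.norm(xb - xa, axis=1)
    p = unbind_probability(params.rebind_rate, params.dt)
    events = np.flatnonzero((~net.cl_bound) & (sep <= params.rebind_reach) & (u < p))
    if len(events):
        net.cl_bound[events] = True
        net.cl_rest[events] = sep[events]
    return events
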