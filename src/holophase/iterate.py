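"""Iterative refinement of a complex object-wave estimate.

Two families, both intended to *refine* a direct-method reconstruction (a
flat or random start usually lands in a poor local optimum):

* :func:`gradient_descent` — steepest descent on the squared intensity
  misfit ``C(u) = sum_D sum_x (|P_D u|^2 - I_D)^2`` with an Armijo
  backtracking line search, so the cost history is non-increasing by
  construction.  ``P_D`` is the (unitary) Fresnel propagator.
* :func:`hio_er` — alternating projections between the detector-modulus
  constraint (|P_D u| = sqrt(I_D)) and per-pixel object-domain constraints
  (support with unit background, optional non-negativity |u| <= 1), in
  error-reduction (ER) or hybrid input-output (HIO) flavour per a schedule
  like ``[("hio", 45), ("er", 5)]``.

The iterate is the full complex wave u = exp(-B + i*phi); phase maps are
read off as arg(u).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError, DivergenceError
from .propagate import ComplexWavefield, fresnel_propagate
from .retrieve import HologramStack

__all__ = [
    "Constraints",
    "IterativeState",
    "misfit",
    "misfit_gradient",
    "gradient_descent",
    "hio_er",
    "averaged_hio_er",
]

#: Unit-transmission background assumed outside the support.
BACKGROUND = 1.0 + 0.0j


@dataclass
class Constraints:
    """Object-domain constraints for HIO/ER.

    ``support_mask`` is True where the object may differ from the unit
    background; ``nonnegativity`` enforces B >= 0, i.e. |u| <= 1;
    ``feedback`` is the HIO relaxation parameter beta (0 < beta <= 1).
    """

    support_mask: np.ndarray | None = None
    nonnegativity: bool = False
    feedback: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 < self.feedback <= 1.0:
            raise DataError(f"feedback must be in (0, 1], got {self.feedback}")
        if self.support_mask is not None:
            self.support_mask = np.asarray(self.support_mask, dtype=bool)


@dataclass
class IterativeState:
    """Result of an iterative run.

    ``cost_history`` holds the objective value per completed iteration plus
    the initial one (misfit for GD, detector-plane modulus residual
    ``sum_D || |P_D u| - sqrt(I_D) ||^2`` for HIO/ER).
    """

    wavefield: ComplexWavefield
    cost_history: list[float] = field(default_factory=list)
    iteration: int = 0

    @property
    def phase(self) -> np.ndarray:
        """Wrapped phase map arg(u) of the current estimate."""
        return np.angle(self.wavefield.values)


def _propagated(u: ComplexWavefield, stack: HologramStack, pad: bool):
    for d in stack.distances:
        yield fresnel_propagate(u, stack.wavelength, float(d), pad=pad)


def misfit(u: ComplexWavefield, stack: HologramStack, pad: bool = False) -> float:
    """Squared intensity misfit C(u) = sum over distances and pixels."""
    if u.shape != stack.shape:
        raise DataError(f"shape mismatch: wave {u.shape} vs stack {stack.shape}")
    c = 0.0
    for u_d, i_d in zip(_propagated(u, stack, pad), stack.images):
        r = np.abs(u_d.values) ** 2 - i_d
        c += float(np.sum(r * r))
    return c


def misfit_gradient(
    u: ComplexWavefield, stack: HologramStack, pad: bool = False
) -> np.ndarray:
    """Gradient of :func:`misfit` with respect to (Re u, Im u), as a complex
    array g = dC/d(Re u) + i dC/d(Im u).

    For each distance the chain rule through the unitary propagator gives
    ``4 * P_{-D}[ (|P_D u|^2 - I_D) * P_D u ]``.
    """
    if u.shape != stack.shape:
        raise DataError(f"shape mismatch: wave {u.shape} vs stack {stack.shape}")
    g = np.zeros(u.shape, dtype=np.complex128)
    for d, i_d in zip(stack.distances, stack.images):
        u_d = fresnel_propagate(u, stack.wavelength, float(d), pad=pad)
        w = (np.abs(u_d.values) ** 2 - i_d) * u_d.values
        back = fresnel_propagate(
            ComplexWavefield(w, u.pixel), stack.wavelength, -float(d), pad=pad
        )
        g += 4.0 * back.values
    return g


def gradient_descent(
    init: ComplexWavefield,
    stack: HologramStack,
    n_iter: int,
    step0: float | None = None,
    armijo_c: float = 1e-4,
    max_backtracks: int = 40,
    pad: bool = False,
) -> IterativeState:
    """Steepest descent on the intensity misfit with Armijo backtracking.

    The initial step is ``1 / (8 * sum_D max I_D)`` unless given; each
    iteration halves the step until ``C(u - t g) <= C(u) - c t ||g||^2``.
    If no acceptable step exists (stationary point to machine precision) the
    run stops early.  The cost history is non-increasing by construction.
    """
    u = init.copy()
    c_cur = misfit(u, stack, pad=pad)
    if not np.isfinite(c_cur):
        raise DivergenceError("non-finite cost at iteration 0")
    history = [c_cur]
    if step0 is None:
        step0 = 1.0 / (8.0 * float(sum(im.max() for im in stack.images)))
    k = 0
    for k in range(1, n_iter + 1):
        g = misfit_gradient(u, stack, pad=pad)
        gnorm2 = float(np.sum(np.abs(g) ** 2))
        if gnorm2 == 0.0:
            k -= 1
            break
        t = step0
        accepted = False
        for _ in range(max_backtracks):
            trial = ComplexWavefield(u.values - t * g, u.pixel)
            c_new = misfit(trial, stack, pad=pad)
            if not np.isfinite(c_new):
                raise DivergenceError(f"non-finite cost at iteration {k}")
            if c_new <= c_cur - armijo_c * t * gnorm2:
                u, c_cur = trial, c_new
                accepted = True
                break
            t *= 0.5
        if not accepted:
            k -= 1
            break
        history.append(c_cur)
    return IterativeState(wavefield=u, cost_history=history, iteration=k)


def _violation_mask(u_vals: np.ndarray, cons: Constraints) -> np.ndarray:
    bad = np.zeros(u_vals.shape, dtype=bool)
    if cons.support_mask is not None:
        bad |= ~cons.support_mask
    if cons.nonnegativity:
        bad |= np.abs(u_vals) > 1.0
    return bad


def _object_project(u_vals: np.ndarray, cons: Constraints) -> np.ndarray:
    """Exact per-pixel projection onto the object-domain constraint set."""
    out = u_vals.copy()
    if cons.nonnegativity:
        mag = np.abs(out)
        over = mag > 1.0
        out[over] = out[over] / mag[over]
    if cons.support_mask is not None:
        out[~cons.support_mask] = BACKGROUND
    return out


def _modulus_residual(
    u: ComplexWavefield, stack: HologramStack, roots: np.ndarray, pad: bool
) -> float:
    r = 0.0
    for u_d, root in zip(_propagated(u, stack, pad), roots):
        diff = np.abs(u_d.values) - root
        r += float(np.sum(diff * diff))
    return r


def hio_er(
    init: ComplexWavefield,
    stack: HologramStack,
    constraints: Constraints,
    schedule: list[tuple[str, int]],
    pad: bool = False,
) -> IterativeState:
    """Hybrid input-output / error reduction with a mode schedule.

    One iteration visits every distance cyclically: propagate, replace the
    modulus by sqrt(I_D) keeping the phase, back-propagate to get the
    constraint-satisfying estimate u'.  Then

    * ER sets u to the object-domain projection of u' (outside support ->
      unit background; |u'| > 1 rescaled when non-negativity is on);
    * HIO keeps u' where it satisfies the constraints and applies the
      relaxed feedback ``u - beta * (u' - 1)`` at violating pixels (the
      background-referenced Fienup update for a unit-transmission
      background).

    Returns the state with the detector-plane modulus residual history (one
    entry per completed iteration plus the initial value).  ER with a single
    distance is an alternating projection, so its residual is
    non-increasing; HIO's is not and may oscillate.
    """
    if np.any(stack.images < 0):
        raise DataError("negative intensities; correct the data upstream")
    if constraints.support_mask is not None and (
        constraints.support_mask.shape != stack.shape
    ):
        raise DataError("support mask shape must match the image shape")
    roots = np.sqrt(stack.images)
    u = init.copy()
    history = [_modulus_residual(u, stack, roots, pad)]
    total = 0
    for mode, count in schedule:
        mode = mode.lower()
        if mode not in ("hio", "er"):
            raise DataError(f"unknown schedule mode {mode!r}")
        for _ in range(count):
            for d, root in zip(stack.distances, roots):
                u_d = fresnel_propagate(u, stack.wavelength, float(d), pad=pad)
                mag = np.abs(u_d.values)
                phase = np.where(mag > 0, u_d.values / np.where(mag > 0, mag, 1.0), 1.0)
                u_prime = fresnel_propagate(
                    ComplexWavefield(root * phase, u.pixel),
                    stack.wavelength,
                    -float(d),
                    pad=pad,
                ).values
                if mode == "er":
                    u = ComplexWavefield(_object_project(u_prime, constraints), u.pixel)
                else:
                    bad = _violation_mask(u_prime, constraints)
                    new = u_prime.copy()
                    new[bad] = u.values[bad] - constraints.feedback * (
                        u_prime[bad] - BACKGROUND
                    )
                    u = ComplexWavefield(new, u.pixel)
            total += 1
            history.append(_modulus_residual(u, stack, roots, pad))
    return IterativeState(wavefield=u, cost_history=history, iteration=total)


def averaged_hio_er(
    init: ComplexWavefield,
    stack: HologramStack,
    constraints: Constraints,
    schedule: list[tuple[str, int]],
    n_cycles: int = 5,
    pad: bool = False,
) -> np.ndarray:
    """Per-distance HIO/ER runs averaged in phase, repeated ``n_cycles`` times.

    Convenience driver: each cycle runs the schedule independently on every
    single-distance sub-stack starting from the current estimate, averages
    the resulting phase maps (amplitudes likewise), and feeds the average
    into the next cycle.  Returns the final averaged phase map.
    """
    u = init.copy()
    for _ in range(n_cycles):
        phases = []
        amps = []
        for i in range(len(stack)):
            sub = HologramStack(
                images=stack.images[i : i + 1],
                distances=stack.distances[i : i + 1],
                pixel=stack.pixel,
                wavelength=stack.wavelength,
            )
            state = hio_er(u, sub, constraints, schedule, pad=pad)
            phases.append(np.angle(state.wavefield.values))
            amps.append(np.abs(state.wavefield.values))
        phi = np.mean(phases, axis=0)
        amp = np.mean(amps, axis=0)
        u = ComplexWavefield(amp * np.exp(1j * phi), u.pixel)
    return np.angle(u.values)
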