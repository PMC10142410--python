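"""Newton solution of the coupled ventricular-arterial coupling equations.

Substituting the empirical slope-ratio relation k = 0.53·x^0.51 (x = Ees/Ea)
into the theoretical coupling equation

    x = (Pad/Pes)·(1 + k·ET/PEP) − 1

gives a single nonlinear equation in x,

    f(x) = c1·x^0.51 − x + c0 = 0,
    c1 = (Pad/Pes)·0.53·(ET/PEP),   c0 = Pad/Pes − 1,

solved by Newton's method with the analytic derivative.  f is strictly
concave on x > 0 with f(0+) = c0 ≤ 0 (since Pes ≥ Pad) and f → −∞; when a
root exists the equation generically has two positive roots, a tiny one
near zero and the physiological one on the decreasing branch beyond the
maximum of f at x_peak = (0.51·c1)^(1/0.49).  The solver targets the
decreasing-branch root: Newton starts at max(x0, 2·x_peak) — x0 = 1 is the
mid-physiological coupling where the k-relation was calibrated, and the
2·x_peak floor keeps the start on the decreasing branch, where the tangent
of a concave function crosses zero at or beyond the root, making the
iteration provably convergent whenever the root exists.  A bracketed
bisection fallback on (x_peak, bracket_hi) covers stalls and the
no-root diagnosis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import bisect

from .model import K_COEF, K_EXP, CouplingSolution, InvalidInputError

__all__ = [
    "SolverConfig",
    "NoSolutionError",
    "coupling_residual",
    "coupling_residual_derivative",
    "solve_coupling",
]


class NoSolutionError(ArithmeticError):
    """The coupling equation has no admissible root for these inputs."""


@dataclass(frozen=True)
class SolverConfig:
    """Newton/bisection settings for the coupling solve.

    ``k_coef``/``k_exp`` override the empirical slope-ratio relation for
    sensitivity work; the defaults are the published regression values.
    """

    x0: float = 1.0
    tol: float = 1e-9
    max_iter: int = 50
    bracket_lo: float = 1e-6
    bracket_hi: float = 100.0
    k_coef: float = K_COEF
    k_exp: float = K_EXP

    def __post_init__(self) -> None:
        if not self.tol > 0:
            raise ValueError("tol must be > 0")
        if not 0 < self.bracket_lo < self.bracket_hi:
            raise ValueError("require 0 < bracket_lo < bracket_hi")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def _check_inputs(pad: float, pes: float, et: float, pep: float) -> None:
    for name, v in (("pad", pad), ("pes", pes), ("et", et), ("pep", pep)):
        if not v > 0:
            raise InvalidInputError(f"{name} must be > 0, got {v!r}")
    if pad > pes:
        raise InvalidInputError(
            f"pad ({pad}) must not exceed pes ({pes}): ejection pressure ordering"
        )


def coupling_residual(
    x: float,
    pad: float,
    pes: float,
    et: float,
    pep: float,
    k_coef: float = K_COEF,
    k_exp: float = K_EXP,
) -> float:
    """Residual f(x) = (Pad/Pes)·(1 + k_coef·x^k_exp·ET/PEP) − 1 − x."""
    if not x > 0:
        raise InvalidInputError(f"x must be > 0 (fractional power), got {x!r}")
    return (pad / pes) * (1.0 + k_coef * x**k_exp * (et / pep)) - 1.0 - x


def coupling_residual_derivative(
    x: float,
    pad: float,
    pes: float,
    et: float,
    pep: float,
    k_coef: float = K_COEF,
    k_exp: float = K_EXP,
) -> float:
    """Analytic df/dx = (Pad/Pes)·k_coef·k_exp·x^(k_exp−1)·(ET/PEP) − 1."""
    if not x > 0:
        raise InvalidInputError(f"x must be > 0, got {x!r}")
    return (pad / pes) * k_coef * k_exp * x ** (k_exp - 1.0) * (et / pep) - 1.0


def solve_coupling(
    pad: float,
    pes: float,
    et: float,
    pep: float,
    config: SolverConfig | None = None,
) -> CouplingSolution:
    """Solve for Ees/Ea given Pad, Pes (mmHg) and ET, PEP (ms).

    Returns a :class:`~edvcalc.model.CouplingSolution` whose residual
    satisfies ``|f(x*)| <= config.tol``, with ``k = k_coef·x*^k_exp`` and
    ``pmax = pes·(1 + x*)``.  Newton steps are clamped to stay strictly
    positive (x cannot cross zero where the fractional power is undefined);
    if Newton exits (0, bracket_hi] or exhausts ``max_iter``, a bracketed
    bisection on the decreasing branch is used and flagged.

    Raises :class:`NoSolutionError` when the residual has no sign change on
    the fallback bracket, and :class:`~edvcalc.model.InvalidInputError` for
    non-positive inputs or pad > pes.
    """
    cfg = config or SolverConfig()
    _check_inputs(pad, pes, et, pep)
    c1 = (pad / pes) * cfg.k_coef * (et / pep)
    # argmax of the concave residual; right of it f is strictly decreasing,
    # so any Newton iterate started there converges monotonically to the
    # physiological root (tangents of a concave f cross zero at or beyond it)
    x_peak = (c1 * cfg.k_exp) ** (1.0 / (1.0 - cfg.k_exp))

    def f(x: float) -> float:
        return coupling_residual(x, pad, pes, et, pep, cfg.k_coef, cfg.k_exp)

    def fprime(x: float) -> float:
        return coupling_residual_derivative(x, pad, pes, et, pep, cfg.k_coef, cfg.k_exp)

    x = max(cfg.x0, 2.0 * x_peak)
    iterations = 0
    converged = False
    used_fallback = False
    for _ in range(cfg.max_iter):
        fx = f(x)
        iterations += 1
        if not math.isfinite(fx):
            raise ArithmeticError(
                f"non-finite residual at iteration {iterations}, x={x!r}"
            )
        if abs(fx) <= cfg.tol:
            converged = True
            # one polishing step: the residual tolerance alone bounds
            # |x - root| only up to 1/|f'|; quadratic convergence makes
            # the polished iterate accurate to near machine precision
            d = fprime(x)
            if d != 0 and math.isfinite(d):
                x_pol = x - fx / d
                if x_pol > 0 and abs(f(x_pol)) <= abs(fx):
                    x = x_pol
            break
        d = fprime(x)
        if d == 0 or not math.isfinite(d):
            break  # stationary point or overflow: hand over to bisection
        x_new = x - fx / d
        # fractional powers demand x > 0; clamp the step rather than fail
        x_new = max(x_new, x / 10.0)
        if x_new > cfg.bracket_hi:
            break
        x = x_new

    if not converged:
        used_fallback = True
        lo = min(max(x_peak, cfg.bracket_lo), cfg.bracket_hi)
        f_lo, f_hi = f(lo), f(cfg.bracket_hi)
        if f_lo == 0.0:
            x = lo
        elif f_lo * f_hi > 0:
            raise NoSolutionError(
                "no sign change on fallback bracket "
                f"[{lo:.6g}, {cfg.bracket_hi:.6g}]: f={f_lo:.6g} and {f_hi:.6g} "
                f"(pad={pad}, pes={pes}, et={et}, pep={pep})"
            )
        else:
            x = bisect(f, lo, cfg.bracket_hi, xtol=1e-15, maxiter=200)
        converged = abs(f(x)) <= cfg.tol
        if not converged:
            raise NoSolutionError(
                f"bisection fallback did not reach tolerance: residual {f(x):.3g}"
            )

    residual = f(x)
    k = cfg.k_coef * x**cfg.k_exp
    return CouplingSolution(
        ees_over_ea=x,
        k=k,
        pes=pes,
        pmax=pes * (1.0 + x),
        iterations=iterations,
        converged=converged,
        residual=residual,
        used_fallback=used_fallback,
    )
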