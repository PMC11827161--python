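"""Fractional-polynomial (FP) bases of degree 1 and 2.

An FP basis evaluates powers of a positive argument ``x`` drawn from the
conventional power set ``S = {-2, -1, -0.5, 0, 0.5, 1, 2, 3}``, where the
power 0 denotes the natural logarithm and a repeated power ``(p, p)``
denotes the pair ``(x**p, x**p * log(x))``.  Because the analysis time
axis spans negative years relative to first pregnancy, times are first
mapped through a stored affine positivity transform
``x = (t - shift) / scale``; the same constants are reused for fitting
and prediction so the basis is identical in both.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError, InputError

#: The conventional fractional-polynomial power set.
FP_POWERS: tuple[float, ...] = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


@dataclass(frozen=True)
class FPSpec:
    """A fractional-polynomial specification.

    Parameters
    ----------
    powers
        Ordered tuple of powers from :data:`FP_POWERS`; its length is the
        degree (1 or 2).
    shift, scale
        Constants of the positivity transform ``x = (t - shift) / scale``.
        They are computed once from the fitting data (:func:`make_positive`)
        and stored so predictions use the identical basis.
    """

    powers: tuple[float, ...]
    shift: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if len(self.powers) not in (1, 2):
            raise InputError(f"FP degree must be 1 or 2, got {len(self.powers)}")
        for p in self.powers:
            if p not in FP_POWERS:
                raise InputError(f"power {p} not in the FP power set {FP_POWERS}")
        if self.scale <= 0:
            raise InputError("scale must be positive")

    @property
    def degree(self) -> int:
        return len(self.powers)

    def term_names(self, prefix: str = "fp") -> list[str]:
        return [f"{prefix}{k + 1}" for k in range(self.degree)]

    def describe(self) -> str:
        pw = ", ".join(f"{p:g}" for p in self.powers)
        return f"FP({pw}); x = (t - {self.shift:g}) / {self.scale:g}"


def _single_power(x: np.ndarray, p: float) -> np.ndarray:
    if p == 0.0:
        return np.log(x)
    return x**p


def fp_transform(t, spec: FPSpec) -> np.ndarray:
    """Evaluate the FP basis at time(s) ``t``.

    Returns an array of shape ``(n, degree)``.  Raises
    :class:`~apotraj.exceptions.DomainError` if any transformed time is
    non-positive; values are never silently clipped.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    x = (t - spec.shift) / spec.scale
    if not np.all(np.isfinite(x)):
        raise DomainError("non-finite time values in FP transform")
    if np.any(x <= 0):
        raise DomainError(
            f"non-positive transformed time (min {x.min():g}); "
            f"the positivity transform (shift={spec.shift:g}, scale={spec.scale:g}) "
            "does not cover these times"
        )
    p1 = spec.powers[0]
    cols = [_single_power(x, p1)]
    if spec.degree == 2:
        p2 = spec.powers[1]
        if p2 == p1:
            # repeated-power convention: second term is x^p * ln x
            cols.append(cols[0] * np.log(x) if p1 != 0.0 else np.log(x) ** 2)
        else:
            cols.append(_single_power(x, p2))
    return np.column_stack(cols)


def enumerate_fp_models(max_degree: int = 2) -> list[FPSpec]:
    """Enumerate candidate FP specifications in deterministic order.

    Degree 1 gives the 8 single powers; degree 2 adds the 8 repeated pairs
    and the 28 unordered distinct pairs (36), i.e. 44 candidates in total.
    """
    if max_degree not in (1, 2):
        raise InputError(f"max_degree must be 1 or 2, got {max_degree}")
    specs = [FPSpec(powers=(p,)) for p in FP_POWERS]
    if max_degree == 2:
        for p, q in itertools.combinations_with_replacement(FP_POWERS, 2):
            specs.append(FPSpec(powers=(p, q)))
    return specs


def make_positive(times, margin: float = 1.0, target_max: float = 2.5) -> tuple[float, float]:
    """Choose (shift, scale) so transformed times lie in ``(0, ~target_max]``.

    ``shift = min(times) - margin``; ``scale`` maps the largest time to
    ``target_max`` (floored at 1 so degenerate spreads fall back to an
    unscaled axis).
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise InputError("empty time vector")
    if not np.all(np.isfinite(times)):
        raise InputError("non-finite time values")
    shift = float(times.min() - margin)
    scale = max((float(times.max()) - shift) / target_max, 1.0)
    return shift, scale


def spec_with_transform(spec: FPSpec, times, margin: float = 1.0) -> FPSpec:
    """Return a copy of ``spec`` with its positivity transform fixed from data."""
    shift, scale = make_positive(times, margin=margin)
    return FPSpec(powers=spec.powers, shift=shift, scale=scale)


AGE_FP_SCALE = 10.0  # conventional decades scaling for the age axis

#: default positivity margin for the relative-time axis: half the
#: pre-pregnancy window, keeping fitted times well clear of the x = 0
#: singularity where the power bases degenerate
TIME_FP_MARGIN = 5.0


def age_spec(spec: FPSpec) -> FPSpec:
    """FP spec for the age axis: age in decades, no shift."""
    return FPSpec(powers=spec.powers, shift=0.0, scale=AGE_FP_SCALE)
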