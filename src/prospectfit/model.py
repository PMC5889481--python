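"""Prospect-theory primitives for two-outcome gambles.

The task elicits certainty equivalents (CEs) for pure-gain and pure-loss
gambles ``(x, p; y, 1-p)`` with ``x > y >= 0`` in magnitude.  Under prospect
theory with a power value function ``v(x) = x**alpha`` and a probability
weight ``w = w(p)``, the CE of such a gamble has the closed form

    CE = [w * (x**alpha - y**alpha) + y**alpha] ** (1/alpha)

which this module implements together with its inverse for ``y = 0`` gambles
and the two standard two-parameter weighting functions:

* Lattimore / Goldstein–Einhorn form
  ``w(p) = delta * p**gamma / (delta * p**gamma + (1-p)**gamma)``, where
  ``gamma`` controls distortion (curvature) and ``delta`` elevation
  (optimism).
* Prelec form ``w(p) = exp(-delta * (-ln p)**gamma)``; note that here a
  *larger* ``delta`` lowers the curve.

Losses are handled by reflection: all model math runs on money magnitudes,
and the sign of the loss domain is applied only at the task/IO boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Literal

import numpy as np

Domain = Literal["gain", "loss"]
WeightingForm = Literal["lattimore", "prelec", "none"]

__all__ = [
    "Gamble",
    "PTParams",
    "GAMBLES",
    "gamble_menu",
    "value_power",
    "w_lattimore",
    "w_prelec",
    "weighting_function",
    "predicted_ce",
    "weight_from_ce",
]


@dataclass(frozen=True)
class Gamble:
    """One two-outcome prospect: win/lose ``x`` with probability ``p``, else ``y``.

    Monetary amounts are stored as positive magnitudes in euros; ``domain``
    records whether they are gains or losses.  ``p`` is kept as an exact
    rational (the task uses multiples of 1/6) to avoid floating drift.
    """

    index: int
    x: float
    p: Fraction
    y: float
    domain: Domain = "gain"

    def __post_init__(self) -> None:
        if not (self.x > self.y >= 0):
            raise ValueError(f"require x > y >= 0, got x={self.x}, y={self.y}")
        if not (0 < self.p < 1):
            raise ValueError(f"require 0 < p < 1, got p={self.p}")
        if self.domain not in ("gain", "loss"):
            raise ValueError(f"unknown domain {self.domain!r}")

    @property
    def p_float(self) -> float:
        return float(self.p)

    @property
    def sign(self) -> int:
        """+1 for gains, -1 for losses; applied only at I/O boundaries."""
        return 1 if self.domain == "gain" else -1

    def expected_value(self) -> float:
        """Expected value on the magnitude scale, p*x + (1-p)*y."""
        return float(self.p) * self.x + float(1 - self.p) * self.y


# The fixed 10-gamble menu of the elicitation task.  Rows: (x, p, y); the
# same magnitudes are used in the loss domain with negative sign.
_MENU: tuple[tuple[int, int, int], ...] = (
    (1200, 1, 0),
    (1200, 2, 0),
    (600, 2, 0),
    (1200, 2, 600),
    (600, 2, 300),
    (1000, 2, 400),
    (1200, 2, 900),
    (1200, 3, 0),
    (1200, 4, 0),
    (1200, 5, 0),
)


def gamble_menu(domain: Domain = "gain") -> list[Gamble]:
    """The canonical 10-gamble menu for one domain, indexed 1..10."""
    return [
        Gamble(index=i, x=float(x), p=Fraction(k, 6), y=float(y), domain=domain)
        for i, (x, k, y) in enumerate(_MENU, start=1)
    ]


GAMBLES: dict[Domain, list[Gamble]] = {
    "gain": gamble_menu("gain"),
    "loss": gamble_menu("loss"),
}


@dataclass
class PTParams:
    """Prospect-theory parameters for one participant x drug x domain cell.

    alpha: value curvature (alpha < 1 concave); delta: elevation; gamma:
    distortion of the weighting function; w26: weight at p = 2/6 (used by the
    semi-parametric first estimation step).
    """

    alpha: float = 1.0
    delta: float = 1.0
    gamma: float = 1.0
    w26: float = field(default=1.0 / 3.0)
    weighting_form: WeightingForm = "lattimore"

    def __post_init__(self) -> None:
        for name in ("alpha", "delta", "gamma"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if not (0 < self.w26 < 1):
            raise ValueError(f"w26 must be in (0,1), got {self.w26}")

    def weight(self, p: float) -> float:
        """Decision weight w(p) under this cell's weighting form."""
        return weighting_function(p, self.delta, self.gamma, self.weighting_form)


def value_power(x, alpha: float):
    """Power value function ``v(x) = x**alpha`` on money magnitudes."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("value_power is defined on magnitudes; got x < 0")
    if not alpha > 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    out = np.power(x, alpha)
    return out if out.ndim else float(out)


def w_lattimore(p, delta: float, gamma: float):
    """Lattimore weighting: delta*p^gamma / (delta*p^gamma + (1-p)^gamma)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    if not (delta > 0 and gamma > 0):
        raise ValueError("delta and gamma must be > 0")
    num = delta * np.power(p, gamma)
    out = num / (num + np.power(1.0 - p, gamma))
    return out if out.ndim else float(out)


def w_prelec(p, delta: float, gamma: float):
    """Prelec weighting exp(-delta*(-ln p)^gamma); w(0)=0 by continuity.

    Elevation convention is inverted relative to the Lattimore form: the
    curve is *lower* for larger delta.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    if not (delta > 0 and gamma > 0):
        raise ValueError("delta and gamma must be > 0")
    with np.errstate(divide="ignore"):
        out = np.where(p > 0, np.exp(-delta * np.power(-np.log(np.maximum(p, 1e-300)), gamma)), 0.0)
    return out if out.ndim else float(out)


def weighting_function(p, delta: float, gamma: float, form: WeightingForm):
    if form == "lattimore":
        return w_lattimore(p, delta, gamma)
    if form == "prelec":
        return w_prelec(p, delta, gamma)
    if form == "none":
        return np.asarray(p, dtype=float) if np.ndim(p) else float(p)
    raise ValueError(f"unknown weighting form {form!r}")


def predicted_ce(gamble: Gamble, alpha: float, w_of_p: float) -> float:
    """Model-implied CE magnitude: [w*(x^a - y^a) + y^a]^(1/a); in [y, x]."""
    if not alpha > 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if not (0 <= w_of_p <= 1):
        raise ValueError(f"w(p) must lie in [0, 1], got {w_of_p}")
    u = w_of_p * (gamble.x**alpha - gamble.y**alpha) + gamble.y**alpha
    return float(u ** (1.0 / alpha))


def weight_from_ce(ce: float, x: float, alpha: float) -> float:
    """Invert the CE formula at y = 0: w = (CE/x)**alpha.

    Exact inverse of :func:`predicted_ce` for zero-floor gambles; the caller
    is responsible for excluding CEs above x (monotonicity violations).
    """
    if not x > 0:
        raise ValueError(f"x must be > 0, got {x}")
    if not alpha > 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if ce < 0 or ce > x * (1.0 + 1e-12):
        raise ValueError(f"CE magnitude {ce} outside [0, {x}]")
    return float(min(ce / x, 1.0) ** alpha)
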