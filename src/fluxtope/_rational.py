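"""Exact rational helpers shared across the package.

All model data and all polyhedral computations are carried out in
:class:`fractions.Fraction`. Unbounded bound values are represented as
``None`` (context decides the sign). Floating-point input is converted via
its shortest decimal representation, so e.g. ``0.5`` becomes ``1/2`` and
``12.77`` becomes ``1277/100`` exactly.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Iterable, Optional

Rat = Fraction
Bound = Optional[Fraction]  # None = unbounded (sign given by context)


def to_rational(x) -> Fraction:
    """Convert int/str/float to an exact Fraction.

    Floats go through their decimal string form (exact decimal-to-rational
    conversion), not their binary expansion.
    """
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    if isinstance(x, float):
        if math.isinf(x) or math.isnan(x):
            raise ValueError(f"non-finite float {x!r} has no rational value")
        return Fraction(str(x))
    if isinstance(x, str):
        return Fraction(x.strip())
    raise TypeError(f"cannot convert {type(x).__name__} to rational")


def parse_bound(token: str, default: Bound) -> Bound:
    token = token.strip()
    if token == "":
        return default
    if token in ("inf", "+inf", "-inf", "INF", "+INF", "-INF"):
        return None
    return to_rational(token)


def format_rational(x: Bound, *, inf_sign: str = "+") -> str:
    if x is None:
        return inf_sign + "inf"
    if x.denominator == 1:
        return str(x.numerator)
    return f"{x.numerator}/{x.denominator}"


def primitive(vec: Iterable[Fraction]) -> list[Fraction]:
    """Scale a rational vector to a primitive integer vector (gcd 1).

    The zero vector is returned unchanged.
    """
    v = list(vec)
    denoms = [f.denominator for f in v if f != 0]
    if not denoms:
        return v
    lcm = 1
    for d in denoms:
        lcm = lcm * d // math.gcd(lcm, d)
    ints = [f * lcm for f in v]
    g = 0
    for f in ints:
        g = math.gcd(g, abs(f.numerator))
    return [f / g for f in ints]


def canonical_sign(vec: list[Fraction]) -> list[Fraction]:
    """Flip the sign so the first nonzero coordinate is positive."""
    for f in vec:
        if f != 0:
            return vec if f > 0 else [-x for x in vec]
    return vec
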