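"""Small shared helpers: report rounding and seed handling."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

DEFAULT_SEED = 20171014  # fixed default so unseeded runs stay reproducible


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, the convention used in the report tables.

    Python's built-in ``round`` is banker's rounding; clinical tables
    conventionally print 2.25 -> 2.3.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(x: float, ndigits: int = 1) -> float:
    """Proportion -> percent, rounded half-up to ``ndigits`` decimals."""
    return round_half_up(100.0 * x, ndigits)
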