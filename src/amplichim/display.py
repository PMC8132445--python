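"""Report-time rounding and formatting helpers.

Estimates are kept at full precision internally; rounding happens only when a
number is displayed, using round-half-up (the convention of the experiment
tables this package reproduces, where e.g. 18.75 prints as 18.8).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(x: float) -> str:
    """One-decimal percentage with trailing '.0' trimmed ('16', '42.9', '100')."""
    r = round_half_up(x, 1)
    return f"{r:.1f}".rstrip("0").rstrip(".")
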