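"""Small shared helpers: rounding conventions and nucleotide utilities."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (half-up), not banker's rounding.

    Percentages in summary tables are conventionally rounded half-up;
    Python's built-in ``round`` rounds half-to-even, which differs on
    exact .5 ties.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def truncate_to(x: float, ndigits: int = 0) -> float:
    """Truncate toward zero at ``ndigits`` decimals (compatibility mode)."""
    factor = 10 ** ndigits
    return int(x * factor) / factor


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def pct(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage rounded half-up; 0 for an empty denominator."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, ndigits)
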