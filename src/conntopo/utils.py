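"""Small numeric helpers: printed-precision comparison of exact values.

Published descriptor tables print small integers exactly and large ones in
scientific notation with ~6 significant digits; comparisons against such
tables must round the exact computed integer to the printed precision.
"""

from __future__ import annotations

import math
from decimal import Decimal
from fractions import Fraction

__all__ = ["round_sig", "printed_sig_digits", "matches_printed"]


def round_sig(value, sig: int):
    """Round an int/float to ``sig`` significant digits (exact for ints)."""
    if value == 0:
        return 0
    if isinstance(value, int):
        exp = len(str(abs(value))) - sig
        if exp <= 0:
            return value
        q = 10 ** exp
        # round-half-up on the integer, avoiding float error
        return ((abs(value) + q // 2) // q) * q * (1 if value > 0 else -1)
    exp = math.floor(math.log10(abs(value)))
    q = 10.0 ** (exp - sig + 1)
    return round(value / q) * q


def printed_sig_digits(printed: str) -> int:
    """Number of significant digits in a printed numeral like '7.46807e12'."""
    mant = printed.lower().split("e")[0].replace(",", "").replace("-", "")
    digits = mant.replace(".", "").lstrip("0")
    return len(digits)


def matches_printed(printed: str, value) -> bool:
    """True if ``value`` rounds to the printed numeral at its own precision.

    ``printed`` may be a plain integer ('4096', '192,080,000') or scientific
    notation ('7.46807e12'); the comparison is exact in integer arithmetic.
    """
    cleaned = printed.replace(",", "").strip()
    sig = printed_sig_digits(cleaned)
    target = Fraction(Decimal(cleaned))
    if "e" not in cleaned.lower() and "." not in cleaned:
        return int(target) == value
    rounded = round_sig(int(value) if float(value).is_integer() else value, sig)
    tol = abs(target) * Fraction(1, 10 ** sig) * 5
    return abs(Fraction(rounded) - target) <= tol
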