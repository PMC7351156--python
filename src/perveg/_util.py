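"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, matching tabular display conventions.

    Python's built-in ``round`` uses banker's rounding on top of binary
    floats (``round(2.45, 1) == 2.4``), which does not match how published
    tables are rounded. Decimal quantisation of the shortest repr avoids both
    pitfalls.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
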