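"""Display rounding helpers.

All chained computations in this package run at full double precision;
rounding is applied only when a number is displayed or written to a report.
Two conventions coexist because the published tables use both: ratios per Mb
display with banker's (half-even) rounding at two decimals, while per-row
harvest percentages display as integers with half-up rounding.
"""

from decimal import ROUND_HALF_UP, Decimal


def round2(x: float) -> float:
    """Half-even rounding to 2 decimals (ratio / mean / percentage display)."""
    return round(float(x), 2)


def pct_int(x: float) -> int:
    """Half-up rounding of a percentage to an integer (tally-row display)."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))
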