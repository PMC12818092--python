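"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero, as tables are conventionally printed.

    Python's builtin ``round`` is banker's rounding (87.25 -> 87.2); reported
    percentages use half-up (87.25 -> 87.3).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def largest_remainder_percentages(counts: dict) -> dict:
    """Integer percentages that sum to exactly 100 (largest-remainder method).

    Plain per-entry rounding of frequency tables can sum to 99 or 101; the
    largest-remainder (Hare) apportionment keeps the printed column consistent.
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    raw = {k: 100.0 * v / total for k, v in counts.items()}
    floors = {k: int(raw[k]) for k in counts}
    shortfall = 100 - sum(floors.values())
    order = sorted(counts, key=lambda k: raw[k] - floors[k], reverse=True)
    for k in order[:shortfall]:
        floors[k] += 1
    return floors
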