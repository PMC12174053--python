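"""Shared display-rounding helpers for summary tables."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half away from zero at *decimals* places (display convention)."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, decimals: int = 1) -> float:
    """count/total as a percentage, rounded half-up for display."""
    if total == 0:
        return 0.0
    return round_half_up(100.0 * count / total, decimals)
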