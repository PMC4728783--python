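"""Composition reporting with round-half-up percentages."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping

__all__ = ["percentage", "composition_report"]


def percentage(part: int, total: int, decimals: int = 1) -> float:
    """100 * part / total, rounded half-up to ``decimals`` places."""
    if total <= 0:
        raise ValueError("total must be positive")
    if part < 0 or part > total:
        raise ValueError(f"part {part} outside [0, {total}]")
    quantum = Decimal(1).scaleb(-decimals)
    value = (Decimal(part) * 100 / Decimal(total)).quantize(quantum, rounding=ROUND_HALF_UP)
    return float(value)


def composition_report(counts: Mapping[str, int], total: int,
                       decimals: int = 1) -> dict[str, float]:
    """Per-label percentage table of labeled parts against a shared total."""
    return {label: percentage(part, total, decimals=decimals)
            for label, part in counts.items()}
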