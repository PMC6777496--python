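"""Shared helpers: configuration errors, funnel logging, rounding."""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal

logger = logging.getLogger("growthnet")


class ConfigurationError(ValueError):
    """Invalid configuration value; the message names the offending field."""


def log_filter(stage: str, n_in: int, n_out: int) -> None:
    """One structured line per filter step: records in -> records out."""
    logger.info("%s: %d in -> %d out (%d removed)", stage, n_in, n_out, n_in - n_out)


def percent(numerator: float, denominator: float, decimals: int = 0) -> float:
    """Percentage rounded half-up to `decimals` places (92/254 -> 36, 6/63 -> 9.5)."""
    if denominator == 0:
        return 0.0
    quantum = Decimal(1).scaleb(-decimals)
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))
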