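"""Small shared helpers: reporting-grade rounding and seeded RNG fan-out."""

from __future__ import annotations

import zlib
from decimal import Decimal, ROUND_HALF_UP

import numpy as np


def round_half_up(x: float, decimals: int = 1) -> float | int:
    """Round with ties away from zero (the convention of printed tables).

    Returns an int when ``decimals == 0``.
    """
    q = Decimal(1).scaleb(-decimals)
    v = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return int(v) if decimals == 0 else float(v)


def ratio_percent(num: int | float, den: int | float, decimals: int = 1,
                  mode: str = "half_up") -> float | int:
    """100 * num / den rounded for reporting.

    ``mode`` is ``half_up`` (tables, abstracts) or ``truncate`` (floor at the
    requested precision); both conventions occur in published summaries.
    """
    if den <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(num) * 100 / Decimal(den)
    q = Decimal(1).scaleb(-decimals)
    if mode == "half_up":
        v = pct.quantize(q, rounding=ROUND_HALF_UP)
    elif mode == "truncate":
        v = pct.quantize(q, rounding="ROUND_DOWN")
    else:
        raise ValueError(f"unknown rounding mode {mode!r}")
    return int(v) if decimals == 0 else float(v)


def substream(seed: int, label: str) -> np.random.Generator:
    """Independent generator for (seed, label).

    Fanning out by a stable label hash keeps each simulated fixture
    byte-reproducible even when new fixtures are added next to it.
    """
    return np.random.default_rng([int(seed) & 0x7FFFFFFF,
                                  zlib.crc32(label.encode())])
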