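"""Small shared helpers."""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "child_seed"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero.

    Report tables round half-up (31.575 -> 31.58, -25.625 -> -25.63) rather
    than using Python's banker's rounding.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def child_seed(root_seed: int, stream: int) -> int:
    """Derive a per-generator seed from one root seed.

    Each generator owns a fixed stream index, so adding a new generator never
    perturbs the draws of existing ones. Result stays below 2**31.
    """
    return (int(root_seed) * 1_000_003 + int(stream) * 7_919 + 12_345) % (2**31)
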