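"""Small shared helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero.

    Table rendering uses commercial (half-up) rounding, not banker's
    rounding, so 0.125 -> 0.13 and -6.35 -> -6.4.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def seeded_rng(seed: int, *stream: str) -> np.random.Generator:
    """Generator for a named sub-stream of a global seed.

    Each component draws from its own stream so that re-running one
    stage of a pipeline does not perturb the draws of another.
    """
    words = [int(seed)] + [int.from_bytes(s.encode(), "little") % (2 ** 32)
                           for s in stream]
    return np.random.default_rng(np.random.SeedSequence(words))
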