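"""Small shared helpers."""

import math


def round_half_up(x: float) -> int:
    """Round a non-negative number to the nearest integer, halves upward.

    Python's built-in ``round`` uses banker's rounding (0.5 -> 0); display
    percentages and the point-scoring rule both need the conventional
    half-up behaviour (6.5 -> 7).
    """
    if x < 0:
        raise ValueError(f"round_half_up expects a non-negative value, got {x}")
    return int(math.floor(x + 0.5))
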