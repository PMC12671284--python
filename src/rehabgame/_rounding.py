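"""Report rounding helpers.

Printed tables round half away from zero, which differs from Python's
built-in banker's rounding for exact .5 values.
"""

from __future__ import annotations

import math


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero."""
    if not math.isfinite(x):
        raise ValueError(f"cannot round non-finite value {x!r}")
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)
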