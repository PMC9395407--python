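"""Small shared helpers."""

from __future__ import annotations

import math


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero, as printed tables do.

    Python's built-in round() is banker's rounding; descriptive tables in
    the livestock-CNV literature round 0.5 up, so summaries use this.
    """
    factor = 10.0**ndigits
    scaled = x * factor
    if scaled >= 0:
        return math.floor(scaled + 0.5) / factor
    return math.ceil(scaled - 0.5) / factor


def round_half_up_int(x: float) -> int:
    return int(round_half_up(x, 0))


def normalize_chrom(name: object) -> str:
    """Strip a leading 'chr'/'Chr' prefix and surrounding whitespace."""
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s
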