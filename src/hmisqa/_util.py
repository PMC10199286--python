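"""Small numeric helpers shared across modules."""

from __future__ import annotations

import math
import zlib


def round_half_up(x: float) -> int:
    """Round a non-negative value to the nearest integer, ties away from zero.

    Report tables print integer percentages; banker's rounding (Python's
    built-in ``round``) would map 97.5 to 98 but 98.5 to 98, whereas the
    display convention here is half-up (97.5 -> 98, 98.5 -> 99).
    """
    if x < 0:
        return -round_half_up(-x)
    return int(math.floor(x + 0.5))


def stable_stream_key(label: str) -> int:
    """Deterministic 32-bit key for a named random substream.

    CRC32 of the label, so the draw sequence of one indicator does not
    depend on which other indicators are configured.
    """
    return zlib.crc32(label.encode("utf-8"))
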