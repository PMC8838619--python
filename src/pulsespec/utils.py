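"""Small shared numerical helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_phase_deg", "spawn_seed"]


def wrap_phase_deg(phi):
    """Map phase angles in degrees onto the principal interval (-180, 180].

    Accepts scalars or arrays; always returns float(s). The right-closed
    convention means +180 and -180 both map to +180, so a phase value never
    compares unequal to itself after a round trip through the wrap.
    """
    phi = np.asarray(phi, dtype=float)
    wrapped = -((-phi + 180.0) % 360.0 - 180.0)
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


def spawn_seed(*keys: int) -> int:
    """Derive a reproducible 31-bit integer seed from a tuple of integers.

    Uses :class:`numpy.random.SeedSequence` so derived streams are
    statistically independent across distinct key tuples.
    """
    state = np.random.SeedSequence([int(k) for k in keys]).generate_state(1)[0]
    return int(state % (2**31))
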