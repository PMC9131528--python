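"""Deterministic seed fan-out: one global seed -> independent child seeds."""

from __future__ import annotations

import numpy as np


def child_seeds(seed: int | None, n: int) -> list[int]:
    """Spawn ``n`` independent 31-bit child seeds from one global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]
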