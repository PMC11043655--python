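"""Stable, label-derived random seeding.

Every stochastic step in the package (surrogate lags, synthetic noise,
permutation draws) gets its own generator derived from a master seed plus
string labels, via SHA-256.  This keeps cohort runs reproducible across
processes and independent of evaluation order; Python's builtin ``hash`` is
salted per process and must not be used here.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["seed_sequence", "rng_for"]


def seed_sequence(*parts: object) -> np.random.SeedSequence:
    """Deterministic SeedSequence from an arbitrary tuple of labels."""
    token = "\x1f".join(str(p) for p in parts)
    digest = hashlib.sha256(token.encode("utf-8")).digest()
    entropy = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
    return np.random.SeedSequence(entropy)


def rng_for(*parts: object) -> np.random.Generator:
    """Deterministic Generator keyed by ``parts``."""
    return np.random.default_rng(seed_sequence(*parts))
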