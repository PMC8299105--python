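"""Small shared helpers (seed derivation, validation)."""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(master_seed: int, label: str) -> int:
    """Derive a reproducible 31-bit child seed from a master seed and a label.

    Used so that pipeline stages (and per-pair bootstrap streams) are
    independently reproducible and invariant to evaluation order.
    """
    h = hashlib.blake2b(f"{int(master_seed)}:{label}".encode(), digest_size=4)
    return int.from_bytes(h.digest(), "big") % (2**31)


def check_finite(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a
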