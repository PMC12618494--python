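"""Deterministic per-stage seed derivation from one global seed."""

import hashlib

import numpy as np


def derive_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Derive a reproducible stage seed (< 2**31) from a master seed.

    Stages drawing independent randomness get distinct, stable streams;
    identical (master_seed, stage, index) always yields the same value.
    """
    digest = hashlib.sha256(f"{int(master_seed)}:{stage}:{int(index)}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def rng_for(master_seed: int, stage: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, stage, index))
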