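"""Shared helpers: seeded random streams and stage logging."""

from __future__ import annotations

import logging
import zlib

import numpy as np

logger = logging.getLogger("phylosalt")

#: the four origin x host treatment codes, in canonical order
TREATMENTS = ("FF", "FS", "SF", "SS")

#: salinity preference labels, in canonical order
PREFERENCES = ("fresh", "salt", "none", "unclassified")


def derive_rng(seed: int | None, stage: str) -> np.random.Generator:
    """Deterministic per-stage random stream derived from one pipeline seed.

    Each randomized stage gets an independent stream keyed by its name, so
    adding or reordering stages never perturbs the draws of another stage.
    """
    if seed is None:
        return np.random.default_rng()
    salt = zlib.crc32(stage.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), salt]))


def log_stage(stage: str, **fields) -> None:
    """One structured log line per pipeline stage."""
    payload = " ".join(f"{k}={v}" for k, v in fields.items())
    logger.info("stage=%s %s", stage, payload)
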