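"""Shared plumbing: error types, seeded RNG streams, logging setup."""

from __future__ import annotations

import logging
import zlib

import numpy as np

log = logging.getLogger("meddecode")
if not log.handlers:  # library default: quiet unless the app configures logging
    log.addHandler(logging.NullHandler())


class FormatError(ValueError):
    """Malformed input file or table (wrong columns, wrong shape)."""


class ValidationError(ValueError):
    """Well-formed input that violates a domain invariant."""


class ConfigurationError(ValueError):
    """Configuration values that are out of range or mutually inconsistent."""


def _key_to_int(key: int | str) -> int:
    if isinstance(key, (int, np.integer)):
        if key < 0:
            raise ValueError("seed keys must be non-negative")
        return int(key)
    return zlib.crc32(key.encode("utf-8"))


def rng_stream(master_seed: int, *keys: int | str) -> np.random.Generator:
    """Deterministic named RNG stream derived from a master seed.

    Every stochastic component draws from its own stream labelled by
    (master_seed, stage label, indices...), so any subset of the pipeline is
    reproducible in isolation.
    """
    entropy = [_key_to_int(master_seed)] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
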