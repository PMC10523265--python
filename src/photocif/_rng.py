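"""Seed-splitting utilities.

One user-facing integer seed is expanded into independent named streams via
``numpy.random.SeedSequence`` spawn keys derived from CRC32 hashes of the
stream labels.  The mapping is stable across sessions and platforms, so any
(seed, labels) pair always yields the same stream.
"""
from __future__ import annotations

import zlib

import numpy as np


def stream_rng(seed: int, *labels: object) -> np.random.Generator:
    """Return a Generator for the stream named by ``labels`` under ``seed``.

    Labels may be strings or integers; they are hashed with CRC32 into the
    SeedSequence spawn key, so distinct label tuples give independent
    streams and identical tuples reproduce the same stream.
    """
    key = tuple(zlib.crc32(str(lab).encode("utf-8")) for lab in labels)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))
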