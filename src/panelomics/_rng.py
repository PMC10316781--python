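"""Seed-stream management.

Every source of randomness in the package descends from a single root
seed through named streams: ``stream(seed, name)`` returns a
``numpy.random.Generator`` seeded by ``SeedSequence(seed, spawn_key=(k,))``
where ``k`` is the stable index of ``name`` in :data:`STREAMS`.  Stages are
therefore independently reproducible: regenerating only the STR genotypes
for a given root seed yields the same table whether or not the other
generators ran first.
"""

from __future__ import annotations

import numpy as np

# Stable stream registry; append only, never reorder.
STREAMS = (
    "annotation",
    "sequence",
    "str_catalog",
    "expression",
    "module_membership",
    "celltype",
    "variants",
    "str_genotypes",
    "repeats",
    "cncr",
    "ewce",
    "selection",
    "embedding",
    "misc",
)

_INDEX = {name: i for i, name in enumerate(STREAMS)}


def stream(seed: int, name: str) -> np.random.Generator:
    """Return the named child generator of the root seed."""
    try:
        key = _INDEX[name]
    except KeyError:
        raise KeyError(f"unknown RNG stream {name!r}; known: {STREAMS}") from None
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def substream(seed: int, name: str, index: int) -> np.random.Generator:
    """A per-replicate child: stream ``name`` further split by ``index``."""
    key = _INDEX[name]
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key, int(index))))
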