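"""Seed fan-out and small shared helpers.

Every source of randomness in the package draws from a named substream of a
single root seed, so that any stage re-run in isolation reproduces the exact
stream it saw inside a full pipeline run.
"""
from __future__ import annotations

import numpy as np

# Fixed registry of per-stage substreams. The spawn key, not the name string,
# enters the bit generator, so renaming a stage would break reproducibility --
# append new stages at the end instead.
_SUBSTREAMS = {
    "expression": 0,
    "perturbagens": 1,
    "bibliometrics": 2,
    "gene_sets": 3,
    "connectivity_perm": 4,
    "enrichment_perm": 5,
    "plot_jitter": 6,
}


def substream(seed: int, stage: str) -> np.random.Generator:
    """Return the dedicated random generator for *stage* under a root seed."""
    try:
        key = _SUBSTREAMS[stage]
    except KeyError:
        raise KeyError(
            f"unknown random substream {stage!r}; known: {sorted(_SUBSTREAMS)}"
        ) from None
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))
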