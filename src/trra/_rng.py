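"""Named, reproducible random substreams.

All randomness in the package flows from one master seed.  Each generator
draws from its own substream so that adding draws to one stage never
perturbs another.
"""

from __future__ import annotations

import numpy as np

# Fixed stream identifiers; appending new names is safe, reordering is not.
_STREAMS = {
    "genomes": 1,
    "scores": 2,
    "expression": 3,
    "simulation": 4,
    "pipeline": 5,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Return the named child generator of ``seed``.

    The same ``(seed, name)`` pair always yields a bit-identical stream.
    """
    try:
        key = _STREAMS[name]
    except KeyError:  # pragma: no cover - programming error
        raise KeyError(f"unknown RNG stream {name!r}") from None
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))
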