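"""Named, independent random substreams derived from one master seed.

Every stochastic stage of a simulation (wiring, grid-cell parameters,
storage subset, cue corruption, ...) draws from its own named stream so
that changing one stage never perturbs the others.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def substream_seed(master_seed: int, name: str) -> int:
    """Deterministic 31-bit seed for the substream `name` under `master_seed`."""
    digest = hashlib.blake2b(name.encode("utf-8"), digest_size=4).digest()
    return (int.from_bytes(digest, "little") ^ (master_seed & 0x7FFFFFFF)) & 0x7FFFFFFF


def substream(master_seed: int, name: str) -> np.random.Generator:
    """A numpy Generator seeded by (master_seed, name)."""
    return np.random.default_rng(
        np.random.SeedSequence([master_seed & 0x7FFFFFFF, substream_seed(0, name)])
    )
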