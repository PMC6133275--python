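"""Named, reproducible random substreams.

Every stochastic stage of the pipeline draws from its own substream, keyed
by a master seed plus a tuple of string/integer tokens (e.g.
``("species", 3, "automaton")``).  Adding a new species or stage therefore
never perturbs the draws of existing ones.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream"]


def _token_entropy(tokens: tuple) -> list[int]:
    out = []
    for tok in tokens:
        h = hashlib.blake2b(repr(tok).encode(), digest_size=4)
        out.append(int.from_bytes(h.digest(), "little"))
    return out


def substream(master_seed: int, *tokens) -> np.random.Generator:
    """Return a Generator for the substream named by ``tokens``.

    The mapping (master_seed, tokens) -> stream is a pure function:
    identical arguments give an identical stream on every platform.
    """
    entropy = [int(master_seed) & 0x7FFFFFFF] + _token_entropy(tokens)
    return np.random.default_rng(np.random.SeedSequence(entropy))
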