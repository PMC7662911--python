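"""Named random substreams derived from a single run seed.

Each consumer of randomness (initialization, mutation, perturbation, the
scenario generator, ...) draws from its own stream keyed by name, so adding
or reordering draws in one component never shifts another's sequence.
"""

from __future__ import annotations

import hashlib

__all__ = ["substream"]


def substream(seed: int, name: str) -> int:
    """A reproducible 31-bit child seed for the named stream."""
    digest = hashlib.sha256(f"{int(seed)}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
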