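"""Deterministic DICOM UID generation under a configurable root."""

from __future__ import annotations

import numpy as np
from pydicom.uid import UID

__all__ = ["UidFactory", "DEFAULT_UID_ROOT"]

#: pydicom's registered UID root; instances minted here hang off a fixed arc.
DEFAULT_UID_ROOT = "1.2.826.0.1.3680043.8.498.1"


class UidFactory:
    """Mint hierarchical DICOM UIDs, reproducibly when seeded.

    With a seed, the sequence of UIDs is a pure function of (root, seed),
    so a re-run of a conversion yields byte-identical identifiers.  Without
    a seed the entropy source is the OS RNG.
    """

    def __init__(self, root: str = DEFAULT_UID_ROOT, seed: int | None = None):
        if not root or not all(part.isdigit() for part in root.split(".")):
            raise ValueError(f"invalid UID root: {root!r}")
        self.root = root.rstrip(".")
        self._rng = np.random.default_rng(seed)
        self._counter = 0

    def new_uid(self) -> str:
        self._counter += 1
        entropy = self._rng.integers(0, 10**12)
        uid = f"{self.root}.{entropy}.{self._counter}"
        if len(uid) > 64:
            raise ValueError(f"UID exceeds 64 characters: {uid}")
        assert UID(uid).is_valid
        return uid
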