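"""Deterministic, random-access synthetic reference sequence.

The breakpoint-assembly step needs to compare read tails against reference
sequence near the deletion flanks. Rather than materializing a whole
chromosome, bases are derived on demand from a keyed hash of the block index,
so any interval can be fetched lazily and reproducibly for a given seed.
This sequence is synthetic: it has uniform base composition and no repeat
structure.
"""

from __future__ import annotations

import hashlib

_BASES = "ACGT"
_BLOCK = 16  # bases per hash block


class SyntheticReference:
    """Callable reference: ``fetch(start, end)`` with 1-based inclusive bounds."""

    def __init__(self, seed: int, chrom: str = "2", length: int = 120_000_000):
        self.seed = int(seed)
        self.chrom = chrom
        self.length = int(length)

    def _block(self, idx: int) -> str:
        h = hashlib.blake2b(
            idx.to_bytes(8, "little"),
            key=self.seed.to_bytes(8, "little", signed=False),
            digest_size=8,
        ).digest()
        # 2 bits per base, 4 bases per byte
        out = []
        for byte in h[: _BLOCK // 4]:
            for shift in (0, 2, 4, 6):
                out.append(_BASES[(byte >> shift) & 3])
        return "".join(out)

    def fetch(self, start: int, end: int) -> str:
        """Sequence of positions ``start..end`` (1-based inclusive)."""
        if start < 1 or end > self.length or end < start:
            raise ValueError(f"interval ({start}, {end}) outside reference 1..{self.length}")
        first = (start - 1) // _BLOCK
        last = (end - 1) // _BLOCK
        seq = "".join(self._block(i) for i in range(first, last + 1))
        off = (start - 1) - first * _BLOCK
        return seq[off : off + (end - start + 1)]

    def __call__(self, start: int, end: int) -> str:
        return self.fetch(start, end)
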