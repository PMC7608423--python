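"""Fixed-length bit-vector carrier sets.

A carrier set marks which of the N study individuals carry at least one
minor allele at a variant site or in a bin (a union of sites). Sets are
stored as Python arbitrary-precision integers: bitwise OR / AND and
``int.bit_count()`` are constant-factor fast for the study sizes this
package targets, and integer equality doubles as set equality.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CarrierSet", "mask_from_bools", "bools_from_mask"]


def mask_from_bools(bits: np.ndarray) -> int:
    """Pack a boolean vector (index 0 = lowest bit) into an int mask."""
    packed = np.packbits(np.asarray(bits, dtype=bool), bitorder="little")
    return int.from_bytes(packed.tobytes(), "little")


def bools_from_mask(mask: int, n: int) -> np.ndarray:
    """Unpack an int mask into a length-``n`` boolean vector."""
    nbytes = (n + 7) // 8
    raw = np.frombuffer(mask.to_bytes(nbytes, "little"), dtype=np.uint8)
    return np.unpackbits(raw, bitorder="little")[:n].astype(bool)


class CarrierSet:
    """Set of carrier individuals over a study of fixed size ``n``.

    Parameters
    ----------
    mask : int
        Bitmask; bit ``b`` set iff individual ``b`` is a carrier.
    n : int
        Number of individuals in the study (constant across a study).
    """

    __slots__ = ("mask", "n", "_popcount")

    def __init__(self, mask: int, n: int):
        if mask < 0:
            raise ValueError("carrier mask must be non-negative")
        if mask >> n:
            raise ValueError(f"carrier mask has bits beyond n={n}")
        self.mask = mask
        self.n = n
        self._popcount = mask.bit_count()

    @classmethod
    def from_indices(cls, indices, n: int) -> "CarrierSet":
        mask = 0
        for i in indices:
            mask |= 1 << int(i)
        return cls(mask, n)

    @classmethod
    def from_bools(cls, bits: np.ndarray) -> "CarrierSet":
        bits = np.asarray(bits, dtype=bool)
        return cls(mask_from_bools(bits), bits.size)

    @property
    def popcount(self) -> int:
        return self._popcount

    @property
    def is_empty(self) -> bool:
        return self.mask == 0

    @property
    def is_full(self) -> bool:
        return self._popcount == self.n

    def indices(self) -> np.ndarray:
        return np.nonzero(self.to_bools())[0]

    def to_bools(self) -> np.ndarray:
        return bools_from_mask(self.mask, self.n)

    def union(self, other: "CarrierSet") -> "CarrierSet":
        self._check(other)
        return CarrierSet(self.mask | other.mask, self.n)

    __or__ = union

    def intersection_count(self, other_mask: int) -> int:
        """Popcount of the intersection with a raw int mask."""
        return (self.mask & other_mask).bit_count()

    def _check(self, other: "CarrierSet") -> None:
        if self.n != other.n:
            raise ValueError("carrier sets belong to studies of different size")

    def __eq__(self, other) -> bool:
        if not isinstance(other, CarrierSet):
            return NotImplemented
        return self.n == other.n and self.mask == other.mask

    def __hash__(self) -> int:
        return hash((self.mask, self.n))

    def __len__(self) -> int:
        return self._popcount

    def __repr__(self) -> str:
        return f"CarrierSet(popcount={self._popcount}, n={self.n})"
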