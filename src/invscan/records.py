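"""Core sequence containers and k-mer machinery shared by all stages.

Sequences are plain uppercase DNA strings over ``{A, C, G, T, N}``; internally
they are encoded as ``uint8`` arrays (A=0, C=1, G=2, T=3, N=4) so that k-mer
codes, reverse complements and window scans are vectorised numpy operations.
All coordinates are 0-based half-open internally; report writers convert to
1-based closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_ALPHABET = "ACGTN"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte value -> code lookup (A=0 C=1 G=2 T=3 N=4, everything else 255)
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(_ALPHABET):
    _ENC[ord(_c)] = _i
_DEC = np.frombuffer(_ALPHABET.encode(), dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 code array."""
    arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() == 255:
        bad = int(np.argmax(arr == 255))
        raise ValueError(f"invalid DNA character {seq[bad]!r} at position {bad}")
    return arr


def decode(arr: np.ndarray) -> str:
    """Decode a uint8 code array back to a DNA string."""
    return _DEC[arr].tobytes().decode("ascii")


def revcomp_codes(arr: np.ndarray) -> np.ndarray:
    """Reverse complement on code arrays; N (4) is preserved."""
    out = arr[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


@dataclass
class SequenceRecord:
    """A named DNA sequence with provenance coordinates.

    ``origin_offset`` is the coordinate of base 0 in the parent coordinate
    system (a chromosome region is stored as offset + length rather than as a
    full-chromosome string); ``build_tag`` names the assembly build the
    coordinates refer to.
    """

    id: str
    seq: str
    origin_offset: int = 0
    build_tag: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("sequence must be nonempty")
        if self.origin_offset < 0:
            raise ValueError("origin_offset must be >= 0")
        if not set(self.seq) <= set(_ALPHABET):
            bad = sorted(set(self.seq) - set(_ALPHABET))
            raise ValueError(f"sequence contains invalid characters: {bad}")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def codes(self) -> np.ndarray:
        return encode(self.seq)

    def reverse_complement(self, id_suffix: str = "_rc") -> "SequenceRecord":
        return SequenceRecord(
            id=self.id + id_suffix,
            seq=revcomp(self.seq),
            origin_offset=self.origin_offset,
            build_tag=self.build_tag,
        )


def kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of all k-mers of a code array.

    Returns ``(codes, valid)`` where ``codes[i]`` encodes ``arr[i:i+k]`` in
    base 4 (most significant base first) and ``valid[i]`` is False for windows
    containing N. Requires ``k <= 31`` so codes fit in int64.
    """
    if k > 31:
        raise ValueError("k must be <= 31 for int64 k-mer codes")
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    a = arr.astype(np.int64)
    is_n = (arr == 4).astype(np.int64)
    a = np.where(arr == 4, 0, a)
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes += a[j : j + n] << (2 * (k - 1 - j))
    cs = np.concatenate(([0], np.cumsum(is_n)))
    valid = (cs[k:] - cs[:-k]) == 0
    return codes, valid
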