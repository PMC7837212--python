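"""Small nucleotide-sequence helpers shared across the package.

Sequences are plain upper-case strings over ``ACGTN``. For numeric work they
are encoded as ``uint8`` codes 0-3 (A, C, G, T) with 4 for N/anything else;
N never matches anything in alignment scoring.
"""

from __future__ import annotations

import hashlib

import numpy as np

BASES = "ACGT"

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lower case

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def check_alphabet(seq: str, name: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"{name} must be non-empty")
    if set(seq) - set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"{name} contains characters outside ACGTN: {bad}")


def derive_seed(seed: int, *labels: str) -> int:
    """Stable sub-stream seed from a top-level seed and string labels.

    Uses SHA-256 so that adding samples never perturbs existing ones and the
    derivation is identical across platforms and Python processes. The result
    fits in 31 bits.
    """
    h = hashlib.sha256()
    h.update(str(int(seed)).encode())
    for lab in labels:
        h.update(b"\x00")
        h.update(str(lab).encode())
    return int.from_bytes(h.digest()[:4], "big") & 0x7FFFFFFF
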