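"""Low-level nucleotide encoding and k-mer machinery shared by the simulator
and the probe-masking scanner.

Bases are encoded A=0, C=1, G=2, T=3; anything else (N, separators) encodes
as 4 and invalidates every window that covers it.  k-mers with k <= 32 are
packed two bits per base into uint64 codes, which lets the masking scanner
compare millions of probe/transcript substring pairs with sorted-array
membership tests instead of string hashing.
"""

from __future__ import annotations

import numpy as np

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[ord(chr(_b).lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

ALPHABET = "ACGT"


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 array (A=0,C=1,G=2,T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def kmer_codes(enc: np.ndarray, k: int, valid: np.ndarray | None = None) -> np.ndarray:
    """Pack every length-k window of an encoded sequence into uint64 codes.

    Parameters
    ----------
    enc : uint8 array of base codes (values >= 4 mark invalid positions).
    k : word size, 1 <= k <= 32.
    valid : optional precomputed boolean mask of valid *positions*; windows
        containing any invalid position are dropped from the output.

    Returns the codes of all fully valid windows (order not guaranteed to be
    positional once filtered).
    """
    if not 1 <= k <= 32:
        raise ValueError(f"k must be in [1, 32], got {k}")
    n = enc.shape[0]
    if n < k:
        return np.empty(0, dtype=np.uint64)
    if valid is None:
        valid = enc < 4
    base = np.where(valid, enc, 0).astype(np.uint64)
    codes = np.zeros(n - k + 1, dtype=np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | base[j : n - k + 1 + j]
    # a window is valid iff it covers no invalid position
    bad = ~valid
    if bad.any():
        cum = np.concatenate(([0], np.cumsum(bad)))
        window_bad = (cum[k:] - cum[:-k]) > 0
        codes = codes[~window_bad]
    return codes


def canonical_kmers(seq: str, k: int) -> set[int]:
    """Strand-canonical k-mer codes of a sequence (min of code and revcomp code).

    Used by the simulator to guarantee that unplanted probes share no k-mer
    with the off-target transcriptome on either strand.
    """
    fwd = kmer_codes(encode(seq), k)
    if fwd.size == 0:
        return set()
    # window i on the forward strand is window (n-k-i) on the reverse strand,
    # so reversing the reverse-strand code array aligns the pairs positionally
    # (sequences here are pure ACGT, so no windows are dropped)
    rev = kmer_codes(encode(revcomp(seq)), k)[::-1]
    return set(np.minimum(fwd, rev).tolist())


def _mismatch_slots(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Number of differing 2-bit slots between packed codes (vectorized)."""
    z = np.bitwise_xor(x, y)
    z |= z >> np.uint64(1)
    z &= np.uint64(0x5555555555555555)
    return np.bitwise_count(z)


def best_identity(
    probe_codes: np.ndarray,
    window_codes: np.ndarray,
    length: int,
    probe_chunk: int = 128,
    window_chunk: int = 1 << 14,
) -> np.ndarray:
    """Best full-length ungapped identity of each probe against any window.

    ``probe_codes`` packs each probe (and typically also its reverse
    complement) as one uint64; ``window_codes`` packs every valid off-target
    window of the same length.  Returns, per probe code, the maximum fraction
    of matching positions over all windows.  Chunked over both axes to keep
    the broadcast temporaries small.
    """
    if window_codes.size == 0 or probe_codes.size == 0:
        return np.zeros(probe_codes.shape[0], dtype=np.float64)
    best = np.zeros(probe_codes.shape[0], dtype=np.int64)
    for p0 in range(0, probe_codes.size, probe_chunk):
        pc = probe_codes[p0 : p0 + probe_chunk][:, None]
        block_best = best[p0 : p0 + probe_chunk]
        for w0 in range(0, window_codes.size, window_chunk):
            block = window_codes[w0 : w0 + window_chunk][None, :]
            mism = _mismatch_slots(pc, block)
            matches = length - mism.min(axis=1).astype(np.int64)
            np.maximum(block_best, matches, out=block_best)
    return best / float(length)
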