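"""Integer encoding of DNA and sliding-window index construction.

Bases map A,C,G,T -> 0..3; anything else encodes as -1 (ambiguous).  The
fitting and scanning code never touches strings in inner loops: sequences
are encoded once into an integer matrix, and every sliding window of motif
length L is represented by flat index arrays into the mononucleotide
(L*4) and dinucleotide ((L-1)*16) parameter vectors.
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError

BASES = "ACGT"

_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode one sequence to int8 codes; ambiguous characters become -1."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_sequences(seqs) -> np.ndarray:
    """Encode equal-length sequences to an (n, len) int8 matrix."""
    seqs = list(seqs)
    if not seqs:
        raise DomainError("no sequences to encode")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise DomainError("sequences must have equal length for matrix encoding")
    joined = "".join(seqs).encode("ascii")
    arr = _LUT[np.frombuffer(joined, dtype=np.uint8)]
    return arr.reshape(len(seqs), lengths.pop())


def decode_codes(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def revcomp_codes(X: np.ndarray) -> np.ndarray:
    """Reverse-complement along the last axis; ambiguity (-1) is preserved."""
    rc = 3 - X[..., ::-1]
    rc[X[..., ::-1] < 0] = -1
    return rc


def revcomp_str(seq: str) -> str:
    comp = str.maketrans("ACGTacgt", "TGCAtgca")
    return seq.translate(comp)[::-1]


def window_view(X: np.ndarray, k: int) -> np.ndarray:
    """All length-k windows of each row: (n, w, k) view, w = len - k + 1."""
    if k > X.shape[-1]:
        raise DomainError(f"window length {k} exceeds sequence length {X.shape[-1]}")
    return np.lib.stride_tricks.sliding_window_view(X, k, axis=-1)


def kmer_codes(W: np.ndarray) -> np.ndarray:
    """Base-4 integer code of each window (first base most significant).

    Windows containing ambiguity codes yield -1.
    """
    k = W.shape[-1]
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = (W.astype(np.int64) * powers).sum(axis=-1)
    codes[(W < 0).any(axis=-1)] = -1
    return codes


def canonical_kmer_codes(W: np.ndarray) -> np.ndarray:
    """min(code, revcomp code) per window; -1 where ambiguous."""
    fwd = kmer_codes(W)
    rev = kmer_codes(revcomp_codes(W))
    canon = np.minimum(fwd, rev)
    canon[(fwd < 0) | (rev < 0)] = -1
    return canon


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def window_design(X: np.ndarray, L: int, both_strands: bool = True):
    """Flat parameter-index arrays for every valid window of every row.

    Returns ``(probe_idx, mono_idx, pair_idx)`` where for window w,
    ``mono_idx[w, i] = 4*i + base_i`` indexes a flattened (L,4) energy
    matrix and ``pair_idx[w, j] = 16*j + 4*base_j + base_{j+1}`` indexes a
    flattened (L-1,16) dinucleotide matrix.  Windows containing ambiguous
    bases are dropped.  With ``both_strands`` the reverse-complement
    windows are appended with the same probe indices.
    """
    if L < 2:
        raise DomainError("motif length must be >= 2")
    strands = [X]
    if both_strands:
        strands.append(revcomp_codes(X))
    probe_parts, mono_parts, pair_parts = [], [], []
    pos4 = 4 * np.arange(L, dtype=np.int32)
    pos16 = 16 * np.arange(L - 1, dtype=np.int32)
    n = X.shape[0]
    for S in strands:
        W = window_view(S, L)              # (n, w, L)
        w = W.shape[1]
        flat = W.reshape(-1, L)
        valid = (flat >= 0).all(axis=1)
        probe = np.repeat(np.arange(n, dtype=np.int32), w)[valid]
        Wv = flat[valid].astype(np.int32)
        mono = pos4[None, :] + Wv
        pair = pos16[None, :] + 4 * Wv[:, :-1] + Wv[:, 1:]
        probe_parts.append(probe)
        mono_parts.append(mono)
        pair_parts.append(pair)
    return (
        np.concatenate(probe_parts),
        np.concatenate(mono_parts),
        np.concatenate(pair_parts),
    )
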