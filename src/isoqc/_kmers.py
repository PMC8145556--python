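"""Shared 2-bit sequence encoding, canonical k-mer extraction and hashing.

Bases are encoded A=0, C=1, G=2, T=3; anything else (incl. N) is 4 and any
k-mer window containing such a base is excluded. K-mers are represented as
64-bit integers (2 bits/base, so k <= 31) and made strand-independent by
taking the minimum of the forward and reverse-complement code ("canonical"
k-mer). Sketch hashing uses splitmix64 of the packed canonical code, which
is fixed so that sketches are reproducible across runs and platforms.
"""

from __future__ import annotations

import numpy as np

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (A,C,G,T -> 0..3, other -> 4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement in code space; non-ACGT codes stay 4."""
    comp = np.where(codes < 4, 3 - codes, np.uint8(4)).astype(np.uint8)
    return comp[::-1] if comp.ndim == 1 else comp[:, ::-1]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def _rolling_codes(vals: np.ndarray, k: int) -> np.ndarray:
    """Packed k-mer integers for every window along the last axis (no N check)."""
    n_win = vals.shape[-1] - k + 1
    out = np.zeros(vals.shape[:-1] + (n_win,), dtype=np.int64)
    for t in range(k):
        out *= 4
        out += vals[..., t : t + n_win]
    return out


def _valid_windows(codes: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of windows free of non-ACGT codes, along the last axis."""
    bad = (codes >= 4).astype(np.int32)
    cb = np.cumsum(bad, axis=-1)
    n_win = codes.shape[-1] - k + 1
    head = cb[..., k - 1 : k - 1 + n_win]
    tail = np.concatenate(
        [np.zeros(codes.shape[:-1] + (1,), dtype=np.int32), cb[..., : n_win - 1]],
        axis=-1,
    )
    return (head - tail) == 0


def kmer_codes(codes: np.ndarray, k: int, canonical: bool = True):
    """Canonical (or forward) k-mer integers and start positions for one sequence.

    Windows containing non-ACGT bases are dropped. Returns ``(kmers, positions)``.
    """
    if codes.shape[-1] < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    vals = codes.astype(np.int64)
    fwd = _rolling_codes(vals, k)
    if canonical:
        rc = _rolling_codes(np.where(codes < 4, 3 - codes, 4).astype(np.int64)[::-1], k)
        fwd = np.minimum(fwd, rc[::-1])
    ok = _valid_windows(codes, k)
    pos = np.nonzero(ok)[0]
    return fwd[pos], pos


def kmer_codes_matrix(
    mat: np.ndarray, k: int, canonical: bool = True, stride: int = 1
) -> np.ndarray:
    """K-mer integers for each row of an (n, L) code matrix.

    Column j holds the window starting at position ``j * stride``; a stride
    above 1 subsamples the windows (the voting and anchoring consumers only
    need a fraction of them). Invalid windows (containing non-ACGT) are set
    to -1. Striding requires ``canonical=False`` (the reverse-strand window
    grid would not line up).
    """
    if mat.shape[1] < k:
        return np.empty((mat.shape[0], 0), dtype=np.int64)
    n_win = mat.shape[1] - k + 1
    if stride == 1:
        vals = mat.astype(np.int64)
        fwd = _rolling_codes(vals, k)
        if canonical:
            rc_mat = np.where(mat < 4, 3 - mat, 4).astype(np.int64)[:, ::-1]
            rc = _rolling_codes(rc_mat, k)[:, ::-1]
            fwd = np.minimum(fwd, rc)
        if (mat >= 4).any():  # N windows only exist when N bases do
            fwd[~_valid_windows(mat, k)] = -1
        return fwd
    if canonical:
        raise ValueError("strided k-mer extraction requires canonical=False")
    m = (n_win + stride - 1) // stride
    out = np.zeros((mat.shape[0], m), dtype=np.int64)
    vals = mat.astype(np.int64)
    for t in range(k):
        out *= 4
        out += vals[:, t : t + n_win : stride]
    if (mat >= 4).any():
        out[~_valid_windows(mat, k)[:, ::stride]] = -1
    return out


def splitmix64(x: np.ndarray) -> np.ndarray:
    """Fixed 64-bit mixing function (splitmix64 finalizer) on uint64 arrays."""
    z = x.astype(np.uint64) + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


class CodeTable:
    """Sorted-array lookup table from k-mer code to a small integer value.

    Duplicate codes must be resolved by the caller before construction.
    Lookup of absent codes yields ``missing`` (default -1).
    """

    def __init__(self, codes: np.ndarray, values: np.ndarray, missing: int = -1):
        order = np.argsort(codes, kind="stable")
        self.codes = np.asarray(codes)[order]
        self.values = np.asarray(values)[order]
        self.missing = missing

    def __len__(self) -> int:
        return len(self.codes)

    def lookup(self, queries: np.ndarray) -> np.ndarray:
        q = np.asarray(queries)
        flat = q.ravel()
        if len(self.codes) == 0:
            return np.full(q.shape, self.missing, dtype=np.int64)
        # searching in sorted-query order is far more cache friendly
        order = np.argsort(flat, kind="stable")
        sorted_q = flat[order]
        idx = np.searchsorted(self.codes, sorted_q)
        idx[idx == len(self.codes)] = 0
        hit = self.codes[idx] == sorted_q
        out_sorted = np.full(flat.shape, self.missing, dtype=np.int64)
        out_sorted[hit] = self.values[idx[hit]]
        out = np.empty_like(out_sorted)
        out[order] = out_sorted
        return out.reshape(q.shape)
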