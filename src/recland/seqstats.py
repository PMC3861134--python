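"""Fast window statistics over nucleotide sequences.

Sequences are handled as uint8 arrays of ASCII codes; :class:`SequenceStats`
precomputes prefix sums so that GC fraction, CpG fraction and N fraction of
any window are O(1).
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from recland.errors import EmptyInputError

_A, _C, _G, _T, _N = (np.uint8(ord(c)) for c in "ACGTN")


def encode(seq: str) -> np.ndarray:
    """Uppercase ASCII byte array for a nucleotide string."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def sequence_composition(seq: str) -> Tuple[float, float, float]:
    """``(gc_fraction, cpg_fraction, n_fraction)`` of a sequence.

    GC fraction is computed over non-N bases; CpG fraction is the number of
    CG dinucleotides divided by the number of dinucleotide start positions
    where both bases are non-N; N fraction is over the full length.
    Alphabet ``{A, C, G, T, N}``, case-insensitive.
    """
    if len(seq) == 0:
        raise EmptyInputError("empty sequence")
    arr = encode(seq)
    bad = ~np.isin(arr, [_A, _C, _G, _T, _N])
    if bad.any():
        raise ValueError(f"invalid base {chr(arr[bad][0])!r}")
    non_n = arr != _N
    n_non_n = int(non_n.sum())
    n_fraction = 1.0 - n_non_n / len(arr)
    if n_non_n == 0:
        return float("nan"), float("nan"), n_fraction
    gc = float(((arr == _G) | (arr == _C)).sum()) / n_non_n
    if len(arr) < 2:
        return gc, 0.0, n_fraction
    valid_pairs = non_n[:-1] & non_n[1:]
    n_valid = int(valid_pairs.sum())
    cg = int(((arr[:-1] == _C) & (arr[1:] == _G)).sum())
    cpg = cg / n_valid if n_valid else float("nan")
    return gc, cpg, n_fraction


class SequenceStats:
    """Prefix-sum window statistics for one chromosome sequence."""

    def __init__(self, seq: str):
        if len(seq) == 0:
            raise EmptyInputError("empty sequence")
        arr = encode(seq)
        self.length = len(arr)
        non_n = arr != _N
        is_gc = ((arr == _G) | (arr == _C)) & non_n
        self._cum_non_n = np.concatenate([[0], np.cumsum(non_n, dtype=np.int64)])
        self._cum_gc = np.concatenate([[0], np.cumsum(is_gc, dtype=np.int64)])
        if self.length >= 2:
            cg_start = (arr[:-1] == _C) & (arr[1:] == _G)
            pair_ok = non_n[:-1] & non_n[1:]
        else:
            cg_start = np.zeros(0, dtype=bool)
            pair_ok = np.zeros(0, dtype=bool)
        self._cum_cg = np.concatenate([[0], np.cumsum(cg_start, dtype=np.int64)])
        self._cum_pair_ok = np.concatenate([[0], np.cumsum(pair_ok, dtype=np.int64)])

    def _check(self, starts: np.ndarray, ends: np.ndarray) -> None:
        if np.any(starts < 0) or np.any(ends > self.length) or np.any(ends <= starts):
            raise ValueError("window outside sequence bounds")

    def window_gc(self, starts, ends) -> np.ndarray:
        """GC fraction of non-N bases per 0-based half-open window (nan if all N)."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        self._check(starts, ends)
        non_n = (self._cum_non_n[ends] - self._cum_non_n[starts]).astype(float)
        gc = (self._cum_gc[ends] - self._cum_gc[starts]).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(non_n > 0, gc / non_n, np.nan)

    def window_cpg(self, starts, ends) -> np.ndarray:
        """CpG-dinucleotide fraction per window (denominator: valid pairs)."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        self._check(starts, ends)
        # dinucleotide start positions inside [start, end) are start..end-2
        hi = np.maximum(ends - 1, starts)
        cg = (self._cum_cg[hi] - self._cum_cg[starts]).astype(float)
        ok = (self._cum_pair_ok[hi] - self._cum_pair_ok[starts]).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(ok > 0, cg / ok, np.nan)

    def window_n_fraction(self, starts, ends) -> np.ndarray:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        self._check(starts, ends)
        non_n = (self._cum_non_n[ends] - self._cum_non_n[starts]).astype(float)
        return 1.0 - non_n / (ends - starts)
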