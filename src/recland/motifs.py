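"""Exact k-mer presence/absence enrichment between case and control sequences.

The statistic is per-sequence *presence* (does the sequence contain >=1
exact occurrence), compared between the two groups with a two-sided Fisher
exact test and Bonferroni correction over the number of distinct motifs
scanned.  Scanning is by default double-stranded: a sequence contains a
motif if either the motif or its reverse complement occurs, and
reverse-complement pairs are collapsed onto the lexicographically smaller
(canonical) k-mer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import fisher_exact

from recland.errors import EmptyInputError, ParameterError

_BASES = "ACGT"
_CODE = {ord(b): i for i, b in enumerate(_BASES)}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

PARTITIONS = ("all", "non-repeat", "repeat")


@dataclass(frozen=True)
class MotifResult:
    """Enrichment result for one k-mer."""

    motif: str
    f_hot: float
    f_cold: float
    enrichment: float
    p_raw: float
    p_bonferroni: float
    partition: str = "all"
    n_hot: int = 0
    n_cold: int = 0


def reverse_complement(motif: str) -> str:
    return "".join(_COMP[b] for b in reversed(motif.upper()))


def motif_presence(seqs: Sequence[str], motif: str, double_strand: bool = False) -> float:
    """Fraction of sequences containing >=1 exact occurrence of ``motif``."""
    if len(seqs) == 0:
        raise EmptyInputError("empty sequence list")
    motif = motif.upper()
    if any(b not in _BASES for b in motif):
        raise ValueError(f"motif must be over {{A,C,G,T}}, got {motif!r}")
    rc = reverse_complement(motif) if double_strand else None
    hits = 0
    for s in seqs:
        s = s.upper()
        if motif in s or (rc is not None and rc in s):
            hits += 1
    return hits / len(seqs)


def _round_count(f: float, n: int) -> int:
    return int(np.floor(f * n + 0.5))


def enrichment_test(
    f_hot: float,
    f_cold: float,
    n_hot: int,
    n_cold: int,
    m_tests: int = 1,
    motif: str = "",
    partition: str = "all",
) -> MotifResult:
    """Fisher exact test on the 2x2 presence table implied by fractions.

    ``enrichment`` is ``f_hot / f_cold`` (``inf`` when ``f_cold == 0`` with
    ``f_hot > 0``); ``p_bonferroni = min(1, m_tests * p_raw)``.
    """
    if n_hot <= 0 or n_cold <= 0:
        raise ParameterError("group sizes must be positive")
    if m_tests < 1:
        raise ParameterError("m_tests must be >= 1")
    k_hot = _round_count(f_hot, n_hot)
    k_cold = _round_count(f_cold, n_cold)
    table = [[k_hot, n_hot - k_hot], [k_cold, n_cold - k_cold]]
    p_raw = float(fisher_exact(table, alternative="two-sided").pvalue)
    if f_cold > 0:
        enrichment = f_hot / f_cold
    elif f_hot > 0:
        enrichment = float("inf")
    else:
        enrichment = float("nan")
    return MotifResult(
        motif=motif,
        f_hot=float(f_hot),
        f_cold=float(f_cold),
        enrichment=enrichment,
        p_raw=p_raw,
        p_bonferroni=min(1.0, m_tests * p_raw),
        partition=partition,
        n_hot=n_hot,
        n_cold=n_cold,
    )


# ---------------------------------------------------------------------------
# bulk k-mer scanning
# ---------------------------------------------------------------------------

def encode_bases(seq: str) -> np.ndarray:
    """Map a sequence to codes 0..3; anything else (N, gaps) becomes 255."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for byte, code in _CODE.items():
        out[arr == byte] = code
    return out


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all valid k-mers of an encoded sequence."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    valid = codes != 255
    ok = valid[:n].copy()
    vals = np.zeros(n, dtype=np.int64)
    for j in range(k):
        window = codes[j : j + n]
        ok &= valid[j : j + n]
        vals = vals * 4 + np.where(window == 255, 0, window)
    return vals[ok]


def _revcomp_codes(vals: np.ndarray, k: int) -> np.ndarray:
    rc = np.zeros_like(vals)
    v = vals.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - (v & 3))
        v >>= 2
    return rc


def decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def presence_counts(
    seqs: Sequence[str], k: int, double_strand: bool = True
) -> np.ndarray:
    """Number of sequences containing each k-mer (index = integer code).

    In double-strand mode counts are accumulated on canonical codes
    (min of a code and its reverse complement); non-canonical entries stay 0.
    """
    counts = np.zeros(4**k, dtype=np.int64)
    for s in seqs:
        vals = _kmer_codes(encode_bases(s), k)
        if double_strand and len(vals):
            vals = np.minimum(vals, _revcomp_codes(vals, k))
        uniq = np.unique(vals)
        counts[uniq] += 1
    return counts


def n_motifs_tested(ks: Iterable[int], double_strand: bool = True) -> int:
    """Distinct motifs scanned across the k range (canonical if double-strand)."""
    total = 0
    for k in ks:
        if double_strand:
            palindromes = 4 ** (k // 2) if k % 2 == 0 else 0
            total += (4**k + palindromes) // 2
        else:
            total += 4**k
    return total


def mask_intervals(seq: str, intervals: Sequence[Tuple[int, int]],
                   invert: bool = False) -> str:
    """Hard-mask (N) the given 0-based intervals, or everything else."""
    arr = bytearray(seq.upper().encode("ascii"))
    if invert:
        keep = bytearray(b"N" * len(arr))
        for s, e in intervals:
            keep[s:e] = arr[s:e]
        return keep.decode("ascii")
    for s, e in intervals:
        arr[s:e] = b"N" * (min(e, len(arr)) - max(s, 0))
    return arr.decode("ascii")


def scan_all_motifs(
    hot_seqs: Sequence[str],
    cold_seqs: Sequence[str],
    ks: Sequence[int] = (6, 7, 8, 9),
    alpha: float = 0.05,
    double_strand: bool = True,
    partition: str = "all",
    m_tests: Optional[int] = None,
) -> List[MotifResult]:
    """Test every k-mer over the given k range; return the significant set.

    Results with Bonferroni-adjusted p below ``alpha`` are returned sorted
    by raw p-value.  ``m_tests`` defaults to the number of distinct motifs
    scanned across ``ks`` (all of them, not only those observed).  For
    partitioned scans, pre-mask the sequences with :func:`mask_intervals`
    and pass the matching ``partition`` label.
    """
    if len(hot_seqs) == 0 or len(cold_seqs) == 0:
        raise EmptyInputError("empty sequence list")
    if partition not in PARTITIONS:
        raise ParameterError(f"partition must be one of {PARTITIONS}")
    n_hot, n_cold = len(hot_seqs), len(cold_seqs)
    m = m_tests if m_tests is not None else n_motifs_tested(ks, double_strand)
    cache: Dict[Tuple[int, int], float] = {}
    results: List[MotifResult] = []
    for k in ks:
        hot_counts = presence_counts(hot_seqs, k, double_strand)
        cold_counts = presence_counts(cold_seqs, k, double_strand)
        observed = np.flatnonzero((hot_counts > 0) | (cold_counts > 0))
        for code in observed:
            kh, kc = int(hot_counts[code]), int(cold_counts[code])
            key = (kh, kc)
            p_raw = cache.get(key)
            if p_raw is None:
                p_raw = float(
                    fisher_exact(
                        [[kh, n_hot - kh], [kc, n_cold - kc]],
                        alternative="two-sided",
                    ).pvalue
                )
                cache[key] = p_raw
            if m * p_raw >= alpha:
                continue
            f_hot, f_cold = kh / n_hot, kc / n_cold
            results.append(
                MotifResult(
                    motif=decode_kmer(int(code), k),
                    f_hot=f_hot,
                    f_cold=f_cold,
                    enrichment=(f_hot / f_cold if f_cold > 0
                                else (float("inf") if f_hot > 0 else float("nan"))),
                    p_raw=p_raw,
                    p_bonferroni=min(1.0, m * p_raw),
                    partition=partition,
                    n_hot=n_hot,
                    n_cold=n_cold,
                )
            )
    results.sort(key=lambda r: (r.p_raw, r.motif))
    return results
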