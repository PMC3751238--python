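"""Independent oracles used by the test suite.

Each function here recomputes, by a route independent of the package
implementation, a quantity the implementation is expected to match:
vectorized brute-force Hamming scans for read placement, exhaustive
enumeration of global alignments for tiny strings, and full pmf
enumeration for binomial p-values.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def brute_force_hits(read: str, exons: list[tuple[str, str]], m: int) -> set:
    """Every (exon_id, start, strand, mismatches) within Hamming distance m,
    scanning all windows of all exons on both strands with numpy.

    'N' on either side counts as a mismatch (including N vs N).
    """
    k = len(read)
    n_byte = ord("N")
    hits = set()
    for strand, seq in (("+", read), ("-", revcomp(seq=read))):
        rvec = _encode(seq)
        for exon_id, target in exons:
            if len(target) < k:
                continue
            tvec = _encode(target)
            windows = np.lib.stride_tricks.sliding_window_view(tvec, k)
            mism = (
                (windows != rvec[None, :])
                | (windows == n_byte)
                | (rvec[None, :] == n_byte)
            ).sum(axis=1)
            for start in np.flatnonzero(mism <= m):
                hits.add((exon_id, int(start), strand, int(mism[start])))
    return hits


def enumerate_global_alignments(a: str, b: str, match=1, mismatch=-1,
                                gap_open=-2, gap_extend=-1):
    """All global alignments of two tiny strings with their affine scores.

    A gap of length L costs |gap_open| + L*|gap_extend|. Returns a list of
    (aligned_a, aligned_b, score); intended for strings of length <= 6.
    """

    def _score(row_a: str, row_b: str) -> float:
        s = 0.0
        for which in (0, 1):
            row = (row_a, row_b)[which]
            in_gap = False
            for c in row:
                if c == "-":
                    if not in_gap:
                        s += gap_open
                        in_gap = True
                    s += gap_extend
                else:
                    in_gap = False
        for ca, cb in zip(row_a, row_b):
            if ca != "-" and cb != "-":
                s += match if ca == cb else mismatch
        return s

    results = []

    def _extend(i, j, row_a, row_b):
        if i == len(a) and j == len(b):
            results.append((row_a, row_b, _score(row_a, row_b)))
            return
        if i < len(a) and j < len(b):
            _extend(i + 1, j + 1, row_a + a[i], row_b + b[j])
        if i < len(a):
            _extend(i + 1, j, row_a + a[i], row_b + "-")
        if j < len(b):
            _extend(i, j + 1, row_a + "-", row_b + b[j])

    _extend(0, 0, "", "")
    # drop alignments with adjacent gap-in-a/gap-in-b columns, which are
    # re-orderings of the same edit; keep them actually -- scores are what
    # matters for the optimum.
    return results


def best_alignment_score(a: str, b: str, **scoring) -> float:
    return max(s for _, _, s in enumerate_global_alignments(a, b, **scoring))


def binom_two_sided_enum(x: int, n: int) -> Fraction:
    """Exact two-sided p at p0=1/2 by minimum-likelihood enumeration of all
    n+1 outcomes, in exact rational arithmetic."""
    probs = [Fraction(comb(n, j), 2**n) for j in range(n + 1)]
    px = probs[x]
    return sum(p for p in probs if p <= px)


def bh_stepup_enum(pvals: list[float], alpha: float) -> list[bool]:
    """Hand-evaluated Benjamini-Hochberg step-up decisions."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    k_max = 0
    for rank, i in enumerate(order, start=1):
        if pvals[i] <= rank / n * alpha:
            k_max = rank
    reject = [False] * n
    for rank, i in enumerate(order, start=1):
        if rank <= k_max:
            reject[i] = True
    return reject
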