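"""Exact binomial testing of allelic imbalance with FDR control.

Real sequencing data samples reads stochastically, so an observed reference
proportion away from 0.5 is not by itself evidence of allelic imbalance.
Each differentiating site with at least ``min_coverage`` informative reads
(default 20) is tested with a two-sided exact binomial test of
ref_count ~ Binomial(ref+alt, 0.5); the Benjamini-Hochberg step-up
procedure controls the false discovery rate (default 0.05) across the
tested sites of the run. "Equal allelic abundance" at a site means it was
tested and not significant.

The two-sided p-value uses the minimum-likelihood ordering (the sum of
probabilities of all outcomes no more likely than the observed one), which
at p0 = 0.5 reduces to twice the smaller tail, capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class TestResult:
    # not a test case, despite the name pytest sees
    __test__ = False

    p_value: float | None
    q_value: float | None
    significant: bool
    tested: bool

    def __post_init__(self) -> None:
        if self.significant and not self.tested:
            raise ValueError("a significant site must have been tested")


def binom_exact_two_sided(x: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p-value (minimum-likelihood ordering)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError("x must satisfy 0 <= x <= n")
    return binomtest(x, n, p0).pvalue


def bh_fdr(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (q_values, significant flags).

    q-values are the monotone step-up adjusted p-values; empty input yields
    empty output.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def test_sites(records: Sequence, min_coverage: int = 20, alpha: float = 0.05) -> list:
    """Attach a TestResult to each SiteRecord.

    Sites with fewer than ``min_coverage`` informative reads are not tested
    (no p-value); the FDR pool is the tested sites of this run only.
    """
    tested_idx = [
        i for i, r in enumerate(records) if r.counts.informative >= min_coverage
    ]
    pvals = [
        binom_exact_two_sided(records[i].counts.ref_count, records[i].counts.informative)
        for i in tested_idx
    ]
    qvals, reject = bh_fdr(pvals, alpha=alpha)
    results: dict[int, TestResult] = {}
    for j, i in enumerate(tested_idx):
        results[i] = TestResult(
            p_value=float(pvals[j]),
            q_value=float(qvals[j]),
            significant=bool(reject[j]),
            tested=True,
        )
    out = []
    for i, r in enumerate(records):
        tr = results.get(
            i, TestResult(p_value=None, q_value=None, significant=False, tested=False)
        )
        out.append(replace(r, test=tr))
    return out
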