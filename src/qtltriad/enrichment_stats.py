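"""Enrichment tests and rank correlation used in result summaries.

``enrichment_test`` computes one-sided upper-tail probabilities P(X >= k)
for an observed success count against either a background proportion
(binomial model) or a finite background population of counts
(hypergeometric model). Tails are evaluated in log space so extremely
significant enrichments remain representable; below the smallest positive
double the result is reported as an upper bound.

``spearman`` is a two-sided Spearman rank correlation with midrank ties;
the p-value is exact (full permutation) for n <= 9 and the usual
t-approximation otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

TINY_P = 1e-320    # below this, p is reported as an upper bound


@dataclass(frozen=True)
class EnrichmentResult:
    k: int                      # observed successes
    n: int                      # trials / draws
    method: str                 # 'binomial' or 'hypergeometric'
    p_one_sided: float
    is_upper_bound: bool = False
    background: tuple = ()


def enrichment_test(k: int, n: int,
                    background: float | tuple[int, int]) -> EnrichmentResult:
    """Upper-tail enrichment of k successes in n trials.

    ``background`` is either a proportion p0 (binomial test) or a
    ``(K, N)`` tuple of background successes in a population of size N
    (hypergeometric test).
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if k == 0:
        method = "binomial" if np.isscalar(background) else "hypergeometric"
        return EnrichmentResult(k, n, method, 1.0,
                                background=tuple(np.atleast_1d(background)))
    if np.isscalar(background):
        p0 = float(background)
        if not 0 <= p0 <= 1:
            raise ValueError("background proportion must lie in [0, 1]")
        logp = stats.binom.logsf(k - 1, n, p0)
        method = "binomial"
        bg = (p0,)
    else:
        K, N = (int(x) for x in background)
        if K > N or n > N:
            raise ValueError("need K <= N and n <= N")
        logp = stats.hypergeom.logsf(k - 1, N, K, n)
        method = "hypergeometric"
        bg = (K, N)
    p = float(np.exp(logp))
    if p > 0:
        return EnrichmentResult(k, n, method, p, background=bg)
    return EnrichmentResult(k, n, method, TINY_P, is_upper_bound=True,
                            background=bg)


def spearman(x: np.ndarray, y: np.ndarray,
             exact_max_n: int = 9) -> tuple[float, float]:
    """Two-sided Spearman rank correlation (rho, p).

    Midrank ties; p exact by enumerating all rank permutations when
    n <= ``exact_max_n``, otherwise the t-distribution approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("spearman needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman undefined for a constant input")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        # exact permutation null over all n! orderings of one rank vector
        obs = abs(rho)
        count = 0
        total = 0
        ry_arr = np.asarray(ry)
        for perm in itertools.permutations(range(n)):
            r = np.corrcoef(rx, ry_arr[list(perm)])[0, 1]
            count += abs(r) >= obs - 1e-12
            total += 1
        return rho, count / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho**2))
    return rho, float(2 * stats.t.sf(abs(t), n - 2))
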