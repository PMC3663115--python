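"""Population-genetic estimators for segregating GRIPs.

Treating each GRIP locus as a segregating site, Watterson's estimator
converts the number of segregating insertions S observed in n
individuals into the population mutation parameter

    theta_W = S / a_n,        a_n = sum_{i=1}^{n-1} 1/i,

and with theta = 4 * Ne * mu this yields the per-generation retro-
position rate mu (conveniently reported as 1/mu, "one new insertion per
so many individuals").  Neutrality of the markers is checked with
Tajima's D, the normalized difference between the mean-pairwise-
difference estimator theta_T and theta_W.  The module also provides the
annotation-coverage and one-sample proportions-test helpers used to
test for enrichment or depletion of insertions in genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

from scipy.stats import chi2 as _chi2


@dataclass(frozen=True)
class PopgenEstimates:
    n: int
    S: int
    a_n: float
    theta_W: float
    theta_T: float | None
    V: float | None
    D: float | None
    Ne: float | None
    mu: float | None
    mu_reciprocal: int | None
    neutrality: str | None = None


def watterson_a(n: int) -> float:
    """Watterson denominator a_n = sum_{i=1}^{n-1} 1/i (n >= 2)."""
    if not isinstance(n, int) or n < 2:
        raise ValueError("n must be an integer >= 2")
    return sum(1.0 / i for i in range(1, n))


def watterson_theta(S: int, n: int) -> float:
    """theta_W = S / a_n."""
    if S < 0:
        raise ValueError("S must be >= 0")
    return S / watterson_a(n)


def retro_rate(theta: float, Ne: float) -> tuple[float, int | None]:
    """Per-generation insertion rate mu = theta / (4 Ne) and 1/mu.

    The reciprocal is rounded to the nearest integer ("one new insertion
    per N individuals"); undefined (None) when mu is 0.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if Ne <= 0:
        raise ValueError("Ne must be positive")
    mu = theta / (4.0 * Ne)
    return mu, (round(1.0 / mu) if mu > 0 else None)


def pairwise_theta(carrier_counts: list[int], n: int) -> float:
    """Mean pairwise difference theta_T from per-locus carrier counts.

    For a locus carried by k of n individuals, a random pair differs
    with probability 2 k (n-k) / (n (n-1)); theta_T sums this over loci.
    Every locus must actually segregate (0 < k < n).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    total = Fraction(0)
    for k in carrier_counts:
        if not 0 < k < n:
            raise ValueError(f"carrier count {k} is not segregating in n={n}")
        total += Fraction(2 * k * (n - k), n * (n - 1))
    return float(total)


def tajima_d(theta_T: float, theta_W: float, V: float) -> float:
    """D = (theta_T - theta_W) / sqrt(V)."""
    if V <= 0:
        raise ValueError("variance must be positive")
    return (theta_T - theta_W) / math.sqrt(V)


def tajima_variance(S: int, n: int) -> float:
    """Standard variance of theta_T - theta_W (coefficients e1, e2).

    The textbook coefficient chain: a1 = sum 1/i, a2 = sum 1/i^2,
    b1 = (n+1)/(3(n-1)), b2 = 2(n^2+n+3)/(9n(n-1)), c1 = b1 - 1/a1,
    c2 = b2 - (n+2)/(a1 n) + a2/a1^2, e1 = c1/a1, e2 = c2/(a1^2+a2);
    V = e1 S + e2 S (S-1).
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    if n < 4:
        raise ValueError("n must be >= 4")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return e1 * S + e2 * S * (S - 1)


def neutrality_label(D: float, critical: float = 2.0) -> str:
    """Interpretive label at the conventional +-2 critical values."""
    if D <= -critical:
        return "purifying"
    if D >= critical:
        return "diversifying"
    return "neutral"


def estimate(n: int, S: int, Ne: float | None = None,
             theta_T: float | None = None,
             variance: float | None = None) -> PopgenEstimates:
    """One-stop estimator chain.

    ``variance`` overrides the standard Tajima coefficients when a
    published V-hat should be reproduced exactly.
    """
    a_n = watterson_a(n)
    th_w = watterson_theta(S, n)
    mu = mu_rec = None
    if Ne is not None:
        mu, mu_rec = retro_rate(th_w, Ne)
    V = D = label = None
    if theta_T is not None:
        V = variance if variance is not None else tajima_variance(S, n)
        D = tajima_d(theta_T, th_w, V)
        label = neutrality_label(D)
    return PopgenEstimates(n=n, S=S, a_n=a_n, theta_W=th_w, theta_T=theta_T,
                           V=V, D=D, Ne=Ne, mu=mu, mu_reciprocal=mu_rec,
                           neutrality=label)


# ---------------------------------------------------------------------------
# annotation coverage and proportions test
# ---------------------------------------------------------------------------

def annotation_coverage(intervals: list[tuple[str, int, int]],
                        chrom_sizes: dict[str, int]) -> float:
    """Fraction of the genome covered by the union of intervals.

    Exact rational interval-union arithmetic; intervals must lie within
    their chromosome bounds.
    """
    total = sum(chrom_sizes.values())
    if total == 0:
        raise ValueError("empty genome")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        if chrom not in chrom_sizes:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if s < 0 or e > chrom_sizes[chrom]:
            raise ValueError(f"interval {chrom}:{s}-{e} beyond chromosome end")
        if s < e:
            by_chrom.setdefault(chrom, []).append((s, e))
    covered = 0
    for ivs in by_chrom.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        covered += cur_e - cur_s
    return float(Fraction(covered, total))


def proportions_test(x: int, n: int, p0: float) -> tuple[float, float]:
    """One-sample proportions test with Yates continuity correction.

    chi2 = (max(0, |x - n p0| - 1/2))^2 / (n p0 (1 - p0)), with the
    correction clamped so the statistic is 0 when observed equals
    expected; two-sided p from the chi-square distribution with 1 df.
    """
    if not 0 <= x <= n:
        raise ValueError("x must be in [0, n]")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be strictly between 0 and 1")
    expected = n * p0
    dev = abs(x - expected)
    corrected = max(0.0, dev - 0.5)
    stat = corrected ** 2 / (n * p0 * (1 - p0))
    p = float(_chi2.sf(stat, df=1))
    return stat, p
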