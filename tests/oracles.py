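"""Independent brute-force oracles used to pin down exact-test conventions.

Everything here is computed with exact rational arithmetic and explicit
enumeration, deliberately sharing no code with the package implementations.
"""

from fractions import Fraction
from itertools import product
from math import comb


def fet_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Minlike two-sided Fisher p for [[a, b], [c, d]] by full enumeration."""
    n = a + b + c + d
    col1, row1 = a + c, a + b
    if col1 in (0, n) or row1 in (0, n):
        return 1.0
    denom = comb(n, row1)
    support = range(max(0, col1 + row1 - n), min(col1, row1) + 1)
    pmf = {k: Fraction(comb(col1, k) * comb(n - col1, row1 - k), denom)
           for k in support}
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs))


def hwe_exact(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Exact HWE p by enumerating the conditional heterozygote distribution.

    Conditional on n diploids and the rare-allele count, the probability of
    k heterozygotes is proportional to 2^k / (n_AA! k! n_BB!).
    """
    n = n_hom_minor + n_het + n_hom_major
    rare = 2 * n_hom_minor + n_het
    rare = min(rare, 2 * n - rare)
    if rare == 0:
        return 1.0
    from math import factorial

    weights = {}
    for k in range(rare % 2, rare + 1, 2):
        n_aa = (rare - k) // 2
        n_bb = n - (rare + k) // 2
        weights[k] = Fraction(2 ** k,
                              factorial(n_aa) * factorial(k) * factorial(n_bb))
    total = sum(weights.values())
    p_obs = weights[n_het]
    return float(sum(w for w in weights.values() if w <= p_obs) / total)


def hypergeom_upper_tail(k: int, n_bg: int, set_size: int, query: int) -> float:
    """P(X >= k) for X ~ Hypergeom(n_bg, set_size, query), exact."""
    denom = comb(n_bg, query)
    tail = sum(Fraction(comb(set_size, x) * comb(n_bg - set_size, query - x), denom)
               for x in range(k, min(set_size, query) + 1))
    return float(tail)


def binomial_two_sided(k: int, n: int) -> float:
    """Minlike two-sided p for k successes out of n at probability 1/2."""
    denom = Fraction(2) ** n
    pmf = [Fraction(comb(n, x)) / denom for x in range(n + 1)]
    p_obs = pmf[k]
    return float(sum(p for p in pmf if p <= p_obs))


def signed_rank_two_sided(diffs) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign flips.

    Zero differences are dropped; |differences| must be untied.  Two-sided by
    doubling the smaller tail of the positive-rank-sum distribution (the
    convention of the mainstream exact implementations).
    """
    d = [x for x in diffs if x != 0]
    n = len(d)
    order = sorted(range(n), key=lambda i: abs(d[i]))
    ranks = [0] * n
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    w_obs = sum(r for x, r in zip(d, ranks) if x > 0)
    total = 2 ** n
    dist = [0] * (n * (n + 1) // 2 + 1)
    for signs in product((0, 1), repeat=n):
        dist[sum(r for s, r in zip(signs, range(1, n + 1)) if s)] += 1
    lower = sum(dist[: w_obs + 1]) / total
    upper = sum(dist[w_obs:]) / total
    return min(1.0, 2 * min(lower, upper))


def optimal_assignment_total(dist_matrix) -> float:
    """Minimum-total bipartite assignment by exhaustive permutation search."""
    from itertools import permutations

    n_a = len(dist_matrix)
    n_b = len(dist_matrix[0])
    best = float("inf")
    for perm in permutations(range(n_b), n_a):
        total = sum(dist_matrix[i][j] for i, j in enumerate(perm))
        best = min(best, total)
    return best
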