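"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written the slow, definitional way (explicit
loops over pairs, exhaustive enumeration) and never shares code with the
package internals it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def pdi_bruteforce(values, denominator=None) -> float:
    """Paired-difference sum evaluated literally: rank the link strengths,
    subtract each from the strongest, divide by the stated denominator."""
    ranked = sorted(values, reverse=True)
    top = ranked[0]
    total = 0.0
    for v in ranked[1:]:
        total += top - v
    if denominator is None:
        denominator = len(ranked) - 1
    return total / denominator


def joint_pdi_bruteforce(rows, denominator=None) -> float:
    rows = np.asarray(rows, dtype=float)
    averaged = [rows[:, j].mean() for j in range(rows.shape[1])]
    return pdi_bruteforce(averaged, denominator)


def expected_joint_pdi_binomial(n: int, p: float = 0.5) -> float:
    """Exact expectation of the 2-genotype, 1-host, n-nodule joint PDI by
    summing over all n+1 binomial outcomes."""
    total = 0.0
    for k in range(n + 1):
        prob = math.comb(n, k) * p**k * (1 - p) ** (n - k)
        links = [k / n, (n - k) / n]
        total += prob * pdi_bruteforce(links)
    return total


def amova_ssds_bruteforce(d: np.ndarray, pop_of: list, group_of: dict):
    """(ssd_groups, ssd_pops_within, ssd_within, ssd_total) from squared
    distances by definition: SSD(S) = sum_{i<j in S} d_ij^2 / |S|."""
    n = d.shape[0]

    def ssd(indices):
        s = 0.0
        for i, j in itertools.combinations(indices, 2):
            s += d[i, j] ** 2
        return s / len(indices)

    ssd_total = ssd(range(n))
    pops = sorted(set(pop_of))
    ssd_within = sum(
        ssd([i for i in range(n) if pop_of[i] == p]) for p in pops
    )
    groups = sorted(set(group_of.values()))
    ssd_within_groups = sum(
        ssd([i for i in range(n) if group_of[pop_of[i]] == g]) for g in groups
    )
    return (
        ssd_total - ssd_within_groups,
        ssd_within_groups - ssd_within,
        ssd_within,
        ssd_total,
    )


def amova_components_bruteforce(d: np.ndarray, pop_of: list, group_of: dict):
    """Variance components from the unbalanced nested expected mean squares,
    coded independently of the package (textbook coefficient formulas)."""
    ssd_a, ssd_b, ssd_c, _ = amova_ssds_bruteforce(d, pop_of, group_of)
    n = d.shape[0]
    pops = sorted(set(pop_of))
    groups = sorted(set(group_of.values()))
    n_p = {p: pop_of.count(p) for p in pops}
    n_g = {g: sum(n_p[p] for p in pops if group_of[p] == g) for g in groups}
    P, G = len(pops), len(groups)
    df_a, df_b, df_c = G - 1, P - G, n - P
    sigma_c = ssd_c / df_c
    A = sum(
        sum(n_p[p] ** 2 for p in pops if group_of[p] == g) / n_g[g]
        for g in groups
    )
    B = sum(n_p[p] ** 2 for p in pops) / n
    C = sum(n_g[g] ** 2 for g in groups) / n
    sigma_b = (ssd_b / df_b - sigma_c) / ((n - A) / df_b) if df_b else 0.0
    if df_a:
        n2 = (A - B) / df_a
        n3 = (n - C) / df_a
        sigma_a = (ssd_a / df_a - sigma_c - n2 * sigma_b) / n3
    else:
        sigma_a = 0.0
    return sigma_a, sigma_b, sigma_c


def phi_st_bruteforce(d: np.ndarray, idx_a, idx_b) -> float | None:
    """One-level Phi_st by definitional SSDs over a two-set split."""
    n = d.shape[0]

    def ssd(indices):
        s = 0.0
        for i, j in itertools.combinations(indices, 2):
            s += d[i, j] ** 2
        return s / len(indices)

    ssd_total = ssd(range(n))
    ssd_within = ssd(idx_a) + ssd(idx_b)
    ssd_among = ssd_total - ssd_within
    df_w = n - 2
    ms_w = ssd_within / df_w
    n_prime = (n - (len(idx_a) ** 2 + len(idx_b) ** 2) / n) / 1
    sigma_a = (ssd_among / 1 - ms_w) / n_prime
    denom = sigma_a + ms_w
    return None if denom == 0 else sigma_a / denom


def phi_st_exact_p(d: np.ndarray, n_a: int) -> float:
    """Exact permutation p for a balanced two-population split: enumerate
    every way to choose the first population's members."""
    n = d.shape[0]
    obs = phi_st_bruteforce(d, list(range(n_a)), list(range(n_a, n)))
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), n_a):
        rest = [i for i in range(n) if i not in combo]
        stat = phi_st_bruteforce(d, list(combo), rest)
        total += 1
        if stat is not None and stat >= obs:
            count += 1
    return count / total


def mantel_r_bruteforce(x: np.ndarray, y: np.ndarray) -> float:
    n = x.shape[0]
    xs, ys = [], []
    for i in range(n):
        for j in range(i):
            xs.append(x[i, j])
            ys.append(y[i, j])
    return float(np.corrcoef(xs, ys)[0, 1])


def mantel_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact one-sided Mantel p by enumerating every joint permutation of y."""
    n = x.shape[0]
    obs = mantel_r_bruteforce(x, y)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        perm = list(perm)
        stat = mantel_r_bruteforce(x, y[np.ix_(perm, perm)])
        total += 1
        if stat >= obs - 1e-12:
            count += 1
    return count / total
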