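"""Independent brute-force oracles used to validate the implementations.

Everything here is written as literal transcription of definitions
(exhaustive enumeration, direct sums over gene copies) with no code
shared with the package.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def allele_freq_tally(calls: np.ndarray) -> dict[int, float]:
    """Tally allele frequencies over raw gene copies of (k, 2) calls."""
    copies = [int(a) for pair in calls for a in pair if a != 0]
    return {a: copies.count(a) / len(copies) for a in set(copies)}


def rarefaction_enumeration(counts: dict[int, int], g: int) -> float:
    """Mean number of distinct alleles over ALL subsets of g gene copies."""
    pool = [a for a, c in counts.items() for _ in range(c)]
    total = 0
    n_subsets = 0
    for subset in itertools.combinations(range(len(pool)), g):
        total += len({pool[i] for i in subset})
        n_subsets += 1
    return total / n_subsets


def _matchings(pool: tuple[int, ...]):
    """Yield every perfect matching of the pool (each exactly once).

    Uniform random re-pairing by shuffling induces the uniform
    distribution over perfect matchings, so enumerating matchings with
    equal weight reproduces the permutation null exactly.
    """
    if not pool:
        yield []
        return
    first, rest = pool[0], pool[1:]
    for i in range(len(rest)):
        partner = rest[i]
        remaining = rest[:i] + rest[i + 1:]
        for tail in _matchings(remaining):
            yield [(first, partner)] + tail


def hwe_exhaustive_p(calls: np.ndarray) -> float:
    """Exact permutation p-value for the heterozygote-deviation test.

    The statistic and the +1/+1 continuity mirror the tested
    implementation's definition; the null is enumerated over all
    perfect matchings of the gene-copy pool.
    """
    pool = tuple(int(a) for pair in calls for a in pair)
    n = len(calls)
    same = sum(comb(pool.count(a), 2) for a in set(pool))
    e_het = n * (1.0 - same / comb(2 * n, 2))
    h_obs = sum(1 for a, b in calls if a != b)
    d_obs = abs(h_obs - e_het)
    hits = total = 0
    for matching in _matchings(pool):
        h = sum(1 for x, y in matching if x != y)
        if abs(h - e_het) >= d_obs - 1e-12:
            hits += 1
        total += 1
    return (hits + 1) / (total + 1)


def wc_theta_oracle(pop_calls: list[np.ndarray]) -> float:
    """Weir & Cockerham (1984) theta over loci for r populations.

    ``pop_calls[p]`` is a (k_p, L, 2) array of diploid calls (0 =
    missing).  Direct transcription of the variance-component formulas,
    summing a over alleles and loci and dividing by the summed
    a + b + c.
    """
    r = len(pop_calls)
    L = pop_calls[0].shape[1]
    num = den = 0.0
    for li in range(L):
        per_pop = []
        for calls in pop_calls:
            c = calls[:, li, :]
            c = c[c[:, 0] != 0]
            per_pop.append(c)
        if any(c.shape[0] < 2 for c in per_pop):
            continue
        ns = [c.shape[0] for c in per_pop]
        nbar = sum(ns) / r
        nc = (r * nbar - sum(n_i**2 for n_i in ns) / (r * nbar)) / (r - 1)
        alleles = sorted({int(a) for c in per_pop for a in c.ravel()})
        for al in alleles:
            ps = []
            hs = []
            for c in per_pop:
                copies = list(c.ravel())
                ps.append(copies.count(al) / len(copies))
                het = sum(
                    1 for x, y in c if x != y and (x == al or y == al)
                )
                hs.append(het / c.shape[0])
            pbar = sum(n_i * p_i for n_i, p_i in zip(ns, ps)) / (r * nbar)
            s2 = sum(
                n_i * (p_i - pbar) ** 2 for n_i, p_i in zip(ns, ps)
            ) / ((r - 1) * nbar)
            hbar = sum(n_i * h_i for n_i, h_i in zip(ns, hs)) / (r * nbar)
            a = (nbar / nc) * (
                s2
                - (1 / (nbar - 1))
                * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - ((r - 1) / r) * s2
                - ((2 * nbar - 1) / (4 * nbar)) * hbar
            )
            cc = hbar / 2
            num += a
            den += a + b + cc
    return num / den if den != 0 else 0.0


def mismatch_bruteforce(seqs: list[str]) -> np.ndarray:
    """Mismatch distribution over an expanded list of sequences,
    comparing gap/N-free columns only."""
    keep = [
        i for i in range(len(seqs[0]))
        if all(s[i] not in "-N" for s in seqs)
    ]
    diffs = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            diffs.append(sum(seqs[i][k] != seqs[j][k] for k in keep))
    mass = np.bincount(diffs)
    return mass / mass.sum()


def stirling_via_polynomial(n: int) -> list[int]:
    """|s(n, k)| as coefficients of theta(theta+1)...(theta+n-1)."""
    coeffs = [1]  # polynomial "1"
    for i in range(n):
        # multiply by (theta + i): shift + scale
        new = [0] * (len(coeffs) + 1)
        for k, c in enumerate(coeffs):
            new[k + 1] += c  # theta * c
            new[k] += i * c
        coeffs = new
    return coeffs  # coeffs[k] = |s(n, k)|
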