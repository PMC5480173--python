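"""Sequence diversity, neutrality tests and mismatch-distribution fits.

All statistics operate on (haplotype, count) pairs and are exactly
equivalent to computing on the count-expanded list of individual
sequences.  Conventions mirror DnaSP: the segregating-site count may
include indel events (a contiguous gap run = one event); nucleotide
diversity, mean pairwise differences, the mismatch distribution and the
neutrality tests use gap-free columns only.  Columns containing an
ambiguous base (N) are excluded throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb, lgamma, log, log1p, exp, sqrt

import numpy as np
from scipy.optimize import minimize

from volesurf.io import HaplotypeData, ValidationError

logger = logging.getLogger(__name__)

GAP = ord("-")
AMBIG = ord("N")

TAU_MAX = 50.0
THETA_MAX = 100.0


# ---------------------------------------------------------------------------
# internal representation
# ---------------------------------------------------------------------------


def _resolve(hd: HaplotypeData, sites=None, group=None, haplotypes=None) -> HaplotypeData:
    if sites is None and group is None and haplotypes is None:
        return hd
    return hd.subset(haplotypes=haplotypes, sites=sites, group=group)


def _matrix(hd: HaplotypeData) -> tuple[list[str], np.ndarray, np.ndarray]:
    """(hap ids, counts, uint8 sequence matrix) for haplotypes with count>0."""
    totals = hd.hap_totals()
    ids = [h for h in hd.haplotypes if totals[h] > 0]
    if not ids:
        raise ValidationError("no sequences in subset")
    counts = np.array([totals[h] for h in ids], dtype=np.int64)
    mat = np.frombuffer(
        "".join(hd.haplotypes[h].upper() for h in ids).encode(), dtype=np.uint8
    ).reshape(len(ids), hd.length)
    return ids, counts, mat


def _clean_columns(mat: np.ndarray) -> np.ndarray:
    """Boolean mask of columns free of gaps and ambiguous bases."""
    return ~np.any((mat == GAP) | (mat == AMBIG), axis=0)


def _pair_diff_matrix(mat: np.ndarray, mask: np.ndarray) -> np.ndarray:
    sub = mat[:, mask]
    k = sub.shape[0]
    d = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        d[i, i + 1:] = np.sum(sub[i] != sub[i + 1:], axis=1)
    return d + d.T


def _mean_pairwise(counts: np.ndarray, diffs: np.ndarray) -> float:
    """Count-weighted mean pairwise difference; self pairs contribute 0."""
    n = int(counts.sum())
    if n < 2:
        raise ValidationError("need n >= 2 sequences")
    w = np.outer(counts, counts).astype(float)
    total = float(np.sum(np.triu(w * diffs, k=1)))
    return total / comb(n, 2)


def segregating_sites(
    hd: HaplotypeData, sites=None, group=None, include_indels: bool = True
) -> int:
    """Number of polymorphic positions among the subset's haplotypes.

    Substitution polymorphisms are counted on gap/N-free columns.  With
    ``include_indels`` each maximal run of contiguous columns containing
    a gap counts as a single event, provided the gap presence/absence
    pattern varies among haplotypes.
    """
    sub = _resolve(hd, sites=sites, group=group)
    _, counts, mat = _matrix(sub)
    clean = _clean_columns(mat)
    s = int(np.sum(np.array([len(set(col)) for col in mat[:, clean].T]) > 1))
    if include_indels:
        gap_cols = np.any(mat == GAP, axis=0)
        j = 0
        L = mat.shape[1]
        while j < L:
            if gap_cols[j]:
                j2 = j
                while j2 + 1 < L and gap_cols[j2 + 1]:
                    j2 += 1
                run = mat[:, j:j2 + 1]
                patterns = {tuple(row == GAP) for row in run}
                if len(patterns) > 1:
                    s += 1
                j = j2 + 1
            else:
                j += 1
    return s


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------


@dataclass
class SeqDiversity:
    n: int
    n_hap: int
    S: int
    Hd: float
    pi: float
    k: float


def seq_diversity(hd: HaplotypeData, sites=None, group=None) -> SeqDiversity:
    """n, number of haplotypes, S, haplotype diversity, pi and k.

    ``Hd = n/(n-1) * (1 - sum p_i^2)`` over haplotype frequencies;
    ``k`` is the count-weighted mean pairwise difference over gap-free
    columns and ``pi = k / L_gap-free``.
    """
    sub = _resolve(hd, sites=sites, group=group)
    _, counts, mat = _matrix(sub)
    n = int(counts.sum())
    if n < 2:
        raise ValidationError("subset has n < 2 sequences; diversity undefined")
    p = counts / n
    hd_val = (n / (n - 1)) * (1.0 - float(np.sum(p**2)))
    clean = _clean_columns(mat)
    diffs = _pair_diff_matrix(mat, clean)
    k = _mean_pairwise(counts, diffs)
    L = int(clean.sum())
    pi = k / L if L > 0 else 0.0
    return SeqDiversity(
        n=n, n_hap=len(counts),
        S=segregating_sites(sub, include_indels=True),
        Hd=hd_val, pi=pi, k=k,
    )


# ---------------------------------------------------------------------------
# neutrality tests
# ---------------------------------------------------------------------------


def _harmonic(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i**power for i in range(1, n)))


def _sub_poly_stats(counts: np.ndarray, mat: np.ndarray) -> tuple[int, int, int]:
    """(S, eta, eta_singletons) on gap/N-free columns, count-expanded.

    ``eta`` counts mutations (distinct bases - 1 per site); a singleton
    is a base carried by exactly one sequence at a site.
    """
    clean = _clean_columns(mat)
    sub = mat[:, clean]
    S = eta = eta_s = 0
    for col in sub.T:
        vals, hap_counts = np.unique(col, return_counts=True)
        if vals.size < 2:
            continue
        S += 1
        eta += vals.size - 1
        seq_counts = np.zeros(vals.size, dtype=np.int64)
        for vi in range(vals.size):
            seq_counts[vi] = counts[col == vals[vi]].sum()
        eta_s += int(np.sum(seq_counts == 1))
    return S, eta, eta_s


def tajimas_d(hd: HaplotypeData, sites=None, group=None) -> float:
    """Tajima's D over gap-free substitution sites (count-expanded n).

    Returns NaN (with a warning) when S = 0.
    """
    sub = _resolve(hd, sites=sites, group=group)
    _, counts, mat = _matrix(sub)
    n = int(counts.sum())
    if n < 4:
        raise ValidationError("Tajima's D needs n >= 4")
    S, _eta, _eta_s = _sub_poly_stats(counts, mat)
    if S == 0:
        logger.warning("S = 0; Tajima's D undefined")
        return float("nan")
    clean = _clean_columns(mat)
    k = _mean_pairwise(counts, _pair_diff_matrix(mat, clean))
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (k - S / a1) / sqrt(e1 * S + e2 * S * (S - 1))


def fu_li_tests(hd: HaplotypeData, sites=None, group=None) -> tuple[float, float]:
    """Outgroup-free Fu & Li D* and F* (Simonsen et al. 1995 constants).

    Returns (NaN, NaN) when S = 0.
    """
    sub = _resolve(hd, sites=sites, group=group)
    _, counts, mat = _matrix(sub)
    n = int(counts.sum())
    if n < 4:
        raise ValidationError("Fu & Li tests need n >= 4")
    S, eta, eta_s = _sub_poly_stats(counts, mat)
    if S == 0:
        logger.warning("S = 0; Fu & Li D*/F* undefined")
        return float("nan"), float("nan")
    clean = _clean_columns(mat)
    k = _mean_pairwise(counts, _pair_diff_matrix(mat, clean))

    an = _harmonic(n)
    bn = _harmonic(n, 2)
    an1 = an + 1.0 / n  # a_{n+1}
    cn = 2 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = (
        cn
        + (n - 2) / (n - 1) ** 2
        + (2 / (n - 1)) * (1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n)
    )
    vD = (
        (n / (n - 1)) ** 2 * bn
        + an**2 * dn
        - 2 * (n * an * (an + 1)) / (n - 1) ** 2
    ) / (an**2 + bn)
    uD = (n / (n - 1)) * (an - n / (n - 1)) - vD
    Dstar = ((n / (n - 1)) * eta - an * eta_s) / sqrt(uD * eta + vD * eta**2)

    vF = (
        (2 * n**3 + 110 * n**2 - 255 * n + 153) / (9 * n**2 * (n - 1))
        + (2 * (n - 1) * an) / n**2
        - (8 * bn) / n
    ) / (an**2 + bn)
    uF = (
        (4 * n**2 + 19 * n + 3 - 12 * (n + 1) * an1) / (3 * n * (n - 1))
    ) / an - vF
    Fstar = (k - ((n - 1) / n) * eta_s) / sqrt(uF * eta + vF * eta**2)
    return Dstar, Fstar


def _log_stirling_first_row(n: int) -> np.ndarray:
    """log of unsigned Stirling numbers of the first kind |s(n, k)|, k=0..n."""
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |s(0,0)| = 1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        # |s(m,k)| = |s(m-1,k-1)| + (m-1)|s(m-1,k)|
        shifted = np.concatenate([[-np.inf], row[:-1]])
        with np.errstate(divide="ignore"):
            scaled = row + (log(m - 1) if m > 1 else -np.inf)
        new = np.logaddexp(shifted, scaled)
        row = new
    return row


def fu_fs(hd: HaplotypeData, sites=None, group=None) -> float:
    """Fu's Fs via the Ewens sampling distribution of haplotype number.

    With ``theta`` set to the mean pairwise difference k, S' is the
    probability of observing at least the sampled number of distinct
    haplotypes, computed with unsigned Stirling numbers of the first
    kind in log space; ``Fs = ln(S' / (1 - S'))``.
    """
    sub = _resolve(hd, sites=sites, group=group)
    _, counts, mat = _matrix(sub)
    n = int(counts.sum())
    if n < 2:
        raise ValidationError("Fu's Fs needs n >= 2")
    clean = _clean_columns(mat)
    k = _mean_pairwise(counts, _pair_diff_matrix(mat, clean))
    if k == 0.0:
        logger.warning("k = 0; Fu's Fs undefined")
        return float("nan")
    k_obs = len(counts)
    theta = k
    log_s = _log_stirling_first_row(n)
    log_pochhammer = float(np.sum(np.log(theta + np.arange(n))))
    ks = np.arange(n + 1)
    log_pk = log_s + ks * log(theta) - log_pochhammer
    log_Sprime = float(np.logaddexp.reduce(log_pk[k_obs:]))
    if log_Sprime >= 0.0:
        logger.warning("S' = 1 to machine precision; Fs = -inf")
        return float("-inf")
    Sprime = exp(log_Sprime)
    if Sprime == 0.0:
        logger.warning("S' underflowed; Fs = +inf")
        return float("inf")
    # ln(S'/(1-S')) computed stably in log space
    return log_Sprime - log1p(-Sprime)


@dataclass
class NeutralityStats:
    n: int
    S: int
    tajima_D: float
    fu_li_Dstar: float
    fu_li_Fstar: float
    fu_Fs: float


def neutrality_tests(hd: HaplotypeData, sites=None, group=None) -> NeutralityStats:
    sub = _resolve(hd, sites=sites, group=group)
    _, counts, mat = _matrix(sub)
    S, _, _ = _sub_poly_stats(counts, mat)
    D = tajimas_d(sub)
    Dstar, Fstar = fu_li_tests(sub)
    Fs = fu_fs(sub)
    return NeutralityStats(
        n=int(counts.sum()), S=S, tajima_D=D,
        fu_li_Dstar=Dstar, fu_li_Fstar=Fstar, fu_Fs=Fs,
    )


# ---------------------------------------------------------------------------
# mismatch distribution and sudden-expansion fit
# ---------------------------------------------------------------------------


def mismatch(hd: HaplotypeData, sites=None, group=None) -> np.ndarray:
    """Distribution of pairwise differences (gap-free columns), sum 1.

    Haplotype pairs are weighted by count products and self pairs by
    C(count, 2) at zero differences.
    """
    sub = _resolve(hd, sites=sites, group=group)
    _, counts, mat = _matrix(sub)
    n = int(counts.sum())
    if n < 2:
        raise ValidationError("mismatch needs n >= 2")
    clean = _clean_columns(mat)
    diffs = _pair_diff_matrix(mat, clean)
    dmax = int(diffs.max(initial=0))
    mass = np.zeros(dmax + 1)
    mass[0] += sum(comb(int(c), 2) for c in counts)
    k = len(counts)
    for i in range(k):
        for j in range(i + 1, k):
            mass[diffs[i, j]] += int(counts[i]) * int(counts[j])
    return mass / comb(n, 2)


def expected_mismatch(j_max: int, tau: float, theta0: float, theta1: float) -> np.ndarray:
    """Sudden-expansion expected mismatch probabilities F_0..F_jmax.

    For a pairwise coalescent with present scaled size theta1 for tau
    mutational time units and theta0 before,
    ``F_j = Fhat_j(theta1) + exp(-tau (theta1+1)/theta1) *
    sum_{i<=j} tau^i/i! (Fhat_{j-i}(theta0) - Fhat_{j-i}(theta1))``
    with the geometric equilibrium ``Fhat_j = theta^j/(1+theta)^{j+1}``.
    """
    j = np.arange(j_max + 1)

    def fhat(theta: float) -> np.ndarray:
        if theta <= 0:
            out = np.zeros(j_max + 1)
            out[0] = 1.0
            return out
        return theta**j / (1 + theta) ** (j + 1)

    f1 = fhat(theta1)
    f0 = fhat(theta0)
    if theta1 <= 0:
        return f1
    expo = tau * (theta1 + 1) / theta1
    damp = exp(-min(expo, 700.0))
    # log-space Poisson weights tau^i / i!
    with np.errstate(divide="ignore"):
        log_w = j * np.log(tau) - np.array([lgamma(i + 1) for i in j]) if tau > 0 else None
    w = np.exp(log_w) if tau > 0 else np.eye(1, j_max + 1)[0]
    diff = f0 - f1
    conv = np.array([np.dot(w[: i + 1], diff[: i + 1][::-1]) for i in j])
    return f1 + damp * conv


def raggedness(mm: np.ndarray) -> float:
    """Harpending's raggedness r = sum_{i=1}^{d+1} (x_i - x_{i-1})^2.

    Classes run over the observed support 0..d with an implicit zero
    class at d+1 (the trailing step); no leading boundary term.
    """
    x = np.concatenate([np.asarray(mm, dtype=float), [0.0]])
    return float(np.sum(np.diff(x) ** 2))


@dataclass
class MismatchFit:
    observed: np.ndarray
    tau: float
    theta0: float
    theta1: float
    ssd: float
    raggedness: float
    p_ssd: float | None
    p_raggedness: float | None
    reps: int
    seed: int | None


def _fit_curve(mm: np.ndarray, n_starts: str = "full") -> tuple[float, float, float, float]:
    """Least-squares fit of (tau, theta0, theta1); multi-start Nelder-Mead."""
    j_max = len(mm) - 1

    def ssd(params: np.ndarray) -> float:
        tau, th0, th1 = params
        if not (0 <= tau <= TAU_MAX and 0 <= th0 <= THETA_MAX and 0 <= th1 <= THETA_MAX):
            return 1e6 + float(np.sum(np.square(params)))
        exp_mm = expected_mismatch(j_max, tau, th0, th1)
        return float(np.sum((mm - exp_mm) ** 2))

    mean_d = float(np.dot(np.arange(j_max + 1), mm))
    starts = [(max(mean_d, 0.1), 0.1, 10.0), (max(mean_d, 0.1), 1.0, 50.0)]
    if n_starts == "full":
        for tau0 in (0.5, 2.0, 5.0, 10.0, 25.0, 45.0):
            for th0 in (0.1, 2.0):
                for th1 in (1.0, 10.0, 80.0):
                    starts.append((tau0, th0, th1))
    best = None
    for x0 in starts:
        res = minimize(ssd, np.array(x0), method="Nelder-Mead",
                       options=dict(maxiter=2000, xatol=1e-8, fatol=1e-12))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("mismatch fit failed to converge from any start")
    tau, th0, th1 = np.clip(best.x, 0, [TAU_MAX, THETA_MAX, THETA_MAX])
    return float(tau), float(th0), float(th1), float(best.fun)


def _simulate_mismatch(
    n: int, tau: float, theta0: float, theta1: float, rng_seed: int
) -> np.ndarray:
    """One coalescent replicate's mismatch distribution under the model."""
    import msprime

    u = 0.5  # per-sequence mutation rate; theta = 2 N u => N = theta
    dem = msprime.Demography()
    dem.add_population(name="pop", initial_size=max(theta1, 1e-3))
    dem.add_population_parameters_change(
        time=max(tau, 1e-9) / (2 * u), initial_size=max(theta0, 1e-3), population="pop"
    )
    ts = msprime.sim_ancestry(
        samples=n, demography=dem, ploidy=1, sequence_length=1,
        discrete_genome=False, random_seed=rng_seed,
    )
    mts = msprime.sim_mutations(
        ts, rate=u, discrete_genome=False, random_seed=rng_seed + 1
    )
    G = mts.genotype_matrix()  # (S, n) 0/1
    if G.size == 0:
        return np.array([1.0])
    G = (G > 0).astype(np.int64)
    c = G.sum(axis=0)
    cross = G.T @ G
    d = c[:, None] + c[None, :] - 2 * cross
    iu = np.triu_indices(n, k=1)
    dv = d[iu]
    mass = np.bincount(dv)
    return mass / mass.sum()


def fit_sudden_expansion(
    mm: np.ndarray, n: int, reps: int = 1000, seed: int | None = None
) -> MismatchFit:
    """Fit the Rogers-Harpending sudden-expansion model to a mismatch
    distribution and bootstrap goodness-of-fit p-values.

    SSD is the sum of squared deviations between observed and expected
    class probabilities over the observed support.  p-values come from
    a parametric bootstrap: coalescent samples of size ``n`` are drawn
    under the fitted model, each replicate is refitted, and p is the
    proportion of replicates with SSD (or raggedness) at least the
    observed value.
    """
    mm = np.asarray(mm, dtype=float)
    if mm.size < 2:
        raise ValidationError("mismatch distribution needs >=2 support points")
    tau, th0, th1, ssd_obs = _fit_curve(mm, n_starts="full")
    r_obs = raggedness(mm)
    p_ssd = p_r = None
    if reps > 0:
        rng = np.random.default_rng(seed)
        hits_ssd = hits_r = 0
        for _ in range(reps):
            rep_seed = int(rng.integers(1, 2**31 - 2))
            sim_mm = _simulate_mismatch(n, tau, th0, th1, rep_seed)
            if sim_mm.size < 2:
                sim_ssd = float(np.sum((sim_mm - expected_mismatch(0, tau, th0, th1)) ** 2))
            else:
                _, _, _, sim_ssd = _fit_curve(sim_mm, n_starts="quick")
            if sim_ssd >= ssd_obs - 1e-15:
                hits_ssd += 1
            if raggedness(sim_mm) >= r_obs - 1e-15:
                hits_r += 1
        p_ssd = (hits_ssd + 1) / (reps + 1)
        p_r = (hits_r + 1) / (reps + 1)
    return MismatchFit(
        observed=mm, tau=tau, theta0=th0, theta1=th1, ssd=ssd_obs,
        raggedness=r_obs, p_ssd=p_ssd, p_raggedness=p_r, reps=reps, seed=seed,
    )
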