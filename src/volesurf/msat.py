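"""Microsatellite summary statistics, differentiation, distance and AMOVA.

Implements the GENALEX/HP-Rare-style diversity summaries (N_a, H_o,
H_e, rarefied allelic richness), a Monte-Carlo Hardy-Weinberg test,
Weir & Cockerham (1984) pairwise theta, Nei's D_a distance, a
neighbour-joining tree, and a hierarchical AMOVA on the
number-of-different-alleles distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from volesurf.io import MISSING, GenotypeTable, SiteTable, FstMatrix, ValidationError

logger = logging.getLogger(__name__)

RARE_THRESHOLD = 0.05  # allele frequency below which an allele counts as rare


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------


def _group_map(gt: GenotypeTable, by: str, meta: SiteTable | None) -> dict[str, str]:
    """Map each individual to its grouping label (site or cluster)."""
    if by == "site":
        return dict(gt.site_of)
    if by == "cluster":
        if meta is None:
            raise ValidationError("cluster grouping requires site metadata")
        return {ind: meta.cluster_of(site) for ind, site in gt.site_of.items()}
    raise ValueError(f"unknown grouping {by!r}")


def allele_counts(
    gt: GenotypeTable, by: str = "site", meta: SiteTable | None = None
) -> dict[tuple[str, str], dict[int, int]]:
    """Gene-copy counts per (group, locus); missing calls excluded."""
    gmap = _group_map(gt, by, meta)
    groups: dict[str, None] = {}
    for ind in gt.individuals:
        groups.setdefault(gmap[ind], None)
    out: dict[tuple[str, str], dict[int, int]] = {}
    for group in groups:
        idx = [i for i, ind in enumerate(gt.individuals) if gmap[ind] == group]
        sub = gt.calls[idx]  # (k, L, 2)
        for li, locus in enumerate(gt.loci):
            copies = sub[:, li, :].ravel()
            copies = copies[copies != MISSING]
            tally: dict[int, int] = {}
            for a in copies:
                tally[int(a)] = tally.get(int(a), 0) + 1
            out[(group, locus)] = tally
    return out


def allele_frequencies(
    gt: GenotypeTable, by: str = "site", meta: SiteTable | None = None
) -> dict[tuple[str, str], dict[int, float]]:
    """Allele frequencies per (group, locus) over non-missing gene copies.

    A group x locus cell with zero non-missing calls maps to an empty
    dict (undefined), never to zeros.
    """
    counts = allele_counts(gt, by=by, meta=meta)
    freqs: dict[tuple[str, str], dict[int, float]] = {}
    for key, tally in counts.items():
        total = sum(tally.values())
        if total == 0:
            logger.warning("no non-missing calls for %s; frequencies undefined", key)
            freqs[key] = {}
        else:
            freqs[key] = {a: c / total for a, c in tally.items()}
    return freqs


# ---------------------------------------------------------------------------
# Diversity summary
# ---------------------------------------------------------------------------


def rarefied_richness(counts: dict[int, int], g: int) -> float:
    """Expected number of distinct alleles in a subsample of ``g`` gene copies.

    Hypergeometric rarefaction: sum over alleles of
    ``1 - C(N - N_i, g) / C(N, g)`` with ``N`` total copies.  Requires
    ``g <= N``; never extrapolates.
    """
    N = sum(counts.values())
    if g > N:
        raise ValidationError(f"rarefaction size g={g} exceeds sample size N={N}")
    if g < 1:
        raise ValidationError("g must be >= 1")
    denom = comb(N, g)
    return float(sum(1.0 - comb(N - ni, g) / denom for ni in counts.values()))


@dataclass
class DiversitySummary:
    """Per site x locus and per-site mean diversity statistics."""

    per_locus: pd.DataFrame  # site, locus, n, Na, Ho, He, uHe, Ar
    per_site: pd.DataFrame  # site, mean Na/Ho/He/uHe/Ar
    private_alleles: dict[str, list[tuple[str, int]]]  # site -> [(locus, allele)]
    rare_alleles: dict[str, list[tuple[str, int]]]  # site -> [(locus, allele)]
    g: int

    def site_value(self, site: str, stat: str) -> float:
        row = self.per_site.loc[self.per_site["site"] == site]
        if row.empty:
            raise KeyError(site)
        return float(row[stat].iloc[0])


def diversity_summary(
    gt: GenotypeTable, meta: SiteTable | None = None, g: int = 14
) -> DiversitySummary:
    """GENALEX-style diversity table with HP-Rare-style rarefaction.

    ``g`` is the standardised subsample size in gene copies (the default
    14 equals 7 diploids).  Sites with fewer than ``g`` non-missing gene
    copies at a locus get an undefined (NaN) A_r there, with a warning.
    H_e is the biased 1 - sum(p^2); uH_e carries the 2n/(2n-1)
    correction.  Per-site means are unweighted over loci.
    """
    counts = allele_counts(gt, by="site")
    rows = []
    for site in gt.sites:
        idx = gt.site_indices(site)
        for li, locus in enumerate(gt.loci):
            calls = gt.calls[idx, li, :]
            ok = calls[:, 0] != MISSING
            n = int(ok.sum())
            tally = counts[(site, locus)]
            N = sum(tally.values())
            if n == 0:
                rows.append(
                    dict(site=site, locus=locus, n=0, Na=np.nan, Ho=np.nan,
                         He=np.nan, uHe=np.nan, Ar=np.nan)
                )
                continue
            p = np.array(list(tally.values()), dtype=float) / N
            he = 1.0 - float(np.sum(p**2))
            uhe = he * (2 * n) / (2 * n - 1) if n > 1 else np.nan
            ho = float(np.sum(ok & (calls[:, 0] != calls[:, 1]))) / n
            if N >= g:
                ar = rarefied_richness(tally, g)
            else:
                ar = np.nan
                logger.warning(
                    "site %s locus %s: N=%d gene copies < g=%d; A_r undefined",
                    site, locus, N, g,
                )
            rows.append(
                dict(site=site, locus=locus, n=n, Na=len(tally), Ho=ho,
                     He=he, uHe=uhe, Ar=ar)
            )
    per_locus = pd.DataFrame(rows)
    per_site = (
        per_locus.groupby("site", sort=False)[["Na", "Ho", "He", "uHe", "Ar"]]
        .mean()
        .reset_index()
    )

    # private alleles: observed in exactly one site (table-wide)
    seen_in: dict[tuple[str, int], set[str]] = {}
    for (site, locus), tally in counts.items():
        for a in tally:
            seen_in.setdefault((locus, a), set()).add(site)
    private: dict[str, list[tuple[str, int]]] = {s: [] for s in gt.sites}
    for (locus, a), sites in seen_in.items():
        if len(sites) == 1:
            private[next(iter(sites))].append((locus, a))

    freqs = allele_frequencies(gt, by="site")
    rare: dict[str, list[tuple[str, int]]] = {s: [] for s in gt.sites}
    for (site, locus), f in freqs.items():
        for a, fa in f.items():
            if 0.0 < fa < RARE_THRESHOLD:
                rare[site].append((locus, a))
    for d in (private, rare):
        for s in d:
            d[s].sort()

    return DiversitySummary(
        per_locus=per_locus, per_site=per_site,
        private_alleles=private, rare_alleles=rare, g=g,
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg test
# ---------------------------------------------------------------------------


@dataclass
class HweResult:
    p_value: float
    het_observed: int
    het_expected: float
    n: int
    monomorphic: bool
    reps: int
    seed: int | None


def _expected_het_pairs(copy_counts: np.ndarray, n_pairs: int) -> float:
    """Exact E[# heterozygous pairs] under random pairing of gene copies."""
    total = int(copy_counts.sum())
    same = sum(comb(int(c), 2) for c in copy_counts)
    return n_pairs * (1.0 - same / comb(total, 2))


def hwe_test(
    gt: GenotypeTable, site: str, locus: str, reps: int = 10000, seed: int | None = None
) -> HweResult:
    """Monte-Carlo exact test of Hardy-Weinberg proportions.

    Gene copies at the site x locus are randomly re-paired ``reps``
    times; the two-sided statistic is the deviation of the heterozygote
    count from its exact random-pairing expectation, and the p-value
    carries a +1 continuity correction on numerator and denominator.
    """
    li = gt.loci.index(locus)
    idx = gt.site_indices(site)
    calls = gt.calls[idx, li, :]
    calls = calls[calls[:, 0] != MISSING]
    n = calls.shape[0]
    if n < 5:
        raise ValidationError(f"need >=5 genotyped individuals, got {n}")
    alleles = np.unique(calls)
    if alleles.size == 1:
        return HweResult(1.0, 0, 0.0, n, True, reps, seed)

    pool = calls.ravel().copy()
    codes = np.searchsorted(alleles, pool)
    copy_counts = np.bincount(codes, minlength=alleles.size)
    e_het = _expected_het_pairs(copy_counts, n)
    h_obs = int(np.sum(calls[:, 0] != calls[:, 1]))
    d_obs = abs(h_obs - e_het)

    rng = np.random.default_rng(seed)
    hits = 0
    work = codes.copy()
    for _ in range(reps):
        rng.shuffle(work)
        h = int(np.sum(work[0::2] != work[1::2]))
        if abs(h - e_het) >= d_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (reps + 1)
    return HweResult(p, h_obs, e_het, n, False, reps, seed)


def hwe_table(
    gt: GenotypeTable, reps: int = 10000, seed: int | None = None,
    bonferroni: bool = True,
) -> pd.DataFrame:
    """HWE p-values for every site x locus, with Bonferroni adjustment."""
    rng = np.random.default_rng(seed)
    rows = []
    for site in gt.sites:
        for locus in gt.loci:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            try:
                res = hwe_test(gt, site, locus, reps=reps, seed=sub_seed)
                rows.append(dict(site=site, locus=locus, p=res.p_value,
                                 monomorphic=res.monomorphic, n=res.n))
            except ValidationError:
                rows.append(dict(site=site, locus=locus, p=np.nan,
                                 monomorphic=False, n=np.nan))
    df = pd.DataFrame(rows)
    if bonferroni:
        m = df["p"].notna().sum()
        df["p_bonferroni"] = np.minimum(df["p"] * m, 1.0)
    return df


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------


def _wc_components_pair(
    calls1: np.ndarray, calls2: np.ndarray
) -> tuple[float, float, float]:
    """Variance components (a, b, c) for one locus, two samples.

    ``calls*`` are (k, 2) arrays of non-missing diploid calls.  Returns
    the allele-summed among-population (a), among-individual (b) and
    within-individual (c) components of Weir & Cockerham (1984).
    """
    r = 2
    n1, n2 = calls1.shape[0], calls2.shape[0]
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    alleles = np.unique(np.concatenate([calls1.ravel(), calls2.ravel()]))
    A = a_sum = b_sum = c_sum = 0.0
    for al in alleles:
        p1 = np.mean(calls1 == al)  # over 2*n1 copies
        p2 = np.mean(calls2 == al)
        h1 = np.mean((calls1[:, 0] != calls1[:, 1]) & np.any(calls1 == al, axis=1))
        h2 = np.mean((calls2[:, 0] != calls2[:, 1]) & np.any(calls2 == al, axis=1))
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
        A += 1
    return a_sum, b_sum, c_sum


def pairwise_fst(gt: GenotypeTable) -> FstMatrix:
    """Pairwise Weir & Cockerham (1984) theta between all sites.

    Per pair, variance components are summed over alleles and loci
    before the ratio is taken; loci with fewer than two genotyped
    individuals in either member are dropped for that pair (logged).
    Negative estimates are retained.
    """
    sites = gt.sites
    if len(sites) < 2:
        raise ValidationError("need >=2 sites for pairwise F_ST")
    idx_of = {s: gt.site_indices(s) for s in sites}
    k = len(sites)
    theta = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            num = den = 0.0
            used = 0
            for li in range(len(gt.loci)):
                c1 = gt.calls[idx_of[sites[i]], li, :]
                c2 = gt.calls[idx_of[sites[j]], li, :]
                c1 = c1[c1[:, 0] != MISSING]
                c2 = c2[c2[:, 0] != MISSING]
                if c1.shape[0] < 2 or c2.shape[0] < 2:
                    logger.warning(
                        "locus %s dropped for pair (%s, %s): <2 genotyped individuals",
                        gt.loci[li], sites[i], sites[j],
                    )
                    continue
                a, b, c = _wc_components_pair(c1, c2)
                num += a
                den += a + b + c
                used += 1
            if used == 0:
                raise ValidationError(
                    f"no usable loci for pair ({sites[i]}, {sites[j]})"
                )
            theta[i, j] = theta[j, i] = num / den if den != 0.0 else 0.0
    return FstMatrix(sites=sites, values=theta)


# ---------------------------------------------------------------------------
# Nei's D_a and neighbour joining
# ---------------------------------------------------------------------------


def nei_da(gt: GenotypeTable) -> tuple[list[str], np.ndarray]:
    """Nei et al. (1983) D_a distance between sites.

    ``D_a = 1 - (1/L) * sum_loci sum_alleles sqrt(x_i * y_i)`` over loci
    with data in both sites.
    """
    sites = gt.sites
    if len(sites) < 2:
        raise ValidationError("need >=2 sites")
    freqs = allele_frequencies(gt, by="site")
    k = len(sites)
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            shared = [
                l for l in gt.loci
                if freqs[(sites[i], l)] and freqs[(sites[j], l)]
            ]
            if not shared:
                raise ValidationError(
                    f"no shared loci with data for pair ({sites[i]}, {sites[j]})"
                )
            total = 0.0
            for l in shared:
                fx, fy = freqs[(sites[i], l)], freqs[(sites[j], l)]
                total += sum(
                    np.sqrt(fx[a] * fy[a]) for a in set(fx) & set(fy)
                )
            D[i, j] = D[j, i] = 1.0 - total / len(shared)
    return sites, D


def nj_tree(labels: list[str], dist: np.ndarray) -> str:
    """Neighbour-joining (Saitou-Nei) tree as a newick string.

    Negative input distances are clamped to zero (logged), and negative
    branch lengths produced by the agglomeration are clamped to zero.
    """
    dist = np.asarray(dist, dtype=float)
    if len(labels) < 3:
        raise ValidationError("need >=3 taxa")
    if dist.shape != (len(labels), len(labels)):
        raise ValidationError("distance matrix shape mismatch")
    if not np.allclose(dist, dist.T):
        raise ValidationError("distance matrix must be symmetric")
    if not np.all(np.isfinite(dist)):
        raise ValidationError("distances must be finite")
    if np.any(dist < 0):
        logger.warning("negative distances clamped to 0 for tree construction")
        dist = np.clip(dist, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    dm = DistanceMatrix(dist, ids=list(labels))
    tree = _skbio_nj(dm, neg_as_zero=True)
    return str(tree).strip()


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


@dataclass
class AmovaResult:
    """Hierarchical analysis of molecular variance.

    Components and percentages follow the Excoffier nested design
    (among clusters / among sites within clusters / within sites);
    p-values come from the standard permutation schemes.
    """

    components: dict[str, float]
    percentages: dict[str, float]
    phi: dict[str, float]
    p_values: dict[str, float]
    reps: int
    seed: int | None
    levels: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for level in self.components:
            rows.append(
                dict(
                    source=level,
                    variance=self.components[level],
                    percent=self.percentages[level],
                    p=self.p_values.get(level, np.nan),
                )
            )
        return pd.DataFrame(rows)


def _locus_units(gt: GenotypeTable, li: int) -> tuple[np.ndarray, np.ndarray]:
    """Gene copies at locus li: (allele codes, individual index) arrays."""
    calls = gt.calls[:, li, :]
    ok = calls[:, 0] != MISSING
    ind_idx = np.repeat(np.nonzero(ok)[0], 2)
    copies = calls[ok].ravel()
    return copies, ind_idx


def _ss_within(copies: np.ndarray, labels: np.ndarray, n_labels: int) -> float:
    """Sum over groups of (pairwise different-allele count) / group size."""
    ss = 0.0
    order = np.argsort(labels, kind="stable")
    copies = copies[order]
    labels = labels[order]
    bounds = np.searchsorted(labels, np.arange(n_labels + 1))
    for g in range(n_labels):
        seg = copies[bounds[g]:bounds[g + 1]]
        Ng = seg.size
        if Ng < 2:
            continue
        counts = np.bincount(seg)
        same = np.sum(counts * (counts - 1)) // 2
        npairs = Ng * (Ng - 1) // 2
        ss += (npairs - same) / Ng
    return ss


def _amova_components_locus(
    copies: np.ndarray,
    pop: np.ndarray,
    grp: np.ndarray,
    n_pops: int,
    n_groups: int,
) -> tuple[float, float, float] | None:
    """Variance components (sigma_a, sigma_b, sigma_c) for one locus.

    Units are gene copies; the distance is 1 between different alleles.
    Returns None when the locus lacks the degrees of freedom.
    """
    N = copies.size
    if N == 0:
        return None
    counts_all = np.bincount(copies)
    same = np.sum(counts_all * (counts_all - 1)) // 2
    ss_total = (N * (N - 1) // 2 - same) / N

    ss_wp = _ss_within(copies, pop, n_pops)
    ss_wg = _ss_within(copies, grp, n_groups)
    ss_ap = ss_wg - ss_wp
    ss_ag = ss_total - ss_wg

    n_p = np.bincount(pop, minlength=n_pops).astype(float)
    N_g = np.bincount(grp, minlength=n_groups).astype(float)
    # group membership of each pop present at this locus
    pop_group = np.full(n_pops, -1, dtype=int)
    pop_group[pop] = grp
    present = n_p > 0
    P = int(present.sum())
    present_groups = N_g > 0
    G = int(present_groups.sum())
    df_wp = N - P
    df_ap = P - G
    df_ag = G - 1
    if df_wp <= 0 or df_ap <= 0 or df_ag <= 0:
        return None

    sum_np2_by_g = np.zeros(n_groups)
    for p_idx in np.nonzero(present)[0]:
        sum_np2_by_g[pop_group[p_idx]] += n_p[p_idx] ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(N_g > 0, sum_np2_by_g / np.where(N_g > 0, N_g, 1), 0.0)
    n1 = (N - ratio.sum()) / df_ap
    n2 = (ratio.sum() - np.sum(n_p**2) / N) / df_ag
    n3 = (N - np.sum(N_g**2) / N) / df_ag

    ms_wp = ss_wp / df_wp
    ms_ap = ss_ap / df_ap
    ms_ag = ss_ag / df_ag
    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    return sigma_a, sigma_b, sigma_c


def _amova_stats(
    gt_calls: np.ndarray,
    loci_units: list[tuple[np.ndarray, np.ndarray]],
    pop_of_ind: np.ndarray,
    grp_of_pop: np.ndarray,
    n_pops: int,
    n_groups: int,
) -> tuple[float, float, float]:
    """Summed-over-loci variance components for given assignments."""
    tot_a = tot_b = tot_c = 0.0
    for copies, ind_idx in loci_units:
        pop = pop_of_ind[ind_idx]
        grp = grp_of_pop[pop]
        res = _amova_components_locus(copies, pop, grp, n_pops, n_groups)
        if res is None:
            continue
        a, b, c = res
        tot_a += a
        tot_b += b
        tot_c += c
    return tot_a, tot_b, tot_c


def amova(
    gt: GenotypeTable,
    meta: SiteTable | None = None,
    reps: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """Hierarchical AMOVA (cluster > site > individual) on gene copies.

    The molecular distance is the number of different alleles between
    gene copies, computed locus by locus and summed (F_ST-like, not
    R_ST-like).  With metadata defining >=2 clusters the full 3-level
    design is fitted; otherwise a 2-level (site > individual) design.
    Permutation schemes: individuals among all sites (Phi_ST),
    individuals among sites within clusters (Phi_SC), whole sites among
    clusters (Phi_CT).
    """
    sites = gt.sites
    site_code = {s: i for i, s in enumerate(sites)}
    pop_of_ind = np.array([site_code[gt.site_of[ind]] for ind in gt.individuals])
    n_pops = len(sites)

    three_level = meta is not None and len(meta.clusters) >= 2
    if three_level:
        meta.check_against(gt)
        clusters = meta.clusters
        cl_code = {c: i for i, c in enumerate(clusters)}
        grp_of_pop = np.array([cl_code[meta.cluster_of(s)] for s in sites])
        for c in clusters:
            k = int(np.sum(grp_of_pop == cl_code[c]))
            if k == 1:
                raise ValidationError(
                    f"cluster {c!r} has a single site; use the 2-level design "
                    "(omit metadata or merge clusters)"
                )
        n_groups = len(clusters)
    else:
        # 2-level design: each site is its own "group"
        grp_of_pop = np.arange(n_pops)
        n_groups = n_pops

    loci_units = [_locus_units(gt, li) for li in range(len(gt.loci))]
    # recode alleles per locus to small ints for bincount
    recoded = []
    for copies, ind_idx in loci_units:
        _, inv = np.unique(copies, return_inverse=True)
        recoded.append((inv.astype(np.int64), ind_idx))
    loci_units = recoded

    if three_level:
        a, b, c = _amova_stats(gt.calls, loci_units, pop_of_ind, grp_of_pop, n_pops, n_groups)
        total = a + b + c
        components = {
            "among_clusters": a,
            "among_sites_within_clusters": b,
            "within_sites": c,
        }
        phi = {
            "phi_CT": a / total,
            "phi_SC": b / (b + c) if (b + c) != 0 else float("nan"),
            "phi_ST": (a + b) / total,
        }
    else:
        _, b2, c2 = _two_level_stats(loci_units, pop_of_ind, n_pops)
        components = {"among_sites": b2, "within_sites": c2}
        total = b2 + c2
        phi = {"phi_ST": b2 / total}

    percentages = {k2: 100.0 * v / total for k2, v in components.items()}

    rng = np.random.default_rng(seed)
    p_values: dict[str, float] = {}
    if reps > 0:
        if three_level:
            obs_ct, obs_sc, obs_st = phi["phi_CT"], phi["phi_SC"], phi["phi_ST"]
            hits_ct = hits_sc = hits_st = 0
            # site composition per cluster for Phi_CT permutation
            for _ in range(reps):
                # Phi_ST: permute individuals among all sites
                perm_pop = rng.permutation(pop_of_ind)
                a_, b_, c_ = _amova_stats(gt.calls, loci_units, perm_pop, grp_of_pop, n_pops, n_groups)
                if (a_ + b_) / (a_ + b_ + c_) >= obs_st - 1e-12:
                    hits_st += 1
                # Phi_SC: permute individuals among sites within clusters
                perm_pop = pop_of_ind.copy()
                for gidx in range(n_groups):
                    pops_in_g = np.nonzero(grp_of_pop == gidx)[0]
                    mask = np.isin(pop_of_ind, pops_in_g)
                    perm_pop[mask] = rng.permutation(pop_of_ind[mask])
                a_, b_, c_ = _amova_stats(gt.calls, loci_units, perm_pop, grp_of_pop, n_pops, n_groups)
                if b_ / (b_ + c_) >= obs_sc - 1e-12:
                    hits_sc += 1
                # Phi_CT: permute whole sites among clusters
                perm_grp = rng.permutation(grp_of_pop)
                a_, b_, c_ = _amova_stats(gt.calls, loci_units, pop_of_ind, perm_grp, n_pops, n_groups)
                if a_ / (a_ + b_ + c_) >= obs_ct - 1e-12:
                    hits_ct += 1
            p_values = {
                "among_clusters": (hits_ct + 1) / (reps + 1),
                "among_sites_within_clusters": (hits_sc + 1) / (reps + 1),
                "within_sites": (hits_st + 1) / (reps + 1),
            }
        else:
            obs = phi["phi_ST"]
            hits = 0
            for _ in range(reps):
                perm_pop = rng.permutation(pop_of_ind)
                _, b_, c_ = _two_level_stats(loci_units, perm_pop, n_pops)
                if b_ / (b_ + c_) >= obs - 1e-12:
                    hits += 1
            p_values = {"among_sites": (hits + 1) / (reps + 1)}

    return AmovaResult(
        components=components,
        percentages=percentages,
        phi=phi,
        p_values=p_values,
        reps=reps,
        seed=seed,
        levels=3 if three_level else 2,
    )


def _two_level_stats(
    loci_units: list[tuple[np.ndarray, np.ndarray]],
    pop_of_ind: np.ndarray,
    n_pops: int,
) -> tuple[float, float, float]:
    """(0, sigma_among_sites, sigma_within_sites) summed over loci."""
    tot_b = tot_c = 0.0
    for copies, ind_idx in loci_units:
        pop = pop_of_ind[ind_idx]
        N = copies.size
        if N == 0:
            continue
        counts_all = np.bincount(copies)
        same = np.sum(counts_all * (counts_all - 1)) // 2
        ss_total = (N * (N - 1) // 2 - same) / N
        ss_wp = _ss_within(copies, pop, n_pops)
        ss_ap = ss_total - ss_wp
        n_p = np.bincount(pop, minlength=n_pops).astype(float)
        P = int(np.sum(n_p > 0))
        df_wp, df_ap = N - P, P - 1
        if df_wp <= 0 or df_ap <= 0:
            continue
        ms_wp = ss_wp / df_wp
        ms_ap = ss_ap / df_ap
        n1 = (N - np.sum(n_p**2) / N) / df_ap
        sigma_c = ms_wp
        sigma_b = (ms_ap - sigma_c) / n1
        tot_b += sigma_b
        tot_c += sigma_c
    return 0.0, tot_b, tot_c
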