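"""Range-expansion and genetic-surfing inference.

The expansion signal is read from microsatellite differentiation:
isolation by distance as F_ST/(1-F_ST) against ln(km), start/arrival
sites from cross-cluster mean F_ST with ANOVA + Tukey follow-up,
diversity and allele-frequency clines against F_ST to the focal site,
and a scan for alleles that are rare in the source cluster but common
in the derived one (the surfing signature).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from math import radians, sin, cos, asin, sqrt, log

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from volesurf.io import FstMatrix, GenotypeTable, SiteTable, ValidationError
from volesurf.msat import (
    DiversitySummary,
    allele_counts,
    diversity_summary,
    pairwise_fst,
)

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088


def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between (lat, lon) points (WGS84 degrees)."""
    lat1, lon1 = map(radians, a)
    lat2, lon2 = map(radians, b)
    h = sin((lat2 - lat1) / 2) ** 2 + cos(lat1) * cos(lat2) * sin((lon2 - lon1) / 2) ** 2
    return 2 * EARTH_RADIUS_KM * asin(min(1.0, sqrt(h)))


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# Isolation by distance
# ---------------------------------------------------------------------------


@dataclass
class IbdResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    mantel_p: float | None
    n_pairs: int
    subset: str


def ibd_regression(
    fst: FstMatrix,
    meta: SiteTable,
    subset: str | list[str] | None = None,
    mantel_reps: int = 0,
    seed: int | None = None,
) -> IbdResult:
    """OLS of theta/(1-theta) on ln(km) over unordered site pairs.

    ``subset`` may be a cluster label or an explicit site list.  Pairs
    with theta >= 1 or zero geographic distance are excluded with a
    warning; negative theta values are retained (the transform is
    monotone below 1).  An optional Mantel permutation test permutes
    site labels of the genetic matrix.
    """
    if isinstance(subset, str):
        sites = [s for s in fst.sites if s in set(meta.sites_in(subset))]
        label = subset
    elif subset is None:
        sites = list(fst.sites)
        label = "all"
    else:
        sites = [s for s in fst.sites if s in set(subset)]
        label = ",".join(subset)
    if len(sites) < 4:
        raise ValidationError(f"IBD needs >=4 sites, got {len(sites)} in {label!r}")

    idx = [fst.sites.index(s) for s in sites]
    theta = fst.values[np.ix_(idx, idx)]
    coords = [meta.coords(s) for s in sites]
    k = len(sites)
    xs, ys = [], []
    for i in range(k):
        for j in range(i + 1, k):
            t = theta[i, j]
            d = haversine_km(coords[i], coords[j])
            if t >= 1.0:
                logger.warning("pair (%s,%s): theta >= 1 excluded", sites[i], sites[j])
                continue
            if d <= 0.0:
                logger.warning("pair (%s,%s): zero distance excluded", sites[i], sites[j])
                continue
            xs.append(log(d))
            ys.append(t / (1.0 - t))
    xs = np.array(xs)
    ys = np.array(ys)
    if xs.size < 3 or np.ptp(xs) == 0.0:
        raise ValidationError("degenerate geographic distances; cannot regress")
    res = stats.linregress(xs, ys)

    mantel_p = None
    if mantel_reps > 0:
        rng = np.random.default_rng(seed)
        D = np.array(
            [[haversine_km(coords[i], coords[j]) for j in range(k)] for i in range(k)]
        )
        iu = np.triu_indices(k, 1)
        with np.errstate(divide="ignore"):
            x_full = np.log(D[iu])
        y_mat = theta / (1.0 - theta)
        obs = stats.pearsonr(x_full, y_mat[iu]).statistic
        hits = 0
        for _ in range(mantel_reps):
            perm = rng.permutation(k)
            yp = y_mat[np.ix_(perm, perm)][iu]
            if abs(stats.pearsonr(x_full, yp).statistic) >= abs(obs) - 1e-12:
                hits += 1
        mantel_p = (hits + 1) / (mantel_reps + 1)

    return IbdResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        mantel_p=mantel_p,
        n_pairs=int(xs.size),
        subset=label,
    )


# ---------------------------------------------------------------------------
# Focal (start/arrival) site inference
# ---------------------------------------------------------------------------


@dataclass
class FocalSiteResult:
    source: str
    target: str
    means: dict[str, float]
    values: dict[str, list[float]]
    anova_F: float
    anova_p: float
    focal: str
    tied: list[str]
    significant: bool


def cross_cluster_mean_fst(
    fst: FstMatrix, meta: SiteTable, source: str, target: str
) -> FocalSiteResult:
    """Mean F_ST from each source-cluster site to all target-cluster sites.

    A one-way ANOVA across source sites (each site contributing its
    vector of pairwise theta values to the target cluster) is followed
    by Tukey's HSD; the focal site minimises the mean, and the
    significance flag is true iff its mean differs from every other
    source site at alpha = 0.05.
    """
    src_sites = [s for s in fst.sites if s in set(meta.sites_in(source))]
    tgt_sites = [s for s in fst.sites if s in set(meta.sites_in(target))]
    if len(src_sites) < 3:
        raise ValidationError(f"source cluster {source!r} needs >=3 sites")
    if len(tgt_sites) < 2:
        raise ValidationError(f"target cluster {target!r} needs >=2 sites")

    vectors = {
        s: np.array([fst.get(s, t) for t in tgt_sites]) for s in src_sites
    }
    means = {s: float(v.mean()) for s, v in vectors.items()}
    groups = [vectors[s] for s in src_sites]
    F, p = stats.f_oneway(*groups)

    order = sorted(src_sites, key=lambda s: means[s])
    best = means[order[0]]
    tied = [s for s in src_sites if abs(means[s] - best) <= 1e-12]
    focal = order[0]
    if len(tied) > 1:
        logger.warning("tie for lowest mean F_ST: %s", tied)

    tukey = stats.tukey_hsd(*groups)
    fi = src_sites.index(focal)
    significant = all(
        tukey.pvalue[fi, j] < 0.05 for j in range(len(src_sites)) if j != fi
    )
    return FocalSiteResult(
        source=source, target=target, means=means,
        values={s: v.tolist() for s, v in vectors.items()},
        anova_F=float(F), anova_p=float(p),
        focal=focal, tied=tied, significant=significant,
    )


@dataclass
class FocalDesignation:
    cluster: str
    other_cluster: str
    role: str  # "starting" | "arrival"
    site: str
    significant: bool
    max_ar: bool | None
    warning: str | None


def identify_focal_sites(
    fst: FstMatrix,
    meta: SiteTable,
    route: list[str],
    diversity: DiversitySummary | None = None,
) -> list[FocalDesignation]:
    """Start/arrival designations along an ordered colonisation route.

    For each consecutive cluster pair (A -> B) the starting site in A
    minimises the mean F_ST to B, annotated with whether it also
    maximises allelic richness in A (a failed check is a warning, not a
    failure); the arrival site in B minimises the mean F_ST to A.
    """
    if len(route) < 2:
        raise ValidationError("route needs >=2 clusters")
    out: list[FocalDesignation] = []
    for a, b in zip(route[:-1], route[1:]):
        for cluster, other, role in ((a, b, "starting"), (b, a, "arrival")):
            res = cross_cluster_mean_fst(fst, meta, cluster, other)
            max_ar: bool | None = None
            warning = None
            if role == "starting" and diversity is not None:
                ar = {
                    s: diversity.site_value(s, "Ar")
                    for s in meta.sites_in(cluster)
                    if s in set(diversity.per_site["site"])
                }
                if ar:
                    best_ar = max(ar, key=lambda s: (ar[s] if not np.isnan(ar[s]) else -np.inf))
                    max_ar = best_ar == res.focal
                    if not max_ar:
                        warning = (
                            f"starting site {res.focal} does not maximise A_r in "
                            f"{cluster} (max is {best_ar}); designation retained"
                        )
                        logger.warning(warning)
            out.append(
                FocalDesignation(
                    cluster=cluster, other_cluster=other, role=role,
                    site=res.focal, significant=res.significant,
                    max_ar=max_ar, warning=warning,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Cline regressions
# ---------------------------------------------------------------------------


@dataclass
class Regression:
    slope: float
    intercept: float
    r: float
    r_squared: float
    p_value: float
    n: int


def _regress(x: np.ndarray, y: np.ndarray) -> Regression:
    res = stats.linregress(x, y)
    return Regression(
        slope=float(res.slope), intercept=float(res.intercept),
        r=float(res.rvalue), r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue), n=int(x.size),
    )


@dataclass
class ClineResult:
    cluster: str
    focal: str
    table: pd.DataFrame  # site, theta_to_focal, He, Ar
    he: Regression
    ar: Regression


def diversity_cline(
    diversity: DiversitySummary,
    fst: FstMatrix,
    focal: str,
    cluster: str,
    meta: SiteTable,
    exclude_focal: bool = True,
) -> ClineResult:
    """Regress per-site H_e and A_r on theta to the focal site.

    The focal site itself is excluded by default: its theta to itself
    is 0 by construction and would anchor the fit.
    """
    sites = [s for s in fst.sites if s in set(meta.sites_in(cluster))]
    if focal not in sites:
        raise ValidationError(f"focal site {focal!r} not in cluster {cluster!r}")
    pts = [s for s in sites if not (exclude_focal and s == focal)]
    if len(pts) < 3:
        raise ValidationError("need >=3 regression sites")
    x = np.array([fst.get(s, focal) for s in pts])
    he = np.array([diversity.site_value(s, "He") for s in pts])
    ar = np.array([diversity.site_value(s, "Ar") for s in pts])
    table = pd.DataFrame({"site": pts, "theta_to_focal": x, "He": he, "Ar": ar})
    ok_ar = ~np.isnan(ar)
    return ClineResult(
        cluster=cluster, focal=focal, table=table,
        he=_regress(x, he),
        ar=_regress(x[ok_ar], ar[ok_ar]),
    )


def allele_cline_scan(
    gt: GenotypeTable,
    fst: FstMatrix,
    focal: str,
    cluster: str,
    meta: SiteTable,
    min_sites: int = 3,
    alpha: float = 0.05,
    exclude_focal: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation of per-site allele frequencies with theta to
    the focal site, for every locus-allele observed in enough sites.

    Returns (cline table, exclusions).  The cline table carries the
    pooled cluster-wide frequency, signed r, R^2, p, significance stars
    at ``alpha`` (no multiple-testing correction, mirroring common
    practice for these scans) and a Benjamini-Hochberg column for
    honest reporting.
    """
    sites = [s for s in fst.sites if s in set(meta.sites_in(cluster))]
    pts = [s for s in sites if not (exclude_focal and s == focal)]
    if len(pts) < max(min_sites, 3):
        raise ValidationError("too few sites for the cline scan")
    x = np.array([fst.get(s, focal) for s in pts])

    counts = allele_counts(gt, by="site")
    rows, excl = [], []
    for locus in gt.loci:
        alleles = sorted(
            {a for s in sites for a in counts.get((s, locus), {})}
        )
        pooled_tot = sum(sum(counts.get((s, locus), {}).values()) for s in sites)
        for a in alleles:
            pooled = sum(counts.get((s, locus), {}).get(a, 0) for s in sites)
            cluster_freq = pooled / pooled_tot if pooled_tot else np.nan
            freqs = []
            n_obs = 0
            for s in pts:
                tal = counts.get((s, locus), {})
                tot = sum(tal.values())
                f = tal.get(a, 0) / tot if tot else np.nan
                if tal.get(a, 0) > 0:
                    n_obs += 1
                freqs.append(f)
            freqs = np.array(freqs)
            if n_obs < min_sites:
                excl.append(dict(locus=locus, allele=a, reason="below min_sites"))
                continue
            ok = ~np.isnan(freqs)
            if np.std(freqs[ok]) == 0.0 or np.std(x[ok]) == 0.0:
                excl.append(dict(locus=locus, allele=a, reason="zero variance"))
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", stats.ConstantInputWarning)
                pr = stats.pearsonr(x[ok], freqs[ok])
            if not np.isfinite(pr.statistic):
                excl.append(dict(locus=locus, allele=a, reason="zero variance"))
                continue
            rows.append(
                dict(
                    locus=locus, allele=a, cluster_freq=cluster_freq,
                    r=float(pr.statistic), r_squared=float(pr.statistic**2),
                    p=float(pr.pvalue), stars=_stars(float(pr.pvalue)),
                    significant=bool(pr.pvalue < alpha),
                )
            )
    table = pd.DataFrame(
        rows, columns=["locus", "allele", "cluster_freq", "r", "r_squared",
                       "p", "stars", "significant"],
    )
    if not table.empty:
        table["p_bh"] = multipletests(table["p"], method="fdr_bh")[1]
    else:
        table["p_bh"] = pd.Series(dtype=float)
    exclusions = pd.DataFrame(excl, columns=["locus", "allele", "reason"])
    return table, exclusions


def count_significant_clines(table: pd.DataFrame) -> dict[str, int]:
    sig = table[table["significant"]]
    return {
        "total": int(len(sig)),
        "increasing": int((sig["r"] > 0).sum()),
        "decreasing": int((sig["r"] < 0).sum()),
    }


# ---------------------------------------------------------------------------
# Rare-to-common allele scan
# ---------------------------------------------------------------------------


@dataclass
class RareToCommonResult:
    source: str
    derived: str
    rare_threshold: float
    common_threshold: float
    table: pd.DataFrame  # locus, allele, source_freq, max_site_freq_derived, derived_freq


def rare_to_common_scan(
    gt: GenotypeTable,
    meta: SiteTable,
    source: str,
    derived: str,
    rare_thresh: float = 0.05,
    common_thresh: float = 0.25,
) -> RareToCommonResult:
    """Alleles rare in the source cluster but common in the derived one.

    Listed alleles have pooled source-cluster frequency below
    ``rare_thresh`` and either a per-site frequency in the derived
    cluster of at least ``common_thresh`` or a pooled derived-cluster
    frequency of at least ``2 * rare_thresh``.  Both evidence columns
    are reported so the threshold choice stays transparent.
    """
    counts_site = allele_counts(gt, by="site")
    counts_cl = allele_counts(gt, by="cluster", meta=meta)
    derived_sites = [s for s in gt.sites if s in set(meta.sites_in(derived))]
    rows = []
    for locus in gt.loci:
        src = counts_cl.get((source, locus), {})
        der = counts_cl.get((derived, locus), {})
        src_tot = sum(src.values())
        der_tot = sum(der.values())
        if src_tot == 0 or der_tot == 0:
            continue
        for a in sorted(set(src) | set(der)):
            f_src = src.get(a, 0) / src_tot
            if f_src >= rare_thresh:
                continue
            f_der = der.get(a, 0) / der_tot
            site_freqs = []
            for s in derived_sites:
                tal = counts_site.get((s, locus), {})
                tot = sum(tal.values())
                if tot:
                    site_freqs.append(tal.get(a, 0) / tot)
            max_site = max(site_freqs) if site_freqs else 0.0
            if max_site >= common_thresh or f_der >= 2 * rare_thresh:
                rows.append(
                    dict(
                        locus=locus, allele=a, source_freq=f_src,
                        max_site_freq_derived=max_site, derived_freq=f_der,
                    )
                )
    table = pd.DataFrame(
        rows, columns=["locus", "allele", "source_freq",
                       "max_site_freq_derived", "derived_freq"],
    )
    return RareToCommonResult(
        source=source, derived=derived,
        rare_threshold=rare_thresh, common_threshold=common_thresh, table=table,
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, dict):
        return {str(k2): _jsonable(v) for k2, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "__dataclass_fields__"):
        return {k2: _jsonable(getattr(obj, k2)) for k2 in obj.__dataclass_fields__}
    return obj


@dataclass
class SurfingReport:
    config: dict
    config_hash: str
    seed: int | None
    version: str
    stages: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = _jsonable(
            dict(config=self.config, config_hash=self.config_hash,
                 seed=self.seed, version=self.version, stages=self.stages)
        )
        return json.dumps(payload, sort_keys=True, indent=1, allow_nan=False, default=str)


def run_surfing_pipeline(
    gt: GenotypeTable,
    meta: SiteTable,
    route: list[str],
    seed: int | None = None,
    rare_thresh: float = 0.05,
    common_thresh: float = 0.25,
    alpha: float = 0.05,
    g: int = 14,
    fst: FstMatrix | None = None,
    mantel_reps: int = 0,
) -> SurfingReport:
    """Run every expansion/surfing stage and return a provenance-stamped report.

    Deterministic given inputs and seed.  Stage failures propagate with
    the stage name prepended.
    """
    from volesurf import __version__

    config = dict(
        route=list(route), rare_thresh=rare_thresh, common_thresh=common_thresh,
        alpha=alpha, g=g, seed=seed, mantel_reps=mantel_reps,
        n_individuals=gt.n_individuals, loci=list(gt.loci), sites=gt.sites,
    )
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    report = SurfingReport(
        config=config, config_hash=config_hash, seed=seed, version=__version__,
    )

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    meta.check_against(gt)
    if fst is None:
        fst = stage("fst", pairwise_fst, gt)
    report.stages["fst"] = dict(sites=fst.sites, matrix=fst.values)

    div = stage("diversity", diversity_summary, gt, meta, g)
    report.stages["diversity"] = dict(
        per_site=div.per_site, g=div.g,
        private_alleles={s: v for s, v in div.private_alleles.items()},
        rare_alleles={s: v for s, v in div.rare_alleles.items()},
    )

    ibd_all = stage("ibd", ibd_regression, fst, meta, None, mantel_reps, seed)
    ibd_by_cluster = {}
    for cl in route:
        if len(meta.sites_in(cl)) >= 4:
            ibd_by_cluster[cl] = stage("ibd", ibd_regression, fst, meta, cl, mantel_reps, seed)
    report.stages["ibd"] = dict(all=ibd_all, by_cluster=ibd_by_cluster)

    desigs = stage("focal", identify_focal_sites, fst, meta, route, div)
    report.stages["focal"] = desigs

    clines = []
    for d in desigs:
        try:
            cr = diversity_cline(div, fst, d.site, d.cluster, meta)
            at, excl = allele_cline_scan(
                gt, fst, d.site, d.cluster, meta, alpha=alpha
            )
            clines.append(
                dict(designation=d, diversity=cr, alleles=at,
                     allele_summary=count_significant_clines(at), exclusions=excl)
            )
        except ValidationError as exc:
            logger.warning("cline stage for %s/%s skipped: %s", d.cluster, d.site, exc)
    report.stages["clines"] = clines

    r2c = []
    for a, b in zip(route[:-1], route[1:]):
        r2c.append(
            stage("rare2common", rare_to_common_scan, gt, meta, a, b,
                  rare_thresh, common_thresh)
        )
    report.stages["rare_to_common"] = r2c
    return report
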