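"""Forward-time stepping-stone range-expansion simulator.

Demes sit on a (possibly bent) chain; colonisation proceeds along the
chain by serial founder events: once the frontier deme reaches a
fraction of its carrying capacity, the next empty deme is seeded by F
founders drawn from it.  Within demes reproduction is diploid
Wright-Fisher with logistic regulation; occupied neighbours exchange
migrants symmetrically.  Microsatellites mutate under the stepwise
model (+-1 repeat, reflecting bounds); every individual carries one
maternally inherited mtDNA sequence under finite-sites mutation.  The
generator exists so that every pipeline stage can be tested against a
known ground truth (origin deme, colonisation order, surfed alleles).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from math import cos, radians

import numpy as np

from volesurf.io import (
    GenotypeTable,
    HaplotypeData,
    SiteTable,
    write_genepop,
    write_fasta_alignment,
    write_site_metadata,
)
import pandas as pd

logger = logging.getLogger(__name__)

REPEAT_MIN, REPEAT_MAX = 5, 60
BASES = np.array([ord(c) for c in "ACGT"], dtype=np.uint8)


@dataclass
class SimConfig:
    """Demographic and mutational parameters of one simulation run.

    Defaults describe a 12-deme linear expansion with strong serial
    founder effects: carrying capacity 200 diploids per deme, founder
    groups of 8, nearest-neighbour migration 0.01 per generation, 12
    stepwise microsatellites at 5e-4 per generation, and a 500-bp
    maternal sequence at 5e-6 per site per generation.
    """

    seed: int
    n_demes: int = 12
    origin: int = 0
    K: int = 200
    growth_rate: float = 0.5
    founder_size: int = 8
    trigger_frac: float = 0.5
    m: float = 0.01
    n_loci: int = 12
    mu_ms: float = 5e-4
    mt_length: int = 500
    mu_mt: float = 5e-6
    burn_in: int = 50
    generations: int = 250
    sample_size: int | list[int] = 50
    deme_spacing_km: float = 100.0
    coords: list[tuple[float, float]] | None = None  # (lat, lon) per deme
    clusters: list[str] | None = None  # per-deme cluster label
    site_names: list[str] | None = None
    init_allele_sd: float = 2.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for rate in (self.m, self.mu_ms, self.mu_mt, self.trigger_frac):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must be in [0, 1]")
        if self.founder_size > self.K:
            raise ValueError("founder size F must not exceed K")
        if not (0 <= self.origin < self.n_demes):
            raise ValueError("origin outside deme layout")


@dataclass
class SimTruth:
    origin: int
    colonization_generation: dict[int, int]
    founder_source: dict[int, int]
    founder_size: int
    surfed_alleles: list[dict]
    initial_allele_counts: list[int]  # distinct alleles per locus at t=0
    initial_he: list[float]  # census 1 - sum(p^2) per locus at t=0

    def to_json(self) -> str:
        payload = asdict(self)
        payload["colonization_generation"] = {
            str(k): v for k, v in self.colonization_generation.items()
        }
        payload["founder_source"] = {
            str(k): v for k, v in self.founder_source.items()
        }
        return json.dumps(payload, sort_keys=True, indent=1)


class _Deme:
    __slots__ = ("ms", "mt", "sex")

    def __init__(self, ms: np.ndarray, mt: np.ndarray, sex: np.ndarray):
        self.ms = ms  # (N, L, 2) int16 repeat counts
        self.mt = mt  # (N,) int32 haplotype ids
        self.sex = sex  # (N,) bool, True = female

    @property
    def n(self) -> int:
        return self.ms.shape[0]


def _default_coords(cfg: SimConfig) -> list[tuple[float, float]]:
    lat = 45.0
    dlon = cfg.deme_spacing_km / (111.32 * cos(radians(lat)))
    return [(lat, 100.0 + i * dlon) for i in range(cfg.n_demes)]


def _reproduce(deme: _Deme, n_next: int, rng: np.random.Generator) -> _Deme | None:
    females = np.nonzero(deme.sex)[0]
    males = np.nonzero(~deme.sex)[0]
    if females.size == 0 or males.size == 0:
        return None
    mothers = females[rng.integers(0, females.size, n_next)]
    fathers = males[rng.integers(0, males.size, n_next)]
    L = deme.ms.shape[1]
    pick_m = rng.integers(0, 2, (n_next, L))
    pick_f = rng.integers(0, 2, (n_next, L))
    cols = np.arange(L)[None, :]
    ms = np.empty((n_next, L, 2), dtype=np.int16)
    ms[:, :, 0] = deme.ms[mothers[:, None], cols, pick_m]
    ms[:, :, 1] = deme.ms[fathers[:, None], cols, pick_f]
    mt = deme.mt[mothers]
    sex = rng.random(n_next) < 0.5
    return _Deme(ms, mt.copy(), sex)


def _mutate_ms(deme: _Deme, mu: float, rng: np.random.Generator) -> None:
    if mu <= 0:
        return
    hits = rng.random(deme.ms.shape) < mu
    if not hits.any():
        return
    steps = rng.choice(np.array([-1, 1], dtype=np.int16), size=int(hits.sum()))
    vals = deme.ms[hits] + steps
    # reflect at the repeat-count bounds
    vals[vals < REPEAT_MIN] = REPEAT_MIN + 1
    vals[vals > REPEAT_MAX] = REPEAT_MAX - 1
    deme.ms[hits] = vals


def _mutate_mt(
    deme: _Deme,
    mu_site: float,
    seqs: dict[int, np.ndarray],
    rng: np.random.Generator,
) -> None:
    """Finite-sites mutation; at most one new mutation per individual per
    generation (multiple same-generation hits are vanishingly rare at
    realistic rates)."""
    if mu_site <= 0:
        return
    L = len(next(iter(seqs.values())))
    p_any = 1.0 - (1.0 - mu_site) ** L
    hits = np.nonzero(rng.random(deme.n) < p_any)[0]
    for i in hits:
        parent = seqs[int(deme.mt[i])]
        child = parent.copy()
        pos = int(rng.integers(0, L))
        alts = BASES[BASES != child[pos]]
        child[pos] = alts[int(rng.integers(0, 3))]
        new_id = len(seqs)
        seqs[new_id] = child
        deme.mt[i] = new_id


def simulate_expansion(
    cfg: SimConfig,
) -> tuple[GenotypeTable, HaplotypeData, SiteTable, SimTruth]:
    """Run the expansion and sample each deme at the end of the run.

    Returns the sampled microsatellite table, the sampled mtDNA
    haplotype data, site metadata with coordinates/cluster labels, and
    the ground truth (origin, colonisation generations, founder
    sources, surfed alleles).
    """
    rng = np.random.default_rng(cfg.seed)
    coords = cfg.coords if cfg.coords is not None else _default_coords(cfg)
    if len(coords) != cfg.n_demes:
        raise ValueError("coords length must equal n_demes")
    clusters = cfg.clusters if cfg.clusters is not None else ["all"] * cfg.n_demes
    names = cfg.site_names if cfg.site_names is not None else [
        f"s{i:02d}" for i in range(cfg.n_demes)
    ]

    # expansion fronts: one chain towards each end of the deme line
    fronts = [list(range(cfg.origin, cfg.n_demes))]
    if cfg.origin > 0:
        fronts.append(list(range(cfg.origin, -1, -1)))
    neighbour_pairs = [(i, i + 1) for i in range(cfg.n_demes - 1)]

    # founding pool: rich microsatellite variation around 20 repeats and
    # two divergent mtDNA matrilines (the "two dominant haplotypes"
    # pattern of intraspecific control-region data)
    init_ms = np.clip(
        np.rint(rng.normal(20.0, cfg.init_allele_sd, (cfg.K, cfg.n_loci, 2))),
        REPEAT_MIN, REPEAT_MAX,
    ).astype(np.int16)
    root = rng.integers(0, 4, cfg.mt_length)
    seq0 = BASES[root]
    seq1 = seq0.copy()
    div_pos = rng.choice(cfg.mt_length, size=5, replace=False)
    for pos in div_pos:
        alts = BASES[BASES != seq1[pos]]
        seq1[pos] = alts[int(rng.integers(0, 3))]
    seqs: dict[int, np.ndarray] = {0: seq0, 1: seq1}
    init_mt = np.where(rng.random(cfg.K) < 0.6, 0, 1).astype(np.int32)

    demes: list[_Deme | None] = [None] * cfg.n_demes
    demes[cfg.origin] = _Deme(init_ms, init_mt, rng.random(cfg.K) < 0.5)

    init_counts, init_he = [], []
    for li in range(cfg.n_loci):
        copies = init_ms[:, li, :].ravel()
        tally = np.bincount(copies)
        p = tally[tally > 0] / copies.size
        init_counts.append(int((tally > 0).sum()))
        init_he.append(float(1.0 - np.sum(p**2)))

    colonized_at: dict[int, int] = {cfg.origin: 0}
    founder_source: dict[int, int] = {}

    total_gens = cfg.burn_in + cfg.generations
    for gen in range(1, total_gens + 1):
        # reproduction with logistic regulation
        for d in range(cfg.n_demes):
            deme = demes[d]
            if deme is None:
                continue
            n = deme.n
            n_next = int(round(n + cfg.growth_rate * n * (1.0 - n / cfg.K)))
            n_next = max(n_next, 2)
            child = _reproduce(deme, n_next, rng)
            if child is None:
                continue  # single-sex deme: adults persist this generation
            _mutate_ms(child, cfg.mu_ms, rng)
            _mutate_mt(child, cfg.mu_mt, seqs, rng)
            demes[d] = child

        # symmetric nearest-neighbour migration between occupied demes:
        # destinations are assigned against the pre-migration arrays,
        # then every deme is rebuilt in one pass
        if cfg.m > 0:
            dest: dict[int, np.ndarray] = {}
            for d in range(cfg.n_demes):
                if demes[d] is None:
                    continue
                nbs = [
                    x for x in (d - 1, d + 1)
                    if 0 <= x < cfg.n_demes and demes[x] is not None
                ]
                if not nbs:
                    continue
                u = rng.random(demes[d].n)
                assign = np.full(demes[d].n, -1, dtype=np.int64)
                lo = 0.0
                for nb in nbs:  # each occupied neighbour draws rate m
                    assign[(u >= lo) & (u < lo + cfg.m)] = nb
                    lo += cfg.m
                if (assign >= 0).any():
                    dest[d] = assign
            if dest:
                old = list(demes)
                for d in range(cfg.n_demes):
                    if old[d] is None:
                        continue
                    pieces = []
                    if d in dest:
                        keep = dest[d] == -1
                        pieces.append(
                            (old[d].ms[keep], old[d].mt[keep], old[d].sex[keep])
                        )
                    else:
                        pieces.append((old[d].ms, old[d].mt, old[d].sex))
                    for nb, assign in dest.items():
                        inc = assign == d
                        if inc.any():
                            pieces.append(
                                (old[nb].ms[inc], old[nb].mt[inc], old[nb].sex[inc])
                            )
                    demes[d] = _Deme(
                        np.concatenate([p[0] for p in pieces]),
                        np.concatenate([p[1] for p in pieces]),
                        np.concatenate([p[2] for p in pieces]),
                    )

        # colonisation: each front seeds at most one new deme per generation
        if gen > cfg.burn_in:
            for chain in fronts:
                for frontier, nxt in zip(chain[:-1], chain[1:]):
                    if demes[nxt] is not None:
                        continue
                    src = demes[frontier]
                    if (
                        src is not None
                        and src.n >= cfg.trigger_frac * cfg.K
                        and src.n > cfg.founder_size
                    ):
                        idx = rng.choice(src.n, size=cfg.founder_size, replace=False)
                        keep = np.ones(src.n, dtype=bool)
                        keep[idx] = False
                        demes[nxt] = _Deme(src.ms[idx], src.mt[idx], src.sex[idx])
                        demes[frontier] = _Deme(
                            src.ms[keep], src.mt[keep], src.sex[keep]
                        )
                        colonized_at[nxt] = gen - cfg.burn_in
                        founder_source[nxt] = frontier
                    break  # only the first empty deme on this front is a frontier

    if all(d is None or d.n == 0 for d in demes):
        raise RuntimeError(
            "all demes extinct; truth log: " + json.dumps(
                {"colonized_at": {str(k): v for k, v in colonized_at.items()}}
            )
        )

    # census allele frequencies for the surfing ground truth
    surfed: list[dict] = []
    origin_deme = demes[cfg.origin]
    for li in range(cfg.n_loci):
        org = origin_deme.ms[:, li, :].ravel()
        org_counts = np.bincount(org, minlength=REPEAT_MAX + 1)
        org_freq = org_counts / org.size
        for d in range(cfg.n_demes):
            if d == cfg.origin or demes[d] is None:
                continue
            copies = demes[d].ms[:, li, :].ravel()
            counts = np.bincount(copies, minlength=REPEAT_MAX + 1)
            freq = counts / copies.size
            hits = np.nonzero((org_freq < 0.05) & (freq >= 0.25))[0]
            for allele in hits:
                surfed.append(
                    dict(locus=f"L{li + 1:02d}", allele=int(allele), deme=d,
                         origin_freq=float(org_freq[allele]),
                         deme_freq=float(freq[allele]))
                )

    # end-of-run sampling without replacement
    sizes = (
        [cfg.sample_size] * cfg.n_demes
        if isinstance(cfg.sample_size, int)
        else list(cfg.sample_size)
    )
    individuals: list[str] = []
    site_of: dict[str, str] = {}
    calls_rows = []
    hap_counts: dict[tuple[str, str], int] = {}
    meta_rows = []
    for d in range(cfg.n_demes):
        deme = demes[d]
        if deme is None:
            continue
        want = sizes[d]
        if want > deme.n:
            logger.warning("deme %d: sample %d > deme size %d; sampling all",
                           d, want, deme.n)
            want = deme.n
        idx = rng.choice(deme.n, size=want, replace=False)
        for k2, i in enumerate(idx):
            ind = f"{names[d]}_{k2 + 1:03d}"
            individuals.append(ind)
            site_of[ind] = names[d]
            calls_rows.append(deme.ms[i])
            hid = f"H{int(deme.mt[i])}"
            key = (hid, names[d])
            hap_counts[key] = hap_counts.get(key, 0) + 1
        meta_rows.append(
            dict(site=names[d], lat=coords[d][0], lon=coords[d][1],
                 cluster=clusters[d], n_sampled=want)
        )

    gt = GenotypeTable(
        individuals=individuals,
        loci=[f"L{li + 1:02d}" for li in range(cfg.n_loci)],
        calls=np.array(calls_rows, dtype=np.int64),
        site_of=site_of,
    )
    # distinct mutation events can yield identical sequences (parallel
    # mutation); collapse them so haplotypes are pairwise distinct
    seq_of = {
        h: "".join(chr(b) for b in seqs[int(h[1:])])
        for h in {h for (h, _s) in hap_counts}
    }
    canon: dict[str, str] = {}
    for h in sorted(seq_of, key=lambda x: int(x[1:])):
        canon.setdefault(seq_of[h], h)
    merged: dict[tuple[str, str], int] = {}
    for (h, s), c in hap_counts.items():
        key = (canon[seq_of[h]], s)
        merged[key] = merged.get(key, 0) + c
    hd = HaplotypeData(
        haplotypes={h: s for s, h in canon.items()},
        counts=merged,
    )
    meta = SiteTable(table=pd.DataFrame(meta_rows))
    truth = SimTruth(
        origin=cfg.origin,
        colonization_generation=colonized_at,
        founder_source=founder_source,
        founder_size=cfg.founder_size,
        surfed_alleles=surfed,
        initial_allele_counts=init_counts,
        initial_he=init_he,
    )
    return gt, hd, meta, truth


# ---------------------------------------------------------------------------
# Fixture profiles
# ---------------------------------------------------------------------------


def _paper_like_config(seed: int) -> SimConfig:
    """23 demes in 3 clusters on a bent SE -> NE -> W route with
    site sample sizes between 15 and 60."""
    n = 23
    cl = ["SE"] * 9 + ["NE"] * 5 + ["W"] * 9
    coords = []
    lat, lon = 43.0, 116.0
    for i in range(n):
        if i < 9:  # SE leg, heading north-east
            coords.append((lat + 0.5 * i, lon + 0.9 * i))
        elif i < 14:  # NE leg, heading north
            j = i - 9
            coords.append((47.5 + 0.8 * j, 124.0 + 0.2 * j))
        else:  # W leg, heading west
            j = i - 14
            coords.append((48.0 + 0.2 * j, 122.0 - 1.6 * j))
    rng = np.random.default_rng(seed + 1)
    sizes = [int(x) for x in rng.integers(15, 61, n)]
    # gentler founder events and more migration than the compact default:
    # at 23 demes they keep per-site diversity in the empirically typical
    # range for colonial rodents (He ~0.5-0.7, ~4-8 alleles per site)
    return SimConfig(
        seed=seed, n_demes=n, origin=0, coords=coords, clusters=cl,
        sample_size=sizes, generations=400, founder_size=40, m=0.05,
        init_allele_sd=3.0,
        site_names=[f"{cl[i]}{i:02d}" for i in range(n)],
    )


PROFILES = {
    "tiny": lambda seed: SimConfig(
        seed=seed, n_demes=4, K=30, founder_size=4, sample_size=8,
        burn_in=10, generations=60, n_loci=4, mt_length=200,
    ),
    "paper-like": _paper_like_config,
    "surf-heavy": lambda seed: SimConfig(
        seed=seed, founder_size=4, m=0.005, generations=300,
    ),
}

_PROFILE_SEEDS = {"tiny": 20201, "paper-like": 20202, "surf-heavy": 20203}


def make_fixture(profile: str, out_dir, seed: int | None = None):
    """Write a deterministic simulated dataset for a named profile.

    Outputs GenePop, FASTA + count sidecar, metadata TSV and a truth
    JSON under ``out_dir``.  Each profile has a fixed embedded seed so
    regeneration is byte-identical; pass ``seed`` to override.
    """
    from pathlib import Path

    if profile not in PROFILES:
        raise ValueError(
            f"unknown profile {profile!r}; available: {sorted(PROFILES)}"
        )
    used_seed = seed if seed is not None else _PROFILE_SEEDS[profile]
    cfg = PROFILES[profile](used_seed)
    gt, hd, meta, truth = simulate_expansion(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_genepop(gt, out / "genotypes.gen")
    write_fasta_alignment(hd, out / "dloop.fasta", out / "hap_counts.tsv")
    write_site_metadata(meta, out / "sites.tsv")
    (out / "truth.json").write_text(truth.to_json())
    return gt, hd, meta, truth
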