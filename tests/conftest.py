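"""Shared fixtures: small genotype tables and simulated datasets.

All fixtures are generated programmatically with fixed seeds; the
heavier simulated dataset is session-scoped so the expansion runs once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from volesurf.io import GenotypeTable, SiteTable, HaplotypeData
from volesurf.simulate import SimConfig, simulate_expansion


def random_genotype_table(
    rng: np.random.Generator,
    n_sites: int = 2,
    n_per_site: int = 4,
    n_loci: int = 2,
    n_alleles: int = 4,
    missing_rate: float = 0.0,
) -> GenotypeTable:
    sites = [f"p{i}" for i in range(n_sites)]
    individuals, site_of, calls = [], {}, []
    for s in sites:
        for k in range(n_per_site):
            ind = f"{s}_{k}"
            individuals.append(ind)
            site_of[ind] = s
            row = rng.integers(1, n_alleles + 1, (n_loci, 2))
            if missing_rate > 0:
                drop = rng.random(n_loci) < missing_rate
                row[drop] = 0
            calls.append(row)
    return GenotypeTable(
        individuals=individuals,
        loci=[f"L{j}" for j in range(n_loci)],
        calls=np.array(calls, dtype=np.int64),
        site_of=site_of,
    )


def hapdata_from_counts(seq_counts: dict[str, dict[str, int]]) -> HaplotypeData:
    """Build HaplotypeData from {sequence: {site: count}}."""
    haps = {f"h{i}": s for i, s in enumerate(seq_counts)}
    rev = {s: h for h, s in haps.items()}
    counts = {
        (rev[s], site): c
        for s, site_counts in seq_counts.items()
        for site, c in site_counts.items()
    }
    return HaplotypeData(haplotypes=haps, counts=counts)


def msprime_hapdata(ts) -> HaplotypeData:
    """Collapse a binary msprime tree sequence into HaplotypeData."""
    n = ts.num_samples
    G = ts.genotype_matrix()
    cols = [np.where(row > 0, "T", "A") for row in G]
    seqs = ["".join(c[i] for c in cols) for i in range(n)] if cols else ["A"] * n
    uniq: dict[str, str] = {}
    counts: dict[tuple[str, str], int] = {}
    for s in seqs:
        hid = uniq.setdefault(s, f"h{len(uniq)}")
        counts[(hid, "all")] = counts.get((hid, "all"), 0) + 1
    return HaplotypeData(
        haplotypes={h: s for s, h in uniq.items()}, counts=counts
    )


CLUSTERS_12 = ["SE"] * 4 + ["NE"] * 4 + ["W"] * 4


@pytest.fixture(scope="session")
def expansion_dataset():
    """One default-parameter expansion with a mid-source origin deme.

    Origin deme 3 sits at the edge of the source cluster facing the
    expansion corridor, matching the study design where the inferred
    starting site borders the colonised range.
    """
    cfg = SimConfig(seed=90210, origin=3, clusters=CLUSTERS_12)
    return simulate_expansion(cfg)


@pytest.fixture(scope="session")
def expansion_fst(expansion_dataset):
    from volesurf.msat import pairwise_fst

    gt, _hd, _meta, _truth = expansion_dataset
    return pairwise_fst(gt)


@pytest.fixture()
def toy_meta():
    return SiteTable(
        pd.DataFrame(
            dict(
                site=["a", "b", "c", "d", "e", "f"],
                lat=[40.0, 40.5, 41.0, 41.5, 42.0, 42.5],
                lon=[100.0, 101.0, 102.0, 103.0, 104.0, 105.0],
                cluster=["X", "X", "X", "Y", "Y", "Y"],
            )
        )
    )
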