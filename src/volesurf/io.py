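"""File formats and validated in-memory containers.

Microsatellite genotypes travel as GenePop files (the de-facto
interchange format for this marker type), mtDNA alignments as FASTA with
an optional per-site haplotype-count sidecar TSV, and site metadata
(coordinates, cluster labels) as TSV.  Parsers validate on read and
raise rather than silently repairing structural problems.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

MISSING = 0  # allele label encoding a missing gene copy

SEQ_ALPHABET = set("ACGT-N")


class ParseError(ValueError):
    """A file could not be parsed as its declared format."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeTable:
    """Diploid microsatellite calls for individuals grouped into sites.

    ``calls`` has shape ``(n_individuals, n_loci, 2)``; allele labels are
    positive integers (fragment sizes or repeat counts) and a wholly
    missing call is ``(0, 0)``.  Half-calls are not representable: any
    zero in a call marks the whole call missing.
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray
    site_of: dict[str, str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, L = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValidationError(
                f"calls shape {self.calls.shape} != ({n}, {L}, 2)"
            )
        if len(set(self.individuals)) != n:
            raise ValidationError("duplicate individual ids")
        if set(self.site_of) != set(self.individuals):
            raise ValidationError("site_of must map every individual to one site")
        if np.any(self.calls < 0):
            raise ValidationError("allele labels must be non-negative integers")
        # enforce the all-or-nothing missing convention
        half = (self.calls == MISSING).sum(axis=2) == 1
        if np.any(half):
            raise ValidationError("half-missing calls are not allowed")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def sites(self) -> list[str]:
        """Site ids in order of first appearance."""
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(self.site_of[ind], None)
        return list(seen)

    def site_indices(self, site: str) -> np.ndarray:
        return np.array(
            [i for i, ind in enumerate(self.individuals) if self.site_of[ind] == site],
            dtype=np.intp,
        )

    def subset_sites(self, sites: list[str]) -> "GenotypeTable":
        keep = [i for i, ind in enumerate(self.individuals) if self.site_of[ind] in set(sites)]
        inds = [self.individuals[i] for i in keep]
        return GenotypeTable(
            individuals=inds,
            loci=list(self.loci),
            calls=self.calls[keep],
            site_of={ind: self.site_of[ind] for ind in inds},
        )

    def equals(self, other: "GenotypeTable") -> bool:
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and self.site_of == other.site_of
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class SiteTable:
    """Per-site coordinates (decimal degrees, WGS84) and cluster label."""

    table: pd.DataFrame  # columns: site, lat, lon, cluster [, n_sampled]

    def __post_init__(self) -> None:
        required = {"site", "lat", "lon", "cluster"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"site metadata missing columns: {sorted(missing)}")
        if self.table["site"].duplicated().any():
            dups = self.table.loc[self.table["site"].duplicated(), "site"].tolist()
            raise ValidationError(f"duplicate site ids: {dups}")
        if not np.isfinite(self.table[["lat", "lon"]].to_numpy(dtype=float)).all():
            raise ValidationError("missing or non-finite coordinates")
        if (self.table["lat"].abs() > 90).any():
            raise ValidationError("latitude out of [-90, 90]")
        if (self.table["lon"].abs() > 180).any():
            raise ValidationError("longitude out of [-180, 180]")
        self.table = self.table.reset_index(drop=True)

    @property
    def sites(self) -> list[str]:
        return self.table["site"].tolist()

    @property
    def clusters(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.table["cluster"]:
            seen.setdefault(c, None)
        return list(seen)

    def sites_in(self, cluster: str) -> list[str]:
        return self.table.loc[self.table["cluster"] == cluster, "site"].tolist()

    def cluster_of(self, site: str) -> str:
        row = self.table.loc[self.table["site"] == site]
        if row.empty:
            raise ValidationError(f"unknown site {site!r}")
        return row["cluster"].iloc[0]

    def coords(self, site: str) -> tuple[float, float]:
        row = self.table.loc[self.table["site"] == site]
        if row.empty:
            raise ValidationError(f"unknown site {site!r}")
        return float(row["lat"].iloc[0]), float(row["lon"].iloc[0])

    def check_against(self, gt: GenotypeTable) -> None:
        """Cross-validate: every genotype site must appear in the metadata."""
        unknown = set(gt.sites) - set(self.sites)
        if unknown:
            raise ValidationError(
                f"genotype sites missing from metadata: {sorted(unknown)}"
            )


@dataclass
class HaplotypeData:
    """Aligned haplotype sequences with per-site occurrence counts.

    The data model stores (haplotype, site) counts rather than
    per-individual assignments, matching how mtDNA haplotype tables are
    published.  ``hap_group`` optionally assigns haplotypes to
    haplogroups (clades taken as an input, never inferred here).
    """

    haplotypes: dict[str, str]
    counts: dict[tuple[str, str], int]
    hap_group: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.haplotypes:
            raise ValidationError("no haplotypes")
        lengths = {len(s) for s in self.haplotypes.values()}
        if len(lengths) != 1:
            raise ValidationError(f"unequal aligned sequence lengths: {sorted(lengths)}")
        for hid, seq in self.haplotypes.items():
            bad = set(seq.upper()) - SEQ_ALPHABET
            if bad:
                raise ValidationError(f"haplotype {hid}: illegal characters {sorted(bad)}")
        seqs = list(self.haplotypes.values())
        if len(set(seqs)) != len(seqs):
            raise ValidationError("haplotype sequences must be pairwise distinct")
        for (hid, _site), c in self.counts.items():
            if hid not in self.haplotypes:
                raise ValidationError(f"count refers to unknown haplotype {hid!r}")
            if not (isinstance(c, (int, np.integer)) and c >= 0):
                raise ValidationError(f"negative or non-integer count for {hid!r}")
        if self.hap_group is not None:
            unknown = set(self.hap_group) - set(self.haplotypes)
            if unknown:
                raise ValidationError(f"hap_group refers to unknown haplotypes {sorted(unknown)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.haplotypes.values())))

    @property
    def total_n(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def sites(self) -> list[str]:
        seen: dict[str, None] = {}
        for (_h, s) in self.counts:
            seen.setdefault(s, None)
        return list(seen)

    def hap_totals(self) -> dict[str, int]:
        out: dict[str, int] = {h: 0 for h in self.haplotypes}
        for (h, _s), c in self.counts.items():
            out[h] += c
        return out

    def subset(
        self,
        haplotypes: list[str] | None = None,
        sites: list[str] | None = None,
        group: str | None = None,
    ) -> "HaplotypeData":
        """Restrict to chosen haplotypes, sites, or a haplogroup."""
        keep_h = set(self.haplotypes)
        if haplotypes is not None:
            keep_h &= set(haplotypes)
        if group is not None:
            if self.hap_group is None:
                raise ValidationError("no haplogroup map available")
            keep_h &= {h for h, g in self.hap_group.items() if g == group}
        counts = {
            (h, s): c
            for (h, s), c in self.counts.items()
            if h in keep_h and (sites is None or s in set(sites)) and c > 0
        }
        used = {h for (h, _s) in counts}
        if not used:
            raise ValidationError("subset selects no sequences")
        return HaplotypeData(
            haplotypes={h: self.haplotypes[h] for h in self.haplotypes if h in used},
            counts=counts,
            hap_group={h: g for h, g in (self.hap_group or {}).items() if h in used} or None,
        )


@dataclass
class FstMatrix:
    """Symmetric matrix of pairwise Weir-Cockerham theta between sites."""

    sites: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.sites)
        if self.values.shape != (k, k):
            raise ValidationError("F_ST matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValidationError("F_ST matrix must be symmetric")
        if not np.all(np.diag(self.values) == 0.0):
            raise ValidationError("F_ST diagonal must be exactly 0")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.sites.index(a), self.sites.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sites, columns=self.sites)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "FstMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(sites=[str(s) for s in df.index], values=df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def read_genepop(path, site_names: list[str] | None = None) -> GenotypeTable:
    """Parse a GenePop file into a :class:`GenotypeTable`.

    Both 2- and 3-digit allele encodings are accepted; the digit width
    is auto-detected from genotype token lengths (4 -> 2-digit,
    6 -> 3-digit) and must be consistent within the file.  A call
    containing a 0-encoded allele is wholly missing.  Site ids are taken
    from the last individual label of each POP block, unless
    ``site_names`` overrides them in POP-block order.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not any(line.strip() for line in lines):
        raise ParseError(f"{path}: empty file")
    if len(lines) < 3:
        raise ParseError(f"{path}: too short to be GenePop (title, loci, Pop)")

    # title line is free text; locus names follow, one per line or
    # comma-separated on a single line, until the first "Pop".
    loci: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i]):
        chunk = lines[i].strip()
        if chunk:
            if "," in chunk:
                loci.extend(tok.strip() for tok in chunk.split(",") if tok.strip())
            else:
                loci.append(chunk)
        i += 1
    if not loci:
        raise ParseError(f"{path}: no locus names before first Pop (line {i + 1})")
    if i == len(lines):
        raise ParseError(f"{path}: no Pop blocks")

    individuals: list[str] = []
    site_of: dict[str, str] = {}
    rows: list[list[tuple[int, int]]] = []
    block_members: list[list[str]] = []
    digit_width: int | None = None

    def parse_geno(tok: str, lineno: int) -> tuple[int, int]:
        nonlocal digit_width
        if len(tok) not in (4, 6) or not tok.isdigit():
            raise ParseError(f"{path}:{lineno}: bad genotype token {tok!r}")
        w = len(tok) // 2
        if digit_width is None:
            digit_width = w
        elif w != digit_width:
            raise ParseError(
                f"{path}:{lineno}: mixed {2 * digit_width}- and {len(tok)}-digit genotypes"
            )
        a, b = int(tok[:w]), int(tok[w:])
        if a == 0 or b == 0:
            return (MISSING, MISSING)
        return (a, b)

    current: list[str] | None = None
    for lineno0, line in enumerate(lines[i:], start=i):
        if _POP_RE.match(line):
            current = []
            block_members.append(current)
            continue
        if not line.strip():
            continue
        if current is None:
            raise ParseError(f"{path}:{lineno0 + 1}: sample row before any Pop")
        if "," not in line:
            raise ParseError(f"{path}:{lineno0 + 1}: missing ',' between label and genotypes")
        label, geno_part = line.split(",", 1)
        label = label.strip()
        toks = geno_part.split()
        if len(toks) != len(loci):
            raise ParseError(
                f"{path}:{lineno0 + 1}: {len(toks)} genotypes for {len(loci)} loci"
            )
        if label in site_of:
            raise ValidationError(f"{path}:{lineno0 + 1}: duplicated individual id {label!r}")
        individuals.append(label)
        site_of[label] = ""  # site filled once the block's trailing label is known
        current.append(label)
        rows.append([parse_geno(t, lineno0 + 1) for t in toks])

    if site_names is not None and len(site_names) != len(block_members):
        raise ValidationError(
            f"{len(site_names)} site names given for {len(block_members)} Pop blocks"
        )
    for bi, members in enumerate(block_members):
        if not members:
            raise ParseError(f"{path}: empty Pop block #{bi + 1}")
        site = site_names[bi] if site_names is not None else members[-1].split("_")[0]
        for ind in members:
            site_of[ind] = site

    calls = np.array(rows, dtype=np.int64)
    return GenotypeTable(individuals=individuals, loci=loci, calls=calls, site_of=site_of)


def write_genepop(gt: GenotypeTable, path, title: str = "volesurf export", digits: int = 3) -> None:
    """Write a GenePop file, one POP block per site, ``digits``-wide alleles.

    Individual labels are written as ``<site>_<k>`` so that site ids
    round-trip through :func:`read_genepop` without a side channel.
    """
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    maxa = int(gt.calls.max(initial=0))
    if maxa >= 10**digits:
        raise ValidationError(f"allele label {maxa} does not fit {digits} digits")
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in gt.loci:
            fh.write(locus + "\n")
        for site in gt.sites:
            fh.write("Pop\n")
            for i in gt.site_indices(site):
                toks = [
                    f"{a:0{digits}d}{b:0{digits}d}" for a, b in gt.calls[i]
                ]
                fh.write(f"{gt.individuals[i]} , " + " ".join(toks) + "\n")


# ---------------------------------------------------------------------------
# FASTA alignment + haplotype counts
# ---------------------------------------------------------------------------


def _site_from_description(desc: str) -> str:
    m = re.search(r"site=(\S+)", desc)
    if m:
        return m.group(1)
    toks = desc.split()
    if len(toks) >= 2:
        return toks[1]
    return "all"


def read_fasta_alignment(path, counts_path=None) -> HaplotypeData:
    """Read an aligned FASTA, collapsing identical sequences to haplotypes.

    Without a sidecar, each record contributes count 1 at the site
    parsed from its header (a ``site=NAME`` token, else the second
    whitespace-separated field, else ``"all"``).  With a sidecar TSV
    (columns ``haplotype, site, count``), record ids must match the
    sidecar's haplotype ids.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: empty or not FASTA")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValidationError(f"{path}: unequal sequence lengths {sorted(lengths)}")

    seq_to_hap: dict[str, str] = {}
    haplotypes: dict[str, str] = {}
    rec_hap: dict[str, str] = {}
    for rec in records:
        seq = str(rec.seq).upper()
        if seq not in seq_to_hap:
            seq_to_hap[seq] = rec.id
            haplotypes[rec.id] = seq
        rec_hap[rec.id] = seq_to_hap[seq]

    counts: dict[tuple[str, str], int] = {}
    if counts_path is not None:
        df = pd.read_csv(counts_path, sep="\t")
        need = {"haplotype", "site", "count"}
        if not need.issubset(df.columns):
            raise ParseError(f"{counts_path}: expected columns {sorted(need)}")
        for _, row in df.iterrows():
            hid = str(row["haplotype"])
            if hid not in rec_hap:
                raise ValidationError(f"{counts_path}: unknown haplotype id {hid!r}")
            key = (rec_hap[hid], str(row["site"]))
            counts[key] = counts.get(key, 0) + int(row["count"])
    else:
        for rec in records:
            site = _site_from_description(rec.description)
            key = (rec_hap[rec.id], site)
            counts[key] = counts.get(key, 0) + 1
    return HaplotypeData(haplotypes=haplotypes, counts=counts)


def write_fasta_alignment(hd: HaplotypeData, fasta_path, counts_path=None) -> None:
    records = [
        SeqRecord(Seq(seq), id=hid, description="")
        for hid, seq in hd.haplotypes.items()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    if counts_path is not None:
        rows = [
            {"haplotype": h, "site": s, "count": c}
            for (h, s), c in sorted(hd.counts.items())
        ]
        pd.DataFrame(rows, columns=["haplotype", "site", "count"]).to_csv(
            counts_path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# Site metadata
# ---------------------------------------------------------------------------


def read_site_metadata(path) -> SiteTable:
    """Read a TSV with columns ``site, lat, lon, cluster`` (extras ignored)."""
    df = pd.read_csv(path, sep="\t")
    need = {"site", "lat", "lon", "cluster"}
    missing = need - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    extra = set(df.columns) - need - {"n_sampled"}
    if extra:
        logger.warning("%s: ignoring unknown columns %s", path, sorted(extra))
    keep = [c for c in ("site", "lat", "lon", "cluster", "n_sampled") if c in df.columns]
    df = df[keep].copy()
    df["site"] = df["site"].astype(str)
    df["cluster"] = df["cluster"].astype(str)
    return SiteTable(table=df)


def write_site_metadata(meta: SiteTable, path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)
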