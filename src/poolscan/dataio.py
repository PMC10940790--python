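"""Readers, writers and in-memory containers for pool-seq data.

Conventions shared by the whole package:

* coordinates are 1-based inclusive (:mod:`poolscan.intervals`); BED input
  (0-based half-open) is converted on read;
* the alt allele as recorded in the VCF is the tracked allele in all count
  matrices — polarisation to the minor allele is an explicit downstream
  operation (:func:`poolscan.poolfreq.polarize_minor`), never done at parse
  time;
* count arrays are laid out SNPs x pools, sorted by (chrom, pos), biallelic
  SNPs only.

The count-TSV dialect is one row per SNP: ``chrom  pos  ref  alt`` followed
by one ``ref:alt`` integer pair per pool, tab-separated, ``.`` for missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

SEASONS = ("spring", "fall", "summer", "mixed")

#: Pool-id suffix convention for seasons (e.g. ``SPH-S`` is a spring pool).
SEASON_SUFFIX = {"S": "spring", "F": "fall", "U": "summer", "M": "mixed"}


@dataclass(frozen=True)
class PoolSample:
    """One sequenced pool of diploid individuals from a spawning site."""

    id: str
    latitude: float
    longitude: float
    season: str
    n_individuals: int

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValueError(
                f"pool {self.id}: season {self.season!r} not in {SEASONS}"
            )
        if self.n_individuals <= 0:
            raise ValueError(f"pool {self.id}: n_individuals must be positive")
        suffix = self.id.rsplit("-", 1)[-1] if "-" in self.id else None
        if suffix in SEASON_SUFFIX and SEASON_SUFFIX[suffix] != self.season:
            raise ValueError(
                f"pool {self.id}: suffix -{suffix} contradicts season "
                f"{self.season!r}"
            )

    @property
    def n_chromosomes(self) -> int:
        """Haploid sample size n = 2 x diploid individuals."""
        return 2 * self.n_individuals


def _check_snps(snps: pd.DataFrame) -> pd.DataFrame:
    required = ["chrom", "pos", "ref", "alt"]
    missing = [c for c in required if c not in snps.columns]
    if missing:
        raise ValueError(f"snp table lacks columns {missing}")
    key = snps[["chrom", "pos"]]
    if not key.equals(key.sort_values(["chrom", "pos"])):
        raise ValueError("SNPs must be sorted by (chrom, pos)")
    return snps.reset_index(drop=True)


@dataclass
class PoolCountMatrix:
    """Per-SNP, per-pool ref/alt read counts — the raw substrate.

    Attributes
    ----------
    snps : DataFrame with columns chrom, pos, ref, alt (sorted).
    ref, alt : int arrays of shape (n_snps, n_pools).
    pools : the :class:`PoolSample` for each column.
    missing : bool mask of shape (n_snps, n_pools); masked cells carry no
        usable counts (filters may mask cells after parsing).
    """

    snps: pd.DataFrame
    ref: np.ndarray
    alt: np.ndarray
    pools: list[PoolSample]
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.snps = _check_snps(self.snps)
        self.ref = np.asarray(self.ref)
        self.alt = np.asarray(self.alt)
        if self.ref.shape != self.alt.shape:
            raise ValueError("ref/alt shape mismatch")
        if self.ref.shape != (len(self.snps), len(self.pools)):
            raise ValueError(
                f"count shape {self.ref.shape} != "
                f"({len(self.snps)}, {len(self.pools)})"
            )
        if (self.ref < 0).any() or (self.alt < 0).any():
            raise ValueError("negative read counts")
        if self.missing is None:
            self.missing = np.zeros(self.ref.shape, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool) | (
            self.coverage == 0
        )

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    @property
    def pool_ids(self) -> list[str]:
        return [p.id for p in self.pools]

    @property
    def coverage(self) -> np.ndarray:
        return self.ref + self.alt

    @property
    def n_chromosomes(self) -> np.ndarray:
        """Haploid pool sizes, one per pool column."""
        return np.array([p.n_chromosomes for p in self.pools])

    def take_snps(self, index) -> "PoolCountMatrix":
        index = np.asarray(index)
        return PoolCountMatrix(
            snps=self.snps.iloc[index].reset_index(drop=True),
            ref=self.ref[index],
            alt=self.alt[index],
            pools=list(self.pools),
            missing=self.missing[index],
        )

    def pool_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {p: i for i, p in enumerate(self.pool_ids)}
        try:
            return np.array([lookup[i] for i in ids])
        except KeyError as e:
            raise KeyError(f"unknown pool id {e.args[0]!r}") from None

    def snps_in(self, region: GenomicInterval) -> np.ndarray:
        """Boolean mask of SNPs falling inside *region*."""
        pos = self.snps["pos"].to_numpy()
        return (self.snps["chrom"].to_numpy() == region.chrom) & (
            (region.start <= pos) & (pos <= region.end)
        )


@dataclass
class GenotypeMatrix:
    """Individual genotypes as alt-allele dosages in {0, 1, 2}, -1 missing."""

    snps: pd.DataFrame
    genotypes: np.ndarray  # (n_snps, n_individuals), int8
    individuals: list[str]

    def __post_init__(self) -> None:
        self.snps = _check_snps(self.snps)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.snps), len(self.individuals)):
            raise ValueError("genotype shape mismatch")
        bad = ~np.isin(self.genotypes, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype dosages must be in {0,1,2} or -1")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def take_snps(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            snps=self.snps.iloc[index].reset_index(drop=True),
            genotypes=self.genotypes[index],
            individuals=list(self.individuals),
        )

    def subset_region(self, region: GenomicInterval) -> "GenotypeMatrix":
        pos = self.snps["pos"].to_numpy()
        mask = (self.snps["chrom"].to_numpy() == region.chrom) & (
            (region.start <= pos) & (pos <= region.end)
        )
        return self.take_snps(np.nonzero(mask)[0])


# ---------------------------------------------------------------------------
# metadata / environment tables


def read_pool_metadata(path) -> list[PoolSample]:
    """Read a pool metadata TSV (columns id, lat, lon, season, n_individuals)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    required = {"id", "lat", "lon", "season", "n_individuals"}
    if not required.issubset(df.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicated pool ids in metadata: {dupes}")
    return [
        PoolSample(
            id=r.id,
            latitude=float(r.lat),
            longitude=float(r.lon),
            season=str(r.season),
            n_individuals=int(r.n_individuals),
        )
        for r in df.itertuples()
    ]


def read_env_table(path, pools: Sequence[PoolSample] | None = None) -> pd.DataFrame:
    """Read a per-pool environmental table (CSV or TSV, one row per pool).

    Returns a DataFrame indexed by pool id with float columns; empty cells
    become NaN (missing, never zero).  If *pools* is given the rows are
    reordered to the metadata order and every pool must be present.
    """
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    id_col = df.columns[0]
    if df[id_col].duplicated().any():
        raise ValueError("duplicated pool id in environment table")
    df = df.set_index(id_col)
    df.index = df.index.astype(str)
    df.index.name = "pool"
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as e:
            raise ValueError(f"non-numeric cell in variable {col!r}: {e}")
    if pools is not None:
        ids = [p.id for p in pools]
        absent = sorted(set(ids) - set(df.index))
        if absent:
            raise ValueError(f"environment table lacks pools {absent}")
        df = df.loc[ids]
    return df


# ---------------------------------------------------------------------------
# pool counts: VCF and count-TSV


def read_pool_counts(path, metadata) -> PoolCountMatrix:
    """Read pooled ref/alt counts from a VCF (AD format field) or count-TSV.

    *metadata* is a list of :class:`PoolSample` or a path to a metadata TSV.
    Sample columns are aligned to metadata order; an unmatched sample name
    is fatal.  Multiallelic sites and indels are dropped with a logged tally.
    """
    if not isinstance(metadata, list):
        metadata = read_pool_metadata(metadata)
    path = Path(path)
    if path.suffix in {".vcf", ".gz", ".bcf"}:
        return _read_vcf_counts(path, metadata)
    return read_counts_tsv(path, metadata)


def _read_vcf_counts(path: Path, pools: list[PoolSample]) -> PoolCountMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_pos = {s: i for i, s in enumerate(vcf.samples)}
    for p in pools:
        if p.id not in sample_pos:
            raise ValueError(
                f"pool {p.id!r} from metadata not among VCF samples "
                f"{vcf.samples}"
            )
    order = np.array([sample_pos[p.id] for p in pools])

    rows, refs, alts = [], [], []
    n_dropped = 0
    for i, v in enumerate(vcf):
        if len(v.ALT) != 1 or not v.is_snp:
            n_dropped += 1
            continue
        ad = v.format("AD")
        if ad is None:
            raise ValueError(
                f"record {v.CHROM}:{v.POS} (line ~{i + 1}) lacks the AD "
                "format field"
            )
        ad = np.asarray(ad)[order]
        if ad.shape[1] < 2:
            raise ValueError(f"malformed AD at {v.CHROM}:{v.POS}")
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        refs.append(np.where(ad[:, 0] < 0, 0, ad[:, 0]))
        alts.append(np.where(ad[:, 1] < 0, 0, ad[:, 1]))
    if n_dropped:
        logger.info("read_pool_counts: dropped %d non-biallelic-SNP records",
                    n_dropped)
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    snps = snps.sort_values(["chrom", "pos"], kind="stable")
    idx = snps.index.to_numpy()
    return PoolCountMatrix(
        snps=snps.reset_index(drop=True),
        ref=np.asarray(refs, dtype=np.int64)[idx],
        alt=np.asarray(alts, dtype=np.int64)[idx],
        pools=pools,
    )


def read_counts_tsv(path, metadata) -> PoolCountMatrix:
    """Read the count-TSV dialect written by :func:`write_counts_tsv`."""
    if not isinstance(metadata, list):
        metadata = read_pool_metadata(metadata)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    pool_cols = [c for c in df.columns if c not in ("chrom", "pos", "ref", "alt")]
    ids = [p.id for p in metadata]
    if set(pool_cols) != set(ids):
        raise ValueError(
            f"count table pools {pool_cols} do not match metadata {ids}"
        )
    n, m = len(df), len(ids)
    ref = np.zeros((n, m), dtype=np.int64)
    alt = np.zeros((n, m), dtype=np.int64)
    missing = np.zeros((n, m), dtype=bool)
    for j, pid in enumerate(ids):
        col = df[pid].astype(str).to_numpy()
        for i, cell in enumerate(col):
            if cell == ".":
                missing[i, j] = True
                continue
            try:
                r, a = cell.split(":")
                ref[i, j], alt[i, j] = int(r), int(a)
            except ValueError:
                raise ValueError(
                    f"malformed count cell {cell!r} at line {i + 2}, "
                    f"pool {pid}"
                ) from None
    snps = df[["chrom", "pos", "ref", "alt"]]
    order = snps.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    return PoolCountMatrix(
        snps=snps.iloc[order].reset_index(drop=True),
        ref=ref[order],
        alt=alt[order],
        pools=metadata,
        missing=missing[order],
    )


def write_counts_tsv(counts: PoolCountMatrix, path) -> None:
    """Write a :class:`PoolCountMatrix` in the count-TSV dialect."""
    out = counts.snps.copy()
    for j, pid in enumerate(counts.pool_ids):
        cells = np.array(
            [f"{r}:{a}" for r, a in zip(counts.ref[:, j], counts.alt[:, j])],
            dtype=object,
        )
        cells[counts.missing[:, j]] = "."
        out[pid] = cells
    out.to_csv(path, sep="\t", index=False)


def write_pool_metadata(pools: Sequence[PoolSample], path) -> None:
    pd.DataFrame(
        {
            "id": [p.id for p in pools],
            "lat": [p.latitude for p in pools],
            "lon": [p.longitude for p in pools],
            "season": [p.season for p in pools],
            "n_individuals": [p.n_individuals for p in pools],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes and regions


def read_genotypes(path) -> GenotypeMatrix:
    """Read individual genotypes from a VCF as alt dosages (biallelic SNPs)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    rows, dosages = [], []
    n_dropped = 0
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            n_dropped += 1
            continue
        gt = np.asarray(v.gt_types)  # 0=hom-ref 1=het 2=unknown 3=hom-alt
        dose = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=-1)
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        dosages.append(dose)
    if n_dropped:
        logger.info("read_genotypes: dropped %d non-biallelic-SNP records",
                    n_dropped)
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    order = snps.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    return GenotypeMatrix(
        snps=snps.iloc[order].reset_index(drop=True),
        genotypes=np.asarray(dosages, dtype=np.int8)[order],
        individuals=individuals,
    )


def read_bed(path) -> list[GenomicInterval]:
    """Read BED (0-based half-open) into 1-based inclusive intervals."""
    ivs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            ivs.append(GenomicInterval(chrom, start + 1, end))
    return ivs


def write_bed(intervals: Sequence[GenomicInterval], path) -> None:
    """Write 1-based inclusive intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\n")
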