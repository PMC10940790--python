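"""Synthetic pool-seq data with the structure of a NW Atlantic herring study.

The generator emulates a two-ecotype (spring/fall spawning) design: ~15
pools of 41-50 diploids each, median read depth in the 57-77x range, a
weakly differentiated background (island-model FST of order 0.01), a small
number of discrete divergent loci between the seasonal groups, and one
inversion-like block whose haplotype frequency follows an environmental
cline.  SNP counts are scaled down from the millions of a real dataset to
the 1e4-1e5 range.

Model
-----
* Background sites are unlinked.  Ancestral frequencies are Uniform(0.05,
  0.95) and pool frequencies follow the Balding-Nichols distribution,
  Beta(p(1-F)/F, (1-p)(1-F)/F), an island-model stand-in.
* At a divergent locus the two seasonal groups' ancestral frequencies
  differ by delta; pools then deviate around their group's ancestral
  frequency with the background F.
* At inversion-diagnostic sites the pool alt frequency tracks the pool's
  inversion-haplotype frequency f = logistic(a + b * env); shared sites are
  polymorphic within both haplotype classes.
* Read counts use two-stage sampling: the realised pool frequency is a
  binomial draw of the 2N chromosomes, and reads (depth ~ Poisson) are then
  binomial around the realised frequency — so the effective-sample-size
  correction has a real effect to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .dataio import PoolCountMatrix, GenotypeMatrix, PoolSample
from .intervals import GenomicInterval


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class DivergentLocus:
    """A planted region where seasonal groups differ by *delta* in frequency."""

    interval: GenomicInterval
    delta: float
    n_snps: int = 200

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must be in [0, 1]")


@dataclass
class InversionConfig:
    """An inversion-like block with an environmental cline.

    Haplotype B frequency in a pool is logistic(cline_a + cline_b * z)
    where z is the pool's standardised value of *env_var*.  The ratio
    n_shared / (n_shared + n_diagnostic) is the simulated gene flux.
    """

    interval: GenomicInterval
    n_diagnostic: int = 100
    n_shared: int = 0
    cline_a: float = 0.0
    cline_b: float = 2.0
    env_var: str = "sst_winter"

    @classmethod
    def from_gene_flux(
        cls, interval: GenomicInterval, n_sites: int, gene_flux: float, **kw
    ) -> "InversionConfig":
        """Build a config with a target shared fraction (gene flux)."""
        if not 0.0 <= gene_flux <= 1.0:
            raise ValueError("gene_flux must be in [0, 1]")
        n_shared = int(round(gene_flux * n_sites))
        return cls(
            interval=interval,
            n_diagnostic=n_sites - n_shared,
            n_shared=n_shared,
            **kw,
        )

    @property
    def gene_flux(self) -> float:
        total = self.n_diagnostic + self.n_shared
        return self.n_shared / total if total else 0.0


#: Study-scale defaults: 15 pools (3 spring, 10 fall, 1 summer, 1 mixed),
#: fall pools split 7 north / 3 south, as in the NW Atlantic design.
DEFAULT_SEASONS = (
    ["spring"] * 3 + ["fall"] * 10 + ["summer", "mixed"]
)
DEFAULT_REGIONS = (
    [None] * 3 + ["north"] * 7 + ["south"] * 3 + [None, None]
)


@dataclass
class SimConfig:
    """Parameters of the synthetic study design."""

    n_pools: int = 15
    n_individuals: tuple[int, int] = (41, 50)  # diploids per pool (range)
    seasons: Sequence[str] | None = None
    regions: Sequence[str | None] | None = None
    n_snps: int = 20_000
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"Chr1": 30_000_000, "Chr2": 25_000_000}
    )
    background_fst: float = 0.01
    divergent_loci: list[DivergentLocus] = field(default_factory=list)
    inversion: InversionConfig | None = None
    depth_mean: float = 67.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.background_fst < 1.0:
            raise ValueError("background_fst must be in (0, 1)")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.seasons is None:
            if self.n_pools == 15:
                self.seasons = list(DEFAULT_SEASONS)
                if self.regions is None:
                    self.regions = list(DEFAULT_REGIONS)
            else:
                half = self.n_pools // 2
                self.seasons = ["spring"] * half + ["fall"] * (
                    self.n_pools - half
                )
        if self.regions is None:
            self.regions = [None] * self.n_pools
        if len(self.seasons) != self.n_pools or len(self.regions) != self.n_pools:
            raise ValueError("seasons/regions length must equal n_pools")
        planted = [l.interval for l in self.divergent_loci]
        if self.inversion is not None:
            planted.append(self.inversion.interval)
        for iv in planted:
            if iv.chrom not in self.chrom_lengths:
                raise ValueError(f"{iv} outside chromosome layout")
            if iv.end > self.chrom_lengths[iv.chrom]:
                raise ValueError(f"{iv} extends past chromosome end")
        for i, a in enumerate(planted):
            for b in planted[i + 1:]:
                if a.overlaps(b):
                    raise ValueError(f"planted intervals overlap: {a} / {b}")

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw.get("divergent_loci"):
            raw["divergent_loci"] = [
                DivergentLocus(
                    interval=GenomicInterval(**l["interval"]),
                    delta=l["delta"],
                    n_snps=l.get("n_snps", 200),
                )
                for l in raw["divergent_loci"]
            ]
        if raw.get("inversion"):
            inv = dict(raw["inversion"])
            inv["interval"] = GenomicInterval(**inv["interval"])
            raw["inversion"] = InversionConfig(**inv)
        if raw.get("chrom_lengths"):
            raw["chrom_lengths"] = dict(raw["chrom_lengths"])
        if raw.get("n_individuals"):
            raw["n_individuals"] = tuple(raw["n_individuals"])
        return cls(**raw)


@dataclass
class SimTruth:
    """Ground truth recorded by the generator for parameter-recovery tests."""

    pool_freqs: np.ndarray          # latent per-pool frequencies (snps x pools)
    realized_freqs: np.ndarray      # after the 2N-chromosome draw
    snp_role: np.ndarray            # 'background'|'divergent<i>'|'inv_diag'|'inv_shared'
    seasons: list[str]
    regions: list[str | None]
    inversion_freq: np.ndarray | None = None   # haplotype-B freq per pool
    karyotypes: list[str] | None = None        # per individual, 'AA'|'AB'|'BB'

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pool_freqs)


_SEASON_SUFFIX = {"spring": "S", "fall": "F", "summer": "U", "mixed": "M"}


def _make_pools(cfg: SimConfig, rng: np.random.Generator) -> list[PoolSample]:
    lo, hi = cfg.n_individuals
    sizes = rng.integers(lo, hi + 1, size=cfg.n_pools)
    # latitude: a south-to-north gradient, 'south' fall pools at the low end
    lats = np.linspace(41.0, 54.0, cfg.n_pools)
    order = np.argsort(
        [
            {"south": 0, None: 1, "north": 2}.get(r, 1)
            + 0.001 * i
            for i, r in enumerate(cfg.regions)
        ]
    )
    lat_by_pool = np.empty(cfg.n_pools)
    lat_by_pool[order] = lats
    pools = []
    for i in range(cfg.n_pools):
        season = cfg.seasons[i]
        pools.append(
            PoolSample(
                id=f"P{i + 1:02d}-{_SEASON_SUFFIX[season]}",
                latitude=float(lat_by_pool[i]),
                longitude=float(-66.0 + rng.normal(0, 2)),
                season=season,
                n_individuals=int(sizes[i]),
            )
        )
    return pools


def _make_env(
    cfg: SimConfig, pools: list[PoolSample], rng: np.random.Generator
) -> pd.DataFrame:
    """Environmental table: winter SST follows latitude (a real cline);
    the other variables are location noise."""
    lat = np.array([p.latitude for p in pools])
    lat_z = (lat - lat.mean()) / lat.std(ddof=1)
    env = pd.DataFrame(
        {
            "sst_winter": 4.0 - 2.0 * lat_z + rng.normal(0, 0.4, cfg.n_pools),
            "sst_summer": 14.0 + rng.normal(0, 1.5, cfg.n_pools),
            "sst_spawn": 9.0 + rng.normal(0, 1.5, cfg.n_pools),
            "day_light_hours": 12.0 + rng.normal(0, 1.0, cfg.n_pools),
        },
        index=pd.Index([p.id for p in pools], name="pool"),
    )
    return env


def _snp_positions(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Place background SNPs uniformly (outside planted loci) and planted
    SNPs uniformly within their intervals."""
    planted = list(cfg.divergent_loci)
    inv_sites = []
    if cfg.inversion is not None:
        inv = cfg.inversion
        n_inv = inv.n_diagnostic + inv.n_shared
        pos = np.sort(
            rng.integers(inv.interval.start, inv.interval.end + 1, n_inv)
        )
        roles = np.array(["inv_diag"] * inv.n_diagnostic +
                         ["inv_shared"] * inv.n_shared, dtype=object)
        rng.shuffle(roles)
        inv_sites = [(inv.interval.chrom, p, r) for p, r in zip(pos, roles)]

    rows = []
    total_len = sum(cfg.chrom_lengths.values())
    for chrom, L in cfg.chrom_lengths.items():
        n_bg = int(round(cfg.n_snps * L / total_len))
        pos = rng.integers(1, L + 1, n_bg)
        keep = np.ones(len(pos), dtype=bool)
        for iv in [l.interval for l in planted] + (
            [cfg.inversion.interval] if cfg.inversion else []
        ):
            if iv.chrom == chrom:
                keep &= ~((pos >= iv.start) & (pos <= iv.end))
        rows += [(chrom, int(p), "background") for p in pos[keep]]
    for i, locus in enumerate(planted):
        pos = rng.integers(locus.interval.start, locus.interval.end + 1,
                           locus.n_snps)
        rows += [(locus.interval.chrom, int(p), f"divergent{i}") for p in pos]
    rows += [(c, int(p), r) for c, p, r in inv_sites]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "role"])
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return df


def _balding_nichols(
    p: np.ndarray, fst: float, size: tuple, rng: np.random.Generator
) -> np.ndarray:
    shape = (1.0 - fst) / fst
    a = np.clip(p * shape, 1e-6, None)
    b = np.clip((1.0 - p) * shape, 1e-6, None)
    return rng.beta(
        np.broadcast_to(a[:, None], size), np.broadcast_to(b[:, None], size)
    )


def simulate_pool_dataset(
    cfg: SimConfig,
) -> tuple[PoolCountMatrix, pd.DataFrame, SimTruth]:
    """Generate pooled read counts, an environmental table and the truth."""
    rng = np.random.default_rng(cfg.seed)
    pools = _make_pools(cfg, rng)
    env = _make_env(cfg, pools, rng)
    sites = _snp_positions(cfg, rng)
    n_snps, n_pools = len(sites), cfg.n_pools
    seasons = np.array(cfg.seasons, dtype=object)

    # latent pool frequencies
    p_anc = rng.uniform(0.05, 0.95, n_snps)
    pool_p = _balding_nichols(p_anc, cfg.background_fst, (n_snps, n_pools), rng)

    role = sites["role"].to_numpy()
    for i, locus in enumerate(cfg.divergent_loci):
        mask = role == f"divergent{i}"
        m = int(mask.sum())
        centre = rng.uniform(locus.delta / 2, 1 - locus.delta / 2, m)
        spring_p = centre - locus.delta / 2
        fall_p = centre + locus.delta / 2
        anc = np.where(
            seasons[None, :] == "spring", spring_p[:, None],
            np.where(seasons[None, :] == "fall", fall_p[:, None],
                     centre[:, None]),
        )
        shape = (1.0 - cfg.background_fst) / cfg.background_fst
        pool_p[mask] = rng.beta(
            np.clip(anc * shape, 1e-6, None),
            np.clip((1 - anc) * shape, 1e-6, None),
        )

    inv_freq = None
    if cfg.inversion is not None:
        inv = cfg.inversion
        z = env[inv.env_var].to_numpy()
        z = (z - z.mean()) / z.std(ddof=1)
        inv_freq = _logistic(inv.cline_a + inv.cline_b * z)
        q_a = rng.uniform(0.0, 0.05, n_snps)    # haplotype-A allele freq
        q_b = rng.uniform(0.95, 1.0, n_snps)
        diag = role == "inv_diag"
        pool_p[diag] = (1 - inv_freq)[None, :] * q_a[diag, None] + \
            inv_freq[None, :] * q_b[diag, None]
        shared = role == "inv_shared"
        qs_a = rng.uniform(0.25, 0.75, n_snps)
        qs_b = rng.uniform(0.25, 0.75, n_snps)
        pool_p[shared] = (1 - inv_freq)[None, :] * qs_a[shared, None] + \
            inv_freq[None, :] * qs_b[shared, None]

    # two-stage read sampling
    two_n = np.array([p.n_chromosomes for p in pools])
    allele_counts = rng.binomial(two_n[None, :], pool_p)
    realized = allele_counts / two_n[None, :]
    depth = rng.poisson(cfg.depth_mean, (n_snps, n_pools))
    alt = rng.binomial(depth, realized)
    ref = depth - alt

    snps = sites[["chrom", "pos"]].copy()
    snps["ref"] = "A"
    snps["alt"] = "C"
    counts = PoolCountMatrix(
        snps=snps, ref=ref, alt=alt, pools=pools
    )
    truth = SimTruth(
        pool_freqs=pool_p,
        realized_freqs=realized,
        snp_role=role,
        seasons=list(cfg.seasons),
        regions=list(cfg.regions),
        inversion_freq=inv_freq,
    )
    return counts, env, truth


def simulate_individual_genotypes(
    cfg: SimConfig,
    n_individuals: int,
    n_flanking: int = 200,
    flank_bp: int = 1_000_000,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate diploid genotypes around the configured inversion.

    Each individual draws two haplotypes (A/B) with its pool's haplotype-B
    frequency; diagnostic sites are near-fixed differences between the
    classes, shared sites are polymorphic within both.  *n_flanking*
    unlinked background SNPs are added on each side up to *flank_bp* away
    for LD contrast.
    """
    if cfg.inversion is None:
        raise ValueError("no inversion configured")
    inv = cfg.inversion
    if inv.n_diagnostic == 0:
        raise ValueError("n_diagnostic must be > 0 (karyotyping undefined)")
    rng = np.random.default_rng(cfg.seed + 1)
    pools = _make_pools(cfg, rng)
    env = _make_env(cfg, pools, rng)
    z = env[inv.env_var].to_numpy()
    z = (z - z.mean()) / z.std(ddof=1)
    inv_freq = _logistic(inv.cline_a + inv.cline_b * z)

    pool_of = np.arange(n_individuals) % cfg.n_pools
    f = inv_freq[pool_of]
    hap1 = rng.random(n_individuals) < f   # True = B haplotype
    hap2 = rng.random(n_individuals) < f
    karyo = np.select(
        [(~hap1) & (~hap2), hap1 & hap2], ["AA", "BB"], default="AB"
    )

    n_inv = inv.n_diagnostic + inv.n_shared
    pos_inv = np.sort(rng.integers(inv.interval.start, inv.interval.end + 1,
                                   n_inv))
    roles = np.array(["inv_diag"] * inv.n_diagnostic +
                     ["inv_shared"] * inv.n_shared, dtype=object)
    rng.shuffle(roles)
    diag = roles == "inv_diag"
    q_a = np.where(diag, rng.uniform(0.0, 0.05, n_inv),
                   rng.uniform(0.25, 0.75, n_inv))
    q_b = np.where(diag, rng.uniform(0.95, 1.0, n_inv),
                   rng.uniform(0.25, 0.75, n_inv))

    g_inv = (
        (rng.random((n_inv, n_individuals))
         < np.where(hap1[None, :], q_b[:, None], q_a[:, None])).astype(np.int8)
        + (rng.random((n_inv, n_individuals))
           < np.where(hap2[None, :], q_b[:, None], q_a[:, None])).astype(np.int8)
    )

    chrom_len = cfg.chrom_lengths[inv.interval.chrom]
    left = rng.integers(max(1, inv.interval.start - flank_bp),
                        inv.interval.start, n_flanking)
    right = rng.integers(inv.interval.end + 1,
                         min(chrom_len, inv.interval.end + flank_bp) + 1,
                         n_flanking)
    pos_fl = np.sort(np.concatenate([left, right]))
    q_fl = rng.uniform(0.1, 0.9, len(pos_fl))
    g_fl = rng.binomial(2, q_fl[:, None],
                        (len(pos_fl), n_individuals)).astype(np.int8)

    pos = np.concatenate([pos_inv, pos_fl])
    geno = np.vstack([g_inv, g_fl])
    role = np.concatenate([roles, np.array(["background"] * len(pos_fl),
                                           dtype=object)])
    order = np.argsort(pos, kind="stable")
    snps = pd.DataFrame(
        {
            "chrom": inv.interval.chrom,
            "pos": pos[order],
            "ref": "A",
            "alt": "C",
        }
    )
    gm = GenotypeMatrix(
        snps=snps,
        genotypes=geno[order],
        individuals=[f"ind{i + 1:03d}" for i in range(n_individuals)],
    )
    truth = SimTruth(
        pool_freqs=np.empty((0, cfg.n_pools)),
        realized_freqs=np.empty((0, cfg.n_pools)),
        snp_role=role[order],
        seasons=list(cfg.seasons),
        regions=list(cfg.regions),
        inversion_freq=inv_freq,
        karyotypes=list(karyo),
    )
    return gm, truth
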