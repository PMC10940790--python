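"""End-to-end orchestration of the pool-seq analysis on files.

A :class:`RunConfig` carries every module parameter with its standard
default (20% missing, MAC 2, 5-99 coverage percentiles, SD bands
0.03/0.09/0.2, 1k/10k thinning, 100-SNP dAF window, 10k/2k diversity
windows, 5-kb LD bins with 1-Mb flanks, 10-kb sharing windows with
10/90% thresholds, |r| 0.7 and VIF 5 pruning, 9999 permutations).
:func:`run_pipeline` executes the stages in dependency order, stamps
every output with the config hash and seed, and skips stages whose
recorded outputs are up to date (matching config hash and checksum);
a corrupted intermediate invalidates its stage and everything downstream.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import dataio, diversity, gea, poolfreq, popstructure, scan, svtools
from . import treebuild
from .simulate import (
    DivergentLocus,
    InversionConfig,
    SimConfig,
    simulate_individual_genotypes,
    simulate_pool_dataset,
)
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "filter",
    "freq",
    "fst",
    "pca",
    "scan",
    "diversity",
    "sv",
    "tree",
    "gea",
)


def _default_sim() -> SimConfig:
    return SimConfig(
        divergent_loci=[
            DivergentLocus(
                GenomicInterval("Chr1", 10_000_000, 10_500_000), delta=0.6
            )
        ],
        inversion=InversionConfig.from_gene_flux(
            GenomicInterval("Chr2", 8_000_000, 12_000_000),
            n_sites=300,
            gene_flux=0.5,
        ),
    )


@dataclass
class RunConfig:
    outdir: str = "poolscan_out"
    seed: int = 0
    sim: SimConfig = field(default_factory=_default_sim)
    max_missing: float = 0.20
    min_mac: int = 2
    coverage_percentiles: tuple[float, float] = (5.0, 99.0)
    sd_band: tuple[float, float] = (0.03, 0.09)
    sd_high: float = 0.2
    thin_undiff_bp: int = 1_000
    thin_diff_bp: int = 10_000
    daf_window: int = 100
    daf_cutoff: float = 0.55
    max_gap: int = 100_000
    min_region_snps: int = 5
    div_window: int = 10_000
    div_step: int = 2_000
    ld_bin: int = 5_000
    ld_flank: int = 1_000_000
    sharing_window: int = 10_000
    sharing_thresholds: tuple[float, float] = (0.1, 0.9)
    r_cut: float = 0.7
    vif_cut: float = 5.0
    nperm: int = 9999
    n_individuals_sim: int = 90

    def config_hash(self) -> str:
        raw = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(raw.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class PipelineRun:
    """Stage runner with config-hash + checksum caching."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        self.old = {}
        if self.manifest_path.exists():
            try:
                self.old = json.loads(self.manifest_path.read_text())
            except json.JSONDecodeError:
                self.old = {}
        self.manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
            "stages": {},
        }
        self._invalidated = False

    def _uptodate(self, stage: str, outputs: list[Path]) -> bool:
        if self._invalidated:
            return False
        if self.old.get("config_hash") != self.manifest["config_hash"]:
            return False
        rec = self.old.get("stages", {}).get(stage)
        if not rec:
            return False
        for p in outputs:
            if not p.exists() or _checksum(p) != rec.get("checksums", {}).get(
                p.name
            ):
                return False
        return True

    def stage(self, name: str, outputs: list[str], fn) -> bool:
        """Run *fn* unless the stage's outputs are up to date.  Returns
        True if the stage executed."""
        paths = [self.outdir / o for o in outputs]
        if self._uptodate(name, paths):
            logger.info("stage %s up to date; skipping", name)
            self.manifest["stages"][name] = dict(
                self.old["stages"][name], skipped=True
            )
            return False
        self._invalidated = True  # downstream stages must rerun
        try:
            fn()
        except Exception as e:
            raise RuntimeError(f"stage {name!r} failed: {e}") from e
        self.manifest["stages"][name] = {
            "outputs": [str(p) for p in paths],
            "checksums": {p.name: _checksum(p) for p in paths if p.exists()},
            "skipped": False,
        }
        return True

    def finish(self) -> dict:
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))
        return self.manifest


def run_pipeline(config: RunConfig) -> dict:
    """Run every applicable stage; returns the provenance manifest."""
    run = PipelineRun(config)
    out = run.outdir
    cfg = config
    state: dict = {}

    def _simulate():
        counts, env, truth = simulate_pool_dataset(cfg.sim)
        dataio.write_counts_tsv(counts, out / "counts.tsv")
        dataio.write_pool_metadata(counts.pools, out / "pools.tsv")
        env.to_csv(out / "env.csv")
        pd.DataFrame(truth.pool_freqs, columns=counts.pool_ids).to_csv(
            out / "truth_freqs.tsv", sep="\t", index=False
        )

    run.stage(
        "simulate",
        ["counts.tsv", "pools.tsv", "env.csv", "truth_freqs.tsv"],
        _simulate,
    )
    pools = dataio.read_pool_metadata(out / "pools.tsv")
    counts = dataio.read_counts_tsv(out / "counts.tsv", pools)
    env = dataio.read_env_table(out / "env.csv", pools)

    def _filter():
        filtered, report = poolfreq.filter_snps(
            counts,
            max_missing=cfg.max_missing,
            min_mac=cfg.min_mac,
            coverage_percentiles=cfg.coverage_percentiles,
        )
        dataio.write_counts_tsv(filtered, out / "counts_filtered.tsv")
        (out / "filter_report.json").write_text(json.dumps(report, indent=2))

    run.stage(
        "filter", ["counts_filtered.tsv", "filter_report.json"], _filter
    )
    filtered = dataio.read_counts_tsv(out / "counts_filtered.tsv", pools)
    state["filtered"] = filtered

    def _freq():
        freqs = poolfreq.allele_frequencies(filtered)
        freqs.to_frame().to_csv(out / "freqs.tsv", sep="\t", index=False)
        part = poolfreq.partition_markers(
            freqs,
            sd_band=cfg.sd_band,
            sd_high=cfg.sd_high,
            thin_undiff_bp=cfg.thin_undiff_bp,
            thin_diff_bp=cfg.thin_diff_bp,
        )
        json.dump(
            {
                "undifferentiated": part.undifferentiated_thinned.tolist(),
                "differentiated": part.differentiated_thinned.tolist(),
            },
            open(out / "partitions.json", "w"),
        )

    run.stage("freq", ["freqs.tsv", "partitions.json"], _freq)
    freqs = poolfreq.allele_frequencies(filtered)
    partitions = json.loads((out / "partitions.json").read_text())

    def _fst():
        fst = popstructure.fst_matrix(filtered)
        fst.to_frame().to_csv(out / "fst.tsv", sep="\t")

    run.stage("fst", ["fst.tsv"], _fst)

    def _pca():
        for name, idx in partitions.items():
            if len(idx) < 2:
                continue
            sub = poolfreq.polarize_minor(freqs).take_snps(np.array(idx))
            p = popstructure.pca(sub)
            df = pd.DataFrame(
                p.scores_,
                index=freqs.pool_ids,
                columns=[f"PC{i+1}" for i in range(p.scores_.shape[1])],
            )
            var = np.full(len(df), np.nan)
            var[: len(p.explained_variance_pct_)] = p.explained_variance_pct_
            df["variance_pct"] = var
            df.to_csv(out / f"pca_{name}.tsv", sep="\t")

    run.stage(
        "pca",
        [
            f"pca_{n}.tsv"
            for n in partitions
            if len(partitions[n]) >= 2
        ],
        _pca,
    )

    contrast = scan.GroupContrast.by_season(pools)

    def _scan():
        track = scan.daf_scan(freqs, contrast)
        scan.rolling_daf(track, window=cfg.daf_window)
        pvals, bonf, min_daf = scan.per_snp_test(filtered, contrast)
        track.pvalues = pvals
        track.bonferroni_alpha = bonf
        track.bonferroni_flag = pvals < bonf
        scan.flag_outliers(track, cfg.daf_cutoff)
        track.to_frame().to_csv(out / "daf_track.tsv", sep="\t", index=False)
        regions = scan.detect_regions(
            track,
            daf_cutoff=cfg.daf_cutoff,
            max_gap=cfg.max_gap,
            min_snps=cfg.min_region_snps,
        )
        scan.regions_to_frame(regions).to_csv(
            out / "regions.tsv", sep="\t", index=False
        )
        dataio.write_bed([r.interval for r in regions], out / "regions.bed")

    run.stage("scan", ["daf_track.tsv", "regions.tsv", "regions.bed"], _scan)

    def _diversity():
        frames = [
            diversity.windowed_stats(
                filtered,
                p.id,
                window=cfg.div_window,
                step=cfg.div_step,
                chrom_lengths=cfg.sim.chrom_lengths,
                seed=cfg.seed,
            )
            for p in pools[: min(4, len(pools))]
        ]
        pd.concat(frames).to_csv(out / "diversity.tsv", sep="\t", index=False)

    run.stage("diversity", ["diversity.tsv"], _diversity)

    has_inv = cfg.sim.inversion is not None
    if has_inv:
        region = cfg.sim.inversion.interval

        def _sv():
            genos, truth = simulate_individual_genotypes(
                cfg.sim, cfg.n_individuals_sim
            )
            calls = svtools.call_karyotypes(genos, region)
            kdf = pd.DataFrame(
                {
                    "individual": [c.individual for c in calls],
                    "call": [c.call for c in calls],
                    "confidence": [c.confidence for c in calls],
                }
            )
            kdf.to_csv(out / "karyotypes.tsv", sep="\t", index=False)
            kmap = dict(zip(kdf["individual"], kdf["call"]))
            ld = svtools.ld_matrix(
                genos, region, flank=cfg.ld_flank, bin_size=cfg.ld_bin
            )
            ld.table.to_csv(out / "ld_all.tsv", sep="\t", index=False)
            aa = [i for i, c in kmap.items() if c == "AA"]
            bb = [i for i, c in kmap.items() if c == "BB"]
            sharing = svtools.allele_sharing(
                genos, aa, bb, region,
                window=cfg.sharing_window,
                thresholds=cfg.sharing_thresholds,
            )
            sharing.to_csv(out / "sharing.tsv", sep="\t", index=False)
            flux = svtools.gene_flux_summary(sharing)
            json.dump(
                {k: v for k, v in flux.items() if k != "per_window"},
                open(out / "gene_flux.json", "w"),
            )

        run.stage(
            "sv",
            ["karyotypes.tsv", "ld_all.tsv", "sharing.tsv", "gene_flux.json"],
            _sv,
        )

    def _tree():
        idx = np.array(partitions["differentiated"], dtype=int)
        sub = freqs.take_snps(idx) if len(idx) >= 2 else freqs
        dist = treebuild.daf_distance(sub)
        dist.to_frame().to_csv(out / "daf_dist.tsv", sep="\t")
        tree = treebuild.nj_tree(dist)
        treebuild.write_newick(tree, out / "tree.nwk")

    run.stage("tree", ["daf_dist.tsv", "tree.nwk"], _tree)

    def _gea():
        std = gea.standardize_env(env)
        prune = gea.prune_collinear(std, r_cut=cfg.r_cut, vif_cut=cfg.vif_cut)
        idx = np.array(partitions["differentiated"], dtype=int)
        if has_inv:
            inv_mask = filtered.snps_in(cfg.sim.inversion.interval)
            cand = np.nonzero(inv_mask)[0]
            if len(cand) >= 2:
                idx = cand
        Y = freqs.freq[idx].T
        Y = np.where(np.isnan(Y), np.nanmean(Y, axis=0, keepdims=True), Y)
        X = std[prune.retained]
        model = gea.rda_fit(Y, X)
        anova = gea.permutation_anova(model, nperm=cfg.nperm, seed=cfg.seed)
        payload = gea.rda_to_tables(model, anova)
        payload["pruned"] = prune.table().to_dict(orient="records")
        (out / "rda.json").write_text(json.dumps(payload, indent=2))

    run.stage("gea", ["rda.json"], _gea)

    return run.finish()
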