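"""End-to-end pipeline: filter -> trees -> D -> rates -> ASR -> summaries.

Every stage writes delimited artifacts into the run directory and the run
closes with a JSON manifest carrying the seed, a hash of the configuration,
and the artifact list, so a rerun with the same configuration is
byte-identical and any stage can be re-run from the previous stage's files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import asr as asr_mod
from . import dstat, hmm, summary
from .matrix import coverage_stats, drop_never_present, read_catalog, read_matrix, write_matrix
from .trees import read_taxonomy, sample_trees, write_trees

__all__ = ["PipelineConfig", "run"]

log = logging.getLogger("phylostab")


@dataclass(frozen=True)
class PipelineConfig:
    matrix: str
    catalog: str
    taxonomy: str
    outdir: str
    n_trees: int = 1000
    n_sim: int = 1000
    n_starts: int = 5
    n_trees_rates: int | None = None  # default: all sampled trees
    thresholds: tuple[float, float] = (0.95, 0.75)
    branch_model: str = "yule"
    seed: int = 0
    scaled_down: bool = False

    def __post_init__(self) -> None:
        for name in ("n_trees", "n_sim", "n_starts"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        hi, mid = self.thresholds
        if not (0.5 < mid < hi < 1.0):
            raise ValueError("thresholds must satisfy 0.5 < t2 < t1 < 1")

    def resolved(self) -> "PipelineConfig":
        """Apply the scaled-down presets and fill derived defaults."""
        cfg = self
        if cfg.scaled_down:
            cfg = replace(cfg, n_trees=min(cfg.n_trees, 100), n_sim=min(cfg.n_sim, 100),
                          n_starts=min(cfg.n_starts, 3))
        if cfg.n_trees_rates is None:
            cfg = replace(cfg, n_trees_rates=cfg.n_trees)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "thresholds" in raw:
            raw["thresholds"] = tuple(raw["thresholds"])
        return cls(**raw)


def _write(df: pd.DataFrame, path: Path, manifest: list[str]) -> None:
    df.to_csv(path)
    manifest.append(path.name)


def run(config: PipelineConfig) -> Path:
    """Execute all stages in order; returns the run directory."""
    cfg = config.resolved()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    t_start = time.time()

    # --- inputs (fail before any compute if anything is unreadable)
    for path, what in ((cfg.matrix, "matrix"), (cfg.catalog, "catalogue"), (cfg.taxonomy, "taxonomy")):
        if not Path(path).is_file():
            raise FileNotFoundError(f"{what} file not found: {path}")
    matrix = read_matrix(cfg.matrix)
    catalog = read_catalog(cfg.catalog)
    taxonomy = read_taxonomy(cfg.taxonomy)
    tax_tips = set(taxonomy.tip_labels)
    mat_taxa = set(matrix.taxa)
    if tax_tips != mat_taxa:
        raise ValueError(
            "taxon mismatch between matrix and taxonomy: "
            f"only in matrix {sorted(mat_taxa - tax_tips)}, "
            f"only in taxonomy {sorted(tax_tips - mat_taxa)}"
        )
    catalog.check_features(matrix.features)

    # --- stage 1: filter
    filtered, removed = drop_never_present(matrix)
    write_matrix(filtered, outdir / "matrix_filtered.csv")
    manifest.append("matrix_filtered.csv")
    pd.Series(removed, name="feature").to_csv(outdir / "features_removed.csv", index=False)
    manifest.append("features_removed.csv")
    cov = coverage_stats(filtered)
    _write(cov["per_feature"].to_frame(), outdir / "coverage_per_feature.csv", manifest)
    _write(cov["per_taxon"].to_frame(), outdir / "coverage_per_taxon.csv", manifest)
    log.info("filter: %d features kept, %d removed", filtered.n_features, len(removed))

    # --- stage 2: trees
    posterior = sample_trees(taxonomy, cfg.n_trees, seed=cfg.seed, branch_model=cfg.branch_model)
    write_trees(posterior, outdir / "posterior.nex", schema="nexus")
    manifest.append("posterior.nex")
    log.info("trees: sampled %d trees", len(posterior))

    # --- stage 3: D statistic
    d_rows, d_median_rows = [], []
    for feat in filtered.features:
        trait = filtered.trait(feat)
        med = dstat.median_D(posterior, trait, n_sim=cfg.n_sim, seed=cfg.seed)
        for k, r in enumerate(med.per_tree):
            d_rows.append(
                {"feature": feat, "tree": k, "d_obs": r.d_obs,
                 "d_random_mean": r.d_random_mean, "d_brownian_mean": r.d_brownian_mean,
                 "D": r.D, "status": r.status}
            )
        d_median_rows.append(
            {"feature": feat, "median_D": med.median, "n_ok": med.n_ok,
             "n_not_ok": med.n_not_ok}
        )
        log.debug("dstat: %s median D = %s", feat, med.median)
    _write(pd.DataFrame(d_rows).set_index("feature"), outdir / "dstat_per_tree.csv", manifest)
    d_medians = pd.DataFrame(d_median_rows).set_index("feature")
    _write(d_medians, outdir / "dstat_median.csv", manifest)
    log.info("dstat: done (%.1fs)", time.time() - t_start)

    # --- stage 4: hidden-rates fits
    rate_trees = list(posterior)[: cfg.n_trees_rates]
    fit_rows = []
    for feat in filtered.features:
        trait = filtered.trait(feat)
        for k, tree in enumerate(rate_trees):
            f = hmm.fit(tree, trait, seed=cfg.seed + 7919 * k, n_starts=cfg.n_starts)
            row = {"feature": feat, "tree": k, "logL": f.log_likelihood,
                   "converged": f.converged, "summary_gain": f.summary_gain,
                   "summary_loss": f.summary_loss, "occupancy": f.class_occupancy}
            row.update({n: getattr(f.rates, n) for n in hmm.RATE_NAMES})
            fit_rows.append(row)
        log.debug("rates: %s fitted on %d trees", feat, len(rate_trees))
    fits = pd.DataFrame(fit_rows)
    _write(fits.set_index("feature"), outdir / "rates_per_tree.csv", manifest)
    rate_medians = (
        fits.assign(
            log_gain=fits["summary_gain"].map(hmm.log10_rate),
            log_loss=fits["summary_loss"].map(hmm.log10_rate),
        )
        .groupby("feature")[["log_gain", "log_loss"]]
        .median()
        .rename(columns={"log_gain": "median_log_gain", "log_loss": "median_log_loss"})
    )
    _write(rate_medians, outdir / "rates_median.csv", manifest)
    log.info("rates: done (%.1fs)", time.time() - t_start)

    # --- stage 5: ancestral reconstruction at family roots
    families = filtered.families.to_dict()
    fam_names = sorted(set(families.values()))
    asr_rows = []
    for feat in filtered.features:
        trait = filtered.trait(feat)
        probs_per_family: dict[str, list[float]] = {f: [] for f in fam_names}
        for k, tree in enumerate(rate_trees):
            row = fits[(fits["feature"] == feat) & (fits["tree"] == k)].iloc[0]
            rates = hmm.RateMatrix(**{n: float(row[n]) for n in hmm.RATE_NAMES})
            rec = asr_mod.marginal_asr(tree, trait, rates)
            for fam in fam_names:
                probs_per_family[fam].append(
                    asr_mod.family_root_presence(rec, fam, families)
                )
        asr_rows.append(
            {"feature": feat, **{f: float(np.median(p)) for f, p in probs_per_family.items()}}
        )
    family_probs = pd.DataFrame(asr_rows).set_index("feature")
    _write(family_probs, outdir / "asr_family_probs.csv", manifest)
    recon = asr_mod.reconstructability_summary(family_probs, thresholds=cfg.thresholds)
    _write(recon["band_proportions"], outdir / "reconstructability_bands.csv", manifest)
    _write(recon["cumulative_proportions"], outdir / "reconstructability_cumulative.csv", manifest)
    overlap = asr_mod.pairwise_family_overlap(family_probs, threshold=cfg.thresholds[0])
    _write(overlap, outdir / "family_overlap.csv", manifest)
    for axis in ("functional_category", "domain", "part_of_speech"):
        norm = asr_mod.category_normalized_reconstruction(
            family_probs, catalog, axis=axis, threshold=cfg.thresholds[0]
        )
        _write(norm, outdir / f"reconstruction_by_{axis}.csv", manifest)
    log.info("asr: done (%.1fs)", time.time() - t_start)

    # --- stage 6: stability summaries
    records = [
        summary.FeatureStability(
            feature=feat,
            median_D=(None if pd.isna(d_medians.at[feat, "median_D"]) else float(d_medians.at[feat, "median_D"])),
            median_log_gain=float(rate_medians.at[feat, "median_log_gain"]),
            median_log_loss=float(rate_medians.at[feat, "median_log_loss"]),
        )
        for feat in filtered.features
    ]
    _write(summary.stability_table(records), outdir / "stability.csv", manifest)
    for axis in ("functional_category", "domain", "part_of_speech"):
        _write(
            summary.category_medians(records, catalog, axis=axis),
            outdir / f"medians_by_{axis}.csv",
            manifest,
        )
    overall = summary.overall_summary(records)
    _write(overall["dispersion"], outdir / "overall_dispersion.csv", manifest)
    _write(overall["d_bins"].to_frame("proportion"), outdir / "d_bins.csv", manifest)
    _write(overall["rate_bins"], outdir / "rate_bins.csv", manifest)
    _write(overall["coarse"].to_frame("proportion"), outdir / "coarse_splits.csv", manifest)

    tau_report: dict[str, object] = {}
    tab = summary.stability_table(records)
    for direction in ("gain", "loss"):
        col = f"median_log_{direction}"
        pairs = tab[["median_D", col]].dropna()
        floored = tab[col] <= np.log10(hmm.RATE_MIN) + 1e-9
        for variant, sel in (("all", pairs), ("excluding_floored", pairs[~floored.loc[pairs.index]])):
            try:
                tau, p = summary.kendall_tau(sel["median_D"], sel[col])
                tau_report[f"tau_{direction}_{variant}"] = {"tau": tau, "p": p, "n": len(sel)}
            except ValueError as e:
                tau_report[f"tau_{direction}_{variant}"] = {"error": str(e)}
    with open(outdir / "kendall_tau.json", "w") as fh:
        json.dump(tau_report, fh, indent=1)
    manifest.append("kendall_tau.json")

    # --- manifest
    meta = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_features": filtered.n_features,
        "n_removed": len(removed),
        "artifacts": manifest,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    log.info("run complete: %d artifacts in %s (%.1fs)", len(manifest), outdir, time.time() - t_start)
    return outdir
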