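"""End-to-end pipeline stages over files.

Each stage reads its inputs from and writes its outputs under the
configured output directory, so stages can be run separately (or through
the command-line interface) and are deterministic under the run seed:

``simulate`` -> recordings + manifest; ``analyze`` -> feature matrix;
``stats`` -> channel t-test table, sex comparison, baseline rank-sums;
``classify`` -> benchmark metrics table; ``report`` -> plots + provenance.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from mfgait.classify import ClassifierSpec, METHODS, benchmark
from mfgait.features import FeatureMatrix, build_feature_matrix, feature_histogram
from mfgait.io import RunConfig, read_cohort, stage_seed, write_cohort
from mfgait.mfdfa import run_mfdfa
from mfgait.stats import baseline_ranksum, channel_ttests, sex_group_comparison
from mfgait.synthetic import gen_cohort

log = logging.getLogger("mfgait")

__all__ = ["simulate", "analyze", "stats_stage", "classify_stage", "report", "run_all"]


def _outdir(config: RunConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def simulate(config: RunConfig) -> Path:
    """Generate the synthetic cohort and write recordings + manifest."""
    out = _outdir(config) / "cohort"
    recs, baseline = gen_cohort(config.cohort)
    if not recs:
        log.warning("cohort spec produced zero subjects")
    mpath = write_cohort(recs, baseline, out)
    log.info("wrote %d recordings to %s", len(recs), out)
    return mpath


def analyze(config: RunConfig, channels: list[str] | None = None) -> Path:
    """Extract the stability feature matrix from the simulated cohort."""
    out = _outdir(config)
    mpath = out / "cohort" / "manifest.tsv"
    if not mpath.exists():
        raise FileNotFoundError(f"manifest not found: {mpath}; run simulate first")
    recs, _ = read_cohort(mpath)
    if channels:
        for rec in recs:
            keep = [i for i, c in enumerate(rec.channel_names) if c in channels]
            missing = set(channels) - set(rec.channel_names)
            if missing:
                raise ValueError(f"unknown channels requested: {sorted(missing)}")
            rec.channels = rec.channels[keep]
            rec.channel_names = [rec.channel_names[i] for i in keep]
    mf_config = config.mfdfa.to_config(recs[0].n_samples)
    log.info("extracting %d channels x %d subjects", recs[0].n_channels, len(recs))
    matrix = build_feature_matrix(recs, mf_config)
    fpath = out / "features.tsv"
    matrix.to_tsv(fpath)
    return fpath


def stats_stage(config: RunConfig) -> dict:
    """Group statistics; writes the channel test table and JSON summaries."""
    out = _outdir(config)
    matrix = FeatureMatrix.read_tsv(out / "features.tsv")
    table = channel_ttests(matrix, alpha_level=config.stats.alpha_level,
                           equal_var=config.stats.equal_var)
    table.to_csv(out / "channel_tests.tsv", sep="\t", index=False)
    sexcmp = sex_group_comparison(matrix, mode=config.stats.posture_mode,
                                  equal_var=config.stats.equal_var)
    _, baseline = read_cohort(out / "cohort" / "manifest.tsv")
    ranksum = baseline_ranksum(baseline)
    summary = {
        "cell_means": sexcmp["cell_means"],
        "tests": sexcmp["tests"],
        "baseline_ranksum": ranksum,
        "n_significant_channels": int(table["significant"].sum()),
        "alpha_level": config.stats.alpha_level,
    }
    (out / "group_stats.json").write_text(json.dumps(summary, indent=2))
    return summary


def classify_stage(config: RunConfig) -> pd.DataFrame:
    """Benchmark the six classifiers on the feature matrix."""
    out = _outdir(config)
    matrix = FeatureMatrix.read_tsv(out / "features.tsv")
    seed = stage_seed(config.seed, "classify")
    specs = [ClassifierSpec(method=m, seed=seed) for m in METHODS]
    table, prov = benchmark(matrix, specs, config.protocol)
    table.to_csv(out / "benchmark.tsv", sep="\t", index=False)
    (out / "benchmark_provenance.json").write_text(json.dumps(prov, indent=2, default=str))
    return table


def report(config: RunConfig) -> Path:
    """Render the spectrum, feature-distribution, group-mean and benchmark
    figures, and bundle run provenance."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = _outdir(config)
    matrix = FeatureMatrix.read_tsv(out / "features.tsv")
    recs, _ = read_cohort(out / "cohort" / "manifest.tsv")

    # singularity spectrum of one example channel (inverted bell)
    mf_config = config.mfdfa.to_config(recs[0].n_samples)
    res = run_mfdfa(recs[0].channels[0], mf_config)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(res.spectrum.alpha, res.spectrum.f_alpha, "o-")
    ax.set_xlabel(r"$\alpha$")
    ax.set_ylabel(r"$f(\alpha)$")
    ax.set_title(f"Singularity spectrum, {recs[0].subject_id} / {recs[0].channel_names[0]}")
    fig.tight_layout()
    fig.savefig(out / "spectrum.png", dpi=120)
    plt.close(fig)

    hist = feature_histogram(matrix)
    fig, ax = plt.subplots(figsize=(8, 4))
    pooled = hist["counts"].sum(axis=0)
    centers = (hist["edges"][:-1] + hist["edges"][1:]) / 2
    ax.bar(centers, pooled, width=np.diff(hist["edges"]) * 0.9)
    ax.set_xlabel(r"$D(\alpha)$")
    ax.set_ylabel("frequency (all channels)")
    fig.tight_layout()
    fig.savefig(out / "feature_distribution.png", dpi=120)
    plt.close(fig)

    stats_file = out / "group_stats.json"
    if stats_file.exists():
        cells = json.loads(stats_file.read_text())["cell_means"]
        names = [k for k, v in cells.items() if v is not None]
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.bar(names, [cells[k] for k in names])
        ax.set_ylabel(r"mean posture stability $D(\alpha)$")
        ax.tick_params(axis="x", rotation=30)
        fig.tight_layout()
        fig.savefig(out / "group_means.png", dpi=120)
        plt.close(fig)

    prov = {
        "seed": config.seed,
        "mfdfa": mf_config.provenance(),
        "cohort": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in config.cohort.__dict__.items()},
        "protocol": dict(config.protocol.__dict__),
    }
    ppath = out / "provenance.json"
    ppath.write_text(json.dumps(prov, indent=2))
    return ppath


def run_all(config: RunConfig) -> None:
    simulate(config)
    analyze(config)
    stats_stage(config)
    classify_stage(config)
    report(config)
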