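"""Reusable study-scale experiments.

These drive the full pipeline at the study's conditions (9 fallers vs 37
non-fallers, 60 s recordings at 60 Hz, per-group cascade weights 0.75 /
0.62) and are shared by the analysis scripts and the acceptance checks.
The cohort-level experiments run on a reduced 12-channel marker set (hip
region plus one foot marker) to keep repeated-seed simulations tractable;
the channel count only scales the averaging, not the group effect.
"""

from __future__ import annotations

import numpy as np

from mfgait.classify import ClassifierSpec, EvaluationProtocol, METHODS, benchmark
from mfgait.features import build_feature_matrix
from mfgait.markers import HIP_MARKERS
from mfgait.stats import sex_group_comparison
from mfgait.synthetic import CohortSpec, gen_cohort

__all__ = ["REDUCED_MARKERS", "recovery_experiment", "cascade_hq_errors", "fgn_h2_errors"]

#: 4 markers x 3 planes = 12 channels
REDUCED_MARKERS = HIP_MARKERS + ("R dorsum of foot",)


def recovery_experiment(
    seeds: list[int],
    duration: float = 60.0,
    markers: tuple[str, ...] = REDUCED_MARKERS,
    run_classifiers: bool = True,
) -> list[dict]:
    """Per-seed group separation and classifier ranking at study conditions.

    For each seed: generate the default-composition cohort, extract the
    stability feature matrix, t-test posture stability between groups, and
    (optionally) benchmark all six classifiers under resubstitution.
    Returns one dict per seed with the group means, the p-value, and
    whether GBDT attains the top accuracy.
    """
    results = []
    for seed in seeds:
        spec = CohortSpec(duration=duration, markers=markers, seed=int(seed))
        recordings, _ = gen_cohort(spec)
        matrix = build_feature_matrix(recordings)
        cmp = sex_group_comparison(matrix)["tests"]["all"]
        row = {
            "seed": int(seed),
            "mean_faller": cmp["mean_faller"],
            "mean_nofaller": cmp["mean_nofaller"],
            "p": cmp["p"],
            "separated": cmp["mean_faller"] > cmp["mean_nofaller"] and cmp["p"] < 0.005,
        }
        if run_classifiers:
            table, _ = benchmark(
                matrix,
                [ClassifierSpec(method=m, seed=int(seed)) for m in METHODS],
                EvaluationProtocol(mode="resubstitution", seed=int(seed)),
                include_baselines=False,
            )
            accs = dict(zip(table["classifier"], table["accuracy"]))
            row["accuracies"] = accs
            row["gbdt_top"] = accs["gbdt"] >= max(accs.values())
        results.append(row)
    return results


def cascade_hq_errors(
    a: float = 0.7, levels: int = 12, q_values=(-4, -3, -2, -1, 1, 2, 3, 4)
) -> dict:
    """Estimated vs closed-form h(q) for the deterministic binomial cascade.

    The cascade's exact exponents are h(q) = 1/q - log2(a^q + (1-a)^q)/q.
    """
    from mfgait.mfdfa import default_config, run_mfdfa
    from mfgait.synthetic import gen_binomial_cascade

    series = gen_binomial_cascade(a, levels)
    res = run_mfdfa(series, default_config(len(series)))
    errors = {}
    for q in q_values:
        closed = 1.0 / q - np.log2(a**q + (1 - a) ** q) / q
        i = int(np.argmin(np.abs(res.hurst.q_grid - q)))
        errors[q] = float(res.hurst.h[i] - closed)
    return errors


def fgn_h2_errors(hursts=(0.3, 0.5, 0.7), n: int = 4096, n_seeds: int = 10, seed0: int = 0) -> dict:
    """Mean h(2) estimation error for fractional Gaussian noise."""
    from mfgait.mfdfa import default_config, run_mfdfa
    from mfgait.synthetic import gen_fgn

    cfg = default_config(n)
    i2 = int(np.argmin(np.abs(cfg.q_grid - 2.0)))
    out = {}
    for hurst in hursts:
        h2 = [
            run_mfdfa(gen_fgn(hurst, n, seed=seed0 + k), cfg).hurst.h[i2]
            for k in range(n_seeds)
        ]
        out[hurst] = float(np.mean(h2) - hurst)
    return out
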