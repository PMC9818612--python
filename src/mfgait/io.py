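"""Plain-text file formats and the run configuration.

Recordings are wide tab-separated tables (column 1 = time in seconds, then
one column per channel named ``<marker>_<x|y|z>`` in serial order); a cohort
manifest is a table of subject_id, label, sex, age, bmi, file.  The run
configuration is a single YAML file that round-trips exactly; unknown keys
are rejected.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mfgait.classify import EvaluationProtocol
from mfgait.synthetic import SAMPLE_RATE, CohortSpec, MarkerRecording

__all__ = [
    "write_recording",
    "read_recording",
    "write_cohort",
    "read_cohort",
    "RunConfig",
    "stage_seed",
]


def write_recording(rec: MarkerRecording, path: str | Path) -> None:
    path = Path(path)
    t = np.arange(rec.n_samples) / rec.sample_rate
    df = pd.DataFrame(rec.channels.T, columns=rec.channel_names)
    df.insert(0, "time", t)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_recording(
    path: str | Path, subject_id: str, label: str, sex: str, age: float, bmi: float
) -> MarkerRecording:
    df = pd.read_csv(path, sep="\t")
    t = df.pop("time").to_numpy()
    rate = 1.0 / np.median(np.diff(t)) if len(t) > 1 else SAMPLE_RATE
    return MarkerRecording(
        subject_id=subject_id,
        channels=df.to_numpy(dtype=float).T,
        channel_names=list(df.columns),
        label=label,
        sex=sex,
        age=age,
        bmi=bmi,
        sample_rate=float(round(rate)),
    )


def write_cohort(
    recordings: list[MarkerRecording], baseline: pd.DataFrame, outdir: str | Path
) -> Path:
    """Write one file per recording plus the manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for rec in recordings:
        fname = f"{rec.subject_id}.tsv"
        write_recording(rec, outdir / fname)
        files.append(fname)
    manifest = baseline.copy()
    manifest["file"] = files if files else pd.Series(dtype=str)
    mpath = outdir / "manifest.tsv"
    manifest.to_csv(mpath, sep="\t", index=False)
    return mpath


def read_cohort(manifest_path: str | Path) -> tuple[list[MarkerRecording], pd.DataFrame]:
    mpath = Path(manifest_path)
    manifest = pd.read_csv(mpath, sep="\t")
    recs = [
        read_recording(
            mpath.parent / row["file"],
            subject_id=row["subject_id"],
            label=row["label"],
            sex=row["sex"],
            age=row["age"],
            bmi=row["bmi"],
        )
        for _, row in manifest.iterrows()
    ]
    return recs, manifest.drop(columns=["file"])


@dataclass
class MfdfaOptions:
    """Serializable MF-DFA settings (scales default to the series length)."""

    q_max: float = 5.0
    q_step: float = 0.5
    detrend_order: int = 1
    segmentation_policy: str = "forward_only"
    d_alpha_formula: str = "arm_asymmetry"
    n_scales: int = 20

    def to_config(self, n_samples: int):
        from mfgait.mfdfa import MfdfaConfig, default_q_grid, default_scales

        return MfdfaConfig(
            scales=default_scales(n_samples, order=self.detrend_order, num=self.n_scales),
            q_grid=default_q_grid(self.q_max, self.q_step),
            detrend_order=self.detrend_order,
            segmentation_policy=self.segmentation_policy,
            d_alpha_formula=self.d_alpha_formula,
        )


@dataclass
class StatsOptions:
    alpha_level: float = 0.005
    equal_var: bool = True
    posture_mode: str = "joint_mean"


@dataclass
class RunConfig:
    """Everything one end-to-end run needs; YAML-serializable."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    mfdfa: MfdfaOptions = field(default_factory=MfdfaOptions)
    stats: StatsOptions = field(default_factory=StatsOptions)
    protocol: EvaluationProtocol = field(default_factory=EvaluationProtocol)
    outdir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        # fan the run seed out to the stages
        self.cohort.seed = stage_seed(self.seed, "cohort")
        self.protocol.seed = stage_seed(self.seed, "protocol")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["cohort"]["markers"] = list(d["cohort"]["markers"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        for key, sub in (
            ("cohort", CohortSpec),
            ("mfdfa", MfdfaOptions),
            ("stats", StatsOptions),
            ("protocol", EvaluationProtocol),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub_known = {f.name for f in fields(sub)}
                sub_unknown = set(kwargs[key]) - sub_known
                if sub_unknown:
                    raise ValueError(f"unknown {key} keys: {sorted(sub_unknown)}")
                if key == "cohort" and "markers" in kwargs[key]:
                    kwargs[key]["markers"] = tuple(kwargs[key]["markers"])
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)


def stage_seed(run_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the run seed (below 2^31)."""
    return int(
        np.random.SeedSequence(
            entropy=int(run_seed), spawn_key=(zlib.crc32(stage.encode()),)
        ).generate_state(1)[0]
        % (2**31)
    )
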