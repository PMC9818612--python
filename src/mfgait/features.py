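"""From marker recordings to the subjects x 126 stability feature matrix.

Each channel (marker x plane) is reduced to its stability index D(alpha) by
MF-DFA; the 126 values per subject, ordered by the marker model's serial
numbers (marker-major, plane-minor x -> y -> z), form one row of the
feature matrix.  Posture stability is the average of the per-joint
stabilities, each joint first averaged over its three planes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mfgait.markers import MARKER_NAMES, PLANES, serial_number
from mfgait.mfdfa import MfdfaConfig, default_config, run_mfdfa
from mfgait.synthetic import MarkerRecording

__all__ = [
    "FeatureMatrix",
    "extract_features",
    "build_feature_matrix",
    "posture_stability",
    "feature_histogram",
    "feature_column_name",
]


def feature_column_name(marker: str, plane: str) -> str:
    return f"{serial_number(marker, plane)}_{marker}_{plane}"


@dataclass
class FeatureMatrix:
    """Subjects x channels table of D(alpha) values plus labels.

    Columns are named ``<serial>_<marker>_<plane>`` and kept in serial
    order; ``labels`` and ``sex`` are aligned with the row index.
    """

    values: pd.DataFrame
    labels: pd.Series
    sex: pd.Series
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.labels.index):
            raise ValueError("labels index must match feature rows")
        if not self.values.index.equals(self.sex.index):
            raise ValueError("sex index must match feature rows")

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        """Write the matrix as a tab-separated table plus a JSON sidecar
        with the MF-DFA configuration provenance."""
        path = Path(path)
        out = self.values.copy()
        out.insert(0, "label", self.labels)
        out.insert(1, "sex", self.sex)
        out.to_csv(path, sep="\t", index_label="subject_id")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"config": self.config}, indent=2))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col="subject_id")
        labels = df.pop("label")
        sex = df.pop("sex")
        sidecar = path.with_suffix(path.suffix + ".json")
        config = {}
        if sidecar.exists():
            config = json.loads(sidecar.read_text()).get("config", {})
        return cls(values=df, labels=labels, sex=sex, config=config)


def extract_features(
    recording: MarkerRecording,
    config: MfdfaConfig | None = None,
    return_side_outputs: bool = False,
):
    """D(alpha) per channel, in the recording's channel order.

    Also logs each channel's h(2) and spectrum width as side outputs when
    requested.  A channel too short for the configured scales raises an
    error naming the channel.
    """
    if config is None:
        config = default_config(recording.n_samples)
    vals = np.empty(recording.n_channels)
    side = {"h2": np.empty(recording.n_channels), "delta_alpha": np.empty(recording.n_channels)}
    i2 = int(np.argmin(np.abs(config.q_grid - 2.0)))
    for k in range(recording.n_channels):
        try:
            res = run_mfdfa(recording.channels[k], config)
        except ValueError as err:
            raise ValueError(f"channel {recording.channel_names[k]!r}: {err}") from err
        vals[k] = res.summary.d_alpha
        side["h2"][k] = res.hurst.h[i2]
        side["delta_alpha"][k] = res.summary.delta_alpha
    if return_side_outputs:
        return vals, side
    return vals


def build_feature_matrix(
    recordings: list[MarkerRecording], config: MfdfaConfig | None = None
) -> FeatureMatrix:
    """Stack per-subject feature vectors into a FeatureMatrix."""
    if not recordings:
        raise ValueError("no recordings")
    cols = [
        feature_column_name(*name.rsplit("_", 1)) for name in recordings[0].channel_names
    ]
    if config is None:
        config = default_config(recordings[0].n_samples)
    rows, labels, sexes, ids = [], [], [], []
    for rec in recordings:
        rows.append(extract_features(rec, config))
        labels.append(rec.label)
        sexes.append(rec.sex)
        ids.append(rec.subject_id)
    values = pd.DataFrame(rows, index=pd.Index(ids, name="subject_id"), columns=cols)
    return FeatureMatrix(
        values=values,
        labels=pd.Series(labels, index=values.index, name="label"),
        sex=pd.Series(sexes, index=values.index, name="sex"),
        config=config.provenance(),
    )


def posture_stability(
    features: np.ndarray | pd.Series,
    mode: str = "joint_mean",
    n_planes: int = len(PLANES),
) -> float:
    """Posture stability: the average of the per-joint stabilities.

    ``"joint_mean"`` averages each joint's planes first and then averages
    joints; ``"grand_mean"`` averages all channels directly.  The two agree
    whenever every joint has the same number of planes.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 1:
        raise ValueError("features must be a single subject's vector")
    if np.any(~np.isfinite(x)):
        raise ValueError("missing or non-finite feature values")
    if mode == "grand_mean":
        return float(x.mean())
    if mode != "joint_mean":
        raise ValueError(f"unknown mode {mode!r}")
    if x.size % n_planes:
        raise ValueError(f"feature length {x.size} not divisible by {n_planes} planes")
    return float(x.reshape(-1, n_planes).mean(axis=1).mean())


def feature_histogram(matrix: FeatureMatrix, bin_width: float = 0.5) -> dict:
    """Per-channel frequency tables over uniform bins of the observed range.

    Returns the bin edges, a channels x bins count table, the global value
    range, and the modal bin of the pooled distribution.
    """
    vals = matrix.values.to_numpy(dtype=float)
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        edges = np.array([lo - bin_width / 2, lo + bin_width / 2])
    else:
        start = np.floor(lo / bin_width) * bin_width
        stop = np.ceil(hi / bin_width) * bin_width
        edges = np.arange(start, stop + bin_width / 2, bin_width)
        if edges[-1] < hi:
            edges = np.append(edges, edges[-1] + bin_width)
    counts = np.vstack(
        [np.histogram(vals[:, j], bins=edges)[0] for j in range(vals.shape[1])]
    )
    pooled = counts.sum(axis=0)
    modal = int(np.argmax(pooled))
    return {
        "edges": edges,
        "counts": pd.DataFrame(
            counts,
            index=matrix.values.columns,
            columns=[f"[{edges[i]:g},{edges[i+1]:g})" for i in range(len(edges) - 1)],
        ),
        "range": (lo, hi),
        "modal_bin": (float(edges[modal]), float(edges[modal + 1])),
    }
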