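"""Synthetic marker recordings, cohorts, and analytic test signals.

The motion-capture recordings behind the original cohort analysis are not
publicly deposited, so this module generates stand-ins that realise exactly
the statistical structure the analysis pipeline assumes:

* **Analytic oracles** — fractional Gaussian noise with a prescribed Hurst
  exponent (circulant spectral synthesis) and binomial multiplicative
  cascades with closed-form generalized Hurst exponents
  ``h(q) = 1/q - log2(a^q + (1-a)^q)/q``.  These validate the MF-DFA
  estimator independently of the gait model.

* **Gait-like trajectories** — a quasi-periodic stride oscillation with
  per-cycle amplitude and frequency jitter, plus an intermittent fluctuation
  component whose local variance is modulated by a randomized binomial
  cascade clipped at its mean.  Clipping removes the cascade's bursts and
  keeps the heterogeneity of its quiescent phases, so the singularity
  spectrum of a channel is right-arm dominant and the stability index
  D(alpha) grows with the cascade weight ``a``: a larger ``a`` means more
  intermittent, less stable motion.  ``a`` is therefore the group knob that
  separates fallers from non-fallers.

* **Cohorts** — 46 subjects by default (1 male + 8 female fallers, 17 male +
  20 female non-fallers) with age/BMI drawn from the published group
  baselines, so that a rank-sum test on age or BMI between groups is null.

Biomechanical realism (joint kinematics, marker occlusion) is explicitly out
of scope; the generator's contract is quasi-periodicity, tunable
multifractality, and group separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from mfgait.markers import MARKER_NAMES, N_CHANNELS, PLANES

__all__ = [
    "gen_fgn",
    "gen_binomial_cascade",
    "gen_marker_trajectory",
    "gen_cohort",
    "CohortSpec",
    "MarkerRecording",
    "TrajectoryParams",
    "SAMPLE_RATE",
]

SAMPLE_RATE = 60.0  # Hz, optical motion-capture frame rate

#: published group baselines: (age mean, age sd, bmi mean, bmi sd)
_BASELINES = {
    ("faller", "male"): (73.0, 0.0, 24.3, 0.0),  # single subject, values verbatim
    ("faller", "female"): (69.0, 5.10, 23.2, 2.79),
    ("nofaller", "male"): (71.9, 7.18, 25.7, 3.18),
    ("nofaller", "female"): (71.6, 7.44, 25.6, 3.01),
}


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_fgn(hurst: float, n: int, seed=None) -> np.ndarray:
    """Fractional Gaussian noise by circulant (Davies-Harte) embedding.

    Returns a stationary zero-mean, unit-variance Gaussian series whose
    k-lag autocovariance is ``( |k+1|^2H - 2|k|^2H + |k-1|^2H ) / 2``.
    ``n`` must be a power of two >= 64 (exact embedding is guaranteed for
    fGn, whose circulant eigenvalues are non-negative).
    """
    if not (0.0 < hurst < 1.0):
        raise ValueError(f"Hurst exponent must lie in (0, 1), got {hurst}")
    if n < 64 or (n & (n - 1)) != 0:
        raise ValueError(f"n must be a power of two >= 64, got {n}")
    rng = _rng(seed)
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst) + np.abs(k - 1) ** (2 * hurst))
    circ = np.concatenate([gamma, gamma[-2:0:-1]])  # length 2n
    lam = np.fft.fft(circ).real
    lam = np.maximum(lam, 0.0)  # clip tiny negative round-off
    m = 2 * n
    a = np.zeros(m, dtype=complex)
    a[0] = np.sqrt(lam[0] / m) * rng.standard_normal()
    a[n] = np.sqrt(lam[n] / m) * rng.standard_normal()
    u = rng.standard_normal(n - 1)
    v = rng.standard_normal(n - 1)
    a[1:n] = np.sqrt(lam[1:n] / (2 * m)) * (u + 1j * v)
    a[n + 1 :] = np.conj(a[n - 1 : 0 : -1])
    x = np.fft.fft(a).real[:n]
    return x


def gen_binomial_cascade(
    a: float, levels: int, seed=None, randomize: bool = False
) -> np.ndarray:
    """Binomial multiplicative measure on 2**levels cells.

    Starting from unit mass, each refinement splits every cell's mass into
    fractions ``a`` and ``1 - a`` (left/right deterministically, or shuffled
    per node when ``randomize``).  The values sum to 1 and the measure's
    generalized Hurst exponents follow the closed form
    ``h(q) = 1/q - log2(a^q + (1-a)^q)/q``.
    """
    if not (0.5 <= a < 1.0):
        raise ValueError(f"cascade weight must satisfy 0.5 <= a < 1, got {a}")
    if levels > 20:
        raise ValueError(f"levels > 20 refused (2^{levels} cells)")
    if levels < 0:
        raise ValueError("levels must be non-negative")
    rng = _rng(seed) if randomize else None
    w = np.array([1.0])
    for lev in range(levels):
        left = np.full(w.size, a)
        if randomize:
            flip = rng.random(w.size) < 0.5
            left[flip] = 1.0 - a
        out = np.empty(2 * w.size)
        out[0::2] = w * left
        out[1::2] = w * (1.0 - left)
        w = out
    return w


@dataclass
class TrajectoryParams:
    """Per-group generator parameters for one gait-like channel."""

    asymmetry: float = 0.62  # cascade weight a; larger = more intermittent
    stride_freq: float = 1.0  # Hz
    base_amplitude: float = 0.5  # stride oscillation amplitude (arbitrary length units)
    cycle_jitter: float = 0.1  # sd of per-cycle relative amplitude/frequency jitter
    noise_sd: float = 3.0  # amplitude of the intermittent fluctuation component


def _quasi_periodic_base(
    n: int, params: TrajectoryParams, rng: np.random.Generator
) -> np.ndarray:
    """Stride sinusoid with per-cycle random frequency and amplitude."""
    dt = 1.0 / SAMPLE_RATE
    n_cycles = int(np.ceil(n * dt * params.stride_freq)) + 2
    freqs = params.stride_freq * (1.0 + params.cycle_jitter * rng.standard_normal(n_cycles))
    freqs = np.clip(freqs, 0.2 * params.stride_freq, 3.0 * params.stride_freq)
    amps = params.base_amplitude * (
        1.0 + params.cycle_jitter * rng.standard_normal(n_cycles)
    )
    phase = np.empty(n)
    amp = np.empty(n)
    ph, cyc = rng.uniform(0, 2 * np.pi), 0
    for i in range(n):
        phase[i] = ph
        amp[i] = amps[cyc]
        ph += 2 * np.pi * freqs[cyc] * dt
        if ph >= 2 * np.pi * (cyc + 1):
            cyc = min(cyc + 1, n_cycles - 1)
    return amp * np.sin(phase)


def _intermittent_component(
    n: int, asymmetry: float, rng: np.random.Generator
) -> np.ndarray:
    """Cascade-modulated noise, clipped at the cascade mean.

    The clip removes the cascade's large-deviation bursts and preserves its
    quiescent-phase heterogeneity, which is what makes the resulting
    singularity spectrum right-arm dominant (D(alpha) > 0) and monotone in
    the cascade weight.
    """
    levels = int(np.ceil(np.log2(max(n, 2))))
    c = gen_binomial_cascade(asymmetry, levels, seed=rng, randomize=True)[:n]
    env = np.minimum(c, c.mean()) / c.mean()
    u = rng.standard_normal(n) * env
    sd = u.std()
    if sd > 0:
        u = (u - u.mean()) / sd
    return u


def gen_marker_trajectory(
    marker: str,
    plane: str,
    duration: float,
    params: TrajectoryParams,
    seed=None,
) -> np.ndarray:
    """One channel: quasi-periodic stride base + intermittent fluctuations.

    ``duration`` is in seconds at 60 Hz and must be >= 10 s so the smallest
    MF-DFA scales have enough windows.
    """
    if duration < 10.0:
        raise ValueError(f"duration must be >= 10 s, got {duration}")
    if marker not in MARKER_NAMES:
        raise ValueError(f"unknown marker {marker!r}")
    if plane not in PLANES:
        raise ValueError(f"unknown plane {plane!r}")
    rng = _rng(seed)
    n = int(round(duration * SAMPLE_RATE))
    base = _quasi_periodic_base(n, params, rng)
    fluct = _intermittent_component(n, params.asymmetry, rng)
    return base + params.noise_sd * fluct


@dataclass
class MarkerRecording:
    """One subject's recording: channels x samples at 60 Hz plus metadata."""

    subject_id: str
    channels: np.ndarray  # (n_channels, n_samples)
    channel_names: list[str]
    label: str  # "faller" | "nofaller"
    sex: str  # "male" | "female"
    age: float
    bmi: float
    sample_rate: float = SAMPLE_RATE

    def __post_init__(self) -> None:
        if self.channels.shape[0] != len(self.channel_names):
            raise ValueError("channel count does not match channel names")
        if self.label not in ("faller", "nofaller"):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]


@dataclass
class CohortSpec:
    """Cohort composition and generator settings.

    Defaults reproduce the published cohort structure: 46 subjects, 9
    fallers (1 male, 8 female) and 37 non-fallers (17 male, 20 female),
    with per-group cascade weights that separate the groups' mean stability
    index.
    """

    n_faller_male: int = 1
    n_faller_female: int = 8
    n_nofaller_male: int = 17
    n_nofaller_female: int = 20
    duration: float = 60.0  # seconds per recording
    asymmetry_faller: float = 0.75
    asymmetry_nofaller: float = 0.62
    noise_sd: float = 3.0
    base_amplitude: float = 0.5
    stride_freq: float = 1.0
    cycle_jitter: float = 0.1
    markers: tuple[str, ...] = MARKER_NAMES  # analyse a subset to cut cost
    #: optional per-marker weight in [0, 1] scaling the group asymmetry
    #: difference (1 = full separation); lets tests concentrate the group
    #: effect on chosen regions, e.g. the hip markers
    emphasis: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_faller_male",
            "n_faller_female",
            "n_nofaller_male",
            "n_nofaller_female",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for a in (self.asymmetry_faller, self.asymmetry_nofaller):
            if not (0.5 <= a < 1.0):
                raise ValueError(f"asymmetry weight must lie in [0.5, 1), got {a}")
        unknown = set(self.markers) - set(MARKER_NAMES)
        if unknown:
            raise ValueError(f"unknown markers: {sorted(unknown)}")

    @property
    def n_subjects(self) -> int:
        return (
            self.n_faller_male
            + self.n_faller_female
            + self.n_nofaller_male
            + self.n_nofaller_female
        )


def _sample_baseline(
    label: str, sex: str, count_in_cell: int, rng: np.random.Generator
) -> tuple[float, float]:
    age_mu, age_sd, bmi_mu, bmi_sd = _BASELINES[(label, sex)]
    if age_sd == 0.0 and count_in_cell == 1:
        return age_mu, bmi_mu  # single printed subject, values verbatim
    # truncated normals: age >= 60 (inclusion criterion), plausible BMI floor
    def trunc(mu, sd, lo):
        if sd == 0.0:
            return mu
        a = (lo - mu) / sd
        return float(stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, random_state=rng))

    return trunc(age_mu, age_sd, 60.0), trunc(bmi_mu, bmi_sd, 15.0)


def gen_cohort(spec: CohortSpec):
    """Generate the cohort: recordings plus a baseline table.

    Returns ``(recordings, baseline)`` where ``baseline`` is a pandas
    DataFrame with columns subject_id, label, sex, age, bmi.  Deterministic
    under ``spec.seed``; every channel is seeded independently per
    (subject, marker, plane) via spawned seed sequences, so recordings are
    reproducible in isolation.
    """
    import pandas as pd

    cells = [
        ("faller", "male", spec.n_faller_male),
        ("faller", "female", spec.n_faller_female),
        ("nofaller", "male", spec.n_nofaller_male),
        ("nofaller", "female", spec.n_nofaller_female),
    ]
    ss = np.random.SeedSequence(spec.seed)
    baseline_rng = np.random.default_rng(ss.spawn(1)[0])
    chan_names = [f"{m}_{p}" for m in spec.markers for p in PLANES]
    recordings: list[MarkerRecording] = []
    rows = []
    subj_idx = 0
    for label, sex, count in cells:
        a_group = spec.asymmetry_faller if label == "faller" else spec.asymmetry_nofaller
        for _ in range(count):
            sid = f"S{subj_idx + 1:03d}"
            age, bmi = _sample_baseline(label, sex, count, baseline_rng)
            chans = np.empty((len(chan_names), int(round(spec.duration * SAMPLE_RATE))))
            k = 0
            for m in spec.markers:
                w = spec.emphasis.get(m, 1.0)
                a_eff = spec.asymmetry_nofaller + w * (a_group - spec.asymmetry_nofaller)
                params = TrajectoryParams(
                    asymmetry=a_eff,
                    stride_freq=spec.stride_freq,
                    base_amplitude=spec.base_amplitude,
                    cycle_jitter=spec.cycle_jitter,
                    noise_sd=spec.noise_sd,
                )
                for p in PLANES:
                    child = np.random.SeedSequence(
                        entropy=spec.seed, spawn_key=(subj_idx, k)
                    )
                    chans[k] = gen_marker_trajectory(
                        m, p, spec.duration, params, seed=np.random.default_rng(child)
                    )
                    k += 1
            recordings.append(
                MarkerRecording(
                    subject_id=sid,
                    channels=chans,
                    channel_names=chan_names,
                    label=label,
                    sex=sex,
                    age=age,
                    bmi=bmi,
                )
            )
            rows.append({"subject_id": sid, "label": label, "sex": sex, "age": age, "bmi": bmi})
            subj_idx += 1
    baseline = pd.DataFrame(rows, columns=["subject_id", "label", "sex", "age", "bmi"])
    return recordings, baseline
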