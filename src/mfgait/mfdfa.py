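"""Multifractal detrended fluctuation analysis (MF-DFA).

Pipeline for one scalar series ``{x_i}``:

1. *Profile*: ``X(k) = sum_{i<=k} (x_i - mean(x))`` — the cumulative sum of
   the mean-centred series.
2. *Local detrending*: the profile is cut into ``L = floor(N/s)``
   non-overlapping windows of length ``s`` (optionally another ``L`` windows
   counted from the tail so the remainder is not discarded); a least-squares
   polynomial is fitted in each window and the mean squared residual
   ``F^2(s, v)`` recorded.
3. *q-order fluctuation function*:
   ``F_q(s) = { mean_v [F^2(s,v)]^(q/2) }^(1/q)`` for ``q != 0`` and the
   logarithmic average ``F_0(s) = exp{ mean_v ln F^2(s,v) / 2 }`` at ``q = 0``.
4. *Generalized Hurst exponents*: ``h(q)`` is the log-log regression slope of
   ``F_q(s)`` on ``s``.
5. *Singularity spectrum* via the Legendre transform:
   ``tau(q) = q h(q) - 1``, ``alpha = dtau/dq``, ``f(alpha) = q alpha - tau``.

The spectrum is summarised by its end points ``alpha_min``/``alpha_max``
(finite-q truncations at the ends of the q grid), its apex ``alpha_0``
(the singularity strength where ``f`` peaks), the width ``delta_alpha``, the
dimension contrast ``delta_f = f(alpha_min) - f(alpha_max)``, and the
stability index

    ``D(alpha) = |alpha_max - alpha_0| - |alpha_min - alpha_0|``,

the length difference between the spectrum's right arm (heterogeneity of the
quiet, weakly fluctuating segments) and its left arm (heterogeneity of the
bursts).  Lower values indicate a more stable trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Series",
    "MfdfaConfig",
    "FluctuationSurface",
    "HurstCurve",
    "SingularitySpectrum",
    "StabilitySummary",
    "MfdfaResult",
    "build_profile",
    "local_detrend_covariances",
    "fluctuation_function",
    "fluctuation_surface",
    "estimate_hurst",
    "legendre_spectrum",
    "summarize_spectrum",
    "run_mfdfa",
    "default_config",
    "default_scales",
    "default_q_grid",
]


@dataclass
class Series:
    """A scalar time series (one marker coordinate in one plane)."""

    values: np.ndarray
    sample_rate: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("series must be one-dimensional")
        bad = np.flatnonzero(~np.isfinite(self.values))
        if bad.size:
            raise ValueError(f"non-finite value at index {bad[0]}")

    def __len__(self) -> int:
        return len(self.values)


def default_scales(n: int, order: int = 1, num: int = 20) -> np.ndarray:
    """~`num` geometrically spaced integer scales from max(16, order+2) to n//4."""
    lo = max(16, order + 2)
    hi = n // 4
    if hi < lo:
        raise ValueError(f"series too short for MF-DFA: n={n} gives max scale {hi} < {lo}")
    raw = np.geomspace(lo, hi, num)
    return np.unique(np.round(raw).astype(int))


def default_q_grid(q_max: float = 5.0, step: float = 0.5) -> np.ndarray:
    """Symmetric q grid including 0; default -5..5 in steps of 0.5."""
    k = int(round(q_max / step))
    return np.arange(-k, k + 1) * step


@dataclass
class MfdfaConfig:
    """Estimator settings.

    Parameters
    ----------
    scales
        Ordered window lengths ``s`` (samples).
    q_grid
        Moment orders, symmetric about 0 and including 0.
    detrend_order
        Degree of the local polynomial fit (1 = classic DFA1).
    segmentation_policy
        ``"forward_only"`` uses ``floor(N/s)`` windows from the head,
        discarding the remainder; ``"bidirectional"`` adds the same count
        from the tail.
    zero_policy
        How zero residual windows are treated when ``q <= 0``:
        ``"exclude"`` drops them (count recorded), ``"floor"`` replaces them
        with ``zero_floor``, ``"error"`` raises.
    d_alpha_formula
        ``"arm_asymmetry"`` is |a_max - a_0| - |a_min - a_0|;
        ``"literal"`` is the alternative reading |a_max - a_0| - a_min - a_0.
    """

    scales: np.ndarray
    q_grid: np.ndarray = field(default_factory=default_q_grid)
    detrend_order: int = 1
    segmentation_policy: str = "forward_only"
    zero_policy: str = "exclude"
    zero_floor: float = 1e-15
    d_alpha_formula: str = "arm_asymmetry"

    def __post_init__(self) -> None:
        self.scales = np.unique(np.asarray(self.scales, dtype=int))
        self.q_grid = np.asarray(self.q_grid, dtype=float)
        if self.scales.size == 0 or self.scales[0] <= self.detrend_order + 1:
            raise ValueError("min(scales) must exceed detrend_order + 1")
        if self.detrend_order < 0:
            raise ValueError("detrend_order must be non-negative")
        if self.segmentation_policy not in ("forward_only", "bidirectional"):
            raise ValueError(f"unknown segmentation_policy {self.segmentation_policy!r}")
        if self.zero_policy not in ("exclude", "floor", "error"):
            raise ValueError(f"unknown zero_policy {self.zero_policy!r}")
        if self.d_alpha_formula not in ("arm_asymmetry", "literal"):
            raise ValueError(f"unknown d_alpha_formula {self.d_alpha_formula!r}")
        if not np.allclose(np.sort(self.q_grid), np.sort(-self.q_grid)):
            raise ValueError("q_grid must be symmetric about 0")
        if not np.any(self.q_grid == 0.0):
            raise ValueError("q_grid must include 0")

    def provenance(self) -> dict:
        return {
            "scales": [int(s) for s in self.scales],
            "q_min": float(self.q_grid.min()),
            "q_max": float(self.q_grid.max()),
            "n_q": int(self.q_grid.size),
            "detrend_order": int(self.detrend_order),
            "segmentation_policy": self.segmentation_policy,
            "zero_policy": self.zero_policy,
            "d_alpha_formula": self.d_alpha_formula,
        }


def default_config(n: int, **kwargs) -> MfdfaConfig:
    """Default configuration for a series of length ``n``."""
    order = kwargs.pop("detrend_order", 1)
    scales = kwargs.pop("scales", None)
    if scales is None:
        scales = default_scales(n, order=order)
    return MfdfaConfig(scales=scales, detrend_order=order, **kwargs)


@dataclass
class FluctuationSurface:
    values: np.ndarray  # (n_q, n_scales), F_q(s)
    scales: np.ndarray
    q_grid: np.ndarray
    segment_counts: np.ndarray  # windows used per scale
    excluded_counts: np.ndarray  # zero-residual windows dropped per scale


@dataclass
class HurstCurve:
    q_grid: np.ndarray
    h: np.ndarray
    fit_r2: np.ndarray


@dataclass
class SingularitySpectrum:
    q_grid: np.ndarray
    tau: np.ndarray
    alpha: np.ndarray
    f_alpha: np.ndarray


@dataclass
class StabilitySummary:
    alpha_min: float
    alpha_max: float
    alpha_0: float
    delta_alpha: float
    delta_f: float
    d_alpha: float
    monofractal: bool = False
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "alpha_min": self.alpha_min,
            "alpha_max": self.alpha_max,
            "alpha_0": self.alpha_0,
            "delta_alpha": self.delta_alpha,
            "delta_f": self.delta_f,
            "d_alpha": self.d_alpha,
            "monofractal": self.monofractal,
            "config": self.provenance,
        }


@dataclass
class MfdfaResult:
    surface: FluctuationSurface
    hurst: HurstCurve
    spectrum: SingularitySpectrum
    summary: StabilitySummary


def build_profile(series: Series | np.ndarray) -> np.ndarray:
    """Cumulative sum of the mean-centred series.

    The final element is 0 up to floating tolerance (the deviations from the
    mean sum to zero); the profile, not the raw series, is detrended.
    """
    if not isinstance(series, Series):
        series = Series(np.asarray(series, dtype=float))
    x = series.values
    if len(x) < 2:
        raise ValueError("series must have length >= 2")
    return np.cumsum(x - x.mean())


def _window_view(profile: np.ndarray, s: int, policy: str) -> np.ndarray:
    """Stack the analysis windows as rows of an (M, s) array."""
    n = len(profile)
    L = n // s
    head = profile[: L * s].reshape(L, s)
    if policy == "forward_only":
        return head
    tail = profile[n - L * s :].reshape(L, s)
    return np.vstack([head, tail])


def _detrend_matrices(s: int, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Vandermonde basis on 1..s and its pseudo-inverse for batched fits."""
    j = np.arange(1, s + 1, dtype=float)
    V = np.vander(j, order + 1, increasing=True)  # (s, order+1)
    pinv = np.linalg.pinv(V)  # (order+1, s)
    return V, pinv


def local_detrend_covariances(
    profile: np.ndarray,
    s: int,
    order: int = 1,
    policy: str = "forward_only",
) -> np.ndarray:
    """Mean squared residual of a per-window polynomial fit, one per window.

    ``F^2(s, v) = (1/s) sum_j { X[(v-1)s + j] - f_v(j) }^2`` with ``f_v`` the
    least-squares polynomial of the given order on window ``v``.
    """
    profile = np.asarray(profile, dtype=float)
    n = len(profile)
    if s > n:
        raise ValueError(f"scale s={s} exceeds profile length {n}")
    if s < order + 2:
        raise ValueError(f"scale s={s} too small for detrend order {order}")
    Y = _window_view(profile, s, policy)
    V, pinv = _detrend_matrices(s, order)
    coeff = Y @ pinv.T  # (M, order+1)
    resid = Y - coeff @ V.T
    return np.mean(resid**2, axis=1)


def fluctuation_function(
    f2: np.ndarray,
    q: float,
    zero_policy: str = "error",
    zero_floor: float = 1e-15,
) -> float:
    """q-order fluctuation function over one scale's window residuals.

    ``q != 0``: ``F_q = { mean_v (F^2_v)^(q/2) }^(1/q)``.
    ``q == 0``: logarithmic average ``F_0 = exp{ mean_v ln F^2_v / 2 }``,
    the q -> 0 limit of the general form.

    Zero residuals are harmless for ``q > 0`` but undefined for ``q <= 0``;
    they are excluded, floored, or raised per ``zero_policy``.
    """
    f2 = np.asarray(f2, dtype=float)
    if f2.size == 0:
        raise ValueError("no windows")
    if np.any(f2 < 0):
        raise ValueError("squared residuals must be non-negative")
    if q <= 0 and np.any(f2 == 0.0):
        if zero_policy == "error":
            raise ValueError(
                "zero residual window with q <= 0; configure zero_policy "
                "'exclude' or 'floor' to proceed"
            )
        if zero_policy == "exclude":
            f2 = f2[f2 > 0]
            if f2.size == 0:
                raise ValueError("all windows have zero residual")
        else:
            f2 = np.maximum(f2, zero_floor)
    if q == 0:
        return float(np.exp(0.5 * np.mean(np.log(f2))))
    return float(np.mean(f2 ** (q / 2.0)) ** (1.0 / q))


def fluctuation_surface(profile: np.ndarray, config: MfdfaConfig) -> FluctuationSurface:
    """F_q(s) over the config's scale and q grids."""
    n_q, n_s = config.q_grid.size, config.scales.size
    values = np.empty((n_q, n_s))
    seg_counts = np.empty(n_s, dtype=int)
    excluded = np.zeros(n_s, dtype=int)
    for k, s in enumerate(config.scales):
        f2 = local_detrend_covariances(
            profile, int(s), config.detrend_order, config.segmentation_policy
        )
        seg_counts[k] = f2.size
        n_zero = int(np.sum(f2 == 0.0))
        if n_zero and config.zero_policy == "exclude":
            excluded[k] = n_zero
        for i, q in enumerate(config.q_grid):
            values[i, k] = fluctuation_function(
                f2, float(q), zero_policy=config.zero_policy, zero_floor=config.zero_floor
            )
    return FluctuationSurface(
        values=values,
        scales=config.scales.copy(),
        q_grid=config.q_grid.copy(),
        segment_counts=seg_counts,
        excluded_counts=excluded,
    )


def estimate_hurst(surface: FluctuationSurface) -> HurstCurve:
    """Per-q log-log regression slope of F_q(s) on s, with R^2."""
    if surface.scales.size < 3:
        raise ValueError("need at least 3 scales for the scaling fit")
    if np.any(surface.values <= 0):
        raise ValueError("fluctuation function must be strictly positive")
    log_s = np.log(surface.scales.astype(float))
    log_f = np.log(surface.values)
    x = log_s - log_s.mean()
    sxx = np.sum(x**2)
    h = (log_f - log_f.mean(axis=1, keepdims=True)) @ x / sxx
    fitted = h[:, None] * x[None, :]
    centred = log_f - log_f.mean(axis=1, keepdims=True)
    ss_res = np.sum((centred - fitted) ** 2, axis=1)
    ss_tot = np.sum(centred**2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
    return HurstCurve(q_grid=surface.q_grid.copy(), h=h, fit_r2=r2)


def legendre_spectrum(hurst: HurstCurve) -> SingularitySpectrum:
    """tau(q) = q h(q) - 1; alpha = dtau/dq by finite differences;
    f(alpha) = q alpha - tau."""
    q = hurst.q_grid
    if q.size < 3:
        raise ValueError("need at least 3 q points")
    tau = q * hurst.h - 1.0
    alpha = np.gradient(tau, q)  # central differences, one-sided at the ends
    f_alpha = q * alpha - tau
    return SingularitySpectrum(q_grid=q.copy(), tau=tau, alpha=alpha, f_alpha=f_alpha)


def summarize_spectrum(
    spec: SingularitySpectrum,
    d_alpha_formula: str = "arm_asymmetry",
    provenance: dict | None = None,
    mono_tol: float = 1e-12,
) -> StabilitySummary:
    """Generalized fractal parameters of a spectrum.

    ``alpha_0`` is the singularity strength at the apex of ``f(alpha)``;
    ``delta_f = f(alpha_min) - f(alpha_max)`` contrasts the fractal
    dimensions of the strongest- and weakest-fluctuation subsets; the
    stability index is the right-minus-left arm-length difference
    (``"arm_asymmetry"``) or the alternative literal reading
    ``|alpha_max - alpha_0| - alpha_min - alpha_0`` (``"literal"``).
    """
    alpha, f = spec.alpha, spec.f_alpha
    if not (np.all(np.isfinite(alpha)) and np.all(np.isfinite(f))):
        raise ValueError("spectrum contains non-finite values")
    i_min = int(np.argmin(alpha))
    i_max = int(np.argmax(alpha))
    alpha_min = float(alpha[i_min])
    alpha_max = float(alpha[i_max])
    alpha_0 = float(alpha[int(np.argmax(f))])
    delta_alpha = alpha_max - alpha_min
    monofractal = delta_alpha <= mono_tol
    if monofractal:
        delta_alpha = 0.0
        delta_f = 0.0
        d_alpha = 0.0
    else:
        delta_f = float(f[i_min] - f[i_max])
        if d_alpha_formula == "arm_asymmetry":
            d_alpha = abs(alpha_max - alpha_0) - abs(alpha_min - alpha_0)
        elif d_alpha_formula == "literal":
            d_alpha = abs(alpha_max - alpha_0) - alpha_min - alpha_0
        else:
            raise ValueError(f"unknown d_alpha_formula {d_alpha_formula!r}")
    return StabilitySummary(
        alpha_min=alpha_min,
        alpha_max=alpha_max,
        alpha_0=alpha_0,
        delta_alpha=delta_alpha,
        delta_f=delta_f,
        d_alpha=float(d_alpha),
        monofractal=monofractal,
        provenance=provenance or {},
    )


def run_mfdfa(series: Series | np.ndarray, config: MfdfaConfig) -> MfdfaResult:
    """Full MF-DFA of one series: profile -> F_q(s) -> h(q) -> spectrum -> summary.

    Deterministic given (series, config); all intermediates are returned for
    inspection and plotting.
    """
    stage = "profile"
    try:
        profile = build_profile(series)
        if len(profile) < 4 * config.scales.min():
            raise ValueError(
                f"series length {len(profile)} < 4 x smallest scale {config.scales.min()}"
            )
        stage = "fluctuation"
        surface = fluctuation_surface(profile, config)
        stage = "hurst"
        hurst = estimate_hurst(surface)
        stage = "spectrum"
        spectrum = legendre_spectrum(hurst)
        stage = "summary"
        summary = summarize_spectrum(
            spectrum,
            d_alpha_formula=config.d_alpha_formula,
            provenance=config.provenance(),
        )
    except ValueError as err:
        raise ValueError(f"[{stage}] {err}") from err
    return MfdfaResult(surface=surface, hurst=hurst, spectrum=spectrum, summary=summary)
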