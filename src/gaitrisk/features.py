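"""The 30 per-epoch gait characteristics from trunk acceleration.

All estimators operate on one 10-s tri-axial epoch of dynamic (gravity-
removed) acceleration. Undefined characteristics propagate as NaN with a
reason code rather than sentinel numbers, so that percentile summarization
downstream skips them.

Conventions fixed here (all exposed through :class:`FeatureConfig`):

* Spectra are Welch estimates with 5-s Hann windows, 50% overlap, constant
  detrend. Harmonic amplitudes are recovered by integrating spectral energy
  over a small bin neighbourhood around each harmonic, which is insensitive
  to scalloping.
* VT and AP carry their fundamental at the *step* frequency (twice the
  stride frequency); ML is fundamental at the stride frequency.
* Stride regularity is the unbiased normalized autocorrelation at the lag
  nearest one stride, peak-refined within +/- 10% of that lag.
* Sample entropy uses template length m = 5 and tolerance r = 0.3 as a
  fraction of the per-epoch, per-axis SD, with self-matches excluded.
* Local dynamic stability is a Rosenstein-style short-term logarithmic
  divergence rate: delay embedding (dimension 5, delay 10 samples), nearest
  neighbour with one-stride temporal exclusion, least-squares slope of the
  mean log-divergence curve over 0 to 0.5 stride time.
* Gait speed uses the inverted-pendulum model on the doubly integrated,
  high-pass-filtered VT acceleration with a configurable leg length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.spatial.distance import cdist

from .errors import InvalidParameterError
from .types import AXES, AccelEpoch

# ---------------------------------------------------------------------------
# Feature names
# ---------------------------------------------------------------------------

_PER_AXIS = (
    "frequency_variability",
    "stride_regularity",
    "rms",
    "low_frequency_percentage",
    "index_of_harmonicity",
    "harmonic_ratio",
    "local_dynamic_stability",
    "sample_entropy",
    "dominant_frequency_amplitude",
)

#: The 30 gait characteristics, in reporting order.
FEATURE_NAMES = tuple(
    ["gait_speed", "speed_variability", "stride_frequency"]
    + [f"{base}_{ax}" for base in _PER_AXIS for ax in AXES]
)

#: Sign with which each characteristic loads on latent gait quality in the
#: synthetic feature-level cohort (field conventions: better gait is faster,
#: more regular, more symmetric and harmonic, less variable, less entropic,
#: more stable, with stronger dominant-frequency content).
FEATURE_QUALITY_SIGN = {}
for _name in FEATURE_NAMES:
    _base = _name.rsplit("_", 1)[0] if _name.split("_")[-1] in AXES else _name
    FEATURE_QUALITY_SIGN[_name] = {
        "gait_speed": +1,
        "speed_variability": -1,
        "stride_frequency": +1,
        "frequency_variability": -1,
        "stride_regularity": +1,
        "rms": +1,
        "low_frequency_percentage": -1,
        "index_of_harmonicity": +1,
        "harmonic_ratio": +1,
        "local_dynamic_stability": -1,
        "sample_entropy": -1,
        "dominant_frequency_amplitude": +1,
    }[_base]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SampEnParams:
    """Sample-entropy settings: template length and tolerance radius.

    ``r`` is interpreted as a fraction of the per-epoch, per-axis SD.
    """

    m: int = 5
    r: float = 0.3

    def validate(self) -> None:
        if self.m < 1:
            raise InvalidParameterError("m must be >= 1")
        if self.r <= 0:
            raise InvalidParameterError("r must be > 0")


@dataclass
class SpectralParams:
    window_s: float = 5.0
    overlap: float = 0.5


@dataclass
class LdsParams:
    dim: int = 5
    delay: int = 10  # samples
    fit_fraction_of_stride: float = 0.5


@dataclass
class FeatureConfig:
    """All tunable settings of the feature extraction chain."""

    sampen: SampEnParams = field(default_factory=SampEnParams)
    spectral: SpectralParams = field(default_factory=SpectralParams)
    lds: LdsParams = field(default_factory=LdsParams)
    leg_length_m: float = 0.9
    stride_band: tuple = (0.4, 1.6)  # Hz, admissible stride frequencies
    lfp_cutoff_hz: dict = field(
        default_factory=lambda: {"vt": 0.7, "ml": 10.0, "ap": 0.7}
    )
    n_harmonics_hr: int = 20
    hr_cap: float = 20.0
    n_harmonics_ih: int = 5
    fv_window_s: float = 2.5
    peak_power_ratio_min: float = 4.0  # spectral peak vs median-power floor
    min_stride_autocorr: float = 0.2  # autocorrelation confirmation of the peak
    speed_highpass_hz: float = 0.4


def _axis_fundamental(axis: str, f_stride: float) -> float:
    """VT/AP are fundamental at step frequency; ML at stride frequency."""
    return f_stride if axis == "ml" else 2.0 * f_stride


# ---------------------------------------------------------------------------
# Spectral helpers
# ---------------------------------------------------------------------------


def _welch(x: np.ndarray, fs: float, cfg: FeatureConfig):
    nper = min(len(x), int(round(cfg.spectral.window_s * fs)))
    nover = int(nper * cfg.spectral.overlap)
    return sps.welch(x, fs=fs, window="hann", nperseg=nper, noverlap=nover,
                     detrend="constant")


def _amplitude_spectrum(x: np.ndarray, fs: float):
    """Hann-windowed one-sided FFT with energy normalization helpers.

    Returns (freqs, |X|^2, energy_norm) where the amplitude of a sinusoid is
    recovered as ``2*sqrt(sum(|X|^2 over its peak bins) / (N * sum(w^2)))``.
    """
    x = x - x.mean()
    n = len(x)
    w = np.hanning(n)
    X = np.fft.rfft(w * x)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    norm = n * np.sum(w * w)
    return freqs, np.abs(X) ** 2, norm


def _peak_amplitude(pow2: np.ndarray, norm: float, idx: int, half_width: int) -> float:
    lo = max(idx - half_width, 0)
    hi = min(idx + half_width + 1, len(pow2))
    return 2.0 * math.sqrt(float(np.sum(pow2[lo:hi])) / norm)


def _parabolic_refine(f: np.ndarray, p: np.ndarray, idx: int) -> float:
    """Quadratic interpolation of a spectral peak location."""
    if idx <= 0 or idx >= len(p) - 1:
        return float(f[idx])
    y0, y1, y2 = p[idx - 1], p[idx], p[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(f[idx])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    return float(f[idx] + delta * (f[1] - f[0]))


# ---------------------------------------------------------------------------
# Autocorrelation helpers
# ---------------------------------------------------------------------------


def _norm_unbiased_autocorr(x: np.ndarray, lag: int) -> float:
    """Unbiased normalized autocorrelation at one lag (mean removed)."""
    x = x - x.mean()
    n = len(x)
    denom = float(x @ x) / n
    if denom == 0 or lag >= n:
        return math.nan
    c = float(x[: n - lag] @ x[lag:]) / (n - lag)
    return c / denom


def _autocorr_peak(x: np.ndarray, lag: int, rel_window: float = 0.1):
    """Max of the unbiased autocorrelation over lags within +/- rel_window."""
    n = len(x)
    lo = max(int(round(lag * (1 - rel_window))), 1)
    hi = min(int(round(lag * (1 + rel_window))), n - 2)
    if hi < lo:
        return math.nan, lag
    vals = [(_norm_unbiased_autocorr(x, k), k) for k in range(lo, hi + 1)]
    best = max(vals, key=lambda t: t[0])
    return best


# ---------------------------------------------------------------------------
# Individual characteristics
# ---------------------------------------------------------------------------


def stride_frequency(epoch: AccelEpoch, config: FeatureConfig | None = None) -> float:
    """Stride frequency (Hz) from the VT spectrum, autocorrelation-confirmed.

    The dominant Welch peak of VT is located in the step band (twice the
    configured stride band). By default that peak is read as the step
    frequency and halved; when the peak could itself be the stride
    fundamental (strong odd-harmonic content in markedly asymmetric gait),
    the two readings are disambiguated by the unbiased autocorrelation at
    the would-be step lag — a genuine step periodicity correlates
    positively there, whereas a stride fundamental does not. The estimate
    is accepted only if the peak rises sufficiently above the spectral
    floor and the autocorrelation near one stride lag confirms
    periodicity; otherwise NaN (feature-undefined signal, dropped
    downstream).
    """
    cfg = config or FeatureConfig()
    fs = epoch.sample_rate
    x = epoch.vt - epoch.vt.mean()
    if np.all(x == 0):
        return math.nan
    f, p = _welch(x, fs, cfg)
    lo, hi = 2.0 * cfg.stride_band[0], 2.0 * cfg.stride_band[1]
    band = (f >= lo) & (f <= hi)
    if not np.any(band):
        return math.nan
    floor = float(np.median(p[f >= 0.1]))
    bidx = np.flatnonzero(band)
    pk = bidx[int(np.argmax(p[band]))]
    if floor > 0 and p[pk] / floor < cfg.peak_power_ratio_min:
        return math.nan
    f_dom = _parabolic_refine(f, p, pk)
    f_str = f_dom / 2.0
    if f_dom <= cfg.stride_band[1]:
        # ambiguous: f_dom may be the stride fundamental itself
        ac_step, _ = _autocorr_peak(x, int(round(fs / (2.0 * f_dom))))
        if not (np.isfinite(ac_step) and ac_step >= cfg.min_stride_autocorr):
            f_str = f_dom
    lag = int(round(fs / f_str))
    ac, _ = _autocorr_peak(x, lag)
    if not np.isfinite(ac) or ac < cfg.min_stride_autocorr:
        return math.nan
    return f_str


def rms(signal: np.ndarray) -> float:
    """Root-mean-square of the mean-removed signal (m/s^2)."""
    x = np.asarray(signal, dtype=float)
    x = x - x.mean()
    return float(np.sqrt(np.mean(x * x)))


def stride_regularity(signal: np.ndarray, stride_lag: int) -> float:
    """Unbiased normalized autocorrelation at the stride lag (peak-refined)."""
    x = np.asarray(signal, dtype=float)
    if stride_lag >= len(x) // 2 or stride_lag < 1:
        return math.nan
    val, _ = _autocorr_peak(x, stride_lag)
    return float(val)


def low_frequency_percentage(
    signal: np.ndarray, fs: float, cutoff: float, config: FeatureConfig | None = None
) -> float:
    """Percent of spectral power below ``cutoff``, within 0.1 Hz to Nyquist.

    Uses a full-epoch Hann periodogram rather than the shorter Welch
    segments: the sub-Hz band needs the finest frequency resolution the
    epoch affords, and a power *fraction* does not benefit from Welch's
    variance reduction.
    """
    cfg = config or FeatureConfig()
    if cutoff >= fs / 2:
        raise InvalidParameterError("cutoff must be below Nyquist")
    x = np.asarray(signal, dtype=float)
    f, p = sps.periodogram(x - x.mean(), fs=fs, window="hann")
    band = f >= 0.1
    total = float(np.sum(p[band]))
    if total == 0:
        return math.nan
    low = float(np.sum(p[band & (f < cutoff)]))
    return 100.0 * low / total


def index_of_harmonicity(
    signal: np.ndarray, fs: float, fundamental: float,
    config: FeatureConfig | None = None,
) -> float:
    """Power at the fundamental over power summed across it and 5 harmonics.

    Powers are integrated over +/- 1 spectral bin around each harmonic of the
    Welch spectrum. 1.0 means all harmonic power sits at the fundamental.
    """
    cfg = config or FeatureConfig()
    f, p = _welch(np.asarray(signal, dtype=float), fs, cfg)
    df = f[1] - f[0]
    powers = []
    for h in range(1, cfg.n_harmonics_ih + 2):
        fh = h * fundamental
        if fh >= fs / 2:
            break
        i = int(round(fh / df))
        lo, hi = max(i - 1, 0), min(i + 2, len(p))
        powers.append(float(np.sum(p[lo:hi])))
    if not powers or sum(powers) == 0:
        return math.nan
    return powers[0] / sum(powers)


def harmonic_ratio(
    signal: np.ndarray, fs: float, stride_freq: float, axis: str,
    config: FeatureConfig | None = None,
) -> tuple[float, bool]:
    """Even/odd stride-harmonic amplitude ratio (odd/even on ML).

    Amplitudes of the first 20 stride harmonics are recovered by integrating
    FFT energy over +/- 1 bin around each harmonic. For VT/AP the in-phase
    (step-symmetric) content lies at even multiples of the stride frequency,
    so the ratio is even/odd; ML is fundamental at the stride frequency and
    the convention inverts. A vanishing denominator is capped at the
    configured maximum; the second return value flags that cap.
    """
    cfg = config or FeatureConfig()
    freqs, pow2, norm = _amplitude_spectrum(np.asarray(signal, dtype=float), fs)
    df = freqs[1] - freqs[0]
    even_sum = odd_sum = 0.0
    for k in range(1, cfg.n_harmonics_hr + 1):
        fh = k * stride_freq
        if fh >= fs / 2:
            break
        i = int(round(fh / df))
        amp = _peak_amplitude(pow2, norm, i, 1)
        if k % 2 == 0:
            even_sum += amp
        else:
            odd_sum += amp
    num, den = (even_sum, odd_sum) if axis != "ml" else (odd_sum, even_sum)
    if den <= 1e-6 * max(num, 1e-300) or num / den >= cfg.hr_cap:
        return cfg.hr_cap, True
    return num / den, False


def frequency_variability(
    signal: np.ndarray, fs: float, band: tuple,
    config: FeatureConfig | None = None,
) -> float:
    """CV of the instantaneous dominant frequency across 2.5-s sub-windows.

    Sub-windows overlap by 50%; the dominant frequency of each is located in
    ``band`` on a zero-padded Hann periodogram with parabolic refinement.
    Undefined with fewer than 3 sub-windows.
    """
    cfg = config or FeatureConfig()
    x = np.asarray(signal, dtype=float)
    n = len(x)
    win = int(round(cfg.fv_window_s * fs))
    step = win // 2
    if win < 8 or n < win:
        return math.nan
    starts = range(0, n - win + 1, step)
    freqs_found = []
    w = np.hanning(win)
    nfft = max(4096, win)
    fgrid = np.fft.rfftfreq(nfft, d=1.0 / fs)
    sel = (fgrid >= band[0]) & (fgrid <= band[1])
    if not np.any(sel):
        return math.nan
    for s in starts:
        seg = x[s : s + win]
        seg = seg - seg.mean()
        spec = np.abs(np.fft.rfft(w * seg, n=nfft)) ** 2
        sub = spec[sel]
        if np.all(sub == 0):
            continue
        i_local = int(np.argmax(sub))
        i = np.flatnonzero(sel)[i_local]
        freqs_found.append(_parabolic_refine(fgrid, spec, i))
    if len(freqs_found) < 3:
        return math.nan
    arr = np.asarray(freqs_found)
    mean = arr.mean()
    if mean == 0:
        return math.nan
    return float(arr.std(ddof=0) / mean)


def local_dynamic_stability(
    signal: np.ndarray, fs: float, stride_samples: int,
    config: FeatureConfig | None = None,
) -> float:
    """Short-term logarithmic divergence rate (1/s); higher = less stable.

    Rosenstein-style: delay embedding, nearest neighbour under a one-stride
    temporal exclusion, mean log Euclidean divergence, least-squares slope
    over 0 to ``fit_fraction_of_stride`` stride times.
    """
    cfg = config or FeatureConfig()
    x = np.asarray(signal, dtype=float)
    n = len(x)
    dim, delay = cfg.lds.dim, cfg.lds.delay
    m_pts = n - (dim - 1) * delay
    if n < 500 or m_pts < 5 * stride_samples:
        return math.nan
    emb = np.column_stack([x[i * delay : i * delay + m_pts] for i in range(dim)])
    dists = cdist(emb, emb)
    idx = np.arange(m_pts)
    excl = np.abs(idx[:, None] - idx[None, :]) < stride_samples
    dists[excl] = np.inf
    k_max = int(round(cfg.lds.fit_fraction_of_stride * stride_samples))
    horizon = m_pts - k_max - 1
    if horizon < 10:
        return math.nan
    # neighbours must leave room to track divergence for k_max steps
    nn = np.argmin(dists[:horizon, :horizon], axis=1)
    valid = np.isfinite(dists[np.arange(horizon), nn])
    if valid.sum() < 10:
        return math.nan
    ii = np.arange(horizon)[valid]
    jj = nn[valid]
    log_div = np.empty(k_max + 1)
    for k in range(k_max + 1):
        d = np.linalg.norm(emb[ii + k] - emb[jj + k], axis=1)
        log_div[k] = float(np.mean(np.log(np.maximum(d, 1e-12))))
    t = np.arange(k_max + 1) / fs
    slope = float(np.polyfit(t, log_div, 1)[0])
    return slope


def sample_entropy(signal: np.ndarray, params: SampEnParams | None = None) -> float:
    """Sample entropy: -ln(A/B) with Chebyshev tolerance r * SD, no self-matches.

    B counts template pairs of length m within tolerance, A the same at
    length m+1, over the first ``N - m`` templates (the Richman-Moorman
    convention, so both counts range over the same template set). A constant
    signal returns 0 (every pair matches at both lengths). If A or B is
    zero the feature is undefined (NaN), not infinite.
    """
    p = params or SampEnParams()
    p.validate()
    x = np.asarray(signal, dtype=float)
    n = len(x)
    m = p.m
    if n <= m + 1:
        return math.nan
    sd = float(x.std(ddof=0))
    if sd == 0.0:
        return 0.0
    r_abs = p.r * sd
    # pairwise Chebyshev matches of length-m templates, built by AND-ing the
    # pointwise match matrix along m (then m+1) diagonal shifts
    close = np.abs(x[:, None] - x[None, :]) <= r_abs
    nt = n - m  # templates 0 .. n-m-1 for both lengths
    match_m = close[:nt, :nt].copy()
    for k in range(1, m):
        match_m &= close[k : k + nt, k : k + nt]
    b_count = (int(np.count_nonzero(match_m)) - nt) // 2  # no self-matches
    match_m &= close[m:n, m:n]
    a_count = (int(np.count_nonzero(match_m)) - nt) // 2
    if a_count <= 0 or b_count <= 0:
        return math.nan
    return float(-np.log(a_count / b_count))


def dominant_frequency_amplitude(
    signal: np.ndarray, fs: float, fundamental: float,
    config: FeatureConfig | None = None,
) -> float:
    """Amplitude (m/s^2, not power) of the spectral peak at the fundamental.

    The peak is searched within +/- 30% of the axis-appropriate fundamental
    and its amplitude recovered by integrating windowed-FFT energy over
    +/- 3 bins, which corrects for window gain and scalloping.
    """
    cfg = config or FeatureConfig()
    freqs, pow2, norm = _amplitude_spectrum(np.asarray(signal, dtype=float), fs)
    band = (freqs >= 0.7 * fundamental) & (freqs <= 1.3 * fundamental)
    if not np.any(band):
        return math.nan
    bidx = np.flatnonzero(band)
    pk = bidx[int(np.argmax(pow2[band]))]
    return _peak_amplitude(pow2, norm, pk, 3)


def gait_speed_and_variability(
    epoch: AccelEpoch, f_stride: float, config: FeatureConfig | None = None
) -> tuple[float, float]:
    """Inverted-pendulum gait speed (m/s) and per-step speed SD.

    VT acceleration is doubly integrated to vertical displacement in the
    frequency domain (spectral division by -omega^2, with content below the
    configured high-pass cutoff zeroed to suppress drift); the per-step
    vertical excursion h gives step length 2*sqrt(2*l*h - h^2) with leg
    length l; speed is mean step length times step frequency, and
    variability the SD of per-step speeds. Edge steps are discarded
    (integration edge effects).
    """
    cfg = config or FeatureConfig()
    fs = epoch.sample_rate
    x = epoch.vt - epoch.vt.mean()
    if np.all(x == 0):
        return 0.0, 0.0
    f_step = 2.0 * f_stride
    X = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    omega2 = (2.0 * math.pi * freqs) ** 2
    D = np.zeros_like(X)
    keep = freqs >= cfg.speed_highpass_hz
    D[keep] = -X[keep] / omega2[keep]
    disp = np.fft.irfft(D, n=len(x))
    step_len_samples = fs / f_step
    n_steps = int(len(x) / step_len_samples)
    if n_steps < 4:
        return math.nan, math.nan
    leg = cfg.leg_length_m
    speeds = []
    for s in range(1, n_steps - 1):  # drop first and last step windows
        lo = int(round(s * step_len_samples))
        hi = int(round((s + 1) * step_len_samples))
        seg = disp[lo:hi]
        h = float(seg.max() - seg.min())
        h = min(h, 2.0 * leg)
        step_length = 2.0 * math.sqrt(max(2.0 * leg * h - h * h, 0.0))
        speeds.append(step_length * f_step)
    speeds = np.asarray(speeds)
    return float(speeds.mean()), float(speeds.std(ddof=1))


# ---------------------------------------------------------------------------
# Full vector
# ---------------------------------------------------------------------------


def extract_features(
    epoch: AccelEpoch, config: FeatureConfig | None = None
) -> tuple[dict, dict]:
    """Compute all 30 characteristics (+ stride_time) for one epoch.

    Returns ``(values, reasons)``: a dict of floats with NaN for undefined
    characteristics, and a dict mapping each undefined name to a reason code
    (``stride_undefined``, ``zero_variance``, ``no_matches`` ...).
    """
    cfg = config or FeatureConfig()
    epoch.validate()
    values: dict[str, float] = {name: math.nan for name in FEATURE_NAMES}
    values["stride_time"] = math.nan
    reasons: dict[str, str] = {}

    axis_sig = {ax: epoch.axis(ax) - epoch.axis(ax).mean() for ax in AXES}
    axis_ok = {ax: float(axis_sig[ax].std(ddof=0)) > 0 for ax in AXES}

    for ax in AXES:
        values[f"rms_{ax}"] = rms(axis_sig[ax])

    f_str = stride_frequency(epoch, cfg)
    stride_ok = np.isfinite(f_str)
    if stride_ok:
        values["stride_frequency"] = f_str
        values["stride_time"] = 1.0 / f_str
    else:
        reasons["stride_frequency"] = "stride_undefined"
        reasons["stride_time"] = "stride_undefined"

    fs = epoch.sample_rate
    for ax in AXES:
        x = axis_sig[ax]
        if not axis_ok[ax]:
            for base in _PER_AXIS:
                if base != "rms":
                    reasons[f"{base}_{ax}"] = "zero_variance"
            continue
        cutoff = cfg.lfp_cutoff_hz[ax]
        if cutoff < fs / 2:
            values[f"low_frequency_percentage_{ax}"] = low_frequency_percentage(
                x, fs, cutoff, cfg
            )
        else:
            reasons[f"low_frequency_percentage_{ax}"] = "cutoff_above_nyquist"
        se = sample_entropy(x, cfg.sampen)
        if np.isfinite(se):
            values[f"sample_entropy_{ax}"] = se
        else:
            reasons[f"sample_entropy_{ax}"] = "no_matches"
        if not stride_ok:
            for base in (
                "frequency_variability",
                "stride_regularity",
                "index_of_harmonicity",
                "harmonic_ratio",
                "local_dynamic_stability",
                "dominant_frequency_amplitude",
            ):
                reasons[f"{base}_{ax}"] = "stride_undefined"
            continue
        fund = _axis_fundamental(ax, f_str)
        stride_lag = int(round(fs / f_str))
        values[f"stride_regularity_{ax}"] = stride_regularity(x, stride_lag)
        values[f"index_of_harmonicity_{ax}"] = index_of_harmonicity(x, fs, fund, cfg)
        hr, capped = harmonic_ratio(x, fs, f_str, ax, cfg)
        values[f"harmonic_ratio_{ax}"] = hr
        if capped:
            reasons[f"harmonic_ratio_{ax}"] = "zero_denominator_capped"
        if ax == "ml":
            band = (cfg.stride_band[0], cfg.stride_band[1])
        else:
            band = (2.0 * cfg.stride_band[0], 2.0 * cfg.stride_band[1])
        values[f"frequency_variability_{ax}"] = frequency_variability(x, fs, band, cfg)
        values[f"local_dynamic_stability_{ax}"] = local_dynamic_stability(
            x, fs, stride_lag, cfg
        )
        values[f"dominant_frequency_amplitude_{ax}"] = dominant_frequency_amplitude(
            x, fs, fund, cfg
        )

    if stride_ok and axis_ok["vt"]:
        speed, var = gait_speed_and_variability(epoch, f_str, cfg)
        values["gait_speed"] = speed
        values["speed_variability"] = var
    else:
        reasons["gait_speed"] = "stride_undefined"
        reasons["speed_variability"] = "stride_undefined"

    for name, v in values.items():
        if not np.isfinite(v):
            reasons.setdefault(name, "undefined")
    return values, reasons


def extract_features_table(
    epochs, config: FeatureConfig | None = None
) -> pd.DataFrame:
    """Per-epoch feature rows for an iterable of epochs.

    Columns: participant_id, epoch_id, the 30 characteristics, stride_time,
    and a semicolon-joined ``undefined_reasons`` column.
    """
    cfg = config or FeatureConfig()
    rows = []
    for ep in epochs:
        values, reasons = extract_features(ep, cfg)
        row = {
            "participant_id": ep.participant_id,
            "epoch_id": ep.epoch_id,
            **values,
            "undefined_reasons": ";".join(
                f"{k}:{v}" for k, v in sorted(reasons.items())
            ),
        }
        rows.append(row)
    return pd.DataFrame(rows)
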