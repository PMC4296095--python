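"""Synthetic gait signals and cohorts with known generative structure.

Two generators are provided, both first-class:

* **Signal level** (:func:`synth_cohort`): every participant gets raw
  tri-axial acceleration epochs built from a stride-harmonic model whose
  degradation parameters (noise, frequency jitter, asymmetry) are driven by a
  latent gait-quality scalar. This is the substrate for testing the feature
  extraction chain end to end.
* **Feature level** (:func:`synth_feature_cohort`): epoch-level values of the
  30 gait characteristics are drawn from a hierarchical Gaussian model
  (participant mean driven by latent quality; participant-specific epoch
  dispersion driven by a second latent), summarized into 10th/50th/90th
  percentiles, and the fall outcome is drawn from a logistic model on the
  z-scaled realized columns. This makes coefficient-recovery and permutation
  studies exact and cheap at study scale (hundreds of participants).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ConfigurationError, InvalidParameterError
from .types import AXES, AccelEpoch

# ---------------------------------------------------------------------------
# Signal model
# ---------------------------------------------------------------------------

#: Default stride-harmonic amplitudes (m/s^2) at even multiples of the stride
#: frequency (2f, 4f, 6f, 8f). On VT/AP these carry the step-periodic (gait
#: symmetric) content; on ML they are the asymmetry-scaled part.
DEFAULT_EVEN_AMPLITUDES = {
    "vt": (1.6, 0.50, 0.22, 0.10),
    "ml": (0.40, 0.15, 0.06, 0.03),
    "ap": (1.00, 0.35, 0.15, 0.06),
}

#: Amplitudes at odd multiples (1f, 3f, 5f, 7f). On VT/AP these are scaled by
#: the asymmetry parameter; on ML the stride-periodic content is fundamental.
DEFAULT_ODD_AMPLITUDES = {
    "vt": (0.90, 0.35, 0.15, 0.06),
    "ml": (0.80, 0.30, 0.12, 0.05),
    "ap": (0.70, 0.28, 0.12, 0.05),
}

# Fixed per-harmonic phase offsets (radians), shared across axes, to avoid an
# artificially cosine-aligned waveform.
_HARMONIC_PHASES = (0.0, 0.9, 1.7, 2.6)


def vt_amplitude_for_excursion(excursion_m: float, stride_frequency: float) -> float:
    """VT acceleration amplitude at step frequency for a given vertical excursion.

    A sinusoidal vertical centre-of-mass displacement with peak-to-peak
    excursion ``h`` at step frequency ``2 f_stride`` has acceleration
    amplitude ``(h/2) * (2*pi*2*f_stride)**2``. Used to plant a known ground
    truth for the inverted-pendulum gait-speed estimator.
    """
    omega = 2.0 * math.pi * 2.0 * stride_frequency
    return 0.5 * excursion_m * omega**2


@dataclass
class GaitSignalParams:
    """Parameters of the stride-harmonic acceleration model for one epoch.

    The signal on each axis is a sum of four even and four odd stride
    harmonics with phase-continuous frequency wander (an Ornstein-Uhlenbeck
    walk of the instantaneous stride frequency, relaxation time 1 s) plus
    additive white noise. ``asymmetry`` scales the odd harmonics on VT/AP and
    the even harmonics on ML, so that increasing it degrades the step
    symmetry that the harmonic ratio measures.
    """

    stride_frequency: float = 1.0  # Hz, typical 0.8-1.2
    harmonic_amplitudes_even: dict = field(
        default_factory=lambda: {a: DEFAULT_EVEN_AMPLITUDES[a] for a in AXES}
    )
    harmonic_amplitudes_odd: dict = field(
        default_factory=lambda: {a: DEFAULT_ODD_AMPLITUDES[a] for a in AXES}
    )
    asymmetry: float = 0.5  # dimensionless >= 0
    freq_jitter_sd: float = 0.02  # Hz, stationary SD of instantaneous frequency
    noise_sd: float = 0.25  # m/s^2 additive white noise
    epoch_duration: float = 10.0  # s
    sample_rate: float = 100.0  # Hz
    jitter_relaxation_s: float = 1.0  # OU relaxation time of frequency wander

    def validate(self) -> None:
        if self.sample_rate <= 0 or self.epoch_duration <= 0:
            raise InvalidParameterError("sample_rate and epoch_duration must be positive")
        n = self.sample_rate * self.epoch_duration
        if abs(n - round(n)) > 1e-9:
            raise InvalidParameterError(
                "sample_rate * epoch_duration must be an integer sample count"
            )
        if self.stride_frequency <= 0:
            raise InvalidParameterError("stride_frequency must be positive")
        if self.asymmetry < 0 or self.freq_jitter_sd < 0 or self.noise_sd < 0:
            raise InvalidParameterError("asymmetry and noise terms must be >= 0")
        for d in (self.harmonic_amplitudes_even, self.harmonic_amplitudes_odd):
            for ax in AXES:
                if any(a < 0 for a in d[ax]):
                    raise InvalidParameterError("harmonic amplitudes must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.sample_rate * self.epoch_duration))


def _instantaneous_frequency(
    params: GaitSignalParams, rng: np.random.Generator, n: int
) -> np.ndarray:
    """OU walk of the instantaneous stride frequency, stationary SD = jitter."""
    f0, sd = params.stride_frequency, params.freq_jitter_sd
    if sd == 0.0:
        return np.full(n, f0)
    dt = 1.0 / params.sample_rate
    a = math.exp(-dt / params.jitter_relaxation_s)
    innov_sd = sd * math.sqrt(1.0 - a * a)
    e = rng.normal(0.0, innov_sd, n)
    e[0] = rng.normal(0.0, sd)  # start in the stationary distribution
    from scipy.signal import lfilter

    dev = lfilter([1.0], [1.0, -a], e)
    return f0 + dev


def synth_gait_epoch(params: GaitSignalParams, seed: int) -> AccelEpoch:
    """Generate one gait-like tri-axial acceleration epoch.

    Deterministic given ``(params, seed)``. With all stochastic terms zero
    the signal is exactly periodic (period ``1/stride_frequency`` on VT/AP
    when asymmetry > 0; ``1/(2 f)`` when the odd content vanishes).
    """
    params.validate()
    n = params.n_samples
    deterministic = params.noise_sd == 0.0 and params.freq_jitter_sd == 0.0
    rng = np.random.default_rng(seed)

    if deterministic:
        t = np.arange(n) / params.sample_rate
        theta = 2.0 * math.pi * params.stride_frequency * t
    else:
        f_inst = _instantaneous_frequency(params, rng, n)
        # phase-continuous advance; theta[0] = 0
        theta = 2.0 * math.pi * (np.cumsum(f_inst) - f_inst[0]) / params.sample_rate

    signals = {}
    for ax in AXES:
        even = np.asarray(params.harmonic_amplitudes_even[ax], dtype=float)
        odd = np.asarray(params.harmonic_amplitudes_odd[ax], dtype=float)
        if ax == "ml":
            odd_eff, even_eff = odd, params.asymmetry * even
        else:
            odd_eff, even_eff = params.asymmetry * odd, even
        x = np.zeros(n)
        for i, amp in enumerate(even_eff):
            k = 2 * (i + 1)
            if amp > 0:
                x += amp * np.sin(k * theta + _HARMONIC_PHASES[i])
        for i, amp in enumerate(odd_eff):
            k = 2 * i + 1
            if amp > 0:
                x += amp * np.sin(k * theta + _HARMONIC_PHASES[i] + 0.4)
        signals[ax] = x
    if not deterministic and params.noise_sd > 0:
        for ax in AXES:
            signals[ax] = signals[ax] + rng.normal(0.0, params.noise_sd, n)

    return AccelEpoch(
        vt=signals["vt"], ml=signals["ml"], ap=signals["ap"],
        sample_rate=params.sample_rate,
    )


# ---------------------------------------------------------------------------
# Shared questionnaire / activity model
# ---------------------------------------------------------------------------

ACTIVITY_NAMES = (
    "lying_duration",
    "sitting_duration",
    "standing_duration",
    "locomotion_duration",
    "shuffling_duration",
    "n_transitions",
    "n_steps",
)

# (mean, sd, loading of latent quality in units of sd). Durations in h/day,
# transitions and steps in counts/day. Plausible for community-dwelling older
# adults wearing the device a full week.
_ACTIVITY_MODEL = {
    "lying_duration": (9.0, 1.2, 0.15),
    "sitting_duration": (5.5, 1.3, -0.10),
    "standing_duration": (3.0, 1.0, 0.0),
    "locomotion_duration": (1.3, 0.5, 0.25),
    "shuffling_duration": (0.25, 0.10, -0.10),
    "n_transitions": (55.0, 15.0, 0.0),
    "n_steps": (6500.0, 2500.0, 0.25),
}

QUESTIONNAIRE_NAMES = ("fall_history", "gds")


def _draw_questionnaire_activities(
    rng: np.random.Generator,
    quality: np.ndarray,
    questionnaire_quality_loading: float = 0.45,
    activity_quality_loading: float = 1.0,
) -> pd.DataFrame:
    """Fall history, GDS and the 7 activity amounts, loaded on latent quality."""
    n = len(quality)
    fall_history = (
        rng.random(n) < expit(-0.85 - questionnaire_quality_loading * quality)
    ).astype(int)
    gds = np.clip(
        rng.normal(3.0 - 1.5 * questionnaire_quality_loading * quality, 2.2), 0.0, 15.0
    )
    cols = {"fall_history": fall_history, "gds": gds}
    for name, (mu, sd, load) in _ACTIVITY_MODEL.items():
        x = rng.normal(mu + activity_quality_loading * load * sd * quality, sd, n)
        cols[name] = np.clip(x, 0.0, None)
    return pd.DataFrame(cols)


def _draw_outcome(
    rng: np.random.Generator,
    table: pd.DataFrame,
    coefficients: dict[str, float],
    intercept: float | None,
    faller_fraction_target: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Bernoulli fall outcome from a logistic model on z-scaled columns."""
    unknown = sorted(set(coefficients) - set(table.columns))
    if unknown:
        raise ConfigurationError(
            f"outcome_coefficients reference unknown features: {unknown}"
        )
    if intercept is None:
        intercept = float(logit(faller_fraction_target))
    eta = np.full(len(table), intercept)
    for name, beta in coefficients.items():
        col = table[name].to_numpy(dtype=float)
        sd = col.std(ddof=0)
        if sd == 0:
            raise ConfigurationError(f"outcome feature {name!r} has zero variance")
        eta += beta * (col - col.mean()) / sd
    prob = expit(eta)
    y = (rng.random(len(table)) < prob).astype(int)
    return y, prob, intercept


# ---------------------------------------------------------------------------
# Signal-level cohort
# ---------------------------------------------------------------------------

#: Generative per-participant parameters the signal-level outcome model may use.
GENERATIVE_FEATURES = (
    "noise_sd",
    "freq_jitter_sd",
    "asymmetry",
    "stride_frequency",
    "vertical_excursion",
) + QUESTIONNAIRE_NAMES + ACTIVITY_NAMES


@dataclass
class CohortParams:
    """Configuration of a signal-level synthetic cohort.

    The cohort shape defaults to the study population this package emulates:
    202 community-dwelling older adults of whom roughly 35% fall at least
    once during 6 months of follow-up. Fall outcomes are drawn from a
    logistic model on z-scaled per-participant generative parameters (see
    ``GENERATIVE_FEATURES``), so ground truth is known exactly.
    """

    n_participants: int = 202
    faller_fraction_target: float = 0.35
    epochs_per_participant: int = 20
    outcome_coefficients: dict = field(default_factory=dict)
    outcome_intercept: float | None = None
    epoch_duration: float = 10.0
    sample_rate: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 2:
            raise InvalidParameterError("n_participants must be >= 2")
        if self.epochs_per_participant < 10:
            raise InvalidParameterError(
                "epochs_per_participant must be >= 10 (percentiles need support)"
            )
        if not 0.0 < self.faller_fraction_target < 1.0:
            raise InvalidParameterError("faller_fraction_target must be in (0, 1)")


@dataclass
class ParticipantWeek:
    """One participant's week: epochs + activity amounts + questionnaire + outcome."""

    participant_id: str
    epochs: list
    fall_history: int
    gds: float
    activities: dict
    faller: int


@dataclass
class GroundTruth:
    """Generative truth returned alongside a synthetic cohort."""

    coefficients: dict
    intercept: float
    latent_quality: np.ndarray
    probabilities: np.ndarray
    participant_table: pd.DataFrame


def _quality_to_signal_params(
    q: float, base: GaitSignalParams
) -> tuple[GaitSignalParams, float]:
    """Map a latent quality scalar to per-participant signal parameters.

    Lower quality means more noise, more frequency wander, more asymmetry,
    slightly lower stride frequency and a smaller vertical excursion (hence
    lower gait speed). Returns the params and the vertical excursion (m).
    """
    noise = float(np.clip(0.25 - 0.08 * q, 0.05, 0.60))
    jitter = float(np.clip(0.020 - 0.008 * q, 0.003, 0.060))
    asym = float(np.clip(0.5 - 0.15 * q, 0.05, 1.20))
    f_stride = float(np.clip(1.0 + 0.05 * q, 0.75, 1.25))
    excursion = float(np.clip(0.022 + 0.004 * q, 0.008, 0.040))
    even = {a: list(base.harmonic_amplitudes_even[a]) for a in AXES}
    amp0 = vt_amplitude_for_excursion(excursion, f_stride)
    scale = amp0 / even["vt"][0]
    even["vt"] = [v * scale for v in even["vt"]]
    p = replace(
        base,
        stride_frequency=f_stride,
        harmonic_amplitudes_even={a: tuple(even[a]) for a in AXES},
        noise_sd=noise,
        freq_jitter_sd=jitter,
        asymmetry=asym,
    )
    return p, excursion


def _synth_week_epochs(
    pid: str,
    base_params: GaitSignalParams,
    n_epochs: int,
    rng: np.random.Generator,
) -> list:
    """Epochs for one participant-week with mild epoch-to-epoch variation."""
    epochs = []
    for e in range(n_epochs):
        p = replace(
            base_params,
            noise_sd=base_params.noise_sd * float(rng.lognormal(0.0, 0.15)),
            freq_jitter_sd=base_params.freq_jitter_sd * float(rng.lognormal(0.0, 0.15)),
            asymmetry=base_params.asymmetry * float(rng.lognormal(0.0, 0.10)),
            stride_frequency=float(
                np.clip(base_params.stride_frequency + rng.normal(0.0, 0.02), 0.5, 1.5)
            ),
        )
        seed = int(rng.integers(0, 2**31 - 1))
        ep = synth_gait_epoch(p, seed)
        ep.participant_id = pid
        ep.epoch_id = f"{pid}_e{e:03d}"
        epochs.append(ep)
    return epochs


def _synth_cohort_impl(
    cohort: CohortParams, n_weeks: int
) -> tuple[list[list[ParticipantWeek]], GroundTruth]:
    cohort.validate()
    rng = np.random.default_rng(cohort.seed)
    n = cohort.n_participants
    q = rng.standard_normal(n)
    qa = _draw_questionnaire_activities(rng, q)

    base = GaitSignalParams(
        epoch_duration=cohort.epoch_duration, sample_rate=cohort.sample_rate
    )
    rows = []
    participant_params = []
    for i in range(n):
        p, excursion = _quality_to_signal_params(q[i], base)
        participant_params.append(p)
        rows.append(
            {
                "noise_sd": p.noise_sd,
                "freq_jitter_sd": p.freq_jitter_sd,
                "asymmetry": p.asymmetry,
                "stride_frequency": p.stride_frequency,
                "vertical_excursion": excursion,
            }
        )
    table = pd.concat([pd.DataFrame(rows), qa], axis=1)
    y, prob, intercept = _draw_outcome(
        rng, table, cohort.outcome_coefficients, cohort.outcome_intercept,
        cohort.faller_fraction_target,
    )
    table = table.assign(faller=y, latent_quality=q)
    table.insert(0, "participant_id", [f"p{i:04d}" for i in range(n)])

    weeks: list[list[ParticipantWeek]] = [[] for _ in range(n_weeks)]
    for i in range(n):
        pid = f"p{i:04d}"
        for w in range(n_weeks):
            epochs = _synth_week_epochs(
                pid, participant_params[i], cohort.epochs_per_participant, rng
            )
            weeks[w].append(
                ParticipantWeek(
                    participant_id=pid,
                    epochs=epochs,
                    fall_history=int(qa["fall_history"][i]),
                    gds=float(qa["gds"][i]),
                    activities={a: float(qa[a][i]) for a in ACTIVITY_NAMES},
                    faller=int(y[i]),
                )
            )
    truth = GroundTruth(
        coefficients=dict(cohort.outcome_coefficients),
        intercept=intercept,
        latent_quality=q,
        probabilities=prob,
        participant_table=table,
    )
    return weeks, truth


def synth_cohort(cohort: CohortParams) -> tuple[list[ParticipantWeek], GroundTruth]:
    """Generate a signal-level cohort: one week of epochs per participant."""
    weeks, truth = _synth_cohort_impl(cohort, n_weeks=1)
    return weeks[0], truth


def synth_two_weeks(
    cohort: CohortParams,
) -> tuple[list[ParticipantWeek], list[ParticipantWeek], GroundTruth]:
    """Two weeks sharing each participant's latent quality, fresh epoch noise.

    The substrate for between-weeks ICC reliability checks.
    """
    weeks, truth = _synth_cohort_impl(cohort, n_weeks=2)
    return weeks[0], weeks[1], truth


def cohort_table(week: list[ParticipantWeek]) -> pd.DataFrame:
    """Questionnaire/activity/outcome table for a signal-level cohort week."""
    rows = []
    for pw in week:
        row = {
            "participant_id": pw.participant_id,
            "fall_history": pw.fall_history,
            "gds": pw.gds,
            "faller": pw.faller,
        }
        row.update(pw.activities)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Feature-level cohort
# ---------------------------------------------------------------------------

from .features import FEATURE_NAMES, FEATURE_QUALITY_SIGN  # noqa: E402


@dataclass
class FeatureCohortParams:
    """Configuration of a feature-level (tabular) synthetic cohort.

    Epoch-level values of each gait characteristic are drawn, on a
    standardized scale, from::

        x[i, e, f] = load_f * q_i + b[i, f] + sigma_i * eps[i, e, f]
        sigma_i    = epoch_sd * exp(dispersion_tau * w_i)

    with latent quality ``q_i ~ N(0,1)``, latent dispersion ``w_i ~ N(0,1)``,
    participant noise ``b ~ N(0, participant_noise_sd^2)``. ``load_f`` carries
    the field's sign conventions (e.g. entropy loads negatively on quality).
    The heteroscedastic dispersion is what makes the 10th/90th percentiles
    carry information beyond the median, mirroring the situational
    variability the percentile extremes are meant to capture. Fall outcomes
    come from a logistic model on z-scaled realized summary columns.
    """

    n_participants: int = 202
    faller_fraction_target: float = 0.35
    epochs_per_participant: int = 50
    quality_loading: float = 0.6
    participant_noise_sd: float = 0.8
    epoch_sd: float = 1.0
    dispersion_tau: float = 0.35
    questionnaire_quality_loading: float = 0.45
    activity_quality_loading: float = 1.0
    outcome_coefficients: dict = field(default_factory=dict)
    outcome_intercept: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 2:
            raise InvalidParameterError("n_participants must be >= 2")
        if self.epochs_per_participant < 10:
            raise InvalidParameterError("epochs_per_participant must be >= 10")
        if not 0.0 < self.faller_fraction_target < 1.0:
            raise InvalidParameterError("faller_fraction_target must be in (0, 1)")


@dataclass
class FeatureCohortTruth:
    """Ground truth of a feature-level cohort (and its optional second week)."""

    coefficients: dict
    intercept: float
    latent_quality: np.ndarray
    latent_dispersion: np.ndarray
    probabilities: np.ndarray
    participant_means: np.ndarray  # (n, n_features)
    epoch_values: list  # list of (n, epochs, n_features) arrays, one per week
    feature_names: tuple


def _feature_epoch_draws(
    p: FeatureCohortParams,
    rng: np.random.Generator,
    q: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
) -> np.ndarray:
    n, f = mu.shape
    eps = rng.standard_normal((n, p.epochs_per_participant, f))
    return mu[:, None, :] + sigma[:, None, None] * eps


def _percentile_summary_df(epoch_values: np.ndarray, names) -> pd.DataFrame:
    p10, p50, p90 = np.percentile(epoch_values, [10, 50, 90], axis=1)
    cols = {}
    for j, name in enumerate(names):
        cols[f"{name}__p10"] = p10[:, j]
        cols[f"{name}__p50"] = p50[:, j]
        cols[f"{name}__p90"] = p90[:, j]
    return pd.DataFrame(cols)


def _synth_feature_impl(
    p: FeatureCohortParams, n_weeks: int
) -> tuple[list[pd.DataFrame], FeatureCohortTruth]:
    p.validate()
    rng = np.random.default_rng(p.seed)
    n = p.n_participants
    names = FEATURE_NAMES
    load = np.array([FEATURE_QUALITY_SIGN[f] for f in names]) * p.quality_loading

    q = rng.standard_normal(n)
    w = rng.standard_normal(n)
    mu = q[:, None] * load[None, :] + rng.normal(
        0.0, p.participant_noise_sd, (n, len(names))
    )
    sigma = p.epoch_sd * np.exp(p.dispersion_tau * w)
    qa = _draw_questionnaire_activities(
        rng, q, p.questionnaire_quality_loading, p.activity_quality_loading
    )

    weeks_values = [
        _feature_epoch_draws(p, rng, q, mu, sigma) for _ in range(n_weeks)
    ]
    summaries = [_percentile_summary_df(v, names) for v in weeks_values]

    # outcome drawn once, on week-1 realized summaries
    table = pd.concat([qa, summaries[0]], axis=1)
    y, prob, intercept = _draw_outcome(
        rng, table, p.outcome_coefficients, p.outcome_intercept,
        p.faller_fraction_target,
    )

    dfs = []
    pid = pd.Series([f"p{i:04d}" for i in range(n)], name="participant_id")
    for s in summaries:
        df = pd.concat([pid, qa, s], axis=1)
        df["faller"] = y
        dfs.append(df)
    truth = FeatureCohortTruth(
        coefficients=dict(p.outcome_coefficients),
        intercept=intercept,
        latent_quality=q,
        latent_dispersion=w,
        probabilities=prob,
        participant_means=mu,
        epoch_values=weeks_values,
        feature_names=tuple(names),
    )
    return dfs, truth


def synth_feature_cohort(
    p: FeatureCohortParams,
) -> tuple[pd.DataFrame, FeatureCohortTruth]:
    """One feature-level cohort table with known logistic ground truth."""
    dfs, truth = _synth_feature_impl(p, n_weeks=1)
    return dfs[0], truth


def synth_feature_two_weeks(
    p: FeatureCohortParams,
) -> tuple[pd.DataFrame, pd.DataFrame, FeatureCohortTruth]:
    """Two feature-level weeks sharing participant-level truth."""
    dfs, truth = _synth_feature_impl(p, n_weeks=2)
    return dfs[0], dfs[1], truth
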