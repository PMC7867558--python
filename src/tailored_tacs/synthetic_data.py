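"""Synthetic resting-state EEG cohorts, crossover outcome tables, and
discrete difference distributions.

The generator emulates the acquisition regime of an open-eyes resting
recording: a 32-electrode 10/10 cap, 5 kHz native sampling (500 Hz is also
accepted), five-minute duration, a 1/f^gamma background, and band-limited
oscillations in the five canonical bands.  Spectral anomalies (e.g. a frontal
or central theta excess, the hallmark of thalamo-cortical slowing) are planted
multiplicatively on chosen electrodes, so that the downstream spectral and
normative-mapping stages can be validated against known ground truth without
any recorded data.

Everything here is a pure function of (spec, seed): the same arguments always
reproduce the same arrays bitwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectral import DEFAULT_BANDS, BandScheme, Recording

__all__ = [
    "DEFAULT_MONTAGE",
    "CohortSpec",
    "AnomalySpec",
    "OutcomeSpec",
    "DiscreteDistribution",
    "generate_recording",
    "generate_control_cohort",
    "generate_outcomes",
    "sample_differences",
]

#: 32-channel 10/10 montage of a standard clinical EEG cap
DEFAULT_MONTAGE: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
)

#: crossover timepoints: baseline, post-cycle, post-wash-out for each arm
TIMEPOINTS: tuple[str, ...] = ("T0", "T1", "T2", "T1'", "T2'")
CONDITIONS: tuple[str, ...] = ("tACS", "RNS")


@dataclass
class CohortSpec:
    """Acquisition and population parameters for synthetic resting EEG.

    montage : ordered 10/10 electrode labels (default: 32-channel cap)
    fs : native sampling rate in Hz (5000 as acquired, or 500 directly)
    duration_s : recording length in seconds (default 300 = five minutes)
    noise_exponent : spectral slope gamma of the 1/f^gamma background
    noise_amplitude : amplitude scale of the background (uV-like units)
    band_gain_mean : per-band mean oscillation amplitude (scalar or per-band)
    band_gain_cv : between-subject coefficient of variation of band
        amplitudes (log-normal across subjects; 0 = identical subjects)
    """

    montage: tuple[str, ...] = DEFAULT_MONTAGE
    fs: float = 5000.0
    duration_s: float = 300.0
    noise_exponent: float = 1.0
    noise_amplitude: float = 1.0
    band_gain_mean: float | dict[str, float] = 1.0
    band_gain_cv: float = 0.2
    bands: BandScheme = field(default_factory=lambda: DEFAULT_BANDS)
    smoothing: float = 0.0  # optional neighbor spatial smoothing weight

    def __post_init__(self) -> None:
        self.montage = tuple(self.montage)
        if len(set(self.montage)) != len(self.montage):
            raise ValueError("montage labels must be unique")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if self.band_gain_cv < 0:
            raise ValueError("band_gain_cv must be nonnegative")
        if not 0.0 <= self.smoothing < 1.0:
            raise ValueError("smoothing must be in [0, 1)")

    def gain_of(self, band: str) -> float:
        if isinstance(self.band_gain_mean, dict):
            return float(self.band_gain_mean.get(band, 0.0))
        return float(self.band_gain_mean)


@dataclass
class AnomalySpec:
    """A planted band-power excess (or deficit) on chosen electrodes.

    gain_factor multiplies the target band's oscillation *amplitude* at the
    target electrodes; gain_factor > 1 plants an excess (band power scales
    roughly with the square of the factor before renormalization).
    """

    target_band: str
    target_electrodes: tuple[str, ...]
    gain_factor: float

    def __post_init__(self) -> None:
        self.target_electrodes = tuple(self.target_electrodes)
        if self.target_band not in DEFAULT_BANDS.names:
            raise ValueError(f"unknown band {self.target_band!r}")
        if not self.gain_factor > 0:
            raise ValueError("gain_factor must be positive")

    def validate_montage(self, montage: tuple[str, ...]) -> None:
        unknown = [e for e in self.target_electrodes if e not in montage]
        if unknown:
            raise ValueError(f"anomaly electrodes not in montage: {unknown}")


@dataclass
class OutcomeSpec:
    """Parameters of a synthetic crossover outcome table.

    measures : measure name -> (low, high) score range (e.g. VAS on (0, 10))
    effects : measure -> {(condition, timepoint): additive shift} applied on
        top of the subject baseline (score units); unlisted cells shift 0
    noise_sd : within-subject measurement noise SD (score units)
    baseline_sd : between-subject baseline SD (score units)
    missing_rate : probability that any post-baseline observation is missing
    """

    n_subjects: int = 15
    measures: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"VAS": (0.0, 10.0)}
    )
    effects: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)
    noise_sd: float = 1.0
    baseline_sd: float = 1.0
    missing_rate: float = 0.0
    baseline_mean: dict[str, float] | None = None
    integer_scores: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ValueError("noise/baseline SDs must be nonnegative")
        for name, (lo, hi) in self.measures.items():
            if not lo < hi:
                raise ValueError(f"empty score range for measure {name!r}")


@dataclass
class DiscreteDistribution:
    """A discrete distribution on a strictly increasing numeric support."""

    support: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.support.ndim != 1 or self.support.size == 0:
            raise ValueError("support must be a non-empty 1-D sequence")
        if np.any(np.diff(self.support) <= 0):
            raise ValueError("support must be strictly increasing")
        if self.probabilities.shape != self.support.shape:
            raise ValueError("support and probabilities must align")
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(self.probabilities.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1 within 1e-12")

    @classmethod
    def uniform(cls, support) -> "DiscreteDistribution":
        support = np.asarray(support, dtype=float)
        return cls(support, np.full(support.size, 1.0 / support.size))

    @classmethod
    def point_mass(cls, value: float) -> "DiscreteDistribution":
        return cls(np.array([value]), np.array([1.0]))

    def shifted(self, c: float) -> "DiscreteDistribution":
        return DiscreteDistribution(self.support + c, self.probabilities.copy())


# ---------------------------------------------------------------------------
# EEG synthesis (frequency domain)
# ---------------------------------------------------------------------------

def _band_amplitude_profile(
    freqs: np.ndarray,
    spec: CohortSpec,
    gains: dict[str, float],
) -> np.ndarray:
    """Target amplitude-spectrum profile A(f): 1/f^(gamma/2) background plus
    flat band-limited components."""
    amp = np.zeros_like(freqs)
    pos = freqs > 0
    if spec.noise_amplitude > 0:
        amp[pos] = spec.noise_amplitude * freqs[pos] ** (-spec.noise_exponent / 2.0)
    for name, (lo, hi) in spec.bands.bands.items():
        g = gains.get(name, 0.0)
        if g > 0:
            amp[(freqs >= lo) & (freqs <= hi)] += g
    return amp


def _subject_gains(spec: CohortSpec, rng: np.random.Generator) -> dict[str, float]:
    """Per-band amplitudes for one subject: log-normal around the cohort mean
    with coefficient of variation band_gain_cv (mean-preserving)."""
    gains = {}
    cv = spec.band_gain_cv
    if cv > 0:
        sigma2 = math.log1p(cv * cv)
        mu = -sigma2 / 2.0
        sigma = math.sqrt(sigma2)
    for name in spec.bands.names:
        base = spec.gain_of(name)
        if cv > 0 and base > 0:
            base *= float(rng.lognormal(mean=mu, sigma=sigma))
        gains[name] = base
    return gains


def generate_recording(
    spec: CohortSpec,
    anomaly: AnomalySpec | None = None,
    seed: int = 0,
    *,
    _gains: dict[str, float] | None = None,
) -> Recording:
    """Synthesize one resting-state EEG recording.

    The signal is built in the frequency domain: each channel's rFFT
    coefficients are complex-Gaussian with expected amplitude following the
    1/f^gamma background plus flat band-limited oscillation components, giving
    exact control of the expected spectrum.  A planted anomaly multiplies the
    target band's oscillation amplitude at the target electrodes.
    """
    if anomaly is not None:
        anomaly.validate_montage(spec.montage)
    rng = np.random.default_rng(seed)
    gains = _gains if _gains is not None else _subject_gains(spec, rng)

    n = int(round(spec.fs * spec.duration_s))
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.fs)
    base_amp = _band_amplitude_profile(freqs, spec, gains)

    n_ch = len(spec.montage)
    data = np.empty((n_ch, n))
    # rfft scaling: divide by sqrt(n) so time-domain variance tracks sum A^2
    for ci, label in enumerate(spec.montage):
        amp = base_amp
        if anomaly is not None and label in anomaly.target_electrodes:
            # scale the whole target-band amplitude (oscillation plus
            # background) so band power scales by gain_factor**2
            amp = base_amp.copy()
            lo, hi = spec.bands.bands[anomaly.target_band]
            sel = (freqs >= lo) & (freqs <= hi)
            amp[sel] *= anomaly.gain_factor
        coeffs = amp * (
            rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
        ) / math.sqrt(2.0)
        data[ci] = np.fft.irfft(coeffs, n=n) * math.sqrt(n)

    if spec.smoothing > 0:
        # crude volume-conduction stand-in: blend each channel with the
        # montage-order neighbors' average
        w = spec.smoothing
        neighbor = (np.roll(data, 1, axis=0) + np.roll(data, -1, axis=0)) / 2.0
        data = (1 - w) * data + w * neighbor

    return Recording(data, spec.fs, list(spec.montage), reference="synthetic")


def generate_control_cohort(
    n: int, spec: CohortSpec, seed: int = 0
) -> list[Recording]:
    """Generate ``n`` healthy-control recordings with between-subject
    log-normal band-amplitude variation.  ``n`` must be at least 2, since a
    single control leaves the normative SD undefined downstream."""
    if n < 2:
        raise ValueError("a control cohort needs at least 2 subjects")
    children = np.random.SeedSequence(seed).spawn(n)
    out = []
    for ss in children:
        rng = np.random.default_rng(ss)
        gains = _subject_gains(spec, rng)
        sub_seed = ss.spawn(1)[0]
        out.append(generate_recording(spec, None, seed=sub_seed, _gains=gains))
    return out


# ---------------------------------------------------------------------------
# crossover outcomes
# ---------------------------------------------------------------------------

def generate_outcomes(spec: OutcomeSpec, seed: int = 0) -> pd.DataFrame:
    """Simulate a long-format crossover outcome table.

    Columns: subject, sequence (tACS-first / RNS-first, alternating),
    timepoint (T0, T1, T2, T1', T2'), condition (tACS / RNS; empty at T0),
    measure, value.  T1/T2 belong to the first-arm condition and T1'/T2' to
    the second.  Values are subject baseline + planted effect + Gaussian
    noise, clamped to the measure's score range.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for si in range(spec.n_subjects):
        subject = f"S{si + 1:02d}"
        first = CONDITIONS[si % 2]
        second = CONDITIONS[(si + 1) % 2]
        sequence = f"{first}-first"
        cond_of = {"T0": "", "T1": first, "T2": first, "T1'": second, "T2'": second}
        for measure, (lo, hi) in spec.measures.items():
            mid = (
                spec.baseline_mean[measure]
                if spec.baseline_mean is not None
                else (lo + hi) / 2.0
            )
            baseline = mid + spec.baseline_sd * rng.standard_normal()
            for tp in TIMEPOINTS:
                cond = cond_of[tp]
                shift = 0.0
                if cond:
                    shift = spec.effects.get(measure, {}).get((cond, tp.rstrip("'")), 0.0)
                value = baseline + shift + spec.noise_sd * rng.standard_normal()
                value = min(max(value, lo), hi)
                if spec.integer_scores:
                    value = float(round(value))
                missing = cond != "" and rng.random() < spec.missing_rate
                if not missing:
                    rows.append((subject, sequence, tp, cond, measure, value))
    return pd.DataFrame(
        rows,
        columns=["subject", "sequence", "timepoint", "condition", "measure", "value"],
    )


def sample_differences(
    dist: DiscreteDistribution, n: int, seed: int = 0
) -> np.ndarray:
    """Draw ``n`` i.i.d. values from a discrete difference distribution."""
    rng = np.random.default_rng(seed)
    return rng.choice(dist.support, size=n, p=dist.probabilities)
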