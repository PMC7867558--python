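"""Resting-state EEG spectral analysis: relative band power per electrode.

The pipeline mirrors standard clinical quantitative-EEG practice: band-pass
filter 1-30 Hz, down-sample to 500 Hz, common average reference, cut into
non-overlapping 2-s epochs, average Hamming-windowed periodograms (Welch with
zero overlap, 0.5 Hz resolution), and express the power of each canonical band
as a percentage of total 1-30 Hz power.

Band scheme (closed intervals, Hz): delta [1, 4], theta [4.5, 7.5],
alpha1 [8, 10], alpha2 [10.5, 12.5], beta [13, 30].  At 0.5 Hz bin spacing
these five bands exactly partition the 59 bins from 1.0 to 30.0 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "Recording",
    "BandScheme",
    "DEFAULT_BANDS",
    "Spectrum",
    "preprocess",
    "rereference_car",
    "segment_epochs",
    "epoch_psd",
    "relative_band_power",
    "band_power_pipeline",
]

#: processing sampling rate (Hz) after down-sampling
TARGET_FS = 500.0
#: epoch length in samples at TARGET_FS (2 s -> 0.5 Hz resolution)
EPOCH_SAMPLES = 1000
#: analysis band-pass (Hz)
PASSBAND = (1.0, 30.0)
#: Butterworth order for the zero-phase band-pass (applied forward-backward)
FILTER_ORDER = 8
#: seconds of filter settle-in discarded at each edge after zero-phase filtering
EDGE_TRIM_S = 1.0


@dataclass
class Recording:
    """A multichannel EEG recording.

    data : (n_channels, n_samples) array, microvolts
    fs : sampling rate in Hz
    labels : electrode names in row order (10/10 system)
    reference : free-text provenance tag (e.g. "raw", "CAR")
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    reference: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = list(self.labels)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channel x sample matrix")
        if self.data.shape[0] != len(self.labels):
            raise ValueError(
                f"{self.data.shape[0]} data rows but {len(self.labels)} labels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("electrode labels must be unique")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class BandScheme:
    """Named frequency bands as closed [low, high] intervals in Hz.

    The closed-interval convention resolves the half-bin gaps between the
    printed band edges: at 0.5 Hz spacing the 4.0 Hz bin belongs to delta and
    the 4.5 Hz bin to theta, so the bands partition [1, 30] without overlap.
    """

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BAND_EDGES)
    )
    total_range: tuple[float, float] = (1.0, 30.0)

    def __post_init__(self) -> None:
        edges = sorted(self.bands.values())
        for (_, hi), (lo, _) in zip(edges, edges[1:]):
            if lo <= hi:
                raise ValueError("band intervals must not overlap")

    @property
    def names(self) -> list[str]:
        return list(self.bands)

    def band_of(self, freq: float) -> str | None:
        """Band containing ``freq`` (closed intervals), or None."""
        for name, (lo, hi) in self.bands.items():
            if lo <= freq <= hi:
                return name
        return None


DEFAULT_BAND_EDGES: tuple[tuple[str, tuple[float, float]], ...] = (
    ("delta", (1.0, 4.0)),
    ("theta", (4.5, 7.5)),
    ("alpha1", (8.0, 10.0)),
    ("alpha2", (10.5, 12.5)),
    ("beta", (13.0, 30.0)),
)

DEFAULT_BANDS = BandScheme()

#: slow-class bands (an excess here is treated as thalamo-cortical slowing)
SLOW_BANDS = ("delta", "theta", "alpha1")
#: fast-class bands
FAST_BANDS = ("alpha2", "beta")


@dataclass
class Spectrum:
    """Per-channel one-sided power spectral density on a uniform grid.

    psd : (n_channels, n_freqs) array, uV^2/Hz
    freqs : frequency grid in Hz (0.5 Hz spacing for 2-s epochs at 500 Hz)
    """

    psd: np.ndarray
    freqs: np.ndarray
    labels: list[str]
    n_epochs: int

    def __post_init__(self) -> None:
        self.psd = np.asarray(self.psd, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.psd.shape != (len(self.labels), self.freqs.size):
            raise ValueError("psd shape must be (n_channels, n_freqs)")
        if np.any(self.psd < -1e-12):
            raise ValueError("PSD values must be nonnegative")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(raw: Recording, *, artifact_hook=None) -> Recording:
    """Band-pass 1-30 Hz and down-sample to 500 Hz, zero-phase.

    Down-sampling uses a polyphase FIR anti-alias resampler; the band-pass is
    a zero-phase (forward-backward) Butterworth applied at the target rate, so
    the output carries no group delay.  ``artifact_hook`` is an optional
    callable ``Recording -> Recording`` applied first; it stands in for manual
    artifact rejection (e.g. ICA component removal), which is outside this
    package's scope.

    Raises ValueError when the input rate is below 500 Hz or the filtered
    recording is shorter than one 2-s epoch.
    """
    if artifact_hook is not None:
        raw = artifact_hook(raw)
    if raw.fs < TARGET_FS:
        raise ValueError(
            f"sampling rate {raw.fs} Hz is below the {TARGET_FS} Hz target"
        )

    x = raw.data
    if raw.fs != TARGET_FS:
        frac = Fraction(TARGET_FS / raw.fs).limit_denominator(10000)
        x = sps.resample_poly(x, frac.numerator, frac.denominator, axis=1)

    # separate high- and low-pass (lower Q than one 1-30 Hz band-pass, so
    # shorter edge transients); generous reflection padding keeps the
    # settle-in of the 1 Hz high-pass out of the returned data
    lo, hi = PASSBAND
    sos_hp = sps.butter(FILTER_ORDER // 2, lo, btype="highpass",
                        fs=TARGET_FS, output="sos")
    sos_lp = sps.butter(FILTER_ORDER, hi, btype="lowpass",
                        fs=TARGET_FS, output="sos")
    padlen = min(x.shape[1] - 1, int(5 * TARGET_FS))
    x = sps.sosfiltfilt(sos_hp, x, axis=1, padlen=padlen)
    x = sps.sosfiltfilt(sos_lp, x, axis=1, padlen=padlen)

    # discard the filter settle-in (up to 1 s per edge), but never trim a
    # short recording below one epoch
    trim = min(int(EDGE_TRIM_S * TARGET_FS),
               max(0, (x.shape[1] - EPOCH_SAMPLES) // 2))
    if trim > 0:
        x = x[:, trim:-trim]

    if x.shape[1] < EPOCH_SAMPLES:
        raise ValueError(
            f"only {x.shape[1]} samples at {TARGET_FS:g} Hz; "
            f"need at least one {EPOCH_SAMPLES}-sample epoch"
        )
    return Recording(x, TARGET_FS, raw.labels, reference=raw.reference)


def rereference_car(rec: Recording) -> Recording:
    """Re-reference to the common average: subtract the instantaneous
    across-channel mean from every channel."""
    if rec.n_channels < 2:
        raise ValueError("common average reference needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return Recording(data, rec.fs, rec.labels, reference="CAR")


def segment_epochs(rec: Recording, epoch_samples: int = EPOCH_SAMPLES) -> np.ndarray:
    """Cut into non-overlapping epochs of ``epoch_samples`` samples.

    Returns an (n_epochs, n_channels, epoch_samples) array; the trailing
    remainder is discarded.  Requires the processed rate of 500 Hz so that
    2-s epochs give exactly 0.5 Hz spectral resolution.
    """
    if rec.fs != TARGET_FS:
        raise ValueError(f"expected {TARGET_FS:g} Hz input; run preprocess first")
    n_epochs = rec.n_samples // epoch_samples
    if n_epochs < 1:
        raise ValueError(
            f"{rec.n_samples} samples is fewer than one {epoch_samples}-sample epoch"
        )
    trimmed = rec.data[:, : n_epochs * epoch_samples]
    return trimmed.reshape(rec.n_channels, n_epochs, epoch_samples).transpose(1, 0, 2)


def epoch_psd(epochs: np.ndarray, labels: list[str], fs: float = TARGET_FS) -> Spectrum:
    """Average Hamming-windowed one-sided periodograms across epochs.

    Equivalent to Welch's method with zero overlap.  The periodogram is
    normalized by the window power (sum of squared window values), so the
    integral of the PSD over frequency equals the mean-square signal
    amplitude; units are uV^2/Hz.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 3 or epochs.shape[0] < 1:
        raise ValueError("need an (n_epochs, n_channels, n_samples) array")
    n_epochs, n_channels, n_samples = epochs.shape
    if n_channels != len(labels):
        raise ValueError("label count does not match channel count")

    # channels x (epochs*samples), segmented back by welch with zero overlap
    freqs, psd = sps.welch(
        epochs,
        fs=fs,
        window="hamming",
        nperseg=n_samples,
        noverlap=0,
        detrend=False,
        scaling="density",
        axis=-1,
    )
    return Spectrum(psd.mean(axis=0), freqs, list(labels), n_epochs)


# ---------------------------------------------------------------------------
# relative band power
# ---------------------------------------------------------------------------

def relative_band_power(
    spectrum: Spectrum, scheme: BandScheme = DEFAULT_BANDS
) -> pd.DataFrame:
    """Relative power (%) per channel and band.

    A frequency bin belongs to a band when its center lies inside the band's
    closed interval.  Band power is the sum of member-bin PSD values; relative
    power is 100 x band power / total power over the scheme's total range.
    Each row of the returned (channels x bands) table sums to 100.
    """
    lo_tot, hi_tot = scheme.total_range
    freqs = spectrum.freqs
    in_total = (freqs >= lo_tot - 1e-9) & (freqs <= hi_tot + 1e-9)
    if not in_total.any():
        raise ValueError("spectrum grid does not cover the analysis range")

    total = spectrum.psd[:, in_total].sum(axis=1)
    if np.any(total <= 0):
        bad = [spectrum.labels[i] for i in np.nonzero(total <= 0)[0]]
        raise ValueError(f"zero total power in 1-30 Hz for channels {bad}")

    cols = {}
    for name, (lo, hi) in scheme.bands.items():
        sel = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
        cols[name] = 100.0 * spectrum.psd[:, sel].sum(axis=1) / total
    table = pd.DataFrame(cols, index=pd.Index(spectrum.labels, name="channel"))
    return table


def band_power_pipeline(
    raw: Recording,
    scheme: BandScheme = DEFAULT_BANDS,
    *,
    artifact_hook=None,
) -> pd.DataFrame:
    """Full raw-recording -> relative band-power table pipeline.

    preprocess -> common average reference -> 2-s epochs -> averaged Hamming
    periodogram -> relative band power.
    """
    rec = preprocess(raw, artifact_hook=artifact_hook)
    rec = rereference_car(rec)
    epochs = segment_epochs(rec)
    spectrum = epoch_psd(epochs, rec.labels, rec.fs)
    return relative_band_power(spectrum, scheme)
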