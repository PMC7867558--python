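"""Normative z-maps and individualized stimulation planning.

A subject's relative band-power table is compared cell-by-cell (electrode x
band) against a healthy-control cohort: z = (subject - control mean) /
control SD, flagged significant at two-sided p < 0.05 (|z| >= 1.959964).
The *prevailing rhythm* is the cell with the largest significant positive z —
the band and scalp site of greatest power excess.  The stimulation rule then
opposes the excess: a slow-band excess (delta, theta, alpha1) is treated with
30 Hz beta-tACS, a fast-band excess (alpha2, beta) with 4 Hz theta-tACS; the
anode goes over the peak electrode and the cathode over the ipsilateral
mastoid (or the adjacent midline site for midline anodes).  Amplitudes stay
within 1-2 mA.  Random noise stimulation (RNS, the active sham) is an
alternating current with amplitude drawn from 1-2 mA and frequency from
0-100 Hz.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .spectral import DEFAULT_BANDS, FAST_BANDS, SLOW_BANDS, BandScheme

__all__ = [
    "Z_THRESHOLD",
    "NormativeModel",
    "ZMap",
    "PrevailingRhythm",
    "StimulationPlan",
    "fit_normative",
    "compute_zmap",
    "prevailing_rhythm",
    "plan_stimulation",
    "synthesize_waveform",
]

#: two-sided 5% normal quantile
Z_THRESHOLD = float(stats.norm.ppf(0.975))  # 1.959964...

SLOW_FREQUENCY_HZ = 30.0  # stimulate a slow-band excess at beta frequency
FAST_FREQUENCY_HZ = 4.0   # stimulate a fast-band excess at theta frequency
AMPLITUDE_RANGE_MA = (1.0, 2.0)
RNS_FREQ_RANGE_HZ = (0.0, 100.0)

#: cathode for a midline anode: adjacent midline electrode (mastoid
#: laterality is undefined on the midline)
MIDLINE_CATHODE = {
    "Fpz": "Fz", "AFz": "Fz", "Fz": "Cz", "FCz": "Fz",
    "Cz": "Fz", "CPz": "Pz", "Pz": "Cz", "POz": "Pz", "Oz": "Pz",
}


@dataclass
class NormativeModel:
    """Control-cohort mean and SD of relative power per electrode x band."""

    mean: pd.DataFrame
    sd: pd.DataFrame
    n_controls: int

    def __post_init__(self) -> None:
        if not self.mean.index.equals(self.sd.index) or not self.mean.columns.equals(
            self.sd.columns
        ):
            raise ValueError("mean and sd tables must share labels and bands")
        if self.n_controls < 2:
            raise ValueError("normative model needs at least 2 controls")


@dataclass
class ZMap:
    """Subject-versus-controls z statistic per electrode x band."""

    z: pd.DataFrame
    threshold: float = Z_THRESHOLD

    @property
    def significant(self) -> pd.DataFrame:
        return self.z.abs() >= self.threshold

    def to_csv(self, path) -> None:
        self.z.to_csv(path)


@dataclass
class PrevailingRhythm:
    """Band and electrode of the maximum significant positive power excess."""

    band: str
    electrode: str
    z: float

    def __post_init__(self) -> None:
        if not self.z > 0:
            raise ValueError("prevailing rhythm requires a positive z")


@dataclass
class StimulationPlan:
    """Individualized stimulation parameters."""

    band_class: str               # "slow-excess" | "fast-excess"
    frequency_hz: float           # 30 or 4
    anode: str
    cathode: str
    amplitude_ma: tuple[float, float] = AMPLITUDE_RANGE_MA
    mode: str = "tACS"            # "tACS" | "RNS"
    target_band: str = ""
    peak_z: float = float("nan")

    def __post_init__(self) -> None:
        if self.mode not in ("tACS", "RNS"):
            raise ValueError(f"unknown mode {self.mode!r}")
        lo, hi = self.amplitude_ma
        if not (AMPLITUDE_RANGE_MA[0] <= lo <= hi <= AMPLITUDE_RANGE_MA[1]):
            raise ValueError("amplitude range must lie within 1-2 mA")
        if self.band_class == "slow-excess" and self.frequency_hz != SLOW_FREQUENCY_HZ:
            raise ValueError("slow-excess implies 30 Hz stimulation")
        if self.band_class == "fast-excess" and self.frequency_hz != FAST_FREQUENCY_HZ:
            raise ValueError("fast-excess implies 4 Hz stimulation")

    def to_json(self, path=None) -> str:
        payload = {
            "mode": self.mode,
            "band_class": self.band_class,
            "target_band": self.target_band,
            "frequency_hz": self.frequency_hz,
            "anode": self.anode,
            "cathode": self.cathode,
            "amplitude_ma_min": self.amplitude_ma[0],
            "amplitude_ma_max": self.amplitude_ma[1],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# normative comparison
# ---------------------------------------------------------------------------

def fit_normative(controls: list[pd.DataFrame]) -> NormativeModel:
    """Cell-wise sample mean and SD (n-1 denominator) across control
    band-power tables.  All tables must share montage and band scheme; any
    zero-SD cell is an error (the z statistic would be undefined)."""
    if len(controls) < 2:
        raise ValueError("need at least 2 control tables")
    first = controls[0]
    for i, tbl in enumerate(controls[1:], start=2):
        if not tbl.index.equals(first.index) or not tbl.columns.equals(first.columns):
            raise ValueError(f"control table {i} montage/bands mismatch")
    stack = np.stack([tbl.to_numpy(dtype=float) for tbl in controls])
    mean = pd.DataFrame(stack.mean(axis=0), index=first.index, columns=first.columns)
    sd = pd.DataFrame(
        stack.std(axis=0, ddof=1), index=first.index, columns=first.columns
    )
    zero = sd.to_numpy() <= 0
    if zero.any():
        ch, bd = np.argwhere(zero)[0]
        raise ValueError(
            f"zero control SD at channel {first.index[ch]!r}, band "
            f"{first.columns[bd]!r}; degenerate cohort"
        )
    return NormativeModel(mean, sd, len(controls))


def compute_zmap(subject: pd.DataFrame, model: NormativeModel) -> ZMap:
    """z = (subject - control mean) / control SD, per electrode x band."""
    if not subject.index.equals(model.mean.index) or not subject.columns.equals(
        model.mean.columns
    ):
        raise ValueError("subject table montage/bands mismatch with model")
    return ZMap((subject - model.mean) / model.sd)


def prevailing_rhythm(
    zmap: ZMap, scheme: BandScheme = DEFAULT_BANDS
) -> PrevailingRhythm | None:
    """The electrode x band cell with the maximum significant positive z.

    Returns None — the explicit "no target" outcome — when no cell shows a
    significant positive excess.  Ties are broken deterministically by band
    order (delta -> beta) then montage order.
    """
    z = zmap.z
    best = None
    for band in scheme.names:
        if band not in z.columns:
            continue
        col = z[band]
        for electrode in z.index:
            val = float(col.loc[electrode])
            if val >= zmap.threshold and (best is None or val > best.z):
                best = PrevailingRhythm(band, str(electrode), val)
    return best


# ---------------------------------------------------------------------------
# stimulation planning
# ---------------------------------------------------------------------------

def _cathode_for(anode: str) -> str:
    """Ipsilateral mastoid (M1 left / M2 right by electrode number parity);
    midline anodes pair with the adjacent midline electrode."""
    m = re.fullmatch(r"([A-Za-z]+)(\d*)(h?)", anode)
    if not m:
        raise ValueError(f"cannot parse electrode label {anode!r}")
    digits = m.group(2)
    if not digits:  # z-suffixed midline label, e.g. Cz, Fpz
        try:
            return MIDLINE_CATHODE[anode]
        except KeyError:
            raise ValueError(f"no midline cathode rule for {anode!r}") from None
    return "M1" if int(digits) % 2 == 1 else "M2"


def plan_stimulation(
    prev: PrevailingRhythm,
    *,
    mode: str = "tACS",
    cathode_override: str | None = None,
) -> StimulationPlan:
    """Map a prevailing rhythm to stimulation parameters.

    Slow-band excess (delta, theta, alpha1) -> 30 Hz; fast-band excess
    (alpha2, beta) -> 4 Hz.  Anode at the peak electrode, cathode at the
    ipsilateral mastoid (override for multi-site or midline montages).
    """
    if prev.band in SLOW_BANDS:
        band_class, freq = "slow-excess", SLOW_FREQUENCY_HZ
    elif prev.band in FAST_BANDS:
        band_class, freq = "fast-excess", FAST_FREQUENCY_HZ
    else:
        raise ValueError(f"unknown band {prev.band!r}")
    cathode = cathode_override if cathode_override else _cathode_for(prev.electrode)
    return StimulationPlan(
        band_class=band_class,
        frequency_hz=freq,
        anode=prev.electrode,
        cathode=cathode,
        mode=mode,
        target_band=prev.band,
        peak_z=prev.z,
    )


# ---------------------------------------------------------------------------
# stimulus waveforms
# ---------------------------------------------------------------------------

def synthesize_waveform(
    plan: StimulationPlan,
    duration_s: float,
    fs: float,
    seed: int = 0,
    *,
    amplitude_ma: float | None = None,
    segment_s: float = 0.05,
) -> np.ndarray:
    """Stimulation current waveform in mA.

    tACS: a fixed-frequency sinusoid at the planned frequency.  RNS: a
    phase-continuous chirp whose instantaneous frequency (Uniform 0-100 Hz)
    and amplitude (Uniform 1-2 mA) are redrawn every ``segment_s`` seconds,
    spreading energy over the whole 0-100 Hz range.  All samples are bounded
    by 2 mA in magnitude.
    """
    if not duration_s > 0:
        raise ValueError("duration_s must be positive")
    max_f = plan.frequency_hz if plan.mode == "tACS" else RNS_FREQ_RANGE_HZ[1]
    if fs < 2.0 * max_f:
        raise ValueError(
            f"fs {fs} Hz below Nyquist for {max_f} Hz stimulation content"
        )
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    if plan.mode == "tACS":
        amp = plan.amplitude_ma[0] if amplitude_ma is None else float(amplitude_ma)
        if not plan.amplitude_ma[0] <= amp <= plan.amplitude_ma[1]:
            raise ValueError("amplitude outside the planned range")
        return amp * np.sin(2.0 * np.pi * plan.frequency_hz * t)

    rng = np.random.default_rng(seed)
    seg = max(1, int(round(segment_s * fs)))
    n_seg = -(-n // seg)
    freqs = rng.uniform(*RNS_FREQ_RANGE_HZ, size=n_seg)
    amps = rng.uniform(*AMPLITUDE_RANGE_MA, size=n_seg)
    inst_f = np.repeat(freqs, seg)[:n]
    inst_a = np.repeat(amps, seg)[:n]
    phase = 2.0 * np.pi * np.cumsum(inst_f) / fs
    return inst_a * np.sin(phase)
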