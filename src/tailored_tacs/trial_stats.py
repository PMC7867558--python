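"""ROI band-power aggregation and crossover outcome statistics.

The crossover analysis follows the trial's scheme: every outcome (EEG ROI
band power, clinical and neuropsychological scores) is compared between
timepoints within condition (baseline T0 vs post-cycle T1, T0 vs post-wash-out
T2, T1 vs T2) and between conditions (tACS vs RNS at matched timepoints) with
the paired Wilcoxon signed-rank test on complete cases, at the usual 0.05
level and with no multiple-comparison correction (the analysis is
exploratory by design).  Location estimates and confidence intervals are
Hodges-Lehmann signed-rank intervals on the paired differences.

The signed-rank p-value is computed exactly (full null distribution by rank
convolution) for tie-free samples up to n = 25, and by the normal
approximation with the standard tie correction otherwise; zero differences
are dropped before ranking (Wilcoxon's original rule).  Two-sided p is
min(1, 2 * min(P(W+ <= w), P(W+ >= w))) under the exact null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("tailored_tacs")

__all__ = [
    "ROIScheme",
    "DEFAULT_ROIS",
    "TestResult",
    "Contrast",
    "DEFAULT_CONTRASTS",
    "roi_band_power",
    "signed_rank_test",
    "paired_wilcoxon",
    "hodges_lehmann_ci",
    "crossover_analysis",
    "results_to_frame",
]

EXACT_N_MAX = 25


@dataclass(frozen=True)
class ROIScheme:
    """Named electrode sets over which relative power is averaged."""

    rois: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_ROI_SETS}
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, electrodes in self.rois.items():
            overlap = seen.intersection(electrodes)
            if overlap:
                raise ValueError(f"ROI {name!r} overlaps earlier ROIs: {overlap}")
            seen.update(electrodes)


# frontal / motor / parietal sets, left and right hemisphere
DEFAULT_ROI_SETS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("left_frontal", ("Fp1", "F7", "F3")),
    ("right_frontal", ("Fp2", "F8", "F4")),
    ("left_motor", ("FC1", "FC5", "C3", "CP1")),
    ("right_motor", ("FC2", "FC6", "C4", "CP2")),
    ("left_parietal", ("CP5", "P7", "P3")),
    ("right_parietal", ("CP6", "P8", "P4")),
)

DEFAULT_ROIS = ROIScheme()


def roi_band_power(table: pd.DataFrame, scheme: ROIScheme = DEFAULT_ROIS) -> pd.DataFrame:
    """Arithmetic mean of member electrodes' relative power, per ROI x band.

    Electrode matching is case-insensitive (montage files vary in casing of
    labels like CP5/Cp5).  A ROI electrode missing from the table is an error
    naming the electrode.
    """
    lower_index = {str(lbl).lower(): lbl for lbl in table.index}
    out = {}
    for roi, electrodes in scheme.rois.items():
        members = []
        for e in electrodes:
            key = e.lower()
            if key not in lower_index:
                raise ValueError(f"ROI {roi!r}: electrode {e!r} missing from table")
            members.append(lower_index[key])
        out[roi] = table.loc[members].mean(axis=0)
    return pd.DataFrame(out).T.rename_axis("roi")


# ---------------------------------------------------------------------------
# signed-rank test
# ---------------------------------------------------------------------------

def _exact_null_counts(n: int) -> np.ndarray:
    """Counts of the W+ null distribution over 0..n(n+1)/2 (tie-free ranks):
    coefficients of prod_r (1 + x^r)."""
    m = n * (n + 1) // 2
    counts = np.zeros(m + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, n + 1):
        nxt = counts.copy()
        nxt[r:] += counts[:-r]
        counts = nxt
    return counts


@dataclass
class TestResult:
    """Result of one paired signed-rank comparison."""

    contrast: str
    measure: str
    n_pairs: int
    statistic: float          # W+ = sum of positive-difference ranks
    p: float
    estimate: float           # Hodges-Lehmann location of the differences
    ci_low: float
    ci_high: float
    method: str = "exact"     # "exact" | "normal-approx" | "degenerate"
    degenerate: bool = False  # all differences zero

    def __post_init__(self) -> None:
        if not (self.degenerate or self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI must bracket the estimate")


def signed_rank_test(diffs: np.ndarray) -> tuple[int, float, float, str]:
    """Wilcoxon signed-rank test of median(diffs) = 0.

    Returns (n used after dropping zeros, W+, two-sided p, method).  Exact
    null distribution for tie-free n <= 25; normal approximation with tie
    correction otherwise.  All-zero input gives p = 1 (method "degenerate").
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 0, 0.0, 1.0, "degenerate"

    absd = np.abs(d)
    ranks = stats.rankdata(absd)
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(absd).size < n

    if not has_ties and n <= EXACT_N_MAX:
        counts = _exact_null_counts(n)
        total = counts.sum()
        w = int(round(w_plus))
        p_le = counts[: w + 1].sum() / total
        p_ge = counts[w:].sum() / total
        return n, w_plus, min(1.0, 2.0 * min(p_le, p_ge)), "exact"

    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(absd, return_counts=True)
    var -= (tie_counts.astype(float) ** 3 - tie_counts).sum() / 48.0
    if var <= 0:  # only possible for n == 1 after tie correction edge cases
        return n, w_plus, 1.0, "degenerate"
    z = (w_plus - mu) / np.sqrt(var)
    return n, w_plus, float(min(1.0, 2.0 * stats.norm.sf(abs(z)))), "normal-approx"


def hodges_lehmann_ci(
    diffs: np.ndarray, level: float = 0.95
) -> tuple[float, float, float]:
    """Hodges-Lehmann estimate and signed-rank CI for paired differences.

    Estimate: median of all Walsh averages (d_i + d_j)/2, i <= j.  The CI
    endpoints are the k-th smallest and k-th largest Walsh averages, with k
    from the signed-rank null distribution (exact for n <= 25, normal
    approximation beyond); when the attainable level is below the requested
    one the CI widens to the full Walsh range.
    """
    d = np.asarray(diffs, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 differences")
    walsh = np.sort((d[:, None] + d[None, :])[np.triu_indices(n)] / 2.0)
    m = walsh.size  # n(n+1)/2
    estimate = float(np.median(walsh))

    alpha = 1.0 - level
    if n <= EXACT_N_MAX:
        counts = _exact_null_counts(n)
        cdf = np.cumsum(counts) / counts.sum()
        # largest c with P(W+ <= c) <= alpha/2
        c = int(np.searchsorted(cdf, alpha / 2.0, side="right")) - 1
    else:
        mu = n * (n + 1) / 4.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        c = int(np.floor(mu + stats.norm.ppf(alpha / 2.0) * sigma))
    k = c + 1  # 1-indexed order statistic
    if k < 1 or m - k < k - 1:
        return estimate, float(walsh[0]), float(walsh[-1])
    return estimate, float(walsh[k - 1]), float(walsh[m - k])


def paired_wilcoxon(
    x: np.ndarray,
    y: np.ndarray,
    *,
    contrast: str = "",
    measure: str = "",
    level: float = 0.95,
) -> TestResult:
    """Paired Wilcoxon signed-rank test on differences x - y.

    Pairs with a missing value in either vector are removed first (complete
    case analysis).  All-zero differences give the degenerate result p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    d = x[keep] - y[keep]
    if d.size == 0:
        raise ValueError("no complete pairs")

    n_used, w_plus, p, method = signed_rank_test(d)
    if n_used == 0:  # every difference is exactly zero
        return TestResult(contrast, measure, int(d.size), 0.0, 1.0,
                          0.0, 0.0, 0.0, "degenerate", degenerate=True)
    est, lo, hi = hodges_lehmann_ci(d, level) if d.size >= 2 else (
        float(d[0]), float(d[0]), float(d[0])
    )
    return TestResult(contrast, measure, int(d.size), w_plus, p, est, lo, hi, method)


# ---------------------------------------------------------------------------
# crossover analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Contrast:
    """A paired comparison between two measurement cells.

    A cell is (condition, timepoint); condition None denotes the shared
    baseline T0.  Timepoints are base names (T1 covers both T1 and T1',
    whichever arm the condition fell in for each subject).
    """

    left: tuple[str | None, str]
    right: tuple[str | None, str]

    @property
    def label(self) -> str:
        def name(cell):
            cond, tp = cell
            return tp if cond is None else f"{cond}-{tp}"
        return f"{name(self.left)} vs {name(self.right)}"


def _default_contrasts() -> list[Contrast]:
    out = []
    for cond in ("tACS", "RNS"):
        out.append(Contrast((None, "T0"), (cond, "T1")))
        out.append(Contrast((None, "T0"), (cond, "T2")))
        out.append(Contrast((cond, "T1"), (cond, "T2")))
    out.append(Contrast(("tACS", "T1"), ("RNS", "T1")))
    out.append(Contrast(("tACS", "T2"), ("RNS", "T2")))
    return out


DEFAULT_CONTRASTS: list[Contrast] = _default_contrasts()


def _cell_values(df: pd.DataFrame, cell: tuple[str | None, str], measure: str) -> pd.Series:
    cond, tp = cell
    sub = df[df["measure"] == measure]
    if cond is None:
        sub = sub[(sub["condition"] == "") & (sub["timepoint"] == tp)]
    else:
        base = sub["timepoint"].str.rstrip("'")
        sub = sub[(sub["condition"] == cond) & (base == tp)]
    return sub.set_index("subject")["value"]


def crossover_analysis(
    outcomes: pd.DataFrame,
    contrasts: list[Contrast] | None = None,
    measures: list[str] | None = None,
    level: float = 0.95,
) -> list[TestResult]:
    """Run every (measure, contrast) paired signed-rank comparison.

    Pairing is by subject on complete cases; data from both sequence orders
    are pooled by condition.  Contrasts with fewer than 2 complete pairs are
    skipped with a logged warning.  No multiplicity correction is applied.
    """
    required = {"subject", "timepoint", "condition", "measure", "value"}
    missing = required - set(outcomes.columns)
    if missing:
        raise ValueError(f"outcome table lacks columns {sorted(missing)}")
    if contrasts is None:
        contrasts = DEFAULT_CONTRASTS
    if measures is None:
        measures = list(pd.unique(outcomes["measure"]))

    results: list[TestResult] = []
    for measure in measures:
        for con in contrasts:
            left = _cell_values(outcomes, con.left, measure)
            right = _cell_values(outcomes, con.right, measure)
            common = left.index.intersection(right.index)
            if common.size < 2:
                logger.warning(
                    "skipping %s for %r: only %d complete pairs",
                    con.label, measure, common.size,
                )
                continue
            results.append(
                paired_wilcoxon(
                    left.loc[common].to_numpy(),
                    right.loc[common].to_numpy(),
                    contrast=con.label,
                    measure=measure,
                    level=level,
                )
            )
    return results


def results_to_frame(results: list[TestResult]) -> pd.DataFrame:
    """Flatten TestResults to the standard results table."""
    return pd.DataFrame(
        [
            {
                "contrast": r.contrast,
                "measure": r.measure,
                "n": r.n_pairs,
                "statistic": r.statistic,
                "p": r.p,
                "estimate": r.estimate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "method": r.method,
            }
            for r in results
        ]
    )
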