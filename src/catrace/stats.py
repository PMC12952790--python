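"""Paired optical-electrophysiology matching and active-zone statistics.

Optical Ca2+ events and electrically recorded miniature events (mEPSPs)
are paired by greedy globally-nearest matching in time; the paired lists
feed the detection fraction, the Pearson amplitude correlation, and
distribution comparisons.  Per-active-zone response matrices are
compared with paired t-tests between every pair of active zones and
flagged against the pooled interquartile range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .model import CaEvent

__all__ = [
    "EphysEvent",
    "MatchResult",
    "AZMatrix",
    "match_events",
    "detection_fraction",
    "amplitude_correlation",
    "az_pairwise_tests",
    "iqr_flags",
    "ks_compare",
]


@dataclass(frozen=True)
class EphysEvent:
    """A miniature postsynaptic potential: time (ms) and amplitude (mV)."""

    time: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("mEPSP amplitude must be positive")


@dataclass
class MatchResult:
    """One-to-one optical/ephys event pairing within a tolerance.

    Every event appears in at most one pair, every pair's |dt| is within
    the tolerance, and pair + unmatched counts conserve both inputs.
    """

    pairs: list[tuple[EphysEvent, CaEvent, float]]
    unmatched_ephys: list[EphysEvent]
    unmatched_optical: list[CaEvent]
    tolerance: float


@dataclass
class AZMatrix:
    """Active-zone x stimulus grid of peak responses (dR/R or dF/F)."""

    amplitudes: np.ndarray
    az_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.ndim != 2:
            raise ValueError("amplitudes must be a 2-D AZ x stimulus array")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("amplitudes must be finite")
        if not self.az_ids:
            self.az_ids = [f"AZ{i}" for i in range(self.amplitudes.shape[0])]
        if len(self.az_ids) != self.amplitudes.shape[0]:
            raise ValueError("az_ids length must match the number of rows")

    @property
    def n_az(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.amplitudes.shape[1]


def match_events(
    optical: Sequence[CaEvent],
    ephys: Sequence[EphysEvent],
    tolerance: float = 50.0,
) -> MatchResult:
    """Greedy globally-nearest one-to-one pairing of cross-modal events.

    The unpaired cross-modal pair with the smallest |dt| <= tolerance is
    paired first, repeatedly; ties are broken toward the earlier ephys
    event, then the earlier optical event, making the result
    deterministic and order-independent.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    optical = sorted(optical, key=lambda e: e.peak_time)
    ephys = sorted(ephys, key=lambda e: e.time)

    candidates = []
    for i, ee in enumerate(ephys):
        for j, oe in enumerate(optical):
            dt = abs(oe.peak_time - ee.time)
            if dt <= tolerance:
                candidates.append((dt, ee.time, oe.peak_time, i, j))
    candidates.sort()

    used_e: set[int] = set()
    used_o: set[int] = set()
    pairs = []
    for dt, _, _, i, j in candidates:
        if i in used_e or j in used_o:
            continue
        used_e.add(i)
        used_o.add(j)
        pairs.append((ephys[i], optical[j], dt))
    return MatchResult(
        pairs=pairs,
        unmatched_ephys=[e for i, e in enumerate(ephys) if i not in used_e],
        unmatched_optical=[o for j, o in enumerate(optical) if j not in used_o],
        tolerance=tolerance,
    )


def detection_fraction(match: MatchResult) -> float:
    """Fraction of electrically recorded events captured optically."""
    n_ephys = len(match.pairs) + len(match.unmatched_ephys)
    if n_ephys == 0:
        raise ValueError("detection fraction is undefined with zero ephys events")
    return len(match.pairs) / n_ephys


def amplitude_correlation(match: MatchResult) -> tuple[float, float, int]:
    """Pearson correlation between paired ephys (mV) and optical amplitudes.

    Returns ``(r, r_squared, n)``; requires >= 3 pairs and non-degenerate
    margins.
    """
    if len(match.pairs) < 3:
        raise ValueError("amplitude correlation needs >= 3 pairs")
    x = np.array([p[0].amplitude for p in match.pairs])
    y = np.array([p[1].amplitude for p in match.pairs])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one margin; correlation undefined")
    r = float(sps.pearsonr(x, y).statistic)
    return r, r * r, x.size


def az_pairwise_tests(
    matrix: AZMatrix,
    alpha: float = 0.05,
    correction: Optional[str] = None,
) -> tuple[float, np.ndarray]:
    """Paired two-tailed t-tests between every pair of active zones.

    Responses are paired by stimulus number.  Returns the fraction of AZ
    pairs significant at ``alpha`` and the symmetric p-value matrix
    (diagonal and zero-variance pairs are NaN; zero-variance pairs are
    excluded from the fraction's denominator).  ``correction`` may be
    "bonferroni" or "bh" to adjust the p-values first; the raw fraction
    convention leaves it off.
    """
    if matrix.n_az < 2:
        raise ValueError("pairwise tests need >= 2 active zones")
    if matrix.n_stimuli < 2:
        raise ValueError("pairwise tests need >= 2 paired observations")
    a = matrix.amplitudes
    n_az, n_stim = a.shape

    iu = np.triu_indices(n_az, k=1)
    diffs = a[iu[0]] - a[iu[1]]  # (n_pairs, n_stim)
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = mean / (sd / np.sqrt(n_stim))
    pvals = 2.0 * sps.t.sf(np.abs(tstat), df=n_stim - 1)
    pvals = np.where(sd == 0, np.nan, pvals)

    valid = ~np.isnan(pvals)
    if correction == "bonferroni":
        pvals = np.where(valid, np.minimum(pvals * valid.sum(), 1.0), np.nan)
    elif correction == "bh":
        m = int(valid.sum())
        order = np.argsort(pvals[valid])
        adj = pvals[valid][order] * m / (np.arange(m) + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        tmp = np.full(m, np.nan)
        tmp[order] = np.minimum(adj, 1.0)
        pvals = pvals.copy()
        pvals[valid] = tmp
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")

    if not valid.any():
        raise ValueError("all AZ pairs have zero-variance differences")
    fraction = float(np.mean(pvals[valid] < alpha))

    p_matrix = np.full((n_az, n_az), np.nan)
    p_matrix[iu] = pvals
    p_matrix[(iu[1], iu[0])] = pvals
    return fraction, p_matrix


def iqr_flags(matrix: AZMatrix) -> tuple[float, float, list[str]]:
    """Flag AZs whose mean response falls outside the pooled IQR.

    Q1 and Q3 are linear-interpolation quartiles over all individual
    responses pooled across AZs; an AZ is flagged iff its mean response
    lies strictly below Q1 or strictly above Q3.
    """
    pooled = matrix.amplitudes.ravel()
    if pooled.size < 4:
        raise ValueError("IQR flagging needs >= 4 pooled values")
    q1, q3 = np.percentile(pooled, [25, 75], method="linear")
    means = matrix.amplitudes.mean(axis=1)
    flagged = [
        az for az, m in zip(matrix.az_ids, means) if m < q1 or m > q3
    ]
    return float(q1), float(q3), flagged


def ks_compare(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of amplitude distributions.

    Returns the statistic ``D = sup |ECDF_a - ECDF_b|`` and the
    asymptotic two-sided p-value.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)
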