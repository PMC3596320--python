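"""Per-gene mRNA decay-rate estimation from transcription-arrest time courses.

After transcription is blocked (e.g. by rifampicin), each transcript's
concentration decays exponentially, so the log of its measured intensity is
linear in time with slope ``-k`` where ``k`` is the first-order degradation
rate constant (min^-1).  This module normalizes raw membrane intensities to
the pre-arrest reference, fits the pooled log-linear regression per gene,
converts rate constants to half-lives (t_1/2 = ln2 / k) and classifies each
fit by the relative uncertainty of its slope:

* ``reliable``          -- sigma_k <= 30 % (configurable),
* ``extremely_stable``  -- flat or rising series, or sigma_k >= 70 %,
* ``not_determined``    -- everything in between, or too few usable points.

sigma_k is the standard error of the fitted slope expressed as a percentage
of the slope magnitude, computed from all replicate series combined.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IntensityMatrix",
    "DecayFit",
    "RELIABLE",
    "NOT_DETERMINED",
    "EXTREMELY_STABLE",
    "normalize_to_reference",
    "fit_decay",
    "fit_all",
    "half_life",
    "mrna_concentrations",
    "summarize_halflives",
]

RELIABLE = "reliable"
NOT_DETERMINED = "not_determined"
EXTREMELY_STABLE = "extremely_stable"

#: default sigma_k (%) at or below which a fit is called reliable
DEFAULT_RELIABLE_MAX = 30.0
#: default sigma_k (%) at or above which a transcript is called extremely stable
DEFAULT_STABLE_MIN = 70.0


@dataclass
class IntensityMatrix:
    """Gene x membrane intensity matrix with membrane metadata.

    ``values`` holds strictly positive fluorescence intensities with gene ids
    as the row index and membrane ids as columns.  ``membranes`` is indexed by
    membrane id and carries ``time_min``, ``bio_rep``, ``tech_rep`` and
    ``batch`` columns.  The membranes measured immediately before
    transcription arrest (``time_min == 0``) act as the per-batch reference.
    """

    values: pd.DataFrame
    membranes: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.membranes.index):
            self.membranes = self.membranes.loc[self.values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def reference_columns(self, batch: str) -> list[str]:
        meta = self.membranes
        mask = (meta["batch"] == batch) & (meta["time_min"] == 0)
        return list(meta.index[mask])

    @property
    def batches(self) -> list[str]:
        return list(dict.fromkeys(self.membranes["batch"]))


def normalize_to_reference(raw: IntensityMatrix) -> IntensityMatrix:
    """Divide each batch by the mean intensity of its pre-arrest membrane.

    The scalar is the mean over genes of the reference (t = 0) membrane of
    the same batch, so a whole-batch gain (labelling efficiency, exposure)
    cancels while within-gene decay slopes are untouched.

    Raises ``ValueError`` if any batch lacks a reference membrane.
    """
    values = raw.values.copy()
    for batch in raw.batches:
        refs = raw.reference_columns(batch)
        if not refs:
            raise ValueError(f"batch {batch!r} has no reference (t=0) membrane")
        scale = float(raw.values[refs].to_numpy().mean())
        cols = raw.membranes.index[raw.membranes["batch"] == batch]
        values[cols] = values[cols] / scale
    return IntensityMatrix(values=values, membranes=raw.membranes.copy())


@dataclass
class DecayFit:
    """Result of a pooled log-linear decay fit for one gene."""

    gene: str
    k: float  # min^-1; -slope of ln(intensity) vs time
    sigma_k_pct: float  # 100 * SE(slope) / |slope|
    t_half_min: float  # ln2/k; NaN unless status == reliable
    n_points: int
    status: str
    reason: str = ""


def _ols_slope(times: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    res = stats.linregress(times, y)
    return float(res.slope), float(res.stderr)


def fit_decay(
    times: Sequence[float],
    intensities: Sequence[float],
    gene: str = "",
    reliable_max: float = DEFAULT_RELIABLE_MAX,
    stable_min: float = DEFAULT_STABLE_MIN,
) -> DecayFit:
    """Fit ln(intensity) = a - k*t by ordinary least squares over pooled points.

    All replicate measurements are pooled into a single regression; the
    uncertainty sigma_k is the standard error of the slope in percent of its
    magnitude.  Non-positive intensities are dropped point-wise (with a
    warning); at least 3 distinct time points must survive, otherwise the fit
    is refused with status ``not_determined``.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.shape != y.shape:
        raise ValueError("times and intensities must have equal length")
    keep = np.isfinite(y) & (y > 0) & np.isfinite(t)
    if keep.sum() < y.size:
        warnings.warn(
            f"gene {gene or '?'}: dropped {int(y.size - keep.sum())} "
            "non-positive/missing intensities",
            stacklevel=2,
        )
    t, y = t[keep], y[keep]
    n = int(t.size)
    if np.unique(t).size < 3:
        return DecayFit(gene, math.nan, math.nan, math.nan, n, NOT_DETERMINED,
                        reason="fewer than 3 usable time points")
    slope, se = _ols_slope(t, np.log(y))
    k = -slope
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma = 100.0 * se / abs(slope) if slope != 0 else math.inf
    if slope >= 0:
        # flat or rising after arrest: decay too slow to resolve in the window
        return DecayFit(gene, k, sigma, math.nan, n, EXTREMELY_STABLE,
                        reason="non-negative slope")
    if sigma >= stable_min:
        return DecayFit(gene, k, sigma, math.nan, n, EXTREMELY_STABLE,
                        reason=f"sigma_k >= {stable_min:g}%")
    if sigma <= reliable_max:
        return DecayFit(gene, k, sigma, half_life(k), n, RELIABLE)
    return DecayFit(gene, k, sigma, math.nan, n, NOT_DETERMINED,
                    reason=f"{reliable_max:g}% < sigma_k < {stable_min:g}%")


def half_life(k: float) -> float:
    """Half-life (min) of a transcript with degradation rate constant ``k``.

    t_1/2 = ln2 / k.  The same formula applied to a growth rate gives the
    doubling time.  ``k`` must be strictly positive.
    """
    if k <= 0:
        raise ValueError("half-life undefined for k <= 0 (extremely stable)")
    return math.log(2.0) / k


def fit_all(
    matrix: IntensityMatrix,
    reliable_max: float = DEFAULT_RELIABLE_MAX,
    stable_min: float = DEFAULT_STABLE_MIN,
) -> pd.DataFrame:
    """Fit every gene of a (normalized) intensity matrix.

    Returns a table with columns gene, k, sigma_k_pct, t_half_min, n_points,
    status, indexed by gene.
    """
    times = matrix.membranes["time_min"].to_numpy(dtype=float)
    vals = matrix.values.to_numpy(dtype=float)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for gene, y in zip(matrix.genes, vals):
            fit = fit_decay(times, y, gene=gene,
                            reliable_max=reliable_max, stable_min=stable_min)
            rows.append((fit.gene, fit.k, fit.sigma_k_pct, fit.t_half_min,
                         fit.n_points, fit.status))
    out = pd.DataFrame(
        rows,
        columns=["gene", "k", "sigma_k_pct", "t_half_min", "n_points", "status"],
    ).set_index("gene")
    return out


def mrna_concentrations(normalized: IntensityMatrix) -> pd.Series:
    """Per-gene pre-arrest mRNA level: mean normalized t=0 intensity.

    After per-batch reference normalization the t=0 value of a gene equals
    its share of the total pre-arrest signal, which is comparable between
    conditions hybridized with equal amounts of total RNA.
    """
    refs = [c for b in normalized.batches for c in normalized.reference_columns(b)]
    return normalized.values[refs].mean(axis=1).rename("mrna")


def summarize_halflives(
    fits: pd.DataFrame,
    status: str = RELIABLE,
    bins: int | Sequence[float] = 20,
    rolling_window: int = 25,
) -> dict:
    """Summary statistics of half-lives for one status class.

    Returns counts per status plus, for the selected class, the mean with its
    standard error, the median, histogram bins and a rolling average of the
    sorted half-lives (the smooth trend line drawn over half-life
    histograms).  An empty selection yields an empty (not raising) summary.
    """
    counts = fits["status"].value_counts().to_dict()
    for s in (RELIABLE, NOT_DETERMINED, EXTREMELY_STABLE):
        counts.setdefault(s, 0)
    sel = fits.loc[fits["status"] == status, "t_half_min"].dropna().sort_values()
    summary: dict = {"counts": counts, "n": int(sel.size)}
    if sel.empty:
        summary.update(mean=math.nan, sem=math.nan, median=math.nan,
                       hist_counts=[], hist_edges=[], rolling=pd.Series(dtype=float))
        return summary
    x = sel.to_numpy()
    sem = float(x.std(ddof=1) / math.sqrt(x.size)) if x.size > 1 else 0.0
    hist_counts, hist_edges = np.histogram(x, bins=bins)
    window = max(1, min(rolling_window, x.size))
    rolling = sel.rolling(window, center=True, min_periods=1).mean()
    summary.update(
        mean=float(x.mean()),
        sem=sem,
        median=float(np.median(x)),
        hist_counts=hist_counts.tolist(),
        hist_edges=hist_edges.tolist(),
        rolling=rolling,
    )
    return summary
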