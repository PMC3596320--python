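"""Partition of mRNA-level changes into transcriptional vs degradational control.

At steady state the transcription rate of a gene balances its losses to
degradation and growth dilution:

    V_T = (mu + k) * [mRNA]

with mu the growth rate (converted h^-1 -> min^-1 before meeting k).  When
dilution is negligible (generation times far exceeding half-lives, true for
the vast majority of bacterial transcripts), a concentration change between
two steady states decomposes into

    d ln V_T = d ln[mRNA] + d ln k

which defines the degradation regulation coefficient

    rho_D = -d ln k / d ln[mRNA],      rho_T = 1 - rho_D,

the opposite slope of the double-logarithmic plot of k versus the initial
(pre-arrest) mRNA concentration across the two conditions.  rho_D sorts genes
into five regulation patterns (I: pure degradation control, II: pure
transcription control, III: shared, IV: mainly degradational with
antagonistic transcription, V: mainly transcriptional with antagonistic
degradation) and three headline bins (rho_D <= 0 mainly transcriptional,
0 < rho_D < 1 shared, rho_D >= 1 mainly degradational).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrowthCondition",
    "TranscriptState",
    "RegulationResult",
    "doubling_time",
    "infer_transcription_rate",
    "dilution_negligible",
    "regulation_coefficients",
    "classify_mode",
    "compare_tables",
    "summarize_regulation",
    "MAINLY_TRANSCRIPTIONAL",
    "SHARED",
    "MAINLY_DEGRADATIONAL",
    "UNDETERMINED",
]

MAINLY_TRANSCRIPTIONAL = "mainly_transcriptional"
SHARED = "shared"
MAINLY_DEGRADATIONAL = "mainly_degradational"
UNDETERMINED = "undetermined"

#: default guard on |d ln mrna| below which rho_D is not computed
DEFAULT_EPSILON = 0.05
#: default half-width of the exact-mode bands around rho_D = 0 and 1
DEFAULT_MODE_TOLERANCE = 0.05
#: default k : dilution ratio above which growth dilution is neglected
DEFAULT_DILUTION_RATIO = 10.0


@dataclass(frozen=True)
class GrowthCondition:
    """A labelled culture condition with growth rate mu (h^-1)."""

    label: str
    mu: float  # h^-1
    culture_mode: str = "chemostat"  # or "batch_phase"

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("growth rate must be non-negative")

    @property
    def doubling_time_h(self) -> float:
        return doubling_time(self.mu)


def doubling_time(mu: float) -> float:
    """Doubling time ln2/mu, in the reciprocal units of ``mu``."""
    if mu <= 0:
        raise ValueError("doubling time undefined for mu <= 0")
    return math.log(2.0) / mu


@dataclass(frozen=True)
class TranscriptState:
    """Steady-state description of one transcript in one condition."""

    gene: str
    mrna: float  # concentration, arbitrary units (pre-arrest)
    k: float  # min^-1
    mu: float  # h^-1

    @property
    def v_t(self) -> float:
        return infer_transcription_rate(self.mrna, self.k, self.mu)


@dataclass(frozen=True)
class RegulationResult:
    gene: str
    d_ln_mrna: float
    d_ln_k: float
    rho_d: float
    rho_t: float
    mode: str  # I..V or "undetermined"
    bin: str
    conditions: tuple[str, str] = ("a", "b")


def infer_transcription_rate(mrna: float, k: float, mu: float) -> float:
    """Steady-state transcription rate V_T = (mu/60 + k) * mrna.

    ``mu`` is in h^-1 and ``k`` in min^-1; the result is in concentration
    units per minute.  V_T is derived, never measured: no genome-wide
    transcription-rate assay backs it, so it serves diagnostics only.
    """
    if mrna < 0 or k < 0 or mu < 0:
        raise ValueError("mrna, k and mu must be non-negative")
    return (mu / 60.0 + k) * mrna


def dilution_negligible(
    k: float, mu: float, ratio_threshold: float = DEFAULT_DILUTION_RATIO
) -> bool:
    """True when degradation outpaces growth dilution by ``ratio_threshold``.

    Compares k (min^-1) against mu/60; with the default factor 10 a
    transcript must turn over at least ten times faster than the culture
    doubles for dilution to be dropped from the balance.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if mu < 0:
        raise ValueError("mu must be non-negative")
    return k >= ratio_threshold * (mu / 60.0)


def classify_mode(
    rho_d: float, tolerance: float = DEFAULT_MODE_TOLERANCE
) -> tuple[str, str]:
    """Regulation pattern (I..V) and headline bin for a finite rho_D.

    Patterns I (pure degradation, rho_D ~ 1) and II (pure transcription,
    rho_D ~ 0) use a +/- ``tolerance`` band; outside the bands, 0 < rho_D < 1
    is shared control (III), rho_D > 1 mainly degradational (IV) and
    rho_D < 0 mainly transcriptional (V).  The bins use closed/open edges
    rho_D <= 0 / 0 < rho_D < 1 / rho_D >= 1.
    """
    if not math.isfinite(rho_d):
        raise ValueError("rho_d must be finite")
    if abs(rho_d - 1.0) <= tolerance:
        mode = "I"
    elif abs(rho_d) <= tolerance:
        mode = "II"
    elif 0.0 < rho_d < 1.0:
        mode = "III"
    elif rho_d > 1.0:
        mode = "IV"
    else:
        mode = "V"
    if rho_d <= 0.0:
        bin_ = MAINLY_TRANSCRIPTIONAL
    elif rho_d < 1.0:
        bin_ = SHARED
    else:
        bin_ = MAINLY_DEGRADATIONAL
    return mode, bin_


def regulation_coefficients(
    a: TranscriptState,
    b: TranscriptState,
    epsilon: float = DEFAULT_EPSILON,
    mode_tolerance: float = DEFAULT_MODE_TOLERANCE,
) -> RegulationResult:
    """rho_D/rho_T for one gene between two steady states.

    Genes whose concentration change is within ``epsilon`` on the natural-log
    scale are reported undetermined rather than forced into a bin (the ratio
    is numerically unstable there).
    """
    if a.gene != b.gene:
        raise ValueError("states describe different genes")
    for s in (a, b):
        if s.mrna <= 0 or s.k <= 0:
            raise ValueError("regulation analysis needs positive mrna and k")
    d_m = math.log(b.mrna / a.mrna)
    d_k = math.log(b.k / a.k)
    if abs(d_m) < epsilon:
        return RegulationResult(a.gene, d_m, d_k, math.nan, math.nan,
                                UNDETERMINED, UNDETERMINED, ("a", "b"))
    rho_d = -d_k / d_m
    mode, bin_ = classify_mode(rho_d, mode_tolerance)
    return RegulationResult(a.gene, d_m, d_k, rho_d, 1.0 - rho_d, mode, bin_,
                            ("a", "b"))


def compare_tables(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    epsilon: float = DEFAULT_EPSILON,
    mode_tolerance: float = DEFAULT_MODE_TOLERANCE,
    require_reliable: bool = True,
) -> pd.DataFrame:
    """Vectorized regulation analysis over two per-gene tables.

    Each table must be indexed by gene and carry columns ``k`` and ``mrna``;
    if a ``status`` column is present and ``require_reliable`` is set, only
    genes reliable in both conditions enter the comparison.  Returns one row
    per analyzable gene with d_ln_mrna, d_ln_k, rho_d, rho_t, mode and bin.
    """
    a, b = table_a, table_b
    if require_reliable:
        if "status" in a.columns:
            a = a[a["status"] == "reliable"]
        if "status" in b.columns:
            b = b[b["status"] == "reliable"]
    genes = a.index.intersection(b.index)
    a, b = a.loc[genes], b.loc[genes]
    ok = (a["k"] > 0) & (b["k"] > 0) & (a["mrna"] > 0) & (b["mrna"] > 0)
    a, b = a[ok], b[ok]
    d_m = np.log(b["mrna"].to_numpy() / a["mrna"].to_numpy())
    d_k = np.log(b["k"].to_numpy() / a["k"].to_numpy())
    determinate = np.abs(d_m) >= epsilon
    with np.errstate(divide="ignore", invalid="ignore"):
        rho_d = np.where(determinate, -d_k / d_m, np.nan)
    rho_t = 1.0 - rho_d
    modes, bins = [], []
    for det, r in zip(determinate, rho_d):
        if not det:
            modes.append(UNDETERMINED)
            bins.append(UNDETERMINED)
        else:
            m, bn = classify_mode(float(r), mode_tolerance)
            modes.append(m)
            bins.append(bn)
    return pd.DataFrame(
        {
            "d_ln_mrna": d_m,
            "d_ln_k": d_k,
            "rho_d": rho_d,
            "rho_t": rho_t,
            "mode": modes,
            "bin": bins,
        },
        index=a.index,
    )


def summarize_regulation(results: pd.DataFrame) -> pd.DataFrame:
    """Headline-bin counts and percentages over determinate genes.

    Mirrors the three-column summary (mainly transcriptional / shared /
    mainly degradational) used to report which mechanism dominates between
    two conditions.  Percentages are over genes with a determinate bin;
    undetermined genes are counted separately with no percentage.
    """
    order = [MAINLY_TRANSCRIPTIONAL, SHARED, MAINLY_DEGRADATIONAL, UNDETERMINED]
    counts = {b: int((results["bin"] == b).sum()) for b in order}
    n_det = sum(counts[b] for b in order[:3])
    rows = []
    for b in order:
        pct = 100.0 * counts[b] / n_det if (n_det and b != UNDETERMINED) else math.nan
        rows.append((b, counts[b], pct))
    return pd.DataFrame(rows, columns=["bin", "n_genes", "pct"]).set_index("bin")
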