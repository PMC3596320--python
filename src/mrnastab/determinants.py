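"""Sequence features and covariance (ANCOVA) modelling of half-life determinants.

Computes per-gene predictors of mRNA stability -- codon adaptation index
(CAI), tRNA adaptation index (tAI), GC content, upstream AGGAG
(ribosome-binding-site-like) motif counts, gene length/position and the
magnitude of the upstream folding free energy |dG| (read from a precomputed
folding-tool table, never folded internally) -- and fits a linear covariance
model of ln(half-life) on quantitative (z-scored) and qualitative (factor)
predictors with bidirectional stepwise selection under the Akaike
information criterion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "extract_upstream",
    "reference_codon_weights",
    "compute_cai",
    "tai_codon_weights",
    "compute_tai",
    "DEFAULT_WOBBLE_PENALTIES",
    "count_motif",
    "gc_content",
    "CovarianceModelFit",
    "fit_covariance_model",
    "growth_rate_only_r2",
    "DEFAULT_QUANTITATIVE",
    "DEFAULT_QUALITATIVE",
]

_BACTERIAL = CodonTable.unambiguous_dna_by_id[11]
_STOPS = set(_BACTERIAL.stop_codons)
_AA_OF = dict(_BACTERIAL.forward_table)
_FAMILIES: dict[str, list[str]] = {}
for codon, aa in _AA_OF.items():
    _FAMILIES.setdefault(aa, []).append(codon)
#: codons excluded from CAI/tAI geometric means: stops plus single-codon
#: families (Met ATG, Trp TGG) whose weight is 1 by construction
_SINGLE_FAMILY = {c for fam in _FAMILIES.values() if len(fam) == 1 for c in fam}


def _clean_dna(seq: str) -> str:
    return str(seq).upper().replace("U", "T")


def _codons(cds: str) -> list[str]:
    cds = _clean_dna(cds)
    if len(cds) % 3:
        raise ValueError("CDS length must be divisible by 3")
    return [cds[i:i + 3] for i in range(0, len(cds), 3)]


# ---------------------------------------------------------------------------
# upstream windows and simple sequence statistics
# ---------------------------------------------------------------------------

def extract_upstream(genome: str, start: int, strand: str) -> str:
    """101-nt window from -100 to +1 relative to a start codon (1-based).

    ``start`` is the genomic coordinate of the first base of the start codon
    on the given strand.  On the minus strand the corresponding genomic
    window runs downstream in plus-strand coordinates and is
    reverse-complemented.  Windows running off the sequence end are truncated
    with a warning.
    """
    genome = _clean_dna(genome)
    n = len(genome)
    if not 1 <= start <= n:
        raise ValueError("start coordinate outside sequence")
    if strand == "+":
        lo, hi = start - 100, start  # 1-based inclusive
        if lo < 1:
            warnings.warn("upstream window truncated at sequence start", stacklevel=2)
            lo = 1
        return genome[lo - 1:hi]
    if strand == "-":
        lo, hi = start, start + 100
        if hi > n:
            warnings.warn("upstream window truncated at sequence end", stacklevel=2)
            hi = n
        return str(Seq(genome[lo - 1:hi]).reverse_complement())
    raise ValueError("strand must be '+' or '-'")


def count_motif(sequence: str, motif: str = "AGGAG") -> int:
    """Overlapping occurrences of ``motif`` on the given strand only."""
    seq = _clean_dna(sequence)
    motif = _clean_dna(motif)
    count = 0
    pos = seq.find(motif)
    while pos != -1:
        count += 1
        pos = seq.find(motif, pos + 1)
    return count


def gc_content(sequence: str) -> float:
    """(G+C) / (A+C+G+T); ambiguity codes are excluded from both counts."""
    seq = _clean_dna(sequence)
    if not seq:
        raise ValueError("empty sequence")
    unambiguous = sum(seq.count(b) for b in "ACGT")
    if unambiguous == 0:
        raise ValueError("no unambiguous bases in sequence")
    return (seq.count("G") + seq.count("C")) / unambiguous


# ---------------------------------------------------------------------------
# codon adaptation index
# ---------------------------------------------------------------------------

def reference_codon_weights(
    reference_cds: Iterable[str], pseudocount: float = 0.5
) -> dict[str, float]:
    """Relative adaptiveness w of every sense codon from a reference set.

    Codon counts are pooled over the reference CDS (typically ribosomal
    protein genes, the most highly expressed); within each synonymous family
    w = count / max count, with ``pseudocount`` substituted for codons never
    observed so that rare codons keep a finite weight.
    """
    counts: dict[str, float] = {c: 0.0 for c in _AA_OF}
    for cds in reference_cds:
        for codon in _codons(cds):
            if codon in counts:
                counts[codon] += 1.0
    weights: dict[str, float] = {}
    for fam in _FAMILIES.values():
        fam_counts = {c: (counts[c] if counts[c] > 0 else pseudocount) for c in fam}
        top = max(fam_counts.values())
        for c in fam:
            weights[c] = fam_counts[c] / top
    return weights


def _geometric_mean_weights(codons: Sequence[str], weights: Mapping[str, float],
                            what: str) -> float:
    logs = []
    skipped = 0
    for i, codon in enumerate(codons):
        if codon in _STOPS:
            if i < len(codons) - 1:
                warnings.warn(f"internal stop codon at position {i}", stacklevel=3)
            continue
        if codon in _SINGLE_FAMILY:
            continue
        if codon not in weights:
            skipped += 1
            continue
        logs.append(math.log(weights[codon]))
    if skipped:
        warnings.warn(f"{what}: {skipped} codons without weights excluded",
                      stacklevel=3)
    if not logs:
        raise ValueError(f"no codons usable for {what}")
    return math.exp(sum(logs) / len(logs))


def compute_cai(cds: str, weights: Mapping[str, float]) -> float:
    """CAI: geometric mean of relative adaptiveness over the CDS codons.

    Stop codons and the single-codon families (Met, Trp) are excluded from
    the product since their weight is 1 irrespective of usage.
    """
    return _geometric_mean_weights(_codons(cds), weights, "CAI")


# ---------------------------------------------------------------------------
# tRNA adaptation index
# ---------------------------------------------------------------------------

#: wobble-pairing selective penalties s (codon 3rd base : anticodon 1st base);
#: Watson-Crick pairs carry no penalty.  Values are the standard optimized
#: defaults of the tAI formulation.
DEFAULT_WOBBLE_PENALTIES: Mapping[str, float] = {
    "WC": 0.0,
    "GU": 0.41,   # codon ...U read by G34 anticodon
    "IC": 0.28,   # codon ...C read by inosine (A34) anticodon
    "IA": 0.9999,  # codon ...A read by inosine (A34) anticodon
    "UG": 0.68,   # codon ...G read by U34 anticodon
}

_WOBBLE_34 = {"T": ("G", "GU"), "C": ("A", "IC"), "A": ("A", "IA"), "G": ("T", "UG")}


def tai_codon_weights(
    trna_copies: Mapping[str, float],
    penalties: Mapping[str, float] = DEFAULT_WOBBLE_PENALTIES,
) -> dict[str, float]:
    """Per-codon tAI weights from genomic tRNA copy numbers.

    ``trna_copies`` maps anticodon sequences (5'->3', DNA alphabet) to gene
    copy numbers.  Each sense codon is read by its Watson-Crick anticodon
    (no penalty) plus one wobble anticodon with penalty s; the absolute
    weight sums (1 - s) * copies over both and is normalized to the maximum.
    Codons recognized by no encoded tRNA get weight 0 (excluded downstream
    with a warning).
    """
    copies = {_clean_dna(a): float(c) for a, c in trna_copies.items()}
    absolute: dict[str, float] = {}
    for codon in _AA_OF:
        wc_anticodon = str(Seq(codon).reverse_complement())
        w = copies.get(wc_anticodon, 0.0)
        wobble_base, pair = _WOBBLE_34[codon[2]]
        wobble_anticodon = wobble_base + wc_anticodon[1:]
        if wobble_anticodon != wc_anticodon:
            w += (1.0 - penalties[pair]) * copies.get(wobble_anticodon, 0.0)
        absolute[codon] = w
    top = max(absolute.values())
    if top <= 0:
        raise ValueError("no tRNA copy numbers match any sense codon")
    return {c: w / top for c, w in absolute.items()}


def compute_tai(
    cds: str,
    trna_copies: Mapping[str, float],
    penalties: Mapping[str, float] = DEFAULT_WOBBLE_PENALTIES,
) -> float:
    """tAI: geometric mean of normalized tRNA-availability weights.

    Codons with zero weight (no recognizing tRNA in the table) are excluded
    with a warning rather than zeroing the whole index.
    """
    weights = tai_codon_weights(trna_copies, penalties)
    usable = {c: w for c, w in weights.items() if w > 0}
    return _geometric_mean_weights(_codons(cds), usable, "tAI")


# ---------------------------------------------------------------------------
# covariance model of ln(half-life)
# ---------------------------------------------------------------------------

DEFAULT_QUANTITATIVE = ("ln_mrna", "length", "position", "cai", "tai", "gc", "abs_dg")
DEFAULT_QUALITATIVE = ("category", "mu_level", "motif_class")


@dataclass
class CovarianceModelFit:
    """AIC-selected linear model of ln(half-life).

    ``terms`` are the selected model terms (quantitative column names and
    ``C(...)`` factors); coefficient tables come from the refitted selected
    model.  ``dropped`` lists candidate terms removed up front for making the
    design rank-deficient.
    """

    terms: list[str]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    aic: float
    r_squared: float
    response: str = "ln_thalf"
    transform: str = "response ln(t_half); quantitative predictors z-scored"
    dropped: list[str] = field(default_factory=list)
    results: object = None  # statsmodels RegressionResults of the final fit


def _zscore(data: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    out = data.copy()
    for col in columns:
        x = out[col].astype(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"quantitative predictor {col!r} has no variance")
        out[col] = (x - x.mean()) / sd
    return out


def _fit_terms(data: pd.DataFrame, response: str, terms: Sequence[str]):
    rhs = " + ".join(terms) if terms else "1"
    return smf.ols(f"{response} ~ {rhs}", data=data).fit()


def _screen_rank(data: pd.DataFrame, response: str,
                 terms: Sequence[str]) -> tuple[list[str], list[str]]:
    """Drop candidate terms that add no rank to the design matrix."""
    kept: list[str] = []
    dropped: list[str] = []
    rank = 1  # intercept
    for term in terms:
        model = smf.ols(f"{response} ~ {' + '.join(kept + [term])}", data=data)
        new_rank = np.linalg.matrix_rank(model.exog)
        if new_rank > rank:
            kept.append(term)
            rank = new_rank
        else:
            dropped.append(term)
    return kept, dropped


def _stepwise_aic(data: pd.DataFrame, response: str,
                  candidates: Sequence[str]) -> list[str]:
    """Bidirectional stepwise search minimizing AIC, from the full model.

    At each step the single add/drop move with the lowest AIC is taken;
    exact ties are broken toward the smaller model.  Accepted moves never
    increase AIC, so the search terminates.
    """
    cache: dict[frozenset, float] = {}

    def aic_of(terms: frozenset) -> float:
        if terms not in cache:
            cache[terms] = _fit_terms(data, response, sorted(terms)).aic
        return cache[terms]

    current = frozenset(candidates)
    current_aic = aic_of(current)
    for _ in range(10 * max(1, len(candidates))):
        moves = []
        for term in current:
            trial = current - {term}
            moves.append((aic_of(trial), len(trial), trial))
        for term in set(candidates) - current:
            trial = current | {term}
            moves.append((aic_of(trial), len(trial), trial))
        if not moves:
            break
        best_aic, best_size, best = min(moves, key=lambda m: (m[0], m[1]))
        tie = abs(best_aic - current_aic) <= 1e-9
        if best_aic < current_aic - 1e-9 or (tie and best_size < len(current)):
            current, current_aic = best, best_aic
        else:
            break
    return sorted(current)


def fit_covariance_model(
    data: pd.DataFrame,
    response: str = "ln_thalf",
    quantitative: Sequence[str] = DEFAULT_QUANTITATIVE,
    qualitative: Sequence[str] = DEFAULT_QUALITATIVE,
) -> CovarianceModelFit:
    """Fit and AIC-select the half-life covariance model.

    One row per gene per growth-rate condition; the response is ln(t_half).
    Quantitative predictors are z-scored (so coefficients are per-SD effects
    on log half-life and comparable across predictors); qualitative ones
    enter as treatment-coded factors.  Rows with missing values in any used
    column are dropped; a rank-deficient candidate design is repaired by
    removing the offending terms, which are reported in ``dropped``.
    """
    quantitative = [q for q in quantitative if q in data.columns]
    qualitative = [q for q in qualitative if q in data.columns]
    used = [response] + quantitative + qualitative
    df = data[used].dropna().reset_index(drop=True)
    if df.empty:
        raise ValueError("no complete observations to fit")
    df = _zscore(df, quantitative)
    candidates = list(quantitative) + [f"C({q})" for q in qualitative]
    candidates, dropped = _screen_rank(df, response, candidates)
    selected = _stepwise_aic(df, response, candidates)
    res = _fit_terms(df, response, selected)
    return CovarianceModelFit(
        terms=selected,
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        aic=float(res.aic),
        r_squared=float(res.rsquared),
        response=response,
        dropped=dropped,
        results=res,
    )


def growth_rate_only_r2(
    data: pd.DataFrame,
    response: str = "ln_thalf",
    quantitative: Sequence[str] = DEFAULT_QUANTITATIVE,
    qualitative: Sequence[str] = DEFAULT_QUALITATIVE,
    growth_col: str = "mu_level",
) -> dict[str, float]:
    """Per-condition model R^2 with the growth-rate factor withheld.

    Fits the same AIC-selected covariance model separately within each
    growth-rate level (the growth-rate term being constant there).
    Comparing these R^2 values with the pooled model's quantifies how much
    of the half-life variance the growth rate alone explains.
    """
    qual = [q for q in qualitative if q != growth_col]
    out: dict[str, float] = {}
    for level, sub in data.groupby(growth_col):
        fit = fit_covariance_model(sub, response=response,
                                   quantitative=quantitative, qualitative=qual)
        out[str(level)] = fit.r_squared
    return out
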