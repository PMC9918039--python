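"""Correlations between questionnaire length/composition and mean overlap.

Three planned comparisons relate a questionnaire's mean Jaccard overlap to
(i) its number of items, (ii) the number of symptoms it probes, and (iii)
the fraction of those symptoms probed only in compound form.  Pearson's
product-moment correlation is the default (a rank correlation is available
via ``method="spearman"``); p-values come from the two-sided test with
n - 2 degrees of freedom and are reported unadjusted — with only three
planned comparisons no multiplicity correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InstrumentLookupError
from .coding import InstrumentSummary
from .overlap import OverlapMatrix


@dataclass(frozen=True)
class CorrelationResult:
    """A correlation coefficient with its two-sided p-value."""

    x_name: str
    y_name: str
    n: int
    r: float
    p_value: float
    method: str = "pearson"
    note: str | None = None


def pearson_correlation(x: Sequence[float], y: Sequence[float],
                        x_name: str = "x", y_name: str = "y",
                        method: str = "pearson") -> CorrelationResult:
    """Correlate two equal-length vectors (n >= 3, neither constant)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DegenerateInputError(
            f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.size < 3:
        raise DegenerateInputError(f"need n >= 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input vector; correlation undefined")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(x_name, y_name, int(x.size),
                             float(res.statistic), float(res.pvalue), method)


def overlap_length_association(summaries: Sequence[InstrumentSummary],
                               overlaps: OverlapMatrix,
                               method: str = "pearson",
                               ) -> list[CorrelationResult]:
    """The three planned length/composition vs mean-overlap correlations.

    Returns results for (n_items, n_total symptoms, fraction compound) each
    against the per-questionnaire mean Jaccard index.  Reference instruments
    never enter.  A degenerate comparison (constant vector) is reported with
    NaN coefficients and an explanatory note instead of aborting the others.
    """
    means = overlaps.per_instrument_mean
    qs = overlaps.questionnaires
    by_name = {s.instrument: s for s in summaries}
    missing = [q for q in qs if q not in by_name]
    if missing:
        raise InstrumentLookupError(f"no summary for instrument(s) {missing}")

    y = [means[q] for q in qs]
    planned = [
        ("n_items", [by_name[q].n_items for q in qs]),
        ("n_symptoms", [by_name[q].n_total for q in qs]),
        ("pct_compound", [by_name[q].pct_compound for q in qs]),
    ]
    out = []
    for name, x in planned:
        try:
            out.append(pearson_correlation(x, y, x_name=name,
                                           y_name="mean_jaccard", method=method))
        except DegenerateInputError as err:
            out.append(CorrelationResult(name, "mean_jaccard", len(qs),
                                         math.nan, math.nan, method, str(err)))
    return out
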