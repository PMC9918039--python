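"""Pairwise Jaccard content overlap between instruments.

For two instruments the Jaccard index is ``s / (u1 + u2 + s)`` where *s* is
the number of symptoms probed by both and *u1*, *u2* the numbers unique to
each.  Presence means code 1 **or** 2: the compound code records how an
instrument probes a symptom, not whether it does.  A pair whose union is
empty (both instruments probe nothing, e.g. after restricting to a category
neither covers) has an undefined index; such pairs are reported and excluded
from means rather than imputed.

Strength labels follow the conventional behavioural-science interpretation
bands (very weak < 0.20 <= weak < 0.40 <= moderate < 0.60 <= strong
< 0.80 <= very strong), applied to the unrounded index.  The printed band
edges in the source convention leave gaps (0.19 -> 0.20); half-open
intervals close them, with each boundary belonging to the upper band.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (InstrumentLookupError, InsufficientInstrumentsError,
                     SymptomOverlapError)
from .matrix import SymptomMatrix

STRENGTH_BANDS = (
    (0.20, "very weak"),
    (0.40, "weak"),
    (0.60, "moderate"),
    (0.80, "strong"),
    (math.inf, "very strong"),
)


@dataclass(frozen=True)
class PairOverlap:
    """Shared/unique symptom counts and Jaccard index for one pair."""

    first: str
    second: str
    s: int
    u1: int
    u2: int

    @property
    def defined(self) -> bool:
        return self.s + self.u1 + self.u2 > 0

    @property
    def index(self) -> float:
        """Jaccard index s/(u1+u2+s); NaN when the union is empty."""
        if not self.defined:
            return math.nan
        return self.s / (self.u1 + self.u2 + self.s)

    def swapped(self) -> "PairOverlap":
        return PairOverlap(self.second, self.first, self.s, self.u2, self.u1)


@dataclass
class OverlapMatrix:
    """Symmetric pairwise Jaccard table with per-instrument and grand means.

    ``values`` has unit diagonal for instruments probing >= 1 symptom and NaN
    where a pair is undefined.  ``per_instrument_mean`` averages each
    instrument's defined indices against the *non-reference* peers only;
    ``grand_mean`` averages the C(n,2) defined non-reference pairs.
    """

    values: pd.DataFrame
    reference_flags: dict[str, bool] = field(default_factory=dict)
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def instruments(self) -> list[str]:
        return list(self.values.columns)

    def is_reference(self, instrument: str) -> bool:
        return self.reference_flags.get(instrument, False)

    @property
    def questionnaires(self) -> list[str]:
        return [i for i in self.instruments if not self.is_reference(i)]

    @property
    def per_instrument_mean(self) -> pd.Series:
        peers = self.questionnaires
        out = {}
        for inst in self.instruments:
            vals = [self.values.at[inst, p] for p in peers
                    if p != inst and not math.isnan(self.values.at[inst, p])]
            out[inst] = float(np.mean(vals)) if vals else math.nan
        return pd.Series(out)

    @property
    def grand_mean(self) -> float:
        """Mean over all defined unordered questionnaire pairs."""
        qs = self.questionnaires
        vals = [self.values.at[a, b] for a, b in itertools.combinations(qs, 2)
                if not math.isnan(self.values.at[a, b])]
        return float(np.mean(vals)) if vals else math.nan

    @property
    def mean_of_instrument_means(self) -> float:
        """Mean of the per-questionnaire means (equals grand_mean when all
        pairs are defined, since each pair enters two instrument means)."""
        pm = self.per_instrument_mean[self.questionnaires]
        return float(pm.mean())


def jaccard_pair(m: SymptomMatrix, a: str, b: str) -> PairOverlap:
    """Shared/unique counts and Jaccard index between instruments a and b."""
    va = m.presence_vector(a).to_numpy()
    vb = m.presence_vector(b).to_numpy()
    s = int(np.sum(va & vb))
    u1 = int(np.sum(va & ~vb))
    u2 = int(np.sum(~va & vb))
    return PairOverlap(a, b, s, u1, u2)


def pairwise_matrix(m: SymptomMatrix,
                    include_reference: bool = True) -> OverlapMatrix:
    """All unordered pairwise Jaccard indices of a matrix.

    ``include_reference=False`` drops the reference classification columns
    from the grid entirely; means always exclude them either way.
    """
    insts = m.instruments if include_reference else m.questionnaires
    if len([i for i in insts if not m.is_reference(i)]) < 2:
        raise InsufficientInstrumentsError(
            "pairwise overlap needs at least two non-reference instruments")
    P = m.presence[insts].to_numpy()
    inter = (P[:, :, None] & P[:, None, :]).sum(axis=0).astype(float)
    tot = P.sum(axis=0)
    union = tot[:, None] + tot[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(union > 0, inter / np.maximum(union, 1), np.nan)
    values = pd.DataFrame(vals, index=insts, columns=insts)
    undefined = [(a, b) for a, b in itertools.combinations(insts, 2)
                 if math.isnan(values.at[a, b])]
    flags = {i: m.is_reference(i) for i in insts}
    return OverlapMatrix(values, flags, undefined)


def category_overlap(m: SymptomMatrix, category: str,
                     include_reference: bool = True) -> OverlapMatrix:
    """Pairwise overlap restricted to the symptoms of one category.

    Pairs where neither instrument probes any symptom of the category are
    undefined (NaN) and excluded from the category mean.
    """
    return pairwise_matrix(m.restrict_to_category(category), include_reference)


def category_means(m: SymptomMatrix) -> pd.DataFrame:
    """Grand mean overlap per category, in matrix category order."""
    rows = []
    for cat in m.category_labels():
        om = category_overlap(m, cat)
        rows.append({"category": cat, "mean_jaccard": om.grand_mean,
                     "n_symptoms": int((m.categories == cat).sum()),
                     "n_undefined_pairs": len(om.undefined_pairs)})
    return pd.DataFrame(rows)


def interpret_strength(index: float) -> str:
    """Map a Jaccard index in [0, 1] to its strength label."""
    if math.isnan(index) or not 0.0 <= index <= 1.0:
        raise SymptomOverlapError(f"index {index!r} outside [0, 1]")
    for upper, label in STRENGTH_BANDS:
        if index < upper:
            return label
    raise AssertionError("unreachable")


def overlap_with_references(m: SymptomMatrix) -> pd.DataFrame:
    """Each questionnaire's Jaccard index against each reference list."""
    om = pairwise_matrix(m, include_reference=True)
    refs = [i for i in om.instruments if om.is_reference(i)]
    if not refs:
        raise InstrumentLookupError("matrix has no reference-flagged columns")
    return om.values.loc[om.questionnaires, refs]
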