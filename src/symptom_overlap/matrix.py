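"""Core data model: the harmonized symptom x instrument coding matrix.

The central object is :class:`SymptomMatrix`, a dense table of integer codes
with one row per harmonized symptom and one column per instrument
(questionnaire or reference classification list).  Codes follow the
three-valued scheme used in questionnaire content-overlap analysis:

* ``0`` — the instrument has no item probing the symptom;
* ``1`` — at least one item probes the symptom specifically (on its own),
  or the symptom is idiosyncratic to this instrument;
* ``2`` — the symptom appears only inside compound items, i.e. items that
  probe two or more distinct symptoms at once.

Reference classification lists (e.g. ICSD-3 and DSM-5 symptom lists) are
stored as ordinary columns with ``reference_flags`` set, so they take part
in pairwise comparisons but are excluded from questionnaire-to-questionnaire
averages.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CategoryError, CodingError, InstrumentLookupError

VALID_CODES = (0, 1, 2)

#: The nine symptom categories used by default (sleep-medicine scheme).
DEFAULT_CATEGORIES = (
    "sleepiness",
    "insomnia",
    "respiratory",
    "psychiatric",
    "behavioral during sleep",
    "motor",
    "sleep period",
    "general",
    "not otherwise specified",
)


def normalize_label(label: str) -> str:
    """Canonicalize a symptom/instrument label: NFC + whitespace trim.

    Matching is exact after this normalization; lumping differently worded
    symptoms is a human harmonization step, never done here.
    """
    return unicodedata.normalize("NFC", str(label)).strip()


@dataclass(frozen=True)
class InstrumentInfo:
    """Per-instrument metadata: questionnaire length and reference status."""

    instrument: str
    n_items: int
    is_reference: bool = False

    def __post_init__(self):
        if self.n_items < 0:
            raise ValueError(f"n_items must be >= 0, got {self.n_items}")


@dataclass(frozen=True)
class ItemRecord:
    """One questionnaire item and the harmonized symptoms it maps to.

    ``not_applicable`` marks items unrelated to symptoms (the four excluded
    kinds: sociodemographic, history, lifestyle, contextual); such items carry
    an empty symptom mapping and are dropped before the coding matrix is
    derived.
    """

    NA_REASONS = ("sociodemographic", "history", "lifestyle", "contextual", "none")

    instrument: str
    item_id: str
    item_text: str = ""
    mapped_symptoms: tuple[str, ...] = ()
    not_applicable: bool = False
    reason: str = "none"

    def __post_init__(self):
        object.__setattr__(self, "mapped_symptoms",
                           tuple(normalize_label(s) for s in self.mapped_symptoms))
        if self.reason not in self.NA_REASONS:
            raise ValueError(f"unknown NA reason {self.reason!r}")
        if self.not_applicable != (len(self.mapped_symptoms) == 0):
            raise ValueError(
                f"item {self.instrument}/{self.item_id}: not_applicable must be "
                "true exactly when no symptoms are mapped")
        if (self.reason != "none") != self.not_applicable:
            raise ValueError(
                f"item {self.instrument}/{self.item_id}: an NA reason is required "
                "iff the item is not applicable")


@dataclass
class SymptomMatrix:
    """Symptoms x instruments coding table with categories and reference flags.

    Parameters
    ----------
    codes
        Integer DataFrame, index = symptom labels, columns = instrument
        identifiers, values in {0, 1, 2}.
    categories
        Series mapping each symptom to exactly one category label.
    reference_flags
        Mapping instrument -> bool; True marks a classification symptom list.
        Instruments absent from the mapping default to False.
    """

    codes: pd.DataFrame
    categories: pd.Series
    reference_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        try:
            if (self.codes.dtypes != np.int64).any():
                as_int = self.codes.astype(np.int64)
                if (as_int == self.codes).all().all():
                    self.codes = as_int
        except (TypeError, ValueError):
            pass  # leave as-is; validate() reports the offending cells
        self.codes.index = [normalize_label(s) for s in self.codes.index]
        self.codes.columns = [normalize_label(i) for i in self.codes.columns]
        cats = {normalize_label(k): normalize_label(v)
                for k, v in dict(self.categories).items()}
        self.categories = pd.Series(cats).reindex(self.codes.index)
        self.reference_flags = {
            normalize_label(k): bool(v) for k, v in self.reference_flags.items()}

    def check(self) -> "SymptomMatrix":
        """Raise a typed error if any invariant is violated; return self."""
        violations = self.validate()
        if violations:
            raise _violation_error(violations)
        return self

    # -- basic views ----------------------------------------------------

    @property
    def symptoms(self) -> list[str]:
        return list(self.codes.index)

    @property
    def instruments(self) -> list[str]:
        return list(self.codes.columns)

    @property
    def n_symptoms(self) -> int:
        return self.codes.shape[0]

    @property
    def n_instruments(self) -> int:
        return self.codes.shape[1]

    def is_reference(self, instrument: str) -> bool:
        return self.reference_flags.get(instrument, False)

    @property
    def questionnaires(self) -> list[str]:
        """Instrument identifiers that are not reference classification lists."""
        return [i for i in self.instruments if not self.is_reference(i)]

    @property
    def references(self) -> list[str]:
        return [i for i in self.instruments if self.is_reference(i)]

    @property
    def presence(self) -> pd.DataFrame:
        """Boolean presence matrix: both specific (1) and compound (2) count."""
        return self.codes > 0

    def presence_vector(self, instrument: str) -> pd.Series:
        if instrument not in self.codes.columns:
            raise InstrumentLookupError(f"unknown instrument {instrument!r}")
        return self.codes[instrument] > 0

    def symptom_set(self, instrument: str) -> frozenset[str]:
        """The set of symptoms an instrument probes (code > 0)."""
        v = self.presence_vector(instrument)
        return frozenset(v.index[v])

    def restrict_to_category(self, category: str) -> "SymptomMatrix":
        from .errors import SymptomOverlapError
        category = normalize_label(category)
        mask = self.categories == category
        if not mask.any():
            raise SymptomOverlapError(f"unknown category {category!r}")
        return SymptomMatrix(self.codes.loc[mask],
                             self.categories[mask],
                             dict(self.reference_flags))

    def category_labels(self) -> list[str]:
        """Categories in first-appearance (row) order."""
        seen: dict[str, None] = {}
        for c in self.categories:
            seen.setdefault(c, None)
        return list(seen)

    # -- validation ------------------------------------------------------

    def validate(self) -> list[str]:
        """Return human-readable descriptions of every invariant violation.

        An empty list means the matrix is valid.  Violations are returned,
        not raised, so callers can report all problems at once.
        """
        out: list[str] = []
        idx = pd.Index(self.codes.index)
        cols = pd.Index(self.codes.columns)
        for lab in idx[idx.duplicated()].unique():
            out.append(f"duplicate symptom label {lab!r}")
        for lab in cols[cols.duplicated()].unique():
            out.append(f"duplicate instrument identifier {lab!r}")
        bad = ~self.codes.isin(VALID_CODES)
        if bad.to_numpy().any():
            for (sym, inst), flag in bad.stack().items():
                if flag:
                    out.append(
                        f"code {self.codes.at[sym, inst]!r} outside {{0,1,2}} at "
                        f"(symptom {sym!r}, instrument {inst!r})")
        for sym, cat in self.categories.items():
            if cat is None or (isinstance(cat, float) and np.isnan(cat)) or cat == "":
                out.append(f"symptom {sym!r} lacks a category")
        for inst in self.reference_flags:
            if inst not in cols:
                out.append(f"reference flag for unknown instrument {inst!r}")
        if not any(not self.is_reference(i) for i in cols):
            out.append("no non-reference instrument present")
        return out

    # -- equality --------------------------------------------------------

    def equals(self, other: "SymptomMatrix") -> bool:
        return (self.codes.equals(other.codes)
                and self.categories.equals(other.categories)
                and {i: self.is_reference(i) for i in self.instruments}
                == {i: other.is_reference(i) for i in other.instruments})


def _violation_error(violations: list[str]) -> Exception:
    msg = "; ".join(violations)
    if any("category" in v for v in violations):
        return CategoryError(msg)
    if any("outside {0,1,2}" in v for v in violations):
        return CodingError(msg)
    if any("reference flag" in v for v in violations):
        return InstrumentLookupError(msg)
    from .errors import SymptomOverlapError
    return SymptomOverlapError(msg)


def validate_matrix(m: SymptomMatrix) -> list[str]:
    """Module-level alias for :meth:`SymptomMatrix.validate`."""
    return m.validate()
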