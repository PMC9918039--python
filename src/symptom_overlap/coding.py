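"""Derivation of the 0/1/2 coding matrix from item mappings, and the
frequency / classification-coverage summaries built on it.

Coding rules
------------
For each (symptom, instrument):

* code **1** (specific) if at least one applicable item of that instrument
  maps to the symptom alone.  Specificity takes precedence: a symptom that
  appears both alone in one item and inside a multi-symptom item is specific.
* code **2** (compound) if the symptom appears only inside items mapping to
  two or more distinct symptoms.
* code **0** if no applicable item of the instrument maps to the symptom.

Idiosyncratic symptoms — present in exactly one questionnaire across the
whole set — are a property of the assembled matrix, not of single items,
and are detected by :func:`idiosyncratic_symptoms`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (CategoryError, DuplicateItemError, FlagError,
                     InstrumentLookupError)
from .matrix import (InstrumentInfo, ItemRecord, SymptomMatrix,
                     normalize_label)


@dataclass(frozen=True)
class InstrumentSummary:
    """Counts of specific/compound symptoms for one questionnaire."""

    instrument: str
    n_items: int
    n_specific: int
    n_compound: int

    @property
    def n_total(self) -> int:
        return self.n_specific + self.n_compound

    @property
    def pct_compound(self) -> float:
        """Compound symptoms as a fraction of all symptoms probed."""
        return self.n_compound / self.n_total if self.n_total else math.nan


@dataclass(frozen=True)
class CoverageReport:
    """How much of a reference symptom list the questionnaires cover."""

    reference: tuple[str, ...]
    n_reference_symptoms: int
    n_found: int
    missing_from_questionnaires: tuple[str, ...]
    extra_beyond_reference: tuple[str, ...]

    @property
    def found_fraction(self) -> float:
        if self.n_reference_symptoms == 0:
            return math.nan
        return self.n_found / self.n_reference_symptoms


def derive_matrix_from_items(items: Sequence[ItemRecord],
                             categories: Mapping[str, str],
                             reference_matrix: SymptomMatrix | None = None,
                             reference_flags: Mapping[str, bool] | None = None,
                             ) -> SymptomMatrix:
    """Build the coding matrix from item-level symptom mappings.

    Not-applicable items are excluded first.  Symptom and instrument order
    follow first appearance among the applicable items; the result does not
    depend on item ordering beyond that.

    Parameters
    ----------
    items
        Item records; duplicates of (instrument, item_id) are an error.
    categories
        Mapping symptom -> category; must cover every mapped symptom.
    reference_matrix
        Optional matrix of reference classification columns to append; its
        symptoms are merged (union) and its columns flagged as references.
    """
    categories = {normalize_label(k): normalize_label(v)
                  for k, v in categories.items()}
    seen_ids: set[tuple[str, str]] = set()
    for it in items:
        key = (it.instrument, it.item_id)
        if key in seen_ids:
            raise DuplicateItemError(
                f"duplicate item id {it.item_id!r} in instrument {it.instrument!r}")
        seen_ids.add(key)

    selected = [it for it in items if not it.not_applicable]
    instruments = list(dict.fromkeys(it.instrument for it in selected))
    symptoms = list(dict.fromkeys(s for it in selected for s in it.mapped_symptoms))
    for s in symptoms:
        if s not in categories:
            raise CategoryError(f"mapped symptom {s!r} has no category")

    specific: set[tuple[str, str]] = set()
    compound: set[tuple[str, str]] = set()
    for it in selected:
        target = specific if len(it.mapped_symptoms) == 1 else compound
        for s in it.mapped_symptoms:
            target.add((s, it.instrument))

    codes = pd.DataFrame(0, index=symptoms, columns=instruments, dtype=int)
    for s, i in compound:
        codes.at[s, i] = 2
    for s, i in specific:      # specificity precedence overrides compound
        codes.at[s, i] = 1

    cats = pd.Series({s: categories[s] for s in symptoms})
    flags = dict(reference_flags or {})

    if reference_matrix is not None:
        ref = reference_matrix
        all_symptoms = symptoms + [s for s in ref.symptoms if s not in codes.index]
        codes = codes.reindex(index=all_symptoms, fill_value=0)
        for inst in ref.instruments:
            codes[inst] = ref.codes[inst].reindex(all_symptoms, fill_value=0)
            flags[inst] = True
        extra_cats = {s: ref.categories[s] for s in ref.symptoms
                      if s not in cats.index}
        cats = pd.concat([cats, pd.Series(extra_cats)]).reindex(all_symptoms)

    return SymptomMatrix(codes, cats, flags).check()


def symptom_frequencies(m: SymptomMatrix) -> pd.DataFrame:
    """Per-symptom count of questionnaires probing it (code > 0).

    Reference classification columns are ignored: they are symptom lists,
    not questionnaires.  Rows are sorted by descending count, ties broken
    alphabetically by symptom label.
    """
    counts = m.presence[m.questionnaires].sum(axis=1).astype(int)
    df = pd.DataFrame({"symptom": m.symptoms,
                       "category": m.categories.tolist(),
                       "count": counts.to_numpy()})
    df = df.sort_values(["count", "symptom"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    return df


def category_frequencies(m: SymptomMatrix) -> pd.DataFrame:
    """Frequency table grouped by category (category-major, count-sorted)."""
    df = symptom_frequencies(m)
    order = {c: k for k, c in enumerate(m.category_labels())}
    df = df.assign(_ord=df["category"].map(order))
    df = df.sort_values(["_ord", "count", "symptom"],
                        ascending=[True, False, True],
                        kind="mergesort").drop(columns="_ord")
    return df.reset_index(drop=True)


def idiosyncratic_symptoms(m: SymptomMatrix) -> list[str]:
    """Symptoms present in exactly one questionnaire (references ignored)."""
    counts = m.presence[m.questionnaires].sum(axis=1)
    return sorted(counts.index[counts == 1])


def n_symptoms_in_half(m: SymptomMatrix, at_least: bool = True) -> int:
    """Count symptoms appearing in (at least) half of the questionnaires.

    ``at_least=True`` counts symptoms with count >= ceil(n/2); False counts
    only those with count exactly n/2 (0 when n is odd).
    """
    n = len(m.questionnaires)
    counts = m.presence[m.questionnaires].sum(axis=1)
    if at_least:
        return int((counts >= math.ceil(n / 2)).sum())
    return int((counts == n / 2).sum()) if n % 2 == 0 else 0


def instrument_summary(m: SymptomMatrix,
                       meta: Iterable[InstrumentInfo]) -> list[InstrumentSummary]:
    """Per-questionnaire specific/compound/total symptom counts.

    Every non-reference instrument must have metadata (for its item count).
    """
    by_name = {mi.instrument: mi for mi in meta}
    out = []
    for inst in m.questionnaires:
        if inst not in by_name:
            raise InstrumentLookupError(f"no metadata for instrument {inst!r}")
        col = m.codes[inst]
        out.append(InstrumentSummary(instrument=inst,
                                     n_items=by_name[inst].n_items,
                                     n_specific=int((col == 1).sum()),
                                     n_compound=int((col == 2).sum())))
    return out


def summary_table(summaries: Iterable[InstrumentSummary],
                  overlaps=None, digits: int = 3) -> pd.DataFrame:
    """Assemble the per-questionnaire summary table (mean overlap first).

    ``overlaps`` is an :class:`~symptom_overlap.overlap.OverlapMatrix`; when
    given, its per-instrument means form the first numeric column.
    """
    rows = []
    for s in summaries:
        row = {"instrument": s.instrument}
        if overlaps is not None:
            row["mean_jaccard"] = round(overlaps.per_instrument_mean[s.instrument],
                                        digits)
        row.update(n_items=s.n_items, n_specific=s.n_specific,
                   n_compound=s.n_compound, n_total=s.n_total)
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values("n_total", ascending=False,
                          kind="mergesort").reset_index(drop=True)


def classification_coverage(m: SymptomMatrix,
                            reference: str | Sequence[str]) -> CoverageReport:
    """Coverage of a reference symptom list by the questionnaires.

    ``reference`` is one reference-flagged instrument or several (their
    symptom sets are pooled by union).  A reference symptom counts as found
    iff some questionnaire has code > 0 for it.  The ``extra`` set holds
    questionnaire symptoms absent from *all* reference columns of the
    matrix, i.e. symptoms with no counterpart in the classifications.
    """
    refs = [reference] if isinstance(reference, str) else list(reference)
    refs = [normalize_label(r) for r in refs]
    for r in refs:
        if r not in m.instruments:
            raise InstrumentLookupError(f"unknown instrument {r!r}")
        if not m.is_reference(r):
            raise FlagError(f"instrument {r!r} is not flagged as a reference list")

    ref_set: set[str] = set()
    for r in refs:
        ref_set |= m.symptom_set(r)
    quest_set: set[str] = set()
    for q in m.questionnaires:
        quest_set |= m.symptom_set(q)
    all_ref_set: set[str] = set()
    for r in m.references:
        all_ref_set |= m.symptom_set(r)

    found = sorted(ref_set & quest_set)
    missing = sorted(ref_set - quest_set)
    extra = sorted(quest_set - all_ref_set)
    return CoverageReport(reference=tuple(refs),
                          n_reference_symptoms=len(ref_set),
                          n_found=len(found),
                          missing_from_questionnaires=tuple(missing),
                          extra_beyond_reference=tuple(extra))
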