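"""Reading and writing coding matrices, item tables, and instrument metadata.

Two plain-text layouts are supported, chosen by the ``layout`` argument:

* **wide** — one row per symptom; columns ``symptom,category,<inst1>,...``.
  Every cell must be present (a complete spreadsheet); missing cells are an
  error, never imputed.
* **long** — columns ``symptom,category,instrument,code``; cells absent from
  the file default to code 0, so sparse listings of nonzero cells are valid.

The delimiter follows the file extension: comma for ``.csv``, tab for
``.tsv``.  Reference flags and column order are stored in a JSON sidecar
(``<path>.meta.json``) so a write→read round trip reproduces the matrix
exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (CategoryError, CodingError, ConflictError,
                     InstrumentLookupError)
from .matrix import (InstrumentInfo, ItemRecord, SymptomMatrix,
                     normalize_label, _violation_error)

LAYOUTS = ("wide", "long")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() == ".tsv" else ","


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def read_symptom_matrix(path, layout: str = "wide",
                        reference_instruments: Sequence[str] | None = None,
                        ) -> SymptomMatrix:
    """Read a coding matrix from a delimited text file.

    Parameters
    ----------
    path
        ``.csv`` (comma) or ``.tsv`` (tab) file.
    layout
        ``"wide"`` or ``"long"`` (see module docstring).
    reference_instruments
        Identifiers to flag as reference classification lists.  When None,
        flags are taken from the sidecar file if one exists.

    Raises
    ------
    CodingError, ConflictError, CategoryError, InstrumentLookupError
        On malformed content; messages name the offending row/column.
    """
    path = Path(path)
    if layout not in LAYOUTS:
        raise ValueError(f"layout must be one of {LAYOUTS}, got {layout!r}")
    sep = _sep_for(path)

    if layout == "wide":
        df = pd.read_csv(path, sep=sep, dtype={0: str, 1: str})
        df.columns = [normalize_label(c) for c in df.columns]
        sym_col, cat_col = df.columns[:2]
        symbols = [normalize_label(s) for s in df[sym_col]]
        codes = df.drop(columns=[sym_col, cat_col])
        if codes.isna().to_numpy().any():
            miss = codes.isna()
            sym, inst = next((symbols[i], c) for c in miss.columns
                             for i in np.flatnonzero(miss[c].to_numpy()))
            raise CodingError(
                f"missing cell at (symptom {sym!r}, instrument {inst!r}); "
                "wide layout requires a complete table")
        codes.index = symbols
        categories = pd.Series(df[cat_col].tolist(), index=symbols)
    else:
        df = pd.read_csv(path, sep=sep, dtype={"symptom": str, "category": str,
                                               "instrument": str})
        required = {"symptom", "category", "instrument", "code"}
        if not required.issubset(df.columns):
            raise ValueError(f"long layout needs columns {sorted(required)}")
        df["symptom"] = df["symptom"].map(normalize_label)
        df["instrument"] = df["instrument"].map(normalize_label)
        df["category"] = df["category"].map(normalize_label)
        dup = df.groupby(["symptom", "instrument"])["code"].nunique()
        conflicts = dup[dup > 1]
        if len(conflicts):
            sym, inst = conflicts.index[0]
            raise ConflictError(
                f"conflicting codes for (symptom {sym!r}, instrument {inst!r})")
        df = df.drop_duplicates(["symptom", "instrument"])
        symptoms = list(dict.fromkeys(df["symptom"]))          # first appearance
        instruments = list(dict.fromkeys(df["instrument"]))
        codes = (df.pivot(index="symptom", columns="instrument", values="code")
                   .reindex(index=symptoms, columns=instruments)
                   .fillna(0))
        codes.columns.name = None
        codes.index.name = None
        ncat = df.groupby("symptom")["category"].nunique()
        twocat = ncat[ncat > 1]
        if len(twocat):
            raise CategoryError(
                f"symptom {twocat.index[0]!r} given two categories")
        categories = df.drop_duplicates("symptom").set_index("symptom")["category"]
        categories = categories.reindex(symptoms)

    bad = ~codes.isin((0, 1, 2))
    if bad.to_numpy().any():
        inst = next(c for c in bad.columns if bad[c].any())
        sym = bad.index[int(np.flatnonzero(bad[inst].to_numpy())[0])]
        raise CodingError(
            f"code {codes.at[sym, inst]!r} outside {{0,1,2}} at "
            f"(symptom {sym!r}, instrument {inst!r})")

    flags: dict[str, bool] = {}
    if reference_instruments is None and _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text(encoding="utf-8"))
        reference_instruments = meta.get("reference_instruments", [])
    for ref in reference_instruments or []:
        ref = normalize_label(ref)
        if ref not in codes.columns:
            raise InstrumentLookupError(
                f"reference instrument {ref!r} not among instruments "
                f"{list(codes.columns)}")
        flags[ref] = True

    m = SymptomMatrix(codes, categories, flags)
    violations = m.validate()
    if violations:
        raise _violation_error(violations)
    return m


def write_symptom_matrix(m: SymptomMatrix, path, layout: str = "wide") -> Path:
    """Write a matrix plus its ``.meta.json`` sidecar; round-trip exact.

    The matrix is validated first; an invalid matrix is refused before any
    file is touched.  Long layout writes every cell (including zeros) so that
    all-zero rows/columns and ordering survive the round trip.
    """
    path = Path(path)
    if layout not in LAYOUTS:
        raise ValueError(f"layout must be one of {LAYOUTS}, got {layout!r}")
    m.check()
    sep = _sep_for(path)
    if layout == "wide":
        out = pd.DataFrame({"symptom": m.symptoms,
                            "category": m.categories.tolist()})
        for inst in m.instruments:
            out[inst] = m.codes[inst].to_numpy()
    else:
        rows = [(s, m.categories[s], i, int(m.codes.at[s, i]))
                for i in m.instruments for s in m.symptoms]
        out = pd.DataFrame(rows, columns=["symptom", "category",
                                          "instrument", "code"])
    out.to_csv(path, sep=sep, index=False, encoding="utf-8", lineterminator="\n")
    meta = {"layout": layout,
            "instruments": m.instruments,
            "reference_instruments": m.references}
    _sidecar(path).write_text(json.dumps(meta, indent=1, ensure_ascii=False) + "\n",
                              encoding="utf-8")
    return path


def read_instrument_info(path) -> list[InstrumentInfo]:
    """Read instrument metadata: columns ``instrument,n_items,is_reference``."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"instrument": str})
    if df["instrument"].duplicated().any():
        dup = df["instrument"][df["instrument"].duplicated()].iloc[0]
        raise InstrumentLookupError(f"duplicate instrument {dup!r} in metadata")
    out = []
    for rec in df.itertuples(index=False):
        is_ref = bool(getattr(rec, "is_reference", False))
        out.append(InstrumentInfo(normalize_label(rec.instrument),
                                  int(rec.n_items), is_ref))
    return out


def write_instrument_info(meta: Iterable[InstrumentInfo], path) -> Path:
    path = Path(path)
    df = pd.DataFrame([{"instrument": i.instrument, "n_items": i.n_items,
                        "is_reference": i.is_reference} for i in meta])
    df.to_csv(path, sep=_sep_for(path), index=False, encoding="utf-8",
              lineterminator="\n")
    return path
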