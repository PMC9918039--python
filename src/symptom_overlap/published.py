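"""Adapter for the published sleep-questionnaire coding spreadsheet.

The original study distributes its harmonized 60-symptom x 14-column coding
matrix (12 adult multi-sleep-disorder screening questionnaires plus the
ICSD-3 and DSM-5 symptom lists) as a spreadsheet in its public repository.
That file is not bundled here; download it and point
:func:`load_published_matrix` (or ``scripts/reproduce_published.py``) at it
to rerun the whole analysis end to end.

Questionnaire item counts are published and keyed in
:data:`PUBLISHED_ITEM_COUNTS`; they are the metadata needed for the
length-overlap correlations.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import SymptomOverlapError
from .matrix import InstrumentInfo, SymptomMatrix, normalize_label

#: Published questionnaire lengths (items per instrument).
PUBLISHED_ITEM_COUNTS = {
    "SDQ": 175, "Sleep50": 50, "ASQ": 84, "SDS-CL-25": 25, "HSDQ": 32,
    "PSQI": 24, "ISDI": 86, "GSAQ": 11, "SDS-CL-17": 17, "SSC": 22,
    "BNSQ": 22, "OSQ": 19,
}

#: Alternate spellings seen for instrument columns, mapped to canonical ids.
_ALIASES = {
    "sleep 50": "Sleep50", "sleep-50": "Sleep50", "sleep50": "Sleep50",
    "sds-cl25": "SDS-CL-25", "sds-cl17": "SDS-CL-17",
    "sds cl 25": "SDS-CL-25", "sds cl 17": "SDS-CL-17",
    "icsd": "ICSD-3", "icsd3": "ICSD-3", "icsd-3": "ICSD-3",
    "dsm": "DSM-5", "dsm5": "DSM-5", "dsm-5": "DSM-5",
}

REFERENCE_COLUMNS = ("ICSD-3", "DSM-5")


def _canonical(name: str) -> str:
    n = normalize_label(name)
    return _ALIASES.get(n.lower(), n)


def published_instrument_info() -> list[InstrumentInfo]:
    info = [InstrumentInfo(q, n, False)
            for q, n in PUBLISHED_ITEM_COUNTS.items()]
    info += [InstrumentInfo(r, 0, True) for r in REFERENCE_COLUMNS]
    return info


def find_published_matrix(root) -> Path:
    """Locate a user-supplied copy of the published spreadsheet under
    ``<root>/data/published/`` (any ``.xlsx``/``.csv``/``.tsv`` file)."""
    base = Path(root) / "data" / "published"
    for ext in ("*.xlsx", "*.xls", "*.csv", "*.tsv"):
        hits = sorted(base.glob(ext))
        if hits:
            return hits[0]
    raise FileNotFoundError(
        f"no published coding spreadsheet under {base}; download it from the "
        "study's public repository and place it there")


def load_published_matrix(path) -> SymptomMatrix:
    """Read the published spreadsheet into a :class:`SymptomMatrix`.

    Accepts ``.xlsx`` (first sheet) or delimited text.  The first column is
    taken as the symptom label; a column named like ``category`` supplies
    categories (otherwise all symptoms fall into one ``unspecified``
    category); remaining recognized columns are the 12 questionnaires and
    the two classification lists.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"published coding spreadsheet not found at {path}; download it "
            "from the study's public repository and pass its path")
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep="\t" if path.suffix.lower() == ".tsv" else ",")
    df.columns = [_canonical(c) for c in df.columns]

    sym_col = df.columns[0]
    cat_col = next((c for c in df.columns if c.lower().startswith("categ")), None)
    known = set(PUBLISHED_ITEM_COUNTS) | set(REFERENCE_COLUMNS)
    inst_cols = [c for c in df.columns if c in known]
    if len(inst_cols) < 12:
        raise SymptomOverlapError(
            f"recognized only {len(inst_cols)} instrument columns "
            f"({inst_cols}); check the spreadsheet layout")

    symptoms = [normalize_label(s) for s in df[sym_col]]
    codes = df[inst_cols].copy()
    codes.index = symptoms
    cats = (pd.Series([normalize_label(c) for c in df[cat_col]], index=symptoms)
            if cat_col else pd.Series("unspecified", index=symptoms))
    flags = {r: True for r in REFERENCE_COLUMNS if r in inst_cols}
    return SymptomMatrix(codes, cats, flags).check()
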