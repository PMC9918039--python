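"""Seeded generation of synthetic coding matrices.

The generator emulates the structure of a harmonized symptom x instrument
spreadsheet: ~60 symptoms partitioned into nine categories, ~12
questionnaires, 0/1/2 codes, a few planted idiosyncratic symptoms, and
optional reference classification columns built as a noisy union of the
questionnaires.

Two generative modes are available:

* ``independent`` (null model) — each (symptom, instrument) cell is present
  independently with its category/instrument probability.  Under this model
  the pairwise Jaccard index between two instruments with common presence
  probability *p* converges to ``p / (2 - p)`` as the number of symptoms
  grows (:func:`expected_jaccard_independent`).
* ``prototype`` — a shared base symptom set is drawn once and each
  instrument flips cells with a small probability, planting controllable
  excess overlap (real coding matrices are strongly dependent across
  instruments).

Default parameters mirror the study conditions the analysis was designed
for: core categories (insomnia, respiratory, sleepiness) have high presence
probabilities and peripheral ones low, giving an expected pairwise index of
about 0.43 under independence; the compound-coding rate is 0.32; four
idiosyncratic symptoms are planted.  Randomness uses numpy's seeded
``default_rng`` (PCG64), so identical configurations reproduce identical
matrices on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, SymptomOverlapError
from .matrix import InstrumentInfo, SymptomMatrix

#: (category, symptom count, presence probability) — study-shaped defaults.
DEFAULT_CATEGORY_PLAN = (
    ("sleepiness", 6, 0.75),
    ("insomnia", 6, 0.85),
    ("respiratory", 8, 0.85),
    ("psychiatric", 6, 0.30),
    ("behavioral during sleep", 8, 0.30),
    ("motor", 6, 0.35),
    ("sleep period", 6, 0.30),
    ("general", 8, 0.35),
    ("not otherwise specified", 6, 0.35),
)


@dataclass(frozen=True)
class ReferenceRule:
    """How reference classification columns are synthesized.

    Each reference column starts from the union of the questionnaires'
    symptom sets, drops union symptoms with probability ``dropout`` and adds
    union-absent symptoms with probability ``addition`` (so the reference
    can both miss questionnaire symptoms and list symptoms no questionnaire
    probes, as real classifications do).
    """

    names: tuple[str, ...] = ("REF-A", "REF-B")
    dropout: float = 0.15
    addition: float = 0.10


@dataclass
class SimConfig:
    """Generative parameters for a synthetic coding matrix."""

    categories: tuple[tuple[str, int], ...] = tuple(
        (c, n) for c, n, _ in DEFAULT_CATEGORY_PLAN)
    presence_prob: float | Mapping[str, float] | Mapping[tuple[str, str], float] = \
        field(default_factory=lambda: {c: p for c, _, p in DEFAULT_CATEGORY_PLAN})
    n_instruments: int = 12
    compound_prob: float = 0.32
    n_idiosyncratic: int = 4
    reference_copies: ReferenceRule | None = field(default_factory=ReferenceRule)
    mode: str = "independent"
    flip_prob: float = 0.05
    instrument_scale: tuple[float, ...] | None = None
    seed: int = 0

    @property
    def n_symptoms(self) -> int:
        return sum(n for _, n in self.categories)

    def validate(self) -> None:
        if self.n_instruments < 1:
            raise ConfigError("n_instruments must be >= 1")
        if any(n < 0 for _, n in self.categories) or self.n_symptoms == 0:
            raise ConfigError("category symptom counts must be >= 0, summing > 0")
        if not 0.0 <= self.compound_prob <= 1.0:
            raise ConfigError(f"compound_prob {self.compound_prob} outside [0,1]")
        if not 0 <= self.n_idiosyncratic <= self.n_symptoms:
            raise ConfigError("n_idiosyncratic must be in [0, n_symptoms]")
        if self.mode not in ("independent", "prototype"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ConfigError(f"flip_prob {self.flip_prob} outside [0,1]")
        grid = _probability_grid(self)
        if ((grid < 0) | (grid > 1)).to_numpy().any():
            raise ConfigError("presence probabilities must lie in [0, 1]")
        if self.reference_copies is not None:
            r = self.reference_copies
            if not (0 <= r.dropout <= 1 and 0 <= r.addition <= 1):
                raise ConfigError("reference dropout/addition outside [0,1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(self.presence_prob, Mapping):
            d["presence_prob"] = {str(k): v for k, v in self.presence_prob.items()}
        return d


def _instrument_names(cfg: SimConfig) -> list[str]:
    return [f"Q{k + 1:02d}" for k in range(cfg.n_instruments)]


def _symptom_labels(cfg: SimConfig) -> tuple[list[str], list[str]]:
    symptoms, cats = [], []
    for cat, n in cfg.categories:
        for k in range(n):
            symptoms.append(f"{cat} symptom {k + 1}")
            cats.append(cat)
    return symptoms, cats


def _probability_grid(cfg: SimConfig) -> pd.DataFrame:
    """Resolve presence_prob to a full symptoms x instruments grid."""
    symptoms, cats = _symptom_labels(cfg)
    insts = _instrument_names(cfg)
    pp = cfg.presence_prob
    if isinstance(pp, Mapping):
        sample = next(iter(pp)) if len(pp) else None
        if isinstance(sample, tuple):       # keyed by (category, instrument)
            arr = np.array([[pp.get((cat, inst), 0.0) for inst in insts]
                            for cat in cats])
        else:                               # keyed by category, broadcast
            col = np.array([pp.get(cat, 0.0) for cat in cats])
            arr = np.repeat(col[:, None], len(insts), axis=1)
        grid = pd.DataFrame(arr, index=symptoms, columns=insts)
    else:
        grid = pd.DataFrame(float(pp), index=symptoms, columns=insts)
    if cfg.instrument_scale is not None:
        if len(cfg.instrument_scale) != cfg.n_instruments:
            raise ConfigError("instrument_scale length must equal n_instruments")
        grid = grid.mul(pd.Series(cfg.instrument_scale, index=insts), axis=1)
        grid = grid.clip(0.0, 1.0)
    return grid


def simulate_matrix(cfg: SimConfig) -> SymptomMatrix:
    """Draw one coding matrix from the configured generative model.

    Planted idiosyncratic symptoms occupy the last ``n_idiosyncratic`` rows:
    background presence is zeroed and each is forced present (code 1, as
    idiosyncratic symptoms are by definition probed specifically) in one
    uniformly chosen instrument.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    symptoms, cats = _symptom_labels(cfg)
    insts = _instrument_names(cfg)
    grid = _probability_grid(cfg).to_numpy()
    n_sym, n_inst = grid.shape

    if cfg.mode == "independent":
        present = rng.random((n_sym, n_inst)) < grid
    else:
        base_p = grid.mean(axis=1)
        base = rng.random(n_sym) < base_p
        flips = rng.random((n_sym, n_inst)) < cfg.flip_prob
        present = base[:, None] ^ flips

    compound_draw = rng.random((n_sym, n_inst)) < cfg.compound_prob
    codes = np.where(present, np.where(compound_draw, 2, 1), 0)

    if cfg.n_idiosyncratic:
        rows = np.arange(n_sym - cfg.n_idiosyncratic, n_sym)
        codes[rows, :] = 0
        hosts = rng.integers(0, n_inst, size=cfg.n_idiosyncratic)
        codes[rows, hosts] = 1

    codes_df = pd.DataFrame(codes, index=symptoms, columns=insts)
    flags: dict[str, bool] = {}
    if cfg.reference_copies is not None:
        rule = cfg.reference_copies
        union = codes_df.to_numpy().sum(axis=1) > 0
        for name in rule.names:
            keep = union & (rng.random(n_sym) >= rule.dropout)
            add = ~union & (rng.random(n_sym) < rule.addition)
            codes_df[name] = np.where(keep | add, 1, 0)
            flags[name] = True

    m = SymptomMatrix(codes_df, pd.Series(cats, index=symptoms), flags)
    return m.check()


def simulate_instrument_info(m: SymptomMatrix, seed: int = 0,
                             items_per_symptom: float = 1.5,
                             ) -> list[InstrumentInfo]:
    """Synthesize questionnaire lengths consistent with a simulated matrix.

    Item counts scale with the number of symptoms probed (about 1.5 items
    per symptom, matching the ratio seen in real multi-disorder screening
    questionnaires) plus Poisson jitter for non-symptom items.
    """
    rng = np.random.default_rng(seed)
    out = []
    for inst in m.instruments:
        n_sym = int(m.presence_vector(inst).sum())
        n_items = max(n_sym, round(n_sym * items_per_symptom)) + int(rng.poisson(2))
        out.append(InstrumentInfo(inst, n_items, m.is_reference(inst)))
    return out


def expected_jaccard_independent(p: float) -> float:
    """Limit of the pairwise Jaccard index under independent presence.

    For two instruments whose symptom presences are i.i.d. Bernoulli(p), the
    index s/(s+u1+u2) converges almost surely to p^2 / (2p - p^2) = p/(2-p)
    as the number of symptoms grows.  Undefined at p = 0 (empty union).
    """
    if not 0.0 < p <= 1.0:
        raise SymptomOverlapError(f"p must lie in (0, 1], got {p}")
    return p / (2.0 - p)


def superset_matrix(n_symptoms: int, lengths: Sequence[int]) -> SymptomMatrix:
    """Deterministic supersets-by-length regime: instrument *i* probes the
    first ``lengths[i]`` symptoms, so longer instruments strictly contain
    shorter ones and length correlates positively with mean overlap."""
    if any(not 0 <= k <= n_symptoms for k in lengths):
        raise ConfigError("every length must lie in [0, n_symptoms]")
    symptoms = [f"symptom {j + 1:02d}" for j in range(n_symptoms)]
    codes = pd.DataFrame(
        {f"Q{i + 1:02d}": [1 if j < k else 0 for j in range(n_symptoms)]
         for i, k in enumerate(lengths)}, index=symptoms)
    cats = pd.Series("block", index=symptoms)
    return SymptomMatrix(codes, cats).check()
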