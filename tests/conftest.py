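import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from symptom_overlap import SymptomMatrix

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_matrix(codes, categories=None, reference=(), symptoms=None,
                instruments=None) -> SymptomMatrix:
    """Build a SymptomMatrix from a plain nested list of codes."""
    arr = np.asarray(codes)
    symptoms = symptoms or [f"s{i}" for i in range(arr.shape[0])]
    instruments = instruments or [f"I{j}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=symptoms, columns=instruments)
    if categories is None:
        cats = pd.Series("general", index=symptoms)
    else:
        cats = pd.Series(list(categories), index=symptoms)
    return SymptomMatrix(df, cats, {r: True for r in reference})


@st.composite
def coding_matrices(draw, max_symptoms=12, max_instruments=6,
                    min_symptoms=1, min_instruments=2, n_categories=3):
    """Random valid coding matrices (no reference columns)."""
    ns = draw(st.integers(min_symptoms, max_symptoms))
    ni = draw(st.integers(min_instruments, max_instruments))
    codes = draw(st.lists(
        st.lists(st.integers(0, 2), min_size=ni, max_size=ni),
        min_size=ns, max_size=ns))
    cats = [f"cat{draw(st.integers(0, n_categories - 1))}" for _ in range(ns)]
    return make_matrix(codes, categories=cats)


@pytest.fixture
def tiny_matrix():
    """3 symptoms x 3 questionnaires + 1 reference column."""
    return make_matrix(
        [[1, 0, 2, 1],
         [2, 1, 0, 1],
         [0, 0, 1, 0]],
        categories=["insomnia", "insomnia", "motor"],
        symptoms=["initiating insomnia", "maintaining insomnia", "leg movement"],
        instruments=["A", "B", "C", "REF"],
        reference=["REF"])


@pytest.fixture
def study_matrix():
    """A study-shaped simulated matrix (60 x 12 + 2 references)."""
    from symptom_overlap import SimConfig, simulate_matrix
    return simulate_matrix(SimConfig(seed=20230120))
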