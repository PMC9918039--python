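#!/usr/bin/env python
"""Rerun the full published-study analysis from its coding spreadsheet.

The original study distributes its harmonized 60-symptom x 14-column coding
matrix in its public repository; place that file (xlsx or csv) under
``data/published/`` (or pass ``--matrix``), then run:

    python scripts/reproduce_published.py --out results/published

This prints the headline numbers (grand mean Jaccard, per-questionnaire
means, extreme pairwise values, per-category means, coverage counts, and
the length-overlap correlations) and writes the complete table/figure
bundle via the report pipeline.
"""

from __future__ import annotations

import argparse
import tempfile
from pathlib import Path

from symptom_overlap import (classification_coverage, category_means,
                             idiosyncratic_symptoms, instrument_summary,
                             interpret_strength, n_symptoms_in_half,
                             overlap_length_association, pairwise_matrix,
                             RunConfig, run_pipeline, symptom_frequencies,
                             write_instrument_info, write_symptom_matrix)
from symptom_overlap.published import (find_published_matrix,
                                       load_published_matrix,
                                       published_instrument_info)

REPO_ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--matrix", type=Path, default=None,
                    help="Path to the published spreadsheet "
                         "(default: search data/published/).")
    ap.add_argument("--out", type=Path, default=Path("results/published"))
    args = ap.parse_args()

    path = args.matrix or find_published_matrix(REPO_ROOT)
    m = load_published_matrix(path)
    meta = published_instrument_info()
    print(f"loaded {path}: {m.n_symptoms} symptoms x {m.n_instruments} "
          f"columns ({len(m.questionnaires)} questionnaires)")

    om = pairwise_matrix(m)
    gm = om.grand_mean
    print(f"\ngrand mean Jaccard = {gm:.3f} ({interpret_strength(gm)})")
    print("\nper-questionnaire mean Jaccard:")
    means = om.per_instrument_mean[m.questionnaires].sort_values(ascending=False)
    for q, v in means.items():
        print(f"  {q:10s} {v:.3f}")

    qv = om.values.loc[m.questionnaires, m.questionnaires]
    stacked = qv.where(~(qv == 1.0)).stack()
    print(f"\nhighest pairwise overlap: {stacked.max():.2f}"
          f"  lowest: {stacked.min():.2f}")

    print("\nper-category mean Jaccard:")
    print(category_means(m).to_string(index=False))

    freq = symptom_frequencies(m)
    print(f"\nidiosyncratic symptoms: {idiosyncratic_symptoms(m)}")
    print(f"symptoms in >= half the questionnaires: {n_symptoms_in_half(m)}")
    cov = classification_coverage(m, m.references)
    print(f"classification coverage: {cov.n_found}/{cov.n_reference_symptoms} "
          f"({100 * cov.found_fraction:.1f}%)")

    summaries = instrument_summary(m, meta)
    for r in overlap_length_association(summaries, om):
        print(f"correlation {r.x_name} vs mean overlap: "
              f"r = {r.r:.3f}, p = {r.p_value:.3f}")

    with tempfile.TemporaryDirectory() as tmp:
        wide = Path(tmp) / "matrix.csv"
        write_symptom_matrix(m, wide, "wide")
        meta_path = Path(tmp) / "meta.csv"
        write_instrument_info(meta, meta_path)
        run_pipeline(RunConfig(wide, args.out, meta_path=meta_path))
    print(f"\nfull artifact bundle -> {args.out}")


if __name__ == "__main__":
    main()
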