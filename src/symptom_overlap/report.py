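"""End-to-end report pipeline: tables, figures, and a checksummed manifest.

Given a coding matrix (plus optional instrument metadata), the pipeline
writes, deterministically:

* ``frequencies.csv`` / ``frequencies_by_category.csv`` — symptom frequency
  bars data (overall and category-major ordering);
* ``instrument_summary.csv`` — per-questionnaire mean Jaccard, item count,
  specific/compound/total symptom counts;
* ``coverage.txt`` — reference-classification coverage report;
* ``overlap_matrix.csv`` / ``overlap_strength.csv`` / ``undefined_pairs.csv``
  — the pairwise Jaccard grid, its strength labels, and undefined pairs;
* ``category_overlap.csv`` — per-category grand means;
* ``correlations.csv`` — the three length/composition correlations;
* ``radar.<fmt>`` and ``heatmap.<fmt>`` figures;
* ``manifest.json`` — every artifact with its SHA-256 checksum.

Indices are rounded to the configured digits (default 3) in presentation
tables; machine-readable outputs keep full precision.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import coding, io, overlap
from .association import overlap_length_association
from .errors import PipelineError, SymptomOverlapError
from .matrix import InstrumentInfo, SymptomMatrix

logger = logging.getLogger("symptom_overlap")


@dataclass
class RunConfig:
    """Inputs and presentation options for one pipeline run."""

    matrix_path: str | Path
    out_dir: str | Path
    layout: str = "wide"
    reference_instruments: tuple[str, ...] | None = None
    meta_path: str | Path | None = None
    figure_format: str = "png"
    digits: int = 3
    radar_order: str = "category"
    correlation_method: str = "pearson"

    def __post_init__(self):
        if self.digits < 0:
            raise SymptomOverlapError("rounding digits must be >= 0")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n",
              float_format="%.10g")


def coverage_text(report: coding.CoverageReport, digits: int = 1) -> str:
    lines = [
        f"reference: {', '.join(report.reference)}",
        f"n_reference_symptoms: {report.n_reference_symptoms}",
        f"n_found: {report.n_found}",
        f"found_fraction: {round(100 * report.found_fraction, digits)}%",
        "missing_from_questionnaires:",
        *[f"  - {s}" for s in report.missing_from_questionnaires],
        "extra_beyond_reference:",
        *[f"  - {s}" for s in report.extra_beyond_reference],
    ]
    return "\n".join(lines) + "\n"


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every analysis stage and write the artifact bundle.

    Returns the manifest dict.  Any stage failure is re-raised as
    :class:`PipelineError` naming the stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as err:
                raise PipelineError(name, str(err)) from err
        return deco

    @stage("load")
    def m() -> SymptomMatrix:
        mat = io.read_symptom_matrix(cfg.matrix_path, cfg.layout,
                                     cfg.reference_instruments)
        logger.info("loaded matrix: %d symptoms x %d instruments "
                    "(%d questionnaires, %d references)",
                    mat.n_symptoms, mat.n_instruments,
                    len(mat.questionnaires), len(mat.references))
        return mat

    @stage("metadata")
    def meta() -> list[InstrumentInfo]:
        if cfg.meta_path is not None:
            return io.read_instrument_info(cfg.meta_path)
        # Without metadata, fall back to symptom counts as lengths.
        return [InstrumentInfo(i, int(m.presence_vector(i).sum()),
                               m.is_reference(i)) for i in m.instruments]

    @stage("frequencies")
    def _freq():
        _write_csv(coding.symptom_frequencies(m), out / "frequencies.csv")
        _write_csv(coding.category_frequencies(m),
                   out / "frequencies_by_category.csv")
        artifacts.extend([out / "frequencies.csv",
                          out / "frequencies_by_category.csv"])

    @stage("overlap")
    def om() -> overlap.OverlapMatrix:
        res = overlap.pairwise_matrix(m, include_reference=True)
        grid = res.values.round(cfg.digits)
        grid.insert(0, "instrument", grid.index)
        _write_csv(grid, out / "overlap_matrix.csv")
        artifacts.append(out / "overlap_matrix.csv")

        rows = []
        for k, a in enumerate(res.instruments):
            for b in res.instruments[k + 1:]:
                v = res.values.at[a, b]
                rows.append({"first": a, "second": b,
                             "jaccard": round(v, cfg.digits) if v == v else "",
                             "strength": overlap.interpret_strength(v)
                             if v == v else "undefined"})
        _write_csv(pd.DataFrame(rows), out / "overlap_strength.csv")
        _write_csv(pd.DataFrame(res.undefined_pairs,
                                columns=["first", "second"]),
                   out / "undefined_pairs.csv")
        artifacts.extend([out / "overlap_strength.csv",
                          out / "undefined_pairs.csv"])
        logger.info("grand mean Jaccard = %.4g (%s)", res.grand_mean,
                    overlap.interpret_strength(res.grand_mean))
        return res

    @stage("summary")
    def summaries():
        s = coding.instrument_summary(m, meta)
        _write_csv(coding.summary_table(s, om, cfg.digits),
                   out / "instrument_summary.csv")
        artifacts.append(out / "instrument_summary.csv")
        return s

    @stage("coverage")
    def _cov():
        if m.references:
            rep = coding.classification_coverage(m, m.references)
            (out / "coverage.txt").write_text(coverage_text(rep),
                                              encoding="utf-8")
            artifacts.append(out / "coverage.txt")

    @stage("categories")
    def _cat():
        df = overlap.category_means(m)
        df["mean_jaccard"] = df["mean_jaccard"].round(cfg.digits)
        _write_csv(df, out / "category_overlap.csv")
        artifacts.append(out / "category_overlap.csv")

    @stage("correlate")
    def _corr():
        res = overlap_length_association(summaries, om,
                                         method=cfg.correlation_method)
        df = pd.DataFrame([{"x_name": r.x_name, "y_name": r.y_name, "n": r.n,
                            "r": round(r.r, cfg.digits) if r.r == r.r else "",
                            "p_value": round(r.p_value, cfg.digits)
                            if r.p_value == r.p_value else "",
                            "note": r.note or ""} for r in res])
        _write_csv(df, out / "correlations.csv")
        artifacts.append(out / "correlations.csv")

    @stage("figures")
    def _figs():
        radar = out / f"radar.{cfg.figure_format}"
        heat = out / f"heatmap.{cfg.figure_format}"
        render_symptom_radar(m, radar, order=cfg.radar_order)
        render_overlap_heatmap(om, heat, digits=cfg.digits)
        artifacts.extend([radar, heat])

    manifest = {
        "inputs": {"matrix": str(cfg.matrix_path), "layout": cfg.layout,
                   "meta": str(cfg.meta_path) if cfg.meta_path else None},
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8")
    return manifest


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

def radar_layout(m: SymptomMatrix, order: str = "category") -> pd.DataFrame:
    """Plotting coordinates for the presence radar, one row per marker.

    Symptoms map to angles (in the requested order), instruments to radii
    with reference lists outermost.  ``filled`` is True for specific (code 1)
    markers, False for compound (code 2); absent symptoms yield no row.
    """
    if order == "frequency":
        sym_order = coding.symptom_frequencies(m)["symptom"].tolist()
    elif order == "category":
        sym_order = coding.category_frequencies(m)["symptom"].tolist()
    else:
        raise SymptomOverlapError(f"unknown radar order {order!r}")
    angle = {s: 2 * np.pi * k / len(sym_order) for k, s in enumerate(sym_order)}
    radial = m.questionnaires + m.references        # references outermost
    radius = {inst: k + 1 for k, inst in enumerate(radial)}
    rows = []
    for inst in radial:
        col = m.codes[inst]
        for s in m.symptoms:
            c = int(col[s])
            if c:
                rows.append({"symptom": s, "instrument": inst,
                             "angle": angle[s], "radius": radius[inst],
                             "code": c, "filled": c == 1})
    return pd.DataFrame(rows)


def render_symptom_radar(m: SymptomMatrix, path, order: str = "category"):
    """Polar scatter of symptom presence: filled = specific, hollow = compound."""
    layout = radar_layout(m, order)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"},
                           figsize=(9, 9))
    for filled, sub in layout.groupby("filled"):
        ax.scatter(sub["angle"], sub["radius"], s=22,
                   facecolors="C0" if filled else "none",
                   edgecolors="C0", linewidths=1.0,
                   label="specific" if filled else "compound")
    radial = m.questionnaires + m.references
    ax.set_rgrids(range(1, len(radial) + 1), labels=radial, fontsize=6)
    sym_order = layout.drop_duplicates("symptom").sort_values("angle")
    ax.set_xticks(sym_order["angle"])
    ax.set_xticklabels(sym_order["symptom"], fontsize=5)
    ax.set_rlim(0, len(radial) + 1)
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.05), fontsize=8)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def heatmap_annotations(om: overlap.OverlapMatrix, digits: int = 3) -> pd.DataFrame:
    """The annotation strings the heatmap prints: fixed-point at ``digits``
    decimals (e.g. ``0.500``), an en-dash for undefined pairs."""
    def fmt(v):
        return f"{v:.{digits}f}" if v == v else "–"
    return om.values.map(fmt)


def render_overlap_heatmap(om: overlap.OverlapMatrix, path, digits: int = 3):
    """Annotated symmetric heatmap of pairwise Jaccard indices.

    Undefined pairs are greyed out and annotated with a dash.
    """
    vals = om.values.to_numpy(dtype=float)
    ann = heatmap_annotations(om, digits).to_numpy()
    n = len(om.instruments)
    fig, ax = plt.subplots(figsize=(0.6 * n + 2, 0.6 * n + 1.5))
    masked = np.ma.masked_invalid(vals)
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("0.85")
    im = ax.imshow(masked, cmap=cmap, vmin=0, vmax=1)
    for i in range(n):
        for j in range(n):
            v = vals[i, j]
            ax.text(j, i, ann[i, j], ha="center", va="center", fontsize=6,
                    color="white" if (v == v and v < 0.6) else "black")
    ax.set_xticks(range(n), om.instruments, rotation=90, fontsize=7)
    ax.set_yticks(range(n), om.instruments, fontsize=7)
    fig.colorbar(im, ax=ax, label="Jaccard index")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
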