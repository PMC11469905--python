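"""Schema-validated CSV I/O, run manifests and the end-to-end pipeline.

Tables travel as UTF-8 comma-separated files with a mandatory header;
empty cells are missing values. Decision labels serialise as lowercase
strings, ordinal scores as integers.

``run_pipeline`` chains the stages the analysis workflow needs:
simulate (optional) -> score -> bootstrap -> agree -> report, writing
scores.csv, bootstrap.csv, pair_match.csv, agreement_matrix.csv,
report.json and a manifest that records the resolved configurations,
seeds and input digests so a run can be reproduced bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import pairwise_agreement_matrix
from .bootstrap import BootstrapConfig, BootstrapUncertainty
from .cohort import CohortConfig, generate_cohort
from .errors import SchemaError
from .scoring import ThresholdConfig, score_table

__all__ = [
    "SLIDE_COLUMNS",
    "ARTERY_COLUMNS",
    "ValidationReport",
    "validate_tables",
    "read_slides",
    "read_arteries",
    "write_table",
    "run_pipeline",
]

SLIDE_COLUMNS = [
    "slide_id", "biopsy_id", "donor_id", "kidney_side", "technique", "stain",
    "width_mm", "depth_mm", "cortex_area_mm2", "n_glomeruli", "n_sclerosed",
    "ifta_pct", "tubular_atrophy_pct",
]
ARTERY_COLUMNS = [
    "slide_id", "artery_id", "lumen_diameter_um", "wall_a_um", "wall_b_um",
    "minor_axis_um", "major_axis_um", "smooth_muscle_layers",
    "overall_diameter_um",
]
#: tubular_atrophy_pct and the artery axis/diameter columns may be empty.
_SLIDE_REQUIRED = SLIDE_COLUMNS[:12]


@dataclass
class ValidationReport:
    """Row-level validation findings; ``ok`` iff no errors."""

    errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_on_error(self) -> None:
        if self.errors:
            raise SchemaError("; ".join(self.errors[:20])
                              + (f" (+{len(self.errors) - 20} more)"
                                 if len(self.errors) > 20 else ""))


def _require_columns(df: pd.DataFrame, cols, table: str, rep: ValidationReport) -> bool:
    missing = [c for c in cols if c not in df.columns]
    for c in missing:
        rep.errors.append(f"{table}: missing required column '{c}'")
    return not missing


def validate_tables(slides: pd.DataFrame,
                    arteries: pd.DataFrame | None = None) -> ValidationReport:
    """Check both measurement tables against their schemas and invariants.

    Reported per offending row (1-based data line, excluding the header):
    range violations, n_sclerosed > n_glomeruli, non-positive areas,
    duplicate slide ids and artery rows referencing unknown slides.
    """
    rep = ValidationReport()
    if not _require_columns(slides, _SLIDE_REQUIRED, "slides", rep):
        return rep

    dup = slides["slide_id"][slides["slide_id"].duplicated()]
    for idx, sid in dup.items():
        rep.errors.append(f"slides line {idx + 1}: duplicate slide_id '{sid}'")
    for idx, row in slides.iterrows():
        line = idx + 1
        if not row["cortex_area_mm2"] > 0:
            rep.errors.append(f"slides line {line}: cortex_area_mm2 must be > 0")
        if row["n_glomeruli"] < 0 or row["n_sclerosed"] < 0 \
                or row["n_sclerosed"] > row["n_glomeruli"]:
            rep.errors.append(
                f"slides line {line}: need 0 <= n_sclerosed <= n_glomeruli")
        for col in ("ifta_pct", "tubular_atrophy_pct"):
            v = row.get(col)
            if v is not None and not pd.isna(v) and not 0 <= v <= 100:
                rep.errors.append(f"slides line {line}: {col} outside [0, 100]")
        if row["kidney_side"] not in ("left", "right"):
            rep.errors.append(f"slides line {line}: kidney_side must be left/right")

    if arteries is not None and len(arteries):
        if not _require_columns(arteries, ["slide_id", "artery_id"], "arteries", rep):
            return rep
        known = set(slides["slide_id"].astype(str))
        for idx, row in arteries.iterrows():
            line = idx + 1
            if str(row["slide_id"]) not in known:
                rep.errors.append(
                    f"arteries line {line}: orphan row, unknown slide_id "
                    f"'{row['slide_id']}'")
            for col in ("lumen_diameter_um", "wall_a_um", "wall_b_um"):
                v = row.get(col)
                if v is not None and not pd.isna(v) and not v > 0:
                    rep.errors.append(f"arteries line {line}: {col} must be > 0")
    return rep


def read_slides(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    rep = ValidationReport()
    if not _require_columns(df, _SLIDE_REQUIRED, "slides", rep):
        rep.raise_on_error()
    if "tubular_atrophy_pct" not in df.columns:
        df["tubular_atrophy_pct"] = np.nan
    return df


def read_arteries(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    rep = ValidationReport()
    if not _require_columns(df, ["slide_id", "artery_id"], "arteries", rep):
        rep.raise_on_error()
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table in the canonical dialect (UTF-8, comma, no index)."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype == float:
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else f"{v:.6g}")
    out.to_csv(path, index=False, encoding="utf-8")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    out_dir,
    cohort: CohortConfig | None = None,
    thresholds: ThresholdConfig | None = None,
    bootstrap: BootstrapConfig | None = None,
    slides_path=None,
    arteries_path=None,
    pairs_path=None,
    adequate_only: bool = False,
    log=print,
) -> Path:
    """Run simulate -> score -> bootstrap -> agree -> report into ``out_dir``.

    When ``slides_path`` is given the simulate stage is skipped and the
    user-provided tables are validated and used instead; generated and
    user-provided inputs flow through identical code after validation.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = thresholds or ThresholdConfig()
    bootstrap = bootstrap or BootstrapConfig()

    if slides_path is None:
        cohort = cohort or CohortConfig()
        log(f"[simulate] generating cohort (seed={cohort.seed})")
        tables = generate_cohort(cohort)
        slides, arteries, pairs = tables.slides, tables.arteries, tables.pairs
        write_table(slides, out / "slides.csv")
        write_table(arteries, out / "arteries.csv")
        write_table(pairs, out / "pairs.csv")
        write_table(tables.latents, out / "latents.csv")
        inputs = {}
    else:
        log(f"[load] reading {slides_path}")
        slides = read_slides(slides_path)
        arteries = read_arteries(arteries_path) if arteries_path else pd.DataFrame(
            columns=ARTERY_COLUMNS)
        pairs = pd.read_csv(pairs_path) if pairs_path else pd.DataFrame(
            columns=["donor_id", "left_side", "right_side"])
        inputs = {str(p): _digest(Path(p))
                  for p in (slides_path, arteries_path, pairs_path) if p}
    validate_tables(slides, arteries).raise_on_error()
    log(f"[score] {len(slides)} slides, {len(arteries)} artery rows")
    scores = score_table(slides, arteries, thresholds)
    write_table(scores, out / "scores.csv")

    log(f"[bootstrap] B={bootstrap.n_replicates}, seed={bootstrap.seed}")
    bu = BootstrapUncertainty(
        n_replicates=bootstrap.n_replicates, seed=bootstrap.seed,
        adequate_only=adequate_only, thresholds=thresholds,
    ).fit(scores, pairs=pairs if len(pairs) else None)
    write_table(bu.summary_, out / "bootstrap.csv")
    if bu.pair_match_ is not None:
        write_table(bu.pair_match_, out / "pair_match.csv")

    log("[agree] pairwise technique agreement")
    mat = pairwise_agreement_matrix(scores, by="technique")
    mat.round(6).to_csv(out / "agreement_matrix.csv", encoding="utf-8")

    scorable = scores.dropna(subset=["total"])
    adequacy = (
        scores.groupby("technique")[["glomerular_adequate", "arterial_adequate",
                                     "adequate"]].mean().round(6)
    )
    report = {
        "n_slides": int(len(scores)),
        "n_scorable": int(len(scorable)),
        "adequacy_by_technique": adequacy.to_dict(orient="index"),
        "kidney_bootstrap": bu.summary_.to_dict(orient="records"),
        "pair_match": (bu.pair_match_.to_dict(orient="records")
                       if bu.pair_match_ is not None else []),
        "technique_agreement": json.loads(mat.to_json()),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2), encoding="utf-8")

    manifest = {
        "tool": "nephromet", "version": __version__,
        "created": datetime.now(timezone.utc).isoformat(),
        "thresholds": thresholds.to_dict(),
        "bootstrap": {"n_replicates": bootstrap.n_replicates,
                      "seed": bootstrap.seed,
                      "subsample_size": bootstrap.subsample_size},
        "cohort": cohort.to_dict() if (slides_path is None and cohort) else None,
        "inputs": inputs,
        "adequate_only": adequate_only,
        "outputs": {p.name: _digest(p) for p in sorted(out.iterdir())
                    if p.suffix in (".csv", ".json") and p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2),
                                       encoding="utf-8")
    log(f"[done] outputs in {out}")
    return out
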