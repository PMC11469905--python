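"""Remuzzi chronic-injury scoring for renal preimplantation biopsies.

The Remuzzi score sums four ordinal 0-3 components measured on one slide —
glomerulosclerosis (GS), interstitial fibrosis (IF), tubular atrophy (TA)
and arteriosclerosis — into a 0-12 total that drives the implantation
decision: totals up to 4 favour single transplantation, 5-6 dual
transplantation (both kidneys into one recipient), and 7 or more discard.

All component thresholds live in :class:`ThresholdConfig` so each symbol is
explicit and overridable:

* arteriosclerosis is the wall-to-lumen ratio of the worst scorable artery,
  banded at 50 / 80 / 120 %;
* IFTA percentages below a 5 % censor score 0 rather than 1;
* a slide is *adequate* when it shows at least 25 glomeruli and one
  scorable artery (>= 2 smooth-muscle layers or diameter > 130 um).

Every band is left-closed: a value equal to a cut-point earns the higher
score, consistent with the inclusive ">= 7 discard" boundary.

Unscorable components (no glomeruli, no scorable artery) are reported as
missing rather than zero; a slide with any missing component has no total
and no decision, but its remaining components are still reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigurationError, InputError

__all__ = [
    "ArteryMeasurement",
    "SlideMeasurement",
    "ThresholdConfig",
    "RemuzziResult",
    "band_score",
    "score_glomerulosclerosis",
    "score_ifta",
    "wall_lumen_ratio",
    "is_scorable_artery",
    "score_arteriosclerosis",
    "assess_adequacy",
    "score_slide",
    "decide_total",
    "decide_continuous",
    "score_table",
    "RemuzziScorer",
    "DECISIONS",
]

#: Decision labels in increasing order of severity.
DECISIONS = ("single", "dual", "discard")

#: Comparison tolerance for continuous values at band cut-points.
_CUT_TOL = 1e-9


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArteryMeasurement:
    """One vessel's lumen/wall geometry, all lengths in micrometres.

    ``minor_axis`` / ``major_axis`` describe the elliptical lumen outline of
    an obliquely (non-transversely) cut vessel; when both are present the
    minor axis is taken as the true lumen diameter.
    """

    artery_id: str
    lumen_diameter: float
    wall_thickness_a: float
    wall_thickness_b: float
    smooth_muscle_layers: int = 0
    overall_diameter: float | None = None
    minor_axis: float | None = None
    major_axis: float | None = None

    def __post_init__(self) -> None:
        for name in ("lumen_diameter", "wall_thickness_a", "wall_thickness_b",
                     "overall_diameter", "minor_axis", "major_axis"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise InputError(f"{name} must be > 0, got {v!r}")
        if self.smooth_muscle_layers < 0 or int(self.smooth_muscle_layers) != self.smooth_muscle_layers:
            raise InputError("smooth_muscle_layers must be a non-negative integer")
        if (self.minor_axis is not None and self.major_axis is not None
                and self.minor_axis > self.major_axis):
            raise InputError("minor_axis must not exceed major_axis")


@dataclass(frozen=True)
class SlideMeasurement:
    """Raw chronic-injury measurements for one slide plus provenance.

    ``tubular_atrophy_pct`` may be omitted; the IFTA percentage then stands
    in for both the IF and TA components (they are treated as a single
    measure of injury) and the result is flagged ``ta_imputed``.
    """

    slide_id: str
    biopsy_id: str
    donor_id: str
    kidney_side: str            # {"left", "right"}
    technique: str              # {"core", "punch", "wedge"}
    stain: str                  # {"HE", "PAS"}
    width: float                # mm
    depth: float                # mm
    cortex_area: float          # mm^2
    n_glomeruli: int
    n_sclerosed: int
    ifta_pct: float
    tubular_atrophy_pct: float | None = None
    arteries: tuple[ArteryMeasurement, ...] = ()

    def __post_init__(self) -> None:
        if self.cortex_area <= 0:
            raise InputError(f"cortex_area must be > 0, got {self.cortex_area!r}")
        if not 0 <= self.n_sclerosed <= self.n_glomeruli:
            raise InputError(
                f"need 0 <= n_sclerosed <= n_glomeruli, got "
                f"{self.n_sclerosed}/{self.n_glomeruli}")
        for name in ("ifta_pct", "tubular_atrophy_pct"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 100:
                raise InputError(f"{name} must lie in [0, 100], got {v!r}")
        object.__setattr__(self, "arteries", tuple(self.arteries))


@dataclass(frozen=True)
class ThresholdConfig:
    """Every threshold symbol of the scoring system in one place.

    The arterial bands (50/80/120), the 5 % IFTA censor, the adequacy
    minima and the decision boundaries are the published values; the
    GS/IF/TA bands ship as the classical "remuzzi-1999" profile
    (0 = none, 1 = < 20 %, 2 = 20-50 %, 3 = > 50 %) and must be adjusted
    if a different banding is in force locally.
    """

    gs_bands: tuple[float, float, float] = (0.0, 20.0, 50.0)
    if_bands: tuple[float, float, float] = (0.0, 20.0, 50.0)
    ta_bands: tuple[float, float, float] = (0.0, 20.0, 50.0)
    arterio_bands: tuple[float, float, float] = (50.0, 80.0, 120.0)
    ifta_censor: float = 5.0
    adequacy_min_glomeruli: int = 25
    adequacy_min_arteries: int = 1
    decision_single_max: int = 4
    decision_dual_max: int = 6
    artery_min_layers: int = 2
    artery_min_diameter: float = 130.0
    max_arteries_assessed: int = 2
    use_minor_axis_correction: bool = True
    band_profile: str = "remuzzi-1999"

    def __post_init__(self) -> None:
        for name in ("gs_bands", "if_bands", "ta_bands", "arterio_bands"):
            bands = tuple(float(b) for b in getattr(self, name))
            object.__setattr__(self, name, bands)
            if len(bands) != 3 or not (bands[0] < bands[1] < bands[2]):
                raise ConfigurationError(
                    f"{name} must be 3 strictly ascending cut-points, got {bands}")
        if not self.decision_single_max < self.decision_dual_max:
            raise ConfigurationError(
                "decision_single_max must be below decision_dual_max")
        if self.ifta_censor < 0:
            raise ConfigurationError("ifta_censor must be >= 0")

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        for k in ("gs_bands", "if_bands", "ta_bands", "arterio_bands"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ThresholdConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def replace(self, **kw) -> "ThresholdConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class RemuzziResult:
    """Component scores, total, adequacy flags and decision for one slide.

    Missing (unscorable) components are ``None``; ``total`` and
    ``decision`` are ``None`` unless all four components are scorable.
    """

    slide_id: str
    score_gs: int | None
    score_if: int | None
    score_ta: int | None
    score_art: int | None
    total: int | None
    glomerular_adequate: bool
    arterial_adequate: bool
    adequate: bool
    decision: str | None
    worst_artery_id: str | None = None
    ta_imputed: bool = False

    @property
    def scorable(self) -> bool:
        return self.total is not None


# ---------------------------------------------------------------------------
# component kernels
# ---------------------------------------------------------------------------

def _check_bands(bands: Sequence[float]) -> tuple[float, float, float]:
    b = tuple(float(x) for x in bands)
    if len(b) != 3 or not (b[0] < b[1] < b[2]):
        raise ConfigurationError(f"bands must be 3 strictly ascending cut-points, got {bands}")
    return b


def band_score(value: float, bands: Sequence[float]) -> int:
    """Ordinal 0-3 score of ``value`` against three ascending cut-points.

    Intervals are left-closed half-open: [0, b1), [b1, b2), [b2, b3),
    [b3, inf) score 0, 1, 2, 3. Values within ``1e-9`` of a cut-point are
    treated as on the cut-point (and therefore in the upper band).
    """
    b = _check_bands(bands)
    if value < 0:
        raise InputError(f"band_score value must be >= 0, got {value!r}")
    return int(sum(value >= cut - _CUT_TOL for cut in b))


def score_glomerulosclerosis(n_glomeruli: int, n_sclerosed: int,
                             cfg: ThresholdConfig | None = None) -> int | None:
    """GS component: percentage of globally sclerosed glomeruli, banded.

    Zero sclerosed glomeruli always scores 0 (the any-vs-none floor), and a
    slide without glomeruli is unscorable (``None``, distinct from 0). The
    percentage is compared to the cut-points as an exact rational so that
    e.g. 1/5 lands exactly on a 20 % boundary.
    """
    cfg = cfg or ThresholdConfig()
    if n_glomeruli < 0 or n_sclerosed < 0 or n_sclerosed > max(n_glomeruli, 0):
        raise InputError("need 0 <= n_sclerosed <= n_glomeruli")
    if n_glomeruli == 0:
        return None
    if n_sclerosed == 0:
        return 0
    pct = Fraction(100 * n_sclerosed, n_glomeruli)
    return int(sum(pct >= Fraction(cut).limit_denominator(10**9)
                   for cut in cfg.gs_bands))


def score_ifta(ifta_pct: float, cfg: ThresholdConfig | None = None,
               tubular_atrophy_pct: float | None = None) -> tuple[int, int]:
    """IF and TA components from percentage cortical involvement.

    Any percentage strictly below the censor (default 5 %) scores 0 — small
    fibrotic foci are disregarded. When no separate tubular-atrophy
    percentage is supplied, the IFTA percentage is scored against both the
    IF and TA bands (single-measure-of-injury convention).
    """
    cfg = cfg or ThresholdConfig()
    for v in (ifta_pct, tubular_atrophy_pct):
        if v is not None and not 0 <= v <= 100:
            raise InputError(f"percentage must lie in [0, 100], got {v!r}")

    def one(pct: float, bands) -> int:
        if pct < cfg.ifta_censor - _CUT_TOL:
            return 0
        return band_score(pct, bands)

    score_if = one(ifta_pct, cfg.if_bands)
    ta_pct = ifta_pct if tubular_atrophy_pct is None else tubular_atrophy_pct
    score_ta = one(ta_pct, cfg.ta_bands)
    return score_if, score_ta


def wall_lumen_ratio(a: ArteryMeasurement, use_minor_axis_correction: bool = True) -> float:
    """Wall-to-lumen ratio in percent.

    The wall thickness is the mean of the two opposing walls and is taken
    relative to the lumen *radius* — equivalently, the total wall tissue
    crossed along a diameter over the lumen diameter:

        ratio = 100 * (wall_a + wall_b) / lumen_diameter.

    On this scale symmetric walls as thick as the lumen radius give 100 %,
    and the >= 120 % top scoring band is attainable in severely narrowed
    vessels. When both lumen axes are recorded (obliquely cut vessel) and
    the correction is enabled, the minor axis replaces the measured lumen
    diameter — the true diameter of an obliquely sectioned cylinder is the
    ellipse minor axis.
    """
    lumen = a.lumen_diameter
    if use_minor_axis_correction and a.minor_axis is not None and a.major_axis is not None:
        lumen = a.minor_axis
    if lumen <= 0:
        raise InputError("lumen diameter must be > 0")
    return 100.0 * (a.wall_thickness_a + a.wall_thickness_b) / lumen


def is_scorable_artery(a: ArteryMeasurement, cfg: ThresholdConfig | None = None) -> bool:
    """A vessel is scorable with >= 2 smooth-muscle layers or diameter > 130 um."""
    cfg = cfg or ThresholdConfig()
    if a.smooth_muscle_layers >= cfg.artery_min_layers:
        return True
    return a.overall_diameter is not None and a.overall_diameter > cfg.artery_min_diameter


def score_arteriosclerosis(
    arteries: Iterable[ArteryMeasurement],
    cfg: ThresholdConfig | None = None,
) -> tuple[int | None, str | None]:
    """Arteriosclerosis component from the worst scorable artery.

    Up to ``max_arteries_assessed`` scorable arteries are considered, taken
    in decreasing order of wall-to-lumen ratio; the score is the band of
    the maximum ratio. Returns ``(None, None)`` when no artery is scorable
    — a valid unscorable state, not an error. Ratio ties break toward the
    lexicographically lower artery id for determinism.
    """
    cfg = cfg or ThresholdConfig()
    scorable = [a for a in arteries if is_scorable_artery(a, cfg)]
    if not scorable:
        return None, None
    ranked = sorted(
        scorable,
        key=lambda a: (-wall_lumen_ratio(a, cfg.use_minor_axis_correction), str(a.artery_id)),
    )[: cfg.max_arteries_assessed]
    worst = ranked[0]
    ratio = wall_lumen_ratio(worst, cfg.use_minor_axis_correction)
    return band_score(ratio, cfg.arterio_bands), str(worst.artery_id)


def assess_adequacy(s: SlideMeasurement,
                    cfg: ThresholdConfig | None = None) -> tuple[bool, bool, bool]:
    """Glomerular, arterial and overall adequacy flags for one slide.

    The two criteria are reported separately because they fail for
    different reasons (small samples lack glomeruli; many samples of any
    size lack a scorable artery).
    """
    cfg = cfg or ThresholdConfig()
    glom_ok = s.n_glomeruli >= cfg.adequacy_min_glomeruli
    n_scorable = sum(is_scorable_artery(a, cfg) for a in s.arteries)
    art_ok = n_scorable >= cfg.adequacy_min_arteries
    return glom_ok, art_ok, glom_ok and art_ok


def decide_total(total: int, cfg: ThresholdConfig | None = None) -> str:
    """Implantation decision from an integer total: <=4 single, 5-6 dual, >=7 discard.

    A total of 0 maps to single transplantation (at least as favourable as 1).
    """
    cfg = cfg or ThresholdConfig()
    if not 0 <= total <= 12 or int(total) != total:
        raise InputError(f"total must be an integer in 0..12, got {total!r}")
    if total <= cfg.decision_single_max:
        return "single"
    if total <= cfg.decision_dual_max:
        return "dual"
    return "discard"


def decide_continuous(mean_score: float, cfg: ThresholdConfig | None = None) -> str:
    """Decision for a continuous (pooled-mean) score on the 0-12 axis.

    Bands follow the continuous shading of the score axis: <= 4 single,
    (4, 7) dual, >= 7 discard. The open interval between the dual maximum
    and the discard threshold (6, 7) is assigned to dual: discard stays an
    inclusive >= 7 rule on the continuous axis as on the integer one.
    """
    cfg = cfg or ThresholdConfig()
    if not 0 <= mean_score <= 12:
        raise InputError(f"mean score must lie in [0, 12], got {mean_score!r}")
    if mean_score <= cfg.decision_single_max + _CUT_TOL:
        return "single"
    if mean_score >= cfg.decision_dual_max + 1 - _CUT_TOL:
        return "discard"
    return "dual"


def score_slide(s: SlideMeasurement, cfg: ThresholdConfig | None = None) -> RemuzziResult:
    """Score one slide: components, total, adequacy and decision.

    Inadequate slides are still scored — adequacy is reported as flags and
    downstream analyses decide whether to filter. Components that cannot
    be assessed are ``None`` and suppress the total and the decision.
    """
    cfg = cfg or ThresholdConfig()
    gs = score_glomerulosclerosis(s.n_glomeruli, s.n_sclerosed, cfg) \
        if s.n_glomeruli > 0 else None
    sif, sta = score_ifta(s.ifta_pct, cfg, s.tubular_atrophy_pct)
    art, worst_id = score_arteriosclerosis(s.arteries, cfg)
    glom_ok, art_ok, ok = assess_adequacy(s, cfg)

    components = (gs, sif, sta, art)
    if all(c is not None for c in components):
        total: int | None = int(sum(components))  # type: ignore[arg-type]
        decision: str | None = decide_total(total, cfg)
    else:
        total = None
        decision = None
    return RemuzziResult(
        slide_id=s.slide_id,
        score_gs=gs, score_if=sif, score_ta=sta, score_art=art,
        total=total,
        glomerular_adequate=glom_ok, arterial_adequate=art_ok, adequate=ok,
        decision=decision, worst_artery_id=worst_id,
        ta_imputed=s.tubular_atrophy_pct is None,
    )


# ---------------------------------------------------------------------------
# table-level API
# ---------------------------------------------------------------------------

_ARTERY_COLS = {
    "lumen_diameter_um": "lumen_diameter",
    "wall_a_um": "wall_thickness_a",
    "wall_b_um": "wall_thickness_b",
    "minor_axis_um": "minor_axis",
    "major_axis_um": "major_axis",
    "smooth_muscle_layers": "smooth_muscle_layers",
    "overall_diameter_um": "overall_diameter",
}


def _slide_from_row(row: pd.Series, arteries: tuple[ArteryMeasurement, ...]) -> SlideMeasurement:
    ta = row.get("tubular_atrophy_pct")
    if ta is not None and pd.isna(ta):
        ta = None
    return SlideMeasurement(
        slide_id=str(row["slide_id"]), biopsy_id=str(row["biopsy_id"]),
        donor_id=str(row["donor_id"]), kidney_side=str(row["kidney_side"]),
        technique=str(row["technique"]), stain=str(row["stain"]),
        width=float(row["width_mm"]), depth=float(row["depth_mm"]),
        cortex_area=float(row["cortex_area_mm2"]),
        n_glomeruli=int(row["n_glomeruli"]), n_sclerosed=int(row["n_sclerosed"]),
        ifta_pct=float(row["ifta_pct"]),
        tubular_atrophy_pct=None if ta is None else float(ta),
        arteries=arteries,
    )


def _arteries_from_rows(rows: pd.DataFrame) -> tuple[ArteryMeasurement, ...]:
    out = []
    for _, r in rows.iterrows():
        kw = {"artery_id": str(r["artery_id"])}
        for col, name in _ARTERY_COLS.items():
            v = r.get(col)
            if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v):
                continue
            kw[name] = int(v) if name == "smooth_muscle_layers" else float(v)
        kw.setdefault("smooth_muscle_layers", 0)
        out.append(ArteryMeasurement(**kw))
    return tuple(out)


def score_table(slides: pd.DataFrame, arteries: pd.DataFrame | None = None,
                cfg: ThresholdConfig | None = None) -> pd.DataFrame:
    """Score every slide of a measurement table.

    ``slides`` follows the slides.csv schema; ``arteries`` the arteries.csv
    schema keyed by ``slide_id``. Returns one row per slide with component
    scores, total, adequacy flags and decision; provenance columns
    (donor_id, kidney_side, technique, stain) are carried through so that
    downstream grouping needs no join.
    """
    cfg = cfg or ThresholdConfig()
    if arteries is None:
        arteries = pd.DataFrame(columns=["slide_id", "artery_id"])
    grouped = dict(tuple(arteries.groupby("slide_id"))) if len(arteries) else {}
    records = []
    for _, row in slides.iterrows():
        sid = str(row["slide_id"])
        art_rows = grouped.get(sid)
        art = _arteries_from_rows(art_rows) if art_rows is not None else ()
        s = _slide_from_row(row, art)
        r = score_slide(s, cfg)
        records.append({
            "slide_id": r.slide_id,
            "biopsy_id": s.biopsy_id,
            "donor_id": s.donor_id,
            "kidney_side": s.kidney_side,
            "technique": s.technique,
            "stain": s.stain,
            "score_gs": r.score_gs, "score_if": r.score_if,
            "score_ta": r.score_ta, "score_art": r.score_art,
            "total": r.total,
            "glomerular_adequate": r.glomerular_adequate,
            "arterial_adequate": r.arterial_adequate,
            "adequate": r.adequate,
            "decision": r.decision,
            "worst_artery_id": r.worst_artery_id,
            "ta_imputed": r.ta_imputed,
        })
    out = pd.DataFrame.from_records(records)
    for col in ("score_gs", "score_if", "score_ta", "score_art", "total"):
        out[col] = out[col].astype("Int64")
    return out


class RemuzziScorer(TransformerMixin, BaseEstimator):
    """Transformer mapping slide/artery measurement tables to score tables.

    Stateless apart from threshold resolution: ``fit`` validates and
    freezes the threshold configuration into ``thresholds_``;
    ``transform`` scores a slides table (pass the arteries table via the
    ``arteries`` keyword or at construction).

    Parameters
    ----------
    thresholds : ThresholdConfig or None
        Scoring thresholds; ``None`` means the published defaults with the
        classical GS/IF/TA band profile.
    """

    def __init__(self, thresholds: ThresholdConfig | None = None):
        self.thresholds = thresholds

    def fit(self, X: pd.DataFrame | None = None, y=None) -> "RemuzziScorer":
        t = self.thresholds if self.thresholds is not None else ThresholdConfig()
        if not isinstance(t, ThresholdConfig):
            t = ThresholdConfig.from_dict(dict(t))
        self.thresholds_ = t
        return self

    def transform(self, X: pd.DataFrame,
                  arteries: pd.DataFrame | None = None) -> pd.DataFrame:
        if not hasattr(self, "thresholds_"):
            self.fit()
        return score_table(X, arteries, self.thresholds_)
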