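"""Synthetic donor-kidney-biopsy cohort generator.

Emulates the structure of a repeat-biopsy study of discarded renal
allografts: 12 donors providing 16 kidneys (4 donors contribute both
kidneys as pairs), 9 biopsies per kidney (3 each by core needle, punch and
wedge), and 2 stained sections per biopsy — 288 slide records at the
defaults. Per-technique biopsy geometry is calibrated so that the mean and
SD of width, depth and cortex area match the published
cross-sectional profile (core biopsies long and thin, mean area
9.04 mm^2; punch consistent, 13.7 mm^2; wedge large and variable,
37.9 mm^2), and glomerular / vessel yields scale with area so that mean
yields land on the published 20.2 / 32.0 / 86.4 glomeruli per technique.

Chronic injury is driven by donor-level latents (glomerulosclerosis
propensity, IFTA fraction, arterial wall-to-lumen ratio); paired kidneys
share their donor's latents up to a small within-pair perturbation, and
slides add within-kidney sampling noise — mirroring the empirical pattern
that repeat slides of one kidney scatter widely while paired kidneys look
alike. The latents table records ground truth for parameter-recovery
tests.

Distribution choices (truncated normal geometry, Poisson glomerular
yield, binomial sclerosis, logit-normal IFTA, negative-binomial artery
counts, lognormal artery ratios) are modelling decisions, not published
facts; see the package methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from functools import lru_cache
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .errors import ConfigurationError
from .scoring import band_score, ThresholdConfig

__all__ = [
    "TechniqueProfile",
    "CohortConfig",
    "CohortTables",
    "generate_cohort",
    "sample_geometry",
    "recover_latents",
    "simulate_paired_score_sets",
    "DEFAULT_TECHNIQUES",
]

_LOGIT = lambda p: math.log(p / (1 - p))


@dataclass(frozen=True)
class TechniqueProfile:
    """Per-technique physical profile and yield targets.

    Geometry targets are the *marginal* mean/SD of each dimension; area is
    drawn from its own truncated normal rather than as width x depth, so
    the area marginal is exact while the product identity is not
    guaranteed (downstream analysis uses area only). Yield targets are
    mean counts per slide at the mean area.
    """

    width_mean: float
    width_sd: float
    depth_mean: float
    depth_sd: float
    area_mean: float
    area_sd: float
    glomeruli_mean: float
    vessels_mean: float

    @property
    def glomerular_density(self) -> float:
        """Glomeruli per mm^2 of cortex such that the mean yield is hit."""
        return self.glomeruli_mean / self.area_mean

    @property
    def artery_rate(self) -> float:
        """Vessels per mm^2 of cortex."""
        return self.vessels_mean / self.area_mean


#: Published cross-sectional profile of the three surgical techniques.
DEFAULT_TECHNIQUES: dict[str, TechniqueProfile] = {
    "core": TechniqueProfile(0.8, 0.2, 13.0, 4.3, 9.04, 5.1, 20.2, 2.86),
    "punch": TechniqueProfile(2.6, 0.4, 5.4, 1.2, 13.7, 3.9, 32.0, 3.5),
    "wedge": TechniqueProfile(10.7, 4.03, 4.5, 2.1, 37.9, 24.8, 86.4, 7.5),
}


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters; the defaults reproduce the cohort design above.

    Injury latents are donor-level: GS propensity ~ Beta with mean
    ``gs_mean`` and concentration ``gs_concentration``; IFTA fraction and
    arterial ratio are logit-/log-normal. ``within_pair_sd`` perturbs a
    donor's latents per kidney (transformed scale); ``within_kidney_sd``
    is the slide-level sampling noise on the same scales.
    """

    n_donors: int = 12
    n_paired_donors: int = 4            # donors contributing both kidneys
    biopsies_per_technique: int = 3
    stains_per_biopsy: int = 2
    techniques: tuple[str, ...] = ("core", "punch", "wedge")
    technique_profiles: dict = field(default_factory=lambda: dict(DEFAULT_TECHNIQUES))
    geometry_floor: float = 0.05        # truncation floor, mm / mm^2
    artery_dispersion: float = 1.2      # negative-binomial shape k
    # donor-level injury latents
    gs_mean: float = 0.10
    gs_concentration: float = 12.0
    ifta_logit_mean: float = _LOGIT(0.18)
    ifta_logit_sd: float = 0.8
    artery_log_ratio_mean: float = math.log(55.0)   # % wall/lumen
    artery_log_ratio_sd: float = 0.45
    within_pair_sd: float = 0.15
    within_kidney_sd: float = 0.35
    # artery geometry
    lumen_log_mean: float = math.log(60.0)          # um
    lumen_log_sd: float = 0.35
    wall_asymmetry_sd: float = 0.08
    smooth_muscle_rate: float = 1.6                 # Poisson mean layers
    oblique_fraction: float = 0.3                   # non-transverse cuts
    subcapsular_bias: float = 0.0   # extra wedge GS propensity (logit); off
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 1 or not 0 <= self.n_paired_donors <= self.n_donors:
            raise ConfigurationError("need 0 <= n_paired_donors <= n_donors >= 1")
        if self.biopsies_per_technique < 1 or self.stains_per_biopsy < 1:
            raise ConfigurationError("biopsy and stain counts must be >= 1")
        profiles = {}
        for t in self.techniques:
            if t not in self.technique_profiles:
                raise ConfigurationError(f"no profile for technique {t!r}")
            p = self.technique_profiles[t]
            if isinstance(p, dict):
                p = TechniqueProfile(**p)
            profiles[t] = p
            for name in ("width", "depth", "area"):
                m, s = getattr(p, f"{name}_mean"), getattr(p, f"{name}_sd")
                if m <= 0 or s < 0:
                    raise ConfigurationError(f"{t} {name}: mean must be > 0, sd >= 0")
                # > 50% of the untruncated mass below the floor is infeasible
                if m <= self.geometry_floor:
                    raise ConfigurationError(
                        f"{t} {name}: mean {m} at or below truncation floor")
        object.__setattr__(self, "technique_profiles", profiles)
        if not 0 <= self.gs_mean < 1:
            raise ConfigurationError("gs_mean must lie in [0, 1)")

    @property
    def n_kidneys(self) -> int:
        return self.n_donors + self.n_paired_donors

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["techniques"] = list(self.techniques)
        d["technique_profiles"] = {
            t: {f.name: getattr(p, f.name) for f in fields(TechniqueProfile)}
            for t, p in self.technique_profiles.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "techniques" in d:
            d["techniques"] = tuple(d["techniques"])
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown cohort keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def replace(self, **kw) -> "CohortConfig":
        return replace(self, **kw)


class CohortTables(NamedTuple):
    """Generated measurement tables plus ground truth."""

    slides: pd.DataFrame
    arteries: pd.DataFrame
    pairs: pd.DataFrame
    latents: pd.DataFrame


# ---------------------------------------------------------------------------
# truncated-normal calibration
# ---------------------------------------------------------------------------

@lru_cache(maxsize=256)
def _trunc_params(target_mean: float, target_sd: float, floor: float) -> tuple[float, float]:
    """Location/scale of a lower-truncated normal whose *truncated* mean
    and SD equal the targets.

    Naive use of the target mean as the location inflates the truncated
    mean (severely so for the wide wedge-area distribution), so the pair
    (mu, sigma) is found by root-finding on the truncnorm moments.
    """
    if target_sd == 0:
        return target_mean, 0.0

    def residual(p):
        mu, log_sigma = p
        sigma = math.exp(log_sigma)
        a = (floor - mu) / sigma
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        return [float(m) - target_mean, math.sqrt(float(v)) - target_sd]

    sol = optimize.root(residual, x0=[target_mean, math.log(target_sd)], method="hybr")
    if not sol.success:  # pragma: no cover - defensive
        raise ConfigurationError(
            f"cannot calibrate truncated normal to mean {target_mean}, sd {target_sd}")
    return float(sol.x[0]), math.exp(float(sol.x[1]))


def _trunc_draw(rng: np.random.Generator, target_mean: float, target_sd: float,
                floor: float, size: int) -> np.ndarray:
    if target_sd == 0:
        return np.full(size, target_mean)
    mu, sigma = _trunc_params(target_mean, target_sd, floor)
    a = (floor - mu) / sigma
    u = rng.random(size)
    lo = stats.norm.cdf(a)
    return stats.norm.ppf(lo + u * (1 - lo)) * sigma + mu


def sample_geometry(technique: str, cfg: CohortConfig | None = None,
                    rng: np.random.Generator | None = None,
                    size: int = 1) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (width mm, depth mm, area mm^2) for ``size`` biopsies.

    Each dimension is an independent truncated normal (floored at a small
    positive value) whose truncated moments match the technique profile;
    area is marginal, not width x depth.
    """
    cfg = cfg or CohortConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    p = cfg.technique_profiles[technique]
    width = _trunc_draw(rng, p.width_mean, p.width_sd, cfg.geometry_floor, size)
    depth = _trunc_draw(rng, p.depth_mean, p.depth_sd, cfg.geometry_floor, size)
    area = _trunc_draw(rng, p.area_mean, p.area_sd, cfg.geometry_floor, size)
    return width, depth, area


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _expected_total(gs_p: float, ifta: float, ratio: float,
                    thr: ThresholdConfig) -> int | None:
    """Remuzzi total of the latent expectations — a coarse ground-truth guide."""
    gs = band_score(100 * gs_p, thr.gs_bands) if gs_p > 0 else 0
    fi = 0 if 100 * ifta < thr.ifta_censor else band_score(100 * ifta, thr.if_bands)
    ta = 0 if 100 * ifta < thr.ifta_censor else band_score(100 * ifta, thr.ta_bands)
    art = band_score(ratio, thr.arterio_bands)
    return gs + fi + ta + art


def generate_cohort(cfg: CohortConfig | None = None) -> CohortTables:
    """Generate slides, arteries, pairs and ground-truth latent tables.

    Deterministic given ``cfg.seed``. At the defaults: 16 kidneys, 144
    biopsies, 288 slide rows. The slides/arteries tables conform to the
    scoring module's CSV schemas; the latents table records each kidney's
    true injury parameters for recovery tests.
    """
    cfg = cfg or CohortConfig()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    thr = ThresholdConfig()

    # -- donors and kidneys -------------------------------------------------
    donor_ids = [f"D{i + 1:02d}" for i in range(cfg.n_donors)]
    a0, b0 = (cfg.gs_mean * cfg.gs_concentration,
              (1 - cfg.gs_mean) * cfg.gs_concentration)
    if cfg.gs_mean == 0:      # sclerosis-free cohort: degenerate latent
        gs_draw = np.zeros(cfg.n_donors)
        donor_gs_logit = np.full(cfg.n_donors, -np.inf)
    else:
        gs_draw = rng.beta(a0, b0, cfg.n_donors)
        donor_gs_logit = np.log(gs_draw) - np.log1p(-gs_draw)
    donor_ifta_logit = rng.normal(cfg.ifta_logit_mean, cfg.ifta_logit_sd, cfg.n_donors)
    donor_log_ratio = rng.normal(cfg.artery_log_ratio_mean, cfg.artery_log_ratio_sd,
                                 cfg.n_donors)

    kidneys = []   # (donor_idx, side)
    pairs_rows = []
    for i, did in enumerate(donor_ids):
        if i < cfg.n_paired_donors:
            kidneys += [(i, "left"), (i, "right")]
            pairs_rows.append({"donor_id": did, "left_side": "left",
                               "right_side": "right"})
        else:
            kidneys.append((i, "left" if i % 2 == 0 else "right"))

    latent_rows = []
    kid_latents = []
    for di, side in kidneys:
        jitter = rng.normal(0, cfg.within_pair_sd, 3)
        with np.errstate(over="ignore"):
            gs_p = float(_sigmoid(donor_gs_logit[di] + jitter[0]))
        ifta = float(_sigmoid(donor_ifta_logit[di] + jitter[1]))
        ratio = float(np.exp(donor_log_ratio[di] + jitter[2]))
        kid_latents.append((gs_p, ifta, ratio))
        latent_rows.append({
            "donor_id": donor_ids[di], "kidney_side": side,
            "gs_propensity": gs_p, "ifta_mean": ifta,
            "arterial_ratio_mean": ratio,
            "expected_total": _expected_total(gs_p, ifta, ratio, thr),
        })

    # -- biopsies and slides ------------------------------------------------
    slide_rows: dict[str, list] = {k: [] for k in (
        "slide_id", "biopsy_id", "donor_id", "kidney_side", "technique", "stain",
        "width_mm", "depth_mm", "cortex_area_mm2", "_kidney_idx")}
    stains = ["HE", "PAS"][: cfg.stains_per_biopsy] + [
        f"S{j}" for j in range(3, cfg.stains_per_biopsy + 1)]
    for ki, (di, side) in enumerate(kidneys):
        did = donor_ids[di]
        for tech in cfg.techniques:
            w, d, ar = sample_geometry(tech, cfg, rng, cfg.biopsies_per_technique)
            for b in range(cfg.biopsies_per_technique):
                bid = f"{did}-{side[0].upper()}-{tech}-{b + 1}"
                for stain in stains:
                    slide_rows["slide_id"].append(f"{bid}-{stain}")
                    slide_rows["biopsy_id"].append(bid)
                    slide_rows["donor_id"].append(did)
                    slide_rows["kidney_side"].append(side)
                    slide_rows["technique"].append(tech)
                    slide_rows["stain"].append(stain)
                    slide_rows["width_mm"].append(float(w[b]))
                    slide_rows["depth_mm"].append(float(d[b]))
                    slide_rows["cortex_area_mm2"].append(float(ar[b]))
                    slide_rows["_kidney_idx"].append(ki)
    slides = pd.DataFrame(slide_rows)
    n_slides = len(slides)
    kidx = slides.pop("_kidney_idx").to_numpy()
    gs_lat = np.array([kid_latents[i][0] for i in kidx])
    ifta_lat = np.array([kid_latents[i][1] for i in kidx])
    ratio_lat = np.array([kid_latents[i][2] for i in kidx])
    tech_arr = slides["technique"].to_numpy()

    dens = np.array([cfg.technique_profiles[t].glomerular_density for t in tech_arr])
    area = slides["cortex_area_mm2"].to_numpy()
    n_glom = rng.poisson(dens * area)

    with np.errstate(divide="ignore"):
        gs_logit = np.log(gs_lat) - np.log1p(-gs_lat)
    if cfg.subcapsular_bias:
        gs_logit = gs_logit + np.where(tech_arr == "wedge", cfg.subcapsular_bias, 0.0)
    with np.errstate(over="ignore"):
        p_slide = _sigmoid(gs_logit + rng.normal(0, cfg.within_kidney_sd, n_slides))
    p_slide = np.where(gs_lat == 0, 0.0, p_slide)
    n_scl = rng.binomial(n_glom, p_slide)

    ifta_logit = np.log(ifta_lat) - np.log1p(-ifta_lat)
    ifta_pct = 100 * _sigmoid(ifta_logit + rng.normal(0, cfg.within_kidney_sd, n_slides))
    ta_pct = 100 * _sigmoid(ifta_logit + rng.normal(0, cfg.within_kidney_sd, n_slides))

    slides["n_glomeruli"] = n_glom
    slides["n_sclerosed"] = n_scl
    slides["ifta_pct"] = np.round(ifta_pct, 6)
    slides["tubular_atrophy_pct"] = np.round(ta_pct, 6)

    # -- arteries -----------------------------------------------------------
    rate = np.array([cfg.technique_profiles[t].artery_rate for t in tech_arr])
    mu = rate * area
    k = cfg.artery_dispersion
    counts = rng.negative_binomial(k, k / (k + mu))
    total = int(counts.sum())
    slide_rep = np.repeat(np.arange(n_slides), counts)
    log_ratio = np.log(ratio_lat)[slide_rep] + rng.normal(0, cfg.within_kidney_sd, total)
    ratio = np.exp(log_ratio)
    lumen = np.exp(rng.normal(cfg.lumen_log_mean, cfg.lumen_log_sd, total))
    w_mean = ratio / 200 * lumen      # per-wall: (a+b)/lumen hits the ratio
    asym = np.clip(rng.normal(0, cfg.wall_asymmetry_sd, total), -0.5, 0.5)
    wall_a = w_mean * (1 + asym)
    wall_b = w_mean * (1 - asym)     # mean preserved: (a+b)/2 == w_mean
    layers = rng.poisson(cfg.smooth_muscle_rate, total)
    overall = lumen + wall_a + wall_b + np.abs(rng.normal(5, 3, total))
    oblique = rng.random(total) < cfg.oblique_fraction
    stretch = 1 + np.abs(rng.normal(0, 0.25, total))
    minor = np.where(oblique, lumen, np.nan)
    major = np.where(oblique, lumen * stretch, np.nan)
    lumen_recorded = np.where(oblique, lumen * stretch, lumen)

    arteries = pd.DataFrame({
        "slide_id": slides["slide_id"].to_numpy()[slide_rep],
        "artery_id": [f"a{j + 1}" for s in counts for j in range(s)],
        "lumen_diameter_um": np.round(lumen_recorded, 3),
        "wall_a_um": np.round(wall_a, 3),
        "wall_b_um": np.round(wall_b, 3),
        "minor_axis_um": np.round(minor, 3),
        "major_axis_um": np.round(major, 3),
        "smooth_muscle_layers": layers,
        "overall_diameter_um": np.round(overall, 3),
    })
    pairs = pd.DataFrame(pairs_rows, columns=["donor_id", "left_side", "right_side"])
    latents = pd.DataFrame(latent_rows)
    return CohortTables(slides=slides, arteries=arteries, pairs=pairs, latents=latents)


# ---------------------------------------------------------------------------
# ground-truth recovery and score-set simulation
# ---------------------------------------------------------------------------

def recover_latents(slides: pd.DataFrame, arteries: pd.DataFrame,
                    latents: pd.DataFrame) -> pd.DataFrame:
    """Estimate each kidney's latent injury from its slides vs ground truth.

    Pooled estimators: GS propensity = total sclerosed / total glomeruli;
    IFTA fraction = mean slide percentage / 100; arterial ratio =
    geometric mean of per-artery measured ratios (minor-axis corrected).
    Returns one row per kidney with estimates, truths and errors; the
    DataFrame carries summary attrs ``bias`` and ``rmse`` per quantity.
    """
    art = arteries.copy()
    lumen_true = art["lumen_diameter_um"].to_numpy().astype(float)
    minor = art["minor_axis_um"].to_numpy().astype(float)
    lumen_corr = np.where(np.isnan(minor), lumen_true, minor)
    art["_ratio"] = 100 * (art["wall_a_um"] + art["wall_b_um"]) / lumen_corr
    art = art.merge(slides[["slide_id", "donor_id", "kidney_side"]], on="slide_id")

    rows = []
    for _, lt in latents.iterrows():
        sl = slides[(slides["donor_id"] == lt["donor_id"])
                    & (slides["kidney_side"] == lt["kidney_side"])]
        ar = art[(art["donor_id"] == lt["donor_id"])
                 & (art["kidney_side"] == lt["kidney_side"])]
        tot_glom = int(sl["n_glomeruli"].sum())
        gs_est = float(sl["n_sclerosed"].sum() / tot_glom) if tot_glom else np.nan
        ifta_est = float(sl["ifta_pct"].mean() / 100)
        ratio_est = float(np.exp(np.mean(np.log(ar["_ratio"])))) if len(ar) else np.nan
        rows.append({
            "donor_id": lt["donor_id"], "kidney_side": lt["kidney_side"],
            "gs_est": gs_est, "gs_true": lt["gs_propensity"],
            "ifta_est": ifta_est, "ifta_true": lt["ifta_mean"],
            "ratio_est": ratio_est, "ratio_true": lt["arterial_ratio_mean"],
        })
    out = pd.DataFrame(rows)
    for q in ("gs", "ifta", "ratio"):
        err = out[f"{q}_est"] - out[f"{q}_true"]
        out[f"{q}_error"] = err
    out.attrs["bias"] = {q: float(np.nanmean(out[f"{q}_error"]))
                         for q in ("gs", "ifta", "ratio")}
    out.attrs["rmse"] = {q: float(np.sqrt(np.nanmean(out[f"{q}_error"] ** 2)))
                         for q in ("gs", "ifta", "ratio")}
    return out


def simulate_paired_score_sets(
    n_pairs: int,
    n_scores: int = 9,
    seed: int = 0,
    boundary_margin: float = 0.75,
    within_pair_sd: float = 0.25,
    score_sd: float = 1.0,
) -> list[tuple["KidneyScoreSet", "KidneyScoreSet"]]:
    """Simulate donor pairs of kidney score sets with shared latent injury.

    Each donor's true mean score is drawn uniformly from the parts of the
    0-12 axis at least ``boundary_margin`` away from the single/dual (4)
    and dual/discard (7) decision boundaries; both kidneys perturb it by
    ``within_pair_sd`` and contribute ``n_scores`` integer scores (rounded
    clipped normal draws with SD ``score_sd``). Used to study the pooling
    effect far from boundaries; set ``boundary_margin=0`` for unrestricted
    means.
    """
    from .bootstrap import KidneyScoreSet  # local import avoids a cycle

    rng = np.random.default_rng(seed)
    m = boundary_margin
    regions = [(1.0, 4.0 - m), (4.0 + m, 7.0 - m), (7.0 + m, 10.5)]
    regions = [(lo, hi) for lo, hi in regions if hi > lo]
    widths = np.array([hi - lo for lo, hi in regions])
    out = []
    for p in range(n_pairs):
        r = rng.choice(len(regions), p=widths / widths.sum())
        mu = rng.uniform(*regions[r])
        kidneys = []
        for side in ("left", "right"):
            mk = np.clip(mu + rng.normal(0, within_pair_sd), 0, 12)
            sc = np.clip(np.round(rng.normal(mk, score_sd, n_scores)), 0, 12)
            kidneys.append(KidneyScoreSet(f"SIM{p + 1:03d}", side,
                                          tuple(int(s) for s in sc)))
        out.append((kidneys[0], kidneys[1]))
    return out
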