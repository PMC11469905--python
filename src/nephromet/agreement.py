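"""Agreement statistics for comparing biopsy techniques and assessment methods.

Three statistics quantify how well two series of assessments of the same
slides or kidneys agree:

* Pearson's r — linear association of continuous measurements;
* Lin's concordance correlation coefficient (CCC) — agreement of
  continuous measurements, penalising both scatter and systematic
  deviation from the 45-degree identity line;
* weighted Cohen's kappa — chance-corrected agreement of ordinal scores,
  with disagreement weighted by category distance (linear |i-j| by
  default, quadratic (i-j)^2 optionally).

Kappa-style values are read against the conventional bands 0-0.2 slight,
0.2-0.4 fair, 0.4-0.6 moderate, 0.6-0.8 substantial, 0.8-1 perfect
(left-closed, matching the scoring module's band convention).

``banding_consistency`` summarises how cleanly continuous injury
measurements separate by the ordinal category a pathologist assigned —
overlapping adjacent categories indicate the cut-points do not partition
the measured injury.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from .errors import DegenerateStatisticError, InputError

__all__ = [
    "AgreementReport",
    "pearson_r",
    "lin_ccc",
    "weighted_kappa",
    "interpret_agreement",
    "report",
    "banding_consistency",
    "pairwise_agreement_matrix",
]

_BANDS = ((0.2, "slight"), (0.4, "fair"), (0.6, "moderate"),
          (0.8, "substantial"), (np.inf, "perfect"))


@dataclass(frozen=True)
class AgreementReport:
    """One agreement statistic with its context."""

    statistic_name: str          # pearson_r | lin_ccc | weighted_kappa
    value: float
    n_pairs: int
    weight_scheme: str | None = None   # kappa only: linear | quadratic
    interpretation: str | None = None
    below_chance: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def _paired(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D vectors of equal length")
    if x.size < min_n:
        raise DegenerateStatisticError(f"need at least {min_n} pairs, got {x.size}")
    return x, y


def pearson_r(x, y) -> float:
    """Product-moment correlation; undefined when either vector is constant."""
    x, y = _paired(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateStatisticError("Pearson r undefined: zero variance")
    return float(stats.pearsonr(x, y).statistic)


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient.

    rho_c = 2 cov(x, y) / (var(x) + var(y) + (mean x - mean y)^2) with
    population (1/n) moments, per Lin's original definition (the
    bias-corrected small-sample variant is deliberately not offered).
    Two identical constant vectors are perfectly concordant by convention
    (rho_c = 1); any other zero-variance input leaves the statistic
    undefined.
    """
    x, y = _paired(x, y)
    vx, vy = np.var(x), np.var(y)
    if vx == 0 or vy == 0:
        if vx == 0 and vy == 0 and np.allclose(x, y):
            return 1.0
        raise DegenerateStatisticError("Lin's CCC undefined: zero variance")
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    return float(2 * sxy / (vx + vy + (x.mean() - y.mean()) ** 2))


def weighted_kappa(a, b, k_categories: int, scheme: str = "linear") -> float:
    """Weighted Cohen's kappa for paired ordinal ratings in 0..k-1.

    kappa_w = 1 - sum(w o) / sum(w e) with disagreement weights
    w_ij = |i - j| (linear) or (i - j)^2 (quadratic); observed matrix o
    from the paired ratings, expected matrix e from the marginal products.
    """
    if scheme not in ("linear", "quadratic"):
        raise InputError(f"unknown weight scheme {scheme!r}")
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise InputError("ratings must be equal-length non-empty 1-D vectors")
    if ((a < 0) | (a >= k_categories) | (b < 0) | (b >= k_categories)).any():
        raise InputError(f"ratings must lie in 0..{k_categories - 1}")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        raise DegenerateStatisticError(
            "weighted kappa undefined: both raters use a single category")
    return float(cohen_kappa_score(a, b, labels=np.arange(k_categories),
                                   weights="linear" if scheme == "linear" else "quadratic"))


def interpret_agreement(value: float) -> tuple[str, bool]:
    """Map an agreement value to its conventional strength band.

    Bands are left-closed ([0.6, 0.8) is substantial, 0.8 and above is
    perfect). Negative (below-chance) values are labelled slight with the
    ``below_chance`` flag set.
    """
    if value > 1:
        raise InputError(f"agreement value must be <= 1, got {value!r}")
    if value < 0:
        return "slight", True
    for cut, label in _BANDS:
        if value < cut:
            return label, False
    return "perfect", False  # pragma: no cover


def report(statistic_name: str, value: float, n_pairs: int,
           weight_scheme: str | None = None) -> AgreementReport:
    """Wrap a computed statistic into an :class:`AgreementReport`."""
    if not -1 - 1e-9 <= value <= 1 + 1e-9:
        raise InputError(f"agreement statistics lie in [-1, 1], got {value!r}")
    interp, below = interpret_agreement(min(value, 1.0))
    return AgreementReport(statistic_name=statistic_name, value=float(value),
                           n_pairs=int(n_pairs), weight_scheme=weight_scheme,
                           interpretation=interp, below_chance=below)


def banding_consistency(measurements, assigned_scores) -> dict:
    """Summarise continuous injury measurements by assigned ordinal category.

    For each category 0..3: n, median and quartiles of the measurements
    assigned to it. For each adjacent pair of non-empty categories: the
    fraction of the lower category's values lying inside the upper
    category's min-max range and vice versa, plus their mean as a single
    overlap index (0 = cleanly separated, 1 = fully nested). The
    ``monotone`` flag records whether category medians are non-decreasing.
    """
    m = np.asarray(measurements, dtype=float)
    s = np.asarray(assigned_scores)
    if m.shape != s.shape or m.ndim != 1:
        raise InputError("measurements and scores must be equal-length 1-D vectors")
    if ((s < 0) | (s > 3)).any():
        raise InputError("assigned scores must lie in 0..3")

    categories = []
    for c in range(4):
        vals = m[s == c]
        categories.append({
            "category": c,
            "n": int(vals.size),
            "median": float(np.median(vals)) if vals.size else None,
            "q1": float(np.percentile(vals, 25)) if vals.size else None,
            "q3": float(np.percentile(vals, 75)) if vals.size else None,
        })

    overlaps = []
    present = [c for c in range(4) if categories[c]["n"] > 0]
    for lo, hi in zip(present, present[1:]):
        a = m[s == lo]
        b = m[s == hi]
        frac_lo = float(np.mean((a >= b.min()) & (a <= b.max())))
        frac_hi = float(np.mean((b >= a.min()) & (b <= a.max())))
        overlaps.append({
            "lower": lo, "upper": hi,
            "frac_lower_in_upper_range": frac_lo,
            "frac_upper_in_lower_range": frac_hi,
            "overlap": 0.5 * (frac_lo + frac_hi),
        })

    medians = [categories[c]["median"] for c in present]
    monotone = all(m2 >= m1 for m1, m2 in zip(medians, medians[1:]))
    return {"categories": categories, "adjacent_overlap": overlaps,
            "monotone": bool(monotone)}


def pairwise_agreement_matrix(scores: pd.DataFrame, by: str = "technique",
                              stat: str = "kappa", scheme: str = "linear",
                              k_categories: int = 13) -> pd.DataFrame:
    """Pairwise agreement of Remuzzi totals between groups (e.g. techniques).

    Slides are paired across two groups by (donor_id, kidney_side,
    replicate, stain) — the replicate index is recovered from the biopsy
    id ordering within each kidney/group — and the chosen statistic is
    computed on the paired totals. Unmatched or unscorable slides are
    dropped. Returns a symmetric matrix as a DataFrame.
    """
    df = scores.dropna(subset=["total"]).copy()
    df["total"] = df["total"].astype(int)
    # replicate index: order of distinct biopsies within kidney x group
    df["_rep"] = (
        df.groupby(["donor_id", "kidney_side", by, "stain"])["biopsy_id"]
        .rank(method="dense").astype(int)
    )
    groups = sorted(df[by].unique())
    mat = pd.DataFrame(np.nan, index=groups, columns=groups, dtype=float)
    key = ["donor_id", "kidney_side", "_rep", "stain"]
    for i, g1 in enumerate(groups):
        mat.loc[g1, g1] = 1.0
        for g2 in groups[i + 1:]:
            left = df[df[by] == g1].set_index(key)["total"]
            right = df[df[by] == g2].set_index(key)["total"]
            joined = pd.concat([left, right], axis=1, join="inner", keys=["a", "b"])
            if len(joined) < 2:
                continue
            try:
                if stat == "kappa":
                    v = weighted_kappa(joined["a"], joined["b"], k_categories, scheme)
                elif stat == "ccc":
                    v = lin_ccc(joined["a"], joined["b"])
                elif stat == "pearson":
                    v = pearson_r(joined["a"], joined["b"])
                else:
                    raise InputError(f"unknown statistic {stat!r}")
            except DegenerateStatisticError:
                continue
            mat.loc[g1, g2] = mat.loc[g2, g1] = v
    mat.index.name = by
    return mat
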