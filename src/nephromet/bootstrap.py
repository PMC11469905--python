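"""Bootstrap uncertainty for per-kidney Remuzzi scores and pair agreement.

Repeat biopsies of the same kidney spread widely on the 0-12 score axis,
often across implantation-decision boundaries. Resampling each kidney's
observed scores with replacement (B = 1000 by default, each resample the
size of the original set) yields empirical distributions of the mean score
without any normality assumption. Mapping each replicate mean through the
continuous decision bands gives the proportion of resamples landing in
each decision category; the modal proportion is the *confidence* of the
recommendation — 1 minus the boundary-crossing proportion.

Two estimators of within-donor-pair agreement are provided:

* ``pair_match_single`` — per replicate, draw one score from each kidney
  and compare the integer-score decisions: the single-slide workflow;
* ``pair_match_pooled`` — per replicate, resample each kidney fully and
  compare the decisions of the subsample means: the pooled workflow.

Because the two kidneys are drawn independently, both match rates equal
sum_c p_left(c) p_right(c) over decision categories; an exact-enumeration
mode evaluates that sum over all n^n resamples when feasible and replaces
Monte Carlo (used as the oracle in tests and available to callers).

Randomness: one root seed spawns an independent, order-insensitive
substream per kidney (keyed by donor id and side), so adding or removing
a kidney never perturbs another kidney's replicates.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import ConfigurationError, DegenerateStatisticError, InputError
from .scoring import DECISIONS, ThresholdConfig, decide_continuous, decide_total

__all__ = [
    "KidneyScoreSet",
    "BootstrapConfig",
    "BootstrapResult",
    "bootstrap_kidney",
    "confidence",
    "pair_match_single",
    "pair_match_pooled",
    "mean_distribution_summary",
    "compare_pairs",
    "kidney_sets_from_scores",
    "BootstrapUncertainty",
    "EXACT_ENUMERATION_LIMIT",
]

#: Exact enumeration replaces Monte Carlo when n**n does not exceed this.
EXACT_ENUMERATION_LIMIT = 10 ** 6


@dataclass(frozen=True)
class KidneyScoreSet:
    """All scorable-slide Remuzzi totals observed for one kidney."""

    donor_id: str
    kidney_side: str
    scores: tuple[int, ...]

    def __post_init__(self) -> None:
        sc = tuple(int(s) for s in self.scores)
        if len(sc) == 0:
            raise InputError("a kidney needs at least one score")
        if any(not 0 <= s <= 12 for s in sc):
            raise InputError("Remuzzi totals must lie in 0..12")
        object.__setattr__(self, "scores", sc)

    @property
    def key(self) -> str:
        return f"{self.donor_id}|{self.kidney_side}"

    @property
    def n(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling parameters: B replicates, root seed, subsample size."""

    n_replicates: int = 1000
    seed: int = 0
    subsample_size: int | None = None   # None = same size as the data

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")


@dataclass(frozen=True)
class BootstrapResult:
    """Replicate statistics and decision distribution for one kidney."""

    donor_id: str
    kidney_side: str
    n_scores: int
    replicate_means: np.ndarray
    replicate_sds: np.ndarray
    decision_proportions: dict[str, float]
    confidence: float
    modal_decision: str

    def summary(self) -> dict:
        means = self.replicate_means
        lo, med, hi = np.percentile(means, [2.5, 50, 97.5])
        return {
            "donor_id": self.donor_id,
            "kidney_side": self.kidney_side,
            "n_scores": self.n_scores,
            "mean_of_means": float(means.mean()),
            "sd_of_means": float(means.std()),
            "p2.5": float(lo), "p50": float(med), "p97.5": float(hi),
            **{f"prop_{d}": self.decision_proportions[d] for d in DECISIONS},
            "confidence": self.confidence,
            "modal_decision": self.modal_decision,
        }


# ---------------------------------------------------------------------------
# randomness plumbing
# ---------------------------------------------------------------------------

def _substream(seed: int, *keys: str) -> np.random.Generator:
    """Independent per-kidney (or per-pair) stream keyed by stable string ids."""
    digest = [zlib.crc32("|".join(keys).encode("utf-8"))]
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                        spawn_key=tuple(digest)))


def _decide_continuous_vec(means: np.ndarray, cfg: ThresholdConfig) -> np.ndarray:
    """Vectorised decide_continuous over an array of mean scores -> 0/1/2."""
    tol = 1e-9
    out = np.ones(means.shape, dtype=np.int8)          # dual
    out[means <= cfg.decision_single_max + tol] = 0    # single
    out[means >= cfg.decision_dual_max + 1 - tol] = 2  # discard
    return out


def _decide_total_vec(scores: np.ndarray, cfg: ThresholdConfig) -> np.ndarray:
    out = np.ones(scores.shape, dtype=np.int8)
    out[scores <= cfg.decision_single_max] = 0
    out[scores > cfg.decision_dual_max] = 2
    return out


def _all_resample_means(scores: np.ndarray, size: int) -> np.ndarray:
    """Means of every possible with-replacement resample (n^size of them)."""
    n = scores.size
    combos = np.array(list(product(range(n), repeat=size)), dtype=np.intp)
    return scores[combos].mean(axis=1)


def _feasible_exact(n: int, size: int) -> bool:
    return n ** size <= EXACT_ENUMERATION_LIMIT


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def bootstrap_kidney(k: KidneyScoreSet, cfg: BootstrapConfig | None = None,
                     thresholds: ThresholdConfig | None = None,
                     exact: bool = False) -> BootstrapResult:
    """Resample one kidney's scores and summarise means, SDs and decisions.

    Each of the B replicates draws ``subsample_size`` scores (default: the
    size of the original set) with replacement; the replicate mean is
    mapped through the continuous decision bands. ``exact=True`` replaces
    Monte Carlo by full enumeration of all resamples (equally weighted),
    feasible for n^n up to 10^6; replicate vectors then hold the
    enumeration rather than B draws.

    Replicate SDs use the population (1/n) convention — the plug-in view
    of the bootstrap.
    """
    cfg = cfg or BootstrapConfig()
    thresholds = thresholds or ThresholdConfig()
    scores = np.asarray(k.scores, dtype=float)
    n = scores.size
    size = cfg.subsample_size or n
    if exact:
        if not _feasible_exact(n, size):
            raise InputError(f"exact enumeration infeasible: {n}^{size} resamples")
        combos = np.array(list(product(range(n), repeat=size)), dtype=np.intp)
        draws = scores[combos]
    else:
        rng = _substream(cfg.seed, k.donor_id, k.kidney_side)
        draws = scores[rng.integers(0, n, size=(cfg.n_replicates, size))]
    means = draws.mean(axis=1)
    sds = draws.std(axis=1)  # ddof=0: population convention
    cats = _decide_continuous_vec(means, thresholds)
    props = {d: float(np.mean(cats == i)) for i, d in enumerate(DECISIONS)}
    modal = max(DECISIONS, key=lambda d: props[d])
    return BootstrapResult(
        donor_id=k.donor_id, kidney_side=k.kidney_side, n_scores=n,
        replicate_means=means, replicate_sds=sds,
        decision_proportions=props, confidence=props[modal],
        modal_decision=modal,
    )


def confidence(k: KidneyScoreSet, cfg: BootstrapConfig | None = None,
               thresholds: ThresholdConfig | None = None,
               exact: bool = False) -> float:
    """Proportion of bootstrap estimates in the modal decision category.

    Equals 1 minus the boundary-crossing proportion: 1.0 means every
    resampled mean recommends the same action.
    """
    return bootstrap_kidney(k, cfg, thresholds, exact=exact).confidence


def _single_draw_decision_dist(k: KidneyScoreSet, thresholds: ThresholdConfig) -> np.ndarray:
    cats = _decide_total_vec(np.asarray(k.scores), thresholds)
    return np.bincount(cats, minlength=3) / k.n


def pair_match_single(left: KidneyScoreSet, right: KidneyScoreSet,
                      cfg: BootstrapConfig | None = None,
                      thresholds: ThresholdConfig | None = None,
                      exact: bool = False) -> float:
    """Within-pair decision agreement of the single-slide workflow.

    Per replicate, one score is drawn uniformly (with replacement) from
    each kidney and the integer-score decisions are compared; the rate is
    the mean match indicator over B replicates. ``exact=True`` returns the
    exact expectation sum_c p_left(c) p_right(c) over the two kidneys'
    single-draw decision distributions.
    """
    cfg = cfg or BootstrapConfig()
    thresholds = thresholds or ThresholdConfig()
    if exact:
        pl = _single_draw_decision_dist(left, thresholds)
        pr = _single_draw_decision_dist(right, thresholds)
        return float(pl @ pr)
    rng = _substream(cfg.seed, left.donor_id, left.kidney_side,
                     right.donor_id, right.kidney_side, "single")
    li = rng.integers(0, left.n, size=cfg.n_replicates)
    ri = rng.integers(0, right.n, size=cfg.n_replicates)
    dl = _decide_total_vec(np.asarray(left.scores)[li], thresholds)
    dr = _decide_total_vec(np.asarray(right.scores)[ri], thresholds)
    return float(np.mean(dl == dr))


def pair_match_pooled(left: KidneyScoreSet, right: KidneyScoreSet,
                      cfg: BootstrapConfig | None = None,
                      thresholds: ThresholdConfig | None = None,
                      exact: bool = False) -> float:
    """Within-pair decision agreement of the pooled-mean workflow.

    Per replicate, each kidney's score set is resampled in full, the two
    subsample means are mapped through the continuous decision bands, and
    the decisions compared. ``exact=True`` enumerates each kidney's
    resample-decision distribution exhaustively (feasible when each n^n
    is within the enumeration limit) and returns the exact match
    probability by independence.
    """
    cfg = cfg or BootstrapConfig()
    thresholds = thresholds or ThresholdConfig()
    if exact:
        dists = []
        for k in (left, right):
            if not _feasible_exact(k.n, k.n):
                raise InputError("exact enumeration infeasible for this kidney")
            means = _all_resample_means(np.asarray(k.scores, dtype=float), k.n)
            cats = _decide_continuous_vec(means, thresholds)
            dists.append(np.bincount(cats, minlength=3) / cats.size)
        return float(dists[0] @ dists[1])
    rng = _substream(cfg.seed, left.donor_id, left.kidney_side,
                     right.donor_id, right.kidney_side, "pooled")
    ls = np.asarray(left.scores, dtype=float)
    rs = np.asarray(right.scores, dtype=float)
    lm = ls[rng.integers(0, left.n, size=(cfg.n_replicates, left.n))].mean(axis=1)
    rm = rs[rng.integers(0, right.n, size=(cfg.n_replicates, right.n))].mean(axis=1)
    dl = _decide_continuous_vec(lm, thresholds)
    dr = _decide_continuous_vec(rm, thresholds)
    return float(np.mean(dl == dr))


def mean_distribution_summary(results) -> pd.DataFrame:
    """Tabulate per-kidney replicate-mean distributions.

    One row per kidney: mean and SD of the replicate means, 2.5/50/97.5
    percentiles, decision-category proportions, confidence and modal
    decision — the numeric backing of a violin-plot view of the
    bootstrapped mean distributions.
    """
    rows = [r.summary() for r in results]
    if not rows:
        raise InputError("at least one kidney result is required")
    return pd.DataFrame(rows)


def compare_pairs(left: KidneyScoreSet, right: KidneyScoreSet) -> float:
    """Two-sample rank-sum (Mann-Whitney U) p-value for two kidneys' scores."""
    if left.n < 3 or right.n < 3:
        raise DegenerateStatisticError("rank test needs n >= 3 per kidney")
    return float(stats.mannwhitneyu(left.scores, right.scores,
                                    alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# table plumbing and estimator facade
# ---------------------------------------------------------------------------

def kidney_sets_from_scores(scores: pd.DataFrame,
                            adequate_only: bool = False) -> list[KidneyScoreSet]:
    """Group a scores table into per-kidney score sets.

    Unscorable slides (missing total) are always dropped; setting
    ``adequate_only`` additionally keeps only adequate slides.
    """
    df = scores.dropna(subset=["total"])
    if adequate_only:
        df = df[df["adequate"].astype(bool)]
    out = []
    for (donor, side), grp in df.groupby(["donor_id", "kidney_side"], sort=True):
        out.append(KidneyScoreSet(str(donor), str(side),
                                  tuple(int(t) for t in grp["total"])))
    return out


class BootstrapUncertainty(BaseEstimator):
    """Estimator facade: fit on a scores table, expose per-kidney results.

    Parameters mirror :class:`BootstrapConfig`; after ``fit`` the fitted
    attributes hold one :class:`BootstrapResult` per kidney
    (``results_``), the summary table (``summary_``) and, when a pairs
    table is given, the within-pair match rates (``pair_match_``).
    """

    def __init__(self, n_replicates: int = 1000, seed: int = 0,
                 adequate_only: bool = False,
                 thresholds: ThresholdConfig | None = None):
        self.n_replicates = n_replicates
        self.seed = seed
        self.adequate_only = adequate_only
        self.thresholds = thresholds

    def fit(self, X: pd.DataFrame, y=None,
            pairs: pd.DataFrame | None = None) -> "BootstrapUncertainty":
        """Bootstrap every kidney found in scores table ``X``.

        ``pairs`` lists donor pairs as rows (donor_id, left_side,
        right_side); both kidneys must be present in ``X``.
        """
        cfg = BootstrapConfig(n_replicates=self.n_replicates, seed=self.seed)
        thr = self.thresholds or ThresholdConfig()
        sets = kidney_sets_from_scores(X, self.adequate_only)
        by_key = {k.key: k for k in sets}
        self.results_ = [bootstrap_kidney(k, cfg, thr) for k in sets]
        self.summary_ = mean_distribution_summary(self.results_)
        self.pair_match_ = None
        if pairs is not None:
            rows = []
            for _, p in pairs.iterrows():
                kl = by_key.get(f"{p['donor_id']}|{p['left_side']}")
                kr = by_key.get(f"{p['donor_id']}|{p['right_side']}")
                if kl is None or kr is None:
                    continue
                rows.append({
                    "donor_id": str(p["donor_id"]),
                    "match_single": pair_match_single(kl, kr, cfg, thr),
                    "match_pooled": pair_match_pooled(kl, kr, cfg, thr),
                })
            self.pair_match_ = pd.DataFrame(
                rows, columns=["donor_id", "match_single", "match_pooled"])
        return self
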