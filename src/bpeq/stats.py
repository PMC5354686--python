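"""Risk statistics: Mann–Whitney, nonparametric ROC, phase/cutoff selection,
and 2x2 odds ratios.

The ROC is empirical ("score >= threshold" calls a subject high-BPER /
positive); its area equals the Mann–Whitney U statistic divided by
n1*n2 — the nonparametric identity this module also exposes as a
cross-check. The operating point is picked by the Youden index, the
odds-ratio confidence interval is the Woolf (logit) interval, and the
2x2 association test is Pearson's chi-square without continuity
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

from .volume import PHASES

_Z95 = 1.959963984540054  # norm.ppf(0.975)


# ---------------------------------------------------------------------------
# Mann–Whitney


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # U statistic of the first sample: #{x > y} + 0.5 #{x = y}
    p: float  # two-sided
    method: str  # "exact" | "asymptotic"


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    r_x = ranks[: x.size].sum()
    return float(r_x - x.size * (x.size + 1) / 2)


def mann_whitney(x, y, exact_limit: int = 20) -> MannWhitneyResult:
    """Rank-sum test with midrank ties.

    Exact two-sided p by enumeration over all assignments of the pooled
    (mid)ranks when both samples have at most ``exact_limit`` observations,
    otherwise a tie-corrected normal approximation (no continuity
    correction). The U convention counts pairs with x > y (ties half).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    u = _u_statistic(x, y)
    mean_u = n1 * n2 / 2

    if max(n1, n2) <= exact_limit and comb(n1 + n2, n1) <= 400_000:
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        total = comb(n1 + n2, n1)
        const = n1 * (n1 + 1) / 2
        dev = abs(u - mean_u) - 1e-12
        hits = 0
        for idx in combinations(range(n1 + n2), n1):
            u_perm = ranks[list(idx)].sum() - const
            if abs(u_perm - mean_u) >= dev:
                hits += 1
        return MannWhitneyResult(u=u, p=hits / total, method="exact")

    n = n1 + n2
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    var_u = n1 * n2 / 12 * (n + 1 - tie_term)
    if var_u <= 0:
        return MannWhitneyResult(u=u, p=1.0, method="asymptotic")
    z = (u - mean_u) / np.sqrt(var_u)
    p = 2 * sps.norm.sf(abs(z))
    return MannWhitneyResult(u=u, p=float(min(p, 1.0)), method="asymptotic")


# ---------------------------------------------------------------------------
# ROC


@dataclass
class RocResult:
    """Empirical ROC with its nonparametric AUC and a DeLong 95% CI."""

    thresholds: np.ndarray  # descending; score >= threshold is "positive"
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    n_pos: int
    n_neg: int

    def u_over_n1n2(self) -> float:
        """AUC recomputed through the Mann–Whitney identity U/(n1 n2)."""
        return self._u / (self.n_pos * self.n_neg)


def _delong_variance(pos: np.ndarray, neg: np.ndarray, auc: float) -> float:
    # placements: V10_i = P(score_i > neg) + .5 P(=), V01_j symmetric
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / neg.size for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / pos.size for q in neg])
    s10 = v10.var(ddof=1) if pos.size > 1 else 0.0
    s01 = v01.var(ddof=1) if neg.size > 1 else 0.0
    return s10 / pos.size + s01 / neg.size


def roc(scores, labels, ci_method: str = "delong") -> RocResult:
    """Empirical ROC over all distinct thresholds of ``scores``.

    ``labels`` are truthy for the positive class (cancer). AUC is the
    trapezoid area, identical to U/(n1 n2) with midrank tie handling.
    CI by DeLong (default) or Hanley–McNeil.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    if scores.size != labels.size:
        raise ValueError("scores and labels differ in length")
    pos, neg = scores[labels], scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")

    thresholds = np.unique(scores)[::-1]
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    # trapezoid over the full curve including the (0,0) and (1,1) endpoints
    fpr = np.concatenate([[0.0], 1 - spec, [1.0]])
    tpr = np.concatenate([[0.0], sens, [1.0]])
    auc = float(np.trapezoid(tpr, fpr))

    if ci_method == "delong":
        var = _delong_variance(pos, neg, auc)
    elif ci_method == "hanley-mcneil":
        q1 = auc / (2 - auc)
        q2 = 2 * auc**2 / (1 + auc)
        var = (
            auc * (1 - auc)
            + (pos.size - 1) * (q1 - auc**2)
            + (neg.size - 1) * (q2 - auc**2)
        ) / (pos.size * neg.size)
    else:
        raise ValueError(f"unknown AUC CI method {ci_method!r}")
    half = _Z95 * np.sqrt(max(var, 0.0))
    result = RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_ci=(max(0.0, auc - half), min(1.0, auc + half)),
        n_pos=pos.size,
        n_neg=neg.size,
    )
    result._u = _u_statistic(pos, neg)
    return result


def best_phase(rocs: dict[str, "RocResult | float"]) -> str:
    """Phase with maximal AUC; ties go to the earlier phase."""
    if not rocs:
        raise ValueError("need at least one phase")
    order = [p for p in PHASES if p in rocs] + [p for p in rocs if p not in PHASES]

    def _auc(v):
        return v.auc if isinstance(v, RocResult) else float(v)

    best = order[0]
    for p in order[1:]:
        if _auc(rocs[p]) > _auc(rocs[best]):
            best = p
    return best


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    degenerate: bool  # J == 0: no operating point beats chance


def youden_cutoff(roc_result: RocResult) -> CutoffResult:
    """Operating point maximising sensitivity + specificity − 1.

    Ties go to the lower threshold. A maximal J of 0 (ROC at or below the
    diagonal everywhere) is flagged as degenerate with a warning.
    """
    j = roc_result.sensitivity + roc_result.specificity - 1.0
    best = j.max()
    idx = np.flatnonzero(j == best)
    i = idx[np.argmin(roc_result.thresholds[idx])]
    degenerate = best <= 0
    if degenerate:
        warnings.warn("Youden index is 0: no cutoff separates the classes", stacklevel=2)
    return CutoffResult(
        cutoff=float(roc_result.thresholds[i]),
        sensitivity=float(roc_result.sensitivity[i]),
        specificity=float(roc_result.specificity[i]),
        youden_j=float(best),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# 2x2 tables


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts; exposure is BPER >= cutoff, outcome is case vs comparison.

    a: cases at/above cutoff, b: cases below, c: comparison at/above,
    d: comparison below.
    """

    a: int
    b: int
    c: int
    d: int
    cutoff: float = float("nan")
    stratum: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")

    def exposure_inverted(self) -> "ContingencyTable":
        """Exposure direction flipped (below vs at/above cutoff): OR -> 1/OR."""
        return ContingencyTable(self.b, self.a, self.d, self.c, self.cutoff, self.stratum)

    def outcome_inverted(self) -> "ContingencyTable":
        """Outcome rows swapped (comparison group as cases): OR -> 1/OR."""
        return ContingencyTable(self.c, self.d, self.a, self.b, self.cutoff, self.stratum)


def dichotomize(
    values,
    groups,
    cutoff: float,
    case_group: str,
    comparison_group: str,
    stratum: str = "",
) -> ContingencyTable:
    """Count subjects at/above vs below ``cutoff`` per group.

    ">= cutoff" is the high-BPER exposure.
    """
    if np.isnan(cutoff):
        raise ValueError("cutoff must not be NaN")
    values = np.asarray(values, dtype=float).ravel()
    groups = np.asarray(groups).ravel()
    case = values[groups == case_group]
    comp = values[groups == comparison_group]
    if case.size == 0 or comp.size == 0:
        raise ValueError("both groups must be present in the stratum")
    return ContingencyTable(
        a=int((case >= cutoff).sum()),
        b=int((case < cutoff).sum()),
        c=int((comp >= cutoff).sum()),
        d=int((comp < cutoff).sum()),
        cutoff=float(cutoff),
        stratum=stratum,
    )


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float  # Pearson chi-square, no continuity correction
    haldane: bool  # True when a zero cell forced the +0.5 fallback


def odds_ratio(table: ContingencyTable) -> OddsRatioResult:
    """OR = ad/bc with the Woolf (logit) 95% CI.

    A zero cell triggers the Haldane–Anscombe +0.5 correction for both the
    estimate and the CI, flagged in the result and by a warning (an
    unexposed-case/exposed-comparison zero makes the raw OR infinite).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    haldane = min(a, b, c, d) == 0
    if haldane:
        warnings.warn(
            "zero cell in 2x2 table: Haldane-Anscombe +0.5 applied to OR and CI",
            stacklevel=2,
        )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci = (float(np.exp(np.log(or_) - _Z95 * se)), float(np.exp(np.log(or_) + _Z95 * se)))
    obs = np.array([[table.a, table.b], [table.c, table.d]])
    if obs.sum(axis=0).min() == 0 or obs.sum(axis=1).min() == 0:
        p = float("nan")
    else:
        p = float(sps.chi2_contingency(obs, correction=False).pvalue)
    return OddsRatioResult(float(or_), ci[0], ci[1], p, haldane)


def format_report_value(kind: str, value: float) -> str:
    """Printed-precision formatting: 1 decimal for OR/CI, 3 for AUC,
    2 for sensitivity/specificity percentages."""
    digits = {"or": 1, "ci": 1, "auc": 3, "pct": 2, "p": 3}[kind]
    return f"{value:.{digits}f}"
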