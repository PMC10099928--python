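"""Statistical tests and the conjunction rule behind the genotoxicity call.

A chemical is called genotoxic when **both** of the following hold at the
same significance level (default alpha = 0.05):

1. the Cochran–Armitage trend test over control + all dose groups finds a
   significant dose trend in the micronucleated-BNC proportion, and
2. Fisher's exact test finds at least one dose group with a significant
   excess of micronucleated BNCs over the concurrent solvent control.

Counts are pooled over replicate inserts before testing.  Pooling assumes
inserts within a group share one MN rate; when the insert-level 2x2 tables
are heterogeneous (chi-square p < 0.05) a warning is attached to the call
so overdispersion-driven false positives are auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .data_model import DoseGroup, Experiment, MnCounts, pool_mn
from .errors import InvalidTableError

__all__ = [
    "TrendSpec",
    "GenotoxCall",
    "fisher_exact",
    "cochran_armitage",
    "welch_t",
    "genotoxic_call",
    "insert_heterogeneity_p",
]

FisherSidedness = Literal["greater", "two_sided"]
TrendSidedness = Literal["increasing", "two_sided"]


@dataclass(frozen=True)
class TrendSpec:
    """Dose scores for the trend test, control first.

    ``from_concentrations`` builds the three conventional choices:
    actual concentrations (``dose``), ranks (``rank``), or
    ``log10(concentration + c)`` with ``c`` = the smallest non-zero
    concentration (``log``).
    """

    scores: tuple[float, ...]
    sidedness: TrendSidedness = "increasing"

    def __post_init__(self):
        object.__setattr__(self, "scores", tuple(float(s) for s in self.scores))
        if len(self.scores) < 2:
            raise InvalidTableError("trend test needs at least two groups")
        if any(b <= a for a, b in zip(self.scores, self.scores[1:])):
            raise InvalidTableError("trend scores must be strictly increasing")

    @staticmethod
    def from_concentrations(
        concentrations: Sequence[float],
        mode: Literal["dose", "rank", "log"] = "dose",
        sidedness: TrendSidedness = "increasing",
    ) -> "TrendSpec":
        c = [float(x) for x in concentrations]
        if mode == "dose":
            scores = c
        elif mode == "rank":
            scores = list(range(len(c)))
        elif mode == "log":
            offset = min(x for x in c if x > 0)
            scores = [math.log10(x + offset) for x in c]
        else:
            raise ValueError(f"unknown score mode {mode!r}")
        return TrendSpec(tuple(scores), sidedness)


@dataclass(frozen=True)
class GenotoxCall:
    """Result of the two-test conjunction rule for one chemical."""

    chemical: str
    trend_z: float
    trend_p: float
    per_dose_fisher_p: dict[float, float]
    alpha: float
    significant_doses: tuple[float, ...]
    verdict: bool
    degenerate_trend: bool = False
    heterogeneity_warning: bool = False
    assumptions: dict = field(default_factory=dict)


def _validate_2x2(a: int, b: int, c: int, d: int) -> None:
    if min(a, b, c, d) < 0:
        raise InvalidTableError("2x2 table has negative cell")
    if a + b == 0 or c + d == 0:
        raise InvalidTableError("2x2 table has an empty margin")


def _hypergeom_weights(n1: int, n2: int, k_total: int) -> tuple[int, list[int]]:
    """Integer weights C(n1,k)*C(n2,K-k) over the support of k.

    Computed by an exact integer recurrence (each step's division is
    exact), so tail sums and most-probable-table comparisons carry no
    floating-point error.
    """
    lo = max(0, k_total - n2)
    hi = min(k_total, n1)
    w = math.comb(n1, lo) * math.comb(n2, k_total - lo)
    weights = [w]
    for k in range(lo, hi):
        w = w * (n1 - k) * (k_total - k) // ((k + 1) * (n2 - k_total + k + 1))
        weights.append(w)
    return lo, weights


def fisher_exact(
    treated: MnCounts,
    control: MnCounts,
    sidedness: FisherSidedness = "two_sided",
) -> float:
    """Exact hypergeometric p-value for treated-vs-control MN excess.

    The 2x2 table is (micronucleated, not micronucleated) x (treated,
    control).  ``greater`` sums all tables with at least the observed
    treated MN count; ``two_sided`` sums every table whose point
    probability does not exceed the observed one's.  Tail sums are exact
    integer arithmetic (no distribution-function roundoff).
    """
    a = treated.n_bnc_mn
    b = treated.n_bnc_scored - treated.n_bnc_mn
    c = control.n_bnc_mn
    d = control.n_bnc_scored - control.n_bnc_mn
    _validate_2x2(a, b, c, d)
    n1, n2 = a + b, c + d
    lo, weights = _hypergeom_weights(n1, n2, a + c)
    total = sum(weights)
    if sidedness == "greater":
        num = sum(weights[a - lo :])
    else:
        observed = weights[a - lo]
        num = sum(w for w in weights if w <= observed)
    return num / total


def cochran_armitage(
    groups: Sequence[MnCounts], spec: TrendSpec
) -> tuple[float, float]:
    """Cochran–Armitage test for trend in proportions across dose groups.

    Returns ``(z, p)`` for the statistic

        Z = sum_i s_i (x_i - n_i pbar)
            / sqrt( pbar (1-pbar) [sum n_i s_i^2 - (sum n_i s_i)^2 / N] )

    with pooled proportion ``pbar`` and the asymptotic normal tail per the
    spec's sidedness (no continuity correction).  With no variation in the
    outcome (pbar 0 or 1) the trend is degenerate: z = 0, p = 1.
    """
    if len(groups) != len(spec.scores):
        raise InvalidTableError(
            f"{len(groups)} groups but {len(spec.scores)} scores"
        )
    if any(g.n_bnc_scored <= 0 for g in groups):
        raise InvalidTableError("every group needs a positive denominator")

    x = np.array([g.n_bnc_mn for g in groups], dtype=float)
    n = np.array([g.n_bnc_scored for g in groups], dtype=float)
    s = np.array(spec.scores, dtype=float)
    big_n = n.sum()
    pbar = x.sum() / big_n
    if pbar == 0.0 or pbar == 1.0:
        return 0.0, 1.0

    num = float(np.sum(s * (x - n * pbar)))
    var = pbar * (1 - pbar) * (
        float(np.sum(n * s**2)) - float(np.sum(n * s)) ** 2 / big_n
    )
    z = num / math.sqrt(var)
    if spec.sidedness == "increasing":
        p = float(sps.norm.sf(z))
    else:
        p = float(2 * sps.norm.sf(abs(z)))
    return z, p


def cochran_armitage_permutation(
    groups: Sequence[MnCounts],
    spec: TrendSpec,
    n_resamples: int = 10_000,
    seed: int = 0,
) -> float:
    """Permutation p-value for the trend statistic (small-count option).

    Resamples the group event counts from the multivariate hypergeometric
    permutation null (fixed group sizes and total events) and reports the
    tail fraction of the score-weighted event sum.  One-sided for
    ``increasing`` specs, folded for ``two_sided``.
    """
    x = np.array([g.n_bnc_mn for g in groups])
    n = np.array([g.n_bnc_scored for g in groups])
    s = np.array(spec.scores, dtype=float)
    total = int(x.sum())
    if total == 0 or total == int(n.sum()):
        return 1.0
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(n, total, size=n_resamples)
    t_null = draws @ s
    t_obs = float(x @ s)
    if spec.sidedness == "increasing":
        exceed = t_null >= t_obs
    else:
        center = float(n @ s) * total / int(n.sum())
        exceed = np.abs(t_null - center) >= abs(t_obs - center)
    # add-one so the observed arrangement counts as achieved
    return float((exceed.sum() + 1) / (n_resamples + 1))


def welch_t(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, two-sided p).

    Used for endpoint comparisons (e.g. TEER of a treatment group against
    its control) where group variances cannot be assumed equal.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidTableError("each sample needs at least two values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), float(
            a.size + b.size - 2
        ), 0.0
    res = sps.ttest_ind(a, b, equal_var=False)
    se2 = va / a.size + vb / b.size
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    return float(res.statistic), float(df), float(res.pvalue)


def insert_heterogeneity_p(group: DoseGroup) -> Optional[float]:
    """Chi-square p for heterogeneity of MN proportions across inserts.

    Returns None when fewer than two inserts carry MN counts (including
    pooled pseudo-inserts, where replicate structure is lost).
    """
    tables = [
        (i.mn_counts.n_bnc_mn, i.mn_counts.n_bnc_scored - i.mn_counts.n_bnc_mn)
        for i in group.inserts
        if i.mn_counts is not None and i.mn_counts.n_bnc_scored > 0
    ]
    if len(tables) < 2:
        return None
    arr = np.array(tables, dtype=float)
    if arr[:, 0].sum() == 0 or arr[:, 1].sum() == 0:
        return None
    return float(sps.chi2_contingency(arr, correction=False).pvalue)


def genotoxic_call(
    experiment: Experiment,
    alpha: float = 0.05,
    spec: Optional[TrendSpec] = None,
    fisher_sidedness: FisherSidedness = "two_sided",
) -> GenotoxCall:
    """Apply the two-test conjunction rule to one chemical's experiment.

    Verdict is genotoxic iff the trend p-value and at least one per-dose
    Fisher p-value fall below ``alpha``.  Any significant dose satisfies
    the pairwise arm of the rule (no specific dose is required).  The
    default trend scores are the actual concentrations with the control
    scored 0.
    """
    groups = experiment.groups
    pooled = [pool_mn(g) for g in groups]
    if spec is None:
        spec = TrendSpec.from_concentrations(
            [g.concentration for g in groups], mode="dose"
        )

    z, trend_p = cochran_armitage(pooled, spec)
    degenerate = z == 0.0 and trend_p == 1.0 and sum(
        p.n_bnc_mn for p in pooled
    ) in (0, sum(p.n_bnc_scored for p in pooled))

    control_mn = pooled[0]
    fisher_p: dict[float, float] = {}
    for g, mn in zip(groups[1:], pooled[1:]):
        fisher_p[g.concentration] = fisher_exact(
            mn, control_mn, sidedness=fisher_sidedness
        )
    significant = tuple(c for c, p in fisher_p.items() if p < alpha)

    heterogeneity = any(
        (p := insert_heterogeneity_p(g)) is not None and p < 0.05
        for g in groups
    )

    return GenotoxCall(
        chemical=experiment.chemical,
        trend_z=z,
        trend_p=trend_p,
        per_dose_fisher_p=fisher_p,
        alpha=alpha,
        significant_doses=significant,
        verdict=trend_p < alpha and len(significant) > 0,
        degenerate_trend=degenerate,
        heterogeneity_warning=heterogeneity,
        assumptions={
            "fisher_sidedness": fisher_sidedness,
            "trend_sidedness": spec.sidedness,
            "trend_scores": spec.scores,
            "any_dose_rule": True,
        },
    )
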