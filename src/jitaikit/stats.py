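"""Trial outcome derivation and effect statistics.

Implements the Russell-standard abstinence derivations (missing = smoking)
and the estimators used for the trial's tables: Wald odds-ratio intervals
on the log scale, Newcombe hybrid Wilson-score intervals for risk
differences, Wald and Clopper-Pearson proportion intervals, the
uncorrected Pearson chi-square, a flat-prior posterior OR-exceedance
probability, and a plain IRLS logistic regression with separation
diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "RussellCriteria",
    "TwoByTwo",
    "EffectEstimate",
    "OutcomeRecord",
    "ZeroCellError",
    "SeparationError",
    "round_half_up",
    "derive_validated_prolonged",
    "derive_validated_7day",
    "derive_self_report_7day",
    "odds_ratio_wald",
    "risk_difference_newcombe",
    "wilson_interval",
    "proportion_ci_wald",
    "proportion_ci_clopper_pearson",
    "pearson_chi_square",
    "posterior_prob_or_exceeds",
    "logistic_fit",
    "feasibility_summary",
    "analyze_trial",
    "recover_numerator",
    "recover_split_counts",
]

Z_975 = 1.959963984540054


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (the convention used for reported results)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def recover_numerator(pct: float, n: int, decimals: int = 1) -> int:
    """The unique integer k in [0, n] whose percentage k/n rounds (half-up)
    to ``pct`` at ``decimals`` places; raises if none or several exist."""
    hits = [k for k in range(n + 1) if round_half_up(100 * k / n, decimals) == pct]
    if len(hits) != 1:
        raise ValueError(f"{len(hits)} numerators consistent with {pct}% of {n}")
    return hits[0]


def recover_split_counts(
    pct1: float, pct2: float, total: int, max_n1: int, max_n2: int, decimals: int = 1
) -> tuple[int, int, int, int]:
    """Recover (k1, n1, k2, n2) with n1 + n2 = total, n1 <= max_n1,
    n2 <= max_n2, and k1/n1, k2/n2 rounding to the reported percentages.
    Raises unless the solution is unique."""
    hits = []
    for n1 in range(1, min(max_n1, total - 1) + 1):
        n2 = total - n1
        if n2 < 1 or n2 > max_n2:
            continue
        k1s = [k for k in range(n1 + 1) if round_half_up(100 * k / n1, decimals) == pct1]
        k2s = [k for k in range(n2 + 1) if round_half_up(100 * k / n2, decimals) == pct2]
        for k1 in k1s:
            for k2 in k2s:
                hits.append((k1, n1, k2, n2))
    if len(hits) != 1:
        raise ValueError(
            f"{len(hits)} count splits consistent with {pct1}%/{pct2}% of {total}"
        )
    return hits[0]


class ZeroCellError(ValueError):
    """A ratio estimator was requested on a table with an empty cell."""


class SeparationError(RuntimeError):
    """Logistic regression is degenerate (complete/quasi-complete separation)."""


@dataclass(frozen=True)
class RussellCriteria:
    max_cigarettes_since_quit: int = 5
    no_smoking_days: int = 7
    cotinine_cutoff_ng_ml: float = 10.0
    anabasine_cutoff_ng_ml: float = 0.2
    missing_is_smoking: bool = True


@dataclass(frozen=True)
class TwoByTwo:
    """Counts: a = exposed events, b = exposed non-events, c/d unexposed."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValueError("cells must be nonnegative integers")

    @classmethod
    def from_events(cls, k1: int, n1: int, k2: int, n2: int) -> "TwoByTwo":
        return cls(k1, n1 - k1, k2, n2 - k2)

    @property
    def n1(self) -> int:
        return self.a + self.b

    @property
    def n2(self) -> int:
        return self.c + self.d


class Method(str, Enum):
    WALD_OR = "wald_or"
    NEWCOMBE_RD = "newcombe_rd"
    WALD_PROP = "wald_prop"
    CLOPPER_PEARSON_PROP = "clopper_pearson_prop"
    CHI_SQUARE = "chi_square"
    POSTERIOR_PROB = "posterior_prob"


@dataclass(frozen=True)
class EffectEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    method: Method
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("interval must contain the point estimate")


@dataclass(frozen=True)
class OutcomeRecord:
    arm: str
    self_report_prolonged: Optional[bool] = None
    self_report_7day_6m: Optional[bool] = None
    self_report_7day_6w: Optional[bool] = None
    cotinine_ng_ml: Optional[float] = None
    anabasine_ng_ml: Optional[float] = None
    nicotine_substitution_use: bool = False
    withdrawn: bool = False

    def __post_init__(self) -> None:
        for v in (self.cotinine_ng_ml, self.anabasine_ng_ml):
            if v is not None and v < 0:
                raise ValueError("assay concentrations cannot be negative")


def _saliva_validates(record: OutcomeRecord, criteria: RussellCriteria) -> bool:
    if record.cotinine_ng_ml is None:
        return False
    if record.cotinine_ng_ml >= criteria.cotinine_cutoff_ng_ml:
        return False
    if record.nicotine_substitution_use:
        if record.anabasine_ng_ml is None:
            return False
        if record.anabasine_ng_ml >= criteria.anabasine_cutoff_ng_ml:
            return False
    return True


def derive_validated_prolonged(record: OutcomeRecord, criteria: RussellCriteria) -> bool:
    """Russell-standard prolonged abstinence: self-reported prolonged and
    7-day abstinence plus biochemical validation; anything missing,
    withdrawn or unreturned counts as smoking."""
    if record.withdrawn:
        return False
    if record.self_report_prolonged is not True or record.self_report_7day_6m is not True:
        return False
    return _saliva_validates(record, criteria)


def derive_validated_7day(record: OutcomeRecord, criteria: RussellCriteria) -> bool:
    if record.withdrawn:
        return False
    if record.self_report_7day_6m is not True:
        return False
    return _saliva_validates(record, criteria)


def derive_self_report_7day(record: OutcomeRecord, at: str = "6m") -> bool:
    """Self-reported 7-day point prevalence; missing = smoking."""
    if record.withdrawn:
        return False
    v = record.self_report_7day_6m if at == "6m" else record.self_report_7day_6w
    return v is True


def odds_ratio_wald(t: TwoByTwo, alpha: float = 0.05) -> EffectEstimate:
    """Sample OR with the log-scale Wald interval."""
    if min(t.a, t.b, t.c, t.d) == 0:
        raise ZeroCellError(f"zero cell in table {t}; no Wald OR estimate")
    or_ = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    z = sps.norm.ppf(1 - alpha / 2)
    return EffectEstimate(
        estimate=or_,
        ci_low=math.exp(math.log(or_) - z * se),
        ci_high=math.exp(math.log(or_) + z * se),
        method=Method.WALD_OR,
        alpha=alpha,
    )


def wilson_interval(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    z = sps.norm.ppf(1 - alpha / 2)
    p = k / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return centre - half, centre + half


def risk_difference_newcombe(t: TwoByTwo, alpha: float = 0.05) -> EffectEstimate:
    """Difference of proportions with Newcombe's hybrid square-and-add
    interval built from per-group Wilson score limits."""
    if t.n1 == 0 or t.n2 == 0:
        raise ValueError("both group sizes must be positive")
    p1, p2 = t.a / t.n1, t.c / t.n2
    l1, u1 = wilson_interval(t.a, t.n1, alpha)
    l2, u2 = wilson_interval(t.c, t.n2, alpha)
    d = p1 - p2
    lower = max(-1.0, d - math.sqrt((p1 - l1) ** 2 + (u2 - p2) ** 2))
    upper = min(1.0, d + math.sqrt((u1 - p1) ** 2 + (p2 - l2) ** 2))
    return EffectEstimate(d, lower, upper, Method.NEWCOMBE_RD, alpha)


def proportion_ci_wald(k: int, n: int, alpha: float = 0.05) -> EffectEstimate:
    if n <= 0:
        raise ValueError("n must be positive")
    if k <= 0 or k >= n:
        raise ValueError(
            "Wald interval is degenerate at k=0 or k=n; use proportion_ci_clopper_pearson"
        )
    p = k / n
    z = sps.norm.ppf(1 - alpha / 2)
    half = z * math.sqrt(p * (1 - p) / n)
    return EffectEstimate(p, p - half, p + half, Method.WALD_PROP, alpha)


def proportion_ci_clopper_pearson(k: int, n: int, alpha: float = 0.05) -> EffectEstimate:
    if n <= 0 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n and n > 0")
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return EffectEstimate(k / n, lo, hi, Method.CLOPPER_PEARSON_PROP, alpha)


def pearson_chi_square(t: TwoByTwo) -> tuple[float, int, float]:
    """Uncorrected Pearson chi-square on a 2x2 table: (statistic, df, p)."""
    obs = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    n = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("chi-square requires positive margins")
    exp = row @ col / n
    stat = float(((obs - exp) ** 2 / exp).sum())
    return stat, 1, float(sps.chi2.sf(stat, 1))


def posterior_prob_or_exceeds(t: TwoByTwo, threshold: float, prior: str = "flat_log_or") -> float:
    """P(true OR >= threshold) under a flat prior on the log odds ratio,
    i.e. the upper tail of Normal(log sample OR, Wald variance)."""
    if prior != "flat_log_or":
        raise ValueError(f"unsupported prior {prior!r}")
    if min(t.a, t.b, t.c, t.d) == 0:
        raise ZeroCellError("posterior approximation needs all cells positive")
    log_or = math.log((t.a * t.d) / (t.b * t.c))
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return float(sps.norm.sf((math.log(threshold) - log_or) / se))


def logistic_fit(
    design: np.ndarray,
    response: Sequence[int],
    add_intercept: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood logistic regression via IRLS.

    Returns (coefficients, standard errors).  Raises SeparationError on
    degenerate responses or (quasi-)complete separation instead of
    reporting unstable estimates.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(response, dtype=float)
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
    if y.min() == y.max():
        raise SeparationError("response is constant; model degenerate")

    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            break
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from None
        beta = beta + step
        if np.max(np.abs(beta)) > 30:
            raise SeparationError(
                "diverging coefficients; complete or quasi-complete separation"
            )
    else:
        raise SeparationError("IRLS failed to converge; fit questionable")

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    cov = np.linalg.inv(info)
    return beta, np.sqrt(np.diag(cov))


@dataclass(frozen=True)
class FeasibilityReport:
    completion_6m: EffectEstimate
    completion_6w: Optional[EffectEstimate]
    install_rate: Optional[EffectEstimate]
    saliva_return_rate: Optional[EffectEstimate]
    cost_per_recruit: float
    cost_breakdown: dict = field(default_factory=dict)


def feasibility_summary(
    n_randomized: int,
    n_followed_6m: int,
    n_followed_6w: Optional[int] = None,
    n_app_arm: Optional[int] = None,
    n_installed: Optional[int] = None,
    n_saliva_requested: Optional[int] = None,
    n_saliva_returned: Optional[int] = None,
    advertising_costs: Optional[dict[str, float]] = None,
    alpha: float = 0.05,
) -> FeasibilityReport:
    """Feasibility proportions with Wald CIs and advertising cost per recruit."""
    if n_randomized <= 0:
        raise ValueError("no randomized participants")

    def prop(k: Optional[int], n: Optional[int]) -> Optional[EffectEstimate]:
        if k is None or n is None:
            return None
        return proportion_ci_wald(k, n, alpha)

    costs = advertising_costs or {}
    total = sum(costs.values())
    return FeasibilityReport(
        completion_6m=proportion_ci_wald(n_followed_6m, n_randomized, alpha),
        completion_6w=prop(n_followed_6w, n_randomized),
        install_rate=prop(n_installed, n_app_arm),
        saliva_return_rate=prop(n_saliva_returned, n_saliva_requested),
        cost_per_recruit=total / n_randomized,
        cost_breakdown={k: v / n_randomized for k, v in costs.items()},
    )


_OUTCOMES = (
    ("validated_prolonged_6m", "6-month prolonged abstinence, validated"),
    ("validated_7day_6m", "7-day point prevalence at 6 months, validated"),
    ("self_report_7day_6m", "7-day point prevalence at 6 months, self-report"),
    ("self_report_7day_6w", "7-day point prevalence at 6 weeks, self-report"),
)


def _derive_all(record: OutcomeRecord, criteria: RussellCriteria) -> dict[str, bool]:
    return {
        "validated_prolonged_6m": derive_validated_prolonged(record, criteria),
        "validated_7day_6m": derive_validated_7day(record, criteria),
        "self_report_7day_6m": derive_self_report_7day(record, "6m"),
        "self_report_7day_6w": derive_self_report_7day(record, "6w"),
    }


def analyze_trial(
    records: Sequence[OutcomeRecord],
    criteria: RussellCriteria = RussellCriteria(),
    app_arm: str = "app",
    alpha: float = 0.05,
) -> list[dict]:
    """Per-outcome rows with counts, percentages, Newcombe risk differences
    and Wald ORs (missing = smoking applied before estimation)."""
    if not records:
        raise ValueError("empty dataset")
    derived = [(r.arm, _derive_all(r, criteria)) for r in records]
    n1 = sum(1 for arm, _ in derived if arm == app_arm)
    n2 = len(derived) - n1
    rows = []
    for key, label in _OUTCOMES:
        k1 = sum(1 for arm, d in derived if arm == app_arm and d[key])
        k2 = sum(1 for arm, d in derived if arm != app_arm and d[key])
        row: dict = {
            "outcome": key,
            "label": label,
            "app_events": k1,
            "app_n": n1,
            "usual_events": k2,
            "usual_n": n2,
            "app_pct": round_half_up(100 * k1 / n1, 1) if n1 else None,
            "usual_pct": round_half_up(100 * k2 / n2, 1) if n2 else None,
        }
        if n1 and n2:
            t = TwoByTwo.from_events(k1, n1, k2, n2)
            rd = risk_difference_newcombe(t, alpha)
            row["difference_pct"] = round_half_up(100 * rd.estimate, 1)
            row["difference_ci"] = (
                round_half_up(100 * rd.ci_low, 1),
                round_half_up(100 * rd.ci_high, 1),
            )
            try:
                orr = odds_ratio_wald(t, alpha)
                row["or"] = round_half_up(orr.estimate, 2)
                row["or_ci"] = (round_half_up(orr.ci_low, 2), round_half_up(orr.ci_high, 2))
            except ZeroCellError:
                row["or"] = None
                row["or_ci"] = None
                row["flag"] = "zero cell; no OR estimate"
        else:
            row["flag"] = "empty arm; no estimate"
        rows.append(row)
    return rows
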