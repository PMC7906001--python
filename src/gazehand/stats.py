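"""Coordination statistics: normality-gated correlation and group comparison.

The analysis correlates three eye-hand metric pairs (FD-SSD, FN-SSN,
SN-SSM) within each skill group.  Pearson's product-moment correlation is
used when both variables pass a Shapiro-Wilk normality check (p > alpha),
otherwise Spearman's rank-order correlation (mid-ranks for ties).
Coefficient magnitudes are labeled with Cohen's conventional strength
bands, and groups are compared with a Mann-Whitney U test using the
tie-corrected normal approximation (an exact permutation p-value is
available for small samples).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import participant_means

__all__ = [
    "CorrelationResult",
    "MWResult",
    "classify_strength",
    "choose_method",
    "correlate_pair",
    "mann_whitney",
    "run_correlation_battery",
    "METRIC_PAIRS",
]

METRIC_PAIRS = [("FD_ms", "SSD_ms"), ("FN", "SSN"), ("SN", "SSM")]
PAIR_LABELS = {("FD_ms", "SSD_ms"): "FD-SSD", ("FN", "SSN"): "FN-SSN", ("SN", "SSM"): "SN-SSM"}


def classify_strength(r: float) -> str:
    """Cohen strength band of a correlation coefficient magnitude.

    small: |r| < 0.3, moderate: 0.3 <= |r| < 0.5, strong: |r| >= 0.5.
    """
    a = abs(r)
    if not a <= 1.0 + 1e-12:  # also rejects NaN
        raise ValueError(f"|r| must not exceed 1, got {r}")
    if a < 0.3:
        return "small"
    if a < 0.5:
        return "moderate"
    return "strong"


def _shapiro_p(x: np.ndarray) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.shapiro(x).pvalue)


def choose_method(x, y, alpha: float = 0.05) -> tuple[str, float, float]:
    """Pick pearson vs spearman from Shapiro-Wilk normality of both vectors.

    Returns ``(method, p_x, p_y)``.  Pearson is chosen only when both
    normality p-values exceed ``alpha``.  Constant vectors (Shapiro-Wilk
    undefined) fall back to spearman with a warning and NaN normality p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4 or y.size < 4:
        raise ValueError("normality gating needs n >= 4 per vector")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(
            "constant vector: Shapiro-Wilk undefined, falling back to spearman",
            stacklevel=2,
        )
        px = float("nan") if np.ptp(x) == 0 else _shapiro_p(x)
        py = float("nan") if np.ptp(y) == 0 else _shapiro_p(y)
        return "spearman", px, py
    px, py = _shapiro_p(x), _shapiro_p(y)
    method = "pearson" if (px > alpha and py > alpha) else "spearman"
    return method, px, py


math_nan = float("nan")  # sentinel for undefined normality p-values


@dataclass
class CorrelationResult:
    pair: str
    group: str
    method: str
    coefficient: float
    p: float
    strength: str
    sign: str
    normality_p_x: float
    normality_p_y: float
    n: int

    def as_row(self) -> dict:
        return {
            "group": self.group,
            "pair": self.pair,
            "method": self.method,
            "coefficient": self.coefficient,
            "p": self.p,
            "strength": self.strength,
            "sign": self.sign,
            "normality_p_x": self.normality_p_x,
            "normality_p_y": self.normality_p_y,
            "n": self.n,
        }


def correlate_pair(
    x,
    y,
    method: str,
    pair: str = "",
    group: str = "",
    normality_p: tuple[float, float] = (math_nan, math_nan),
) -> CorrelationResult:
    """Correlate two equal-length vectors with the given method.

    Two-sided p-value; Spearman uses mid-ranks for ties.  Zero-variance
    input with Pearson is an error (the coefficient is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("correlation needs n >= 4")
    if method == "pearson":
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError("pearson correlation undefined for zero-variance input")
        res = sps.pearsonr(x, y)
    elif method == "spearman":
        res = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    coef = float(res.statistic)
    return CorrelationResult(
        pair=pair,
        group=group,
        method=method,
        coefficient=coef,
        p=float(res.pvalue),
        strength=classify_strength(coef) if np.isfinite(coef) else "undefined",
        sign="+" if coef >= 0 else "-",
        normality_p_x=normality_p[0],
        normality_p_y=normality_p[1],
        n=int(x.size),
    )


@dataclass
class MWResult:
    U: float
    z: float
    p: float
    mean_rank_1: float
    mean_rank_2: float
    n1: int
    n2: int
    exact: bool = False


def _min_u_and_ranks(a: np.ndarray, b: np.ndarray):
    n1, n2 = a.size, b.size
    ranks = sps.rankdata(np.concatenate([a, b]))
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    return min(u1, u2), ranks, r1


def mann_whitney(a, b, exact: bool | None = None) -> MWResult:
    """Mann-Whitney U with mid-ranks, tie-corrected z and two-sided p.

    ``U`` is the smaller of the two rank-sum statistics.  The p-value comes
    from the tie-corrected normal approximation; with ``exact=True`` (or by
    default when n1 + n2 <= 12) it is the exact permutation probability of
    observing a min-U at least as small, over all group assignments.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    u, ranks, r1 = _min_u_and_ranks(a, b)
    n = n1 + n2
    mean_rank_1 = r1 / n1
    mean_rank_2 = float(ranks[n1:].sum()) / n2
    mu_u = n1 * n2 / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        z, p = 0.0, 1.0
    else:
        z = (u - mu_u) / np.sqrt(var_u)
        p = float(2.0 * sps.norm.sf(abs(z)))
    use_exact = exact if exact is not None else (n <= 12)
    if use_exact:
        pooled = np.concatenate([a, b])
        pooled_ranks = sps.rankdata(pooled)
        count = 0
        total = 0
        for idx in itertools.combinations(range(n), n1):
            total += 1
            r = float(pooled_ranks[list(idx)].sum())
            u1 = r - n1 * (n1 + 1) / 2.0
            if min(u1, n1 * n2 - u1) <= u + 1e-9:
                count += 1
        p = count / total
    return MWResult(
        U=float(u), z=float(z), p=min(float(p), 1.0),
        mean_rank_1=mean_rank_1, mean_rank_2=mean_rank_2,
        n1=int(n1), n2=int(n2), exact=bool(use_exact),
    )


def outlier_report(x, z_cut: float = 3.0) -> np.ndarray:
    """Indices of |z-score| > z_cut values.  Reported, never removed."""
    x = np.asarray(x, dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        return np.array([], dtype=int)
    z = (x - x.mean()) / x.std(ddof=1)
    return np.nonzero(np.abs(z) > z_cut)[0]


def run_correlation_battery(
    records: pd.DataFrame,
    groups: dict[str, str],
    unit: str = "participant",
    alpha: float = 0.05,
) -> list[CorrelationResult]:
    """Correlate the three eye-hand metric pairs within each group.

    ``unit`` selects the correlation unit: ``"participant"`` (each point is
    one participant's mean over tasks, the small-n design) or ``"task"``
    (each point is one participant-task).  Rows with a missing value in a
    pair are dropped pairwise.
    """
    if unit == "participant":
        data = participant_means(records)
    elif unit == "task":
        data = records
    else:
        raise ValueError(f"unknown correlation unit {unit!r}")
    data = data.copy()
    data["group"] = data["participant"].map(groups)
    results = []
    for group in sorted(data["group"].dropna().unique()):
        sub = data[data["group"] == group]
        for mx, my in METRIC_PAIRS:
            pair = sub[[mx, my]].dropna()
            if len(pair) < 4:
                raise ValueError(
                    f"group {group!r} pair {mx}-{my}: need >= 4 units, got {len(pair)}"
                )
            x, y = pair[mx].to_numpy(), pair[my].to_numpy()
            method, px, py = choose_method(x, y, alpha=alpha)
            results.append(
                correlate_pair(
                    x, y, method,
                    pair=PAIR_LABELS[(mx, my)], group=group, normality_p=(px, py),
                )
            )
    return results
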