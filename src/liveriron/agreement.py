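"""Method-agreement statistics.

Ordinary least-squares regression, Bland-Altman limits of agreement,
Lin's concordance correlation coefficient, contingency tables, overall
percent agreement and unweighted (identity-weight) Cohen's kappa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "ContingencyTable",
    "AgreementResult",
    "BlandAltman",
    "linear_regression",
    "bland_altman",
    "lin_ccc",
    "rate_ccc",
    "build_contingency",
    "overall_agreement",
    "cohens_kappa",
    "round_half_up",
]


def round_half_up(value: float, ndigits: int) -> float:
    """Round with ties away from zero, as tables are conventionally printed."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable:
    """Square cross-classification counts; rows index method A, columns method B."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if counts.shape[0] != len(self.labels):
            raise ValueError("labels must match the matrix size")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        if counts.sum() <= 0:
            raise ValueError("table total must be positive")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.counts.T.copy(), self.labels)


@dataclass(frozen=True)
class AgreementResult:
    statistic_name: str
    value: float
    se: float | None = None
    ci: tuple[float, float] | None = None
    n: int = 0
    extra: dict = field(default_factory=dict)


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


def linear_regression(x, y) -> tuple[float, float, float]:
    """OLS fit y = slope*x + intercept; returns (slope, intercept, r_squared)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D vectors, n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x must not be constant")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    sxy = float(xc @ yc)
    syy = float(yc @ yc)
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    r_squared = 0.0 if syy == 0 else sxy * sxy / (sxx * syy)
    return slope, intercept, r_squared


def bland_altman(x, y) -> BlandAltman:
    """Differences y - x; SD with n-1 denominator; limits at +/- 1.96 SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D vectors, n >= 2")
    d = y - x
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(mean_diff=mean, sd_diff=sd,
                       loa_low=mean - 1.96 * sd, loa_high=mean + 1.96 * sd,
                       n=x.size)


def lin_ccc(x, y, alpha: float = 0.05) -> AgreementResult:
    """Lin's concordance correlation coefficient with Fisher-z CI.

    CCC = 2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2) using n-denominator
    moments; the confidence interval is computed on the z-transformed scale
    with Lin's asymptotic variance.
    """
    from scipy.stats import norm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D vectors, n >= 3")
    n = x.size
    mx, my = x.mean(), y.mean()
    sx2 = float(np.mean((x - mx) ** 2))
    sy2 = float(np.mean((y - my) ** 2))
    sxy = float(np.mean((x - mx) * (y - my)))
    denom = sx2 + sy2 + (mx - my) ** 2
    ccc = 2.0 * sxy / denom

    ci = None
    se = None
    r = sxy / np.sqrt(sx2 * sy2) if sx2 > 0 and sy2 > 0 else np.nan
    if np.isfinite(r) and abs(r) > 0 and abs(ccc) < 1:
        u = (mx - my) / (sx2 * sy2) ** 0.25
        c2 = ccc * ccc
        var_z = ((1 - r * r) * c2 / ((1 - c2) * r * r)
                 + 4 * ccc ** 3 * (1 - ccc) * u * u / (r * (1 - c2) ** 2)
                 - 2 * ccc ** 4 * u ** 4 / (r * r * (1 - c2) ** 2)) / (n - 2)
        if var_z > 0:
            se_z = float(np.sqrt(var_z))
            z = np.arctanh(ccc)
            zcrit = float(norm.ppf(1 - alpha / 2))
            ci = (float(np.tanh(z - zcrit * se_z)),
                  float(np.tanh(z + zcrit * se_z)))
            se = se_z
    return AgreementResult(statistic_name="lin_ccc", value=float(ccc),
                           se=se, ci=ci, n=n,
                           extra={"pearson_r": float(r),
                                  "rating": rate_ccc(float(ccc))})


def rate_ccc(value: float) -> str:
    """Qualitative agreement rating for a concordance coefficient."""
    if value < 0.9:
        return "poor"
    if value < 0.95:
        return "moderate"
    if value <= 0.99:
        return "substantial"
    return "almost perfect"


def build_contingency(class_a, class_b, labels) -> ContingencyTable:
    """Cross-tabulate two equal-length label vectors over an ordered label set."""
    class_a = list(class_a)
    class_b = list(class_b)
    if len(class_a) != len(class_b):
        raise ValueError("class vectors must have equal length")
    labels = tuple(str(x) for x in labels)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for a, b in zip(class_a, class_b):
        try:
            counts[index[str(a)], index[str(b)]] += 1
        except KeyError as err:
            raise ValueError(f"label {err.args[0]!r} not in label set") from None
    return ContingencyTable(counts, labels)


def overall_agreement(table: ContingencyTable) -> float:
    """100 * trace / total (percent of exactly agreeing cases)."""
    return 100.0 * float(np.trace(table.counts)) / table.n


def cohens_kappa(table: ContingencyTable,
                 weighting: str = "identity") -> AgreementResult:
    """Cohen's kappa with identity (unweighted) agreement weights.

    kappa = (p_o - p_e) / (1 - p_e), with p_e from the marginal products.
    The standard error uses the simple asymptotic formula
    sqrt(p_o (1 - p_o) / (n (1 - p_e)^2)).  Degenerate marginals
    (p_e = 1) yield a NaN value flagged in ``extra``.
    """
    if weighting != "identity":
        raise ValueError("only identity (unweighted) kappa is supported")
    counts = table.counts.astype(float)
    n = table.n
    p = counts / n
    p_o = float(np.trace(p))
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_e = float(row @ col)
    if abs(1.0 - p_e) < 1e-15:
        return AgreementResult(statistic_name="cohens_kappa",
                               value=float("nan"), se=None, n=n,
                               extra={"undefined": True, "p_o": p_o, "p_e": p_e})
    kappa = (p_o - p_e) / (1.0 - p_e)
    se = float(np.sqrt(max(p_o * (1.0 - p_o), 0.0) / (n * (1.0 - p_e) ** 2)))
    return AgreementResult(statistic_name="cohens_kappa", value=float(kappa),
                           se=se, n=n, extra={"p_o": p_o, "p_e": p_e})
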