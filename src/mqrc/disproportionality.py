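"""Disproportionality analysis by Reporting Odds Ratio (ROR).

For a medicine (or stratum) of interest and a complaint category of
interest, the complaint cohort is cross-classified into the 2×2 table

====================  =================  =================
\\                     category           other categories
====================  =================  =================
medicine of interest  a                  b
other medicines       c                  d
====================  =================  =================

and the reporting odds ratio is ``ROR = ad / bc``: the odds that a report
of the medicine of interest falls in the category, relative to the same
odds among all other medicines. ROR > 1 means the category is reported
disproportionately often for that medicine.

The 95% confidence interval is the Wald interval on the log scale,
``exp(ln ROR ± z·sqrt(1/a + 1/b + 1/c + 1/d))``, defined only when all
four cells are positive. Significance uses the Pearson chi-square test on
the 2×2 table without continuity correction (df = 1). A stratum×category
pair is flagged as a suspected poor-quality medicine *signal* when
ROR ≥ 2.0 and p < 0.05.

Zero cells follow single-sided conventions: ``bc = 0`` with ``ad > 0``
yields ROR = ∞ (the category is reported *only* for the medicine of
interest), ``ad = 0`` with ``bc > 0`` yields ROR = 0; both products zero is
degenerate and raises. A Haldane–Anscombe +0.5 continuity correction is
available but off by default.
"""
from __future__ import annotations

import dataclasses
import enum
import math
from typing import Callable, Iterable, Optional

from scipy import stats

from .classify import ClassifiedRecord
from .model import IcsrRecord, MqrcCategory

#: 97.5% standard-normal quantile used for the two-sided 95% Wald CI.
Z_95 = 1.959964

#: Signal rule defaults: ROR at or above this with p below alpha.
ROR_SIGNAL_THRESHOLD = 2.0
SIGNAL_ALPHA = 0.05


class DegenerateTableError(ValueError):
    """Both ad and bc are zero (or a margin is zero): no ROR/p is defined."""


class ZeroCell(enum.Enum):
    NONE = "none"
    NUMERATOR_ZERO = "numerator_zero"
    DENOMINATOR_ZERO = "denominator_zero"


@dataclasses.dataclass(frozen=True)
class ContingencyTable:
    """2×2 counts (a, b, c, d) for one stratum × category pair."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def transposed(self) -> "ContingencyTable":
        return ContingencyTable(self.a, self.c, self.b, self.d)

    def swapped_categories(self) -> "ContingencyTable":
        return ContingencyTable(self.b, self.a, self.d, self.c)


@dataclasses.dataclass
class DisproportionalityResult:
    """ROR, Wald CI, chi-square p and signal flag for one 2×2 table."""

    table: ContingencyTable
    ror: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    se_log_ror: Optional[float] = None
    chi2: Optional[float] = None
    p_value: Optional[float] = None
    p_bucket: Optional[str] = None
    zero_cell: ZeroCell = ZeroCell.NONE
    is_signal: Optional[bool] = None


def build_contingency(
    cohort: Iterable[ClassifiedRecord],
    selector: Callable[[IcsrRecord], bool],
    category: MqrcCategory,
) -> ContingencyTable:
    """Cross-classify a classified cohort into the 2×2 table.

    ``selector`` is a total predicate over the underlying ICSR records
    identifying the medicine/stratum of interest.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    a = b = c = d = 0
    for cr in cohort:
        sel = bool(selector(cr.record))
        cat = cr.category is category
        if sel and cat:
            a += 1
        elif sel:
            b += 1
        elif cat:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def compute_ror(
    t: ContingencyTable,
    z: float = Z_95,
    continuity: bool = False,
) -> DisproportionalityResult:
    """ROR with Wald 95% CI (CI only when all cells are positive).

    ``continuity=True`` applies the Haldane–Anscombe +0.5 correction to
    every cell before computing ROR and CI; the default reproduces the
    uncorrected ``ad/bc`` form.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if continuity:
        af, bf, cf, df = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        ror = (af * df) / (bf * cf)
        se = math.sqrt(1 / af + 1 / bf + 1 / cf + 1 / df)
        return DisproportionalityResult(
            table=t,
            ror=ror,
            se_log_ror=se,
            ci_low=math.exp(math.log(ror) - z * se),
            ci_high=math.exp(math.log(ror) + z * se),
        )
    ad, bc = a * d, b * c
    if ad == 0 and bc == 0:
        raise DegenerateTableError(f"both ad and bc are zero in {t}")
    if bc == 0:
        return DisproportionalityResult(
            table=t, ror=math.inf, zero_cell=ZeroCell.DENOMINATOR_ZERO
        )
    if ad == 0:
        return DisproportionalityResult(
            table=t, ror=0.0, zero_cell=ZeroCell.NUMERATOR_ZERO
        )
    ror = ad / bc
    result = DisproportionalityResult(table=t, ror=ror)
    if min(a, b, c, d) > 0:
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        result.se_log_ror = se
        result.ci_low = math.exp(math.log(ror) - z * se)
        result.ci_high = math.exp(math.log(ror) + z * se)
    return result


def chi_square_p(t: ContingencyTable) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction, df=1) and its p-value.

    Requires all four margins positive; equivalently
    ``chi2 = N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))``.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a + b, c + d, a + c, b + d) == 0:
        raise DegenerateTableError(f"zero margin in {t}")
    chi2, p, _, _ = stats.chi2_contingency([[a, b], [c, d]], correction=False)
    return float(chi2), float(p)


#: Upper bucket edges of the printed p-value ranges, ascending.
_P_EDGES = (0.001, 0.002, 0.005, 0.01, 0.02, 0.025, 0.05, 0.1, 0.2, 0.975, 0.995)


def p_to_bucket(p: float) -> str:
    """Map a p-value onto the printed interval labels.

    Labels run from ``"<0.001"`` through ``"0.002-0.001"`` ... ``">0.995"``;
    each interval is half-open and includes its smaller-p boundary
    (e.g. ``"0.05-0.025"`` covers 0.025 ≤ p < 0.05).
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value {p!r} outside [0, 1]")
    if p < _P_EDGES[0]:
        return "<0.001"
    for lo, hi in zip(_P_EDGES, _P_EDGES[1:]):
        if lo <= p < hi:
            return f"{hi:g}-{lo:g}"
    return ">0.995"


def flag_signal(
    r: DisproportionalityResult,
    ror_threshold: float = ROR_SIGNAL_THRESHOLD,
    alpha: float = SIGNAL_ALPHA,
) -> bool:
    """Signal rule: ROR at/above threshold (∞ counts) and p below alpha."""
    if r.p_value is None:
        raise ValueError("p-value not computed; run chi_square_p first")
    above = r.ror >= ror_threshold or r.zero_cell is ZeroCell.DENOMINATOR_ZERO
    return bool(above and r.p_value < alpha)


def analyze_table(
    t: ContingencyTable,
    z: float = Z_95,
    ror_threshold: float = ROR_SIGNAL_THRESHOLD,
    alpha: float = SIGNAL_ALPHA,
    continuity: bool = False,
) -> DisproportionalityResult:
    """Full per-table analysis: ROR, CI, chi-square p, bucket, signal flag."""
    result = compute_ror(t, z=z, continuity=continuity)
    result.chi2, result.p_value = chi_square_p(t)
    result.p_bucket = p_to_bucket(result.p_value)
    result.is_signal = flag_signal(result, ror_threshold, alpha)
    return result
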