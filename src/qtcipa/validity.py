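"""Content-validity statistics over a raters × items Likert matrix.

An expert panel rates each item (here: each decision statement of the
algorithm) on a 4-point scale; ratings of 3 or 4 count as agreement that
the item is relevant/valid.  Four statistics summarise the panel:

* **I-CVI** — item-level content validity index, A/N where N is the
  number of raters scoring the item and A the number scoring 3 or 4.
  Items with I-CVI below a cutoff (default 0.78) are rejected.
* **Ave-CVI** — the mean of the item I-CVIs; 0.9 or above is read as
  excellent content validity.
* **PC** — the probability of chance agreement, the binomial(N, 1/2)
  mass at A: ``C(N, A) · 0.5^N``.  Evaluated with exact integer
  binomial coefficients (arbitrary-precision), never floating
  factorials, which lose precision long before they overflow.
* **κ\\*** — modified kappa, ``(I-CVI − PC) / (1 − PC)``, the I-CVI
  corrected for chance agreement, with the conventional interpretation
  bands (slight/fair/moderate/substantial/almost perfect).

For panels of 20+ raters and well-rated items PC is tiny, so κ* is
numerically almost identical to I-CVI — which is why a study's reported
I-CVI and κ* ranges typically coincide.

Missing ratings are allowed: each item's N is its own non-missing count,
so a rater skipping an item shrinks that item's denominator only.

Statistics are computed at full precision; reporting rounds to two
decimals, half away from zero.
"""

from __future__ import annotations

import csv
import math
from enum import Enum
from fractions import Fraction
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field

__all__ = [
    "MISSING",
    "ItemVerdict",
    "RatingMatrix",
    "ItemValiditySummary",
    "ValidityReport",
    "item_cvi",
    "chance_agreement_pc",
    "modified_kappa",
    "interpret_kappa",
    "classify_item",
    "validate_survey",
    "read_rating_csv",
    "write_rating_csv",
    "round2",
]

#: Sentinel for a missing rating (stored as NaN internally).
MISSING = None

_LIKERT = frozenset({1, 2, 3, 4})

DEFAULT_CUTOFF = 0.78
EXCELLENT_AVE_CVI = 0.9


class ItemVerdict(str, Enum):
    RETAIN = "RETAIN"
    REJECT = "REJECT"


def round2(x: float) -> float:
    """Round to two decimals, half away from zero (matches 2-dp reporting)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


class RatingMatrix:
    """Raters × items matrix of 1–4 Likert ratings with missing cells.

    Stored as a float array with NaN for missing; labels are preserved
    in order.  ``attribute`` names what the panel rated (e.g.
    appropriateness, safety, reliability); the statistics themselves are
    attribute-agnostic.
    """

    def __init__(
        self,
        ratings: np.ndarray,
        raters: Sequence[str],
        items: Sequence[str],
        attribute: str = "appropriateness",
    ):
        ratings = np.asarray(ratings, dtype=float)
        if ratings.ndim != 2:
            raise ValueError("ratings must be a 2-D raters × items array")
        if ratings.shape != (len(raters), len(items)):
            raise ValueError("ratings shape must match rater and item label counts")
        if len(set(raters)) != len(raters):
            raise ValueError("duplicate rater label")
        if len(set(items)) != len(items):
            raise ValueError("duplicate item label")
        present = ~np.isnan(ratings)
        vals = ratings[present]
        if not np.all(np.isin(vals, list(_LIKERT))):
            bad = vals[~np.isin(vals, list(_LIKERT))]
            raise ValueError(f"ratings must be in {{1,2,3,4}}; found {bad[:5]}")
        if not present.any(axis=0).all():
            empty = [items[j] for j in np.where(~present.any(axis=0))[0]]
            raise ValueError(f"item(s) with no ratings at all: {empty}")
        self.ratings = ratings
        self.raters = list(raters)
        self.items = list(items)
        self.attribute = attribute

    @property
    def shape(self) -> tuple[int, int]:
        return self.ratings.shape

    def item_ratings(self, item: str) -> list[Optional[int]]:
        j = self.items.index(item)
        col = self.ratings[:, j]
        return [None if math.isnan(v) else int(v) for v in col]

    def __eq__(self, other) -> bool:
        if not isinstance(other, RatingMatrix):
            return NotImplemented
        return (
            self.raters == other.raters
            and self.items == other.items
            and self.attribute == other.attribute
            and np.array_equal(self.ratings, other.ratings, equal_nan=True)
        )


class ItemValiditySummary(BaseModel):
    item: str
    n_raters: int = Field(ge=1)
    n_agree: int = Field(ge=0)
    i_cvi: float = Field(ge=0, le=1)
    pc: float = Field(ge=0, le=1)
    kappa_star: float = Field(le=1)
    mean_rating: float = Field(ge=1, le=4)
    verdict: ItemVerdict
    agreement_band: str


class ValidityReport(BaseModel):
    items: tuple[ItemValiditySummary, ...]
    ave_cvi: float = Field(ge=0, le=1)
    cutoff: float = DEFAULT_CUTOFF
    excellent_flag: bool
    attribute: str = "appropriateness"


def item_cvi(ratings: Iterable[Optional[int]]) -> tuple[int, int, float]:
    """(N, A, I-CVI) for one item's ratings; missing entries are skipped.

    N is the non-missing count, A the count of ratings of 3 or 4, and
    I-CVI = A/N as an exact ratio (rounding happens only at reporting).
    """
    present = [r for r in ratings if r is not None and not (
        isinstance(r, float) and math.isnan(r))]
    if not present:
        raise ValueError("item has no ratings")
    for r in present:
        if int(r) != r or int(r) not in _LIKERT:
            raise ValueError(f"rating outside the 1-4 scale: {r!r}")
    n = len(present)
    a = sum(1 for r in present if r >= 3)
    return n, a, a / n


def chance_agreement_pc(n: int, a: int) -> float:
    """Probability of chance agreement: binomial(N, 1/2) mass at A.

    Exact integer arithmetic (``math.comb`` over 2**N as a Fraction)
    so the result is correctly rounded for any panel size.
    """
    if n < 1:
        raise ValueError("N must be >= 1")
    if not 0 <= a <= n:
        raise ValueError(f"A must be in [0, N]; got A={a}, N={n}")
    return float(Fraction(math.comb(n, a), 2**n))


def modified_kappa(i_cvi: float, pc: float) -> float:
    """κ* = (I-CVI − PC) / (1 − PC); equals 1 at unanimous agreement."""
    if not 0 <= pc < 1:
        raise ValueError("PC must be in [0, 1)")
    return (i_cvi - pc) / (1.0 - pc)


_KAPPA_BANDS = (
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


def interpret_kappa(kappa_star: float) -> str:
    """Conventional agreement band for a κ* value.

    Half-open intervals close the gaps in the published touching ranges:
    <0 no agreement; [0, 0.20] slight; (0.20, 0.40] fair; (0.40, 0.60]
    moderate; (0.60, 0.80] substantial; (0.80, 1] almost perfect.
    """
    if kappa_star > 1:
        raise ValueError("kappa* cannot exceed 1")
    if kappa_star < 0:
        return "no agreement"
    for upper, label in _KAPPA_BANDS:
        if kappa_star <= upper:
            return label
    return "almost perfect"  # pragma: no cover


def classify_item(i_cvi: float, cutoff: float = DEFAULT_CUTOFF) -> ItemVerdict:
    """REJECT strictly below the cutoff, RETAIN at or above it."""
    return ItemVerdict.REJECT if i_cvi < cutoff else ItemVerdict.RETAIN


def validate_survey(
    matrix: RatingMatrix, cutoff: float = DEFAULT_CUTOFF
) -> ValidityReport:
    """Per-item validity summaries plus the panel-level Ave-CVI."""
    if not matrix.items:
        raise ValueError("empty rating matrix")
    summaries: list[ItemValiditySummary] = []
    for item in matrix.items:
        ratings = matrix.item_ratings(item)
        n, a, icvi = item_cvi(ratings)
        pc = chance_agreement_pc(n, a)
        kappa = modified_kappa(icvi, pc)
        present = [r for r in ratings if r is not None]
        summaries.append(
            ItemValiditySummary(
                item=item,
                n_raters=n,
                n_agree=a,
                i_cvi=icvi,
                pc=pc,
                kappa_star=kappa,
                mean_rating=sum(present) / n,
                verdict=classify_item(icvi, cutoff),
                agreement_band=interpret_kappa(kappa),
            )
        )
    ave = sum(s.i_cvi for s in summaries) / len(summaries)
    return ValidityReport(
        items=tuple(summaries),
        ave_cvi=ave,
        cutoff=cutoff,
        excellent_flag=ave >= EXCELLENT_AVE_CVI,
        attribute=matrix.attribute,
    )


def read_rating_csv(path: str | Path, attribute: str = "appropriateness") -> RatingMatrix:
    """Read a rating matrix from CSV.

    Layout: header row ``rater,<item labels...>``; one row per rater;
    blank cells are missing.  Values are validated to the 1–4 scale with
    the offending rater and item named on failure.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows or len(rows[0]) < 2:
        raise ValueError(f"{path}: expected a header row with item labels")
    items = [c.strip() for c in rows[0][1:]]
    raters: list[str] = []
    data = np.full((len(rows) - 1, len(items)), np.nan)
    for i, row in enumerate(rows[1:]):
        rater = row[0].strip() if row else ""
        if not rater:
            raise ValueError(f"{path} row {i + 2}: missing rater label")
        if rater in raters:
            raise ValueError(f"{path}: duplicate rater label {rater!r}")
        raters.append(rater)
        for j, cell in enumerate(row[1:]):
            cell = cell.strip()
            if not cell:
                continue
            try:
                val = int(cell)
                if val not in _LIKERT:
                    raise ValueError
            except ValueError:
                raise ValueError(
                    f"{path}: non-Likert value {cell!r} for rater {rater!r}, "
                    f"item {items[j]!r}"
                ) from None
            data[i, j] = val
    return RatingMatrix(data, raters, items, attribute=attribute)


def write_rating_csv(matrix: RatingMatrix, path: str | Path) -> None:
    """Write a rating matrix to CSV (blank cells for missing ratings)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["rater", *matrix.items])
        for i, rater in enumerate(matrix.raters):
            row: list[str] = [rater]
            for v in matrix.ratings[i]:
                row.append("" if math.isnan(v) else str(int(v)))
            writer.writerow(row)
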