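"""Two-alternative choice collation and the preference-strength statistic.

Preference strength (PS, in [0, 1]) measures how far a set of n
two-alternative choices deviates from an equal split:

    PS = (k - e) / (n - e)

where k is the majority count (k >= n - k) and e is the equal-choice point:
n/2 for even n, and for odd n the first possible count above 50 %,
e = (n + 1)/2. Thus 5/10 and 2/3 both give PS = 0, while 10/10 and 3/3 give
PS = 1. The pair (k - e, n - e) — deviation and maximum possible deviation —
is the binomial success/trial response used by downstream models.

Cells with a single choice carry no information about deviation from equal
choice (n - e = 0) and are excluded. Trials scored as no-choice are excluded
from counts but conserved in bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PreferenceCell",
    "CollationResult",
    "preference_strength",
    "equal_choice_point",
    "collate",
    "binomial_response",
    "mean_preference",
    "SCHEMES",
]

SCHEMES = {
    "per_stimulus": ["stimulus_id", "female_origin", "female_treatment"],
    "per_pair": ["rival_pair_id", "male_treatment"],
}
# long-form aliases matching the two collations used in analysis
SCHEMES["per_stimulus_by_female_origin_treatment"] = SCHEMES["per_stimulus"]
SCHEMES["per_rival_pair_by_male_treatment"] = SCHEMES["per_pair"]


class ExcludedCellError(ValueError):
    """Cell has too few choices (n < 2) to carry a preference strength."""


def equal_choice_point(n: int) -> Fraction:
    """Equal-choice count e: n/2 for even n, (n+1)/2 for odd n."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    return Fraction(n, 2) if n % 2 == 0 else Fraction(n + 1, 2)


def preference_strength(n: int, k: int) -> Fraction:
    """Deviation of the majority count from equal choice, scaled to [0, 1].

    ``k`` must be the majority count (k >= n - k). Returns an exact rational;
    use ``float()`` for reporting.
    """
    if n < 2:
        raise ExcludedCellError(f"cells with n={n} choices are excluded (need n >= 2)")
    if k > n or k < n - k:
        raise ValueError(f"k={k} is not a majority count for n={n}")
    e = equal_choice_point(n)
    return Fraction(k - e, n - e)


@dataclass(frozen=True)
class PreferenceCell:
    """A collated (n, k) choice cell with its preference-strength statistic."""

    key: tuple
    n: int
    k: int

    def __post_init__(self) -> None:
        preference_strength(self.n, self.k)  # validates

    @property
    def e(self) -> Fraction:
        return equal_choice_point(self.n)

    @property
    def deviation(self) -> Fraction:
        return self.k - self.e

    @property
    def max_deviation(self) -> Fraction:
        return self.n - self.e

    @property
    def ps(self) -> Fraction:
        return preference_strength(self.n, self.k)


@dataclass(frozen=True)
class CollationResult:
    cells: tuple[PreferenceCell, ...]
    excluded: tuple[tuple, ...]  # keys of n=1 cells
    n_no_choice: int

    def frame(self) -> pd.DataFrame:
        key_cols = [f"key_{i}" for i in range(len(self.cells[0].key))] if self.cells else []
        rows = []
        for c in self.cells:
            row = dict(zip(key_cols, c.key))
            row.update(
                n=c.n, k=c.k, e=float(c.e),
                deviation=float(c.deviation),
                max_deviation=float(c.max_deviation),
                ps=float(c.ps),
            )
            rows.append(row)
        return pd.DataFrame(rows)


def collate(trials: pd.DataFrame, scheme: str = "per_stimulus") -> CollationResult:
    """Group choice trials into preference cells.

    ``trials`` needs a ``chosen`` column in {'A', 'B', 'none'} plus the
    grouping columns of the scheme (see :data:`SCHEMES`). k is the majority
    count max(#A, #B) per group; single-choice groups are listed in
    ``excluded`` rather than turned into cells.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown collation scheme {scheme!r}; valid: {sorted(SCHEMES)}")
    keys = SCHEMES[scheme]
    missing = set(keys + ["chosen"]) - set(trials.columns)
    if missing:
        raise ValueError(f"trials table missing columns {sorted(missing)}")
    bad = set(trials["chosen"].unique()) - {"A", "B", "none"}
    if bad:
        raise ValueError(f"invalid chosen codes {sorted(bad)}")

    n_no_choice = int((trials["chosen"] == "none").sum())
    chosen = trials[trials["chosen"].isin(["A", "B"])]
    cells, excluded = [], []
    for key, grp in chosen.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        n = len(grp)
        if n < 2:
            excluded.append(key)
            continue
        n_a = int((grp["chosen"] == "A").sum())
        cells.append(PreferenceCell(key=key, n=n, k=max(n_a, n - n_a)))
    return CollationResult(
        cells=tuple(cells), excluded=tuple(excluded), n_no_choice=n_no_choice
    )


def binomial_response(cell: PreferenceCell) -> tuple[int, int]:
    """(successes, trials) = (deviation, max deviation), exact integers.

    e is an integer for both parities (n/2 even, (n+1)/2 odd), so deviation
    and maximum deviation are integers and successes/trials equals PS exactly.
    """
    dev, mx = cell.deviation, cell.max_deviation
    if mx == 0:
        raise ExcludedCellError("cell has no possible deviation (n <= 1)")
    return int(dev), int(mx)


def mean_preference(
    cells: Sequence[PreferenceCell], weighting: str = "unweighted"
) -> float:
    """Mean preference strength across cells, unweighted or weighted by n."""
    if not cells:
        raise ValueError("mean preference needs at least one cell")
    ps = np.array([float(c.ps) for c in cells])
    if weighting == "unweighted":
        return float(ps.mean())
    if weighting == "by_n":
        w = np.array([c.n for c in cells], dtype=float)
        return float((ps * w).sum() / w.sum())
    raise ValueError(f"unknown weighting {weighting!r}")
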