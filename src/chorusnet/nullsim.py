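"""Random-choice null distribution of mean preference strength.

Under the null that every female choice is an independent fair coin, the
majority count of an n-choice cell is the folded Binomial(n, 1/2), so each
cell's preference strength has a known discrete distribution, and the mean PS
across the observed cells has a distribution obtained by convolution. The
observed mean PS is compared against the 2.5th/97.5th percentiles of this
null — estimated by Monte-Carlo (1,000 replicates by default) conditioning on
the observed cell sizes, with an exact-enumeration oracle available whenever
the joint support is tractable.

Because each replicate conditions on the same cell sizes, the null interval
is asymmetric with a nonzero lower bound for small cells; simulating choices
at the trial level or at the cell level is equivalent given fixed cell sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from pathlib import Path

import numpy as np

from .preference import preference_strength

__all__ = [
    "NullResult",
    "simulate_null",
    "exact_null",
    "compare_observed",
    "cell_ps_distribution",
]

DEFAULT_N_SIMS = 1000
CI_PERCENTILES = (2.5, 97.5)
EXACT_SUPPORT_LIMIT = 10**6


class OracleUnavailableError(ValueError):
    """Exact enumeration refused: joint support too large."""


@dataclass
class NullDistribution:
    """Reference distribution of mean PS under random choice."""

    cell_sizes: tuple[int, ...]
    weighting: str
    ci_low: float
    ci_high: float
    simulated_means: np.ndarray | None = None
    exact_pmf: dict[Fraction, Fraction] | None = None
    n_sims: int | None = None
    seed: int | None = None

    @property
    def mean(self) -> float:
        if self.exact_pmf is not None:
            return float(sum(v * p for v, p in self.exact_pmf.items()))
        return float(self.simulated_means.mean())


@dataclass
class NullResult:
    """Observed mean PS against its random-choice reference interval."""

    observed_mean_ps: float
    ci_low: float
    ci_high: float
    exceeds_null: bool
    cell_sizes: tuple[int, ...]
    weighting: str
    n_sims: int | None = None
    seed: int | None = None
    exact_tail_prob: float | None = None  # P(null mean PS >= observed)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "observed_mean_ps": self.observed_mean_ps,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "exceeds_null": self.exceeds_null,
            "cell_sizes": list(self.cell_sizes),
            "weighting": self.weighting,
            "n_sims": self.n_sims,
            "seed": self.seed,
            "exact_tail_prob": self.exact_tail_prob,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _validate_cells(cell_sizes) -> tuple[int, ...]:
    sizes = tuple(int(n) for n in cell_sizes)
    if not sizes:
        raise ValueError("need at least one cell")
    if any(n < 2 for n in sizes):
        raise ValueError("all cell sizes must be >= 2 (n=1 cells are excluded upstream)")
    return sizes


def _weights(sizes: tuple[int, ...], weighting: str) -> np.ndarray:
    if weighting == "unweighted":
        return np.full(len(sizes), 1.0 / len(sizes))
    if weighting == "by_n":
        w = np.array(sizes, dtype=float)
        return w / w.sum()
    raise ValueError(f"unknown weighting {weighting!r}")


def simulate_null(
    cell_sizes,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int = 0,
    weighting: str = "unweighted",
) -> NullDistribution:
    """Monte-Carlo null: per replicate, each cell's n choices are fair coins.

    Each replicate draws the per-cell majority count from Binomial(n, 1/2)
    (folded), computes the cell PS, and averages across cells with the given
    weighting. The 95 % interval is the empirical 2.5/97.5 percentile with
    linear interpolation. One seeded generator drives all cells; replicate r,
    cell c is the (r, c) entry of a single vectorized draw, so outputs are
    byte-identical under a fixed seed.
    """
    sizes = _validate_cells(cell_sizes)
    w = _weights(sizes, weighting)
    rng = np.random.default_rng(seed)
    means = np.zeros(n_sims)
    for c, n in enumerate(sizes):
        heads = rng.binomial(n, 0.5, size=n_sims)
        k = np.maximum(heads, n - heads)
        e = n / 2 if n % 2 == 0 else (n + 1) / 2
        ps = np.maximum(k - e, 0.0) / (n - e)
        means += w[c] * ps
    lo, hi = np.percentile(means, CI_PERCENTILES)
    return NullDistribution(
        cell_sizes=sizes, weighting=weighting,
        ci_low=float(lo), ci_high=float(hi),
        simulated_means=means, n_sims=n_sims, seed=seed,
    )


def cell_ps_distribution(n: int) -> dict[Fraction, Fraction]:
    """Exact pmf of one cell's PS when its n choices are fair coins."""
    pmf: dict[Fraction, Fraction] = {}
    denom = 2**n
    for heads in range(n + 1):
        k = max(heads, n - heads)  # majority count >= e, so PS >= 0
        ps = preference_strength(n, k)
        pmf[ps] = pmf.get(ps, Fraction(0)) + Fraction(comb(n, heads), denom)
    return pmf


def exact_null(
    cell_sizes, weighting: str = "unweighted", support_limit: int = EXACT_SUPPORT_LIMIT
) -> NullDistribution:
    """Exact distribution of the mean PS by per-cell enumeration + convolution.

    Raises :class:`OracleUnavailableError` when the running support size
    would exceed ``support_limit`` (fall back to Monte-Carlo).
    """
    sizes = _validate_cells(cell_sizes)
    _weights(sizes, weighting)  # validates the weighting name
    if weighting == "unweighted":
        w = [Fraction(1, len(sizes))] * len(sizes)
    else:
        total = sum(sizes)
        w = [Fraction(n, total) for n in sizes]

    dist: dict[Fraction, Fraction] = {Fraction(0): Fraction(1)}
    for c, n in enumerate(sizes):
        cell = cell_ps_distribution(n)
        new: dict[Fraction, Fraction] = {}
        for v, p in dist.items():
            for ps, q in cell.items():
                key = v + w[c] * ps
                new[key] = new.get(key, Fraction(0)) + p * q
        dist = new
        if len(dist) > support_limit:
            raise OracleUnavailableError(
                f"exact null support exceeds {support_limit} points"
            )
    lo = _exact_quantile(dist, Fraction(str(CI_PERCENTILES[0])) / 100)
    hi = _exact_quantile(dist, Fraction(str(CI_PERCENTILES[1])) / 100)
    return NullDistribution(
        cell_sizes=sizes, weighting=weighting,
        ci_low=float(lo), ci_high=float(hi), exact_pmf=dist,
    )


def _exact_quantile(pmf: dict[Fraction, Fraction], q: Fraction) -> Fraction:
    """Lower quantile of a discrete pmf: smallest v with P(X <= v) >= q."""
    acc = Fraction(0)
    for v in sorted(pmf):
        acc += pmf[v]
        if acc >= q:
            return v
    return max(pmf)


def compare_observed(
    observed_mean_ps: float,
    null: NullDistribution,
    cell_sizes=None,
    weighting: str | None = None,
) -> NullResult:
    """Compare an observed mean PS against a null distribution.

    When ``cell_sizes``/``weighting`` are passed they must match those the
    null was computed on. ``exceeds_null`` is a strict comparison against the
    upper interval bound; the exact upper-tail probability
    P(null mean >= observed) is reported when the null is exact.
    """
    if cell_sizes is not None and tuple(int(n) for n in cell_sizes) != null.cell_sizes:
        raise ValueError("cell sizes do not match the null distribution")
    if weighting is not None and weighting != null.weighting:
        raise ValueError("weighting does not match the null distribution")
    tail = None
    if null.exact_pmf is not None:
        tail = float(
            sum(p for v, p in null.exact_pmf.items() if float(v) >= observed_mean_ps)
        )
    return NullResult(
        observed_mean_ps=float(observed_mean_ps),
        ci_low=null.ci_low,
        ci_high=null.ci_high,
        exceeds_null=bool(observed_mean_ps > null.ci_high),
        cell_sizes=null.cell_sizes,
        weighting=null.weighting,
        n_sims=null.n_sims,
        seed=null.seed,
        exact_tail_prob=tail,
    )
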