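"""Citation-frequency validation for ultra-flash profiling descriptors.

A panel of J assessors each cites between 1 and n_max distinct attributes
from a wheel of d selectable attributes for every product. If an assessor
picked a subset uniformly at random, the chance P that a given attribute is
in that subset follows from subset combinatorics:

    TC = sum_{k=1..n_max} C(d, k)          all non-empty subsets of size <= n_max
    C  = sum_{k=1..n_max} C(d-1, k-1)      those containing one fixed attribute
    P  = C / TC

The expected citation count under pure chance is E = P * J. A descriptor is
validated for a product when its observed count is unlikely under
Binomial(J, P): an exact one-sided upper-tail test, preferred over chi-square
because E is small. The classic alternative — keep anything cited at least
three times — is provided for comparison.

With the default 46-attribute wheel and up to five picks, P is about 10.6%,
E rounds to 2 citations for a 15-assessor panel, and significance at the 5%
level requires more than four citations.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from math import comb
from pathlib import Path

import pandas as pd

__all__ = [
    "CitationTable",
    "SelectionModel",
    "selection_probability",
    "expected_frequency",
    "binomial_gof",
    "significance_threshold",
    "classic_selection",
    "gof_table",
]

# Heatmap gradation: darkest bin for the smallest p-values.
HEAT_BINS = (1e-6, 1e-5, 1e-4, 1e-3, 1e-2)


@dataclass(frozen=True)
class CitationTable:
    """Per-assessor, per-product descriptor citations (long form).

    Each record is one assessor citing 1..n_max distinct selectable
    attributes for one product; at most one record per assessor x product.
    """

    records: tuple[tuple[str, str, tuple[str, ...]], ...]  # (assessor, product, descriptors)
    selectable: tuple[str, ...] | None = None
    n_max: int = 5

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        allowed = set(self.selectable) if self.selectable is not None else None
        for assessor, product, descs in self.records:
            if not 1 <= len(descs) <= self.n_max:
                raise ValueError(
                    f"assessor {assessor!r}, product {product!r}: {len(descs)} descriptors "
                    f"cited; must be between 1 and {self.n_max}"
                )
            if len(set(descs)) != len(descs):
                raise ValueError(f"assessor {assessor!r}, product {product!r}: repeated descriptor")
            if allowed is not None:
                bad = [d for d in descs if d not in allowed]
                if bad:
                    raise ValueError(
                        f"assessor {assessor!r}, product {product!r}: not in the wheel's "
                        f"selectable set: {bad}"
                    )
            key = (assessor, product)
            if key in seen:
                raise ValueError(f"duplicate record for assessor {assessor!r}, product {product!r}")
            seen.add(key)

    @property
    def assessors(self) -> tuple[str, ...]:
        return tuple(sorted({a for a, _, _ in self.records}))

    @property
    def products(self) -> tuple[str, ...]:
        return tuple(sorted({p for _, p, _ in self.records}))

    @property
    def J(self) -> int:
        return len(self.assessors)

    def counts(self) -> pd.DataFrame:
        """Observed frequency matrix, products x descriptors."""
        descs = self.selectable or tuple(
            sorted({d for _, _, ds in self.records for d in ds})
        )
        mat = pd.DataFrame(0, index=list(self.products), columns=list(descs))
        for _, product, ds in self.records:
            for d in ds:
                mat.loc[product, d] += 1
        return mat

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (a, p, d) for a, p, ds in self.records for d in ds
        ]
        return pd.DataFrame(rows, columns=["assessor", "product", "descriptor"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        selectable: tuple[str, ...] | None = None,
        n_max: int = 5,
    ) -> "CitationTable":
        records = []
        for (a, p), grp in frame.groupby(["assessor", "product"], sort=True):
            records.append((str(a), str(p), tuple(grp["descriptor"])))
        return cls(tuple(records), selectable=selectable, n_max=n_max)


@dataclass(frozen=True)
class SelectionModel:
    """Chance model for citing one attribute out of d, with <= n_max picks."""

    d: int
    n_max: int
    TC: int
    C: int
    P_exact: Fraction
    J: int
    alpha: float = 0.05

    @property
    def P(self) -> float:
        return float(self.P_exact)

    @property
    def E(self) -> float:
        return self.P * self.J

    @property
    def E_rounded(self) -> int:
        return _round_half_up(self.J * self.P_exact)

    @classmethod
    def build(
        cls, d: int, n_max: int, J: int, alpha: float = 0.05, verbatim_eq8: bool = False
    ) -> "SelectionModel":
        TC, C, P = selection_probability(d, n_max, verbatim_eq8=verbatim_eq8)
        return cls(d=d, n_max=n_max, TC=TC, C=C, P_exact=P, J=J, alpha=alpha)


def _round_half_up(x: float | Fraction) -> int:
    from math import floor

    return floor(Fraction(x) + Fraction(1, 2))


def selection_probability(
    d: int, n_max: int, verbatim_eq8: bool = False
) -> tuple[int, int, Fraction]:
    """Exact (TC, C, P) for citing a fixed attribute from a d-attribute wheel.

    ``verbatim_eq8`` switches the numerator to sum C(d-1, k) for k = 1..n_max
    — the form printed in the source literature — which counts subsets of the
    *other* d-1 attributes rather than subsets containing the fixed one and
    is kept only for audit; the default C(d-1, k-1) form reproduces the
    published checkpoints (P ~ 10%, E = 2, significance above four citations).
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    if not 1 <= n_max <= d:
        raise ValueError("n_max must satisfy 1 <= n_max <= d")
    TC = sum(comb(d, k) for k in range(1, n_max + 1))
    if verbatim_eq8:
        C = sum(comb(d - 1, k) for k in range(1, n_max + 1))
    else:
        C = sum(comb(d - 1, k - 1) for k in range(1, n_max + 1))
    return TC, C, Fraction(C, TC)


def expected_frequency(P: float | Fraction, J: int) -> tuple[float, int]:
    """Expected citation count E = P * J, with its half-up rounding."""
    if not 0 <= float(P) <= 1:
        raise ValueError("P must be a probability")
    if J < 1:
        raise ValueError("J must be >= 1")
    return float(P) * J, _round_half_up(Fraction(P) * J)


def binomial_gof(observed: int, J: int, P: float | Fraction) -> float:
    """Exact upper-tail p-value Pr(X >= observed), X ~ Binomial(J, P).

    Computed by exact rational summation of the pmf — no normal
    approximation, safe for the small expected counts this design produces.
    """
    if not 0 <= observed <= J:
        raise ValueError("observed must be between 0 and J")
    return _tail_table(J, _as_fraction(P))[observed]


def _as_fraction(P: float | Fraction) -> Fraction:
    return P if isinstance(P, Fraction) else Fraction(P).limit_denominator(10**12)


@lru_cache(maxsize=128)
def _tail_table(J: int, p: Fraction) -> tuple[float, ...]:
    """Upper-tail probabilities Pr(X >= k) for k = 0..J by exact summation."""
    q = 1 - p
    pmf = [comb(J, k) * p**k * q ** (J - k) for k in range(J + 1)]
    tails: list[Fraction] = [Fraction(0)] * (J + 1)
    acc = Fraction(0)
    for k in range(J, -1, -1):
        acc += pmf[k]
        tails[k] = acc
    return tuple(float(t) for t in tails)


def significance_threshold(J: int, P: float | Fraction, alpha: float = 0.05) -> int:
    """Smallest count c with Pr(X >= c) < alpha; J+1 if none is attainable."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    for c in range(0, J + 1):
        if binomial_gof(c, J, P) < alpha:
            return c
    return J + 1


def classic_selection(
    table: CitationTable, min_citations: int = 3
) -> set[tuple[str, str]]:
    """(product, descriptor) pairs cited at least ``min_citations`` times."""
    counts = table.counts()
    return {
        (p, d)
        for p in counts.index
        for d in counts.columns
        if counts.loc[p, d] >= min_citations
    }


def gof_table(table: CitationTable, model: SelectionModel) -> pd.DataFrame:
    """Per product x descriptor: observed count, exact p-value, flag, heat bin.

    ``significant`` uses strict p < alpha. ``heat_bin`` indexes the grayscale
    gradation used for p-value heatmaps (0 = darkest, p < 1e-6; 4 = lightest,
    p < 0.01; -1 = not significant at that scale).
    """
    if model.J != table.J:
        raise ValueError(f"model J={model.J} does not match table J={table.J}")
    counts = table.counts()
    rows = []
    for product in counts.index:
        for desc in counts.columns:
            obs = int(counts.loc[product, desc])
            p = binomial_gof(obs, model.J, model.P_exact)
            rows.append(
                {
                    "product": product,
                    "descriptor": desc,
                    "observed": obs,
                    "expected": model.E,
                    "p_value": p,
                    "significant": p < model.alpha,
                    "heat_bin": next(
                        (i for i, edge in enumerate(HEAT_BINS) if p < edge), -1
                    ),
                }
            )
    return pd.DataFrame(rows)
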