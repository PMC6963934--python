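"""Physicochemical quality indices for fruit juices.

Sweetness-related indices from total soluble solids (TSS, %) and titratable
acidity (TA, g malic acid / 100 g):

* TSS/TA ratio — the classic sweetness predictor; apples with a ratio over
  20 taste sweet, under 20 sour.
* BrimA = TSS − k·TA ("Brix minus acidity", k = 10 for apples) — subtracts
  rather than divides, so small acidity changes move the index as much as
  comparable sugar changes, matching the tongue's higher acid sensitivity.

Plus gravimetric dry matter and the CIELAB-derived color indices chroma
(C* = sqrt(a*^2 + b*^2), saturation) and hue angle (h*, degrees in
[0, 360), quadrant-aware). Rankings use competition ("minimum rank") ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "JuiceSample",
    "brima",
    "ratio_and_class",
    "dm_percent",
    "chroma",
    "hue_angle",
    "rank_samples",
    "index_table",
]


@dataclass(frozen=True)
class JuiceSample:
    """One juice's measurements; weights and color are optional."""

    name: str
    tss: float  # percent
    ta: float   # g malic acid / 100 g
    weights: tuple[float, float, float] | None = None  # (dish A, dish+fresh B, dish+dry C), g
    lab: tuple[float, float, float] | None = None      # (L*, a*, b*)

    def __post_init__(self) -> None:
        if self.tss < 0 or self.ta < 0:
            raise ValueError(f"{self.name}: TSS and TA must be non-negative")
        if self.weights is not None:
            a, b, c = self.weights
            if not b > a:
                raise ValueError(f"{self.name}: fresh weight B must exceed dish weight A")
            if not a <= c <= b:
                raise ValueError(f"{self.name}: dry weight C must lie between A and B")


def brima(tss: float, ta: float, k: float = 10.0) -> float:
    """BrimA index TSS − k·TA; negative values are legal (no clamping)."""
    if k <= 0:
        raise ValueError("k must be positive")
    if tss < 0 or ta < 0:
        raise ValueError("TSS and TA must be non-negative")
    return tss - k * ta


def ratio_and_class(tss: float, ta: float, threshold: float = 20.0) -> tuple[float, str]:
    """TSS/TA ratio with its sweet/sour class.

    Sweet iff the ratio strictly exceeds the threshold; a ratio exactly at
    the threshold is classed sour (the sweet rule is strict "over").
    """
    if ta <= 0:
        raise ValueError("TA must be positive; the ratio is undefined at TA = 0")
    ratio = tss / ta
    return ratio, ("sweet" if ratio > threshold else "sour")


def dm_percent(A: float, B: float, C: float) -> float:
    """Gravimetric dry matter: 100·(C−A)/(B−A) with dish A, fresh B, dry C."""
    if B <= A:
        raise ValueError("fresh weight B must exceed dish weight A")
    if not A <= C <= B:
        raise ValueError("dry weight C must lie between A and B")
    return 100.0 * (C - A) / (B - A)


def chroma(a: float, b: float) -> float:
    """CIELAB chroma C* = sqrt(a*^2 + b*^2)."""
    return math.hypot(a, b)


def hue_angle(a: float, b: float) -> float:
    """CIELAB hue angle in degrees, quadrant-aware, in [0, 360).

    The textbook one-argument arctan(b*/a*) is ambiguous for a* < 0; the
    two-argument form resolves the quadrant. Undefined at the achromatic
    point a* = b* = 0.
    """
    if a == 0 and b == 0:
        raise ValueError("hue angle is undefined at a* = b* = 0 (achromatic)")
    return math.degrees(math.atan2(b, a)) % 360.0


def rank_samples(values: pd.Series | dict[str, float]) -> pd.Series:
    """Descending competition ranks: 1 = largest; ties share the smaller rank."""
    s = pd.Series(values, dtype=float)
    if s.empty:
        raise ValueError("need at least one sample to rank")
    return s.rank(method="min", ascending=False).astype(int)


def index_table(samples: list[JuiceSample], k: float = 10.0, threshold: float = 20.0) -> pd.DataFrame:
    """Full quality-index table with descending ranks for ratio and BrimA.

    Mirrors the classic two-index presentation (value + rank per index) and
    appends dry matter and color indices where the measurements exist.
    """
    rows = {}
    for s in samples:
        ratio, cls = ratio_and_class(s.tss, s.ta, threshold)
        row = {
            "tss": s.tss,
            "ta": s.ta,
            "ratio_tss_ta": ratio,
            "brima": brima(s.tss, s.ta, k),
            "sweet_sour_class": cls,
            "dm_pct": dm_percent(*s.weights) if s.weights else np.nan,
        }
        if s.lab is not None:
            L, a, b = s.lab
            row["L_star"] = L
            row["chroma"] = chroma(a, b)
            row["hue_deg"] = hue_angle(a, b) if not (a == 0 and b == 0) else np.nan
        rows[s.name] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.insert(3, "rank_by_ratio", rank_samples(table["ratio_tss_ta"]))
    table["rank_by_brima"] = rank_samples(table["brima"])
    cols = list(table.columns)
    cols.insert(cols.index("sweet_sour_class"), cols.pop(cols.index("rank_by_brima")))
    return table[cols].rename_axis("sample")
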