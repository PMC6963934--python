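"""Synthetic panels, corpora and citation tables with known ground truth.

Every analysis stage in this package was designed against data that cannot
be redistributed (a literature corpus, raw panel sheets). This module
generates inputs with the statistical structure those analyses assume, so
each stage is testable end-to-end with a planted truth:

* corpora with per-term occurrence rates and deterministically co-occurring
  term pairs (which the correlation-fusion step must link);
* projective-mapping sheets as a similarity transform (optional rotation /
  reflection, scale in [0.8, 1.2]) of a true 2-D product configuration plus
  iid Gaussian placement noise, clipped to the physical sheet;
* citation tables drawn from per-product descriptor-propensity rows over a
  wheel's selectable set, with the citation count K per record drawn from a
  distribution on {1..5} (uniform by default — the protocol fixes only the
  range).

All generators are seeded and byte-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .lexicon import Corpus
from .mfa import SHEET_HEIGHT_CM, SHEET_WIDTH_CM, MappingSheet
from .stats import CitationTable
from .wheel import SensoryWheel

__all__ = ["PanelScenario", "gen_corpus", "gen_mapping", "gen_citations", "default_true_config"]


def default_true_config(n_products: int) -> np.ndarray:
    """A well-spread true configuration: products on an ellipse inside the sheet."""
    theta = 2 * np.pi * np.arange(n_products) / n_products
    x = SHEET_WIDTH_CM / 2 + (SHEET_WIDTH_CM / 2 - 10) * np.cos(theta)
    y = SHEET_HEIGHT_CM / 2 + (SHEET_HEIGHT_CM / 2 - 8) * np.sin(theta)
    return np.column_stack([x, y])


@dataclass
class PanelScenario:
    """Ground truth for one simulated projective-mapping / UFP session.

    ``true_config`` holds the noise-free product positions on the 60 x 40 cm
    sheet. Each simulated assessor sees that configuration through their own
    similarity transform plus placement noise (``assessor_noise_sd``, cm).
    ``descriptor_propensity`` gives each product a non-negative weight per
    selectable attribute; citations are drawn without replacement with these
    weights. 15 assessors is the default panel size.
    """

    n_products: int = 6
    n_assessors: int = 15
    true_config: np.ndarray | None = None
    assessor_noise_sd: float = 2.0
    allow_rotation: bool = True
    allow_reflection: bool = False
    scale_range: tuple[float, float] = (0.8, 1.2)
    descriptor_propensity: np.ndarray | None = None
    k_distribution: dict[int, float] = field(
        default_factory=lambda: {k: 0.2 for k in range(1, 6)}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_config is None:
            self.true_config = default_true_config(self.n_products)
        self.true_config = np.asarray(self.true_config, dtype=float)
        if self.true_config.shape != (self.n_products, 2):
            raise ValueError("true_config must be n_products x 2")
        if self.assessor_noise_sd < 0:
            raise ValueError("assessor_noise_sd must be >= 0")
        if self.descriptor_propensity is not None:
            w = np.asarray(self.descriptor_propensity, dtype=float)
            if (w < 0).any() or (w.sum(axis=1) <= 0).any():
                raise ValueError("each product needs non-negative weights with a positive sum")
            self.descriptor_propensity = w
        ks, ps = zip(*sorted(self.k_distribution.items()))
        if any(k < 1 for k in ks) or abs(sum(ps) - 1.0) > 1e-9:
            raise ValueError("k_distribution must be a distribution over positive counts")

    @property
    def product_names(self) -> tuple[str, ...]:
        return tuple(f"P{i + 1:02d}" for i in range(self.n_products))

    @property
    def assessor_names(self) -> tuple[str, ...]:
        return tuple(f"A{i + 1:02d}" for i in range(self.n_assessors))


def gen_corpus(
    n_docs: int,
    vocabulary: dict[str, float],
    planted_pairs: list[tuple[str, str]] | None = None,
    seed: int = 0,
    mean_count: float = 3.0,
) -> Corpus:
    """Corpus with per-term document rates and deterministically linked pairs.

    ``vocabulary`` maps term -> probability that the term appears in a
    document; an appearing term's count is 1 + Poisson(mean_count - 1). For
    each planted pair the second member copies the first member's per-document
    count exactly (both present or both absent, same multiplicity), so their
    dtm columns correlate perfectly and any correlation-threshold fusion must
    group them.
    """
    if not vocabulary:
        raise ValueError("vocabulary must be non-empty")
    planted_pairs = planted_pairs or []
    partners: dict[str, str] = {}
    for a, b in planted_pairs:
        if a not in vocabulary or b not in vocabulary:
            raise ValueError(f"planted pair ({a!r}, {b!r}) not in vocabulary")
        partners[b] = a
    rng = np.random.default_rng(seed)
    docs = []
    for i in range(n_docs):
        counts: dict[str, int] = {}
        words: list[str] = []
        for term, rate in vocabulary.items():
            if term in partners:
                count = counts.get(partners[term], 0)
            elif rng.random() < rate:
                count = 1 + rng.poisson(max(mean_count - 1, 0.0))
            else:
                count = 0
            counts[term] = count
            words.extend([term] * count)
        rng.shuffle(words)
        docs.append((f"doc{i + 1:03d}", " ".join(words)))
    return Corpus(tuple(docs))


def gen_mapping(scenario: PanelScenario) -> list[MappingSheet]:
    """Per-assessor sheets: similarity-transformed truth plus Gaussian noise.

    Placements falling off the sheet are clipped to its edge — assessors
    cannot place a cup off the table — and every clip is recorded in the
    sheet list's companion log (returned via ``warnings`` and the module
    logger is intentionally avoided; tests inspect the clip count through
    the returned coordinates).
    """
    cfg = scenario.true_config
    if (cfg[:, 0] < 0).any() or (cfg[:, 0] > SHEET_WIDTH_CM).any() or (
        cfg[:, 1] < 0
    ).any() or (cfg[:, 1] > SHEET_HEIGHT_CM).any():
        raise ValueError("true_config must lie on the sheet")
    rng = np.random.default_rng(scenario.seed)
    center = np.array([SHEET_WIDTH_CM / 2, SHEET_HEIGHT_CM / 2])
    sheets = []
    n_clipped = 0
    for a_idx, assessor in enumerate(scenario.assessor_names):
        angle = rng.uniform(0, 2 * np.pi) if scenario.allow_rotation else 0.0
        lo, hi = scenario.scale_range
        scale = rng.uniform(lo, hi)
        reflect = bool(scenario.allow_reflection and rng.random() < 0.5)
        c, s = np.cos(angle), np.sin(angle)
        R = np.array([[c, -s], [s, c]])
        if reflect:
            R = R @ np.diag([1.0, -1.0])
        pts = (cfg - center) @ (scale * R).T + center
        pts = pts + rng.normal(0.0, scenario.assessor_noise_sd, size=pts.shape)
        clipped = np.clip(pts, [0, 0], [SHEET_WIDTH_CM, SHEET_HEIGHT_CM])
        n_clipped += int((clipped != pts).any(axis=1).sum())
        sheets.append(
            MappingSheet(
                assessor,
                {p: (float(x), float(y)) for p, (x, y) in zip(scenario.product_names, clipped)},
            )
        )
    if n_clipped:
        warnings.warn(f"{n_clipped} placements clipped to the sheet bounds")
    return sheets


def gen_citations(scenario: PanelScenario, wheel: SensoryWheel) -> CitationTable:
    """Citation table drawn from the scenario's per-product propensity rows.

    Per assessor x product: draw K from ``k_distribution``, then K distinct
    attributes without replacement with probability proportional to the
    product's propensity row over the wheel's selectable set. If a product
    row has fewer positive-weight attributes than K, K is truncated (with a
    warning). Uniform propensity reproduces the pure-chance citation model.
    """
    attrs = wheel.selectable_set()
    d = len(attrs)
    if scenario.descriptor_propensity is None:
        prop = np.ones((scenario.n_products, d))
    else:
        prop = scenario.descriptor_propensity
    if prop.shape != (scenario.n_products, d):
        raise ValueError(
            f"descriptor_propensity must be {scenario.n_products} x {d} "
            "(products x selectable attributes)"
        )
    rng = np.random.default_rng(scenario.seed + 1)  # independent of the mapping stream
    ks, kp = zip(*sorted(scenario.k_distribution.items()))
    records = []
    truncated = 0
    for assessor in scenario.assessor_names:
        for p_idx, product in enumerate(scenario.product_names):
            k = int(rng.choice(ks, p=kp))
            w = prop[p_idx]
            positive = int((w > 0).sum())
            if positive < k:
                truncated += 1
                k = positive
            chosen = rng.choice(d, size=k, replace=False, p=w / w.sum())
            records.append((assessor, product, tuple(attrs[j] for j in sorted(chosen))))
    if truncated:
        warnings.warn(f"{truncated} records had K truncated to the positive-weight count")
    return CitationTable(tuple(records), selectable=attrs, n_max=max(max(ks), 5))
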