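"""Multiple factor analysis of projective-mapping data.

Each assessor places every product on a 60 x 40 cm sheet; the assessor's
(x, y) columns form one group of two active variables. MFA balances the
groups by dividing each centered group block by its first singular value —
so no single assessor dominates the first dimension — and then performs a
global SVD of the weighted, concatenated products x (2 * assessors) matrix.
Columns are centered but not scaled to unit variance: the sheet coordinates
already share a unit (cm).

The global product configuration lives in the row scores. Each assessor
also has *partial coordinates*: the projection of their own (weighted) block
onto the global axes, inflated by the number of groups so that the average
of partial coordinates over assessors equals the global coordinate — the
standard MFA identity that makes per-assessor disagreement visible around
each product.

Confidence regions for product positions use the partial bootstrap:
resample assessors with replacement, average their partial coordinates per
product, and fit a bivariate-normal ellipse to the replicate cloud at the
chi-square(2 df) quantile. Because resampling happens on partial
coordinates in the fixed global space, the regions exclude between-assessor
variability and compare products only.

Descriptor citation frequencies enter as supplementary variables: each
descriptor's coordinate on an axis is the Pearson correlation between its
per-product frequency profile and the products' global scores on that axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SHEET_WIDTH_CM",
    "SHEET_HEIGHT_CM",
    "MappingSheet",
    "MFAResult",
    "ConfidenceEllipse",
    "sheets_from_frame",
    "fit_mfa",
    "project_supplementary",
    "bootstrap_ellipses",
    "ellipses_to_frame",
]

SHEET_WIDTH_CM = 60.0
SHEET_HEIGHT_CM = 40.0


@dataclass(frozen=True)
class MappingSheet:
    """One assessor's product placements on the tabletop sheet."""

    assessor_id: str
    placements: dict[str, tuple[float, float]]  # product -> (x, y) in cm
    width: float = SHEET_WIDTH_CM
    height: float = SHEET_HEIGHT_CM

    def __post_init__(self) -> None:
        for product, (x, y) in self.placements.items():
            if not (0 <= x <= self.width and 0 <= y <= self.height):
                raise ValueError(
                    f"assessor {self.assessor_id!r}: product {product!r} at "
                    f"({x}, {y}) is off the {self.width} x {self.height} cm sheet"
                )

    @property
    def products(self) -> tuple[str, ...]:
        return tuple(sorted(self.placements))

    def matrix(self, products: tuple[str, ...]) -> np.ndarray:
        return np.array([self.placements[p] for p in products], dtype=float)


@dataclass(frozen=True)
class MFAResult:
    """Fitted MFA decomposition of a projective-mapping panel."""

    products: tuple[str, ...]
    assessors: tuple[str, ...]
    eigenvalues: np.ndarray                 # descending, >= 0
    explained_variance_pct: np.ndarray      # sums to 100 over all dimensions
    global_coords: np.ndarray               # products x dims
    partial_coords: np.ndarray              # products x assessors x dims
    group_weights: np.ndarray               # per assessor, 1 / sigma1^2
    column_loadings: np.ndarray             # (2*assessors) x dims right singular vectors
    column_means: np.ndarray                # per-column centering offsets
    supplementary_coords: pd.DataFrame | None = None

    @property
    def n_dims(self) -> int:
        return self.global_coords.shape[1]

    def global_frame(self) -> pd.DataFrame:
        cols = [f"dim{s + 1}" for s in range(self.n_dims)]
        return pd.DataFrame(self.global_coords, index=list(self.products), columns=cols)

    def partial_frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.products):
            for g, a in enumerate(self.assessors):
                rows.append(
                    {"product": p, "assessor": a}
                    | {f"dim{s + 1}": self.partial_coords[i, g, s] for s in range(self.n_dims)}
                )
        return pd.DataFrame(rows)

    def eigen_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "eigenvalue": self.eigenvalues,
                "explained_variance_pct": self.explained_variance_pct,
                "cumulative_pct": np.cumsum(self.explained_variance_pct),
            },
            index=[f"dim{s + 1}" for s in range(self.n_dims)],
        )


@dataclass(frozen=True)
class ConfidenceEllipse:
    """Bootstrap confidence region for one product's position."""

    product: str
    center: tuple[float, float]
    covariance: np.ndarray  # 2x2, symmetric PSD
    coverage: float
    boundary: np.ndarray  # (n_vertices, 2) polyline

    @property
    def area(self) -> float:
        r2 = sps.chi2.ppf(self.coverage, df=2)
        det = float(np.linalg.det(self.covariance))
        return float(np.pi * r2 * np.sqrt(max(det, 0.0)))

    def contains(self, point: tuple[float, float]) -> bool:
        """Mahalanobis membership test against the coverage contour."""
        r2 = sps.chi2.ppf(self.coverage, df=2)
        delta = np.asarray(point, dtype=float) - np.asarray(self.center)
        cov = self.covariance + 1e-15 * np.eye(2)  # guard exact degeneracy
        return float(delta @ np.linalg.solve(cov, delta)) <= r2


def sheets_from_frame(frame: pd.DataFrame) -> list[MappingSheet]:
    """Build per-assessor sheets from long-form columns assessor, product, x_cm, y_cm."""
    sheets = []
    for assessor, grp in frame.groupby("assessor", sort=True):
        dup = grp["product"].duplicated()
        if dup.any():
            raise ValueError(
                f"assessor {assessor!r} places {grp['product'][dup].iloc[0]!r} more than once"
            )
        placements = {
            str(r["product"]): (float(r["x_cm"]), float(r["y_cm"])) for _, r in grp.iterrows()
        }
        sheets.append(MappingSheet(str(assessor), placements))
    return sheets


def _group_blocks(sheets: list[MappingSheet]) -> tuple[tuple[str, ...], np.ndarray]:
    products = sheets[0].products
    for sh in sheets[1:]:
        if sh.products != products:
            raise ValueError(
                f"assessor {sh.assessor_id!r} placed products {sh.products}, "
                f"expected {products}: every assessor must place every product"
            )
    X = np.stack([sh.matrix(products) for sh in sheets], axis=1)  # (n, G, 2)
    return products, X


def fit_mfa(sheets: list[MappingSheet]) -> MFAResult:
    """Fit unscaled MFA with each assessor's (x, y) as one active group.

    Steps: center each column; weight group g by 1/sigma1(g)^2 where sigma1
    is the first singular value of the centered block (a degenerate block —
    every product at one point — raises, naming the assessor); SVD the
    weighted concatenation; partial coordinate of product i for group g is
    G times the projection of that group's weighted row onto the axes.
    """
    if len(sheets) < 2:
        raise ValueError("MFA needs at least 2 assessors")
    products, X = _group_blocks(sheets)
    n, G, _ = X.shape
    if n < 3:
        raise ValueError("MFA needs at least 3 products")

    centered = X - X.mean(axis=0, keepdims=True)
    weights = np.empty(G)
    for g in range(G):
        s1 = np.linalg.svd(centered[:, g, :], compute_uv=False)[0]
        if s1 <= 1e-12:
            raise ValueError(
                f"assessor {sheets[g].assessor_id!r} placed all products at the same "
                "point; the group has no variance and cannot be weighted"
            )
        weights[g] = 1.0 / s1**2
    # The extra 1/G keeps the solution invariant under duplicating the whole
    # panel: group weights renormalize instead of inflating the inertia.
    Z = centered * np.sqrt(weights / G)[None, :, None]
    Zc = Z.reshape(n, 2 * G)

    U, S, Vt = np.linalg.svd(Zc, full_matrices=False)
    r = int(np.sum(S > S[0] * 1e-12)) if S.size else 0
    U, S, Vt = U[:, :r], S[:r], Vt[:r]
    # Fix the sign convention: largest-magnitude global score positive per axis.
    F = U * S
    signs = np.sign(F[np.argmax(np.abs(F), axis=0), np.arange(r)])
    signs[signs == 0] = 1.0
    F *= signs
    Vt = Vt * signs[:, None]

    eig = S**2
    evp = 100.0 * eig / eig.sum()
    # Partial coordinates: G * (group block projected on the axes).
    partial = np.empty((n, G, r))
    for g in range(G):
        partial[:, g, :] = G * Z[:, g, :] @ Vt[:, 2 * g : 2 * g + 2].T

    return MFAResult(
        products=products,
        assessors=tuple(sh.assessor_id for sh in sheets),
        eigenvalues=eig,
        explained_variance_pct=evp,
        global_coords=F,
        partial_coords=partial,
        group_weights=weights,
        column_loadings=Vt.T,
        column_means=X.mean(axis=0).reshape(-1),
    )


def project_supplementary(result: MFAResult, freq: pd.DataFrame) -> pd.DataFrame:
    """Project a products x descriptors citation-frequency table onto the map.

    The coordinate of a descriptor on an axis is the Pearson correlation
    between its frequency column and the global scores on that axis, so all
    supplementary coordinates live in [-1, 1] regardless of citation scale.
    Descriptors with zero variance across products carry no positional
    information; they are excluded and listed in ``attrs['excluded']``.
    """
    missing = set(result.products) - set(freq.index)
    extra = set(freq.index) - set(result.products)
    if missing or extra:
        raise ValueError(
            f"frequency table products do not match the fitted configuration "
            f"(missing={sorted(missing)}, unknown={sorted(extra)})"
        )
    fv = freq.loc[list(result.products)].astype(float)
    excluded = [c for c in fv.columns if fv[c].std(ddof=1) == 0]
    kept = [c for c in fv.columns if c not in excluded]
    if excluded:
        warnings.warn(f"zero-variance descriptors excluded: {excluded}")
    coords = pd.DataFrame(
        index=kept, columns=[f"dim{s + 1}" for s in range(result.n_dims)], dtype=float
    )
    for c in kept:
        for s in range(result.n_dims):
            axis = result.global_coords[:, s]
            if axis.std(ddof=1) == 0:
                coords.loc[c, f"dim{s + 1}"] = 0.0
            else:
                coords.loc[c, f"dim{s + 1}"] = float(np.corrcoef(fv[c], axis)[0, 1])
    coords.attrs["excluded"] = excluded
    return coords


def bootstrap_ellipses(
    result: MFAResult,
    coverage: float = 0.95,
    n_boot: int = 500,
    seed: int | None = None,
    n_vertices: int = 100,
) -> list[ConfidenceEllipse]:
    """Partial-bootstrap confidence ellipses for product positions (dims 1-2).

    Each replicate draws assessors with replacement and averages their
    partial coordinates per product; the ellipse is the bivariate-normal
    contour of the replicate cloud at the chi-square(2) quantile for the
    requested coverage. Deterministic under a fixed seed.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if not 0 < coverage < 1:
        raise ValueError("coverage must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n, G, _ = result.partial_coords.shape
    pc = result.partial_coords[:, :, :2]
    idx = rng.integers(0, G, size=(n_boot, G))
    # replicate means: (n_boot, products, 2)
    reps = pc[:, idx, :].mean(axis=2).transpose(1, 0, 2)
    r2 = sps.chi2.ppf(coverage, df=2)
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=True)
    circle = np.column_stack([np.cos(theta), np.sin(theta)])
    out = []
    for i, product in enumerate(result.products):
        cloud = reps[:, i, :]
        center = cloud.mean(axis=0)
        cov = np.cov(cloud, rowvar=False)
        cov = (cov + cov.T) / 2.0
        vals, vecs = np.linalg.eigh(cov)
        vals = np.clip(vals, 0.0, None)
        boundary = center + (circle * np.sqrt(r2 * vals)) @ vecs.T
        out.append(
            ConfidenceEllipse(
                product=product,
                center=(float(center[0]), float(center[1])),
                covariance=cov,
                coverage=coverage,
                boundary=boundary,
            )
        )
    return out


def ellipses_to_frame(ellipses: list[ConfidenceEllipse]) -> pd.DataFrame:
    """Long-form boundary table: product, vertex_index, dim1, dim2."""
    rows = []
    for e in ellipses:
        for k, (d1, d2) in enumerate(e.boundary):
            rows.append({"product": e.product, "vertex_index": k, "dim1": d1, "dim2": d2})
    return pd.DataFrame(rows)
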