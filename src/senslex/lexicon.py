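"""Sensory-lexicon mining from a plain-text corpus.

The pipeline mirrors the text-mining workflow used to build descriptor
lexica for food products: preprocess each document into tokens, assemble a
document-term matrix (dtm), drop terms too rare across documents, measure
pairwise term correlations, fuse synonymous / strongly co-occurring terms
into normalized entries, and rank the resulting lexicon by frequency. A
term co-occurrence network summarises which descriptors travel together
across the literature.

All steps are deterministic: the same corpus and options yield a
byte-identical lexicon.
"""

from __future__ import annotations

import json
import re
import unicodedata
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Corpus",
    "DocumentTermMatrix",
    "FusionMap",
    "RankedLexicon",
    "load_default_stopwords",
    "preprocess",
    "build_dtm",
    "filter_sparse_terms",
    "term_correlations",
    "propose_fusions",
    "apply_normalization",
    "cooccurrence_network",
]

_TOKEN_SPLIT = re.compile(r"[^\w\-]+", flags=re.UNICODE)
_LEMMA_RULES = (
    ("nesses", "ness"),
    ("iest", "y"),
    ("ness", ""),
    ("ies", "y"),
    ("est", ""),
    ("ing", ""),
    ("ed", ""),
    ("s", ""),
)


def load_default_stopwords() -> frozenset[str]:
    """Return the fixed English stopword list shipped with the package."""
    text = resources.files("senslex.data").joinpath("stopwords_en.txt").read_text("utf-8")
    return frozenset(
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


@dataclass(frozen=True)
class Corpus:
    """A collection of (doc_id, text) documents with unique ids."""

    documents: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.documents:
            raise ValueError("a corpus needs at least one document")
        ids = [d for d, _ in self.documents]
        if len(set(ids)) != len(ids):
            raise ValueError("document ids must be unique")

    @classmethod
    def from_dir(cls, path: str | Path, pattern: str = "*.txt") -> "Corpus":
        """Load a corpus from a directory of text files (doc_id = file stem)."""
        files = sorted(Path(path).glob(pattern))
        if not files:
            raise FileNotFoundError(f"no {pattern} files under {path}")
        return cls(tuple((f.stem, f.read_text("utf-8")) for f in files))

    @classmethod
    def from_texts(cls, texts: dict[str, str]) -> "Corpus":
        return cls(tuple(texts.items()))


@dataclass(frozen=True)
class DocumentTermMatrix:
    """Documents x terms count matrix with document-frequency metadata."""

    doc_ids: tuple[str, ...]
    terms: tuple[str, ...]
    counts: np.ndarray  # (n_docs, n_terms) non-negative ints

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.doc_ids), len(self.terms)):
            raise ValueError("counts shape does not match doc_ids x terms")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def doc_frequency(self) -> np.ndarray:
        """Per-term number of documents in which the term occurs."""
        return (self.counts > 0).sum(axis=0)

    @property
    def term_frequency(self) -> np.ndarray:
        """Per-term total occurrence count over the corpus."""
        return self.counts.sum(axis=0)

    @property
    def sparsity(self) -> float:
        """Fraction of zero cells, in [0, 1]."""
        if self.counts.size == 0:
            return 0.0
        return float((self.counts == 0).mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.doc_ids), columns=list(self.terms))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("doc_id").to_csv(path)

    def to_mtx(self, path: str | Path) -> None:
        """Write the counts as a MatrixMarket sparse triplet file."""
        from scipy import io as sio
        from scipy import sparse

        sio.mmwrite(str(path), sparse.coo_matrix(self.counts))


@dataclass
class FusionMap:
    """Normalized term -> member raw terms (similar + related), one level deep.

    ``entries`` maps each normalized term to the raw terms folded into it; a
    normalized term may (and usually does) appear among its own members.
    ``provenance`` records whether the map was proposed automatically from
    correlations or curated by an expert.
    """

    entries: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    provenance: str = "expert"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for norm, groups in self.entries.items():
            members = self.members(norm)
            for m in members:
                if m in seen:
                    raise ValueError(f"raw term {m!r} appears in more than one entry")
                seen.add(m)
            for key in groups:
                if key not in ("similar_terms", "related_terms"):
                    raise ValueError(f"unknown member class {key!r}")

    def members(self, normalized_term: str) -> list[str]:
        groups = self.entries[normalized_term]
        out = list(groups.get("similar_terms", [])) + list(groups.get("related_terms", []))
        if normalized_term not in out:
            out.insert(0, normalized_term)
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"provenance": self.provenance, "entries": self.entries}, indent=2),
            "utf-8",
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "FusionMap":
        raw = json.loads(Path(path).read_text("utf-8"))
        return cls(entries=raw["entries"], provenance=raw.get("provenance", "expert"))


@dataclass(frozen=True)
class RankedLexicon:
    """(term, frequency) pairs sorted by frequency desc, ties lexicographic."""

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        key = [(-f, t) for t, f in self.entries]
        if key != sorted(key):
            raise ValueError("lexicon entries are not in ranked order")

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.entries)

    def frequency(self, term: str) -> int:
        return dict(self.entries)[term]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["term", "frequency"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps([list(e) for e in self.entries], indent=2), "utf-8")


def _lemmatize(token: str) -> str:
    for suffix, repl in _LEMMA_RULES:
        if token.endswith(suffix) and len(token) - len(suffix) >= 3:
            return token[: -len(suffix)] + repl
    return token


def preprocess(
    text: str,
    stopwords: frozenset[str] | set[str] | None = None,
    keep_hyphenated_tuples: bool = True,
    lemmatize: bool = False,
    bigrams: set[tuple[str, str]] | None = None,
) -> list[str]:
    """Tokenize raw text for the lexicon pipeline.

    Lowercases, strips punctuation and numbers, removes stopwords. Hyphenated
    tuples such as ``green-apple`` survive as single tokens when
    ``keep_hyphenated_tuples`` is on; an explicit ``bigrams`` set merges the
    listed adjacent token pairs into hyphenated tuples after tokenization.
    Suffix lemmatization exists but is off by default: collapsing inflected
    forms is handled better by the expert fusion map, and naive stemming can
    destroy descriptors (flowery -> flow).
    """
    if stopwords is None:
        stopwords = load_default_stopwords()
    text = unicodedata.normalize("NFKC", text).lower()
    tokens: list[str] = []
    for raw in _TOKEN_SPLIT.split(text):
        raw = raw.strip("-")
        if not raw or any(ch.isdigit() for ch in raw):
            continue
        if "-" in raw and not keep_hyphenated_tuples:
            parts = [p for p in raw.split("-") if p]
        else:
            parts = [raw]
        for tok in parts:
            if tok in stopwords:
                continue
            tokens.append(_lemmatize(tok) if lemmatize else tok)
    if bigrams:
        merged: list[str] = []
        i = 0
        while i < len(tokens):
            if i + 1 < len(tokens) and (tokens[i], tokens[i + 1]) in bigrams:
                merged.append(f"{tokens[i]}-{tokens[i + 1]}")
                i += 2
            else:
                merged.append(tokens[i])
                i += 1
        tokens = merged
    return tokens


def build_dtm(corpus: Corpus, **preprocess_options) -> DocumentTermMatrix:
    """Tokenize every document and assemble the document-term count matrix.

    Documents that are empty after preprocessing are excluded with a warning.
    Terms are sorted lexicographically so the matrix is deterministic.
    """
    if "stopwords" not in preprocess_options:
        preprocess_options["stopwords"] = load_default_stopwords()
    per_doc: list[tuple[str, list[str]]] = []
    for doc_id, text in corpus.documents:
        toks = preprocess(text, **preprocess_options)
        if not toks:
            warnings.warn(f"document {doc_id!r} is empty after preprocessing; excluded")
            continue
        per_doc.append((doc_id, toks))
    if not per_doc:
        raise ValueError("corpus is empty after preprocessing")
    terms = sorted({t for _, toks in per_doc for t in toks})
    index = {t: j for j, t in enumerate(terms)}
    counts = np.zeros((len(per_doc), len(terms)), dtype=np.int64)
    for i, (_, toks) in enumerate(per_doc):
        for t in toks:
            counts[i, index[t]] += 1
    return DocumentTermMatrix(tuple(d for d, _ in per_doc), tuple(terms), counts)


def filter_sparse_terms(
    dtm: DocumentTermMatrix, min_doc_fraction: float = 0.10
) -> DocumentTermMatrix:
    """Drop terms absent from too many documents.

    A term survives iff its document frequency is at least
    ``ceil(min_doc_fraction * n_docs)`` — "present in at least 10% of the
    documents" read as a whole number of documents, rounding up.
    """
    if not 0 < min_doc_fraction <= 1:
        raise ValueError("min_doc_fraction must be in (0, 1]")
    n_docs = len(dtm.doc_ids)
    need = int(np.ceil(min_doc_fraction * n_docs))
    keep = dtm.doc_frequency >= need
    return DocumentTermMatrix(
        dtm.doc_ids,
        tuple(t for t, k in zip(dtm.terms, keep) if k),
        dtm.counts[:, keep],
    )


def term_correlations(dtm: DocumentTermMatrix) -> pd.DataFrame:
    """Pearson correlation between per-document count vectors of every term pair.

    Zero-variance terms cannot be correlated; their rows/columns are returned
    as NaN and listed in the frame's ``attrs['zero_variance_terms']`` so the
    caller sees the flag rather than silently propagated NaNs.
    """
    if len(dtm.doc_ids) < 2:
        raise ValueError("correlations require at least 2 documents")
    frame = dtm.to_frame().astype(float)
    sd = frame.std(axis=0, ddof=1)
    flagged = [t for t in dtm.terms if sd[t] == 0]
    corr = frame.corr(method="pearson")  # covariance / (sd_i * sd_j)
    np.fill_diagonal(corr.values, 1.0)
    corr.loc[flagged, :] = np.nan
    corr.loc[:, flagged] = np.nan
    corr.attrs["zero_variance_terms"] = flagged
    return corr


def propose_fusions(
    correlations: pd.DataFrame,
    threshold: float = 0.50,
    term_frequency: dict[str, int] | None = None,
) -> FusionMap:
    """Group terms whose pairwise correlation strictly exceeds ``threshold``.

    Pairs above the threshold form graph edges; each connected component
    becomes one proposed entry whose representative is the
    highest-total-frequency member (lexicographic tie-break). The result is a
    starting point for expert review, never a final normalization.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    terms = list(correlations.columns)
    g = nx.Graph()
    g.add_nodes_from(terms)
    vals = correlations.values
    for i in range(len(terms)):
        for j in range(i + 1, len(terms)):
            if np.isfinite(vals[i, j]) and vals[i, j] > threshold:
                g.add_edge(terms[i], terms[j])
    freq = term_frequency or {}
    entries: dict[str, dict[str, list[str]]] = {}
    for comp in nx.connected_components(g):
        members = sorted(comp)
        rep = min(members, key=lambda t: (-freq.get(t, 0), t))
        entries[rep] = {"similar_terms": members, "related_terms": []}
    return FusionMap(entries=dict(sorted(entries.items())), provenance="auto-proposed")


def apply_normalization(
    dtm: DocumentTermMatrix, fusion_map: FusionMap
) -> tuple[DocumentTermMatrix, RankedLexicon]:
    """Fuse member columns into their normalized term and rank the lexicon.

    Member columns are summed into the normalized term's column, so total
    token mass is conserved. Members absent from the dtm are skipped with a
    warning (expert maps may reference terms the corpus never produced).
    Terms not covered by the map pass through unchanged.
    """
    frame = dtm.to_frame()
    covered: set[str] = set()
    out = {}
    for norm in fusion_map.entries:
        cols = []
        for member in fusion_map.members(norm):
            if member not in frame.columns:
                warnings.warn(f"fusion member {member!r} not in dtm; skipped")
                continue
            cols.append(member)
            covered.add(member)
        if cols:
            out[norm] = frame[cols].sum(axis=1)
    for term in frame.columns:
        if term not in covered:
            out[term] = frame[term]
    new = pd.DataFrame(out).reindex(sorted(out), axis=1)
    dtm2 = DocumentTermMatrix(dtm.doc_ids, tuple(new.columns), new.to_numpy(np.int64))
    totals = new.sum(axis=0)
    ranked = sorted(((t, int(f)) for t, f in totals.items()), key=lambda e: (-e[1], e[0]))
    return dtm2, RankedLexicon(tuple(ranked))


def cooccurrence_network(
    dtm: DocumentTermMatrix, min_edge_weight: int = 1
) -> pd.DataFrame:
    """Edge list (term_a, term_b, weight) of shared-document counts.

    The weight of an edge is the number of documents where both terms occur;
    edges lighter than ``min_edge_weight`` are dropped. The frame is
    plot-ready for any network renderer.
    """
    if not dtm.terms:
        raise ValueError("dtm has no terms")
    present = (dtm.counts > 0).astype(np.int64)
    w = present.T @ present  # shared-document counts
    rows = []
    for i in range(len(dtm.terms)):
        for j in range(i + 1, len(dtm.terms)):
            if w[i, j] >= min_edge_weight:
                rows.append((dtm.terms[i], dtm.terms[j], int(w[i, j])))
    return pd.DataFrame(rows, columns=["term_a", "term_b", "weight"])
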