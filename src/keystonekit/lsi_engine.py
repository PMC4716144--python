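"""Latent semantic indexing over gene-word documents.

Each gene carries one document (a token multiset).  The term-document count
matrix is weighted with the classic log-entropy scheme, factored by a
truncated singular value decomposition, and gene<->term associations are
read off as cosine similarities between singular-value-scaled latent
vectors.  Scores are declared to span [0, 1]: negative cosines are clamped
to 0, and a score >= 0.1 (inclusive) marks an *implicit* association — a
gene-term link inferred from shared latent structure rather than direct
co-mention.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import linalg

from .io_formats import Corpus

logger = logging.getLogger(__name__)

IMPLICIT_THRESHOLD = 0.1


@dataclass
class TermDocumentMatrix:
    """Terms x documents weighted counts with the label vectors."""

    vocabulary: list[str]
    gene_ids: list[str]
    values: np.ndarray  # (n_terms, n_docs)


@dataclass
class LsiModel:
    vocabulary: list[str]
    gene_ids: list[str]
    weighted: np.ndarray  # (n_terms, n_docs)
    rank_k: int
    term_factors: np.ndarray  # (n_terms, k), rows = U * S
    doc_factors: np.ndarray  # (n_docs, k), rows = V * S
    singular_values: np.ndarray  # (k,), descending
    weighting: str = "log-entropy"
    _term_index: dict[str, int] = field(init=False, repr=False)
    _doc_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._term_index = {t: i for i, t in enumerate(self.vocabulary)}
        self._doc_index = {}
        for i, g in enumerate(self.gene_ids):
            self._doc_index[g] = i
            self._doc_index.setdefault(g.casefold(), i)

    def term_index(self, term: str) -> int | None:
        return self._term_index.get(term.lower())

    def doc_index(self, gene_id: str) -> int | None:
        idx = self._doc_index.get(gene_id)
        if idx is None:
            idx = self._doc_index.get(gene_id.casefold())
        return idx

    def reconstruct(self) -> np.ndarray:
        """Rank-k reconstruction of the weighted matrix."""
        s = self.singular_values
        safe = np.where(s > 0, s, 1.0)
        # term_factors = U S and doc_factors = V S, so U S V^T = T diag(1/s) D^T
        return (self.term_factors / safe) @ self.doc_factors.T


@dataclass
class AssociationTable:
    """Scores of every document (or term) against a query, with the
    implicit-association threshold applied in the ``associated`` view."""

    query: str
    scores: dict[str, float]
    threshold: float = IMPLICIT_THRESHOLD

    @property
    def associated(self) -> list[tuple[str, float]]:
        hits = [(k, v) for k, v in self.scores.items() if v >= self.threshold]
        hits.sort(key=lambda kv: (-kv[1], kv[0]))
        return hits


def weight_matrix(corpus: Corpus) -> TermDocumentMatrix:
    """Log-entropy weighting: cell(t, d) = log2(1 + tf) * g_t with global
    weight g_t = 1 + sum_d p log2 p / log2 D, p = tf/gf.

    A term spread with uniform frequency over every document gets g_t = 0; a
    term confined to a single document gets g_t = 1.
    """
    genes = corpus.gene_ids
    D = len(genes)
    if D < 2:
        raise ValueError("log-entropy weighting needs at least 2 documents")
    vocab = corpus.vocabulary()
    tf = np.zeros((len(vocab), D))
    vidx = {t: i for i, t in enumerate(vocab)}
    for j, g in enumerate(genes):
        for tok, c in corpus.documents[g].items():
            tf[vidx[tok], j] = c
    gf = tf.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(gf > 0, tf / gf, 0.0)
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    g = 1.0 + plogp.sum(axis=1) / np.log2(D)
    g = np.clip(g, 0.0, 1.0)  # numerical guard; entropy term lies in [-log2 D, 0]
    values = np.log2(1.0 + tf) * g[:, None]
    return TermDocumentMatrix(vocab, list(genes), values)


def _fix_signs(U: np.ndarray, Vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic sign convention: the largest-|loading| term coefficient
    of each latent dimension is made positive."""
    for j in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
            Vt[j, :] = -Vt[j, :]
    return U, Vt


def default_rank(n_terms: int, n_docs: int) -> int:
    return min(100, min(n_terms, n_docs) - 1)


def fit_lsi(matrix: TermDocumentMatrix, rank_k: int | None = None) -> LsiModel:
    """Truncated SVD of the weighted matrix; factors are scaled by the
    singular values so terms and documents share one latent space."""
    n_terms, n_docs = matrix.values.shape
    if rank_k is None:
        rank_k = default_rank(n_terms, n_docs)
    if not 1 <= rank_k <= min(n_terms, n_docs):
        raise ValueError(
            f"rank_k must lie in [1, {min(n_terms, n_docs)}], got {rank_k}"
        )
    U, s, Vt = linalg.svd(matrix.values, full_matrices=False)
    U, Vt = _fix_signs(U[:, :rank_k].copy(), Vt[:rank_k, :].copy())
    s = s[:rank_k]
    return LsiModel(
        vocabulary=list(matrix.vocabulary),
        gene_ids=list(matrix.gene_ids),
        weighted=matrix.values,
        rank_k=rank_k,
        term_factors=U * s,
        doc_factors=Vt.T * s,
        singular_values=s,
    )


def fit_corpus(corpus: Corpus, rank_k: int | None = None) -> LsiModel:
    """Weight + decompose in one step."""
    return fit_lsi(weight_matrix(corpus), rank_k)


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def cosine_gene_term(
    model: LsiModel, gene_id: str, term: str, clamp: bool = True
) -> float:
    """Cosine between a gene's and a term's latent vectors, clamped to [0, 1].

    Out-of-vocabulary terms or unknown genes soft-fail to 0 with a warning.
    """
    ti = model.term_index(term)
    di = model.doc_index(gene_id)
    if ti is None or di is None:
        warnings.warn(
            f"{'term ' + term if ti is None else 'gene ' + gene_id!r} not in model; "
            "score 0",
            stacklevel=2,
        )
        return 0.0
    c = _cosine(model.term_factors[ti], model.doc_factors[di])
    return min(max(c, 0.0), 1.0) if clamp else c


def query_term(
    model: LsiModel, term: str, threshold: float = IMPLICIT_THRESHOLD
) -> AssociationTable:
    """Score every gene document against one interrogation term."""
    ti = model.term_index(term)
    if ti is None:
        warnings.warn(f"term {term!r} out of vocabulary; empty result", stacklevel=2)
        return AssociationTable(term, {g: 0.0 for g in model.gene_ids}, threshold)
    tv = model.term_factors[ti]
    tn = np.linalg.norm(tv)
    dn = np.linalg.norm(model.doc_factors, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos = np.where(
            (dn > 0) & (tn > 0), model.doc_factors @ tv / (dn * tn), 0.0
        )
    cos = np.clip(cos, 0.0, 1.0)
    return AssociationTable(term, dict(zip(model.gene_ids, cos.tolist())), threshold)


def associate_words(
    model: LsiModel, gene_set: Iterable[str], top_m: int = 50
) -> tuple[list[tuple[str, float]], np.ndarray, list[str], list[str]]:
    """Words most associated with a gene set: per-term mean cosine over the
    set's documents.

    Returns (top-m (term, score) list, per-gene x per-term score grid for
    those terms, grid gene ids, grid terms).
    """
    idx = []
    kept_genes = []
    for g in gene_set:
        di = model.doc_index(g)
        if di is not None:
            idx.append(di)
            kept_genes.append(model.gene_ids[di])
    if not idx:
        raise ValueError("gene set does not overlap the model's documents")
    docs = model.doc_factors[idx]  # (m, k)
    dn = np.linalg.norm(docs, axis=1, keepdims=True)
    tn = np.linalg.norm(model.term_factors, axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        grid = docs @ model.term_factors.T
        grid = np.where((dn > 0) & (tn.T > 0), grid / (dn * tn.T), 0.0)
    grid = np.clip(grid, 0.0, 1.0)  # genes x terms
    agg = grid.mean(axis=0)
    order = np.lexsort((np.array(model.vocabulary), -agg))[:top_m]
    top = [(model.vocabulary[i], float(agg[i])) for i in order]
    return top, grid[:, order], kept_genes, [model.vocabulary[i] for i in order]


# --------------------------------------------------------------------------
# plain-text persistence: numeric tables + a JSON manifest


def save_model(model: LsiModel, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savetxt(d / "weighted.tsv", model.weighted, delimiter="\t")
    np.savetxt(d / "term_factors.tsv", model.term_factors, delimiter="\t")
    np.savetxt(d / "doc_factors.tsv", model.doc_factors, delimiter="\t")
    np.savetxt(d / "singular_values.tsv", model.singular_values, delimiter="\t")
    manifest = {
        "vocabulary": model.vocabulary,
        "gene_ids": model.gene_ids,
        "rank_k": model.rank_k,
        "weighting": model.weighting,
    }
    (d / "manifest.json").write_text(json.dumps(manifest))


def load_model(directory: str | Path) -> LsiModel:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    return LsiModel(
        vocabulary=manifest["vocabulary"],
        gene_ids=manifest["gene_ids"],
        weighted=np.atleast_2d(np.loadtxt(d / "weighted.tsv", delimiter="\t")),
        rank_k=manifest["rank_k"],
        term_factors=np.atleast_2d(
            np.loadtxt(d / "term_factors.tsv", delimiter="\t")
        ),
        doc_factors=np.atleast_2d(np.loadtxt(d / "doc_factors.tsv", delimiter="\t")),
        singular_values=np.atleast_1d(
            np.loadtxt(d / "singular_values.tsv", delimiter="\t")
        ),
        weighting=manifest["weighting"],
    )
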