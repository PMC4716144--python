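"""Cross-pathway keystone-transcript discovery.

The workflow: turn each enriched pathway into an LSI interrogation query
(its name tokenised, generic pathway words removed), score every gene
against every pathway query (mean cosine over the query's tokens), keep
genes implicitly associated (score >= 0.1) with at least two pathways,
count per gene how many pathways it associates with ("conservation"), and
admit the top percentile *class* of that count distribution — the whole
tied top class, never a split — as the keystone set.  A keystone/hub gene
is one whose transcript ties together an unusually high number of
otherwise-separate pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import tokenize
from .lsi_engine import IMPLICIT_THRESHOLD, LsiModel, query_term

logger = logging.getLogger(__name__)

# generic words carrying no pathway-specific meaning in pathway names
QUERY_STOPWORDS = frozenset(
    {"of", "and", "the", "in", "by", "pathway", "pathways", "signaling",
     "signalling", "disease"}
)

MIN_PATHWAYS_DEFAULT = 2
PERCENTILE_DEFAULT = 99.0


@dataclass
class PathwayCosineMatrix:
    gene_ids: list[str]  # retained rows (>= min_pathways associations)
    pathway_ids: list[str]
    scores: np.ndarray  # (n_genes, n_pathways), cosines in [0, 1]
    threshold: float = IMPLICIT_THRESHOLD
    min_pathways: int = MIN_PATHWAYS_DEFAULT

    @property
    def cell_count(self) -> int:
        return int(self.scores.size)

    def is_empty(self) -> bool:
        return len(self.gene_ids) == 0


@dataclass
class KeystoneSet:
    members: list[str]
    conservation: dict[str, int]
    percentile: float
    cut_value: int


def pathway_query_tokens(name: str) -> list[str]:
    """Tokenise a pathway name into interrogation terms, dropping generic
    pathway vocabulary ('of', 'and', 'pathway', 'signaling', ...)."""
    return [t for t in tokenize(name) if t not in QUERY_STOPWORDS]


def build_pathway_matrix(
    model: LsiModel,
    pathway_terms: Mapping[str, str | Sequence[str]],
    genes: Iterable[str] | None = None,
    threshold: float = IMPLICIT_THRESHOLD,
    min_pathways: int = MIN_PATHWAYS_DEFAULT,
) -> PathwayCosineMatrix:
    """Genes x pathway-queries cosine matrix, filtered to multi-pathway genes.

    Each pathway maps to one or more query terms (a bare string is tokenised
    with :func:`pathway_query_tokens`); a gene's score against a pathway is
    the mean cosine over the query's in-vocabulary terms.  Pathways whose
    query is fully out-of-vocabulary are dropped with a warning, never
    silently zero-filled.  Rows associated (score >= threshold) with fewer
    than ``min_pathways`` pathways are dropped.
    """
    if len(pathway_terms) < 2:
        raise ValueError("need at least 2 pathway queries")
    if genes is None:
        gene_list = list(model.gene_ids)
    else:
        gene_list = [g for g in genes if model.doc_index(g) is not None]

    columns: dict[str, np.ndarray] = {}
    for pid, query in pathway_terms.items():
        terms = pathway_query_tokens(query) if isinstance(query, str) else list(query)
        per_term = []
        for t in terms:
            if model.term_index(t) is None:
                continue
            table = query_term(model, t, threshold=threshold)
            per_term.append(
                np.array(
                    [table.scores[model.gene_ids[model.doc_index(g)]]
                     for g in gene_list]
                )
            )
        if not per_term:
            logger.warning("pathway %r: query fully out of vocabulary; dropped", pid)
            continue
        columns[pid] = np.mean(per_term, axis=0)
    if len(columns) < 2:
        raise ValueError("fewer than 2 pathway queries survive vocabulary filtering")

    pathway_ids = list(columns)
    scores = np.column_stack([columns[p] for p in pathway_ids])
    keep = (scores >= threshold).sum(axis=1) >= min_pathways
    retained = [g for g, k in zip(gene_list, keep) if k]
    matrix = PathwayCosineMatrix(
        gene_ids=retained,
        pathway_ids=pathway_ids,
        scores=scores[keep],
        threshold=threshold,
        min_pathways=min_pathways,
    )
    if matrix.is_empty():
        logger.warning("no multi-pathway transcripts at threshold %g", threshold)
    logger.info(
        "pathway matrix: %d genes x %d pathways = %d cells",
        len(matrix.gene_ids), len(pathway_ids), matrix.cell_count,
    )
    return matrix


def conservation_counts(m: PathwayCosineMatrix) -> dict[str, int]:
    """Per gene, the number of pathway columns with score >= threshold."""
    if m.is_empty():
        raise ValueError("empty pathway matrix")
    counts = (m.scores >= m.threshold).sum(axis=1)
    return {g: int(c) for g, c in zip(m.gene_ids, counts)}


def percentile_class(
    counts: Mapping[str, int],
    percentile: float = PERCENTILE_DEFAULT,
    cosine_sums: Mapping[str, float] | None = None,
) -> KeystoneSet:
    """Class-based percentile selection of the most cross-pathway conserved
    genes.

    cut_value is the smallest conservation count c for which the fraction of
    genes with count < c reaches percentile/100; every gene with count >=
    cut_value (the whole tied class and above) is admitted.  If no class
    boundary clears the percentile (the top class holds more than
    1 - percentile/100 of the genes — e.g. all genes share one count), the
    top class alone is admitted; this keeps selection monotone in the
    percentile.

    ``cosine_sums`` switches the statistic to a supplied per-gene score
    (sensitivity-analysis variant); selection semantics are unchanged.
    """
    if not counts:
        raise ValueError("empty counts")
    if not 0 < percentile < 100:
        raise ValueError(f"percentile must lie in (0, 100), got {percentile}")
    stat: Mapping[str, float] = cosine_sums if cosine_sums is not None else counts
    values = np.array([stat[g] for g in counts])
    total = len(values)
    cut = None
    for c in np.unique(values):  # ascending
        if np.count_nonzero(values < c) / total >= percentile / 100.0:
            cut = c
            break
    if cut is None:
        cut = values.max()
    members = sorted(g for g in counts if stat[g] >= cut)
    return KeystoneSet(
        members=members,
        conservation=dict(counts),
        percentile=percentile,
        cut_value=int(cut) if cosine_sums is None else cut,
    )


def keystone_analysis(
    model: LsiModel,
    pathway_terms: Mapping[str, str | Sequence[str]],
    threshold: float = IMPLICIT_THRESHOLD,
    min_pathways: int = MIN_PATHWAYS_DEFAULT,
    percentile: float = PERCENTILE_DEFAULT,
) -> tuple[PathwayCosineMatrix, KeystoneSet]:
    """End-to-end: pathway matrix -> conservation counts -> percentile class."""
    matrix = build_pathway_matrix(
        model, pathway_terms, threshold=threshold, min_pathways=min_pathways
    )
    if matrix.is_empty():
        return matrix, KeystoneSet([], {}, percentile, 0)
    return matrix, percentile_class(conservation_counts(matrix), percentile)
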