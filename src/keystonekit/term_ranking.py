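"""Age-trajectory ranking of interrogation terms.

For each timepoint's LSI model and each interrogation term: take the
implicitly associated transcripts (cosine >= 0.1), average their cosine
scores, rank the terms within the timepoint by that mean (rank 1 =
highest), and reciprocally transform the rank (1/rank) for presentation.
A term with no associated transcripts gets mean 0 and ranks below every
scored term; ties break lexicographically on the term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .lsi_engine import IMPLICIT_THRESHOLD, LsiModel, query_term


@dataclass
class TermTrajectory:
    term: str
    timepoint: str
    mean_score: float
    n_associated: int
    rank: int
    reciprocal_rank: float
    no_hits: bool  # flagged when no transcript cleared the threshold


def term_trajectories(
    models: Mapping[str, LsiModel],
    terms: Sequence[str],
    threshold: float = IMPLICIT_THRESHOLD,
) -> list[TermTrajectory]:
    """Rank every term within every timepoint by mean associated-transcript
    cosine; reciprocal of the rank is attached for trajectory plots."""
    if not terms:
        raise ValueError("empty term list")
    if len(set(terms)) != len(terms):
        raise ValueError("duplicate terms in list")
    if not models:
        raise ValueError("need at least one timepoint model")
    out: list[TermTrajectory] = []
    for timepoint, model in models.items():
        rows = []
        for term in terms:
            hits = query_term(model, term, threshold=threshold).associated
            mean = sum(s for _, s in hits) / len(hits) if hits else 0.0
            rows.append((term, mean, len(hits)))
        # rank: mean descending, lexicographic term on ties; empty terms
        # (mean 0) necessarily trail because associated scores are >= threshold
        rows.sort(key=lambda r: (-r[1], r[0]))
        for rank, (term, mean, n_hits) in enumerate(rows, start=1):
            out.append(
                TermTrajectory(
                    term=term,
                    timepoint=timepoint,
                    mean_score=mean,
                    n_associated=n_hits,
                    rank=rank,
                    reciprocal_rank=1.0 / rank,
                    no_hits=n_hits == 0,
                )
            )
    return out
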