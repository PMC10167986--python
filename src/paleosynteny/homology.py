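"""Step 1 — conserved-gene detection from aggregated HSP statistics.

For every (query, subject) gene pair the HSPs are aggregated into

* ``AL`` — cumulative aligned length, the plain sum of HSP lengths
  (overlapping HSPs are summed without trimming, so CALP may exceed 100%);
* ``CIP`` — cumulative identity percentage,
  ``100 * (sum of identities over HSPs) / AL``;
* ``CALP`` — cumulative alignment length percentage,
  ``100 * AL / query_length`` (the denominator is always the query's own
  length, never the subject's).

A pair is conserved when CIP >= cip_min and CALP >= calp_min (inclusive
thresholds, both defaulting to 50).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import HspRecord

__all__ = [
    "AlignmentSummary",
    "ConservedPair",
    "summarize_hsps",
    "filter_conserved_pairs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentSummary:
    """Per (query, subject) aggregation of HSPs."""

    query_id: str
    subject_id: str
    al: int
    total_identities: int
    query_length: int
    cip: float
    calp: float
    score: float  # max HSP score, used for ranking downstream


@dataclass(frozen=True)
class ConservedPair:
    """An unordered conserved gene pair retained by the Step-1 filter.

    Stored once with ``gene_a < gene_b`` lexicographically; ``cip``,
    ``calp`` and ``score`` are the direction-maximal values.
    """

    gene_a: str
    gene_b: str
    species_a: str
    species_b: str
    cip: float
    calp: float
    score: float


def summarize_hsps(
    hsps: Iterable[HspRecord], query_lengths: Mapping[str, int]
) -> list[AlignmentSummary]:
    """Aggregate HSPs into one summary per (query, subject) pair.

    Raises ``KeyError`` naming the gene if a query length is missing.
    """
    acc: dict[tuple[str, str], list[int | float]] = {}
    for h in hsps:
        key = (h.query_id, h.subject_id)
        if key in acc:
            entry = acc[key]
            entry[0] += h.hsp_length
            entry[1] += h.n_identities
            entry[2] = max(entry[2], h.score)
        else:
            acc[key] = [h.hsp_length, h.n_identities, h.score]

    out: list[AlignmentSummary] = []
    for (q, s), (al, nid, score) in sorted(acc.items()):
        if q not in query_lengths:
            raise KeyError(f"no query length for gene {q!r}")
        qlen = query_lengths[q]
        calp = 100.0 * al / qlen
        if calp > 100.0:
            logger.debug("CALP > 100%% for pair (%s, %s): overlapping HSPs", q, s)
        out.append(
            AlignmentSummary(
                query_id=q,
                subject_id=s,
                al=al,
                total_identities=nid,
                query_length=qlen,
                cip=100.0 * nid / al,
                calp=calp,
                score=score,
            )
        )
    return out


def filter_conserved_pairs(
    summaries: Sequence[AlignmentSummary],
    species_of: Mapping[str, str],
    cip_min: float = 50.0,
    calp_min: float = 50.0,
    direction: str = "either",
) -> list[ConservedPair]:
    """Retain gene pairs meeting the CIP/CALP thresholds.

    ``direction="either"`` (default) keeps a pair when the thresholds are
    met with at least one of the two genes as query; ``"both"`` requires
    both directions to pass (a direction absent from ``summaries`` fails).
    Retained pairs carry the direction-maximal CIP, CALP and score.
    """
    if direction not in ("either", "both"):
        raise ValueError(f"direction must be 'either' or 'both', got {direction!r}")

    by_pair: dict[tuple[str, str], list[AlignmentSummary]] = {}
    for s in summaries:
        a, b = sorted((s.query_id, s.subject_id))
        by_pair.setdefault((a, b), []).append(s)

    out: list[ConservedPair] = []
    for (a, b), dirs in sorted(by_pair.items()):
        passing = [s for s in dirs if s.cip >= cip_min and s.calp >= calp_min]
        if direction == "either":
            ok = bool(passing)
        else:
            queries = {s.query_id for s in passing}
            ok = a in queries and b in queries
        if not ok:
            continue
        out.append(
            ConservedPair(
                gene_a=a,
                gene_b=b,
                species_a=species_of[a],
                species_b=species_of[b],
                cip=max(s.cip for s in dirs),
                calp=max(s.calp for s in dirs),
                score=max(s.score for s in dirs),
            )
        )
    return out
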