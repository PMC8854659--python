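"""Assign elements to genes within a flank of the coding span, and
cross-run summaries."""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

from .io import GeneModel, GenomicInterval

DEFAULT_FLANK = 10_000


@dataclasses.dataclass(frozen=True)
class ElementGeneAssignment:
    element_id: str
    gene_id: str
    #: signed gap in bp: 0 when the element overlaps the coding span,
    #: negative when the element lies left of the gene, positive when right
    distance: int


def map_elements_to_genes(
    elements: Iterable[GenomicInterval],
    genes: Sequence[GeneModel],
    flank: int = DEFAULT_FLANK,
) -> list[ElementGeneAssignment]:
    """Many-to-many assignment of elements to genes within ``flank`` bp.

    An element is assigned to every gene whose coding span lies within
    ``flank`` bp (gap <= flank; a gap of flank+1 is excluded).  Elements on
    chromosomes with no genes are simply unassigned.  Strand is ignored:
    the flank is symmetric.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    arrays = {}
    for chrom, gs in by_chrom.items():
        gs.sort(key=lambda g: (g.start, g.end))
        arrays[chrom] = (np.array([g.start for g in gs]),
                         np.array([g.end for g in gs]), gs)

    out: list[ElementGeneAssignment] = []
    for el in elements:
        if el.chrom not in arrays:
            continue
        starts, ends, gs = arrays[el.chrom]
        left_gap = starts - el.end    # >0: element entirely left of gene
        right_gap = el.start - ends   # >0: element entirely right of gene
        gap = np.maximum(0, np.maximum(left_gap, right_gap))
        for idx in np.nonzero(gap <= flank)[0]:
            if left_gap[idx] > 0:
                dist = -int(left_gap[idx])
            elif right_gap[idx] > 0:
                dist = int(right_gap[idx])
            else:
                dist = 0
            out.append(ElementGeneAssignment(
                el.name or f"{el.chrom}:{el.start}-{el.end}",
                gs[idx].gene_id, dist))
    return out


def unique_genes(assignments: Iterable[ElementGeneAssignment],
                 ) -> tuple[list[str], int]:
    """Deduplicated, sorted gene ids with their count."""
    ids = sorted({a.gene_id for a in assignments})
    return ids, len(ids)


@dataclasses.dataclass(frozen=True)
class OverlapSummary:
    shared: int
    total_calls: int
    fraction: float
    percent: int       # rounded for display, matching printed summaries


def overlap_between_runs(
    calls_a: Iterable[str],
    calls_b: Iterable[str],
    universe_a: Iterable[str] | None = None,
    universe_b: Iterable[str] | None = None,
) -> OverlapSummary:
    """Shared calls between two runs over the same element universe.

    The displayed percentage counts each run's calls once in the
    denominator: ``100 * shared / (|a| + |b|)``, rounded to the nearest
    whole percent; the exact fraction is also reported.
    """
    if universe_a is not None or universe_b is not None:
        if universe_a is None or universe_b is None or \
                set(universe_a) != set(universe_b):
            raise ValueError("runs were made over different element universes")
    a, b = set(calls_a), set(calls_b)
    shared = len(a & b)
    total = len(a) + len(b)
    fraction = shared / total if total else 0.0
    return OverlapSummary(shared, total, fraction,
                          int(np.floor(100.0 * fraction + 0.5)))
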