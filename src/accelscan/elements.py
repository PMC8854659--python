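"""Regularize conserved elements into fixed-width tiles and attach
per-tile multi-species alignments."""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

from .io import (ExtractedAlignment, GenomicInterval, MafBlock,
                 extract_interval_alignment)
from .phylo import MISSING_CHARS, NeutralModel

log = logging.getLogger(__name__)

DEFAULT_WIDTH = 50
DEFAULT_MIN_SPECIES = 3


@dataclasses.dataclass
class SplitElement:
    """A fixed-width fragment of a conserved element plus its alignment."""

    id: str
    chrom: str
    start: int
    end: int
    seqs: dict[str, str] | None = None
    presence: frozenset[str] = frozenset()
    covered: int = 0

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.id)


def merge_intervals(elements: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort and merge overlapping/adjacent-overlapping intervals per chrom."""
    merged: list[GenomicInterval] = []
    for iv in sorted(elements, key=lambda e: (e.chrom, e.start, e.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end,
                                             last.name)
        else:
            merged.append(iv)
    return merged


def split_elements(elements: Iterable[GenomicInterval],
                   width: int = DEFAULT_WIDTH) -> list[GenomicInterval]:
    """Tile each element with non-overlapping ``width``-bp fragments.

    Tiles are laid from the element start; a terminal remainder shorter than
    ``width`` is dropped.  Overlapping inputs are merged first, so no output
    tile crosses an element boundary and splitting is idempotent.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    tiles = []
    for element in merge_intervals(elements):
        parent = element.name or f"{element.chrom}:{element.start}-{element.end}"
        n_full = element.width // width
        for k in range(n_full):
            start = element.start + k * width
            tiles.append(GenomicInterval(element.chrom, start, start + width,
                                         f"{parent}.{k}"))
    tiles.sort(key=lambda t: (t.chrom, t.start))
    return tiles


def _presence(seqs: dict[str, str]) -> frozenset:
    return frozenset(sp for sp, seq in seqs.items()
                     if any(c not in MISSING_CHARS for c in seq))


def attach_alignments(
    tiles: Sequence[GenomicInterval],
    maf_blocks: Sequence[MafBlock],
    model: NeutralModel,
    ref_species: str,
    min_species: int = DEFAULT_MIN_SPECIES,
) -> tuple[list[SplitElement], int]:
    """Attach per-tile sub-alignments; drop under-covered tiles.

    Returns the retained tiles and the count of exclusions (tiles with no
    aligned data or fewer than ``min_species`` species present).
    """
    if min_species < 2:
        raise ValueError("min_species must be >= 2")
    species = model.leaf_names
    kept: list[SplitElement] = []
    n_excluded = 0
    for tile in tiles:
        extracted: ExtractedAlignment = extract_interval_alignment(
            maf_blocks, tile, species, ref_species)
        presence = _presence(extracted.seqs)
        if not extracted.has_data or len(presence) < min_species:
            n_excluded += 1
            continue
        kept.append(SplitElement(tile.name or f"{tile.chrom}:{tile.start}",
                                 tile.chrom, tile.start, tile.end,
                                 extracted.seqs, presence, extracted.covered))
    if n_excluded:
        log.info("excluded %d/%d tiles with <%d species or no data",
                 n_excluded, len(tiles), min_species)
    return kept, n_excluded
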