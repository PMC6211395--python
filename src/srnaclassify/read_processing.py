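"""Multimapper filtering and rRNA exclusion.

Reads mapping to more than ``max_mappings`` genomic loci (default 50) are
dropped entirely; a parallel subset keeps only uniquely mapping reads, so the
downstream cluster analyses can be run on the all-read and unique-read
populations independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .io_model import AnnotationTrack, MappedRead

DEFAULT_MAX_MAPPINGS = 50


@dataclass
class FilteredLibrary:
    """Reads surviving the multimapper filter, plus the unique subset."""

    all_reads: list[MappedRead] = field(default_factory=list)
    unique_reads: list[MappedRead] = field(default_factory=list)


def filter_multimappers(
    reads: list[MappedRead], max_mappings: int = DEFAULT_MAX_MAPPINGS
) -> FilteredLibrary:
    """Drop reads mapping to more than ``max_mappings`` loci.

    Returns both the retained reads (1 <= n_mappings <= max_mappings) and the
    uniquely mapping subset (n_mappings == 1).  Idempotent.
    """
    if max_mappings < 1:
        raise ValueError("max_mappings must be >= 1")
    kept = [r for r in reads if r.n_mappings <= max_mappings]
    unique = [r for r in kept if r.n_mappings == 1]
    return FilteredLibrary(all_reads=kept, unique_reads=unique)


def _build_trees(
    track: AnnotationTrack, stranded: bool
) -> dict:
    trees: dict = {}
    for scaffold, start, end, strand, _name in track:
        key = (scaffold, strand) if stranded else scaffold
        trees.setdefault(key, IntervalTree()).addi(start, end)
    return trees


def exclude_rrna(
    reads: list[MappedRead], rrna_track: AnnotationTrack, stranded: bool = False
) -> list[MappedRead]:
    """Remove reads overlapping an rRNA interval by >= 1 nt.

    Overlap is strand-agnostic by default (``stranded=True`` restricts removal
    to same-strand overlap).  Half-open intervals that merely abut do not
    overlap.
    """
    if not rrna_track.intervals:
        return list(reads)
    trees = _build_trees(rrna_track, stranded)
    out = []
    for r in reads:
        key = (r.scaffold, r.strand) if stranded else r.scaffold
        tree = trees.get(key)
        if tree is not None and tree.overlaps(r.start, r.end):
            continue
        out.append(r)
    return out
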