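"""Merging mapped reads into genomic clusters and the uniformity index.

A cluster is a run of read mappings on one scaffold in which consecutive
intervals are separated by at most ``window`` nt (single-linkage, transitive,
strand-agnostic).  Clusters must contain at least ``min_distinct`` distinct
reads that are not all perfectly overlapping, and span at least
``min_cluster_len`` bp.

The uniformity index (UI) of a cluster is its total read abundance divided by
its number of distinct reads.  miRNA-like loci emit a few highly abundant
reads (high UI); endo-siRNA and piRNA loci emit many individually rare reads
(UI near 1).  Because UI grows with sequencing depth, UI / library depth is
reported alongside for between-library comparison.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from .io_model import MappedRead

DEFAULT_WINDOW = 150
DEFAULT_MIN_DISTINCT = 3
DEFAULT_MIN_CLUSTER_LEN = 51
DEFAULT_HU_THRESHOLD = 3.0


@dataclass
class Cluster:
    scaffold: str
    start: int
    end: int
    reads: list[MappedRead] = field(default_factory=list)
    label: Optional[str] = None
    ui_normalized: Optional[float] = None
    context: Optional[str] = None
    fold: Optional[object] = None  # structure.FoldResult once folded

    @property
    def total_count(self) -> int:
        return sum(r.count for r in self.reads)

    @property
    def distinct_reads(self) -> int:
        return len({r.key for r in self.reads})

    @property
    def ui(self) -> float:
        return compute_uniformity_index(self)

    @property
    def length_histogram(self) -> dict[int, int]:
        hist: Counter = Counter()
        for r in self.reads:
            hist[r.length] += r.count
        return dict(hist)

    @property
    def strands_present(self) -> set[str]:
        return {r.strand for r in self.reads}

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def is_multi_mapping(self) -> bool:
        """True if any constituent read maps to more than one locus."""
        return any(r.n_mappings > 1 for r in self.reads)


def build_clusters(
    reads: list[MappedRead],
    window: int = DEFAULT_WINDOW,
    min_distinct: int = DEFAULT_MIN_DISTINCT,
    min_cluster_len: int = DEFAULT_MIN_CLUSTER_LEN,
) -> list[Cluster]:
    """Merge reads into clusters and apply the retention filters.

    Distinctness is on (scaffold, start, end, strand, sequence); a cluster
    whose distinct reads all share one interval (perfect overlap) is rejected
    regardless of their number.  Output is sorted by (scaffold, start) and
    independent of input order.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    by_scaffold: dict[str, list[MappedRead]] = {}
    for r in reads:
        by_scaffold.setdefault(r.scaffold, []).append(r)

    clusters: list[Cluster] = []
    for scaffold in sorted(by_scaffold):
        chunk = sorted(by_scaffold[scaffold], key=lambda r: (r.start, r.end, r.strand, r.sequence))
        current: list[MappedRead] = []
        cur_end = -1
        for r in chunk:
            if current and r.start - cur_end > window:
                clusters.append(Cluster(scaffold, current[0].start, cur_end, current))
                current = []
                cur_end = -1
            current.append(r)
            cur_end = max(cur_end, r.end)
        if current:
            clusters.append(Cluster(scaffold, current[0].start, cur_end, current))

    kept = []
    for c in clusters:
        keys = {r.key for r in c.reads}
        if len(keys) < min_distinct:
            continue
        if min_distinct >= 2 and len({(k[1], k[2]) for k in keys}) < 2:
            continue  # all distinct reads perfectly overlap
        if c.span < min_cluster_len:
            continue
        kept.append(c)
    return kept


def compute_uniformity_index(cluster: Cluster) -> float:
    """UI = total abundance / number of distinct reads (>= 1 by construction)."""
    distinct = cluster.distinct_reads
    if distinct == 0:
        raise ValueError("uniformity index undefined for a cluster with no reads")
    return cluster.total_count / distinct


def normalize_ui(ui: float, library_depth: int) -> float:
    """Depth-normalised UI (UI / depth), comparable across libraries."""
    if library_depth <= 0:
        raise ValueError("library depth must be > 0")
    return ui / library_depth


def segregate_hu_lu(
    clusters: list[Cluster],
    threshold: float = DEFAULT_HU_THRESHOLD,
    quantile: Optional[float] = None,
) -> tuple[list[Cluster], list[Cluster]]:
    """Partition clusters into high-uniformity (UI >= threshold) and the rest.

    With ``quantile`` (e.g. 0.05), the threshold is instead the (1-q) quantile
    of the UI distribution of this cluster set, which is robust to depth.
    """
    if quantile is not None:
        import numpy as np

        if not clusters:
            return [], []
        threshold = float(np.quantile([c.ui for c in clusters], 1.0 - quantile))
    elif threshold <= 1:
        raise ValueError("HU threshold must be > 1")
    hu = [c for c in clusters if c.ui >= threshold]
    lu = [c for c in clusters if c.ui < threshold]
    return hu, lu
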