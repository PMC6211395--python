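"""Genomic context of clusters: element attribution, coverage, enrichment,
and cis-natural antisense transcript (cis-NAT) prediction.

A cluster is attributed to a genomic element class when at least 51% of its
length overlaps the union of that class's intervals; every class meeting the
threshold is recorded (a region can encode several element types, so
per-class percentages may total slightly over 100), and a cluster meeting
none is intergenic.  Genic tracks are first masked by transposons: any exon,
intron or UTR interval overlapping a predicted transposon by >= 1 nt is
removed, so transposon-derived clusters are not also counted as genic.

Enrichment of cluster/reference overlap is tested by a length-preserving
permutation null: cluster intervals are replaced uniformly at random within
their scaffolds and the overlap count recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .clustering import Cluster
from .io_model import AnnotationTrack

DEFAULT_MIN_FRACTION = 0.51

CONTEXT_CLASSES = (
    "exon",
    "utr5",
    "utr3",
    "intron",
    "transposon_known",
    "transposon_unknown",
)

#: precedence for the single-label context summary
CONTEXT_PRECEDENCE = (
    "exon",
    "utr5",
    "utr3",
    "intron",
    "transposon_known",
    "transposon_unknown",
)


@dataclass
class ContextAssignment:
    cluster_id: str
    element_classes: list[str] = field(default_factory=list)
    overlap_fractions: dict[str, float] = field(default_factory=dict)

    @property
    def primary(self) -> str:
        for cls in CONTEXT_PRECEDENCE:
            if cls in self.element_classes:
                return cls
        return "intergenic"

    @property
    def is_intergenic(self) -> bool:
        return not self.element_classes


def _merge(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _merged_by_scaffold(track: AnnotationTrack) -> dict[str, list[tuple[int, int]]]:
    per: dict[str, list[tuple[int, int]]] = {}
    for scaffold, start, end, _strand, _name in track:
        per.setdefault(scaffold, []).append((start, end))
    return {k: _merge(v) for k, v in per.items()}


def _overlap_bp(start: int, end: int, merged: list[tuple[int, int]]) -> int:
    bp = 0
    for s, e in merged:
        if s >= end:
            break
        if e > start:
            bp += min(end, e) - max(start, s)
    return bp


def mask_genic_by_transposon(
    tracks: dict[str, AnnotationTrack]
) -> dict[str, AnnotationTrack]:
    """Remove genic intervals overlapping any transposon interval by >= 1 nt.

    Applies to exon, intron, utr5 and utr3 tracks; other tracks pass through
    unchanged.  Returns a new track dict.
    """
    transposons: list = []
    for cls in ("transposon_known", "transposon_unknown"):
        if cls in tracks:
            transposons.extend(tracks[cls].intervals)
    if not transposons:
        return dict(tracks)
    tn = _merged_by_scaffold(AnnotationTrack("transposon_known", transposons))
    out = {}
    for cls, track in tracks.items():
        if cls not in ("exon", "intron", "utr5", "utr3"):
            out[cls] = track
            continue
        kept = [
            iv
            for iv in track.intervals
            if _overlap_bp(iv[1], iv[2], tn.get(iv[0], [])) == 0
        ]
        out[cls] = AnnotationTrack(cls, kept)
    return out


def assign_context(
    cluster: Cluster,
    tracks: dict[str, AnnotationTrack],
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> ContextAssignment:
    """Attribute a cluster to every element class covering >= min_fraction
    of its span (class-union overlap); none qualifying means intergenic."""
    cid = f"{cluster.scaffold}:{cluster.start}-{cluster.end}"
    assignment = ContextAssignment(cid)
    span = cluster.span
    for cls in CONTEXT_CLASSES:
        track = tracks.get(cls)
        if track is None or not track.intervals:
            continue
        merged = _merged_by_scaffold(track).get(cluster.scaffold, [])
        frac = _overlap_bp(cluster.start, cluster.end, merged) / span
        if (frac >= min_fraction and min_fraction > 0) or (
            min_fraction == 0 and frac > 0
        ):
            assignment.element_classes.append(cls)
            assignment.overlap_fractions[cls] = frac
    cluster.context = assignment.primary
    return assignment


def genome_coverage(
    tracks: dict[str, AnnotationTrack], genome_lengths: dict[str, int]
) -> pd.DataFrame:
    """Percentage of genome bp covered by each track's interval union."""
    total = sum(genome_lengths.values())
    rows = {}
    for cls, track in tracks.items():
        bp = 0
        for scaffold, merged in _merged_by_scaffold(track).items():
            if scaffold not in genome_lengths:
                raise ValueError(f"interval on unknown scaffold {scaffold!r}")
            if merged and merged[-1][1] > genome_lengths[scaffold]:
                raise ValueError(
                    f"interval beyond end of scaffold {scaffold!r} "
                    f"({merged[-1][1]} > {genome_lengths[scaffold]})"
                )
            bp += sum(e - s for s, e in merged)
        rows[cls] = 100.0 * bp / total
    return pd.DataFrame.from_dict(rows, orient="index", columns=["genome_pct"])


def context_summary(
    assignments_by_class: dict[str, list[ContextAssignment]]
) -> pd.DataFrame:
    """Per cluster class, percentage of clusters attributed to each element.

    Multi-assignment means rows can total slightly over 100%.
    """
    rows = {}
    cols = list(CONTEXT_CLASSES) + ["intergenic"]
    for cls, assignments in assignments_by_class.items():
        n = len(assignments)
        row = {c: 0.0 for c in cols}
        for a in assignments:
            if a.is_intergenic:
                row["intergenic"] += 1
            else:
                for ec in a.element_classes:
                    row[ec] += 1
        rows[cls] = {c: (100.0 * v / n if n else 0.0) for c, v in row.items()}
    return pd.DataFrame.from_dict(rows, orient="index")[cols]


def overlap_enrichment_test(
    clusters: Sequence[Cluster],
    reference_loci: AnnotationTrack,
    genome_lengths: dict[str, int],
    n_permutations: int = 1000,
    rng_seed: int = 0,
) -> tuple[int, float]:
    """Permutation test of cluster / reference-locus overlap.

    Observed statistic: number of clusters overlapping >= 1 reference locus
    by >= 1 nt.  Null: each cluster interval is placed uniformly at random
    within its scaffold (length preserved), ``n_permutations`` times.
    Returns (observed, p) with the add-one p-value convention.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    ref = _merged_by_scaffold(reference_loci)
    # flatten reference per scaffold into sorted edge arrays for searchsorted
    edges = {
        scaffold: (
            np.array([s for s, _ in merged]),
            np.array([e for _, e in merged]),
        )
        for scaffold, merged in ref.items()
    }

    def overlaps_any(scaffold: str, starts: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        if scaffold not in edges:
            return np.zeros(starts.shape, dtype=bool)
        ref_s, ref_e = edges[scaffold]
        ends = starts + lengths
        # a cluster overlaps some interval iff the first interval with
        # end > cluster.start also has start < cluster.end
        idx = np.searchsorted(ref_e, starts, side="right")
        valid = idx < len(ref_s)
        hit = np.zeros(starts.shape, dtype=bool)
        hit[valid] = ref_s[np.minimum(idx[valid], len(ref_s) - 1)] < ends[valid]
        return hit

    rng = np.random.default_rng(rng_seed)
    by_scaffold: dict[str, list[int]] = {}
    observed = 0
    for c in clusters:
        L = c.span
        scaffold_len = genome_lengths.get(c.scaffold, 0)
        if L > scaffold_len:
            import warnings

            warnings.warn(
                f"cluster {c.scaffold}:{c.start}-{c.end} longer than scaffold; skipped"
            )
            continue
        by_scaffold.setdefault(c.scaffold, []).append(L)
        if overlaps_any(c.scaffold, np.array([c.start]), np.array([L]))[0]:
            observed += 1

    null = np.zeros(n_permutations, dtype=int)
    for scaffold, lengths in by_scaffold.items():
        lengths_arr = np.array(lengths)
        max_start = genome_lengths[scaffold] - lengths_arr  # inclusive
        starts = rng.integers(
            0, max_start[None, :] + 1, size=(n_permutations, len(lengths))
        )
        hits = np.zeros((n_permutations, len(lengths)), dtype=bool)
        for j in range(len(lengths)):
            hits[:, j] = overlaps_any(
                scaffold, starts[:, j], np.full(n_permutations, lengths_arr[j])
            )
        null += hits.sum(axis=1)

    p = (1 + int((null >= observed).sum())) / (n_permutations + 1)
    return observed, p


def predict_cis_nats(gene_models: AnnotationTrack) -> set[str]:
    """Genes overlapping a gene on the opposite strand by >= 1 nt.

    Returns the names of all partners; the relation is symmetric.
    """
    per_scaffold: dict[str, list] = {}
    for iv in gene_models:
        per_scaffold.setdefault(iv[0], []).append(iv)
    cis: set[str] = set()
    for ivs in per_scaffold.values():
        ivs = sorted(ivs, key=lambda x: x[1])
        for i, a in enumerate(ivs):
            for b in ivs[i + 1 :]:
                if b[1] >= a[2]:
                    break
                if a[3] != b[3]:
                    cis.add(a[4])
                    cis.add(b[4])
    return cis


def cis_nat_srna_fraction(
    unique_endo_clusters: Sequence[Cluster],
    gene_models: AnnotationTrack,
    cis_nat_set: Optional[set[str]] = None,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> tuple[float, float]:
    """(fraction of genes that are cis-NAT, fraction of coding-gene-aligned
    unique endo-siRNA clusters whose gene is cis-NAT).

    A cluster is coding-gene-aligned when >= ``min_fraction`` of its span
    overlaps the gene-model union; it counts as cis-NAT-derived when any
    overlapping gene is in the cis-NAT set.
    """
    if cis_nat_set is None:
        cis_nat_set = predict_cis_nats(gene_models)
    names = {iv[4] for iv in gene_models}
    gene_fraction = len(cis_nat_set) / len(names) if names else 0.0

    merged = _merged_by_scaffold(gene_models)
    per_scaffold: dict[str, list] = {}
    for iv in gene_models:
        per_scaffold.setdefault(iv[0], []).append(iv)

    aligned = 0
    cis_aligned = 0
    for c in unique_endo_clusters:
        frac = _overlap_bp(c.start, c.end, merged.get(c.scaffold, [])) / c.span
        if frac < min_fraction:
            continue
        aligned += 1
        for iv in per_scaffold.get(c.scaffold, []):
            if iv[1] < c.end and iv[2] > c.start and iv[4] in cis_nat_set:
                cis_aligned += 1
                break
    cluster_fraction = cis_aligned / aligned if aligned else 0.0
    return gene_fraction, cluster_fraction
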