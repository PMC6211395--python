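"""Cluster class assignment.

Clusters overlapping known miRNA / tRNA / snoRNA annotation are labelled by
overlap (precedence known_miRNA > tRNA > snoRNA).  The remainder are
classified from the read-length composition: a cluster whose modal read
length L falls in a class's peak set, and whose summed abundance over
L-1..L+1 strictly exceeds the summed abundance of all other lengths, is
assigned that class.  Peak sets are species presets:

========== =========== ============ ==========
preset     endo-siRNA  piRNA        25-mer
========== =========== ============ ==========
drosophila 20,21,22    24,25,26     —
nonbilaterian 20,21,22 26,27,28     —
mnemiopsis 20,21,22    26,27,28     24,25,26
========== =========== ============ ==========

Dicer-length clusters with a high uniformity index are routed to
``miRNA_candidate_HU`` rather than endo_siRNA, since high-uniformity loci at
those lengths are dominated by miRNA-like, tRNA, snoRNA and rDNA loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd
from intervaltree import IntervalTree

from .clustering import Cluster, DEFAULT_HU_THRESHOLD, segregate_hu_lu
from .io_model import AnnotationTrack


@dataclass
class ClassConfig:
    """Peak sets and options for length-peak classification."""

    endo_peaks: frozenset[int] = frozenset({20, 21, 22})
    pirna_peaks: frozenset[int] = frozenset({26, 27, 28})
    mer25_peaks: frozenset[int] = frozenset()
    peak_halo: int = 1
    apply_hu_filter: bool = True


PRESETS: dict[str, ClassConfig] = {
    "drosophila": ClassConfig(pirna_peaks=frozenset({24, 25, 26})),
    "nonbilaterian": ClassConfig(),
    "mnemiopsis": ClassConfig(mer25_peaks=frozenset({24, 25, 26})),
}


def get_preset(name: str) -> ClassConfig:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None


def peak_length(length_histogram: dict[int, int]) -> int:
    """Modal read length by summed count; ties break toward the shorter length."""
    if not length_histogram:
        raise ValueError("empty length histogram")
    best = max(length_histogram.values())
    return min(l for l, c in length_histogram.items() if c == best)


def _halo_sum(hist: dict[int, int], center: int, halo: int) -> int:
    return sum(c for l, c in hist.items() if abs(l - center) <= halo)


def classify_by_peak(
    cluster: Cluster,
    config: ClassConfig,
    is_hu: bool = False,
) -> str:
    """Length-peak classification of a single (unannotated) cluster.

    The dominance rule uses strict inequality: the peak +/- halo sum must
    exceed the summed abundance of every other length; equality leaves the
    cluster unclassified.  Where a preset makes two classes eligible for the
    same modal length (25-mer vs piRNA at 26 nt), the class whose full peak
    set carries more summed abundance wins, ties to piRNA.
    """
    hist = cluster.length_histogram
    L = peak_length(hist)
    halo = _halo_sum(hist, L, config.peak_halo)
    others = cluster.total_count - halo
    if halo <= others:
        return "unclassified"

    eligible = []
    if L in config.endo_peaks:
        eligible.append("endo_siRNA")
    if L in config.pirna_peaks:
        eligible.append("piRNA")
    if L in config.mer25_peaks:
        eligible.append("mer25")

    if not eligible:
        return "unclassified"
    if len(eligible) > 1:
        if set(eligible) == {"piRNA", "mer25"}:
            pirna_mass = sum(hist.get(l, 0) for l in config.pirna_peaks)
            mer25_mass = sum(hist.get(l, 0) for l in config.mer25_peaks)
            label = "mer25" if mer25_mass > pirna_mass else "piRNA"
        else:  # overlapping peak sets are rejected by preset validation
            label = eligible[0]
    else:
        label = eligible[0]

    if label == "endo_siRNA" and config.apply_hu_filter and is_hu:
        return "miRNA_candidate_HU"
    return label


_ANNOT_PRECEDENCE = ("known_miRNA", "tRNA", "snoRNA")


def annotate_known_loci(
    clusters: list[Cluster], tracks: dict[str, AnnotationTrack]
) -> list[Cluster]:
    """Label clusters overlapping known miRNA / tRNA / snoRNA loci (>= 1 nt).

    Labelled clusters bypass length-peak classification.  Returns the input
    list with labels set in place.
    """
    trees: dict[str, dict[str, IntervalTree]] = {}
    for cls in _ANNOT_PRECEDENCE:
        track = tracks.get(cls)
        if track is None:
            continue
        per_scaffold: dict[str, IntervalTree] = {}
        for scaffold, start, end, _strand, _name in track:
            per_scaffold.setdefault(scaffold, IntervalTree()).addi(start, end)
        trees[cls] = per_scaffold
    for c in clusters:
        for cls in _ANNOT_PRECEDENCE:
            tree = trees.get(cls, {}).get(c.scaffold)
            if tree is not None and tree.overlaps(c.start, c.end):
                c.label = cls
                break
    return clusters


def classify_clusters(
    clusters: list[Cluster],
    config: ClassConfig,
    tracks: Optional[dict[str, AnnotationTrack]] = None,
    hu_threshold: float = DEFAULT_HU_THRESHOLD,
) -> list[Cluster]:
    """Full classification: known-locus annotation, HU segregation, peaks."""
    annotate_known_loci(clusters, tracks or {})
    hu, _lu = segregate_hu_lu(clusters, threshold=hu_threshold)
    hu_set = set(map(id, hu))
    for c in clusters:
        if c.label is None:
            c.label = classify_by_peak(c, config, is_hu=id(c) in hu_set)
    return clusters


def tabulate_classes(
    clusters_by_library: dict[str, list[Cluster]]
) -> pd.DataFrame:
    """Per-library class counts in the unique / multi-mapping split.

    A multi-mapping cluster contains at least one read with n_mappings > 1;
    all other clusters are unique.  The miRNA column counts known miRNAs plus
    high-uniformity miRNA candidates.
    """
    rows = []
    for lib, clusters in clusters_by_library.items():
        row = {
            "library": lib,
            "miRNA": 0,
            "unique_endo_siRNA": 0,
            "multi_endo_siRNA": 0,
            "unique_piRNA": 0,
            "multi_piRNA": 0,
            "mer25": 0,
        }
        for c in clusters:
            multi = c.is_multi_mapping
            if c.label in ("known_miRNA", "miRNA_candidate_HU"):
                row["miRNA"] += 1
            elif c.label == "endo_siRNA":
                row["multi_endo_siRNA" if multi else "unique_endo_siRNA"] += 1
            elif c.label == "piRNA":
                row["multi_piRNA" if multi else "unique_piRNA"] += 1
            elif c.label == "mer25":
                row["mer25"] += 1
        rows.append(row)
    return pd.DataFrame(rows).set_index("library")
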