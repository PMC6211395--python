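"""Developmental co-expression links between cluster loci.

Clusters are called per developmental stage; loci are matched across stages
by >= 1 nt span overlap (connected components over all stages).  A link is
emitted for every unordered stage pair in which the same locus expresses an
endo-siRNA or piRNA cluster at or above ``min_expression`` reads, so a locus
expressed in k stages yields C(k, 2) links.  The link table follows the
Circos link convention (two scaffold spans per row).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .clustering import Cluster

LINK_CLASSES = ("endo_siRNA", "piRNA")


@dataclass(frozen=True)
class StageLink:
    locus_id: str
    scaffold: str
    start: int
    end: int
    stage_a: str
    stage_b: str
    count_a: int
    count_b: int

    def __post_init__(self) -> None:
        if self.stage_a == self.stage_b:
            raise ValueError("a link must join two different stages")


def _merge_loci(
    clusters_by_stage: dict[str, list[Cluster]]
) -> list[tuple[str, int, int]]:
    """Merge cluster spans from all stages into loci by >= 1 nt overlap."""
    per_scaffold: dict[str, list[tuple[int, int]]] = {}
    for clusters in clusters_by_stage.values():
        for c in clusters:
            per_scaffold.setdefault(c.scaffold, []).append((c.start, c.end))
    loci = []
    for scaffold in sorted(per_scaffold):
        ivs = sorted(per_scaffold[scaffold])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s < cur_e:  # strict overlap; abutting spans are distinct loci
                cur_e = max(cur_e, e)
            else:
                loci.append((scaffold, cur_s, cur_e))
                cur_s, cur_e = s, e
        loci.append((scaffold, cur_s, cur_e))
    return loci


def coexpression_links(
    clusters_by_stage: dict[str, list[Cluster]],
    min_expression: int = 1,
    link_classes: Sequence[str] = LINK_CLASSES,
    class_matched: bool = True,
) -> list[StageLink]:
    """Links between stages co-expressing a cluster at the same locus.

    Only clusters labelled with one of ``link_classes`` participate.  With
    ``class_matched`` (default) the two stages must express the same class at
    the locus; otherwise any class pair links.  Stage order within a link is
    canonical: the order of the keys of ``clusters_by_stage``.
    """
    stage_order = {s: i for i, s in enumerate(clusters_by_stage)}
    filtered = {
        stage: [c for c in clusters if c.label in link_classes]
        for stage, clusters in clusters_by_stage.items()
    }
    loci = _merge_loci(filtered)

    links: list[StageLink] = []
    for scaffold, s, e in loci:
        # per stage: total count and classes expressed at this locus
        expr: dict[str, dict[str, int]] = {}
        for stage, clusters in filtered.items():
            for c in clusters:
                if c.scaffold == scaffold and c.start < e and c.end > s:
                    expr.setdefault(stage, {})
                    expr[stage][c.label] = expr[stage].get(c.label, 0) + c.total_count
        stages = [
            st
            for st, by_class in expr.items()
            if any(v >= min_expression for v in by_class.values())
        ]
        stages.sort(key=stage_order.get)
        locus_id = f"{scaffold}:{s}-{e}"
        for a, b in combinations(stages, 2):
            if class_matched:
                shared = {
                    cls
                    for cls in expr[a]
                    if expr[a][cls] >= min_expression
                    and expr[b].get(cls, 0) >= min_expression
                }
                if not shared:
                    continue
                count_a = sum(expr[a][cls] for cls in shared)
                count_b = sum(expr[b][cls] for cls in shared)
            else:
                count_a = sum(expr[a].values())
                count_b = sum(expr[b].values())
            links.append(StageLink(locus_id, scaffold, s, e, a, b, count_a, count_b))
    return links


def restrict_to_scaffolds(
    links: Iterable[StageLink],
    scaffold_lengths: dict[str, int],
    top_n_scaffolds: int,
) -> list[StageLink]:
    """Keep links on the ``top_n_scaffolds`` longest scaffolds."""
    ranked = sorted(scaffold_lengths, key=lambda k: (-scaffold_lengths[k], k))
    keep = set(ranked[:top_n_scaffolds])
    return [l for l in links if l.scaffold in keep]


def write_links(links: Iterable[StageLink], path) -> None:
    """Circos-style link TSV: both spans plus stage labels and counts."""
    with open(path, "w") as fh:
        fh.write(
            "scaffold\tstart\tend\tscaffold_b\tstart_b\tend_b\t"
            "stage_a\tstage_b\tcount_a\tcount_b\n"
        )
        for l in links:
            fh.write(
                f"{l.scaffold}\t{l.start}\t{l.end}\t{l.scaffold}\t{l.start}\t{l.end}\t"
                f"{l.stage_a}\t{l.stage_b}\t{l.count_a}\t{l.count_b}\n"
            )
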