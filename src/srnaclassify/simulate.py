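"""Synthetic genomes, annotation tracks and small-RNA libraries.

The generator plants loci with the statistical structure that separates the
small-RNA classes in real libraries:

* miRNA-like loci: imperfect hairpin cassettes emitting one dominant mature
  sequence plus rare length/offset variants, so the uniformity index is high;
* endo-siRNA-like loci: hairpins emitting many distinct, individually rare
  20-22 nt reads from both strands (low uniformity, structured precursor);
* piRNA-like loci: unstructured regions emitting diverse 26-28 nt reads with
  an enforced 5' uridine bias, position-10 adenosine bias and a downstream
  guanosine tail, the ping-pong-era signatures;
* 25-mer loci: diverse 24-26 nt reads with a 5' uridine bias only.

Multimapping is created by literal sequence duplication (transposon copies),
so the mapping multiplicity of every read equals its exact occurrence count
in the genome and needs no aligner.  All randomness is seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_model import (
    AnnotationTrack,
    Library,
    MappedRead,
    reverse_complement_dna,
)

_DNA = np.array(list("ACGT"))


@dataclass
class SimSpec:
    """Study conditions for one synthetic dataset.

    Frequencies are fractions in [0, 1]; lengths in nt; counts in reads.
    """

    rng_seed: int = 1
    n_scaffolds: int = 3
    scaffold_length: int = 50_000

    n_mirna: int = 10
    mirna_known_fraction: float = 0.5
    mirna_dominant_count: int = 120
    mirna_n_variants: int = 5

    n_endo: int = 12
    endo_reads_per_locus: int = 30
    endo_lengths: tuple[int, ...] = (20, 21, 22)

    n_pirna: int = 12
    pirna_reads_per_locus: int = 60
    pirna_lengths: tuple[int, ...] = (26, 27, 28)
    pirna_u1_freq: float = 0.8
    pirna_a10_freq: float = 0.6
    pirna_downstream_g: bool = True

    n_mer25: int = 6
    mer25_reads_per_locus: int = 40
    mer25_lengths: tuple[int, ...] = (24, 25, 26)
    mer25_u1_freq: float = 0.8

    n_trna: int = 2
    n_rrna: int = 2

    n_genes: int = 12
    n_cisnat_pairs: int = 4

    transposon_copy_number: int = 4
    transposon_classes: tuple[str, ...] = ("piRNA", "endo_siRNA")

    stages: tuple[str, ...] = ("s1", "s2", "s3", "s4")
    stage_expression_prob: float = 0.7

    def validate(self) -> None:
        for f in (
            self.mirna_known_fraction,
            self.pirna_u1_freq,
            self.pirna_a10_freq,
            self.mer25_u1_freq,
            self.stage_expression_prob,
        ):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency {f} outside [0, 1]")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_DNA[rng.integers(0, 4, n)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = str(_DNA[rng.integers(0, 4)])
    return "".join(chars)


def _hairpin(rng: np.random.Generator, arm: int, loop: int, mismatch: float) -> str:
    """arm + loop + (imperfectly) reverse-complemented arm."""
    a = _random_dna(rng, arm)
    return a + _random_dna(rng, loop) + _mutate(rng, reverse_complement_dna(a), mismatch)


_PIRNA_ANCHOR_STEP = 7
_MER25_ANCHOR_STEP = 5


def _pirna_region(rng: np.random.Generator, n: int, downstream_g: bool) -> str:
    """Random DNA with T/A/G anchors every 7 nt (read-relative 1U, 10A, 26G)."""
    chars = list(_random_dna(rng, n))
    for a in range(0, n - 30, _PIRNA_ANCHOR_STEP):
        chars[a] = "T"
        chars[a + 9] = "A"
        if downstream_g:
            chars[a + 25] = "G"
            chars[a + 26] = "G"
    return "".join(chars)


def _mer25_region(rng: np.random.Generator, n: int) -> str:
    chars = list(_random_dna(rng, n))
    for a in range(0, n - 28, _MER25_ANCHOR_STEP):
        chars[a] = "T"
    return "".join(chars)


TRUTH_COLUMNS = ["scaffold", "start", "end", "class", "known", "multi", "family"]


def simulate_genome(
    spec: SimSpec,
) -> tuple[dict[str, str], dict[str, AnnotationTrack], pd.DataFrame]:
    """Build a genome with planted loci; returns (genome, tracks, truth).

    ``truth`` has one row per planted locus copy with its class, whether it
    is in the known-miRNA track, whether it is a multimapper (transposon
    copy), and a family id shared by copies of one transposon.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)

    # cassettes to place: (kind, payload) where payload carries the DNA and
    # the read-generating sub-interval relative to cassette start
    cassettes: list[dict] = []

    for i in range(spec.n_mirna):
        dna = _hairpin(rng, arm=30, loop=15, mismatch=0.15)
        known = i < round(spec.n_mirna * spec.mirna_known_fraction)
        cassettes.append(
            {"kind": "miRNA", "dna": dna, "sub": (0, len(dna)), "known": known}
        )
    for _ in range(spec.n_endo):
        dna = _hairpin(rng, arm=55, loop=10, mismatch=0.1)
        cassettes.append({"kind": "endo_siRNA", "dna": dna, "sub": (0, len(dna))})
    for _ in range(spec.n_pirna):
        dna = _pirna_region(rng, 400, spec.pirna_downstream_g)
        cassettes.append({"kind": "piRNA", "dna": dna, "sub": (0, len(dna))})
    for _ in range(spec.n_mer25):
        dna = _mer25_region(rng, 300)
        cassettes.append({"kind": "mer25", "dna": dna, "sub": (0, len(dna))})
    for _ in range(spec.n_trna):
        dna = _random_dna(rng, 80)
        cassettes.append({"kind": "tRNA", "dna": dna, "sub": (0, len(dna))})
    for _ in range(spec.n_rrna):
        dna = _random_dna(rng, 500)
        cassettes.append({"kind": "rRNA", "dna": dna, "sub": (0, len(dna))})

    # transposon families: consensus with an embedded read-generating region,
    # pasted copy_number times to create exact multimappers
    for fam_idx, cls in enumerate(spec.transposon_classes):
        if cls == "piRNA":
            region = _pirna_region(rng, 400, spec.pirna_downstream_g)
        elif cls == "endo_siRNA":
            region = _hairpin(rng, arm=55, loop=10, mismatch=0.1)
        else:
            raise ValueError(f"unsupported transposon class {cls!r}")
        pad5, pad3 = _random_dna(rng, 100), _random_dna(rng, 100)
        consensus = pad5 + region + pad3
        for copy in range(spec.transposon_copy_number):
            cassettes.append(
                {
                    "kind": cls,
                    "dna": consensus,
                    "sub": (100, 100 + len(region)),
                    "family": f"TE{fam_idx}",
                    "copy": copy,
                    "transposon": True,
                }
            )

    for g in range(spec.n_genes):
        parts = [
            ("utr5", _random_dna(rng, 120)),
            ("exon", _random_dna(rng, 250)),
            ("intron", _random_dna(rng, 150)),
            ("exon", _random_dna(rng, 250)),
            ("utr3", _random_dna(rng, 120)),
        ]
        cassettes.append(
            {
                "kind": "gene",
                "dna": "".join(p[1] for p in parts),
                "parts": parts,
                "strand": "+" if rng.random() < 0.5 else "-",
                "name": f"gene{g}",
            }
        )
    for p in range(spec.n_cisnat_pairs):
        # two single-exon genes on opposite strands overlapping by 200 nt,
        # with an endo-siRNA hairpin planted inside the overlap
        hair = _hairpin(rng, arm=55, loop=10, mismatch=0.1)
        pre = _random_dna(rng, 500)
        overlap = _random_dna(rng, 40) + hair + _random_dna(rng, 40)
        post = _random_dna(rng, 500)
        dna = pre + overlap + post
        cassettes.append(
            {
                "kind": "cisnat_pair",
                "dna": dna,
                "sub": (540, 540 + len(hair)),
                "genes": [
                    (0, 500 + len(overlap), "+", f"cisnatA{p}"),
                    (500, len(dna), "-", f"cisnatB{p}"),
                ],
            }
        )

    order = rng.permutation(len(cassettes))
    scaffolds = {f"scaffold_{i+1}": [] for i in range(spec.n_scaffolds)}
    cursors = {name: 0 for name in scaffolds}
    placements: list[tuple[dict, str, int]] = []
    names = list(scaffolds)
    for j, idx in enumerate(order):
        cas = cassettes[idx]
        name = names[j % len(names)]
        gap = int(rng.integers(200, 600))
        start = cursors[name] + gap
        if start + len(cas["dna"]) > spec.scaffold_length:
            raise ValueError("planted loci exceed genome size; enlarge scaffolds")
        scaffolds[name].append((_random_dna(rng, gap), cas["dna"]))
        placements.append((cas, name, start))
        cursors[name] = start + len(cas["dna"])

    genome = {}
    for name in names:
        body = "".join(g + d for g, d in scaffolds[name])
        tail = spec.scaffold_length - len(body)
        genome[name] = body + _random_dna(rng, tail)

    tracks: dict[str, list] = {
        cls: []
        for cls in (
            "exon",
            "intron",
            "utr5",
            "utr3",
            "transposon_known",
            "transposon_unknown",
            "rRNA",
            "tRNA",
            "snoRNA",
            "known_miRNA",
            "gene_model",
        )
    }
    truth_rows = []
    for cas, scaffold, start in placements:
        end = start + len(cas["dna"])
        kind = cas["kind"]
        if kind == "gene":
            pos = start
            tracks["gene_model"].append(
                (scaffold, start, end, cas["strand"], cas["name"])
            )
            for part_cls, part_dna in cas["parts"]:
                tracks[part_cls].append(
                    (scaffold, pos, pos + len(part_dna), cas["strand"], cas["name"])
                )
                pos += len(part_dna)
            continue
        if kind == "cisnat_pair":
            for gs, ge, strand, gname in cas["genes"]:
                tracks["gene_model"].append(
                    (scaffold, start + gs, start + ge, strand, gname)
                )
                tracks["exon"].append((scaffold, start + gs, start + ge, strand, gname))
            s0, s1 = cas["sub"]
            truth_rows.append(
                [scaffold, start + s0, start + s1, "endo_siRNA", False, False, ""]
            )
            continue
        if cas.get("transposon"):
            fam = cas["family"]
            tracks["transposon_known"].append((scaffold, start, end, "+", fam))
        if kind in ("rRNA", "tRNA"):
            tracks[kind].append((scaffold, start, end, "+", kind))
        if kind == "miRNA" and cas.get("known"):
            tracks["known_miRNA"].append((scaffold, start, end, "+", "mir"))
        s0, s1 = cas["sub"]
        truth_rows.append(
            [
                scaffold,
                start + s0,
                start + s1,
                kind,
                bool(cas.get("known", False)),
                bool(cas.get("transposon", False)),
                cas.get("family", ""),
            ]
        )

    track_objs = {
        cls: AnnotationTrack(cls, ivs) for cls, ivs in tracks.items()
    }
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return genome, track_objs, truth


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------

def count_genome_occurrences(sequence_dna: str, genome: dict[str, str]) -> int:
    """Exact occurrence count of a read sequence across both genome strands."""
    return len(find_genome_occurrences(sequence_dna, genome))


def find_genome_occurrences(
    sequence_dna: str, genome: dict[str, str]
) -> list[tuple[str, int, str]]:
    """All (scaffold, start, strand) at which the read sequence occurs.

    A minus-strand occurrence is a match of the reverse complement on the
    forward genome string.
    """
    rc = reverse_complement_dna(sequence_dna)
    sites = []
    for scaffold, seq in genome.items():
        for query, strand in ((sequence_dna, "+"), (rc, "-")):
            if strand == "-" and rc == sequence_dna:
                continue  # palindromic read: both strands are the same match
            pos = seq.find(query)
            while pos != -1:
                sites.append((scaffold, pos, strand))
                pos = seq.find(query, pos + 1)
    return sites


def _weighted_choice(rng, values: tuple[int, ...]) -> int:
    # middle value twice as likely: peaked length distribution
    w = np.ones(len(values))
    w[len(values) // 2] = 2.0
    return int(rng.choice(values, p=w / w.sum()))


def simulate_library(
    spec: SimSpec, genome: dict[str, str], truth: pd.DataFrame
) -> dict[str, Library]:
    """Draw per-stage read populations from the planted loci.

    Each locus family is expressed in a random subset of stages (each stage
    with probability ``stage_expression_prob``, at least one).  Reads are
    exact genome substrings; each read record carries the occurrence count of
    its sequence as ``n_mappings`` and one record is emitted per occurrence.
    """
    rng = np.random.default_rng(spec.rng_seed + 1)

    # one generating unit per locus; transposon families generate from their
    # first copy only (the sequence is identical at every copy)
    units = []
    seen_families: set[str] = set()
    for row in truth.to_dict("records"):
        if row["family"]:
            if row["family"] in seen_families:
                continue
            seen_families.add(row["family"])
        units.append(row)
    # rRNA/tRNA loci are in the tracks, not the truth table; re-derive their
    # read-generating intervals is not needed -- they are planted separately
    stage_sets = {}
    for i, unit in enumerate(units):
        expressed = [
            s for s in spec.stages if rng.random() < spec.stage_expression_prob
        ]
        if not expressed:
            expressed = [spec.stages[int(rng.integers(len(spec.stages)))]]
        stage_sets[i] = set(expressed)

    libraries = {}
    for stage in spec.stages:
        counter: dict[str, int] = {}

        def emit(seq_dna: str, count: int = 1) -> None:
            counter[seq_dna] = counter.get(seq_dna, 0) + count

        for i, unit in enumerate(units):
            if stage not in stage_sets[i]:
                continue
            region = genome[unit["scaffold"]][unit["start"] : unit["end"]]
            cls = unit["class"]
            if cls == "miRNA":
                # mature guide from the 5' arm plus a rarer star from the 3'
                # arm (both substrings of the one precursor transcript), and
                # low-frequency offset/length variants
                dom_start = 4
                dom = region[dom_start : dom_start + 22]
                emit(dom, int(rng.poisson(spec.mirna_dominant_count)) or 1)
                star_start = len(region) - 26
                emit(region[star_start : star_start + 22], int(rng.poisson(12)) or 1)
                for _ in range(spec.mirna_n_variants):
                    off = int(rng.integers(-2, 3))
                    ln = int(rng.integers(21, 24))
                    s = max(0, dom_start + off)
                    emit(region[s : s + ln], 1)
            elif cls == "endo_siRNA":
                for _ in range(spec.endo_reads_per_locus):
                    ln = _weighted_choice(rng, spec.endo_lengths)
                    s = int(rng.integers(0, len(region) - ln + 1))
                    seq = region[s : s + ln]
                    if rng.random() < 0.5:
                        seq = reverse_complement_dna(seq)
                    emit(seq, 1 + (rng.random() < 0.2))
            elif cls == "piRNA":
                anchors = list(range(0, len(region) - 30, _PIRNA_ANCHOR_STEP))
                t_pos = [p for p in range(len(region) - 30) if region[p] == "T"]
                for _ in range(spec.pirna_reads_per_locus):
                    ln = _weighted_choice(rng, spec.pirna_lengths)
                    u = rng.random()
                    if u < spec.pirna_a10_freq:
                        s = int(rng.choice(anchors))
                    elif u < spec.pirna_u1_freq and t_pos:
                        s = int(rng.choice(t_pos))
                    else:
                        s = int(rng.integers(0, len(region) - ln + 1))
                    emit(region[s : s + ln], 1 + (rng.random() < 0.15))
            elif cls == "mer25":
                t_pos = [p for p in range(len(region) - 28) if region[p] == "T"]
                for _ in range(spec.mer25_reads_per_locus):
                    ln = _weighted_choice(rng, spec.mer25_lengths)
                    if rng.random() < spec.mer25_u1_freq and t_pos:
                        s = int(rng.choice(t_pos))
                    else:
                        s = int(rng.integers(0, len(region) - ln + 1))
                    emit(region[s : s + ln], 1 + (rng.random() < 0.15))
            elif cls == "rRNA":
                # degradation-like fragments; removed by the rRNA filter
                for _ in range(10):
                    ln = int(rng.integers(18, 31))
                    s = int(rng.integers(0, len(region) - ln + 1))
                    emit(region[s : s + ln], int(rng.integers(1, 6)))
            elif cls == "tRNA":
                # tRNA-fragment-like: one dominant 21-mer, high uniformity
                emit(region[10:31], int(rng.poisson(60)) or 1)
                emit(region[9:31], 1)
                emit(region[10:32], 1)

        reads = []
        for seq_dna, count in sorted(counter.items()):
            sites = find_genome_occurrences(seq_dna, genome)
            n = len(sites)
            for scaffold, pos, strand in sites:
                # the read as sequenced is seq_dna on both strands; a minus
                # site is where the genome carries its reverse complement
                reads.append(
                    MappedRead(
                        scaffold,
                        pos,
                        pos + len(seq_dna),
                        strand,
                        seq_dna,
                        count,
                        n,
                    )
                )
        libraries[stage] = Library(name=stage, stage_label=stage, reads=reads)
    return libraries
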