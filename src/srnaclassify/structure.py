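"""Precursor folding and the shuffle-based MFE significance test.

A cluster's putative precursor is the genomic span it occupies.  The strand
to fold follows the reads: single-strand clusters fold that strand, mixed
clusters fold both and keep the lower minimum free energy (ties go to the
plus strand, a deterministic stand-in for an arbitrary choice).

The folding engine is a pluggable contract.  The reference backend is the
ViennaRNA thermodynamic folder (when its python bindings are importable),
run with a maximum base-pair span so that only locally stable structures are
scored.  The built-in fallback is a Nussinov-style minimisation over an
energy proxy (-1.0 per GC, -0.7 per AU, -0.5 per GU pair, minimum hairpin
loop 3, same span cap), used consistently for native and shuffled sequences.

Significance is an empirical p-value against dinucleotide-preserving
shuffles of the native sequence (Altschul-Erickson Eulerian-walk shuffle):

    p = (1 + #{shuffles with MFE <= native MFE}) / (n_shuffles + 1)

so p is bounded in [1/(N+1), 1] and a homopolymer scores exactly 1.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .clustering import Cluster
from .io_model import reverse_complement_rna, to_rna

DEFAULT_LOCAL_SPAN = 150
DEFAULT_N_SHUFFLES = 100
MIN_LOOP = 3

_PAIR_ENERGY = {
    frozenset("GC"): -1.0,
    frozenset("AU"): -0.7,
    frozenset("GU"): -0.5,
}

# base encoding A=0 C=1 G=2 U=3; energy matrix for the proxy engine
_ENC = {"A": 0, "C": 1, "G": 2, "U": 3}
_EMAT = np.zeros((4, 4))
_EMAT[2, 1] = _EMAT[1, 2] = -1.0
_EMAT[0, 3] = _EMAT[3, 0] = -0.7
_EMAT[2, 3] = _EMAT[3, 2] = -0.5


@dataclass
class FoldResult:
    strand: str
    mfe: float
    structure: str
    randfold_p: Optional[float] = None
    n_shuffles: int = 0


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_ENC[b] for b in sequence], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-ACGU character in sequence: {exc}") from None


@njit(cache=True)
def _nussinov_fill(enc, emat, span, min_loop):  # pragma: no cover - jit
    n = enc.shape[0]
    dp = np.zeros((n + 1, n + 1))
    for length in range(min_loop + 2, n + 1):
        for i in range(0, n - length + 1):
            j = i + length - 1
            best = dp[i + 1, j + 1]  # i unpaired; dp row shifted by +1 on j
            for k in range(i + min_loop + 1, j + 1):
                if k - i > span:
                    break
                e = emat[enc[i], enc[k]]
                if e < 0.0:
                    cand = dp[i + 1, k] + e + dp[k + 1, j + 1]
                    if cand < best:
                        best = cand
            dp[i, j + 1] = best
    return dp


def _nussinov_traceback(enc: np.ndarray, dp: np.ndarray, span: int) -> str:
    n = len(enc)
    pairs = ["."] * n
    stack = [(0, n - 1)]
    eps = 1e-9
    while stack:
        i, j = stack.pop()
        if j - i < MIN_LOOP + 1:
            continue
        if abs(dp[i, j + 1] - dp[i + 1, j + 1]) < eps:
            stack.append((i + 1, j))
            continue
        for k in range(i + MIN_LOOP + 1, min(j, i + span) + 1):
            e = _EMAT[enc[i], enc[k]]
            if e < 0.0 and abs(dp[i, j + 1] - (dp[i + 1, k] + e + dp[k + 1, j + 1])) < eps:
                pairs[i], pairs[k] = "(", ")"
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                break
        else:  # numerical safety: treat i as unpaired
            stack.append((i + 1, j))
    return "".join(pairs)


def _fold_builtin(sequence: str, local_span: int) -> tuple[float, str]:
    enc = _encode(sequence)
    if len(enc) < 2:
        return 0.0, "." * len(enc)
    dp = _nussinov_fill(enc, _EMAT, local_span, MIN_LOOP)
    mfe = float(dp[0, len(enc)])
    structure = _nussinov_traceback(enc, dp, local_span)
    return mfe, structure


def _have_vienna() -> bool:
    try:
        import RNA  # noqa: F401

        return True
    except ImportError:
        return False


def _fold_vienna(sequence: str, local_span: int) -> tuple[float, str]:
    import RNA

    md = RNA.md()
    md.max_bp_span = int(local_span)
    fc = RNA.fold_compound(sequence, md)
    structure, mfe = fc.mfe()
    if mfe >= 0.0:
        return 0.0, "." * len(sequence)
    return float(mfe), structure


def resolve_backend(backend: str = "auto") -> str:
    """Resolve 'auto' to 'vienna' when the bindings import, else 'builtin'."""
    if backend == "auto":
        return "vienna" if _have_vienna() else "builtin"
    if backend not in ("vienna", "builtin"):
        raise ValueError(f"unknown fold backend {backend!r}")
    return backend


def fold_mfe(
    sequence: str, local_span: int = DEFAULT_LOCAL_SPAN, backend: str = "auto"
) -> tuple[float, str]:
    """Minimum free energy and dot-bracket structure of ``sequence``.

    Only pairings with span <= ``local_span`` are allowed.  The MFE is <= 0
    by convention (0 with an all-dots structure for unstructured sequences).
    Deterministic: identical inputs give identical results.
    """
    sequence = to_rna(sequence)
    if len(sequence) < 10:
        raise ValueError("sequence too short to fold (< 10 nt)")
    bad = set(sequence) - set("ACGU")
    if bad:
        raise ValueError(f"non-ACGU characters in sequence: {sorted(bad)}")
    if resolve_backend(backend) == "vienna":
        return _fold_vienna(sequence, local_span)
    return _fold_builtin(sequence, local_span)


def select_fold_strand(
    cluster: Cluster,
    genome: dict[str, str],
    local_span: int = DEFAULT_LOCAL_SPAN,
    backend: str = "auto",
) -> tuple[str, float, str]:
    """Fold the cluster span on the strand(s) its reads come from.

    Single-strand clusters fold that strand only; mixed clusters fold both
    and keep the lower MFE, ties resolved to the plus strand.
    """
    if cluster.scaffold not in genome:
        raise KeyError(f"scaffold {cluster.scaffold!r} absent from genome")
    plus = to_rna(genome[cluster.scaffold][cluster.start : cluster.end])
    strands = cluster.strands_present or {"+"}
    results = {}
    if "+" in strands:
        results["+"] = fold_mfe(plus, local_span, backend)
    if "-" in strands:
        results["-"] = fold_mfe(reverse_complement_rna(plus), local_span, backend)
    if len(results) == 1:
        strand, (mfe, structure) = next(iter(results.items()))
        return strand, mfe, structure
    if results["+"][0] <= results["-"][0]:
        return "+", *results["+"]
    return "-", *results["-"]


# ---------------------------------------------------------------------------
# Dinucleotide shuffle (Altschul-Erickson)
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(sequence: str, rng_seed=0) -> str:
    """Shuffle preserving exact mono- and dinucleotide counts.

    Altschul-Erickson Eulerian-walk shuffle: the sequence is a walk on the
    graph whose edges are its dinucleotides; a random last-edge in-tree
    toward the terminal base is drawn, remaining edges are permuted, and the
    walk is replayed.  Deterministic given ``rng_seed`` (an int seed or a
    ``random.Random``).
    """
    s = to_rna(sequence)
    if len(s) < 2:
        raise ValueError("sequence must have length >= 2")
    if len(set(s)) == 1:
        return s
    rng = rng_seed if isinstance(rng_seed, random.Random) else random.Random(rng_seed)

    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    last = s[-1]
    vertices = [v for v in edges if v != last]

    for _ in range(10000):
        last_edge = {}
        ok = True
        for v in vertices:
            last_edge[v] = rng.choice(edges[v])
        # the chosen edges must form an in-tree toward `last`
        for v in vertices:
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in last_edge:
                    ok = False
                    break
                seen.add(cur)
                cur = last_edge[cur]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("failed to draw a connected last-edge tree")

    shuffled: dict[str, list[str]] = {}
    for v, out in edges.items():
        rest = list(out)
        if v in last_edge:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        if v in last_edge:
            rest.append(last_edge[v])
        shuffled[v] = rest

    out_chars = [s[0]]
    counters = {v: 0 for v in shuffled}
    cur = s[0]
    for _ in range(len(s) - 1):
        nxt = shuffled[cur][counters[cur]]
        counters[cur] += 1
        out_chars.append(nxt)
        cur = nxt
    return "".join(out_chars)


def randfold_test(
    sequence: str,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    rng_seed: int = 0,
    local_span: int = DEFAULT_LOCAL_SPAN,
    backend: str = "auto",
) -> float:
    """Empirical p-value of the native MFE against dinucleotide shuffles.

    p = (1 + #{shuffle MFE <= native MFE}) / (n_shuffles + 1); the add-one
    pseudo-count keeps p in [1/(N+1), 1].  The same folding engine scores the
    native and every shuffled sequence.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    backend = resolve_backend(backend)
    sequence = to_rna(sequence)
    native, _ = fold_mfe(sequence, local_span, backend)
    rng = random.Random(rng_seed)
    hits = 0
    for _ in range(n_shuffles):
        shuf = dinucleotide_shuffle(sequence, rng)
        mfe, _ = fold_mfe(shuf, local_span, backend)
        if mfe <= native + 1e-9:
            hits += 1
    return (1 + hits) / (n_shuffles + 1)


def fold_cluster(
    cluster: Cluster,
    genome: dict[str, str],
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    rng_seed: int = 0,
    local_span: int = DEFAULT_LOCAL_SPAN,
    backend: str = "auto",
) -> FoldResult:
    """Strand-resolved fold plus shuffle test; attaches the result to the cluster."""
    strand, mfe, structure = select_fold_strand(cluster, genome, local_span, backend)
    seq = to_rna(genome[cluster.scaffold][cluster.start : cluster.end])
    if strand == "-":
        seq = reverse_complement_rna(seq)
    p = randfold_test(seq, n_shuffles, rng_seed, local_span, backend)
    result = FoldResult(strand, mfe, structure, p, n_shuffles)
    cluster.fold = result
    return result


DEFAULT_P_CUTOFFS = (0.01, 0.02, 0.05, 0.1)


def structure_enrichment_curves(
    clusters: Iterable[Cluster],
    target_classes: Sequence[str] = ("endo_siRNA", "piRNA"),
    cutoffs: Sequence[float] = DEFAULT_P_CUTOFFS,
) -> pd.DataFrame:
    """Percentage of clusters with shuffle-test p <= cutoff, per class.

    The background row pools all clusters not labelled with any target class,
    mirroring how structured classes are compared against the remainder of a
    library.  Clusters without a fold result are ignored.
    """
    groups: dict[str, list[float]] = {cls: [] for cls in target_classes}
    groups["background"] = []
    for c in clusters:
        if c.fold is None or c.fold.randfold_p is None:
            continue
        key = c.label if c.label in groups else "background"
        groups[key].append(c.fold.randfold_p)
    rows = {}
    for cls, ps in groups.items():
        arr = np.asarray(ps)
        rows[cls] = [
            100.0 * float((arr <= cut).mean()) if arr.size else 0.0 for cut in cutoffs
        ]
    return pd.DataFrame(rows, index=pd.Index(cutoffs, name="p_cutoff")).T
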