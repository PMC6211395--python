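"""Positional nucleotide-bias matrices and biogenesis-signature detection.

Reads are anchored at their 5' nucleotide; position p of the matrix holds the
percentage of each base among reads long enough to cover p.  Two signatures
are scored on such matrices:

* the ping-pong signature of secondary piRNA biogenesis — uridine bias at
  position 1 together with adenosine bias at position 10;
* guanosine enrichment downstream of position 25, the G-quadruplex-like
  landmark reported for piRNA-producing loci.

Endo-siRNA populations typically show only the position-1 uridine bias, which
detect_ping_pong correctly rejects (no 10A requirement is met).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .io_model import MappedRead

BASES = ("A", "C", "G", "U")

DEFAULT_U1_MIN = 40.0
DEFAULT_A10_MIN = 35.0
DEFAULT_G_FROM_POSITION = 25
DEFAULT_G_ENRICHMENT_FACTOR = 1.25


def positional_bias(
    reads: Iterable[MappedRead], weight_by_count: bool = True
) -> pd.DataFrame:
    """5'-anchored position x base percentage matrix.

    Rows are positions 1..P (P = longest read); columns A, C, G, U.  Each
    covered position sums to 100; positions no read covers are NaN.  Weights
    are read counts when ``weight_by_count`` else 1 per distinct read record.
    """
    reads = list(reads)
    if not reads:
        raise ValueError("positional_bias requires at least one read")
    P = max(r.length for r in reads)
    counts = np.zeros((P, 4))
    index = {b: i for i, b in enumerate(BASES)}
    for r in reads:
        w = r.count if weight_by_count else 1
        seq = r.sequence
        for p, base in enumerate(seq):
            counts[p, index[base]] += w
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(totals > 0, counts / totals * 100.0, np.nan)
    return pd.DataFrame(pct, index=pd.RangeIndex(1, P + 1, name="position"), columns=BASES)


@dataclass
class SignatureResult:
    positive: bool
    summary: dict

    def __bool__(self) -> bool:
        return self.positive


def detect_ping_pong(
    bias: pd.DataFrame,
    u1_min: float = DEFAULT_U1_MIN,
    a10_min: float = DEFAULT_A10_MIN,
) -> SignatureResult:
    """Ping-pong signature: modal U at position 1 and modal A at position 10.

    Positive iff U is the most frequent base at position 1 with frequency
    >= ``u1_min`` percent AND A is the most frequent base at position 10 with
    frequency >= ``a10_min`` percent.
    """
    if len(bias) < 10:
        raise ValueError("bias matrix must cover at least 10 positions")
    p1 = bias.loc[1]
    p10 = bias.loc[10]
    u1 = float(p1["U"])
    a10 = float(p10["A"])
    positive = (
        p1.idxmax() == "U" and u1 >= u1_min and p10.idxmax() == "A" and a10 >= a10_min
    )
    return SignatureResult(bool(positive), {"u1_pct": u1, "a10_pct": a10})


def detect_downstream_g(
    bias: pd.DataFrame,
    from_position: int = DEFAULT_G_FROM_POSITION,
    enrichment_factor: float = DEFAULT_G_ENRICHMENT_FACTOR,
) -> SignatureResult:
    """Guanosine enrichment downstream of ``from_position``.

    Positive iff the mean G percentage over covered positions beyond
    ``from_position`` exceeds ``enrichment_factor`` times the mean G
    percentage over positions 2..from_position.  Returns an indeterminate
    result (positive=False, status 'indeterminate') when no read extends past
    ``from_position``.
    """
    g = bias["G"]
    down = g.loc[g.index > from_position].dropna()
    up = g.loc[(g.index >= 2) & (g.index <= from_position)].dropna()
    if down.empty or up.empty:
        return SignatureResult(False, {"status": "indeterminate"})
    ratio = float(down.mean()) / float(up.mean()) if up.mean() > 0 else np.inf
    positive = ratio > enrichment_factor
    return SignatureResult(
        bool(positive),
        {
            "status": "ok",
            "mean_g_downstream": float(down.mean()),
            "mean_g_upstream": float(up.mean()),
            "ratio": float(ratio),
        },
    )


def write_bias_matrix(bias: pd.DataFrame, path) -> None:
    """TSV with position rows and base columns; uncovered positions as NA."""
    bias.to_csv(path, sep="\t", float_format="%.4f", na_rep="NA")
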