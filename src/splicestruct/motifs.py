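"""Polyadenylation-signal (PAS) scanning around splice junctions.

The canonical PAS hexamer AAUAAA — the binding site of the CPSF complex —
is searched in genomic DNA as AATAAA on the plus strand and as its reverse
complement TTTATT on the minus strand.  The scan window is the union of
two intervals of +/- ``window`` bp around the junction's start and end
coordinates (a junction has two endpoints and either may sit near a
cleavage site); junctions of unknown strand are scanned on both strands.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .ase import AseCall
from .io import JunctionID, SequenceRecord

__all__ = ["MotifHit", "find_pas_motifs", "scan_ase_set", "PAS_DNA"]

PAS_DNA = "AATAAA"
_PAS_RC = "TTTATT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    """One PAS occurrence near a junction.

    ``position`` is the 1-based genomic coordinate of the match start;
    ``offset`` is the signed distance from the nearest junction endpoint
    (negative = upstream of it); ``matched_text`` is the hexamer as read
    on the reported strand.
    """

    junction: JunctionID
    position: int
    strand: str
    offset: int
    matched_text: str


def _merged_windows(junction: JunctionID, window: int) -> list[tuple[int, int]]:
    a = (junction.start - window, junction.start + window)
    b = (junction.end - window, junction.end + window)
    if a[1] >= b[0] - 1:
        return [(a[0], max(a[1], b[1]))]
    return [a, b]


def find_pas_motifs(
    seq: SequenceRecord, junction: JunctionID, window: int = 500
) -> list[MotifHit]:
    """All PAS hexamer matches within ``window`` bp of either junction endpoint.

    The sequence must cover both junction endpoints.  Hits are
    deduplicated by (position, strand) and sorted by position; for a
    stranded junction only the annotated strand is scanned.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    lo, hi = seq.span
    if not (lo <= junction.start <= hi and lo <= junction.end <= hi):
        raise ValueError(
            f"junction {junction} outside sequence coverage [{lo}, {hi}]"
        )
    if junction.strand == "+":
        strands = [("+", PAS_DNA)]
    elif junction.strand == "-":
        strands = [("-", _PAS_RC)]
    else:
        strands = [("+", PAS_DNA), ("-", _PAS_RC)]

    hits: dict[tuple[int, str], MotifHit] = {}
    for w_lo, w_hi in _merged_windows(junction, window):
        w_lo = max(w_lo, lo)
        w_hi = min(w_hi, hi)
        if w_hi - w_lo + 1 < 6:
            continue
        region = seq.sequence[w_lo - seq.offset : w_hi - seq.offset + 1]
        for strand, pattern in strands:
            start = region.find(pattern)
            while start != -1:
                pos = w_lo + start
                d_start = pos - junction.start
                d_end = pos - junction.end
                offset = d_start if abs(d_start) <= abs(d_end) else d_end
                hits.setdefault(
                    (pos, strand),
                    MotifHit(
                        junction=junction,
                        position=pos,
                        strand=strand,
                        offset=offset,
                        matched_text=PAS_DNA,
                    ),
                )
                start = region.find(pattern, start + 1)
    return sorted(hits.values(), key=lambda h: (h.position, h.strand))


def scan_ase_set(
    ases: list[AseCall],
    seqs: list[SequenceRecord],
    window: int = 500,
    top_k: int = 20,
) -> pd.DataFrame:
    """Scan the top-k ASEs for nearby PAS hexamers.

    ``ases`` is assumed to be in significance order; the first ``top_k``
    entries are scanned (all of them when the list is shorter).  Sequences
    are matched to ASEs by gene symbol; an ASE without a sequence is
    recorded as untested rather than failing the scan.
    """
    by_gene = {s.name: s for s in seqs}
    rows = []
    for call in ases[:top_k]:
        junction = call.junction
        seq = by_gene.get(junction.gene)
        if seq is None:
            rows.append(
                {
                    "junction_id": str(junction),
                    "gene": junction.gene,
                    "status": "untested",
                    "has_motif": False,
                    "n_hits": 0,
                    "nearest_offset": pd.NA,
                }
            )
            continue
        hits = find_pas_motifs(seq, junction, window)
        rows.append(
            {
                "junction_id": str(junction),
                "gene": junction.gene,
                "status": "scanned",
                "has_motif": bool(hits),
                "n_hits": len(hits),
                "nearest_offset": min((abs(h.offset) for h in hits), default=pd.NA),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["junction_id", "gene", "status", "has_motif", "n_hits", "nearest_offset"],
    )
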