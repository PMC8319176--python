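"""Catalytic and substrate-binding motif scanning for LPAAT-family proteins.

LPAAT acyltransferases carry an HX4D catalytic motif (His and Asp separated
by four residues, as in PlsC and OlsA).  SalA-clade enzymes instead carry an
extended HX5D motif (e.g. His109/Asp115) together with the substrate-binding
motif FP[E/S]G[T/V] downstream.  The scanner reports 1-based positions of all
(possibly overlapping) matches; the classifier turns them into a
SalA-like / PlsC-OlsA-like / indeterminate call.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "AMINO_ACIDS",
    "MOTIFS",
    "MotifHit",
    "LpaatClass",
    "scan_motifs",
    "classify_lpaat",
    "scan_fasta",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: wildcard positions accept any residue letter including ambiguous X;
#: motif-specified residues must match literally (X never qualifies)
_WILD = f"[{AMINO_ACIDS}X]"

MOTIFS = {
    "HX4D": re.compile(f"(?=(H{_WILD}{{4}}D))"),
    "HX5D": re.compile(f"(?=(H{_WILD}{{5}}D))"),
    "FPxGx": re.compile(f"(?=(FP[ES]G[TV]))"),
}

CATALYTIC_MOTIFS = ("HX4D", "HX5D")

#: default maximum residue distance from a catalytic-motif anchor to a
#: downstream substrate-binding motif for the pair to count as co-occurring
DEFAULT_WINDOW = 120


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    start: int  # 1-based position of the anchor residue (H or F)
    span: str


@dataclass(frozen=True)
class LpaatClass:
    label: str  # SalA_like | PlsC_OlsA_like | indeterminate
    evidence: tuple


def _clean(sequence: str) -> str:
    seq = sequence.strip().upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    for pos, ch in enumerate(seq, start=1):
        if ch not in AMINO_ACIDS and ch != "X":
            raise ValueError(
                f"illegal character {ch!r} at position {pos} in protein sequence"
            )
    return seq


def scan_motifs(sequence: str) -> list[MotifHit]:
    """All motif matches (overlaps allowed), 1-based, in position order."""
    seq = _clean(sequence)
    hits = []
    for motif_id, rx in MOTIFS.items():
        for m in rx.finditer(seq):
            hits.append(MotifHit(motif_id, m.start() + 1, m.group(1)))
    hits.sort(key=lambda h: (h.start, h.motif_id))
    return hits


def _qualifies(catalytic: Iterable[MotifHit], binding: Iterable[MotifHit], window: int):
    """Catalytic hits with a substrate-binding motif within ``window`` downstream."""
    return [
        h
        for h in catalytic
        if any(0 < b.start - h.start <= window for b in binding)
    ]


def classify_lpaat(sequence: str, window: int = DEFAULT_WINDOW) -> LpaatClass:
    """SalA-like vs PlsC/OlsA-like call from catalytic-motif spacing.

    A lone catalytic motif type decides the call outright; when both HX4D and
    HX5D occur, the one anchored by a downstream FPxGx motif within the
    window wins; no (or ambiguous) anchoring -> indeterminate.
    """
    hits = scan_motifs(sequence)
    h4 = [h for h in hits if h.motif_id == "HX4D"]
    h5 = [h for h in hits if h.motif_id == "HX5D"]
    fp = [h for h in hits if h.motif_id == "FPxGx"]
    if h5 and not h4:
        return LpaatClass("SalA_like", tuple(h5 + fp))
    if h4 and not h5:
        return LpaatClass("PlsC_OlsA_like", tuple(h4 + fp))
    if not h4 and not h5:
        return LpaatClass("indeterminate", ())
    q5 = _qualifies(h5, fp, window)
    q4 = _qualifies(h4, fp, window)
    if q5 and not q4:
        return LpaatClass("SalA_like", tuple(q5 + fp))
    if q4 and not q5:
        return LpaatClass("PlsC_OlsA_like", tuple(q4 + fp))
    return LpaatClass("indeterminate", tuple(hits))


def scan_fasta(path, window: int = DEFAULT_WINDOW):
    """Scan every record of a protein FASTA; returns rows of
    (seq_id, motif_id, start, span, class label).

    Gap characters (alignment input) are stripped with a warning; description
    lines are preserved as sequence ids.
    """
    import warnings

    from Bio import SeqIO

    rows = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq)
        if "-" in seq:
            warnings.warn(f"stripping alignment gaps from {record.id}")
            seq = seq.replace("-", "")
        label = classify_lpaat(seq, window=window).label
        hits = scan_motifs(seq)
        if not hits:
            rows.append((record.description, "", None, "", label))
        for h in hits:
            rows.append((record.description, h.motif_id, h.start, h.span, label))
    return rows
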