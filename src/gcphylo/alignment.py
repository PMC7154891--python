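"""Gap-free nucleotide alignments.

Alignment columns containing any gap are removed on load (columnwise
stripping keeps sites synchronized across taxa).  IUPAC ambiguity codes
are kept in the matrix and treated as missing data by the likelihood
(partial likelihood 1 over compatible states); composition counts skip
them entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP_CHARS = frozenset("-.")

# IUPAC nucleotide codes -> compatible {A,C,G,T} state sets
AMBIGUITY = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT", "?": "ACGT",
}

STATES = "ACGT"
STATE_INDEX = {c: i for i, c in enumerate(STATES)}


@dataclass
class Alignment:
    """Equal-length nucleotide sequences keyed by taxon name."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {t: len(s) for t, s in self.sequences.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"unequal sequence lengths: {lengths}")
        for taxon, seq in self.sequences.items():
            bad = set(seq) - set(AMBIGUITY)
            if bad & GAP_CHARS:
                raise ValueError(f"gap characters remain in {taxon!r}; strip gaps on load")
            if bad:
                raise ValueError(f"invalid characters {sorted(bad)} in {taxon!r}")

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def gc_content(self, taxon: str) -> float:
        """Observed GC fraction of one row, over unambiguous bases only."""
        seq = self.sequences[taxon]
        acgt = sum(seq.count(c) for c in STATES)
        if acgt == 0:
            raise ValueError(f"no unambiguous bases in {taxon!r}")
        return (seq.count("G") + seq.count("C")) / acgt

    def state_mask(self, order: list[str] | None = None) -> np.ndarray:
        """(n_taxa, n_sites, 4) indicator of compatible states per cell."""
        taxa = order if order is not None else self.taxa
        out = np.zeros((len(taxa), self.n_sites, 4))
        for i, taxon in enumerate(taxa):
            for j, ch in enumerate(self.sequences[taxon]):
                for st in AMBIGUITY[ch]:
                    out[i, j, STATE_INDEX[st]] = 1.0
        return out

    def write_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=taxon, description="")
            for taxon, seq in self.sequences.items()
        ]
        SeqIO.write(records, path, "fasta")


def _strip_gap_columns(rows: dict[str, str]) -> dict[str, str]:
    taxa = list(rows)
    mat = np.array([list(rows[t]) for t in taxa])
    keep = ~np.isin(mat, list(GAP_CHARS)).any(axis=0)
    return {t: "".join(mat[i, keep]) for i, t in enumerate(taxa)}


def read_alignment(source, strip_gaps: bool = True) -> Alignment:
    """Read a FASTA alignment (path, handle, or string of FASTA text).

    Uppercases sequences, maps U->T, strips gap-containing columns when
    `strip_gaps` (sites must stay synchronized, so stripping is always
    columnwise).  Unequal post-strip lengths raise with the offending taxa.
    """
    if isinstance(source, str) and source.lstrip().startswith(">"):
        source = StringIO(source)
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(source, "fasta"):
        if rec.id in rows:
            raise ValueError(f"duplicate taxon {rec.id!r} in FASTA")
        rows[rec.id] = str(rec.seq).upper().replace("U", "T")
    if not rows:
        raise ValueError("no FASTA records found")
    lengths = {t: len(s) for t, s in rows.items()}
    if len(set(lengths.values())) > 1:
        common = max(set(lengths.values()), key=list(lengths.values()).count)
        odd = sorted(t for t, n in lengths.items() if n != common)
        raise ValueError(f"unequal sequence lengths; offending taxa: {odd}")
    if strip_gaps:
        rows = _strip_gap_columns(rows)
    return Alignment(rows)
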