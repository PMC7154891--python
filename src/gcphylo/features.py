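"""Per-genome feature extraction: length, GC, non-coding fraction,
gene counts, and repeat statistics.

Variables per genome (one row of the feature table):

* ``GL`` — genome length in bp
* ``pct_GC`` — GC fraction of the whole sequence (unambiguous bases)
* ``pct_NC`` — non-coding fraction: 1 minus the per-base union of
  annotated gene intervals over GL
* ``NPG`` — number of protein-coding genes (gene features with a CDS
  child; rRNA/tRNA genes counted separately)
* ``NRS`` — number of maximal repeat pairs at the configured minimum length
* ``RSL`` — total length of the per-base union of all repeat copies
* ``gc_in_repeats`` — GC fraction over that union

Genomes are treated as linear by default; pass ``circular=True`` to
search repeats across the origin (the sequence is virtually doubled and
hits spanning the join are mapped back).
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import pandas as pd
from Bio import SeqIO

from .repeats import KINDS, RepeatHit, find_maximal_repeats, repeat_stats

FEATURE_COLUMNS = ["GL", "pct_GC", "pct_NC", "NPG", "NRS", "RSL", "gc_in_repeats"]


def gc_content(seq: str) -> float:
    """GC fraction over unambiguous (A/C/G/T) bases."""
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return (counts["G"] + counts["C"]) / total


@dataclass
class GeneFeature:
    """One annotated feature interval (1-based inclusive, GFF3 convention)."""

    feature_id: str
    ftype: str
    start: int
    end: int
    parent: str | None = None


def parse_gff3(text: str) -> list[GeneFeature]:
    """Minimal GFF3 reader: the 9 standard columns, ID/Parent attributes.

    Only the feature types used downstream (gene, CDS, rRNA, tRNA) are
    retained.
    """
    keep = {"gene", "CDS", "rRNA", "tRNA"}
    out: list[GeneFeature] = []
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"GFF3 line {ln}: expected 9 columns, got {len(cols)}")
        ftype, start, end, attrs = cols[2], int(cols[3]), int(cols[4]), cols[8]
        if ftype not in keep:
            continue
        fields = dict(
            kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
        )
        out.append(
            GeneFeature(
                feature_id=fields.get("ID", f"line{ln}"),
                ftype=ftype,
                start=start,
                end=end,
                parent=fields.get("Parent"),
            )
        )
    return out


def noncoding_fraction(genome_len: int, features: list[GeneFeature]) -> float:
    """1 - (bases covered by the union of gene intervals) / genome_len.

    Overlapping genes are counted once.  Intervals must lie within
    [1, genome_len].
    """
    genes = [f for f in features if f.ftype == "gene"]
    covered: set[int] = set()
    for f in genes:
        if f.start < 1 or f.end > genome_len or f.start > f.end:
            raise ValueError(
                f"feature {f.feature_id!r} interval [{f.start},{f.end}] out of "
                f"bounds for genome length {genome_len}"
            )
        covered.update(range(f.start, f.end + 1))
    return 1.0 - len(covered) / genome_len


def count_protein_genes(features: list[GeneFeature]) -> int:
    """Genes whose children include a CDS feature."""
    cds_parents = {f.parent for f in features if f.ftype == "CDS" and f.parent}
    return sum(1 for f in features if f.ftype == "gene" and f.feature_id in cds_parents)


def _circular_hits(seq: str, min_len: int, kinds) -> list[RepeatHit]:
    """Repeat search on the virtually doubled sequence, mapped back."""
    n = len(seq)
    doubled = seq + seq
    raw = find_maximal_repeats(doubled, min_len=min_len, kinds=kinds)
    out = set()
    for h in raw:
        if h.length > n or h.start1 > n:
            continue  # doubling artifact / duplicate image of a hit
        s1 = (h.start1 - 1) % n + 1
        s2 = (h.start2 - 1) % n + 1
        if s1 > s2:
            s1, s2 = s2, s1
        out.add(RepeatHit(s1, s2, h.length, h.kind))
    return sorted(out, key=lambda h: (h.start1, h.start2, KINDS.index(h.kind)))


@dataclass
class GenomeFeatures:
    GL: int
    pct_GC: float
    pct_NC: float
    NPG: int
    NRS: int
    RSL: int
    gc_in_repeats: float | None


def genome_features(
    seq: str,
    gff3_text: str = "",
    min_repeat_len: int = 20,
    kinds=KINDS,
    circular: bool = False,
) -> GenomeFeatures:
    """Compute all per-genome variables for one sequence + annotation."""
    seq = seq.upper()
    feats = parse_gff3(gff3_text) if gff3_text else []
    if circular:
        hits = _circular_hits(seq, min_repeat_len, kinds)
    else:
        hits = find_maximal_repeats(seq, min_len=min_repeat_len, kinds=kinds)
    nrs, rsl, gc_rep = repeat_stats(hits, seq)
    return GenomeFeatures(
        GL=len(seq),
        pct_GC=gc_content(seq),
        pct_NC=noncoding_fraction(len(seq), feats),
        NPG=count_protein_genes(feats),
        NRS=nrs,
        RSL=rsl,
        gc_in_repeats=gc_rep,
    )


def build_feature_table(
    genomes: dict[str, tuple[str, str]],
    min_repeat_len: int = 20,
    kinds=KINDS,
    circular: bool = False,
) -> pd.DataFrame:
    """Feature table over {species: (fasta_text_or_path, gff3_text)}.

    FASTA input may be raw FASTA text or a file path; the first record is
    the genome.  Returns a DataFrame indexed by species with the columns
    GL, pct_GC, pct_NC, NPG, NRS, RSL, gc_in_repeats.
    """
    rows = {}
    for species, (fasta, gff3_text) in genomes.items():
        if species in rows:
            raise ValueError(f"duplicate species {species!r}")
        handle = StringIO(fasta) if fasta.lstrip().startswith(">") else fasta
        record = next(SeqIO.parse(handle, "fasta"))
        gf = genome_features(
            str(record.seq), gff3_text, min_repeat_len, kinds, circular
        )
        rows[species] = vars(gf)
    table = pd.DataFrame.from_dict(rows, orient="index")[FEATURE_COLUMNS]
    table.index.name = "species"
    return table
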