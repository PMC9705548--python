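"""Ingest genomes and tRNA gene annotations into transcript-oriented gene records.

A tRNA locus is stored in *transcript orientation*: the spliced mature body
(no intron, no CCA — CCA is added post-transcriptionally and is never genomic
here), the discriminator base N73 (3'-most mature nucleotide), an upstream
flank whose 3'-most base is the last leader nucleotide N-1, and a downstream
flank starting at the first nucleotide past N73, where the Pol III terminator
(a run of >=4 T on the coding strand) is sought.

Coordinates are 0-based half-open internally.  BED12 is consumed natively;
GtRNAdb-style 1-based inclusive tables are converted on ingest.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: catalog TSV column order (stable on round trip)
CATALOG_COLUMNS = [
    "gene_id", "species", "isotype", "anticodon", "contig", "start", "end",
    "strand", "mature_sequence", "discriminator", "upstream_flank",
    "downstream_flank", "flags",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _open_text(path: str | Path) -> TextIO:
    """Open a possibly gzip-compressed text file."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


@dataclass
class GenomeSource:
    """Uppercase DNA contigs keyed by contig id."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {cid!r} is empty")
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(f"contig {cid!r} has invalid characters {sorted(bad)}")


@dataclass
class GeneAnnotation:
    """One tRNA gene locus on the genome (0-based half-open)."""

    gene_id: str
    species: str
    isotype: str
    anticodon: str
    contig: str
    start: int
    end: int
    strand: str
    intron_blocks: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: unknown strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.gene_id}: bad interval [{self.start},{self.end})")
        prev_end = self.start
        for (s, e) in sorted(self.intron_blocks):
            if not (self.start < s < e < self.end):
                raise ValueError(f"{self.gene_id}: intron ({s},{e}) outside gene body")
            if s < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping introns")
            prev_end = e


@dataclass
class TRNAGene:
    """A tRNA locus in transcript orientation with flanking sequence.

    ``mature_sequence`` is the spliced gene body (+1 .. N73, introns removed,
    no CCA).  ``upstream_flank`` reads 5'→3' along the transcript and ends at
    N-1; ``downstream_flank`` starts immediately 3' of N73.
    """

    gene_id: str
    species: str
    isotype: str
    anticodon: str
    contig: str
    start: int
    end: int
    strand: str
    mature_sequence: str
    discriminator: str
    upstream_flank: str
    downstream_flank: str
    flags: tuple[str, ...] = ()

    @property
    def intron_removed_length(self) -> int:
        return (self.end - self.start) - len(self.mature_sequence)

    @property
    def isoacceptor(self) -> str:
        return f"{self.isotype}-{self.anticodon}"

    @property
    def n_minus_1(self) -> str | None:
        """Last base of the 5'-leader (immediately upstream of +1)."""
        return self.upstream_flank[-1] if self.upstream_flank else None

    def __post_init__(self) -> None:
        if self.mature_sequence and self.discriminator != self.mature_sequence[-1]:
            raise ValueError(f"{self.gene_id}: discriminator/mature mismatch")


def load_genome(path: str | Path) -> GenomeSource:
    """Read a (possibly gzipped) FASTA genome.

    Sequences are uppercased and U converted to T; duplicate contig ids and
    characters outside {A,C,G,T,N} are hard errors.
    """
    contigs: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in contigs:
                raise ValueError(f"duplicate contig id {rec.id!r}")
            contigs[rec.id] = str(rec.seq).upper().replace("U", "T")
    if not contigs:
        raise ValueError(f"no sequences found in {path}")
    return GenomeSource(contigs)


def _bed12_to_annotation(fields: list[str], species: str) -> GeneAnnotation:
    contig, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
    strand = fields[5]
    n_blocks = int(fields[9])
    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
    offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
    if len(sizes) != n_blocks or len(offsets) != n_blocks:
        raise ValueError(f"{name}: blockCount disagrees with block lists")
    blocks = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
    # introns are the gaps between consecutive blocks
    introns = [(blocks[i][1], blocks[i + 1][0]) for i in range(len(blocks) - 1)]
    isotype, anticodon = _parse_trna_name(name)
    return GeneAnnotation(
        gene_id=name, species=species, isotype=isotype, anticodon=anticodon,
        contig=contig, start=start, end=end, strand=strand, intron_blocks=introns,
    )


def _parse_trna_name(name: str) -> tuple[str, str]:
    """Pull isotype/anticodon from GtRNAdb-style names like ``tRNA-Gln-TTG-1-1``."""
    parts = name.split("tRNA-")[-1].split("-")
    if len(parts) >= 2 and len(parts[1]) == 3:
        return parts[0], parts[1].upper().replace("U", "T")
    return "Und", "NNN"


_TSV_REQUIRED = {"gene_id", "contig", "start", "end", "strand", "isotype", "anticodon"}


def parse_annotations(path: str | Path, species: str) -> list[GeneAnnotation]:
    """Parse tRNA gene annotations from BED12 or a GtRNAdb-style TSV.

    Dialect is auto-detected: a header line containing ``gene_id`` selects the
    TSV reader (1-based inclusive coordinates, optional comma-separated
    ``intron_starts``/``intron_ends`` columns, also 1-based inclusive);
    otherwise lines must be 12-column BED (0-based half-open, blocks → exons).
    Records with a bad strand or with introns outside the gene body are
    rejected with a logged warning rather than aborting the run.
    """
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"no annotation records in {path}")
    header_fields = lines[0].split("\t")
    annotations: list[GeneAnnotation] = []
    if "gene_id" in header_fields:
        idx = {name: i for i, name in enumerate(header_fields)}
        missing = _TSV_REQUIRED - set(idx)
        if missing:
            raise ValueError(f"TSV missing required columns: {sorted(missing)}")
        for ln in lines[1:]:
            f = ln.split("\t")
            try:
                start1, end1 = int(f[idx["start"]]), int(f[idx["end"]])
                introns = []
                if "intron_starts" in idx and f[idx["intron_starts"]].strip():
                    istarts = [int(x) for x in f[idx["intron_starts"]].split(",")]
                    iends = [int(x) for x in f[idx["intron_ends"]].split(",")]
                    introns = [(s - 1, e) for s, e in zip(istarts, iends)]
                annotations.append(GeneAnnotation(
                    gene_id=f[idx["gene_id"]], species=species,
                    isotype=f[idx["isotype"]],
                    anticodon=f[idx["anticodon"]].upper().replace("U", "T"),
                    contig=f[idx["contig"]], start=start1 - 1, end=end1,
                    strand=f[idx["strand"]], intron_blocks=introns,
                ))
            except ValueError as exc:
                log.warning("rejected annotation row %r: %s", ln[:60], exc)
    else:
        for ln in lines:
            f = ln.split("\t")
            if len(f) < 12:
                raise ValueError(f"expected BED12 (12 columns), got {len(f)}")
            try:
                annotations.append(_bed12_to_annotation(f, species))
            except ValueError as exc:
                log.warning("rejected BED record %r: %s", ln[:60], exc)
    return annotations


def extract_gene(genome: GenomeSource, ann: GeneAnnotation,
                 l_up: int = 20, l_down: int = 60) -> TRNAGene:
    """Extract the transcript-oriented record for one annotated locus.

    Minus-strand loci are reverse-complemented so both flanks read 5'→3'
    along the transcript.  Flank windows truncated at a contig edge keep the
    gene but add a ``short_flank`` flag; an N inside the mature body adds
    ``ambiguous_mature``.
    """
    seq = genome.contigs.get(ann.contig)
    if seq is None:
        raise KeyError(f"{ann.gene_id}: contig {ann.contig!r} not in genome")
    if ann.end > len(seq):
        raise ValueError(f"{ann.gene_id}: gene body extends past contig end")
    flags: list[str] = []

    body = seq[ann.start:ann.end]
    spliced = body
    for (s, e) in sorted(ann.intron_blocks, reverse=True):
        spliced = spliced[:s - ann.start] + spliced[e - ann.start:]

    left = seq[max(0, ann.start - (l_up if ann.strand == "+" else l_down)):ann.start]
    right = seq[ann.end:ann.end + (l_down if ann.strand == "+" else l_up)]
    if ann.strand == "+":
        mature, upstream, downstream = spliced, left, right
        if len(left) < l_up or len(right) < l_down:
            flags.append("short_flank")
    else:
        mature = reverse_complement(spliced)
        upstream = reverse_complement(right)
        downstream = reverse_complement(left)
        if len(right) < l_up or len(left) < l_down:
            flags.append("short_flank")
    if not mature:
        raise ValueError(f"{ann.gene_id}: empty mature sequence")
    if "N" in mature:
        flags.append("ambiguous_mature")
    return TRNAGene(
        gene_id=ann.gene_id, species=ann.species, isotype=ann.isotype,
        anticodon=ann.anticodon, contig=ann.contig, start=ann.start,
        end=ann.end, strand=ann.strand, mature_sequence=mature,
        discriminator=mature[-1], upstream_flank=upstream,
        downstream_flank=downstream, flags=tuple(flags),
    )


def build_catalog(genome: GenomeSource, annotations: Iterable[GeneAnnotation],
                  l_up: int = 20, l_down: int = 60) -> list[TRNAGene]:
    """Extract every annotation; loci that fail extraction are logged and dropped."""
    genes = []
    for ann in annotations:
        try:
            genes.append(extract_gene(genome, ann, l_up=l_up, l_down=l_down))
        except (ValueError, KeyError) as exc:
            log.warning("dropped %s: %s", ann.gene_id, exc)
    return genes


def write_catalog(genes: Iterable[TRNAGene], path: str | Path) -> None:
    rows = []
    for g in genes:
        rows.append({
            "gene_id": g.gene_id, "species": g.species, "isotype": g.isotype,
            "anticodon": g.anticodon, "contig": g.contig, "start": g.start,
            "end": g.end, "strand": g.strand, "mature_sequence": g.mature_sequence,
            "discriminator": g.discriminator, "upstream_flank": g.upstream_flank,
            "downstream_flank": g.downstream_flank, "flags": ",".join(g.flags),
        })
    pd.DataFrame(rows, columns=CATALOG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_catalog(path: str | Path) -> list[TRNAGene]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    genes = []
    for row in df.itertuples(index=False):
        genes.append(TRNAGene(
            gene_id=row.gene_id, species=row.species, isotype=row.isotype,
            anticodon=row.anticodon, contig=row.contig, start=int(row.start),
            end=int(row.end), strand=row.strand,
            mature_sequence=row.mature_sequence, discriminator=row.discriminator,
            upstream_flank=row.upstream_flank, downstream_flank=row.downstream_flank,
            flags=tuple(f for f in row.flags.split(",") if f),
        ))
    return genes


def filter_determined(genes: Iterable[TRNAGene]) -> list[TRNAGene]:
    """Drop pseudogene-like entries (anticodon NNN or isotype Und) from statistics."""
    return [g for g in genes if g.anticodon != "NNN" and g.isotype != "Und"]
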