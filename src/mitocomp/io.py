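"""Readers and writers for annotated mitogenomes and interchange formats.

GenBank flat files (read/write, via Biopython), single-record FASTA plus a
tab-separated feature table (read/write), and per-gene FASTA export.  All
readers normalize into the :class:`~mitocomp.genome.Mitogenome` model:
0-based half-open coordinates on the deposited J strand, ``complement``
locations mapped to strand N, origin-spanning ``join`` locations flagged
``wraps_origin``, and gene names mapped to canonical symbols.
"""

from __future__ import annotations

import io as _io
import logging
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import (CompoundLocation, SeqFeature, SimpleLocation)
from Bio.SeqRecord import SeqRecord

from .genome import (GeneFeature, Mitogenome, feature_sequence,
                     normalize_gene_name)

logger = logging.getLogger(__name__)

_FTYPE_BY_KEY = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}

FEATURE_TABLE_COLUMNS = ("name", "ftype", "start", "end", "strand")


class FormatError(ValueError):
    """Raised for unparseable or inconsistent input records."""


def _feature_label(bio_feat: SeqFeature) -> str:
    for key in ("gene", "product", "locus_tag", "note"):
        if key in bio_feat.qualifiers:
            return str(bio_feat.qualifiers[key][0])
    return "unknown"


def _from_bio_feature(bio_feat: SeqFeature, length: int) -> GeneFeature:
    ftype = _FTYPE_BY_KEY[bio_feat.type]
    loc = bio_feat.location
    strand = "N" if loc.strand == -1 else "J"
    wraps = False
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        # An origin-spanning join has one part ending at the terminus and
        # one starting at 0.
        if (len(parts) == 2 and int(parts[0].start) == 0
                and int(parts[1].end) == length):
            start, end, wraps = int(parts[1].start), int(parts[0].end), True
        else:
            start, end = int(loc.start), int(loc.end)
    else:
        start, end = int(loc.start), int(loc.end)
    anticodon = None
    if "anticodon" in bio_feat.qualifiers:
        raw = str(bio_feat.qualifiers["anticodon"][0])
        anticodon = raw.rsplit(":", 1)[-1].strip("() ")
    name = normalize_gene_name(_feature_label(bio_feat), anticodon=anticodon)
    return GeneFeature(name=name, ftype=ftype, start=start, end=end,
                       strand=strand, wraps_origin=wraps)


def read_genbank(stream: TextIO | str) -> list[Mitogenome]:
    """Parse a GenBank flat file into a list of Mitogenome records."""
    if not isinstance(stream, str):
        stream = stream.read()
    genomes: list[Mitogenome] = []
    try:
        records = list(SeqIO.parse(_io.StringIO(stream), "genbank"))
    except ValueError as exc:
        raise FormatError(f"unparseable GenBank record: {exc}") from exc
    if not records and stream.strip():
        raise FormatError("no parseable GenBank record in input")
    for rec in records:
        feats = [
            _from_bio_feature(bf, len(rec.seq))
            for bf in rec.features if bf.type in _FTYPE_BY_KEY
        ]
        circular = rec.annotations.get("topology", "circular") == "circular"
        genomes.append(Mitogenome(
            id=rec.id if rec.id != "<unknown id>" else rec.name,
            sequence=str(rec.seq).upper(),
            is_circular=circular,
            features=feats,
            source="genbank",
        ))
    return genomes


def write_genbank(genomes: Iterable[Mitogenome], handle: TextIO) -> None:
    """Write genomes as GenBank flat files (inverse of :func:`read_genbank`)."""
    records = []
    for g in genomes:
        rec = SeqRecord(Seq(g.sequence), id=g.id, name=g.id[:16],
                        description=f"{g.id} mitochondrion")
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = "circular" if g.is_circular else "linear"
        key_by_ftype = {v: k for k, v in _FTYPE_BY_KEY.items()}
        for f in g.features:
            strand = -1 if f.strand == "N" else 1
            if f.wraps_origin:
                loc = CompoundLocation([
                    SimpleLocation(f.start, len(g.sequence), strand),
                    SimpleLocation(0, f.end, strand),
                ]) if strand == 1 else CompoundLocation([
                    SimpleLocation(0, f.end, strand),
                    SimpleLocation(f.start, len(g.sequence), strand),
                ])
            else:
                loc = SimpleLocation(f.start, f.end, strand)
            qualifiers = {"gene": [f.name]}
            bio = SeqFeature(loc, type=key_by_ftype[f.ftype],
                             qualifiers=qualifiers)
            rec.features.append(bio)
        records.append(rec)
    SeqIO.write(records, handle, "genbank")


def read_fasta_with_features(fasta_stream: TextIO | str,
                             table_stream: TextIO | str,
                             is_circular: bool = True) -> Mitogenome:
    """Read one FASTA record plus a TSV feature table into a Mitogenome.

    The table has columns name, ftype, start, end, strand with 1-based
    inclusive coordinates and +/- strand symbols.  On a circular genome a
    row with end < start wraps the origin.
    """
    if isinstance(fasta_stream, str):
        fasta_stream = _io.StringIO(fasta_stream)
    if isinstance(table_stream, str):
        table_stream = _io.StringIO(table_stream)
    records = list(SeqIO.parse(fasta_stream, "fasta"))
    if len(records) != 1:
        raise FormatError(f"expected exactly one FASTA record, got {len(records)}")
    rec = records[0]
    length = len(rec.seq)
    feats = []
    for lineno, line in enumerate(table_stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#") or line.startswith("name\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise FormatError(f"feature table line {lineno}: expected 5 "
                              f"tab-separated columns, got {len(parts)}")
        name, ftype, start_s, end_s, strand_sym = parts
        start1, end1 = int(start_s), int(end_s)
        wraps = False
        if end1 < start1:
            if not is_circular:
                raise FormatError(
                    f"feature table line {lineno}: end < start on a "
                    f"non-circular genome")
            wraps = True
        if not (1 <= start1 <= length) or not (1 <= end1 <= length):
            raise FormatError(f"feature table line {lineno}: coordinates "
                              f"outside sequence [1, {length}]")
        feats.append(GeneFeature(
            name=normalize_gene_name(name),
            ftype=ftype,
            start=start1 - 1,
            end=end1,
            strand="N" if strand_sym == "-" else "J",
            wraps_origin=wraps,
        ))
    return Mitogenome(id=rec.id, sequence=str(rec.seq).upper(),
                      is_circular=is_circular, features=feats,
                      source="fasta+table")


def write_feature_table(genome: Mitogenome, handle: TextIO) -> None:
    """Write the TSV feature table (1-based inclusive, +/- strands)."""
    handle.write("\t".join(FEATURE_TABLE_COLUMNS) + "\n")
    for f in genome.features:
        handle.write("\t".join([
            f.name, f.ftype, str(f.start + 1), str(f.end),
            "-" if f.strand == "N" else "+",
        ]) + "\n")


def write_fasta(entries: Iterable[tuple[str, str]], handle: TextIO,
                width: int = 70) -> None:
    for header, seq in entries:
        handle.write(f">{header}\n")
        for i in range(0, len(seq), width):
            handle.write(seq[i:i + width] + "\n")


def read_fasta(stream: TextIO | str) -> list[tuple[str, str]]:
    """Read a (possibly aligned) FASTA into (label, sequence) pairs."""
    if isinstance(stream, str):
        stream = _io.StringIO(stream)
    return [(rec.description or rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(stream, "fasta")]


def export_gene_set(genomes: Iterable[Mitogenome], gene_name: str,
                    handle: TextIO) -> int:
    """Write a FASTA with one sense-strand record per genome carrying a gene.

    Headers are ``genomeID|geneName``.  Genomes lacking the gene are
    skipped with a warning; returns the number of records written.
    """
    written = 0
    for g in genomes:
        feat = g.get_feature(gene_name)
        if feat is None:
            logger.warning("genome %s lacks gene %s; skipped", g.id, gene_name)
            continue
        write_fasta([(f"{g.id}|{gene_name}", feature_sequence(g, feat))],
                    handle)
        written += 1
    if written == 0:
        raise ValueError(f"gene {gene_name!r} absent from all genomes")
    return written


def parse_gene_set_header(header: str) -> tuple[str, str]:
    """Inverse of the export header convention: 'id|gene' -> (id, gene)."""
    genome_id, _, gene = header.rpartition("|")
    if not genome_id:
        raise FormatError(f"header {header!r} is not of the form id|gene")
    return genome_id, gene
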