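"""Core data model for annotated mitochondrial genomes.

Coordinates are 0-based half-open on the deposited forward (J) strand
throughout the package; readers convert from 1-based inclusive formats at
the boundary.  A feature on the minority (N) strand stores its interval on
the deposited strand and its sense sequence is recovered by reverse
complementation.  Features may wrap the origin of the circular molecule,
in which case ``start > end`` and the interval is read as
``[start, length) + [0, end)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: The 13 protein-coding genes in the fixed concatenation order used for
#: supermatrix export (genome order of the typical insect arrangement).
PCG_ORDER = (
    "ND2", "COI", "COII", "ATP8", "ATP6", "COIII", "ND3",
    "ND5", "ND4", "ND4L", "ND6", "CytB", "ND1",
)

TRNA_NAMES = (
    "tRNA-Ile", "tRNA-Gln", "tRNA-Met", "tRNA-Trp", "tRNA-Cys", "tRNA-Tyr",
    "tRNA-Leu2", "tRNA-Lys", "tRNA-Asp", "tRNA-Gly", "tRNA-Ala", "tRNA-Arg",
    "tRNA-Asn", "tRNA-Ser1", "tRNA-Glu", "tRNA-Phe", "tRNA-His", "tRNA-Thr",
    "tRNA-Pro", "tRNA-Ser2", "tRNA-Leu1", "tRNA-Val",
)

RRNA_NAMES = ("rRNA-12S", "rRNA-16S")

#: Synonym map from common annotation spellings to canonical symbols.
GENE_SYNONYMS = {
    "COX1": "COI", "COX2": "COII", "COX3": "COIII",
    "CO1": "COI", "CO2": "COII", "CO3": "COIII",
    "COB": "CytB", "CYTB": "CytB", "CYB": "CytB",
    "ATP6": "ATP6", "ATP8": "ATP8", "ATPASE6": "ATP6", "ATPASE8": "ATP8",
    "NAD1": "ND1", "NAD2": "ND2", "NAD3": "ND3", "NAD4": "ND4",
    "NAD4L": "ND4L", "NAD5": "ND5", "NAD6": "ND6",
    "NADH1": "ND1", "NADH2": "ND2", "NADH3": "ND3", "NADH4": "ND4",
    "NADH4L": "ND4L", "NADH5": "ND5", "NADH6": "ND6",
    "RRNL": "rRNA-16S", "RRNS": "rRNA-12S",
    "16S": "rRNA-16S", "12S": "rRNA-12S",
    "L-RRNA": "rRNA-16S", "S-RRNA": "rRNA-12S",
    "16S RIBOSOMAL RNA": "rRNA-16S", "12S RIBOSOMAL RNA": "rRNA-12S",
    "LARGE SUBUNIT RIBOSOMAL RNA": "rRNA-16S",
    "SMALL SUBUNIT RIBOSOMAL RNA": "rRNA-12S",
}

#: Amino-acid 3-letter codes used in tRNA names.
_AA3 = {
    "ALA": "Ala", "ARG": "Arg", "ASN": "Asn", "ASP": "Asp", "CYS": "Cys",
    "GLN": "Gln", "GLU": "Glu", "GLY": "Gly", "HIS": "His", "ILE": "Ile",
    "LEU": "Leu", "LYS": "Lys", "MET": "Met", "PHE": "Phe", "PRO": "Pro",
    "SER": "Ser", "THR": "Thr", "TRP": "Trp", "TYR": "Tyr", "VAL": "Val",
}

# Anticodon classes disambiguating the two Ser / Leu tRNA paralogs.
# Ser1 reads AGN codons (GCU-class anticodon), Ser2 reads UCN (UGA-class);
# Leu1 reads CUN (UAG-class), Leu2 reads UUR (UAA-class).
SER1_ANTICODONS = {"GCT", "GCU", "TCT", "UCU"}
SER2_ANTICODONS = {"TGA", "UGA"}
LEU1_ANTICODONS = {"TAG", "UAG"}
LEU2_ANTICODONS = {"TAA", "UAA"}


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_gene_name(raw: str, anticodon: str | None = None) -> str:
    """Map a raw annotation label to the canonical 37-gene symbol.

    Unknown names are returned unchanged (with a logged warning) so that
    partially annotated records remain usable.
    """
    name = raw.strip()
    upper = name.upper().replace("-", "").replace("_", "").replace(" ", "")
    canonical = {
        "COI", "COII", "COIII", "CYTB", "ATP6", "ATP8",
        "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
    }
    if upper in canonical:
        return {"CYTB": "CytB"}.get(upper, upper)
    plain = name.upper().replace("_", "").replace(" ", "").replace("-", "")
    if plain in GENE_SYNONYMS:
        return GENE_SYNONYMS[plain]
    if name.upper().replace("_", "-").replace(" ", "-") in GENE_SYNONYMS:
        return GENE_SYNONYMS[name.upper().replace("_", "-").replace(" ", "-")]
    # tRNA forms: trnL, trnS2, tRNA-Ser, tRNA-Ser1, trnL(tag) ...
    u = name.upper()
    if u.startswith("TRNA-") or u.startswith("TRN"):
        body = u.removeprefix("TRNA-").removeprefix("TRN")
        acod = anticodon
        if "(" in body and body.endswith(")"):
            body, _, paren = body.partition("(")
            acod = acod or paren.rstrip(")")
        body = body.strip("-")
        suffix = ""
        if body and body[-1] in "12":
            suffix = body[-1]
            body = body[:-1]
        aa = None
        if body in _AA3:
            aa = _AA3[body]
        elif len(body) == 1:
            lookup = {"A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp",
                      "C": "Cys", "Q": "Gln", "E": "Glu", "G": "Gly",
                      "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
                      "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser",
                      "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val"}
            aa = lookup.get(body)
        if aa is not None:
            if aa in ("Ser", "Leu") and not suffix and acod:
                ac = acod.upper()
                if aa == "Ser":
                    suffix = "1" if ac in SER1_ANTICODONS else (
                        "2" if ac in SER2_ANTICODONS else "")
                else:
                    suffix = "1" if ac in LEU1_ANTICODONS else (
                        "2" if ac in LEU2_ANTICODONS else "")
            return f"tRNA-{aa}{suffix}"
    if u in ("RRNA-12S", "RRNA-16S"):
        return "rRNA-" + u[-3:]
    logger.warning("unrecognized gene name %r kept as-is", raw)
    return name


@dataclass
class GeneFeature:
    """One annotated subunit (PCG, tRNA or rRNA) of a mitogenome."""

    name: str
    ftype: str  # "PCG" | "tRNA" | "rRNA"
    start: int  # 0-based inclusive on the deposited (J) strand
    end: int    # 0-based exclusive
    strand: str = "J"  # "J" (forward/majority) or "N" (reverse/minority)
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.ftype not in ("PCG", "tRNA", "rRNA"):
            raise ValueError(f"unknown feature type {self.ftype!r}")
        if self.strand not in ("J", "N"):
            raise ValueError(f"strand must be J or N, got {self.strand!r}")

    def length(self, genome_length: int) -> int:
        """Feature length in nucleotides, handling origin wrap."""
        if self.wraps_origin:
            return (genome_length - self.start) + self.end
        return self.end - self.start


@dataclass
class Mitogenome:
    """Circular (by default) annotated mitochondrial genome."""

    id: str
    sequence: str
    is_circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)
    source: str = "synthetic"  # genbank | fasta+table | synthetic

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("empty genome sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
        self.features.sort(key=lambda f: (f.start, f.end))
        for f in self.features:
            if not (0 <= f.start < len(self.sequence)):
                raise ValueError(f"{f.name}: start {f.start} out of range")
            if not (0 < f.end <= len(self.sequence)):
                raise ValueError(f"{f.name}: end {f.end} out of range")
            if not f.wraps_origin and f.end <= f.start:
                raise ValueError(
                    f"{f.name}: end <= start without wraps_origin")

    def __len__(self) -> int:
        return len(self.sequence)

    def features_of_type(self, ftype: str) -> list[GeneFeature]:
        return [f for f in self.features if f.ftype == ftype]

    def get_feature(self, name: str) -> GeneFeature | None:
        for f in self.features:
            if f.name == name:
                return f
        return None


def feature_sequence(genome: Mitogenome, feat: GeneFeature) -> str:
    """Sense-strand sequence of a feature.

    Forward slice for strand J, reverse complement for strand N; a feature
    wrapping the origin concatenates tail + head before orientation.
    """
    if feat.wraps_origin:
        raw = genome.sequence[feat.start:] + genome.sequence[:feat.end]
    else:
        raw = genome.sequence[feat.start:feat.end]
    return reverse_complement(raw) if feat.strand == "N" else raw
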