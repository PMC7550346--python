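"""Codon counting, RSCU and terminal-codon classification.

Everything here runs under the invertebrate mitochondrial genetic code
(NCBI translation table 5): AGA/AGG encode serine (an 8-codon Ser
family), ATA encodes methionine, TGA encodes tryptophan, and only TAA and
TAG are stops, leaving 62 sense codons.

RSCU (relative synonymous codon usage) of a codon c in a synonymous
family F is::

    RSCU(c) = count(c) * |F| / sum_{c' in F} count(c')

i.e. the observed count divided by the count expected if all members of
the family were used uniformly.  Family values therefore sum to |F|.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

from Bio.Data import CodonTable

_TABLE5 = CodonTable.unambiguous_dna_by_id[5]

#: codon -> one-letter amino acid, stops mapped to '*'
CODON_TO_AA: dict[str, str] = dict(_TABLE5.forward_table)
for _stop in _TABLE5.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = frozenset(_TABLE5.stop_codons)          # {TAA, TAG}
START_CODONS = frozenset(_TABLE5.start_codons)
SENSE_CODONS = tuple(sorted(c for c in CODON_TO_AA if c not in STOP_CODONS))

#: amino acid -> tuple of synonymous codons (stops excluded)
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    FAMILIES.setdefault(CODON_TO_AA[_codon], ())
FAMILIES = {aa: tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa)
            for aa in FAMILIES}

AA_THREE = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}


def as_rna(codon: str) -> str:
    """Display form of a codon (U for T), used in RSCU output tables."""
    return codon.replace("T", "U")


def translate(cds_sense_seq: str) -> str:
    """Table-5 translation; terminal stop rendered '*', N-codons as 'X'."""
    seq = cds_sense_seq.upper()
    seq = seq[:len(seq) - len(seq) % 3]
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        out.append("X" if "N" in codon else CODON_TO_AA[codon])
    return "".join(out)


def iter_codons(cds_sense_seq: str):
    seq = cds_sense_seq.upper()
    for i in range(0, len(seq) - len(seq) % 3, 3):
        yield seq[i:i + 3]


@dataclass
class CodonUsageTable:
    """Per-codon counts over a CDS set, with stop-included and
    stop-excluded totals."""

    counts: Counter = field(default_factory=Counter)

    @property
    def total_codons(self) -> int:
        """All complete codons, stops included (concatenated length / 3)."""
        return sum(self.counts.values())

    @property
    def sense_codon_count(self) -> int:
        """Complete codons excluding stop codons."""
        return sum(n for c, n in self.counts.items() if c not in STOP_CODONS)

    def __add__(self, other: "CodonUsageTable") -> "CodonUsageTable":
        return CodonUsageTable(self.counts + other.counts)


def count_codons(cds_sense_seqs: list[str]) -> CodonUsageTable:
    """Count every complete codon of every CDS (order-invariant)."""
    counts: Counter = Counter()
    for seq in cds_sense_seqs:
        counts.update(c for c in iter_codons(seq) if "N" not in c)
    return CodonUsageTable(counts)


def rscu(table: CodonUsageTable) -> dict[str, float]:
    """RSCU per sense codon; an empty family yields 0 for all its codons."""
    values: dict[str, float] = {}
    for aa, family in FAMILIES.items():
        family_total = sum(table.counts.get(c, 0) for c in family)
        for c in family:
            if family_total == 0:
                values[c] = 0.0
            else:
                values[c] = table.counts.get(c, 0) * len(family) / family_total
    return values


def amino_acid_frequencies(table: CodonUsageTable) -> dict[str, float]:
    """Per-amino-acid usage in percent of all sense codons."""
    grand = table.sense_codon_count
    if grand == 0:
        return {aa: float("nan") for aa in FAMILIES}
    return {
        aa: 100.0 * sum(table.counts.get(c, 0) for c in family) / grand
        for aa, family in FAMILIES.items()
    }


def mean_rscu(tables: list[CodonUsageTable]) -> dict[str, float]:
    """Unweighted mean of per-table RSCU values (default averaging mode;
    pooled-count RSCU is available via summing tables first)."""
    per_table = [rscu(t) for t in tables]
    return {c: sum(v[c] for v in per_table) / len(per_table)
            for c in SENSE_CODONS}


@dataclass(frozen=True)
class TerminalCodons:
    start: str
    stop: str
    start_class: str  # ATN | TTG | GTG | other
    stop_class: str   # "complete TAA" | "complete TAG" | "incomplete T/TA" | other


def terminal_codons(cds_sense_seq: str) -> TerminalCodons:
    """Classify the start and stop codon of a CDS.

    A CDS whose length is not a multiple of 3 is taken to end in an
    incomplete stop (T or TA completed by polyadenylation).
    """
    seq = cds_sense_seq.upper()
    if len(seq) < 6:
        raise ValueError("CDS too short to classify terminal codons")
    start = seq[:3]
    if start.startswith("AT"):
        start_class = "ATN"
    elif start in ("TTG", "GTG"):
        start_class = start
    else:
        start_class = "other"
    rem = len(seq) % 3
    if rem:
        stop = seq[-rem:]
        stop_class = ("incomplete T/TA"
                      if stop in ("T", "TA") else "other")
    else:
        stop = seq[-3:]
        stop_class = (f"complete {stop}" if stop in STOP_CODONS else "other")
    return TerminalCodons(start, stop, start_class, stop_class)


def random_sense_codon(rng, forbid_stop: bool = True) -> str:
    """Uniform random codon (sense-only by default); helper for simulation."""
    while True:
        codon = "".join(rng.choice("ACGT") for _ in range(3))
        if not (forbid_stop and codon in STOP_CODONS):
            return codon


# --- single-mutation neighborhoods (shared with the divergence module) ----

def codon_neighbors(codon: str):
    """All 9 single-base variants of a codon with the changed position."""
    for pos, alt in itertools.product(range(3), "ACGT"):
        if alt != codon[pos]:
            yield pos, codon[:pos] + alt + codon[pos + 1:]
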