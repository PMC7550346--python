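"""Base composition and strand-asymmetry (skew) statistics.

Skews follow the standard asymmetry definitions

    AT-skew = (A - T) / (A + T)        GC-skew = (G - C) / (G + C)

computed from raw counts (identical to the percentage-based form, as the
scale factors cancel).  Ambiguity code N never enters a numerator or a
denominator.  Per-gene and per-class statistics are computed on each
gene's SENSE strand: this is what makes the protein-coding genes show
uniformly negative AT-skews while positive GC-skews stay confined to the
minority-strand genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .genome import Mitogenome, feature_sequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompositionStats:
    """Counts and derived fractions/skews for one sequence or category."""

    A: int
    C: int
    G: int
    T: int

    @property
    def length_counted(self) -> int:
        return self.A + self.C + self.G + self.T

    @property
    def at_content(self) -> float:
        n = self.length_counted
        return (self.A + self.T) / n if n else math.nan

    @property
    def gc_content(self) -> float:
        n = self.length_counted
        return (self.G + self.C) / n if n else math.nan

    @property
    def at_skew(self) -> float:
        at = self.A + self.T
        return (self.A - self.T) / at if at else math.nan

    @property
    def gc_skew(self) -> float:
        gc = self.G + self.C
        return (self.G - self.C) / gc if gc else math.nan

    def __add__(self, other: "CompositionStats") -> "CompositionStats":
        return CompositionStats(self.A + other.A, self.C + other.C,
                                self.G + other.G, self.T + other.T)


def base_composition(seq: str) -> CompositionStats:
    """Single-pass base tally; N excluded from every count."""
    return CompositionStats(A=seq.count("A"), C=seq.count("C"),
                            G=seq.count("G"), T=seq.count("T"))


def codon_position_content(cds_sense_seqs: list[str],
                           position: int) -> CompositionStats:
    """Composition of one codon position (1, 2 or 3) over a CDS set.

    Each sequence is trimmed to a multiple of 3; a trailing remainder is
    dropped with a warning (it belongs to no complete codon).
    """
    if position not in (1, 2, 3):
        raise ValueError("position must be 1, 2 or 3")
    total = CompositionStats(0, 0, 0, 0)
    for seq in cds_sense_seqs:
        trimmed_len = len(seq) - len(seq) % 3
        if trimmed_len != len(seq):
            logger.warning("CDS length %d not a multiple of 3; trailing "
                           "%d base(s) dropped", len(seq), len(seq) % 3)
        total = total + base_composition(seq[position - 1:trimmed_len:3])
    return total


# Categories reported for every genome, in output order.
REPORT_CATEGORIES = ("whole_genome", "PCGs", "tRNAs", "rRNAs",
                     "PCG_pos1", "PCG_pos2", "PCG_pos3")


def genome_report(genome: Mitogenome) -> dict[str, CompositionStats]:
    """Composition statistics at every aggregation level.

    Keys: ``whole_genome``, ``PCGs``/``tRNAs``/``rRNAs`` (sense-strand
    concatenations in genome order), ``PCG_pos1..3`` (codon positions of
    the PCG concatenation), and ``gene:<name>`` per individual gene.
    Whole-genome statistics are computed on the deposited J strand.
    """
    report: dict[str, CompositionStats] = {
        "whole_genome": base_composition(genome.sequence)
    }
    by_class: dict[str, list[str]] = {"PCG": [], "tRNA": [], "rRNA": []}
    for feat in genome.features:
        sense = feature_sequence(genome, feat)
        by_class[feat.ftype].append(sense)
        report[f"gene:{feat.name}"] = base_composition(sense)
    for ftype, key in (("PCG", "PCGs"), ("tRNA", "tRNAs"), ("rRNA", "rRNAs")):
        seqs = by_class[ftype]
        if not seqs:
            logger.warning("genome %s has no %s features; category undefined",
                           genome.id, ftype)
            continue
        report[key] = base_composition("".join(seqs))
    if by_class["PCG"]:
        for pos in (1, 2, 3):
            report[f"PCG_pos{pos}"] = codon_position_content(
                by_class["PCG"], pos)
    return report
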