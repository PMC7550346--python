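"""Alignment-based divergence statistics.

Nucleotide diversity (pi) with a 200/25 sliding window, pairwise
p / Jukes-Cantor / Tamura-Nei (TN93) distances, and Nei-Gojobori (1986)
counting of synonymous and non-synonymous sites and differences with
Jukes-Cantor correction:

    pN = Nd / N,  pS = Sd / S,  d = -3/4 * ln(1 - 4p/3),  omega = dN/dS

Sites are counted from single-mutation neighborhoods under translation
table 5 and averaged over the two sequences; differences between codons
differing at k positions are averaged over all k! minimal mutational
pathways, excluding (and renormalizing over) pathways that pass through a
stop codon.  Gapped, ambiguous and stop-containing codons are excluded
pairwise.  All pairwise statistics use pairwise deletion: a column enters
a comparison only when both rows carry an unambiguous base there.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .codons import CODON_TO_AA, STOP_CODONS

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_VALID = frozenset(_BASES)


@dataclass
class Alignment:
    """Equal-length rows over {A,C,G,T,N,-} with ordered labels."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in number")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def slice_cols(self, start: int, end: int) -> "Alignment":
        """Column slice [start, end) in 0-based coordinates."""
        return Alignment(self.labels, [r[start:end] for r in self.rows])


def ungapped_codon_alignment(labels: list[str],
                             cds_sense_seqs: list[str]) -> Alignment:
    """Identity codon alignment for equal-length orthologous CDSs.

    Orthologs of unequal length require an external aligner; this raises
    rather than guessing an alignment.
    """
    lengths = {len(s) for s in cds_sense_seqs}
    if len(lengths) > 1:
        raise ValueError(
            f"CDS lengths differ ({sorted(lengths)}); align the sequences "
            "with an external aligner before codon-wise analysis")
    (length,) = lengths
    if length % 3:
        raise ValueError(f"CDS length {length} is not a multiple of 3")
    return Alignment(labels, list(cds_sense_seqs))


# ------------------------------------------------------------------ pi ----

def _pair_diff(row1: str, row2: str) -> tuple[int, int]:
    """(differences, compared sites) under pairwise deletion."""
    diffs = sites = 0
    for a, b in zip(row1, row2):
        if a in _VALID and b in _VALID:
            sites += 1
            if a != b:
                diffs += 1
    return diffs, sites


def nucleotide_diversity(alignment: Alignment) -> float:
    """Average pairwise proportion of differing sites (pi).

    Each pair contributes differences / sites-compared; pairs with no
    comparable site are excluded.  NaN when nothing is comparable.
    """
    if alignment.n_rows < 2:
        raise ValueError("pi requires at least 2 rows")
    vals = []
    for r1, r2 in itertools.combinations(alignment.rows, 2):
        d, s = _pair_diff(r1, r2)
        if s:
            vals.append(d / s)
    return float(np.mean(vals)) if vals else math.nan


@dataclass(frozen=True)
class WindowValue:
    start: int      # 1-based alignment column
    end: int        # 1-based inclusive
    midpoint: float
    pi: float
    sites_used: int
    partial: bool = False


def sliding_window_diversity(alignment: Alignment, window: int = 200,
                             step: int = 25) -> list[WindowValue]:
    """Sliding-window pi at columns [1,200], [26,225], ...

    The trailing partial window is included and flagged; an alignment
    shorter than the window yields a single whole-alignment window.
    """
    if not (window >= step >= 1):
        raise ValueError("need window >= step >= 1")
    length = alignment.n_cols
    out: list[WindowValue] = []
    if length <= window:
        sub = alignment
        pi = nucleotide_diversity(sub)
        return [WindowValue(1, length, (1 + length) / 2, pi, length,
                            partial=length < window)]
    start = 0
    while start < length:
        end = min(start + window, length)
        sub = alignment.slice_cols(start, end)
        pi = nucleotide_diversity(sub)
        out.append(WindowValue(start + 1, end, (start + 1 + end) / 2, pi,
                               end - start, partial=(end - start) < window))
        if end == length:
            break
        start += step
    return out


# ------------------------------------------------------------- distances --

def jukes_cantor(p: float) -> float:
    """JC69 correction; NaN outside the log domain (p >= 3/4)."""
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def p_distance(row1: str, row2: str) -> float:
    d, s = _pair_diff(row1, row2)
    if s == 0:
        return math.nan
    return d / s


_PURINES = frozenset("AG")
_TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


def tn93_distance(row1: str, row2: str) -> float:
    """Tamura-Nei (1993) distance with separate transition classes.

    Base frequencies are averaged over the two rows at shared sites; P1
    and P2 are the purine and pyrimidine transition proportions, Q the
    transversion proportion.
    """
    counts = {b: 0 for b in _BASES}
    sites = p1 = p2 = q = 0
    for a, b in zip(row1, row2):
        if a in _VALID and b in _VALID:
            sites += 1
            counts[a] += 1
            counts[b] += 1
            if a != b:
                if (a, b) in _TRANSITIONS:
                    if a in _PURINES:
                        p1 += 1
                    else:
                        p2 += 1
                else:
                    q += 1
    if sites == 0:
        return math.nan
    g = {b: counts[b] / (2 * sites) for b in _BASES}
    gR = g["A"] + g["G"]
    gY = g["C"] + g["T"]
    P1, P2, Q = p1 / sites, p2 / sites, q / sites
    if gR == 0 or gY == 0:
        return math.nan
    k1 = 2 * g["A"] * g["G"] / gR
    k2 = 2 * g["T"] * g["C"] / gY
    k3 = 2 * (gR * gY - g["A"] * g["G"] * gY / gR - g["T"] * g["C"] * gR / gY)
    try:
        w1 = 1 - P1 / k1 - Q / (2 * gR) if k1 > 0 else 1.0
        w2 = 1 - P2 / k2 - Q / (2 * gY) if k2 > 0 else 1.0
        w3 = 1 - Q / (2 * gR * gY)
        if min(w1, w2, w3) <= 0:
            return math.nan
        d = 0.0
        if k1 > 0:
            d -= k1 * math.log(w1)
        if k2 > 0:
            d -= k2 * math.log(w2)
        d -= k3 * math.log(w3)
        return d
    except (ValueError, ZeroDivisionError):
        return math.nan


def pairwise_distance(row1: str, row2: str, model: str = "p") -> float:
    if model == "p":
        return p_distance(row1, row2)
    if model.lower() in ("jc", "jc69"):
        return jukes_cantor(p_distance(row1, row2))
    if model.lower() == "tn93":
        return tn93_distance(row1, row2)
    raise ValueError(f"unknown distance model {model!r}")


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray
    model: str = "p"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")

    def value(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])

    def to_tsv(self) -> str:
        lines = ["\t".join([""] + self.labels)]
        for lab, row in zip(self.labels, self.matrix):
            lines.append("\t".join([lab] + [f"{v:.6f}" for v in row]))
        return "\n".join(lines) + "\n"

    def to_phylip(self) -> str:
        lines = [f" {len(self.labels)}"]
        for lab, row in zip(self.labels, self.matrix):
            lines.append("  ".join([f"{lab:<10}"]
                                   + [f"{v:.6f}" for v in row]))
        return "\n".join(lines) + "\n"


def distance_matrix(alignment: Alignment, model: str = "p") -> DistanceMatrix:
    n = alignment.n_rows
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = pairwise_distance(alignment.rows[i], alignment.rows[j], model)
        if math.isnan(d):
            logger.warning("distance %s/%s undefined under %s",
                           alignment.labels[i], alignment.labels[j], model)
        mat[i, j] = mat[j, i] = d
    return DistanceMatrix(list(alignment.labels), mat, model)


# ----------------------------------------------------------------- NG86 ---

@lru_cache(maxsize=None)
def synonymous_site_fraction(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Each position contributes the fraction of its three single-base
    changes that are synonymous; changes creating a stop codon count as
    nonsynonymous.
    """
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for pos in range(3):
        s = 0
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if mutant not in STOP_CODONS and CODON_TO_AA[mutant] == aa:
                s += 1
        syn += s / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _codon_path_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) differences between two codons, averaged over all
    minimal mutational pathways that avoid stop codons.

    If every pathway passes through a stop, all pathways are used (the
    standard fallback), so the counts always total the number of
    differing positions.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    fallback: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        syn = non = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
            if CODON_TO_AA.get(nxt, "*") == CODON_TO_AA[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        (fallback if blocked else valid).append((syn, non))
    paths = valid or fallback
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


@dataclass
class PairwiseRates:
    """Nei-Gojobori site/difference counts and corrected rates for one
    codon-aligned sequence pair."""

    N_sites: float
    S_sites: float
    Nd: float
    Sd: float
    codons_compared: int
    excluded_codons: int = 0

    @property
    def pN(self) -> float:
        return self.Nd / self.N_sites if self.N_sites else math.nan

    @property
    def pS(self) -> float:
        return self.Sd / self.S_sites if self.S_sites else math.nan

    @property
    def dN(self) -> float:
        return jukes_cantor(self.pN)

    @property
    def dS(self) -> float:
        return jukes_cantor(self.pS)

    @property
    def ratio(self) -> float:
        """dN/dS; NaN when dS is 0 or undefined (flagged upstream)."""
        ds = self.dS
        if math.isnan(ds) or ds == 0.0:
            return math.nan
        return self.dN / ds


def _clean_codon_pairs(cds1: str, cds2: str):
    if len(cds1) != len(cds2):
        raise ValueError("NG86 requires a codon-aligned pair of equal length")
    if len(cds1) % 3:
        raise ValueError("aligned CDS length must be a multiple of 3")
    excluded = 0
    for i in range(0, len(cds1), 3):
        a, b = cds1[i:i + 3].upper(), cds2[i:i + 3].upper()
        if (set(a) | set(b)) - _VALID or a in STOP_CODONS or b in STOP_CODONS:
            excluded += 1
            continue
        yield a, b
    if excluded:
        logger.debug("NG86: excluded %d gapped/ambiguous/stop codon pairs",
                     excluded)


def ng86_pair(cds1: str, cds2: str) -> PairwiseRates:
    """Nei-Gojobori site and difference counts for one codon-aligned pair."""
    N = S = Nd = Sd = 0.0
    compared = 0
    total_codons = len(cds1) // 3
    for a, b in _clean_codon_pairs(cds1, cds2):
        compared += 1
        sa, na = synonymous_site_fraction(a)
        sb, nb = synonymous_site_fraction(b)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        syn, non = _codon_path_diffs(a, b)
        Sd += syn
        Nd += non
    return PairwiseRates(N_sites=N, S_sites=S, Nd=Nd, Sd=Sd,
                         codons_compared=compared,
                         excluded_codons=total_codons - compared)
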