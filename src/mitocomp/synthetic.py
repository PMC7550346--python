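"""Synthetic annotated mitogenomes and evolved gene sets with known truth.

The generator emulates the typical insect mitochondrial molecule: a
circular ~15 kb sequence carrying 13 protein-coding genes, 22 tRNAs and
2 rRNAs in the standard insect arrangement with genes on both strands,
AT content near 79%, a slightly positive whole-genome AT-skew, a clearly
negative GC-skew, and a strong A/T bias at third codon positions.  Every
generated quantity is recorded in a truth log so estimator tests compare
against logged expectations rather than magic numbers.

Base sampling: a genome-wide base distribution is derived from the AT
content and skew targets; third codon positions of PCGs are sampled from
an AT-boosted version of it (skews preserved), and genes annotated on
the minority strand are sampled from the complemented distribution on
their sense strand so that the deposited strand keeps the target
composition.  PCGs start with ATN (TTG for ATP6), end with TAA, and are
internally stop-free under translation table 5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .codons import CODON_TO_AA, STOP_CODONS
from .divergence import Alignment
from .genome import (GeneFeature, Mitogenome, reverse_complement)

_BASES = np.array(list("ACGT"))

#: (name, ftype, strand, length) in the typical insect gene arrangement,
#: starting at tRNA-Ile.  PCG lengths are typical culicid values.
GENE_TEMPLATE: tuple[tuple[str, str, str, int], ...] = (
    ("tRNA-Ile", "tRNA", "J", 0), ("tRNA-Gln", "tRNA", "N", 0),
    ("tRNA-Met", "tRNA", "J", 0), ("ND2", "PCG", "J", 1023),
    ("tRNA-Trp", "tRNA", "J", 0), ("tRNA-Cys", "tRNA", "N", 0),
    ("tRNA-Tyr", "tRNA", "N", 0), ("COI", "PCG", "J", 1536),
    ("tRNA-Leu2", "tRNA", "J", 0), ("COII", "PCG", "J", 684),
    ("tRNA-Lys", "tRNA", "J", 0), ("tRNA-Asp", "tRNA", "J", 0),
    ("ATP8", "PCG", "J", 162), ("ATP6", "PCG", "J", 678),
    ("COIII", "PCG", "J", 786), ("tRNA-Gly", "tRNA", "J", 0),
    ("ND3", "PCG", "J", 354), ("tRNA-Ala", "tRNA", "J", 0),
    ("tRNA-Arg", "tRNA", "J", 0), ("tRNA-Asn", "tRNA", "J", 0),
    ("tRNA-Ser1", "tRNA", "J", 0), ("tRNA-Glu", "tRNA", "J", 0),
    ("tRNA-Phe", "tRNA", "N", 0), ("ND5", "PCG", "N", 1719),
    ("tRNA-His", "tRNA", "N", 0), ("ND4", "PCG", "N", 1341),
    ("ND4L", "PCG", "N", 294), ("tRNA-Thr", "tRNA", "J", 0),
    ("tRNA-Pro", "tRNA", "N", 0), ("ND6", "PCG", "J", 519),
    ("CytB", "PCG", "J", 1134), ("tRNA-Ser2", "tRNA", "J", 0),
    ("ND1", "PCG", "N", 939), ("tRNA-Leu1", "tRNA", "N", 0),
    ("rRNA-16S", "rRNA", "N", 1360), ("tRNA-Val", "tRNA", "N", 0),
    ("rRNA-12S", "rRNA", "N", 792),
)


class SpecError(ValueError):
    """Raised for infeasible generator specifications."""


def base_probabilities(at: float, at_skew: float,
                       gc_skew: float) -> dict[str, float]:
    """Per-base probabilities realizing an AT content and both skews."""
    if not (0.0 < at < 1.0):
        raise SpecError(f"AT content {at} outside (0, 1)")
    for name, skew in (("AT", at_skew), ("GC", gc_skew)):
        if not (-1.0 <= skew <= 1.0):
            raise SpecError(f"{name}-skew {skew} outside [-1, 1]")
    gc = 1.0 - at
    return {
        "A": at * (1 + at_skew) / 2, "T": at * (1 - at_skew) / 2,
        "G": gc * (1 + gc_skew) / 2, "C": gc * (1 - gc_skew) / 2,
    }


def _complement_probs(p: dict[str, float]) -> dict[str, float]:
    return {"A": p["T"], "T": p["A"], "G": p["C"], "C": p["G"]}


def _sample(rng: np.random.Generator, probs: dict[str, float],
            n: int) -> str:
    weights = np.array([probs[b] for b in "ACGT"])
    return "".join(rng.choice(_BASES, size=n, p=weights / weights.sum()))


@dataclass
class GenomeSpec:
    """Targets for one synthetic mitogenome (the study conditions)."""

    at_content: float = 0.79           # whole-genome AT target
    at_skew: float = 0.011             # deposited-strand AT-skew target
    gc_skew: float = -0.166            # deposited-strand GC-skew target
    third_position_at: float = 0.95    # AT target at PCG third positions
    n_spacers: int = 24                # intergenic spacers (lengths 1..47)
    max_spacer: int = 47
    wobble_rate: float = 0.04          # per stem pair, GU instead of WC
    mismatch_rate: float = 0.004       # per stem pair, random mismatch
    seed: int = 0

    def __post_init__(self) -> None:
        base_probabilities(self.at_content, self.at_skew, self.gc_skew)
        if not (0.0 < self.third_position_at < 1.0):
            raise SpecError("third_position_at outside (0, 1)")
        if self.n_spacers < 0 or self.max_spacer < 1:
            raise SpecError("invalid spacer parameters")


def _boosted_probs(p: dict[str, float], at_target: float) -> dict[str, float]:
    """Rescale a distribution to a new AT content, preserving both skews."""
    at = p["A"] + p["T"]
    gc = p["G"] + p["C"]
    if at == 0 or gc == 0:
        raise SpecError("cannot boost a degenerate base distribution")
    return {
        "A": p["A"] / at * at_target, "T": p["T"] / at * at_target,
        "G": p["G"] / gc * (1 - at_target), "C": p["C"] / gc * (1 - at_target),
    }


def _pcg_sequence(rng: np.random.Generator, length: int,
                  probs12: dict[str, float], probs3: dict[str, float],
                  start_codon: str) -> str:
    """Internally stop-free CDS: fixed start codon, TAA terminator."""
    n_codons = length // 3
    codons = [start_codon]
    for _ in range(n_codons - 2):
        c12 = _sample(rng, probs12, 2)
        while True:
            c3 = _sample(rng, probs3, 1)
            if c12 + c3 not in STOP_CODONS:
                break
        codons.append(c12 + c3)
    codons.append("TAA")
    return "".join(codons)


def _trna_template(rng: np.random.Generator, with_dhu: bool):
    """Cloverleaf segment plan: list of (kind, size) with kind 'stem'
    (paired run, appears 5' then mirrored 3') handled positionally."""
    dhu_loop = int(rng.integers(6, 9))
    var_loop = int(rng.integers(2, 5))
    parts: list[tuple[str, int]] = [("stem_open", 7), ("loop", 2)]
    if with_dhu:
        parts += [("stem_open", 4), ("loop", dhu_loop), ("stem_close", 4)]
    else:
        parts += [("loop", dhu_loop + 2)]
    parts += [("loop", 1),
              ("stem_open", 5), ("loop", 7), ("stem_close", 5),
              ("loop", var_loop),
              ("stem_open", 5), ("loop", 7), ("stem_close", 5),
              ("stem_close", 7), ("loop", 1)]
    return parts


_WC_PARTNER = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _trna_from_template(rng: np.random.Generator, parts,
                        probs: dict[str, float], wobble_rate: float,
                        mismatch_rate: float):
    """Build (rna_seq, dotbracket, truth) from a segment plan."""
    seq: list[str] = []
    db: list[str] = []
    open_stack: list[list[int]] = []  # positions of open stem runs
    truth = {"wc": 0, "wobble": 0, "mismatch": 0}
    rna_probs = {("U" if b == "T" else b): v for b, v in probs.items()}

    def draw() -> str:
        bases = ["A", "C", "G", "U"]
        w = np.array([rna_probs[b] for b in bases])
        return str(rng.choice(np.array(bases), p=w / w.sum()))

    for kind, size in parts:
        if kind == "loop":
            for _ in range(size):
                seq.append(draw())
                db.append(".")
        elif kind == "stem_open":
            run = []
            for _ in range(size):
                seq.append(draw())
                db.append("(")
                run.append(len(seq) - 1)
            open_stack.append(run)
        else:  # stem_close: mirror the most recent open run
            run = open_stack.pop()
            for pos in reversed(run):
                five = seq[pos]
                u = rng.random()
                if u < mismatch_rate:
                    partner = draw()
                    while partner == _WC_PARTNER[five]:
                        partner = draw()
                    cls = ("wobble" if {five, partner} == {"G", "U"}
                           else "mismatch")
                elif u < mismatch_rate + wobble_rate and five in "GU":
                    partner = "U" if five == "G" else "G"
                    cls = "wobble"
                else:
                    partner = _WC_PARTNER[five]
                    cls = "wc"
                truth[cls] += 1
                seq.append(partner)
                db.append(")")
    return "".join(seq), "".join(db), truth


def _effective_at(spec: GenomeSpec) -> float:
    """Non-third-position AT needed to hit the whole-genome AT target in
    expectation despite the boosted PCG third positions."""
    pcg_nt = sum(ln for _, ft, _, ln in GENE_TEMPLATE if ft == "PCG")
    rrna_nt = sum(ln for _, ft, _, ln in GENE_TEMPLATE if ft == "rRNA")
    trna_nt = 70 * 21 + 64          # expected cloverleaf lengths
    exp_spacer = round(min(spec.n_spacers, len(GENE_TEMPLATE))
                       * (1 + 1 / 0.12))
    exp_length = pcg_nt + rrna_nt + trna_nt + exp_spacer
    n_pos3 = pcg_nt // 3
    at_eff = ((spec.at_content * exp_length
               - spec.third_position_at * n_pos3) / (exp_length - n_pos3))
    if not (0.0 < at_eff < 1.0):
        raise SpecError(
            f"infeasible composition targets: whole-genome AT "
            f"{spec.at_content} with third-position AT "
            f"{spec.third_position_at} requires non-third-position AT "
            f"{at_eff:.3f}")
    return at_eff


def simulate_mitogenome(spec: GenomeSpec) -> tuple[Mitogenome, dict]:
    """Generate one annotated circular mitogenome plus its truth log.

    Generation is two-pass: a pilot genome is measured and the input base
    probabilities are corrected by the residual before the final draw, so
    systematic composition shifts introduced by the codon constraints
    (stop avoidance, fixed terminal codons, stem complementarity, wobble
    pairs) cancel instead of biasing the targets.

    Returns ``(genome, truth)`` where truth records the spec, per-gene
    sense sequences and lengths, tRNA structures with pair-class counts,
    spacer lengths, and the expected composition targets.
    """
    from .composition import base_composition, codon_position_content

    at_eff = _effective_at(spec)
    at3 = spec.third_position_at
    at, skA, skG = at_eff, spec.at_skew, spec.gc_skew
    genome = truth = None
    for pass_no, sub_seed in enumerate((spec.seed + 1_000_003, spec.seed)):
        probs = base_probabilities(
            min(max(at, 1e-3), 1 - 1e-3),
            min(max(skA, -0.999), 0.999), min(max(skG, -0.999), 0.999))
        probs3 = _boosted_probs(probs, min(max(at3, 1e-3), 1 - 1e-3))
        rng = np.random.default_rng(sub_seed)
        genome, truth = _generate(spec, rng, probs, probs3)
        if pass_no == 1:
            break
        # residual correction from the pilot pass
        whole = base_composition(genome.sequence)
        pcg_sense = [truth["genes"][n]["sense_sequence"]
                     for n, ft, _, _ in GENE_TEMPLATE if ft == "PCG"]
        pos3 = codon_position_content(pcg_sense, 3)
        at = at + (spec.at_content - whole.at_content)
        skA = skA + (spec.at_skew - whole.at_skew)
        skG = skG + (spec.gc_skew - whole.gc_skew)
        at3 = at3 + (spec.third_position_at - pos3.at_content)
    truth["expected"] = {"at_content": spec.at_content,
                         "at_skew": spec.at_skew, "gc_skew": spec.gc_skew,
                         "nonpos3_at": at_eff}
    return genome, truth


def _generate(spec: GenomeSpec, rng: np.random.Generator,
              probs: dict[str, float], probs3: dict[str, float]
              ) -> tuple[Mitogenome, dict]:

    # choose spacer positions among the 37 inter-gene junctions
    n_junctions = len(GENE_TEMPLATE)
    k = min(spec.n_spacers, n_junctions)
    spacer_slots = set(rng.choice(n_junctions, size=k, replace=False).tolist())
    # small spacers: geometric-ish lengths capped at max_spacer
    spacer_lengths = {
        slot: int(min(1 + rng.geometric(0.12), spec.max_spacer))
        for slot in sorted(spacer_slots)
    }

    start_by_gene = {"ATP6": "TTG"}
    atn = ("ATA", "ATT", "ATG", "ATC")

    seq_parts: list[str] = []
    features: list[GeneFeature] = []
    structures: dict[str, tuple[str, str]] = {}
    truth: dict = {
        "spec": {
            "at_content": spec.at_content, "at_skew": spec.at_skew,
            "gc_skew": spec.gc_skew,
            "third_position_at": spec.third_position_at,
            "seed": spec.seed,
        },
        "genes": {}, "spacers": spacer_lengths,
        "pair_classes": {}, "start_codons": {},
    }
    truth["spacer_sequences"] = {}
    cursor = 0
    for slot, (name, ftype, strand, length) in enumerate(GENE_TEMPLATE):
        if slot in spacer_lengths:
            spacer = _sample(rng, probs, spacer_lengths[slot])
            truth["spacer_sequences"][slot] = spacer
            seq_parts.append(spacer)
            cursor += len(spacer)
        # sense-strand base distribution: complemented for N-strand genes
        sense_probs = probs if strand == "J" else _complement_probs(probs)
        sense_probs3 = probs3 if strand == "J" else _complement_probs(probs3)
        if ftype == "PCG":
            start_codon = start_by_gene.get(
                name, atn[int(rng.integers(0, len(atn)))])
            sense = _pcg_sequence(rng, length, sense_probs, sense_probs3,
                                  start_codon)
            truth["start_codons"][name] = start_codon
        elif ftype == "tRNA":
            parts = _trna_template(rng, with_dhu=(name != "tRNA-Ser1"))
            rna, db, pc = _trna_from_template(
                rng, parts, sense_probs, spec.wobble_rate, spec.mismatch_rate)
            sense = rna.replace("U", "T")
            structures[name] = (rna, db)
            truth["pair_classes"][name] = pc
        else:  # rRNA
            sense = _sample(rng, sense_probs, length)
        deposited = sense if strand == "J" else reverse_complement(sense)
        features.append(GeneFeature(name=name, ftype=ftype, start=cursor,
                                    end=cursor + len(deposited),
                                    strand=strand))
        truth["genes"][name] = {"length": len(sense), "strand": strand,
                                "sense_sequence": sense}
        seq_parts.append(deposited)
        cursor += len(deposited)

    genome = Mitogenome(id=f"synthetic-{spec.seed}",
                        sequence="".join(seq_parts), is_circular=True,
                        features=features, source="synthetic")
    truth["length"] = len(genome.sequence)
    truth["structures"] = structures
    truth["total_spacer_nt"] = sum(spacer_lengths.values())
    return genome, truth


def simulate_study_genomes(n: int = 4, seed: int = 0,
                           spec: GenomeSpec | None = None
                           ) -> tuple[list[Mitogenome], list[dict]]:
    """A set of independently sampled genomes under the same targets."""
    base = spec or GenomeSpec(seed=seed)
    genomes, truths = [], []
    for i in range(n):
        s = GenomeSpec(**{**base.__dict__, "seed": seed + i})
        g, t = simulate_mitogenome(s)
        g.id = f"synthetic-{seed + i}"
        genomes.append(g)
        truths.append(t)
    return genomes, truths


# ------------------------------------------------------ codon evolution ---

@dataclass
class EvolutionSpec:
    """Ground-truth codon substitution process for a pair of orthologs."""

    n_codons: int = 500
    divergence: float = 0.2   # expected proposed changes per site (pairwise)
    omega: float = 0.1        # acceptance probability of nonsynonymous changes
    kappa: float = 1.0        # transition/transversion proposal ratio
    n_lineages: int = 2       # star tree, each branch divergence/2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise SpecError("omega must be non-negative")
        if self.divergence < 0 or self.n_codons < 1 or self.n_lineages < 2:
            raise SpecError("invalid evolution spec")


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _propose_base(rng: np.random.Generator, base: str, kappa: float) -> str:
    """Single-base proposal with transition bias kappa."""
    others = [b for b in "ACGT" if b != base]
    weights = np.array([kappa if _TRANSITION[base] == b else 1.0
                        for b in others])
    return str(rng.choice(np.array(others), p=weights / weights.sum()))


def _random_ancestor(rng: np.random.Generator, n_codons: int) -> str:
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(_BASES, size=3))
        if c not in STOP_CODONS:
            codons.append(c)
    return "".join(codons)


def evolve_cds(espec: EvolutionSpec) -> tuple[Alignment, dict]:
    """Evolve orthologous CDSs under an accept/reject codon process.

    A proposed single-base change is accepted with probability 1 if
    synonymous, ``omega`` if nonsynonymous, and never if it creates a
    stop codon.  Realized event counts per lineage are logged.
    """
    rng = np.random.default_rng(espec.seed)
    ancestor = _random_ancestor(rng, espec.n_codons)
    L = 3 * espec.n_codons
    branch = espec.divergence / 2.0
    rows, labels = [], []
    truth: dict = {"omega": espec.omega, "divergence": espec.divergence,
                   "ancestor": ancestor, "lineages": {}}
    for lineage in range(espec.n_lineages):
        seq = list(ancestor)
        n_prop = int(rng.poisson(branch * L))
        syn = non = rejected = 0
        for _ in range(n_prop):
            pos = int(rng.integers(0, L))
            codon_start = pos - pos % 3
            old_codon = "".join(seq[codon_start:codon_start + 3])
            alt = _propose_base(rng, seq[pos], espec.kappa)
            new_codon = (old_codon[:pos - codon_start] + alt
                         + old_codon[pos - codon_start + 1:])
            if new_codon in STOP_CODONS:
                rejected += 1
                continue
            if CODON_TO_AA[new_codon] == CODON_TO_AA[old_codon]:
                seq[pos] = alt
                syn += 1
            elif rng.random() < espec.omega:
                seq[pos] = alt
                non += 1
            else:
                rejected += 1
        label = f"lineage{lineage + 1}"
        labels.append(label)
        rows.append("".join(seq))
        truth["lineages"][label] = {
            "proposals": n_prop, "synonymous": syn,
            "nonsynonymous": non, "rejected": rejected,
        }
    return Alignment(labels, rows), truth


# -------------------------------------------------- alignment mutation ----

def mutate_alignment(ancestor: str, p: float, n_rows: int,
                     seed: int = 0) -> tuple[Alignment, dict]:
    """Rows derived i.i.d. from an ancestor by per-site substitution.

    Each site of each row is replaced with probability ``p`` by a uniform
    different base.  The expected pairwise difference fraction has the
    closed form ``2 p (1-p) + (2/3) p**2``, recorded in the truth log
    together with its per-pair standard error.
    """
    if not (0.0 <= p < 0.75):
        raise SpecError("substitution probability must be in [0, 0.75)")
    rng = np.random.default_rng(seed)
    L = len(ancestor)
    anc = np.array(list(ancestor))
    rows = []
    for _ in range(n_rows):
        row = anc.copy()
        hits = rng.random(L) < p
        for idx in np.nonzero(hits)[0]:
            choices = [b for b in "ACGT" if b != row[idx]]
            row[idx] = choices[int(rng.integers(0, 3))]
        rows.append("".join(row))
    expected = 2 * p * (1 - p) + (2.0 / 3.0) * p * p
    truth = {
        "p": p, "n_rows": n_rows, "length": L,
        "expected_pairwise_diff": expected,
        "se_single_pair": math.sqrt(expected * (1 - expected) / L),
    }
    labels = [f"row{i + 1}" for i in range(n_rows)]
    return Alignment(labels, rows), truth


# ------------------------------------------------------ genome families ---

#: Default study topology: a five-taxon ingroup (a cherry, then two
#: successively earlier-diverging lineages) plus a distant outgroup.
DEFAULT_FAMILY_TREE = (
    "((((taxonA:0.02,taxonB:0.02):0.015,taxonC:0.035):0.015,"
    "taxonD:0.05):0.03,taxonE:0.08,outgroup:0.25):0;"
)


#: Default gene-specific omega, ordered like the purifying-selection
#: strength typically seen in mosquito mitogenomes: strongest constraint
#: on the complex III/IV genes (COI in particular), weakest on ATP8 and
#: the NADH subunits.
DEFAULT_PER_GENE_OMEGA = {
    "COI": 0.012, "COII": 0.020, "CytB": 0.025, "ATP6": 0.030,
    "COIII": 0.035, "ND3": 0.040, "ND1": 0.045, "ND4L": 0.050,
    "ND4": 0.060, "ND5": 0.065, "ND2": 0.070, "ND6": 0.080, "ATP8": 0.100,
}


@dataclass
class FamilySpec:
    """A set of orthologous mitogenomes evolved along a known tree.

    Branch lengths are expected proposed substitutions per site; PCGs
    evolve under the accept/reject codon process with a gene's omega
    (first and last codons frozen so annotation semantics survive), all
    other positions evolve neutrally.
    """

    genome: GenomeSpec = field(default_factory=GenomeSpec)
    tree: str = DEFAULT_FAMILY_TREE
    omega: float = 0.05
    per_gene_omega: dict[str, float] | None = field(
        default_factory=lambda: dict(DEFAULT_PER_GENE_OMEGA))
    kappa: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.omega < 0 or (self.per_gene_omega is not None
                              and min(self.per_gene_omega.values()) < 0):
            raise SpecError("omega must be non-negative")

    def gene_omega(self, gene: str) -> float:
        if self.per_gene_omega is None:
            return self.omega
        return self.per_gene_omega.get(gene, self.omega)


def _evolve_neutral(rng: np.random.Generator, seq: str, t: float,
                    kappa: float) -> tuple[str, int]:
    """Neutral substitution: Poisson(t*L) proposals, all accepted."""
    s = list(seq)
    L = len(s)
    n = int(rng.poisson(t * L)) if L else 0
    for _ in range(n):
        pos = int(rng.integers(0, L))
        s[pos] = _propose_base(rng, s[pos], kappa)
    return "".join(s), n


def _evolve_pcg(rng: np.random.Generator, seq: str, t: float,
                omega: float, kappa: float) -> tuple[str, dict]:
    """Codon accept/reject process over internal codons only."""
    s = list(seq)
    L = len(s)
    lo, hi = 3, L - 3  # freeze start and stop codons
    counts = {"synonymous": 0, "nonsynonymous": 0, "rejected": 0}
    n = int(rng.poisson(t * L))
    for _ in range(n):
        pos = int(rng.integers(lo, hi))
        cstart = pos - pos % 3
        old = "".join(s[cstart:cstart + 3])
        alt = _propose_base(rng, s[pos], kappa)
        new = old[:pos - cstart] + alt + old[pos - cstart + 1:]
        if new in STOP_CODONS:
            counts["rejected"] += 1
            continue
        if CODON_TO_AA[new] == CODON_TO_AA[old]:
            s[pos] = alt
            counts["synonymous"] += 1
        elif rng.random() < omega:
            s[pos] = alt
            counts["nonsynonymous"] += 1
        else:
            counts["rejected"] += 1
    return "".join(s), counts


def _assemble_genome(gid: str, gene_seqs: dict[str, str],
                     spacer_seqs: dict[int, str]) -> Mitogenome:
    """Rebuild a deposited-strand genome from per-gene sense sequences
    and per-junction spacers, following the template arrangement."""
    seq_parts: list[str] = []
    features: list[GeneFeature] = []
    cursor = 0
    for slot, (name, ftype, strand, _ln) in enumerate(GENE_TEMPLATE):
        if slot in spacer_seqs:
            seq_parts.append(spacer_seqs[slot])
            cursor += len(spacer_seqs[slot])
        sense = gene_seqs[name]
        deposited = sense if strand == "J" else reverse_complement(sense)
        features.append(GeneFeature(name=name, ftype=ftype, start=cursor,
                                    end=cursor + len(deposited),
                                    strand=strand))
        seq_parts.append(deposited)
        cursor += len(deposited)
    return Mitogenome(id=gid, sequence="".join(seq_parts), is_circular=True,
                      features=features, source="synthetic")


def evolve_genome_family(fspec: FamilySpec
                         ) -> tuple[list[Mitogenome], dict]:
    """Simulate an ancestral mitogenome and evolve it along a tree.

    Returns the leaf genomes (in tree leaf order) and a truth log with
    the generating topology, per-branch event counts, per-leaf tRNA
    structures (ancestral pairing template with the leaf's sequence) and
    the ancestor's truth.
    """
    from .phylo import parse_newick

    anc_spec = GenomeSpec(**{**fspec.genome.__dict__, "seed": fspec.seed})
    _, anc_truth = simulate_mitogenome(anc_spec)
    rng = np.random.default_rng(fspec.seed + 7_777_777)
    tree = parse_newick(fspec.tree)
    anc_genes = {name: info["sense_sequence"]
                 for name, info in anc_truth["genes"].items()}
    anc_spacers = {int(k): v
                   for k, v in anc_truth["spacer_sequences"].items()}
    ftype_of = {name: ft for name, ft, _, _ in GENE_TEMPLATE}
    truth: dict = {"tree": fspec.tree, "omega": fspec.omega,
                   "ancestor": anc_truth, "branches": {}}
    genomes: list[Mitogenome] = []

    def walk(node, genes: dict[str, str], spacers: dict[int, str],
             path: str) -> None:
        t = node.length
        if t > 0:
            new_genes: dict[str, str] = {}
            events = {"synonymous": 0, "nonsynonymous": 0, "rejected": 0,
                      "neutral": 0}
            for name, seq in genes.items():
                if ftype_of[name] == "PCG":
                    seq, counts = _evolve_pcg(rng, seq, t,
                                              fspec.gene_omega(name),
                                              fspec.kappa)
                    for k, v in counts.items():
                        events[k] += v
                else:
                    seq, n = _evolve_neutral(rng, seq, t, fspec.kappa)
                    events["neutral"] += n
                new_genes[name] = seq
            new_spacers = {}
            for slot, seq in spacers.items():
                seq, n = _evolve_neutral(rng, seq, t, fspec.kappa)
                events["neutral"] += n
                new_spacers[slot] = seq
            genes, spacers = new_genes, new_spacers
            truth["branches"][path] = events
        if node.is_leaf:
            genomes.append(_assemble_genome(node.name, genes, spacers))
        else:
            for k, child in enumerate(node.children):
                walk(child, dict(genes), dict(spacers), f"{path}/{k}")

    walk(tree, anc_genes, anc_spacers, "root")
    # per-leaf tRNA structures: ancestral pairing with the leaf sequence
    anc_db = {name: db for name, (_, db) in anc_truth["structures"].items()}
    truth["structures"] = {
        g.id: {f.name: (feature_sequence_rna(g, f), anc_db[f.name])
               for f in g.features_of_type("tRNA")}
        for g in genomes
    }
    return genomes, truth


def feature_sequence_rna(genome: Mitogenome, feat: GeneFeature) -> str:
    from .genome import feature_sequence
    return feature_sequence(genome, feat).replace("T", "U")
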