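"""Structural genome metrics: intergenic spacers and overlaps on the
circular molecule, signed gene-order strings, and tRNA secondary-structure
pair classification from dot-bracket strings.

Secondary structures are INPUT (annotation-server output or the synthetic
module); no folding is performed here.  Pairing classes follow RNA
conventions: {AU, UA, GC, CG} are Watson-Crick, {GU, UG} are wobble
pairs, anything else is a mismatch whose identity is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TextIO

from .genome import Mitogenome


@dataclass(frozen=True)
class Spacer:
    """Non-coding gap (length >= 1) between consecutive features in
    circular order; ``spans_origin`` marks a gap crossing the terminus."""

    left: str
    right: str
    start: int
    length: int
    spans_origin: bool = False


@dataclass(frozen=True)
class Overlap:
    """Negative gap between consecutive features (shared nucleotides)."""

    left: str
    right: str
    length: int  # magnitude of the overlap, > 0


def intergenic_spacers(genome: Mitogenome
                       ) -> tuple[list[Spacer], list[Overlap]]:
    """Spacers and overlaps between consecutive features in circular order.

    Features are taken in start order; the gap after the last feature back
    to the first (crossing the origin on a circular molecule) is included.
    Total non-coding nucleotides = sum of spacer lengths; overlaps are
    kept separate so they never reduce that total.
    """
    feats = sorted(genome.features, key=lambda f: (f.start, f.end))
    if len(feats) < 2:
        return [], []
    n = len(genome.sequence)
    spacers: list[Spacer] = []
    overlaps: list[Overlap] = []
    for prev, nxt in zip(feats, feats[1:] + feats[:1]):
        prev_end = prev.end if not prev.wraps_origin else prev.end + n
        if nxt is feats[0]:
            gap = (nxt.start + n) - prev_end
            spans = gap > 0 and prev_end < n
        else:
            gap = nxt.start - prev_end
            spans = False
        if not genome.is_circular and nxt is feats[0]:
            continue
        if gap > 0:
            spacers.append(Spacer(prev.name, nxt.name, prev_end % n, gap,
                                  spans_origin=spans))
        elif gap < 0:
            overlaps.append(Overlap(prev.name, nxt.name, -gap))
    return spacers, overlaps


def total_noncoding(genome: Mitogenome) -> int:
    spacers, _ = intergenic_spacers(genome)
    return sum(s.length for s in spacers)


def gene_order(genome: Mitogenome, anchor: str = "tRNA-Ile") -> str:
    """Signed, rotation-normalized gene-order string.

    Features in circular start order, rotated to begin at ``anchor`` when
    present, each token ``name(+)`` / ``name(-)`` for the J / N strand.
    """
    feats = sorted(genome.features, key=lambda f: (f.start, f.end))
    names = [f.name for f in feats]
    if anchor in names:
        i = names.index(anchor)
        feats = feats[i:] + feats[:i]
    return " ".join(
        f"{f.name}({'+' if f.strand == 'J' else '-'})" for f in feats)


# ---------------------------------------------------------------- tRNA ----

@dataclass
class PairClassCounts:
    watson_crick: int = 0
    gu_wobble: int = 0
    mismatch: int = 0
    mismatch_identities: list[str] = field(default_factory=list)

    @property
    def total_pairs(self) -> int:
        return self.watson_crick + self.gu_wobble + self.mismatch

    def __add__(self, other: "PairClassCounts") -> "PairClassCounts":
        return PairClassCounts(
            self.watson_crick + other.watson_crick,
            self.gu_wobble + other.gu_wobble,
            self.mismatch + other.mismatch,
            self.mismatch_identities + other.mismatch_identities)


class StructureError(ValueError):
    """Raised for unbalanced dot-bracket strings."""


def paired_positions(dotbracket: str) -> list[tuple[int, int]]:
    """Base pairs (i, j), i < j, from a balanced dot-bracket string."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureError(
                    f"unbalanced ')' at position {i} in dot-bracket")
            pairs.append((stack.pop(), i))
        elif ch != ".":
            raise StructureError(f"illegal character {ch!r} in dot-bracket")
    if stack:
        raise StructureError(f"unclosed '(' at position {stack[-1]}")
    return sorted(pairs)


_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def pair_classes(trna_seq: str, dotbracket: str) -> PairClassCounts:
    """Classify every base pair of one tRNA structure.

    DNA input is read as RNA (T -> U).  Mismatch identities are recorded
    5'-base first (e.g. 'UU').
    """
    seq = trna_seq.upper().replace("T", "U")
    if len(seq) != len(dotbracket):
        raise StructureError(
            f"sequence length {len(seq)} != structure length {len(dotbracket)}")
    out = PairClassCounts()
    for i, j in paired_positions(dotbracket):
        duo = (seq[i], seq[j])
        if duo in _WC:
            out.watson_crick += 1
        elif duo in _WOBBLE:
            out.gu_wobble += 1
        else:
            out.mismatch += 1
            out.mismatch_identities.append("".join(duo))
    return out


@dataclass(frozen=True)
class CloverleafReport:
    arms_present: frozenset[str]  # subset of {acceptor, DHU, anticodon, TPsiC}
    dhu_arm_replaced_by_loop: bool


def _stems(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Group base pairs into stems (maximal runs of stacked pairs);
    each stem is represented by its outermost pair."""
    stems: list[tuple[int, int]] = []
    current: tuple[int, int] | None = None
    for i, j in pairs:
        if current is not None and (i, j) == (prev_i + 1, prev_j - 1):
            pass  # continuation of the current stem
        else:
            current = (i, j)
            stems.append(current)
        prev_i, prev_j = i, j
    return stems


def cloverleaf_arms(dotbracket: str) -> CloverleafReport:
    """Identify canonical cloverleaf arms from pairing topology alone.

    The outermost stem is the acceptor stem; internal stems nested
    directly inside it are, in 5'->3' order, the DHU, anticodon and
    T-Psi-C arms (a variable loop may follow the anticodon arm and is not
    an arm).  Exactly two internal stems means the DHU arm is missing,
    replaced by a plain loop — the pattern shown by mitochondrial
    tRNA-Ser1.
    """
    pairs = paired_positions(dotbracket)
    if not pairs:
        return CloverleafReport(frozenset(), False)
    stems = _stems(pairs)
    acceptor = stems[0]
    internal = [s for s in stems[1:]
                if acceptor[0] < s[0] and s[1] < acceptor[1]]
    # keep only stems at top nesting level inside the acceptor stem
    top: list[tuple[int, int]] = []
    for s in internal:
        if not any(t[0] < s[0] and s[1] < t[1] for t in internal if t != s):
            top.append(s)
    arms = {"acceptor"}
    dhu_missing = False
    if len(top) >= 3:
        arms |= {"DHU", "anticodon", "TPsiC"}
    elif len(top) == 2:
        arms |= {"anticodon", "TPsiC"}
        dhu_missing = True
    elif len(top) == 1:
        arms |= {"anticodon"}
    return CloverleafReport(frozenset(arms), dhu_missing)


def read_structures(stream: TextIO | str) -> dict[str, tuple[str, str]]:
    """Read the 2-line-per-tRNA structure format.

    Each entry is ``>name`` then the sequence line then the dot-bracket
    line (a documented dialect of Vienna-style output)::

        >tRNA-Phe
        GCUUCAAUAGCUUAA...
        ((((((..((((.......)))).(((((.......)))))....)))))).

    Returns {name: (sequence, dotbracket)}.
    """
    import io as _io
    if isinstance(stream, str):
        stream = _io.StringIO(stream)
    lines = [ln.rstrip("\n") for ln in stream if ln.strip()]
    entries: dict[str, tuple[str, str]] = {}
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise StructureError(
                f"expected '>name' line, got {lines[i]!r}")
        try:
            name, seq, db = lines[i][1:].strip(), lines[i + 1], lines[i + 2]
        except IndexError as exc:
            raise StructureError(
                f"truncated structure entry for {lines[i][1:]!r}") from exc
        entries[name] = (seq.strip(), db.strip())
        i += 3
    return entries


def write_structures(entries: dict[str, tuple[str, str]],
                     handle: TextIO) -> None:
    for name, (seq, db) in entries.items():
        handle.write(f">{name}\n{seq}\n{db}\n")
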