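"""IUPAC consensus scanning of promoter sequences in ATG-anchored coordinates.

The promoter coordinate frame follows the convention used when the
translation start codon designates the origin: the base immediately
upstream of the ATG is -1, the A of the ATG is +1, and there is no
position 0.  Hits are reported by the 5'-most matched base on the plus
strand; minus-strand hits are matches of the reverse-complemented pattern
and carry the same plus-strand index convention.

An N in the scanned sequence never matches any pattern position, including
the fully degenerate code N.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import PromoterSequence

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: Default consensus patterns: the canonical GATA-factor element WGATAR and a
#: purine-flanked ETS core for PU.1.  These are configurable defaults, not
#: ground truth for any particular promoter.
DEFAULT_PATTERNS: dict[str, str] = {"GATA1": "WGATAR", "PU1": "RRGGAA"}


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA or IUPAC consensus string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifPattern:
    """A named IUPAC consensus with its scanning mode."""

    name: str
    iupac: str
    scan_strands: str = "both"  # "both" | "plus"

    def __post_init__(self) -> None:
        if self.scan_strands not in ("both", "plus"):
            raise ValueError("scan_strands must be 'both' or 'plus'")
        compile_pattern(self.iupac)  # validates the alphabet

    def __len__(self) -> int:
        return len(self.iupac)


@dataclass(frozen=True)
class MotifHit:
    """One consensus match.

    ``seq_index`` is the 0-based index of the 5'-most matched base on the
    plus strand; ``promoter_pos`` is the same base in the ATG frame.
    """

    pattern: str
    seq_index: int
    strand: str
    match: str
    promoter_pos: int

    def overlaps(self, other: "MotifHit") -> bool:
        return (
            self.seq_index < other.seq_index + len(other.match)
            and other.seq_index < self.seq_index + len(self.match)
        )


class CompiledPattern:
    """A compiled IUPAC consensus: per-position allowed-base sets."""

    def __init__(self, iupac: str) -> None:
        if not iupac:
            raise ValueError("pattern must be non-empty")
        sets = []
        for ch in iupac.upper():
            if ch not in IUPAC_CODES:
                raise ValueError(f"invalid IUPAC code: {ch!r}")
            sets.append(IUPAC_CODES[ch])
        self.iupac = iupac.upper()
        self.position_sets: tuple[frozenset[str], ...] = tuple(sets)

    def __len__(self) -> int:
        return len(self.position_sets)

    def matches(self, word: str) -> bool:
        """Whether ``word`` is one of the concrete DNA words of the consensus."""
        if len(word) != len(self.position_sets):
            return False
        return all(b in s for b, s in zip(word.upper(), self.position_sets))

    def reverse_complement(self) -> "CompiledPattern":
        return CompiledPattern(reverse_complement(self.iupac))


def compile_pattern(iupac: str) -> CompiledPattern:
    """Compile an IUPAC consensus into a matcher over concrete DNA words."""
    return CompiledPattern(iupac)


def to_promoter_coords(seq_index: int, atg_index: int) -> int:
    """Convert a 0-based sequence index into the no-zero ATG frame."""
    if seq_index < atg_index:
        return seq_index - atg_index
    return seq_index - atg_index + 1


def from_promoter_coords(promoter_pos: int, atg_index: int) -> int:
    """Inverse of :func:`to_promoter_coords`."""
    if promoter_pos == 0:
        raise ValueError("the ATG frame has no position 0")
    if promoter_pos < 0:
        return promoter_pos + atg_index
    return promoter_pos + atg_index - 1


def scan(seq: PromoterSequence | str, pattern: MotifPattern) -> list[MotifHit]:
    """Find all consensus matches, including overlapping and nested hits.

    Plus-strand matches are matches of the pattern itself; minus-strand
    matches (when ``pattern.scan_strands == "both"``) are matches of the
    reverse-complemented pattern on the plus-strand text.  Hits are sorted
    by ``seq_index``, plus strand first at equal index.
    """
    if isinstance(seq, PromoterSequence):
        text, atg_index = seq.sequence, seq.atg_index
    else:
        text, atg_index = seq, 0
    text = text.upper()
    compiled = compile_pattern(pattern.iupac)
    searches = [("+", compiled)]
    if pattern.scan_strands == "both":
        searches.append(("-", compiled.reverse_complement()))

    k = len(compiled)
    hits: list[MotifHit] = []
    for strand, comp in searches:
        for i in range(len(text) - k + 1):
            word = text[i : i + k]
            if comp.matches(word):
                hits.append(
                    MotifHit(
                        pattern=pattern.name,
                        seq_index=i,
                        strand=strand,
                        match=word,
                        promoter_pos=to_promoter_coords(i, atg_index),
                    )
                )
    hits.sort(key=lambda h: (h.seq_index, h.strand))
    return hits


_TRANSVERSION = {"A": "C", "C": "A", "G": "T", "T": "G"}


def mutate_site(seq: str, hit: MotifHit, pattern: MotifPattern) -> str:
    """Abolish one binding site by transversions at invariant pattern bases.

    The smallest set of non-degenerate pattern positions whose transversion
    leaves no hit of the pattern overlapping the original site is applied.
    When overlapping occurrences share only degenerate positions with the
    site (so no in-site core change can remove them), the invariant cores
    of those occurrences are mutated as well.  Positions outside the
    mutated cores are never touched.  Mirrors mutant probe design, where
    the minimal core change that abolishes factor binding is introduced.
    """
    import itertools

    seq = seq.upper()
    k = len(pattern.iupac)
    if hit.seq_index < 0 or hit.seq_index + k > len(seq):
        raise ValueError("hit does not lie within the sequence")

    compiled = compile_pattern(pattern.iupac)
    oriented = compiled if hit.strand == "+" else compiled.reverse_complement()
    # positions within the site whose pattern base is invariant
    site_positions = [
        i for i, s in enumerate(oriented.position_sets) if len(s) == 1
    ]
    if not site_positions:
        raise ValueError(
            f"pattern {pattern.iupac!r} has no invariant position to mutate"
        )

    def overlapping(mutated: str) -> bool:
        return any(h.overlaps(hit) for h in scan(mutated, pattern))

    for size in range(1, len(site_positions) + 1):
        for subset in itertools.combinations(site_positions, size):
            chars = list(seq)
            for pos in subset:
                idx = hit.seq_index + pos
                chars[idx] = _TRANSVERSION.get(chars[idx], "C")
            mutated = "".join(chars)
            if not overlapping(mutated):
                return mutated

    # fallback: break every overlapping occurrence at its own invariant core
    rc = compiled.reverse_complement()
    chars = list(seq)
    for _ in range(50):
        blocking = [h for h in scan("".join(chars), pattern) if h.overlaps(hit)]
        if not blocking:
            return "".join(chars)
        h0 = blocking[0]
        sets = (compiled if h0.strand == "+" else rc).position_sets
        for pos, allowed in enumerate(sets):
            if len(allowed) == 1:
                idx = h0.seq_index + pos
                chars[idx] = _TRANSVERSION.get(chars[idx], "C")
                break
        else:
            raise ValueError(
                "could not abolish the site by mutating invariant bases"
            )
    raise ValueError("could not abolish the site by mutating invariant bases")
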