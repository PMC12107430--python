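"""Reference construct, library designs, and variant identity.

Coordinates are 1-based, inclusive, in the numbering of the source viral
genome, so positions printed in the literature (6029, 6218, ...) can be used
verbatim. The construct's first base carries coordinate ``genomic_offset``.
The internal alphabet is RNA (ACGU); DNA input (T) is converted at the
boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")
_ALTERNATIVES = {b: tuple(sorted(RNA_ALPHABET - {b})) for b in RNA_ALPHABET}


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class ReferenceConstruct:
    """Wild-type construct with genomic coordinate mapping and landmarks.

    Parameters
    ----------
    sequence
        RNA sequence (ACGU).
    genomic_offset
        Genomic coordinate of the first sequence position (1-based).
    cleavage_position
        Genomic coordinate whose base is the final base of a cleaved read
        (RelE cuts between the second and third A-site codon nucleotides).
    first_codon_span
        Inclusive genomic interval of the first translatable codon.
    """

    sequence: str
    genomic_offset: int
    cleavage_position: int
    first_codon_span: tuple[int, int]

    def __post_init__(self) -> None:
        seq = _to_rna(self.sequence)
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)
        lo, hi = self.first_codon_span
        if hi - lo != 2:
            raise ValueError("first_codon_span must cover exactly 3 nucleotides")
        for pos in (self.cleavage_position, lo, hi):
            if not self.contains(pos):
                raise ValueError(f"landmark {pos} outside the construct")
        if self.cleavage_position != lo + 1:
            raise ValueError(
                "cleavage_position must be the middle base of the first codon"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def genomic_end(self) -> int:
        """Genomic coordinate of the last base."""
        return self.genomic_offset + len(self.sequence) - 1

    def contains(self, position: int) -> bool:
        return self.genomic_offset <= position <= self.genomic_end

    def index(self, position: int) -> int:
        """0-based string index of a genomic coordinate."""
        if not self.contains(position):
            raise ValueError(f"position {position} outside the construct")
        return position - self.genomic_offset

    def base_at(self, position: int) -> str:
        return self.sequence[self.index(position)]


@dataclass(frozen=True)
class LibraryDesign:
    """A named set of mutagenized genomic intervals with a doping rate.

    ``doping_rate_per_alternative`` is the probability, per position, of each
    of the three alternative bases; the total per-position substitution
    probability is three times this value.
    """

    name: str
    intervals: tuple[tuple[int, int], ...]
    doping_rate_per_alternative: float
    max_mutations_tracked: int = 2

    def __post_init__(self) -> None:
        ivals = tuple(sorted((int(a), int(b)) for a, b in self.intervals))
        for a, b in ivals:
            if a > b:
                raise ValueError(f"interval {a}-{b} is reversed")
        for (_, b0), (a1, _) in zip(ivals, ivals[1:]):
            if a1 <= b0:
                raise ValueError("intervals overlap")
        object.__setattr__(self, "intervals", ivals)
        if not 0 <= 3 * self.doping_rate_per_alternative < 1:
            raise ValueError("3 x doping rate must lie in [0, 1)")

    @property
    def substitution_rate(self) -> float:
        """Total per-position substitution probability."""
        return 3.0 * self.doping_rate_per_alternative


@dataclass(frozen=True, order=True)
class VariantKey:
    """Canonical identity of a 0-, 1-, or 2-substitution variant.

    ``substitutions`` is a position-sorted tuple of
    ``(genomic position, reference base, alternative base)``; an empty tuple
    denotes wild type.
    """

    substitutions: tuple[tuple[int, str, str], ...] = field(default=())

    def __post_init__(self) -> None:
        subs = tuple(sorted((int(p), r, a) for p, r, a in self.substitutions))
        if len(subs) > 2:
            raise ValueError("variants track at most 2 substitutions")
        positions = [p for p, _, _ in subs]
        if len(set(positions)) != len(positions):
            raise ValueError("duplicate substitution positions")
        for _, ref, alt in subs:
            if ref == alt:
                raise ValueError("alternative base equals reference base")
            if ref not in RNA_ALPHABET or alt not in RNA_ALPHABET:
                raise ValueError("substitution bases must be ACGU")
        object.__setattr__(self, "substitutions", subs)

    @property
    def n_substitutions(self) -> int:
        return len(self.substitutions)

    @property
    def is_wild_type(self) -> bool:
        return not self.substitutions


WILD_TYPE = VariantKey()


def load_reference(
    fasta_path,
    genomic_offset: int,
    cleavage_position: int,
    first_codon_span: tuple[int, int],
) -> ReferenceConstruct:
    """Read a single-record FASTA into a validated :class:`ReferenceConstruct`.

    T is accepted and converted to U. Raises ``ValueError`` for a
    multi-record FASTA, non-nucleotide characters, or landmarks outside the
    sequence.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, found {len(records)}")
    return ReferenceConstruct(
        sequence=str(records[0].seq),
        genomic_offset=genomic_offset,
        cleavage_position=cleavage_position,
        first_codon_span=tuple(first_codon_span),
    )


def positions_of(design: LibraryDesign) -> list[int]:
    """Sorted, deduplicated union of a design's inclusive intervals."""
    out: set[int] = set()
    for a, b in design.intervals:
        out.update(range(a, b + 1))
    return sorted(out)


def _check_positions(reference: ReferenceConstruct, positions: Iterable[int]) -> None:
    for p in positions:
        if not reference.contains(p):
            raise ValueError(f"design position {p} outside the reference")


def enumerate_single_variants(
    reference: ReferenceConstruct, design: LibraryDesign
) -> list[VariantKey]:
    """All single-substitution variants of a design: 3 per position, ordered
    by position then alternative base."""
    positions = positions_of(design)
    _check_positions(reference, positions)
    out = []
    for pos in positions:
        ref = reference.base_at(pos)
        for alt in _ALTERNATIVES[ref]:
            out.append(VariantKey(((pos, ref, alt),)))
    return out


def enumerate_double_variants(
    reference: ReferenceConstruct, design: LibraryDesign
) -> list[VariantKey]:
    """All double-substitution variants: 9 per unordered position pair."""
    positions = positions_of(design)
    _check_positions(reference, positions)
    out = []
    for i, p1 in enumerate(positions):
        r1 = reference.base_at(p1)
        for p2 in positions[i + 1 :]:
            r2 = reference.base_at(p2)
            for a1 in _ALTERNATIVES[r1]:
                for a2 in _ALTERNATIVES[r2]:
                    out.append(VariantKey(((p1, r1, a1), (p2, r2, a2))))
    return out


def variant_label(v: VariantKey, reference: ReferenceConstruct) -> str:
    """Human-readable label: ``WT``, ``U6101A``, or ``U6101A;A6137U``."""
    if v.is_wild_type:
        return "WT"
    parts = []
    for pos, ref, alt in v.substitutions:
        if reference.base_at(pos) != ref:
            raise ValueError(
                f"variant reference base {ref} at {pos} disagrees with the "
                f"construct ({reference.base_at(pos)})"
            )
        parts.append(f"{ref}{pos}{alt}")
    return ";".join(parts)


def parse_variant_label(label: str, reference: ReferenceConstruct) -> VariantKey:
    """Inverse of :func:`variant_label`; validates reference bases."""
    label = label.strip()
    if label.upper() == "WT":
        return WILD_TYPE
    subs = []
    for part in label.split(";"):
        part = part.strip()
        if len(part) < 3 or part[0] not in "ACGUT" or part[-1] not in "ACGUT":
            raise ValueError(f"malformed variant label part: {part!r}")
        ref, alt = _to_rna(part[0]), _to_rna(part[-1])
        try:
            pos = int(part[1:-1])
        except ValueError as exc:
            raise ValueError(f"malformed variant label part: {part!r}") from exc
        actual = reference.base_at(pos)
        if actual != ref:
            raise ValueError(
                f"label {part!r}: construct carries {actual} at {pos}, not {ref}"
            )
        subs.append((pos, ref, alt))
    return VariantKey(tuple(subs))


# The three mutant library designs used in the study: a single-mutant doped
# library over the whole element, and two double-mutant libraries focused on
# the ribosome-binding domains and on the tRNA-mimicking (PKI) region.
def single_mutant_design() -> LibraryDesign:
    return LibraryDesign("single", ((6029, 6216),), 0.006)


def ribosome_binding_design() -> LibraryDesign:
    return LibraryDesign("ribosome_binding", ((6054, 6073), (6096, 6170)), 0.007)


def pki_design() -> LibraryDesign:
    return LibraryDesign(
        "pki",
        ((6029, 6036), (6043, 6053), (6062, 6067), (6074, 6084), (6089, 6096), (6165, 6216)),
        0.007,
    )


def study_designs() -> dict[str, LibraryDesign]:
    designs = [single_mutant_design(), ribosome_binding_design(), pki_design()]
    return {d.name: d for d in designs}


def design_from_dict(spec: dict) -> LibraryDesign:
    """Build a design from a config mapping with ``name``, ``intervals`` as
    ``"start-end"`` strings, and ``doping_rate_per_alternative``."""
    intervals = []
    for item in spec["intervals"]:
        a, b = str(item).split("-")
        intervals.append((int(a), int(b)))
    return LibraryDesign(
        name=spec["name"],
        intervals=tuple(intervals),
        doping_rate_per_alternative=float(spec["doping_rate_per_alternative"]),
        max_mutations_tracked=int(spec.get("max_mutations_tracked", 2)),
    )
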