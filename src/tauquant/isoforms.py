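"""Tau isoform sequences, coordinate projection, and in-silico tryptic digestion.

The canonical residue frame is the 441-residue human 2N4R tau sequence; all
positions named in the literature (T231, S262, K254, P301 ...) refer to this
frame. Shorter splice isoforms (1N4R, 412 aa) are projected onto it through a
block-wise offset map computed once by pairwise global alignment against the
canonical sequence, so positions inside a spliced-out insert are reported as
unmapped rather than silently shifted.

All coordinates are 1-based and inclusive throughout the package; conversion to
0-based happens only at string-indexing boundaries inside this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

from Bio import Align, SeqIO

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

CANONICAL_NAME = "2N4R"
CANONICAL_LENGTH = 441

#: cleavage happens C-terminal to these residues (classical trypsin)
_CLEAVE_AFTER = frozenset("KR")
#: ... unless the next residue is proline
_SUPPRESSOR = "P"

DEFAULT_MIN_LEN = 6
DEFAULT_MAX_LEN = 50
DEFAULT_MAX_MISSED = 3


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty sequence")
    for ch in sequence:
        if ch not in STANDARD_AA:
            raise ValueError(f"non-standard residue {ch!r} in sequence")


@dataclass(frozen=True)
class Peptide:
    """One tryptic peptide located within its parent isoform (1-based, inclusive)."""

    sequence: str
    local_start: int
    local_end: int
    missed_cleavages: int

    def __post_init__(self) -> None:
        if self.local_end - self.local_start + 1 != len(self.sequence):
            raise ValueError("peptide span does not match sequence length")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be non-negative")


@dataclass
class Isoform:
    """A tau splice isoform with a projection onto canonical 2N4R coordinates.

    ``canonical_offset_map`` is a list of aligned blocks
    ``(local_start, local_end, canonical_start)``: local positions in
    ``[local_start, local_end]`` map one-to-one onto canonical positions
    starting at ``canonical_start``. Blocks are non-overlapping, strictly
    increasing, and cover every local position exactly once.
    """

    name: str
    sequence: str
    canonical_offset_map: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        _validate_sequence(self.sequence)
        if not self.canonical_offset_map:
            # identity map (the canonical isoform itself)
            self.canonical_offset_map = [(1, len(self.sequence), 1)]
        self._check_blocks()
        self._inverse = {
            cs + i: ls + i
            for ls, le, cs in self.canonical_offset_map
            for i in range(le - ls + 1)
        }

    def _check_blocks(self) -> None:
        covered = 0
        prev_local_end = 0
        prev_canon_end = 0
        for ls, le, cs in self.canonical_offset_map:
            if ls <= prev_local_end or cs <= prev_canon_end:
                raise ValueError(f"{self.name}: offset map blocks not strictly increasing")
            if ls != prev_local_end + 1:
                raise ValueError(f"{self.name}: offset map leaves local positions uncovered")
            covered += le - ls + 1
            prev_local_end = le
            prev_canon_end = cs + (le - ls)
        if covered != len(self.sequence):
            raise ValueError(f"{self.name}: offset map does not cover every local position")

    def __len__(self) -> int:
        return len(self.sequence)

    def to_canonical(self, local_pos: int) -> Optional[int]:
        """Project a local 1-based position to the canonical 2N4R frame.

        Returns ``None`` for positions with no canonical image (cannot occur
        for the packaged isoforms, whose residues all align, but supported for
        generality). Raises ``IndexError`` when out of range.
        """
        if not 1 <= local_pos <= len(self.sequence):
            raise IndexError(
                f"{self.name}: local position {local_pos} outside 1..{len(self.sequence)}"
            )
        for ls, le, cs in self.canonical_offset_map:
            if ls <= local_pos <= le:
                return cs + (local_pos - ls)
        return None

    def from_canonical(self, canonical_pos: int) -> Optional[int]:
        """Inverse projection; ``None`` when the canonical position falls in a
        spliced-out insert (absent from this isoform)."""
        if not 1 <= canonical_pos <= CANONICAL_LENGTH:
            raise IndexError(
                f"canonical position {canonical_pos} outside 1..{CANONICAL_LENGTH}"
            )
        return self._inverse.get(canonical_pos)

    def mapped_canonical_positions(self) -> set[int]:
        return set(self._inverse)

    @classmethod
    def from_alignment(cls, name: str, sequence: str, canonical_sequence: str) -> "Isoform":
        """Build the offset map by global pairwise alignment to the canonical
        sequence. Mismatched columns (point mutations such as P301S) stay
        aligned; only indels break blocks."""
        _validate_sequence(sequence)
        _validate_sequence(canonical_sequence)
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 2
        aligner.mismatch_score = -1
        aligner.open_gap_score = -10
        aligner.extend_gap_score = -0.5
        aln = aligner.align(canonical_sequence, sequence)[0]
        blocks = []
        for (c0, c1), (l0, l1) in zip(*aln.aligned):
            assert c1 - c0 == l1 - l0
            blocks.append((l0 + 1, l1, c0 + 1))  # 0-based half-open -> 1-based inclusive
        return cls(name=name, sequence=sequence, canonical_offset_map=blocks)


class IsoformRegistry:
    """Named collection of isoforms sharing one canonical frame."""

    def __init__(self, canonical: Isoform):
        if len(canonical.sequence) != CANONICAL_LENGTH:
            raise ValueError(
                f"canonical isoform must have {CANONICAL_LENGTH} residues, "
                f"got {len(canonical.sequence)}"
            )
        self._isoforms: dict[str, Isoform] = {canonical.name: canonical}
        self.canonical = canonical

    def add(self, name: str, sequence: str) -> Isoform:
        iso = Isoform.from_alignment(name, sequence, self.canonical.sequence)
        self._isoforms[name] = iso
        return iso

    def __getitem__(self, name: str) -> Isoform:
        try:
            return self._isoforms[name]
        except KeyError:
            raise KeyError(f"isoform {name!r} not registered") from None

    def __contains__(self, name: str) -> bool:
        return name in self._isoforms

    def names(self) -> list[str]:
        return list(self._isoforms)


def read_isoform_fasta(path) -> dict[str, str]:
    """Read isoform sequences from FASTA; keys are the first word of each header."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def load_default_registry() -> IsoformRegistry:
    """Registry of the packaged tau isoforms: 2N4R (canonical), 1N4R, 1N4R-P301S."""
    with resources.as_file(
        resources.files("tauquant.data").joinpath("tau_isoforms.fasta")
    ) as p:
        seqs = read_isoform_fasta(p)
    registry = IsoformRegistry(Isoform(name=CANONICAL_NAME, sequence=seqs[CANONICAL_NAME]))
    for name, seq in seqs.items():
        if name != CANONICAL_NAME:
            registry.add(name, seq)
    return registry


def cleavage_sites(sequence: str) -> list[int]:
    """1-based positions after which trypsin cuts (K/R not followed by P),
    excluding the C-terminus."""
    return [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in _CLEAVE_AFTER and sequence[i + 1] != _SUPPRESSOR
    ]


def digest(
    isoform: Isoform | str,
    max_missed: int = DEFAULT_MAX_MISSED,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> set[Peptide]:
    """Fully tryptic digest with up to ``max_missed`` missed cleavages.

    Cleavage is C-terminal to K or R, suppressed when the next residue is P.
    Returns every peptide bounded by cleavage sites (or the protein termini)
    spanning 0..max_missed internal cleavage sites, with length in
    [min_len, max_len].
    """
    sequence = isoform.sequence if isinstance(isoform, Isoform) else isoform
    _validate_sequence(sequence)
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if not 1 <= min_len <= max_len:
        raise ValueError("need 1 <= min_len <= max_len")

    boundaries = [0] + cleavage_sites(sequence) + [len(sequence)]
    peptides: set[Peptide] = set()
    for i in range(len(boundaries) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(boundaries))):
            start, end = boundaries[i] + 1, boundaries[j]
            if min_len <= end - start + 1 <= max_len:
                peptides.add(
                    Peptide(
                        sequence=sequence[start - 1 : end],
                        local_start=start,
                        local_end=end,
                        missed_cleavages=j - i - 1,
                    )
                )
    return peptides
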