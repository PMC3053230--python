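"""Sequence-level RING-finger analysis.

A RING finger binds two Zn2+ ions through eight side chains (cysteines in
the C4C4 family; seven cysteines plus a histidine in the common C3HC4
E3-ligase arrangement).  Because the ligands are recognisable from sequence
alone — eight allowed residues whose pairwise spacings fall inside narrow
consensus windows — the domain can be located by constraint satisfaction:
enumerate every way of placing candidate residues into the eight ligand
slots such that each inter-ligand gap lies within its allowed range.

This module provides that scanner (:func:`scan_ring_ligands`), the spacing
consensus it checks against (:class:`SpacingModel`), global pairwise
alignment with identity/similarity statistics, and windowed (C-terminal
tail) divergence statistics for cross-species comparisons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX")

#: Canonical RING cross-brace: ligands 1,2,5,6 chelate the first zinc,
#: ligands 3,4,7,8 the second (0-based slot indices below).
CROSS_BRACE = ((0, 1, 4, 5), (2, 3, 6, 7))

#: Consensus inter-ligand spacing windows (residues strictly between
#: consecutive ligands) for the RING finger family; config-overridable.
DEFAULT_GAP_RANGES = ((2, 2), (9, 39), (1, 3), (2, 4), (2, 2), (4, 48), (2, 2))


class RingScanError(ValueError):
    """Invalid input to the motif scanner."""


class NoMotifError(LookupError):
    """The scan produced no valid ligand assignment."""


class AmbiguousMotifError(LookupError):
    """The scan produced more than one valid ligand assignment."""

    def __init__(self, assignments: Sequence["LigandAssignment"]):
        self.assignments = list(assignments)
        super().__init__(
            f"ambiguous RING motif: {len(self.assignments)} valid assignments"
        )


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence with an explicit residue-numbering offset.

    ``numbering_offset`` is the number printed for the first residue, so a
    fragment starting at residue 670 of a full-length protein reports
    positions in full-length coordinates (e.g. C678 rather than C9).
    """

    id: str
    residues: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty sequence")
        bad = set(self.residues.upper()) - AMINO_ACIDS
        if bad:
            raise ValueError(f"non-amino-acid letters in sequence: {sorted(bad)}")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def positions(self) -> range:
        return range(self.numbering_offset, self.numbering_offset + len(self))

    def residue_at(self, position: int) -> str:
        if position not in self.positions:
            raise IndexError(
                f"position {position} outside "
                f"[{self.numbering_offset}, {self.numbering_offset + len(self) - 1}]"
            )
        return self.residues[position - self.numbering_offset]

    @classmethod
    def from_fasta(cls, path, numbering_offset: int = 1) -> list["ProteinSequence"]:
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no FASTA records in {path}")
        return [cls(r.id, str(r.seq), numbering_offset) for r in records]


def _default_slots() -> tuple[frozenset, ...]:
    return (frozenset("C"),) * 8


@dataclass(frozen=True)
class SpacingModel:
    """Allowed ligand residues per slot and inter-ligand spacing windows.

    ``gap_ranges[i]`` bounds the number of residues strictly between
    ligand i+1 and ligand i+2 (1-based slot numbering).
    """

    ligand_count: int = 8
    gap_ranges: tuple[tuple[int, int], ...] = DEFAULT_GAP_RANGES
    allowed_residues_per_slot: tuple[frozenset, ...] = field(
        default_factory=_default_slots
    )
    #: Reject assignments that leave an unassigned cysteine strictly inside
    #: the matched span: a free thiol within the cross-brace core would
    #: compete for Zn2+ coordination.  Candidates outside the span (like a
    #: cysteine just upstream of ligand 1) are merely excluded, not fatal.
    forbid_internal_free_cysteines: bool = True

    def __post_init__(self) -> None:
        if len(self.gap_ranges) != self.ligand_count - 1:
            raise ValueError(
                f"need {self.ligand_count - 1} gap ranges, got {len(self.gap_ranges)}"
            )
        if len(self.allowed_residues_per_slot) != self.ligand_count:
            raise ValueError("one residue set required per ligand slot")
        for lo, hi in self.gap_ranges:
            if lo < 0 or lo > hi:
                raise ValueError(f"impossible gap range ({lo}, {hi})")
        if any(not s for s in self.allowed_residues_per_slot):
            raise ValueError("empty residue set for a ligand slot")

    @classmethod
    def c4c4(cls, gap_ranges=DEFAULT_GAP_RANGES, permit_aspartate: bool = False):
        """All-cysteine RING (the SPE-42 family pattern).

        ``permit_aspartate`` additionally allows D in every slot, matching
        the broader family definition (C/H/D side chains can chelate Zn).
        """
        allowed = frozenset("CD") if permit_aspartate else frozenset("C")
        return cls(8, tuple(gap_ranges), (allowed,) * 8)

    @classmethod
    def c3hc4(cls, gap_ranges=DEFAULT_GAP_RANGES):
        """Classic E3-ligase RING: histidine permitted at slot 4."""
        slots = [frozenset("C")] * 8
        slots[3] = frozenset("CH")
        return cls(8, tuple(gap_ranges), tuple(slots))

    @property
    def candidate_alphabet(self) -> frozenset:
        out = frozenset()
        for s in self.allowed_residues_per_slot:
            out |= s
        return out

    def min_span(self) -> int:
        """Minimum motif length (ligands + minimal gaps)."""
        return self.ligand_count + sum(lo for lo, _ in self.gap_ranges)


@dataclass(frozen=True)
class LigandAssignment:
    """One placement of residues into the eight zinc-ligand slots."""

    positions: tuple[int, ...]
    excluded_candidates: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("ligand positions must be strictly increasing")

    @property
    def gaps(self) -> tuple[int, ...]:
        """Residues strictly between consecutive ligands."""
        return tuple(b - a - 1 for a, b in zip(self.positions, self.positions[1:]))

    @property
    def zinc_partition(self) -> tuple[frozenset, frozenset]:
        """Cross-brace partition: slots {1,2,5,6} vs {3,4,7,8}."""
        return tuple(
            frozenset(self.positions[i] for i in group) for group in CROSS_BRACE
        )

    def to_dict(self) -> dict:
        zn1, zn2 = self.zinc_partition
        return {
            "positions": list(self.positions),
            "gaps": list(self.gaps),
            "zinc_1_ligands": sorted(zn1),
            "zinc_2_ligands": sorted(zn2),
            "excluded_candidates": list(self.excluded_candidates),
        }


def validate_assignment(
    seq: ProteinSequence, model: SpacingModel, positions: Sequence[int]
) -> bool:
    """Check one slot assignment against the spacing model (no search)."""
    if len(positions) != model.ligand_count:
        return False
    for slot, pos in enumerate(positions):
        if pos not in seq.positions:
            return False
        if seq.residue_at(pos) not in model.allowed_residues_per_slot[slot]:
            return False
    for (lo, hi), a, b in zip(model.gap_ranges, positions, positions[1:]):
        if not lo <= b - a - 1 <= hi:
            return False
    if model.forbid_internal_free_cysteines:
        used = set(positions)
        for p in range(positions[0] + 1, positions[-1]):
            if p in seq.positions and p not in used and seq.residue_at(p) == "C":
                return False
    return True


def candidate_positions(seq: ProteinSequence, model: SpacingModel) -> list[int]:
    alpha = model.candidate_alphabet
    return [p for p in seq.positions if seq.residue_at(p) in alpha]


def scan_ring_ligands(
    seq: ProteinSequence, model: SpacingModel | None = None
) -> list[LigandAssignment]:
    """Enumerate every valid zinc-ligand assignment in a sequence.

    Complete depth-first search over candidate residues: slot s may take
    candidate position p if p's residue is allowed in slot s and the gap to
    the previous slot's position lies in the model's window.  Results are
    sorted by position tuple, which orders them by start position first.
    """
    model = model or SpacingModel.c4c4()
    candidates = candidate_positions(seq, model)
    results: list[tuple[int, ...]] = []

    def extend(partial: list[int], start_idx: int) -> None:
        slot = len(partial)
        if slot == model.ligand_count:
            results.append(tuple(partial))
            return
        allowed = model.allowed_residues_per_slot[slot]
        for i in range(start_idx, len(candidates)):
            pos = candidates[i]
            if partial:
                gap = pos - partial[-1] - 1
                lo, hi = model.gap_ranges[slot - 1]
                if gap > hi:
                    break  # candidates ascend; all later gaps larger
                if gap < lo:
                    continue
            if seq.residue_at(pos) in allowed:
                partial.append(pos)
                extend(partial, i + 1)
                partial.pop()

    extend([], 0)
    if model.forbid_internal_free_cysteines:
        results = [
            pos
            for pos in results
            if not any(
                seq.residue_at(p) == "C"
                for p in range(pos[0] + 1, pos[-1])
                if p not in set(pos)
            )
        ]
    results.sort()
    cand_set = set(candidates)
    return [
        LigandAssignment(pos, tuple(sorted(cand_set - set(pos)))) for pos in results
    ]


def assign_unique(assignments: Sequence[LigandAssignment]) -> LigandAssignment:
    """The single assignment of an unambiguous scan, or a loud failure."""
    if not assignments:
        raise NoMotifError("no RING motif found")
    if len(assignments) > 1:
        raise AmbiguousMotifError(assignments)
    return assignments[0]


# ---------------------------------------------------------------------------
# Pairwise alignment and divergence statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DivergenceReport:
    """Percent identity/similarity over an alignment (or a window of it)."""

    percent_identity: float
    percent_similarity: float
    window: tuple[int, int] | None = None  # alignment-column interval, if windowed

    def __post_init__(self) -> None:
        for v in (self.percent_identity, self.percent_similarity):
            if not 0.0 <= v <= 100.0:
                raise ValueError("percentages must lie in [0, 100]")
        if self.percent_identity > self.percent_similarity + 1e-9:
            raise ValueError("identity cannot exceed similarity")


@dataclass(frozen=True)
class AlignmentParams:
    """Affine-gap global alignment parameters (BLOSUM62 by default)."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def matrix(self):
        return substitution_matrices.load(self.matrix_name)


@dataclass(frozen=True)
class PairwiseAlignment:
    """A computed global alignment: gapped rows plus summary statistics."""

    aligned_a: str
    aligned_b: str
    score: float
    params: AlignmentParams
    report: DivergenceReport

    def __len__(self) -> int:
        return len(self.aligned_a)


def _column_stats(cols_a: str, cols_b: str, matrix) -> tuple[float, float]:
    """Identity/similarity percentages over paired gapped strings.

    Denominator includes gap columns.  Similar = substitution score > 0.
    """
    n = len(cols_a)
    if n == 0:
        return 0.0, 0.0
    ident = sim = 0
    for x, y in zip(cols_a, cols_b):
        if x == "-" or y == "-":
            continue
        if x == y:
            ident += 1
            sim += 1
        elif matrix[x, y] > 0:
            sim += 1
    return 100.0 * ident / n, 100.0 * sim / n


def pairwise_global_align(
    a: ProteinSequence, b: ProteinSequence, params: AlignmentParams | None = None
) -> PairwiseAlignment:
    """Needleman–Wunsch global alignment with affine gap penalties.

    Identity counts identical columns over all alignment columns (gap
    columns included in the denominator); similarity additionally counts
    substitutions with a positive matrix score.  The traceback is
    deterministic: the aligner's fixed tie-breaking yields the same optimal
    alignment on every run.
    """
    params = params or AlignmentParams()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = params.matrix()
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    aln = aligner.align(a.residues, b.residues)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    ident, sim = _column_stats(row_a, row_b, params.matrix())
    return PairwiseAlignment(
        aligned_a=row_a,
        aligned_b=row_b,
        score=float(aln.score),
        params=params,
        report=DivergenceReport(ident, sim),
    )


def cterminal_divergence(
    aln: PairwiseAlignment, tail_a: int, tail_b: int
) -> DivergenceReport:
    """Identity/similarity restricted to the C-terminal tails of each row.

    A column is in the window if it contains one of the last ``tail_a``
    residues of sequence a or the last ``tail_b`` residues of b.  Used for
    questions like "how diverged are the final ~30 residues of two
    orthologs", where the tail often sits on its own exon.
    """
    len_a = sum(1 for c in aln.aligned_a if c != "-")
    len_b = sum(1 for c in aln.aligned_b if c != "-")
    if tail_a > len_a or tail_b > len_b:
        raise ValueError("tail longer than sequence")
    first_a = len_a - tail_a  # residue index where tail a starts
    first_b = len_b - tail_b
    ia = ib = 0
    cols_a, cols_b = [], []
    window_cols = []
    for col, (x, y) in enumerate(zip(aln.aligned_a, aln.aligned_b)):
        in_win = (x != "-" and ia >= first_a) or (y != "-" and ib >= first_b)
        if in_win:
            cols_a.append(x)
            cols_b.append(y)
            window_cols.append(col)
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
    ident, sim = _column_stats("".join(cols_a), "".join(cols_b), aln.params.matrix())
    window = (window_cols[0], window_cols[-1]) if window_cols else None
    return DivergenceReport(ident, sim, window=window)


def enumerate_assignments_bruteforce(
    seq: ProteinSequence, model: SpacingModel
) -> list[tuple[int, ...]]:
    """Exhaustive reference enumeration for small inputs (test oracle).

    Checks every k-combination of candidate positions against the model
    with the standalone validator; exponential, so only for short
    sequences, but entirely independent of the scanner's pruned search.
    """
    cands = candidate_positions(seq, model)
    return [
        combo
        for combo in itertools.combinations(cands, model.ligand_count)
        if validate_assignment(seq, model, combo)
    ]
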