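"""Anticodon-arm location within tRNA gene sequences.

The anticodon arm is modelled with canonical geometry: a 5-bp stem closing
a 7-nt loop. The loop is indexed 0–6 and corresponds to standard tRNA
positions 32–38, so the anticodon sits at loop indices 2–4 (positions
34–36). Cleavage bonds reported by :mod:`phagetrna.nuclease_catalog` are
phosphodiester bonds between adjacent loop indices in this frame.

Stems may pair Watson–Crick (A:T, G:C) or G:T wobble; expanded loops
(8–9 nt) are rejected rather than guessed at.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .errors import PhagetrnaError, ValidationError
from .io_formats import AnnotationRow, SequenceRecord

STEM_LEN = 5
LOOP_LEN = 7
ARM_LEN = 2 * STEM_LEN + LOOP_LEN  # 17 nt
#: anticodon position within the loop (indices 2–4 = tRNA positions 34–36)
ANTICODON_SLICE = slice(2, 5)

#: fraction of the gene length where the loop is expected to start; ~position
#: 32 of a 76-nt tRNA, used only to break ties between equally paired arms
POSITIONAL_PRIOR = 0.42

_PAIRS = {
    ("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"),
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GeneOrigin(str, Enum):
    ANNOTATION_TABLE = "annotation_table"
    ARM_FINDER = "arm_finder"


@dataclass(frozen=True, order=True)
class IsoacceptorKey:
    """(isotype, anticodon) pair identifying an isoacceptor family.

    The anticodon is stored lowercase; ``*`` is the catalog wildcard
    meaning every isoacceptor of the isotype.
    """

    isotype: str
    anticodon: str

    def __post_init__(self) -> None:
        ac = self.anticodon.lower()
        object.__setattr__(self, "anticodon", ac)
        if ac != "*" and (len(ac) != 3 or set(ac) - set("acgt")):
            raise ValidationError(f"invalid anticodon {self.anticodon!r}")

    def __str__(self) -> str:
        return f"{self.isotype}({self.anticodon})"


@dataclass(frozen=True)
class TRNAGene:
    """One annotated tRNA gene, sequence stored as the sense strand."""

    gene_id: str
    source_genome: str
    isotype: str
    anticodon: str  # uppercase DNA 3-mer
    sequence: str
    origin: GeneOrigin = GeneOrigin.ANNOTATION_TABLE

    @property
    def key(self) -> IsoacceptorKey:
        return IsoacceptorKey(self.isotype, self.anticodon.lower())


@dataclass(frozen=True)
class AnticodonArm:
    stem5: str
    loop: str
    stem3: str
    loop_start: int  # 0-based index of the loop within the gene sequence
    pairing_count: int

    @property
    def anticodon(self) -> str:
        return self.loop[ANTICODON_SLICE]


class ArmNotFoundError(PhagetrnaError):
    """No candidate arm met the stem-pairing threshold.

    ``best_candidate`` carries the highest-scoring rejected arm (or None
    if the sequence admitted no window at all) for diagnostics.
    """

    def __init__(self, message: str, best_candidate: AnticodonArm | None = None):
        super().__init__(message)
        self.best_candidate = best_candidate


def pairing_count(stem5: str, stem3: str) -> int:
    """Number of paired positions between a 5' stem and its 3' partner.

    Position i of ``stem5`` is checked against position 4-i of ``stem3``
    (the stems run antiparallel); A:T, G:C and G:T wobble all count.
    """
    if len(stem5) != STEM_LEN or len(stem3) != STEM_LEN:
        raise ValueError("stems must be 5-mers")
    return sum(
        (stem5[i], stem3[STEM_LEN - 1 - i]) in _PAIRS for i in range(STEM_LEN)
    )


def _candidate_at(sequence: str, loop_start: int) -> AnticodonArm | None:
    if loop_start < STEM_LEN or loop_start + LOOP_LEN + STEM_LEN > len(sequence):
        return None
    stem5 = sequence[loop_start - STEM_LEN : loop_start]
    loop = sequence[loop_start : loop_start + LOOP_LEN]
    stem3 = sequence[loop_start + LOOP_LEN : loop_start + LOOP_LEN + STEM_LEN]
    return AnticodonArm(
        stem5=stem5,
        loop=loop,
        stem3=stem3,
        loop_start=loop_start,
        pairing_count=pairing_count(stem5, stem3),
    )


def find_anticodon_arm(sequence: str,
                       anticodon_hint: str | None = None) -> AnticodonArm:
    """Locate the anticodon arm in a tRNA gene sequence.

    With a hint, every occurrence of the hint trimer is treated as a
    putative anticodon (loop indices 2–4) and candidates pairing at ≥3 of
    5 stem positions are kept; without a hint every loop placement is
    scored and the threshold rises to ≥4. Among admissible candidates the
    best-paired one wins; ties go to the candidate whose loop start is
    closest to ``POSITIONAL_PRIOR × length``, then to the smallest start.
    """
    if len(sequence) < ARM_LEN:
        raise ValueError(f"sequence shorter than one arm ({ARM_LEN} nt)")
    sequence = sequence.upper()

    if anticodon_hint is not None:
        hint = anticodon_hint.upper().replace("U", "T")
        if len(hint) != 3:
            raise ValueError("anticodon hint must be a 3-mer")
        starts = []
        p = sequence.find(hint)
        while p != -1:
            starts.append(p - 2)  # anticodon at loop indices 2-4
            p = sequence.find(hint, p + 1)
        threshold = 3
    else:
        starts = list(range(len(sequence)))
        threshold = 4

    candidates = [c for s in starts if (c := _candidate_at(sequence, s))]
    if not candidates:
        raise ArmNotFoundError(
            "no admissible arm window"
            + (f" for anticodon {anticodon_hint!r}" if anticodon_hint else "")
        )
    admissible = [c for c in candidates if c.pairing_count >= threshold]
    if not admissible:
        best = max(candidates, key=lambda c: c.pairing_count)
        raise ArmNotFoundError(
            f"best candidate pairs at only {best.pairing_count}/5 "
            f"(threshold {threshold})",
            best_candidate=best,
        )
    prior = POSITIONAL_PRIOR * len(sequence)
    return min(
        admissible,
        key=lambda c: (-c.pairing_count, abs(c.loop_start - prior), c.loop_start),
    )


def extract_loop(gene: TRNAGene) -> str:
    """The gene's 7-nt anticodon loop, located with its anticodon as hint."""
    if gene.anticodon.upper() not in gene.sequence.upper():
        raise ValueError(
            f"{gene.gene_id}: anticodon {gene.anticodon!r} does not occur "
            "in the gene sequence"
        )
    return find_anticodon_arm(gene.sequence, gene.anticodon).loop


def normalize_gene(row: AnnotationRow, genome: SequenceRecord,
                   gene_id: str | None = None) -> TRNAGene:
    """Build a sense-strand :class:`TRNAGene` from an annotation row.

    Minus-strand rows (``begin > end``) are reverse-complemented so the
    stored sequence reads 5'→3' on the tRNA sense strand.
    """
    lo, hi = sorted((row.begin, row.end))
    if lo < 1 or hi > len(genome.residues):
        raise ValidationError(
            f"{row.source_sequence}.{row.gene_index}: coordinates "
            f"{row.begin}..{row.end} outside genome of length "
            f"{len(genome.residues)}"
        )
    segment = genome.residues[lo - 1 : hi]
    if row.is_reverse:
        segment = reverse_complement(segment)
    return TRNAGene(
        gene_id=gene_id or f"{row.source_sequence}.trna{row.gene_index}",
        source_genome=genome.identifier,
        isotype=row.isotype,
        anticodon=row.anticodon.upper(),
        sequence=segment,
        origin=GeneOrigin.ANNOTATION_TABLE,
    )
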