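"""Anticodon nucleases and their per-isoacceptor target specifications.

An anticodon nuclease (tRNAse) is a host toxin — VapC, PrrC, Colicin D,
Colicin E5, RelE, MazF and relatives — that cleaves specific tRNAs inside
the anticodon loop, depleting the translation-competent tRNA pool. Each
:class:`TargetSpec` records where in the 7-nt loop frame (indices 0–6,
tRNA positions 32–38) one nuclease cuts one isoacceptor:

* an integer cleavage bond ``b`` (0–5) is the phosphodiester bond between
  loop indices ``b`` and ``b+1``;
* the sentinel ``"anticodon"`` means the cut lies inside the anticodon
  (indices 2–4) but the exact bond is uncharacterized;
* an optional 2-nt motif names the dinucleotide straddling the cut.

Two catalogs ship with the package (``data/catalog_mycobacteria.tsv`` and
``data/catalog_enterobacteria.tsv``); both are plain TSV and user-editable.
Entries with ``modification_dependent`` set (Colicin E5) cannot be called
cleaved/uncleaved from sequence alone because cleavage requires a wobble
modification this package cannot see; they are reported in a separate
call class downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

from .errors import ValidationError
from .trna_structure import ANTICODON_SLICE, LOOP_LEN, IsoacceptorKey, TRNAGene

ANTICODON_INDICES = frozenset(range(ANTICODON_SLICE.start, ANTICODON_SLICE.stop))


@dataclass(frozen=True)
class TargetSpec:
    """One nuclease's specification for one isoacceptor (or an isotype
    wildcard, anticodon ``*``)."""

    key: IsoacceptorKey
    cleavage_bond: int | str  # 0..5 or the sentinel "anticodon"
    motif: str | None = None
    citation_note: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.cleavage_bond, int):
            if not 0 <= self.cleavage_bond <= 5:
                raise ValidationError(
                    f"cleavage bond {self.cleavage_bond} outside 0..5"
                )
        elif self.cleavage_bond != "anticodon":
            raise ValidationError(
                f"cleavage_bond must be 0..5 or 'anticodon', "
                f"got {self.cleavage_bond!r}"
            )
        if self.motif is not None and len(self.motif) != 2:
            raise ValidationError(f"motif {self.motif!r} is not a 2-mer")


@dataclass(frozen=True)
class NucleaseEntry:
    name: str
    source_organism: str
    modification_dependent: bool
    targets: tuple[TargetSpec, ...]

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValidationError(f"nuclease {self.name!r} has no targets")


def _motif_anticodon_placements(spec: TargetSpec) -> list[int]:
    """Loop indices where the motif can sit consistently with the spec's
    (known) anticodon, restricted to placements overlapping the anticodon.

    Flank positions (loop indices 0–1 and 5–6) are not fixed by a spec, so
    only placements that overlap indices 2–4 can be checked; a placement is
    legal when every motif base falling inside the anticodon matches it.
    """
    if spec.motif is None or spec.key.anticodon == "*":
        return []
    anticodon = spec.key.anticodon.upper()
    placements = []
    for start in range(LOOP_LEN - 1):  # motif occupies start, start+1
        covered = {start, start + 1}
        if not covered & ANTICODON_INDICES:
            continue
        ok = True
        for offset, base in enumerate(spec.motif):
            idx = start + offset
            if idx in ANTICODON_INDICES and anticodon[idx - 2] != base:
                ok = False
                break
        if ok:
            placements.append(start)
    return placements


def bond_in_anticodon(spec: TargetSpec) -> bool:
    """Whether the spec's cut lies within the anticodon itself.

    True when the bond is the ``"anticodon"`` sentinel, when both
    nucleotides flanking an integer bond fall inside loop indices 2–4
    (bonds 2 and 3), or when every anticodon-consistent placement of the
    spec's motif lies entirely within indices 2–4.
    """
    if spec.cleavage_bond == "anticodon":
        return True
    if isinstance(spec.cleavage_bond, int) and spec.cleavage_bond in (2, 3):
        return True
    placements = _motif_anticodon_placements(spec)
    return bool(placements) and all(
        {p, p + 1} <= ANTICODON_INDICES for p in placements
    )


def targets_for(
    key: IsoacceptorKey, catalog: Sequence[NucleaseEntry]
) -> list[tuple[NucleaseEntry, TargetSpec]]:
    """All (nuclease, spec) pairs targeting the given isoacceptor.

    Exact (isotype, anticodon) matches and isotype wildcards both count;
    order follows the catalog.
    """
    hits = []
    for entry in catalog:
        for spec in entry.targets:
            if spec.key.isotype != key.isotype:
                continue
            if spec.key.anticodon in ("*", key.anticodon):
                hits.append((entry, spec))
    return hits


def targeted_isoacceptors(
    host_set: Iterable[TRNAGene], catalog: Sequence[NucleaseEntry]
) -> list[IsoacceptorKey]:
    """Distinct host isoacceptors with at least one matching target spec,
    sorted by (isotype, anticodon)."""
    keys = {g.key for g in host_set}
    return sorted(k for k in keys if targets_for(k, catalog))


def builtin_catalog(name: str) -> list[NucleaseEntry]:
    """Load a shipped catalog: ``"mycobacteria"`` or ``"enterobacteria"``."""
    from .io_formats import load_catalog

    ref = resources.files("phagetrna.data") / f"catalog_{name}.tsv"
    with resources.as_file(ref) as path:
        return load_catalog(path)
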