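"""Phage-versus-host anticodon-loop comparison across a phage collection.

For every phage tRNA that a catalogued anticodon nuclease targets, the
gene is matched to its host counterpart, both anticodon loops are placed
in the fixed 0–6 frame, and the differing positions are classified
against the nuclease's cleavage site:

* ``mutated_at_cleavage_site`` — a difference touches a cleavage-site
  position (predicted insensitive to the nuclease);
* ``mutated_in_loop`` — differences only elsewhere in the 7-nt loop;
* ``loop_identical`` — no difference (predicted still cleavable);
* ``modification_dependent_unresolved`` — the nuclease needs a base
  modification to act, so no cleaved/uncleaved prediction is made;
* ``no_host_counterpart`` — the host lacks the isotype entirely.

Calls are predictions from sequence alone, mirroring the comparative
inference they implement; no biochemical claim is attached. The module
also computes isoacceptor prevalence across the collection (fraction of
phages encoding each key, copy number ignored) and avoidance records for
host isoacceptors cleaved within the anticodon itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import edlib

from .nuclease_catalog import (
    ANTICODON_INDICES,
    NucleaseEntry,
    TargetSpec,
    bond_in_anticodon,
    targeted_isoacceptors,
    targets_for,
)
from .trna_structure import (
    LOOP_LEN,
    ArmNotFoundError,
    IsoacceptorKey,
    TRNAGene,
    extract_loop,
)

logger = logging.getLogger(__name__)


class Call(str, Enum):
    MUTATED_AT_CLEAVAGE_SITE = "mutated_at_cleavage_site"
    MUTATED_IN_LOOP = "mutated_in_loop"
    LOOP_IDENTICAL = "loop_identical"
    MODIFICATION_DEPENDENT_UNRESOLVED = "modification_dependent_unresolved"
    NO_HOST_COUNTERPART = "no_host_counterpart"


class MatchLevel(str, Enum):
    EXACT = "exact"          # same (isotype, anticodon)
    ISOTYPE = "isotype"      # same isotype, different anticodon
    NONE = "none"


@dataclass(frozen=True)
class SensitivityCall:
    phage_id: str
    phage_gene_id: str
    host_gene_id: str | None
    nuclease_name: str
    isotype: str
    anticodon: str
    cleavage_bond: str
    motif: str
    call: Call
    differing_positions: tuple[int, ...]
    host_match_level: MatchLevel


@dataclass(frozen=True)
class PrevalenceRecord:
    isotype: str
    anticodon: str
    phages_encoding: int
    collection_size: int
    fraction: float


@dataclass(frozen=True)
class AvoidanceRecord:
    isotype: str
    anticodon: str
    nuclease_name: str
    within_anticodon: bool
    prevalence_fraction: float
    avoided: bool


@dataclass(frozen=True)
class SkipRecord:
    phage_id: str
    gene_id: str
    reason: str


@dataclass(frozen=True)
class CollectionSummary:
    """Counts for the collection-level question: of the targeted
    isoacceptors any phage encodes, how many carry a cleavage-site
    mutation wherever they occur? Gene copies and isoacceptor species
    are both reported because the two tallies can differ."""

    n_phages: int
    n_genes: int
    n_genes_skipped: int
    targeted_keys_encoded: tuple[str, ...]
    n_targeted_keys_encoded: int
    n_targeted_keys_mutated_in_all_phages: int
    n_targeted_gene_copies: int
    n_targeted_copies_mutated_at_site: int


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b)["editDistance"]


def match_host_counterpart(
    phage_gene: TRNAGene, host_set: Sequence[TRNAGene]
) -> tuple[TRNAGene | None, MatchLevel]:
    """Pick the host tRNA a phage gene should be compared against.

    Exact (isotype, anticodon) matches win; among several host copies the
    one at the smallest full-sequence edit distance is used, ties broken
    by gene id. Without an exact key match the search falls back to the
    same isotype (anticodon-shifted phage tRNAs are exactly the
    interesting evasion candidates, so they are flagged rather than
    dropped). Returns ``(None, MatchLevel.NONE)`` when the host lacks the
    isotype entirely.
    """
    exact = [g for g in host_set if g.key == phage_gene.key]
    pool, level = (exact, MatchLevel.EXACT) if exact else (
        [g for g in host_set if g.isotype == phage_gene.isotype],
        MatchLevel.ISOTYPE,
    )
    if not pool:
        return None, MatchLevel.NONE
    best = min(
        pool,
        key=lambda g: (_edit_distance(phage_gene.sequence, g.sequence), g.gene_id),
    )
    return best, level


def cleavage_site_positions(spec: TargetSpec, host_loop: str) -> frozenset[int]:
    """Loop indices counted as the cleavage site for one target spec.

    Integer bond b → the two flanking indices {b, b+1}; a motif → every
    index covered by an occurrence of the motif in the HOST loop; the
    bare ``"anticodon"`` sentinel → the anticodon indices {2, 3, 4}.
    """
    if isinstance(spec.cleavage_bond, int):
        return frozenset({spec.cleavage_bond, spec.cleavage_bond + 1})
    if spec.motif:
        positions: set[int] = set()
        start = host_loop.find(spec.motif)
        while start != -1:
            positions.update({start, start + 1})
            start = host_loop.find(spec.motif, start + 1)
        if positions:
            return frozenset(positions)
    return frozenset(ANTICODON_INDICES)


def compare_loops(
    host_loop: str,
    phage_loop: str,
    spec: TargetSpec,
    modification_dependent: bool = False,
) -> tuple[Call, tuple[int, ...]]:
    """Classify a phage loop against its host counterpart for one spec."""
    if len(host_loop) != LOOP_LEN or len(phage_loop) != LOOP_LEN:
        raise ValueError("loops must be 7-mers")
    host_loop = host_loop.upper()
    phage_loop = phage_loop.upper()
    differing = tuple(
        i for i in range(LOOP_LEN) if host_loop[i] != phage_loop[i]
    )
    if not differing:
        return Call.LOOP_IDENTICAL, differing
    if modification_dependent:
        return Call.MODIFICATION_DEPENDENT_UNRESOLVED, differing
    site = cleavage_site_positions(spec, host_loop)
    if any(i in site for i in differing):
        return Call.MUTATED_AT_CLEAVAGE_SITE, differing
    return Call.MUTATED_IN_LOOP, differing


def analyze_collection(
    phage_sets: Mapping[str, Sequence[TRNAGene]],
    host_set: Sequence[TRNAGene],
    catalog: Sequence[NucleaseEntry],
) -> tuple[list[SensitivityCall], CollectionSummary, list[SkipRecord]]:
    """One sensitivity call per (phage gene, matching target spec).

    Genes whose anticodon arm cannot be located are skipped with a
    logged :class:`SkipRecord`; ordering is deterministic (phage id,
    gene id, catalog order).
    """
    calls: list[SensitivityCall] = []
    skips: list[SkipRecord] = []
    host_loops: dict[str, str] = {}
    n_genes = 0

    for phage_id in sorted(phage_sets):
        for gene in sorted(phage_sets[phage_id], key=lambda g: g.gene_id):
            n_genes += 1
            specs = targets_for(gene.key, catalog)
            if not specs:
                continue
            try:
                phage_loop = extract_loop(gene)
            except (ArmNotFoundError, ValueError) as exc:
                logger.warning("skipping %s/%s: %s", phage_id, gene.gene_id, exc)
                skips.append(SkipRecord(phage_id, gene.gene_id, str(exc)))
                continue
            host_gene, level = match_host_counterpart(gene, host_set)
            host_loop: str | None = None
            if host_gene is not None:
                if host_gene.gene_id not in host_loops:
                    try:
                        host_loops[host_gene.gene_id] = extract_loop(host_gene)
                    except (ArmNotFoundError, ValueError) as exc:
                        logger.warning(
                            "host gene %s unusable: %s", host_gene.gene_id, exc
                        )
                        host_loops[host_gene.gene_id] = ""
                host_loop = host_loops[host_gene.gene_id] or None
            for entry, spec in specs:
                if host_loop is None:
                    call, differing = Call.NO_HOST_COUNTERPART, ()
                else:
                    call, differing = compare_loops(
                        host_loop, phage_loop, spec, entry.modification_dependent
                    )
                calls.append(
                    SensitivityCall(
                        phage_id=phage_id,
                        phage_gene_id=gene.gene_id,
                        host_gene_id=host_gene.gene_id if host_gene else None,
                        nuclease_name=entry.name,
                        isotype=gene.isotype,
                        anticodon=gene.anticodon.lower(),
                        cleavage_bond=str(spec.cleavage_bond),
                        motif=spec.motif or "-",
                        call=call,
                        differing_positions=differing,
                        host_match_level=level,
                    )
                )

    summary = _summarize(phage_sets, calls, n_genes, len(skips))
    return calls, summary, skips


def _summarize(
    phage_sets: Mapping[str, Sequence[TRNAGene]],
    calls: Sequence[SensitivityCall],
    n_genes: int,
    n_skipped: int,
) -> CollectionSummary:
    targeted_keys = sorted({(c.isotype, c.anticodon) for c in calls})
    # phage -> key -> has a cleavage-site-mutation call
    mutated_by: dict[tuple[str, str], dict[str, bool]] = {
        k: {} for k in targeted_keys
    }
    copies: set[tuple[str, str]] = set()
    mutated_copies: set[tuple[str, str]] = set()
    for c in calls:
        key = (c.isotype, c.anticodon)
        per_phage = mutated_by[key]
        hit = c.call is Call.MUTATED_AT_CLEAVAGE_SITE
        per_phage[c.phage_id] = per_phage.get(c.phage_id, False) or hit
        copies.add((c.phage_id, c.phage_gene_id))
        if hit:
            mutated_copies.add((c.phage_id, c.phage_gene_id))
    n_all_mutated = sum(
        1 for key in targeted_keys if all(mutated_by[key].values())
    )
    return CollectionSummary(
        n_phages=len(phage_sets),
        n_genes=n_genes,
        n_genes_skipped=n_skipped,
        targeted_keys_encoded=tuple(
            f"{iso}({ac})" for iso, ac in targeted_keys
        ),
        n_targeted_keys_encoded=len(targeted_keys),
        n_targeted_keys_mutated_in_all_phages=n_all_mutated,
        n_targeted_gene_copies=len(copies),
        n_targeted_copies_mutated_at_site=len(mutated_copies),
    )


def prevalence(
    phage_sets: Mapping[str, Sequence[TRNAGene]]
) -> list[PrevalenceRecord]:
    """Fraction of phages encoding each observed isoacceptor; a phage
    counts once per key regardless of copy number."""
    if not phage_sets:
        raise ValueError("empty phage collection")
    n = len(phage_sets)
    seen: dict[IsoacceptorKey, set[str]] = {}
    for phage_id, genes in phage_sets.items():
        for gene in genes:
            seen.setdefault(gene.key, set()).add(phage_id)
    return [
        PrevalenceRecord(
            isotype=key.isotype,
            anticodon=key.anticodon,
            phages_encoding=len(phages),
            collection_size=n,
            fraction=len(phages) / n,
        )
        for key in sorted(seen)
        for phages in [seen[key]]
    ]


def avoidance(
    phage_sets: Mapping[str, Sequence[TRNAGene]],
    host_set: Sequence[TRNAGene],
    catalog: Sequence[NucleaseEntry],
    threshold: float = 0.05,
) -> list[AvoidanceRecord]:
    """Avoidance records for host isoacceptors cleaved within the
    anticodon itself: avoided when ≤ ``threshold`` of phages encode them.
    """
    prev = {
        (r.isotype, r.anticodon): r.fraction for r in prevalence(phage_sets)
    }
    records = []
    for key in targeted_isoacceptors(host_set, catalog):
        within = [
            entry.name
            for entry, spec in targets_for(key, catalog)
            if bond_in_anticodon(spec)
        ]
        if not within:
            continue
        fraction = prev.get((key.isotype, key.anticodon), 0.0)
        records.append(
            AvoidanceRecord(
                isotype=key.isotype,
                anticodon=key.anticodon,
                nuclease_name=",".join(dict.fromkeys(within)),
                within_anticodon=True,
                prevalence_fraction=fraction,
                avoided=fraction <= threshold,
            )
        )
    return records
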