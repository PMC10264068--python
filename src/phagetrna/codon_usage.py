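"""Codon-usage tables and the statistics of the codon-compensation test.

The table reproduces the semantics of the EMBOSS ``cusp`` utility: per
codon, the raw count, the fraction among synonymous codons, and the
frequency per 1000 codons, under the bacterial/archaeal genetic code
(translation table 11). On top of the tables sit the two hypothesis
tests used to probe codon compensation: a Welch two-sample t-test
(codon frequencies of tRNA-decoded versus non-decoded codons, or any two
independent groups) and a paired t-test (phage versus host frequency of
the same codons). Both statistics are computed from their defining
formulas; only the t distribution's tail function comes from SciPy, so
``scipy.stats.ttest_ind``/``ttest_rel`` remain available as independent
cross-checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

from .errors import DegenerateInputError
from .io_formats import SequenceRecord
from .trna_structure import IsoacceptorKey, reverse_complement

logger = logging.getLogger(__name__)

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_BASES = "ACGT"

#: all 64 codons in alphabetical order
CODONS: tuple[str, ...] = tuple(
    a + b + c for a in _BASES for b in _BASES for c in _BASES
)
#: codon → one-letter amino acid, stops mapped to ``*``
CODON_TO_AA: dict[str, str] = {
    **_TABLE11.forward_table,
    **{c: "*" for c in _TABLE11.stop_codons},
}
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in CODONS if CODON_TO_AA[c] != "*"
)


@dataclass(frozen=True)
class CodonUsageTable:
    """cusp-style usage table over all 64 codons.

    ``fraction`` is the share within the synonymous family (all zero for
    a family never observed); ``per_1000`` is count / total × 1000.
    """

    counts: Mapping[str, int]
    total: int
    skipped: int  # codons containing N, excluded from every statistic

    @classmethod
    def from_counts(cls, counts: Mapping[str, int],
                    skipped: int = 0) -> "CodonUsageTable":
        full = {c: int(counts.get(c, 0)) for c in CODONS}
        return cls(counts=full, total=sum(full.values()), skipped=skipped)

    def as_dataframe(self) -> pd.DataFrame:
        rows = []
        family_totals: dict[str, int] = {}
        for codon in CODONS:
            family_totals[CODON_TO_AA[codon]] = (
                family_totals.get(CODON_TO_AA[codon], 0) + self.counts[codon]
            )
        for codon in CODONS:
            aa = CODON_TO_AA[codon]
            count = self.counts[codon]
            fam = family_totals[aa]
            rows.append(
                {
                    "codon": codon,
                    "amino_acid": aa,
                    "count": count,
                    "fraction": count / fam if fam else 0.0,
                    "per_1000": count / self.total * 1000 if self.total else 0.0,
                }
            )
        return pd.DataFrame(rows)

    def per_1000(self, codon: str) -> float:
        return self.counts[codon] / self.total * 1000 if self.total else 0.0

    def fraction(self, codon: str) -> float:
        aa = CODON_TO_AA[codon]
        fam = sum(self.counts[c] for c in CODONS if CODON_TO_AA[c] == aa)
        return self.counts[codon] / fam if fam else 0.0


@dataclass(frozen=True)
class PreferredCodon:
    amino_acid: str
    codon: str
    tie_flag: bool


@dataclass(frozen=True)
class PreferredCodonComparison:
    amino_acid: str
    phage_preferred: str
    host_preferred: str
    match: bool
    tie_flag: bool


@dataclass(frozen=True)
class StatResult:
    test_name: str
    statistic: float
    df: float
    p_value: float


def count_codons(cds_set: Sequence[SequenceRecord]) -> CodonUsageTable:
    """Count codons over a CDS set in frame 0.

    A trailing partial codon is truncated with a logged warning; codons
    containing N are excluded and tallied in ``skipped``.
    """
    if not cds_set:
        raise ValueError("empty CDS set")
    counts: dict[str, int] = {}
    skipped = 0
    for rec in cds_set:
        seq = rec.residues
        if len(seq) % 3:
            logger.warning(
                "%s: length %d not divisible by 3; trailing partial codon "
                "truncated", rec.identifier, len(seq),
            )
            seq = seq[: len(seq) - len(seq) % 3]
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if "N" in codon:
                skipped += 1
                continue
            counts[codon] = counts.get(codon, 0) + 1
    return CodonUsageTable.from_counts(counts, skipped=skipped)


def preferred_codons(table: CodonUsageTable) -> dict[str, PreferredCodon]:
    """Most frequent codon per synonymous family (families with zero
    counts are omitted); ties resolved alphabetically and flagged."""
    by_family: dict[str, list[tuple[str, int]]] = {}
    for codon in CODONS:
        by_family.setdefault(CODON_TO_AA[codon], []).append(
            (codon, table.counts[codon])
        )
    out: dict[str, PreferredCodon] = {}
    for aa, members in sorted(by_family.items()):
        best_count = max(n for _, n in members)
        if best_count == 0:
            continue
        winners = [c for c, n in members if n == best_count]
        out[aa] = PreferredCodon(
            amino_acid=aa, codon=min(winners), tie_flag=len(winners) > 1
        )
    return out


def concordance(
    phage_table: CodonUsageTable,
    host_table: CodonUsageTable,
    families: Iterable[str] | None = None,
) -> tuple[list[PreferredCodonComparison], int]:
    """Compare preferred codons of phage and host per amino-acid family.

    ``families`` restricts the comparison (e.g. to the amino acids whose
    codons the phage tRNA repertoire decodes); by default every amino
    acid observed in both tables is compared. Stop codons are never
    compared (the question is per amino acid). Returns the comparison
    list and the mismatch count.
    """
    phage_pref = preferred_codons(phage_table)
    host_pref = preferred_codons(host_table)
    if families is None:
        wanted = sorted(set(phage_pref) & set(host_pref) - {"*"})
    else:
        wanted = sorted(set(families) - {"*"})
    comparisons = []
    for aa in wanted:
        if aa not in phage_pref or aa not in host_pref:
            continue
        p, h = phage_pref[aa], host_pref[aa]
        comparisons.append(
            PreferredCodonComparison(
                amino_acid=aa,
                phage_preferred=p.codon,
                host_preferred=h.codon,
                match=p.codon == h.codon,
                tie_flag=p.tie_flag or h.tie_flag,
            )
        )
    mismatches = sum(1 for c in comparisons if not c.match)
    return comparisons, mismatches


def codons_decoded_by(repertoire: Iterable[IsoacceptorKey]) -> list[str]:
    """Codons read by a tRNA repertoire under strict Watson–Crick
    pairing: the reverse complement of each anticodon, no wobble
    expansion; deduplicated and sorted."""
    return sorted(
        {
            reverse_complement(key.anticodon.upper())
            for key in repertoire
            if key.anticodon != "*"
        }
    )


def families_decoded_by(repertoire: Iterable[IsoacceptorKey]) -> set[str]:
    """Amino-acid families whose codons the repertoire decodes."""
    return {
        CODON_TO_AA[c] for c in codons_decoded_by(repertoire)
    } - {"*"}


def per_cds_group_frequency(
    cds_set: Sequence[SequenceRecord], codons: Iterable[str]
) -> list[float]:
    """Per-CDS frequency (per 1000 codons) of a codon group.

    One value per CDS: how often any codon of the group occurs in that
    CDS, per 1000 codons. Unlike per-codon columns of a pooled usage
    table, these values are independent across CDSs, so they are the
    right sampling unit for comparing codon-group frequencies between
    two gene sets with a t-test.
    """
    wanted = {c.upper() for c in codons}
    values = []
    for rec in cds_set:
        seq = rec.residues[: len(rec.residues) - len(rec.residues) % 3]
        total = 0
        hits = 0
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if "N" in codon:
                continue
            total += 1
            hits += codon in wanted
        values.append(hits / total * 1000 if total else 0.0)
    return values


def welch_t_test(group_a: Sequence[float],
                 group_b: Sequence[float]) -> StatResult:
    """Welch's two-sample t-test (unequal variances), two-sided.

    t = (x̄_a − x̄_b) / sqrt(s²_a/n_a + s²_b/n_b) with unbiased sample
    variances; degrees of freedom by Welch–Satterthwaite.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n ≥ 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise DegenerateInputError("both groups have zero variance")
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (
        sa**2 / (a.size - 1) + sb**2 / (b.size - 1)
    )
    p = 2 * stats.t.sf(abs(t), df)
    return StatResult("welch_two_sample_t", float(t), float(df), float(p))


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Paired t-test: one-sample t on the index-wise differences,
    df = n − 1, two-sided."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("paired samples must have equal length")
    if xa.size < 2:
        raise ValueError("need n ≥ 2 pairs")
    d = xa - ya
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("all paired differences identical")
    t = d.mean() / (sd / np.sqrt(d.size))
    df = d.size - 1
    p = 2 * stats.t.sf(abs(t), df)
    return StatResult("paired_t", float(t), float(df), float(p))
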