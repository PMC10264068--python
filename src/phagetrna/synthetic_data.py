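"""Seeded generator of host/phage fixtures with known ground truth.

A :class:`Scenario` pins down the study conditions — which isoacceptors
the host encodes, which of them anticodon nucleases target and where,
which targets the phages avoid entirely, which loop position each
targeted phage copy mutates, and the codon-weight profiles behind the
CDS sets — so every pipeline stage can be exercised against a planted
truth with no downloads.

Generated tRNA genes have canonical geometry: random flanks around a
perfectly paired 5-bp stem and a 7-nt loop ``CT<anticodon>AA`` (U33 and
the conserved purines 37–38 rendered in DNA). Phage genes copy host
genes; a planned mutation substitutes the planted loop position with the
next base in A<C<G<T cyclic order so fixtures stay checkable by eye.
Avoided isoacceptors are simply omitted from every phage. The generator
is a pure function of the scenario: one pseudo-random stream per
scenario seed, with sub-streams derived from stable labels (host key,
phage index, CDS index) so adding a phage never perturbs earlier ones.

These fixtures emulate the evasion pattern under study, not real genome
evolution: no phylogeny, no drift, no annotation noise.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .codon_usage import CODON_TO_AA, SENSE_CODONS
from .errors import ValidationError
from .io_formats import (
    AnnotationRow,
    SequenceRecord,
    write_fasta,
    write_report_tsv,
    write_trnascan_table,
)
from .nuclease_catalog import NucleaseEntry, TargetSpec
from .sensitivity_analysis import Call, cleavage_site_positions
from .trna_structure import (
    GeneOrigin,
    IsoacceptorKey,
    TRNAGene,
    find_anticodon_arm,
    reverse_complement,
)

_BASES = "ACGT"
_CYCLE = {"A": "C", "C": "G", "G": "T", "T": "A"}

#: gene layout: 26-nt 5' flank, 5-bp stem, 7-nt loop, 5-bp stem, 33-nt
#: 3' flank → 76 nt with the loop starting at index 31 (anticodon ≈
#: position 34 of a canonical tRNA)
_PREFIX_LEN = 26
_SUFFIX_LEN = 33
_LOOP_START = _PREFIX_LEN + 5


def loop_for(anticodon: str) -> str:
    """The planted 7-nt loop for an anticodon: ``CT<anticodon>AA``."""
    return "CT" + anticodon.upper() + "AA"


@dataclass(frozen=True)
class ScenarioTarget:
    """One synthetic nuclease→isoacceptor assignment."""

    nuclease_name: str
    key: IsoacceptorKey
    cleavage_bond: int | str
    motif: str | None = None

    def spec(self) -> TargetSpec:
        return TargetSpec(
            key=self.key,
            cleavage_bond=self.cleavage_bond,
            motif=self.motif,
            citation_note="synthetic scenario target",
        )


@dataclass(frozen=True)
class GroundTruthRow:
    phage_id: str
    gene_id: str
    isotype: str
    anticodon: str
    expected_call: str  # Call value, or "" for untargeted genes


@dataclass(frozen=True)
class Scenario:
    seed: int
    n_phages: int
    host_keys: tuple[IsoacceptorKey, ...]
    targets: tuple[ScenarioTarget, ...]
    avoided_keys: tuple[IsoacceptorKey, ...]
    #: per targeted key, the loop index to mutate in every phage copy,
    #: or None for "no planted mutation"
    mutation_plan: Mapping[IsoacceptorKey, int | None] = field(
        default_factory=dict
    )
    phage_profile: Mapping[str, float] | str = "gc_rich"
    host_profile: Mapping[str, float] | str = "gc_rich"
    n_cds: int = 40
    cds_length: int = 300

    @property
    def targeted_keys(self) -> tuple[IsoacceptorKey, ...]:
        return tuple(dict.fromkeys(t.key for t in self.targets))

    def target_for(self, key: IsoacceptorKey) -> ScenarioTarget:
        for t in self.targets:
            if t.key == key:
                return t
        raise KeyError(str(key))

    def validate(self) -> None:
        host = set(self.host_keys)
        targeted = set(self.targeted_keys)
        avoided = set(self.avoided_keys)
        if not targeted <= host:
            raise ValidationError(
                f"targeted keys not in host set: "
                f"{sorted(str(k) for k in targeted - host)}"
            )
        if not avoided <= targeted:
            raise ValidationError(
                f"avoided keys not targeted: "
                f"{sorted(str(k) for k in avoided - targeted)}"
            )
        for key, idx in self.mutation_plan.items():
            if key not in targeted:
                raise ValidationError(
                    f"mutation planned for untargeted key {key}"
                )
            if idx is None:
                continue
            if not 0 <= idx <= 6:
                raise ValidationError(
                    f"{key}: mutation index {idx} outside the loop (0..6)"
                )
            spec = self.target_for(key).spec()
            site = cleavage_site_positions(spec, loop_for(key.anticodon))
            if idx not in site:
                raise ValidationError(
                    f"{key}: planned index {idx} is not a cleavage-site "
                    f"position (site = {sorted(site)})"
                )
        if self.cds_length % 3:
            raise ValidationError("cds_length must be divisible by 3")
        if self.n_phages < 1:
            raise ValidationError("need at least one phage")


def codon_profile(profile: Mapping[str, float] | str) -> dict[str, float]:
    """Resolve a named preset or explicit codon-weight mapping.

    Presets: ``uniform`` (equal weight on all sense codons) and
    ``gc_rich`` (weight 2^(G+C per codon), a caricature of a high-GC
    genome such as a mycobacterium's, with a deterministic 1.5× ranking
    inside each synonymous family so every family has a stable preferred
    codon rather than sampling-noise ties).
    """
    if isinstance(profile, str):
        if profile == "uniform":
            return {c: 1.0 for c in SENSE_CODONS}
        if profile == "gc_rich":
            weights = {}
            by_family: dict[str, list[str]] = {}
            for c in SENSE_CODONS:
                by_family.setdefault(CODON_TO_AA[c], []).append(c)
            for members in by_family.values():
                ranked = sorted(
                    members, key=lambda c: (sum(b in "GC" for b in c), c)
                )
                for rank, c in enumerate(ranked):
                    weights[c] = float(
                        2 ** sum(b in "GC" for b in c) * 1.5**rank
                    )
            return weights
        raise ValidationError(f"unknown codon profile preset {profile!r}")
    weights = {c: float(w) for c, w in profile.items()}
    if any(w < 0 for w in weights.values()):
        raise ValidationError("codon weights must be non-negative")
    if not any(w > 0 for w in weights.values()):
        raise ValidationError("codon weights are all zero")
    return weights


def _rng(seed: int, *labels: object) -> np.random.Generator:
    parts = [seed & 0x7FFFFFFF] + [
        zlib.crc32(str(lab).encode()) & 0x7FFFFFFF for lab in labels
    ]
    return np.random.default_rng(parts)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def generate_host_trnas(scenario: Scenario) -> list[TRNAGene]:
    """One canonical host tRNA gene per host isoacceptor key.

    Each gene carries a perfectly paired planted arm and its anticodon
    occurs exactly once in the sequence, so arm finding with the
    anticodon hint is unambiguous. Deterministic under the scenario seed.
    """
    scenario.validate()

    def resolves_cleanly(seq: str, anticodon: str) -> bool:
        # the planted arm must be the unique, winning candidate
        if seq.count(anticodon) != 1:
            return False
        return find_anticodon_arm(seq, anticodon).loop_start == _LOOP_START

    genes = []
    targeted = set(scenario.targeted_keys)
    for i, key in enumerate(scenario.host_keys):
        rng = _rng(scenario.seed, "host", str(key))
        anticodon = key.anticodon.upper()
        loop = loop_for(anticodon)
        plan = scenario.mutation_plan.get(key) if key in targeted else None
        for _attempt in range(200):
            stem5 = _random_dna(rng, 5)
            stem3 = reverse_complement(stem5)
            seq = (
                _random_dna(rng, _PREFIX_LEN)
                + stem5 + loop + stem3
                + _random_dna(rng, _SUFFIX_LEN)
            )
            if not resolves_cleanly(seq, anticodon):
                continue
            if plan is not None:
                # the phage copy with the planted mutation must resolve too
                pos = _LOOP_START + plan
                mutated = seq[:pos] + _CYCLE[seq[pos]] + seq[pos + 1 :]
                hint = (
                    mutated[_LOOP_START + 2 : _LOOP_START + 5]
                    if 2 <= plan <= 4
                    else anticodon
                )
                if not resolves_cleanly(mutated, hint):
                    continue
            break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError(f"could not place a unique anticodon for {key}")
        genes.append(
            TRNAGene(
                gene_id=f"host.trna{i + 1:02d}_{key.isotype}_{key.anticodon}",
                source_genome="host_genome",
                isotype=key.isotype,
                anticodon=anticodon,
                sequence=seq,
                origin=GeneOrigin.ANNOTATION_TABLE,
            )
        )
    return genes


def generate_phage_collection(
    scenario: Scenario, host_genes: Sequence[TRNAGene]
) -> tuple[dict[str, list[TRNAGene]], list[GroundTruthRow]]:
    """Copy the host repertoire into each phage, planting the scenario's
    mutations and omitting avoided isoacceptors; ground truth is emitted
    alongside, one row per generated gene."""
    scenario.validate()
    avoided = set(scenario.avoided_keys)
    targeted = set(scenario.targeted_keys)
    phage_sets: dict[str, list[TRNAGene]] = {}
    truth: list[GroundTruthRow] = []
    for j in range(1, scenario.n_phages + 1):
        phage_id = f"phage_{j:03d}"
        genes: list[TRNAGene] = []
        for host_gene in host_genes:
            key = host_gene.key
            if key in avoided:
                continue
            seq = host_gene.sequence
            anticodon = host_gene.anticodon
            expected = ""
            if key in targeted:
                plan = scenario.mutation_plan.get(key)
                if plan is None:
                    expected = Call.LOOP_IDENTICAL.value
                else:
                    pos = _LOOP_START + plan
                    seq = seq[:pos] + _CYCLE[seq[pos]] + seq[pos + 1 :]
                    if 2 <= plan <= 4:
                        anticodon = seq[
                            _LOOP_START + 2 : _LOOP_START + 5
                        ]
                    expected = Call.MUTATED_AT_CLEAVAGE_SITE.value
            gene = TRNAGene(
                gene_id=f"{phage_id}.{host_gene.gene_id.split('.', 1)[1]}",
                source_genome=phage_id,
                isotype=host_gene.isotype,
                anticodon=anticodon,
                sequence=seq,
                origin=GeneOrigin.ANNOTATION_TABLE,
            )
            genes.append(gene)
            truth.append(
                GroundTruthRow(
                    phage_id=phage_id,
                    gene_id=gene.gene_id,
                    isotype=gene.isotype,
                    anticodon=gene.anticodon.lower(),
                    expected_call=expected,
                )
            )
        phage_sets[phage_id] = genes
    return phage_sets, truth


def generate_cds_set(
    weights: Mapping[str, float] | str,
    n_cds: int,
    cds_length: int,
    seed: int,
    label: str = "cds",
) -> list[SequenceRecord]:
    """CDS records with internal codons drawn i.i.d. from a weight
    profile; the first codon is forced to ATG and the last to a stop.

    Internal draws are restricted to sense codons so every record is a
    plausible open reading frame. Deterministic under (seed, label).
    """
    prof = codon_profile(weights)
    if cds_length % 3:
        raise ValueError("cds_length must be divisible by 3")
    if cds_length < 9:
        raise ValueError("cds_length must allow start + codon + stop")
    sense = [c for c in sorted(prof) if CODON_TO_AA.get(c, "*") != "*"]
    sense = [c for c in sense if prof[c] > 0]
    if not sense:
        raise ValueError("profile has no positive-weight sense codon")
    p = np.array([prof[c] for c in sense], dtype=float)
    p /= p.sum()
    stops = [c for c in ("TAA", "TAG", "TGA") if prof.get(c, 0) > 0]
    stop_w = None
    if stops:
        stop_w = np.array([prof[c] for c in stops], dtype=float)
        stop_w /= stop_w.sum()
    else:
        stops = ["TAA"]
    n_internal = cds_length // 3 - 2
    records = []
    for i in range(n_cds):
        rng = _rng(seed, label, i)
        internal = rng.choice(sense, size=n_internal, p=p)
        stop = stops[0] if stop_w is None else str(
            rng.choice(stops, p=stop_w)
        )
        records.append(
            SequenceRecord(
                identifier=f"{label}_{i + 1:04d}",
                description=f"{label}_{i + 1:04d} synthetic CDS",
                residues="ATG" + "".join(internal) + stop,
            )
        )
    return records


def scenario_catalog(scenario: Scenario) -> list[NucleaseEntry]:
    """The scenario's targets grouped into an in-memory nuclease catalog
    (the same content ``write_scenario_fixtures`` writes to catalog.tsv)."""
    grouped: dict[str, list[TargetSpec]] = {}
    for t in scenario.targets:
        grouped.setdefault(t.nuclease_name, []).append(t.spec())
    return [
        NucleaseEntry(
            name=name,
            source_organism="synthetic",
            modification_dependent=False,
            targets=tuple(specs),
        )
        for name, specs in grouped.items()
    ]


def default_scenario(seed: int = 101) -> Scenario:
    """The shipped study conditions: 12 host isoacceptors, 4 targeted
    with planted cleavage-site mutations, 2 anticodon-targeted and
    avoided, 20 phages, identical phage/host codon profiles (the
    no-compensation null)."""
    k = IsoacceptorKey
    mutated = [
        ScenarioTarget("VapC-like", k("Thr", "tgt"), 0),
        ScenarioTarget("PrrC-like", k("Lys", "ttt"), 1),
        ScenarioTarget("MazF-like", k("Gly", "gcc"), 4),
        ScenarioTarget("RelE-like", k("Leu", "taa"), 5),
    ]
    avoided = [
        ScenarioTarget("VapC", k("Ser", "gga"), "anticodon", motif="GA"),
        ScenarioTarget("VapC", k("Ser", "tga"), "anticodon", motif="GA"),
    ]
    untargeted = [
        k("Ser", "gct"), k("Ala", "agc"), k("Arg", "acg"),
        k("Asn", "gtt"), k("Gln", "ttg"), k("Pro", "tgg"),
    ]
    return Scenario(
        seed=seed,
        n_phages=20,
        host_keys=tuple(
            [t.key for t in mutated] + [t.key for t in avoided] + untargeted
        ),
        targets=tuple(mutated + avoided),
        avoided_keys=tuple(t.key for t in avoided),
        mutation_plan={
            k("Thr", "tgt"): 0,
            k("Lys", "ttt"): 1,
            k("Gly", "gcc"): 5,
            k("Leu", "taa"): 6,
        },
        phage_profile="gc_rich",
        host_profile="gc_rich",
        n_cds=40,
        cds_length=300,
    )


# --- scenario (de)serialization -------------------------------------------

def _key_to_str(key: IsoacceptorKey) -> str:
    return f"{key.isotype}:{key.anticodon}"


def _key_from_str(s: str) -> IsoacceptorKey:
    isotype, _, anticodon = s.partition(":")
    return IsoacceptorKey(isotype, anticodon)


def scenario_to_json(scenario: Scenario) -> dict:
    return {
        "seed": scenario.seed,
        "n_phages": scenario.n_phages,
        "host_keys": [_key_to_str(key) for key in scenario.host_keys],
        "targets": [
            {
                "nuclease_name": t.nuclease_name,
                "key": _key_to_str(t.key),
                "cleavage_bond": t.cleavage_bond,
                "motif": t.motif,
            }
            for t in scenario.targets
        ],
        "avoided_keys": [_key_to_str(key) for key in scenario.avoided_keys],
        "mutation_plan": {
            _key_to_str(key): ("none" if idx is None else idx)
            for key, idx in scenario.mutation_plan.items()
        },
        "phage_profile": scenario.phage_profile
        if isinstance(scenario.phage_profile, str)
        else dict(scenario.phage_profile),
        "host_profile": scenario.host_profile
        if isinstance(scenario.host_profile, str)
        else dict(scenario.host_profile),
        "n_cds": scenario.n_cds,
        "cds_length": scenario.cds_length,
    }


def scenario_from_json(data: Mapping) -> Scenario:
    return Scenario(
        seed=int(data["seed"]),
        n_phages=int(data["n_phages"]),
        host_keys=tuple(_key_from_str(s) for s in data["host_keys"]),
        targets=tuple(
            ScenarioTarget(
                nuclease_name=t["nuclease_name"],
                key=_key_from_str(t["key"]),
                cleavage_bond=t["cleavage_bond"],
                motif=t.get("motif"),
            )
            for t in data["targets"]
        ),
        avoided_keys=tuple(
            _key_from_str(s) for s in data["avoided_keys"]
        ),
        mutation_plan={
            _key_from_str(s): (None if idx == "none" else int(idx))
            for s, idx in data.get("mutation_plan", {}).items()
        },
        phage_profile=data.get("phage_profile", "gc_rich"),
        host_profile=data.get("host_profile", "gc_rich"),
        n_cds=int(data.get("n_cds", 40)),
        cds_length=int(data.get("cds_length", 300)),
    )


def load_scenario(path: str | Path) -> Scenario:
    with open(path) as fh:
        scenario = scenario_from_json(json.load(fh))
    scenario.validate()
    return scenario


# --- on-disk fixture layout ------------------------------------------------

def _assemble_genome(
    genes: Sequence[TRNAGene], genome_id: str, rng: np.random.Generator
) -> tuple[SequenceRecord, list[AnnotationRow]]:
    """Concatenate genes into a toy genome with random spacers; every
    third gene is placed on the minus strand to exercise strand
    handling."""
    parts = [_random_dna(rng, int(rng.integers(20, 41)))]
    offset = len(parts[0])
    rows = []
    for i, gene in enumerate(genes, start=1):
        reverse = i % 3 == 0
        placed = (
            reverse_complement(gene.sequence) if reverse else gene.sequence
        )
        begin_plus = offset + 1
        end_plus = offset + len(placed)
        rows.append(
            AnnotationRow(
                source_sequence=genome_id,
                gene_index=i,
                begin=end_plus if reverse else begin_plus,
                end=begin_plus if reverse else end_plus,
                isotype=gene.isotype,
                anticodon=gene.anticodon,
                score=99.9,
            )
        )
        spacer = _random_dna(rng, int(rng.integers(20, 41)))
        parts.extend([placed, spacer])
        offset = end_plus + len(spacer)
    genome = SequenceRecord(
        identifier=genome_id,
        description=f"{genome_id} synthetic tRNA-cluster genome",
        residues="".join(parts),
    )
    return genome, rows


def write_scenario_fixtures(scenario: Scenario,
                            outdir: str | Path) -> dict[str, Path]:
    """Materialize a scenario as files: host and per-phage genome FASTA +
    tRNAscan-SE-dialect tables, the scenario catalog TSV, the phage tRNA
    repertoire, two CDS FASTA sets, ground_truth.tsv and scenario.json.

    Byte-identical across runs with the same scenario.
    """
    scenario.validate()
    outdir = Path(outdir)
    (outdir / "phages").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    host_genes = generate_host_trnas(scenario)
    phage_sets, truth = generate_phage_collection(scenario, host_genes)

    genome, rows = _assemble_genome(
        host_genes, "host_genome", _rng(scenario.seed, "genome", "host")
    )
    paths["host_fasta"] = write_fasta([genome], outdir / "host.fasta")
    paths["host_annot"] = write_trnascan_table(
        rows, outdir / "host.trnascan.tsv"
    )

    for phage_id in sorted(phage_sets):
        genome, rows = _assemble_genome(
            phage_sets[phage_id],
            phage_id,
            _rng(scenario.seed, "genome", phage_id),
        )
        write_fasta([genome], outdir / "phages" / f"{phage_id}.fasta")
        write_trnascan_table(
            rows, outdir / "phages" / f"{phage_id}.trnascan.tsv"
        )
    paths["phage_dir"] = outdir / "phages"

    catalog_rows = [
        {
            "nuclease_name": t.nuclease_name,
            "source_organism": "synthetic",
            "isotype": t.key.isotype,
            "anticodon": t.key.anticodon,
            "cleavage_bond": t.cleavage_bond,
            "motif": t.motif or "-",
            "modification_dependent": 0,
            "citation_note": "synthetic scenario target",
        }
        for t in scenario.targets
    ]
    paths["catalog"] = write_report_tsv(
        catalog_rows, outdir / "catalog.tsv"
    )

    repertoire = sorted(
        {g.key for genes in phage_sets.values() for g in genes}
    )
    paths["repertoire"] = write_report_tsv(
        [
            {"isotype": key.isotype, "anticodon": key.anticodon}
            for key in repertoire
        ],
        outdir / "repertoire.tsv",
        columns=["isotype", "anticodon"],
    )

    paths["phage_cds"] = write_fasta(
        generate_cds_set(
            scenario.phage_profile, scenario.n_cds, scenario.cds_length,
            scenario.seed, label="phage_cds",
        ),
        outdir / "phage_cds.fasta",
    )
    paths["host_cds"] = write_fasta(
        generate_cds_set(
            scenario.host_profile, scenario.n_cds, scenario.cds_length,
            scenario.seed, label="host_cds",
        ),
        outdir / "host_cds.fasta",
    )

    paths["ground_truth"] = write_report_tsv(
        truth,
        outdir / "ground_truth.tsv",
        columns=[
            "phage_id", "gene_id", "isotype", "anticodon", "expected_call"
        ],
    )

    scenario_path = outdir / "scenario.json"
    with open(scenario_path, "w", newline="\n") as fh:
        json.dump(scenario_to_json(scenario), fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["scenario"] = scenario_path
    return paths
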