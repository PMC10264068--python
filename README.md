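# phagetrna

Do phage-encoded tRNAs evade the host's tRNA-cleaving defenses?

Many bacteria respond to phage infection by depleting their own tRNA
pool with **anticodon nucleases** (tRNAses) such as VapC, PrrC,
Colicin D, Colicin E5, MazF and RelE: toxins that cut specific tRNAs
inside the anticodon loop and stall translation. Phages — especially
tRNA-rich ones such as cluster C1 mycobacteriophages — carry large tRNA
clusters of their own, and a comparison of those tRNAs with their host
counterparts shows a striking pattern: wherever a host isoacceptor is a
nuclease target, the phage copy carries mutations at the cleavage site,
and where the cut falls *inside the anticodon itself* (so that no
mutation could rescue both cleavage resistance and decoding), phages
tend not to encode that isoacceptor at all. `phagetrna` implements that
comparative analysis as a tested, reusable pipeline, together with the
codon-usage statistics needed to test the classical alternative
explanation (codon compensation) and a seeded synthetic-data generator
that provides ground-truthed fixtures for every stage.

## The analysis in brief

* **Anticodon arm model.** The anticodon arm is a 5-bp stem closing a
  7-nt loop; loop indices 0–6 correspond to standard tRNA positions
  32–38, the anticodon sits at indices 2–4 (positions 34–36). Stems may
  pair Watson–Crick or G:T wobble. `find_anticodon_arm` locates the arm
  either from an annotated anticodon (every occurrence is scored as a
  putative loop centre, stem pairing ≥ 3/5 required) or ab initio
  (pairing ≥ 4/5), with deterministic tie-breaks.
* **Nuclease catalog.** Each target specification names an isoacceptor
  (isotype + anticodon, wildcards allowed), a cleavage bond *b* — the
  phosphodiester bond between loop indices *b* and *b*+1 — or the
  sentinel `anticodon`, and optionally the dinucleotide motif straddling
  the cut (e.g. the GA site of serine tRNAs). Two editable TSV catalogs
  ship with the package (mycobacterial and enterobacterial main-text
  targets).
* **Sensitivity calls.** Each phage tRNA is matched to its host
  counterpart (exact isoacceptor first, isotype fallback, edit-distance
  tie-breaks) and the two loops are compared position by position:
  `mutated_at_cleavage_site`, `mutated_in_loop`, `loop_identical`,
  `modification_dependent_unresolved` (Colicin E5-style targets whose
  cleavage needs a wobble modification the sequence cannot show), or
  `no_host_counterpart`.
* **Prevalence and avoidance.** Prevalence is the fraction of phages in
  the collection encoding an isoacceptor (copy number ignored). Host
  isoacceptors cleaved within the anticodon are reported as *avoided*
  when that fraction is ≤ 0.05 (configurable).
* **Codon-usage arm.** cusp-style tables (count, synonymous fraction,
  frequency per 1000; genetic code 11), preferred-codon concordance per
  amino-acid family, the strict reverse-complement map from anticodons
  to decoded codons, and two tests implemented from their defining
  formulas: Welch's two-sample *t* (Welch–Satterthwaite df) and the
  paired *t*.

## Worked example

`examples/synthetic_pipeline.py` generates the default study conditions
(12 host isoacceptors; 4 targeted by nucleases, with a cleavage-site
mutation planted in every phage copy; 2 serine isoacceptors targeted
within the anticodon and omitted from every phage; 20 phages) and runs
the full comparison:

```
phages: 20, phage tRNA genes: 200
targeted isoacceptors encoded: ('Gly(gcc)', 'Leu(taa)', 'Lys(ttt)', 'Thr(tgt)')
targeted gene copies mutated at the cleavage site: 80/80
call classes: {'mutated_at_cleavage_site': 80}
Ser(gga) targeted by VapC within the anticodon: prevalence 0.00 -> avoided=True
Ser(tga) targeted by VapC within the anticodon: prevalence 0.00 -> avoided=True
Lys(ttt) encoded by 20/20 phages (fraction 1.00)
```

Every targeted phage tRNA copy (80/80) is called mutated at its
nuclease's cleavage site, and both anticodon-targeted isoacceptors are
absent from all 20 phages — the evasion-plus-avoidance pattern the
pipeline is built to detect. `examples/codon_statistics.py` runs the
codon arm on CDS sets drawn from identical codon-weight profiles:

```
preferred-codon concordance: 0 mismatches in 10 amino-acid families
Welch decoded vs non-decoded: t=-0.9993 df=19.372 p=0.3300
paired phage vs host (decoded codons): t=1.1457 df=9 p=0.2815
```

Neither test rejects: the codons decoded by the phage repertoire are
not used unusually often, i.e. no sign of codon compensation in these
data. The same analyses are available from a shell:

```sh
phagetrna all --seed 11 --out run/       # simulate + both analysis arms
phagetrna sensitivity --host-fasta ... --host-annot ... \
    --phage-dir ... --catalog ... --out reports/
```

Real inputs are genome FASTA plus tRNAscan-SE v2.0 tabular annotation
for the host and for each phage, a catalog TSV, and (for the codon arm)
CDS FASTA sets.

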