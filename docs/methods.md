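# Methods

## The comparison being computed

The pipeline asks two questions of a phage collection and its bacterial
host. First, for every phage tRNA whose isoacceptor (isotype +
anticodon) is the target of a host anticodon nuclease, does the phage
copy differ from the host tRNA at the nuclease's cleavage site? Such
differences are reported as *predicted* insensitivity — the inference
is comparative, from sequence alone; no biochemical claim is attached.
Second, for host isoacceptors cleaved *within the anticodon itself*
(where any rescuing mutation would also change decoding), does the
phage collection simply avoid encoding them? A codon-usage arm tests
the classical alternative hypothesis, codon compensation: if phage
tRNAs existed to supply rare codons, the codons they decode should be
enriched in phage genes relative to non-decoded codons, and phage and
host usage of those codons should differ.

## Loop coordinate frame

All cleavage geometry lives in one frame: the 7-nt anticodon loop is
indexed 0–6, corresponding to standard tRNA positions 32–38, with the
anticodon at indices 2–4. A cleavage bond *b* ∈ {0..5} is the
phosphodiester bond between loop indices *b* and *b*+1; its
cleavage-site positions are the two flanking indices {*b*, *b*+1}. For
motif-specified cuts (e.g. the GA dinucleotide of VapC-sensitive serine
tRNAs) the site positions are every index covered by an occurrence of
the motif in the **host** loop. For the sentinel bond `anticodon`
(cut known to lie inside the anticodon, exact bond uncharacterized,
and no motif available) the site is the anticodon indices {2, 3, 4};
this completes the definition for the one case the bond/motif rules do
not cover. A cut is "within the anticodon" when the bond is the
sentinel, the bond is 2 or 3, or every anticodon-consistent placement
of the motif lies wholly inside indices 2–4. Placements that could
straddle an unconstrained flank position (possible for anticodons
ending in G followed by the motif's first base, e.g. aga with motif GA)
are *not* counted as within-anticodon from the motif alone; catalog
rows that need the stronger claim carry the explicit sentinel.

## Arm finding

Canonical geometry only: a 5-bp stem closing a 7-nt loop. Watson–Crick
pairs and G:T wobble count as paired; expanded loops (8–9 nt) are
rejected with a diagnostic rather than guessed at. With an anticodon
hint, every occurrence of the hint trimer is scored as a putative loop
centre and candidates pairing at ≥ 3 of 5 stem positions are kept;
without a hint all loop placements are scored and the threshold rises
to 4/5 (a random 5-bp window pairs ≥ 4/5 with probability ≈ 4%, so the
hintless threshold trades some sensitivity for specificity). The
best-paired candidate wins; ties break to the loop start closest to
0.42 × sequence length (anticodon ≈ position 34 of a ~76-nt tRNA),
then to the smallest start. The finder is verified against an
independent exhaustive search (same scoring, written flat) on hundreds
of random planted-arm sequences per run of the acceptance script.
Annotated inputs (tRNAscan-SE tables) bypass the search entirely except
for loop extraction.

## Host matching and call classes

A phage tRNA is compared against the host gene with the same
isoacceptor key; among several host copies the full-sequence edit
distance (edlib) decides, then the gene identifier. When the host has
the isotype but not the anticodon, the comparison falls back to the
isotype level and the call is flagged — anticodon-shifted phage tRNAs
are precisely the interesting evasion candidates, so they are kept, not
dropped. Calls: `mutated_at_cleavage_site` (a differing loop position
touches the cleavage site), `mutated_in_loop` (differences elsewhere in
the loop; used deliberately broadly since the loop is only 7 nt and no
distance cutoff is defensible), `loop_identical`,
`modification_dependent_unresolved` (targets such as Colicin E5's,
whose cleavage depends on a wobble modification invisible to sequence
comparison — any non-identity is reported without a cleaved/uncleaved
verdict), and `no_host_counterpart`. The collection summary reports
both isoacceptor species and gene-copy tallies, since "N targeted
tRNAs" can mean either.

## Prevalence and avoidance

Prevalence is presence/absence per phage (copy number ignored), so a
record is the fraction of phages encoding the key. Avoidance is
reported only for host isoacceptors cleaved within the anticodon;
`avoided` means prevalence ≤ 0.05 of the collection. The 0.05 default
operationalizes "rarely encode" without privileging exact absence; it
is a parameter of the avoidance call, exposed on the CLI.

## Codon-usage arm

Tables reproduce cusp semantics: per codon, raw count, fraction among
synonymous codons, and frequency per 1000 codons, under genetic code
11 (bacterial). CDS records with a trailing partial codon are truncated
with a warning; codons containing N are excluded and tallied. Preferred
codons are per amino-acid family (stop codons excluded from
concordance), ties broken alphabetically and flagged. The
anticodon→codon map is the strict reverse complement — no wobble or
superwobble expansion — because any wobble rule set would inject
assumptions the comparison does not need; the repertoire therefore
defines both the decoded codon set and the amino-acid families compared
for concordance.

Both t statistics are computed from their defining formulas (Welch's
unpooled t with Welch–Satterthwaite df; paired t as a one-sample t on
differences), with only the t distribution's tail function taken from
SciPy, so `scipy.stats.ttest_ind`/`ttest_rel` remain genuinely
independent cross-checks in the test suite. Degenerate inputs (zero
variance in both groups; all paired differences equal) raise a typed
error that the CLI records in `stats.tsv` rather than masking with an
arbitrary number.

Two statistical design points deserve note, both consequences of the
per-1000 sum constraint of a pooled usage table:

* the paired phage-vs-host test is run over the repertoire-decoded
  codons only — across *all* sense codons the per-1000 values of two
  tables with equal stop fractions sum to the same total, forcing the
  mean paired difference to ≈ 0 and making the test vacuous;
* type-I calibration of the Welch test is measured on per-CDS
  frequencies of a fixed codon group (one value per CDS, independent
  across CDSs), not on per-codon columns of one table, which are
  multinomially dependent and would mis-calibrate any i.i.d.-based
  test.

## Synthetic data

The generator emulates exactly the evasion pattern under study. Host
genes are 76 nt: random flanks, a perfectly paired random 5-bp stem,
and the loop `CT<anticodon>AA` (U33 and the conserved 37–38 purines in
DNA form), with the anticodon placed so the loop starts at index 31;
candidate sequences are redrawn until the anticodon occurs exactly once
and both the gene and its planned mutant resolve to the planted arm, so
ground-truth recovery holds by construction for every seed. Phages copy
every non-avoided host gene; planned mutations substitute one
cleavage-site loop position with the next base in A<C<G<T cyclic order
(checkable by eye); avoided keys are omitted from every phage. Fixtures
are written as toy genomes (genes concatenated with random spacers,
every third gene on the minus strand to exercise strand handling) plus
tRNAscan-SE-dialect tables, a catalog TSV, CDS FASTA sets, ground truth
and the scenario itself. Generation is a pure function of the scenario:
one stream per seed with sub-streams derived from stable labels, so
adding a phage never perturbs earlier ones.

Default conditions (the shipped scenario): 12 host isoacceptors, 4
targeted with planted cleavage-site mutations (bonds 0, 1, 4, 5 —
outside the anticodon, so the isoacceptor identity is preserved), 2
serine isoacceptors targeted within the anticodon via the GA motif and
avoided, 20 phages, and identical phage/host codon profiles (the
no-compensation null). The `gc_rich` codon profile weights codons by
2^(G+C) with a deterministic 1.5× ranking within each synonymous family
so every family has a stable preferred codon; `uniform` is also
available. CDS sets default to 40 records of 300 nt (start forced to
ATG, final codon a stop, internal codons drawn i.i.d. from the profile
restricted to sense codons — premature stops would make the records
implausible ORFs and distort the stop family's fractions).

What the fixtures do **not** model: phylogenetic correlation between
phages, annotation errors, introns, expanded loops, base
modifications, partial gene copies, and recognition-site (as opposed to
cleavage-site) determinants. Passing on synthetic data therefore
demonstrates correctness of the implemented comparison, not robustness
to real annotation noise; real analyses should feed tRNAscan-SE tables
and inspect the skipped-gene report.

## Problem sizes and runtime choices

The shipped scenario (20 phages × 10 tRNAs) runs in seconds. The
acceptance script uses 500 planted arms for oracle agreement, 100
random CDS sets for table invariants, 100 random datasets for
statistic/reference agreement, and 1000 replicates (2 × 20 CDS of
300 nt each) for Welch calibration — sizes at which the binomial noise
on the calibration estimate (≈ 0.7 percentage points s.d.) is well
inside the ±2-point acceptance band.

## Known limitations

* One annotation dialect (tRNAscan-SE tabular); disagreements between
  annotation tools must be resolved upstream.
* Catalog fixtures encode only well-attested main-text targets; the
  catalog is data, and real studies should extend it from primary
  literature (the Colicin D row records its loop-edge bond
  approximation in its citation note; one catalog row transcribes a
  published Gln(cga) RelE target verbatim and flags that the anticodon
  would not decode a Gln codon).
* Recognition-site mutations cannot be distinguished from neutral loop
  differences when a nuclease's recognition sequence is unknown; calls
  outside the cleavage site are deliberately coarse (`mutated_in_loop`).
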