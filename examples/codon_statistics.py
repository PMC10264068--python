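"""Codon-usage tables and the codon-compensation statistics.

Generates phage and host CDS sets from the same codon-weight profile
(the no-compensation null), builds cusp-style usage tables, compares
preferred codons per amino acid, and runs the two t-tests: Welch
(decoded vs non-decoded codons within the phage genes) and paired
(phage vs host frequency of the decoded codons).
"""

from phagetrna import (
    IsoacceptorKey,
    codons_decoded_by,
    concordance,
    count_codons,
    generate_cds_set,
    paired_t_test,
    welch_t_test,
)
from phagetrna.codon_usage import SENSE_CODONS, families_decoded_by

phage_cds = generate_cds_set("gc_rich", 40, 300, seed=101, label="phage_cds")
host_cds = generate_cds_set("gc_rich", 40, 300, seed=101, label="host_cds")
phage_table = count_codons(phage_cds)
host_table = count_codons(host_cds)

# the phage tRNA repertoire of the shipped scenario (avoided keys absent)
repertoire = [
    IsoacceptorKey(i, a)
    for i, a in [
        ("Thr", "tgt"), ("Lys", "ttt"), ("Gly", "gcc"), ("Leu", "taa"),
        ("Ser", "gct"), ("Ala", "agc"), ("Arg", "acg"), ("Asn", "gtt"),
        ("Gln", "ttg"), ("Pro", "tgg"),
    ]
]
decoded = codons_decoded_by(repertoire)
print(f"codons decoded by the phage repertoire: {decoded}")

comparisons, mismatches = concordance(
    phage_table, host_table, families_decoded_by(repertoire)
)
print(
    f"preferred-codon concordance: {mismatches} mismatches in "
    f"{len(comparisons)} amino-acid families"
)

welch = welch_t_test(
    [phage_table.per_1000(c) for c in SENSE_CODONS if c in decoded],
    [phage_table.per_1000(c) for c in SENSE_CODONS if c not in decoded],
)
print(
    f"Welch decoded vs non-decoded: t={welch.statistic:.4f} "
    f"df={welch.df:.3f} p={welch.p_value:.4f}"
)

paired = paired_t_test(
    [phage_table.per_1000(c) for c in decoded],
    [host_table.per_1000(c) for c in decoded],
)
print(
    f"paired phage vs host (decoded codons): t={paired.statistic:.4f} "
    f"df={paired.df:.0f} p={paired.p_value:.4f}"
)
# Non-significant p-values here mean the phage's decoded codons are not
# used unusually often -- no sign of codon compensation in this dataset.
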