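"""Novelty-screen a designed promoter against its source genome and
build a TATA-box knockout variant by transversion.

Run:  python examples/screen_and_variants.py
"""

from plantelements.element_designer import PromoterConstraints, design_promoter, validate_element
from plantelements.motif_variants import make_variant
from plantelements.race_simulator import make_toy_genome
from plantelements.sequence_screen import scan_orfs, screen_diversity

toy = make_toy_genome(seed=9, n_genes=20, chrom_length=150_000)
genome_seq = "".join(
    line for line in toy.fasta.splitlines() if not line.startswith(">")
)

el = design_promoter(None, None, PromoterConstraints(), seed=3)

# Longest run of continuous identity against the genome, both strands;
# designs should stay at or below the 22 bp ceiling.
report = screen_diversity(el.sequence, {"chr1": genome_seq}, max_run=22)
print(f"longest shared identity run: {report.max_run_length} bp "
      f"(threshold 22) -> {'PASS' if report.passed else 'FAIL'}")
qs, qe = report.query_interval
print(f"  witness: element [{qs},{qe}) vs chr1 "
      f"{report.reference_interval} on strand {report.strand}")

orfs = scan_orfs(el.sequence, min_codons=30)
print(f"unintended ORFs of >=30 codons: {len(orfs)}")

# Transversion knockout of the TATA box (AT-rich -> GC-rich, same length).
variant, edits = make_variant(el, {"TATA_BOX"})
edit = edits[0]
print(f"variant {variant.element_id}: {edit.before} -> {edit.after} "
      f"at element offsets {edit.interval}")
changed = sum(a != b for a, b in zip(el.sequence, variant.sequence))
print(f"bases changed: {changed} (= TATA interval length)")
report = validate_element(variant.sequence, variant.features, PromoterConstraints())
print(f"variant still satisfies promoter constraints: {report.passed} "
      f"(violations: {[v[0] for v in report.violations]})")
# Knockouts keep the element length and everything outside the motif;
# the validator names exactly the constraint the knockout broke.
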