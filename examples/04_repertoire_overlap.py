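"""TCR repertoire overlap between two sorted T-cell fractions.

Simulates a pair of immunoSEQ-style repertoires (e.g. T cells proliferating
to a tumour-vaccine peptide pool vs. a bacterial peptide pool) with a
constructed 3.7% shared-clone fraction, then computes the overlap
statistics and the cumulative frequency of the shared clones in a bulk
reference repertoire.
"""

import epitopescan as es

table_a, table_b = es.simulate_repertoire_pair(
    n_a=1000, n_b=1000, shared_fraction_of_a=0.037, seed=1
)
rep_a = es.load_repertoire(table_a, sample="vaccine_pool")
rep_b = es.load_repertoire(table_b, sample="bacteria_pool")
ov = es.overlap_stats(rep_a, rep_b)

print(f"unique productive clones: A={len(rep_a)}  B={len(rep_b)}")
print(f"shared clones (CDR3aa+V+J): {ov.shared}")
print(f"overlap: {ov.pct_of_a:.1f}% of A, {ov.pct_of_b:.1f}% of B, "
      f"Jaccard {ov.jaccard:.4f}")
# 3.7% of the vaccine-responsive clones are also found among the
# bacteria-responsive clones - cross-reactive T cells.

bulk_a, _ = es.simulate_repertoire_pair(5000, 100, 0.0, seed=2)
bulk = es.load_repertoire(bulk_a, sample="bulk_tils")
freq = es.shared_frequency(ov.shared_keys, rep_a)
print(f"shared clones comprise {100 * freq:.2f}% of the focal repertoire's templates")
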