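"""Relative qPCR quantification with the 2^-ddCt method.

Replicate Ct values are averaged, normalized against an endogenous control
(TBP), and expressed relative to a reference: either the highest expressor
(lowest normalized Ct) or the mean of a reference group of samples.
"""

from est2tse import generate_ct_table, relative_expression_frame

ct = generate_ct_table(n_samples=6, genes=("GENE1",), control_gene="TBP",
                       seed=11)
print("replicate Ct table (first rows):")
print(ct.head(4).to_string(index=False))

out = relative_expression_frame(ct, "TBP", reference="min")
print("\nrelative expression (reference = lowest normalized Ct):")
print(out.round(4).to_string(index=False))

# rq = 1 marks the reference sample; every cycle of extra dCt halves rq.
ref = out.loc[out.rq.idxmax()]
print(f"\nreference sample: {ref.sample_id} (rq = {ref.rq:.3f}); "
      f"all other samples have rq < 1")
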