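"""Association between gene detection and a clinical covariate.

A 2x2 contingency table of marker detection (rows) against lymph-node
positivity (columns) is tested with the likelihood-ratio chi-square
(G-test): G = 2 * sum O ln(O/E), df = 1.
"""

from est2tse import lr_chisq

# detected: 11 node-positive, 4 node-negative; non-detected: 5 vs 10
table = [[11, 4], [5, 10]]
g, df, p = lr_chisq(table)
print(f"table {table}")
print(f"G = {g:.4f}, df = {df}, p = {p:.4f}")
print("-> detection is associated with node positivity at p < 0.05"
      if p < 0.05 else "-> no significant association")

# The zero-cell convention 0*ln(0) = 0 keeps sparse tables well-defined:
table2 = [[4, 5], [0, 6]]
g2, _, p2 = lr_chisq(table2)
print(f"sparse table {table2}: G = {g2:.4f}, p = {p2:.4f}")
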