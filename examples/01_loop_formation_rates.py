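"""Two-motor loop-formation-rate simulation across activation folds.

A translocase dimer anchors with one motor (mean 65 bp/s) while the other,
activated by its recombinase partner, runs A-fold faster; the loop between
them grows at |v1 - v2|. Prints the mean +/- SD loop-formation rate at each
activation fold: with sigma = mu = 65 bp/s the fivefold condition lands near
240 bp/s, the regime reported for the active complex.
"""

from pscloop import lfr_table

table = lfr_table(mu=65.0, sigma=65.0, folds=[1, 2, 3, 5, 10], n=1000, seed=1)
print(table.to_string(index=False, float_format="%.1f"))
print("\nEach row: mean loop-growth rate (bp/s) over 1000 sampled motor "
      "pairs,\nwith negative velocity draws redrawn (n_discarded counts them).")
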