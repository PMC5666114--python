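"""Consensus-protein design: identity filtering and majority-rule consensus.

Generates a synthetic alignment by mutating a known 240-residue consensus at
10% per column, filters it to 90% maximum pairwise identity, and shows that
majority rule recovers the original sequence exactly, with the per-column
support profile tracking the substitution rate.
"""

import numpy as np

from openring import (consensus_sequence, filter_max_identity,
                      make_synthetic_msa, pairwise_identity, random_consensus)

truth = random_consensus(length=240, seed=1)
msa = make_synthetic_msa(truth, n_seqs=50, sub_rate=0.10, seed=2)
print(f"alignment: {msa.n_sequences} sequences x {msa.n_columns} columns, "
      "mutated from a hidden consensus at 10%/column")

ident = pairwise_identity(msa.sequences[0], msa.sequences[1])
print(f"typical pairwise identity between two sequences: {ident:.2f}")

filtered = filter_max_identity(msa, threshold=0.90)
print(f"after filtering to <= 90% pairwise identity: "
      f"{filtered.n_sequences} sequences kept")

result = consensus_sequence(msa)
exact = result.consensus == truth
print(f"majority-rule consensus recovers the hidden sequence exactly: {exact}")
print(f"mean per-column support: {np.mean(result.column_support):.3f} "
      "(= 1 - substitution rate, as expected)")
print(f"tied columns flagged: {len(result.tie_columns)}")
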