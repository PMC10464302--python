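"""Batch-scan a synthetic proteome and measure enrichment.

Generates a small FASTA of designed sequences (a phase-separation-prone
minority among folded/disordered background), scans it, and compares the
PS-potential distribution of a query subset against the full set with a
recall curve: AUC > 0.5 means the query is enriched in phase-separation
potential.
"""

import io

import numpy as np

from parse2 import recall_auc, scan_fasta
from parse2.batch import read_fasta
from parse2.synthetic import generate_class_sequence

rng = np.random.default_rng(0)
entries = []
for i in range(60):
    klass = "P" if i % 6 == 0 else ("F" if i % 2 else "D")
    seq = generate_class_sequence(klass, int(rng.integers(80, 160)), seed=rng)
    entries.append(f">syn{i}_{klass}\n{seq}")
records = read_fasta(io.StringIO("\n".join(entries) + "\n"))

result = scan_fasta(records)
summary = result.summary
print(summary.sort_values("ps_potential", ascending=False)
      .head(5)[["id", "length", "ps_potential", "longest_ps_idr"]]
      .to_string(index=False))
print(f"... {len(summary)} rows; "
      f"{len(result.ps_idrs)} PS-IDRs of >= 50 residues exported")

is_ps = summary["id"].str.endswith("_P")
curve = recall_auc(summary.loc[is_ps, "ps_potential"],
                   summary["ps_potential"])
print(f"recall AUC, designed-PS subset vs whole set: {curve.auc:.3f}")
# Sorting the summary by ps_potential ranks candidate phase separators;
# the designed P sequences dominate the top of the table, and their AUC
# near 1 confirms strong enrichment over the mixed background.
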