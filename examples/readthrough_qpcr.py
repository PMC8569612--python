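"""Quantify transcriptional read-through from a qPCR Ct table with the
2^-ddCt method.

Run:  python examples/readthrough_qpcr.py
"""

import pandas as pd

from plantelements.transcript_metrics import readthrough_percent

# Ct values for the reporter (GUS), a read-through amplicon downstream
# of the 3' UTR, and two normalizer genes, per plant sample. A 2-cycle
# Ct gap between read-through and GUS means 4-fold less transcript.
table = pd.DataFrame([
    {"sample_id": "terminator_A", "target": "GUS",           "ct": 21.0},
    {"sample_id": "terminator_A", "target": "READTHROUGH",   "ct": 25.6},
    {"sample_id": "terminator_A", "target": "NORMALIZER_ef1a", "ct": 18.2},
    {"sample_id": "terminator_A", "target": "NORMALIZER_ubq",  "ct": 19.0},
    {"sample_id": "terminator_A_NUE", "target": "GUS",           "ct": 22.3},
    {"sample_id": "terminator_A_NUE", "target": "READTHROUGH",   "ct": 24.3},
    {"sample_id": "terminator_A_NUE", "target": "NORMALIZER_ef1a", "ct": 18.1},
    {"sample_id": "terminator_A_NUE", "target": "NORMALIZER_ubq",  "ct": 19.2},
])

result = readthrough_percent(table)
print(result.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
# pct_readthrough = 100 * 2^-(dCt_readthrough - dCt_GUS): an effective
# terminator keeps it in the single digits; knocking out its
# polyadenylation signal (here the NUE variant) raises it.
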