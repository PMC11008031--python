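"""Detect the hAT structural hallmarks of a freshly inserted element.

A hAT-style element carries ~15 bp terminal inverted repeats and, after
integration, sits between two copies of an ~8 bp target site duplication.
"""

import numpy as np

from httscan import find_tirs, find_tsd, longest_orf_aa
from httscan._seq import random_seq
from httscan.synthetic_data import insert_te, make_te_consensus

te = make_te_consensus(3000, tir_length=15, seed=5, orf_aa=620)
host = random_seq(np.random.default_rng(5), 50_000, 0.44)
genome, iv, tsd = insert_te(host, te, 20_000, tsd_length=8)

tir = find_tirs(genome[iv.start:iv.end])
tsd_rep = find_tsd(genome[iv.start - 30:iv.start], genome[iv.end:iv.end + 30])
orf = longest_orf_aa(te)

print(f"element: {len(te)} bp, inserted at {iv.start}")
print(f"TIR: found={tir.found} length={tir.length} mismatches={tir.mismatches}")
print(f"  5' arm {tir.left_arm[:15]}... matches the reverse complement of the 3' end")
print(f"TSD: found={tsd_rep.found} length={tsd_rep.length} site={tsd_rep.left_site}")
print(f"longest ORF: {orf} aa ({'coding-capable' if orf >= 600 else 'degraded'}: "
      f"hAT transposases exceed 600 aa)")
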