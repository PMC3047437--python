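"""Scan translated reads for conserved heavy-chain amino-acid motifs.

The default catalog carries the teleost DH-JH motif family
(FDYWGKGT[M/K]VTV[SS/TS/ST]) and the VH-region motif EDTAVYYCAR with its
shark-shared core AVYYCAR.  The synthetic germline plants these motifs, so
simulated reads carry them unless mutation destroys the encoding.
"""

from ignet import (SimulationConfig, scan_motifs, simulate_repertoire,
                   synthetic_reference)

ref = synthetic_reference()
rep = simulate_repertoire(ref, SimulationConfig(n_sequences=300, seed=6))

hits, freq = scan_motifs(rep.reads, max_mismatch=0)
print("exact-match motif frequencies (fraction of reads):")
print(freq[["motif_name", "motif", "fraction"]].to_string(index=False))

hits1, freq1 = scan_motifs(rep.reads, max_mismatch=1)
print("\nallowing one mismatching residue:")
print(freq1[["motif_name", "fraction"]].to_string(index=False))
print("\nNote dhjh_mvtvst stays near zero exactly: that variant is absent "
      "from the synthetic germline, mirroring its absence in zebrafish.")
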