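"""Build the single-edit sequence-similarity network of a repertoire.

Identical reads collapse into weighted vertices; edges join sequences one
substitution (red), one deletion (blue), or one deletion plus one
substitution (green) apart.  A random repertoire fragments into many small
components — far more than the 975 germline recipes — because independent
mutations rarely leave sequences one step apart.
"""

from collections import Counter

from ignet import (SimulationConfig, build_network_from_reads,
                   export_network, simulate_repertoire, synthetic_reference)

ref = synthetic_reference()
rep = simulate_repertoire(ref, SimulationConfig(n_sequences=5000, seed=4))

net = build_network_from_reads(rep.reads)
print(f"{net.total_reads} reads -> {len(net.vertices)} vertices, "
      f"{len(net.edges)} edges, {len(net.components)} components")
print("edge colors:", dict(Counter(e.edge_type for e in net.edges)))
print(f"max vertex size: {max(v.multiplicity for v in net.vertices)} "
      "(no dominant clone in a random repertoire)")

export_network(net, "pajek_net", "scratch_network.net")
print("wrote scratch_network.net (+ .clu component partition) "
      "for external graph tools")
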