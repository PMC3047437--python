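"""Classify repertoires as poorly vs highly connected.

A naive repertoire has small vertices and diffuse V/J usage; a repertoire
containing a clonal expansion concentrates reads into one big clone and one
germline recipe.  The classifier calls a repertoire highly connected when
the largest clone holds more than 10% of reads or one V or J segment
accounts for at least 40% of them.
"""

from ignet import (ExpansionConfig, SegmentAssigner, SimulationConfig,
                   build_network_from_reads, centrality_report,
                   classify_phenotype, compare_profiles, filter_repertoire,
                   group_means, simulate_repertoire, synthetic_reference,
                   vj_usage_table)

ref = synthetic_reference()
assigner = SegmentAssigner(ref)

reports, labels, groups = [], [], []
for name, expansion in (("naive", None),
                        ("expanded", ExpansionConfig(lineage_fraction=0.4))):
    rep = simulate_repertoire(ref, SimulationConfig(
        n_sequences=300, seed=5, expansion=expansion))
    kept, _, _ = filter_repertoire(assigner.assign_repertoire(rep.reads))
    report = centrality_report(build_network_from_reads(rep.reads))
    call = classify_phenotype(report, vj_usage_table(kept, ref))
    print(f"{name:9s} largest clone {report.largest_clone_percent:5.1f}% "
          f"max degree {report.max_degree:3d} "
          f"max betweenness {report.max_betweenness:.3f} -> {call.label}"
          + (f"  (fired: {', '.join(call.criteria_fired)})"
             if call.criteria_fired else ""))
    reports.append(report)
    labels.append(name)
    groups.append(name)

df = compare_profiles(reports, labels, groups)
print("\ncentrality profile table:")
print(df.to_string(index=False))
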