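from itertools import product

import numpy as np
import pytest
from Bio.Seq import Seq

from ignet.assignment import SegmentAssigner, filter_repertoire
from ignet.mutations import (GENETIC_CODE, MutationCaller, MutationRecord,
                             classify_silent_replacement, spectrum)
from ignet.simulate import SimulationConfig, simulate_repertoire


class TestSilentReplacement:
    def test_synonymous_codon_is_silent(self):
        # GGA -> GGG, both glycine
        assert classify_silent_replacement("GGA", 2, "G", 0) == "silent"

    def test_nonsynonymous_codon_is_replacement(self):
        # ATG -> ATA, Met -> Ile
        assert classify_silent_replacement("ATG", 2, "A", 0) == "replacement"

    def test_unknown_frame_untranslatable(self):
        assert classify_silent_replacement("GGA", 2, "G", None) == \
            "untranslatable"

    def test_incomplete_codon_untranslatable(self):
        # frame anchor 1: position 0 precedes the first full codon
        assert classify_silent_replacement("GGAA", 0, "C", 1) == \
            "untranslatable"

    def test_all_single_base_changes_match_translation_oracle(self):
        """All 64 codons x 3 positions x 3 alternative bases classified
        identically to direct translation of the two codons."""
        n = 0
        for codon in ("".join(c) for c in product("ACGT", repeat=3)):
            for pos in range(3):
                for alt in "ACGT":
                    if alt == codon[pos]:
                        continue
                    mutated = codon[:pos] + alt + codon[pos + 1:]
                    expected = ("silent"
                                if str(Seq(codon).translate())
                                == str(Seq(mutated).translate())
                                else "replacement")
                    got = classify_silent_replacement(codon, pos, alt, 0)
                    assert got == expected, (codon, pos, alt)
                    n += 1
        assert n == 576


class TestCallMutations:
    def _assign(self, ref, reads):
        assigner = SegmentAssigner(ref)
        assignments = assigner.assign_repertoire(reads)
        kept, _, _ = filter_repertoire(assignments)
        return {a.read_id: a for a in kept}

    def test_unmutated_read_yields_no_records(self, default_ref):
        cfg = SimulationConfig(n_sequences=5, seed=1, sub_rate=0, del_rate=0,
                               ins_rate=0)
        rep = simulate_repertoire(default_ref, cfg)
        by_id = self._assign(default_ref, rep.reads)
        caller = MutationCaller(default_ref)
        for read in rep.reads:
            assert caller.call(read, by_id[read.read_id]) == []

    def test_single_substitution_called(self, default_ref):
        cfg = SimulationConfig(n_sequences=1, seed=1, sub_rate=0, del_rate=0,
                               ins_rate=0)
        rep = simulate_repertoire(default_ref, cfg)
        read = rep.reads[0]
        v_seq = default_ref.get("V", read.truth.v_name).sequence
        pos = 50
        alt = "A" if v_seq[pos] != "A" else "C"
        mutated = read.sequence[:pos] + alt + read.sequence[pos + 1:]
        from ignet.reference import IgRead
        mread = IgRead(read.read_id, mutated)
        by_id = self._assign(default_ref, [mread])
        records = MutationCaller(default_ref).call(mread, by_id[read.read_id])
        assert len(records) == 1
        r = records[0]
        assert (r.seg_class, r.kind, r.germline_pos, r.from_base, r.to_base) \
            == ("V", "substitution", pos, v_seq[pos], alt)

    def test_substitutions_match_truth_positionwise(self, default_ref):
        """With substitutions only, called V/J mutations equal the
        position-by-position difference between read and naive sequence."""
        cfg = SimulationConfig(n_sequences=60, seed=9, sub_rate=3,
                               del_rate=0, ins_rate=0)
        rep = simulate_repertoire(default_ref, cfg)
        by_id = self._assign(default_ref, rep.reads)
        caller = MutationCaller(default_ref)
        v_len = len(default_ref.v_segments[0].sequence)
        for read in rep.reads:
            if read.read_id not in by_id:
                continue
            a = by_id[read.read_id]
            if (a.v_hit.segment_name != read.truth.v_name
                    or a.j_hit.segment_name != read.truth.j_name):
                continue
            naive = rep.naive_sequence(read)
            d_len = len(default_ref.get("D", read.truth.d_name).sequence)
            j_start = v_len + d_len
            expected = set()
            for i, (x, y) in enumerate(zip(naive, read.sequence)):
                if x == y:
                    continue
                if i < v_len:
                    expected.add(("V", i, x, y))
                elif i >= j_start:
                    expected.add(("J", i - j_start, x, y))
            got = {(r.seg_class, r.germline_pos, r.from_base, r.to_base)
                   for r in caller.call(read, a)}
            assert got == expected

    def test_rejects_unfiltered_assignment(self, default_ref):
        from ignet.assignment import SegmentAssignment
        from ignet.reference import IgRead
        bad = SegmentAssignment("r", None, None, "", False, "no_v_hit")
        with pytest.raises(ValueError):
            MutationCaller(default_ref).call(IgRead("r", "ACGT"), bad)


class TestSpectrum:
    def _record(self, f, t, effect="replacement"):
        return MutationRecord("r", "V", "substitution", 0, f, t, effect)

    def test_single_record_origin_100pct(self):
        spec = spectrum([self._record("C", "T")])
        assert spec.origin_percent()["C"] == 100.0

    def test_equal_counts_quarter_each(self):
        recs = [self._record(f, "A" if f != "A" else "C") for f in "ACGT"]
        spec = spectrum(recs)
        assert all(v == pytest.approx(25.0)
                   for v in spec.origin_percent().values())

    def test_conservation_invariants(self, default_ref):
        cfg = SimulationConfig(n_sequences=80, seed=21, sub_rate=3)
        rep = simulate_repertoire(default_ref, cfg)
        assigner = SegmentAssigner(default_ref)
        kept, _, _ = filter_repertoire(assigner.assign_repertoire(rep.reads))
        records = MutationCaller(default_ref).call_repertoire(rep.reads, kept)
        spec = spectrum(records)
        n_subs = sum(1 for r in records if r.kind == "substitution")
        assert spec.total_substitutions == n_subs
        assert spec.transition_matrix.sum(axis=1).tolist() == [
            spec.origin_counts[b] for b in "ACGT"]
        assert np.trace(spec.transition_matrix) == 0
        n_classified = (sum(spec.silent_counts.values())
                        + sum(spec.replacement_counts.values()))
        assert n_classified <= n_subs
        assert sum(v for v in spec.origin_percent().values()) == \
            pytest.approx(100.0, abs=0.01)

    def test_empty_spectrum_flagged(self):
        spec = spectrum([])
        assert spec.total_substitutions == 0
        with pytest.raises(ValueError):
            spec.origin_percent()

    def test_silent_replacement_table_layout(self):
        recs = [self._record("C", "T", "silent"),
                self._record("C", "T", "replacement"),
                self._record("G", "A", "replacement")]
        table = spectrum(recs).silent_replacement_table()
        assert len(table) == 12  # all ordered base pairs
        row = table[(table.from_base == "C") & (table.to_base == "T")]
        assert int(row["silent"].iloc[0]) == 1
        assert int(row["replacement"].iloc[0]) == 1


class TestParameterRecovery:
    def test_origin_weights_recovered_within_ci(self, default_ref):
        """Simulator origin weights recovered by the spectrum within the
        binomial 95% CI (pooled over reads) across 10 seeds."""
        weights = dict(zip("ACGT", (0.14, 0.46, 0.36, 0.04)))
        failures = 0
        for seed in range(10):
            cfg = SimulationConfig(n_sequences=60, seed=100 + seed,
                                   sub_rate=4, del_rate=0, ins_rate=0)
            rep = simulate_repertoire(default_ref, cfg)
            counts = {b: 0 for b in "ACGT"}
            for r in rep.reads:
                for e in r.truth.edits:
                    counts[e.ref] += 1
            total = sum(counts.values())
            for b, p in weights.items():
                half = 1.96 * np.sqrt(p * (1 - p) / total)
                if abs(counts[b] / total - p) > half + 0.01:
                    failures += 1
        assert failures <= 2  # 40 binomial checks at 95% coverage
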