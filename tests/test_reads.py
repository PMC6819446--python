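"""Pair merging, amplicon assignment, profile calling and QC filtering."""

import numpy as np
import pytest
from scipy import stats

import epiamplicon as ea
from epiamplicon.amplicon import bisulfite_reference, define_amplicon, revcomp
from epiamplicon.reads import MergedRead

from conftest import ideal_config, run_pipeline, site_probs_from_meth

RNG = np.random.default_rng(1234)


def _random_seq(n, rng=RNG):
    return "".join(rng.choice(list("ACGT"), size=n))


def _pair_from(seq, cut1, cut2, q1=None, q2=None):
    """R1 = seq[:cut1], R2 = revcomp(seq[cut2:]); constant Q40 by default."""
    r1 = seq[:cut1]
    r2 = revcomp(seq[cut2:])
    q1 = q1 if q1 is not None else "I" * len(r1)
    q2 = q2 if q2 is not None else "I" * len(r2)
    return [("p0", r1, q1)], [("p0", r2, q2)]


class TestMergePairs:
    def test_error_free_pair_reconstructs_molecule(self):
        seq = _random_seq(120)
        r1, r2 = _pair_from(seq, 80, 35)  # true overlap 45
        merged, counts = ea.merge_pairs(r1, r2)
        assert counts["merged"] == 1
        assert merged[0].sequence == seq
        assert merged[0].overlap_len == 45

    def test_short_overlap_rejected_and_counted(self):
        seq = _random_seq(150)
        r1, r2 = _pair_from(seq, 80, 50)  # true overlap 30 < 40
        merged, counts = ea.merge_pairs(r1, r2, min_overlap=40)
        assert merged == []
        assert counts["short_overlap"] == 1
        # the same pair merges once the threshold admits its overlap
        merged2, _ = ea.merge_pairs(r1, r2, min_overlap=25)
        assert merged2 and merged2[0].sequence == seq

    def test_low_identity_overlap_rejected(self):
        seq = _random_seq(120)
        r1 = seq[:80]
        # corrupt 20% of the overlap on the R2 side
        tail = list(seq[35:])
        for i in range(0, 45, 5):
            tail[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[tail[i]]
        r2 = revcomp("".join(tail))
        merged, counts = ea.merge_pairs(
            [("p0", r1, "I" * 80)], [("p0", r2, "I" * len(r2))]
        )
        assert counts["low_overlap_identity"] + counts["short_overlap"] == 1
        assert merged == []

    def test_unpaired_input_rejected(self):
        with pytest.raises(ValueError, match="unpaired"):
            ea.merge_pairs([("a", "ACGT", "IIII")], [])

    def test_truncated_fastq_rejected(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@r1\nACGT\n+\n")
        with pytest.raises(ValueError, match="truncated"):
            ea.merge_pairs(p, p)

    @pytest.mark.parametrize("b1,b2", [(a, b) for a in "ACGT" for b in "ACGT"])
    @pytest.mark.parametrize("qrel", ["r1_higher", "r2_higher", "tie"])
    def test_overlap_consensus_matches_bruteforce_oracle(self, b1, b2, qrel):
        """Every base/quality combination resolves to the brute-force consensus."""
        seq = _random_seq(120, np.random.default_rng(7))
        pos = 60  # inside the 45-nt overlap [35, 80)
        r1 = seq[:80][:pos] + b1 + seq[pos + 1: 80]
        r2f = seq[35:][: pos - 35] + b2 + seq[pos + 1:]
        q1c, q2c = {"r1_higher": ("I", "5"), "r2_higher": ("5", "I"),
                    "tie": ("I", "I")}[qrel]
        q1 = "I" * pos + q1c + "I" * (80 - pos - 1)
        q2f = "I" * (pos - 35) + q2c + "I" * (len(r2f) - (pos - 35) - 1)
        merged, counts = ea.merge_pairs(
            [("p0", r1, q1)], [("p0", revcomp(r2f), q2f[::-1])]
        )
        assert counts["merged"] == 1
        # brute-force consensus: disagreeing bases go to the higher quality,
        # ties to R1
        if b1 == b2:
            expected = b1
        else:
            expected = b2 if ord(q2c) > ord(q1c) else b1
        assert merged[0].sequence[pos] == expected
        # flanks always come from the read that covers them
        assert merged[0].sequence[:35] == seq[:35]
        assert merged[0].sequence[81:] == seq[81:]


class TestAssignAmplicon:
    def test_synthetic_read_assigned_to_source(self, pr1_spec, spikein_spec):
        read = MergedRead("r", pr1_spec.reference_seq.replace("C", "T"),
                          np.full(len(pr1_spec), 40), 100)
        name, offset = ea.assign_amplicon(read, [pr1_spec, spikein_spec])
        assert (name, offset) == (pr1_spec.name, 0)

    def test_random_read_unassigned(self, pr1_spec, spikein_spec):
        read = MergedRead("r", _random_seq(350, np.random.default_rng(3)),
                          np.full(350, 40), 100)
        name, _ = ea.assign_amplicon(read, [pr1_spec, spikein_spec])
        assert name is None

    def test_tie_on_shared_primer_prefers_higher_identity_then_name(self):
        base = ("TTGACGTAGGATACCATGATTGGCTTAAGCAGTTACGGATCATTAGGC"
                "ATTGAACCGTAGGTTACAGGATTCATA")
        twin = base[:-8] + "GGGGGGGG"  # same primer region, worse 3' identity
        spec_a = define_amplicon("ampB", base, tss_index=None)
        spec_z = define_amplicon("ampZ", twin, tss_index=None)
        converted = bisulfite_reference(spec_a).converted_seq.replace("Y", "T")
        read = MergedRead("r", converted, np.full(len(converted), 40), 40)
        # exhaustive scorer: identity of the read against each converted ref
        from epiamplicon.reads import _identity_vs_reference

        idents = {s.name: _identity_vs_reference(read.sequence, bisulfite_reference(s))
                  for s in (spec_a, spec_z)}
        assert idents["ampB"] > idents["ampZ"]
        name, _ = ea.assign_amplicon(read, [spec_z, spec_a])
        assert name == "ampB"
        # exact tie: identical references under different names -> smallest name
        spec_dup = define_amplicon("ampA", base, tss_index=None)
        name, _ = ea.assign_amplicon(read, [spec_a, spec_dup])
        assert name == "ampA"


class TestCallProfile:
    def test_single_cpg_no_noncpg_c(self):
        spec = define_amplicon("t", "ACGTT", tss_index=None)
        read = MergedRead("r", "ACGTT", np.full(5, 40), 5)
        prof = ea.call_profile(read, spec)
        assert prof.calls.tolist() == [1]
        assert prof.conversion_rate_read is None  # zero non-CpG Cs covered

    def test_conversion_rate_over_noncpg_cs(self):
        # 10 non-CpG Cs; read converts 9 of them and keeps the CpG T
        ref = "ACATT" + "CA" * 10 + "CGTT"
        spec = define_amplicon("t", ref, tss_index=None)
        assert spec.n_sites == 1
        read_seq = "ATATT" + "TA" * 9 + "CA" + "TGTT"
        read = MergedRead("r", read_seq, np.full(len(ref), 40), 5)
        prof = ea.call_profile(read, spec, exclude_primers=False)
        assert prof.calls.tolist() == [0]
        assert prof.conversion_rate_read == pytest.approx(10 / 11)

    def test_fully_unmethylated_ideal_sample(self, pr1_spec):
        cfg = ideal_config(
            pr1_spec,
            populations=[ea.Population(1.0, site_probs=site_probs_from_meth([0.0] * 4))],
            n_molecules=20, seed=5)
        states, _ = ea.simulate_molecules(cfg)
        seqs = ea.apply_chemistry(states, cfg)
        for row in seqs:
            read = MergedRead("r", row.tobytes().decode(), np.full(len(row), 40), 100)
            prof = ea.call_profile(read, pr1_spec)
            assert prof.calls.tolist() == [0, 0, 0, 0]
            assert prof.conversion_rate_read == pytest.approx(1.0)
            assert prof.identity == pytest.approx(1.0)

    def test_truncated_read_keeps_covered_calls(self, pr1_spec):
        full = pr1_spec.reference_seq.replace("C", "T")
        read_full = MergedRead("r", full, np.full(len(full), 40), 100)
        read_cut = MergedRead("r", full[:250], np.full(250, 40), 100)
        prof_full = ea.call_profile(read_full, pr1_spec)
        prof_cut = ea.call_profile(read_cut, pr1_spec)
        # sites at +7/+101/+217 are covered by 250 nt, +334 is not
        assert prof_cut.calls.tolist()[:3] == prof_full.calls.tolist()[:3]
        assert prof_cut.calls[3] == -1

    def test_short_read_all_ambiguous(self, pr1_spec):
        read = MergedRead("r", "TTG", np.full(3, 40), 3)
        prof = ea.call_profile(read, pr1_spec)
        assert (prof.calls == -1).all()


class TestFilterProfiles:
    def _profile(self, conv, ident=1.0, calls=(0, 0, 0, 0)):
        return ea.ReadProfile("r", "a", np.array(calls, dtype=np.int8), conv, ident)

    def test_low_conversion_fails_with_reason(self):
        passing, rep = ea.filter_profiles([self._profile(0.95)], min_conversion=0.98)
        assert passing == []
        assert rep.failed_by_reason == {"low_conversion": 1}

    def test_undefined_conversion_passes(self):
        passing, rep = ea.filter_profiles([self._profile(None)])
        assert rep.passing == 1

    def test_ambiguous_and_identity_reasons(self):
        profs = [self._profile(1.0, ident=0.5),
                 self._profile(1.0, calls=(0, -1, 0, 0))]
        passing, rep = ea.filter_profiles(profs)
        assert rep.failed_by_reason == {"low_identity": 1, "ambiguous_calls": 1}
        assert rep.total - rep.passing == sum(rep.failed_by_reason.values())

    def test_ideal_profiles_all_pass(self, pr1_spec):
        profs = [self._profile(1.0) for _ in range(1000)]
        passing, rep = ea.filter_profiles(profs)
        assert rep.passing == 1000 and rep.failed_by_reason == {}

    def test_failure_fraction_matches_binomial_prediction(self, pr1_spec):
        """conversion_rate 0.97 vs threshold 0.98: closed-form binomial check."""
        n = 3000
        cfg = ea.SimulationConfig(
            amplicon=pr1_spec,
            populations=[ea.Population(1.0, site_probs=site_probs_from_meth([0.0] * 4))],
            n_molecules=n, conversion_rate=0.97, mc_failure_rate=0.0,
            seq_error_rate=0.0, seed=17)
        states, _ = ea.simulate_molecules(cfg)
        seqs = ea.apply_chemistry(states, cfg)
        profs = [
            ea.call_profile(
                MergedRead(f"m{i}", row.tobytes().decode(), np.full(len(row), 40), 100),
                pr1_spec)
            for i, row in enumerate(seqs)
        ]
        _, rep = ea.filter_profiles(profs, min_conversion=0.98)
        # number of non-CpG Cs scored per read (primer footprints excluded)
        s = pr1_spec
        k = sum(1 for i in range(len(s.fw_primer), len(s) - len(s.rv_primer))
                if s.reference_seq[i] == "C" and i not in s.site_indices)
        threshold = int(np.ceil(0.98 * k))
        p_fail = float(stats.binom.cdf(threshold - 1, k, 0.97))
        observed = (rep.total - rep.passing) / rep.total
        se = np.sqrt(p_fail * (1 - p_fail) / n)
        assert abs(observed - p_fail) <= 3 * se


class TestSpikeinConversion:
    def test_all_converted_reads_give_one(self, spikein_spec):
        seq = spikein_spec.reference_seq.replace("C", "T")
        reads = [MergedRead("r", seq, np.full(len(seq), 40), 100)]
        assert ea.estimate_spikein_conversion(reads, spikein_spec) == 1.0

    def test_empty_read_set_undefined(self, spikein_spec):
        with pytest.warns(UserWarning, match="undefined"):
            assert ea.estimate_spikein_conversion([], spikein_spec) is None

    def test_recovers_simulated_conversion_rate(self, spikein_spec):
        n = 10_000
        cfg = ea.unmethylated_config(spikein_spec, n_molecules=n,
                                     conversion_rate=0.99, seed=23)
        states, _ = ea.simulate_molecules(cfg)
        seqs = ea.apply_chemistry(states, cfg)
        reads = [MergedRead(f"m{i}", row.tobytes().decode(),
                            np.full(len(row), 40), 100)
                 for i, row in enumerate(seqs)]
        est = ea.estimate_spikein_conversion(reads, spikein_spec)
        n_c = sum(1 for i in range(len(spikein_spec.fw_primer),
                                   len(spikein_spec) - len(spikein_spec.rv_primer))
                  if spikein_spec.reference_seq[i] == "C")
        se = np.sqrt(0.99 * 0.01 / (n * n_c))
        assert abs(est - 0.99) <= 3 * se


class TestPipelineProperties:
    def test_end_to_end_identity_and_counting_conservation(self, pr1_spec):
        """Error-free reads recover every molecule's true epiallele exactly."""
        pops = [ea.Population(0.6, epiallele_probs={"1100": 0.5, "0011": 0.5}),
                ea.Population(0.4, site_probs=site_probs_from_meth([0.3] * 4))]
        cfg = ideal_config(pr1_spec, populations=pops, n_molecules=400, seed=31)
        rng = cfg.rng()
        states, truth = ea.simulate_molecules(cfg, rng)
        seqs = ea.apply_chemistry(states, cfg, rng)
        r1, r2 = ea.emit_reads(seqs, cfg, rng)
        profiles, counts, unassigned = run_pipeline(r1, r2, pr1_spec)
        assert counts["merged"] == counts["total"] == 400
        assert len(profiles) + unassigned == counts["merged"]
        passing, rep = ea.filter_profiles(profiles)
        assert rep.passing + sum(rep.failed_by_reason.values()) == len(profiles)
        assert rep.passing == 400
        called = [p.pattern() for p in passing]
        assert called == truth.true_patterns()
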