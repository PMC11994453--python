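"""Candidate search, enrichment testing, ambiguity removal, target analytics."""

import math

import numpy as np
import pandas as pd
import pytest

from scissionkit import nominate, simdata
from scissionkit._seq import hamming, random_dna, revcomp

from conftest import make_pileup


def brute_force_candidates(genome, spacer, max_mm=7, pam_tail="GG"):
    """Independent all-positions Hamming scan (oracle for the fast search)."""
    hits = set()
    for chrom, seq in genome.items():
        L = len(seq)
        for strand in "+-":
            scan = seq if strand == "+" else revcomp(seq)
            for s in range(L - 22):
                if scan[s + 21 : s + 23] != pam_tail:
                    continue
                d = sum(1 for a, b in zip(scan[s : s + 20], spacer) if a != b)
                if d <= max_mm:
                    start = s if strand == "+" else L - s - 20
                    hits.add((chrom, start, strand, d))
    return hits


class TestFindCandidateSites:
    def test_agrees_exactly_with_brute_force_scan(self):
        rng = np.random.default_rng(0)
        genome = {"chr1": random_dna(rng, 30_000)}
        spacer = random_dna(rng, 20)
        fast = nominate.find_candidate_sites(genome, ("g", spacer))
        got = {
            (r.chrom, r.start, r.strand, r.n_mismatches)
            for r in fast.itertuples(index=False)
        }
        assert got == brute_force_candidates(genome, spacer)

    def test_planted_on_target_found_with_zero_mismatches(self, sim_bundle):
        truth, genome = sim_bundle["truth"], sim_bundle["genome"]
        g = truth.guides.iloc[0]
        cand = nominate.find_candidate_sites(genome, (g["name"], g["spacer"]))
        planted = truth.sites[(truth.sites["guide"] == g["name"])
                              & (truth.sites["n_mismatches"] == 0)]
        merged = planted.merge(cand, on=["chrom", "start", "strand"])
        assert len(merged) == len(planted)
        assert (merged["n_mismatches_y"] == 0).all()

    def test_seven_mismatches_found_eight_absent(self):
        rng = np.random.default_rng(1)
        spacer = random_dna(rng, 20)
        for n_mm, expect in [(7, True), (8, False)]:
            proto = list(spacer)
            for i in range(n_mm):
                proto[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[proto[i]]
            genome = {"chr1": random_dna(rng, 100) + "".join(proto) + "AGG" + random_dna(rng, 100)}
            cand = nominate.find_candidate_sites(genome, ("g", spacer))
            assert bool((cand["start"] == 100).any()) is expect

    def test_nnn_pam_returns_superset_of_ngg(self, sim_bundle):
        genome = sim_bundle["genome"]
        g = sim_bundle["truth"].guides.iloc[1]
        ngg = nominate.find_candidate_sites(genome, (g["name"], g["spacer"]))
        nnn = nominate.find_candidate_sites(genome, (g["name"], g["spacer"]), pam_pattern="NNN")
        key = ["chrom", "start", "strand"]
        assert set(map(tuple, ngg[key].to_numpy())) <= set(map(tuple, nnn[key].to_numpy()))
        assert len(nnn) > len(ngg)

    def test_bad_spacer_length_rejected(self):
        with pytest.raises(ValueError, match="20 nt"):
            nominate.find_candidate_sites({"chr1": "ACGT" * 100}, ("g", "ACGT"))


def poisson_tail_oracle(k, lam):
    """Direct tail summation P(X >= k) in log space."""
    if k <= 0:
        return 1.0
    total, j = 0.0, k
    while True:
        term = math.exp(-lam + j * math.log(lam) - math.lgamma(j + 1))
        total += term
        j += 1
        if term < 1e-18 * max(total, 1e-300) and j > lam + k:
            break
    return min(total, 1.0)


class TestEnrichmentPvalue:
    def test_zero_observation_has_pvalue_one(self):
        assert nominate.enrichment_pvalue(0, 5, 1.0) == 1.0

    @pytest.mark.parametrize(
        "obs,ntc,ratio", [(10, 0, 1.0), (3, 0, 1.0), (50, 50, 1.0), (20, 3, 0.5), (7, 2, 2.0)]
    )
    def test_matches_direct_tail_summation(self, obs, ntc, ratio):
        lam = (ntc + 1) * ratio
        expected = poisson_tail_oracle(obs, lam)
        got = nominate.enrichment_pvalue(obs, ntc, ratio)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_monotone_decreasing_in_observation(self):
        ps = [nominate.enrichment_pvalue(k, 2, 1.0) for k in range(1, 30)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestCallTargets:
    def _candidate(self):
        return pd.DataFrame(
            [{"chrom": "chr1", "start": 100, "end": 120, "strand": "+", "pam": "AGG",
              "protospacer": "A" * 20, "guide": "g", "n_mismatches": 0,
              "mismatch_positions": "", "mm_nonseed": 0, "mm_seed": 0}]
        )

    def test_three_molecule_stack_with_empty_control_is_nominated(self):
        pile = make_pileup([("chr1", 117, "+", 3)])  # boundary label 17
        # the minimal 3-molecule stack sits at p = P(Pois(1) >= 3) = 0.0803,
        # so it clears the stack filter and any FDR threshold above that
        out = nominate.call_targets(self._candidate(), pile, make_pileup([]),
                                    min_stack=3, fdr_threshold=0.1)
        assert len(out) == 1 and out.loc[0, "total_count"] == 3
        assert out.loc[0, "pvalue"] == pytest.approx(poisson_tail_oracle(3, 1.0), rel=1e-12)

    def test_two_molecules_below_min_stack_not_nominated(self):
        pile = make_pileup([("chr1", 117, "+", 2)])
        out = nominate.call_targets(self._candidate(), pile, make_pileup([]), min_stack=3)
        assert out.empty

    def test_signal_equal_to_control_is_not_significant(self):
        # Poisson-tail oracle: obs=50 vs lambda=(50+1)*1 gives p around 0.5
        pile = make_pileup([("chr1", 117, "+", 50)])
        ntc = make_pileup([("chr1", 117, "+", 50)])
        out = nominate.call_targets(
            self._candidate(), pile, ntc, min_stack=3, fdr_threshold=1.1, size_ratio=1.0
        )
        p = out.loc[0, "pvalue"]
        assert p == pytest.approx(poisson_tail_oracle(50, 51), rel=1e-12)
        assert 0.3 < p < 0.7

    def test_chrom_mismatch_raises_coordinate_error(self):
        pile = make_pileup([("chr2", 117, "+", 3)])
        with pytest.raises(ValueError, match="chromosome"):
            nominate.call_targets(self._candidate(), pile, make_pileup([]))


class TestRemoveAmbiguous:
    def _targets(self, proto):
        return pd.DataFrame(
            [{"chrom": "chr1", "start": 0, "end": 20, "strand": "+",
              "protospacer": proto, "guide": "g1"}]
        )

    def test_locus_shared_by_two_close_guides_is_dropped(self):
        spacer = "A" * 20
        other = "A" * 15 + "CCCCC"  # Hamming 5 from the locus
        guides = pd.DataFrame({"name": ["g1", "g2"], "spacer": [spacer, other]})
        out = nominate.remove_ambiguous(guides, self._targets(spacer))
        assert out.empty

    def test_distant_guides_do_not_trigger_removal(self):
        spacer = "A" * 20
        far = "C" * 12 + "A" * 8  # Hamming 12
        guides = pd.DataFrame({"name": ["g1", "g2"], "spacer": [spacer, far]})
        out = nominate.remove_ambiguous(guides, self._targets(spacer))
        assert len(out) == 1

    def test_single_guide_run_is_identity(self):
        guides = pd.DataFrame({"name": ["g1"], "spacer": ["A" * 20]})
        t = self._targets("A" * 20)
        pd.testing.assert_frame_equal(nominate.remove_ambiguous(guides, t), t)


class TestTargetAnalytics:
    def test_mismatch_profile_all_on_targets_is_zero(self):
        t = pd.DataFrame({"mismatch_positions": ["", "", ""]})
        prof = nominate.mismatch_position_profile(t)
        assert (prof["mismatch_rate"] == 0).all()

    def test_mismatch_profile_single_position(self):
        t = pd.DataFrame({"mismatch_positions": ["1", "1"]})
        prof = nominate.mismatch_position_profile(t)
        assert prof.loc[prof["position"] == 1, "mismatch_rate"].item() == 1.0
        assert prof["mismatch_rate"].sum() == 1.0

    def test_simulated_pam_distal_bias_is_recovered(self, sim_bundle):
        # generator places mismatches with 2:1 weight on positions 1-10
        sites = sim_bundle["truth"].sites
        prof = nominate.mismatch_position_profile(sites[sites["n_mismatches"] > 0])
        distal = prof.loc[prof["position"] <= 10, "mismatch_rate"].mean()
        proximal = prof.loc[prof["position"] > 10, "mismatch_rate"].mean()
        assert distal > proximal

    def test_pam_usage_frequencies_sum_to_one_and_classify(self):
        t = pd.DataFrame({"pam": ["AGG", "TGG", "AAG", "TAG"]})
        table = nominate.pam_usage(t)
        assert table["frequency"].sum() == pytest.approx(1.0)
        classes = nominate.pam_class_usage(t)
        assert classes["NGG"] == pytest.approx(0.5)
        assert classes["NAG"] == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "seq,expected",
        [("ACGT" * 5, 2.0), ("A" * 20, 0.0), ("A" * 10 + "C" * 10, 1.0)],
        ids=["uniform", "mono", "two-base"],
    )
    def test_shannon_complexity_known_values(self, seq, expected):
        assert nominate.shannon_complexity(seq) == pytest.approx(expected)

    def test_shannon_complexity_rejects_non_acgt(self):
        with pytest.raises(ValueError):
            nominate.shannon_complexity("N" * 20)

    def test_activity_and_specificity_scores(self):
        ref = pd.DataFrame({"n_mismatches": [0, 1], "total_count": [100, 50]})
        half = pd.DataFrame({"n_mismatches": [0, 1], "total_count": [50, 50]})
        clean = pd.DataFrame({"n_mismatches": [0], "total_count": [100]})
        out = nominate.activity_specificity({"half": half, "clean": clean}, ref)
        out = out.set_index("nuclease")
        assert out.loc["half", "activity"] == pytest.approx(0.5)
        assert out.loc["clean", "specificity"] == pytest.approx(1.0)
        assert out.loc["clean", "activity"] == pytest.approx(1.0)

    def test_activity_undefined_without_reference_signal(self):
        ref = pd.DataFrame({"n_mismatches": [1], "total_count": [50]})
        with pytest.raises(ValueError, match="on-target"):
            nominate.activity_specificity({}, ref)
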