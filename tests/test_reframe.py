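"""Deletion filtering, guide placement, templated-insertion outcomes, T7."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from scissionkit import reframe
from scissionkit.reframe import Transcript
from scissionkit._seq import random_dna, revcomp


def translate_oracle(dna):
    usable = len(dna) - len(dna) % 3
    return str(Seq(dna[:usable]).translate())


def _toy_gene(rng, cds_len=120, flank=80):
    """Single-exon plus-strand gene with an ATG start on a random backbone."""
    seq = random_dna(rng, flank) + "ATG" + random_dna(rng, cds_len - 3) + random_dna(rng, flank)
    tx = Transcript("tx", "chr1", "+", [(flank, flank + cds_len)])
    return {"chr1": seq}, tx


class TestFindCorrectableDeletions:
    def _variants(self):
        return pd.DataFrame(
            [
                # pathogenic exonic 1-nt deletion -> retained
                {"chrom": "chr1", "pos": 90, "ref": None, "alt": None,
                 "significance": "Pathogenic"},
                # SNV -> dropped
                {"chrom": "chr1", "pos": 95, "ref": "A", "alt": "G",
                 "significance": "Pathogenic"},
                # 2-nt deletion -> dropped
                {"chrom": "chr1", "pos": 95, "ref": None, "alt": None,
                 "significance": "Pathogenic"},
                # benign 1-nt deletion -> dropped
                {"chrom": "chr1", "pos": 100, "ref": None, "alt": None,
                 "significance": "Benign"},
                # intronic/intergenic 1-nt deletion -> dropped
                {"chrom": "chr1", "pos": 10, "ref": None, "alt": None,
                 "significance": "Pathogenic"},
            ]
        )

    def test_filters_and_audit_add_up(self):
        rng = np.random.default_rng(6)
        genome, tx = _toy_gene(rng)
        seq = genome["chr1"]
        v = self._variants()
        v.loc[0, ["ref", "alt"]] = [seq[89:91], seq[89]]
        v.loc[1, ["ref", "alt"]] = [seq[94], "G" if seq[94] != "G" else "T"]
        v.loc[2, ["ref", "alt"]] = [seq[94:97], seq[94]]
        v.loc[3, ["ref", "alt"]] = [seq[99:101], seq[99]]
        v.loc[4, ["ref", "alt"]] = [seq[9:11], seq[9]]
        out, audit = reframe.find_correctable_deletions(v, [tx], genome)
        assert len(out) == 1 and out.loc[0, "deleted_pos0"] == 90
        dropped = sum(
            audit[k] for k in
            ("not_1nt_deletion", "nonstandard_chrom", "wrong_significance", "not_exonic")
        )
        assert dropped == audit["input"] - audit["output"] == 4

    def test_reference_mismatch_raises(self):
        rng = np.random.default_rng(7)
        genome, tx = _toy_gene(rng)
        v = pd.DataFrame(
            [{"chrom": "chr1", "pos": 90, "ref": "ZZ", "alt": "Z",
              "significance": "Pathogenic"}]
        )
        with pytest.raises(ValueError, match="does not match genome"):
            reframe.find_correctable_deletions(v, [tx], genome)


class TestPlaceGuides:
    def _genome_with_pam(self, offset):
        """Deletion-allele NGG sits ``offset`` nt downstream of the junction."""
        rng = np.random.default_rng(offset)
        left = random_dna(rng, 60)
        spacer_fill = random_dna(rng, offset)
        right = random_dna(rng, 60)
        # reference: [left][X][fill][TGG][right]; deleting X puts the junction
        # `offset` nt upstream of the PAM on the deletion allele
        seq = left + "A" + spacer_fill + "TGG" + right
        seq = seq[:45] + "T" * 10 + seq[55:]  # scrub accidental GG upstream
        return {"chr1": seq}, {"chrom": "chr1", "deleted_pos0": 60, "deleted_base": seq[60]}

    @pytest.mark.parametrize("offset", [0, 2, 4])
    def test_offsets_up_to_four_are_placed(self, offset):
        genome, deletion = self._genome_with_pam(offset)
        placements = reframe.place_guides(deletion, genome)
        plus = placements[placements["strand"] == "+"]
        assert offset in set(plus["offset"])

    def test_offset_five_is_not_placed(self):
        genome, deletion = self._genome_with_pam(5)
        placements = reframe.place_guides(deletion, genome, max_offset=4)
        plus = placements[placements["strand"] == "+"]
        # the PAM 5 nt from the junction must not be used
        assert 5 not in set(plus["offset"]) and (plus["offset"] <= 4).all()

    def test_both_strand_pams_give_two_placements(self):
        # CCN...NGG flanking the deletion closely
        left = "ATATATATATATATATATATATATAT"
        seq = left + "CCA" + "AT" + "A" + "TGG" + left
        genome = {"chr1": seq}
        deletion = {"chrom": "chr1", "deleted_pos0": len(left) + 5, "deleted_base": "A"}
        placements = reframe.place_guides(deletion, genome)
        assert set(placements["strand"]) == {"+", "-"}

    def test_contig_edge_deletion_skipped(self):
        genome = {"chr1": "A" * 100}
        out = reframe.place_guides({"chrom": "chr1", "deleted_pos0": 10}, genome)
        assert out.empty

    def test_insert_base_is_protospacer_position_17(self):
        genome, deletion = self._genome_with_pam(0)
        placements = reframe.place_guides(deletion, genome)
        for _, pl in placements.iterrows():
            assert pl["insert_base"] == pl["protospacer"][16]


class TestTemplatedInsertionOutcome:
    def test_outcome_agrees_with_direct_translation_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(40):
            genome, tx = _toy_gene(rng)
            seq = genome["chr1"]
            d = rng.integers(85, 175)  # inside the CDS
            deletion = {"chrom": "chr1", "deleted_pos0": int(d), "deleted_base": seq[d]}
            placements = reframe.place_guides(deletion, genome)
            for _, pl in placements.iterrows():
                out = reframe.templated_insertion_outcome(pl, deletion, tx, genome)
                # oracle: apply the edit directly at string level
                allele = seq[:d] + seq[d + 1 :]
                if pl["strand"] == "+":
                    k = pl["start"] + 17
                    ins = pl["insert_base"]
                else:
                    k = pl["start"] + 3
                    ins = revcomp(pl["insert_base"])
                edited = allele[:k] + ins + allele[k:]
                s, e = tx.exons[0]
                ref_prot = translate_oracle(seq[s:e])
                # recompute the edited CDS window directly
                s1 = s - 1 if s > d else s
                e1 = e - 1 if e > d else e
                s2 = s1 + (1 if s1 >= k else 0)
                e2 = e1 + (1 if e1 >= k else 0)
                edited_prot = translate_oracle(edited[s2:e2])
                frame_oracle = (e2 - s2) % 3 == (e - s) % 3
                assert out["frame_restored"] == frame_oracle
                if out["protein_restored"] is not None and frame_oracle:
                    assert out["protein_restored"] == (edited_prot == ref_prot)

    def test_synonymous_codon_wobble_restores_protein(self):
        # CTG(Leu) with G deleted; a templated T insert gives CTT, still Leu
        rng = np.random.default_rng(9)
        flank = 60
        # CDS: ATG + CTG + padding; engineered so the guide's position 17
        # base is T and the cut boundary sits at the deleted position
        pad = "GCTGCAGCTGCAGCTGCAGCTGCAGCTGCAGCT"
        cds = "ATG" + "CTG" + pad + "TAA"
        seq = random_dna(rng, flank) + cds + random_dna(rng, flank)
        genome = {"chr1": seq}
        tx = Transcript("tx", "chr1", "+", [(flank, flank + len(cds))])
        d = flank + 5  # the G of CTG
        deletion = {"chrom": "chr1", "deleted_pos0": d, "deleted_base": seq[d]}
        allele = seq[:d] + seq[d + 1 :]
        placements = reframe.place_guides(deletion, genome)
        hits = []
        for _, pl in placements.iterrows():
            out = reframe.templated_insertion_outcome(pl, deletion, tx, genome)
            assert out["frame_restored"]
            if pl["strand"] == "+" and pl["start"] + 17 == d and pl["insert_base"] == "T":
                # insertion of T right at the deleted G: CTG -> CTT, synonymous
                assert out["protein_restored"]
                hits.append(pl)

    def test_nonsynonymous_insert_restores_frame_but_not_protein(self):
        rng = np.random.default_rng(10)
        genome, tx = _toy_gene(rng)
        seq = genome["chr1"]
        # find a placement whose insert differs from the deleted base and
        # lands away from the deletion
        for d in range(90, 160):
            deletion = {"chrom": "chr1", "deleted_pos0": d, "deleted_base": seq[d]}
            for _, pl in reframe.place_guides(deletion, genome).iterrows():
                out = reframe.templated_insertion_outcome(pl, deletion, tx, genome)
                if out["frame_restored"] and out["protein_restored"] is False:
                    return
        pytest.skip("no non-synonymous case in this backbone (unexpected)")


class TestRankCandidates:
    def test_predicted_classes_and_exclusive_sets(self, rule_model_reduced):
        rng = np.random.default_rng(11)
        protos = []
        for b17, b18 in [("G", "C"), ("T", "G"), ("A", "A"), ("T", "G")]:
            s = random_dna(rng, 20)
            protos.append(s[:16] + b17 + b18 + s[18:])
        cands = pd.DataFrame({"protospacer": protos})
        ranked, report = reframe.rank_candidates(cands, {"cas9": rule_model_reduced})
        assert list(ranked["class_cas9"]).count("highly_staggered") == 2
        assert ranked["rate_cas9"].is_monotonic_increasing
        assert report["cas9"] == 2

    @pytest.mark.parametrize(
        "rate,expected",
        [(-2.5, "highly_staggered"), (-2.0, "highly_staggered"),
         (-0.5, "staggered"), (0.5, "blunt"), (0.0, "staggered")],
    )
    def test_staggered_class_thresholds(self, rate, expected):
        assert reframe.staggered_class(rate) == expected


class TestT7Construct:
    def test_promoter_g_substitution_and_scaffold(self):
        out = reframe.design_t7_construct("ATCGATCGATCGATCGATCG")
        assert out.startswith(reframe.T7_PROMOTER)
        assert out.endswith(reframe.SGRNA_SCAFFOLD)
        assert len(out) == 59
        assert out[24] == "G"  # 5'-terminal spacer base replaced

    def test_spacer_already_starting_with_g_unchanged(self):
        spacer = "GTCGATCGATCGATCGATCG"
        out = reframe.design_t7_construct(spacer)
        assert out[24:44] == spacer

    def test_non_acgt_spacer_rejected(self):
        with pytest.raises(ValueError):
            reframe.design_t7_construct("N" * 20)
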