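import pytest
from Bio.Seq import Seq

from tillkit.annotate import (
    EffectCall,
    GeneModel,
    classify_effect,
    classify_transition,
    dedupe_sibling_repeats,
    effect_from_aa_change,
    parse_nucleotide_change,
    summarize_effects,
)
from tillkit.simulate import MutationRecord, ReferenceSequence


class TestClassifyTransition:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("C", "T", "C>T"),
            ("G", "A", "G>A"),
            ("A", "G", "non_canonical"),
            ("T", "C", "non_canonical"),
            ("G", "T", "non_canonical"),
        ],
    )
    def test_classes(self, ref, alt, expected):
        assert classify_transition(ref, alt) == expected

    def test_identical_bases_rejected(self):
        with pytest.raises(ValueError):
            classify_transition("C", "C")


def _single_exon_gene(cds, strand="+", pad=6):
    """Embed a CDS in a padded reference; return (reference, model)."""
    genomic = cds if strand == "+" else str(Seq(cds).reverse_complement())
    residues = "A" * pad + genomic + "A" * pad
    ref = ReferenceSequence(id="syn", residues=residues)
    model = GeneModel(
        gene_id="syn", strand=strand, exons=((pad, pad + len(cds)),)
    )
    return ref, model


class TestClassifyEffect:
    def test_stop_gained_is_nonsense(self):
        # codon 10 TGG -> TGA (W10*)
        cds = "ATGGCTGCTGCTGCTGCTGCTGCTGCT" + "TGG" + "GCTTAA"
        ref, model = _single_exon_gene(cds)
        site = model.exons[0][0] + 29  # third base of codon 10
        assert ref.residues[site] == "G"
        call = classify_effect(MutationRecord(site=site, ref="G", alt="A"), model, ref)
        assert call == EffectCall(effect="nonsense", protein_notation="W10*")

    def test_missense_with_notation(self):
        cds = "ATG" + "GGA" + "TAA"  # M G *
        ref, model = _single_exon_gene(cds)
        site = model.exons[0][0] + 4  # GGA -> GAA = G2E
        call = classify_effect(MutationRecord(site=site, ref="G", alt="A"), model, ref)
        assert call == EffectCall(effect="missense", protein_notation="G2E")

    def test_third_position_silent(self):
        cds = "ATG" + "GGG" + "TAA"
        ref, model = _single_exon_gene(cds)
        site = model.exons[0][0] + 5  # GGG -> GGA, still Gly
        call = classify_effect(MutationRecord(site=site, ref="G", alt="A"), model, ref)
        assert call.effect == "silent" and call.protein_notation == "G2G"

    def test_intron_vs_splice_junction_window(self):
        # two exons separated by a 30 bp intron
        residues = "G" * 100
        ref = ReferenceSequence(id="x", residues=residues)
        model = GeneModel(gene_id="x", strand="+", exons=((10, 40), (70, 100)))
        rec = lambda site: MutationRecord(site=site, ref="G", alt="A")
        assert classify_effect(rec(40), model, ref).effect == "splice_junction"
        assert classify_effect(rec(41), model, ref).effect == "splice_junction"
        assert classify_effect(rec(42), model, ref).effect == "intron"
        assert classify_effect(rec(68), model, ref).effect == "splice_junction"
        assert classify_effect(rec(67), model, ref).effect == "intron"

    def test_site_outside_region_and_ref_mismatch_rejected(self):
        cds = "ATGGGATAA"
        ref, model = _single_exon_gene(cds)
        with pytest.raises(ValueError, match="outside"):
            classify_effect(MutationRecord(site=0, ref="A", alt="T"), model, ref)
        site = model.exons[0][0]
        with pytest.raises(ValueError, match="does not match"):
            classify_effect(MutationRecord(site=site, ref="C", alt="T"), model, ref)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_agrees_with_full_protein_translation_oracle(self, strand):
        # independent oracle: mutate the genome, re-extract and translate the
        # whole CDS, and diff the two proteins residue by residue
        cds = "ATGGCTTGGCGATGCCTGGAACACGGTTGTCCGAGTTAA"
        ref, model = _single_exon_gene(cds, strand=strand)
        lo, hi = model.exons[0]
        checked = 0
        for site in range(lo, hi):
            base = ref.residues[site]
            if base not in "GC":
                continue
            alt = {"G": "A", "C": "T"}[base]
            call = classify_effect(MutationRecord(site=site, ref=base, alt=alt), model, ref)
            mutated = ref.residues[:site] + alt + ref.residues[site + 1 :]
            extract = lambda seq: seq[lo:hi] if strand == "+" else str(
                Seq(seq[lo:hi]).reverse_complement()
            )
            before = str(Seq(extract(ref.residues)).translate())
            after = str(Seq(extract(mutated)).translate())
            diffs = [
                (i + 1, a, b) for i, (a, b) in enumerate(zip(before, after)) if a != b
            ]
            if call.effect == "silent":
                assert diffs == []
            else:
                ((pos, a, b),) = diffs
                assert call.protein_notation == f"{a}{pos}{b}"
                assert call.effect == ("nonsense" if b == "*" else "missense")
            checked += 1
        assert checked > 15

    def test_reverse_strand_notation_matches_forward_encoding(self):
        # the same protein encoded on either strand yields the same call
        cds = "ATGGGATGGTAA"
        ref_f, model_f = _single_exon_gene(cds, "+")
        ref_r, model_r = _single_exon_gene(cds, "-")
        # forward: GGA->GAA at cds pos 4; reverse genome has complement C->T
        site_f = model_f.exons[0][0] + 4
        site_r = model_r.exons[0][1] - 1 - 4
        call_f = classify_effect(
            MutationRecord(site=site_f, ref="G", alt="A"), model_f, ref_f
        )
        call_r = classify_effect(
            MutationRecord(site=site_r, ref="C", alt="T"), model_r, ref_r
        )
        assert call_f == call_r == EffectCall("missense", "G2E")


class TestDedupe:
    def _ann(self, indiv, change):
        from tillkit.io import parse_mutation_table
        import pandas as pd

        df = pd.DataFrame(
            [
                {
                    "individual": indiv,
                    "nucleotide_change": change,
                    "amino_acid_change": "Intron",
                    "pssm": ".",
                    "sift": ".",
                    "zygosity": "Het",
                    "type": ".",
                }
            ]
        )
        return parse_mutation_table(df)[0]

    def test_all_distinct_input_unchanged(self):
        records = [self._ann("P1-1", "C100T"), self._ann("P2-1", "G200A")]
        unique, groups = dedupe_sibling_repeats(records)
        assert unique == records and groups == []

    def test_same_substitution_in_two_lines_stays_distinct(self):
        records = [self._ann("P1-1", "C100T"), self._ann("P2-1", "C100T")]
        unique, groups = dedupe_sibling_repeats(records)
        assert len(unique) == 2 and groups == []

    def test_sibling_repeat_collapses_and_flags(self):
        records = [self._ann("P1-1", "C100T"), self._ann("P1-2", "C100T")]
        unique, groups = dedupe_sibling_repeats(records)
        assert len(unique) == 1 and unique[0].repeat
        assert len(groups) == 1 and len(groups[0]) == 2

    def test_published_allele_table_collapses_to_15(self, bundled):
        unique, groups = dedupe_sibling_repeats(bundled.ppd_mutations)
        assert len(unique) == 15
        assert sorted(len(g) for g in groups) == [2, 2, 2]
        repeat_changes = {
            (g[0].record.site + 1, g[0].record.ref, g[0].record.alt) for g in groups
        }
        assert repeat_changes == {(1856, "C", "T"), (2401, "G", "A"), (2777, "G", "A")}
        # recomputed repeat flags agree with the transcribed annotations
        flagged = {id(r) for g in groups for r in g}
        for ann in bundled.ppd_mutations:
            assert (id(ann) in flagged) == ann.repeat


class TestSummaries:
    def test_empty_input_all_zero(self):
        summary = summarize_effects([])
        assert set(summary["effects"].values()) == {0}
        assert summary["zygosity"] == {"het": 0, "hom": 0}

    def test_parsers(self):
        assert parse_nucleotide_change("C1687T") == (1686, "C", "T")
        assert effect_from_aa_change("S242S").effect == "silent"
        assert effect_from_aa_change("T438M").effect == "missense"
        assert effect_from_aa_change("W10*").effect == "nonsense"
        assert effect_from_aa_change("Intron").effect == "intron"
        with pytest.raises(ValueError):
            parse_nucleotide_change("C16X87T")
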