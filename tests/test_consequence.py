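"""Codon-aware consequence classification and isoform aggregation."""

from __future__ import annotations

import warnings

import pytest
from Bio.Seq import Seq

from conftest import mirror_dataset
from regbash.annotation import revcomp
from regbash.consequence import (
    TranscriptConsequence,
    aggregate_consequences,
    classify_against_transcript,
    classify_alleles,
    flag_ectopic_splice_donor,
)
from regbash.variants import Allele


def _sub(pos, ref, alt, aid="x"):
    return Allele(id=aid, chrom="chrT", pos=pos, ref=ref, alt=alt)


# mini genome layout (see conftest): gA CDS (10,28) = ATG AAA CTT TAC TGG TAA
@pytest.mark.parametrize(
    "pos,ref,alt,expected",
    [
        (18, "T", "C", "synonymous"),     # CTT -> CTC (Leu)
        (14, "A", "C", "missense"),       # AAA -> ACA (Lys -> Thr)
        (21, "C", "A", "stop_gained"),    # TAC -> TAA
        (10, "A", "G", "start_lost"),     # ATG -> GTG
        (27, "A", "C", "stop_lost"),      # TAA -> TAC
    ],
)
def test_cds_substitution_categories(mini_genome, pos, ref, alt, expected):
    tx = mini_genome.transcripts["tA.1"]
    tc = classify_against_transcript(_sub(pos, ref, alt), tx, mini_genome)
    assert tc.category == expected


def test_splice_donor_hit_first_intron_base(mini_genome):
    tx = mini_genome.transcripts["tB.1"]
    tc = classify_against_transcript(_sub(70, "G", "A"), tx, mini_genome)
    assert tc.category == "splice_donor"
    tc = classify_against_transcript(_sub(79, "G", "C"), tx, mini_genome)
    assert tc.category == "splice_acceptor"
    tc = classify_against_transcript(_sub(75, "C", "G"), tx, mini_genome)
    assert tc.category == "intronic"


def test_cds_indels_frameshift_vs_inframe(mini_genome):
    tx = mini_genome.transcripts["tB.1"]
    four = Allele(id="d4", chrom="chrT", pos=60, ref="AGCA", alt="")
    assert classify_against_transcript(four, tx, mini_genome).category == "frameshift"
    three = Allele(id="d3", chrom="chrT", pos=58, ref="GCA", alt="")
    assert classify_against_transcript(three, tx, mini_genome).category == "inframe_deletion"
    ins = Allele(id="i3", chrom="chrT", pos=58, ref="", alt="TGG")
    assert classify_against_transcript(ins, tx, mini_genome).category == "inframe_insertion"


def test_whole_gene_deletion_is_transcript_ablation(mini_genome):
    tx = mini_genome.transcripts["tA.1"]
    seq = mini_genome.sequences["chrT"][0:40]
    dele = Allele(id="abl", chrom="chrT", pos=0, ref=seq, alt="")
    assert classify_against_transcript(dele, tx, mini_genome).category == "transcript_ablation"


def test_utr_and_flank_lookup(mini_genome):
    tx = mini_genome.transcripts["tA.1"]
    assert classify_against_transcript(_sub(7, "C", "G"), tx, mini_genome).category == "five_prime_UTR"
    assert classify_against_transcript(_sub(30, "C", "G"), tx, mini_genome).category == "three_prime_UTR"
    assert classify_against_transcript(_sub(2, "C", "G"), tx, mini_genome).category == "upstream"
    assert classify_against_transcript(_sub(35, "C", "G"), tx, mini_genome).category == "downstream"
    # beyond the 5-bp flank of every gene
    assert classify_against_transcript(_sub(45, "C", "G"), tx, mini_genome).category == "intergenic"


class TestEctopicSpliceDonor:
    # gC CDS (115,133) = ATG GGA TTT ...; GGA->GGG at pos 120 creates G|GT
    def test_synonymous_change_creating_gt_flagged(self, mini_genome):
        tx = mini_genome.transcripts["tC.1"]
        allele = _sub(120, "A", "G")
        tc = classify_against_transcript(allele, tx, mini_genome)
        assert tc.category == "synonymous" and tc.ectopic_donor_flag
        assert flag_ectopic_splice_donor(allele, tx, mini_genome)

    def test_synonymous_change_without_gt_not_flagged(self, mini_genome):
        tx = mini_genome.transcripts["tA.1"]
        allele = _sub(18, "T", "C")  # CTT -> CTC
        assert not flag_ectopic_splice_donor(allele, tx, mini_genome)

    def test_non_substitution_violates_contract(self, mini_genome):
        tx = mini_genome.transcripts["tA.1"]
        with pytest.raises(ValueError, match="substitutions only"):
            flag_ectopic_splice_donor(
                Allele(id="d", chrom="chrT", pos=18, ref="TT", alt=""), tx, mini_genome)


class TestAggregation:
    def test_any_protein_changing_isoform_wins(self):
        per = [TranscriptConsequence("a", "t1", "five_prime_UTR"),
               TranscriptConsequence("a", "t2", "missense")]
        gene_cat, fine, tid = aggregate_consequences(per)
        assert (gene_cat, fine, tid) == ("coding", "missense", "t2")

    def test_ectopic_donor_reclassifies_synonymous_to_coding(self):
        per = [TranscriptConsequence("a", "t1", "synonymous", ectopic_donor_flag=True),
               TranscriptConsequence("a", "t2", "synonymous")]
        gene_cat, fine, _ = aggregate_consequences(per)
        assert gene_cat == "coding" and fine == "synonymous"

    def test_intergenic_singleton(self):
        gene_cat, fine, _ = aggregate_consequences(
            [TranscriptConsequence("a", None, "intergenic")])
        assert (gene_cat, fine) == ("intergenic_unassigned", "intergenic")

    def test_severity_tie_broken_by_transcript_id(self):
        per = [TranscriptConsequence("a", "t9", "missense"),
               TranscriptConsequence("a", "t1", "missense")]
        assert aggregate_consequences(per)[2] == "t1"

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            aggregate_consequences([])


def test_unknown_chromosome_warns_and_yields_intergenic(mini_genome):
    allele = Allele(id="x", chrom="chrZ", pos=5, ref="A", alt="G")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        calls = classify_alleles([allele], mini_genome)
    assert calls[0].gene_category == "intergenic_unassigned"
    assert any("chrZ" in str(w.message) for w in caught)


def test_forced_labels_recovered_exactly(toy_dataset):
    """Fine categories match construction-forced ground truth for all alleles."""
    gt = toy_dataset["ground_truth"].allele_categories
    calls = toy_dataset["calls"]
    assert len(calls) == len(gt)
    mismatches = [(c.allele_id, gt[c.allele_id], c.fine_category)
                  for c in calls if c.fine_category != gt[c.allele_id]]
    assert mismatches == []


def test_every_allele_gets_exactly_one_gene_category(toy_dataset):
    calls = toy_dataset["calls"]
    assert len({c.allele_id for c in calls}) == len(toy_dataset["alleles"])
    from regbash.consequence import GENE_CATEGORY_OF

    assert all(c.gene_category in set(GENE_CATEGORY_OF.values()) for c in calls)


def test_strand_mirror_invariance(toy_dataset):
    """Classifying the reverse-complemented, mirrored fixture is identical."""
    _, mirrored_ann, mirrored_alleles = mirror_dataset(
        toy_dataset["sequences"], toy_dataset["annotation"], toy_dataset["alleles"])
    mirrored_calls = {c.allele_id: c.fine_category
                      for c in classify_alleles(mirrored_alleles, mirrored_ann)}
    for call in toy_dataset["calls"]:
        assert mirrored_calls[call.allele_id] == call.fine_category


def _mutated_cds(ann, tx, allele) -> str:
    """Independent reconstruction of the spliced CDS after applying an edit."""
    seq = ann.sequences[tx.chrom]
    edited = seq[: allele.pos] + allele.alt + seq[allele.pos + len(allele.ref):]
    delta = len(allele.alt) - len(allele.ref)
    parts = []
    for c in tx.cds_genomic:
        s, e = c.start, c.end
        if e <= allele.pos:
            pass
        elif s >= allele.pos + len(allele.ref) and not (not allele.ref and s == allele.pos):
            s, e = s + delta, e + delta
        else:
            e += delta
        parts.append(edited[s:e])
    cds = "".join(parts)
    return cds if tx.strand == "+" else revcomp(cds)


def test_brute_force_protein_oracle_on_cds_alleles(toy_dataset):
    """Translating the rebuilt mutant CDS confirms every coding call."""
    ann = toy_dataset["annotation"]
    gt = toy_dataset["ground_truth"].allele_categories
    checked = 0
    for allele in toy_dataset["alleles"]:
        category = gt[allele.id]
        if category not in {"synonymous", "missense", "stop_gained", "stop_lost",
                            "start_lost", "inframe_deletion", "inframe_insertion",
                            "frameshift"}:
            continue
        tids = [t.id for t in ann.transcripts_near(allele.chrom, allele.pos,
                                                   max(allele.end, allele.pos + 1), pad=0)]
        for tid in tids:
            tx = ann.transcripts[tid]
            in_cds = any(c.start < max(allele.end, allele.pos + 1) and allele.pos < c.end
                         for c in tx.cds)
            if not in_cds:
                continue
            if category == "start_lost":
                # only isoforms whose annotated start codon is hit lose it;
                # in a longer isoform the same base is an internal Met codon
                first = tx.cds[0]
                start_region = (range(first.start, first.start + 3)
                                if tx.strand == "+" else range(first.end - 3, first.end))
                if allele.pos not in start_region:
                    continue
            ref_prot = str(Seq(ann.cds_sequence(tid)).translate(to_stop=True))
            mut_cds = _mutated_cds(ann, tx, allele)
            if category == "frameshift":
                assert len(mut_cds) % 3 != 0
                continue
            mut_prot = str(Seq(mut_cds).translate(to_stop=True))
            if category == "synonymous":
                assert mut_prot == ref_prot
            elif category == "missense":
                assert len(mut_prot) == len(ref_prot) and mut_prot != ref_prot
            elif category == "stop_gained":
                assert len(mut_prot) < len(ref_prot)
            elif category == "stop_lost":
                assert len(mut_prot) > len(ref_prot) or not mut_cds.endswith(
                    ("TAA", "TAG", "TGA"))
            elif category == "start_lost":
                assert not mut_cds.startswith("ATG")
            elif category == "inframe_deletion":
                assert len(mut_prot) == len(ref_prot) - 1
            elif category == "inframe_insertion":
                assert len(mut_prot) == len(ref_prot) + 1
            checked += 1
    assert checked >= 500  # the default mixture is dominated by coding alleles
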