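"""Discriminating sites, melting temperature, and assay design."""

import numpy as np
import pytest

from pseudoquant.discrimination import (
    DesignError,
    PrimerConstraints,
    align_to_target,
    design_junction_assay,
    design_primary_transcript_assay,
    enumerate_allele_specific_primers,
    find_discriminating_sites,
    melting_temperature,
    pair_allele_specific_assay,
)
from pseudoquant.seqio import GeneModel, GenomicInterval, SequenceRecord, reverse_complement


def _random_seq(seed, n):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), n))


def _substitute(seq, pos1, base=None):
    old = seq[pos1 - 1]
    new = base or {"A": "C", "C": "G", "G": "T", "T": "A"}[old]
    return seq[: pos1 - 1] + new + seq[pos1:]


# ---------------------------------------------------------------------------
# melting temperature

# SantaLucia (1998) unified parameters, re-tabulated independently for the
# hand computation below.
_HAND_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2), "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3), "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "AG": (-7.8, -21.0), "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4), "GG": (-8.0, -19.9),
    "CC": (-8.0, -19.9),
}


def _hand_tm(seq):
    import math

    dh = ds = 0.0
    for end in (seq[0], seq[-1]):
        if end in "GC":
            dh += 0.1
            ds += -2.8
        else:
            dh += 2.3
            ds += 4.1
    for i in range(len(seq) - 1):
        h, s = _HAND_NN[seq[i : i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(0.05)
    return 1000 * dh / (ds + 1.987 * math.log(500e-9 / 4)) - 273.15


class TestMeltingTemperature:
    def test_wallace_rule_below_14(self):
        assert melting_temperature("AAAAAAAAAA") == 20.0
        assert melting_temperature("GGGGGGGGGG") == 40.0

    def test_nearest_neighbor_matches_hand_computation(self):
        seq = "ATGCCTAGGATCCGTAACGT"  # fixed 20-mer
        assert melting_temperature(seq) == pytest.approx(_hand_tm(seq), abs=1e-9)

    def test_matches_biopython_reference(self):
        from Bio.SeqUtils import MeltingTemp as mt

        rng = np.random.default_rng(11)
        for _ in range(10):
            s = "".join(rng.choice(list("ACGT"), 22))
            ref = mt.Tm_NN(s, dnac1=125, dnac2=0, Na=50, saltcorr=5)
            assert melting_temperature(s) == pytest.approx(ref, abs=0.3)

    def test_n_is_rejected(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGTNACGTACGTACG")


# ---------------------------------------------------------------------------
# star alignment and sites


class TestAlignToTarget:
    def test_identical_paralog_all_columns_agree(self):
        target = SequenceRecord("t", _random_seq(0, 300))
        table = align_to_target(target, [SequenceRecord("p", target.seq)])
        assert (table.columns["p"].values == list(target.seq)).all()

    def test_single_substitution_single_disagreement(self):
        target = SequenceRecord("t", _random_seq(1, 300))
        p = SequenceRecord("p", _substitute(target.seq, 137))
        table = align_to_target(target, [p])
        diff = [i for i in table.columns.index if table.columns.at[i, "p"] != target.seq[i - 1]]
        assert diff == [137]

    def test_planted_substitution_set_recovered(self):
        target = SequenceRecord("t", _random_seq(2, 500))
        planted = sorted({17, 101, 250, 333, 480})
        seq = target.seq
        for p in planted:
            seq = _substitute(seq, p)
        table = align_to_target(target, [SequenceRecord("p", seq)])
        diff = [i for i in table.columns.index if table.columns.at[i, "p"] != target.seq[i - 1]]
        assert diff == planted

    def test_low_coverage_paralog_excluded(self):
        target = SequenceRecord("t", _random_seq(3, 600))
        # a 200-bp fragment covers only a third of the target
        stub = SequenceRecord("stub", _random_seq(3, 600)[:200])
        with pytest.warns(UserWarning, match="stub"):
            table = align_to_target(
                target, [SequenceRecord("p", target.seq), stub]
            )
        assert table.paralog_ids == ["p"]


class TestDiscriminatingSites:
    def test_identical_set_yields_nothing(self):
        target = SequenceRecord("t", _random_seq(5, 200))
        table = align_to_target(target, [SequenceRecord("p", target.seq)])
        assert find_discriminating_sites(table) == []

    def test_unique_to_paralog(self):
        target = SequenceRecord("t", _random_seq(6, 300))
        p1 = SequenceRecord("p1", _substitute(target.seq, 120))
        p2 = SequenceRecord("p2", target.seq)
        table = align_to_target(target, [p1, p2])
        sites = find_discriminating_sites(table, "unique_to_paralog", "p1")
        assert [s.position for s in sites] == [120]
        assert sites[0].distinguishing == frozenset({"p1"})

    def test_unknown_paralog_id(self):
        target = SequenceRecord("t", _random_seq(7, 200))
        table = align_to_target(target, [SequenceRecord("p", target.seq)])
        with pytest.raises(KeyError):
            find_discriminating_sites(table, "unique_to_paralog", "nope")

    def test_near_identical_paralog_offers_few_specific_sites(self):
        """A nearly identical homolog (2 private variants) leaves almost no
        handle for specific primers — why such primer sets stay leaky."""
        target = SequenceRecord("t", _random_seq(8, 800))
        p_close = _substitute(_substitute(target.seq, 100), 600)
        p_far = target.seq
        rng = np.random.default_rng(9)
        for pos in rng.choice(800, 40, replace=False):
            p_far = _substitute(p_far, int(pos) + 1)
        table = align_to_target(
            target,
            [SequenceRecord("pc", p_close), SequenceRecord("pf", p_far)],
        )
        sites = find_discriminating_sites(table, "unique_to_paralog", "pc")
        assert len(sites) <= 2


# ---------------------------------------------------------------------------
# allele-specific primers


class TestAlleleSpecificPrimers:
    WIDE = PrimerConstraints(tm_min=40, tm_max=80, gc_min=0.0, gc_max=1.0)

    def test_empty_sites_empty_list(self):
        assert enumerate_allele_specific_primers(_random_seq(10, 400), [], self.WIDE) == []

    def test_three_prime_terminus_on_site(self):
        template = _random_seq(11, 400)
        primers = enumerate_allele_specific_primers(template, [200], self.WIDE)
        assert primers
        for p in primers:
            assert p.three_prime_pos == 200
            assert 0 in p.anchored_offsets
            if p.strand == "+":
                assert p.seq[-1] == template[199]
            else:
                assert p.seq[-1] == reverse_complement(template[199])

    def test_enumeration_matches_brute_force(self):
        """Candidate count equals an independent enumeration over every
        (site, length, strand) triple with the same filters."""
        template = _random_seq(12, 480)
        sites = [60, 240, 420]  # spaced farther apart than max primer length
        c = self.WIDE
        primers = enumerate_allele_specific_primers(template, sites, c)
        brute = 0
        for p in sites:
            for L in range(c.min_len, c.max_len + 1):
                for strand in "+-":
                    if strand == "+":
                        if p - L + 1 < 1:
                            continue
                        s = template[p - L : p]
                    else:
                        if p + L - 1 > len(template):
                            continue
                        s = reverse_complement(template[p - 1 : p + L - 1])
                    gc = (s.count("G") + s.count("C")) / len(s)
                    tm = melting_temperature(s)
                    if c.gc_min <= gc <= c.gc_max and c.tm_min <= tm <= c.tm_max:
                        brute += 1
        assert len(primers) == brute

    def test_primer_three_prime_base_differs_from_paralogs(self, study17):
        """Re-projection through the column table: every designed
        allele-specific primer terminates on a base its off-targets lack."""
        ls = study17.locus_set
        pseudo_names = [n for n in study17.templates if n != ls.cdna.id]
        for name in pseudo_names:
            assay = study17.assays[f"as_{name}"]
            others = [ls.cdna] + [study17.templates[n] for n in pseudo_names if n != name]
            table = align_to_target(study17.templates[name], others)
            for primer in (assay.forward, assay.reverse):
                if 0 not in primer.anchored_offsets:
                    continue
                pos = primer.three_prime_pos
                own_base = study17.templates[name].seq[pos - 1]
                row = table.columns.loc[pos]
                assert all(row[p] != own_base for p in table.paralog_ids)


# ---------------------------------------------------------------------------
# junction and primary-transcript assays


def _toy_gene(seed=20, exon=60, intron=300, n_exons=2):
    rng = np.random.default_rng(seed)
    chrom_parts, exons, pos = [], [], 0
    for i in range(n_exons):
        exons.append(GenomicInterval("c", pos + 1, pos + exon))
        chrom_parts.append("".join(rng.choice(list("ACGT"), exon)))
        pos += exon
        if i < n_exons - 1:
            chrom_parts.append("".join(rng.choice(list("ACGT"), intron)))
            pos += intron
    chrom = "".join(chrom_parts)
    model = GeneModel("toy", "c", "+", tuple(exons))
    return model, chrom


WIDE = PrimerConstraints(tm_min=40, tm_max=80, gc_min=0.0, gc_max=1.0,
                         product_min=50, product_max=250)


class TestJunctionAssay:
    def test_forward_primer_straddles_junction(self):
        model, chrom = _toy_gene(exon=120, n_exons=2)
        cdna = model.spliced_sequence(chrom)
        assay = design_junction_assay(model, cdna, (1, 2), WIDE)
        J = model.cdna_junctions()[0]
        f = assay.forward
        assert f.start <= J - 3 and f.end >= J + 4  # >= 4-base overhang each side
        assert assay.assay_class == "splice_junction"
        assert assay.amplicon_length == assay.reverse.end - assay.forward.start + 1

    def test_nonexistent_junction_is_error(self):
        model, chrom = _toy_gene(n_exons=2)
        cdna = model.spliced_sequence(chrom)
        with pytest.raises(DesignError):
            design_junction_assay(model, cdna, (2, 3), WIDE)

    def test_junction_too_close_to_end(self):
        model, chrom = _toy_gene(exon=20, n_exons=2)
        cdna = model.spliced_sequence(chrom)
        with pytest.raises(DesignError, match="no feasible design"):
            design_junction_assay(model, cdna, (1, 2), WIDE)

    def test_cdna_amplicon_shorter_than_genomic_span(self):
        model, chrom = _toy_gene(exon=120, intron=300, n_exons=2)
        cdna = model.spliced_sequence(chrom)
        assay = design_junction_assay(model, cdna, (1, 2), WIDE)
        genomic = model.genomic_span_of_cdna_interval(
            assay.forward.start, assay.reverse.end
        )
        assert genomic == assay.amplicon_length + 300


class TestPrimaryTranscriptAssay:
    def test_single_exon_gene_is_error(self):
        rng = np.random.default_rng(30)
        chrom = "".join(rng.choice(list("ACGT"), 500))
        model = GeneModel("one", "c", "+", (GenomicInterval("c", 1, 500),))
        with pytest.raises(DesignError, match="no introns"):
            design_primary_transcript_assay(model, chrom, "intra_intron", 1, WIDE)

    def test_intra_intron_primers_inside_intron(self):
        model, chrom = _toy_gene(exon=100, intron=300, n_exons=2)
        assay = design_primary_transcript_assay(model, chrom, "intra_intron", 1, WIDE)
        intron = model.introns[0]
        for p in (assay.forward, assay.reverse):
            assert intron.start <= p.start and p.end <= intron.end
        assert assay.assay_class == "intra_intron"

    def test_exon_intron_amplicon_crosses_boundary(self):
        model, chrom = _toy_gene(exon=100, intron=300, n_exons=2)
        assay = design_primary_transcript_assay(model, chrom, "exon_intron", 1, WIDE)
        exon, intron = model.exons[0], model.introns[0]
        assert exon.start <= assay.forward.start and assay.forward.end <= exon.end
        assert intron.start <= assay.reverse.start and assay.reverse.end <= intron.end
        assert assay.forward.start <= exon.end < assay.reverse.end

    def test_short_intron_rejected_for_intra(self):
        model, chrom = _toy_gene(exon=100, intron=40, n_exons=2)
        with pytest.raises(DesignError):
            design_primary_transcript_assay(model, chrom, "intra_intron", 1, WIDE)


class TestPairAssay:
    def test_pair_on_distinct_template(self):
        template = SequenceRecord("p", _random_seq(40, 600))
        sites = [100, 140, 400, 430]
        assay = pair_allele_specific_assay(template, sites, WIDE)
        assert assay.assay_class == "allele_specific"
        assert 0 in assay.forward.anchored_offsets
        assert WIDE.product_min <= assay.amplicon_length <= WIDE.product_max
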