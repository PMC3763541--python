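import numpy as np
import pytest

from conftest import random_dna
from mist.calling import (
    CallerConfig,
    annotate_effect,
    call_variants,
    calls_to_tsv,
    flank_context,
    skew_flag,
    strand_skew,
    write_vcf,
)
from mist.pileup import PileupColumn
from mist.reference import ExonTarget, GenomeRef, TranscriptModel
from mist.seq import revcomp


def make_target(rng, n=300, start=1000):
    seq = random_dna(rng, n)
    return ExonTarget("T", "chr1", start, start + n, "+", start + 70, start + n - 70, 70, seq)


def column(target, offset, alleles):
    """alleles: {allele: (plus, minus)}"""
    col = PileupColumn("T", offset, target.sequence[offset])
    for a, (p, m) in alleles.items():
        col.counts[a] = [p, m]
        col.raw_counts[a] = [p, m]
    return col


def pileup_with(target, sites):
    cols = [PileupColumn("T", i, target.sequence[i]) for i in range(len(target.sequence))]
    for off, alleles in sites.items():
        cols[off] = column(target, off, alleles)
    return cols


class TestStrandSkew:
    @pytest.mark.parametrize("p,m,expected", [(5, 5, 0.0), (10, 0, 1.0), (6, 2, 0.5)])
    def test_values(self, p, m, expected):
        assert strand_skew(p, m) == pytest.approx(expected)

    def test_antisymmetry(self):
        for p, m in [(3, 9), (1, 0), (17, 4)]:
            assert strand_skew(p, m) == -strand_skew(m, p)

    def test_zero_total_is_an_error(self):
        with pytest.raises(ValueError):
            strand_skew(0, 0)


class TestSkewFlag:
    def test_both_alleles_equally_skewed_not_flagged(self):
        # a variant with strong skew is kept when the reference allele
        # shows the same skew
        assert not skew_flag(0.9, 0.85, 0.5)

    def test_opposite_extreme_skews_flagged(self):
        assert skew_flag(0.0, 1.0, 0.5)

    def test_moderate_difference_below_delta(self):
        assert not skew_flag(0.1, 0.4, 0.5)


class TestCallVariants:
    def test_thresholds(self, rng):
        t = make_target(rng)

        def alt_for(off):
            return "A" if t.sequence[off] != "A" else "C"

        sites = {
            100: {t.sequence[100]: (6, 6), alt_for(100): (4, 4)},  # cov 20, freq 0.40 -> call
            120: {t.sequence[120]: (4, 3), alt_for(120): (4, 3)},  # cov 14, freq 0.5 -> below coverage
            140: {t.sequence[140]: (8, 8), alt_for(140): (2, 2)},  # cov 20, freq 0.2 -> below frequency
        }
        calls = call_variants(pileup_with(t, sites), t, CallerConfig())
        assert len(calls) == 1
        c = calls[0]
        assert c.pos == t.start + 101
        assert c.coverage == 20 and c.alt_count == 8
        assert c.genotype == "het"

    def test_skewed_site_called_when_reference_equally_skewed(self, rng):
        """Coverage 45, allele frequency 0.444, both alleles strongly
        plus-skewed: called, and not skew-flagged."""
        t = make_target(rng)
        ref = t.sequence[150]
        alt = "T" if ref != "T" else "C"
        cols = pileup_with(t, {150: {ref: (23, 2), alt: (18, 2)}})
        calls = call_variants(cols, t, CallerConfig())
        assert len(calls) == 1
        c = calls[0]
        assert c.coverage == 45
        assert c.alt_freq == pytest.approx(0.444, abs=1e-3)
        assert not c.skew_flagged

    def test_multiple_qualifying_alts_emit_multiple_calls(self, rng):
        t = make_target(rng)
        ref = t.sequence[90]
        others = [b for b in "ACGT" if b != ref]
        cols = pileup_with(
            t, {90: {ref: (3, 3), others[0]: (7, 7), others[1]: (5, 5)}}
        )
        calls = call_variants(cols, t, CallerConfig())
        assert len(calls) == 2
        assert {c.alt_allele for c in calls} == {others[0], others[1]}

    def test_deletion_run_left_anchored(self, rng):
        t = make_target(rng)
        ref = t.sequence
        cols = pileup_with(
            t,
            {
                119: {ref[119]: (10, 10)},
                120: {ref[120]: (4, 4), "del": (6, 6)},
                121: {ref[121]: (4, 4), "del": (6, 6)},
                122: {ref[122]: (10, 10)},
            },
        )
        calls = call_variants(cols, t, CallerConfig())
        assert len(calls) == 1
        c = calls[0]
        assert c.vtype == "DEL"
        assert len(c.ref_allele) == 3 and len(c.alt_allele) == 1
        # leftmost-equivalent anchor never sits right of the run start
        assert c.pos <= t.start + 120

    def test_threshold_monotonicity(self, rng):
        t = make_target(rng)
        rng2 = np.random.default_rng(7)
        sites = {}
        for off in range(30, 250, 9):
            ref = t.sequence[off]
            alt = "A" if ref != "A" else "G"
            cov = int(rng2.integers(5, 60))
            altn = int(rng2.integers(0, cov + 1))
            sites[off] = {ref: (cov - altn, 0), alt: (altn, 0)}
        cols = pileup_with(t, sites)
        base = call_variants(cols, t, CallerConfig())
        for cfg in (CallerConfig(min_coverage=25), CallerConfig(min_alt_freq=0.5)):
            subset = call_variants(cols, t, cfg)
            assert {(c.pos, c.alt_allele) for c in subset} <= {
                (c.pos, c.alt_allele) for c in base
            }


class TestFlankContext:
    def test_unique_flank_maps_once(self, rng):
        genome = GenomeRef({"chr1": random_dna(rng, 3000)})
        t = ExonTarget("T", "chr1", 1000, 1300, "+", 1070, 1230, 70,
                       genome.slice("chr1", 1000, 1300))
        cols = pileup_with(t, {150: {t.sequence[150]: (8, 8),
                                     ("A" if t.sequence[150] != "A" else "C"): (8, 8)}})
        (call,) = call_variants(cols, t, CallerConfig())
        flank, n = flank_context(call, t, genome)
        assert len(flank) == 21
        assert flank == genome.sequences["chr1"][1000 + 140 : 1000 + 161]
        assert n == 1

    def test_repeat_planted_35_times(self, rng):
        """A flank inside a 35-copy repeat reports 35 genome mappings."""
        t_rng = np.random.default_rng(99)
        unit = random_dna(t_rng, 21)
        genome_seq = "".join(
            random_dna(t_rng, 40) + unit for _ in range(35)
        ) + random_dna(t_rng, 200)
        genome = GenomeRef({"chr1": genome_seq}); t = ExonTarget(
            "T", "chr1", 40, 40 + 61, "+", 50, 90, 10, genome.slice("chr1", 40, 101)
        )
        # variant centred on the first repeat copy: offset of unit centre
        off = 10  # target offset such that flank [0,21) == unit
        ref = t.sequence[off]
        alt = "A" if ref != "A" else "C"
        cols = pileup_with(t, {off: {ref: (10, 10), alt: (10, 10)}})
        (call,) = call_variants(cols, t, CallerConfig())
        flank, n = flank_context(call, t, genome)
        assert flank == unit
        assert n == 35

    def test_flank_clamped_near_target_edge(self, rng):
        genome = GenomeRef({"chr1": random_dna(rng, 500)})
        t = ExonTarget("T", "chr1", 100, 200, "+", 104, 196, 4, genome.slice("chr1", 100, 200))
        ref = t.sequence[4]
        alt = "A" if ref != "A" else "C"
        cols = pileup_with(t, {4: {ref: (10, 10), alt: (10, 10)}})
        (call,) = call_variants(cols, t, CallerConfig())
        flank, _ = flank_context(call, t, genome)
        assert len(flank) == 15  # 4 left bases + variant + 10 right


def make_coding_scene(codon, alt_base, codon_index=3):
    """Single-exon CDS transcript carrying `codon` at `codon_index`."""
    rng = np.random.default_rng(5)
    pre = "ATG" + random_dna(rng, 3 * (codon_index - 1))
    post = random_dna(rng, 9) + "TAA"
    cds = pre + codon + post
    left = random_dna(rng, 50)
    genome = GenomeRef({"chr1": left + cds + random_dna(rng, 50)})
    tx = TranscriptModel("tx", "chr1", "+", [(50, 50 + len(cds))], 50, 50 + len(cds))
    t = ExonTarget("T", "chr1", 0, len(genome.sequences["chr1"]), "+",
                   50, 50 + len(cds), 0, genome.sequences["chr1"])
    pos = 50 + 3 * codon_index  # first base of the codon, 0-based
    return genome, tx, t, pos


class TestAnnotateEffect:
    def snv_call(self, t, pos0, ref, alt):
        from mist.calling import VariantCall

        return VariantCall(
            target_id="T", chrom="chr1", pos=pos0 + 1, ref_allele=ref, alt_allele=alt,
            vtype="SNV", coverage=30, alt_count=15, ref_plus=8, ref_minus=7,
            alt_plus=8, alt_minus=7,
        )

    def test_missense_arg_to_trp(self):
        genome, tx, t, pos = make_coding_scene("CGG", "T")
        call = self.snv_call(t, pos, "C", "T")
        assert annotate_effect(call, tx, genome) == "missense"

    def test_synonymous_wobble(self):
        genome, tx, t, pos = make_coding_scene("CTT", "C")
        call = self.snv_call(t, pos + 2, "T", "C")
        assert annotate_effect(call, tx, genome) == "synonymous"

    def test_nonsense(self):
        genome, tx, t, pos = make_coding_scene("CAA", "T")
        call = self.snv_call(t, pos, "C", "T")
        assert annotate_effect(call, tx, genome) == "nonsense"

    def test_minus_strand_transcript(self):
        # CGG codon on the minus strand: genome carries its reverse complement
        rng = np.random.default_rng(6)
        cds_fwd = "ATG" + "CGG" + random_dna(rng, 9) + "TAA"
        genome = GenomeRef({"chr1": random_dna(rng, 30) + revcomp(cds_fwd) + random_dna(rng, 30)})
        n = len(cds_fwd)
        tx = TranscriptModel("tx", "chr1", "-", [(30, 30 + n)], 30, 30 + n)
        t = ExonTarget("T", "chr1", 0, len(genome.sequences["chr1"]), "+", 30, 30 + n, 0,
                       genome.sequences["chr1"])
        # codon CGG occupies CDS positions 3..5 => genomic offsets (end-1-5)..
        pos0 = 30 + n - 1 - 3  # genomic position of codon base 'C' (CDS pos 3)
        ref = genome.sequences["chr1"][pos0]
        assert ref == "G"  # revcomp of C
        call = self.snv_call(t, pos0, ref, "A")  # C>T on transcript strand
        assert annotate_effect(call, tx, genome) == "missense"

    def test_outside_transcript_is_none(self):
        genome, tx, t, pos = make_coding_scene("CGG", "T")
        call = self.snv_call(t, 2, "A", "C")
        assert annotate_effect(call, tx, genome) is None

    def test_cds_indel_frameshift_vs_inframe(self):
        genome, tx, t, pos = make_coding_scene("CGG", "T")
        from mist.calling import VariantCall

        fs = VariantCall("T", "chr1", pos + 1, "CG", "C", "DEL", 30, 15, 8, 7, 8, 7)
        inf = VariantCall("T", "chr1", pos + 1, "CGGA", "C", "DEL", 30, 15, 8, 7, 8, 7)
        assert annotate_effect(fs, tx, genome) == "frameshift"
        assert annotate_effect(inf, tx, genome) == "inframe"


class TestVcfOutput:
    def make_called_scene(self, rng):
        genome = GenomeRef({"chr1": random_dna(rng, 2000)})
        t = ExonTarget("T", "chr1", 500, 900, "+", 570, 830, 70, genome.slice("chr1", 500, 900))
        ref = t.sequence[200]
        alt = "A" if ref != "A" else "G"
        cols = pileup_with(t, {200: {ref: (10, 9), alt: (9, 8)}})
        calls = call_variants(cols, t, CallerConfig())
        return genome, t, calls

    def test_round_trip_through_pysam(self, tmp_path, rng):
        pysam = pytest.importorskip("pysam")
        genome, t, calls = self.make_called_scene(rng)
        path = tmp_path / "x.vcf"
        path.write_text(write_vcf(calls, genome))
        (rec,) = list(pysam.VariantFile(str(path)))
        c = calls[0]
        assert rec.pos == c.pos
        assert rec.ref == c.ref_allele
        assert rec.alts == (c.alt_allele,)
        assert rec.info["DP"] == c.coverage
        assert rec.info["AF"][0] == pytest.approx(c.alt_freq, abs=1e-5)
        assert tuple(rec.info["SA"]) == (c.alt_plus, c.alt_minus)

    def test_skew_flag_propagates_to_filter(self, rng):
        genome = GenomeRef({"chr1": random_dna(rng, 2000)})
        t = ExonTarget("T", "chr1", 500, 900, "+", 570, 830, 70, genome.slice("chr1", 500, 900))
        ref = t.sequence[200]
        alt = "A" if ref != "A" else "G"
        cols = pileup_with(t, {200: {ref: (10, 10), alt: (17, 0)}})
        (call,) = call_variants(cols, t, CallerConfig())
        assert call.skew_flagged
        body = [l for l in write_vcf([call], genome).splitlines() if not l.startswith("#")]
        assert body[0].split("\t")[6] == "skew"

    def test_unsorted_calls_rejected(self, rng):
        import copy

        genome, t, calls = self.make_called_scene(rng)
        earlier = copy.deepcopy(calls[0])
        earlier.pos -= 10
        with pytest.raises(ValueError):
            write_vcf([calls[0], earlier], genome)

    def test_tsv_mirrors_fields(self, rng):
        genome, t, calls = self.make_called_scene(rng)
        tsv = calls_to_tsv(calls)
        lines = tsv.strip().split("\n")
        assert len(lines) == 2
        fields = lines[1].split("\t")
        assert fields[0] == "T" and int(fields[2]) == calls[0].pos


def test_error_coincidence_bound():
    """Two independent Q30 base calls err at the same site with probability
    1e-6, under the 1-in-10000 bound that justifies dropping qualities."""
    per_base = 10 ** (-30 / 10)
    assert per_base ** 2 == pytest.approx(1e-6)
    assert per_base ** 2 < 1e-4
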