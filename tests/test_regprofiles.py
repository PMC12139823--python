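"""Gene-body coverage, TE obs/exp, locus comparison, eRNA metrics."""

import numpy as np
import pandas as pd
import pytest

from stormkit import regprofiles as reg
from stormkit import synthdata as sd
from stormkit.artifacts import ALIGNMENT_COLUMNS
from stormkit.intervals import IntervalSet


def frame(rows):
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


def read(chrom, start, end, strand="+", cell="c1", umi="", feature=None):
    return (cell, chrom, start, end, strand, umi, True, feature)


TRANSCRIPTS = pd.DataFrame({
    "gene_id": ["gA", "gB"], "chrom": ["chr1", "chr1"],
    "start": [1000, 5000], "end": [3000, 7000], "strand": ["+", "-"],
})


class TestGenebodyProfile:
    def test_uniform_coverage_is_flat(self):
        """Reads with uniformly distributed starts give a flat profile
        (bin CV < 0.1) — the closed-form expectation for uniform
        fragmentation."""
        rng = np.random.default_rng(8)
        rows = [read("chr1", int(s), int(s) + 10)
                for s in rng.integers(1000, 2990, 20_000)]
        prof = reg.genebody_profile(frame(rows), TRANSCRIPTS.iloc[[0]])
        assert prof.values.mean() == pytest.approx(1.0)
        assert prof.cv() < 0.1

    def test_localized_read_hits_expected_bins(self):
        # one read over the first 10% of gA -> bins 0..9 only
        rows = [read("chr1", 1000, 1200)]
        prof = reg.genebody_profile(frame(rows), TRANSCRIPTS.iloc[[0]],
                                    normalize=False)
        assert prof.values[:10].sum() > 0
        assert prof.values[10:].sum() == 0

    def test_minus_strand_transcript_flips_orientation(self):
        # genomic-left read on a minus-strand transcript -> 3' bins
        rows = [read("chr1", 5000, 5200, strand="-")]
        prof = reg.genebody_profile(frame(rows), TRANSCRIPTS.iloc[[1]],
                                    normalize=False)
        assert prof.values[90:].sum() > 0
        assert prof.values[:90].sum() == 0

    def test_transcript_order_invariance(self):
        rng = np.random.default_rng(9)
        rows = [read("chr1", int(s), int(s) + 50)
                for s in rng.integers(1000, 6900, 500)]
        fwd = reg.genebody_profile(frame(rows), TRANSCRIPTS)
        rev = reg.genebody_profile(frame(rows), TRANSCRIPTS.iloc[::-1])
        assert np.allclose(fwd.values, rev.values)

    def test_flipping_all_strands_reverses_profile(self):
        rng = np.random.default_rng(10)
        rows = [read("chr1", int(s), int(s) + 20)
                for s in np.sort(rng.integers(1000, 2000, 300))]
        flipped = TRANSCRIPTS.iloc[[0]].assign(strand="-")
        fwd = reg.genebody_profile(frame(rows), TRANSCRIPTS.iloc[[0]])
        rev = reg.genebody_profile(frame(rows), flipped)
        assert np.allclose(fwd.values, rev.values[::-1])

    def test_min_length_filter_errors_when_empty(self):
        with pytest.raises(ValueError, match="min_length|length"):
            reg.genebody_profile(frame([read("chr1", 1000, 1100)]),
                                 TRANSCRIPTS, min_length=50_000)


class TestTEObsExp:
    te = IntervalSet.from_tuples([
        ("chr1", 0, 600, "LINE/L1"), ("chr1", 1000, 1400, "LINE/L1"),
        ("chr1", 2000, 2300, "SINE/Alu"), ("chr1", 3000, 3700, "SINE/Alu"),
    ])  # L1: 1000 bp, Alu: 1000 bp

    def test_ratio_arithmetic(self):
        # 60% of reads in a family holding 30% of TE bp -> score 2
        te = IntervalSet.from_tuples([("chr1", 0, 300, "A"),
                                      ("chr1", 1000, 1700, "B")])
        rows = ([read("chr1", 10, 60, feature="A")] * 6
                + [read("chr1", 1100, 1150, feature="B")] * 4)
        scores = reg.te_family_obs_exp(frame(rows), te).set_index("family")
        assert scores.loc["A", "score"] == pytest.approx(0.6 / 0.3)
        assert scores.loc["B", "score"] == pytest.approx(0.4 / 0.7)

    def test_fractions_sum_to_one(self):
        reads = sd.sample_te_reads(self.te, 2000, seed=1)
        scores = reg.te_family_obs_exp(reads, self.te)
        assert scores["observed_fraction"].sum() == pytest.approx(1.0)
        assert scores["expected_fraction"].sum() == pytest.approx(1.0)

    def test_bp_proportional_sampling_scores_one(self):
        reads = sd.sample_te_reads(self.te, 40_000, seed=2)
        scores = reg.te_family_obs_exp(reads, self.te).set_index("family")
        for fam in ("LINE/L1", "SINE/Alu"):
            e = scores.loc[fam, "expected_fraction"]
            se = np.sqrt(e * (1 - e) / 40_000) / e
            assert abs(scores.loc[fam, "score"] - 1.0) <= 3 * se

    def test_degenerate_all_reads_one_family(self):
        rows = [read("chr1", 10, 60)] * 5
        scores = reg.te_family_obs_exp(frame(rows), self.te)
        scores = scores.set_index("family")
        assert scores.loc["LINE/L1", "score"] == pytest.approx(
            1 / scores.loc["LINE/L1", "expected_fraction"])
        assert scores.loc["SINE/Alu", "score"] == 0.0

    def test_max_overlap_assignment_is_unique_and_deterministic(self):
        te = IntervalSet.from_tuples([("chr1", 0, 100, "A"),
                                      ("chr1", 80, 300, "B")])
        # read overlaps A by 20, B by 70 -> B
        assigned = reg.assign_te_reads(frame([read("chr1", 80, 150)]), te)
        assert assigned.iloc[0].endswith("|B")


class TestCompareLocus:
    def test_identity_gives_r2_one(self):
        counts = pd.Series([10, 40, 5, 100, 7], index=list("abcde"))
        res = reg.compare_locus_te(counts, counts)
        assert res["r_squared"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(1.0)

    def test_shared_truth_high_r2_permutation_null(self):
        sc, bulk = sd.simulate_locus_counts(500, seed=4)
        res = reg.compare_locus_te(sc, bulk)
        assert res["r_squared"] >= 0.9
        rng = np.random.default_rng(0)
        perm = pd.Series(sc.to_numpy()[rng.permutation(len(sc))],
                         index=sc.index)
        assert reg.compare_locus_te(perm, bulk)["r_squared"] < 0.05

    def test_too_few_loci_errors(self):
        s = pd.Series([1, 2], index=list("ab"))
        with pytest.raises(ValueError, match=">= 3"):
            reg.compare_locus_te(s, s)


@pytest.fixture(scope="module")
def enhancer_world():
    model = sd.build_transcriptome(10, (200, 600),
                                   intergenic_fraction=0.995, seed=21)
    bundle = sd.build_annotations(model, {"LINE/L1": 1.0}, n_enhancers=40,
                                  seed=22, te_fraction_of_intergenic=0.01)
    rng = np.random.default_rng(23)
    transcribed = sorted(rng.choice(bundle.enhancer_midpoints.index, 10,
                                    replace=False))
    cells = [f"c{i}" for i in range(6)]
    reads = sd.simulate_enhancer_reads(bundle, transcribed, cells, seed=24)
    return bundle, transcribed, cells, reads


class TestDetectErnas:
    def test_minimal_divergent_pair(self):
        enh = IntervalSet.from_tuples([("chr1", 1000, 1300, "e1")])
        rows = [read("chr1", 1200, 1250, strand="+", umi="AAAA"),
                read("chr1", 1050, 1100, strand="-", umi="CCCC")]
        det = reg.detect_ernas(frame(rows), enh)
        row = det.table.iloc[0]
        assert row["detected"] and row["bidirectional"]

    def test_no_reads_not_detected(self):
        enh = IntervalSet.from_tuples([("chr1", 1000, 1300, "e1")])
        det = reg.detect_ernas(frame([]), enh)
        assert det.table.empty

    def test_negative_pad_rejected(self):
        enh = IntervalSet.from_tuples([("chr1", 0, 100, "e1")])
        with pytest.raises(ValueError, match="pad"):
            reg.detect_ernas(frame([]), enh, pad=-1)

    def test_counts_monotone_in_min_umis(self, enhancer_world):
        bundle, _, cells, reads = enhancer_world
        d1 = reg.detect_ernas(reads, bundle.enhancers,
                              bundle.enhancer_midpoints, min_umis=1)
        d3 = reg.detect_ernas(reads, bundle.enhancers,
                              bundle.enhancer_midpoints, min_umis=3)
        c1 = d1.per_cell_counts().reindex(cells, fill_value=0)
        c3 = d3.per_cell_counts().reindex(cells, fill_value=0)
        assert (c3 <= c1).all()

    def test_planted_enhancers_recovered(self, enhancer_world):
        bundle, transcribed, cells, reads = enhancer_world
        det = reg.detect_ernas(reads, bundle.enhancers,
                               bundle.enhancer_midpoints)
        for cell in cells:
            got = det.detected_ids(cell)
            assert set(transcribed) <= got


class TestMetaprofile:
    def test_swapping_strand_labels_swaps_profiles(self, enhancer_world):
        bundle, _, _, reads = enhancer_world
        plus, minus, _ = reg.erna_metaprofile(reads, bundle.enhancers,
                                              bundle.enhancer_midpoints)
        swapped = reads.assign(
            strand=reads["strand"].map({"+": "-", "-": "+"}))
        plus2, minus2, _ = reg.erna_metaprofile(swapped, bundle.enhancers,
                                                bundle.enhancer_midpoints)
        assert np.allclose(plus.values, minus2.values)
        assert np.allclose(minus.values, plus2.values)

    def test_divergent_simulation_scores_high_asymmetry(self, enhancer_world):
        bundle, transcribed, _, reads = enhancer_world
        # profile over the transcribed elements (neighbours inside the
        # +-2 kb window would otherwise bleed into each other's flanks in
        # this deliberately small test genome)
        sub = IntervalSet(bundle.enhancers.df[
            bundle.enhancers.df["name"].isin(transcribed)])
        _, _, asym = reg.erna_metaprofile(reads, sub,
                                          bundle.enhancer_midpoints)
        assert asym > 0.9

    def test_no_reads_all_zero(self):
        enh = IntervalSet.from_tuples([("chr1", 5000, 5400, "e1")])
        plus, minus, asym = reg.erna_metaprofile(frame([]), enh)
        assert plus.values.sum() == 0 and minus.values.sum() == 0
        assert asym == 0.0


class TestEnhancerSharing:
    def _detection(self, pattern):
        rows = []
        for enh, cells in pattern.items():
            for c in cells:
                rows.append((c, enh, 1, 1, 2, True, True))
        table = pd.DataFrame(rows, columns=[
            "cell", "enhancer", "plus_umis", "minus_umis", "total_umis",
            "detected", "bidirectional"])
        return reg.EnhancerDetection(table, 1)

    def test_ceiling_and_floor_bins(self):
        cells = [f"c{i}" for i in range(10)]
        det = self._detection({"eAll": cells, "eOne": cells[:1]})
        hist = reg.enhancer_sharing(det, n_cells=10)
        assert hist.iloc[-1] == 1   # (0.9, 1.0]
        assert hist.iloc[0] == 1    # (0.0, 0.1]

    def test_conservation(self):
        det = self._detection({f"e{i}": [f"c{j}" for j in range(i + 1)]
                               for i in range(7)})
        hist = reg.enhancer_sharing(det, n_cells=10)
        assert hist.sum() == 7
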