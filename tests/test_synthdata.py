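"""Generator correctness: determinism, invariants, truth-label recovery."""

import numpy as np
import pandas as pd
import pytest

from stormkit import synthdata as sd
from stormkit.readstruct import ReadStructure, parse_read_pair
from stormkit.seqio import read_fastq
from stormkit.spikein import SpikeInDesign, synthetic_mix


class TestBuildTranscriptome:
    def test_fixed_seed_outputs_are_byte_identical(self, tmp_path):
        paths = []
        for run in ("a", "b"):
            model = sd.build_transcriptome(10, (200, 2000), seed=7)
            fa = model.write_fasta(tmp_path / f"{run}.fa")
            gtf = model.write_gtf(tmp_path / f"{run}.gtf")
            paths.append((fa.read_bytes(), gtf.read_bytes()))
        assert paths[0] == paths[1]

    def test_degenerate_length_range(self):
        model = sd.build_transcriptome(1, (100, 100), seed=0)
        assert len(model.genes) == 1
        assert int(model.genes["length"].iloc[0]) == 100

    def test_gene_ids_unique_and_within_bounds(self):
        model = sd.build_transcriptome(50, (200, 1000), seed=3)
        assert model.genes["gene_id"].nunique() == 50
        for row in model.genes.itertuples():
            assert 0 <= row.start < row.end <= len(model.sequences[row.chrom])

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError, match="min 500 > max 100"):
            sd.build_transcriptome(5, (500, 100))

    def test_intergenic_fraction_respected(self):
        model = sd.build_transcriptome(30, (200, 800),
                                       intergenic_fraction=0.6, seed=1)
        total = sum(model.chrom_lengths.values())
        gene_bp = int(model.genes["length"].sum())
        assert abs(1 - gene_bp / total - 0.6) < 0.01


class TestBuildAnnotations:
    def test_family_bp_tracks_weights(self, small_model):
        bundle = sd.build_annotations(
            small_model, {"LINE/L1": 0.5, "SINE/Alu": 0.5}, seed=2)
        fam_bp = bundle.te_family_bp()
        fracs = fam_bp / fam_bp.sum()
        assert abs(fracs["LINE/L1"] - 0.5) < 0.05
        assert abs(fracs["SINE/Alu"] - 0.5) < 0.05

    def test_no_enhancers_is_valid(self, small_model):
        bundle = sd.build_annotations(
            small_model, {"LINE/L1": 1.0}, n_enhancers=0, seed=2)
        assert len(bundle.enhancers) == 0
        assert len(bundle.enhancer_midpoints) == 0

    def test_enhancers_disjoint_from_transcripts(self, small_model,
                                                 small_bundle):
        tx = small_model.transcript_intervals()
        for row in small_bundle.enhancers.iter_rows():
            assert not tx.overlaps(row["chrom"], row["start"], row["end"])

    def test_insufficient_space_errors(self):
        tiny = sd.build_transcriptome(5, (500, 900),
                                      intergenic_fraction=0.05, seed=1)
        with pytest.raises(ValueError, match="intergenic space"):
            sd.build_annotations(tiny, {"LINE/L1": 1.0}, n_enhancers=500,
                                 enhancer_length=5000, seed=0)

    def test_weights_must_sum_to_one(self, small_model):
        with pytest.raises(ValueError, match="sum to 1"):
            sd.build_annotations(small_model, {"LINE/L1": 0.8})


class TestSimulateCells:
    def test_poisson_limit_flag(self, small_model):
        truth = sd.simulate_cells(small_model, 40, mean_molecules=5.0,
                                  dispersion=np.inf, seed=9)
        counts = truth.gene_counts.to_numpy().ravel()
        # Poisson: variance ~= mean (index of dispersion ~ 1)
        assert abs(counts.var() / counts.mean() - 1.0) < 0.15

    def test_negative_binomial_overdispersion(self, small_model):
        truth = sd.simulate_cells(small_model, 60, mean_molecules=10.0,
                                  dispersion=1.0, seed=9)
        counts = truth.gene_counts.to_numpy().ravel()
        # variance = mu + mu^2/r = 10 + 100 = 110 -> var/mean = 11
        assert counts.var() / counts.mean() == pytest.approx(11, rel=0.3)

    def test_degenerate_umi_composition(self, small_model):
        truth = sd.simulate_cells(small_model, 2, mean_molecules=3,
                                  umi_weights={"A": 1.0}, umi_length=6,
                                  seed=1)
        assert (truth.molecules["umi"] == "AAAAAA").all()

    def test_dispersion_must_be_positive(self, small_model):
        with pytest.raises(ValueError, match="dispersion"):
            sd.simulate_cells(small_model, 2, dispersion=0.0)

    def test_spikein_counts_poisson_consistent(self, small_model):
        """Species at ~5 expected copies over 200 cells: truth copies mean
        within 3 SE of the Poisson expectation, variance/mean ~ 1."""
        conc = 5.0 / (1e-18 * 6.02214076e23 * 1e-6 * 1.0)
        design = SpikeInDesign(
            pd.DataFrame({"id": ["SPK-1"], "length_bp": [1000],
                          "amol_per_uL": [conc]}),
            dilution=1e-6, volume_uL=1.0)
        expected = float(design.expected_copies().iloc[0])
        truth = sd.simulate_cells(small_model, 200, mean_molecules=0.5,
                                  spikein=design, seed=21)
        per_cell = truth.spike_counts().loc["SPK-1"]
        se = np.sqrt(expected / 200)
        assert abs(per_cell.mean() - expected) < 3 * se
        assert per_cell.var() / per_cell.mean() == pytest.approx(1.0,
                                                                 abs=0.35)


class TestEmitLibrary:
    def test_no_artifacts_all_labeled_none(self, small_model, tmp_path):
        truth = sd.simulate_cells(small_model, 2, mean_molecules=5, seed=3)
        lib = sd.emit_library(truth, ReadStructure(), sd.ArtifactRates(),
                              tmp_path, seed=4)
        assert (lib.reads["artifact_class"] == "none").all()

    def test_artifact_fraction_binomial_recovery(self, small_library):
        reads = small_library.reads
        n = len(reads)
        for cls, p in [("gdna_background", 0.1), ("strand_invasion", 0.02)]:
            k = int((reads["artifact_class"] == cls).sum())
            se = np.sqrt(n * p * (1 - p))
            assert abs(k - n * p) <= 3 * se

    def test_record_counts_agree_across_outputs(self, small_library):
        import pysam

        n_truth = len(small_library.reads)
        n_fastq = sum(1 for _ in read_fastq(small_library.fastq_r1))
        with pysam.AlignmentFile(str(small_library.truth_sam),
                                 check_sq=False) as fh:
            n_sam = sum(1 for _ in fh)
        table = pd.read_csv(small_library.truth_table, sep="\t")
        assert n_fastq == n_truth == n_sam == len(table)

    def test_reads_map_to_exactly_one_truth_record(self, small_library,
                                                   small_truth):
        reads = small_library.reads
        assert reads["read_id"].is_unique
        known = set(small_truth.molecules["molecule_id"])
        assert set(reads["molecule_id"]) <= known

    def test_parse_recovers_truth_umi_for_all_reads(self, small_library):
        structure = small_library.structure
        truth_umi = small_library.reads.set_index("read_id")["umi"]
        n = 0
        for r1, r2 in zip(read_fastq(small_library.fastq_r1),
                          read_fastq(small_library.fastq_r2)):
            parsed = parse_read_pair(r1, r2, structure)
            assert parsed.passed
            assert parsed.umi == truth_umi[parsed.read_id]
            n += 1
        assert n == len(small_library.reads)

    def test_fixed_seed_library_byte_identical(self, small_model, tmp_path):
        digests = []
        for run in ("a", "b"):
            truth = sd.simulate_cells(small_model, 2, mean_molecules=8,
                                      seed=13)
            lib = sd.emit_library(
                truth, ReadStructure(),
                sd.ArtifactRates(gdna_fraction=0.1), tmp_path / run, seed=14)
            digests.append((lib.fastq_r1.read_bytes(),
                            lib.fastq_r2.read_bytes(),
                            lib.truth_sam.read_bytes(),
                            lib.truth_table.read_bytes()))
        assert digests[0] == digests[1]

    def test_rates_summing_above_one_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            sd.ArtifactRates(gdna_fraction=0.7,
                             strand_invasion_fraction=0.5)

    def test_spike_reads_land_on_spike_contigs(self, small_model, tmp_path):
        design = SpikeInDesign(synthetic_mix(5, seed=0), dilution=1e-6,
                               volume_uL=20.0)
        truth = sd.simulate_cells(small_model, 3, mean_molecules=2,
                                  spikein=design, seed=6)
        lib = sd.emit_library(truth, ReadStructure(), sd.ArtifactRates(),
                              tmp_path, seed=7)
        spike_ids = set(design.species["id"])
        spike_reads = lib.reads[lib.reads["feature"].isin(spike_ids)]
        assert (spike_reads["chrom"] == spike_reads["feature"]).all()
        assert set(spike_ids) <= set(lib.genome)
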