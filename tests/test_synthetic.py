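"""Generator: determinism, planted structure, module correlations, hits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aponet import (IntervalSet, SimulationParams, StudyDesign, filter_hits,
                    generate_annotation_and_hits, generate_counts,
                    plant_modules)
from aponet.synteny import Interval


def _pair_design(clones=3):
    return StudyDesign(classes=(("A", 1), ("B", 1)), clones_per_genotype=clones)


class TestGenerateCounts:
    def test_seeded_determinism(self):
        design = StudyDesign()
        params = SimulationParams(n_transcripts=300, seed=42)
        m1, t1 = generate_counts(design, params)
        m2, t2 = generate_counts(design, params)
        assert m1.data.equals(m2.data)
        assert t1.specific_sets == t2.specific_sets
        assert t1.acr_set == t2.acr_set

    def test_specific_transcripts_zero_outside_class(self):
        design = StudyDesign()
        params = SimulationParams(
            n_transcripts=1000,
            frac_specific_per_class={"4X_apo": 0.1}, frac_de=0.0,
            n_modules=0, module_size=0, seed=2)
        matrix, truth = generate_counts(design, params)
        assert len(truth.specific_sets["4X_apo"]) == 100  # floor rule
        meta = design.metadata()
        outside = meta.loc[meta.phenotypic_class != "4X_apo", "sample_id"]
        sub = matrix.data.loc[sorted(truth.specific_sets["4X_apo"]), outside]
        assert (sub.to_numpy() == 0).all()
        # and exactly those transcripts are all-zero outside the class
        all_zero = set(matrix.data.index[
            (matrix.data[outside].to_numpy() == 0).all(axis=1)])
        assert all_zero == truth.specific_sets["4X_apo"]

    def test_planted_log2fc_recovered_at_many_replicates(self):
        # Monte-Carlo: 30 clones per genotype, planted shift 2 on log2 scale
        design = _pair_design(clones=30)
        params = SimulationParams(n_transcripts=400, genotype_sd=0.0,
                                  frac_specific_per_class={}, frac_de=0.2,
                                  de_log2fc=2.0, n_modules=0, module_size=0,
                                  seed=1)
        matrix, truth = generate_counts(design, params)
        meta = design.metadata()
        cols_a = meta.loc[meta.phenotypic_class == "A", "sample_id"]
        cols_b = meta.loc[meta.phenotypic_class == "B", "sample_id"]
        up_a, up_b = truth.de_sets[("A", "B")]
        for ids, sign in ((up_a, 1.0), (up_b, -1.0)):
            sub = matrix.data.loc[sorted(ids)]
            ratio = np.log2(sub[cols_a].mean(axis=1) / sub[cols_b].mean(axis=1))
            dev = np.abs(ratio - sign * 2.0)
            assert abs(ratio.mean() - sign * 2.0) < 0.3
            # individual low-expression transcripts are noisier; only a small
            # tail may exceed the band
            assert (dev > 0.3).mean() <= 0.10

    def test_non_planted_transcripts_class_independent(self):
        design = _pair_design(clones=30)
        params = SimulationParams(n_transcripts=500, genotype_sd=0.0,
                                  frac_specific_per_class={}, frac_de=0.1,
                                  n_modules=0, module_size=0, seed=9)
        matrix, truth = generate_counts(design, params)
        meta = design.metadata()
        cols_a = meta.loc[meta.phenotypic_class == "A", "sample_id"]
        cols_b = meta.loc[meta.phenotypic_class == "B", "sample_id"]
        null_ids = sorted(set(matrix.transcript_ids) - truth.de_union())
        sub = matrix.data.loc[null_ids]
        _, p = stats.ttest_ind(sub[cols_a], sub[cols_b], axis=1)
        assert (p < 0.01).mean() < 0.03  # near nominal at alpha = 0.01

    def test_inconsistent_fractions_rejected(self):
        with pytest.raises(ValueError, match="jointly"):
            SimulationParams(frac_specific_per_class={"4X_apo": 0.8},
                             frac_de=0.4)
        with pytest.raises(ValueError, match="exceeds"):
            SimulationParams(n_transcripts=100, n_modules=5, module_size=30)


class TestPlantModules:
    def test_zero_noise_gives_exact_unit_correlation(self):
        design = _pair_design()
        params = SimulationParams(n_transcripts=100, n_modules=2,
                                  module_size=10, module_noise_sd=0.0,
                                  frac_specific_per_class={}, frac_de=0.0,
                                  seed=5)
        matrix, _ = generate_counts(design, params)
        matrix, truth = plant_modules(matrix, params)
        for mod in range(2):
            ids = [t for t, m in truth.module_assignment.items() if m == mod]
            c = np.corrcoef(matrix.data.loc[ids].to_numpy())
            np.testing.assert_allclose(c, 1.0, atol=1e-12)

    def test_default_noise_within_and_between_module_correlation(self):
        # 20 samples: 2 classes x 2 genotypes x 5 clones
        design = StudyDesign(classes=(("A", 2), ("B", 2)), clones_per_genotype=5)
        params = SimulationParams(n_transcripts=200, n_modules=4,
                                  module_size=20,
                                  frac_specific_per_class={}, frac_de=0.0,
                                  seed=1)
        matrix, _ = generate_counts(design, params)
        matrix, truth = plant_modules(matrix, params)
        by_mod = {}
        for t, m in truth.module_assignment.items():
            by_mod.setdefault(m, []).append(t)
        for ids in by_mod.values():
            c = np.corrcoef(matrix.data.loc[sorted(ids)].to_numpy())
            within = c[np.triu_indices_from(c, 1)]
            assert within.mean() >= 0.8
        # transcripts of different modules: near-zero correlation on average
        cross_vals = []
        mods = sorted(by_mod)
        for i, mi in enumerate(mods):
            for mj in mods[i + 1:]:
                a = matrix.data.loc[sorted(by_mod[mi])].to_numpy()
                b = matrix.data.loc[sorted(by_mod[mj])].to_numpy()
                cross_vals.append(np.abs(np.corrcoef(a, b)[:len(a), len(a):]))
        assert np.concatenate([c.ravel() for c in cross_vals]).mean() < 0.3

    def test_never_recruits_planted_labels(self):
        design = StudyDesign()
        params = SimulationParams(n_transcripts=400, seed=8)
        matrix, truth = generate_counts(design, params)
        matrix, truth = plant_modules(matrix, params, truth)
        module_ids = set(truth.module_assignment)
        labelled = truth.de_union().union(*truth.specific_sets.values())
        assert not (module_ids & labelled)


class TestAnnotationAndHits:
    @pytest.fixture()
    def intervals(self):
        return IntervalSet([Interval("chr2", 1000, 5000, "iv2"),
                            Interval("chr12", 9000, 12000, "iv12")])

    def test_acr_hits_survive_downstream_filter(self, intervals):
        design = StudyDesign()
        params = SimulationParams(n_transcripts=300, seed=6)
        _, truth = generate_counts(design, params)
        _, hits = generate_annotation_and_hits(truth, n_go_terms=50,
                                               intervals=intervals, seed=6)
        acr, _ = filter_hits(hits, intervals, evalue_cutoff=1e-5)
        assert acr == truth.acr_set  # all planted survive, every decoy removed

    def test_decoy_above_evalue_cutoff_is_removed(self, intervals):
        hits = pd.DataFrame(
            [["q1", "chr2", 95.0, 100, 0, 0, 1, 100, 1500, 1599, 1e-4, 80.0]],
            columns=["qseqid", "sseqid", "pident", "length", "mismatch",
                     "gapopen", "qstart", "qend", "sstart", "send", "evalue",
                     "bitscore"])
        acr, _ = filter_hits(hits, intervals, evalue_cutoff=1e-5)
        assert acr == set()

    def test_empty_acr_set_yields_no_survivors(self, intervals):
        design = StudyDesign()
        params = SimulationParams(n_transcripts=200, n_acr=0, seed=6)
        _, truth = generate_counts(design, params)
        _, hits = generate_annotation_and_hits(truth, n_go_terms=10,
                                               intervals=intervals, seed=6)
        acr, _ = filter_hits(hits, intervals, evalue_cutoff=1e-5)
        assert acr == set()

    def test_go_map_structure(self, intervals):
        design = StudyDesign()
        params = SimulationParams(n_transcripts=200, seed=6)
        _, truth = generate_counts(design, params)
        go_map, _ = generate_annotation_and_hits(truth, n_go_terms=30,
                                                 intervals=intervals, seed=6)
        assert set(go_map.columns) == {"transcript_id", "term_id"}
        per_transcript = go_map.groupby("transcript_id").size()
        assert per_transcript.max() <= 5
        assert truth.go_map  # annotated ids recorded on the truth object
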