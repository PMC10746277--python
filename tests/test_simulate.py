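"""Simulator contracts: genome/TU layout, library design, count model."""

import numpy as np
import pandas as pd
import pytest

from aeroscreen.counting import count_spacers
from aeroscreen.simulate import (
    CONTROL,
    SimConfig,
    _spacer_fitness,
    build_library,
    emit_fastq,
    make_effects,
    quick_library,
    revcomp,
    simulate_counts,
    simulate_genome,
)


class TestSimulateGenome:
    def test_single_gene_single_tu(self):
        cfg = SimConfig(n_genes=1, genes_per_tu_dist={1: 1.0}, n_controls=5, seed=1)
        annotation, tu_table, genome = simulate_genome(cfg)
        assert len(annotation) == 1
        assert len(tu_table) == 1
        assert tu_table.members.iloc[0] == annotation.gene_id.iloc[0]

    def test_forced_two_gene_tus(self):
        cfg = SimConfig(n_genes=100, genes_per_tu_dist={2: 1.0}, n_controls=5, seed=2)
        annotation, tu_table, _ = simulate_genome(cfg)
        assert len(annotation) == 100
        assert len(tu_table) == 50
        assert all(len(m.split(",")) == 2 for m in tu_table.members)

    def test_genes_non_overlapping_and_within_genome(self):
        cfg = SimConfig(n_genes=30, n_controls=5, seed=3)
        annotation, _, genome = simulate_genome(cfg)
        sorted_ = annotation.sort_values("start")
        assert (sorted_.start.values[1:] > sorted_.end.values[:-1]).all()
        assert annotation.end.max() <= len(genome)
        assert (annotation.start >= 1).all()

    def test_infeasible_gene_length_raises(self):
        cfg = SimConfig(n_genes=2, n_controls=5, gene_length=20, seed=4)
        with pytest.raises(ValueError, match="too short"):
            simulate_genome(cfg)


class TestBuildLibrary:
    def test_library_size_arithmetic(self, small_genome):
        lib = small_genome["library"]
        cfg = small_genome["config"]
        assert len(lib) == cfg.n_genes * cfg.guides_per_gene + cfg.n_controls
        targeting = lib[lib.gene_id != CONTROL]
        assert (targeting.groupby("gene_id").size() == cfg.guides_per_gene).all()

    def test_targeting_spacers_are_genomic_substrings(self, small_genome):
        genome = small_genome["genome"]
        rc = revcomp(genome)
        targeting = small_genome["library"].query("gene_id != 'CONTROL'")
        for seq in targeting.sequence:
            assert seq in genome or seq in rc

    def test_controls_absent_from_genome_both_strands(self, small_genome):
        genome = small_genome["genome"]
        rc = revcomp(genome)
        controls = small_genome["library"].query("gene_id == 'CONTROL'")
        for seq in controls.sequence:
            assert seq not in genome and seq not in rc
        assert (controls.efficiency == 0).all()

    def test_sequences_unique_and_20nt(self, small_genome):
        lib = small_genome["library"]
        assert lib.sequence.is_unique
        assert (lib.sequence.str.len() == 20).all()

    def test_fixed_seed_reproduces_library(self, small_genome):
        cfg = small_genome["config"]
        rng1 = np.random.default_rng(cfg.seed)
        ann1, _, gen1 = simulate_genome(cfg, rng1)
        lib1 = build_library(gen1, ann1, cfg, rng1)
        rng2 = np.random.default_rng(cfg.seed)
        ann2, _, gen2 = simulate_genome(cfg, rng2)
        lib2 = build_library(gen2, ann2, cfg, rng2)
        assert gen1 == gen2
        pd.testing.assert_frame_equal(lib1, lib2)


class TestCountModel:
    def _one_effect_library(self, n_neutral=200, depth=500.0, n_replicates=200, s=-0.3):
        cfg = SimConfig(
            n_genes=n_neutral + 1, guides_per_gene=1, n_controls=50,
            depth=depth, dispersion=0.05, n_replicates=n_replicates, seed=5,
        )
        rng = np.random.default_rng(cfg.seed)
        lib = quick_library(cfg, rng)
        target = lib.index[lib.gene_id == "gene0000"][0]
        lib.loc[lib.gene_id != CONTROL, "efficiency"] = 1.0
        effects = pd.DataFrame(
            dict(
                gene_id=sorted(set(lib.gene_id) - {CONTROL}),
                s_aerobic=0.0,
                s_anaerobic=0.0,
                class_label="neutral",
            )
        )
        effects.loc[effects.gene_id == "gene0000", "s_aerobic"] = s
        return cfg, lib, effects, target, rng

    def _empirical_lfc(self, counts, cfg):
        ti = counts.counts[counts.sample_ids(condition="aerobic", timepoint="Ti")]
        tf = counts.counts[counts.sample_ids(condition="aerobic", timepoint="Tf")]
        return np.log2((tf.to_numpy() + 0.5) / (ti.to_numpy() + 0.5))

    def test_expected_lfc_closed_form(self):
        # e = 1, s = -0.3, G = 10 on neutral background => mean LFC -> -3
        cfg, lib, effects, target, rng = self._one_effect_library()
        counts = simulate_counts(lib, effects, cfg, "aerobic", rng=rng)
        lfc = self._empirical_lfc(counts, cfg)
        assert abs(lfc[target].mean() - (-3.0)) < 0.1

    def test_controls_fitness_neutral(self):
        cfg, lib, effects, target, rng = self._one_effect_library()
        counts = simulate_counts(lib, effects, cfg, "aerobic", rng=rng)
        lfc = self._empirical_lfc(counts, cfg)
        ctrl = lib.gene_id.to_numpy() == CONTROL
        assert abs(lfc[ctrl].mean()) < 0.05

    def test_depth_invariance_of_expected_lfc(self):
        cfg, lib, effects, target, rng = self._one_effect_library(n_replicates=300)
        c1 = simulate_counts(lib, effects, cfg, "aerobic", rng=np.random.default_rng(9))
        cfg2 = cfg.replace(depth=cfg.depth * 2)
        c2 = simulate_counts(lib, effects, cfg2, "aerobic", rng=np.random.default_rng(9))
        m1 = self._empirical_lfc(c1, cfg)[target].mean()
        m2 = self._empirical_lfc(c2, cfg2)[target].mean()
        assert abs(m1 - m2) < 0.1

    def test_missing_effect_raises(self, toy_library):
        effects = pd.DataFrame(
            dict(gene_id=["g1"], s_aerobic=[0.0], s_anaerobic=[0.0], class_label=["neutral"])
        )
        cfg = SimConfig(n_genes=2, n_controls=2, seed=0)
        with pytest.raises(ValueError, match="missing TrueEffect"):
            simulate_counts(toy_library, effects, cfg, "aerobic")

    def test_make_effects_enforces_essential_magnitude(self):
        cfg = SimConfig(n_genes=5, n_controls=2, doublings=10.0, seed=0)
        ann = pd.DataFrame(dict(gene_id=[f"g{i}" for i in range(5)]))
        with pytest.raises(ValueError, match="G\\*s"):
            make_effects(ann, cfg, n_general=1, s_essential=-0.2)


class TestPolarity:
    def _tu_setup(self, polar, rp5=0.5, rp3=0.1):
        lib = pd.DataFrame(
            dict(
                spacer_id=["up_5p", "up_3p", "down_sp"],
                sequence=["A" * 20, "C" * 20, "G" * 20],
                gene_id=["gup", "gup", "gdown"],
                offset_frac=[0.0, 1.0, 0.5],
                efficiency=[1.0, 1.0, 1.0],
            )
        )
        effects = pd.DataFrame(
            dict(
                gene_id=["gup", "gdown"],
                s_aerobic=[0.0, -0.6],
                s_anaerobic=[0.0, -0.6],
                class_label=["neutral", "generally_essential"],
            )
        )
        tu = pd.DataFrame(
            dict(tu_id=["TU0"], replicon=["chr"], start=[1], end=[2000],
                 strand=["+"], members=["gup,gdown"])
        )
        cfg = SimConfig(n_genes=2, n_controls=2, polar=polar,
                        reverse_polar_5p=rp5, reverse_polar_3p=rp3, seed=0)
        return lib, effects, tu, cfg

    def test_polar_off_isolates_gene_effect(self):
        lib, effects, tu, cfg = self._tu_setup(polar=False)
        s = _spacer_fitness(lib, effects, cfg, "aerobic", tu)
        assert s[0] == 0.0 and s[1] == 0.0 and s[2] == -0.6

    def test_downstream_full_and_reverse_polar_interpolated(self):
        lib, effects, tu, cfg = self._tu_setup(polar=True, rp5=0.5, rp3=0.1)
        s = _spacer_fitness(lib, effects, cfg, "aerobic", tu)
        # guides on the upstream gene inherit the downstream gene's full effect
        assert s[0] == pytest.approx(-0.6)
        assert s[1] == pytest.approx(-0.6)
        # guide on the downstream gene feels no upstream effect (s_up = 0) plus own
        assert s[2] == pytest.approx(-0.6)

    def test_reverse_polar_attenuation_by_offset(self):
        lib, effects, tu, cfg = self._tu_setup(polar=True, rp5=0.5, rp3=0.1)
        # flip roles: upstream gene essential, downstream neutral
        effects = pd.DataFrame(
            dict(gene_id=["gup", "gdown"], s_aerobic=[-0.6, 0.0],
                 s_anaerobic=[-0.6, 0.0], class_label=["generally_essential", "neutral"])
        )
        s = _spacer_fitness(lib, effects, cfg, "aerobic", tu)
        # downstream guide at offset 0.5 picks up attenuated upstream effect
        att = 0.5 + (0.1 - 0.5) * 0.5
        assert s[2] == pytest.approx(att * -0.6)


class TestEmitFastq:
    def test_roundtrip_through_counting(self, toy_library, tmp_path):
        counts = pd.Series([5, 0, 3, 2, 7, 0], index=toy_library.spacer_id)
        f1, f2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        n = emit_fastq(counts, toy_library, f1, f2, read_length=60, seed=0)
        assert n == counts.sum()
        got, rep = count_spacers(f1, f2, toy_library)
        pd.testing.assert_series_equal(
            got.sort_index(), counts.sort_index(), check_names=False
        )
        assert rep.n_no_match == 0 and rep.n_ambiguous == 0

    def test_zero_counts_give_empty_fastq(self, toy_library, tmp_path):
        counts = pd.Series(0, index=toy_library.spacer_id)
        f1, f2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        n = emit_fastq(counts, toy_library, f1, f2, read_length=60, seed=0)
        assert n == 0
        assert f1.read_text() == "" and f2.read_text() == ""

    def test_read_length_too_short_raises(self, toy_library, tmp_path):
        counts = pd.Series(1, index=toy_library.spacer_id)
        with pytest.raises(ValueError, match="read_length"):
            emit_fastq(counts, toy_library, tmp_path / "a", tmp_path / "b", read_length=30)
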