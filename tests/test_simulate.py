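"""Synthetic-data generator: composition logic, NB counts, transcripts, round trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import neoblastsig as nb
from neoblastsig.simulate import (
    DEFAULT_BASE_COMPOSITION,
    SimulationError,
    build_sample_sheet,
    expected_counts,
)


class TestComposition:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(SimulationError):
            nb.CellComposition({"differentiated": 0.5, "somatic_neoblast": 0.4})
        with pytest.raises(SimulationError):
            nb.CellComposition({"differentiated": 1.5, "somatic_neoblast": -0.5})

    def test_irradiation_ablation_removes_proliferating_cells(self):
        for t in (12, 24, 72):
            comp = nb.composition_for_sample("irradiation", "irradiated", timepoint_h=t)
            assert comp["differentiated"] == pytest.approx(1.0)
            assert comp["somatic_neoblast"] == 0.0
            assert comp["germline_proliferating"] == 0.0

    def test_irradiation_t0_is_base(self):
        comp = nb.composition_for_sample("irradiation", "control", timepoint_h=0)
        assert comp.fractions == DEFAULT_BASE_COMPOSITION.fractions

    def test_facs_2c_is_differentiated_only(self):
        for cond in ("intact", "juvenile", "head"):
            comp = nb.composition_for_sample("facs", cond, gate="2C")
            assert comp["differentiated"] == 1.0

    def test_facs_4c_intact_renormalizes_proliferating(self):
        comp = nb.composition_for_sample("facs", "intact", gate="4C")
        assert comp["differentiated"] == 0.0
        assert comp["somatic_neoblast"] == pytest.approx(0.045 / 0.065)
        assert comp["germline_proliferating"] == pytest.approx(0.020 / 0.065)

    def test_facs_4c_gonad_free_is_pure_neoblast(self):
        for cond in ("juvenile", "head"):
            comp = nb.composition_for_sample("facs", cond, gate="4C")
            assert comp.fractions["somatic_neoblast"] == 1.0

    def test_composition_always_sums_to_one(self):
        sheet = build_sample_sheet(nb.SimulationConfig(n_clusters=10))
        for _, row in sheet.iterrows():
            comp = nb.composition_for_sample(
                row["dataset"],
                row["condition"],
                timepoint_h=int(row["timepoint_h"]) if row["dataset"] == "irradiation" else None,
                gate=row["gate"] if row["dataset"] == "facs" else None,
            )
            assert comp.as_array().sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"design": "irradiation", "condition": "zapped", "timepoint_h": 12},
            {"design": "irradiation", "condition": "irradiated", "timepoint_h": -5},
            {"design": "facs", "condition": "embryo", "gate": "4C"},
            {"design": "facs", "condition": "intact", "gate": "8C"},
        ],
    )
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(SimulationError):
            nb.composition_for_sample(**kwargs)


class TestSimulateCounts:
    def test_same_seed_identical(self):
        cfg = nb.SimulationConfig(n_clusters=200, seed=5)
        c1, s1, t1 = nb.simulate_counts(cfg)
        c2, s2, t2 = nb.simulate_counts(cfg)
        pd.testing.assert_frame_equal(c1, c2)
        assert t1.cluster_program == t2.cluster_program

    def test_neoblast_clusters_zero_after_irradiation(self, small_dataset):
        truth = small_dataset.truth
        prog = pd.Series(truth.cluster_program)
        ablated = [
            s
            for s in small_dataset.samples.index
            if small_dataset.samples.loc[s, "dataset"] == "irradiation"
            and small_dataset.samples.loc[s, "timepoint_h"] >= 12
        ]
        neo = prog[prog == "neoblast"].index
        assert (small_dataset.counts.loc[neo, ablated].to_numpy() == 0).all()

    def test_germline_zero_in_gonad_free_4c(self, small_dataset):
        prog = pd.Series(small_dataset.truth.cluster_program)
        gonad_free = [
            s
            for s in small_dataset.samples.index
            if small_dataset.samples.loc[s, "gate"] == "4C"
            and small_dataset.samples.loc[s, "condition"] in {"juvenile", "head"}
        ]
        germ = prog[prog == "germline"].index
        assert (small_dataset.counts.loc[germ, gonad_free].to_numpy() == 0).all()

    def test_housekeeping_mean_stable_across_ablation(self):
        """Law of large numbers: ablation does not move housekeeping expectations."""
        cfg = nb.SimulationConfig(
            n_clusters=50,
            replicates=200,
            designs=("irradiation",),
            timepoints_h=(0, 72),
            batch_factor_sd=0.0,
            base_mean_sdlog=0.0,
            programs=tuple(
                nb.GeneProgram(p.program_label, p.base_mean, 1e-8) for p in nb.SimulationConfig().programs
            ),
            seed=9,
        )
        counts, sheet, truth = nb.simulate_counts(cfg)
        prog = pd.Series(truth.cluster_program)
        hk = prog[prog == "housekeeping"].index
        t0 = sheet.index[sheet["timepoint_h"] == 0]
        t72 = sheet.index[sheet["timepoint_h"] == 72]
        m0 = counts.loc[hk, t0].to_numpy().mean()
        m72 = counts.loc[hk, t72].to_numpy().mean()
        assert abs(m0 - m72) / m0 < 0.02

    def test_poisson_limit_variance_over_mean(self):
        """With dispersion -> 0 and batch off, var/mean -> 1."""
        cfg = nb.SimulationConfig(
            n_clusters=300,
            replicates=100,
            designs=("irradiation",),
            timepoints_h=(0,),
            batch_factor_sd=0.0,
            programs=tuple(
                nb.GeneProgram(p.program_label, p.base_mean, 1e-8) for p in nb.SimulationConfig().programs
            ),
            seed=13,
        )
        counts, _, _ = nb.simulate_counts(cfg)
        x = counts.to_numpy(dtype=float)
        expressed = x.mean(axis=1) > 5
        ratio = x[expressed].var(axis=1, ddof=1) / x[expressed].mean(axis=1)
        assert abs(np.median(ratio) - 1.0) < 0.1

    def test_expected_counts_formula_spot_check(self):
        cfg = nb.SimulationConfig(n_clusters=4, batch_factor_sd=0.0)
        sheet = build_sample_sheet(cfg)
        programs = np.array(["housekeeping", "neoblast", "germline", "tissue"])
        base = np.array([100.0, 100.0, 100.0, 100.0])
        mu = expected_counts(cfg, programs, base, sheet, np.zeros(4), np.zeros(len(sheet)))
        j0 = list(sheet.index).index("irr_0h_r1")
        assert mu[0, j0] == pytest.approx(100.0)  # housekeeping: all compartments
        assert mu[1, j0] == pytest.approx(4.5)  # neoblast: 4.5% of cells
        assert mu[2, j0] == pytest.approx(2.0)  # germline: 2.0% of cells
        j4c = list(sheet.index).index("facs_intact_4C_r1")
        assert mu[1, j4c] == pytest.approx(100.0 * 0.045 / 0.065)
        assert mu[3, j4c] == 0.0  # tissue program absent from the 4C gate

    def test_zero_replicates_rejected(self):
        with pytest.raises(SimulationError):
            nb.SimulationConfig(n_clusters=10, replicates=0)


class TestTranscripts:
    def test_leader_fraction_extremes(self):
        cfg0 = nb.SimulationConfig(n_clusters=5, n_transcripts=50, leader_fraction=0.0, seed=2)
        recs, flags = nb.generate_transcripts(cfg0)
        assert not any(flags.values())
        assert not any(str(r.seq).startswith(nb.SL_LEADER) for r in recs)
        cfg1 = nb.SimulationConfig(n_clusters=5, n_transcripts=10, leader_fraction=1.0, seed=2)
        recs, flags = nb.generate_transcripts(cfg1)
        assert all(flags.values())
        assert all(str(r.seq).startswith(nb.SL_LEADER) for r in recs)

    def test_planted_count_in_binomial_interval(self):
        """Planted-leader count falls in the central 99% binomial interval."""
        cfg = nb.SimulationConfig(n_clusters=5, n_transcripts=2000, leader_fraction=0.3, seed=8)
        _, flags = nb.generate_transcripts(cfg)
        lo, hi = stats.binom.ppf([0.005, 0.995], 2000, 0.3)
        assert lo <= sum(flags.values()) <= hi

    def test_leader_longer_than_min_length_rejected(self):
        with pytest.raises(SimulationError):
            nb.SimulationConfig(n_clusters=5, transcript_length_range=(30, 100))


class TestWriteDataset(object):
    def test_round_trip_and_manifest(self, tmp_path, small_dataset):
        from neoblastsig import io as nio

        manifest = nb.write_dataset(small_dataset, tmp_path)
        assert len(manifest) == 5
        counts = nio.read_counts(manifest["counts"])
        pd.testing.assert_frame_equal(counts, small_dataset.counts, check_names=False)
        sheet = nio.read_sample_sheet(manifest["samples"])
        assert list(sheet.index) == list(small_dataset.samples.index)
        truth = nio.read_truth(manifest["truth"])
        assert len(truth) == small_dataset.config.n_clusters + small_dataset.config.n_transcripts
        recs = nio.read_fasta(manifest["transcripts"])
        assert len(recs) == small_dataset.config.n_transcripts
        assert str(recs[0].seq) == str(small_dataset.transcripts[0].seq)

    def test_identical_seed_byte_identical_files(self, tmp_path):
        cfg = nb.SimulationConfig(n_clusters=100, n_transcripts=50, seed=4)
        m1 = nb.write_dataset(nb.simulate_dataset(cfg), tmp_path / "a")
        m2 = nb.write_dataset(nb.simulate_dataset(cfg), tmp_path / "b")
        for key in m1:
            assert m1[key].read_bytes() == m2[key].read_bytes()
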