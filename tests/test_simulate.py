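"""Forward model: doped templates, cleavage kinetics, FASTQ emission."""
import math

import numpy as np
import pytest

from smarti.reference import LibraryDesign, VariantKey, WILD_TYPE, positions_of
from smarti.simulate import (
    AdapterSpec,
    KineticTruth,
    TimepointSample,
    TruthSet,
    cleavage_fraction,
    exact_mode_simulate,
    sample_doped_template,
    simulate_gel_timecourse,
    simulate_timepoint_fastq,
)


class TestKineticTruth:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            KineticTruth(WILD_TYPE, Y0=-1, amplitude=10, k=0.1)
        with pytest.raises(ValueError):
            KineticTruth(WILD_TYPE, Y0=60, amplitude=50, k=0.1)

    def test_cleavage_fraction_limits(self):
        truth = KineticTruth(WILD_TYPE, Y0=3.0, amplitude=40.0, k=0.2)
        assert cleavage_fraction(truth, 0.0) == pytest.approx(3.0)
        assert cleavage_fraction(truth, 1e6) == pytest.approx(43.0)
        # half-life identity
        assert cleavage_fraction(truth, math.log(2) / 0.2) == pytest.approx(23.0)
        with pytest.raises(ValueError):
            cleavage_fraction(truth, -1.0)


class TestDopedTemplates:
    def test_rate_zero_always_wild_type(self, reference):
        design = LibraryDesign("null", ((6029, 6216),), 0.0)
        rng = np.random.default_rng(0)
        assert all(sample_doped_template(reference, design, rng) == [] for _ in range(50))

    def test_substitutions_confined_to_design(self, reference, designs):
        design = designs["ribosome_binding"]
        allowed = set(positions_of(design))
        rng = np.random.default_rng(1)
        for _ in range(500):
            for pos, ref, alt in sample_doped_template(reference, design, rng):
                assert pos in allowed
                assert reference.base_at(pos) == ref != alt

    def test_mean_substitution_count_matches_doping_rate(self, reference, designs):
        """Mean substitutions/template over the 188-position library at 1.8%
        converges to 188*0.018 = 3.384 (within 3 MC standard errors)."""
        design = designs["single"]
        n, p, L = 20_000, design.substitution_rate, 188
        rng = np.random.default_rng(2)
        total = sum(len(sample_doped_template(reference, design, rng)) for _ in range(n))
        se = math.sqrt(L * p * (1 - p) / n)
        assert abs(total / n - L * p) < 3 * se

    def test_zero_substitution_fraction_matches_binomial(self, reference, designs):
        design = designs["single"]
        n = 20_000
        rng = np.random.default_rng(3)
        n_wt = sum(
            1 for _ in range(n) if not sample_doped_template(reference, design, rng)
        )
        p0 = (1 - design.substitution_rate) ** 188  # ~0.0326
        se = math.sqrt(p0 * (1 - p0) / n)
        assert abs(n_wt / n - p0) < 3 * se


def _read_fastq(path):
    reads = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    for i in range(0, len(lines), 4):
        reads.append(lines[i + 1])
    return reads


class TestFastqSimulation:
    def test_certainty_limit_all_cleaved(self, reference, adapter, tmp_path):
        truth = KineticTruth(WILD_TYPE, Y0=0.0, amplitude=100.0, k=50.0)
        truths = TruthSet(default=truth)
        sample = TimepointSample("r", 60.0, 300, seed=7)
        summary = simulate_timepoint_fastq(
            reference, None, truths, sample, adapter, tmp_path / "a.fastq",
            variant_mix=[(WILD_TYPE, 300)],
        )
        assert summary.set_index(["variant", "status"])["n"].to_dict() == {
            ("WT", "cleaved"): 300
        }
        cut_len = reference.index(reference.cleavage_position) + 1
        for seq in _read_fastq(tmp_path / "a.fastq"):
            insert = seq[: -(adapter.umi_length + len(adapter.constant))]
            assert len(insert) == cut_len

    def test_zero_amplitude_never_cleaves(self, reference, adapter, tmp_path):
        truth = KineticTruth(WILD_TYPE, Y0=0.0, amplitude=0.0, k=0.2)
        sample = TimepointSample("r", 60.0, 200, seed=8)
        summary = simulate_timepoint_fastq(
            reference, None, TruthSet(default=truth), sample, adapter,
            tmp_path / "b.fastq", variant_mix=[(WILD_TYPE, 200)],
        )
        assert set(summary["status"]) == {"full_length"}

    def test_adapter_and_umi_structure(self, reference, designs, adapter, tmp_path):
        truth = KineticTruth(WILD_TYPE, Y0=5.0, amplitude=30.0, k=0.2)
        sample = TimepointSample("r", 10.0, 200, seed=9)
        simulate_timepoint_fastq(
            reference, designs["single"], TruthSet(default=truth), sample, adapter,
            tmp_path / "c.fastq",
        )
        constant_dna = adapter.constant.replace("U", "T")
        for seq in _read_fastq(tmp_path / "c.fastq"):
            # constant occurs exactly once, at the 3' end, preceded by the UMI
            assert seq.endswith(constant_dna)
            assert seq.count(constant_dna) == 1
            umi = seq[-(len(constant_dna) + adapter.umi_length) : -len(constant_dna)]
            assert len(umi) == adapter.umi_length and set(umi) <= set("ACGT")

    def test_counts_conservation_and_observed_fraction(
        self, reference, designs, adapter, tmp_path
    ):
        """Cleaved + full-length reads = n_reads, and the wild-type observed
        cleaved fraction sits within 3 binomial SEs of the forward model."""
        truth = KineticTruth(WILD_TYPE, Y0=0.0, amplitude=18.0, k=0.15)
        t = 60.0
        sample = TimepointSample("r", t, 20_000, seed=10)
        summary = simulate_timepoint_fastq(
            reference, designs["single"], TruthSet(default=truth), sample, adapter,
            tmp_path / "d.fastq",
        )
        assert int(summary["n"].sum()) == 20_000
        wt = summary[summary["variant"] == "WT"].set_index("status")["n"]
        n_wt = int(wt.sum())
        p = cleavage_fraction(truth, t) / 100
        se = math.sqrt(p * (1 - p) / n_wt)
        assert abs(wt.get("cleaved", 0) / n_wt - p) < 3 * se

    def test_missing_truth_without_default_raises(self, reference, adapter, tmp_path):
        truths = TruthSet()  # no default
        sample = TimepointSample("r", 5.0, 10, seed=11)
        with pytest.raises(KeyError):
            simulate_timepoint_fastq(
                reference, None, truths, sample, adapter, tmp_path / "e.fastq",
                variant_mix=[(WILD_TYPE, 10)],
            )

    def test_sequencing_errors_add_extra_mismatches(self, reference, adapter, tmp_path):
        truth = KineticTruth(WILD_TYPE, Y0=0.0, amplitude=0.0, k=0.1)
        sample = TimepointSample("r", 0.0, 100, seed=12)
        simulate_timepoint_fastq(
            reference, None, TruthSet(default=truth), sample, adapter,
            tmp_path / "f.fastq", variant_mix=[(WILD_TYPE, 100)], error_rate=0.05,
        )
        ref_dna = reference.sequence.replace("U", "T")
        mismatched = sum(
            1
            for seq in _read_fastq(tmp_path / "f.fastq")
            if seq[: len(ref_dna)] != ref_dna
        )
        assert mismatched > 50  # 229 nt at 5% error: nearly every read


class TestGelMode:
    def test_large_n_limit_approaches_model(self):
        truth = KineticTruth(WILD_TYPE, Y0=2.0, amplitude=50.0, k=0.2)
        rng = np.random.default_rng(13)
        tc = simulate_gel_timecourse(truth, [0, 5, 30], 2_000_000, rng)
        for row in tc.itertuples():
            assert row.pct_cleaved == pytest.approx(
                cleavage_fraction(truth, row.time_min), abs=0.15
            )

    def test_zero_amplitude_stays_at_y0(self):
        truth = KineticTruth(WILD_TYPE, Y0=20.0, amplitude=0.0, k=0.3)
        rng = np.random.default_rng(14)
        tc = simulate_gel_timecourse(truth, [0, 2, 5, 10, 20, 30, 60], 10_000, rng)
        se = 100 * math.sqrt(0.2 * 0.8 / 10_000)
        assert np.all(np.abs(tc["pct_cleaved"] - 20.0) < 4 * se)

    def test_requires_positive_molecule_count(self):
        truth = KineticTruth(WILD_TYPE, Y0=0.0, amplitude=10.0, k=0.1)
        with pytest.raises(ValueError):
            simulate_gel_timecourse(truth, [0], 0, np.random.default_rng(0))


class TestExactMode:
    def test_rounding_rule(self, reference, adapter, tmp_path):
        # 25% of 100 -> exactly 25; 0.4% of 100 -> 0 under round-half-even
        t25 = KineticTruth(WILD_TYPE, Y0=25.0, amplitude=0.0, k=0.1)
        sample = TimepointSample("r", 0.0, 100, seed=0)
        table = exact_mode_simulate(
            reference, TruthSet(default=t25), sample, adapter,
            {WILD_TYPE: 100}, tmp_path / "x.fastq",
        )
        assert table.loc[0, "n_cleaved"] == 25
        t04 = KineticTruth(WILD_TYPE, Y0=0.4, amplitude=0.0, k=0.1)
        table = exact_mode_simulate(
            reference, TruthSet(default=t04), sample, adapter,
            {WILD_TYPE: 100}, tmp_path / "y.fastq",
        )
        assert table.loc[0, "n_cleaved"] == 0

    def test_exact_counts_for_variant_mix(self, reference, adapter, tmp_path):
        v = VariantKey(((6101, "U", "A"),))
        truths = TruthSet(
            truths={
                WILD_TYPE: KineticTruth(WILD_TYPE, Y0=0.0, amplitude=18.0, k=0.15),
                v: KineticTruth(v, Y0=0.0, amplitude=40.0, k=0.15),
            }
        )
        sample = TimepointSample("r", 60.0, 0, seed=0)
        table = exact_mode_simulate(
            reference, truths, sample, adapter,
            {WILD_TYPE: 1000, v: 500}, tmp_path / "z.fastq",
        ).set_index("variant")
        assert table.loc["WT", "n_cleaved"] == round(1000 * 18.0 * (1 - math.exp(-9)) / 100)
        assert table.loc["U6101A", "n_cleaved"] + table.loc["U6101A", "n_full"] == 500
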