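"""Generator contracts: determinism, ground-truth fidelity, profile shape."""

import math

import numpy as np
import pytest

from cernet import simulate
from cernet.de import screen_differential
from cernet.quant import relative_expression
from cernet.simulate import (
    GroundTruth,
    PlanError,
    generate_de_table,
    generate_mirna_set,
    generate_od_table,
    generate_qpcr_plate,
    generate_transcripts,
)
from cernet.targets import canonical_site_sequence, write_fasta


class TestMirnaSet:
    def test_contract(self):
        mirnas = generate_mirna_set(3, (21, 23), rng_seed=1)
        assert len({m.id for m in mirnas}) == 3
        assert all(21 <= len(m.sequence) <= 23 for m in mirnas)
        assert all(set(m.sequence) <= set("ACGU") for m in mirnas)
        assert all(m.seed6 == m.sequence[1:7] for m in mirnas)

    def test_determinism_byte_identical(self, tmp_path):
        paths = []
        for name in ("a.fasta", "b.fasta"):
            mirnas = generate_mirna_set(1, (22, 22), rng_seed=7)
            p = tmp_path / name
            write_fasta(p, {m.id: m.sequence for m in mirnas})
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_universe_size(self):
        mirnas = generate_mirna_set(119, (21, 23), rng_seed=2)
        assert len(mirnas) == 119
        assert len({m.seed7 for m in mirnas}) == 119

    @pytest.mark.parametrize("kwargs", [
        {"n": 0},
        {"n": 3, "length_range": (17, 22)},
        {"n": 3, "length_range": (23, 21)},
    ])
    def test_argument_errors(self, kwargs):
        with pytest.raises(ValueError):
            generate_mirna_set(**{"length_range": (21, 23), "rng_seed": 0, **kwargs})


class TestTranscripts:
    def test_implant_readback(self):
        mirnas = generate_mirna_set(2, rng_seed=3)
        plan = [(mirnas[0].id, "tx1", 100, "8mer")]
        seqs, gt = generate_transcripts(mirnas, ["tx1"], plan, length=1000, rng_seed=3)
        expected = canonical_site_sequence(mirnas[0], "8mer")
        assert seqs["tx1"][100:108] == expected
        assert gt.implant_plan == plan

    def test_every_planned_site_recoverable(self):
        mirnas = generate_mirna_set(5, rng_seed=4)
        plan = [(m.id, "tx", 50 + 20 * i, "8mer") for i, m in enumerate(mirnas)]
        seqs, gt = generate_transcripts(mirnas, ["tx"], plan, length=400, rng_seed=4)
        for mid, tid, start, site_type in gt.implant_plan:
            site = canonical_site_sequence({m.id: m for m in mirnas}[mid], site_type)
            assert seqs[tid][start : start + len(site)] == site

    def test_empty_plan_is_pure_background(self):
        mirnas = generate_mirna_set(1, rng_seed=5)
        seqs, gt = generate_transcripts(mirnas, ["tx"], [], length=200, rng_seed=5)
        assert len(seqs["tx"]) == 200
        assert gt.implant_plan == []

    def test_gc_fraction_realized(self):
        mirnas = generate_mirna_set(1, rng_seed=6)
        seqs, _ = generate_transcripts(
            mirnas, ["tx"], [], length=10000, gc_fraction=0.5, rng_seed=6
        )
        gc = sum(b in "GC" for b in seqs["tx"]) / 10000
        assert abs(gc - 0.5) < 0.03  # ~6 sigma of the binomial SE

    def test_overlapping_sites_rejected(self):
        mirnas = generate_mirna_set(2, rng_seed=7)
        plan = [(mirnas[0].id, "tx", 100, "8mer"), (mirnas[1].id, "tx", 104, "8mer")]
        with pytest.raises(PlanError):
            generate_transcripts(mirnas, ["tx"], plan, length=500, rng_seed=7)

    def test_unknown_mirna_rejected(self):
        mirnas = generate_mirna_set(1, rng_seed=8)
        with pytest.raises(ValueError):
            generate_transcripts(
                mirnas, ["tx"], [("nope", "tx", 0, "8mer")], length=100, rng_seed=8
            )

    def test_determinism(self):
        mirnas = generate_mirna_set(3, rng_seed=9)
        plan = [(mirnas[0].id, "tx", 10, "8mer")]
        a, _ = generate_transcripts(mirnas, ["tx"], plan, length=300, rng_seed=9)
        b, _ = generate_transcripts(mirnas, ["tx"], plan, length=300, rng_seed=9)
        assert a == b


class TestDeTable:
    def test_profile_shape_recovered_by_screen(self):
        df, gt = generate_de_table(351, 297, 1000, rng_seed=3)
        assert len(df) == 351 + 297 + 1000  # conservation
        result = screen_differential(df, min_abs_log2fc=1.0, max_p=0.05)
        assert (result.n_total, result.n_up, result.n_down) == (648, 351, 297)
        gt.validate_against(counts=(351, 297, 1000))

    def test_null_only_table_screens_empty(self):
        df, _ = generate_de_table(0, 0, 10, rng_seed=4)
        assert screen_differential(df).n_total == 0

    def test_fold_change_column_definition(self):
        df, _ = generate_de_table(5, 5, 5, rng_seed=5)
        assert np.allclose(df["fold_change"], np.exp2(df["log2fc"]), rtol=1e-9)

    def test_pinned_ids(self):
        df, gt = generate_de_table(3, 3, 3, rng_seed=6, down_ids=("LINC01260",))
        assert gt.true_de_labels["LINC01260"] == "down"
        assert gt.true_log2fc["LINC01260"] <= -1

    def test_argument_errors(self):
        with pytest.raises(ValueError):
            generate_de_table(-1, 0, 0)
        with pytest.raises(ValueError):
            generate_de_table(1, 1, 1, effect_low=0.5)
        with pytest.raises(ValueError):
            generate_de_table(1, 1, 1, p_sig=0.2)


class TestQpcrPlate:
    def test_zero_noise_exact_recovery(self):
        plate, _ = generate_qpcr_plate(
            ["LINC01260", "ACTB"], ["control", "OA"],
            {("LINC01260", "OA"): 0.35}, n_replicates=3, ct_noise_sd=0.0, rng_seed=1,
        )
        folds, excluded = relative_expression(plate, "LINC01260", "ACTB", "control")
        assert excluded == []
        oa = folds.loc[folds["group"] == "OA", "fold"]
        assert np.allclose(oa, 0.35)

    def test_unit_folds_give_unit_expression(self):
        plate, _ = generate_qpcr_plate(
            ["G1", "ACTB"], ["control", "t"], {}, ct_noise_sd=0.0, rng_seed=2,
        )
        folds, _ = relative_expression(plate, "G1", "ACTB", "control")
        assert np.allclose(folds["fold"], 1.0)

    def test_noisy_recovery_monte_carlo(self):
        plate, _ = generate_qpcr_plate(
            ["G1", "ACTB"], ["control", "t"], {("G1", "t"): 0.5},
            n_replicates=100, ct_noise_sd=0.1, rng_seed=3,
        )
        folds, _ = relative_expression(plate, "G1", "ACTB", "control")
        assert abs(folds.loc[folds["group"] == "t", "fold"].mean() - 0.5) < 0.05

    def test_reference_ct_independent_of_group(self):
        plate, _ = generate_qpcr_plate(
            ["G1", "ACTB"], ["control", "t"], {("G1", "t"): 2.0},
            ct_noise_sd=0.0, rng_seed=4,
        )
        ref = plate.loc[plate["gene"] == "ACTB", "ct"]
        assert ref.nunique() == 1

    def test_missing_reference_or_control(self):
        with pytest.raises(ValueError):
            generate_qpcr_plate(["G1"], ["control"], {})
        with pytest.raises(ValueError):
            generate_qpcr_plate(["G1", "ACTB"], ["t"], {})


def test_od_table_shape_and_determinism():
    params = {"control": (0.22, 0.028), "OA": (0.51, 0.02)}
    a = generate_od_table(params, n_replicates=4, rng_seed=5)
    b = generate_od_table(params, n_replicates=4, rng_seed=5)
    assert a.equals(b)
    assert len(a) == 8 and (a["od510"] >= 0).all()


def test_ground_truth_text_round_trip(tmp_path):
    gt = GroundTruth(
        rng_seed=9,
        implant_plan=[("mir-1", "tx", 10, "8mer")],
        true_de_labels={"tx": "up"},
        true_log2fc={"tx": 1.5},
        true_fold={("G1", "t"): 0.35},
    )
    path = tmp_path / "truth.txt"
    gt.write(path)
    back = GroundTruth.read(path)
    assert back.rng_seed == 9
    assert back.implant_plan == gt.implant_plan
    assert back.true_de_labels == gt.true_de_labels
    assert back.true_log2fc == gt.true_log2fc
    assert back.true_fold == gt.true_fold


def test_masked_fixture_target_sets_equal_plan(cerna_fixture, cerna_targetmap):
    """With chance-site masking, 8mer prediction recovers the plan exactly."""
    planned: dict[str, set[str]] = {}
    for mid, tid, _start, _st in cerna_fixture.ground_truth.implant_plan:
        planned.setdefault(tid, set()).add(mid)
    assert cerna_targetmap.targets == planned
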