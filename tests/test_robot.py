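"""Picklist compilation, simulation fidelity, and validation."""

import numpy as np
import pytest

from acidbase.bnn import BNNModel, ImageSample, chemical_neuron
from acidbase.chem import ph
from acidbase.robot import (
    PLATE_1536LDV,
    PLATE_384PP,
    CapacityError,
    NoiseModel,
    Picklist,
    PicklistCompiler,
    Plate,
    RobotError,
    Transfer,
    TransferError,
    layout_stock_plate,
    parse_well,
    read_picklist_csv,
    simulate_picklist,
    validate_picklist,
    well_name,
    write_picklist_csv,
)


def sample_and_model(rng, n=6, width=3, height=2, max_level=1, classes=2):
    choices = [v for v in range(-max_level, max_level + 1) if v != 0]
    x = ImageSample(rng.choice(choices, size=n), width, height, max_level)
    m = BNNModel(rng.choice([-1, 1], size=(classes, n)))
    return x, m


class TestWellNaming:
    @pytest.mark.parametrize("rc,name", [((0, 0), "A1"), ((15, 23), "P24"), ((26, 0), "AA1"), ((31, 47), "AF48")])
    def test_round_trip(self, rc, name):
        assert well_name(*rc) == name
        assert parse_well(name, PLATE_1536LDV) == rc

    def test_out_of_plate_rejected(self):
        with pytest.raises(RobotError):
            parse_well("AA1", PLATE_384PP)  # only 16 rows
        with pytest.raises(RobotError):
            parse_well("A0", PLATE_384PP)


class TestStockLayout:
    def test_default_rows_populated(self):
        plate = layout_stock_plate(4, 4, 2, 50.0)
        assert len(plate.wells) == 10 * 24
        kinds = [plate.stock[well_name(r, 0)][0] for r in range(10)]
        assert kinds == ["acid"] * 4 + ["base"] * 4 + ["water"] * 2
        assert plate.wells["A1"].acid_umol == pytest.approx(5.0)

    def test_overfill_rejected(self):
        with pytest.raises(CapacityError):
            layout_stock_plate(4, 4, 2, 70.0)  # above the 60 uL maximum

    def test_too_many_rows_rejected(self):
        with pytest.raises(CapacityError):
            layout_stock_plate(8, 8, 2)

    def test_zero_rows_gives_empty_plate(self):
        assert layout_stock_plate(0, 0, 0).wells == {}


class TestCompileEncoding:
    def test_binary_2x3_two_neurons_counts(self, rng):
        x, m = sample_and_model(rng)
        compiler = PicklistCompiler()
        pl = compiler.compile_encoding(x, m)
        # 2 neurons x 6 pixels x 2 wells, one reagent transfer per well, no water
        assert len(pl) == 24
        assert len({(t.dst_plate, t.dst_well) for t in pl}) == 24

    def test_negative_pixel_negative_weight_gives_acid_first(self):
        x = ImageSample(np.array([-1]), 1, 1, 1)
        m = BNNModel(np.array([[-1], [1]]))
        compiler = PicklistCompiler()
        pl = compiler.compile_encoding(x, m)
        # neuron 0: (-1) * (-1) = +1 -> acid into the first well
        first = pl.transfers[0]
        assert compiler.stock_plate.stock[first.src_well][0] == "acid"
        # neuron 1: (-1) * (+1) = -1 -> base first
        third = pl.transfers[2]
        assert compiler.stock_plate.stock[third.src_well][0] == "base"

    def test_full_scale_3bit_has_no_water(self, rng):
        x = ImageSample(np.array([4, -4, 4, -4]), 2, 2, 4)
        m = BNNModel(rng.choice([-1, 1], size=(2, 4)))
        pl = PicklistCompiler(dilution_mode="eq5").compile_encoding(x, m)
        assert len(pl) == 16  # reagent only

    def test_eq5_low_levels_overflow_ldv_wells(self, rng):
        x = ImageSample(np.array([1, -1, 1, -1]), 2, 2, 4)
        m = BNNModel(rng.choice([-1, 1], size=(2, 4)))
        compiler = PicklistCompiler(dilution_mode="eq5")
        with pytest.raises(CapacityError):
            compiler.compile_encoding(x, m)  # 2.4 + 7.2 uL > 4 uL max

    def test_capacity_check_can_be_deferred_to_validation(self, rng):
        x = ImageSample(np.array([1, -1, 1, -1]), 2, 2, 4)
        m = BNNModel(rng.choice([-1, 1], size=(2, 4)))
        compiler = PicklistCompiler(dilution_mode="eq5")
        pl = compiler.compile_encoding(x, m, check_capacity=False)
        violations = validate_picklist(pl, compiler.initial_plates())
        assert any(v.kind == "capacity" for v in violations)

    def test_stock_cursor_rotates_wells(self):
        # 50 uL fill, 10 uL min fill -> 40 uL budget = 16 transfers of 2.4 uL
        x = ImageSample(np.ones(20, dtype=int), 20, 1, 1)
        m = BNNModel(np.stack([np.ones(20, dtype=int), np.ones(20, dtype=int)]))
        pl = PicklistCompiler().compile_encoding(x, m)
        acid_sources = {t.src_well for t in pl if t.src_well.startswith("A")}
        assert len(acid_sources) >= 2  # 40 acid transfers need 3 wells

    def test_too_many_wells_rejected(self, rng):
        x, m = sample_and_model(rng, n=784, width=28, height=28)
        with pytest.raises(CapacityError):
            PicklistCompiler().compile_encoding(x, m)  # 3136 wells > 1536


class TestCompilePooling:
    def test_counts_and_volumes(self, rng):
        x, m = sample_and_model(rng, n=64, width=8, height=8)
        compiler = PicklistCompiler()
        enc = compiler.compile_encoding(x, m)
        pool = compiler.compile_pooling(200.0)
        assert len(pool) == 2 * 64 * 2  # neurons x pixels x rails
        final = simulate_picklist(enc + pool, compiler.initial_plates())
        ph_well, _ = compiler.neuron_output_wells[0]
        assert final["stock"].wells[ph_well].volume_uL == pytest.approx(64 * 0.2)

    def test_requires_encoding_first(self):
        with pytest.raises(RobotError):
            PicklistCompiler().compile_pooling()

    def test_sub_granularity_aliquot_rejected(self, rng):
        x, m = sample_and_model(rng)
        compiler = PicklistCompiler()
        compiler.compile_encoding(x, m)
        with pytest.raises(RobotError):
            compiler.compile_pooling(10.0)


class TestSimulate:
    @pytest.mark.parametrize("max_level,mode", [(1, "constant"), (4, "constant"), (4, "eq5")])
    def test_pipeline_reproduces_chemical_neuron_bit_for_bit(self, max_level, mode, rng):
        """compile + simulate == direct chemical_neuron, field for field."""
        for _ in range(20):
            x, m = sample_and_model(rng, n=9, width=3, height=3, max_level=max_level)
            compiler = PicklistCompiler(
                dilution_mode=mode,
                enc_spec=PLATE_1536LDV if mode == "constant" else PlateSpecBig(),
            )
            enc = compiler.compile_encoding(x, m, check_capacity=(mode == "constant"))
            pool = compiler.compile_pooling(200.0)
            final = simulate_picklist(enc + pool, compiler.initial_plates())
            for j, (ph_w, co_w) in enumerate(compiler.neuron_output_wells):
                direct = chemical_neuron(x, m.weights[j], dilution_mode=mode)
                sim_ph = final["stock"].wells[ph_w]
                sim_co = final["stock"].wells[co_w]
                assert sim_ph == direct.ph_rail  # dataclass eq: bitwise fields
                assert sim_co == direct.comp_rail

    def test_volume_conservation_noise_free(self, rng):
        x, m = sample_and_model(rng, n=16, width=4, height=4)
        compiler = PicklistCompiler()
        pl = compiler.compile_encoding(x, m) + compiler.compile_pooling()
        plates = compiler.initial_plates()
        before = sum(p.total_volume_uL() for p in plates.values())
        final = simulate_picklist(pl, plates)
        after = sum(p.total_volume_uL() for p in final.values())
        assert after == pytest.approx(before, abs=1e-9)

    def test_noise_zero_equals_noise_free(self, rng):
        x, m = sample_and_model(rng)
        compiler = PicklistCompiler()
        pl = compiler.compile_encoding(x, m) + compiler.compile_pooling()
        clean = simulate_picklist(pl, compiler.initial_plates())
        zeroed = simulate_picklist(pl, compiler.initial_plates(), NoiseModel(0.0))
        assert clean["stock"].wells == zeroed["stock"].wells

    def test_noisy_run_is_seed_reproducible(self, rng):
        x, m = sample_and_model(rng)
        compiler = PicklistCompiler()
        pl = compiler.compile_encoding(x, m) + compiler.compile_pooling()
        a = simulate_picklist(pl, compiler.initial_plates(), NoiseModel(0.1, seed=5))
        b = simulate_picklist(pl, compiler.initial_plates(), NoiseModel(0.1, seed=5))
        c = simulate_picklist(pl, compiler.initial_plates(), NoiseModel(0.1, seed=6))
        assert a["stock"].wells == b["stock"].wells
        assert a["stock"].wells != c["stock"].wells

    def test_transfer_from_undefined_well_rejected(self):
        pl = Picklist([Transfer("enc", "A1", "stock", "A1", 100.0)])
        plates = {"stock": layout_stock_plate(), "enc": Plate("enc", PLATE_1536LDV)}
        with pytest.raises(TransferError):
            simulate_picklist(pl, plates)

    def test_source_underflow_rejected(self):
        pl = Picklist([Transfer("stock", "A1", "enc", "A1", 60000.0)])
        plates = {"stock": layout_stock_plate(), "enc": Plate("enc", PLATE_1536LDV)}
        with pytest.raises(TransferError):
            simulate_picklist(pl, plates)


class TestValidate:
    def plates(self):
        return {"stock": layout_stock_plate(), "enc": Plate("enc", PLATE_1536LDV)}

    def test_granularity(self):
        ok = Picklist([Transfer("stock", "A1", "enc", "A1", 2400.0)])
        assert validate_picklist(ok, self.plates()) == []
        bad = Picklist([Transfer("stock", "A1", "enc", "A1", 2410.0)])
        assert [v.kind for v in validate_picklist(bad, self.plates())] == ["granularity"]

    def test_use_before_fill(self):
        pl = Picklist(
            [
                Transfer("enc", "B1", "stock", "L1", 200.0),  # B1 not yet filled
                Transfer("stock", "A1", "enc", "B1", 2400.0),
            ]
        )
        kinds = [v.kind for v in validate_picklist(pl, self.plates())]
        assert "use-before-fill" in kinds

    def test_min_fill_underflow_reported(self):
        # 17 x 2.4 uL from a 50 uL well crosses the 10 uL minimum
        pl = Picklist(
            [Transfer("stock", "A1", "enc", well_name(0, i), 2400.0) for i in range(17)]
        )
        violations = validate_picklist(pl, self.plates())
        assert [v.kind for v in violations] == ["min-fill"]
        assert violations[0].transfer_index == 16


class TestPicklistCSV:
    def test_round_trip_bit_exact(self, rng, tmp_path):
        x, m = sample_and_model(rng, n=9, width=3, height=3, max_level=4)
        compiler = PicklistCompiler()
        pl = compiler.compile_encoding(x, m) + compiler.compile_pooling()
        path = tmp_path / "picklist.csv"
        write_picklist_csv(pl, path)
        again = read_picklist_csv(path)
        assert again.transfers == pl.transfers

    def test_header_checked(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b,c\n1,2,3\n")
        with pytest.raises(RobotError):
            read_picklist_csv(path)


def PlateSpecBig():
    """An oversized destination plate used to host eq5-diluted rails."""
    from acidbase.robot import PlateSpec

    return PlateSpec("deepwell", 32, 48, 0.0, 100.0)
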