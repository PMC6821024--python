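import pytest

from dmnlkit.classify import classify
from dmnlkit.dmnl import (
    DmnlVariantConfig,
    config_for_type,
    default_promoters,
    dimerize,
    nonrandom_loss,
    read_config,
    run_dmnl,
    transcription_units,
    write_config,
)
from dmnlkit.model import SPECIES_TYPE, arrangements_equal, bothid_fixture


class TestDimerize:
    def test_double_gene_count(self, canonical):
        dimer = dimerize(canonical)
        assert len(dimer.genes()) == 74
        assert dimer.is_dimer

    def test_two_crs_two_ols(self, canonical):
        dimer = dimerize(canonical)
        names = dimer.names()
        assert sum(1 for n in names if n == "CR") == 2
        assert sum(1 for n in names if n == "OL") == 2

    def test_second_copy_is_prime(self, canonical):
        dimer = dimerize(canonical)
        tags = [f.copy_tag for f in dimer.features]
        half = len(tags) // 2
        assert set(tags[:half]) == {"plain"}
        assert set(tags[half:]) == {"prime"}

    def test_dimer_of_dimer_rejected(self, canonical):
        with pytest.raises(ValueError):
            dimerize(dimerize(canonical))


class TestTranscription:
    def test_four_promoters(self, canonical):
        dimer = dimerize(canonical)
        proms = default_promoters(dimer)
        assert len(proms) == 4
        assert {p.strand for p in proms} == {"H", "L"}

    def test_units_cover_every_gene(self, canonical):
        dimer = dimerize(canonical)
        units = transcription_units(dimer, default_promoters(dimer))
        covered = set()
        for u in units:
            covered.update(u.covered)
        gene_positions = {
            i for i, f in enumerate(dimer.features) if f.is_gene
        }
        assert gene_positions <= covered

    def test_h_and_l_units_per_promoter_pair(self, canonical):
        dimer = dimerize(canonical)
        units = transcription_units(dimer, default_promoters(dimer))
        assert len(units) == 4


class TestNonrandomLoss:
    def test_result_has_37_genes(self, canonical):
        res = nonrandom_loss(dimerize(canonical), config_for_type("III"))
        assert len(res.final.genes()) == 37

    def test_degenerated_count(self, canonical):
        # 74 - 37 = 37 gene copies degenerate in every variant
        for label in ("I", "II", "III", "IV"):
            res = nonrandom_loss(dimerize(canonical), config_for_type(label))
            gene_losses = [
                d for d in res.degenerated if not d[0].startswith("CR")
            ]
            assert len(gene_losses) == 37, label

    def test_plain_n_retained(self, canonical):
        # tRNA-N survives as the copy adjacent to the surviving COI,
        # not the transcription-expected prime copy
        res = nonrandom_loss(dimerize(canonical), config_for_type("III"))
        names = [f.name for f in res.final.features]
        i = names.index("N")
        assert names[(i + 1) % len(names)] == "OL"

    def test_cr_count_per_mode(self, canonical):
        for label, expect in (("I", 1), ("II", 1), ("III", 2), ("IV", 1)):
            res = nonrandom_loss(dimerize(canonical), config_for_type(label))
            crs = [f for f in res.final.features if f.category == "control"]
            assert len(crs) == expect, label


class TestRunDmnl:
    @pytest.mark.parametrize("code", list(SPECIES_TYPE))
    def test_reproduces_every_fixture(self, canonical, code):
        label, v_shuffled = SPECIES_TYPE[code]
        config = config_for_type(label, d_timing="after", v_shuffle=v_shuffled)
        res = run_dmnl(canonical, config)
        assert arrangements_equal(res.final, bothid_fixture(code))

    @pytest.mark.parametrize("label", ["I", "II", "III", "IV"])
    @pytest.mark.parametrize("timing", ["before", "after"])
    def test_classifier_closure(self, canonical, label, timing):
        config = config_for_type(label, d_timing=timing)
        res = run_dmnl(canonical, config)
        assert classify(res.final).label == label

    def test_event_log_nonempty(self, canonical):
        res = run_dmnl(canonical, config_for_type("III"))
        assert res.event_log
        assert any("dimer" in line.lower() for line in res.event_log)

    def test_before_and_after_agree_at_order_level(self, canonical):
        # both timings must land on the same final arrangement
        for label in ("I", "II", "III", "IV"):
            after = run_dmnl(canonical, config_for_type(label, d_timing="after"))
            before = run_dmnl(canonical, config_for_type(label, d_timing="before"))
            assert arrangements_equal(after.final, before.final), label

    def test_spacer_variant_carries_provenance(self, canonical):
        res = run_dmnl(canonical, config_for_type("III"))
        spacers = [
            f for f in res.final_with_spacers.features if f.category == "spacer"
        ]
        assert spacers
        assert all(f.provenance for f in spacers)

    def test_v_shuffle_only_type_iv(self):
        with pytest.raises(ValueError):
            config_for_type("II", v_shuffle=True)


class TestConfigValidation:
    def test_bad_label(self):
        with pytest.raises(ValueError):
            DmnlVariantConfig(type_label="V")

    def test_bad_cr_mode(self):
        with pytest.raises(ValueError):
            DmnlVariantConfig(type_label="I", cr_mode="drop_all")

    def test_bad_timing(self):
        with pytest.raises(ValueError):
            DmnlVariantConfig(type_label="I", d_timing="during")


class TestConfigIO:
    @pytest.mark.parametrize("label", ["I", "II", "III", "IV"])
    def test_round_trip(self, tmp_path, label):
        config = config_for_type(label, v_shuffle=(label == "IV"))
        path = tmp_path / "variant.cfg"
        write_config(config, path)
        assert read_config(path) == config

    def test_none_timing_round_trip(self, tmp_path):
        config = config_for_type("III", d_timing=None)
        path = tmp_path / "variant.cfg"
        write_config(config, path)
        assert read_config(path).d_timing is None

    def test_missing_type_label(self, tmp_path):
        path = tmp_path / "bad.cfg"
        path.write_text("cr_mode = retain_both\n")
        with pytest.raises(ValueError, match="type_label"):
            read_config(path)

    def test_unknown_key(self, tmp_path):
        path = tmp_path / "bad.cfg"
        path.write_text("type_label = I\nflux = 7\n")
        with pytest.raises(ValueError, match="flux"):
            read_config(path)
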