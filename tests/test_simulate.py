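import dataclasses
import random

import pytest

from mipscan import (
    FixtureSpec,
    ProteinRecord,
    Proteome,
    generate_fixture,
    read_fixture,
    read_truth,
    verify_fixture,
    write_fixture,
    write_truth,
)
from mipscan.io_formats import AMINO_ACIDS
from mipscan.simulate import ALL_CLASSES


def _spec(**overrides):
    return dataclasses.replace(FixtureSpec(), **overrides)


class TestDeterminism:
    def test_equal_specs_give_byte_identical_files(self, tmp_path):
        d1, d2 = tmp_path / "one", tmp_path / "two"
        write_fixture(generate_fixture(FixtureSpec()), d1)
        write_fixture(generate_fixture(FixtureSpec()), d2)
        for name in [
            "proteome.fasta", "tfs.fasta", "unwanted.txt",
            "domain_lib.tsv", "truth.tsv",
        ]:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_different_seeds_differ(self):
        fx1 = generate_fixture(_spec(seed=1))
        fx2 = generate_fixture(_spec(seed=2))
        assert [r.sequence for r in fx1.proteome] != [r.sequence for r in fx2.proteome]


class TestCounting:
    def test_no_decoys_one_family(self):
        spec = _spec(
            n_tf_families=1,
            tfs_per_family=2,
            mips_per_family=2,
            decoy_counts={
                "dbd_retaining": 0, "oversized_paralog": 0,
                "foreign_domain": 0, "unrelated_random": 0, "tier2_distant": 0,
            },
        )
        fx = generate_fixture(spec)
        assert len(fx.proteome) == 2 + 2  # the TFs themselves + their miPs
        assert len(fx.tfs) == 2

    def test_every_protein_labeled_exactly_once(self, default_fixture):
        fx = default_fixture
        assert set(fx.truth.labels) == set(fx.proteome.ids())
        assert set(fx.truth.labels.values()) <= ALL_CLASSES

    def test_default_class_counts(self, default_fixture):
        counts = {
            c: len(default_fixture.truth.of_class(c))
            for c in sorted(set(default_fixture.truth.labels.values()))
        }
        assert counts == {
            "decoy_dbd": 4, "decoy_foreign": 4, "decoy_oversized": 4,
            "decoy_random": 4, "tf": 4,
            "true_mip_tier1": 6, "true_mip_tier2": 3,
        }


class TestVerifyFixture:
    def test_default_fixture_has_no_violations(self, default_fixture):
        assert verify_fixture(default_fixture) == []

    def test_doctored_mip_listed_as_violation(self, default_fixture):
        fx = default_fixture
        victim = fx.truth.of_class("true_mip_tier1")[0]
        rng = random.Random(0)
        doctored = Proteome(
            rec
            if rec.id != victim
            else ProteinRecord(
                id=rec.id,
                sequence="".join(rng.choice(AMINO_ACIDS) for _ in range(len(rec))),
            )
            for rec in fx.proteome
        )
        broken = dataclasses.replace(fx, proteome=doctored)
        violations = verify_fixture(broken)
        assert any(v.startswith(f"{victim}:") for v in violations)

    def test_zero_mips_yields_empty_violations(self):
        spec = _spec(
            mips_per_family=0,
            decoy_counts={
                "dbd_retaining": 1, "oversized_paralog": 1,
                "foreign_domain": 1, "unrelated_random": 1, "tier2_distant": 0,
            },
        )
        assert verify_fixture(generate_fixture(spec)) == []


class TestInfeasibleSpecs:
    def test_mip_range_too_short_rejected_before_generation(self):
        with pytest.raises(ValueError):
            _spec(mip_length_range=(10, 20))

    def test_mip_range_must_stay_below_550(self):
        with pytest.raises(ValueError):
            _spec(mip_length_range=(80, 600))

    def test_rates_must_be_probabilities(self):
        with pytest.raises(ValueError):
            _spec(mutation_rate=1.5)


class TestFixtureIO:
    def test_write_read_round_trip(self, default_fixture, tmp_path):
        write_fixture(default_fixture, tmp_path / "fx")
        back = read_fixture(tmp_path / "fx")
        assert back.proteome == default_fixture.proteome
        assert back.tfs == default_fixture.tfs
        assert back.unwanted == default_fixture.unwanted
        assert back.library == default_fixture.library
        assert back.truth.labels == default_fixture.truth.labels
        assert back.truth.expected_targets == default_fixture.truth.expected_targets

    def test_truth_round_trip(self, default_fixture, tmp_path):
        path = tmp_path / "truth.tsv"
        write_truth(default_fixture.truth, path)
        back = read_truth(path)
        assert back.labels == default_fixture.truth.labels
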