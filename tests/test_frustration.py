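import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import frustmap as fm
from frustmap.energy import Contact
from frustmap.frustration import (
    HIGHLY_FRUSTRATED,
    MINIMALLY_FRUSTRATED,
    NEUTRAL,
    DegenerateDecoyError,
    FrustrationRecord,
    Thresholds,
    classify,
    frustration_histogram,
    residue_frustration,
    z_from_ensemble,
)

from _oracles import exhaustive_mutational_z, mc_standard_error
from conftest import make_chain, make_profile


class TestClassify:
    @pytest.mark.parametrize(
        "z,expected",
        [
            (0.78, MINIMALLY_FRUSTRATED),   # boundary inclusive
            (2.5, MINIMALLY_FRUSTRATED),
            (0.779, NEUTRAL),
            (0.0, NEUTRAL),
            (-1.0, NEUTRAL),                # strictly below −1 only
            (-1.2, HIGHLY_FRUSTRATED),
            (-4.0, HIGHLY_FRUSTRATED),
        ],
    )
    def test_threshold_boundaries(self, z, expected):
        assert classify(z) == expected

    @settings(deadline=None, derandomize=True)
    @given(z=st.floats(-10, 10, allow_nan=False))
    def test_every_value_gets_exactly_one_class(self, z):
        assert classify(z) in (MINIMALLY_FRUSTRATED, NEUTRAL, HIGHLY_FRUSTRATED)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify(float("nan"))

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError, match="ordered"):
            Thresholds(minimal=-2.0, frustrated=-1.0, highlight=0.0).validate()


class TestZScore:
    def test_native_at_decoy_mean_scores_zero(self):
        assert z_from_ensemble(1.3, 1.3, 0.7) == pytest.approx(0.0)

    def test_stabilising_native_is_positive(self):
        # decoy mean 0, sd 1, native −0.78 → index +0.78 → minimally frustrated
        z = z_from_ensemble(-0.78, 0.0, 1.0)
        assert z == pytest.approx(0.78)
        assert classify(z) == MINIMALLY_FRUSTRATED

    def test_zero_spread_raises(self):
        with pytest.raises(DegenerateDecoyError):
            z_from_ensemble(1.0, 1.0, 0.0)


class TestResidueAggregation:
    def _rec(self, i, j, z):
        return FrustrationRecord(
            contact=Contact(i=i, j=j, distance=5.0, native_energy=0.0),
            z_score=z,
            class_label=classify(z),
        )

    def test_mean_of_incident_contacts(self):
        chain = make_chain([(0, 0, 0), (5, 0, 0), (10, 0, 0)], "AAA")
        recs = [self._rec(1, 2, 1.0), self._rec(1, 3, 3.0)]
        idx = residue_frustration(recs, chain)
        assert idx[1] == pytest.approx(2.0)  # mean of +1 and +3
        assert idx[2] == pytest.approx(1.0)  # singleton
        assert idx[3] == pytest.approx(3.0)

    def test_contactless_residues_absent(self):
        chain = make_chain([(0, 0, 0), (5, 0, 0), (10, 0, 0)], "AAA")
        idx = residue_frustration([self._rec(1, 2, 0.0)], chain)
        assert 3 not in idx

    def test_zero_scores_propagate(self):
        chain = make_chain([(0, 0, 0), (5, 0, 0), (10, 0, 0)], "AAA")
        recs = [self._rec(1, 2, 0.0), self._rec(2, 3, 0.0)]
        assert all(v == 0.0 for v in residue_frustration(recs, chain).values())

    def test_unknown_endpoint_rejected(self):
        chain = make_chain([(0, 0, 0), (5, 0, 0)], "AA")
        with pytest.raises(KeyError):
            residue_frustration([self._rec(1, 99, 0.0)], chain)


class TestProfileStructure:
    def test_deterministic_under_fixed_seed(self, designed30, potential):
        p1 = fm.profile_structure(designed30, scheme="mutational", n_decoys=500,
                                  seed=1, potential=potential)
        p2 = fm.profile_structure(designed30, scheme="mutational", n_decoys=500,
                                  seed=1, potential=potential)
        assert [r.z_score for r in p1.contact_records] == [
            r.z_score for r in p2.contact_records
        ]
        assert p1.residue_index == p2.residue_index

    def test_seed_change_stays_within_sampling_error(self, designed30, potential):
        n = 2000
        p1 = fm.profile_structure(designed30, scheme="mutational", n_decoys=n,
                                  seed=1, potential=potential)
        p2 = fm.profile_structure(designed30, scheme="mutational", n_decoys=n,
                                  seed=2, potential=potential)
        bad = 0
        for r1, r2 in zip(p1.contact_records, p2.contact_records):
            se = mc_standard_error(r1.z_score, n)
            if abs(r1.z_score - r2.z_score) > 3 * np.sqrt(2) * se:
                bad += 1
        assert bad <= max(1, int(0.01 * len(p1.contact_records)))

    def test_uniform_composition_is_degenerate(self, potential):
        uniform = fm.generate_structure(
            fm.ToyFoldSpec(30, "helix_bundle", "uniform", "constant", 0), potential
        )
        with pytest.raises(DegenerateDecoyError):
            fm.profile_structure(uniform, scheme="mutational", n_decoys=100,
                                 seed=0, potential=potential)

    def test_too_short_chain_rejected(self, potential):
        chain = make_chain([(k * 4.0, 0, 0) for k in range(10)], "ILVAFMKEST")
        with pytest.raises(ValueError, match=">= 20 residues"):
            fm.profile_structure(chain, potential=potential)

    def test_every_contacted_residue_has_an_index(self, designed30, potential):
        prof = fm.profile_structure(designed30, n_decoys=200, seed=0,
                                    potential=potential)
        touched = {sid for r in prof.contact_records for sid in (r.contact.i, r.contact.j)}
        assert touched == set(prof.residue_index)

    def test_class_counts_partition_contacts(self, designed30, potential):
        prof = fm.profile_structure(designed30, n_decoys=200, seed=0,
                                    potential=potential)
        fractions = prof.class_fractions()
        assert sum(fractions.values()) == pytest.approx(1.0)


class TestOracleEquivalence:
    def test_sampled_matches_exhaustive_enumeration(self, designed30, potential):
        """Mutational Z-scores converge to the composition-weighted
        enumeration over all identity pairs."""
        cm = fm.build_contact_map(designed30, potential=potential)
        n = 20_000
        bad = 0
        for c in cm.contacts:
            rec = fm.contact_frustration(
                c, designed30, cm, scheme="mutational", n_decoys=n,
                rng_seed=11, potential=potential,
            )
            z_exact = exhaustive_mutational_z(c, designed30, potential)
            if abs(rec.z_score - z_exact) > 3 * mc_standard_error(z_exact, n):
                bad += 1
        assert bad <= max(1, int(0.01 * len(cm)))


class TestAffineInvariance:
    @pytest.mark.parametrize("scale,shift", [(3.7, 0.0), (1.0, 5.0), (3.7, 5.0)])
    def test_zscores_unchanged_by_affine_energy_map(self, designed30, potential,
                                                    scale, shift):
        base = fm.profile_structure(designed30, scheme="configurational",
                                    n_decoys=300, seed=7, potential=potential)
        mapped = fm.profile_structure(designed30, scheme="configurational",
                                      n_decoys=300, seed=7, potential=potential,
                                      energy_scale=scale, energy_shift=shift)
        z0 = np.array([r.z_score for r in base.contact_records])
        z1 = np.array([r.z_score for r in mapped.contact_records])
        assert np.max(np.abs(z0 - z1)) < 1e-9


class TestHistogram:
    def test_counting(self):
        prof = make_profile({1: 0.5, 2: 0.5, 3: -1.5})
        h = frustration_histogram([prof], bin_width=1.0)
        row = h[(h.bin_left == 0.0)].iloc[0]
        assert row["count"] == 2
        row = h[(h.bin_left == -2.0)].iloc[0]
        assert row["count"] == 1

    def test_spans_at_least_minus4_plus4(self):
        h = frustration_histogram([make_profile({1: 0.0})], bin_width=0.5)
        assert h.bin_left.min() <= -4.0 and h.bin_right.max() >= 4.0

    def test_frequencies_normalised(self, designed30, potential):
        prof = fm.profile_structure(designed30, n_decoys=200, seed=0,
                                    potential=potential)
        h = frustration_histogram([prof])
        assert h.frequency.sum() == pytest.approx(1.0, abs=1e-9)

    def test_pooling_doubles_counts(self):
        prof = make_profile({1: 0.5, 2: -0.5, 3: 2.0})
        h1 = frustration_histogram([prof], 0.5)
        h2 = frustration_histogram([prof, prof], 0.5)
        assert (h2["count"].values == 2 * h1["count"].values).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            frustration_histogram([])
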