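"""Ground-truth recovery from the synthetic EEG and cohort generators."""

import numpy as np
import pytest

from plinet.cohort import IMPAIRMENT_THRESHOLD
from plinet.connectivity import mean_pli, pli_matrix
from plinet.montage import CANONICAL_16
from plinet.preprocessing import (bandpass_phase, rereference_average,
                                  segment_epochs, select_montage)
from plinet.stats import kendall_tau_b
from plinet.synthetic import (CohortSpec, CouplingSpec, generate_cohort,
                              generate_coupled_eeg, generate_followup,
                              generate_norms, raw_scores_from_domains)


def pipeline_matrix(rec, band="alpha", epoch=0, reref=True):
    r = select_montage(rec)
    if reref:
        r = rereference_average(r)
    ph = bandpass_phase(segment_epochs(r), band)
    return pli_matrix(ph, epoch)


def pair_value(cm, a, b):
    labels = cm.channel_labels
    return cm.values[labels.index(a), labels.index(b)]


class TestCouplingSpecValidation:
    def test_unknown_label_rejected(self):
        spec = CouplingSpec(node_pairs=[("T5", "XX")])
        with pytest.raises(ValueError, match="XX"):
            spec.validate()

    def test_zero_lag_rejected(self):
        spec = CouplingSpec(node_pairs=[("T5", "P3")], phase_lag=0.0)
        with pytest.raises(ValueError, match="nonzero"):
            spec.validate()

    def test_strength_out_of_range_rejected(self):
        spec = CouplingSpec(node_pairs=[("T5", "P3")], coupling_strength=1.2)
        with pytest.raises(ValueError, match=r"\[0,1\]"):
            spec.validate()

    def test_too_short_recording_reports_minimum(self):
        spec = CouplingSpec(node_pairs=[("T5", "P3")])
        with pytest.raises(ValueError, match="20480"):
            generate_coupled_eeg(spec, duration_s=10.0, min_samples=5 * 4096)


class TestCoupledEeg:
    def test_deterministic_constant_lag_gives_exact_pli_one(self):
        spec = CouplingSpec(node_pairs=[("T5", "P3")], phase_lag=np.pi / 4,
                            coupling_strength=1.0, noise_sd=0.0, seed=3)
        cm = pipeline_matrix(generate_coupled_eeg(spec))
        assert abs(pair_value(cm, "T5", "P3") - 1.0) < 1e-9

    def test_no_coupling_matches_null_level(self):
        # strength 0 everywhere: mean PLI at the independent-noise level
        spec = CouplingSpec(node_pairs=[("T5", "P3")], coupling_strength=0.0,
                            noise_sd=1.0, seed=4)
        cm = pipeline_matrix(generate_coupled_eeg(spec))
        null_sigma = np.sqrt(2 / (np.pi * 2 * 2.0 * 8.192))
        assert pair_value(cm, "T5", "P3") < 3 * null_sigma
        assert mean_pli(cm) < 2 * null_sigma

    def test_recording_shape_and_labels(self):
        spec = CouplingSpec(node_pairs=[("T5", "P3")], seed=0)
        rec = generate_coupled_eeg(spec, duration_s=41.0, fs=500.0)
        assert rec.channel_labels == CANONICAL_16
        assert rec.n_samples == 20500

    def test_seed_reproducibility(self):
        spec = CouplingSpec(node_pairs=[("T5", "P3")], seed=5)
        r1 = generate_coupled_eeg(spec)
        r2 = generate_coupled_eeg(spec)
        np.testing.assert_array_equal(r1.data, r2.data)

    def test_planted_edge_set_recovered_at_high_strength(self):
        # strength 0.9, noise 0.5: thresholding PLI at 0.5 recovers the
        # planted pairs (validated on the generated phases; the
        # structural check precedes montage re-referencing)
        pairs = [("T5", "P3"), ("F3", "F7"), ("O2", "T6")]
        planted = {tuple(sorted(p)) for p in pairs}
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            spec = CouplingSpec(node_pairs=pairs, phase_lag=np.pi / 3,
                                coupling_strength=0.9, noise_sd=0.5,
                                band_center_hz=10.0, seed=seed)
            cm = pipeline_matrix(generate_coupled_eeg(spec), reref=False)
            found = {tuple(sorted((CANONICAL_16[i], CANONICAL_16[j])))
                     for i in range(16) for j in range(i + 1, 16)
                     if cm.values[i, j] > 0.5}
            hits += found == planted
        assert hits >= 0.9 * n_seeds


class TestCohortGeneration:
    def test_null_taus_stay_small_at_large_n(self):
        cohort = generate_cohort(CohortSpec(n_patients=1000, n_controls=3,
                                            seed=1))
        pat = cohort[cohort.group == "patient"]
        for metric in ("Diam_theta", "SWI_alpha", "pli_mean_theta"):
            for domain in ("word_retrieval", "writing"):
                tau = kendall_tau_b(pat[metric], pat[f"z_{domain}"]).statistic
                assert abs(tau) < 0.08

    def test_comonotone_pair_gives_tau_one(self):
        cohort = generate_cohort(CohortSpec(
            n_patients=50, n_controls=3, seed=2,
            planted_tau={("Diam_theta", "word_retrieval"): 1.0}))
        pat = cohort[cohort.group == "patient"]
        tau = kendall_tau_b(pat["Diam_theta"], pat["z_word_retrieval"])
        assert tau.statistic == pytest.approx(1.0)

    def test_planted_tau_converges(self):
        cohort = generate_cohort(CohortSpec(
            n_patients=2000, n_controls=3, seed=3,
            planted_tau={("Diam_theta", "word_retrieval"): 0.5}))
        pat = cohort[cohort.group == "patient"]
        tau = kendall_tau_b(pat["Diam_theta"], pat["z_word_retrieval"])
        assert abs(tau.statistic - 0.5) < 0.05

    def test_impairment_fraction_exact_count(self):
        # 0.6 of 15 patients -> exactly 9 impaired
        cohort = generate_cohort(CohortSpec(n_patients=15, n_controls=15,
                                            impairment_fraction=0.6, seed=4))
        pat = cohort[cohort.group == "patient"]
        zcols = [c for c in cohort.columns if c.startswith("z_")]
        n_impaired = int((pat[zcols].min(axis=1)
                          <= IMPAIRMENT_THRESHOLD).sum())
        assert n_impaired == 9
        assert int(pat["impaired"].sum()) == 9

    def test_impairment_shift_preserves_planted_tau(self):
        spec = CohortSpec(n_patients=500, n_controls=3, seed=5,
                          planted_tau={("Diam_theta", "word_retrieval"): 0.6},
                          impairment_fraction=0.9)
        pat = generate_cohort(spec).query("group == 'patient'")
        tau = kendall_tau_b(pat["Diam_theta"], pat["z_word_retrieval"])
        assert abs(tau.statistic - 0.6) < 0.08

    def test_infeasible_tau_matrix_reported(self):
        # two metrics strongly coupled to two domains with contradictory
        # signs: the implied latent correlation matrix is not PSD
        spec = CohortSpec(n_patients=10, n_controls=3, seed=6, planted_tau={
            ("Diam_theta", "word_retrieval"): 0.95,
            ("Diam_theta", "writing"): 0.95,
            ("Ecc_theta", "word_retrieval"): 0.95,
            ("Ecc_theta", "writing"): -0.95,
        })
        with pytest.raises(ValueError, match="positive semi-definite"):
            generate_cohort(spec)

    def test_unknown_metric_or_domain_rejected(self):
        with pytest.raises(ValueError, match="metric"):
            generate_cohort(CohortSpec(
                planted_tau={("bogus_theta", "writing"): 0.5}))
        with pytest.raises(ValueError, match="domain"):
            generate_cohort(CohortSpec(
                planted_tau={("Diam_theta", "bogus"): 0.5}))

    def test_followup_drops_patients_and_keeps_schema(self):
        cohort = generate_cohort(CohortSpec(n_patients=15, n_controls=15,
                                            seed=7))
        t2 = generate_followup(cohort, n_dropout=2, seed=8)
        assert len(t2) == 13
        assert (t2["timepoint"] == "T2").all()
        assert set(t2.columns) == set(cohort.columns)


class TestNorms:
    def test_single_test_norm(self):
        norms = generate_norms(["object_naming"])
        mean, sd = norms.norms["object_naming"]
        assert sd > 0

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            generate_norms(["reading", "reading"])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            generate_norms([])

    def test_z_identity_and_boundary(self):
        norms = generate_norms(["object_naming"], seed=1)
        mean, sd = norms.norms["object_naming"]
        assert norms.z("object_naming", mean) == 0.0
        assert norms.z("object_naming", mean - 1.5 * sd) == pytest.approx(-1.5)

    def test_raw_scores_round_trip_domain_z(self):
        from plinet.cohort import DEFAULT_DOMAIN_MAP, score_language
        full_tests = [t for ts in DEFAULT_DOMAIN_MAP.values() for t in ts]
        norms = generate_norms(full_tests, seed=2)
        domain_z = {"word_retrieval": -1.7, "phonology": 0.3,
                    "semantics": 0.0, "grammar": -0.2,
                    "comprehension_auditory": 0.1,
                    "comprehension_visual": 0.4, "reading": -0.5,
                    "writing": -1.0}
        raw = raw_scores_from_domains(domain_z, norms)
        prof = score_language(raw, norms)
        for dom, z in domain_z.items():
            assert prof.domain_z[dom] == pytest.approx(z)
        assert prof.impaired
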