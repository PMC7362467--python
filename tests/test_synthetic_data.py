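"""Synthetic-cohort generator: determinism, invariants and planted structure."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from rheumqc.chemometrics import spearman_rho, ttest_two_group
from rheumqc.synthetic_data import (
    COMPOUNDS,
    FREE_ANTHRAQUINONES,
    GLYCOSIDES,
    POLYPHENOLS,
    CohortSpec,
    generate_bioassay,
    generate_cohort,
    generate_compounds,
    generate_dl,
    generate_peaks,
)


def test_compound_panel_is_fifteen_in_three_classes():
    assert len(COMPOUNDS) == 15
    assert len(FREE_ANTHRAQUINONES) == 5
    assert len(GLYCOSIDES) == 8
    assert len(POLYPHENOLS) == 2


def test_full_determinism():
    a = generate_cohort(CohortSpec.commercial_default(9))
    b = generate_cohort(CohortSpec.commercial_default(9))
    pd.testing.assert_frame_equal(a.compounds, b.compounds)
    pd.testing.assert_frame_equal(a.peak_tables, b.peak_tables)
    pd.testing.assert_frame_equal(a.defecation, b.defecation)
    assert all(
        np.array_equal(x.counts, y.counts) for x, y in zip(a.dl_curves, b.dl_curves)
    )
    c = generate_cohort(CohortSpec.commercial_default(10), simulate_curves=False)
    assert not a.compounds.equals(c.compounds)


def test_class_totals_are_exact_member_sums(commercial_cohort_nocurves):
    co = commercial_cohort_nocurves
    assert np.allclose(
        co.class_totals["glycoside_total"], co.compounds[list(GLYCOSIDES)].sum(axis=1)
    )
    assert np.allclose(
        co.class_totals["free_anthraquinone_total"],
        co.compounds[list(FREE_ANTHRAQUINONES)].sum(axis=1),
    )


def test_generated_artifacts_satisfy_type_invariants(commercial_cohort):
    co = commercial_cohort
    assert (co.compounds.to_numpy() > 0).all()
    assert (co.dl_truth[["I0", "Tau", "Beta", "T"]].to_numpy() > 0).all()
    assert len(co.dl_curves) == 28 * 3
    for curve in co.dl_curves[:6]:
        assert curve.n_bins == 600
        assert (curve.counts >= 0).all()
    prop = co.propulsion
    assert (prop["distance_cm"] <= prop["length_cm"]).all()


def test_null_effect_rejects_at_alpha():
    """With no planted group difference the glycoside-total t test rejects
    at about the nominal 5% level."""
    means = {c: (3.0, 3.0) for c in COMPOUNDS}
    rejections = 0
    n_rep = 200
    for seed in range(n_rep):
        spec = dataclasses.replace(
            CohortSpec(), compound_means=means, n_spike_glycosides=0, seed=seed
        )
        rng = np.random.default_rng(spec.seed)
        compounds, totals, groups, _ = generate_compounds(spec, rng)
        g = totals["glycoside_total"]
        p = ttest_two_group(g[groups == "A"], g[groups == "B"])[2]
        rejections += p < 0.05
    assert rejections / n_rep < 0.12


def test_planted_effect_power():
    """The default planted glycoside effect is detected in essentially every
    cohort draw."""
    hits = 0
    for seed in range(20):
        spec = CohortSpec.commercial_default(seed)
        rng = np.random.default_rng(seed)
        _, totals, groups, _ = generate_compounds(spec, rng)
        g = totals["glycoside_total"]
        p = ttest_two_group(g[groups == "A"], g[groups == "B"])[2]
        hits += (p < 0.05) and (g[groups == "B"].mean() > g[groups == "A"].mean())
    assert hits >= 19


class TestDLGeneration:
    def test_zero_noise_gives_perfect_negative_rank_link(self):
        spec = dataclasses.replace(
            CohortSpec(),
            dl_link={"I0": (9000.0, 1600.0, 0.0), "Tau": (0.62, 0.11, 0.0), "Beta": (2.6, 0.20, 0.0)},
            seed=4,
        )
        rng = np.random.default_rng(4)
        compounds, totals, _, _ = generate_compounds(spec, rng)
        dl_truth, _ = generate_dl(spec, compounds, rng, simulate_curves=False)
        g = totals["glycoside_total"].to_numpy()
        assert spearman_rho(g, dl_truth["Tau"].to_numpy()) == pytest.approx(-1.0)
        assert spearman_rho(g, dl_truth["T"].to_numpy()) == pytest.approx(-1.0)

    def test_zero_slope_no_link(self):
        spec = dataclasses.replace(
            CohortSpec(),
            dl_link={"I0": (3000.0, 0.0, 300.0), "Tau": (0.3, 0.0, 0.03), "Beta": (1.5, 0.0, 0.15)},
            seed=5,
        )
        rng = np.random.default_rng(5)
        compounds, totals, _, _ = generate_compounds(spec, rng)
        dl_truth, _ = generate_dl(spec, compounds, rng, simulate_curves=False)
        g = totals["glycoside_total"].to_numpy()
        rhos = [abs(spearman_rho(g, dl_truth[p].to_numpy())) for p in ("I0", "Tau", "Beta")]
        assert max(rhos) < 0.5  # no planted link beyond chance


class TestPeakGeneration:
    def test_zero_noise_relative_areas_proportional_to_concentrations(self):
        spec = dataclasses.replace(
            CohortSpec(), peak_noise_sd=0.0, rt_jitter_sd=0.0, calibration_slope=1.0, seed=6
        )
        rng = np.random.default_rng(6)
        compounds, _, _, _ = generate_compounds(spec, rng)
        peaks = generate_peaks(spec, compounds, rng)
        s0 = compounds.index[0]
        sub = peaks[peaks.sample_id == s0].set_index("peak_id")
        from rheumqc.synthetic_data import DEFAULT_PEAK_MAP, REFERENCE_PEAK

        ref_area = sub.loc[REFERENCE_PEAK, "area"]
        for comp, pid in DEFAULT_PEAK_MAP.items():
            assert sub.loc[pid, "area"] / ref_area == pytest.approx(
                compounds.at[s0, comp] / (spec.baseline_area * 1.2), rel=1e-12
            )

    def test_duplicated_samples_have_cosine_one(self):
        from rheumqc.fingerprint import build_common_peak_matrix, relative_quantities, similarity
        from rheumqc.pipeline import _peak_tables_from_frame

        spec = dataclasses.replace(CohortSpec(), peak_noise_sd=0.0, rt_jitter_sd=0.0, seed=7)
        rng = np.random.default_rng(7)
        compounds, _, _, _ = generate_compounds(spec, rng)
        compounds.iloc[1] = compounds.iloc[0]
        peaks = generate_peaks(spec, compounds, rng)
        vecs = relative_quantities(
            build_common_peak_matrix(_peak_tables_from_frame(peaks))
        )
        by_id = {v.sample_id: v for v in vecs}
        ids = list(compounds.index[:2])
        assert similarity(by_id[ids[0]], by_id[ids[1]]) == pytest.approx(1.0, abs=1e-12)

    def test_rsi_grouping_tracks_true_labels(self, commercial_cohort_nocurves):
        from rheumqc.fingerprint import build_common_peak_matrix, relative_quantities, similarity_matrix
        from rheumqc.pipeline import _peak_tables_from_frame

        co = commercial_cohort_nocurves
        sim = similarity_matrix(
            relative_quantities(
                build_common_peak_matrix(_peak_tables_from_frame(co.peak_tables))
            )
        )
        is_b = (co.group_labels.loc[list(sim.sample_ids)] == "B").astype(float).to_numpy()
        assert spearman_rho(sim.rsi, is_b) < 0  # glycoside-rich group scores lower


class TestBioassayGeneration:
    def test_zero_probability_no_diarrhea(self):
        spec = dataclasses.replace(
            CohortSpec(),
            control_p_loose=0.0,
            diarrhea_logit={"S10": (-50.0, 0.0), "S22": (-50.0, 0.0)},
            seed=8,
        )
        defecation, _ = generate_bioassay(spec, np.random.default_rng(8))
        assert defecation["loose"].sum() == 0

    def test_high_dose_rate_matches_planted_probability(self):
        # logit chosen so p(loose | S22, dose 5) ~ 0.9
        spec = dataclasses.replace(
            CohortSpec(), diarrhea_logit={"S10": (-4.4, 0.8), "S22": (2.1972 - 5.0, 1.0)}, seed=0
        )
        rates = []
        for seed in range(150):
            defecation, _ = generate_bioassay(
                spec.with_seed(seed), np.random.default_rng(seed)
            )
            grp = defecation[defecation.group == "S22-High"]
            rates.append(100.0 * grp["loose"].mean())
        assert np.mean(rates) == pytest.approx(90.0, abs=4.0)

    def test_distances_never_exceed_lengths(self, commercial_cohort_nocurves):
        prop = commercial_cohort_nocurves.propulsion
        assert (prop["distance_cm"] <= prop["length_cm"]).all()
        assert (prop["distance_cm"] > 0).all()
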