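"""dcfs and Patterson's D: worked examples, hand-enumerated trees, oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcfs.coalsim import SampleConfig, simulate_replicates
from dcfs.demography import AdmixtureParams, build_clean_split_model
from dcfs.stats import (
    DCFS,
    GenotypeTable,
    branch_dcfs,
    branch_patterson_d,
    patterson_d_sites,
    r_squared,
    site_dcfs,
)
from dcfs.synthetic import ToyPanelSpec, ToySite, build_toy_panel

from conftest import manual_genealogy


class TestSiteDCFS:
    def test_worked_example_lands_in_class_three(self):
        """Chimp A, Neandertal G, African A, three Europeans carrying G."""
        panel = build_toy_panel(ToyPanelSpec(
            sites=[ToySite("A", "G", "A", derived_count=3)], nE=10))
        result = site_dcfs(panel)
        assert result.n_sites_used == 1
        np.testing.assert_array_equal(
            result.weights, [0, 0, 1, 0, 0, 0, 0, 0, 0, 0])

    @pytest.mark.parametrize("site", [
        ToySite("A", "A", "A", derived_count=3),  # Neandertal matches chimp
        ToySite("A", "G", "G", derived_count=3),  # African carries the derived allele
        ToySite("A", "G", "A", derived_count=0),  # absent from the European panel
    ])
    def test_conditioning_excludes_non_qualifying_sites(self, site):
        result = site_dcfs(build_toy_panel(ToyPanelSpec(sites=[site], nE=10)))
        assert result.n_sites_used == 0
        assert result.undefined

    def test_multiallelic_and_missing_sites_are_skipped_and_counted(self):
        panel = build_toy_panel(ToyPanelSpec(
            sites=[ToySite("A", "G", "A", 2), ToySite("A", "G", "C", 2)], nE=4))
        panel.data.loc[2] = panel.data.loc[0]
        panel.data.loc[2, "eur_3"] = "N"
        result = site_dcfs(GenotypeTable(panel.data))
        assert result.n_skipped == 2
        assert result.n_sites_used == 1

    def test_undefined_spectrum_has_no_proportions(self):
        result = site_dcfs(build_toy_panel(ToyPanelSpec(sites=[], nE=5)))
        assert result.undefined and result.proportions is None


class TestBranchDCFS:
    def test_caterpillar_enumeration(self):
        """(((N,E1),E2),A): one unit branch in class 1, one in class 2."""
        # nodes: 0=N 1=E1 2=E2 3=A, internal 4 (t=1), 5 (t=2), 6 (t=3)
        gen = manual_genealogy(
            node_times=[0, 0, 0, 0, 1.0, 2.0, 3.0],
            edges=[(4, 0), (4, 1), (5, 4), (5, 2), (6, 5), (6, 3)],
            roles=[1, 3, 3, 2],
        )
        result = branch_dcfs([gen], nE=2)
        np.testing.assert_allclose(result.weights, [1.0, 1.0])

    def test_african_inside_every_neandertal_clade_contributes_nothing(self):
        # ((N,A),(E1,E2)): the African joins the Neandertal first
        gen = manual_genealogy(
            node_times=[0, 0, 0, 0, 1.0, 1.0, 3.0],
            edges=[(4, 0), (4, 1), (5, 2), (5, 3), (6, 4), (6, 5)],
            roles=[1, 2, 3, 3],
        )
        result = branch_dcfs([gen], nE=2)
        assert result.weights.sum() == 0

    def test_null_model_matches_exchangeable_closed_form(self):
        """Panmictic clean split: class proportions follow (nE + 1 - i).

        For a fully exchangeable sample of 1 Neandertal + 1 African +
        nE Europeans, E[branch length subtending j leaves] ~ 1/j and
        counting configurations gives p_i proportional to (nE + 1 - i).
        """
        nE = 10
        p = AdmixtureParams(N_anc=10_000, N_afr=10_000, N_eur=10_000,
                            N_bottleneck=10_000, t_ooa=2_500, t_admix=1_000)
        demog = build_clean_split_model(p)
        sample = SampleConfig(n_european=nE)
        chunks = []
        for b in range(4):
            dc = branch_dcfs(simulate_replicates(demog, sample, 6_000, seed=600 + b))
            chunks.append(dc.proportions)
        chunks = np.array(chunks)
        mean = chunks.mean(axis=0)
        se = chunks.std(axis=0, ddof=1) / 2
        expected = np.arange(nE, 0, -1.0) + 0.0
        expected = (nE + 1 - np.arange(1, nE + 1)) / (nE * (nE + 1) / 2)
        assert np.all(np.abs(mean - expected) <= 3 * se + 1e-9)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            branch_dcfs([])


class TestPattersonDSites:
    def _panel(self, n_abba, n_baba, n_mono=0):
        rows = []
        for _ in range(n_abba):
            rows.append({"chimp_0": "A", "nea_0": "G", "afr_0": "A", "eur_0": "G"})
        for _ in range(n_baba):
            rows.append({"chimp_0": "A", "nea_0": "G", "afr_0": "G", "eur_0": "A"})
        for _ in range(n_mono):
            rows.append({"chimp_0": "A", "nea_0": "A", "afr_0": "A", "eur_0": "A"})
        import pandas as pd

        return GenotypeTable(pd.DataFrame(rows))

    def test_six_abba_two_baba_gives_half(self):
        assert patterson_d_sites(self._panel(6, 2)).d == pytest.approx(0.5)

    def test_balanced_panel_gives_zero(self):
        assert patterson_d_sites(self._panel(4, 4)).d == 0.0

    def test_monomorphic_panel_flagged_undefined(self):
        result = patterson_d_sites(self._panel(0, 0, n_mono=5))
        assert result.undefined and result.d is None

    def test_swapping_roles_flips_the_sign(self):
        table = self._panel(6, 2)
        swapped = GenotypeTable(table.data.rename(
            columns={"afr_0": "eur_0", "eur_0": "afr_0"}))
        assert patterson_d_sites(swapped).d == pytest.approx(-0.5)


class TestBranchPattersonD:
    def test_cherry_with_no_baba_branch_gives_one(self):
        # ((N,E),A): the cherry stem is pure ABBA weight
        gen = manual_genealogy(
            node_times=[0, 0, 0, 1.0, 3.0],
            edges=[(3, 0), (3, 1), (4, 3), (4, 2)],
            roles=[1, 3, 2],
        )
        assert branch_patterson_d([gen]).d == pytest.approx(1.0)

    def test_symmetric_demography_gives_zero_within_error(self):
        """African and European exchangeable: D ~ 0."""
        p = AdmixtureParams(N_afr=5_000, N_eur=5_000, N_bottleneck=5_000,
                            t_ooa=2_500, t_admix=1_000)
        demog = build_clean_split_model(p)
        sample = SampleConfig(n_european=1, neandertal_time=50_000.0)
        ds = []
        for b in range(5):
            stat = branch_patterson_d(
                simulate_replicates(demog, sample, 5_000, seed=700 + b))
            ds.append(stat.d)
        ds = np.array(ds)
        se = ds.std(ddof=1) / np.sqrt(len(ds))
        assert abs(ds.mean()) <= 3 * se


class TestRSquared:
    def test_perfect_prediction_is_hundred_percent(self):
        obs = DCFS.from_proportions([0.5, 0.3, 0.2])
        assert r_squared(obs, obs) == pytest.approx(100.0)

    def test_uniform_prediction_of_nonuniform_observation_is_zero(self):
        obs = DCFS.from_proportions([0.5, 0.3, 0.2])
        pred = DCFS.from_proportions([1 / 3] * 3)
        assert r_squared(pred, obs) == pytest.approx(0.0)

    def test_hand_computed_three_class_case(self):
        obs = DCFS.from_proportions([0.5, 0.3, 0.2])
        pred = DCFS.from_proportions([0.4, 0.4, 0.2])
        assert r_squared(pred, obs) == pytest.approx(100 * (1 - 0.02 / (7 / 150)),
                                                     abs=1e-9)

    def test_constant_observation_undefined(self):
        obs = DCFS.from_proportions([0.25] * 4)
        pred = DCFS.from_proportions([0.4, 0.3, 0.2, 0.1])
        assert r_squared(pred, obs) is None

    def test_pearson_variant_and_class_mismatch(self):
        obs = DCFS.from_proportions([0.5, 0.3, 0.2])
        pred = DCFS.from_proportions([0.45, 0.35, 0.2])
        assert 0 < r_squared(pred, obs, method="pearson") <= 100
        with pytest.raises(ValueError, match="mismatch"):
            r_squared(DCFS.from_proportions([0.5, 0.5]), obs)


@settings(deadline=None, max_examples=50)
@given(st.floats(0, 1e6), st.floats(0, 1e6))
def test_dstat_value_always_in_unit_interval(a, b):
    from dcfs.stats import DStat

    stat = DStat(a, b)
    if a + b > 0:
        assert -1.0 <= stat.d <= 1.0
        assert (stat.d > 0) == (a > b)
    else:
        assert stat.undefined


@settings(deadline=None, max_examples=50)
@given(st.lists(st.floats(0, 100), min_size=2, max_size=12).filter(lambda w: sum(w) > 0))
def test_dcfs_proportions_normalise(weights):
    dc = DCFS(np.array(weights), n_sites_used=sum(weights))
    assert dc.proportions.sum() == pytest.approx(1.0)
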