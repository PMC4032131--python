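"""Structural tests of the three demographic model builders."""

import dataclasses

import pytest

from dcfs.demography import (
    AdmixtureParams,
    DemographicEvent,
    DemographyValidationError,
    SpatialParams,
    TwoPopParams,
    build_admixture_model,
    build_clean_split_model,
    build_spatial_model,
    build_two_population_model,
    model_from_config,
    params_from_config,
    validate_demography,
)


class TestSpatialModel:
    def test_minimal_chain_has_single_ancestral_adjacency(self):
        # a 2-deme ancestral chain has exactly one adjacency
        demog = build_spatial_model(SpatialParams(k_demes=2))
        chain = {d.id for d in demog.demes if d.id.startswith(("nea_", "afr_"))}
        chain_edges = [e for e in demog.edges
                       if e.from_deme in chain and e.to_deme in chain]
        assert len(chain_edges) == 1

    def test_default_model_validates_cleanly(self):
        assert validate_demography(build_spatial_model(SpatialParams())) == []

    def test_neandertal_split_time_in_generations(self):
        # 320 ky at 25 y/generation
        demog = build_spatial_model(SpatialParams(generation_time=25.0))
        split = [e for e in demog.events if e.kind == "chain_split"]
        assert len(split) == 1
        assert split[0].time == pytest.approx(12_800.0)

    def test_eight_free_parameters(self):
        demog = build_spatial_model(SpatialParams())
        assert demog.n_free_parameters == 8
        assert set(demog.free_parameters) == {
            "k_demes", "N_anc", "m0", "N_mod", "m",
            "t_modern", "t_exit", "founder_size"}

    @pytest.mark.parametrize("bad,field", [
        (dict(t_exit=200_000.0), "t_exit < t_modern"),
        (dict(t_modern=400_000.0), "t_modern < t_neandertal_split"),
        (dict(founder_size=0.0), "founder_size"),
        (dict(k_demes=1), "k_demes"),
    ])
    def test_invalid_params_name_the_violated_inequality(self, bad, field):
        with pytest.raises(DemographyValidationError, match=field.split()[0]):
            build_spatial_model(SpatialParams(**bad))

    def test_serial_colonisation_is_ordered(self):
        demog = build_spatial_model(SpatialParams(n_eurasian_demes=4))
        founds = sorted((e.time, e.payload["deme"]) for e in demog.events
                        if e.kind == "range_expansion")
        # backward time: the deme farthest from Africa was founded last
        assert [d for _, d in founds] == ["eur_3", "eur_2", "eur_1", "eur_0"]

    def test_events_sorted_by_time_in_table(self):
        table = build_spatial_model(SpatialParams()).event_table()
        assert table["time_generations"].is_monotonic_increasing


class TestTwoPopModel:
    def test_symmetric_construction_is_exchangeable(self):
        p = TwoPopParams(N_afr=8000.0, N_eur=8000.0)
        demog = build_two_population_model(p)
        afr = demog.deme("afr")
        eur = demog.deme("eur")
        assert afr.size == eur.size
        (edge,) = demog.edges
        assert {edge.from_deme, edge.to_deme} == {"afr", "eur"}

    def test_post_ooa_migration_must_decrease(self):
        warnings = TwoPopParams(m_high=1e-4, m_low=1e-4).validation_warnings()
        assert len(warnings) == 1 and "decrease" in warnings[0]
        assert TwoPopParams().validation_warnings() == []

    def test_single_neandertal_deme(self):
        demog = build_two_population_model(TwoPopParams())
        assert [d.id for d in demog.demes if d.label == "neandertal"] == ["nea"]

    def test_time_ordering_enforced(self):
        with pytest.raises(DemographyValidationError, match="t_ooa"):
            build_two_population_model(TwoPopParams(t_ooa=350_000.0))


class TestAdmixtureModel:
    def test_zero_pulse_identical_to_clean_split(self):
        p = AdmixtureParams(f=0.0)
        admix = build_admixture_model(p)
        clean = build_clean_split_model(p)
        assert admix.events == clean.events
        assert [dataclasses.astuple(d) for d in admix.demes] == \
               [dataclasses.astuple(d) for d in clean.demes]

    def test_full_pulse_moves_all_eurasian_lineages(self):
        demog = build_admixture_model(AdmixtureParams(f=1.0))
        pulse = [e for e in demog.events if e.kind == "mass_migration"]
        assert len(pulse) == 1
        assert pulse[0].payload == {"deme": "eur", "dest": "nea", "f": 1.0}

    def test_fraction_outside_unit_interval_rejected(self):
        for f in (-0.1, 1.5):
            with pytest.raises(DemographyValidationError, match="f in"):
                build_admixture_model(AdmixtureParams(f=f))

    def test_nine_free_parameters(self):
        demog = build_admixture_model(AdmixtureParams(f=0.02))
        assert demog.n_free_parameters == 9


class TestValidateDemography:
    def test_negative_deme_size_names_the_deme(self):
        demog = build_spatial_model(SpatialParams())
        demog.demes[2].size = -5.0
        issues = validate_demography(demog)
        assert len(issues) == 1
        assert demog.demes[2].id in issues[0]

    def test_event_touching_merged_deme_flagged(self):
        demog = build_two_population_model(TwoPopParams())
        t_struct = demog.params.t_structure / demog.generation_time
        demog.events.append(DemographicEvent(
            time=t_struct + 100.0, kind="parameter_change",
            payload={"demes": ["eur"], "rate": 1e-4}))
        issues = validate_demography(demog)
        assert len(issues) == 1 and "merged away" in issues[0]

    def test_unknown_deme_in_edge_flagged(self):
        demog = build_two_population_model(TwoPopParams())
        demog.edges[0].to_deme = "ghost"
        assert any("ghost" in issue for issue in validate_demography(demog))

    def test_outgroup_split_must_be_deepest(self):
        demog = build_two_population_model(TwoPopParams())
        demog.events.append(DemographicEvent(
            time=demog.outgroup_split_time + 1.0, kind="parameter_change",
            payload={}))
        assert any("deepest" in issue for issue in validate_demography(demog))


class TestConfigInterface:
    def test_years_and_generations_agree(self):
        years = {"model": "spatial", "units": "years", "t_exit": 50_000.0}
        gens = {"model": "spatial", "units": "generations", "t_exit": 2_000.0}
        _, p1 = params_from_config(years)
        _, p2 = params_from_config(gens)
        assert p1 == p2

    def test_unknown_model_and_fields_rejected(self):
        with pytest.raises(DemographyValidationError, match="model"):
            params_from_config({"model": "island", "units": "years"})
        with pytest.raises(DemographyValidationError, match="units"):
            params_from_config({"model": "spatial"})
        with pytest.raises(DemographyValidationError, match="unknown param"):
            params_from_config({"model": "spatial", "units": "years", "zeta": 1})

    def test_model_from_config_builds_and_validates(self):
        demog = model_from_config(
            {"model": "two_pop", "units": "years", "m_high": 2e-4})
        assert demog.kind == "two_pop"
        assert demog.validate() == []
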