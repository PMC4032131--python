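"""Demographic models: stepping-stone chain, two-population structure, admixture.

Three families of history for the chimp / Neandertal / African / European
panel, all expressed as time-inhomogeneous deme graphs and compiled to
:class:`msprime.Demography` for simulation.  Times in the parameter
dataclasses are **years before present**; the compiled graphs and the
event tables are in **generations** (``time / generation_time``).  All
population sizes are diploid individuals.

Forward-time reading of the spatial model (the package's centrepiece):
a linear chain of ``k_demes`` demes of size ``N_anc`` exchanges nearest
neighbour migrants at rate ``m0``.  At the Neandertal split (320 kya,
fixed) the chain is cut between the Neandertal segment at one end and
the African segment, with no change in sizes or rates.  At ``t_modern``
the African demes become anatomically modern: size ``N_mod``, migration
``m``.  At ``t_exit`` modern humans expand into Eurasia from the African
deme closest to the old Neandertal range, founding Eurasian demes
serially with ``founder_size`` founders each; migration within the
modern human range stays at ``m`` throughout, so the Africa/Eurasia
separation is produced by the range expansion alone, not by a rate
change.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Optional

import msprime
import pandas as pd

__all__ = [
    "DEFAULT_GENERATION_TIME",
    "NEANDERTAL_SPLIT_YEARS",
    "DEFAULT_OUTGROUP_SPLIT_YEARS",
    "Deme",
    "MigrationEdge",
    "DemographicEvent",
    "Demography",
    "DemographyValidationError",
    "SpatialParams",
    "TwoPopParams",
    "AdmixtureParams",
    "build_spatial_model",
    "build_two_population_model",
    "build_admixture_model",
    "build_clean_split_model",
    "validate_demography",
    "params_from_config",
    "model_from_config",
]

#: Conventional human generation time (years); configurable per model.
DEFAULT_GENERATION_TIME = 25.0
#: Neandertal speciation time, held fixed across the spatial sweep (years).
NEANDERTAL_SPLIT_YEARS = 320_000.0
#: Chimpanzee (outgroup) divergence, held fixed (years).
DEFAULT_OUTGROUP_SPLIT_YEARS = 6_000_000.0

_EVENT_KIND_RANK = {
    "deme_merge": 0,
    "parameter_change": 1,
    "range_expansion": 2,
    "mass_migration": 3,
    "chain_split": 4,
}


class DemographyValidationError(ValueError):
    """Raised when model parameters violate a structural invariant."""


@dataclass
class Deme:
    """One population in the deme graph (size = diploid individuals)."""

    id: str
    size: float
    label: str  # ancestral | neandertal | african | eurasian | chimp-stem


@dataclass
class MigrationEdge:
    """Symmetric nearest-neighbour adjacency with its initial backward rate."""

    from_deme: str
    to_deme: str
    rate: float


@dataclass
class DemographicEvent:
    """High-level event in the history, time in generations before present."""

    time: float
    kind: str  # chain_split | parameter_change | range_expansion | mass_migration | deme_merge
    payload: dict = field(default_factory=dict)

    def sort_key(self):
        return (self.time, _EVENT_KIND_RANK.get(self.kind, 99), str(self.payload.get("deme", "")))


@dataclass
class Demography:
    """A compiled demographic model.

    Wraps the :class:`msprime.Demography` actually simulated together
    with an explicit record of demes, migration edges and events for
    validation, export and inspection.  ``sampling_demes`` maps the
    panel roles (chimp / neandertal / african / european) to the deme
    each is drawn from by default.
    """

    kind: str
    demes: list[Deme]
    edges: list[MigrationEdge]
    events: list[DemographicEvent]
    generation_time: float
    root_deme: str
    outgroup_split_time: float  # generations
    msprime_demography: msprime.Demography
    sampling_demes: dict[str, str]
    free_parameters: tuple[str, ...]
    params: Any = None

    def validate(self) -> list[str]:
        return validate_demography(self)

    @property
    def n_free_parameters(self) -> int:
        return len(self.free_parameters)

    def deme(self, deme_id: str) -> Deme:
        for d in self.demes:
            if d.id == deme_id:
                return d
        raise KeyError(deme_id)

    def event_table(self) -> pd.DataFrame:
        """Event table (time in generations) for inspection and export."""
        rows = [
            {
                "time_generations": ev.time,
                "kind": ev.kind,
                "payload": json.dumps(ev.payload, sort_keys=True),
            }
            for ev in sorted(self.events, key=DemographicEvent.sort_key)
        ]
        return pd.DataFrame(rows, columns=["time_generations", "kind", "payload"])

    def to_event_tsv(self, path) -> None:
        from dcfs import io as _io

        _io.write_tsv(self.event_table(), path, provenance={"model": self.kind})


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise DemographyValidationError(message)


# ---------------------------------------------------------------------------
# Parameter sets
# ---------------------------------------------------------------------------


@dataclass
class SpatialParams:
    """Parameters of the stepping-stone spatial model.

    The eight *free* parameters (the ones a calibration sweeps) are
    ``k_demes, N_anc, m0, N_mod, m, t_modern, t_exit, founder_size``;
    the Neandertal split, outgroup split, generation time and chain
    geometry fields are held fixed.
    """

    k_demes: int = 10  # ancestral chain length (Neandertal + African demes)
    N_anc: float = 1000.0  # ancestral deme size (diploid)
    m0: float = 0.0015  # ancestral per-lineage migration rate /generation
    N_mod: float = 5000.0  # modern-human deme size
    m: float = 0.005  # modern-human migration rate
    t_modern: float = 100_000.0  # years: African demes become AMH
    t_exit: float = 60_000.0  # years: expansion into Eurasia begins
    founder_size: float = 2000.0  # founders per newly colonised Eurasian deme

    # fixed configuration
    generation_time: float = DEFAULT_GENERATION_TIME
    t_neandertal_split: float = NEANDERTAL_SPLIT_YEARS  # years
    outgroup_split: float = DEFAULT_OUTGROUP_SPLIT_YEARS  # years
    n_neandertal_demes: int = 1  # chain demes assigned to Neandertal at the split
    n_eurasian_demes: int = 4  # demes founded by the out-of-Africa expansion
    colonization_span: float = 5_000.0  # years to colonise the full Eurasian chain
    african_sample_deme: Optional[str] = None  # default: far end of the African chain
    european_sample_deme: Optional[str] = None  # default: last-colonised Eurasian deme

    FREE_PARAMETERS = (
        "k_demes",
        "N_anc",
        "m0",
        "N_mod",
        "m",
        "t_modern",
        "t_exit",
        "founder_size",
    )

    def validate(self) -> None:
        _require(self.k_demes >= 2, "k_demes >= 2 violated (need Neandertal and African segments)")
        _require(0 < self.n_neandertal_demes < self.k_demes,
                 "0 < n_neandertal_demes < k_demes violated")
        _require(self.n_eurasian_demes >= 1, "n_eurasian_demes >= 1 violated")
        _require(self.N_anc > 0 and self.N_mod > 0, "deme sizes must be positive")
        _require(self.m0 >= 0 and self.m >= 0, "migration rates must be non-negative")
        _require(0 < self.founder_size <= self.N_mod,
                 f"0 < founder_size <= N_mod violated: founder_size={self.founder_size}, N_mod={self.N_mod}")
        _require(self.t_exit < self.t_modern,
                 f"t_exit < t_modern violated: t_exit={self.t_exit}, t_modern={self.t_modern}")
        _require(self.t_modern < self.t_neandertal_split,
                 f"t_modern < t_neandertal_split violated: t_modern={self.t_modern}, "
                 f"t_neandertal_split={self.t_neandertal_split}")
        _require(self.t_neandertal_split < self.outgroup_split,
                 "t_neandertal_split < outgroup_split violated")
        _require(0 < self.colonization_span <= self.t_exit,
                 "0 < colonization_span <= t_exit violated")


@dataclass
class TwoPopParams:
    """Parameters of the coarse two-population ancient-structure model.

    The ancestor of Neandertal and modern humans is structured into two
    populations exchanging migrants at rate ``m_high``; Neandertal
    branches from the population whose descendants later leave Africa,
    and at the out-of-Africa time the exchange decreases (but does not
    stop) to ``m_low``.
    """

    N_anc: float = 10_000.0  # panmictic root size
    N_afr: float = 10_000.0  # African subpopulation / descendant size
    N_eur: float = 5_000.0  # Neandertal-parent subpopulation / Eurasian size
    N_nea: float = 2_500.0
    m_high: float = 1e-4  # pre-OOA exchange between the two subpopulations
    m_low: float = 1e-5  # post-OOA exchange
    t_structure: float = 550_000.0  # years: structure arises in the ancestor
    t_neandertal_split: float = NEANDERTAL_SPLIT_YEARS
    t_ooa: float = 60_000.0

    generation_time: float = DEFAULT_GENERATION_TIME
    outgroup_split: float = DEFAULT_OUTGROUP_SPLIT_YEARS

    FREE_PARAMETERS = (
        "N_anc",
        "N_afr",
        "N_eur",
        "N_nea",
        "m_high",
        "m_low",
        "t_structure",
        "t_ooa",
    )

    def validate(self) -> None:
        for name in ("N_anc", "N_afr", "N_eur", "N_nea"):
            _require(getattr(self, name) > 0, f"{name} must be positive")
        _require(self.m_high >= 0 and self.m_low >= 0, "migration rates must be non-negative")
        _require(self.t_ooa < self.t_neandertal_split,
                 f"t_ooa < t_neandertal_split violated: t_ooa={self.t_ooa}")
        _require(self.t_neandertal_split < self.t_structure,
                 f"t_neandertal_split < t_structure violated: "
                 f"t_neandertal_split={self.t_neandertal_split}, t_structure={self.t_structure}")
        _require(self.t_structure < self.outgroup_split,
                 "t_structure < outgroup_split violated")

    def validation_warnings(self) -> list[str]:
        warnings = []
        if self.m_low >= self.m_high:
            warnings.append(
                "post-OOA migration m_low >= pre-OOA m_high: the exchange is "
                "expected to decrease (but not stop) at the out-of-Africa event"
            )
        return warnings


@dataclass
class AdmixtureParams:
    """Clean-split model with a Neandertal-to-Eurasian admixture pulse.

    Nine free parameters: the four population sizes, the Neandertal
    split and out-of-Africa times, the out-of-Africa bottleneck size,
    and the pulse time and fraction ``f``.  With ``f = 0`` the model is
    the clean-split null used as the panmictic baseline.
    """

    N_anc: float = 10_000.0
    N_afr: float = 10_000.0
    N_eur: float = 5_000.0
    N_nea: float = 2_500.0
    t_neandertal_split: float = NEANDERTAL_SPLIT_YEARS
    t_ooa: float = 60_000.0
    N_bottleneck: float = 1_500.0  # Eurasian founder size at the OOA event
    t_admix: float = 50_000.0  # years: Neandertal gene flow into Eurasians
    f: float = 0.0  # admixture fraction

    generation_time: float = DEFAULT_GENERATION_TIME
    outgroup_split: float = DEFAULT_OUTGROUP_SPLIT_YEARS
    bottleneck_duration: float = 2_500.0  # years the founder size persists

    FREE_PARAMETERS = (
        "N_anc",
        "N_afr",
        "N_eur",
        "N_nea",
        "t_neandertal_split",
        "t_ooa",
        "N_bottleneck",
        "t_admix",
        "f",
    )

    def validate(self) -> None:
        for name in ("N_anc", "N_afr", "N_eur", "N_nea", "N_bottleneck"):
            _require(getattr(self, name) > 0, f"{name} must be positive")
        _require(0.0 <= self.f <= 1.0, f"admixture fraction f in [0, 1] violated: f={self.f}")
        _require(self.t_admix <= self.t_ooa,
                 f"t_admix <= t_ooa violated: t_admix={self.t_admix}, t_ooa={self.t_ooa}")
        _require(self.t_ooa < self.t_neandertal_split,
                 f"t_ooa < t_neandertal_split violated: t_ooa={self.t_ooa}")
        _require(self.t_neandertal_split < self.outgroup_split,
                 "t_neandertal_split < outgroup_split violated")
        _require(self.bottleneck_duration > 0, "bottleneck_duration must be positive")


# ---------------------------------------------------------------------------
# Model builders
# ---------------------------------------------------------------------------


def build_spatial_model(params: SpatialParams) -> Demography:
    """Compile the stepping-stone spatial model to a deme graph.

    Chain geometry (positions left to right): ``nea_0 .. nea_{n-1}``
    then ``afr_0 .. afr_{a-1}``, with ``afr_0`` the African deme closest
    to the Neandertal range.  Eurasian demes ``eur_0 .. eur_{e-1}`` are
    founded serially from ``afr_0`` (``eur_0`` first), extending the
    chain into Eurasia; they never exchange migrants with the Neandertal
    demes.  All remaining lineages coalesce in a single ancestral deme
    at the outgroup split.
    """
    params.validate()
    g = params.generation_time
    n_nea = params.n_neandertal_demes
    n_afr = params.k_demes - n_nea
    n_eur = params.n_eurasian_demes
    t_exit = params.t_exit / g
    t_modern = params.t_modern / g
    t_split = params.t_neandertal_split / g
    t_chimp = params.outgroup_split / g
    dt_col = params.colonization_span / g / n_eur

    nea_ids = [f"nea_{i}" for i in range(n_nea)]
    afr_ids = [f"afr_{i}" for i in range(n_afr)]
    eur_ids = [f"eur_{i}" for i in range(n_eur)]

    demes = (
        [Deme("chimp", params.N_anc, "chimp-stem")]
        + [Deme(i, params.N_anc, "neandertal") for i in nea_ids]
        + [Deme(i, params.N_mod, "african") for i in afr_ids]
        + [Deme(i, params.N_mod, "eurasian") for i in eur_ids]
        + [Deme("anc", params.N_anc, "ancestral")]
    )

    dem = msprime.Demography()
    for d in demes:
        dem.add_population(name=d.id, initial_size=d.size)

    edges: list[MigrationEdge] = []

    def _adj(a: str, b: str, rate: float) -> None:
        dem.set_symmetric_migration_rate([a, b], rate)
        edges.append(MigrationEdge(a, b, rate))

    # present-day adjacencies: linear chain with no wraparound
    for i in range(n_nea - 1):
        _adj(nea_ids[i], nea_ids[i + 1], params.m0)
    for i in range(n_afr - 1):
        _adj(afr_ids[i], afr_ids[i + 1], params.m)
    _adj(afr_ids[0], eur_ids[0], params.m)
    for i in range(n_eur - 1):
        _adj(eur_ids[i], eur_ids[i + 1], params.m)

    events: list[DemographicEvent] = []

    # serial colonisation of Eurasia, backward in time: eur_j was founded
    # (forward) at t_exit - j*dt_col with founder_size founders, growing to
    # N_mod over the colonisation interval.
    for j in range(n_eur):
        founded = t_exit - j * dt_col
        source = afr_ids[0] if j == 0 else eur_ids[j - 1]
        dem.add_population_parameters_change(
            time=founded - dt_col, population=eur_ids[j], initial_size=params.founder_size
        )
        dem.add_mass_migration(time=founded, source=eur_ids[j], dest=source, proportion=1.0)
        # once a deme is empty (backward in time it does not exist yet,
        # forward in time), no lineage may migrate into it: cut every
        # edge incident to it at its founding time
        neighbors = [source] + ([eur_ids[j + 1]] if j < n_eur - 1 else [])
        for nb in neighbors:
            dem.add_migration_rate_change(time=founded, rate=0.0,
                                          source=eur_ids[j], dest=nb)
            dem.add_migration_rate_change(time=founded, rate=0.0,
                                          source=nb, dest=eur_ids[j])
        events.append(DemographicEvent(
            time=founded, kind="range_expansion",
            payload={"deme": eur_ids[j], "source": source,
                     "founder_size": params.founder_size}))

    # African demes become ancestral-type at t_modern (backward)
    for i, a in enumerate(afr_ids):
        dem.add_population_parameters_change(time=t_modern, population=a,
                                             initial_size=params.N_anc)
        if i < n_afr - 1:
            dem.add_migration_rate_change(time=t_modern, rate=params.m0,
                                          source=a, dest=afr_ids[i + 1])
            dem.add_migration_rate_change(time=t_modern, rate=params.m0,
                                          source=afr_ids[i + 1], dest=a)
    events.append(DemographicEvent(
        time=t_modern, kind="parameter_change",
        payload={"demes": afr_ids, "size": params.N_anc, "rate": params.m0}))

    # the chain was whole before the Neandertal split: reconnect the
    # boundary adjacency, with no change in demographic parameters
    dem.add_migration_rate_change(time=t_split, rate=params.m0,
                                  source=nea_ids[-1], dest=afr_ids[0])
    dem.add_migration_rate_change(time=t_split, rate=params.m0,
                                  source=afr_ids[0], dest=nea_ids[-1])
    events.append(DemographicEvent(
        time=t_split, kind="chain_split",
        payload={"deme": afr_ids[0], "neighbor": nea_ids[-1], "rate": params.m0}))
    edges.append(MigrationEdge(nea_ids[-1], afr_ids[0], 0.0))

    # everything coalesces in a single ancestral deme at the outgroup split
    for pid in nea_ids + afr_ids:
        dem.add_mass_migration(time=t_chimp, source=pid, dest="anc", proportion=1.0)
    dem.add_mass_migration(time=t_chimp, source="chimp", dest="anc", proportion=1.0)
    dem.add_migration_rate_change(time=t_chimp, rate=0.0)
    events.append(DemographicEvent(
        time=t_chimp, kind="deme_merge",
        payload={"demes": nea_ids + afr_ids + ["chimp"], "dest": "anc"}))

    dem.sort_events()

    sampling = {
        "chimp": "chimp",
        "neandertal": nea_ids[0],
        "african": params.african_sample_deme or afr_ids[-1],
        "european": params.european_sample_deme or eur_ids[-1],
    }
    return Demography(
        kind="spatial",
        demes=demes,
        edges=edges,
        events=sorted(events, key=DemographicEvent.sort_key),
        generation_time=g,
        root_deme="anc",
        outgroup_split_time=t_chimp,
        msprime_demography=dem,
        sampling_demes=sampling,
        free_parameters=SpatialParams.FREE_PARAMETERS,
        params=params,
    )


def build_two_population_model(params: TwoPopParams) -> Demography:
    """Compile the coarse two-population ancient-structure model.

    Backward in time: African and Eurasian populations exchange migrants
    at ``m_low`` until the out-of-Africa event, at ``m_high`` between the
    out-of-Africa event and ``t_structure``; the Neandertal lineage joins
    the Eurasian-ancestor subpopulation at the Neandertal split; the two
    subpopulations merge into the panmictic root at ``t_structure``.
    """
    params.validate()
    g = params.generation_time
    t_ooa = params.t_ooa / g
    t_split = params.t_neandertal_split / g
    t_struct = params.t_structure / g
    t_chimp = params.outgroup_split / g

    demes = [
        Deme("chimp", params.N_anc, "chimp-stem"),
        Deme("afr", params.N_afr, "african"),
        Deme("eur", params.N_eur, "eurasian"),
        Deme("nea", params.N_nea, "neandertal"),
        Deme("anc", params.N_anc, "ancestral"),
    ]
    dem = msprime.Demography()
    for d in demes:
        dem.add_population(name=d.id, initial_size=d.size)
    dem.set_symmetric_migration_rate(["afr", "eur"], params.m_low)
    edges = [MigrationEdge("afr", "eur", params.m_low)]

    events = []
    dem.add_migration_rate_change(time=t_ooa, rate=params.m_high, source="afr", dest="eur")
    dem.add_migration_rate_change(time=t_ooa, rate=params.m_high, source="eur", dest="afr")
    events.append(DemographicEvent(
        time=t_ooa, kind="parameter_change",
        payload={"demes": ["afr", "eur"], "rate": params.m_high}))

    dem.add_mass_migration(time=t_split, source="nea", dest="eur", proportion=1.0)
    events.append(DemographicEvent(
        time=t_split, kind="chain_split", payload={"deme": "nea", "parent": "eur"}))

    for pid in ("afr", "eur"):
        dem.add_mass_migration(time=t_struct, source=pid, dest="anc", proportion=1.0)
    dem.add_migration_rate_change(time=t_struct, rate=0.0)
    events.append(DemographicEvent(
        time=t_struct, kind="deme_merge", payload={"demes": ["afr", "eur"], "dest": "anc"}))

    dem.add_mass_migration(time=t_chimp, source="chimp", dest="anc", proportion=1.0)
    events.append(DemographicEvent(
        time=t_chimp, kind="deme_merge", payload={"demes": ["chimp"], "dest": "anc"}))

    dem.sort_events()
    sampling = {"chimp": "chimp", "neandertal": "nea", "african": "afr", "european": "eur"}
    return Demography(
        kind="two_pop",
        demes=demes,
        edges=edges,
        events=sorted(events, key=DemographicEvent.sort_key),
        generation_time=g,
        root_deme="anc",
        outgroup_split_time=t_chimp,
        msprime_demography=dem,
        sampling_demes=sampling,
        free_parameters=TwoPopParams.FREE_PARAMETERS,
        params=params,
    )


def build_admixture_model(params: AdmixtureParams) -> Demography:
    """Compile the clean-split model with a Neandertal admixture pulse.

    With ``f = 0`` the pulse event is omitted entirely, so the returned
    graph is identical to :func:`build_clean_split_model` on the same
    parameters.
    """
    params.validate()
    g = params.generation_time
    t_admix = params.t_admix / g
    t_ooa = params.t_ooa / g
    t_split = params.t_neandertal_split / g
    t_chimp = params.outgroup_split / g
    t_bneck = t_ooa - params.bottleneck_duration / g

    demes = [
        Deme("chimp", params.N_anc, "chimp-stem"),
        Deme("afr", params.N_afr, "african"),
        Deme("eur", params.N_eur, "eurasian"),
        Deme("nea", params.N_nea, "neandertal"),
        Deme("anc", params.N_anc, "ancestral"),
    ]
    dem = msprime.Demography()
    for d in demes:
        dem.add_population(name=d.id, initial_size=d.size)
    edges: list[MigrationEdge] = []
    events = []

    if params.f > 0.0:
        dem.add_mass_migration(time=t_admix, source="eur", dest="nea", proportion=params.f)
        events.append(DemographicEvent(
            time=t_admix, kind="mass_migration",
            payload={"deme": "eur", "dest": "nea", "f": params.f}))

    # out-of-Africa founder bottleneck: the Eurasian population holds at
    # N_bottleneck for bottleneck_duration after its founding (forward)
    if t_bneck > 0:
        dem.add_population_parameters_change(time=t_bneck, population="eur",
                                             initial_size=params.N_bottleneck)
        events.append(DemographicEvent(
            time=t_bneck, kind="parameter_change",
            payload={"deme": "eur", "size": params.N_bottleneck}))
    dem.add_mass_migration(time=t_ooa, source="eur", dest="afr", proportion=1.0)
    events.append(DemographicEvent(
        time=t_ooa, kind="deme_merge", payload={"demes": ["eur"], "dest": "afr"}))

    dem.add_mass_migration(time=t_split, source="afr", dest="anc", proportion=1.0)
    dem.add_mass_migration(time=t_split, source="nea", dest="anc", proportion=1.0)
    events.append(DemographicEvent(
        time=t_split, kind="deme_merge", payload={"demes": ["afr", "nea"], "dest": "anc"}))

    dem.add_mass_migration(time=t_chimp, source="chimp", dest="anc", proportion=1.0)
    events.append(DemographicEvent(
        time=t_chimp, kind="deme_merge", payload={"demes": ["chimp"], "dest": "anc"}))

    dem.sort_events()
    sampling = {"chimp": "chimp", "neandertal": "nea", "african": "afr", "european": "eur"}
    return Demography(
        kind="admixture" if params.f > 0 else "clean_split",
        demes=demes,
        edges=edges,
        events=sorted(events, key=DemographicEvent.sort_key),
        generation_time=g,
        root_deme="anc",
        outgroup_split_time=t_chimp,
        msprime_demography=dem,
        sampling_demes=sampling,
        free_parameters=AdmixtureParams.FREE_PARAMETERS,
        params=params,
    )


def build_clean_split_model(params: Optional[AdmixtureParams] = None, **kwargs) -> Demography:
    """Clean-split panmictic null model (admixture model with ``f = 0``)."""
    if params is None:
        params = AdmixtureParams(**kwargs)
    if params.f != 0.0:
        params = dataclasses.replace(params, f=0.0)
    return build_admixture_model(params)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_demography(demog: Demography) -> list[str]:
    """Check the structural invariants of a deme graph.

    Returns a list of human-readable issues (empty iff the graph is
    well-formed); problems are reported, not raised.
    """
    issues: list[str] = []
    ids = [d.id for d in demog.demes]
    seen = set()
    for i in ids:
        if i in seen:
            issues.append(f"duplicate deme id: {i}")
        seen.add(i)
    for d in demog.demes:
        if not d.size > 0:
            issues.append(f"deme {d.id}: size must be positive, got {d.size}")
    for e in demog.edges:
        if e.rate < 0:
            issues.append(f"edge {e.from_deme}->{e.to_deme}: negative migration rate {e.rate}")
        for end in (e.from_deme, e.to_deme):
            if end not in seen:
                issues.append(f"edge {e.from_deme}->{e.to_deme}: unknown deme {end}")

    merged_at: dict[str, float] = {}
    for ev in demog.events:
        if ev.time < 0:
            issues.append(f"event {ev.kind} at negative time {ev.time}")
        for key in ("deme", "dest", "source", "neighbor", "parent"):
            target = ev.payload.get(key)
            if target is not None and target not in seen:
                issues.append(f"event {ev.kind} at t={ev.time}: unknown deme {target}")
        for target in ev.payload.get("demes", []):
            if target not in seen:
                issues.append(f"event {ev.kind} at t={ev.time}: unknown deme {target}")
        if ev.kind == "deme_merge":
            for target in ev.payload.get("demes", []):
                merged_at[target] = min(ev.time, merged_at.get(target, math.inf))

    # a migration edge must not be (re)activated after either end merged away
    for ev in demog.events:
        if ev.kind in ("parameter_change", "chain_split") and "rate" in ev.payload:
            involved = ev.payload.get("demes", [])
            for key in ("deme", "neighbor"):
                if ev.payload.get(key):
                    involved = involved + [ev.payload[key]]
            for target in involved:
                if target in merged_at and ev.time > merged_at[target]:
                    issues.append(
                        f"event {ev.kind} at t={ev.time}: deme {target} was merged away "
                        f"at t={merged_at[target]}")

    if demog.events:
        latest_other = max((ev.time for ev in demog.events
                            if not (ev.kind == "deme_merge" and ev.time == demog.outgroup_split_time)),
                           default=0.0)
        if demog.outgroup_split_time <= 0:
            issues.append("outgroup_split_time must be positive")
        elif latest_other > demog.outgroup_split_time:
            issues.append(
                f"outgroup_split_time {demog.outgroup_split_time} is not the deepest event "
                f"(found event at {latest_other})")

    # connectivity: every pair of demes must share ancestry through
    # migration edges or merge events, else some lineage pairs never coalesce
    parent: dict[str, str] = {i: i for i in seen}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for e in demog.edges:
        if e.from_deme in seen and e.to_deme in seen:
            union(e.from_deme, e.to_deme)
    for ev in demog.events:
        dest = ev.payload.get("dest") or ev.payload.get("source") or ev.payload.get("parent") \
            or ev.payload.get("neighbor")
        members = [t for t in ([ev.payload.get("deme")] + list(ev.payload.get("demes", [])))
                   if t in seen]
        if dest in seen:
            members.append(dest)
        for a, b in zip(members, members[1:]):
            union(a, b)
    roots = {find(i) for i in seen}
    if len(roots) > 1:
        issues.append(f"deme graph is disconnected: {len(roots)} components")

    return issues


# ---------------------------------------------------------------------------
# Config-file interface
# ---------------------------------------------------------------------------

_MODEL_PARAMS = {
    "spatial": SpatialParams,
    "two_pop": TwoPopParams,
    "admixture": AdmixtureParams,
    "clean_split": AdmixtureParams,
}
_MODEL_BUILDERS = {
    "spatial": build_spatial_model,
    "two_pop": build_two_population_model,
    "admixture": build_admixture_model,
    "clean_split": build_clean_split_model,
}

_TIME_FIELDS = {
    "t_modern", "t_exit", "t_neandertal_split", "outgroup_split", "colonization_span",
    "t_structure", "t_ooa", "t_admix", "bottleneck_duration",
}


def params_from_config(config: dict):
    """Build a parameter set from a flat JSON-compatible mapping.

    The mapping must carry a ``model`` discriminator (spatial | two_pop |
    admixture | clean_split) and a ``units`` field (``years`` |
    ``generations``) governing every time-valued entry.
    """
    cfg = dict(config)
    model = cfg.pop("model", None)
    if model not in _MODEL_PARAMS:
        raise DemographyValidationError(
            f"config must set model to one of {sorted(_MODEL_PARAMS)}, got {model!r}")
    units = cfg.pop("units", None)
    if units not in ("years", "generations"):
        raise DemographyValidationError(
            "config must set units to 'years' or 'generations'")
    cls = _MODEL_PARAMS[model]
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(cfg) - valid
    if unknown:
        raise DemographyValidationError(f"unknown parameters for model {model}: {sorted(unknown)}")
    if units == "generations":
        g = cfg.get("generation_time", DEFAULT_GENERATION_TIME)
        for k in list(cfg):
            if k in _TIME_FIELDS:
                cfg[k] = cfg[k] * g
    return model, cls(**cfg)


def model_from_config(config: dict) -> Demography:
    """Compile a demographic model straight from a config mapping."""
    model, params = params_from_config(config)
    return _MODEL_BUILDERS[model](params)
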