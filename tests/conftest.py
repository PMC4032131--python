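"""Shared fixtures: minimal demographies and hand-built genealogies."""

import msprime
import numpy as np
import pytest
import tskit

from dcfs.coalsim import SampleConfig
from dcfs.demography import Deme, Demography, MigrationEdge


def bare_demography(msp_dem, demes, edges=None, sampling=None, kind="custom"):
    """Wrap a raw msprime demography for tests that bypass the builders."""
    return Demography(
        kind=kind,
        demes=demes,
        edges=edges or [],
        events=[],
        generation_time=25.0,
        root_deme=demes[-1].id,
        outgroup_split_time=0.0,
        msprime_demography=msp_dem,
        sampling_demes=sampling or {},
        free_parameters=(),
    )


@pytest.fixture
def single_deme():
    """One panmictic deme of diploid size 500; every role samples from it."""
    N = 500.0
    dem = msprime.Demography()
    dem.add_population(name="pop0", initial_size=N)
    sampling = {r: "pop0" for r in ("chimp", "neandertal", "african", "european")}
    demog = bare_demography(dem, [Deme("pop0", N, "ancestral")], sampling=sampling)
    return demog, N


def chain_demography(k, N, m):
    """Homogeneous symmetric stepping-stone chain, all roles sampling deme 0."""
    dem = msprime.Demography()
    for i in range(k):
        dem.add_population(name=f"d{i}", initial_size=N)
    edges = []
    for i in range(k - 1):
        dem.set_symmetric_migration_rate([f"d{i}", f"d{i+1}"], m)
        edges.append(MigrationEdge(f"d{i}", f"d{i+1}", m))
    demes = [Deme(f"d{i}", N, "ancestral") for i in range(k)]
    sampling = {r: "d0" for r in ("chimp", "neandertal", "african", "european")}
    return bare_demography(dem, demes, edges, sampling)


@pytest.fixture
def pair_sample():
    """Two contemporaneous European chromosomes plus the minimal other roles."""
    return SampleConfig(n_chimp=1, n_neandertal=1, n_african=1, n_european=2,
                        neandertal_time=0.0)


def manual_genealogy(node_times, edges, roles, labels=None):
    """Build a Genealogy from explicit (parent, child) edges and node times."""
    from dcfs.coalsim import Genealogy

    tables = tskit.TableCollection(sequence_length=1.0)
    tables.populations.metadata_schema = tskit.MetadataSchema.permissive_json()
    tables.populations.add_row(metadata={"name": "pop0"})
    n_samples = len(roles)
    for i, t in enumerate(node_times):
        flags = tskit.NODE_IS_SAMPLE if i < n_samples else 0
        tables.nodes.add_row(flags=flags, time=t, population=0)
    for parent, child in edges:
        tables.edges.add_row(left=0, right=1, parent=parent, child=child)
    tables.sort()
    ts = tables.tree_sequence()
    roles = np.asarray(roles, dtype=np.int8)
    if labels is None:
        labels = [f"leaf_{i}" for i in range(n_samples)]
    return Genealogy(ts, roles, labels)
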