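"""Structured-coalescent simulation of unlinked loci.

Each locus is an independent non-recombining genealogy of the
chimp / Neandertal / African / European panel, simulated under a
compiled :class:`~dcfs.demography.Demography` with msprime's exact
continuous-time structured coalescent (pairwise coalescence at rate
``1/(2N)`` per generation within a deme of diploid size ``N``, lineage
migration along the active edges, demographic events applied at their
times).  Mutations are dropped under the infinite-sites model.

All randomness flows from a single master seed: per-call msprime seeds
are derived with :func:`numpy.random.SeedSequence`, so identical
``(inputs, seed)`` give identical trees, and the single-genealogy and
replicated entry points draw from the same stream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import msprime
import numpy as np
import tskit

from dcfs.demography import Demography

__all__ = [
    "ROLE_CHIMP",
    "ROLE_NEANDERTAL",
    "ROLE_AFRICAN",
    "ROLE_EUROPEAN",
    "ROLE_NAMES",
    "SampleConfig",
    "Genealogy",
    "NonCoalescingError",
    "simulate_genealogy",
    "simulate_replicates",
    "drop_mutations",
]

ROLE_CHIMP, ROLE_NEANDERTAL, ROLE_AFRICAN, ROLE_EUROPEAN = 0, 1, 2, 3
ROLE_NAMES = ("chimp", "nea", "afr", "eur")


class NonCoalescingError(RuntimeError):
    """The sampled lineages cannot all reach a common ancestor."""


@dataclass
class SampleConfig:
    """Sampled chromosomes per panel role.

    Counts are haploid chromosomes (``n_european = 10`` is five diploid
    Europeans).  ``demes`` overrides the model's default sampling demes
    per role; the Neandertal is an ancient sample drawn
    ``neandertal_time`` years before present.
    """

    n_chimp: int = 1
    n_neandertal: int = 1
    n_african: int = 1
    n_european: int = 10
    demes: dict[str, str] = field(default_factory=dict)
    neandertal_time: float = 50_000.0  # years before present

    def validate(self) -> None:
        for name in ("n_chimp", "n_neandertal", "n_african", "n_european"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        # dcfs computations additionally require n_european >= 2 (two
        # frequency classes); pure D panels may use a single European.

    @property
    def n_total(self) -> int:
        return self.n_chimp + self.n_neandertal + self.n_african + self.n_european

    def roles(self) -> np.ndarray:
        """Role code of each sampled chromosome, in sampling order."""
        return np.repeat(
            np.arange(4, dtype=np.int8),
            [self.n_chimp, self.n_neandertal, self.n_african, self.n_european],
        )

    def labels(self) -> list[str]:
        out = []
        for code, n in zip(ROLE_NAMES,
                           (self.n_chimp, self.n_neandertal, self.n_african, self.n_european)):
            out.extend(f"{code}_{i}" for i in range(n))
        return out

    def sample_sets(self, demog: Demography) -> list[msprime.SampleSet]:
        nea_time = self.neandertal_time / demog.generation_time
        spec = [
            ("chimp", self.n_chimp, 0.0),
            ("neandertal", self.n_neandertal, nea_time),
            ("african", self.n_african, 0.0),
            ("european", self.n_european, 0.0),
        ]
        sets = []
        for role, n, time in spec:
            deme = self.demes.get(role, demog.sampling_demes[role])
            sets.append(msprime.SampleSet(n, population=deme, time=time, ploidy=1))
        return sets


@dataclass
class Genealogy:
    """One unlinked locus: a rooted labeled coalescent tree.

    Thin wrapper over a single-tree :class:`tskit.TreeSequence` carrying
    the panel role of each leaf.  Node times are in generations; leaves
    sit at their sampling times (the Neandertal leaf in the past).
    """

    ts: tskit.TreeSequence
    roles: np.ndarray
    labels: list[str]

    @property
    def tree(self) -> tskit.Tree:
        return self.ts.first()

    @property
    def num_leaves(self) -> int:
        return len(self.roles)

    @property
    def tmrca(self) -> float:
        tree = self.tree
        if tree.num_roots != 1:
            raise NonCoalescingError("genealogy has multiple roots")
        return tree.time(tree.root)

    @property
    def total_branch_length(self) -> float:
        return self.tree.total_branch_length

    def newick(self) -> str:
        tree = self.tree
        node_labels = {u: self.labels[u] for u in self.ts.samples()}
        return tree.as_newick(node_labels=node_labels)

    def relabel_europeans(self, permutation: Iterable[int]) -> "Genealogy":
        """Permute European leaf labels (exchangeability checks)."""
        perm = list(permutation)
        eur_ids = [i for i, r in enumerate(self.roles) if r == ROLE_EUROPEAN]
        labels = list(self.labels)
        for new_pos, old_pos in enumerate(perm):
            labels[eur_ids[new_pos]] = self.labels[eur_ids[old_pos]]
        return dataclasses.replace(self, labels=labels)


def derive_seed(master_seed: int, index: int = 0) -> int:
    """Deterministic msprime-safe seed from a master seed and stream index."""
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, int(index)])
    return int(ss.generate_state(1, np.uint64)[0] % (2**31 - 2)) + 1


def _run_ancestry(demog: Demography, sample: SampleConfig, seed: int,
                  num_replicates: Optional[int], max_time: Optional[float]):
    sample.validate()
    try:
        return msprime.sim_ancestry(
            samples=sample.sample_sets(demog),
            demography=demog.msprime_demography,
            sequence_length=1,
            discrete_genome=False,
            ploidy=2,
            random_seed=seed,
            num_replicates=num_replicates,
            end_time=max_time,
        )
    except Exception as err:  # msprime raises LibraryError on infinite waiting times
        if "infinite" in str(err).lower():
            raise NonCoalescingError(
                "sampled lineages cannot coalesce under this demography: " + str(err)
            ) from err
        raise


def _check_coalesced(ts: tskit.TreeSequence, max_time: Optional[float]) -> None:
    if ts.first().num_roots > 1:
        raise NonCoalescingError(
            f"lineages had not coalesced by the maximum time horizon ({max_time} generations)")


def simulate_genealogy(demog: Demography, sample: SampleConfig, seed: int,
                       max_time: Optional[float] = None) -> Genealogy:
    """Simulate one genealogy of the panel under ``demog``.

    ``max_time`` (generations) bounds the simulation; if the lineages
    have not coalesced by then (e.g. a disconnected deme graph) a
    :class:`NonCoalescingError` is raised.
    """
    ts = _run_ancestry(demog, sample, derive_seed(seed), None, max_time)
    _check_coalesced(ts, max_time)
    return Genealogy(ts, sample.roles(), sample.labels())


def simulate_replicates(demog: Demography, sample: SampleConfig, n_loci: int, seed: int,
                        max_time: Optional[float] = None) -> Iterator[Genealogy]:
    """Stream ``n_loci`` independent genealogies (unlinked loci).

    A generator: trees are produced lazily so large replicate counts
    never sit in memory at once.  The whole stream is a deterministic
    function of the master ``seed``; the first replicate equals
    ``simulate_genealogy(demog, sample, seed)``.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    roles = sample.roles()
    labels = sample.labels()
    reps = _run_ancestry(demog, sample, derive_seed(seed), n_loci, max_time)
    for locus, ts in enumerate(reps):
        try:
            _check_coalesced(ts, max_time)
        except NonCoalescingError as err:
            raise NonCoalescingError(f"locus {locus}: {err}") from err
        yield Genealogy(ts, roles, labels)


def drop_mutations(tree: Genealogy, mu: float, seed: int):
    """Drop infinite-sites mutations on a genealogy.

    ``mu`` is the per-locus mutation rate per generation; mutation
    counts per branch are Poisson with mean ``mu × branch length`` and
    every mutation creates one new biallelic site carried by the
    branch's descendant leaves.  Returns a
    :class:`~dcfs.stats.GenotypeTable` of 0/1 alleles (0 = simulated
    ancestral state); downstream statistics re-polarise against the
    chimp chromosome, exactly as with real data.
    """
    from dcfs.stats import GenotypeTable

    if mu <= 0:
        raise ValueError("mu must be > 0")
    mts = msprime.sim_mutations(
        tree.ts, rate=mu, random_seed=derive_seed(seed),
        model=msprime.BinaryMutationModel(), discrete_genome=False,
    )
    matrix = mts.genotype_matrix()  # sites x samples, 0 = ancestral
    return GenotypeTable.from_matrix(matrix, tree.roles, labels=tree.labels)


def mutate_replicates(trees: Iterable[Genealogy], mu: float, seed: int):
    """Drop infinite-sites mutations on a stream of genealogies.

    Returns one concatenated :class:`~dcfs.stats.GenotypeTable` with a
    ``locus`` column; per-locus mutation seeds derive from ``seed``.
    Considerably faster than one table per locus for large streams.
    """
    from dcfs.stats import GenotypeTable

    if mu <= 0:
        raise ValueError("mu must be > 0")
    matrices = []
    loci = []
    labels = None
    roles = None
    for locus, gen in enumerate(trees):
        labels, roles = gen.labels, gen.roles
        mts = msprime.sim_mutations(
            gen.ts, rate=mu, random_seed=derive_seed(seed, locus),
            model=msprime.BinaryMutationModel(), discrete_genome=False,
        )
        if mts.num_sites:
            matrices.append(mts.genotype_matrix())
            loci.append(np.full(mts.num_sites, locus))
    if labels is None:
        raise ValueError("trees must be a nonempty collection")
    if not matrices:
        matrix = np.zeros((0, len(labels)), dtype=np.int8)
        locus_col = np.zeros(0, dtype=int)
    else:
        matrix = np.vstack(matrices)
        locus_col = np.concatenate(loci)
    table = GenotypeTable.from_matrix(matrix, roles, labels=labels)
    table.data.insert(0, "locus", locus_col)
    return table
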