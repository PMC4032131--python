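"""Low-variance expected Patterson's D for the stepping-stone model.

The ABBA/BABA branch weights behind Patterson's D can only start
accruing once the Neandertal lineage can meet modern-human lineages —
i.e. after (backward in time) the chain reconnects at the Neandertal
split.  Before that the Neandertal segment exchanges no migrants with
the modern range, so the *entire* contribution of a genealogy to D is a
function of the lineage configuration at the split time: the chain
positions of the Neandertal, European and African lineages (or of the
European/African common ancestor, which contributes nothing).

The ancestral phase older than the split is a time-homogeneous
stepping-stone chain, so the conditional expectations

* ``u(s)`` — expected total time during which an ancestor of exactly
  {Neandertal, European} is extant (the ABBA branch weight), and
* ``v(s)`` — the {Neandertal, African} analogue (BABA),

given configuration ``s``, solve small sparse linear systems of the
structured coalescent (states = lineage positions on the chain;
transitions = single-deme migration steps at rate ``m0`` per direction
and pairwise coalescence at ``1/(2N)`` within a deme).  The estimator
simulates ``n_histories`` recent-epoch genealogies, reads the
configuration at the split from a census, and averages the exact
conditional weights.  It is unbiased for the same expectations as
:func:`dcfs.stats.branch_patterson_d` but removes the Monte Carlo noise
of the deep ancestral phase, which dominates the variance of the plain
branch sums.

Two approximations, both conservative at these time scales: the chimp
lineage is ignored (it cannot join the ingroup before the outgroup
merge, ~2.3e5 generations deeper than typical ingroup coalescence) and
the ancestral phase is integrated to an infinite horizon (the
probability of the ingroup not coalescing before the outgroup merge is
exponentially small).
"""

from __future__ import annotations

import copy
from typing import Optional

import msprime
import numpy as np
import scipy.sparse
import scipy.sparse.linalg

from dcfs.coalsim import derive_seed
from dcfs.demography import Demography, SpatialParams, build_spatial_model
from dcfs.stats import DStat

__all__ = [
    "chain_pair_coalescence_time",
    "chain_abba_weight",
    "expected_patterson_d_spatial",
    "exact_patterson_d_spatial",
]


def _chain_neighbors(k: int) -> list[list[int]]:
    return [[j for j in (i - 1, i + 1) if 0 <= j < k] for i in range(k)]


def chain_pair_coalescence_time(k: int, N: float, m0: float) -> np.ndarray:
    """Expected coalescence time tau[i, j] of two lineages on the chain.

    Linear chain of ``k`` demes of diploid size ``N``, migration ``m0``
    per lineage per direction per generation, coalescence at ``1/(2N)``
    when co-located.  Solves ``(-Q) tau = 1`` over the k^2 transient
    states.
    """
    if m0 <= 0 and k > 1:
        raise ValueError("m0 must be positive for a connected chain")
    c = 1.0 / (2.0 * N)
    nbrs = _chain_neighbors(k)
    n = k * k
    rows, cols, vals = [], [], []
    diag = np.zeros(n)

    def sid(i, j):
        return i * k + j

    for i in range(k):
        for j in range(k):
            s = sid(i, j)
            out = 0.0
            for i2 in nbrs[i]:
                rows.append(s); cols.append(sid(i2, j)); vals.append(m0)
                out += m0
            for j2 in nbrs[j]:
                rows.append(s); cols.append(sid(i, j2)); vals.append(m0)
                out += m0
            if i == j:
                out += c  # coalescence exits the transient class
            diag[s] = out
    Q = scipy.sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    A = scipy.sparse.diags(diag) - Q
    tau = scipy.sparse.linalg.spsolve(A.tocsc(), np.ones(n))
    return tau.reshape(k, k)


def chain_abba_weight(k: int, N: float, m0: float,
                      tau: Optional[np.ndarray] = None) -> np.ndarray:
    """Expected ABBA branch weight u[i, j, l] on the ancestral chain.

    ``i, j, l`` are the chain positions of the Neandertal, European and
    African lineages when the ancestral phase begins.  ``u`` is the
    expected total time during which an ancestor of exactly the
    Neandertal and European chromosomes is extant: entered when those
    two coalesce first (reward: the pair coalescence time of the merged
    lineage with the African lineage), zero if any other pair coalesces
    first.  The BABA weight is ``u[i, l, j]`` by exchangeability of the
    two modern lineages in the ancestral phase.
    """
    if tau is None:
        tau = chain_pair_coalescence_time(k, N, m0)
    c = 1.0 / (2.0 * N)
    nbrs = _chain_neighbors(k)
    n = k * k * k
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    b = np.zeros(n)

    def sid(i, j, l):
        return (i * k + j) * k + l

    for i in range(k):
        for j in range(k):
            for l in range(k):
                s = sid(i, j, l)
                out = 0.0
                for i2 in nbrs[i]:
                    rows.append(s); cols.append(sid(i2, j, l)); vals.append(m0)
                    out += m0
                for j2 in nbrs[j]:
                    rows.append(s); cols.append(sid(i, j2, l)); vals.append(m0)
                    out += m0
                for l2 in nbrs[l]:
                    rows.append(s); cols.append(sid(i, j, l2)); vals.append(m0)
                    out += m0
                if i == j:  # Neandertal-European coalescence starts the ABBA clock
                    out += c
                    b[s] += c * tau[i, l]
                if i == l:  # Neandertal-African coalescence: no ABBA time ever
                    out += c
                if j == l:  # the two moderns coalesce: no ABBA time ever
                    out += c
                diag[s] = out
    Q = scipy.sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    A = scipy.sparse.diags(diag) - Q
    u = scipy.sparse.linalg.spsolve(A.tocsc(), b)
    return u.reshape(k, k, k)


def _chain_position_map(params: SpatialParams) -> dict[str, int]:
    pos = {f"nea_{q}": q for q in range(params.n_neandertal_demes)}
    pos.update({f"afr_{q}": params.n_neandertal_demes + q
                for q in range(params.k_demes - params.n_neandertal_demes)})
    return pos


def expected_patterson_d_spatial(params: SpatialParams, n_histories: int, seed: int,
                                 demog: Optional[Demography] = None) -> DStat:
    """Rao-Blackwellised branch-expectation D for the spatial model.

    Simulates ``n_histories`` recent-epoch genealogies of
    {1 Neandertal, 1 African, 1 European} down to the Neandertal split,
    censuses the lineage configuration there, and averages the exact
    conditional ABBA/BABA weights of the homogeneous ancestral chain.
    Returns a :class:`~dcfs.stats.DStat` whose weights are the summed
    expected branch lengths.
    """
    if demog is None:
        demog = build_spatial_model(params)
    if demog.kind != "spatial":
        raise ValueError("this estimator is specific to the spatial model")
    g = params.generation_time
    t_split = params.t_neandertal_split / g
    nea_time = 50_000.0 / g  # matches SampleConfig's default ancient sampling

    dem = copy.deepcopy(demog.msprime_demography)
    census_time = t_split - 0.5
    dem.add_census(time=census_time)
    dem.sort_events()

    samples = [
        msprime.SampleSet(1, population=demog.sampling_demes["neandertal"],
                          time=nea_time, ploidy=1),
        msprime.SampleSet(1, population=demog.sampling_demes["african"],
                          time=0, ploidy=1),
        msprime.SampleSet(1, population=demog.sampling_demes["european"],
                          time=0, ploidy=1),
    ]
    NEA, AFR, EUR = 0, 1, 2

    tau = chain_pair_coalescence_time(params.k_demes, params.N_anc, params.m0)
    u = chain_abba_weight(params.k_demes, params.N_anc, params.m0, tau)
    pos_of_pop = _chain_position_map(params)

    reps = msprime.sim_ancestry(
        samples=samples, demography=dem, sequence_length=1, discrete_genome=False,
        ploidy=2, random_seed=derive_seed(seed), num_replicates=n_histories,
        end_time=t_split,
    )
    sum_abba = 0.0
    sum_baba = 0.0
    census_flag = msprime.NODE_IS_CEN_EVENT
    for ts in reps:
        flags = ts.tables.nodes.flags
        pops = ts.tables.nodes.population
        census_nodes = np.flatnonzero(flags & census_flag)
        tree = ts.first()
        pos = {}
        ea_coalesced = False
        for cn in census_nodes:
            below = frozenset(tree.leaves(cn))
            name = ts.population(pops[cn]).metadata["name"]
            if below == {NEA}:
                pos["N"] = pos_of_pop[name]
            elif below == {AFR}:
                pos["A"] = pos_of_pop[name]
            elif below == {EUR}:
                pos["E"] = pos_of_pop[name]
            elif below == {AFR, EUR}:
                ea_coalesced = True
            else:  # pragma: no cover - impossible before the split
                raise RuntimeError(f"unexpected lineage content at census: {set(below)}")
        if ea_coalesced or "N" not in pos:
            continue  # no ABBA/BABA weight can ever accrue
        sum_abba += u[pos["N"], pos["E"], pos["A"]]
        sum_baba += u[pos["N"], pos["A"], pos["E"]]
    return DStat(sum_abba, sum_baba)


# ---------------------------------------------------------------------------
# Fully deterministic expectation (no Monte Carlo at all)
# ---------------------------------------------------------------------------
#
# The recent phase (present back to the Neandertal split) is itself a
# piecewise time-homogeneous Markov process on a small state space: the
# African/European lineage pair random-walks over the modern deme graph
# (whose geometry changes at the colonisation, out-of-Africa and
# modernisation events) and may coalesce; the Neandertal lineage walks
# its own isolated segment.  Propagating the state distribution through
# each epoch with matrix exponentials and closing with the exact
# ancestral-chain weights gives the model's predicted D with no
# sampling noise whatsoever.  This is the estimator calibration sweeps
# should filter on: the subsetting criterion targets the expectation of
# D, not one Monte Carlo realisation of it.


def _pair_generator(demes: list[str], sizes: dict[str, float],
                    edges: list[tuple[str, str]], m: dict[tuple[str, str], float]):
    """Generator matrix of the (E, A) pair walk with coalescence absorbing."""
    idx = {d: i for i, d in enumerate(demes)}
    n = len(demes)
    nstates = n * n + 1  # + absorbed (coalesced)
    ABS = n * n
    Q = np.zeros((nstates, nstates))

    def sid(a, b):
        return idx[a] * n + idx[b]

    rate = {}
    for (a, b) in edges:
        rate[(a, b)] = m[(a, b)]
        rate[(b, a)] = m[(a, b)]
    for d1 in demes:
        for d2 in demes:
            s = sid(d1, d2)
            for (a, b), r in rate.items():
                if a == d1:
                    Q[s, sid(b, d2)] += r
                if a == d2:
                    Q[s, sid(d1, b)] += r
            if d1 == d2:
                Q[s, ABS] += 1.0 / (2.0 * sizes[d1])
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q, idx, ABS


def _single_generator(k: int, m0: float) -> np.ndarray:
    """Generator of one lineage's walk on a linear segment of k demes."""
    Q = np.zeros((k, k))
    for i in range(k):
        for j in (i - 1, i + 1):
            if 0 <= j < k:
                Q[i, j] = m0
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def exact_patterson_d_spatial(params: SpatialParams) -> DStat:
    """Deterministic branch-expectation Patterson's D for the spatial model.

    Integrates the structured coalescent exactly: the modern-phase
    distribution of the African/European lineage pair is pushed through
    the colonisation, out-of-Africa and modernisation epochs by matrix
    exponentials, the Neandertal lineage's position distribution over
    its own segment likewise, and the ancestral chain phase is closed
    with :func:`chain_abba_weight`.  Returns the expected ABBA/BABA
    branch weights per locus; ``.d`` is the model's predicted D.

    Exact up to two exponentially small truncations (chimp involvement
    in ingroup genealogies; ingroup coalescence outlasting the outgroup
    split), shared with :func:`expected_patterson_d_spatial`.
    """
    import scipy.linalg

    params.validate()
    g = params.generation_time
    n_nea = params.n_neandertal_demes
    n_afr = params.k_demes - n_nea
    n_eur = params.n_eurasian_demes
    t_exit = params.t_exit / g
    t_modern = params.t_modern / g
    t_split = params.t_neandertal_split / g
    dt = params.colonization_span / g / n_eur
    afr = [f"afr_{q}" for q in range(n_afr)]
    eur = [f"eur_{j}" for j in range(n_eur)]

    def afr_edges(rate):
        return [(afr[q], afr[q + 1]) for q in range(n_afr - 1)], rate

    # state distribution starts with E in the last-colonised deme and A
    # at the far end of the African chain (the default sampling demes)
    e_start = params.european_sample_deme or eur[-1]
    a_start = params.african_sample_deme or afr[-1]

    # --- epoch list: (duration, demes, sizes, edges-with-rates, jump) ---
    epochs = []
    full_eur_edges = [(afr[0], eur[0])] + [(eur[j], eur[j + 1]) for j in range(n_eur - 1)]
    t_prev = 0.0
    # colonisation countdown, most recently founded deme first
    for j in reversed(range(n_eur)):
        founded = t_exit - j * dt
        start = founded - dt
        active_eur = eur[:j + 1]
        demes = afr + active_eur
        sizes = {d: params.N_mod for d in demes}
        sizes[eur[j]] = params.founder_size
        edges = [(a, b) for (a, b) in full_eur_edges if a in demes and b in demes]
        chain, rate = afr_edges(params.m)
        rates = {e: params.m for e in chain + edges}
        jump = {eur[j]: afr[0] if j == 0 else eur[j - 1]}
        if start > t_prev:  # leading slice with everything at N_mod
            sizes0 = {d: params.N_mod for d in demes}
            epochs.append((start - t_prev, demes, sizes0, rates, None))
        epochs.append((dt, demes, sizes, rates, jump))
        t_prev = founded
    # modern African phase
    chain, _ = afr_edges(params.m)
    epochs.append((t_modern - t_exit, afr, {d: params.N_mod for d in afr},
                   {e: params.m for e in chain}, None))
    # ancestral-parameter phase up to the split
    epochs.append((t_split - t_modern, afr, {d: params.N_anc for d in afr},
                   {e: params.m0 for e in chain}, None))

    # --- propagate the (E, A) pair distribution ---
    p = None
    for duration, demes, sizes, rates, jump in epochs:
        Q, idx, ABS = _pair_generator(demes, sizes, list(rates), rates)
        n = len(demes)
        if p is None:
            p = np.zeros(n * n + 1)
            p[idx[e_start] * n + idx[a_start]] = 1.0
        if duration > 0:
            p = p @ scipy.linalg.expm(Q * duration)
        if jump:
            newdemes = [d for d in demes if d not in jump]
            nn = len(newdemes)
            nidx = {d: i for i, d in enumerate(newdemes)}
            pnew = np.zeros(nn * nn + 1)
            move = {d: jump.get(d, d) for d in demes}
            for d1 in demes:
                for d2 in demes:
                    pnew[nidx[move[d1]] * nn + nidx[move[d2]]] += p[idx[d1] * n + idx[d2]]
            pnew[nn * nn] = p[ABS]
            p = pnew
            # re-index for next epoch: next epoch's deme list must match
    # final pair distribution over the African chain
    pair = p[:-1].reshape(n_afr, n_afr)  # [E position, A position]

    # --- Neandertal lineage marginal on its own segment ---
    nea_time = 50_000.0 / g
    if n_nea == 1:
        p_nea = np.array([1.0])
    else:
        Qn = _single_generator(n_nea, params.m0)
        p0 = np.zeros(n_nea)
        p0[0] = 1.0  # sampled at the chain end
        p_nea = p0 @ scipy.linalg.expm(Qn * (t_split - nea_time))

    # --- close with the exact ancestral-chain weights ---
    k = params.k_demes
    tau = chain_pair_coalescence_time(k, params.N_anc, params.m0)
    u = chain_abba_weight(k, params.N_anc, params.m0, tau)
    abba = 0.0
    baba = 0.0
    for i in range(n_nea):
        if p_nea[i] <= 0:
            continue
        for je in range(n_afr):
            for la in range(n_afr):
                w = p_nea[i] * pair[je, la]
                if w <= 0:
                    continue
                abba += w * u[i, n_nea + je, n_nea + la]
                baba += w * u[i, n_nea + la, n_nea + je]
    return DStat(abba, baba)


# ---------------------------------------------------------------------------
# Deterministic expectation for the two-population structure model
# ---------------------------------------------------------------------------


def _occupation_and_terminal(Q: np.ndarray, p0: np.ndarray, T: float):
    """Occupation-time vector and terminal distribution of a CTMC over [0, T].

    Returns ``(occ, pT)`` with ``occ[s] = E[time in s]`` via the
    augmented-generator matrix exponential.
    """
    import scipy.linalg

    n = Q.shape[0]
    aug = np.zeros((2 * n, 2 * n))
    aug[:n, :n] = Q
    aug[:n, n:] = np.eye(n)
    E = scipy.linalg.expm(aug * T)
    pT = p0 @ E[:n, :n]
    occ = p0 @ E[:n, n:]
    return occ, pT


def exact_patterson_d_two_pop(params) -> DStat:
    """Deterministic branch-expectation Patterson's D for the two-population model.

    Same conditioning logic as the spatial solver: no ABBA/BABA weight
    can accrue before the Neandertal split.  The African/European pair
    distribution is propagated through the post-out-of-Africa and
    structured epochs; the structured ancestral phase (three lineages on
    the two subpopulations, exchange ``m_high``) is integrated over its
    finite horizon; the panmictic root phase contributes symmetrically
    (``2 N_anc`` expected pair time regardless of which pair coalesced
    first) and therefore dilutes but cannot bias D.
    """
    import scipy.linalg

    params.validate()
    g = params.generation_time
    t_ooa = params.t_ooa / g
    t_split = params.t_neandertal_split / g
    t_struct = params.t_structure / g
    sizes = {0: params.N_afr, 1: params.N_eur}  # 0 = African, 1 = Eurasian-parent

    # --- recent phase: (E, A) pair on the two demes, EA lineage keeps walking
    # states: (dE, dA) for separate pair (4), then EA-merged at deme d (2)
    def pair_Q(mrate):
        Q = np.zeros((6, 6))
        for dE in (0, 1):
            for dA in (0, 1):
                s = dE * 2 + dA
                Q[s, (1 - dE) * 2 + dA] += mrate
                Q[s, dE * 2 + (1 - dA)] += mrate
                if dE == dA:
                    Q[s, 4 + dE] += 1.0 / (2.0 * sizes[dE])
        for d in (0, 1):
            Q[4 + d, 4 + (1 - d)] += mrate
        np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
        return Q

    p = np.zeros(6)
    p[1 * 2 + 0] = 1.0  # European sampled in deme 1, African in deme 0
    p = p @ scipy.linalg.expm(pair_Q(params.m_low) * t_ooa)
    p = p @ scipy.linalg.expm(pair_Q(params.m_high) * (t_split - t_ooa))

    # --- structured ancestral phase: N joins deme 1; 21 states
    # 0..7   (nN, nE, nA) three lineages separate
    # 8..11  NE merged at d, A at d'   (ABBA-marked)
    # 12..15 NA merged at d, E at d'   (BABA-marked)
    # 16..19 EA merged at d, N at d'
    # 20     done (second coalescence reached)
    m = params.m_high
    Q = np.zeros((21, 21))

    def c(d):
        return 1.0 / (2.0 * sizes[d])

    def s3(nN, nE, nA):
        return (nN * 2 + nE) * 2 + nA

    for nN in (0, 1):
        for nE in (0, 1):
            for nA in (0, 1):
                s = s3(nN, nE, nA)
                Q[s, s3(1 - nN, nE, nA)] += m
                Q[s, s3(nN, 1 - nE, nA)] += m
                Q[s, s3(nN, nE, 1 - nA)] += m
                if nN == nE:
                    Q[s, 8 + nN * 2 + nA] += c(nN)
                if nN == nA:
                    Q[s, 12 + nN * 2 + nE] += c(nN)
                if nE == nA:
                    Q[s, 16 + nE * 2 + nN] += c(nE)
    for base in (8, 12, 16):
        for d in (0, 1):
            for d2 in (0, 1):
                s = base + d * 2 + d2
                Q[s, base + (1 - d) * 2 + d2] += m
                Q[s, base + d * 2 + (1 - d2)] += m
                if d == d2:
                    Q[s, 20] += c(d)
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))

    p3 = np.zeros(21)
    for dE in (0, 1):
        for dA in (0, 1):
            p3[s3(1, dE, dA)] = p[dE * 2 + dA]
    for d in (0, 1):
        p3[16 + d * 2 + 1] = p[4 + d]  # EA merged at d, N in deme 1
    occ, pT = _occupation_and_terminal(Q, p3, t_struct - t_split)

    abba = occ[8:12].sum()
    baba = occ[12:16].sum()
    # panmictic root closure: symmetric, so only surviving marked pairs
    # and the 1/3 chance of an NE (or NA) first coalescence contribute
    root_pair = 2.0 * params.N_anc
    three = pT[:8].sum()
    abba += pT[8:12].sum() * root_pair + three * root_pair / 3.0
    baba += pT[12:16].sum() * root_pair + three * root_pair / 3.0
    return DStat(abba, baba)
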