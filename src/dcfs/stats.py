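"""The doubly conditioned frequency spectrum and Patterson's D.

A site is *doubly conditioned* when the chimp and Neandertal genomes
carry different alleles and the African chromosome carries the chimp
(ancestral) allele; the dcfs is the distribution of the Neandertal
allele's count ``i`` (``1 <= i <= nE``) in the European panel over such
sites.  Patterson's D contrasts ABBA sites (derived allele shared by
the European and Neandertal chromosomes) with BABA sites (shared by the
African and Neandertal chromosomes): ``D = (ABBA - BABA)/(ABBA + BABA)``,
positive when Europeans match Neandertal more often than Africans do.

Both statistics are computed two ways:

* the **site path** counts qualifying sites in a genotype table, after
  polarising every site against the chimp chromosome — the estimator
  one would run on sequenced genomes;
* the **branch path** accumulates, over simulated genealogies, the
  length of every branch on which a mutation would create a qualifying
  site.  This is the infinite-sites expectation of the site path, free
  of the mutation rate and of mutational noise, and is used for
  calibration sweeps.

Branch weights are polarised the same way as sites: a branch whose
descendant set contains the chimp chromosome contributes through the
*complement* of its descendant set, because a mutation there makes every
other chromosome look derived relative to chimp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from dcfs.coalsim import (
    ROLE_AFRICAN,
    ROLE_CHIMP,
    ROLE_EUROPEAN,
    ROLE_NEANDERTAL,
    Genealogy,
    SampleConfig,
)

__all__ = [
    "DCFS",
    "DStat",
    "GenotypeTable",
    "site_dcfs",
    "branch_dcfs",
    "patterson_d_sites",
    "branch_patterson_d",
    "r_squared",
]

_MISSING = {"N", "n", ".", "-", ""}

try:  # pragma: no cover - exercised implicitly
    import numba

    @numba.njit(cache=False)
    def _accumulate_counts(parent, order, init_counts):
        counts = init_counts
        for i in range(order.shape[0]):
            u = order[i]
            p = parent[u]
            if p != -1:
                for k in range(counts.shape[1]):
                    counts[p, k] += counts[u, k]
        return counts

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def _accumulate_counts(parent, order, init_counts):
        counts = init_counts
        for u in order:
            p = parent[u]
            if p != -1:
                counts[p] += counts[u]
        return counts


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class DCFS:
    """Doubly conditioned frequency spectrum over classes ``1..nE``.

    ``weights`` are raw class accumulations (site counts or branch
    lengths); ``proportions`` are the normalised spectrum, ``None`` when
    nothing was retained (the undefined, flagged state).
    """

    weights: np.ndarray
    n_sites_used: float
    n_skipped: int = 0

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)

    @property
    def n_classes(self) -> int:
        return len(self.weights)

    @property
    def undefined(self) -> bool:
        return not self.weights.sum() > 0

    @property
    def proportions(self) -> Optional[np.ndarray]:
        total = self.weights.sum()
        if not total > 0:
            return None
        return self.weights / total

    @classmethod
    def from_proportions(cls, proportions: Sequence[float],
                         n_sites_used: float = 1.0) -> "DCFS":
        p = np.asarray(proportions, dtype=float)
        if p.min() < 0:
            raise ValueError("dcfs proportions must be non-negative")
        return cls(weights=p * n_sites_used, n_sites_used=n_sites_used)

    def to_frame(self) -> pd.DataFrame:
        props = self.proportions
        return pd.DataFrame({
            "class": np.arange(1, self.n_classes + 1),
            "proportion": props if props is not None else np.full(self.n_classes, np.nan),
            "weight": self.weights,
        })


@dataclass
class DStat:
    """Patterson's D with its ABBA/BABA weights (counts or branch lengths)."""

    n_abba: float
    n_baba: float

    @property
    def n_informative(self) -> float:
        return self.n_abba + self.n_baba

    @property
    def undefined(self) -> bool:
        return not self.n_informative > 0

    @property
    def d(self) -> Optional[float]:
        if self.undefined:
            return None
        return (self.n_abba - self.n_baba) / (self.n_abba + self.n_baba)

    def to_dict(self) -> dict:
        return {
            "n_abba": float(self.n_abba),
            "n_baba": float(self.n_baba),
            "n_informative": float(self.n_informative),
            "d": None if self.undefined else float(self.d),
        }


class GenotypeTable:
    """Per-site alleles for the chimp / Neandertal / African / European panel.

    Wraps a DataFrame whose sample columns are named ``chimp_i``,
    ``nea_i``, ``afr_i``, ``eur_i``; any other columns (``locus``,
    ``site``) are carried as metadata.  Alleles may be nucleotide
    letters or 0/1 codes — all statistics only compare alleles against
    the chimp chromosome, never interpret them.
    """

    ROLE_PREFIXES = ("chimp_", "nea_", "afr_", "eur_")

    def __init__(self, data: pd.DataFrame):
        self.data = data.reset_index(drop=True)
        self.sample_columns = [c for c in data.columns
                               if any(c.startswith(p) for p in self.ROLE_PREFIXES)]
        if not any(c.startswith("chimp_") for c in self.sample_columns):
            raise ValueError("genotype table needs at least one chimp_* column")

    def columns_for(self, prefix: str) -> list[str]:
        cols = [c for c in self.sample_columns if c.startswith(prefix)]
        return sorted(cols, key=lambda c: int(c.rsplit("_", 1)[1]))

    @property
    def n_sites(self) -> int:
        return len(self.data)

    @property
    def n_european(self) -> int:
        return len(self.columns_for("eur_"))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, roles: np.ndarray,
                    labels: Optional[list[str]] = None,
                    locus: Optional[int] = None) -> "GenotypeTable":
        """Build from a (sites × samples) 0/1 matrix in sampling order."""
        if labels is None:
            prefixes = ("chimp", "nea", "afr", "eur")
            counters = [0, 0, 0, 0]
            labels = []
            for r in roles:
                labels.append(f"{prefixes[r]}_{counters[r]}")
                counters[r] += 1
        df = pd.DataFrame(np.asarray(matrix), columns=labels)
        if locus is not None:
            df.insert(0, "locus", locus)
        return cls(df)

    @classmethod
    def concat(cls, tables: Iterable["GenotypeTable"]) -> "GenotypeTable":
        frames = [t.data for t in tables]
        if not frames:
            raise ValueError("no tables to concatenate")
        return cls(pd.concat(frames, ignore_index=True))

    def _allele_arrays(self):
        """String allele matrix, chimp reference column, missing/multiallelic masks."""
        arr = self.data[self.sample_columns].to_numpy(dtype=str)
        chimp_col = self.sample_columns.index(self.columns_for("chimp_")[0])
        chimp = arr[:, chimp_col]
        missing = np.isin(arr, sorted(_MISSING)).any(axis=1)
        derived = arr != chimp[:, None]
        any_derived = derived.any(axis=1)
        first_idx = np.argmax(derived, axis=1)
        other = np.where(any_derived, arr[np.arange(len(arr)), first_idx], chimp)
        multi = (derived & (arr != other[:, None])).any(axis=1)
        return arr, derived, missing | multi


# ---------------------------------------------------------------------------
# Site-path statistics
# ---------------------------------------------------------------------------


def site_dcfs(table: GenotypeTable, nE: Optional[int] = None,
              all_africans: bool = False) -> DCFS:
    """Doubly conditioned spectrum from a genotype table.

    A site is retained iff (after polarising against the chimp
    chromosome) the Neandertal carries the derived allele, the
    conditioning African chromosome(s) carry the chimp allele, and the
    derived count ``i`` among the ``nE`` European chromosomes satisfies
    ``1 <= i <= nE``.  By default a single African chromosome conditions
    the spectrum (a modern African genome); ``all_africans=True``
    requires every African chromosome to be ancestral.  Sites with
    missing or more than two alleles are skipped and counted.
    """
    eur_cols = table.columns_for("eur_")
    nea_cols = table.columns_for("nea_")
    afr_cols = table.columns_for("afr_")
    if nE is None:
        nE = len(eur_cols)
    if len(eur_cols) != nE:
        raise ValueError(f"table has {len(eur_cols)} European chromosomes, expected {nE}")
    if nE < 2:
        raise ValueError("the dcfs needs at least two European chromosomes")
    if not nea_cols or not afr_cols:
        raise ValueError("table needs Neandertal and African columns")
    if table.n_sites == 0:
        return DCFS(np.zeros(nE), n_sites_used=0)

    cols = table.sample_columns
    _, derived, skip = table._allele_arrays()
    nea_derived = derived[:, [cols.index(c) for c in nea_cols]].all(axis=1)
    afr_idx = [cols.index(c) for c in (afr_cols if all_africans else afr_cols[:1])]
    afr_ancestral = ~derived[:, afr_idx].any(axis=1)
    eur_count = derived[:, [cols.index(c) for c in eur_cols]].sum(axis=1)

    keep = ~skip & nea_derived & afr_ancestral & (eur_count >= 1) & (eur_count <= nE)
    weights = np.bincount(eur_count[keep], minlength=nE + 1)[1:nE + 1].astype(float)
    return DCFS(weights, n_sites_used=int(keep.sum()), n_skipped=int(skip.sum()))


def patterson_d_sites(table: GenotypeTable, african_index: int = 0,
                      european_index: int = 0) -> DStat:
    """Patterson's D from a genotype table (panel of four).

    Larger panels are reduced to one African and one European
    chromosome chosen by index.  Informative sites are those where the
    Neandertal differs from the chimp and exactly one of the chosen
    African/European chromosomes matches the Neandertal allele.
    """
    cols = table.sample_columns
    nea_cols = table.columns_for("nea_")
    afr_col = table.columns_for("afr_")[african_index]
    eur_col = table.columns_for("eur_")[european_index]
    if table.n_sites == 0:
        return DStat(0.0, 0.0)

    _, derived, skip = table._allele_arrays()
    nea_derived = derived[:, [cols.index(c) for c in nea_cols]].all(axis=1)
    afr_derived = derived[:, cols.index(afr_col)]
    eur_derived = derived[:, cols.index(eur_col)]

    abba = ~skip & nea_derived & eur_derived & ~afr_derived
    baba = ~skip & nea_derived & afr_derived & ~eur_derived
    return DStat(float(abba.sum()), float(baba.sum()))


# ---------------------------------------------------------------------------
# Branch-path statistics
# ---------------------------------------------------------------------------


def _tree_branch_arrays(gen: Genealogy, tracked_roles: np.ndarray):
    """Per-node polarised role counts and branch lengths for one genealogy.

    ``tracked_roles[i]`` is the role code of sample ``i`` or -1 to
    ignore it.  Rows where the tracked chimp chromosome descends from
    the node are replaced by their complement (mutations there look
    derived in everyone else relative to chimp).
    """
    tree = gen.tree
    parent = tree.parent_array
    order = tree.postorder()
    time = gen.ts.tables.nodes.time
    n_nodes = gen.ts.num_nodes
    init = np.zeros((n_nodes, 4), dtype=np.int64)
    tracked = tracked_roles >= 0
    init[np.flatnonzero(tracked), tracked_roles[tracked]] = 1
    counts = _accumulate_counts(parent.astype(np.int64), order.astype(np.int64), init)

    nodes = order[parent[order] != -1]  # every node with a branch above it
    c = counts[nodes].copy()
    totals = np.bincount(tracked_roles[tracked], minlength=4)
    in_chimp = c[:, ROLE_CHIMP] > 0
    c[in_chimp] = totals[None, :] - c[in_chimp]
    blen = time[parent[nodes]] - time[nodes]
    return c, blen


def branch_dcfs(trees: Iterable[Genealogy], sample: Optional[SampleConfig] = None,
                nE: Optional[int] = None) -> DCFS:
    """Expected dcfs from branch lengths over simulated genealogies.

    For each genealogy, class ``i`` accumulates the total length of
    branches whose polarised descendant set is exactly the Neandertal
    chromosome(s) plus ``i`` European chromosomes — no African, no
    chimp.  The normalised accumulation is the infinite-sites
    expectation of :func:`site_dcfs`, independent of the mutation rate.
    """
    trees = iter(trees)
    first = next(trees, None)
    if first is None:
        raise ValueError("trees must be a nonempty collection")
    if nE is None:
        nE = int((first.roles == ROLE_EUROPEAN).sum()) if sample is None else sample.n_european
    if nE < 2:
        raise ValueError("the dcfs needs at least two European chromosomes")
    n_nea = int((first.roles == ROLE_NEANDERTAL).sum())
    weights = np.zeros(nE, dtype=float)
    n_trees = 0

    def _one(gen: Genealogy):
        nonlocal n_trees
        tracked = _tracked_first_chimp(gen.roles)
        c, blen = _tree_branch_arrays(gen, tracked)
        mask = ((c[:, ROLE_CHIMP] == 0) & (c[:, ROLE_AFRICAN] == 0)
                & (c[:, ROLE_NEANDERTAL] == n_nea)
                & (c[:, ROLE_EUROPEAN] >= 1) & (c[:, ROLE_EUROPEAN] <= nE))
        np.add.at(weights, c[mask, ROLE_EUROPEAN] - 1, blen[mask])
        n_trees += 1

    _one(first)
    for gen in trees:
        _one(gen)
    return DCFS(weights, n_sites_used=float(weights.sum()), n_skipped=0)


def _tracked_first_chimp(roles: np.ndarray) -> np.ndarray:
    """Track all samples but only the first chimp chromosome (the reference)."""
    tracked = roles.astype(np.int64).copy()
    chimp_ids = np.flatnonzero(roles == ROLE_CHIMP)
    tracked[chimp_ids[1:]] = -1
    return tracked


def branch_patterson_d(trees: Iterable[Genealogy], sample: Optional[SampleConfig] = None,
                       african_index: int = 0, european_index: int = 0) -> DStat:
    """Expected Patterson's D from branch lengths over genealogies.

    ABBA weight: total length of branches whose polarised descendant set
    contains the Neandertal and the chosen European chromosome but not
    the chosen African chromosome nor the chimp; BABA symmetric with the
    African and European roles swapped.  Chromosomes outside the panel
    of four are marginalised out.
    """
    n_abba = 0.0
    n_baba = 0.0
    n_trees = 0
    for gen in trees:
        tracked = np.full(len(gen.roles), -1, dtype=np.int64)
        chimps = np.flatnonzero(gen.roles == ROLE_CHIMP)
        if len(chimps):  # chimp-free trees need no re-polarisation
            tracked[chimps[0]] = ROLE_CHIMP
        tracked[np.flatnonzero(gen.roles == ROLE_NEANDERTAL)] = ROLE_NEANDERTAL
        tracked[np.flatnonzero(gen.roles == ROLE_AFRICAN)[african_index]] = ROLE_AFRICAN
        tracked[np.flatnonzero(gen.roles == ROLE_EUROPEAN)[european_index]] = ROLE_EUROPEAN
        n_nea = int((tracked == ROLE_NEANDERTAL).sum())
        c, blen = _tree_branch_arrays(gen, tracked)
        base = (c[:, ROLE_CHIMP] == 0) & (c[:, ROLE_NEANDERTAL] == n_nea)
        abba = base & (c[:, ROLE_EUROPEAN] == 1) & (c[:, ROLE_AFRICAN] == 0)
        baba = base & (c[:, ROLE_AFRICAN] == 1) & (c[:, ROLE_EUROPEAN] == 0)
        n_abba += blen[abba].sum()
        n_baba += blen[baba].sum()
        n_trees += 1
    if n_trees == 0:
        raise ValueError("trees must be a nonempty collection")
    return DStat(n_abba, n_baba)


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------


def r_squared(predicted: DCFS, observed: DCFS,
              method: str = "determination") -> Optional[float]:
    """Fit of a predicted dcfs to an observed one, as a percentage.

    Default is the coefficient of determination over frequency classes,
    ``1 - SS_res/SS_tot`` with ``SS_tot`` taken around the observed
    mean; ``method="pearson"`` gives the squared Pearson correlation
    instead.  Returns ``None`` (undefined) when either spectrum is
    undefined or the observed vector is constant.
    """
    if predicted.n_classes != observed.n_classes:
        raise ValueError(
            f"class count mismatch: {predicted.n_classes} vs {observed.n_classes}")
    pred = predicted.proportions
    obs = observed.proportions
    if pred is None or obs is None:
        return None
    if method == "determination":
        ss_tot = float(((obs - obs.mean()) ** 2).sum())
        if ss_tot == 0:
            return None
        ss_res = float(((obs - pred) ** 2).sum())
        return 100.0 * (1.0 - ss_res / ss_tot)
    elif method == "pearson":
        if np.std(obs) == 0 or np.std(pred) == 0:
            return None
        r = float(np.corrcoef(obs, pred)[0, 1])
        return 100.0 * r * r
    raise ValueError(f"unknown method {method!r}")
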