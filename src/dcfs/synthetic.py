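"""Synthetic stand-ins for empirical inputs.

Real applications of the dcfs consume sequenced genomes and a spectrum
estimated from them; neither ships with this package.  This module
generates the corresponding synthetic objects: pseudo-observed dcfs
vectors (a generating demography's branch-expectation spectrum plus
multinomial sampling noise at a stated number of doubly conditioned
loci, since the loci are unlinked) and toy genotype panels built from
explicit per-site descriptors for worked examples and tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from dcfs import demography as dm
from dcfs.calibrate import _build_model
from dcfs.coalsim import SampleConfig, derive_seed, simulate_replicates
from dcfs.stats import DCFS, GenotypeTable, branch_dcfs

__all__ = [
    "PseudoObservedSpec",
    "ToySite",
    "ToyPanelSpec",
    "generate_pseudo_observed",
    "build_toy_panel",
]


@dataclass
class PseudoObservedSpec:
    """Recipe for a pseudo-observed dcfs.

    The generating model's branch dcfs (over ``n_trees`` genealogies)
    plays the role of the population truth; ``n_dc_sites`` doubly
    conditioned loci are then drawn multinomially from it, emulating the
    sampling noise of an empirical spectrum.
    """

    model: str = "spatial"
    params: dict = field(default_factory=dict)
    n_dc_sites: int = 10_000
    n_trees: int = 20_000
    nE: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_dc_sites < 1:
            raise ValueError("n_dc_sites must be >= 1")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.model not in dm._MODEL_BUILDERS:
            raise ValueError(f"unknown model {self.model!r}")


def generate_pseudo_observed(spec: PseudoObservedSpec) -> tuple[DCFS, dict]:
    """Simulate a noisy empirical-style dcfs plus its provenance record.

    Returns ``(observed, provenance)`` where ``observed`` holds the
    multinomial class counts over ``n_dc_sites`` loci and ``provenance``
    records the generating model, parameters, seed and the true
    underlying proportions.
    """
    spec.validate()
    demog = _build_model(spec.model, spec.params)
    sample = SampleConfig(n_european=spec.nE)
    truth = branch_dcfs(
        simulate_replicates(demog, sample, spec.n_trees, derive_seed(spec.seed, 1)))
    p = truth.proportions
    if p is None:
        raise ValueError("generating model produced no doubly conditioned branch weight")
    rng = np.random.default_rng(derive_seed(spec.seed, 2))
    counts = rng.multinomial(spec.n_dc_sites, p)
    observed = DCFS(counts.astype(float), n_sites_used=spec.n_dc_sites)
    provenance = {
        "generator": "generate_pseudo_observed",
        "model": spec.model,
        "params": dict(sorted(spec.params.items())),
        "n_dc_sites": spec.n_dc_sites,
        "n_trees": spec.n_trees,
        "nE": spec.nE,
        "seed": spec.seed,
        "true_proportions": [float(x) for x in p],
    }
    return observed, provenance


@dataclass
class ToySite:
    """One site descriptor: alleles per role and the European derived count."""

    chimp: str = "A"
    neandertal: str = "G"
    african: str = "A"
    derived_count: int = 0  # Europeans carrying the Neandertal allele


@dataclass
class ToyPanelSpec:
    """A toy genotype panel given site by site."""

    sites: Sequence[ToySite] = ()
    nE: int = 10

    def validate(self) -> None:
        if self.nE < 2:
            raise ValueError("nE must be >= 2")
        for k, site in enumerate(self.sites):
            if not 0 <= site.derived_count <= self.nE:
                raise ValueError(
                    f"site {k}: derived count {site.derived_count} exceeds nE={self.nE}")


def build_toy_panel(spec: ToyPanelSpec) -> GenotypeTable:
    """Materialise a descriptor list as a :class:`GenotypeTable`.

    Each site's European panel carries the Neandertal allele on the
    first ``derived_count`` chromosomes and the chimp allele on the
    rest, so ``site_dcfs`` of the panel reproduces the descriptors'
    class histogram exactly.
    """
    spec.validate()
    rows = []
    for k, site in enumerate(spec.sites):
        row = {
            "site": k,
            "chimp_0": site.chimp,
            "nea_0": site.neandertal,
            "afr_0": site.african,
        }
        for j in range(spec.nE):
            row[f"eur_{j}"] = site.neandertal if j < site.derived_count else site.chimp
        rows.append(row)
    columns = (["site", "chimp_0", "nea_0", "afr_0"]
               + [f"eur_{j}" for j in range(spec.nE)])
    return GenotypeTable(pd.DataFrame(rows, columns=columns))
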