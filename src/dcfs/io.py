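"""Readers and writers for the package's plain-text formats.

Universal dialect: tab-separated tables preceded by ``#``-prefixed
provenance header lines (``# key=value``).  Provenance records carry
the tool version, a hash of the generating configuration and the master
seed — never timestamps, so re-running a command reproduces its output
byte for byte.  VCF input is read-only and optional (cyvcf2).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from dcfs.stats import DCFS, DStat, GenotypeTable

__all__ = [
    "make_provenance",
    "write_tsv",
    "read_tsv",
    "dcfs_to_tsv",
    "read_dcfs_tsv",
    "genotype_table_to_tsv",
    "read_genotype_tsv",
    "write_newick",
    "read_newick",
    "dstat_to_json",
    "read_genotype_vcf",
    "read_config",
]


def _version() -> str:
    from dcfs import __version__

    return __version__


def config_hash(config) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()) \
        .hexdigest()[:16]


def make_provenance(seed: Optional[int] = None, config=None, **extra) -> dict:
    prov = {"tool": "dcfs", "version": _version()}
    if seed is not None:
        prov["seed"] = seed
    if config is not None:
        prov["config_hash"] = config_hash(config)
    prov.update(extra)
    return prov


def _header_lines(provenance: Optional[dict]) -> list[str]:
    prov = dict(provenance or {})
    prov.setdefault("tool", "dcfs")
    prov.setdefault("version", _version())
    return [f"# {k}={prov[k]}" for k in prov]


def write_tsv(df: pd.DataFrame, path, provenance: Optional[dict] = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in _header_lines(provenance):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    provenance = {}
    skip = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                provenance[k.strip()] = v.strip()
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    return df, provenance


# ---------------------------------------------------------------------------
# DCFS
# ---------------------------------------------------------------------------


def dcfs_to_tsv(dcfs: DCFS, path, provenance: Optional[dict] = None) -> None:
    write_tsv(dcfs.to_frame(), path, provenance)


def read_dcfs_tsv(path) -> tuple[DCFS, dict]:
    df, prov = read_tsv(path)
    for col in ("class", "proportion"):
        if col not in df.columns:
            raise ValueError(f"dcfs TSV must have a '{col}' column")
    df = df.sort_values("class")
    expected = np.arange(1, len(df) + 1)
    if not np.array_equal(df["class"].to_numpy(), expected):
        raise ValueError("dcfs TSV classes must be 1..nE")
    if "weight" in df.columns and df["weight"].notna().all():
        weights = df["weight"].to_numpy(float)
        return DCFS(weights, n_sites_used=float(weights.sum())), prov
    return DCFS.from_proportions(df["proportion"].to_numpy(float)), prov


# ---------------------------------------------------------------------------
# Genotype tables
# ---------------------------------------------------------------------------


def genotype_table_to_tsv(table: GenotypeTable, path,
                          provenance: Optional[dict] = None) -> None:
    write_tsv(table.data, path, provenance)


def read_genotype_tsv(path) -> tuple[GenotypeTable, dict]:
    df, prov = read_tsv(path)
    return GenotypeTable(df), prov


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def write_newick(trees: Iterable, path, provenance: Optional[dict] = None) -> None:
    """One newick string per line, branch lengths in generations."""
    path = Path(path)
    with path.open("w") as fh:
        for line in _header_lines(provenance):
            fh.write(line + "\n")
        for gen in trees:
            fh.write(gen.newick() + "\n")


def read_newick(path) -> tuple[list[str], dict]:
    provenance = {}
    newicks = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    provenance[k.strip()] = v.strip()
            elif line:
                newicks.append(line)
    return newicks, provenance


# ---------------------------------------------------------------------------
# D reports
# ---------------------------------------------------------------------------


def dstat_to_json(dstat: DStat, path, provenance: Optional[dict] = None) -> None:
    record = {"provenance": dict(provenance or make_provenance())}
    record.update(dstat.to_dict())
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# VCF (optional, read-only)
# ---------------------------------------------------------------------------


def read_genotype_vcf(path, chimp: str, neandertal: str, african: str,
                      europeans: list[str]) -> tuple[GenotypeTable, dict]:
    """Build a genotype table from a VCF.

    One named sample each maps to the chimp, Neandertal and African
    roles (their first allele is used, i.e. the sample is treated as a
    sequenced chromosome); every sample in ``europeans`` contributes
    both alleles of its unphased genotype to the European panel.  Only
    biallelic SNPs are kept; skipped sites are counted in the returned
    provenance.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    for name in [chimp, neandertal, african] + list(europeans):
        if name not in samples:
            raise ValueError(f"sample {name!r} not in VCF (has {samples})")
    idx = {name: samples.index(name) for name in set([chimp, neandertal, african] + list(europeans))}

    rows = []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or not variant.is_snp:
            n_skipped += 1
            continue
        alleles = [variant.REF] + variant.ALT
        gts = variant.genotypes  # [allele0, allele1, phased]
        def allele(sample, which):
            code = gts[idx[sample]][which]
            if code is None or code < 0:
                return "N"
            return alleles[code]
        row = {
            "site": variant.POS,
            "chimp_0": allele(chimp, 0),
            "nea_0": allele(neandertal, 0),
            "afr_0": allele(african, 0),
        }
        j = 0
        for name in europeans:
            row[f"eur_{j}"] = allele(name, 0)
            row[f"eur_{j+1}"] = allele(name, 1)
            j += 2
        rows.append(row)
    columns = (["site", "chimp_0", "nea_0", "afr_0"]
               + [f"eur_{j}" for j in range(2 * len(europeans))])
    table = GenotypeTable(pd.DataFrame(rows, columns=columns))
    return table, {"n_skipped_non_biallelic": n_skipped}


# ---------------------------------------------------------------------------
# Config files
# ---------------------------------------------------------------------------


def read_config(path) -> dict:
    """Flat JSON config file."""
    with Path(path).open() as fh:
        return json.load(fh)
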