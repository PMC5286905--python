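"""Readers and writers for the plain-text formats used by the pipeline.

Conventions: pedigree as CSV (``id,sire,dam`` with "0"/empty for unknown
parents), genotypes as a tab-delimited additive-coded matrix (header of SNP
ids, rows of individual id + 0/1/2 codes, "NA" missing) with a read-only
VCF alternative, phenotypes and kinship matrices as TSV, and long-format
TSV as the canonical results dialect.  Write->read round-trips preserve
values to full precision and id order.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinship import GenotypeMatrix, KinshipMatrix
from .pedigree import Pedigree
from .simulate import SimDataset

logger = logging.getLogger("kinblend")

__all__ = [
    "write_pedigree",
    "write_genotypes",
    "read_genotypes",
    "read_vcf",
    "write_kinship",
    "write_kinship_long",
    "read_kinship",
    "write_phenotypes",
    "read_phenotypes",
    "write_sim_dataset",
    "load_config",
    "write_manifest",
]

_GENO_TOKENS = {"0": 0.0, "1": 1.0, "2": 2.0, "NA": np.nan}


def write_pedigree(pedigree: Pedigree, path) -> None:
    rows = [
        {"id": ind, "sire": s if s is not None else "0",
         "dam": d if d is not None else "0"}
        for ind, s, d in pedigree.records()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_genotypes(g: GenotypeMatrix, path) -> None:
    codes = g.codes
    integral = np.isnan(codes) | (codes == np.round(codes))
    if not integral.all():
        raise ValueError("genotype file format holds integer codes only; "
                         "imputed dosages cannot be written")
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(g.snp_ids) + "\n")
        for ind, row in zip(g.individual_ids, codes):
            toks = ["NA" if np.isnan(v) else str(int(v)) for v in row]
            fh.write(ind + "\t" + "\t".join(toks) + "\n")


def read_genotypes(path) -> GenotypeMatrix:
    """Read a tab-delimited additive-coded genotype matrix.

    Only the tokens 0, 1, 2 and NA are legal; anything else is a parse
    error naming the offending line.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "id":
            raise ValueError(f"{path}: first header column must be 'id'")
        snp_ids = header[1:]
        inds, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            toks = line.rstrip("\n").split("\t")
            if len(toks) != len(snp_ids) + 1:
                raise ValueError(
                    f"{path}: line {lineno} has {len(toks)} fields, "
                    f"expected {len(snp_ids) + 1}"
                )
            inds.append(toks[0])
            try:
                rows.append([_GENO_TOKENS[t] for t in toks[1:]])
            except KeyError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: illegal genotype token {exc.args[0]!r} "
                    "(expected 0, 1, 2 or NA)"
                ) from None
    return GenotypeMatrix(np.array(rows, dtype=float), inds, snp_ids)


def read_vcf(path) -> GenotypeMatrix:
    """Read genotypes from a VCF, converting GT fields to alt-allele dosage."""
    from cyvcf2 import VCF  # optional dependency, imported on demand

    vcf = VCF(str(path))
    inds = list(vcf.samples)
    snp_ids, cols = [], []
    for variant in vcf:
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        col = np.full(len(inds), np.nan)
        for i, gt in enumerate(variant.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if len(alleles) == 2:
                col[i] = float(sum(alleles))
        cols.append(col)
    codes = np.column_stack(cols) if cols else np.empty((len(inds), 0))
    return GenotypeMatrix(codes, inds, snp_ids)


def write_kinship(k: KinshipMatrix, path) -> None:
    df = pd.DataFrame(k.values, index=k.ids, columns=k.ids)
    df.index.name = "id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_kinship_long(k: KinshipMatrix, path) -> None:
    """Long-format (id1, id2, value) upper triangle including the diagonal."""
    iu = np.triu_indices(k.n)
    df = pd.DataFrame({
        "id1": [k.ids[i] for i in iu[0]],
        "id2": [k.ids[j] for j in iu[1]],
        "value": k.values[iu],
    })
    df.to_csv(path, sep="\t", index=False)


def read_kinship(path, kind: str = "K_blend") -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: kinship row and column labels disagree")
    return KinshipMatrix(df.to_numpy(dtype=float), list(df.index), kind=kind)


def write_phenotypes(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index = out.index.astype(str)
    out.index.name = "id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    return df


def write_sim_dataset(ds: SimDataset, outdir) -> dict[str, Path]:
    """Write a simulated dataset: pedigree CSV, genotype TSV, phenotype TSV
    (traits + nuisance columns), and the generating truth (true breeding
    values plus Q_true / R_true)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": outdir / "pedigree.csv",
        "genotypes": outdir / "genotypes.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "true_breeding_values": outdir / "true_breeding_values.tsv",
        "truth_covariances": outdir / "truth_covariances.tsv",
    }
    write_pedigree(ds.pedigree, paths["pedigree"])
    if ds.genotypes is not None:
        write_genotypes(ds.genotypes, paths["genotypes"])
    write_phenotypes(ds.phenotype_frame(), paths["phenotypes"])
    write_phenotypes(ds.breeding_value_frame(), paths["true_breeding_values"])
    names = list(ds.truth.trait_names)
    rows = []
    for label, M in (("Q_true", ds.truth.Q_true), ("R_true", ds.truth.R_true)):
        for i, x in enumerate(names):
            for j, y in enumerate(names):
                rows.append({"matrix": label, "trait_x": x, "trait_y": y,
                             "value": M[i, j]})
    pd.DataFrame(rows).to_csv(paths["truth_covariances"], sep="\t", index=False)
    return paths


def load_config(path) -> dict:
    """Plain-text (YAML) key-value configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a key-value mapping")
    return cfg


def write_manifest(outdir, config: dict, seed: int | None = None,
                   extra: dict | None = None, started: float | None = None) -> Path:
    """Machine-readable run manifest (config echo, seed, version, timing)."""
    from . import __version__

    manifest = {
        "package": "kinblend",
        "version": __version__,
        "seed": seed,
        "config": _jsonable(config),
        "wall_clock_s": None if started is None else round(time.time() - started, 3),
    }
    if extra:
        manifest.update(_jsonable(extra))
    path = Path(outdir) / "manifest.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
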