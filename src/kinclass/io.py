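"""Readers, writers, run configuration and deterministic seeding.

Genotypes travel either as VCF 4.2 (biallelic sites, GT field, ``./.`` for
missing) or as a plain tab-separated 0/1/2 matrix whose header row carries the
individual ids and whose first column carries locus ids ("." for missing
genotypes).  Pedigrees use a PED-like 6-column table and truth labels a flat
CSV.  All report tables are written with fixed column order, 6-decimal floats
and deterministic row order so identical runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import DEGREE_OF_TYPE, MISSING, DiploidGenotypes, GeneticMap, PedigreeSpec

logger = logging.getLogger("kinclass")

GER_GRID = (0.0, 0.01, 0.03, 0.05, 0.07, 0.1)


class ParseError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# Run configuration and seeding
# ---------------------------------------------------------------------------


def stage_seed(master_seed: int, stage: str, replicate: int = 0) -> int:
    """Deterministic per-stage seed derived from the master seed.

    Hashing (seed, stage, replicate) yields independent streams per stage
    while keeping every value below 2**31.
    """
    digest = hashlib.blake2b(
        f"{master_seed}:{stage}:{replicate}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "little") % (2**31)


@dataclass
class RunConfig:
    """Resolved configuration of a full replication run.

    The master seed deterministically fixes every stochastic stage via
    :func:`stage_seed`.  The ``desk`` preset is the scaled-down default
    (2,000 families x 30,000 synthetic SNPs); ``full`` restores the
    full-size design (10,000 families x 582,000 SNPs).
    """

    n_families: int = 2000
    n_loci: int = 30_000
    gers: tuple[float, ...] = GER_GRID
    deletion_rates: tuple[float, ...] = (0.5, 0.75, 0.9)
    backend: str = "rf"
    rf_trees: int = 300
    svm_c: float = 1.0
    k_folds: int = 10
    max_steps: int = 17
    selection_families: int = 120
    selection_trees: int = 40
    selection_folds: int = 5
    missing_runs: int = 10
    grid_replicates: int = 3
    seed: int = 0
    out_dir: str = "kinclass_report"
    scale: str = "desk"

    @classmethod
    def preset(cls, scale: str = "desk", **overrides) -> "RunConfig":
        if scale == "full":
            base = dict(n_families=10_000, n_loci=582_000, scale="full")
        elif scale == "desk":
            base = dict(scale="desk")
        else:
            raise ValueError(f"unknown scale preset {scale!r}")
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("gers", "deletion_rates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["gers"] = list(self.gers)
        data["deletion_rates"] = list(self.deletion_rates)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def stage_seed(self, stage: str, replicate: int = 0) -> int:
        return stage_seed(self.seed, stage, replicate)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: DiploidGenotypes, path, gmap: GeneticMap | None = None) -> None:
    """Write genotypes as a minimal biallelic VCF 4.2 (GT only)."""
    n_ind, n_loci = g.matrix.shape
    if gmap is not None and gmap.n_loci != n_loci:
        raise ParseError("genetic map length does not match genotype matrix")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.individual_ids)
            + "\n"
        )
        for m in range(n_loci):
            if gmap is not None:
                chrom, pos = str(gmap.chrom[m]), str(gmap.pos_bp[m])
            else:
                chrom, pos = "1", str(m + 1)
            gts = "\t".join(_GT_STRINGS[int(v)] for v in g.matrix[:, m])
            fh.write(f"{chrom}\t{pos}\t{g.locus_ids[m]}\tA\tG\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path) -> DiploidGenotypes:
    """Read a biallelic VCF into a 0/1/2 matrix; multi-allelic sites dropped."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    individual_ids = list(vcf.samples)
    rows, locus_ids = [], []
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        gt = np.asarray(variant.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING  # gts012: 3 encodes unknown
        rows.append(gt)
        locus_ids.append(variant.ID or f"c{variant.CHROM}:{variant.POS}")
    vcf.close()
    if n_multi:
        logger.warning("skipped %d multi-allelic sites", n_multi)
    if not rows:
        raise ParseError(f"no usable biallelic records in {path}")
    return DiploidGenotypes(np.stack(rows, axis=1), individual_ids, locus_ids)


# ---------------------------------------------------------------------------
# Plain matrix, pedigree, labels
# ---------------------------------------------------------------------------


def write_matrix(g: DiploidGenotypes, path) -> None:
    """Tab-separated loci x individuals matrix; header row of individual ids."""
    df = pd.DataFrame(g.matrix.T, index=g.locus_ids, columns=g.individual_ids)
    df = df.astype(object).where(df != MISSING, ".")
    df.to_csv(path, sep="\t", index_label="locus")


def read_matrix(path) -> DiploidGenotypes:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["."])
    except Exception as exc:
        raise ParseError(f"cannot parse genotype matrix {path}: {exc}") from exc
    matrix = df.to_numpy(dtype=float).T
    matrix = np.where(np.isnan(matrix), MISSING, matrix).astype(np.int8)
    return DiploidGenotypes(matrix, list(df.columns), [str(i) for i in df.index])


def read_genotypes(path, fmt: str = "vcf") -> DiploidGenotypes:
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "matrix":
        return read_matrix(path)
    raise ParseError(f"unknown genotype format {fmt!r}")


def write_pedigree(pedigree: PedigreeSpec, path, family: str = "fam1") -> None:
    """PED-like table: family, id, father, mother, sex, founder-flag."""
    with open(path, "w") as fh:
        fh.write("family\tid\tfather\tmother\tsex\tfounder\n")
        for m in pedigree.members:
            fa, mo = pedigree.parents.get(m, ("0", "0"))
            founder = 1 if m not in pedigree.parents else 0
            fh.write(f"{family}\t{m}\t{fa}\t{mo}\t{pedigree.sex.get(m, 'U')}\t{founder}\n")


def write_labels(table: pd.DataFrame, path) -> None:
    """Truth labels CSV: pair_id, id1, id2, type, degree, ger."""
    cols = ["pair_id", "id1", "id2", "type", "degree", "ger"]
    table[cols].to_csv(path, index=False)


def read_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"pair_id", "id1", "id2", "type"} - set(df.columns)
    if missing:
        raise ParseError(f"labels file lacks columns {sorted(missing)}")
    if "degree" not in df.columns:
        df["degree"] = df["type"].map(DEGREE_OF_TYPE)
    return df


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path) -> None:
    """CSV with 6-decimal floats and deterministic row order."""
    df.to_csv(path, index=False, float_format="%.6f")


def write_report_tables(results: dict[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write every result table under ``out_dir``; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(results):
        path = out / f"{name}.csv"
        write_table(results[name], path)
        written.append(path)
    return written


def write_seeds(seeds: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        json.dump(seeds, fh, indent=2, sort_keys=True)
        fh.write("\n")
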