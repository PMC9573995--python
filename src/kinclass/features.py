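"""The 17 genotype-only relatedness measures for pairs of SNP profiles.

For a pair of diploid biallelic genotype vectors (coded 0/1/2 as the count of
allele 1, -1 missing) the measures are, in fixed order::

    K0, K1, IBS0, IBS1, IBS2, IBS01, IBS12, IBS02, j1, ..., j9

* ``K1`` is the KING-robust kinship estimator built from heterozygote and
  opposite-homozygote counts; it requires no allele frequencies and is robust
  to population structure.
* ``K0`` is the KING-homo kinship estimator for a homogeneous population,
  built from squared genotype differences and sample allele frequencies
  estimated once from all genotypes in the analyzed dataset.
* ``IBS0/1/2`` are the fractions of loci sharing 0, 1 or 2 alleles identical
  by state; ``IBS01``, ``IBS12`` and ``IBS02`` are the pairwise unions.
* ``j1..j9`` are the nine ordered joint-genotype category fractions, row-major
  in (g_i, g_j): j1=(0,0), j2=(0,1), j3=(0,2), j4=(1,0), j5=(1,1), j6=(1,2),
  j7=(2,0), j8=(2,1), j9=(2,2).

Loci with a missing genotype in either profile are excluded from every count.
Measures based on population allele frequencies beyond the sample estimate,
and on IBD segments, are deliberately out of scope: the features must be
computable from the two genotype vectors alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import DEGREE_OF_TYPE, MISSING, PairDataset

logger = logging.getLogger("kinclass")

FEATURE_NAMES: tuple[str, ...] = (
    "K0", "K1", "IBS0", "IBS1", "IBS2", "IBS01", "IBS12", "IBS02",
    "j1", "j2", "j3", "j4", "j5", "j6", "j7", "j8", "j9",
)

LABEL_COLUMNS = ("pair_id", "id1", "id2", "type", "degree", "ger")

# squared genotype difference for each ordered joint category (row-major)
_SQ_DIFF = np.array([0, 1, 4, 1, 0, 1, 4, 1, 0], dtype=np.int64)
_HET_I = (3, 4, 5)   # categories where individual i is heterozygous
_HET_J = (1, 4, 7)
_OPP_HOM = (2, 6)    # (0,2) and (2,0)
_IBS2_CAT = (0, 4, 8)


class FeatureInputError(ValueError):
    """Malformed input to a feature computation."""


@dataclass
class PairCounts:
    """Ordered 3x3 joint genotype counts for one pair (both loci observed).

    ``table[a, b]`` counts loci where individual i carries genotype ``a`` and
    individual j carries ``b``.  ``sum_pq`` optionally carries the summed
    allele-frequency variance term over the same loci, needed only by K0.
    """

    table: np.ndarray  # (3, 3) int64
    sum_pq: float | None = None

    @property
    def n_valid(self) -> int:
        return int(self.table.sum())

    @property
    def flat(self) -> np.ndarray:
        """Row-major j1..j9 counts."""
        return self.table.reshape(9)


def compute_pair_counts(
    gi: np.ndarray, gj: np.ndarray, allele_freq: np.ndarray | None = None
) -> PairCounts:
    """Tally the nine ordered joint-genotype counts for one pair of profiles."""
    gi = np.asarray(gi, dtype=np.int8)
    gj = np.asarray(gj, dtype=np.int8)
    if gi.shape != gj.shape or gi.ndim != 1:
        raise FeatureInputError("genotype vectors must be 1-D with equal length")
    valid = (gi != MISSING) & (gj != MISSING)
    code = 3 * gi[valid].astype(np.int64) + gj[valid]
    table = np.bincount(code, minlength=9).reshape(3, 3)
    sum_pq = None
    if allele_freq is not None:
        p = np.asarray(allele_freq, dtype=float)
        if p.shape != gi.shape:
            raise FeatureInputError("allele_freq must match genotype length")
        sum_pq = float(np.sum(p[valid] * (1.0 - p[valid])))
    return PairCounts(table=table, sum_pq=sum_pq)


def king_robust(counts: PairCounts, denominator: str = "symmetric") -> float:
    """KING-robust kinship K1 from the joint counts.

    The default "symmetric" form, K1 = (n11 - 2 (n02 + n20)) /
    (N_het(i) + N_het(j)), is invariant to pair order.  The "min" form
    divides by 2 min(N_het(i), N_het(j)) instead, the between-family variant
    conditioning on the less heterozygous individual.  NaN when neither
    individual is heterozygous at any shared locus.
    """
    c = counts.flat
    het_i = int(c[list(_HET_I)].sum())
    het_j = int(c[list(_HET_J)].sum())
    if denominator == "symmetric":
        denom = het_i + het_j
    elif denominator == "min":
        denom = 2 * min(het_i, het_j)
    else:
        raise FeatureInputError(f"unknown K1 denominator {denominator!r}")
    if denom == 0:
        return float("nan")
    n11 = int(c[4])
    opp = int(c[list(_OPP_HOM)].sum())
    return (n11 - 2.0 * opp) / denom


def king_homo(gi: np.ndarray, gj: np.ndarray, allele_freq: np.ndarray) -> float:
    """KING-homo kinship K0 = (1 - D / (4 sum p(1-p))) / 2.

    ``D`` is the squared genotype difference summed over mutually observed
    loci; the frequency-variance sum runs over the same loci.  NaN when the
    denominator vanishes.
    """
    counts = compute_pair_counts(gi, gj, allele_freq=allele_freq)
    d = float(counts.flat @ _SQ_DIFF)
    if counts.sum_pq is None or counts.sum_pq <= 0.0:
        return float("nan")
    return 0.5 * (1.0 - d / (4.0 * counts.sum_pq))


def ibs_fractions(counts: PairCounts) -> tuple[float, float, float, float, float, float]:
    """(IBS0, IBS1, IBS2, IBS01, IBS12, IBS02) as fractions of valid loci."""
    n = counts.n_valid
    if n == 0:
        nan = float("nan")
        return (nan,) * 6
    c = counts.flat
    ibs0 = c[list(_OPP_HOM)].sum() / n
    ibs2 = c[list(_IBS2_CAT)].sum() / n
    ibs1 = 1.0 - ibs0 - ibs2
    return (ibs0, ibs1, ibs2, ibs0 + ibs1, ibs1 + ibs2, ibs0 + ibs2)


def joint_fractions(counts: PairCounts) -> tuple[float, ...]:
    """(j1..j9): the ordered joint-genotype fractions, row-major in (gi, gj)."""
    n = counts.n_valid
    if n == 0:
        return (float("nan"),) * 9
    return tuple(counts.flat / n)


def feature_vector(
    gi: np.ndarray, gj: np.ndarray, allele_freq: np.ndarray
) -> np.ndarray:
    """All 17 measures for one pair, in ``FEATURE_NAMES`` order."""
    counts = compute_pair_counts(gi, gj, allele_freq=allele_freq)
    k0 = king_homo(gi, gj, allele_freq)
    k1 = king_robust(counts)
    return np.array([k0, k1, *ibs_fractions(counts), *joint_fractions(counts)])


# ---------------------------------------------------------------------------
# Vectorized batch computation
# ---------------------------------------------------------------------------


def estimate_allele_freq(genotype_matrices) -> np.ndarray:
    """Per-locus sample frequency of allele 1 across all given genotypes.

    Accepts an iterable of (n, n_loci) int8 matrices (missing coded -1) and
    pools all individuals; this is the dataset-wide estimate used by K0.
    """
    num = None
    den = None
    for g in genotype_matrices:
        obs = g != MISSING
        contrib = np.where(obs, g, 0).sum(axis=0, dtype=np.int64)
        cnt = obs.sum(axis=0, dtype=np.int64)
        num = contrib if num is None else num + contrib
        den = cnt if den is None else den + cnt
    if num is None:
        raise FeatureInputError("no genotype matrices given")
    with np.errstate(invalid="ignore"):
        return num / (2.0 * den)


def pair_feature_matrix(
    gi: np.ndarray,
    gj: np.ndarray,
    allele_freq: np.ndarray,
    chunk: int = 1024,
) -> np.ndarray:
    """(n_pairs, 17) feature matrix for row-aligned genotype matrices.

    Chunked over pairs to bound peak memory; exactly equivalent to calling
    :func:`feature_vector` per row.
    """
    gi = np.atleast_2d(np.asarray(gi, dtype=np.int8))
    gj = np.atleast_2d(np.asarray(gj, dtype=np.int8))
    if gi.shape != gj.shape:
        raise FeatureInputError("genotype matrices must have equal shape")
    n_pairs = gi.shape[0]
    pq = (allele_freq * (1.0 - allele_freq)).astype(np.float64)
    out = np.empty((n_pairs, len(FEATURE_NAMES)), dtype=np.float64)
    for lo in range(0, n_pairs, chunk):
        sl = slice(lo, min(lo + chunk, n_pairs))
        a, b = gi[sl], gj[sl]
        valid = (a != MISSING) & (b != MISSING)
        code = (3 * a.astype(np.int16) + b)
        counts = np.empty((a.shape[0], 9), dtype=np.int64)
        for k in range(9):
            counts[:, k] = ((code == k) & valid).sum(axis=1)
        n_valid = counts.sum(axis=1).astype(np.float64)
        sum_pq = valid.astype(np.float64) @ pq
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = counts / n_valid[:, None]
            d = (counts @ _SQ_DIFF).astype(np.float64)
            k0 = 0.5 * (1.0 - d / (4.0 * sum_pq))
            k0[sum_pq <= 0.0] = np.nan
            het = (
                counts[:, list(_HET_I)].sum(axis=1)
                + counts[:, list(_HET_J)].sum(axis=1)
            ).astype(np.float64)
            k1 = (counts[:, 4] - 2.0 * counts[:, list(_OPP_HOM)].sum(axis=1)) / het
            k1[het == 0] = np.nan
            ibs0 = frac[:, list(_OPP_HOM)].sum(axis=1)
            ibs2 = frac[:, list(_IBS2_CAT)].sum(axis=1)
            ibs1 = 1.0 - ibs0 - ibs2
        out[sl, 0] = k0
        out[sl, 1] = k1
        out[sl, 2] = ibs0
        out[sl, 3] = ibs1
        out[sl, 4] = ibs2
        out[sl, 5] = ibs0 + ibs1
        out[sl, 6] = ibs1 + ibs2
        out[sl, 7] = ibs0 + ibs2
        out[sl, 8:] = frac
    return out


def extract_features(
    dataset: PairDataset,
    pair_types: list[str] | None = None,
    allele_freq: np.ndarray | None = None,
) -> pd.DataFrame:
    """Feature table for every pair in the dataset (one row per pair).

    Columns: pair_id, id1, id2, type, degree, ger, then the 17 features.
    Degenerate pairs (no mutually observed loci or a zero denominator) are
    excluded with a logged count.  Allele frequencies for K0 are estimated
    from all genotypes in the dataset unless given explicitly.
    """
    catalog = dataset.catalog
    if pair_types is not None:
        catalog = tuple(e for e in catalog if e[0] in pair_types)
        if not catalog:
            raise FeatureInputError(f"no catalog entries match {pair_types!r}")
    if allele_freq is None:
        allele_freq = estimate_allele_freq(dataset.genotypes.values())
    frames = []
    n_fam = dataset.n_families
    for pair_type, a, b in catalog:
        feats = pair_feature_matrix(dataset.genotypes[a], dataset.genotypes[b], allele_freq)
        df = pd.DataFrame(feats, columns=list(FEATURE_NAMES))
        df.insert(0, "pair_id", [f"{pair_type}-{i}" for i in range(n_fam)])
        df.insert(1, "id1", a)
        df.insert(2, "id2", b)
        df.insert(3, "type", pair_type)
        df.insert(4, "degree", DEGREE_OF_TYPE[pair_type])
        df.insert(5, "ger", dataset.ger)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    bad = table[list(FEATURE_NAMES)].isna().any(axis=1)
    if bad.any():
        logger.warning("dropping %d degenerate pairs (undefined features)", int(bad.sum()))
        table = table.loc[~bad].reset_index(drop=True)
    return table
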