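"""Pedigree genotype simulation: founders, gene dropping, and error injection.

Founder haplotypes are drawn in linkage equilibrium with per-locus allele
frequencies uniform on a configurable interval, so founder genotypes are in
Hardy-Weinberg equilibrium by construction.  Descendants are produced by gene
dropping: each meiosis samples crossovers as a Poisson process on the genetic
map (count ~ Poisson(chromosome length in Morgans), positions uniform in cM)
and alternates between the two parental haplotypes from a fair random start,
independently per chromosome.  Genotyping error corrupts each called genotype
independently with probability ``ger`` by flipping one of its two alleles.

The default pedigree is a 12-member, 4-generation family whose sampled pairs
cover the ten relationship types used throughout the package: one pair per
type per simulated family, giving balanced classes by design.
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass, field, replace

import numpy as np

MISSING = -1

#: relationship type -> degree (0 encodes "unrelated")
DEGREE_OF_TYPE = {
    "unrelated": 0,
    "parent-child": 1,
    "full-sibling": 1,
    "grandparent": 2,
    "half-sibling": 2,
    "uncle-nephew": 2,
    "first-cousin": 3,
    "grand-uncle": 3,
    "half-uncle": 3,
    "great-grandparent": 3,
}

RELATIONSHIP_TYPES = tuple(DEGREE_OF_TYPE)

TYPES_BY_DEGREE = {
    1: ("parent-child", "full-sibling"),
    2: ("grandparent", "half-sibling", "uncle-nephew"),
    3: ("first-cousin", "grand-uncle", "half-uncle", "great-grandparent"),
}

DEGREE_LABELS = {0: "unrelated", 1: "1st", 2: "2nd", 3: "3rd"}


class ConfigurationError(ValueError):
    """Invalid simulation or analysis configuration."""


class PedigreeError(ValueError):
    """Structurally invalid pedigree (cycle, missing parent, bad catalog)."""


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneticMap:
    """Physical and genetic positions of the simulated loci.

    Attributes
    ----------
    chrom : per-locus chromosome id (contiguous blocks, ascending).
    pos_bp : per-locus physical position, strictly ascending within chromosome.
    pos_cm : per-locus genetic position in centimorgan, non-decreasing within
        chromosome.
    """

    chrom: np.ndarray
    pos_bp: np.ndarray
    pos_cm: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.chrom)
        if not (len(self.pos_bp) == len(self.pos_cm) == n):
            raise ConfigurationError("map fields must have equal length")
        for c in np.unique(self.chrom):
            sel = self.chrom == c
            if np.any(np.diff(self.pos_bp[sel]) <= 0):
                raise ConfigurationError(f"physical positions not ascending on chrom {c}")
            if np.any(np.diff(self.pos_cm[sel]) < 0):
                raise ConfigurationError(f"genetic positions decreasing on chrom {c}")

    @property
    def n_loci(self) -> int:
        return len(self.chrom)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.unique(self.chrom)

    def chrom_slices(self) -> list[tuple[int, slice]]:
        """(chromosome id, locus slice) in genome order; loci are contiguous."""
        out = []
        start = 0
        for c in self.chromosomes:
            n_c = int(np.sum(self.chrom == c))
            out.append((int(c), slice(start, start + n_c)))
            start += n_c
        return out

    @property
    def total_morgans(self) -> float:
        return sum(
            (self.pos_cm[sl][-1] - self.pos_cm[sl][0]) / 100.0
            for _, sl in self.chrom_slices()
        )

    @classmethod
    def uniform(
        cls, n_loci: int, n_chromosomes: int = 22, total_cm: float = 3500.0
    ) -> "GeneticMap":
        """Evenly spaced loci on equal-length pseudo-chromosomes (~1 cM/Mb)."""
        if n_loci < 1 or n_chromosomes < 1:
            raise ConfigurationError("n_loci and n_chromosomes must be positive")
        if total_cm < 0:
            raise ConfigurationError("total_cm must be non-negative")
        per = np.full(n_chromosomes, n_loci // n_chromosomes, dtype=int)
        per[: n_loci % n_chromosomes] += 1
        per = per[per > 0]
        len_cm = total_cm / len(per)
        chrom, bp, cm = [], [], []
        for i, n_c in enumerate(per):
            chrom.append(np.full(n_c, i + 1, dtype=np.int32))
            g = np.linspace(0.0, len_cm, n_c) if n_c > 1 else np.array([0.0])
            cm.append(g)
            # ~1 cM/Mb; the arange term keeps bp strictly ascending on flat maps
            bp.append(np.round(g * 1e6).astype(np.int64) + np.arange(n_c) + 1)
        return cls(np.concatenate(chrom), np.concatenate(bp), np.concatenate(cm))


# ---------------------------------------------------------------------------
# Founder panel
# ---------------------------------------------------------------------------


@dataclass
class FounderPanel:
    """Phased founder haplotypes with per-locus allele frequencies and map."""

    haplotypes: np.ndarray  # (2 * n_founders, n_loci) uint8 in {0, 1}
    allele_freq: np.ndarray  # sampling frequency p_m of allele 1 per locus
    gmap: GeneticMap

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[1]


def simulate_founder_panel(
    n_founders: int,
    n_loci: int,
    freq_bounds: tuple[float, float] = (0.05, 0.95),
    gmap: GeneticMap | None = None,
    seed: int = 0,
) -> FounderPanel:
    """Draw unrelated founders in HWE and linkage equilibrium.

    Per-locus allele-1 frequencies are sampled uniformly on ``freq_bounds``;
    haplotype alleles are independent Bernoulli draws at those frequencies.
    """
    f_min, f_max = freq_bounds
    if n_founders <= 0 or n_loci <= 0:
        raise ConfigurationError("n_founders and n_loci must be positive")
    if not (0.0 < f_min <= f_max < 1.0):
        raise ConfigurationError(f"invalid frequency bounds {freq_bounds!r}")
    if gmap is None:
        gmap = GeneticMap.uniform(n_loci)
    if gmap.n_loci != n_loci:
        raise ConfigurationError("genetic map length does not match n_loci")
    rng = np.random.default_rng(seed)
    p = rng.uniform(f_min, f_max, size=n_loci)
    haps = (rng.random(size=(2 * n_founders, n_loci)) < p).astype(np.uint8)
    return FounderPanel(haplotypes=haps, allele_freq=p, gmap=gmap)


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PedigreeSpec:
    """Pedigree topology plus the labeled pairs sampled from each family.

    ``parents`` maps each non-founder to its (father, mother); members absent
    from ``parents`` are founders.  ``pair_catalog`` lists, per relationship
    type, the ordered member pair extracted from every simulated family.
    """

    members: tuple[str, ...]
    parents: dict[str, tuple[str, str]]
    sex: dict[str, str]
    pair_catalog: tuple[tuple[str, str, str], ...]  # (type, id1, id2)

    def __post_init__(self) -> None:
        ids = set(self.members)
        for child, (fa, mo) in self.parents.items():
            if child not in ids or fa not in ids or mo not in ids:
                raise PedigreeError(f"unknown member in parent link for {child!r}")
        try:
            self.topological_order()
        except graphlib.CycleError as exc:  # pragma: no cover - defensive
            raise PedigreeError("pedigree contains a cycle") from exc
        types = [t for t, _, _ in self.pair_catalog]
        if sorted(types) != sorted(RELATIONSHIP_TYPES):
            raise PedigreeError(
                "pair catalog must contain each of the 10 relationship types once"
            )
        for t, a, b in self.pair_catalog:
            if a not in ids or b not in ids:
                raise PedigreeError(f"catalog pair ({a}, {b}) references unknown member")

    @property
    def founders(self) -> tuple[str, ...]:
        return tuple(m for m in self.members if m not in self.parents)

    def topological_order(self) -> list[str]:
        ts = graphlib.TopologicalSorter(
            {m: set(self.parents.get(m, ())) for m in self.members}
        )
        return list(ts.static_order())


def default_pedigree() -> PedigreeSpec:
    """The built-in 12-member, 4-generation pedigree.

    Six founders (F1-F3 plus married-in S1-S3) and six descendants yield one
    pair of each of the ten relationship types; the unrelated pair is taken
    between two married-in founders of the same family.
    """
    members = ("F1", "F2", "F3", "S1", "S2", "S3", "C1", "C2", "C3", "G1", "H1", "GG1")
    parents = {
        "C1": ("F1", "F2"),
        "C2": ("F1", "F2"),
        "C3": ("F1", "F3"),
        "G1": ("C1", "S1"),
        "H1": ("C2", "S2"),
        "GG1": ("G1", "S3"),
    }
    sex = {
        "F1": "M", "F2": "F", "F3": "F", "S1": "F", "S2": "F", "S3": "F",
        "C1": "M", "C2": "M", "C3": "M", "G1": "M", "H1": "M", "GG1": "M",
    }
    catalog = (
        ("unrelated", "F2", "F3"),
        ("parent-child", "C1", "G1"),
        ("full-sibling", "C1", "C2"),
        ("grandparent", "F1", "G1"),
        ("half-sibling", "C1", "C3"),
        ("uncle-nephew", "C2", "G1"),
        ("first-cousin", "G1", "H1"),
        ("grand-uncle", "C2", "GG1"),
        ("half-uncle", "C3", "G1"),
        ("great-grandparent", "F1", "GG1"),
    )
    return PedigreeSpec(members, parents, sex, catalog)


# ---------------------------------------------------------------------------
# Meiosis and gene dropping
# ---------------------------------------------------------------------------


def sample_meiosis_indicators(
    gmap: GeneticMap, n_meioses: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample which parental haplotype is transmitted at every locus.

    Returns ``(indicator, n_crossovers)`` where ``indicator`` is a
    (n_meioses, n_loci) uint8 array choosing haplotype 0 or 1, and
    ``n_crossovers`` is the total crossover count per meiosis.  Crossover
    counts are Poisson in the chromosome's genetic length (Morgans), positions
    uniform in cM, with an independent fair random start per chromosome.
    """
    n_loci = gmap.n_loci
    indicator = np.empty((n_meioses, n_loci), dtype=np.uint8)
    n_x = np.zeros(n_meioses, dtype=np.int64)
    for _, sl in gmap.chrom_slices():
        cm = gmap.pos_cm[sl]
        length_m = (cm[-1] - cm[0]) / 100.0
        start = rng.integers(0, 2, size=n_meioses, dtype=np.uint8)
        n_c = sl.stop - sl.start
        if length_m <= 0:
            indicator[:, sl] = start[:, None]
            continue
        k = rng.poisson(length_m, size=n_meioses)
        n_x += k
        pos = rng.uniform(cm[0], cm[-1], size=int(k.sum()))
        meiosis_idx = np.repeat(np.arange(n_meioses), k)
        # locus index of the first locus strictly after each crossover
        loc = np.searchsorted(cm, pos, side="right")
        hits = np.zeros((n_meioses, n_c), dtype=np.int32)
        keep = loc < n_c
        np.add.at(hits, (meiosis_idx[keep], loc[keep]), 1)
        parity = np.cumsum(hits, axis=1, dtype=np.int32) & 1
        indicator[:, sl] = (start[:, None] ^ parity).astype(np.uint8)
    return indicator, n_x


def _transmit(
    hap0: np.ndarray, hap1: np.ndarray, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """One gamete per row of the (n, n_loci) parental haplotype pair."""
    indicator, _ = sample_meiosis_indicators(gmap, hap0.shape[0], rng)
    return np.where(indicator == 0, hap0, hap1)


def _drop_haplotypes(
    pedigree: PedigreeSpec,
    panel: FounderPanel,
    founder_rows: dict[str, tuple[np.ndarray, np.ndarray]],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Gene-drop haplotypes through the pedigree; returns member genotypes.

    ``founder_rows`` maps each founder to its two haplotype arrays of shape
    (n_families, n_loci).  Haplotypes of members with no remaining offspring
    are freed as the drop proceeds to bound peak memory.
    """
    order = pedigree.topological_order()
    children_of: dict[str, list[str]] = {m: [] for m in pedigree.members}
    for child, (fa, mo) in pedigree.parents.items():
        children_of[fa].append(child)
        children_of[mo].append(child)
    pending = {m: len(children_of[m]) for m in pedigree.members}

    haps: dict[str, tuple[np.ndarray, np.ndarray]] = dict(founder_rows)
    genotypes: dict[str, np.ndarray] = {}
    for member in order:
        if member in pedigree.parents:
            fa, mo = pedigree.parents[member]
            paternal = _transmit(*haps[fa], panel.gmap, rng)
            maternal = _transmit(*haps[mo], panel.gmap, rng)
            haps[member] = (paternal, maternal)
            for parent in (fa, mo):
                pending[parent] -= 1
                if pending[parent] == 0:
                    del haps[parent]
        h0, h1 = haps[member]
        genotypes[member] = (h0 + h1).astype(np.int8)
        if pending[member] == 0:
            del haps[member]
    return genotypes


def _sample_founder_rows(
    pedigree: PedigreeSpec,
    panel: FounderPanel,
    n_families: int,
    rng: np.random.Generator,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    founders = pedigree.founders
    if panel.n_founders < len(founders):
        raise ConfigurationError(
            f"panel has {panel.n_founders} founders; pedigree needs {len(founders)}"
        )
    # distinct founders within each family; independent draws across families
    order = np.argsort(rng.random((n_families, panel.n_founders)), axis=1)
    picks = order[:, : len(founders)]
    rows = {}
    for j, member in enumerate(founders):
        idx = picks[:, j]
        rows[member] = (panel.haplotypes[2 * idx], panel.haplotypes[2 * idx + 1])
    return rows


@dataclass
class DiploidGenotypes:
    """Genotype matrix (individuals x loci) counting allele 1; -1 is missing."""

    matrix: np.ndarray  # int8
    individual_ids: list[str]
    locus_ids: list[str]

    def __post_init__(self) -> None:
        vals = np.unique(self.matrix)
        if not np.all(np.isin(vals, [MISSING, 0, 1, 2])):
            raise ConfigurationError("genotypes must be in {0, 1, 2, MISSING}")


def gene_drop(
    pedigree: PedigreeSpec, panel: FounderPanel, seed: int = 0, n_families: int = 1
) -> DiploidGenotypes:
    """Simulate one or more families; rows are ``fam{i}_{member}``."""
    rng = np.random.default_rng(seed)
    rows = _sample_founder_rows(pedigree, panel, n_families, rng)
    genos = _drop_haplotypes(pedigree, panel, rows, rng)
    order = pedigree.topological_order()
    matrix = np.concatenate([genos[m] for m in order], axis=0)
    ids = [f"fam{i}_{m}" for m in order for i in range(n_families)]
    locus_ids = [f"c{c}:{p}" for c, p in zip(panel.gmap.chrom, panel.gmap.pos_bp)]
    return DiploidGenotypes(matrix, ids, locus_ids)


# ---------------------------------------------------------------------------
# Genotyping error and SNP deletion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ErrorModel:
    """Single-allele-flip genotyping error at per-genotype rate ``ger``."""

    ger: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ger <= 1.0):
            raise ConfigurationError(f"genotyping error rate {self.ger} outside [0, 1]")


def _corrupt(matrix: np.ndarray, ger: float, rng: np.random.Generator) -> np.ndarray:
    """Flip one uniformly chosen allele of each selected genotype.

    Homozygotes always become heterozygous; heterozygotes become either
    homozygote with equal probability.  Every flip changes the called genotype,
    so the changed fraction equals ``ger`` in expectation.
    """
    if ger == 0.0:
        return matrix.copy()
    r = rng.random(matrix.shape, dtype=np.float32)
    hit = (r < ger) & (matrix != MISSING)
    # conditional on a hit, r < ger/2 is a fair coin for which allele flips
    up = r < ger / 2.0
    flipped = np.where(matrix == 1, np.where(up, 2, 0), 1).astype(np.int8)
    return np.where(hit, flipped, matrix)


def apply_genotyping_error(g: DiploidGenotypes, model: ErrorModel) -> DiploidGenotypes:
    rng = np.random.default_rng(model.seed)
    return DiploidGenotypes(_corrupt(g.matrix, model.ger, rng), list(g.individual_ids), list(g.locus_ids))


def delete_snps(g: DiploidGenotypes, deletion_rate: float, seed: int = 0) -> DiploidGenotypes:
    """Remove a uniformly random ``floor(rate * n_loci)`` subset of loci."""
    keep = _deletion_keep_index(len(g.locus_ids), deletion_rate, seed)
    return DiploidGenotypes(
        g.matrix[:, keep],
        list(g.individual_ids),
        [g.locus_ids[i] for i in keep],
    )


def _deletion_keep_index(n_loci: int, deletion_rate: float, seed: int) -> np.ndarray:
    if not (0.0 <= deletion_rate < 1.0):
        raise ConfigurationError(f"deletion rate {deletion_rate} outside [0, 1)")
    n_drop = int(np.floor(deletion_rate * n_loci))
    rng = np.random.default_rng(seed)
    drop = rng.choice(n_loci, size=n_drop, replace=False)
    keep = np.setdiff1d(np.arange(n_loci), drop)
    return keep


# ---------------------------------------------------------------------------
# Pair dataset
# ---------------------------------------------------------------------------


@dataclass
class PairDataset:
    """Labeled pairs of genotype vectors, the unit of training and testing.

    ``genotypes`` maps pedigree member names to (n_families, n_loci) int8
    matrices; ``catalog`` lists one (type, id1, id2) entry per relationship
    type, so the dataset holds ``len(catalog) * n_families`` pairs with
    balanced per-type counts.
    """

    genotypes: dict[str, np.ndarray]
    catalog: tuple[tuple[str, str, str], ...]
    n_families: int
    ger: float
    gmap: GeneticMap
    locus_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.locus_index is None:
            self.locus_index = np.arange(self.gmap.n_loci)

    @property
    def n_pairs(self) -> int:
        return len(self.catalog) * self.n_families

    @property
    def n_loci(self) -> int:
        return next(iter(self.genotypes.values())).shape[1]

    def subset(self, pair_types: list[str]) -> "PairDataset":
        """Restrict to a subset of relationship types (and their members)."""
        catalog = tuple(e for e in self.catalog if e[0] in pair_types)
        if not catalog:
            raise ConfigurationError(f"no catalog entries match {pair_types!r}")
        members = {m for _, a, b in catalog for m in (a, b)}
        genos = {m: self.genotypes[m] for m in members}
        return replace(self, genotypes=genos, catalog=catalog)

    def subset_families(self, n_families: int) -> "PairDataset":
        """Restrict to the first ``n_families`` simulated families."""
        if not (0 < n_families <= self.n_families):
            raise ConfigurationError("n_families out of range")
        genos = {m: g[:n_families] for m, g in self.genotypes.items()}
        return replace(self, genotypes=genos, n_families=n_families)

    def with_error(self, ger: float, seed: int = 0) -> "PairDataset":
        """Return a copy with fresh genotyping error at rate ``ger``.

        Intended for corrupting an error-free dataset; per-member error
        streams are derived deterministically from ``seed``.
        """
        ErrorModel(ger)  # validate
        ss = np.random.SeedSequence(seed)
        genos = {}
        for member, child_ss in zip(sorted(self.genotypes), ss.spawn(len(self.genotypes))):
            rng = np.random.default_rng(child_ss)
            genos[member] = _corrupt(self.genotypes[member], ger, rng)
        return replace(self, genotypes=genos, ger=ger)

    def delete_snps(self, deletion_rate: float, seed: int = 0) -> "PairDataset":
        keep = _deletion_keep_index(self.n_loci, deletion_rate, seed)
        genos = {m: g[:, keep] for m, g in self.genotypes.items()}
        return replace(self, genotypes=genos, locus_index=self.locus_index[keep])

    def pair_arrays(self, pair_type: str) -> tuple[np.ndarray, np.ndarray]:
        """(Gi, Gj) genotype matrices for all families' pairs of one type."""
        for t, a, b in self.catalog:
            if t == pair_type:
                return self.genotypes[a], self.genotypes[b]
        raise KeyError(pair_type)


def build_pair_dataset(
    n_families: int,
    ger: float = 0.0,
    n_loci: int = 30_000,
    seed: int = 0,
    pedigree: PedigreeSpec | None = None,
    panel: FounderPanel | None = None,
    n_founders: int = 503,
    freq_bounds: tuple[float, float] = (0.05, 0.95),
    gmap: GeneticMap | None = None,
) -> PairDataset:
    """Simulate ``n_families`` families and collect the balanced pair catalog.

    The result holds exactly ``10 * n_families`` labeled pairs, one pair of
    each relationship type per family.
    """
    if n_families <= 0:
        raise ConfigurationError("n_families must be positive")
    ErrorModel(ger)  # validate rate
    if pedigree is None:
        pedigree = default_pedigree()
    ss = np.random.SeedSequence(seed)
    s_panel, s_drop, s_err = ss.spawn(3)
    if panel is None:
        panel = simulate_founder_panel(
            n_founders, n_loci, freq_bounds, gmap=gmap, seed=s_panel
        )
    rng = np.random.default_rng(s_drop)
    rows = _sample_founder_rows(pedigree, panel, n_families, rng)
    genotypes = _drop_haplotypes(pedigree, panel, rows, rng)
    members = {m for _, a, b in pedigree.pair_catalog for m in (a, b)}
    genotypes = {m: g for m, g in genotypes.items() if m in members}
    dataset = PairDataset(
        genotypes=genotypes,
        catalog=tuple(pedigree.pair_catalog),
        n_families=n_families,
        ger=0.0,
        gmap=panel.gmap,
    )
    if ger > 0.0:
        dataset = dataset.with_error(ger, seed=int(s_err.generate_state(1)[0] % 2**31))
    return dataset
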