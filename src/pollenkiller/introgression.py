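"""Patterson f4 introgression statistics and Fisher's combined test.

Works on a populations-by-sites matrix of derived-allele frequencies and a
rooted species tree.  The f4 statistic for an arrangement (A, B; C, D) is
the mean over sites of (pA - pB)(pC - pD); it has expectation 0 whenever
the four populations are related by the unrooted topology [(A, B), (C, D)],
so a large |f4| on a tree-consistent arrangement indicates gene flow that
violates the tree.  Per-locus outlier ranks against an empirical null are
combined across loci with Fisher's method.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AlleleFrequencyMatrix",
    "CombinedTestResult",
    "f4_statistic",
    "tree_consistent_quadruplets",
    "max_f4_over_quadruplets",
    "percentile_p",
    "fisher_combined",
    "load_species_tree",
    "frequencies_from_fasta",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlleleFrequencyMatrix:
    """Per-population per-site derived-allele frequencies.

    ``values`` is a populations x sites float array aligned with
    ``populations``; every entry must lie in [0, 1].
    """

    populations: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] != len(self.populations):
            raise ValueError("values must be a populations x sites matrix")
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("allele frequencies must lie in [0, 1]")
        object.__setattr__(self, "values", vals)

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    def row(self, population: str) -> np.ndarray:
        return self.values[self.populations.index(population)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.populations))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AlleleFrequencyMatrix":
        return cls(tuple(str(i) for i in df.index), df.to_numpy(dtype=float))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "AlleleFrequencyMatrix":
        """Read a tab-separated table with population labels in the first column."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(df)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.columns = [f"site{j}" for j in range(self.n_sites)]
        df.to_csv(path, sep="\t", index_label="population")


def f4_statistic(
    pA: np.ndarray, pB: np.ndarray, pC: np.ndarray, pD: np.ndarray
) -> float:
    """Mean over usable sites of (pA - pB) * (pC - pD).

    Sites where any of the four frequencies is missing (NaN) are excluded;
    raises if no usable site remains.
    """
    arrs = [np.asarray(v, dtype=float) for v in (pA, pB, pC, pD)]
    n = arrs[0].shape[0]
    if any(a.shape != (n,) for a in arrs) or n == 0:
        raise ValueError("frequency vectors must be equal-length and nonempty")
    ok = np.ones(n, dtype=bool)
    for a in arrs:
        ok &= np.isfinite(a)
    if not ok.any():
        raise ValueError("no usable sites (all have missing values)")
    a, b, c, d = (v[ok] for v in arrs)
    return float(np.mean((a - b) * (c - d)))


def load_species_tree(source: str | Path) -> dendropy.Tree:
    """Load a rooted Newick species tree from a file path or a Newick string."""
    src = str(source)
    if "(" in src:
        return dendropy.Tree.get(data=src, schema="newick")
    return dendropy.Tree.get(path=src, schema="newick")


def _leaf_bipartitions(tree: dendropy.Tree) -> list[frozenset[str]]:
    """Leaf-label sets below each internal edge of the tree."""
    sets = []
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        sets.append(
            frozenset(lf.taxon.label for lf in node.leaf_iter())
        )
    return sets


def tree_consistent_quadruplets(
    tree: dendropy.Tree, populations: Iterable[str] | None = None
) -> list[tuple[str, str, str, str]]:
    """Enumerate (A, B; C, D) arrangements with f4 expectation 0 under the tree.

    For every 4-leaf subset, the species tree restricted to those leaves has
    (at most) one internal edge splitting them 2|2; the arrangement puts the
    two sides of that split as (A, B) and (C, D).  Subsets whose restriction
    is unresolved (a star) are skipped with a warning.
    """
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if populations is not None:
        wanted = set(populations)
        missing = wanted - set(leaves)
        if missing:
            raise ValueError(f"populations absent from tree: {sorted(missing)}")
        leaves = [l for l in leaves if l in wanted]
    clades = _leaf_bipartitions(tree)
    quads: list[tuple[str, str, str, str]] = []
    for subset in itertools.combinations(sorted(leaves), 4):
        sset = set(subset)
        split = None
        for clade in clades:
            inside = sset & clade
            if len(inside) == 2:
                split = (tuple(sorted(inside)), tuple(sorted(sset - inside)))
                break
        if split is None:
            logger.warning("quadruplet %s unresolved on the tree; skipped", subset)
            continue
        (a, b), (c, d) = split
        quads.append((a, b, c, d))
    return quads


def max_f4_over_quadruplets(
    freqs: AlleleFrequencyMatrix, tree: dendropy.Tree
) -> tuple[float, tuple[str, str, str, str], pd.DataFrame]:
    """Maximum |f4| across all tree-consistent quadruplets.

    Returns the maximal |f4| (the introgression indicator for the region),
    the arrangement that attains it, and a per-quadruplet table with the
    signed f4 values.
    """
    if len(freqs.populations) < 4:
        raise ValueError("need at least 4 populations")
    quads = tree_consistent_quadruplets(tree, freqs.populations)
    if not quads:
        raise ValueError("no resolved quadruplets on the tree")
    rows = []
    for a, b, c, d in quads:
        val = f4_statistic(freqs.row(a), freqs.row(b), freqs.row(c), freqs.row(d))
        rows.append({"A": a, "B": b, "C": c, "D": d, "f4": val, "abs_f4": abs(val)})
    table = pd.DataFrame(rows)
    best = table["abs_f4"].idxmax()
    arrangement = tuple(table.loc[best, ["A", "B", "C", "D"]])
    return float(table.loc[best, "abs_f4"]), arrangement, table


def percentile_p(observed: float, null_values: Sequence[float]) -> float:
    """Empirical upper-tail p-value of an observation against a null sample.

    Uses the add-one rule p = (1 + #{null >= observed}) / (1 + n), which
    never returns 0 for a finite null.
    """
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("null sample must be nonempty")
    return float((1 + np.count_nonzero(null >= observed)) / (1 + null.size))


@dataclass(frozen=True)
class CombinedTestResult:
    """Fisher's combined probability test over per-locus p-values."""

    pvalues: tuple[float, ...]
    statistic: float
    df: int
    combined_p: float


def fisher_combined(pvalues: Sequence[float]) -> CombinedTestResult:
    """Combine p-values with Fisher's method.

    X^2 = -2 * sum(ln p) is compared to a chi-square distribution with
    2m degrees of freedom.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    x2 = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return CombinedTestResult(
        pvalues=tuple(float(v) for v in p),
        statistic=x2,
        df=df,
        combined_p=float(stats.chi2.sf(x2, df)),
    )


_UNAMBIGUOUS = set("ACGTacgt")


def frequencies_from_fasta(
    fasta_paths: dict[str, str | Path], reference_id: str
) -> AlleleFrequencyMatrix:
    """Derived-allele frequencies from per-population haplotype alignments.

    ``fasta_paths`` maps population label to a FASTA alignment of equal-length
    haplotype sequences; every file must contain a sequence named
    ``reference_id`` giving the ancestral state per site (it is not counted
    as a haplotype).  A site's derived-allele frequency in a population is
    the fraction of its haplotypes differing from the reference base; sites
    with a gap or ambiguity code in any sequence of any population are
    excluded (set to NaN) across all populations.
    """
    from Bio import SeqIO

    pop_freqs: dict[str, np.ndarray] = {}
    bad_sites: np.ndarray | None = None
    n_sites = None
    for pop, path in fasta_paths.items():
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if reference_id not in records:
            raise ValueError(f"reference {reference_id!r} missing from {path}")
        ref = records.pop(reference_id)
        if not records:
            raise ValueError(f"no haplotype sequences in {path}")
        lengths = {len(seq) for seq in records.values()} | {len(ref)}
        if len(lengths) != 1:
            raise ValueError(f"sequences in {path} are not aligned")
        if n_sites is None:
            n_sites = len(ref)
            bad_sites = np.zeros(n_sites, dtype=bool)
        elif len(ref) != n_sites:
            raise ValueError("alignments differ in length across populations")
        haps = np.array([list(seq.upper()) for seq in records.values()])
        refarr = np.array(list(ref.upper()))
        valid = np.isin(haps, list("ACGT")).all(axis=0) & np.isin(refarr, list("ACGT"))
        bad_sites |= ~valid
        pop_freqs[pop] = (haps != refarr[None, :]).mean(axis=0)
    assert bad_sites is not None
    values = np.vstack([pop_freqs[p] for p in pop_freqs])
    values[:, bad_sites] = np.nan
    return AlleleFrequencyMatrix(tuple(pop_freqs), values)
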