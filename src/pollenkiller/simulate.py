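"""Synthetic-data generators.

Two generators make the rest of the package testable without external data:

* a finite-population Wright–Fisher realization of the pollen-killer mating
  model, whose large-N mean trajectory converges to the deterministic
  recursion (used as a stochastic oracle), and
* a multi-species biallelic site generator that drifts allele frequencies
  down a species tree, with an optional donor-to-recipient introgression
  event (used as input for the f4 machinery).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .introgression import AlleleFrequencyMatrix
from .model import (
    GENOTYPE_NAMES,
    GENOTYPES,
    N_GENOTYPES,
    ModelParams,
    build_gamete_matrices,
    fertility,
    pollen_availability,
    pollen_pool_frequencies,
)

__all__ = [
    "WFConfig",
    "WFResult",
    "simulate_wright_fisher",
    "IntrogressionSpec",
    "simulate_species_alleles",
    "write_fixtures",
]


@dataclass(frozen=True)
class WFConfig:
    """Configuration of the finite-population simulation."""

    params: ModelParams
    N: int = 1000
    generations: int = 50
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("population size N must be >= 2")
        if self.generations < 0 or self.replicates < 1:
            raise ValueError("generations must be >= 0 and replicates >= 1")


@dataclass(frozen=True)
class WFResult:
    """Genotype counts per generation for every replicate.

    ``counts`` has shape (replicates, generations + 1, 10) and sums to N
    along the last axis; ``extinct_at`` holds, per replicate, the generation
    at which all flowers became sterile (-1 if that never happened; counts
    for later generations are frozen at the extinction state).
    """

    config: WFConfig
    counts: np.ndarray
    extinct_at: np.ndarray

    def frequencies(self) -> np.ndarray:
        return self.counts / self.config.N

    def mean_frequencies(self) -> np.ndarray:
        """Mean genotype frequencies across replicates, per generation."""
        return self.frequencies().mean(axis=0)


def simulate_wright_fisher(cfg: WFConfig, theta0: np.ndarray) -> WFResult:
    """Finite-population counterpart of the deterministic recursion.

    Each generation, every one of the N offspring independently draws a
    maternal flower with probability proportional to (empirical genotype
    frequency x fertility) — fertility acts as a soft selection weight —
    and then draws its genotype from that flower's offspring distribution.
    Equivalently, N offspring are drawn multinomially from the mixture
    distribution, which is exactly the deterministic one-generation update
    applied to the empirical frequencies.
    """
    rng = np.random.default_rng(cfg.seed)
    G = build_gamete_matrices(cfg.params)
    N_avail = pollen_availability(G, cfg.params)
    phi = fertility(N_avail, cfg.params)
    theta0 = np.asarray(theta0, dtype=float)

    counts = np.zeros((cfg.replicates, cfg.generations + 1, N_GENOTYPES), dtype=np.int64)
    extinct_at = np.full(cfg.replicates, -1, dtype=np.int64)
    for rep in range(cfg.replicates):
        current = rng.multinomial(cfg.N, theta0 / theta0.sum())
        counts[rep, 0] = current
        for gen in range(1, cfg.generations + 1):
            theta_hat = current / cfg.N
            weights = theta_hat * phi
            total = weights.sum()
            if total <= 0.0:
                extinct_at[rep] = gen
                counts[rep, gen:] = current
                break
            pool = pollen_pool_frequencies(G, theta_hat)
            # mixture over maternal genotypes of their offspring distributions
            pollen = cfg.params.M_self * G.Gm + cfg.params.M_pool * pool[None, :]
            with np.errstate(invalid="ignore", divide="ignore"):
                pollen = np.where(N_avail[:, None] > 0, pollen / N_avail[:, None], 0.0)
            q = np.zeros(N_GENOTYPES)
            for j, (h1, h2) in enumerate(GENOTYPES):
                col = G.Gf[:, h1] * pollen[:, h2]
                if h1 != h2:
                    col = col + G.Gf[:, h2] * pollen[:, h1]
                q[j] = weights @ col
            q = q / q.sum()
            current = rng.multinomial(cfg.N, q)
            counts[rep, gen] = current
    return WFResult(config=cfg, counts=counts, extinct_at=extinct_at)


@dataclass(frozen=True)
class IntrogressionSpec:
    """A single donor-to-recipient introgression event.

    At ``fraction`` of sites (chosen uniformly at random), the recipient
    population's allele frequency is replaced by the donor's.
    """

    donor: str
    recipient: str
    fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.donor == self.recipient:
            raise ValueError("donor and recipient must differ")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")


def simulate_species_alleles(
    tree: dendropy.Tree,
    intensity: float = 0.02,
    n_sites: int = 1000,
    spec: IntrogressionSpec | None = None,
    seed: int = 0,
    root_freq_range: tuple[float, float] = (0.1, 0.9),
) -> AlleleFrequencyMatrix:
    """Evolve biallelic site frequencies down a species tree by Gaussian drift.

    Each site starts from a uniform root frequency and accumulates, along
    every branch, an independent zero-mean Gaussian increment with variance
    ``intensity`` times the branch length, truncated to [0, 1].  Because the
    increments are independent and zero-mean, every tree-consistent
    quadruplet has E[f4] = 0 in the absence of introgression (truncation
    introduces a small bias at extreme frequencies, which is why the default
    intensity is kept low).  If ``spec`` is given, the recipient's value is
    replaced by the donor's at the specified fraction of sites.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if spec is not None:
        for label in (spec.donor, spec.recipient):
            if label not in leaves:
                raise ValueError(f"{label!r} is not a leaf of the tree")

    lo, hi = root_freq_range
    node_freqs: dict[int, np.ndarray] = {}
    root = tree.seed_node
    node_freqs[id(root)] = rng.uniform(lo, hi, size=n_sites)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        length = node.edge.length if node.edge.length is not None else 0.0
        parent = node_freqs[id(node.parent_node)]
        drift = rng.normal(0.0, np.sqrt(intensity * max(length, 0.0)), size=n_sites)
        node_freqs[id(node)] = np.clip(parent + drift, 0.0, 1.0)

    values = np.vstack(
        [node_freqs[id(lf)] for lf in tree.leaf_node_iter()]
    )
    labels = tuple(leaves)
    if spec is not None and spec.fraction > 0.0:
        n_intro = int(round(spec.fraction * n_sites))
        sites = rng.choice(n_sites, size=n_intro, replace=False)
        di = labels.index(spec.donor)
        ri = labels.index(spec.recipient)
        values[ri, sites] = values[di, sites]
    return AlleleFrequencyMatrix(labels, values)


#: Default species tree used by the fixture writer: a ladder of seven
#: populations, mirroring the shape of an AA-genome *Oryza* phylogeny.
DEFAULT_FIXTURE_TREE = (
    "(P1:1.0,(P2:0.8,(P3:0.6,(P4:0.45,(P5:0.3,(P6:0.15,P7:0.15):0.15)"
    ":0.15):0.15):0.2):0.2):0.0;"
)


def write_fixtures(
    outdir: str | Path,
    seed: int = 20240627,
    n_sites: int = 200,
    n_haplotypes: int = 10,
    n_null: int = 200,
) -> dict[str, str]:
    """Write a deterministic, versioned fixture set for the test suite.

    Emits, under ``outdir``: a Newick species tree, a populations x sites
    frequency table (TSV), one FASTA haplotype alignment per population that
    reparses exactly to the table, a null-values file (one |f4| per line
    from independent no-introgression draws), and a JSON manifest with
    SHA-256 checksums.  All frequencies are multiples of 1/n_haplotypes so
    the FASTA round trip is exact; all files are bit-identical for a seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    tree = dendropy.Tree.get(data=DEFAULT_FIXTURE_TREE, schema="newick")
    tree_path = outdir / "species_tree.nwk"
    tree_path.write_text(DEFAULT_FIXTURE_TREE + "\n")

    afm = simulate_species_alleles(
        tree, intensity=0.02, n_sites=n_sites, seed=int(rng.integers(2**31))
    )
    # snap frequencies to multiples of 1/n_haplotypes for exact FASTA round trip
    counts = np.rint(afm.values * n_haplotypes).astype(int)
    afm = AlleleFrequencyMatrix(afm.populations, counts / n_haplotypes)
    table_path = outdir / "frequencies.tsv"
    afm.write_tsv(table_path)

    fasta_paths: dict[str, Path] = {}
    for pi, pop in enumerate(afm.populations):
        lines = [">ancestral", "A" * n_sites]
        for h in range(n_haplotypes):
            # haplotype h carries the derived base T at site j iff h < count_j,
            # so per-site derived fractions equal the table exactly
            seq = "".join("T" if h < counts[pi, j] else "A" for j in range(n_sites))
            lines.append(f">{pop}_hap{h}")
            lines.append(seq)
        path = outdir / f"{pop}.fasta"
        path.write_text("\n".join(lines) + "\n")
        fasta_paths[pop] = path

    from .introgression import max_f4_over_quadruplets

    null_vals = []
    for _ in range(n_null):
        sim = simulate_species_alleles(
            tree, intensity=0.02, n_sites=n_sites, seed=int(rng.integers(2**31))
        )
        max_abs, _arr, _tab = max_f4_over_quadruplets(sim, tree)
        null_vals.append(max_abs)
    null_path = outdir / "null_values.txt"
    null_path.write_text("".join(f"{v:.12g}\n" for v in null_vals))

    files = {
        "species_tree.nwk": tree_path,
        "frequencies.tsv": table_path,
        "null_values.txt": null_path,
        **{f"{pop}.fasta": p for pop, p in fasta_paths.items()},
    }
    manifest = {
        name: hashlib.sha256(path.read_bytes()).hexdigest()
        for name, path in sorted(files.items())
    }
    (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
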