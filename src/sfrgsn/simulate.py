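"""Synthetic expression / label / PPI generator with planted rewiring.

Latent per-sample log-expression is drawn from a multivariate normal whose
pairwise correlation is ``base_corr`` everywhere except the planted gene
pairs, which are shifted to ``base_corr + delta_r`` in their target disease
group only; the reference group never carries planted signal. Latents map to
counts through a Gaussian-copula lognormal (exp of the latent, scaled by a
lognormal per-sample library factor, rounded) — the pipeline consumes
correlation structure, not mean-variance structure, so no attempt is made to
match negative-binomial dispersion or real PPI topology. The PPI handed to
the pipeline is the planted pairs plus random decoy pairs at ``ppi_density``.
Everything is reproducible from ``seed``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (ExpressionMatrix, GroupLabels, Pair, PPINetwork,
                 canonical_pair)

logger = logging.getLogger(__name__)


@dataclass
class SimulationSpec:
    """Stated world of one synthetic dataset.

    ``planted_edges`` lists (gene pair, disease group, delta_r) triples;
    every planted pair is automatically part of the generated PPI.

    ``de_shift`` (default 0: pure rewiring) additionally shifts the latent
    log-mean of each planted pair's genes by that many latent SD units in the
    pair's target group, emulating the differential expression that
    accompanies rewiring in real tumors. A lone added sample moves a Pearson
    correlation by only O(1/n_ref), so with ``de_shift=0`` individual
    disease samples are nearly invisible to the ΔPCC test; mean-shifted
    samples are joint-distribution outliers and perturb strongly.
    """

    n_genes: int = 100
    groups: list[tuple[str, int]] = field(default_factory=lambda: [
        # reference first; imbalanced disease groups at desk scale
        ("Normal", 30), ("I", 55), ("II", 24), ("III", 17), ("IV", 10),
    ])
    reference_group: str = "Normal"
    planted_edges: list[tuple[Pair, str, float]] = field(default_factory=list)
    base_corr: float = 0.1
    noise_sd: float = 0.5
    ppi_density: float = 0.04
    library_size_mean: float = 1e5
    de_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        names = [g for g, _ in self.groups]
        if self.reference_group not in names:
            raise ValueError("reference group missing from group list")
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names")
        if any(n < 1 for _, n in self.groups):
            raise ValueError("group sizes must be positive")
        if self.n_genes < 2 or self.library_size_mean <= 0 or self.noise_sd <= 0:
            raise ValueError("count parameters must be positive")
        if not 0.0 <= self.ppi_density <= 1.0:
            raise ValueError("ppi_density must lie in [0, 1]")
        if abs(self.base_corr) > 0.99:
            raise ValueError("|base_corr| must be <= 0.99")
        for pair, group, dr in self.planted_edges:
            if group == self.reference_group or group not in names:
                raise ValueError(f"planted edge targets invalid group {group!r}")
            if abs(self.base_corr + dr) > 0.99:
                raise ValueError(
                    f"|base_corr + delta_r| = {abs(self.base_corr + dr):.3f} > 0.99 "
                    f"for planted pair {pair}"
                )

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"g{k:0{width}d}" for k in range(self.n_genes)]


def _group_correlation(spec: SimulationSpec, group: str,
                       gene_pos: dict[str, int]) -> np.ndarray:
    corr = np.full((spec.n_genes, spec.n_genes), spec.base_corr)
    np.fill_diagonal(corr, 1.0)
    if group != spec.reference_group:
        for (a, b), g, dr in spec.planted_edges:
            if g == group:
                i, j = gene_pos[a], gene_pos[b]
                corr[i, j] = corr[j, i] = spec.base_corr + dr
    return corr


def _safe_cholesky(corr: np.ndarray, group: str) -> np.ndarray:
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        eigvals, eigvecs = np.linalg.eigh(corr)
        deficit = -float(eigvals.min())
        if deficit > 1e-6:
            raise ValueError(
                f"group {group!r}: correlation matrix not positive definite "
                f"(eigenvalue deficit {deficit:.3g}); reduce delta_r or base_corr"
            ) from None
        logger.warning("group %r: nearest-PD repair applied (deficit %.3g)",
                       group, deficit)
        eigvals = np.clip(eigvals, 1e-8, None)
        repaired = eigvecs @ np.diag(eigvals) @ eigvecs.T
        d = np.sqrt(np.diag(repaired))
        repaired = repaired / np.outer(d, d)
        return np.linalg.cholesky(repaired)


def generate_dataset(spec: SimulationSpec, return_latent: bool = False):
    """Draw one dataset: (ExpressionMatrix, GroupLabels, PPINetwork, ground_truth).

    ``ground_truth`` maps "planted" to the (pair, group, delta_r) list; with
    ``return_latent`` it also carries the latent gene x sample matrix on which
    the planted correlations hold exactly in expectation.
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids
    gene_pos = {g: k for k, g in enumerate(genes)}
    for (a, b), _, _ in spec.planted_edges:
        if a not in gene_pos or b not in gene_pos:
            raise ValueError(f"planted pair ({a}, {b}) uses unknown genes")

    # per-gene base log-mean, shared across groups; sets each gene's scale
    total = spec.library_size_mean
    mu = rng.normal(math.log(total / spec.n_genes), 0.8, size=spec.n_genes)

    columns, labels, latent_cols = [], {}, []
    sample_names = []
    for group, size in spec.groups:
        L = _safe_cholesky(_group_correlation(spec, group, gene_pos), group)
        z = L @ rng.standard_normal((spec.n_genes, size))
        if spec.de_shift and group != spec.reference_group:
            for (a, b), g, _dr in spec.planted_edges:
                if g == group:
                    z[gene_pos[a]] += spec.de_shift
                    z[gene_pos[b]] += spec.de_shift
        latent_cols.append(z)
        lib = rng.lognormal(0.0, 0.2, size=size)
        counts = np.rint(lib[None, :] * np.exp(mu[:, None] + spec.noise_sd * z))
        columns.append(counts)
        for k in range(size):
            name = f"{group}_{k:03d}"
            sample_names.append(name)
            labels[name] = group

    data = pd.DataFrame(np.hstack(columns), index=genes, columns=sample_names)
    expr = ExpressionMatrix(data, unit="counts")
    group_labels = GroupLabels(labels, spec.reference_group)

    planted_pairs = {canonical_pair(a, b) for (a, b), _, _ in spec.planted_edges}
    all_pairs = [(genes[i], genes[j]) for i in range(spec.n_genes)
                 for j in range(i + 1, spec.n_genes)]
    decoy_pool = [p for p in all_pairs if p not in planted_pairs]
    n_decoys = int(round(spec.ppi_density * len(decoy_pool)))
    decoy_idx = rng.choice(len(decoy_pool), size=n_decoys, replace=False)
    edges = planted_pairs | {decoy_pool[k] for k in decoy_idx}
    ppi = PPINetwork(set(edges), {e: 900.0 for e in edges})

    ground_truth: dict = {
        "planted": [(canonical_pair(a, b), g, dr)
                    for (a, b), g, dr in spec.planted_edges],
        "decoys": sorted(edges - planted_pairs),
    }
    if return_latent:
        ground_truth["latent"] = pd.DataFrame(
            np.hstack(latent_cols), index=genes, columns=sample_names)
    return expr, group_labels, ppi, ground_truth


def benchmark_spec(seed: int = 0) -> SimulationSpec:
    """The strong-rewiring benchmark world: four balanced disease groups of
    60 samples plus 60 reference samples, five planted pairs (delta_r = 0.8)
    spread round-robin over the disease groups, ~200 decoy PPI pairs."""
    groups = [("Normal", 60), ("G1", 60), ("G2", 60), ("G3", 60), ("G4", 60)]
    spec = SimulationSpec(
        n_genes=100,
        groups=groups,
        reference_group="Normal",
        base_corr=0.1,
        noise_sd=0.5,
        ppi_density=0.04,
        library_size_mean=1e5,
        seed=seed,
    )
    gene = spec.gene_ids
    targets = ["G1", "G2", "G3", "G4", "G1"]
    spec.planted_edges = [
        (canonical_pair(gene[2 * k], gene[2 * k + 1]), targets[k], 0.8)
        for k in range(5)
    ]
    spec.__post_init__()
    return spec


def write_ground_truth(ground_truth: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tgroup\tdelta_r\n")
        for (a, b), g, dr in ground_truth["planted"]:
            fh.write(f"{a}\t{b}\t{g}\t{dr:g}\n")
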