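"""Single-cell RNA-seq count simulation with GO-derived signatures.

Cell types are defined by elevated expression of signature gene sets drawn
from chosen ontology terms: each signature cell type expresses its own
signature genes at ``signature_mean`` and everything else at
``baseline_mean``; a baseline cell type expresses no signature.  Counts
follow a zero-inflated negative binomial: a negative binomial draw (mean m,
size/dispersion r, so variance m + m^2/r) that is replaced by zero with
probability ``dropout_prob`` — the "drop-outs" characteristic of single-cell
protocols.  The marginal mean of a gene is therefore
``(1 - dropout_prob) * m``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np

from .dag import AnnotationMap, OntologyDAG

__all__ = ["ScSimConfig", "ScDataset", "select_signatures", "simulate_sc", "write_mtx"]


@dataclass(frozen=True)
class ScSimConfig:
    """Configuration of the signature-structured ZINB simulator.

    Defaults mirror a three-signature design (e.g. cell-cycle transition
    programs) over a baseline population: 10 signature genes per term, cell
    counts (120, 150, 100) per signature type plus 300 baseline cells.
    """

    signature_terms: tuple[str, ...] = ()
    genes_per_term: int = 10
    cells_per_type: tuple[int, ...] = (120, 150, 100, 300)  # last entry = baseline
    baseline_mean: float = 1.0
    signature_mean: float = 8.0
    dispersion: float = 2.0
    dropout_prob: float = 0.3
    extra_genes: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if len(self.cells_per_type) != len(self.signature_terms) + 1:
            raise ValueError("need one cell count per signature type plus baseline")


@dataclass
class ScDataset:
    """genes × cells integer count matrix with type labels."""

    counts: np.ndarray
    genes: list[str]
    cell_type_of: list[str]
    signature_of: dict[str, str]  # gene → signature type (absent = background)


def select_signatures(
    dag: OntologyDAG, ann: AnnotationMap, cfg: ScSimConfig
) -> dict[str, str]:
    """Sample ``genes_per_term`` signature genes per chosen term.

    Sampling is uniform and seeded.  A gene annotating several chosen terms
    is assigned to the first term that samples it and removed from later
    terms' pools, so the signature assignment is a function (disjoint sets).
    """
    rng = np.random.default_rng(cfg.seed)
    taken: set[str] = set()
    assignment: dict[str, str] = {}
    for term in cfg.signature_terms:
        if term not in dag:
            raise KeyError(f"unknown term: {term!r}")
        pool = sorted(ann.genes_of[term] - taken)
        if len(pool) < cfg.genes_per_term:
            raise ValueError(
                f"term {term!r} has only {len(pool)} available genes, "
                f"need {cfg.genes_per_term}"
            )
        picked = rng.choice(pool, size=cfg.genes_per_term, replace=False)
        for gene in picked:
            assignment[str(gene)] = term
            taken.add(str(gene))
    return assignment


def simulate_sc(
    cfg: ScSimConfig,
    signatures: dict[str, str],
    background_genes: Sequence[str] = (),
) -> ScDataset:
    """Draw the zero-inflated negative binomial count matrix.

    Signature genes use ``signature_mean`` in cells of their own type and
    ``baseline_mean`` elsewhere; background genes always use
    ``baseline_mean``.  Each entry is NB(mean, size=dispersion), then zeroed
    with probability ``dropout_prob``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    sig_genes = sorted(signatures, key=lambda g: (cfg.signature_terms.index(signatures[g]), g))
    bg = [g for g in background_genes if g not in signatures]
    if not bg and cfg.extra_genes:
        bg = [f"BG{i:04d}" for i in range(cfg.extra_genes)]
    genes = sig_genes + list(bg)

    types = list(cfg.signature_terms) + ["baseline"]
    cell_types = [t for t, n in zip(types, cfg.cells_per_type) for _ in range(n)]
    n_cells = len(cell_types)

    mean = np.full((len(genes), n_cells), cfg.baseline_mean)
    type_arr = np.array(cell_types)
    for i, gene in enumerate(genes):
        term = signatures.get(gene)
        if term is not None:
            mean[i, type_arr == term] = cfg.signature_mean

    r = cfg.dispersion
    p = r / (r + mean)  # numpy's NB success probability for mean `mean`, size r
    counts = rng.negative_binomial(r, p)
    if cfg.dropout_prob > 0.0:
        drop = rng.random(counts.shape) < cfg.dropout_prob
        counts = np.where(drop, 0, counts)
    return ScDataset(counts.astype(np.int64), genes, cell_types, dict(signatures))


def write_mtx(ds: ScDataset, matrix: IO, cells_tsv: IO[str], genes_tsv: IO[str]) -> None:
    """Write the counts as MatrixMarket sparse triplets plus TSV sidecars."""
    from scipy.io import mmwrite
    from scipy.sparse import coo_matrix

    mmwrite(matrix, coo_matrix(ds.counts))
    cells_tsv.write("cell\tcell_type\n")
    for j, t in enumerate(ds.cell_type_of):
        cells_tsv.write(f"cell{j:05d}\t{t}\n")
    genes_tsv.write("gene\tsignature\n")
    for g in ds.genes:
        genes_tsv.write(f"{g}\t{ds.signature_of.get(g, '-')}\n")
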