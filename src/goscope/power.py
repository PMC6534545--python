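"""Power analysis for GO enrichment testing.

The simulator fixes a ground truth (a set of truly differentially expressed
genes, chosen as all or a fraction of the annotation of user-selected
terms), classifies every term as null or non-null under one of two standard
frameworks, generates gene expression data, carries out gene- and term-level
testing with multiplicity correction, and summarizes empirical power and
false discovery proportion over replications.

Null frameworks
---------------
* **self-contained** — a term is null iff none of its annotated genes is
  truly differentially expressed; term p-values combine the gene p-values of
  the term's annotation with Simes' rule.
* **competitive** — a term is null iff its genes are at most as often
  differentially expressed as the genes outside it; testing first selects
  significant genes at a gene-wide threshold and applies a hypergeometric
  (over-representation) test against the term's annotation.

Data model: control samples are drawn from N(0, I) over the g genes; case
samples from N(mu, I) where mu equals ``beta_effect`` at the truly
differentially expressed genes and 0 elsewhere.  Gene p-values come from a
two-sided pooled-variance two-sample t-test (the generative model has equal
unit variances).  Multiplicity is corrected with Benjamini-Hochberg by
default (Bonferroni available; the interface accepts a custom procedure).

With non-null set A1 and rejection set R,

    Power = |A1 ∩ R| / max(|A1|, 1),    FDP = |R \\ A1| / max(|R|, 1)

and the mean FDP over replications estimates the FDR.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dag import AnnotationMap, OntologyDAG

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ExpressionDataset",
    "TestOutcome",
    "PowerReport",
    "designate_ground_truth",
    "classify_nulls",
    "testable_terms",
    "simulate_expression",
    "gene_pvalues",
    "simes_pvalue",
    "hypergeom_pvalue",
    "bh_reject",
    "bonferroni_reject",
    "power_fdp",
    "term_pvalues",
    "run_power_study",
]

Framework = Literal["self_contained", "competitive"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one power-simulation condition.

    ``beta_effect`` is the mean shift (in expression units, i.e. standard
    deviations, since the noise is unit-variance) applied to truly
    differentially expressed genes in the case group.  ``gene_alpha`` is the
    gene-wide significance cut used by the competitive pipeline; ``None``
    means Bonferroni at 0.05/g.  ``rho`` optionally introduces equicorrelated
    gene noise (default independent).
    """

    beta_effect: float = 1.0
    n_control: int = 50
    n_case: int = 50
    q: float = 0.1
    reps: int = 100
    seed: int = 0
    framework: Framework = "self_contained"
    correction: str = "bh"  # bh | bonferroni
    gene_alpha: float | None = None
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_case < 2:
            raise ValueError("need at least two samples per group")
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must lie in (0, 1)")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")


@dataclass(frozen=True)
class GroundTruth:
    """Truly differentially expressed genes and per-framework non-null terms."""

    de_genes: frozenset[str]
    nonnull_terms: frozenset[str]
    framework: Framework


@dataclass
class ExpressionDataset:
    """genes × samples expression matrix with group labels."""

    matrix: np.ndarray  # shape (g, n_control + n_case)
    genes: list[str]
    group_of: np.ndarray  # 0 = control, 1 = case

    @property
    def n_control(self) -> int:
        return int(np.sum(self.group_of == 0))

    @property
    def n_case(self) -> int:
        return int(np.sum(self.group_of == 1))


@dataclass
class TestOutcome:
    gene_pvalues: dict[str, float]
    term_pvalues: dict[str, float]
    rejected: frozenset[str]


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


def designate_ground_truth(
    dag: OntologyDAG,
    ann: AnnotationMap,
    chosen_terms: Iterable[str],
    fraction: float = 1.0,
    seed: int = 0,
) -> frozenset[str]:
    """Pick the truly differentially expressed genes.

    For each chosen term, ``ceil(fraction * size)`` genes are sampled
    uniformly (without replacement, reproducibly under ``seed``) from its
    propagated annotation; the per-term samples are unioned.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    de: set[str] = set()
    for term in sorted(set(chosen_terms)):
        if term not in dag:
            raise KeyError(f"unknown term: {term!r}")
        genes = sorted(ann.genes_of[term])
        if not genes:
            raise ValueError(f"term {term!r} has an empty annotation")
        k = math.ceil(fraction * len(genes))
        de |= set(rng.choice(genes, size=k, replace=False)) if k < len(genes) else set(genes)
    return frozenset(de)


def classify_nulls(
    ann: AnnotationMap, de_genes: Iterable[str], framework: Framework
) -> frozenset[str]:
    """Return the non-null term set A1 under the given framework.

    Self-contained: non-null iff the term's annotation intersects the DE set.
    Competitive: non-null iff the DE fraction inside the term strictly
    exceeds the DE fraction among genes outside the term; terms annotated
    with the entire universe have no complement and are never non-null (they
    are excluded from testing upstream).
    """
    de = set(de_genes)
    nonnull: set[str] = set()
    for term, genes in ann.genes_of.items():
        if not genes:
            continue
        if framework == "self_contained":
            if genes & de:
                nonnull.add(term)
        elif framework == "competitive":
            comp = ann.universe - genes
            if not comp:
                continue
            inside = len(genes & de) / len(genes)
            outside = len(comp & de) / len(comp)
            if inside > outside:
                nonnull.add(term)
        else:
            raise ValueError(f"unknown framework: {framework!r}")
    return frozenset(nonnull)


def testable_terms(ann: AnnotationMap, framework: Framework) -> list[str]:
    """Terms entering the hypothesis family: non-empty annotation, and (for
    competitive tests) a non-empty gene complement."""
    out = []
    for term in sorted(ann.genes_of):
        genes = ann.genes_of[term]
        if not genes:
            continue
        if framework == "competitive" and not (ann.universe - genes):
            continue
        out.append(term)
    return out


# ---------------------------------------------------------------------------
# data generation and gene-level testing
# ---------------------------------------------------------------------------


def simulate_expression(
    genes: Sequence[str],
    de_genes: Iterable[str],
    beta_effect: float,
    n_control: int,
    n_case: int,
    rng: np.random.Generator,
    rho: float = 0.0,
) -> ExpressionDataset:
    """Draw a genes × samples matrix: controls ~ N(0, I), cases ~ N(mu, I)
    with mu = ``beta_effect`` at DE genes and 0 elsewhere.

    With ``rho`` > 0 the identity covariance is replaced by an
    equicorrelation matrix (shared per-sample factor), relaxing the
    independent-genes assumption.
    """
    genes = list(genes)
    g = len(genes)
    n = n_control + n_case
    de = set(de_genes)
    unknown = de - set(genes)
    if unknown:
        raise KeyError(f"DE genes outside the universe: {sorted(unknown)[:5]}")
    x = rng.standard_normal((g, n))
    if rho > 0.0:
        shared = rng.standard_normal(n)
        x = math.sqrt(rho) * shared[None, :] + math.sqrt(1.0 - rho) * x
    mu = np.array([beta_effect if gene in de else 0.0 for gene in genes])
    x[:, n_control:] += mu[:, None]
    group = np.concatenate([np.zeros(n_control, dtype=int), np.ones(n_case, dtype=int)])
    return ExpressionDataset(x, genes, group)


def gene_pvalues(data: ExpressionDataset) -> dict[str, float]:
    """Two-sided pooled-variance two-sample t-test per gene.

    Genes with zero pooled variance are reported as p = 1 with a warning
    (a degenerate draw carries no evidence either way).
    """
    ctrl = data.matrix[:, data.group_of == 0]
    case = data.matrix[:, data.group_of == 1]
    if ctrl.shape[1] < 2 or case.shape[1] < 2:
        raise ValueError("need at least two samples per group")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(ctrl, case, axis=1, equal_var=True)
    p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} genes had zero pooled variance; p set to 1")
        p[bad] = 1.0
    return dict(zip(data.genes, p))


# ---------------------------------------------------------------------------
# term-level statistics
# ---------------------------------------------------------------------------


def simes_pvalue(pvals: Sequence[float]) -> float:
    """Simes' combined p-value: min over k of m * p_(k) / k, capped at 1."""
    p = np.sort(np.asarray(pvals, dtype=float))
    if p.size == 0:
        raise ValueError("Simes' rule needs at least one p-value")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    return float(min(1.0, np.min(m * p / np.arange(1, m + 1))))


def hypergeom_pvalue(k_in_sig: int, term_size: int, n_sig: int, universe: int) -> float:
    """Upper-tail hypergeometric over-representation p-value P(X >= k).

    X counts the overlap between the ``n_sig`` significant genes and the
    ``term_size`` genes of the term, drawn from a universe of ``universe``
    genes without replacement.
    """
    if not (0 <= k_in_sig <= min(term_size, n_sig) <= universe):
        raise ValueError("inconsistent hypergeometric counts")
    if term_size > universe or n_sig > universe:
        raise ValueError("term or significant set larger than the universe")
    return float(stats.hypergeom.sf(k_in_sig - 1, universe, term_size, n_sig))


def bh_reject(term_pvalues: Mapping[str, float], q: float) -> frozenset[str]:
    """Benjamini-Hochberg step-up at FDR level q."""
    terms = sorted(term_pvalues)
    if not terms:
        raise ValueError("empty hypothesis family")
    p = np.array([term_pvalues[t] for t in terms])
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return frozenset(t for t, r in zip(terms, reject) if r)


def bonferroni_reject(term_pvalues: Mapping[str, float], q: float) -> frozenset[str]:
    """Bonferroni correction at family-wise level q."""
    terms = sorted(term_pvalues)
    if not terms:
        raise ValueError("empty hypothesis family")
    p = np.array([term_pvalues[t] for t in terms])
    reject, *_ = multipletests(p, alpha=q, method="bonferroni")
    return frozenset(t for t, r in zip(terms, reject) if r)


_CORRECTIONS: dict[str, Callable[[Mapping[str, float], float], frozenset[str]]] = {
    "bh": bh_reject,
    "bonferroni": bonferroni_reject,
}


def power_fdp(a1: Iterable[str], rejected: Iterable[str]) -> tuple[float, float]:
    """Empirical power and false discovery proportion for one realization."""
    a1, r = set(a1), set(rejected)
    power = len(a1 & r) / max(len(a1), 1)
    fdp = len(r - a1) / max(len(r), 1)
    return power, fdp


def term_pvalues(
    ann: AnnotationMap,
    gene_p: Mapping[str, float],
    framework: Framework,
    terms: Sequence[str],
    gene_alpha: float | None = None,
) -> dict[str, float]:
    """Term-level p-values for the family ``terms``.

    Self-contained: Simes over the term's gene p-values.  Competitive:
    significant genes at ``gene_alpha`` (default Bonferroni 0.05/g), then the
    upper-tail hypergeometric test of term/significant overlap.
    """
    if framework == "self_contained":
        return {t: simes_pvalue([gene_p[g] for g in ann.genes_of[t]]) for t in terms}
    if framework == "competitive":
        g = len(gene_p)
        alpha = gene_alpha if gene_alpha is not None else 0.05 / g
        sig = {gene for gene, p in gene_p.items() if p <= alpha}
        out = {}
        for t in terms:
            genes = ann.genes_of[t]
            out[t] = hypergeom_pvalue(len(genes & sig), len(genes), len(sig), g)
        return out
    raise ValueError(f"unknown framework: {framework!r}")


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------


@dataclass
class PowerReport:
    """Results of a power study over a sample-size grid.

    One row per grid point in ``summary``; ``rejection_freq`` maps a grid
    point to per-term rejection fractions; ``power_samples`` /
    ``fdp_samples`` hold the per-replication realizations.
    """

    grid: list[tuple[int, int]]
    rejection_freq: dict[tuple[int, int], dict[str, float]]
    power_samples: dict[tuple[int, int], np.ndarray]
    fdp_samples: dict[tuple[int, int], np.ndarray]
    nonnull_terms: frozenset[str]
    tested_terms: list[str]
    config: SimulationConfig = field(default_factory=SimulationConfig)

    def summary(self) -> pd.DataFrame:
        rows = []
        for nc, na in self.grid:
            rows.append(
                {
                    "n_control": nc,
                    "n_case": na,
                    "mean_power": float(np.mean(self.power_samples[(nc, na)])),
                    "mean_fdp": float(np.mean(self.fdp_samples[(nc, na)])),
                    "sd_power": float(np.std(self.power_samples[(nc, na)], ddof=1)),
                    "sd_fdp": float(np.std(self.fdp_samples[(nc, na)], ddof=1)),
                }
            )
        return pd.DataFrame(rows)

    def rejection_table(self) -> pd.DataFrame:
        """Terms × grid-points table of rejection fractions (binder heatmap)."""
        cols = {f"n{nc}_{na}": self.rejection_freq[(nc, na)] for nc, na in self.grid}
        return pd.DataFrame(cols).reindex(self.tested_terms)

    def to_json_dict(self) -> dict:
        return {
            "framework": self.config.framework,
            "q": self.config.q,
            "beta_effect": self.config.beta_effect,
            "reps": self.config.reps,
            "seed": self.config.seed,
            "nonnull_terms": sorted(self.nonnull_terms),
            "tested_terms": self.tested_terms,
            "grid": [list(g) for g in self.grid],
            "rejection_freq": {
                f"{nc},{na}": self.rejection_freq[(nc, na)] for nc, na in self.grid
            },
            "power": {f"{nc},{na}": self.power_samples[(nc, na)].tolist() for nc, na in self.grid},
            "fdp": {f"{nc},{na}": self.fdp_samples[(nc, na)].tolist() for nc, na in self.grid},
        }


def run_power_study(
    dag: OntologyDAG,
    ann: AnnotationMap,
    de_genes: Iterable[str],
    cfg: SimulationConfig,
    grid: Sequence[tuple[int, int]] | None = None,
) -> PowerReport:
    """Run the full power simulation over a sample-size grid.

    The ground truth (DE genes, hence A1) stays fixed; for each grid point,
    ``cfg.reps`` independent expression datasets are generated, tested and
    corrected, and per-term rejection frequencies plus per-replication
    Power/FDP are collected.  A refined DAG is recommended upstream so that
    no two tested terms carry identical annotations.  Replication RNG
    streams are spawned from the master seed, so grid points are independent
    and the whole report is reproducible.
    """
    de = frozenset(de_genes)
    terms = testable_terms(ann, cfg.framework)
    if not terms:
        raise ValueError("no testable terms (all annotations empty?)")
    a1 = classify_nulls(ann, de, cfg.framework) & frozenset(terms)
    genes = sorted(ann.universe)
    if grid is None:
        grid = [(cfg.n_control, cfg.n_case)]
    correct = _CORRECTIONS[cfg.correction]

    master = np.random.SeedSequence(cfg.seed)
    point_seeds = master.spawn(len(grid))

    rej_freq: dict[tuple[int, int], dict[str, float]] = {}
    powers: dict[tuple[int, int], np.ndarray] = {}
    fdps: dict[tuple[int, int], np.ndarray] = {}
    for (nc, na), ss in zip(grid, point_seeds):
        counts = {t: 0 for t in terms}
        pw = np.empty(cfg.reps)
        fd = np.empty(cfg.reps)
        for rep, rep_ss in enumerate(ss.spawn(cfg.reps)):
            rng = np.random.default_rng(rep_ss)
            data = simulate_expression(
                genes, de, cfg.beta_effect, nc, na, rng, rho=cfg.rho
            )
            gp = gene_pvalues(data)
            tp = term_pvalues(ann, gp, cfg.framework, terms, cfg.gene_alpha)
            rejected = correct(tp, cfg.q)
            for t in rejected:
                counts[t] += 1
            pw[rep], fd[rep] = power_fdp(a1, rejected)
        rej_freq[(nc, na)] = {t: counts[t] / cfg.reps for t in terms}
        powers[(nc, na)] = pw
        fdps[(nc, na)] = fd
    return PowerReport(list(grid), rej_freq, powers, fdps, a1, terms, cfg)
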