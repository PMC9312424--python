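"""Synthetic data with the statistical structure the stability analysis assumes.

The generator emulates, at desk scale, the features of real expression
compendia that the analysis relies on:

* a minority of *stable* genes — modest per-gene baseline (log-normal around
  ~20 abundance units) with small multiplicative sample noise, so their Gini
  coefficients are low;
* a majority of *variable* genes — high expression in a random subset of
  samples (tissue/cell-type restricted) and zero elsewhere, so their Gini
  coefficients are high;
* GO-like annotation terms, some of which are planted to draw most of their
  genes from the stable set;
* essentiality labels correlated with stability, scored as arrested
  replicates out of six RNAi treatments;
* multi-organism 1:1-ortholog matrices where some stable genes are shared by
  all organisms and others are stable only within a clade, giving the
  Gini-correlation structure that clade clustering must recover.

Every generator is deterministic given its seed; the pipeline derives
per-stage substream seeds from one master seed via ``numpy``'s
``SeedSequence``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import AnnotationSet
from .essentiality import classify_rnai_phenotypes
from .io import ExpressionMatrix, GeneList, OrthologMap, Unit

__all__ = [
    "SimulationTruth",
    "simulate_expression",
    "simulate_annotations",
    "simulate_essentiality",
    "simulate_multispecies",
]


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of a simulation run, for recovery checks."""

    stable_genes: GeneList
    variable_genes: GeneList
    planted_terms: frozenset = frozenset()
    essential_genes: GeneList = GeneList(frozenset(), "essential")
    clade_assignment: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.stable_genes.genes & self.variable_genes.genes:
            raise ValueError("a gene cannot be both stable and variable")


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal noise with unit mean and coefficient of variation cv."""
    sigma2 = math.log(1.0 + cv * cv)
    sigma = math.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=size)


def simulate_expression(
    n_genes: int = 5000,
    n_samples: int = 30,
    frac_stable: float = 0.2,
    stable_cv: float = 0.1,
    active_fraction: float = 0.2,
    seed=None,
    *,
    stable_baseline: float = 20.0,
    active_level: float = 200.0,
) -> tuple:
    """Simulate a genes x samples expression matrix with planted stable genes.

    Stable genes get a per-gene log-normal baseline around ``stable_baseline``
    (sigma 0.6) times multiplicative noise with coefficient of variation
    ``stable_cv``. Variable genes are expressed (log-normally around
    ``active_level``) in a random ~``active_fraction`` of samples — at least
    one — and are exactly zero elsewhere. Returns
    ``(ExpressionMatrix, SimulationTruth)``.
    """
    if not 0 < frac_stable < 1:
        raise ValueError("frac_stable must lie in (0, 1)")
    if stable_cv <= 0:
        raise ValueError("stable_cv must be positive")
    if not 0 < active_fraction <= 1:
        raise ValueError("active_fraction must lie in (0, 1]")
    if n_genes < 2 or n_samples < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    samples = [f"s{j:03d}" for j in range(n_samples)]
    n_stable = round(n_genes * frac_stable)
    stable_idx = rng.choice(n_genes, size=n_stable, replace=False)
    stable_mask = np.zeros(n_genes, dtype=bool)
    stable_mask[stable_idx] = True

    values = np.zeros((n_genes, n_samples))
    baselines = rng.lognormal(mean=math.log(stable_baseline), sigma=0.6, size=n_stable)
    values[stable_mask] = baselines[:, None] * _lognormal_noise(rng, stable_cv, (n_stable, n_samples))

    n_var = n_genes - n_stable
    active = rng.random((n_var, n_samples)) < active_fraction
    silent = ~active.any(axis=1)
    if silent.any():  # guarantee at least one active sample per variable gene
        active[silent, rng.integers(0, n_samples, size=int(silent.sum()))] = True
    levels = rng.lognormal(mean=math.log(active_level), sigma=0.5, size=(n_var, n_samples))
    values[~stable_mask] = np.where(active, levels, 0.0)

    matrix = ExpressionMatrix(gene_ids=genes, sample_ids=samples, values=values, unit=Unit.RAW)
    truth = SimulationTruth(
        stable_genes=GeneList(frozenset(np.array(genes)[stable_mask]), "stable"),
        variable_genes=GeneList(frozenset(np.array(genes)[~stable_mask]), "variable"),
        seed=int(seed) if seed is not None else 0,
    )
    return matrix, truth


def simulate_annotations(
    truth: SimulationTruth,
    n_terms: int = 200,
    planted_fraction: float = 0.1,
    term_size_range: tuple = (10, 50),
    seed=None,
) -> tuple:
    """Simulate BP-aspect annotations with terms planted on the stable genes.

    Planted terms draw at least 80% of their genes from ``truth.stable_genes``
    (the remainder uniformly from the whole universe); null terms draw all
    genes uniformly. Returns ``(AnnotationSet, truth-with-planted-terms)``.
    """
    lo, hi = int(term_size_range[0]), int(term_size_range[1])
    if lo < 3:
        raise ValueError("term sizes must be >= 3")
    universe = sorted(truth.stable_genes.genes | truth.variable_genes.genes)
    stable = sorted(truth.stable_genes.genes)
    if hi > len(universe):
        raise ValueError("term size exceeds the annotated universe")
    if not 0 <= planted_fraction <= 1:
        raise ValueError("planted_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_planted = round(n_terms * planted_fraction)
    term_to_genes = {}
    planted = set()
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        term = f"GO:SIM{t:05d}"
        if t < n_planted:
            k_stable = math.ceil(0.8 * size)
            members = set(rng.choice(stable, size=min(k_stable, len(stable)), replace=False))
            pool = [g for g in universe if g not in members]
            extra = rng.choice(pool, size=size - len(members), replace=False)
            members |= set(extra)
            planted.add(term)
        else:
            members = set(rng.choice(universe, size=size, replace=False))
        term_to_genes[term] = frozenset(members)
    annotations = AnnotationSet(term_to_genes, aspect="BP")
    return annotations, replace(truth, planted_terms=frozenset(planted))


def simulate_essentiality(
    truth: SimulationTruth,
    p_ess_stable: float = 0.5,
    p_ess_variable: float = 0.05,
    reps: int = 6,
    arrest_p_ess: float = 0.9,
    arrest_p_non: float = 0.05,
    seed=None,
) -> tuple:
    """Simulate RNAi arrest counts with essentiality biased toward stable genes.

    Each gene is essential with probability ``p_ess_stable`` (stable genes)
    or ``p_ess_variable`` (variable genes); its arrested-replicate count is
    Binomial(``reps``, ``arrest_p_ess`` or ``arrest_p_non``). Classes follow
    the RNAi classifier. Returns ``(table, truth-with-essential-genes)``
    where the table has columns ``arrested_reps``, ``tested_reps``,
    ``class`` and ``essential``.
    """
    for name, p in [
        ("p_ess_stable", p_ess_stable),
        ("p_ess_variable", p_ess_variable),
        ("arrest_p_ess", arrest_p_ess),
        ("arrest_p_non", arrest_p_non),
    ]:
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = sorted(truth.stable_genes.genes | truth.variable_genes.genes)
    is_stable = np.array([g in truth.stable_genes for g in genes])
    p_ess = np.where(is_stable, p_ess_stable, p_ess_variable)
    essential = rng.random(len(genes)) < p_ess
    arrest_p = np.where(essential, arrest_p_ess, arrest_p_non)
    arrested = rng.binomial(reps, arrest_p)
    classes = [classify_rnai_phenotypes(int(a), reps) for a in arrested]
    table = pd.DataFrame(
        {
            "arrested_reps": arrested,
            "tested_reps": reps,
            "class": classes,
            "essential": essential,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    new_truth = replace(truth, essential_genes=GeneList(frozenset(np.array(genes)[essential]), "essential"))
    return table, new_truth


def simulate_multispecies(
    n_organisms: int = 9,
    clades: Sequence[int] = (5, 4),
    n_genes: int = 3000,
    shared_stable_frac: float = 0.2,
    clade_stable_frac: float = 0.1,
    n_samples: int = 15,
    stable_cv_range: tuple = (0.05, 0.3),
    active_fraction: float = 0.2,
    seed=None,
) -> tuple:
    """Simulate per-organism matrices with shared- and clade-specific stable genes.

    Every gene is a 1:1 ortholog row across all organisms. Shared-stable
    genes are stable in every organism; each clade additionally owns
    ``clade_stable_frac`` of the genes, stable only inside that clade and
    tissue-restricted (variable) outside it. A stable gene keeps one
    per-gene noise CV across all organisms where it is stable, so its Gini
    coefficient is reproducibly low there — the signal that makes Gini
    vectors correlate more within clades than between them. Remaining genes
    are variable in every organism with independent sample structure.

    Returns ``(matrices, ortholog_map, truth)`` with one ExpressionMatrix per
    organism label and a fully 1:1 OrthologMap.
    """
    clades = [int(c) for c in clades]
    if len(clades) < 2:
        raise ValueError("need at least 2 clades")
    if sum(clades) != n_organisms:
        raise ValueError(f"clade sizes {clades} must sum to n_organisms={n_organisms}")
    if shared_stable_frac + clade_stable_frac * len(clades) > 1:
        raise ValueError("stable-gene fractions sum to more than 1")
    rng = np.random.default_rng(seed)
    organisms = [f"org{i:02d}" for i in range(n_organisms)]
    clade_of = {}
    start = 0
    for c, size in enumerate(clades):
        for org in organisms[start : start + size]:
            clade_of[org] = f"clade{c}"
        start += size

    genes = [f"og{i:05d}" for i in range(n_genes)]
    n_shared = round(n_genes * shared_stable_frac)
    n_clade = round(n_genes * clade_stable_frac)
    perm = rng.permutation(n_genes)
    shared_idx = perm[:n_shared]
    clade_idx = {
        f"clade{c}": perm[n_shared + c * n_clade : n_shared + (c + 1) * n_clade]
        for c in range(len(clades))
    }
    # per-gene stable noise CV, shared across organisms where the gene is stable
    gene_cv = rng.uniform(stable_cv_range[0], stable_cv_range[1], size=n_genes)
    gene_baseline = rng.lognormal(mean=math.log(20.0), sigma=0.6, size=n_genes)

    matrices = {}
    samples = [f"s{j:03d}" for j in range(n_samples)]
    for org in organisms:
        stable_mask = np.zeros(n_genes, dtype=bool)
        stable_mask[shared_idx] = True
        stable_mask[clade_idx[clade_of[org]]] = True
        values = np.zeros((n_genes, n_samples))
        ns = int(stable_mask.sum())
        if ns:
            noise = np.stack([_lognormal_noise(rng, cv, n_samples) for cv in gene_cv[stable_mask]])
            values[stable_mask] = gene_baseline[stable_mask, None] * noise
        nv = n_genes - ns
        active = rng.random((nv, n_samples)) < active_fraction
        silent = ~active.any(axis=1)
        if silent.any():
            active[silent, rng.integers(0, n_samples, size=int(silent.sum()))] = True
        levels = rng.lognormal(mean=math.log(200.0), sigma=0.5, size=(nv, n_samples))
        values[~stable_mask] = np.where(active, levels, 0.0)
        matrices[org] = ExpressionMatrix(
            gene_ids=[f"{org}:{g}" for g in genes],
            sample_ids=samples,
            values=values,
            unit=Unit.RAW,
        )

    table = pd.DataFrame({org: [f"{org}:{g}" for g in genes] for org in organisms},
                         index=pd.Index(genes, name="ortholog_id"))
    ortholog_map = OrthologMap(table=table, one_to_one=pd.Series(True, index=table.index))

    shared_set = frozenset(np.array(genes)[shared_idx])
    clade_sets = {c: frozenset(np.array(genes)[idx]) for c, idx in clade_idx.items()}
    stable_union = shared_set.union(*clade_sets.values())
    truth = SimulationTruth(
        stable_genes=GeneList(stable_union, "stable-any"),
        variable_genes=GeneList(frozenset(genes) - stable_union, "variable"),
        clade_assignment=dict(clade_of),
        seed=int(seed) if seed is not None else 0,
    )
    return matrices, ortholog_map, truth
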