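"""Genome-wide extent of splicing coordination and down-sampling controls.

The fraction of genes with detectable coordination rises with the number
of informative molecules available per exon pair, simply because power
rises. This module estimates the fraction of coordinated genes as a
function of an informative-count cutoff (with 95% confidence intervals),
and implements the down-sampling control: tables with many informative
molecules (list H, n_t >= 500) are down-sampled (multivariate
hypergeometric draws from the four cells) to reproduce the size
distribution of the low-count list (L, n_t >= 25). If down-sampled
fractions match L's own fraction, the difference between L and H reflects
statistical power, not biology of highly expressed genes.

The pass criterion is a fixed genome-wide significance bar: Fisher
P <= 5e-7 (a Bonferroni bar for 100,000 tests at 0.05) together with
|log2 odds ratio| >= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .coordination import ContingencyTable, fisher_two_sided, log_odds

__all__ = [
    "ExtentEstimate",
    "DownsampleRun",
    "P_CUTOFF",
    "LOR_CUTOFF",
    "passes_criterion",
    "select_max_pair_per_gene",
    "sweep_cutoffs",
    "downsample_table",
    "downsample_experiment",
]

P_CUTOFF = 5e-7  # 0.05 Bonferroni-corrected for 100,000 tests
LOR_CUTOFF = 0.5

DEFAULT_CUTOFFS = (25, 50, 100, 200, 500, 1000)


@dataclass
class ExtentEstimate:
    cutoff: int
    genes_tested: int
    fraction_coordinated: float
    ci_low: float
    ci_high: float


@dataclass
class DownsampleRun:
    low_cutoff: int
    high_cutoff: int
    replicates: int
    seed: int
    fractions: list[float] = field(default_factory=list)
    low_fraction: float = float("nan")
    high_fraction: float = float("nan")


def passes_criterion(
    t: ContingencyTable,
    p_cutoff: float = P_CUTOFF,
    lor_cutoff: float = LOR_CUTOFF,
) -> bool:
    """True iff the table clears both the significance and the effect bar."""
    if t.n_t == 0:
        return False
    return abs(log_odds(t)) >= lor_cutoff and fisher_two_sided(t) <= p_cutoff


def select_max_pair_per_gene(
    tables: Sequence[tuple[str, object, ContingencyTable]],
) -> list[tuple[str, object, ContingencyTable]]:
    """Keep one table per gene: the one with the highest n_t; ties broken by
    the pair's position in the input (upstream pairs listed first win)."""
    best: dict[str, tuple[str, object, ContingencyTable]] = {}
    for gene_id, pair, table in tables:
        cur = best.get(gene_id)
        if cur is None or table.n_t > cur[2].n_t:
            best[gene_id] = (gene_id, pair, table)
    return [best[g] for g in sorted(best)]


def _wilson_ci(k: int, n: int, method: str = "wilson") -> tuple[float, float]:
    lo, hi = proportion_confint(k, n, alpha=0.05, method=method)
    return float(lo), float(hi)


def sweep_cutoffs(
    tables: Sequence[tuple[str, object, ContingencyTable]],
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
    per_gene: bool = False,
    ci_method: str = "wilson",
) -> list[ExtentEstimate]:
    """Fraction of genes with >=1 passing table at each informative-count
    cutoff, with 95% CIs (Wilson score by default)."""
    if list(cutoffs) != sorted(cutoffs):
        raise ValueError("cutoffs must be sorted ascending")
    pass_cache = {id(t): passes_criterion(t) for _, _, t in tables}
    out: list[ExtentEstimate] = []
    for cutoff in cutoffs:
        kept = [(g, p, t) for g, p, t in tables if t.n_t >= cutoff]
        if per_gene:
            kept = select_max_pair_per_gene(kept)
        genes = {g for g, _, _ in kept}
        if not genes:
            import warnings

            warnings.warn(f"cutoff {cutoff} retains no genes; estimate omitted")
            continue
        hit_genes = {g for g, _, t in kept if pass_cache[id(t)]}
        k, n = len(hit_genes), len(genes)
        lo, hi = _wilson_ci(k, n, ci_method)
        out.append(ExtentEstimate(cutoff, n, k / n, lo, hi))
    return out


def downsample_table(
    h: ContingencyTable, n: int, rng: np.random.Generator | int
) -> ContingencyTable:
    """Draw ``n`` informative units without replacement from the four cells
    of ``h`` (multivariate hypergeometric); the result has n_t == n."""
    if n > h.n_t:
        raise ValueError(f"cannot draw {n} units from a table of {h.n_t}")
    if n == h.n_t:
        return h
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    a, b, c, d = rng.multivariate_hypergeometric([h.a, h.b, h.c, h.d], n)
    return ContingencyTable(int(a), int(b), int(c), int(d))


def _fraction_passing(tables: Sequence[ContingencyTable]) -> float:
    return sum(passes_criterion(t) for t in tables) / len(tables)


def downsample_experiment(
    L: Sequence[ContingencyTable],
    H: Sequence[ContingencyTable],
    replicates: int = 50,
    seed: int = 0,
) -> DownsampleRun:
    """Down-sampling control.

    Per replicate, every table l in L is replaced by a table drawn from a
    uniformly chosen member h of H with n_h >= n_l, down-sampled to n_l
    units; the replicate's statistic is the fraction of down-sampled tables
    passing the criterion. The down-sampled list therefore has the identical
    n_t multiset as L in every replicate.
    """
    if not L or not H:
        raise ValueError("both table lists must be non-empty")
    rng = np.random.default_rng(seed)
    h_sizes = np.array([t.n_t for t in H])
    eligible_cache: dict[int, np.ndarray] = {}
    for l in L:
        if l.n_t not in eligible_cache:
            idx = np.flatnonzero(h_sizes >= l.n_t)
            if idx.size == 0:
                raise ValueError(f"no donor table in H with n_t >= {l.n_t}")
            eligible_cache[l.n_t] = idx
    run = DownsampleRun(
        low_cutoff=min(t.n_t for t in L),
        high_cutoff=min(t.n_t for t in H),
        replicates=replicates,
        seed=seed,
        low_fraction=_fraction_passing(L),
        high_fraction=_fraction_passing(H),
    )
    for _ in range(replicates):
        ds = []
        for l in L:
            idx = eligible_cache[l.n_t]
            donor = H[int(idx[rng.integers(idx.size)])]
            ds.append(downsample_table(donor, l.n_t, rng))
        run.fractions.append(_fraction_passing(ds))
    return run
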