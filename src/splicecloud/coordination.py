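"""Coordination testing between distant alternative splicing events.

For each pair of alternative events, molecules (barcode-level calls) whose
splicing status is determined for *both* events are tabulated in a 2x2
table: a = both included, b = first only, c = second only, d = both
skipped. Coordination — statistical dependence between the two events
within single molecules — is assessed with a two-sided Fisher's exact
test; its extent is measured by the log2-odds-ratio with a 0.5 pseudocount
in every cell (Haldane–Anscombe), finite even when the table holds zeros.
Multiple testing is controlled with Benjamini–Yekutieli across all tested
internal exon pairs and with Benjamini–Hochberg across the per-gene
terminal-site tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import ExonPair, IntronKey, SkippableExon, TerminalSitePair

__all__ = [
    "ContingencyTable",
    "CoordinationResult",
    "pair_status",
    "build_table",
    "fisher_two_sided",
    "log_odds",
    "adjust_fdr",
    "analyze_tables",
    "run_internal_coordination",
    "run_terminal_coordination",
    "coding_noncoding_comparison",
    "frame_analysis",
]

# relative tolerance for probability ties in the two-sided test
_TIE_RTOL = 1e-7

DEFAULT_MIN_INFORMATIVE = 25
DEFAULT_FDR = 0.05


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # both included (or both top-ranked forms)
    b: int  # first only
    c: int  # second only
    d: int  # neither

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n_t(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class CoordinationResult:
    pair: object  # ExonPair | TerminalSitePair | opaque id
    gene_id: str
    table: ContingencyTable
    p_value: float
    lor: float
    p_adjusted: float = math.nan
    significant: bool = False
    category: Optional[str] = None
    pair_coding: Optional[str] = None


def pair_status(
    cell: Mapping[IntronKey, int],
    pair: ExonPair,
) -> str:
    """Splicing status of one barcode for both exons of a pair.

    Returns one of ``both``, ``first_only``, ``second_only``, ``neither``
    or ``uninformative``; the per-exon call follows the same
    inclusion-vs-skip evidence rule as percent-spliced-in.
    """

    def exon_state(exon: SkippableExon) -> Optional[bool]:
        u, d = exon.inclusion_introns
        has_inc = u in cell or d in cell
        has_skip = exon.skipping_intron in cell
        if has_inc and not has_skip:
            return True
        if has_skip and not has_inc:
            return False
        return None  # no evidence, or conflicting (collision handled upstream)

    s1 = exon_state(pair.first)
    s2 = exon_state(pair.second)
    if s1 is None or s2 is None:
        return "uninformative"
    if s1 and s2:
        return "both"
    if s1:
        return "first_only"
    if s2:
        return "second_only"
    return "neither"


def build_table(
    pair: ExonPair,
    gene_evidence: Mapping[str, Mapping[IntronKey, int]],
    collision_flags: Optional[Mapping[str, bool]] = None,
) -> ContingencyTable:
    """2x2 table of informative, non-collision barcodes for an exon pair."""
    counts = {"both": 0, "first_only": 0, "second_only": 0, "neither": 0}
    for barcode, cell in gene_evidence.items():
        if collision_flags is not None and collision_flags.get(barcode, False):
            continue
        status = pair_status(cell, pair)
        if status != "uninformative":
            counts[status] += 1
    return ContingencyTable(
        counts["both"], counts["first_only"], counts["second_only"], counts["neither"]
    )


def fisher_two_sided(t: ContingencyTable) -> float:
    """Two-sided Fisher's exact test p-value.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed one (within a
    relative tie tolerance of 1e-7).
    """
    if t.n_t == 0:
        raise ValueError("empty contingency table")
    n = t.n_t
    r1 = t.a + t.b
    c1 = t.a + t.c
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(t.a, n, r1, c1)
    p = float(pmf[pmf <= p_obs * (1 + _TIE_RTOL)].sum())
    return min(p, 1.0)


def log_odds(t: ContingencyTable) -> float:
    """log2 odds ratio with a 0.5 pseudocount in every cell.

    Positive values indicate co-inclusion / co-exclusion association;
    always finite. Swapping the rows (a<->c, b<->d) negates it.
    """
    return math.log2(
        ((t.a + 0.5) * (t.d + 0.5)) / ((t.b + 0.5) * (t.c + 0.5))
    )


def adjust_fdr(p_values: Sequence[float], method: str = "BY") -> np.ndarray:
    """Step-up FDR adjustment, Benjamini–Yekutieli or Benjamini–Hochberg."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"BY": "fdr_by", "BH": "fdr_bh"}.get(method.upper())
    if key is None:
        raise ValueError(f"unknown FDR method: {method!r}")
    return multipletests(p, method=key)[1]


def analyze_tables(
    entries: Sequence[tuple[object, str, ContingencyTable]],
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
    fdr: float = DEFAULT_FDR,
    fdr_method: str = "BY",
) -> list[CoordinationResult]:
    """Test a batch of tables in one multiple-testing family.

    ``entries`` are (pair, gene_id, table) triples; tables with fewer than
    ``min_informative`` informative molecules are not tested. Results are
    sorted by adjusted p, then gene id (deterministic output).
    """
    tested = [
        CoordinationResult(
            pair=pair,
            gene_id=gene_id,
            table=table,
            p_value=fisher_two_sided(table),
            lor=log_odds(table),
        )
        for pair, gene_id, table in entries
        if table.n_t >= min_informative
    ]
    if not tested:
        return []
    adjusted = adjust_fdr([r.p_value for r in tested], fdr_method)
    for r, padj in zip(tested, adjusted):
        r.p_adjusted = float(padj)
        r.significant = bool(padj <= fdr)
    tested.sort(key=lambda r: (r.p_adjusted, r.gene_id, r.p_value))
    return tested


def run_internal_coordination(
    pairs: Sequence[ExonPair],
    evidence_by_gene: Mapping[str, Mapping[str, Mapping[IntronKey, int]]],
    collision_flags: Optional[Mapping[str, Mapping[str, bool]]] = None,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
    fdr: float = DEFAULT_FDR,
    fdr_method: str = "BY",
) -> tuple[list[CoordinationResult], set[str]]:
    """Genome-wide internal exon-pair coordination scan.

    Builds a table for every pair with >= ``min_informative`` informative
    molecules, applies one Benjamini–Yekutieli correction across all tested
    pairs, and returns the results plus the genes with at least one
    significant pair.
    """
    entries = []
    for pair in pairs:
        gene_ev = evidence_by_gene.get(pair.gene_id, {})
        flags = collision_flags.get(pair.gene_id) if collision_flags else None
        table = build_table(pair, gene_ev, flags)
        entries.append((pair, pair.gene_id, table))
    results = analyze_tables(entries, min_informative, fdr, fdr_method)
    for r in results:
        if isinstance(r.pair, ExonPair):
            r.pair_coding = r.pair.pair_coding
    if not results:
        warnings.warn("no exon pair reached the informative-molecule threshold")
    genes = {r.gene_id for r in results if r.significant}
    return results, genes


def _terminal_table(
    site_pair: TerminalSitePair,
    gene_evidence: Mapping[str, Mapping[IntronKey, int]],
    collision_flags: Optional[Mapping[str, bool]] = None,
) -> ContingencyTable:
    """2x2 (donor form x acceptor form) over the two best-supported forms.

    A barcode is informative when its evidence selects exactly one of the
    top-two donor forms and exactly one of the top-two acceptor forms.
    """
    d1, d2 = site_pair.donor.alternative_forms[:2]
    a1, a2 = site_pair.acceptor.alternative_forms[:2]
    counts = [[0, 0], [0, 0]]
    for barcode, cell in gene_evidence.items():
        if collision_flags is not None and collision_flags.get(barcode, False):
            continue
        dhit = [d1 in cell, d2 in cell]
        ahit = [a1 in cell, a2 in cell]
        if sum(dhit) != 1 or sum(ahit) != 1:
            continue
        counts[dhit.index(True)][ahit.index(True)] += 1
    return ContingencyTable(counts[0][0], counts[0][1], counts[1][0], counts[1][1])


def run_terminal_coordination(
    site_pairs: Sequence[TerminalSitePair],
    evidence_by_gene: Mapping[str, Mapping[str, Mapping[IntronKey, int]]],
    collision_flags: Optional[Mapping[str, Mapping[str, bool]]] = None,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
    fdr: float = DEFAULT_FDR,
) -> tuple[list[CoordinationResult], dict[str, tuple[ContingencyTable, float]]]:
    """Per-gene coordination test between the gene's terminal alternative
    donor and acceptor events (one test per gene, Benjamini–Hochberg), plus
    a category-enrichment Fisher test: category membership x significance.
    """
    entries = []
    for sp in site_pairs:
        gene_ev = evidence_by_gene.get(sp.gene_id, {})
        flags = collision_flags.get(sp.gene_id) if collision_flags else None
        table = _terminal_table(sp, gene_ev, flags)
        entries.append((sp, sp.gene_id, table))
    results = analyze_tables(entries, min_informative, fdr, fdr_method="BH")
    for r in results:
        r.category = r.pair.category
    enrichment: dict[str, tuple[ContingencyTable, float]] = {}
    categories = sorted({r.category for r in results})
    for cat in categories:
        in_sig = sum(1 for r in results if r.category == cat and r.significant)
        in_non = sum(1 for r in results if r.category == cat and not r.significant)
        out_sig = sum(1 for r in results if r.category != cat and r.significant)
        out_non = sum(1 for r in results if r.category != cat and not r.significant)
        table = ContingencyTable(in_sig, in_non, out_sig, out_non)
        enrichment[cat] = (table, fisher_two_sided(table) if table.n_t else math.nan)
    return results, enrichment


def coding_noncoding_comparison(
    results: Sequence[CoordinationResult],
    seed: int = 0,
) -> tuple[float, float, ContingencyTable]:
    """Compare coordination frequency between entirely-coding exon pairs and
    pairs involving noncoding sequence, matched on informative-molecule
    counts.

    Greedy nearest-neighbour matching without replacement on n_t (the
    smaller group drives the matching; ties among equally distant partners
    are broken with the seeded RNG). Returns (Fisher p, frequency ratio,
    group x coordinated table).
    """
    coding = [r for r in results if r.pair_coding == "entirely_coding"]
    noncod = [r for r in results if r.pair_coding == "contains_noncoding"]
    if not coding or not noncod:
        raise ValueError("both coding and noncoding groups must be non-empty")
    rng = np.random.default_rng(seed)
    small, large = (coding, noncod) if len(coding) <= len(noncod) else (noncod, coding)
    available = list(range(len(large)))
    matched_small, matched_large = [], []
    for r in sorted(small, key=lambda r: (r.table.n_t, r.gene_id)):
        dists = np.array([abs(large[j].table.n_t - r.table.n_t) for j in available])
        best = np.flatnonzero(dists == dists.min())
        pick = int(best[rng.integers(len(best))]) if len(best) > 1 else int(best[0])
        matched_small.append(r)
        matched_large.append(large[available.pop(pick)])
    m_coding, m_noncod = (
        (matched_small, matched_large)
        if small is coding
        else (matched_large, matched_small)
    )
    cs = sum(r.significant for r in m_coding)
    ns = sum(r.significant for r in m_noncod)
    table = ContingencyTable(cs, len(m_coding) - cs, ns, len(m_noncod) - ns)
    p = fisher_two_sided(table)
    f_c = cs / len(m_coding)
    f_n = ns / len(m_noncod)
    ratio = math.inf if f_n == 0 and f_c > 0 else (f_c / f_n if f_n else math.nan)
    return p, ratio, table


def frame_analysis(significant_pairs: Sequence[CoordinationResult]) -> Optional[float]:
    """Fraction of significant (entirely coding) exon pairs where both exon
    lengths are divisible by three, i.e. joint inclusion/skipping preserves
    the reading frame."""
    pairs = [r.pair for r in significant_pairs if isinstance(r.pair, ExonPair)]
    if not pairs:
        return None
    both = sum(1 for p in pairs if p.first.frame_preserving and p.second.frame_preserving)
    return both / len(pairs)
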