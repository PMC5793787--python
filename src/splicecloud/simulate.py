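"""Synthetic droplet-barcoded spliced-read data with known truth.

The generator emulates the statistical structure of a microfluidic
linked-read isoform experiment: RNA molecules of each gene carry a joint
inclusion pattern for a planted pair of alternative exons (marginals
psi1/psi2 plus an odds ratio), are encapsulated uniformly at random into
droplets (per-gene occupancy is then approximately Poisson distributed),
and are sequenced by linear random-primed amplification — modelled as
independent random read starts along the mature molecule. A junction is
observed by a read only when the read covers at least a configurable
anchor on both sides of it. A configurable fraction of molecules is
unspliced (contributing no junction reads), and reads can be misassigned
to a random other droplet's barcode at a configurable rate.

Collisions (two non-identical molecules of a gene in one droplet) arise
naturally from multi-occupancy; they are not injected.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, IntronKey, Transcript
from .coordination import ContingencyTable
from .readclouds import JunctionEvidence

__all__ = [
    "SimConfig",
    "SimTruth",
    "joint_probs",
    "make_annotation",
    "write_gtf",
    "simulate_dataset",
    "simulate_tables",
    "expected_collision_fraction",
]


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiment.

    Defaults mirror the regime the method targets: ~200,000 droplets,
    about one third of molecules unspliced, ~20 reads per molecule from
    linear amplification, and 6-bp junction anchors.
    """

    n_genes: int = 10
    molecules_per_gene: int | Sequence[int] = 1000
    psi1: float = 0.5
    psi2: float = 0.5
    odds_ratio: float | Sequence[float] = 1.0
    n_droplets: int = 200_000
    reads_per_molecule: float = 20.0  # Poisson mean
    read_length: int = 150
    min_anchor: int = 6
    unspliced_fraction: float = 1 / 3
    barcode_misassignment_rate: float = 0.0
    coding: bool = True
    with_terminal: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("psi1", "psi2", "unspliced_fraction", "barcode_misassignment_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_droplets < 1:
            raise ValueError("n_droplets must be >= 1")
        ors = np.atleast_1d(np.asarray(self.odds_ratio, dtype=float))
        if np.any(ors <= 0):
            raise ValueError("odds_ratio must be > 0")

    def odds_ratio_for(self, gene_index: int) -> float:
        ors = np.atleast_1d(np.asarray(self.odds_ratio, dtype=float))
        return float(ors[gene_index % ors.size])

    def molecules_for(self, gene_index: int) -> int:
        m = self.molecules_per_gene
        if isinstance(m, (int, np.integer)):
            return int(m)
        return int(m[gene_index % len(m)])


@dataclass
class SimTruth:
    """Ground truth written alongside every simulated dataset."""

    config: SimConfig
    pair_params: pd.DataFrame  # gene_id, psi1, psi2, odds_ratio, log2_or
    molecules: pd.DataFrame  # gene_id, molecule, pattern, droplet, barcode, unspliced

    def occupancy_collision_fraction(self, gene_id: str) -> float:
        """Fraction of droplets holding >=2 molecules of the gene among the
        droplets holding >=1 — the quantity the conditional-Poisson closed
        form describes."""
        drops = self.molecules.loc[self.molecules.gene_id == gene_id, "droplet"]
        counts = drops.value_counts()
        if counts.empty:
            return 0.0
        return float((counts >= 2).sum() / len(counts))

    def pattern_frequencies(self, gene_id: str) -> np.ndarray:
        pats = self.molecules.loc[self.molecules.gene_id == gene_id, "pattern"]
        return np.array([(pats == k).mean() for k in ("11", "10", "01", "00")])


def joint_probs(psi1: float, psi2: float, odds_ratio: float) -> tuple[float, float, float, float]:
    """Joint inclusion distribution (p11, p10, p01, p00) of two alternative
    exons with the given inclusion marginals and odds ratio.

    Solves p(1 - psi1 - psi2 + p) = OR (psi1 - p)(psi2 - p) for the unique
    root in the Frechet interval [max(0, psi1+psi2-1), min(psi1, psi2)].
    """
    if not (0 < psi1 < 1 and 0 < psi2 < 1):
        raise ValueError("marginals must lie strictly in (0, 1)")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be > 0")
    if odds_ratio == 1.0:
        p11 = psi1 * psi2
    else:
        # quadratic (1-OR) p^2 + [1 - psi1 - psi2 + OR(psi1+psi2)] p - OR psi1 psi2 = 0
        A = 1.0 - odds_ratio
        B = 1.0 - psi1 - psi2 + odds_ratio * (psi1 + psi2)
        C = -odds_ratio * psi1 * psi2
        disc = B * B - 4 * A * C
        assert disc >= 0
        sq = math.sqrt(disc)
        roots = [(-B + sq) / (2 * A), (-B - sq) / (2 * A)]
        lo, hi = max(0.0, psi1 + psi2 - 1.0), min(psi1, psi2)
        feasible = [r for r in roots if lo - 1e-12 <= r <= hi + 1e-12]
        assert feasible, "no feasible root (cannot occur for OR > 0)"
        p11 = min(max(feasible[0], lo), hi)
    p10 = psi1 - p11
    p01 = psi2 - p11
    p00 = 1.0 - psi1 - psi2 + p11
    return p11, p10, p01, p00


# ---------------------------------------------------------------------------
# annotation fixtures
# ---------------------------------------------------------------------------

_GENE_SPAN = 100_000


def _gene_coordinates(gene_index: int) -> dict[str, tuple[int, int]]:
    """Exon layout of one synthetic gene (all genes share the template).

    Constitutive scaffold E0-B-E4-LAST with two planted pure-skipping
    exons A (90 bp) and C (93 bp), both frame-preserving, separated by the
    constitutive exon B.
    """
    x = 1000 + gene_index * _GENE_SPAN
    return {
        "E0": (x, x + 150),
        "A": (x + 650, x + 740),  # 90 bp
        "B": (x + 1240, x + 1360),
        "C": (x + 1860, x + 1953),  # 93 bp
        "E4": (x + 2453, x + 2603),
        "LAST": (x + 3103, x + 3303),
    }


def _terminal_coordinates(gene_index: int) -> dict[str, tuple[int, int]]:
    """Layout for terminal-site genes: two alternative first exons F1/F2
    sharing the acceptor of M1 (a first-donor event) and two alternative
    last-exon acceptors L1/L2 sharing the donor of M3 (a last-acceptor
    event), separated by constitutive exons M1-M3."""
    x = 1000 + gene_index * _GENE_SPAN
    return {
        "F1": (x, x + 150),
        "F2": (x + 300, x + 450),
        "M1": (x + 950, x + 1100),
        "M2": (x + 1600, x + 1750),
        "M3": (x + 2250, x + 2400),
        "L1": (x + 2900, x + 3200),
        "L2": (x + 3000, x + 3200),
    }


def make_annotation(config: SimConfig) -> tuple[list[GeneModel], dict]:
    """Build the synthetic gene models plus truth labels.

    Internal-pair genes get four transcripts (every inclusion combination
    of the planted exons A and C); terminal genes get the four
    first-exon x last-acceptor combinations.
    """
    genes: list[GeneModel] = []
    truth: dict = {"pairs": {}, "terminal": {}}
    chrom = "chrS"
    for gi in range(config.n_genes):
        gene_id = f"GENE{gi:04d}"
        if config.with_terminal:
            co = _terminal_coordinates(gi)
            combos = {
                "11": ["F1", "M1", "M2", "M3", "L1"],
                "10": ["F1", "M1", "M2", "M3", "L2"],
                "01": ["F2", "M1", "M2", "M3", "L1"],
                "00": ["F2", "M1", "M2", "M3", "L2"],
            }
            truth["terminal"][gene_id] = {
                "donor_forms": [
                    IntronKey(chrom, co["F1"][1], co["M1"][0], "+"),
                    IntronKey(chrom, co["F2"][1], co["M1"][0], "+"),
                ],
                "acceptor_forms": [
                    IntronKey(chrom, co["M3"][1], co["L1"][0], "+"),
                    IntronKey(chrom, co["M3"][1], co["L2"][0], "+"),
                ],
            }
        else:
            co = _gene_coordinates(gi)
            combos = {
                "11": ["E0", "A", "B", "C", "E4", "LAST"],
                "10": ["E0", "A", "B", "E4", "LAST"],
                "01": ["E0", "B", "C", "E4", "LAST"],
                "00": ["E0", "B", "E4", "LAST"],
            }
            truth["pairs"][gene_id] = {"first_exon": co["A"], "second_exon": co["C"]}
        gene = GeneModel(gene_id, chrom, "+",
                         "protein_coding" if config.coding else "lincRNA")
        span = (min(iv[0] for iv in co.values()), max(iv[1] for iv in co.values()))
        for pattern, names in combos.items():
            exons = [co[n] for n in names]
            tx = Transcript(f"{gene_id}.{pattern}", exons, chrom, "+")
            if config.coding:
                cds_lo, cds_hi = span[0] + 30, span[1] - 50
                tx.cds = [
                    (max(s, cds_lo), min(e, cds_hi))
                    for s, e in exons
                    if max(s, cds_lo) < min(e, cds_hi)
                ]
            gene.transcripts.append(tx)
        genes.append(gene)
    return genes, truth


def write_gtf(path, genes: Sequence[GeneModel]) -> None:
    """Write gene models as GENCODE-style GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for gene in genes:
            start = min(tx.start for tx in gene.transcripts)
            end = max(tx.end for tx in gene.transcripts)
            attrs = f'gene_id "{gene.gene_id}"; gene_type "{gene.biotype}";'
            fh.write(
                f"{gene.chrom}\tsim\tgene\t{start + 1}\t{end}\t.\t{gene.strand}\t.\t{attrs}\n"
            )
            for tx in gene.transcripts:
                tattrs = attrs + f' transcript_id "{tx.tx_id}";'
                fh.write(
                    f"{gene.chrom}\tsim\ttranscript\t{tx.start + 1}\t{tx.end}\t.\t"
                    f"{gene.strand}\t.\t{tattrs}\n"
                )
                for s, e in tx.exons:
                    fh.write(
                        f"{gene.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t{tattrs}\n"
                    )
                for s, e in tx.cds:
                    fh.write(
                        f"{gene.chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t{gene.strand}\t0\t{tattrs}\n"
                    )


# ---------------------------------------------------------------------------
# dataset simulation
# ---------------------------------------------------------------------------

def _pattern_layout(gene: GeneModel) -> dict[str, tuple[list[tuple[int, int]], list[tuple[int, IntronKey]]]]:
    """Per isoform pattern: (exon list, [(mature junction offset, intron)])."""
    out = {}
    for tx in gene.transcripts:
        pattern = tx.tx_id.rsplit(".", 1)[1]
        juncs = []
        offset = 0
        introns = tx.introns
        for i, (s, e) in enumerate(tx.exons[:-1]):
            offset += e - s
            juncs.append((offset, introns[i]))
        out[pattern] = (tx.exons, juncs)
    return out


def simulate_dataset(
    config: SimConfig,
    sam_path: Optional[str] = None,
) -> tuple[list[JunctionEvidence], list[GeneModel], SimTruth]:
    """Generate a full synthetic dataset: gene models, molecules, droplets,
    reads, and the aggregated junction evidence, plus the ground truth.

    Returns (evidence, gene models, truth). When ``sam_path`` is given, a
    minimal SAM file with BX barcode tags is written as well (intended for
    small configurations).
    """
    rng = np.random.default_rng(config.seed)
    genes, labels = make_annotation(config)
    pattern_names = np.array(["11", "10", "01", "00"])

    mol_rows = []
    evidence_counts: dict[tuple[str, str, IntronKey], int] = {}
    sam_reads: list[tuple[str, str, int, str, str]] = []

    rl = config.read_length
    anchor = config.min_anchor
    n_droplets = config.n_droplets

    pair_rows = []
    for gi, gene in enumerate(genes):
        n_mol = config.molecules_for(gi)
        orat = config.odds_ratio_for(gi)
        probs = joint_probs(config.psi1, config.psi2, orat)
        pair_rows.append(
            (gene.gene_id, config.psi1, config.psi2, orat, math.log2(orat))
        )
        layout = _pattern_layout(gene)
        patterns = pattern_names[rng.choice(4, size=n_mol, p=probs)]
        droplets = rng.integers(n_droplets, size=n_mol)
        unspliced = rng.random(n_mol) < config.unspliced_fraction
        n_reads = rng.poisson(config.reads_per_molecule, size=n_mol)

        for mi in range(n_mol):
            droplet = int(droplets[mi])
            barcode = f"BC{droplet:07d}"
            pattern = str(patterns[mi])
            mol_rows.append(
                (gene.gene_id, mi, pattern, droplet, barcode, bool(unspliced[mi]))
            )
            if unspliced[mi] or n_reads[mi] == 0:
                continue
            exons, juncs = layout[pattern]
            mature_len = sum(e - s for s, e in exons)
            max_start = max(mature_len - rl, 0)
            starts = rng.integers(0, max_start + 1, size=n_reads[mi])
            for offset, intron in juncs:
                # read start window from which both anchors are covered
                lo = max(offset - rl + anchor, 0)
                hi = offset - anchor
                if hi < lo:
                    continue
                count = int(np.count_nonzero((starts >= lo) & (starts <= hi)))
                if count:
                    key = (barcode, gene.gene_id, intron)
                    evidence_counts[key] = evidence_counts.get(key, 0) + count
            if sam_path is not None:
                for ri, s in enumerate(starts):
                    sam_reads.append(
                        _sam_read(gene, exons, int(s), rl, barcode,
                                  f"{gene.gene_id}.m{mi}.r{ri}")
                    )

    # barcode misassignment: move a binomial share of each evidence unit's
    # reads to uniformly chosen other droplets
    if config.barcode_misassignment_rate > 0:
        moved: dict[tuple[str, str, IntronKey], int] = {}
        for (barcode, gene_id, intron), count in list(evidence_counts.items()):
            n_move = int(rng.binomial(count, config.barcode_misassignment_rate))
            if n_move == 0:
                continue
            evidence_counts[(barcode, gene_id, intron)] = count - n_move
            for _ in range(n_move):
                new_bc = f"BC{int(rng.integers(n_droplets)):07d}"
                k = (new_bc, gene_id, intron)
                moved[k] = moved.get(k, 0) + 1
        for k, n in moved.items():
            evidence_counts[k] = evidence_counts.get(k, 0) + n
        evidence_counts = {k: v for k, v in evidence_counts.items() if v > 0}

    evidence = [
        JunctionEvidence(bc, gid, intron, n)
        for (bc, gid, intron), n in sorted(evidence_counts.items())
    ]
    molecules = pd.DataFrame(
        mol_rows,
        columns=["gene_id", "molecule", "pattern", "droplet", "barcode", "unspliced"],
    )
    pair_params = pd.DataFrame(
        pair_rows, columns=["gene_id", "psi1", "psi2", "odds_ratio", "log2_or"]
    )
    truth = SimTruth(config=config, pair_params=pair_params, molecules=molecules)

    if sam_path is not None:
        _write_sam(sam_path, genes, sam_reads)
    return evidence, genes, truth


def _sam_read(
    gene: GeneModel,
    exons: list[tuple[int, int]],
    mature_start: int,
    read_length: int,
    barcode: str,
    qname: str,
) -> tuple[str, str, int, str, str]:
    """Project a mature-coordinate read onto the genome as (qname, chrom,
    pos, cigar, barcode)."""
    remaining = read_length
    cigar: list[str] = []
    pos = None
    offset = 0
    prev_end = None
    for s, e in exons:
        elen = e - s
        if mature_start >= offset + elen:
            offset += elen
            continue
        within = max(mature_start - offset, 0)
        gstart = s + within
        take = min(elen - within, remaining)
        if pos is None:
            pos = gstart
        else:
            cigar.append(f"{gstart - prev_end}N")
        cigar.append(f"{take}M")
        prev_end = gstart + take
        remaining -= take
        offset += elen
        if remaining == 0:
            break
    assert pos is not None
    return qname, gene.chrom, pos, "".join(cigar), barcode


def _write_sam(path, genes: Sequence[GeneModel], reads) -> None:
    chroms: dict[str, int] = {}
    for gene in genes:
        end = max(tx.end for tx in gene.transcripts)
        chroms[gene.chrom] = max(chroms.get(gene.chrom, 0), end + 1000)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, ln in sorted(chroms.items()):
            fh.write(f"@SQ\tSN:{chrom}\tLN:{ln}\n")
        for qname, chrom, pos, cigar, barcode in reads:
            seq_len = sum(
                int(n) for n, op in re.findall(r"(\d+)([MN])", cigar) if op == "M"
            )
            fh.write(
                f"{qname}\t0\t{chrom}\t{pos + 1}\t60\t{cigar}\t*\t0\t0\t"
                f"{'A' * seq_len}\t*\tBX:Z:{barcode}\n"
            )


def simulate_tables(
    n_pairs: int,
    psi1: float,
    psi2: float,
    odds_ratio: float,
    n_t: int,
    rng: np.random.Generator | int = 0,
) -> list[ContingencyTable]:
    """Draw 2x2 tables directly from the joint inclusion distribution
    (multinomial with ``n_t`` informative molecules per pair) — the
    molecule-level model without the read layer."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    probs = joint_probs(psi1, psi2, odds_ratio)
    draws = rng.multinomial(n_t, probs, size=n_pairs)
    return [ContingencyTable(*map(int, row)) for row in draws]


def expected_collision_fraction(lam: float) -> float:
    """Closed-form collision fraction under Poisson(lam) per-droplet
    occupancy: P(>=2 molecules | >=1 molecule)."""
    if lam <= 0:
        return 0.0
    denom = 1.0 - math.exp(-lam)
    return (denom - lam * math.exp(-lam)) / denom
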