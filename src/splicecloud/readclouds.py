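"""Read-cloud deconvolution: from barcoded spliced alignments to molecules.

A *read cloud* is the set of short reads sharing a droplet barcode and
mapping to one gene; it is treated as evidence for a single RNA molecule.
This module extracts splice junctions from gapped alignments (with a
minimum anchor on either side of the junction), assigns them to annotated
introns, calls molecules per (gene, barcode), flags *collisions*
(conflicting splicing evidence under one barcode, i.e. two non-identical
molecules of the gene in one droplet), and computes per-gene expression
(molecules per million, MPM) and percent-spliced-in (psi).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .annotation import GeneModel, IntronKey, SkippableExon

__all__ = [
    "JunctionEvidence",
    "BarcodeStats",
    "MoleculeCall",
    "EvidenceCounters",
    "extract_junctions",
    "build_evidence",
    "barcode_qc",
    "call_molecules",
    "detect_collisions",
    "compute_mpm",
    "estimate_total_molecules",
    "compute_psi",
    "group_evidence",
    "evidence_to_frame",
    "frame_to_evidence",
    "read_evidence_tsv",
    "write_evidence_tsv",
]

DEFAULT_MIN_ANCHOR = 6

# CIGAR operations that consume the reference
_REF_OPS = {0, 2, 7, 8}  # M, D, =, X
_SKIP_OP = 3  # N


@dataclass(frozen=True)
class JunctionEvidence:
    """Reads of one barcode spanning one annotated intron of one gene."""

    barcode: str
    gene_id: str
    intron: IntronKey
    read_count: int

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")


@dataclass
class BarcodeStats:
    barcode: str
    total_reads: int = 0
    spliced_gene_count: int = 0


@dataclass(frozen=True)
class MoleculeCall:
    gene_id: str
    barcode: str
    spliced_read_support: int
    collision: bool = False


@dataclass
class EvidenceCounters:
    """Summary counters reported by :func:`build_evidence`."""

    reads: int = 0
    barcodeless_reads: int = 0
    unassigned_junctions: int = 0
    multi_gene_junctions: int = 0


def extract_junctions(alignment, min_anchor: int = DEFAULT_MIN_ANCHOR) -> list[IntronKey]:
    """Splice junctions of one aligned record (``pysam.AlignedSegment``).

    One :class:`IntronKey` per N (reference-skip) CIGAR operation whose
    flanking aligned blocks each cover at least ``min_anchor`` reference
    bases. Unmapped or unspliced records yield an empty list.
    """
    if alignment.is_unmapped or alignment.cigartuples is None:
        return []
    chrom = alignment.reference_name
    strand = "-" if alignment.is_reverse else "+"
    # collapse CIGAR into alternating reference blocks and skips
    blocks: list[int] = []  # reference bases in each aligned block
    skips: list[tuple[int, int]] = []  # (block index before skip, skip length)
    cur = 0
    for op, length in alignment.cigartuples:
        if op == _SKIP_OP:
            blocks.append(cur)
            skips.append((len(blocks) - 1, length))
            cur = 0
        elif op in _REF_OPS:
            cur += length
    blocks.append(cur)

    out: list[IntronKey] = []
    block_start = alignment.reference_start
    for bi, blen in enumerate(blocks[:-1]):
        junc_start = block_start + blen
        _, skip_len = skips[bi]
        if blen >= min_anchor and blocks[bi + 1] >= min_anchor:
            out.append(IntronKey(chrom, junc_start, junc_start + skip_len, strand))
        block_start = junc_start + skip_len
    return out


def _barcode_of(alignment, tag: str = "BX", name_separator: Optional[str] = None):
    try:
        return alignment.get_tag(tag)
    except KeyError:
        pass
    if name_separator is not None:
        name = alignment.query_name or ""
        if name_separator in name:
            return name.rsplit(name_separator, 1)[1]
    return None


def _intron_gene_index(
    annotation: Sequence[GeneModel],
    extra_junctions: Optional[Mapping[IntronKey, str] | set] = None,
) -> dict[IntronKey, Optional[str]]:
    """intron -> gene_id; ``None`` marks introns shared by several genes."""
    index: dict[IntronKey, Optional[str]] = {}
    for gene in annotation:
        for intron in gene.introns:
            if intron in index and index[intron] != gene.gene_id:
                index[intron] = None
            else:
                index[intron] = gene.gene_id
    if extra_junctions:
        if isinstance(extra_junctions, Mapping):
            items = extra_junctions.items()
        else:  # a bare set is only usable if unambiguous by position
            items = ((k, None) for k in extra_junctions)
        for intron, gene_id in items:
            if gene_id is None:
                continue
            if intron in index and index[intron] not in (None, gene_id):
                index[intron] = None
            elif intron not in index:
                index[intron] = gene_id
    return index


def build_evidence(
    alignments: Iterable,
    annotation: Sequence[GeneModel],
    extra_junctions: Optional[Mapping[IntronKey, str]] = None,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    barcode_tag: str = "BX",
    name_separator: Optional[str] = None,
) -> tuple[list[JunctionEvidence], list[BarcodeStats], EvidenceCounters]:
    """Aggregate junction evidence per (barcode, gene, intron).

    Junctions matching exactly one gene's annotated intron set (or an
    extra junction attributable to one gene) count; junctions matching
    zero or several genes are dropped and tallied in the counters.
    """
    index = _intron_gene_index(annotation, extra_junctions)
    counts: dict[tuple[str, str, IntronKey], int] = defaultdict(int)
    reads_per_barcode: dict[str, int] = defaultdict(int)
    spliced_genes: dict[str, set[str]] = defaultdict(set)
    counters = EvidenceCounters()

    for aln in alignments:
        if aln.is_unmapped:
            continue
        counters.reads += 1
        barcode = _barcode_of(aln, barcode_tag, name_separator)
        if barcode is None:
            counters.barcodeless_reads += 1
            continue
        reads_per_barcode[barcode] += 1
        for intron in extract_junctions(aln, min_anchor):
            gene_id = index.get(intron, "__absent__")
            if gene_id == "__absent__":
                counters.unassigned_junctions += 1
            elif gene_id is None:
                counters.multi_gene_junctions += 1
            else:
                counts[(barcode, gene_id, intron)] += 1
                spliced_genes[barcode].add(gene_id)

    evidence = [
        JunctionEvidence(barcode, gene_id, intron, n)
        for (barcode, gene_id, intron), n in sorted(counts.items())
    ]
    stats = [
        BarcodeStats(bc, reads_per_barcode[bc], len(spliced_genes.get(bc, ())))
        for bc in sorted(reads_per_barcode)
    ]
    return evidence, stats, counters


def barcode_qc(
    stats: Sequence[BarcodeStats],
    molecule_calls: Sequence[MoleculeCall],
    read_cutoff: int,
) -> tuple[set[str], float]:
    """Retain barcodes with more than ``read_cutoff`` reads.

    The misidentification rate is the fraction of molecule calls whose
    barcode falls at or below the cutoff — molecules likely attributed to
    a spuriously identified droplet barcode.
    """
    if not stats:
        raise ValueError("no barcode statistics supplied")
    reads = {s.barcode: s.total_reads for s in stats}
    retained = {bc for bc, n in reads.items() if n > read_cutoff}
    if not molecule_calls:
        return retained, 0.0
    bad = sum(1 for call in molecule_calls if reads.get(call.barcode, 0) <= read_cutoff)
    return retained, bad / len(molecule_calls)


def group_evidence(
    evidence: Iterable[JunctionEvidence],
) -> dict[str, dict[str, dict[IntronKey, int]]]:
    """gene_id -> barcode -> {intron: read count}."""
    grouped: dict[str, dict[str, dict[IntronKey, int]]] = defaultdict(
        lambda: defaultdict(dict)
    )
    for ev in evidence:
        cell = grouped[ev.gene_id][ev.barcode]
        cell[ev.intron] = cell.get(ev.intron, 0) + ev.read_count
    return grouped


def call_molecules(
    evidence: Sequence[JunctionEvidence], k: int = 1
) -> list[MoleculeCall]:
    """One molecule per (gene, barcode) supported by >= ``k`` spliced reads.

    Spliced-read support is summed over all introns of the gene seen for
    the barcode; the number of calls is non-increasing in ``k``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    support: dict[tuple[str, str], int] = defaultdict(int)
    for ev in evidence:
        support[(ev.gene_id, ev.barcode)] += ev.read_count
    return [
        MoleculeCall(gene_id, barcode, n)
        for (gene_id, barcode), n in sorted(support.items())
        if n >= k
    ]


def _introns_conflict(a: IntronKey, b: IntronKey) -> bool:
    """Two distinct overlapping introns cannot coexist on one molecule."""
    return a != b and a.start < b.end and b.start < a.end


def detect_collisions(
    gene_evidence: Mapping[str, Mapping[IntronKey, int]],
    events: Sequence[SkippableExon],
    general_rule: bool = False,
) -> tuple[dict[str, bool], float]:
    """Flag barcodes with conflicting spliced evidence for one gene.

    A barcode is a collision when it carries evidence for both an
    inclusion intron and the skipping intron of the same skippable exon
    (the exon is seen both included and skipped in one droplet). With
    ``general_rule`` any two overlapping non-identical introns conflict.
    Returns per-barcode flags and the gene's collision fraction.
    """
    flags: dict[str, bool] = {}
    for barcode, cell in gene_evidence.items():
        introns = set(cell)
        hit = False
        for ev in events:
            u, d = ev.inclusion_introns
            if ev.skipping_intron in introns and (u in introns or d in introns):
                hit = True
                break
        if not hit and general_rule:
            ordered = sorted(introns)
            for i, a in enumerate(ordered):
                for b in ordered[i + 1 :]:
                    if b.start >= a.end:
                        break
                    if _introns_conflict(a, b):
                        hit = True
                        break
                if hit:
                    break
        flags[barcode] = hit
    n = len(flags)
    fraction = (sum(flags.values()) / n) if n else 0.0
    return flags, fraction


def compute_mpm(calls: Sequence[MoleculeCall]) -> dict[str, float]:
    """Molecules per million: per-gene molecule calls scaled so the total
    over genes is exactly 1e6."""
    if not calls:
        raise ValueError("no molecule calls")
    per_gene: dict[str, int] = defaultdict(int)
    for call in calls:
        per_gene[call.gene_id] += 1
    total = len(calls)
    return {g: n / (total / 1e6) for g, n in sorted(per_gene.items())}


def estimate_total_molecules(spliced_count: float, spliced_fraction: float = 2 / 3) -> float:
    """Total (spliced + unspliced) molecules given the spliced count and the
    assumed fraction of molecules that are spliced."""
    if not 0 < spliced_fraction <= 1:
        raise ValueError("spliced_fraction must be in (0, 1]")
    if spliced_count < 0:
        raise ValueError("spliced_count must be >= 0")
    return spliced_count / spliced_fraction


@dataclass
class PsiResult:
    psi: float
    inclusion: int
    exclusion: int


def compute_psi(
    gene_evidence: Mapping[str, Mapping[IntronKey, int]],
    exon: SkippableExon,
    collision_flags: Optional[Mapping[str, bool]] = None,
) -> Optional[PsiResult]:
    """Percent-spliced-in of an alternative exon over non-collision barcodes.

    Inclusion barcodes carry evidence for >=1 inclusion intron and not the
    skipping intron; exclusion barcodes the skipping intron only. Returns
    ``None`` when no barcode is informative.
    """
    u, d = exon.inclusion_introns
    inc = exc = 0
    for barcode, cell in gene_evidence.items():
        if collision_flags is not None and collision_flags.get(barcode, False):
            continue
        has_inc = u in cell or d in cell
        has_skip = exon.skipping_intron in cell
        if has_inc and not has_skip:
            inc += 1
        elif has_skip and not has_inc:
            exc += 1
    if inc + exc == 0:
        return None
    return PsiResult(inc / (inc + exc), inc, exc)


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------

_EVIDENCE_COLUMNS = [
    "chrom", "intron_start", "intron_end", "strand", "gene_id", "barcode", "read_count",
]


def evidence_to_frame(evidence: Iterable[JunctionEvidence]) -> pd.DataFrame:
    rows = [
        (e.intron.chrom, e.intron.start, e.intron.end, e.intron.strand,
         e.gene_id, e.barcode, e.read_count)
        for e in evidence
    ]
    return pd.DataFrame(rows, columns=_EVIDENCE_COLUMNS)


def frame_to_evidence(df: pd.DataFrame) -> list[JunctionEvidence]:
    return [
        JunctionEvidence(
            str(r.barcode), str(r.gene_id),
            IntronKey(str(r.chrom), int(r.intron_start), int(r.intron_end), str(r.strand)),
            int(r.read_count),
        )
        for r in df.itertuples(index=False)
    ]


def write_evidence_tsv(path, evidence: Iterable[JunctionEvidence]) -> None:
    evidence_to_frame(evidence).to_csv(path, sep="\t", index=False)


def read_evidence_tsv(path) -> list[JunctionEvidence]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "barcode": str, "gene_id": str})
    missing = [c for c in _EVIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"evidence TSV missing columns: {missing}")
    return frame_to_evidence(df)
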