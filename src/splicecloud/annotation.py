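"""Gene-model parsing and splicing-event classification.

This module reads a GTF annotation into light-weight :class:`GeneModel`
objects (0-based half-open coordinates throughout) and classifies the
splicing events that the coordination analysis consumes:

* **pure exon-skipping events** — internal exons that are either fully
  included or fully skipped in every overlapping transcript, with no
  alternative splice sites, transcription start/end variation inside the
  skipped region, or retention of the flanking introns;
* **separated exon pairs** — two pure exon-skipping events with at least
  one constitutive exon between them;
* **terminal alternative sites** — the most upstream alternative donor
  and the most downstream alternative acceptor of a gene, used to probe
  linkage between promoter/poly(A) choice and internal splicing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "IntronKey",
    "Transcript",
    "GeneModel",
    "SkippableExon",
    "ExonPair",
    "SpliceSiteEvent",
    "TerminalSitePair",
    "GtfParseError",
    "parse_gtf",
    "classify_pure_skipping",
    "enumerate_separated_pairs",
    "find_terminal_alt_sites",
    "mature_length",
    "constitutive_exons",
    "write_skippable_bed",
]

Interval = tuple[int, int]


@dataclass(frozen=True, order=True)
class IntronKey:
    """One intron: ``start`` is the first intronic base, ``end`` exclusive."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"intron start must precede end: {self}")


@dataclass
class Transcript:
    tx_id: str
    exons: list[Interval]  # sorted by genomic coordinate, non-overlapping
    chrom: str = ""
    strand: str = "+"
    cds: list[Interval] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[IntronKey]:
        """Gaps between consecutive exons, in genomic order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append(IntronKey(self.chrom, e1, s2, self.strand))
        return out

    def exon_length_sum(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    biotype: str = "other"
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def cds_intervals(self) -> set[Interval]:
        out: set[Interval] = set()
        for tx in self.transcripts:
            out.update(tx.cds)
        return out

    @property
    def introns(self) -> set[IntronKey]:
        out: set[IntronKey] = set()
        for tx in self.transcripts:
            out.update(tx.introns)
        return out


@dataclass(frozen=True)
class SkippableExon:
    """A pure exon-skipping event."""

    exon: Interval
    inclusion_introns: tuple[IntronKey, IntronKey]  # (upstream, downstream) genomic
    skipping_intron: IntronKey
    coding_status: str  # entirely_coding | contains_noncoding
    frame_preserving: bool

    @property
    def length(self) -> int:
        return self.exon[1] - self.exon[0]


@dataclass(frozen=True)
class ExonPair:
    first: SkippableExon  # upstream in genomic coordinates
    second: SkippableExon
    gene_id: str
    separated: bool
    pair_coding: str
    intermediate_bases: int


@dataclass(frozen=True)
class SpliceSiteEvent:
    """>=2 alternative donors sharing an acceptor (or vice versa)."""

    site_kind: str  # donor | acceptor
    anchor_position: int  # genomic coordinate of the shared partner site
    alternative_forms: tuple[IntronKey, ...]  # ranked by observed support

    def __post_init__(self) -> None:
        if len(self.alternative_forms) < 2:
            raise ValueError("a splice-site event needs >=2 alternative forms")


@dataclass(frozen=True)
class TerminalSitePair:
    gene_id: str
    donor: SpliceSiteEvent
    acceptor: SpliceSiteEvent
    donor_class: str  # first | internal
    acceptor_class: str  # last | internal

    @property
    def category(self) -> str:
        d = "first" if self.donor_class == "first" else "internal"
        a = "last" if self.acceptor_class == "last" else "internal"
        return f"{d}-{a}"


class GtfParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# GTF parsing
# ---------------------------------------------------------------------------

def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


_BIOTYPES = {"protein_coding", "lincRNA", "antisense", "pseudogene"}


def _normalise_biotype(raw: str) -> str:
    if raw in _BIOTYPES:
        return raw
    if raw.endswith("pseudogene"):
        return "pseudogene"
    return "other"


def parse_gtf(path) -> list[GeneModel]:
    """Read a GTF file into :class:`GeneModel` objects.

    GTF 1-based inclusive coordinates are converted to 0-based half-open.
    Transcripts with overlapping exons are rejected with a warning.
    Raises :class:`GtfParseError` (naming the line) on malformed records.
    """
    genes: dict[str, GeneModel] = {}
    tx_map: dict[str, Transcript] = {}
    tx_gene: dict[str, str] = {}
    gene_biotype: dict[str, str] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start, end, _score, strand, _frame, attr_text = fields
            if feature not in ("gene", "transcript", "exon", "CDS"):
                continue
            try:
                iv = (int(start) - 1, int(end))
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: bad coordinates") from exc
            if iv[0] >= iv[1]:
                raise GtfParseError(f"line {lineno}: empty interval")
            attrs = _parse_attributes(attr_text)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise GtfParseError(f"line {lineno}: missing gene_id attribute")
            biotype = attrs.get("gene_type", attrs.get("gene_biotype", ""))
            if biotype:
                gene_biotype[gene_id] = _normalise_biotype(biotype)
            if gene_id not in genes:
                genes[gene_id] = GeneModel(gene_id, chrom, strand,
                                           gene_biotype.get(gene_id, "other"))
            genes[gene_id].biotype = gene_biotype.get(gene_id, genes[gene_id].biotype)
            if feature == "gene":
                continue
            tx_id = attrs.get("transcript_id")
            if tx_id is None:
                raise GtfParseError(f"line {lineno}: missing transcript_id attribute")
            if tx_id not in tx_map:
                tx_map[tx_id] = Transcript(tx_id, [], chrom, strand)
                tx_gene[tx_id] = gene_id
            if feature == "exon":
                tx_map[tx_id].exons.append(iv)
            elif feature == "CDS":
                tx_map[tx_id].cds.append(iv)

    for tx_id, tx in tx_map.items():
        tx.exons.sort()
        tx.cds.sort()
        if any(e1 > s2 for (_, e1), (s2, _) in zip(tx.exons, tx.exons[1:])):
            warnings.warn(f"transcript {tx_id} has overlapping exons; skipped")
            continue
        if not tx.exons:
            continue
        genes[tx_gene[tx_id]].transcripts.append(tx)

    out = [g for g in genes.values() if g.transcripts]
    out.sort(key=lambda g: (g.chrom, min(t.start for t in g.transcripts), g.gene_id))
    return out


# ---------------------------------------------------------------------------
# event classification
# ---------------------------------------------------------------------------

def _exon_fully_coding(gene: GeneModel, exon: Interval) -> bool:
    """True iff every base of the exon is CDS in every transcript carrying it."""
    carriers = [tx for tx in gene.transcripts if exon in tx.exons]
    if not carriers:
        return False
    for tx in carriers:
        covered = 0
        for s, e in tx.cds:
            lo, hi = max(s, exon[0]), min(e, exon[1])
            if lo < hi:
                covered += hi - lo
        if covered < exon[1] - exon[0]:
            return False
    return True


def classify_pure_skipping(gene: GeneModel) -> list[SkippableExon]:
    """Return the gene's pure exon-skipping events.

    An exon qualifies when (i) some transcript includes it as an internal
    exon flanked by introns (u, d), (ii) some transcript carries the direct
    skip intron u.start -> d.end, (iii) its boundaries are identical in every
    transcript containing it and its flanking introns are unique (no
    alternative splice sites interfere), (iv) no transcript begins or ends
    strictly inside the skipped region, and (v) no transcript retains u or d.
    """
    if len(gene.transcripts) < 2:
        return []
    all_introns = gene.introns

    # candidate internal exons with their flanking introns
    flanks: dict[Interval, set[tuple[IntronKey, IntronKey]]] = {}
    for tx in gene.transcripts:
        introns = tx.introns
        for i, exon in enumerate(tx.exons):
            if 0 < i < len(tx.exons) - 1:
                flanks.setdefault(exon, set()).add((introns[i - 1], introns[i]))

    out: list[SkippableExon] = []
    for exon in sorted(flanks):
        if len(flanks[exon]) != 1:
            continue  # alternative flanking splice sites interfere
        u, d = next(iter(flanks[exon]))
        skip = IntronKey(gene.chrom, u.start, d.end, gene.strand)
        if skip not in all_introns:
            continue
        # identical boundaries in all transcripts containing (overlapping) it
        if any(
            ex != exon and ex[0] < exon[1] and exon[0] < ex[1]
            for tx in gene.transcripts
            for ex in tx.exons
        ):
            continue
        # no transcript starts/ends strictly inside the skipped span
        if any(
            skip.start < pos < skip.end
            for tx in gene.transcripts
            for pos in (tx.start, tx.end)
        ):
            continue
        # no intron retention of the flanking introns
        retained = any(
            ex[0] <= intr.start and intr.end <= ex[1]
            for tx in gene.transcripts
            for ex in tx.exons
            for intr in (u, d)
        )
        if retained:
            continue
        length = exon[1] - exon[0]
        coding = "entirely_coding" if _exon_fully_coding(gene, exon) else "contains_noncoding"
        out.append(
            SkippableExon(
                exon=exon,
                inclusion_introns=(u, d),
                skipping_intron=skip,
                coding_status=coding,
                frame_preserving=(length % 3 == 0),
            )
        )
    return out


def constitutive_exons(gene: GeneModel) -> list[Interval]:
    """Exons present with identical boundaries in every transcript whose span
    covers them."""
    all_exons = {ex for tx in gene.transcripts for ex in tx.exons}
    out = []
    for exon in sorted(all_exons):
        ok = True
        for tx in gene.transcripts:
            if tx.start <= exon[0] and exon[1] <= tx.end and exon not in tx.exons:
                ok = False
                break
        if ok:
            out.append(exon)
    return out


def enumerate_separated_pairs(
    gene: GeneModel, events: Sequence[SkippableExon]
) -> list[ExonPair]:
    """All ordered pairs of pure-skipping exons separated by >=1 constitutive
    exon; ``first`` is genomically upstream. ``intermediate_bases`` is the
    maximum over transcripts of annotated exonic bases strictly between the
    two exons."""
    const = constitutive_exons(gene)
    events = sorted(events, key=lambda ev: ev.exon)
    out: list[ExonPair] = []
    for i, e1 in enumerate(events):
        for e2 in events[i + 1 :]:
            between = [c for c in const if e1.exon[1] <= c[0] and c[1] <= e2.exon[0]]
            if not between:
                continue
            inter = 0
            for tx in gene.transcripts:
                bases = sum(
                    ex[1] - ex[0]
                    for ex in tx.exons
                    if e1.exon[1] <= ex[0] and ex[1] <= e2.exon[0]
                )
                inter = max(inter, bases)
            coding = (
                "entirely_coding"
                if e1.coding_status == e2.coding_status == "entirely_coding"
                else "contains_noncoding"
            )
            out.append(
                ExonPair(
                    first=e1,
                    second=e2,
                    gene_id=gene.gene_id,
                    separated=True,
                    pair_coding=coding,
                    intermediate_bases=inter,
                )
            )
    return out


def _rank_forms(
    forms: Iterable[IntronKey],
    support: Optional[Mapping[IntronKey, int]],
    tx_usage: Mapping[IntronKey, int],
) -> tuple[IntronKey, ...]:
    """Rank alternative forms by observed molecule support (falling back to
    annotated transcript usage), ties broken by coordinate."""

    def key(f: IntronKey):
        s = support.get(f, 0) if support is not None else 0
        return (-s, -tx_usage.get(f, 0), f)

    return tuple(sorted(forms, key=key))


def find_terminal_alt_sites(
    gene: GeneModel,
    support: Optional[Mapping[IntronKey, int]] = None,
) -> Optional[TerminalSitePair]:
    """The most upstream alternative-donor event paired with the most
    downstream alternative-acceptor event, if the donor event lies upstream
    and at least one intermediate exon is guaranteed between them in every
    annotated transcript spanning the window. Returns ``None`` otherwise.
    """
    plus = gene.strand == "+"
    introns = sorted(gene.introns)
    if not introns:
        return None
    tx_usage: dict[IntronKey, int] = {}
    for tx in gene.transcripts:
        for intr in tx.introns:
            tx_usage[intr] = tx_usage.get(intr, 0) + 1

    # genomic coordinate of donor / acceptor side of an intron
    def donor_pos(i: IntronKey) -> int:
        return i.start if plus else i.end

    def acceptor_pos(i: IntronKey) -> int:
        return i.end if plus else i.start

    # donor events: >=2 donors sharing one acceptor
    by_acceptor: dict[int, list[IntronKey]] = {}
    by_donor: dict[int, list[IntronKey]] = {}
    for i in introns:
        by_acceptor.setdefault(acceptor_pos(i), []).append(i)
        by_donor.setdefault(donor_pos(i), []).append(i)

    donor_events = [
        SpliceSiteEvent("donor", anchor, _rank_forms(forms, support, tx_usage))
        for anchor, forms in by_acceptor.items()
        if len({donor_pos(f) for f in forms}) >= 2
    ]
    acceptor_events = [
        SpliceSiteEvent("acceptor", anchor, _rank_forms(forms, support, tx_usage))
        for anchor, forms in by_donor.items()
        if len({acceptor_pos(f) for f in forms}) >= 2
    ]
    if not donor_events or not acceptor_events:
        return None

    # 5'->3' position for ordering events along the transcript
    def upstream_key(ev: SpliceSiteEvent) -> int:
        pos = min(min(f.start, f.end) for f in ev.alternative_forms) if plus else \
            -max(max(f.start, f.end) for f in ev.alternative_forms)
        return pos

    donor_ev = min(donor_events, key=upstream_key)  # most upstream
    acceptor_ev = max(acceptor_events, key=upstream_key)  # most downstream

    # window between the donor event's shared acceptor and the acceptor
    # event's shared donor; an exon must lie inside it in every spanning tx
    if plus:
        lo, hi = donor_ev.anchor_position, acceptor_ev.anchor_position
    else:
        lo, hi = acceptor_ev.anchor_position, donor_ev.anchor_position
    if lo >= hi:
        return None
    for tx in gene.transcripts:
        if tx.start <= lo and hi <= tx.end:
            if not any(lo <= s and e <= hi for s, e in tx.exons):
                return None

    first_donors = {
        (tx.exons[0][1] if plus else tx.exons[-1][0]) for tx in gene.transcripts
    }
    last_acceptors = {
        (tx.exons[-1][0] if plus else tx.exons[0][1]) for tx in gene.transcripts
    }
    donor_class = (
        "first"
        if any(donor_pos(f) in first_donors for f in donor_ev.alternative_forms)
        else "internal"
    )
    acceptor_class = (
        "last"
        if any(acceptor_pos(f) in last_acceptors for f in acceptor_ev.alternative_forms)
        else "internal"
    )
    return TerminalSitePair(gene.gene_id, donor_ev, acceptor_ev, donor_class, acceptor_class)


def mature_length(gene: GeneModel) -> int:
    """Length of the gene's longest transcript, introns excluded."""
    if not gene.transcripts:
        raise ValueError(f"gene {gene.gene_id} has no transcripts")
    return max(tx.exon_length_sum() for tx in gene.transcripts)


def write_skippable_bed(path, gene: GeneModel, events: Sequence[SkippableExon]) -> None:
    """BED6 export of classified skippable exons."""
    with open(path, "a") as fh:
        for ev in events:
            name = f"{gene.gene_id}|{ev.coding_status}"
            fh.write(
                f"{gene.chrom}\t{ev.exon[0]}\t{ev.exon[1]}\t{name}\t0\t{gene.strand}\n"
            )
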