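import numpy as np
import pysam
import pytest
from scipy import stats as sps

from splicecloud import annotation, readclouds, simulate
from splicecloud.annotation import IntronKey
from splicecloud.readclouds import (
    BarcodeStats,
    JunctionEvidence,
    MoleculeCall,
    barcode_qc,
    build_evidence,
    call_molecules,
    compute_mpm,
    compute_psi,
    detect_collisions,
    estimate_total_molecules,
    extract_junctions,
    group_evidence,
)

from conftest import build_gene

HEADER = pysam.AlignmentHeader.from_dict(
    {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 1_000_000}]}
)


def make_read(cigar, start=1000, barcode="BC1", name="r1", mapped=True):
    a = pysam.AlignedSegment(HEADER)
    a.query_name = name
    a.flag = 4 if not mapped else 0
    a.reference_id = 0 if mapped else -1
    a.reference_start = start if mapped else -1
    if mapped:
        a.cigarstring = cigar
        n_m = sum(
            length for op, length in a.cigartuples if op in (0, 1, 4, 7, 8)
        )
        a.query_sequence = "A" * n_m
        a.mapping_quality = 60
    if barcode is not None:
        a.set_tag("BX", barcode)
    return a


class TestExtractJunctions:
    def test_single_junction_coordinates(self):
        [j] = extract_junctions(make_read("20M100N20M", start=1000))
        assert (j.chrom, j.start, j.end) == ("chr1", 1020, 1120)

    def test_short_anchor_rejected(self):
        assert extract_junctions(make_read("5M100N20M")) == []
        assert extract_junctions(make_read("20M100N5M")) == []

    def test_boundary_anchor_accepted(self):
        [j] = extract_junctions(make_read("6M50N6M", start=100))
        assert (j.start, j.end) == (106, 156)

    def test_two_junctions(self):
        js = extract_junctions(make_read("20M100N30M200N20M", start=0))
        assert [(j.start, j.end) for j in js] == [(20, 120), (150, 350)]

    def test_deletion_counts_as_reference_anchor(self):
        # 4M2D ahead of the junction covers 6 reference bases
        [j] = extract_junctions(make_read("4M2D100N20M", start=0))
        assert (j.start, j.end) == (6, 106)

    def test_unmapped_and_unspliced(self):
        assert extract_junctions(make_read("", mapped=False)) == []
        assert extract_junctions(make_read("40M")) == []


class TestBuildEvidence:
    def gene(self):
        return build_gene(
            "G",
            {
                "inc": [(900, 1020), (1120, 1220), (1320, 1400)],
                "skip": [(900, 1020), (1320, 1400)],
            },
        )

    def test_same_barcode_aggregates(self):
        reads = [make_read("20M100N20M", name=f"r{i}") for i in range(3)]
        ev, stats, counters = build_evidence(reads, [self.gene()])
        assert ev == [
            JunctionEvidence("BC1", "G", IntronKey("chr1", 1020, 1120, "+"), 3)
        ]
        assert stats[0].total_reads == 3 and stats[0].spliced_gene_count == 1
        assert counters.unassigned_junctions == 0

    def test_junction_in_two_genes_dropped(self):
        g2 = self.gene()
        g2.gene_id = "G2"
        ev, _, counters = build_evidence([make_read("20M100N20M")], [self.gene(), g2])
        assert ev == []
        assert counters.multi_gene_junctions == 1

    def test_unannotated_junction_dropped_and_extra_junctions_rescue(self):
        novel = [make_read("20M50N20M", start=500)]
        ev, _, counters = build_evidence(novel, [self.gene()])
        assert ev == [] and counters.unassigned_junctions == 1
        extra = {IntronKey("chr1", 520, 570, "+"): "G"}
        ev2, _, c2 = build_evidence(novel, [self.gene()], extra_junctions=extra)
        assert len(ev2) == 1 and ev2[0].gene_id == "G"
        assert c2.unassigned_junctions == 0

    def test_barcodeless_read_counted(self):
        _, _, counters = build_evidence(
            [make_read("20M100N20M", barcode=None)], [self.gene()]
        )
        assert counters.barcodeless_reads == 1

    def test_barcode_from_read_name(self):
        read = make_read("20M100N20M", barcode=None, name="r1:BCX")
        ev, _, _ = build_evidence(
            [read], [self.gene()], name_separator=":"
        )
        assert ev[0].barcode == "BCX"


class TestBarcodeQC:
    def stats(self):
        return [BarcodeStats(f"B{i}", reads) for i, reads in
                enumerate([5, 50, 500, 5000])]

    def test_cutoff_zero_retains_all(self):
        calls = [MoleculeCall("G", f"B{i}", 3) for i in range(4)]
        retained, rate = barcode_qc(self.stats(), calls, 0)
        assert len(retained) == 4 and rate == 0.0

    def test_rate_is_fraction_of_molecule_calls(self):
        calls = [MoleculeCall("G", "B0", 1)] + [
            MoleculeCall("G", "B3", 1) for _ in range(9)
        ]
        _, rate = barcode_qc(self.stats(), calls, 10)
        assert rate == pytest.approx(0.10)

    def test_cutoff_above_everything(self):
        calls = [MoleculeCall("G", "B1", 1)]
        retained, rate = barcode_qc(self.stats(), calls, 10_000)
        assert retained == set() and rate == 1.0

    def test_empty_stats_error(self):
        with pytest.raises(ValueError):
            barcode_qc([], [], 0)


class TestCallMolecules:
    I = IntronKey("chr1", 100, 200, "+")

    def test_threshold_counts_summed_reads(self):
        ev = [JunctionEvidence("B", "G", self.I, 2),
              JunctionEvidence("B", "G", IntronKey("chr1", 300, 400, "+"), 1)]
        for k, expected in [(1, 1), (3, 1), (4, 0)]:
            assert len(call_molecules(ev, k)) == expected

    def test_monotone_in_k(self, small_dataset):
        _, evidence, _, _ = small_dataset
        counts = [len(call_molecules(evidence, k)) for k in range(1, 101)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_empty_evidence(self):
        assert call_molecules([], 1) == []

    def test_two_barcodes_one_passes(self):
        ev = [JunctionEvidence("B1", "G", self.I, 1),
              JunctionEvidence("B2", "G", self.I, 5)]
        calls = call_molecules(ev, 2)
        assert [c.barcode for c in calls] == ["B2"]


class TestCollisions:
    def exon(self):
        gene = build_gene(
            "G",
            {
                "inc": [(0, 100), (200, 300), (400, 500)],
                "skip": [(0, 100), (400, 500)],
            },
        )
        return annotation.classify_pure_skipping(gene)[0]

    def test_inclusion_plus_skip_is_collision(self):
        ev = self.exon()
        u, _ = ev.inclusion_introns
        cell = {"B1": {u: 2, ev.skipping_intron: 1}, "B2": {u: 3}}
        flags, frac = detect_collisions(cell, [ev])
        assert flags == {"B1": True, "B2": False}
        assert frac == pytest.approx(0.5)

    def test_only_inclusion_not_collision(self):
        ev = self.exon()
        u, d = ev.inclusion_introns
        flags, frac = detect_collisions({"B": {u: 1, d: 4}}, [ev])
        assert flags == {"B": False} and frac == 0.0

    def test_general_rule_flags_overlapping_introns(self):
        a = IntronKey("chr1", 100, 400, "+")
        b = IntronKey("chr1", 100, 200, "+")
        flags, _ = detect_collisions({"B": {a: 1, b: 1}}, [], general_rule=True)
        assert flags["B"]
        flags2, _ = detect_collisions({"B": {a: 1, b: 1}}, [], general_rule=False)
        assert not flags2["B"]

    def test_collision_fraction_increases_with_expression(self):
        """More highly expressed genes collide more often (positive rank
        correlation between expression and collision fraction)."""
        expr = [100, 300, 1000, 3000, 10_000]
        cfg = simulate.SimConfig(
            n_genes=5, molecules_per_gene=expr, odds_ratio=1.0,
            n_droplets=5000, reads_per_molecule=12.0,
            unspliced_fraction=0.0, seed=5,
        )
        evidence, genes, _ = simulate.simulate_dataset(cfg)
        grouped = group_evidence(evidence)
        fracs = []
        for gene in genes:
            events = annotation.classify_pure_skipping(gene)
            _, frac = detect_collisions(grouped[gene.gene_id], events)
            fracs.append(frac)
        rho = sps.spearmanr(expr, fracs).statistic
        assert rho > 0
        assert fracs[-1] > fracs[0]


class TestMpmAndTotals:
    def test_mpm_proportionality_and_conservation(self):
        calls = [MoleculeCall("A", f"B{i}", 1) for i in range(1)] + [
            MoleculeCall("C", f"B{i}", 1) for i in range(3)
        ]
        mpm = compute_mpm(calls)
        assert mpm["A"] == pytest.approx(250_000)
        assert mpm["C"] == pytest.approx(750_000)
        assert sum(mpm.values()) == pytest.approx(1e6)

    def test_single_gene_all_calls(self):
        mpm = compute_mpm([MoleculeCall("A", "B", 1)])
        assert mpm["A"] == pytest.approx(1e6)

    def test_zero_calls_error(self):
        with pytest.raises(ValueError):
            compute_mpm([])

    @pytest.mark.parametrize(
        "spliced,fraction,expected",
        [(11.6, 2 / 3, 17.4), (16.7, 2 / 3, 25.05), (7.0, 1.0, 7.0)],
    )
    def test_total_molecule_estimate(self, spliced, fraction, expected):
        assert estimate_total_molecules(spliced, fraction) == pytest.approx(expected)

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            estimate_total_molecules(1.0, 0.0)


class TestPsi:
    def test_basic_fraction(self):
        exon = TestCollisions().exon()
        u, d = exon.inclusion_introns
        cells = {f"I{i}": {u: 1} for i in range(8)}
        cells.update({f"E{i}": {exon.skipping_intron: 1} for i in range(2)})
        res = compute_psi(cells, exon)
        assert res.psi == pytest.approx(0.8)
        assert (res.inclusion, res.exclusion) == (8, 2)

    def test_all_exclusion(self):
        exon = TestCollisions().exon()
        cells = {f"E{i}": {exon.skipping_intron: 1} for i in range(5)}
        assert compute_psi(cells, exon).psi == 0.0

    def test_uninformative_returns_none(self):
        exon = TestCollisions().exon()
        other = IntronKey("chr1", 700, 800, "+")
        assert compute_psi({"B": {other: 1}}, exon) is None

    def test_recovers_generating_marginal(self, small_dataset):
        cfg, evidence, genes, truth = small_dataset
        grouped = group_evidence(evidence)
        for gene in genes[:2]:
            events = annotation.classify_pure_skipping(gene)
            flags, _ = detect_collisions(grouped[gene.gene_id], events)
            res = compute_psi(grouped[gene.gene_id], events[0], flags)
            n = res.inclusion + res.exclusion
            se = np.sqrt(cfg.psi1 * (1 - cfg.psi1) / n)
            assert abs(res.psi - cfg.psi1) < 4 * se


class TestEvidenceTsv:
    def test_round_trip(self, tmp_path, small_dataset):
        _, evidence, _, _ = small_dataset
        path = tmp_path / "ev.tsv"
        readclouds.write_evidence_tsv(path, evidence)
        back = readclouds.read_evidence_tsv(path)
        assert back == evidence
        header = path.read_text().splitlines()[0]
        assert header.split("\t") == [
            "chrom", "intron_start", "intron_end", "strand",
            "gene_id", "barcode", "read_count",
        ]

    def test_missing_column_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chrom\tbarcode\nchr1\tB\n")
        with pytest.raises(ValueError, match="missing columns"):
            readclouds.read_evidence_tsv(path)
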