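# Methods

## Model and procedure

`splicecloud` analyses droplet-barcoded spliced short reads under one
central assumption: reads sharing a droplet barcode and mapping to one
gene originate from a single RNA molecule. Under that assumption a read
cloud is a sparse observation of one isoform, and the splicing status of
two distant alternative exons can be read off the same molecule.

The pipeline is:

1. **Junction extraction.** Each gapped alignment contributes one
   candidate junction per skipped reference segment (CIGAR `N`), kept
   only when the flanking aligned blocks each cover at least
   `min_anchor` reference bases (default 6 bp). Deletions (`D`) count as
   aligned reference bases when measuring anchors; insertions and
   soft-clips do not. Junctions are assigned to a gene only on an exact
   two-sided match with an annotated intron (or a user-supplied extra
   junction attributable to one gene); junctions matching zero or
   several genes are dropped and tallied. This is deliberately
   stringent: molecule identification tolerates no ambiguity.
2. **Molecule calling.** A molecule of gene *g* is called for barcode
   *b* when at least *k* spliced reads of *b* span introns of *g*
   (default *k* = 1; support is summed over introns). The total-molecule
   estimate divides the spliced-molecule count by the fraction of
   molecules assumed spliced (default 2/3).
3. **Collision flagging.** Two non-identical molecules of one gene in
   one droplet produce conflicting evidence. The default detector flags
   a barcode when it carries evidence for an inclusion intron *and* the
   skipping intron of the same skippable exon; an optional general rule
   also flags any two overlapping non-identical introns. Flagged
   barcodes are excluded from Ψ and coordination counting.
4. **Event classification.** A *pure exon-skipping event* is an internal
   exon with a unique flanking intron pair (u, d), an annotated direct
   skip intron u.start→d.end, identical boundaries in every transcript
   overlapping it, no transcript boundary strictly inside the skipped
   span, and no retention of u or d. The flank-uniqueness requirement
   operationalises "no interfering alternative splice sites": it also
   excludes immediately adjacent alternative exons, whose neighbouring
   intron necessarily has two alternative ends. A *constitutive exon* is
   one present with identical boundaries in every transcript whose span
   covers it; exon pairs must have at least one constitutive exon
   strictly between them.
5. **Coordination testing.** Informative molecules (status determined
   for both events, no collision) fill a 2×2 table; dependence is tested
   with a two-sided Fisher's exact test and quantified by the
   log₂-odds-ratio with a 0.5 pseudocount per cell. All internal exon
   pairs with ≥ `min_informative` (default 25) molecules form one
   Benjamini–Yekutieli family (BY is robust to the dependence among
   pairs sharing molecules); the per-gene terminal-site tests form a
   separate Benjamini–Hochberg family, as they constitute one test per
   gene.
6. **Terminal sites.** Per gene, alternative donors sharing one acceptor
   and alternative acceptors sharing one donor are grouped into events;
   the most upstream donor event is paired with the most downstream
   acceptor event, kept only when the donor event lies upstream and an
   intermediate exon is guaranteed between them in every spanning
   transcript (the two sites are then defined by distinct splicing
   reactions). Events with more than two forms are dichotomised to the
   two best-supported forms; other forms are uninformative.
7. **Extent and down-sampling.** The coordinated fraction of genes is
   estimated at informative-count cutoffs {25, 50, 100, 200, 500, 1000}
   using a fixed criterion — Fisher P ≤ 5×10⁻⁷ (a Bonferroni bar for an
   upper bound of 100,000 genome-wide tests at 0.05) and |LOR| ≥ 0.5 —
   with Wilson 95% confidence intervals (a normal-approximation CI is
   available behind a flag). The down-sampling control replaces every
   low-count table by a uniformly chosen high-count donor table (n_h ≥
   n_l) down-sampled to n_l units via a multivariate hypergeometric
   draw, repeated 50 times; per-gene analyses first keep only the
   highest-n_t table of each gene (ties go to the upstream pair) to
   avoid genes with many tables dominating.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `min_anchor` | 6 bp | aligned reference bases required on each side of a junction |
| `k` (molecule threshold) | 1 read | spliced reads per (gene, barcode) to call a molecule |
| `min_informative` | 25 molecules | informative molecules required to test a pair |
| `fdr` | 0.05 | FDR level for BY/BH |
| extent criterion | P ≤ 5×10⁻⁷, \|LOR\| ≥ 0.5 | fixed genome-wide bar for the cutoff sweep |
| `spliced_fraction` | 2/3 | assumed fraction of molecules that are spliced |
| `n_droplets` | 200,000 | droplets in the simulated run |
| `unspliced_fraction` | 1/3 | simulated molecules carrying no junctions |
| `reads_per_molecule` | Poisson(20) | linear-amplification read yield per molecule |

## What the simulator emulates — and what it does not

The generator reproduces the statistical structure the method relies on:
per-pair joint inclusion given marginals ψ₁, ψ₂ and an odds ratio (the
unique feasible root of p(1−ψ₁−ψ₂+p) = OR·(ψ₁−p)(ψ₂−p)); uniform
molecule-to-droplet assignment, so per-gene occupancy is asymptotically
Poisson(molecules/droplets) and collisions arise naturally from
multi-occupancy rather than being injected; linear random-primed
amplification as independent uniform read starts on the mature molecule,
so junction observation is anchor-limited; an unspliced molecule
fraction; and read-level barcode misassignment.

It does **not** model base-level sequencing error, mismapping to
paralogs/pseudogenes, fragment-size distributions, coverage bias along
the molecule, or annotation incompleteness. Passing tests therefore
demonstrate correctness of the inference given clean alignments and a
faithful annotation — not robustness to mapping artefacts, which in real
data are handled upstream by stringent alignment and are visible here
only through the (tallied) unassigned-junction counters.

Simulated problem sizes in the test-suite are desk-scale by design —
hundreds to thousands of molecules per gene, thousands to hundreds of
thousands of droplets, 100–1000 tables per calibration — chosen so each
statistical check has the power it needs (e.g. 3 Monte-Carlo standard
errors for the collision closed form, ±0.2 for mean LOR recovery at
n_t = 1000).

## Numerical choices

* Coordinates are 0-based half-open throughout; GTF is converted on
  read. Strand is kept genomic internally; 5′→3′ order is derived from
  strand where it matters (terminal events).
* The two-sided Fisher p sums hypergeometric probabilities of all tables
  with the observed margins whose probability is ≤ the observed one
  within a relative tie tolerance of 10⁻⁷ (floating-point-stable version
  of the standard definition; verified against exact rational
  enumeration in the tests).
* The 0.5 pseudocount (Haldane–Anscombe) keeps the LOR finite for any
  table, at the price of shrinking extreme estimates toward 0.
* FDR adjustment, Wilson intervals and multivariate-hypergeometric
  sampling are delegated to statsmodels and numpy; outputs are sorted
  deterministically (adjusted p, then gene id) and every stochastic step
  takes an explicit seed, so identical configuration and seed give
  byte-identical outputs.
* Degenerate inputs: an all-zero table has LOR 0 and is never tested
  (n_t < 25); Ψ with no informative barcode is reported as absent, not
  0; a cutoff retaining no genes is omitted from the sweep with a
  warning; a low-count table with no eligible high-count donor aborts
  the down-sampling with an error naming the offending size.

## Design choices where the design was open

* **Informative unit.** Tables count molecules (barcode-level calls),
  not raw reads; read counting would overweight deeply amplified
  molecules. A config switch (`informative_unit`) is the natural
  extension point but molecules are the only unit used here.
* **Misidentification-rate denominator.** The barcode-QC
  misidentification rate is the fraction of *molecule calls* in
  below-cutoff barcodes, since molecule calls are what downstream
  analysis consumes.
* **Coding status.** An exon is `entirely_coding` only if every base is
  CDS in every transcript carrying it; genes without CDS records (e.g.
  lincRNA) are `contains_noncoding` throughout.
* **Down-sampling list nesting.** With cutoffs 25 and 500 the high list
  is a subset of the low list (H ⊆ L); donors are drawn uniformly among
  eligible tables, with eligibility recomputed per target size.
* **Coding-vs-noncoding comparison.** Greedy nearest-neighbour matching
  without replacement on n_t, smaller group first, seeded tie-breaking —
  deterministic given the seed and preserving group sizes.

## Limitations

* Gene assignment requires exact intron matches, so novel junctions are
  invisible unless supplied as extra junctions; genes sharing introns
  are mutually blind spots (such junctions are dropped as ambiguous).
* Collision detection is conservative: co-encapsulated molecules with
  identical splicing patterns, or with no overlapping informative
  junctions, are not detectable as collisions, so the evidence-level
  collision fraction underestimates true multi-occupancy (the simulator
  exposes the occupancy-level truth for calibration).
* The terminal-site test dichotomises multi-form events to the top two
  forms and gives up the information in rarer forms.
* Read clouds are never assembled into full molecule sequences; the
  method reports junction-level patterns only.
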