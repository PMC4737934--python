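# Methods

This note documents the models, parameter choices and numerical
conventions behind the package, in the order data flows through it.

## Emulsion design arithmetic

Droplets are treated as monodisperse spheres at the mean diameter for
design purposes: volume *(π/6)d³*, droplet count = aqueous volume /
droplet volume, solute loading = concentration × N_A × droplet volume,
and occupancy from the Poisson law at λ = occupants/droplets. Real
emulsions are polydisperse (roughly 5–30 μm with a mode near 10 μm); the
monodisperse approximation is used because the standard recipe numbers
(~5 × 10⁸ droplets from 255 μl, ~3 barcode molecules per droplet at
10 pM) are self-consistent under it. Two published-style figures are
*not* consistent with it and are deliberately not hard-coded anywhere:
a "one nanoliter" droplet volume (a 10 μm sphere is 0.52 pL — three
orders of magnitude smaller, and 255 μl of 1 nL droplets could not give
5 × 10⁸ of them) and a "less than one droplet in 100" occupancy
(14 × 10⁶ cells in 4.9 × 10⁸ droplets gives 2.8%). The calculators take
all quantities as inputs; nothing is asserted about either claim.

Unit convention: volumes are carried in litres internally and converted
at the API boundary (μm³, pL, μl). Display rounding follows the field's
reporting style — one significant figure for droplet counts, nearest
integer for molecules per droplet — but functions always return the
unrounded value.

## The synthetic-data generator

The simulator emulates the structure of a two-assay spike-in experiment
on a MiSeq-style 250 bp paired-end run. Per droplet:

* **Diameter**: lognormal with median 10 μm and log-sd 0.30, truncated
  to [5, 30] μm. Barcode loading scales with each droplet's own volume.
* **Cells**: Poisson(`cell_lambda`, default 0.0287 = 14 × 10⁶ / 4.87 × 10⁸);
  each cell is a taxon drawn by relative abundance and kept with its
  `permeabilization_prob` (default 0.9) — unpermeabilized cells
  contribute no template, which is how lysis-dependent recovery
  differences (with/without extra lysis reagents) are modelled.
* **Barcode molecules**: Poisson with mean from the barcode
  concentration (default 10 pM, the concentration stated for the
  experiment; a conflicting 100 fM figure appears in the methods-style
  text and is not used) and the droplet volume.
* **Control beads**: disjoint random droplet subsets (default 1% + 1%)
  carry a negative bead (mock-16S only) or a positive bead (mock-16S +
  mock-target). A bead displaces environmental cells in its droplet.

**Fusion chemistry.** Full fusion amplicons
[F1|target-or-barcode|bridge|16S] form for each (target-side template,
16S template) pair in a droplet with probability `fusion_efficiency`
(default 0.9). One-sided (partial) amplicons are emitted at
`partial_fusion_rate` (default 0.1) relative weight, but only in
droplets containing a 16S template: an isolated barcode or target
molecule never reaches exponential phase, and blocking primers remove
most unfused pieces — emitting partials only from engaged droplets keeps
the simulated library composition realistic instead of letting the vast
excess of barcode-only droplets dominate the read pool.

**Chimeras** are single-crossover recombinants of two equal-length full
fusions from the same droplet. The breakpoint is uniform over the
positions at which the recombinant differs from both parents (outside
that range the product *is* one of the parents, i.e. no artifact
exists). A chimera's emission weight is `chimera_rate` (default 0.02)
times the mean of its parents' weights, reflecting that recombination
consumes a small fraction of parent product. Chimeras never span
droplets; cross-droplet contamination is a separate, default-off
`leakage_rate` knob that re-pairs a fusion's 16S side with a template
drawn from the whole emulsion.

**Reads.** Per-droplet copy numbers are multiplied by a lognormal(0,
`amp_log_sd`=1) factor, so read counts deliberately do not track
template abundances (the data are a qualitative species list, not
quantitative ratios). Read pairs per amplicon are
Poisson(`mean_reads_per_droplet` × weight); the default depth of 15 is a
desk-scale choice that keeps a 10⁴-droplet experiment around 60 k reads.
Substitution errors are applied per base (default 10⁻³); indels are not
simulated by default (`indel_error_rate` exists but is 0), matching the
ungapped structure parser. Quality strings are a high-Q plateau (~Q38)
with 3′ decay, and a `degraded_frac` (default 5%) of read pairs gets
flat ~Q11 strings to exercise the Phred filter. R1 carries the sample
barcode as a prefix. All randomness flows from one seeded generator:
identical configs give byte-identical FASTQ and truth tables.

**What the simulator does not model** — and hence what passing tests do
not demonstrate about real data: PCR thermodynamics and primer-dimer
chemistry, polymerase error spectra and homopolymer artifacts, indels,
quality-correlated errors, bead physics, emulsion coalescence, and
between-run batch effects. Specificity results on simulated data show
the *pipeline* introduces no false links; they cannot show a wet-lab
emulsion never leaks.

## Read processing

Stage order: demultiplex → merge pairs → quality filter → de novo
chimera removal → structure validation → V4 trim → (barcode assay)
collapse.

* **Demultiplex**: exact R1-prefix match by default (`max_mm=0`);
  ambiguous or unmatched reads go to an `unassigned` bin.
* **Merge**: the longest ungapped overlap (≥ 20 bp) with mismatch
  fraction ≤ 0.1, scanned longest-first; random sequence disagrees at
  ~75% of positions, so spurious overlaps fail the threshold long before
  a true overlap does. Disagreements resolve to the higher-quality base
  (ties to forward).
* **Quality**: "Phred > Q20" is read as *mean* read quality strictly
  greater than 20, plus zero ambiguous bases; the least surprising
  reading of a bare threshold, and configurable.
* **Chimera flagging**: a query is flagged when two distinct same-length
  parents, each ≥ 2× its abundance, admit a crossover with composite
  identity ≥ 0.99 that beats the best single-parent identity by ≥ 2
  percentage points (common de novo practice). Uniques are visited in
  decreasing abundance and flagged sequences are excluded from later
  parent sets, so a chimera cannot shield its own error variants.
  Candidate parents come from an exact shared-chunk index (8 chunks,
  posting lists capped at the most abundant entries) plus the
  lexicographic prefix/suffix neighbourhoods of the query, which
  guarantee the best exact-prefix and exact-suffix parents are
  considered; the top 64 candidates by shared chunks then abundance are
  scored exactly. Note an inherent ambiguity: in a droplet with two
  distinct cells, genuine cross-fusions (target of one cell, 16S of the
  other) are sequence-identical to chimeras and will be flagged; at the
  method's operating λ ≪ 1 such droplets are rare. A crossover landing
  within ~2% of one parent is mathematically unflaggable under the
  2-point divergence rule (composite identity cannot exceed 1), so the
  detector benchmark measures recall over *detectably divergent*
  chimeras (≥ 2% from every co-droplet fusion) and false positives over
  reads from single-fusion droplets.
* **Structure validation**: ungapped sliding-window matching with
  IUPAC-aware mismatch counting, ≤ `max_mm` (default 1) substitutions
  per element; the bridge hit must be unique. Reject reasons are
  per-element (`f1`, `bridge`, `bridge_ambiguous`, `missing_ssu`, `r2`,
  `barcode_len`, `anchor`, `short_ssu`). In the barcode assay the span
  between F1 and bridge must be exactly 20 nt.
* **Trim**: 121 bp immediately after the conserved V4 anchor (best,
  then leftmost, hit at ≤ 1 mismatch). The anchor sequence is a config
  item (the packaged default is the 515F-region motif the simulator
  uses) because the exact conserved site is construct-specific.
* **Collapse**: exact (barcode, 16S segment) matching only — "identical"
  pairs — with the highest-mean-quality read as representative (ties by
  read id, making the operation order-independent and idempotent).
  Sequencing errors within the 20-nt barcode are not merged; an
  edit-distance-tolerant mode was considered and rejected as a default
  because it risks merging truly distinct droplets (20-nt random barcodes sit
  at expected pairwise distance ~15).

Coordinates are 0-based half-open internally; report files state their
convention in headers.

## Identity, clustering and linkage

**Identity** is computed from a *glocal* alignment: the shorter sequence
aligns end to end, terminal gaps are free only in the longer sequence
and excluded from the column count, internal gaps count as mismatch
columns (match +1, mismatch −1, gap −2, linear). This keeps a 121 bp
segment at identity 1.0 inside its full-length source gene, while
avoiding the overlap-alignment pathology in which two unrelated
sequences score ~0.95 over a short accidental corner overlap — fatal for
novelty calls, which is why fully-free end gaps were rejected. The DP is
row-vectorized with a running-maximum trick for the linear gap penalty;
traceback prefers diagonal, then gap-in-longer, then gap-in-shorter, and
the end column maximizes (score, coverage), making results deterministic
and symmetric (equal-length pairs are canonicalized lexicographically).

**Clustering** is the exact abundance-sorted greedy centroid rule:
visit sequences in decreasing abundance (ties by id); join the first
existing centroid, in founding order, with identity ≥ threshold;
otherwise found a new cluster. No word-count heuristics — the rule is
the specification, and a literal reference implementation is the test
oracle. Cluster counts at 0.80/0.95/0.97 are monotone in practice but
greedy clustering guarantees no strict nesting, so only count
monotonicity is asserted.

**Nearest reference / novelty**: argmax of glocal identity over a
user-supplied FASTA (ties to the smaller reference id); an OTU is novel
below 0.95. This replaces database taxonomy assignment while preserving
the novelty-call logic; rarefaction is seeded subsampling without
replacement.

**Linkage**: reads contribute one fusion count to their (target cluster
at 0.95, 16S OTU at 0.97) cell; representatives and novelty annotations
ride along.

## In-silico PCR

Percent-cutoff semantics with the budget rounded *down*:
floor(`max_mismatch_frac` × primer length) substitutions (a 19-nt primer
at 20% tolerates 3). Rounding is stated explicitly because it is the
main dialect risk between implementations. Template ambiguity codes
match a primer code when the two expansions intersect; template N always
counts as a mismatch; indels are not considered. Both strands are
scanned; products require non-overlapping primer footprints and a
length inside [40, 5000] bp by default (suppressing degenerate
pairings). Nested (two-step) amplification re-amplifies only the
first-round product sequences.

## Spike-in specificity and recovery

Control classification assigns a read to the control whose trimmed
mock-16S segment it matches at ≥ 0.97 identity (the finest OTU threshold
in use), else environmental; the control set must be mutually distinct
below the cutoff. The specificity report tabulates per-assay class
counts; its headline number is negative-control reads among targeted
fusions, which is zero for any leakage-free run. Recovery comparison is
presence/absence per taxon group across bulk and fusion treatments, with
fusion presence requiring ≥ 2 reads to damp singleton noise.

## Problem sizes and test design

The packaged experiment sizes are desk-scale choices: 10⁴ droplets for
the two-assay spike-in (≈ 60 k reads), 3 × 10³ droplets for the
error-free link-fidelity run, 2.5 × 10³ for the skew/collapse census,
10⁵ droplets for occupancy law checks, and ≤ 5 kb templates for the
in-silico PCR oracles. Oracle tests pin the exact greedy clustering
partition, the glocal identity values, and the primer-scan hit sets
against independent brute-force implementations; distributional claims
(occupancy, error rates, degraded fractions) are asserted within three
standard errors; structural claims (zero negative controls in targeted
fusions, zero false links, the 121 bp contract, collapse census) are
asserted exactly.

## Known limitations

* The chimera detector's candidate prescreen is a heuristic; pathological
  inputs (e.g. thousands of equally abundant near-duplicates) could hide
  a true parent, trading recall for tractability.
* Structure parsing is substitution-only; reads with indels in construct
  elements are rejected rather than rescued (consistent with the
  simulator, conservative on real data).
* Glocal identity with a linear gap penalty is not substitution-model
  aware; it is a clustering metric, not an evolutionary distance.
* The simulator's per-phylum lysis model is a single Bernoulli
  probability per taxon; real lysis efficiency varies continuously with
  wall structure and treatment.
* Real-data read counts from the deposited experiment depend on the
  original sequencing depth and reference databases and are outside what
  simulation can or should reproduce.
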