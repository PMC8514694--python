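# Methods

This note documents the models, defaults and numerical choices behind the
package, and what the synthetic benchmarks do and do not demonstrate.

## Synthetic data model

`synthetic_data` plants satellite families into random genomic backgrounds
and simulates uniform-coverage short reads. The model:

- **Monomers.** Each family has a consensus of length RUL (repeat unit
  length) drawn with a target A+T fraction. Copies are mutated
  independently under a two-rate substitution scheme: per-site transition
  probability `p_ts` and transversion probability `p_tv` are solved
  numerically (Brent's method) so that the expected Kimura 2-parameter
  distance of a copy to its consensus equals the requested
  `divergence_target`, at the requested transition/transversion ratio
  (default 2.0, a typical nuclear-DNA value). Substitution-only by default;
  an optional per-site indel rate (default 0) exists because monomers are
  treated as fixed-length units throughout.
- **Arrays.** Each locus is a perfect head-to-tail tandem of independently
  mutated copies — no higher-order repeat structure. Array orientation is
  chosen uniformly per locus. Copies are split as evenly as possible across
  the sex's locus count. Arrays are spliced into the background at uniform
  positions, so truth coordinates and per-family genome proportions are
  exact by construction.
- **Reads.** Fragments are uniform over the genome, strands uniform,
  per-base substitution errors at `error_rate` (default 0.002 in the
  scenario, matching trimmed-Illumina quality), constant Phred 37
  qualities. Paired mode draws insert sizes from a clipped normal. A guard
  refuses libraries above 10^9 bp unless overridden.
- **Seeding.** Every stochastic routine takes one integer seed and derives
  named child streams via `numpy.random.SeedSequence` spawn keys (purpose
  strings hashed with CRC32), so any fixture is reproducible from a single
  integer and sub-streams are independent.

### The built-in two-sex scenario

`two_sex_scenario` emulates a fish satellitome with a heteromorphic,
satellite-enriched W chromosome in the female: 30 families, RUL 11–245 bp
(mean 43), A+T 0.31–0.80 (mean 0.60), female genome proportions
0.001–0.484% summing to ~5.1% (male ~4.5%, F/M ≈ 1.14, i.e. ~14% female
enrichment), three families with ~3x female amplification, one
female-exclusive family, and divergence assigned inversely to abundance
(abundant families 3–12% K2P, rare families 15–30%) — the pattern real
satellitomes show, where the most diverged families are also the rarest.
Both sexes share one background (the autosomal complement) and differ only
in planted satellite content.

Deliberate desk-scale compromises: 3 Mb backgrounds and 200k x 100 bp reads
per sex (~2 x 10^7 bp of sequence, ~6x coverage) rather than Gb-scale
libraries; a compressed abundance ladder (no families between 0.03% and
0.15%, where estimates would sit at ~2 sigma of sampling noise at this
coverage); and a 0.001% floor on proportions, because a 0.0001% family is
under 4 bp at 3 Mb. Proportions down to 0.0001% are exercised separately in
a planting-bookkeeping test on an 11 Mb genome.

**What passing tests show — and don't.** Recovery results on this generator
demonstrate correctness of the pipeline's bookkeeping, alignment, and
statistics under the stated model. Real libraries additionally contain
higher-order repeat structure, indels, transposable elements and multigene
families, PCR/optical duplicates, quality decay and adapter remnants, none
of which are modelled; absolute recall/precision on real data will differ.

## Mining

Per round: sample `base_sample * 2^(round-1)` reads without replacement,
cluster, detect tandems, build consensuses, then remove matching reads from
the library and repeat. Stops when a round contributes nothing new (every
candidate matches a prior consensus at >= 80% identity) or after
`max_rounds` (default 8).

- **Clustering.** Edge between reads sharing >= 3 canonical 13-mers;
  connected components of size >= 2 are clusters. In high-coverage samples,
  ordinary read overlap on unique sequence also creates edges, so the round
  loop only lets k-mers whose sample multiplicity exceeds 3x the median
  multiplicity generate edges — a repetitiveness filter that leaves
  satellite k-mers (multiplicity ~ copy number x coverage) untouched.
  Satellite clusters are near-cliques; overlap chains are sparse. A cluster
  is a satDNA candidate when its graph density is >= 0.2 *and* a tandem
  period is found (density separates satellite clusters from dispersed
  repeats; periodicity is the defining satDNA property). Clusters below 5
  reads are deferred to later, larger samples.
- **Tandem period.** Smallest shift p in [5, len/2] at which the sequence
  matches itself with >= 80% identity over the overlap. When polling
  *cluster reads* for their period the bar is 70%: neighbouring array
  copies at consensus divergence d agree at only ~(1-d)^2 + d^2/3 of sites,
  so 80% would cap minable divergence near 10% while the design target is
  15%; random sequence sits near 25% shift-identity, far below either bar.
  A period must win a plurality of polled reads (>= max(3, polled/4)) so a
  single self-similar read cannot impose a bogus period.
- **Consensus.** Reads are folded at the period; each fold is phased onto a
  reference fold by exhaustive rotation/strand search, votes are summed per
  column and the majority base taken. Monomers longer than half the read
  cannot fold within reads; those clusters are greedily assembled
  (exact-seed overlap extension — legitimate because overlapping reads are
  genomically identical up to sequencing error) and the contig is folded
  instead. Consensuses are reported in the canonical monomer frame: the
  lexicographically minimal rotation over both strands, so the same family
  mined in different phases or strands compares equal.
- **Filtering.** Reads whose best local alignment to any new consensus
  (tiled, see below) reaches 70% identity over max(25, min(RUL,
  read_len/2)) columns are removed — permissive repeat-masking practice.

## Classification

- **Identity.** Best global identity over every rotation frame of either
  strand, computed by aligning the shorter monomer into a doubled copy of
  the longer (edit-distance alignment; identity = matches / alignment
  columns). Because unrelated random monomers still reach 55–65% under such
  an alignment, homology additionally requires an exact shared canonical
  10-mer (rotation/strand-insensitive) — the analogue of an
  alignment-seeded search reporting no hit for unrelated pairs. Pairs
  without an anchor score 0.
- **Tiers.** Single-linkage components at 80% identity are families; each
  member record is a variant (95%+ subgroups are also counted, as
  near-duplicate "variant groups"); components at 60% joining two or more
  families define superfamilies (SF1, SF2, ...). Defaults are consistent
  with the one anchoring datum available: two families sharing a
  superfamily at 76.7% identity. Single-linkage is used because any
  detected homology groups; thresholds are configurable.
- **Representative and naming.** The family representative is the medoid
  variant (maximal summed identity to the other members; ties by sequence)
  — abundance-based choice would be circular, since quantification itself
  maps against the representative. Families are named
  `<prefix>Sat<NN>-<RUL>` ranked by decreasing female abundance; ties break
  by smaller RUL, then representative sequence. The default prefix is
  "Mel"; derive yours from genus + species initials.

## Quantification

- **Mapping.** Each consensus is tiled head-to-tail max(3,
  ceil(read_len/RUL)+2) times so a read starting anywhere, including at
  monomer junctions, aligns in one piece. Candidate (read, family) pairs
  must share a canonical 11-mer with the tiled target (tolerant to ~25%
  divergence at 100 bp reads); candidates are aligned locally (match +1,
  mismatch -1, gap open -3, extend -1), strand chosen by a cheap
  semi-global edit distance. A hit needs identity >= 70%, >= max(25,
  min(RUL, read_len/2)) aligned columns, and alignment score (matches -
  mismatches - gap columns) >= 25. The score floor is the package's noise
  cutoff in the spirit of repeat-masking minimum scores: with +/-1 scoring,
  the Karlin–Altschul expectation of chance local alignments between a
  multi-Mb genome and a tiled monomer crosses 1 near score 20, and score 25
  drives it well below 1 — without it, a sex-exclusive family can acquire a
  phantom abundance in the other sex from a single chance-similar
  background locus. Each read counts for its single best family (ties:
  longer alignment, then family id), preventing double-counting across
  homologous families.
- **Divergence.** P and Q are computed over non-gap columns only (gap
  columns are excluded from both the aligned-nucleotide numerator and the
  P/Q denominators, keeping K2P well-defined). Hits outside the K2P domain
  (1-2P-Q <= 0 or 1-2Q <= 0) are flagged saturated: they still count
  toward abundance but are excluded from landscapes and mean divergence,
  with a logged count.
- **Abundance and landscapes.** Abundance = aligned nucleotides / library
  size in bp (paired reads contribute both mates' bases). Landscapes add
  each hit's aligned nucleotides to bin floor(K2P x 100); the x-axis is
  capped at 50% with higher divergences pooled into the last bin (standard
  landscape convention). Bin sums equal the (unsaturated) abundance
  exactly because both derive from the same integer nucleotide counts.
- **Sex bias.** R = A_female/A_male per family; R > 1 female-biased, R < 1
  male-biased, abundance in exactly one sex = exclusive to it (R carries an
  infinity sentinel for female-exclusive). Library totals sum family
  abundances; enrichment = 100 x (F_total/M_total - 1), reported at full
  precision and rounded to integer percent.

## Profiles

Pileups over the consensus monomer frame (tiled-target positions folded
modulo RUL); read deletions count into a fifth gap state so coordinates
stay frame-stable; insertions relative to the consensus are off-frame and
dropped. A position is a sex signature when both libraries have >= 20 reads
of coverage there (default) and either the major base differs or the
variant fractions differ by >= 0.30. A sex whose coverage never reaches the
floor is reported as having an incomplete profile rather than producing
flags. The pipeline profiles the 22 most female-biased and 22 most
male-biased families by default (configurable).

## Haplotype networks

Full monomers are cut from hits at consensus-period boundaries (only
complete, indel-free periods). Monomers are anchored to the consensus
frame; columns gapped in the majority of rows are dropped. Identical rows
collapse into haplotypes with per-source counts (order: total count
descending, then sequence). The minimum spanning tree is built by Kruskal
over all pairwise difference counts, where gap-vs-base counts as one
difference and gap-vs-gap as none; equal-weight edges are taken in
ascending (weight, node_a, node_b) order, so the tree is reproducible. A
seeded subsample caps monomers at 500 per source to keep all-pairs
distances at desk scale.

## Pipeline, formats, determinism

Stages chain as simulate/load -> mine (female library first, later
libraries deduplicated against earlier consensuses) -> classify -> quantify
-> profile -> network -> report. Reports are TSV with `.` for missing
values (absence distinguishable from true zero), 0-based half-open
coordinates for intervals (BED convention) and 1-based positions in
profiles (pileup convention). Gzip output is written with a zeroed mtime
and the manifest omits the output path, so identical config + seed yield a
byte-identical artifact set; the manifest lists every file with its SHA-256.

## Problem sizes used by the test suite and acceptance script

Chosen as desk-scale study conditions: the mining benchmark plants ten
families (0.05–0.5% of a 1 Mb genome, divergence 0–15%, RUL 21–46) and
mines a 100k x 100 bp library from a 10k-read base sample; the
quantification benchmark is the full built-in scenario (3 Mb backgrounds,
200k reads per sex); the determinism check runs the entire pipeline twice
on a 120 kb / 8k-read configuration; MST optimality is verified on 100
random instances (exhaustive spanning-tree enumeration up to 6 nodes, an
independent library implementation above that).

## Known limitations

- Substitution-only defaults: indel-rich satellites would need the indel
  rate exposed and a gap-aware consensus step.
- The greedy assembler for long monomers assumes locally unique overlaps;
  interleaved families with shared boxes could chimerize at very high
  divergence.
- Abundance is alignment-based and therefore conservative for families
  diverged far beyond the 70% identity floor, as in any homology-search
  quantification.
- Superfamily detection below ~60% identity is fundamentally
  noise-limited for short monomers; the anchor-word gate trades a little
  sensitivity for specificity there.
- The read simulator does not model duplicates, quality decay or adapter
  contamination, and satellite arrays are strictly homogeneous tandems.
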