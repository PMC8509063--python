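# Methods

`memtol` re-implements, as a tested library, the computational pipeline of
a saturation-mutagenesis study of a single-pass (bitopic) transmembrane
toxin: pooled phenotype-sequencing statistics, family-alignment analyses,
and structural packing/geometry analyses. This note records the models,
the tunable parameters, and the design choices made where a definition was
genuinely open.

## Screen model and enrichment statistic

The screen expresses a toxin under an inducible promoter: cells carrying a
functional toxin die (*wild-type phenotype*, no colonies), cells carrying
an inactivated variant grow (*mutant phenotype*). Colonies from each
phenotype are pooled and the mutagenized ORF amplicon is deep-sequenced,
so each variant i acquires two counts, WT_i and MUT_i. The enrichment
statistic is

    F(mut_i) = 100 * (WT_i - MUT_i) / (WT_i + MUT_i)   (percent, in [-100, 100])

Variants with |F| at or below the experimental-error band are *incorrect
sequence-phenotype assignments* (ISPAs) and are excluded from
classification. F above the band means the variant is enriched in the
wild-type pool — the toxin still kills, the mutation is **tolerated**;
F below the negative band means **deleterious** (loss of function). Note
that the source text's prose description of the sign is the opposite of
the printed formula; the formula is implemented literally, which is the
reading consistent with the tolerated/deleterious semantics above.

Parameters:

* `error_rate` — the ISPA band, percent. Default **4.0**, the screen's
  stated experimental error rate. The boundary is inclusive (|F| = band
  is an ISPA).
* `min_total` — minimum WT+MUT count for a variant to be scored.
  Default 1. The recovery analyses in the test-suite use **10** at a
  simulated depth of 500 reads/variant: planted variants arrive at
  hundreds of reads while single sequencing-error genotypes arrive at
  ~1–3, so any threshold well inside that two-orders-of-magnitude gap
  separates signal from noise without touching real variants.

### Two-tier counting

Counts are kept at two levels. *Genotype-level* counts treat each
distinct substitution set as a variant; *substitution-level* counts
aggregate every genotype containing a substitution. Deleterious and
tolerance calls are made on the **single-mutant variant's own counts**
(`CountTables.single_variant_counts`), not on the aggregate: a mutation
that is individually deleterious but frequently rescued inside
multi-mutants would otherwise inherit the rescuers' wild-type reads and
be misclassified as tolerated — exactly the situation the compensatory
analysis is designed to detect. The aggregated table is still computed
and exported for reporting.

### Criticality, compensation, summary

A position is **critical** when its deleterious (intolerant)
substitutions strictly outnumber the tolerated ones (ratio > 1; a tie is
not critical). A **compensatory** record is a genotype with at least two
substitutions, classified tolerated, containing at least one individually
deleterious substitution; `min_count` (default 0; the headline table of
the original screen used >100) suppresses rare records. Screen summaries
report `100*n_detected/n_expected` and
`100*(n_detected - n_deleterious)/n_detected`, rounded half-up for
display with full precision retained.

"Beyond position `max_pos`" filtering is strict (`>`), so the boundary
residue itself is analyzed. Reads with a stop codon inside the
mutagenized span are counted as nonsense and excluded from missense
statistics (the SNS design encodes no stops, so these indicate errors);
frame-broken or short reads are discarded and counted. Indels are not
called, and reads are assumed quality-trimmed upstream.

## Library design

Degenerate codons are modelled as one nucleotide alphabet per codon
position (IUPAC symbols accepted, e.g. SNS = {G,C} x {A,C,G,T} x {G,C}).
Enumeration is the cartesian product translated through the standard
genetic code (NCBI table 1; other tables by id). SNS encodes 10 amino
acids (L, P, H, Q, R, V, A, D, E, G) and no stops; schemes that can reach
stops report them separately from the amino-acid set. Region tilings are
validated (sorted, non-overlapping, within the reference); the default
7-region layout tiles residues 2–24 of the toxin's transmembrane ORF with
regions II = 7–9 and VI = 19–21. Expected-diversity arithmetic is
`L*k` single variants and `k^L` combinations for an L-residue region at
k amino acids per position.

## Family-alignment analyses

Conservation is identity to the reference row: score(p) = rows matching
the reference residue at p / total rows. A gap never matches; gapped rows
stay in the denominator by default (`include_gapped_rows=False` drops
them). Homolog substitution sets are positionwise diffs in reference
coordinates, skipping gaps and non-standard codes. A **compensated
sequence** is a homolog row with >= 2 substitutions of which at least one
is in the screen's deleterious set.

The **correlated-mutation index** conditions on structure: every
contacting residue pair (5 A any-atom contacts by default) is typed by
its reference amino-acid pair — 400 ordered types, with the pair ordered
by sequence position; the unordered 210-type view is obtainable by
symmetrization. A contacting pair is *mutated* in a row when both
positions carry non-gap residues differing from the reference. The index
of a type is `mutated_events / observed_pairs` — the convention of the
defining worked example (30 Ala–Ala contacting pairs mutated 15 times
gives 0.5, i.e. 50%) — under which the value scales with alignment depth.
The alternative `pair_rows` normalizer divides additionally by the number
of homolog rows and estimates a per-homolog co-mutation rate; it is the
right scale for comparing against a planted co-mutation probability.
Columns where the reference is gapped never enter the contact mapping.

## Contact graphs and packing

Two residues are in contact when any atom pair lies strictly closer than
the cutoff (default **5.0 A**). Hydrogens are excluded at load time by
default (deposited crystal structures usually lack them; `heavy_only=False`
keeps them). Sequence-adjacent contacts are included
(`min_seq_separation` raises the threshold). Multi-chain files are
processed one chain at a time; alternate conformations keep the first
conformer; waters and non-amino-acid residues are dropped; residues are
re-indexed 1..n in file order.

Packing density is measured two ways, reported side by side: the
ordinary-least-squares slope of order (contacts) against size (residues)
across a cohort, and the per-chain mean degree `2*order/size`. Maximal
cliques — cliques not contained in any larger clique — are enumerated
with the pivoting Bron–Kerbosch algorithm (networkx `find_cliques`) and
counted at sizes 3, 4, 5, with larger cliques tallied separately as a
diagnostic.

## Hydrophobic-contact geometry

The source analysis never defines its "spherical angles" precisely; the
interpretation chosen here is rotation-invariant and frame-free: for each
hydrophobic residue (default set {A, V, L, I, M, F, W, C}) with at least
two hydrophobic contacting neighbours, the representative point is the
side-chain centroid (CA for glycine), and the residue's vector holds the
angles subtended at that point by every pair of neighbour points, sorted
descending.

Vectors of different lengths are compared by Euclidean distance after
truncation to the shorter length (zero-padding available). The protein-
level comparison is the symmetric Hausdorff distance between vector sets.
The truncation rule is not a true metric across mixed lengths (the
triangle inequality can fail when a short vector mediates between two
long ones), so the pseudometric properties are guaranteed — and tested —
on equal-length vectors.

The **minimum** Hausdorff distance is searched over a global angular
offset added to one protein's vectors, a one-parameter transform family
on which an exhaustive 1-degree grid provides an independent oracle. A
seeded simulated annealing (Metropolis acceptance; geometric cooling,
T0 = 100, alpha = 0.95, 5000 steps; proposal width shrinking with
temperature) starts at the identity offset — so the result never exceeds
the unminimized distance — and is finished by a bounded deterministic
1-D polish around the best offset. Cohort comparisons are restricted to
pairs with the same CATH class and length difference <= 20 residues
(strict); a pair has "identical orientation" when the minimized distance
is at most `tolerance` (default 1 degree — the source analysis states no
threshold, so the identical-orientation fractions should be read
qualitatively and the knob varied).

## Synthetic data: what it emulates and what it does not

* **Read pools.** Planted tolerated singles, deleterious singles, and
  compensatory combinations are each sequenced to a fixed depth
  (default 500 reads/variant); the phenotype rule assigns a genotype the
  mutant phenotype iff it carries a planted deleterious single not
  accompanied by its planted compensating partner(s). Sequencing errors
  are applied per base (default 0.5%) *before* translation, so noise
  reaches the statistics through the real mechanism (spurious
  substitutions, nonsense reads, position-24 overruns). The default
  truth uses the toxin's real reference ORF, seven deleterious singles
  and eight compensatory pairs mirroring the screen's most frequent
  combinations, and all remaining SNS-reachable substitutions over the
  7-region tiling as tolerated. Not emulated: variable per-variant
  depth, PCR jackpotting, quality-score structure, indels, and
  biological noise in the phenotype assignment itself — so passing
  recovery tests demonstrate the statistics' correctness under the
  stated noise model, not robustness to every artefact of a real run.
* **Alignments.** Rows are i.i.d.: background columns substitute to a
  random non-reference residue at a per-column rate (default 0.1);
  planted correlated pairs co-substitute both-or-neither at their stated
  rate; correlated columns receive no additional background. Default
  family size 148 rows. No phylogenetic correlation and no gaps are
  generated, so conservation and correlated-mutation recoveries are
  clean-room checks, not claims about tree-induced covariation.
* **Structures.** Ideal poly-Ala helices are built by natural-extension
  (NeRF) from canonical backbone dihedrals (phi = -57, psi = -47,
  omega = 180) with full N/CA/C/O backbone plus CB, reproducing the
  textbook 1.5 A rise, ~100-degree twist, 3.8 A CA–CA spacing and the
  (i, i+1)/(i, i+3)/(i, i+4) contact pattern at 5 A. Globular decoys
  place residues on the jittered cubic-lattice ball nearest the origin
  (spacing 4.2 A, uniform jitter radius 0.3 A), guaranteeing minimum
  inter-residue distance >= 3.5 A, nearest-neighbour distances < 5 A and
  a connected 5 A contact graph; they emulate compact self-avoiding
  packing, not real side-chain chemistry.

All generators are bit-reproducible given (parameters, seed) and write
machine-readable truth tables.

## Numerical choices and problem sizes

* Contact search uses a k-d tree over atoms with an inclusive radius
  query, then applies the strict `<` cutoff on exact distances.
* Degenerate inputs raise typed errors: zero-count F statistics,
  all-equal-size packing fits, empty chains/alignments/vector sets,
  invalid annealing schedules.
* Report percentages round half-up; TSV outputs keep full precision.
* The test-suite's heavier checks are sized to run in minutes on one
  core: clique profiles are verified against an exhaustive bitset
  subset-enumeration oracle on 50 seeded G(30, 0.2) graphs; the annealed
  offset search is verified against the 1-degree grid oracle on 20
  seeded instances; screen recovery simulates ~230 variants at depth
  500; alignment recovery uses 200 rows.

## Known limitations

* The correspondence between the per-base error rate of the generator
  and the screen's 4% variant-level error band is mechanistic, not
  calibrated: a 0.5% base error over an ~90 nt amplicon produces roughly
  one error per three reads, which lands in the ISPA band only through
  the counting pipeline itself.
* The angular-offset transform family is one interpretation of
  "minimum Hausdorff distance"; other families (per-vector offsets,
  correspondence reassignment) would give different minima. The
  implementation isolates this choice behind `min_hausdorff`.
* Identity-based conservation ignores substitution similarity and
  phylogeny by design; it matches the reference-centric score the
  pipeline needs, not evolutionary-rate estimators.
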