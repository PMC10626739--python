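# Methods

## Scope and model

`quorumtrace` infers a directed, time-resolved quorum-sensing (QS)
communication network from three inputs: a reference database of QS
synthase/receptor proteins keyed by signal class, a protein gene catalog
with per-gene read counts over a (day × replicate) sample grid, and
genus-level taxonomy plus free-text functional annotations per gene. The
chain is: homolog retrieval → abundance normalization → pathway
completeness and phase specificity → cross-talk network → qualitative
interference prediction. A synthetic-community generator with known ground
truth exercises every stage.

## Homolog retrieval

Retrieval uses optimal local alignment (Smith–Waterman with affine gaps)
of every catalog protein against every reference. The dynamic programming
kernel is biotite's C implementation; this package owns the reported
statistics and their conventions:

* **identity** — exact matches / aligned columns, gap columns included
  (the convention of the BLAST tool family);
* **coverage** — fraction of the *reference* spanned by the local
  alignment. Covering the reference guarantees the functional domain is
  present; query coverage is also computed and can be selected with
  `SearchThresholds(coverage_of="query")`;
* **e-value** — Karlin–Altschul E = K·m·n·e^(−λS) with the classic gapped
  BLOSUM62 constants λ = 0.267, K = 0.041, query length m and database
  size n = total catalog residues. On small synthetic catalogs e-values
  are generous (n is tiny), so the identity and coverage filters do the
  discriminative work; the e-value bound mainly rejects short spurious
  islands.

Defaults: BLOSUM62, gap open 11, gap extend 1 (a gap of length g costs
11 + (g−1)·1), identity ≥ 0.30, coverage ≥ 0.50, e-value ≤ 1e−5. Each gene
receives at most one best reference (highest score; ties by lower e-value,
then reference file order) — homolog abundances are later summed per
(signal, role), which presumes a unique assignment.

A second filter discards genes whose annotation does not contain the
matched reference's domain keyword (case-insensitive substring). This
stands in for a conserved-domain database cross-check, which needs
network access and a curated domain model per family; the keyword
surrogate has the same shape — an annotation-based veto on alignment-only
hits — and in the synthetic benchmark restores precision to 1.0 when a
shuffled decoy slips past the aligner.

## Abundance model

* Relative abundance: a_gs = (c_gs/L_g) / Σ_g′(c_g′s/L_g′). Length
  division removes the read-count/length confound; columns sum to 1.
* Per-cell abundance of a (signal, role): Σ matching genes' a_gs divided
  by the summed relative abundance of recA genes in the sample. recA is a
  single-copy housekeeping gene, so this ratio estimates mean gene copies
  per cell. The denominator pools recA community-wide; a per-genus
  denominator would estimate copies per cell *of that genus* and is easy
  to add, but the community-wide ratio is what a whole-community homolog
  sum calls for. recA genes are identified from the truth table
  (synthetic data) or an annotation keyword (real catalogs).
* Shannon diversity uses the natural log, the ecology-toolkit default.

## Phase scheme and pathway classification

Days map to phases through half-open windows AP1 [0,1), AP2 [1,2),
GP [2,5), MP [5,11], the terminal day inclusive; AP1 ∪ AP2 = AP. The
boundary days (2 and 5) open the later phase; the prose convention
"day 2 to day 5" does not fix the endpoints, and half-open windows are the
only self-consistent total assignment.

A signal is **complete** iff both a synthase-side (synthase or peptide
processor — processors sit on the production arm) and a receptor homolog
survive both filters. Only complete signals can carry information and
enter the network.

**Phase specificity** of a pathway's per-cell series: compute coarse-phase
means; if max/runner-up ≥ 1.5 the pathway is argmax-phase-specific;
otherwise a flat profile — relative range (max − min)/mean < 0.25 — is
called GP-specific, capturing pathways that hold steady abundance through
the whole assembly; anything else stays `unclassified` rather than being
forced into a bin. The relative range was chosen over a coefficient of
variation as the stability statistic because it is the sharper test of
"no phase stands out" for three-point profiles (a CV of 0.25 already
tolerates a 1.6-fold spread); both thresholds are exposed.

## Cross-talk network

For each complete signal, an edge runs from every synthase-carrying genus
to every receptor-carrying genus whose mean relative abundance in its own
peak phase reaches `min_genus_abundance` (default 0.01 — a genus that
never reaches 1 % cannot anchor a community-level claim). The genus peak
phase is the coarse phase of maximal mean relative abundance, ties to the
earliest phase. Edge direction compares peak-phase ranks: forward
(receiver later), reverse (receiver earlier), intra (equal, including
self-talk); intra edges are kept for completeness but never propagate
interference, since within-phase talk has no longitudinal direction.

**Hubs** are genera that carry both a synthase-side and a receptor homolog
(over any signals) and participate in ≥ `min_signals` (default 2) distinct
complete signals of the network — generalists relaying information across
the succession.

**Interference prediction** for a blocked signal: receivers of forward
edges lose their go signal → `delayed_or_suppressed`, and the delay
propagates transitively down forward chains; receivers of reverse edges
lose a brake imposed by later colonizers → `prolonged_or_enhanced`. When
both rules hit a genus, delay wins by default: losing one's own incoming
go signal outweighs losing a late arrival's brake, so only genera with no
forward in-edge — the initial colonizers — are released. The alternative
resolution (`reverse_release_dominates=True`) is exposed.

## Synthetic community generator

The generator emulates the study conditions end to end: five genera with
assigned peak phases (Streptococcus→AP, Veillonella/Megasphaera→GP,
Prevotella/Fusobacterium→MP), days 0–11, 8 replicates, 100 000 reads per
sample, ~500 genes.

* **Trajectories**: per-genus Gaussian bump over days centered in the peak
  phase (centers 1.0/3.5/8.0, widths 1.0/1.3/2.4 days) on a 0.02 baseline,
  multiplied by log-normal replicate noise (σ = 0.05) and renormalized per
  sample. The simplest shape producing unimodal succession curves.
* **Planted QS genes**: reference sequences mutated by substitutions at
  uniformly chosen positions (replacements from natural residue
  frequencies, no indels by default) to a target identity; realized
  identity is verified by a global alignment. Verification is global
  because a local alignment of a heavily mutated pair collapses onto a
  short high-identity island, which would misstate how far a 20%-identity
  negative control actually is from its reference. Default plants span
  identities 0.56–0.90 plus two 0.20 negatives below the retrieval floor.
* **Decoys**: residue-shuffled reference sequences — identical composition
  with no preserved alignment, the hardest null for a local aligner —
  annotated without the domain keyword.
* **recA**: one gene per genus at 1 copy per cell (genus-specific 95 %
  variants of a common backbone).
* **Counts**: one multinomial draw per sample over all genes with
  probability ∝ genus abundance × copies per cell × nucleotide length,
  reproducing exactly the confound the length normalization removes, so
  copy numbers round-trip: a gene planted at 2 copies per cell is
  recovered as ≈ 2.0 by recA normalization.
* **Interference scenarios**: `simulate_interference` applies the network
  prediction to the trajectory parameters — delayed genera get peak shift
  +1 day and amplitude ×0.6; prolonged genera width ×1.6 and amplitude
  ×1.4 — and records the applied effects in the truth object, closing the
  predict/simulate loop.

What the generator does **not** model: read-level errors, assembly
artifacts and chimeras, strain-level variation within genera, horizontal
transfer (every planted gene's genus is unambiguous), absolute biomass
(only relative composition), and real homolog sequence divergence
structure (mutations are i.i.d. substitutions, not phylogenetically
clustered). Passing the benchmark therefore demonstrates correctness of
the inference chain under its own assumptions — thresholds applied
faithfully, normalizations exact, network logic sound — not retrieval
sensitivity on real metagenomes, where domain architecture and alignment
heuristics dominate.

## Numerical and engineering choices

* Determinism: all randomness flows through `numpy.random.default_rng`
  seeded from the spec seed (child streams for trajectories and catalog);
  alignment scores are integers; reruns are bit-identical and the run
  report carries a config fingerprint.
* The fixture reference DB (21 signals: 10 with both roles, 11 one-role)
  uses synthetic sequences drawn once from natural residue frequencies at
  a fixed seed; homology search only ever compares catalog genes derived
  from these same references, so sequence realism is immaterial.
* Degenerate inputs are hard errors naming the offender: empty FASTA,
  FASTA id without metadata, zero-count samples, zero recA abundance,
  invalid residues (with position), out-of-range days.
* Empty local alignments (no positive-scoring cell) return score 0 with
  zero coverage rather than erroring, and are removed by the thresholds.
* Problem sizes in tests and the acceptance script (catalog ~500 genes ×
  37 references; 200 oracle pairs ≤ 30 aa) were chosen so a full run
  completes in well under a minute on one CPU while still exercising every
  code path at the study's gene-inventory scale.

## Known limitations

* The aligner is exact but quadratic per pair with no seeding heuristics;
  catalogs beyond ~10⁵ genes want an external accelerated aligner, which
  can be slotted in behind the same `AlignmentResult` contract.
* E-value calibration uses fixed ungapped-approximation constants rather
  than per-matrix estimation; absolute e-values on small databases should
  not be over-interpreted.
* The interference model is qualitative by design — the underlying growth
  dynamics are not parameterized, so predictions are direction-of-effect
  labels, not magnitudes or time courses.
* Completeness is binary per signal; multi-step synthases (e.g. Pfs/LuxS)
  are not required to be jointly present — any synthase-side homolog
  counts, which is permissive for pathways whose steps are split across
  genera.
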