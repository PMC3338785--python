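# Methods

`itsdiv` analyses intraspecific variation in an alignment of conspecific
DNA barcodes (the motivating case is the ITS1-5.8S-ITS2 rDNA region of an
aquatic hyphomycete, ~462–465 bp). The input is a pre-aligned FASTA plus an
optional isolate metadata table; the outputs are the standard table set of
a barcode diversity study: per-population diversity summaries, pairwise
F_ST with permutation significance, per-country haplotype frequencies,
Nei within/between/net distances, and an NJ tree with bootstrap support.

## Data model and conventions

* Alphabet `{A, C, G, T, N, -}` after upper-casing, `U → T`. `-` is the
  only gap character; `.` is rejected rather than guessed at. `N` is
  missing data and is excluded from every pairwise comparison.
* Columns are 0-based internally; all user-facing reports are 1-based.
* Columns that are gaps in every sequence (alignment-deposit padding) are
  stripped on load by default; a flag retains them.
* Dates in the metadata are tolerated as free text and normalised to
  ISO-8601 (unparseable values become empty); no statistic uses them.

Two comparability conventions coexist deliberately and are kept separate
throughout:

1. **Pairwise deletion** — for each sequence pair independently, columns
   where either member carries `-` or `N` are dropped. Used for K2P
   distances and percent similarity (the conventions of the distance
   software this mirrors).
2. **Raw difference counts** — a base opposite a gap is one difference
   (one per column; a k-column gap run counts k), gap-vs-gap is no
   difference, and only `N` columns are dropped per pair. Used for mean
   pairwise differences, the Nei within/between/net tables and F_ST.

Convention 2 is the only one under which a population whose sole
variation is a single indel column carried by half its members shows a
nonzero mean pairwise difference (k(n−k)/C(n,2), e.g. 16/28 = 0.57 for
4 of 8 carriers) while still containing one haplotype.

## Site classification

Each column is classified from its allele multiset (ignoring `N`):
monomorphic; transition (exactly two base alleles forming A/G or C/T);
transversion (two base alleles otherwise); mixed substitution (≥3 base
alleles); indel (gap plus one base allele); indel-plus-substitution (gap
plus ≥2 base alleles). *Site* counts tally columns per category; *event*
counts tally distinct alleles minus one per column, so the two agree on
strictly biallelic data. A column that is both indel and substitution
increments both site categories, and the polymorphic-site count S is
`substitution_sites + indel_sites`; this double-counting case is reported
as such rather than arbitrated, since the biallelic regime the package
targets never produces it. Mixed-substitution columns contribute
`alleles − 1` substitution events but are not split into
transition/transversion events.

## Distances

* **K2P** — d = −½·ln(1−2P−Q) − ¼·ln(1−2Q), with P and Q the transition
  and transversion proportions over the pairwise-deleted columns. A log
  argument ≤ 0 yields `+inf` (saturated) instead of an exception:
  conspecific data never saturate, but congeneric outgroups (>20%
  divergence) can, and a flagged entry is more useful than an abort. NJ
  refuses matrices containing saturated entries. A pair with zero
  comparable columns is an error. Distances are reported to 4 decimals;
  percent divergence is 100·d.
* **Percent similarity** — 100·(1 − p-distance), pairwise deletion; the
  substrate for OTU clustering.
* **Nei population distances** — within = mean raw difference count over
  pairs inside a population (0, flagged, for n = 1); between = mean over
  all cross pairs; net dA = between − (within_a + within_b)/2, exactly.
  The report writes the Fig-4-style square: between above the diagonal,
  within on it, net below.

All pairwise kernels are one-hot matrix products over the integer-coded
alignment, which keeps the bootstrap loop fast without compiled code.

## Neighbour joining and bootstrap

Saitou–Nei agglomeration on the Q criterion, terminating at a central
trifurcation (unrooted). Ties in the Q minimisation are broken on the
lowest (row, column) index pair, making the construction deterministic.
Negative branch-length estimates (non-additive input) are clamped to 0
with the deficit transferred to the sister branch; every clamp is logged
and surfaces in the run log. On additive matrices the leaf-to-leaf path
lengths reproduce the input to ≤1e-9 (tested on random 4–10-taxon trees).

Bootstrap resamples alignment *columns* with replacement (1000 replicates
by default), rebuilds K2P + NJ per replicate, and scores each internal
edge of the full-data tree by the percentage of replicates containing the
same bipartition (bipartitions are canonicalised, so support is attached
by split identity, not node identity). Replicates in which a pair loses
all comparable columns or saturates are redrawn, counted, and capped at
10× the requested replicates, beyond which the alignment is reported as
degenerate. Support is stored on `node.support` and emitted as standard
internal Newick labels.

## OTUs and haplotypes

* **OTU clustering** — agglomerative on percent similarity; single
  linkage by default (two sequences share an OTU iff chained through
  pairs at or above the threshold), complete linkage by flag. Labels
  `OTU-1…` by decreasing size, then first-member order. The threshold is
  a required analysis parameter — there is no defensible universal
  default for conspecific data — and the pipeline can additionally report
  partitions across a sweep (100, 99.5, 99, 98.5, 98) for sensitivity.
  The cut uses `(100 − threshold) + 1e-9` so pairs exactly at the
  threshold merge despite float round-off.
* **Haplotypes** — two sequences share a haplotype iff identical at every
  column free of gaps and `N` within the analysed subset. Ignoring indel
  and missing columns is the only rule consistent with a population that
  has one indel site yet one haplotype, alongside populations whose two
  haplotypes differ at substitution sites. Labels `H1…` by decreasing
  frequency. The haplotype partition refines the OTU partition and is
  idempotent and order-invariant (tested).
* **Country table** — countries with ≥4 isolates (configurable) are each
  subsampled without replacement, seeded, to 4 isolates; haplotypes are
  collapsed over the pooled subsample, and counts plus relative
  frequencies are reported per country. Subsampling is seeded because the
  original analysis does not state how its per-country subsets were
  chosen.

## Diversity estimators

θ_S = S/a_n (Watterson) with a_n = Σ_{i=1}^{n−1} 1/i, and θ_π = mean
pairwise differences. Both are reported **per locus** (difference-count
units, not per site), matching how such tables are printed for short
barcode loci, and S includes indel columns, consistently with the π
convention. No variances are reported. For n = 2 both reduce to the raw
difference count.

## F_ST and permutation significance

Both estimators run on the same raw difference-count matrix:

* `nei_ratio` (default): F_ST = 1 − H_w/H_b with H_w the unweighted mean
  of the two within-population averages and H_b the cross-pair average.
  H_b = 0 with distinct labels returns 0, flagged degenerate.
* `amova`: the two-population variance-component form, with difference
  counts serving as squared distances in the SSD partition,
  σ²_w = SSD_within/(N−2), n' = N − (n1²+n2²)/N,
  σ²_a = (SSD_among − σ²_w)/n', F_ST = σ²_a/(σ²_a+σ²_w).

Both are clamped to [0, 1] for reporting with the raw value retained in a
side column, both equal 1 for internally monomorphic, mutually distinct
populations and 0 for identical ones, and the long-format report always
carries both (the run log notes pairs where they differ by >0.01, since
which variant produced any given published table is generally not
recoverable). Populations of one isolate use within = 0, flagged.

Significance: individuals are reassigned between the two populations with
sizes preserved. When the number of distinct assignments C(N, n1) fits in
the permutation budget the test is **exact** (full enumeration, p =
fraction of assignments with F_ST ≥ observed) — so a 2-vs-2 pair has only
3 distinct splits and can never reach p ≤ 0.05, whatever the divergence.
Otherwise a Monte-Carlo test with the add-one correction
p = (1 + #{F_ST_perm ≥ obs})/(n_perm + 1) is used, so p ≥ 1/(n_perm+1).
The default of 110 permutations mirrors the analysis this package
re-creates; a warning notes its ≈0.009 p-granularity. Permutations are
seeded per population pair (canonicalised by label), so p-values are
independent of label order and of other stages' workloads.

## Synthetic data generator

`generate_dataset` emulates the structure of a conspecific barcode study:
a random reference sequence; per population a scaffold differing from the
reference at `scaffold_divergence` private columns (default 12 ≈ 2.6% of
464, so within-population divergence ≤8 columns stays strictly below
between-population divergence, echoing the ≤1.3% within vs ~2.2% maximum
regime of such data); at most two variants per population separated by
stated transition/transversion/indel columns, all mutated columns
pairwise distinct. Indels are always single-column. Expected statistics
are returned in closed form (π = D·c1·c2/C(n,2), S = D, θ_S = S/a_n,
haplotype count ignoring indel-only separation) and depend only on the
difference structure, so different seeds give different sequences but
identical expected summaries. Metadata fields (country, substrate, date)
are decorative draws that no statistic may depend on.

`table1_preset` encodes the nine-population structure the package's
acceptance checks target: sizes (16, 2, 12, 3, 8, 3, 8, 3, 8); two
populations split 2/1 and 6/2 over haplotypes differing at 2 transitions,
5 transversions and 1 indel; and one population of 8 whose only variation
is a single indel column carried by 4 members — 4 is the only carrier
count consistent with a printed mean pairwise difference of 0.57
(k(8−k)/28 = 0.571 ⇒ k = 4), and is documented here as a derived
reconstruction. The five isolates of the original 68 that were assigned
to no OTU are not emulated: the rule that excluded them is not stated.

`neutral_panmictic_preset` supports the estimator-agreement property:
each replicate carries exactly `mu_columns` biallelic substitution
columns, the derived-allele count k per column drawn from the neutral
infinite-sites frequency spectrum (P(k) ∝ 1/k) with carriers a uniform
subset of that size. Under that spectrum E[θ_π] = E[θ_S] exactly (each
segregating column contributes 1/a_n to both in expectation), which is
what the 3-standard-error agreement test asserts over 200 replicates.
A uniform choice over all subsets would *not* have this property — it
inflates θ_π by ≈30% at n = 8 — which is why the spectrum, not the
subset, is uniform.

What the generator does **not** emulate: recombination, realistic indel
length distributions, rate heterogeneity along the locus, sequencing
error, and base-composition signal (scaffold content is random, so the
nucleotide-composition block of real data is not reproduced — only its
invariants, e.g. percentages summing to 100, are checked). Passing tests
therefore demonstrate correctness of the statistics on data with the
assumed structure, not robustness to alignment error or model violations
in real barcodes.

## Pipeline and reproducibility

One run configuration (YAML-serialisable `RunConfig`) drives all stages.
All randomness derives from a single seed through named substreams
(`bootstrap`, `permutation`, `subsample`, `generator` via CRC-32 of the
stage name into a `SeedSequence`), so changing one stage's workload never
shifts another's draws; reruns under the same config are byte-identical.
The run log records package/library versions, the seed, the full config
and every clamped or flagged event. CLI exit codes: 0 success, 2
validation error, 3 computation error.

Default problem sizes used by the test suite and acceptance script — the
63-sequence, 464-column preset, 10–100 bootstrap replicates in tests,
110 permutations, 200 neutral replicates — run in seconds on one core;
the 1000-replicate bootstrap default on the preset takes on the order of
ten seconds.

## Known limitations

* The AMOVA form is the plain two-population decomposition; hierarchical
  (multi-level) designs are out of scope.
* No variance or confidence intervals for distances, θ or F_ST.
* K2P only; no JC69/TN93/GTR, no ML distances.
* Haplotype networks and species-delimitation models are out of scope.
* The similarity definition underlying published OTU tables from legacy
  GUI software is not exactly recoverable; the threshold sweep is the
  honest substitute.
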