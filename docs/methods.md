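# Methods

## The question and the data model

Retroposition copies a spliced mRNA back into the genome, so the derived
copy lacks introns while the ancestral copy retains them. When the
parental copy subsequently degenerates, the retrogene is its functional
substitute and the pair of copy types directly polarizes the relocation:
whatever element the intron-bearing copies sit on is the source, whatever
element the intronless copies sit on is the target. The package works on a
gene × species matrix of Muller-element assignments annotated with exactly
that copy-type information, plus a sex-bias expression matrix, a rooted
12-species tree, and (for de novo calling) per-species gene models with an
ortholog map.

Muller elements (A–F) are the six conserved chromosome arms; orthologous
genes stay on the same element across the genus even as karyotypes
rearrange. Element A is the X in every species. Element D is ancestrally
autosomal but was fused into a neo-X in the obscura clade, so linkage
(X vs autosome) is always evaluated per species through a `MullerMap`;
the packaged map marks D as X-linked in Dpse and Dper only.

## Retrogene screening

A family is a candidate when some species has a copy with zero CDS introns
and some species has a copy with at least one. UTR-only introns do not
disqualify intronless status by default — a retroposed ORF can acquire (or
retain, if the parental UTR introns lay outside the retrocopied region)
spliced UTRs — but such candidates are flagged and retained only through
an explicit include override backed by external evidence. Intron counts
come from the isoform with the fewest CDS introns, the conservative
summary when all isoforms of the parental gene show the loss.

Parental loss requires that no species carries both an intact
intron-bearing and an intronless copy; a species with both shows a
retro-duplication (second origin) rather than a substitution, and degraded
remnants do not count as retained copies (configurable). Relocation is
confirmed from flanking genes: at least one relocated species' flanking
orthologs (window of 2 per side) must be fully disjoint from the flanking
orthologs of the intron-bearing copies, and at least one flanking ortholog
must support the new context in every relocated species with data. Absent
flanking data is a distinct "insufficient data" outcome, not a negative.
Low-coverage-genome exclusions are an input blacklist: no sequence-quality
metric is defined by the data model, so that judgment cannot be inferred.

## Ancestral reconstruction and movement classes

Minimum-change ancestral states are computed with a unit-cost Sankoff
up/down dynamic program (tip ambiguity sets cost 0 for any member; leaves
without data are wildcards). This returns the Fitch minimum together with
exact per-node MPR state sets and the set of branches carrying a change in
at least one most-parsimonious reconstruction; it handles multifurcations,
although the packaged tree is binary, where the minimum equals the number
of empty intersections of the classic Fitch pass (tested). Parsimony alone
cannot polarize a change that sits on the root bipartition — both root
edges are equally parsimonious — which is precisely why the copy-type
flags are the primary basis for direction: source = consensus element of
the parental species, target = consensus element of the retro species,
with the parsimony root used only as a fallback (and required to be a
unique MPR state there).

Consensus voting: every cell votes for each element it allows; a unique
plurality wins; ties prefer elements backed by unambiguous cells, then
alphabetical order, and mark the event ambiguous. Degraded copies are
excluded from consensus (their location evidence is unreliable), as are
literal `X` entries that are ambiguous between elements A and D under an
obscura-clade map. Secondary-copy annotations (`A (C)`) record independent
second origins and never enter the primary event. The event branch is the
MPR change branch leading only to retro-carrying species when that is
unique, otherwise the MPR branch closest to the root, flagged ambiguous.

A movement is classed by the linkage of source and target under the map
of the species carrying the derived copy (majority rule across them), so
an event landing on element D reads X-linked only when observed in the
obscura clade.

## The null model and the heterogeneity test

Under random retroposition the source element i is drawn with probability
w_i·g_i / Σ w·g — g_i the element's gene count (more genes, more
transcripts available for reverse transcription) and w_i a
dosage-compensation weight (autosomes 1; the hyper-transcribed male X > 1)
— and the target j ≠ i with probability s_j / Σ_{k≠i} s_k, proportional to
euchromatin size (insertion is taken as uniform in space).  Same-element
events are excluded from the sample space (configurable). Ordered pairs
pool into X→A, A→X, A→A (and X→X for karyotypes with two X-linked
elements; zero pairs under the melanogaster map). Observed counts are
compared with Pearson's χ² = Σ(O−E)²/E, df = classes − 1, upper-tail
chi-square p. Because expected counts near 3–5 strain the asymptotic
distribution at N = 21, a multinomial Monte-Carlo version draws replicate
count vectors from the class probabilities and reports
p = (1 + #{χ²_rep ≥ χ²_obs}) / (reps + 1), seeded and reproducible.

The packaged configuration uses round FlyBase-era reference values for
g_i (2300, 2700, 3100, 2800, 3600, 100 genes on A–F) and s_i (22.4, 23.0,
21.1, 24.5, 27.9, 1.3 Mb) and solves the single X weight (1.63512) so the
observed (15, 3, 3) yields χ² = 27.884 — the expectation vector
(4.917, 3.754, 12.329) then follows. This is a documented calibration
(`scripts/calibrate_null_config.py` regenerates it), flagged as
`calibrated_config` in every report: the exact constants behind the
published expectation are not recoverable from the study tables, only the
model structure and the resulting statistic are.

The χ² comparison partitions observed events by the *null config's*
karyotype; context-aware classification can place a simulated event on a
lineage-specific neo-X (class X→X), which has no pairs under the
melanogaster null — the reported movement counts keep the context-aware
classes, the test uses the config partition. On the study cohort the two
coincide.

## Expression

A cell is male-biased iff its signed log male/female ratio is positive and
flagged significant, female-biased iff negative and significant, unbiased
when assayed but not significant. Only the positive-is-male sign
convention is consistent with the study matrix's marginal counts, so it is
fixed. Cross-species consistency means an identical class in every
*assayed* species (missing cells ignored; fewer than two assayed cells is
an error, not "consistent"). Significance flags in the packaged matrix are
inputs (they derive from replicate-level tests on the original microarray
data, which is not part of the matrix); the replicate-level machinery —
Mann–Whitney U with exact enumeration for combined n ≤ 10 and
tie-corrected normal approximation above, Benjamini–Hochberg step-up at
q = 0.05 — exists for synthetic and user replicate data. The
testis-expression call (signal ≥ threshold, optional testis/ovary
enrichment ratio) is a configurable proxy; the original atlas criteria are
not fully specified by any input the package takes.

## Synthetic data: what it emulates and what it does not

The generator plants events exactly under the analysis's assumptions:
source ∝ w·g, target ∝ size, branch uniform over tree edges, species below
the branch carrying only the intronless copy at the target, all others
only the intron-bearing copy at the source. Genes are laid out on one
scaffold per element at fixed 10 kb spacing; an intact-neighborhood
relocation is written between two dedicated background genes (present in
all species) so its flanking context is new, consistent across relocated
species, and disjoint from the ancestral context; a fragmented assembly is
emulated by an orphan scaffold holding the relocated copy alone, which the
screen must report as unconfirmable rather than call either way.
Expression replicates are Gaussian (baseline 5.0, noise SD 0.5, 4
replicates/sex) with a ±effect/2 shift per sex for planted genes, the same
direction in every species.

Defaults mirror the study conditions: 46 families (the screened candidate
count), event probability 0.5, neighborhood intactness 0.45 (≈ the
fraction of candidates surviving flanking confirmation), planted-bias
fraction 0.3 (≈ the share of significant cells in the study matrix),
effect 1.0 log2 units. One root seed spawns named child streams, so
identically configured runs are byte-identical on disk.

What passing tests therefore show: the pipeline recovers exactly what was
planted when the data satisfy its assumptions, its false-positive behavior
is controlled, and the test is calibrated under its own null. What they do
not show: robustness to annotation error, incomplete assemblies beyond
the orphan-scaffold idealization, lineage-specific intron gain/loss
unrelated to retroposition, or expression noise structure beyond i.i.d.
Gaussian replicates.

## Numerical and design notes

- Coordinates are 1-based inclusive throughout (GFF3-native); strand is
  ignored for intron counting.
- Missing matrix cells mean "unknown", not "gene absent": annotation gaps
  in draft genomes are imperfections, not losses.
- The Mann–Whitney exact path enumerates all C(n+m, n) group assignments
  and is tie-safe; all-tied inputs return p = 1. At the n = 10 boundary
  the exact and asymptotic paths agree within |Δp| ≤ 0.02 (tested).
  With 4 replicates/sex the smallest attainable two-sided exact p is
  2/70 ≈ 0.029, so the BH step-up at q = 0.05 can only reject when a
  sizeable fraction (≥ 0.05/0.029 ≈ 57%) of tested cells reach it — a
  discreteness property of small-sample rank tests worth remembering when
  choosing replicate counts; the power checks use a planted-bias fraction
  of 0.6 accordingly.
- Monte-Carlo p-values use the add-one estimator, never exactly zero.
- Chi-square requires strictly positive expected counts in every class;
  classes with zero pairs are dropped from the partition rather than
  carried at E = 0.
- Test-suite problem sizes (cohorts of 30–50 families, 200 calibration
  runs at 2000 Monte-Carlo replicates, 500-family frequency checks) were
  chosen as the smallest sizes at which the asserted statistical
  tolerances (3 SE bands, KS at α = 0.01) are meaningful.

## Known limitations

- The calibrated null config reproduces the published statistic by
  construction; it is a transparent stand-in for constants the study does
  not print, not an independent re-derivation.
- The upstream 46-candidate screen depended on an external relocated-gene
  dataset; the packaged cohort starts from the curated 21-gene matrix, and
  the screening logic is validated on synthetic cohorts instead.
- Parsimony fallback direction requires a unique root state; root-spanning
  changes (e.g. a relocation separating the two subgenera) are decidable
  only with copy-type flags.
- The `C/B` ambiguity cells resolve to the unique plurality element of the
  retro consensus; the event stays flagged ambiguous, and `--strict` mode
  turns such flags into errors.
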