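# Methods

This document records the model implemented by `reannot`, every tunable
parameter with its default and rationale, the scope of the synthetic-data
generator, numerical choices, and known limitations.

## 1. Genome model (`reannot.genome`)

A genome is an ordered list of CDS records with 1-based inclusive coordinates
on the forward strand (minus-strand features keep forward coordinates with
`strand='-'`). Each record carries one of five curation categories:

| Category | Meaning |
|---|---|
| `KNOWN` | accepted function |
| `HYPOTHETICAL` | predicted protein, no supported function |
| `PUTATIVE` | function inferred from motif/structure/limited similarity |
| `NEW` | CDS absent from the original annotation |
| `PSEUDOGENE` | gene remnant, excluded from functional re-annotation |

Record invariants enforced at construction: locus tags match
`prefix_nnnn` (≥ 4 digits); non-pseudogene lengths are multiples of 3;
confidence 1–5 only on `KNOWN`/`PUTATIVE`.

**ORF enumeration.** Maximal ORFs under translation table 11 (starts ATG,
GTG, TTG; stops TAA, TAG, TGA). Within each frame, the interval between two
stops contributes at most one ORF, from the first start after the upstream
stop through the downstream stop (stop codon included in the length). The
length cut is strict: `length > min_len_nt` (default 60), so a 60-nt ORF is
rejected and a 63-nt one kept. Any `N` inside a candidate discards it —
ambiguity is not resolved silently. `circular=True` scans a doubled sequence
and keeps origin-spanning ORFs (reported with `end > L`).

**Locus tags.** Assigned in coordinate order, `'+'` before `'-'` on tied
starts; four digits widen to five with a warning past 9,999 ORFs.

**Census.** `CategoryCensus` uses free string keys so reports can split
categories (e.g. `HYPOTHETICAL_NEW`); `total` is always the sum.
`update_census(before, moves)` replays `(from, to, count)` reassignments and
rejects overdrawing a category — this makes published before/after figures
exactly auditable.

## 2. Evidence consensus (`reannot.evidence`)

Five sources: `PSI_BLAST`, `BLASTO`, `PFAM`, `INTERPROSCAN`, `ANNIE`.

**Filters** (best-hit level):

| Parameter | Default | Rationale |
|---|---|---|
| PSI-BLAST min identity | 40 (strict >) | published best-hit cut-off |
| PSI-BLAST max e-value | 1e-52 (strict <) | published best-hit cut-off |
| Pfam-A max e-value | 1e-02 (inclusive ≤) | published domain cut-off |

**Voting.** Descriptions are normalised to token sets (lower-case,
punctuation stripped, generic words such as *protein*, *domain*, *family*,
*putative* removed; wholly uninformative products like *hypothetical protein*
normalise to the empty set and carry no vote). Agreement is token-set Jaccard
≥ `agree_threshold` (default 0.6 — requires a clear majority of shared
informative tokens while tolerating one divergent qualifier). One vote per
independent method: within a source the lowest-e-value hit speaks; an
InterProScan/ANNIE record whose `member_database` names a source already
voting with an equivalent description is dropped (intrinsic-overlap
avoidance, so a Pfam domain seen twice never counts as two votes).

**Confidence.** With at most five votes, the largest mutually agreeing subset
is found by exact subset enumeration (≤ 2⁵ subsets — no heuristic needed);
its size is the `k/5` confidence. The consensus description is the most
frequent raw description in the winning subset, ties broken lexicographically.
Call classes: `DEFINED` unless the consensus carries a putative/probable
marker or is supported only by motif-level sources (Pfam/InterProScan), which
yield `PUTATIVE`; no informative votes yield `NONE`.

**Reclassification** (defaults: `min_conf_known = 2`): hypothetical, new and
putative genes become `KNOWN` on a DEFINED call with ≥ 2 agreeing methods
(one method alone is treated as unreplicated); weaker DEFINED and all
PUTATIVE calls yield `PUTATIVE` with a `putative ` product prefix; `KNOWN`
genes are never demoted; pseudogenes are never reclassified. Category totals
are conserved by construction.

## 3. Motif patterns (`reannot.prosite`)

A PROSITE-syntax subset: fixed residues, alternative sets `[..]`, exclusions
`{..}`, wildcard `x`, repeats `(n)`/`(n,m)`, anchors `<`/`>`. Compiling then
rendering round-trips the pattern text (written residue order preserved).
Scanning reports *every* matching window, overlapping matches included, as
1-based inclusive positions; variable repeats are expanded by depth-first
search over the admissible repeat counts.

## 4. Homology (`reannot.homology`)

**Alignment.** Smith–Waterman local alignment via Biopython's
`PairwiseAligner` (`mode="local"`), BLOSUM62, linear gap −8 (open = extend;
a single well-understood penalty rather than an affine pair, adequate for
the indel-free default simulation). `Lmatch` counts alignment columns
including gap columns (configurable to residue-pairs-only via
`Scoring.count_gap_columns`). Score ≤ 0 means "no alignment" (Lmatch 0).

**Coverage ratios.** `minLrap = Lmatch / min(L₁, L₂)`,
`maxLrap = Lmatch / max(L₁, L₂)`, giving the three interpretive cases:
(1, 1) → `FULL` (full-length alignment), (1, < 1) → `PARTIAL` (the shorter
protein fully covered — possible fusion/fission or modular architecture),
(< 1, < 1) → `POOR` (local similarity only).

**BBH orthologs.** Mutual best hits; ties on raw score broken by higher
identity, then lexicographic subject id (determinism). **Homologs**: BBH
pairs with minLrap > 0.8 and identity > 30% (both strict). **Core genome**:
pivot genes with a homolog in *every* comparison genome; **specific genes**:
in none.

**Essential genes** (default `min_minlrap = 0.5`): a reference essential gene
is present when some genome gene shares a BBH with it at minLrap > 0.5, *or*
belongs to the same synteny group; an empty synteny map reduces the criterion
to pure BBH coverage.

**COG assignment** (default `bet_cutoff = 3`): a protein joins every COG
supported by genome-specific best hits from ≥ 3 distinct reference genomes
(fewer reference genomes than the cutoff is an error, not a silent pass).
The census splits each functional-category count into old/new CDSs (X/Y) and
errors on a COG id missing from the category map.

## 5. Synteny and context (`reannot.synteny`)

**Synteny groups** (default `max_gap = 5`): ortholog pairs sorted by pivot
index are chained greedily while (a) indices progress monotonically on both
genomes, (b) the direction on the second genome is uniform within a chain
(collinear or uniformly inverted — inverted blocks are conserved context
too), and (c) at most `max_gap` genes intervene on either genome.

**Context scores.** Neighborhood: fraction of co-hosting genomes where the
two families sit within `max_dist = 3` gene indices on the same strand
(genomes lacking either family are excluded from the denominator; no
co-hosting genome → 0, absence of evidence is not evidence). Co-occurrence:
Jaccard of presence profiles. Channels combine by noisy-or
`1 − ∏(1 − sᵢ)` — independent weak evidence accumulates, and the combined
score never drops below the strongest channel. An association passes only if
the combined score strictly exceeds `0.4` ("medium confidence").
Unknown genes take the majority label among labelled partners on passing
edges; ties and isolated genes stay unlabelled (`None`) rather than guessing.

## 6. ROC evaluation (`reannot.roc`)

Cases pair binary truth with ordinal ratings (study scale 2–5). Sweeping
"positive iff rating ≥ t" over the distinct ratings traces the empirical ROC
from (0,0) to (1,1); its trapezoidal area equals the Mann–Whitney statistic
(#concordant + ½ #tied)/(n₁n₀) and is invariant under monotone re-coding of
the scale. The default operating threshold maximises Youden's J
(sensitivity + specificity − 1), ties resolved toward the lower threshold
(favouring sensitivity). `mean_accuracy` is the unweighted mean over sources.

## 7. Synthetic data (`reannot.simulate`)

**Scope.** The generator produces exactly the inputs the pipeline consumes —
proteomes with gene orders, curation categories, evidence tables, an
essential-gene reference, rating cases — at desk scale, with ground truth
recorded for every quantity the pipeline estimates. It is a validation
instrument, not a realistic evolution model.

**Genome families.** Star topology from a random ancestral proteome
(lengths ~ Poisson(`mean_protein_len`, default 120, floored at 30; leading M).
Per non-pivot branch: each family lost with `loss_prob` (0.08), duplicated
with `duplication_prob` (0 — duplication off by default so single-copy
orthology is well defined), surviving copies mutated by i.i.d. residue
substitutions at `substitution_rate` (0.05/site — diverged but comfortably
alignable), and with `inversion_prob` (0.3) one random block inversion.
`pivot_private_fraction` (0.10) of families exist only in the pivot;
`essential_fraction` (0.15) of shared families form the essential reference;
`essential_missing` (0) of them are deleted from the pivot as planted
negatives. Categories are drawn at the proportions of a typical re-annotated
chromosome (1854 : 781 : 47 : 231 : 104).

**Evidence.** Per pivot gene and source: correct hit with `p_correct` (0.9),
decoy label with `p_wrong` (0.05), silence with `p_nocall` (0.05). Planted
hit statistics always pass the corresponding source filter, so filter and
consensus effects are separable. Decoy labels come from a vocabulary disjoint
from true labels, making "agreement" unambiguous. `p_overlap` optionally
marks integrated-source hits with `member_database="PFAM"` to exercise
intrinsic-overlap deduplication.

**Ratings.** Positives rate (2,3,4,5) with probabilities (.05,.10,.25,.60),
negatives reversed, prevalence 0.5; the expected AUC has the closed form
P(r₁ > r₀) + ½ P(r₁ = r₀) = 0.8975 under the defaults.

**Determinism.** All streams are children of one `numpy` `SeedSequence`
(`spawn`), one per sub-generator, so outputs are bit-reproducible and
enlarging one component (e.g. more rating cases) does not perturb another.

## 8. Numerical choices

- Alignment scores come from Biopython's C implementation; the test suite
  pins its semantics against a hand-rolled Smith–Waterman DP oracle, itself
  validated against exhaustive substring-pair enumeration on small cases.
- AUC uses `numpy.trapezoid` on exact rational ROC points; equality with the
  all-pairs Mann–Whitney count is tested to 1e-12.
- Threshold semantics are explicit everywhere: strict `>` for PSI-BLAST
  identity/e-value, homolog constraints, essential minLrap and the 0.4
  context threshold; inclusive `≤` for Pfam; inclusive `≥` for Jaccard
  agreement and the rating rule. Boundary tests cover each.
- Consensus clustering and confidence use exact subset enumeration (≤ 5
  votes), avoiding any dependence on clustering heuristics or input order.
- All report writers emit sorted, timestamp-free output; byte-identical
  reruns are an acceptance criterion, not an aspiration.

## 9. Limitations

- The evolution model has no indels by default, no HGT, no rate variation
  across sites; substitution is uniform over the 19 alternatives rather than
  BLOSUM-biased. Lmatch/Lrap behaviour under indels is exercised only via
  hand-constructed alignments in tests.
- The linear (non-affine) gap penalty is a deliberate simplification; with
  indel-free simulations it changes nothing, but on real proteins affine
  penalties usually align better.
- Evidence sources are sampled independently per gene; real tools share
  databases and fail in correlated ways, so real consensus confidence is
  more optimistic than the independence model suggests.
- COG assignment uses unsplit whole proteins; multi-domain proteins with
  different-COG domains are not split as full COGNITOR does.
- Context association uses only neighborhood and co-occurrence channels
  (no gene-fusion channel) and transfers labels by simple majority.
- Empirical claims in this document are limited to what the package computes
  on its own simulations; no external-database results are asserted.
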