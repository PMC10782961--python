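# Methods

## Two-tier domain annotation

Domain evidence comes in two tiers. Tier 1 is a sequence-to-profile scan
(`hmmscan --domtblout`); each hit carries a bit score, an independent
E-value, and three coordinate systems (envelope, alignment, model). Tier 2
is a profile-profile "rescue" search of the kind applied to long
unannotated regions; each hit carries a probability in percent. The rescue
input is a fixed tabular dialect (`protein_id model_name probability
env_start env_end hmm_start hmm_end model_length`) rather than a raw
report-format file: the tabular form is what a pipeline can parse and
round-trip deterministically, and a converter from report formats is out
of scope.

Envelope coordinates define domain extent everywhere (they are the scan's
best estimate of where the domain lies); model (hmm) coordinates decide
whether two partial hits are halves of one domain. All coordinates are
1-based inclusive.

## Resolution procedure

Per protein: filter → compete overlaps → merge split hits → map labels →
canonical string.

* **Filtering.** Tier-1 hits pass at independent E-value ≤ `1e-5`
  (conservative, standard for architecture surveys; the boundary is a
  config key). Tier-2 hits pass at probability ≥ 90.0, inclusive — the
  threshold is quoted in the field as "above 90%", and boundary hits are
  rare; inclusivity is documented and configurable.
* **Overlap competition.** The kept subset maximizes total score subject
  to every pair overlapping by ≤ `overlap_tol` = 15 envelope residues.
  Scores are commensurated across tiers as bits for tier 1 and
  probability/10 bits-equivalent for tier 2 — arbitrary, but cross-tier
  overlaps are rare and the rule is configurable. The search is exact
  (branch-and-bound over hits in canonical order: score desc, envelope
  length desc, start asc), not a greedy or chain-DP approximation: overlap
  tolerance breaks the interval-scheduling structure (a chain whose
  consecutive pairs are compatible can still contain an incompatible
  distant pair when short intervals nest inside long ones). Hit lists per
  protein are small, so exact search is cheap; tie-breaking by the
  canonical order makes the selection unique and input-order independent.
* **Split-hit merging.** Two consecutive hits to the same model merge into
  one domain when the sequence gap between them is ≤ `merge_max_gap` = 75
  aa and the model coordinates are collinear (the later hit's hmm_start ≥
  the earlier hit's hmm_end − 20). The motivating artifact is a ~50-aa
  insertion mid-CheW that splits one domain into two hits; 75 gives
  headroom over that exemplar while staying below the 100-aa rescue-region
  threshold, so a merged gap can never itself become a rescue query. Two
  full-length matches fail collinearity and stay separate copies — true
  duplications survive. Merging is left-to-right and transitive, and
  idempotent on its own output.
* **Unannotated regions.** Maximal uncovered intervals ≥ `gap_min_length`
  = 100 aa (the average domain size) are reported, terminal gaps included
  — whether the original rule covered termini is unknowable from the
  description, and including them is the conservative choice for finding
  rescue candidates.
* **Vocabulary.** Model names collapse onto unified labels before string
  construction: P2 and CheY-binding (clan mates modelling one docking
  domain) → `P2/CheY-binding`; Response_reg and CheY-like-superfamily
  members → `CheY-like`; CheC and CheX (one clan, one fold) → `CheC/CheX`;
  unknown models → `other:<name>`. The mapping ships as an editable TSV.

Dimerization domains are classified *classical* at ≤ 70 aa and *extended*
above (lengths up to ~170 aa occur); no third class is introduced — the
length itself is always reported.

## CheA-specific analyses

* **Identity.** A protein is a CheA homolog iff it carries ≥1 `HATPase_c`
  and ≥1 `CheW`. These two models are both sensitive and specific, and
  their joint presence in one protein distinguishes CheA from lone kinases
  and from CheW adaptor proteins. Identity is monotone: adding domains
  never revokes it.
* **Conserved histidine.** Each Hpt copy's sequence is globally aligned to
  a reference Hpt (BLOSUM62, affine gaps open 11 / extend 1 — community
  defaults, configurable), and the query column aligned to reference
  position 48 is inspected. A query gap at that column returns
  position None / present False. The packaged reference is a *synthetic*
  130-aa Hpt-like sequence with H at position 48 (no external sequence
  deposit is bundled); users can supply their own reference FASTA and site
  via config.
* **Bipartite Hpt.** "Same operon" is operationalized as same contig, same
  strand, gene-rank distance ≤ 3 — a standard gene-neighborhood proxy, as
  no operon model is available; the window is configurable. A CheA with no
  Hpt is paired with standalone Hpt-only proteins (≥1 Hpt, no HATPase_c,
  no CheW — multi-domain partners are a different phenomenon and are not
  counted as bipartite partners).
* **Contig-end truncation.** An Hpt-less CheA whose gene lies within 100
  bp (configurable) of a contig edge is flagged as a likely assembly
  artifact. The gene-table format carries no contig length, so contig
  length is taken as the maximum gene end on that contig — exact when the
  table covers the contig's genes, conservative otherwise.

## Cohort statistics

Domain and architecture frequencies use CheA *proteins* as denominator;
the phosphate-sink test uses *genomes*. The multi-Hpt x CheY-like
association is reported as a 2x2 table, the conditional fraction
P(CheY-like | multi-Hpt) and an odds ratio (Haldane–Anscombe +0.5
correction when a cell is zero); a Fisher exact p-value is available but
off by default — the association is descriptive, not a hypothesis test.
Phosphate-sink eligibility is strict (exactly one CheA in the genome, that
CheA carrying CheY-like); a relaxed mode (≥1 CheA, all CheY-like-bearing)
exists for sensitivity analysis. Class consensus reports each class's
modal canonical string and homogeneity, with lexicographic tie-break.

## Synthetic cohorts

The generator plants class-conditional architectures and emits every input
the pipeline reads. Default study conditions:

| class | freq | template | Hpt copies |
|-------|------|----------|------------|
| F1    | 0.26 | Hpt\|P2/CheY-binding\|H-kinase_dim\|HATPase_c\|CheW | 1 |
| F6    | 0.20 | (classical, as F1) | 1 |
| F2    | 0.08 | Hpt\|H-kinase_dim\|HATPase_c\|CheW | 1 |
| F7    | 0.06 | (as F2) | 1 |
| F3    | 0.14 | Hpt\|H-kinase_dim\|HATPase_c\|CheW\|CheY-like | 1 |
| F4    | 0.06 | three Hpt + core | 3 |
| F5    | 0.08 | Hpt\|H-kinase_dim\|HATPase_c\|CheW\|CheW\|CheY-like | 1 |
| ACF   | 0.04 | two Hpt + core + CheY-like | 2 |
| Tfp   | 0.08 | multi-Hpt + core + CheY-like | 2–14, mode 5–6 |

These marginals put the planted cohort at 46% classical architectures,
8% dual CheW (class F5), 18% multi-Hpt (F4 + ACF + Tfp), 34% CheY-like,
and ~52% of CheAs lacking P2/CheY-binding — the shape of a realistic CheA
survey. Genomes carry 0–4 CheAs (mean 1.85 among CheA-containing genomes);
phosphatase absence is drawn at 0.93 among sink-eligible genomes.
Truncation and bipartite plantings each occur at rate 0.01, so planted Hpt
presence is ≈98%.

Noise knobs model annotation imperfection: per-label miss probabilities
default to 0.3 (Hpt), 0.4 (P2/CheY-binding), 0.3 (H-kinase_dim) — the
low-sensitivity models — with 90% of misses re-emitted in the rescue table
at probabilities drawn Uniform(90.5, 99.9); CheW/Hpt hits split around a
Uniform(30, 70)-aa insertion with probability 0.05 (always below the merge
gap, so the pipeline must re-merge them); off-target decoy hits arrive at
0.1 per protein with log-uniform E-values spanning the significance
threshold. Sequences are uniform random amino acids except Hpt copies,
which are 20%-point-mutated copies of the reference (so alignment-based
His projection is meaningful), with the phospho-site His present at rate
0.9 per copy. Hit scores are Uniform(25, 120) bits with uniformly
log-spaced small E-values: the generator tests plumbing and statistics,
not HMM emission realism. It also does not emulate compositional bias,
homologous linkers, or correlated misses within a genome — so passing
recovery tests demonstrates correctness of the resolution and tallying
machinery, not expected accuracy on real proteomes.

`evaluate_against_truth` compares each observed statistic with its planted
(manifest-realized) value and reports membership in the 99% binomial
interval at the observed denominator, plus exact-string architecture
accuracy when per-protein observed architectures are supplied (they cannot
be reconstructed from the aggregate summary alone).

## Problem sizes and determinism

The test suite and acceptance script run at 500 genomes (noise-free
identity), 4,200 genomes / ≥2,000 CheAs / ≥500 sink-eligible genomes
(noisy recovery), and 1,000 random instances (overlap-competition
exactness against exhaustive subset search) — sizes at which binomial 99%
intervals are tight enough to be informative while the whole suite runs in
seconds. All randomness flows from a single seeded NumPy generator;
generator output, architecture reports, and summaries are byte-identical
across reruns with equal inputs.

## Degenerate inputs and tie-breaks

Hit-free proteins yield an empty architecture whose whole length is one
unannotated region. Duplicate (protein, model, envelope) hit rows are
dropped with a warning. Equal-score overlap competitions resolve by
higher score, longer envelope, then smaller start. Modal-architecture ties
resolve lexicographically. An empty CheA cohort raises rather than
returning NaNs; a phosphate-sink test with zero eligible genomes reports
fraction None.

## Known limitations

* The overlap-competition rule (max total score) and the significance
  defaults are reconstructions of common practice; real survey pipelines
  may have competed hits differently.
* The operon proxy (contig + strand + rank ≤ 3) and the 100-bp contig-edge
  margin are heuristics; both are configurable.
* The rescue tier is consumed as a table; running or parsing an actual
  profile-profile search tool is out of scope, as are structure-based
  analyses, phylogenetics, and assessing whether duplicated or degenerate
  domain copies are functional.
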