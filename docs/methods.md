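# Methods

## The model

The pipeline operationalises a simple idea: a gene repeatedly implicated
in AF genetics, expressed consequentially in cardiac tissue, and
tractable to drugging, is a good candidate target — and any drug already
acting on it is a repurposing candidate whose clinical record can be
audited.

Evidence enters as *gene reports*: one observation per (study, analysis
class, gene), where the analysis class is a genetic association analysis
(GWAS on SNPs or CNVs, whole-genome sequencing, exome-wide, rare-variant,
replication) carrying a trait (AF, PR indices, LA indices), or an
expression-level analysis (TWAS, eQTL colocalization) carrying a cardiac
tissue (left atrium, right atrium, left ventricle). Reports are
harmonised in three steps:

* **Symbol resolution.** Published labels drift from approved HGNC
  symbols. Resolution proceeds exact match → registry synonym → curated
  manual map → unresolved, after normalisation (trim, case-fold, strip a
  trailing `.N` version suffix). A synonym shared by two registry entries
  is an error listing the candidates; ambiguous hits are logged and
  excluded, never guessed. Resolution is idempotent: resolving a resolved
  symbol is an exact match.
* **Variant annotation.** Variants present in the variant-to-gene (V2G)
  lookup take the V2G gene; absent variants (or variants mapped to an
  empty gene) keep the original authors' annotation, with the source
  recorded. Variant ids are opaque keys; no coordinates are parsed.
* **Collapse.** One profile per resolved gene: the set of traits with at
  least one association report, the set of tissues with at least one TWAS
  *or* eQTL report (unioned — one per tissue), a rare-variant flag, and
  per-class report counts. Exactly identical reports count once, so the
  collapse is invariant under permutation and duplication.

### Scoring

Druggability is scored in two domains. Small molecule (0–2): one point
for membership in a druggable protein family, one for a usable
structural pocket. The pocket score in [0, 1] is tiered high (≥ 0.7) and
medium (0–0.7); both tiers earn the same single point, so the
implementation awards it for any assessed score strictly above zero — an
assessed score of exactly 0 means no usable pocket, and a missing score
(no structural assessment) is distinct from 0 and earns nothing.
Antibody (0–3): one point per source (UniProt, GO, HPA) with a
high-confidence accessible localisation — plasma membrane, extracellular
matrix or secreted. Accessibility is what makes a protein tractable to
biologics, which is how the two phrasings of this criterion in the
source material are reconciled. A target is druggability-prioritised
when either domain exceeds 1.

The genetic prioritisation score (0–7) adds one point per trait with
association evidence, one per tissue with expression evidence, and one
for rare-variant support; gene priority requires a total > 1. Repeated
studies of the same trait or tissue count once. An RVAS is itself an AF
association study, so its reports could arguably feed both the trait
domain and the rare-variant domain; we count RVAS reports only in the
rare-variant domain, keeping the three domains disjoint as described.
Both > 1 cut-offs are configuration keys (default 1) for sensitivity
analyses. Ranking is by descending score with an alphabetical tie-break
on symbol (no tie-break is stated in the source; alphabetical makes the
order deterministic).

### Drug cross-referencing

Mechanism-of-action rows join targets to drugs by Ensembl id; a
mechanism naming an unknown drug id is a hard error, and targets with
zero links are reported as druggable-but-undrugged candidates. Salt and
ester formulations collapse to a parent drug by repeatedly stripping
trailing counter-ion tokens (packaged lexicon, case-folded,
user-extendable); conjugates of two active moieties (e.g. antibody-drug
conjugates) are kept unique via an explicit whitelist rather than name
parsing — the underlying distinction is pharmacological, and a token
list cannot decide it. The grouping partitions the input exactly and is
idempotent and order-invariant.

Indications arrive ontology-coded and are decoded through a flat
term → (label, specialty, secondary) mapping; DailyMed-sourced rows are
excluded (unreliable coding), and unmapped terms are retained with an
`UNMAPPED` specialty and logged. Literature queries follow the fixed
templates: a MEDLINE boolean string and a registry
(condition, intervention) pair — two query records per parent drug.

### Evidence synthesis

Per drug, the maximum level of evidence is the supremum under
Guideline > Systematic Review > RCT > Observational. The overall effect
is reconciled among items at that maximum level only — lower-level
contradictions do not dilute the verdict, matching a table that prints
one effect at one stated level. Opposing directions give Mixed; a
unanimous direction is kept; harm seen only at observational level is
downgraded to Potential Harm; guideline-listed drugs are Existing
treatments regardless of items. "Neutral (compared with another drug of
the same class)" is Neutral plus a comparator annotation, not a separate
category. Guideline membership is an input list (region-tagged), never
inferred. A drug is high-priority when any linked target has gene
priority.

### Summary structures

The indication adjacency matrix counts *drugs* (not indication rows):
entry (i, j) is the number of parent drugs indicated for both specialty
i and j, the diagonal counts drugs per specialty, so the matrix is
symmetric and every off-diagonal entry is bounded by the smaller of its
two diagonals. Categories are ordered by descending diagonal then
alphabetically. The action dendrogram nests action type → target class →
target → drug, restricted to high-priority targets; its leaf multiset
equals the filtered (drug, target, action) link multiset. The trait
partition gives mutually exclusive counts over the subsets of
{AF, PR indices, LA indices} and always sums to the number of targets
counted.

## Packaged fixtures

Two published tables are transcribed verbatim as tab-separated fixtures
with SHA-256 checksums: the 68 drug-interacting targets (symbol,
approved name, subcellular location, target class, TWAS and eQTL tissue
lists; printed dashes become empty sets) and the drug-evidence table (72
rows: targets, maximum level, overall effect, warnings, withdrawal, and
the bold high-priority flag). Reconstruction from these fixtures
reproduces level and effect for every row. The bold flags mark drugs,
while priority lives on targets; the per-target labelling is inferred as
the best-fit assignment under "bold iff any target is priority"
(majority vote plus deterministic single-flip refinement). No assignment
reproduces the printed bolding exactly — the source table bolds and
un-bolds identical target sets (e.g. two corticosteroids acting on the
same receptor disagree) — so the two residual rows are reported as a
concordance figure rather than forced.

Also packaged: the printed 31-gene blood-pressure-associated target list
(transcribed verbatim, including one printed misspelling that the manual
symbol map resolves), the printed 12-gene drug-associated-but-not-
druggable list, the 21-drug guideline list, the salt lexicon and the
conjugate whitelist.

## The synthetic world

The generator emits every input table with known ground truth: planted
priority genes (evidence summing to ≥ 2 points; all other genes capped
at ≤ 1), true trait/tissue/rare-variant assignments per gene, a known
parent-drug partition (salt forms expanded from parent stems, plus
whitelisted two-moiety conjugates), mechanisms, ontology-coded
indications and curated evidence items (at most one guideline flag per
drug). Names use a pronounceable-token scheme disjoint from real HGNC
symbols and drug names, preventing fixture collisions.

Default conditions: 150 genes across 18 studies, 25% planted priority,
70% V2G coverage, 40 parent drugs with salt multiplicity {1: 0.6,
2: 0.3, 3: 0.1} and mean 1.8 targets per drug — scaled-down but
structurally faithful to a corpus of sparse multi-study gene evidence
and many-to-many drug-target links. Real-world marginal counts (about a
thousand genes, six hundred drugs) are deliberately not matched; they
depend on external database snapshots, and no pipeline behaviour depends
on scale.

What passing recovery tests show: the pipeline's bookkeeping —
resolution, precedence, collapse, scoring arithmetic, partitioning — is
exact on inputs whose truth is known. What they do not show: robustness
to the messiness of real extractions (conflicting author annotations,
registry drift, indication coding noise), which the corrupt modes probe
only pointwise (`drop_v2g`, `scramble_symbols`, `inject_dailymed`,
`dangling_mechanism`).

Determinism: all sampling flows from one integer-seeded generator
(numpy PCG64); the same config yields a byte-identical serialised
bundle, and a pipeline rerun on identical inputs yields identical output
checksums.

## Numerical and degenerate-input choices

* Missing pocket score is an explicit `NA` sentinel in tables, never 0.
* Empty evidence-item sets give level `NONE`/effect `NONE`; empty
  indication tables give a 0-dimensional adjacency matrix; no
  high-priority links give an empty dendrogram.
* Enum cells compare case-insensitively on read and serialise canonical
  upper-case; write → read → write is byte-identical.
* Salt stripping never reduces a drug name to the empty string (a name
  that *is* a lexicon token keeps it).

## Known limitations

* Per-target trait and rare-variant evidence for the 68 fixture targets
  was published only in supplementary material, so fixture-derived
  profiles carry tissue evidence only; full prioritisation scores are
  exercised on synthetic worlds.
* The specialty coding of indications is a flat configurable mapping at
  clinical-specialty granularity; no ontology reasoning is performed.
* Literature queries are constructed, not executed; screening and
  eligibility judgement are out of scope, as are live database clients
  and the internals of V2G scoring (only its lookup-with-fallback
  contract is modelled).
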