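# Methods

## Model and assumptions

The pipeline classifies each focal-species gene by its pattern of
retention and loss across a rooted species taxonomy with designated
*focal taxonomic groups* (clades of roughly order-to-family rank). Its
core assumption is that absence of a gene from **every** species of a
focal group reflects a real loss in that group's common ancestor, whereas
absence from a subset of a group is more often an annotation or assembly
artifact; single-species absences therefore never generate loss events.
Entirely absent sibling clades are merged recursively into one loss at
their common ancestor, so the reported events are maximal fully-absent
clades and the "independently lost in ≥ 2 taxa" criterion counts
post-merge clades, not raw absent groups.

A second assumption is that ortholog groups can be delimited from gene
trees by the species-overlap rule alone: any internal node whose child
subtrees share a species is a duplication, and maximal duplication-free
subtrees are ortholog groups. This requires no duplication/loss rate
model but is sensitive to tree quality, which is why very short internal
branches (default < 0.0025 substitutions/site, strict) are collapsed
into multifurcations before annotation.

Rooting uses an age-balanced outgroup heuristic. The cited literature
names the procedure but not its algorithm, so this package fixes one
deterministically and isolates it behind a single operation
(`root_by_age_balance`): every edge of the unrooted topology is a
candidate; the candidate's outgroup side is the side without focal-species
leaves (if both or neither side carries one, both sides are scored); the
root maximises (minimum divergence rank of the outgroup side, then
smaller side, then lexicographically smallest leaf label). For
duplication-free trees the choice of root never changes the extracted
ortholog group membership — only the internal event labels — so the
heuristic's residual arbitrariness is confined to duplicated families.

## Parameters that matter

| parameter | default | unit | why |
|---|---|---|---|
| `min_branch_length` | 0.0025 | subst./site | collapse threshold for unreliable bifurcations; strict `<` |
| `min_loss_events` | 2 | clades | independence requirement for "elusive" |
| `max_duplicates` | 3 | copies | keeps elusive calls to near-single-copy families |
| `h_threshold` | 1.0 | nats | restricted (`H′ < 1`) vs ubiquitous expression |
| `atac_flank` | 2000 | bp | margin around the gene body for peak density; the source analyses do not state it, so it is config-exposed |
| `tad_containment` | true | – | a gene is "in" a TAD only if fully contained; an overlap-based mode is available |
| `significance` | 0.05 | – | q-value threshold after BH within each feature family |

Gene density is reported as genes/Mb over the window from the 3rd gene
upstream to the 3rd gene downstream (the "7-gene window"), so that
"high density" is numerically high; near chromosome ends the window
simply uses the genes that exist and divides by their actual count,
which is unbiased but gives edge genes a noisier estimate. GC content
excludes ambiguous bases from numerator and denominator. Constraint
Z-score columns are negated on ingestion so that, like every other
feature, larger values mean "more mutable / less constrained".

## Statistical machinery

The Mann–Whitney U test uses midranks and is exact — by enumeration of
all C(n₁+n₂, n₁) rank assignments — whenever n₁+n₂ ≤ 20, *including tied
data* (the enumeration over midranks remains a valid permutation test, and
degenerate inputs such as identical samples correctly give p = 1); larger
samples use the normal approximation with tie correction and continuity
correction. Fisher's exact test is two-sided by the
probability-at-most-observed rule with hypergeometric ties admitted at a
relative tolerance of 1e-7, matching the convention of the R
implementation most analyses of this kind use; the pmf vector is
normalised before summation so the all-tables case is exactly 1.
Benjamini–Hochberg is the classic step-up, applied within each declared
feature family per contrast. BH is not idempotent in general (re-applying
it can only raise q-values), so no fixed-point behaviour is assumed
anywhere.

## What the synthetic cohort emulates — and what it does not

The generator plants two gene classes. `loss_prone` mirrors the empirical
profile of elusive genes: per-branch loss probability 1 − exp(−λ) with
λ = 0.30 on every taxonomy branch off the focal lineage (branch length 1
per edge), 5% family duplication, doubled gene-tree branch lengths, GC
0.55 vs 0.42, exponential intergenic spacing 10 kb vs 30 kb, lognormal
gene length median 3 kb vs 6 kb, Dirichlet tissue-profile concentration
α = 0.05 vs 5 over 54 tissues (mean `H′` = ψ(54α+1) − ψ(α+1) ≈ 1.69 vs
≈ 3.9), 20% silent genes, lower total expression, 0.1 vs 0.4 ATAC
peaks/kb, LAD probability 0.5 vs 0.25 (odds ratio 3), TAD-boundary-rich
surroundings, and a −20 vs +8 offset on a smooth replication-timing
baseline. `conserved` has loss rate 0 and no duplications, matching the
definition of the non-elusive reference set. Losses are simulated on the
*species taxonomy*, not on gene trees, so planted truth lives exactly at
the clade level where inference operates; the emitted gene tree is the
induced taxonomy tree on surviving leaves with lognormal branch-length
noise, written in unrooted form so the rooting step does real work.
Duplications copy the whole family at its root (the second focal copy
evolves its own species complement), which exercises the duplicate
counting and subtree extraction without a full birth–death simulator.

Passing recovery tests on this cohort therefore show that the inference
chain is *self-consistent*: it recovers clade-level losses that really
happened under the generative assumptions the inference itself makes.
They do not show robustness to the failure modes of real data — wrong
gene trees, fragmentary assemblies, annotation gaps correlated with
genome quality, hidden paralogy — which the exclusion-list mechanism only
models as an oracle.

Default problem sizes (1000 genes, 15 groups × 3 species, 4 chromosomes,
~30 Mb of sequence) keep a full simulate → classify → features → compare
cycle under a minute on one CPU while leaving Monte-Carlo error far below
the planted effect sizes.

The null calibration study draws 2000 replicate null cohorts with all
class parameters equal and tests one numeric (Mann–Whitney) expression
contrast per replicate at n = 60 + 60; the rejection rate is checked
against the 99% binomial band around 0.05. Numeric contrasts are used
because the exact Fisher test on boolean features is intrinsically
conservative at these sample sizes (its discrete null rejects below the
nominal level), so pooling it would test a known property of discrete
tests rather than the calibration of the comparison machinery.

## Numerical and design choices

* All-zero TPM rows get `H′ = 0` and class *restricted* — unexpressed
  genes belong with the spatially restricted ones rather than being
  dropped.
* Branch lengths exactly at the collapse threshold are kept (`<` is
  strict); missing branch lengths are never collapsed.
* Nested TADs report the longest containing domain; mean signal is
  overlap-length-weighted; variant overlap is ≥ 1 bp intersection.
* GFF3/GTF coordinates convert to 0-based half-open on read; BED and
  bedGraph are consumed natively.
* Every generator stream derives from the single cohort seed via named
  substreams, so outputs are byte-identical across reruns and independent
  across modules.
* Ties in rooting and extraction are broken lexicographically; all stage
  outputs are sorted, making every TSV deterministic.
* Species assigned to no focal group participate only in the
  "present in all species" test; their absences can block sibling-clade
  merging but never produce a loss event of their own.

## Known limitations

* The age-balanced rooting score is a documented stand-in for an
  unpublished algorithm; on families with duplications a different root
  can split one copy's ortholog group and induce one spurious loss event.
* Gene age is a divergence *rank*, not an absolute time; an externally
  supplied older age (e.g. from a curated ortholog database) overrides it.
* The ≤ 3-duplicates rule counts focal-species copies in the whole source
  tree family, not per ortholog group.
* K_A/K_S/K_I and constraint Z-scores are ingested, never computed; the
  pipeline has no sequence-level re-validation of absences beyond the
  exclusion list.
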