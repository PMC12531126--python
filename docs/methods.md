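# Methods

`clonespread` reconstructs the spatiotemporal spread of solid tumors from
multiregional genomic data: SNP-array copy-number segments and targeted
deep-sequencing (TDS) variant calls from several samples of the primary
tumor and of each metastatic site of a patient. This note documents the
models, the estimation choices, what the synthetic cohorts do and do not
emulate, and known limitations.

## Clone-fraction model

Each sample is modeled as a mixture of normal cells and tumor subclones.
For an alteration with total copy number `Nt` in altered cells on a
background of ploidy `Np` (2 for diploid, 4 after whole-genome doubling —
always supplied by the caller, never inferred), the mean copy number is
`Np + MSF*(Nt−Np)` where MSF is the *mutated sample fraction*, so

    MSF = Np*(2^log2R − 1) / (Nt − Np).

Copy-number-neutral imbalances are invisible in log2R; the mirrored BAF of
a mixture of altered cells with allelic composition (NA, NB) inverts to

    MSF = (Np/2 − Np*mBAF) / (mBAF*(NA+NB−Np) − NB + Np/2),

which at `Np = 2` equals the familiar diploid-background form
`(1 − 2·mBAF)/(mBAF·(NA+NB−2) − NB + 1)`. The general form is used because
the copy-neutral invariant `NA + NB = Np` must also hold on genome-doubled
backgrounds. Raw fractions are clamped into [0, 1]; values outside
[−0.02, 1.05] raise a quality warning (FFPE noise).

The *mutated clone fraction* MCF = MSF/TCF rescales to the tumor-cell
compartment; alterations whose MCF falls inside the clonal interval
`(TCF ± 2·SD_MSF)/TCF` are called clonal and pinned to MCF = 1.

**Purity (TCF).** The tumor cell fraction of each sample is the mean MSF of
its clearly clonal alterations. Within the pipeline the anchor set is the
*truncal* alterations: footprints that recur in every sample of the patient
(presence calls are curated upstream, so this set is reliable); their MSF
level per sample is located with a kernel-density mode (per-measurement
bandwidths — BAF-derived values are far more precise than log2R-derived
ones and sharpen the mode). With fewer than three truncal alterations a
sample falls back to the highest substantial density mode of all its raw
MSFs. The anchor standard deviation is floored at the assumed assay noise
(`2·ln2·sd_log2R` per segment), so the clonal interval is never narrower
than the measurement permits. A per-sample `--tcf` override is available.

**Variants (Eq for VAF).** MCF is recovered from the VAF with copy-number
and purity context: `MCF = VAF*(CN1*TCF*f1 + CN2*(TCF − TCF*f2) + 2*(1 −
TCF))/(M*TCF)` with `f2 = f1` (the CNA-bearing tumor fraction), the only
reading that reduces to the textbook diploid `2*VAF/TCF`. `M` (mutated
allele copies) defaults to 1 and is raised to 2 when the raw MCF exceeds
1.1. In the pipeline the sample's clonal interval is consulted first: a raw
MCF inside it is pinned to 1 before the escalation rule is considered —
otherwise purity jitter of a few percent halves the MCF of every clonal
heterozygous variant.

## Variant filtering

Calls must pass caller-internal filters and population-database /
panel-of-normals screening (boolean input columns), then per call: tumor
VAF ≥ 0.05, normal VAF ≤ 0.05, tumor and normal depth ≥ 20, mapping
quality ≥ 50 (applied per call). Per locus: detected in ≥ 2 samples by ≥ 2
distinct callers in total, or in one sample by ≥ 2 callers; and inside the
targeted (BED) regions, with half-open BED semantics. When callers agree,
the reported VAF is the depth-weighted mean (configurable choice; the
callers' VAFs at a shared locus are estimates of the same quantity).

## Subclonal deconvolution

Quantified alterations are merged into patient-level events (same-kind
copy-number footprints with reciprocal overlap ≥ 0.9; point mutations by
exact locus). Presence of an event in a sample is treated as reliable — it
reflects review-verified segment calls — while the MCF value carries a
propagated measurement SD (slope of the inversion × assay noise / TCF;
zero for values pinned clonal).

Events are grouped into clusters sharing a cross-sample MCF profile by
agglomerative merging: a merge requires identical curated presence
patterns, co-occurrence evidence (a sample where the fractions sum above
1 + tolerance, or joint presence in ≥ 2 samples), and a normalized squared
profile distance below threshold in the mean (≤ 2) and in the single worst
sample (≤ 7). An all-SNV cluster may be absent where a partner is below
MCF 0.25, because the tumor-VAF floor makes low-fraction SNV absence
uninformative. Cluster uncertainty combines averaged measurement noise, a
shared purity-calibration floor, and the within-cluster scatter.

Clusters are then arranged into a nesting forest:

* **dominance** — a cluster can contain another only if it is present (and
  at least as frequent, within noise) wherever the other is present; the
  presence half of this test is exact and carries most of the structure;
* **pigeonhole forcing** — clusters whose fractions sum above 1 +
  tolerance in some sample must overlap, hence nest; under noise a sum is
  only trusted when one side is pinned clonal or both are precise, because
  two genuinely disjoint clusters sum to at most 1 and noise alone can
  drift them over the line;
* remaining nested-versus-disjoint ambiguities default to disjoint and are
  flagged; capacity overflows are repaired by pushing the smallest child
  under a dominating sibling, or reported when no nesting explains them;
* nodes are re-hung under the deepest dominating forced cluster (placement
  order independence) and *edge fragments* — a child whose profile matches
  its parent except in one noisy sample (for siblings: one sample where
  one side is pinned clonal and the other noisy) — are re-absorbed; a
  measurement outlier on a single segment otherwise splits an edge in two.

Subclone fractions are the node-minus-children residuals; residuals within
2.5 propagated SDs are zeroed (they are noise, not detections), and a
sample whose fractions total above 1 is rescaled onto the simplex. An
event is "present" in a sample at MCF ≥ 0.05 (detection threshold), the
clustering tolerance is 0.1; both are configurable and deliberately
generous for FFPE SNP-array data.

## Phylogeny

The binary subclone × event matrix is analyzed under unordered binary
Fitch parsimony with an all-zero normal outgroup at the root. Search is
exact (branch-and-bound over rooted topologies, with the score's
monotonicity under leaf insertion as the bound) up to 9 subclones and
seeded stepwise addition + NNI hill climbing beyond. Equally parsimonious
trees are broken deterministically: fewer internal nodes after collapsing
zero-length edges, then lexicographic order of the sorted leaf partitions.
Character states are backtraced top-down preferring the parental state
(ties toward presence), events map to the edges where their state changes,
and zero-length edges collapse so ancestral subclones sit at internal
nodes. Output is Newick (edge lengths = event counts) plus an edge table.

## Spread classification

With per-node sample/site detections (subclone fraction ≥ 0.05 in a
sample of the site):

* the **primary MRCA** is the deepest node ancestral to every subclone
  detected in a primary sample;
* a seeding lineage is **earlier** iff its divergence from the
  primary-detected lineage set — the deepest ancestor-or-self of the
  lineage root that leads to a primary-detected subclone — is a *strict*
  ancestor of the primary MRCA (attachment exactly at the MRCA counts as
  later);
* **lineages** per site are the maximal site-detected subtrees; one
  lineage = monoclonal, several = polyclonal;
* the patient is **monophyletic** iff all lineage attachments lie on one
  root-to-leaf path;
* an **intermetastatic** edge A→B needs a subclone detected at A, never in
  a primary sample, absent from B, with a strict descendant detected at B;
  a shared non-primary subclone without such a private ancestor yields an
  unresolved link reported in both orientations. Relapse samples count as
  metastatic sites only when anatomically distinct from the primary.

The index of genomic diversity of a node set is IGD = Σd/(Σd + l·N) with d
the event-count distances from the set's closest common node, l the stem
length and N the set size. Cohort statistics use the two-sided
Mann–Whitney U test (independent comparisons, e.g. alteration burden by
sample class) and the paired t test (per-patient IGD, primary versus
distant), significance at p < 0.05.

## Synthetic cohorts

The generator forward-models the entire chain. Defaults (the study
conditions of the validation suite): 2–4 primary subclones below the
primary root, 2–4 events per branch and 5–10 truncal events, 70% CNAs
(gains/losses/CNNIs 45/35/20) with footprints of 1–30 Mb placed without
overlap on hg38 autosomes, TDS (SNVs on a 150-region synthetic panel) in
half the patients, TCF uniform on (0.5, 0.9), depth 1000×, log2R SD 0.1,
mBAF SD 0.01, spread-mode frequencies echoing a relapsing pediatric
cohort (earlier 0.6, polyclonal 0.45, polyphyletic 0.45, intermetastatic
0.8 given ≥ 2 metastatic sites, relapse sampling 0.15).

Site colonization realizes the requested modes constructively (an earlier
lineage attaches above the primary root, polyclonal sites receive two
incomparable lineages, intermetastatic chains place a site-private clone
whose descendant seeds a second site); ground-truth labels are then read
off the noise-free truth tree by the spread classifier itself, so labels
are consistent with the tree by construction. Multiregion sampling is
emulated by making every clone the regionally dominant population
(fraction ≈ 0.6) of one sample from a site carrying it, with up to two
minor clones ≥ 0.12 per sample; this mirrors the spatial clustering of
clones in real multiregion sections and is also what renders the mixtures
identifiable. Segment rows are emitted only where an alteration is truly
present (≥ 0.05), matching review-verified absence calls; noise perturbs
values, not presence. Sequencing artifacts (single-caller singletons and
sub-threshold VAFs) are injected and must be removed by the filters.

What the generator does **not** emulate: FFPE deamination artifact
spectra, subclonal copy-number *within* an alteration (each event has one
integer state), overlapping CNAs at one locus, horizontal plasticity of
footprint boundaries between samples, and germline contamination beyond a
constant normal-VAF of zero. Passing label-recovery tests therefore shows
the inference is sound under the stated measurement model, not that every
real FFPE cohort will reach the same accuracy.

## Numerical choices and degenerate inputs

Tie-breaks are deterministic everywhere (genomic order of events,
lexicographic subclone ids, seeded RNG in the heuristic search); two runs
on the same input are byte-identical. Negative MSFs clamp to 0 with a QC
warning. A zero denominator in the mBAF inversion (balanced composition)
raises a degenerate-composition error. IGD with zero stem and zero
divergence returns 0 with a QC flag. Patients failing deconvolution are
flagged not-evaluable; cohort runs continue.

## Validation results and limitations

On noise-free cohorts the pipeline recovers subclone event sets, event
matrices and all four spread labels exactly (100/100 patients), and
conservation — each event's MCF equals the summed fractions of the
subclones carrying it — holds to numerical precision. At the validation
noise (1000× depth, log2R SD 0.1) per-label accuracy is ≈ 90–97% across
seeds (earlier ≈ 92%, polyclonal ≈ 94%, polyphyletic ≈ 97%,
intermetastatic ≈ 90% over 600 simulated patients).

Per-pair conservation under that noise is *not* attainable: a single
segment's MCF measurement error is ≈ ±0.27 at 2 SD, wider than the ±0.2
conservation band, so no mixture assignment can reproduce every individual
measurement within the band (the median gap is ≈ 0.05; ≈ 65% of
event-sample pairs fall inside the band at full noise, ≈ 94% at a nominal
segment-level noise of log2R SD 0.03). A related corner: an all-SNV branch
at clone fraction f in a sample with purity t is invisible there whenever
f·t/2 < 0.05 (the tumor-VAF floor), which can leave a small residual
fraction on the parent clone even in noise-free data.

Validation problem sizes (50–100 patients per check, ≤ 7 subclones for
exhaustive-enumeration comparisons, 100 random matrices) keep the full
suite in a few minutes on one core while covering every tree shape the
generator produces.
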