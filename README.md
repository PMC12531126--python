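# clonespread

Tracing metastatic spread in solid tumors from multiregional copy-number
and targeted deep-sequencing data.

Pediatric solid tumors (neuroblastoma, Wilms tumor, gonadal tumors) are
routinely archived as FFPE blocks from several regions of the primary
tumor and of each metastasis. `clonespread` turns such multiregional data —
SNP-array copy-number segments (log2R, mirrored BAF, allelic composition)
and multi-caller targeted-sequencing variant tables — into a per-patient
reconstruction of *when and how* the metastases were seeded. It is aimed
at cancer-genomics analysts who have per-sample segment and variant calls
and want subclone trees and spread-mode calls without whole-genome
sequencing.

The pipeline:

1. **Clone fractions.** Each alteration's mutated sample fraction is
   inverted from its measurement — `MSF = Np(2^log2R − 1)/(Nt − Np)` for
   copy-number changes, `MSF = (Np/2 − Np·mBAF)/(mBAF(NA+NB−Np) − NB +
   Np/2)` for allelic imbalances, and a copy-number/purity-aware VAF model
   for point mutations — then rescaled by the tumor cell fraction (TCF,
   estimated from the clearly clonal, truncal alterations) to the mutated
   clone fraction MCF = MSF/TCF. Alterations with MCF inside
   `(TCF ± 2·SD_MSF)/TCF` are clonal (MCF := 1).
2. **Variant filtering.** Per call: tumor VAF ≥ 0.05, normal VAF ≤ 0.05,
   depth ≥ 20 in both, mapping quality ≥ 50; per locus: support from ≥ 2
   callers (in one sample) or ≥ 2 samples and ≥ 2 callers in total, inside
   the targeted regions.
3. **Subclonal deconvolution.** Alterations are merged into patient-level
   events; events sharing a cross-sample MCF profile form clusters, and
   clusters nest by dominance and the pigeonhole principle (fractions
   summing above 1 must overlap), yielding subclones with per-sample
   fractions and a binary subclone × event matrix.
4. **Phylogeny.** A rooted maximum-parsimony tree (unordered binary Fitch,
   normal all-zero root; exact search up to 9 subclones) with events
   mapped to edges; the stem carries the truncal events.
5. **Spread modes.** Per metastatic site: *earlier/later* seeding
   (divergence above/below the primary tumor's MRCA), *mono/polyclonal*
   (number of independent seeding lineages); per patient:
   *mono/polyphyletic* and *intermetastatic* edges (site-private subclones
   with descendants at another site); plus the index of genomic diversity
   IGD = Σd/(Σd + l·N) and cohort-level tests (Mann–Whitney U, paired t).

A synthetic-cohort generator (`clonespread.simulate`) forward-models the
entire measurement chain with known ground truth, so every stage is
testable end to end without any external data. See `docs/methods.md` for
the models, estimation details and limitations.

## Worked example

```python
import clonespread as cs

cfg = cs.SimulationConfig(seed=11, n_patients=2, depth=None,
                          log2r_sd=0.0, baf_sd=0.0)   # noise-free cohort
cohort = cs.simulate_cohort(cfg)
patient = cohort.patients[0]

result = cs.analyze_patient(patient.patient_id, patient.segments,
                            patient.variants, cohort.bed, patient.metadata,
                            cs.PipelineConfig())
print("tree:", result.tree.newick())
report = result.report
for site, call in report.sites.items():
    print(f"{site}: {call.timing}, {call.clonality} ({call.n_seeding_lineages} lineage(s))")
print("phyletic pattern:", report.phyletic)
print("intermetastatic edges:",
      [(a, b, "resolved" if r else "unresolved")
       for a, b, m, r in report.intermetastatic_edges])
print("IGD by class:", {k.split(':')[1]: round(v, 3)
                        for k, v in report.igd.items() if k.startswith('class')})
```

prints

```
tree: ((SC3:4,(((SC6:2)SC5:2)SC4:4)SC2:3)SC1:5)normal:0;
M1: later, polyclonal (2 lineage(s))
M2: later, monoclonal (1 lineage(s))
phyletic pattern: polyphyletic
intermetastatic edges: [('M1', 'M2', 'resolved')]
IGD by class: {'primary': 0.4, 'lymph_node': 0.0, 'distant': 0.565}
```

Reading: the tumor MRCA (`SC1`, stem of 5 truncal events) spawned a primary
lineage (`SC2 → SC4 → SC5 → SC6`) and a separate branch (`SC3`). Site M1
was colonized by two independent lineages after the primary MRCA emerged
(later, polyclonal spread from two branches — polyphyletic), and a subclone
private to M1 left a descendant at M2: directed intermetastatic spread
M1 → M2. The distant site's low IGD (0, one clone) against the primary's
0.4 reflects the tighter bottleneck of distant colonization.

The same analysis runs from files via the CLI:

```
clonespread simulate --outdir sim --seed 11 --n-patients 3 --depth 0 --log2r-sd 0 --baf-sd 0
clonespread run --segments sim/segments.tsv --metadata sim/metadata.tsv \
    --variants sim/variants.tsv --bed sim/panel.bed --outdir results
```

which writes, per patient, the quantified segment file, event matrix,
subclone fractions, Newick tree, edge table and spread report, plus the
cohort grid (spread modes × patients), IGD table and statistics. The
stages are also available individually (`quantify`, `filter-variants`,
`deconvolve`, `tree`, `classify`, `report`).

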