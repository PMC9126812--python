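# corticell

Cell-type-patterned analysis of cortical thickness (CTh) heterogeneity.

Brain-morphometry studies of schizophrenia report thinner cortex on
average, but the *regional pattern* of thinning differs markedly between
individuals. `corticell` implements a multi-scale pipeline that asks
whether this heterogeneity is organized by neural cell types, linking
three levels of data for the 34 left-hemisphere Desikan–Killiany regions:

1. **Normative charts** — per region, quantile regression of CTh on age
   and sex in healthy subjects at τ = 0.05, 0.50, 0.95. Each subject is
   scored with a continuous deviation
   `Δz = (CTh − q̂₀.₅(age, sex)) / σ̂`, and categorized infra-/supra-normal
   against the 5%–95% band.
2. **Cell-type transcriptional maps** — region-wise mean expression of
   seven marker gene sets (astrocyte, endothelial, microglia, OPC,
   excitatory, inhibitory, oligodendrocyte), z-scored across regions.
3. **Spatial coupling** — per patient, Pearson correlation of the
   34-region deviation profile with each cell-type map; the distribution
   of coupling coefficients over patients is compared against a
   permutation null (region labels shuffled, 1000 iterations) with the
   Ansari–Bradley rank test of dispersion and Benjamini–Hochberg control
   across the seven cell types.
4. **Subtyping** — PCA (4 components) of the patient × cell-type coupling
   matrix, Ward's linkage, cluster count selected by the gap statistic
   (k = 1..7, uniform reference, one-SE rule), plus continuous
   inverse-distance soft memberships.
5. **Polygenic validation** — polygenic scores restricted to SNPs in (or
   within a genic boundary of) each cell type's marker genes; per subtype,
   partial correlation between the matched cell-set score and whole-brain
   mean Δz, controlling sex, the genome-wide score, and familial
   relatedness.

Real imaging, expression, and genotype cohorts for this design are
access-restricted, so the package ships a first-class synthetic-data
generator (`corticell.simulate`) that plants known structure at every
level — subtype-patterned deviations, marker-structured expression, and a
genetic burden that scales deviation severity — together with a
`TruthRecord` for parameter-recovery testing.

## Worked example

```sh
corticell simulate --n-healthy 2000 --n-patient 200 --seed 0 --out data/
corticell run-all --config run.yaml --out results/
```

with `run.yaml` pointing at the files written into `data/` (defaults match
the generator's file names, so `cohort_path: data/cohort.tsv` etc. plus
`seed: 0` suffice). The same analysis from Python:

```python
from corticell import *
from corticell.simulate import SimConfig, gen_fixture_bundle

bundle = gen_fixture_bundle(SimConfig(seed=0))
model  = fit_normative_model(bundle.healthy)            # 34 quantile charts
dev    = deviation_scores(model, bundle.patients)       # patient x region Δz
cmap   = build_cell_map(bundle.expression, bundle.gene_sets)
C      = compute_coupling(dev.delta_z, cmap)            # 200 x 7 coupling
disp   = dispersion_test(C, dev.delta_z, cmap, n_perm=1000, seed=11)
sol    = solve_subtypes(C, seed=7)

print(coverage(model, bundle.healthy).min())  # 0.898
print(disp.significant_cell_types)
# ['astrocyte', 'endothelial', 'OPC', 'excitatory', 'inhibitory']
print(sol.chosen_k)                           # 3
```

Reading the numbers: 89.8% of healthy subjects fall inside their own
5%–95% normative band in the least-covered region (the in-sample quantile
property pins this at ~90%); the dispersion test flags exactly the five
cell types whose maps carry planted coupling, leaving microglia and
oligodendrocytes null; and the gap statistic recovers the three planted
patient subtypes. `validate_subtypes` then yields negative partial
correlations (≈ −0.3 to −0.5 on the default study) between each subtype's
cell-set polygenic score and whole-brain deviation severity in that
subtype's members.

## Layout

| module | contents |
| --- | --- |
| `corticell.simulate` | synthetic cohorts, expression, genotypes, truth |
| `corticell.io` / `containers` / `config` | TSV/GMT/JSON formats, typed tables, run configuration |
| `corticell.normative` | quantile fits, deviation scores, coverage, bootstrap bands |
| `corticell.cellmaps` | cell-type maps, mean-CTh association |
| `corticell.coupling` | coupling matrix, permutation null, Ansari–Bradley |
| `corticell.subtypes` | PCA, Ward, gap statistic, memberships, profiles |
| `corticell.genetics` | cell-set PRS, partial correlation, validation |
| `corticell.pipeline` / `cli` | orchestration and the `corticell` command |

See `docs/methods.md` for the statistical model, generator assumptions,
and design choices.
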