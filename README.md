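# tetracolour

Tetrahedral colour-space modelling of reflectance spectra for
tetrachromatic (avian) vision, plus a phylogenetic test of convergent
evolution into regions of that colour space.

The pipeline:

1. **spectra** — read wide-CSV reflectance spectra (300–700 nm), average
   replicates, smooth (degree-2 local regression), remove negative values,
   resample to a fixed 1-nm grid.
2. **visual** — von Kries-adapted quantum catches of four receptor classes
   (packaged violet-sensitive *VS* and ultraviolet-sensitive *UVS* systems,
   or custom CSV curves), embedded barycentrically as a colour locus in a
   regular tetrahedron (centroid at origin, long-wavelength vertex on +x).
3. **geometry** — convex-hull morphospace occupancy, exact/Monte-Carlo hull
   overlap, and minimum-volume enclosing ellipsoids (Khachiyan ascent with
   away steps) used as convergence target regions.
4. **phylo** — Newick/Nexus trees (polytomies welcome), maximum-likelihood
   ancestral state reconstruction under Brownian motion (sparse harmonic
   solve, equivalent to dense GLS), evolutionary rate matrices from
   standardized independent contrasts, and multivariate BM simulation.
5. **convergence** — the convergence index (branches whose parent state is
   outside a target region and child state inside), its simulation-based
   null distribution with add-one p-values, and Holm sequential-Bonferroni
   correction.
6. **synthetic** — seeded toy visual systems, spectra, Yule trees and
   planted-convergence datasets used as positive/negative controls.

## CLI

```sh
# synthetic fixture set (spectra, sensitivities, tree, loci, target region)
tetracolour simulate --seed 7 --n-species 50 --out-dir fixtures/

# spectra -> colour loci (or pass precomputed loci through --loci)
tetracolour loci --spectra fixtures/spectra.csv --visual-system VS \
    --species-table species.csv --out loci.csv

# hull volumes, % of tetrahedron, group overlaps
tetracolour occupancy --loci loci.csv --out occupancy.csv

# convergence counts + BM null + Holm correction (CSV + JSON sidecar)
tetracolour convergence --loci loci.csv --tree fixtures/tree.nwk \
    --n-sim 999 --seed 1 --out convergence.csv
```

Options can also come from a YAML config (`--config run.yaml`); explicit
flags win. Reports are byte-identical across reruns with the same config
and seed.

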