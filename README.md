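# vesselfc — automatic 3D liver-vessel segmentation from CT

`vesselfc` segments the hepatic vasculature in contrast-enhanced CT volumes,
given the CT image and a binary liver mask. It is aimed at treatment-planning
pipelines (resection, ablation, navigation) where the vessel tree must be
extracted automatically, without user-placed seeds, including on low-contrast
scans.

## Method

The pipeline combines an improved multiscale Hessian vesselness filter with a
single-seed fuzzy-connectedness (FC) segmentation whose affinity operates on
the vesselness image instead of the raw intensities:

1. **Liver VOI.** The CT volume is restricted to the liver mask; outside
   voxels are filled with the minimum in-mask intensity.
2. **Adaptive sigmoid contrast enhancement.** In-mask intensities are
   clustered into K = 5 regions by K-means (background, tumor, parenchyma,
   low-intensity vessel mixed with parenchyma, high-intensity vessel). With
   m₁, m₂ the two brightest cluster means, the window
   α = (m₂ − m₁)/2, β = (m₂ + m₁)/2 defines
   I' = 1 / (1 + exp(−(I − β)/α)), mapping vessels toward 1.
3. **Isotropic resampling** to the smallest in-plane spacing (linear for the
   image, nearest-neighbour for masks).
4. **Improved vesselness.** At each scale σ the sign-flipped, σ²-normalized
   Hessian eigenvalues |λ₁| ≤ |λ₂| ≤ |λ₃| are computed; λ₃ is
   piecewise-compensated with threshold τ (default 0.6) against its volume
   maximum, giving λ_ρ. The response is 0 where λ₂ ≤ 0 or λ_ρ ≤ 0, 1 where
   λ₂ ≥ λ_ρ/2 > 0, and otherwise
   λ₂²(λ_ρ − λ₂)[3/(λ₂ + λ_ρ)]³ · (1 − exp(−R_s²/2γ)) with
   R_s² = λ₁² + λ₂² + λ_ρ² and γ = λ_ρ/3 — the last factor suppresses
   low-magnitude background responses. Responses are combined across scales
   by the voxelwise supremum.
5. **Fuzzy connectedness.** Two-threshold Otsu on the vesselness sample
   initializes the affinity statistics (m, s); the single seed is picked
   automatically as the 5×5×3-block maximum whose surrounding block mean is
   largest. The affinity of a 6-adjacent pair combines an object term
   h₁ = exp(−½[((f(c)+f(d))/2 − m)/s]²) and a homogeneity term
   h₂ = exp(−½[(|f(c)−f(d)| − m)/s]²) with pair-adaptive weights
   ω₁ = h₁/(h₁+h₂). The fuzzy scene — each voxel's maximin path strength to
   the seed — is computed by best-first max-heap propagation and binarized
   at T (default 0.05), then resampled back to the input grid.

A synthetic phantom generator (bifurcating vascular trees inside a
liver-like ellipsoid, CE-CT-like intensity levels, additive Gaussian white
noise with σ² ∈ {0, 30, 45, 60}) provides paired gold standards so the whole
pipeline is testable without any data download. Evaluation reports voxelwise
accuracy, sensitivity, specificity, and Dice = 2TP/(2TP+FN+FP).

## Worked example

```sh
vesselfc phantom --output-prefix ph --noise-variance 30 --seed 2
# phantom written with prefix ph (15 bifurcations)

vesselfc segment --input ph_image.nii.gz --liver-mask ph_liver.nii.gz \
                 --output vessel.nii.gz --report report.json
# vessel mask written to vessel.nii.gz (1410 voxels)

vesselfc evaluate --pred vessel.nii.gz --gold ph_gold.nii.gz --region ph_liver.nii.gz
# accuracy: 0.9944
# sensitivity: 0.6107
# specificity: 0.9992
# dice: 0.7295
```

The phantom is a 96×96×48 voxel, 1 mm isotropic volume holding a
15-bifurcation vessel tree (root radius 3 mm) at 160 HU inside an 80 HU
liver ellipsoid, with σ² = 30 Gaussian noise added. The segmentation
recovers the tree with Dice 0.73 against the gold mask; specificity is
evaluated inside the liver only, so the 0.999 means almost no parenchyma is
mislabelled as vessel. `report.json` records every stage's parameters
(cluster means, sigmoid window, Otsu thresholds, affinity statistics, seed
location), which fully determine a re-run.

The same pipeline is callable as a library:

```python
import vesselfc as v

image, gold, liver = v.generate_phantom(v.VesselPhantomSpec(noise_variance=30))
mask, report = v.run_pipeline(v.PipelineConfig(), image, liver)
print(v.evaluate(mask, gold, region=liver))
```

`vesselfc sweep --parameter T --values 0.01,...,0.09` scores a range of the
scene threshold T (or of the compensation threshold τ) against a gold mask
and writes a CSV table.

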