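# pollenoptics

Analysis pipeline for multi-angle elastic light-scattering pollen counters —
the class of low-cost airflow cytometers being deployed as real-time
alternatives to manual Hirst-trap pollen monitoring.

The instrument records, every 10 s, particle counts over 19
scattered-intensity bins on four photodiodes (15°, 60°, 125°, 160°). The
near-forward channel sizes particles through a power law `F = a·d^b` over
5–100 µm; the three side/back channels respond to shape, surface and
absorbance. From those frames the package:

1. **sizes** particles and filters contaminated frames with a tuned Local
   Outlier Factor filter;
2. **oversamples** inlier frames into cumulative size distributions (≥ 20
   particles per occupied bin, 30 per species), checks clusterability with
   the Hopkins statistic, and groups species by **complete-linkage
   hierarchical clustering** (cluster count by a ten-index validity vote);
3. computes **speciation indices**: for particles counted at intensity `F1`
   on channel 1, solve `dN/dF1(F1) = dN/dFc(Fc)` and report `S_c = F1/Fc`
   (c = 2, 3, 4); the six-element **optical signature**
   `(S2, S3, S4, S2/S3, S2/S4, S3/S4)` is the classifier feature vector —
   for a channel seeing a pure gain g of channel 1, `S_c = 1/g`, so
   transparent droplets, absorbing soot, minerals and semi-transparent
   pollen separate;
4. **classifies** species within each size cluster by one-vs-one logistic
   regression with per-pair F1-optimized decision thresholds, evaluated by
   repeated stratified 10-fold cross-validation (per-class recall +
   confusion matrices).

Laboratory data for such instruments is rarely public, so a first-class
synthetic module (`pollenoptics.simulate`) generates measurement sessions
with ground truth: 12 pollen taxa at their supplier diameters (13–48 µm),
plus droplet, carbonaceous and two mineral-dust classes, with lognormal
grain sizes, Poisson counting, per-class channel-gain triples, optical
sizing dispersion, and ambient/aggregate/debris contamination. See
`docs/methods.md` for the model and every numerical choice.

## Worked example

```python
from pollenoptics.pipeline import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(k=3), seed=1, out_dir="out")
print("hopkins", round(result.hopkins, 3))
print(result.species_clusters)
for cid, report in sorted(result.reports.items()):
    print("cluster", cid, "mean recall", round(report.recall.mean(), 3))
```

This simulates one 179–299-frame session per species (12 pollens + 4
non-pollen classes), LOF-filters each, builds the 360 × 19 cumulative
dataset, clusters it, speciates, and cross-validates the per-cluster
classifiers (a few minutes on one core). Output for seed 1:

```
hopkins 0.965
{'Alnus glutinosa': 3, 'Anthoxanthum odoratum': 2, 'Ambrosia artemisiifolia': 3,
 'Betula pendula': 3, 'Corylus avellana': 3, 'Cupressus sempervirens': 3,
 'Festuca pratensis': 2, 'Fraxinus excelsior': 3, 'Olea euopaea': 3,
 'Parietaria officinalis': 1, 'Platanus acerifolia': 3, 'Quercus robur': 2}
cluster 1 mean recall 0.973
cluster 2 mean recall 0.994
cluster 3 mean recall 0.988
```

Hopkins 0.965 says the normalized cumulative size distributions are strongly
clusterable (0.5 would be spatial randomness). The three clusters order the
species by diameter — wall pellitory (14 µm) alone in the small cluster, the
grasses and oak in the large one — and within each cluster the one-vs-one
classifier recovers every class with recall ≥ 0.94, including the non-pollen
aerosols. `out/` holds the frame tables, cumulative dataset, cluster
assignments, signature table, per-cluster confusion matrices and a manifest
recording the seed and configuration hash.

The same stages are exposed as a CLI:

```bash
pollenoptics simulate --species "Olea euopaea" --frames 240 --seed 1 --out sessions/
pollenoptics size-cluster --sessions sessions/ --k auto --seed 1 --out sizing/
pollenoptics speciate --sessions sessions/ --out signatures.csv
pollenoptics run-all --seed 1 --out out/
```

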