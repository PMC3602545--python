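# slfcmap

Voxel-wise cerebral-blood-flow (CBF) activation mapping, seed-based
functional connectivity, and **structurally linked functional connectivity
(SLFC)** for small-animal autoradiographic brain volumes — with a synthetic
cohort generator so every stage of the analysis is testable end to end
without any imaging data on disk.

## Who this is for

Chronic psychological stress changes how the medial prefrontal cortex
modulates visceral pain circuits. A classic rodent design probes this with
a 2×2 cohort — treatment (water-avoidance stress, WAS, vs sham) crossed
with noxious colorectal distension (CRD, 60 vs 0 mmHg) — measuring regional
CBF via perfusion-tracer autoradiography: serial coronal sections are
digitized to optical density (OD), reconstructed into per-animal 3D
volumes, and analyzed voxel-by-voxel. `slfcmap` re-implements that analysis
chain as a tested, reusable Python library:

- **`emg_vmr`** (`slfcmap.emg`) — visceromotor response to CRD from
  abdominal EMG: 20-Hz high-pass ("lowcut") filter, full-wave
  rectification, 20-s epoch AUC normalized by the preceding 20-s baseline,
  percent of the day-0 60-mmHg control.
- **`volume_pipeline`** (`slfcmap.volume`) — sequential rigid
  slice-to-slice registration and 3D reconstruction (nearest-neighbour
  resampling), 12-parameter affine normalization to a reference, template
  averaging, in-plane Gaussian smoothing (FWHM = 3 × the 40-µm in-plane
  voxel), and the 70 %-of-mean intensity mask.
- **`stats_mapping`** (`slfcmap.mapping`) — per-treatment 60-vs-0-mmHg
  pooled-variance t contrasts, the WAS × CRD factorial interaction, cluster
  thresholding at voxel p < .05 with a 100-voxel extent criterion (scaled
  to small grids), seed-ROI extraction and across-animal seed-correlation
  maps.
- **`connectome`** — collated structural-connectivity (SC) reports with
  qualitative strengths on a 1–7 scale (1 = very strong … 7 = very weak),
  filtered by the standard rules: drop 'very weak', 'fibers of passage',
  and contralateral reports; aggregate the rest into a directed graph.
- **`slfc`** — the core construct: intersect the seed's functional
  connectivity with its structural neighbourhood. Each surviving edge
  inherits *direction* from SC and *sign* from FC, labelled with motifs
  such as `PrL[-]←La` (negative FC over an afferent projection from the
  lateral amygdaloid nucleus).
- **`synthetic_data`** (`slfcmap.synthetic`) — cohorts with planted ground
  truth: regional group effects, a latent-variable seed-coupling model that
  makes planted FC signs exact in expectation, SC tables with planted
  edges, and EMG traces with distension bursts.

## The statistics in brief

At each voxel v inside the intensity mask, the CRD contrast is the pooled
two-sample t

    t(v) = (x̄_60(v) − x̄_0(v)) / √(s_p²(v) (1/n_60 + 1/n_0)),   df = n_60 + n_0 − 2

and the WAS × CRD interaction is the cell-means contrast
(WAS60 − WAS0) − (sham60 − sham0) over its pooled-variance standard error
(df = N − 4). Seed FC is the across-animal Pearson correlation r(v)
between voxel OD and the mean OD of the seed ROI (the PrL atlas region ∩
its CRD activation cluster), converted to t with n − 2 df. Suprathreshold
voxels (one-sided p < .05 per direction) form signed 6-connected clusters;
clusters below the extent threshold are discarded. SLFC keeps only
functionally connected regions with a direct structural projection to or
from the seed.

## Worked example

The demonstration workflow plants the key phenomenon — negative
seed–amygdala coupling under sham that disappears under chronic stress —
and recovers it through the full pipeline:

```python
from slfcmap import RunConfig, run_demo, motif_label

report = run_demo(RunConfig(rng_seed=0))
print([motif_label(e) for e in report.slfc_results["sham"].edges])
print(report.changes.to_string(index=False))
```

prints

```
['PrL[-]←La']
partner change  sign_a  sign_b   motif_a    motif_b
    CA1 gained       0       1           PrL[+]←CA1
     La   lost      -1       0 PrL[-]←La
```

Under sham, the seed (PrL) shows negative FC with the amygdala analog (La)
over its afferent structural projection — motif `PrL[-]←La`. Under WAS
that edge is reported `lost`, reproducing the planted stress-induced loss
of prefrontal–amygdala coupling. (`CA1 gained` is a single
false-positive edge of the kind the n = 10 design admits at these
thresholds.) The same workflow is available from the shell:

```bash
slfcmap demo --out out/ --seed 0
```

All written artifacts carry the configuration hash and RNG seed; re-running
with the same seed reproduces them byte for byte.

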