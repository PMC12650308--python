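# strokemap

Spatiotemporal metabolic mapping of cerebral ischemia–reperfusion from
microdialysis time courses and mass-spectrometry-imaging pixel grids.

During a transient middle-cerebral-artery occlusion (MCAO/R) experiment,
microdialysis probes sample brain interstitial fluid every 15 minutes across
five operational phases — probe implantation (I), occlusion surgery (II),
early and late ischemia (IIIA/IIIB), and reperfusion (IV) — giving every
metabolite feature a 21-point trajectory per subject.  `strokemap` implements
the analysis chain that turns those trajectories into interpretable kinetic
labels, and the companion spatial chain that segments imaging grids and
scores lesion-vs-contralateral differences.  It is aimed at analysts working
with time-resolved metabolomics of acute injury models who need the pipeline
to be reproducible and testable without animal data: a bundled synthetic
generator emulates the full 5-subject × 21-collection design with planted
ground truth.

## The model

Preprocessed, z-scored trajectories $x_i$ are soft-clustered by fuzzy
c-means.  Membership of feature $i$ in cluster $k$ with centroids $v_k$ and
fuzzifier $m > 1$ is

$$u_{ik} = \left[ \sum_{j=1}^{c} \left( \frac{\lVert x_i - v_k \rVert}{\lVert x_i - v_j \rVert} \right)^{2/(m-1)} \right]^{-1},
\qquad v_k = \frac{\sum_i u_{ik}^m x_i}{\sum_i u_{ik}^m},$$

iterated to convergence; rows of $U$ sum to 1.  The cluster count $c$ and
fuzzifier $m$ are chosen by minimizing the Xie–Beni validity index

$$\mathrm{XB} = \frac{\sum_{i=1}^{n}\sum_{k=1}^{c} u_{ik}^m \lVert x_i - v_k \rVert^2}{n \cdot \min_{k \neq l} \lVert v_k - v_l \rVert^2},$$

the ratio of fuzzy within-cluster compactness to minimum squared centroid
separation (lower is better).

Because soft clustering concentrates membership mass in a few dominant
clusters (typically global monotone or fluctuating shapes), features with
distinctive transient dynamics get masked — the *drowning effect*.  The
correction takes each feature's **primary characteristic** to be its
highest-membership cluster *outside* the dominant set, and selects features
whose non-dominant membership strictly exceeds 0.5.  Each trajectory is then
summarized by its **SD Energy** (standard deviation across collections, a
global fluctuation magnitude) and its **key-time fold change**
(mean over the signature phase ÷ mean over the phase-I baseline).

The spatial chain bins per-pixel peaks into ±0.180 Da consensus windows
(keeping each pixel's maximum-intensity peak per window and discarding bins
detected in < 3.84 % of pixels), normalizes pixels to unit RMS, segments
them by Ward-linkage agglomeration on cosine distances, and flags bins with
$|\log_2 \mathrm{FC}| > 1$ between regions of interest.  Pathway
over-representation uses a one-sided Fisher's exact test at p < 0.01.

## Worked example

The numbered scripts under `analysis/` run the full story on synthetic data
(a 1,600-feature demonstration of the 10,529-feature design, with a planted
ten-fold reperfusion urea-like surge and a six-fold ischemic
citrulline-like plateau):

```
$ python analysis/01_simulate.py
schedule: 21 collections/subject x 5 subjects = 105 samples
temporal table: 1600 features x 105 samples (4.8% missing)
pixel grid: 40x40, 285 peaks, 21 up / 29 down planted in lesion

$ python analysis/02_preprocess.py
filter >500 counts: 1599 retained, 1 dropped
gap fill: 7995 cells imputed at half-minimum

$ python analysis/03_cluster.py
Xie-Beni fuzzifier selection at c = 16: m* = 1.1
fit: 209 iterations, converged=True, XB = 2.4689

$ python analysis/04_label.py
dominant clusters (top-4 membership mass): ['L', 'N', 'O', 'P']
1000 features selected (non-dominant membership > 0.5); 590 rescued from
dominant clusters by the correction

$ python analysis/05_phase_stats.py
F001590: planted IV fold change 10 -> recovered 10.40 (SD Energy 31092.7)
F001591: planted IIIA-IIIB fold change 6 -> recovered 5.10 (SD Energy 6573.1)

$ python analysis/06_spatial.py
peak binning: 285 bins retained from 456000 pixel peaks
differential: 50 features at |log2FC| > 1 (21 up, 29 down in the lesion)

$ python analysis/07_enrich.py
1 pathway(s) pass Fisher p < 0.01
```

The dominant set contains the global monotone/fluctuating clusters, so the
correction rescues 590 features whose transient phase-locked dynamics would
otherwise be hidden; the planted fold-change events come back at 10.4 and
5.1 against true values of 10 and 6.  The same stages are available as a
CLI (`strokemap simulate|preprocess|cluster|label|stats|spatial|enrich|run-all`)
and as library calls (`strokemap.fcm`, `strokemap.labeling`, …).

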