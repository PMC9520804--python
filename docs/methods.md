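# Methods

This note documents the generative model, the measurement chain, the
statistical procedures, and the design decisions behind `telo3d`, including
what the synthetic data do and do not establish about real microscopy.

## The generative model

Each synthetic nucleus is an ellipsoid (semi-axes a ≥ b ≥ c, in nm) centred
in a 60 × 128 × 128 stack sampled at 102 nm laterally and 200 nm axially —
a typical deconvolved widefield 3D Q-FISH acquisition.  The lateral crop of
128 voxels (~13 µm) is the smallest power-of-two field that holds the
largest blast-phase nuclei with margin; it keeps a two-cohort run of 1080
nuclei to a few minutes on one CPU.

**Telomere signals.**  A nucleus carries `n_telomeres` signal objects
(count drawn from a rounded normal), of which `n_aggregates` are telomere
aggregates.  A *signal* is the unit the microscope resolves; an *aggregate*
is one signal composed of k ≥ 2 true telomeres (k ∈ {2, 3, 4} with
probabilities 0.3/0.5/0.2) whose member positions lie within 45 nm lateral
/ 112 nm axial of a common centre, i.e. pairwise well below the 200/500 nm
resolution limit, so they render as a single unresolvable object.  Member
intensities are drawn from a three-component lognormal mixture
(short/intermediate/long telomeres; default component means 1000/1200/1500
a.u., log-SD 0.10, weights 0.20/0.55/0.25); an aggregate's intensity is the
sum over its members.  Intensities are arbitrary units, as in Q-FISH
practice — no absolute-length calibration is attempted.

**Placement.**  Signal centres are sampled uniformly inside the nuclear
ellipsoid and the axial coordinate of the cloud is divided by a
`flattening` factor, which gives the telomere point cloud an analytic
principal-axis a/c ratio of `flattening · a/c` — the oracle for the a/c
tests.  Distinct signals are kept at least (600, 1200) nm apart
(lateral, axial) by rejection sampling.  These radii are 4× the PSF sigma
per axis; on the elliptical constraint boundary this equals a uniform
4-sigma separation in PSF units, so only deliberately placed aggregates can
fuse in the detector.  Chance near-coincidences are excluded by
construction precisely so that "configured aggregate count" is a
well-defined ground truth.

**Rendering.**  Each member contributes an integrated-intensity Gaussian
with the PSF sigma (150/150/300 nm — already-deconvolved scale; no
deconvolution is modelled) evaluated at voxel centres, over a flat
background (20 a.u.) with Gaussian noise (SD 2).  The DAPI channel is the
filled ellipsoid (level 100) with a softened edge; FITC is a uniform level
inside the nucleus (60 if CD34+, 6 otherwise).  Optical realism beyond this
(aberration, bleaching, scattering) is out of scope: passing tests show the
measurement chain is correct on clean, PSF-limited data, not that it is
robust to every real-microscope artefact.

**Cohorts.**  A phase cohort is 18 patients × 30 nuclei.  The packaged
calibrations put the chronic phase at 39.45 signals and 3.37 aggregates per
nucleus and the blast phase at 41.51 and 4.73, with nuclear volumes of
~192 vs ~329 µm³, cloud a/c of ~2.55 vs ~6.65, and a 1.2× brighter blast
intensity mixture.  The printed per-nucleus SDs (6.49/5.25 for counts,
1.19/0.92 for aggregates) are split into a patient-level component
(SD 0.5 shifts of the per-patient mean, for both parameters) and a
nucleus-level remainder.  The split itself is not published anywhere; it is
back-calculated from the reported cohort-level significance (p < 0.001 with
18 patients per phase bounds the patient-level SD of counts at roughly
1.6), and 0.5 is chosen as a comfortably consistent value.  Nuclear radii
get lognormal jitter (log-SD 0.03 patient, 0.06 nucleus, clipped at 2 SD so
every nucleus fits the stack).  Seeding uses `numpy.random.SeedSequence`
spawning per patient and nucleus, so output is byte-identical for a fixed
configuration and seed, and any nucleus can be regenerated independently.

**qPCR tables.**  Per-sample fold changes are drawn on the 2^(−ΔΔCt) scale
around the configured group means (AURKA: 1.0/2.85/4.12, AURKB:
1.0/2.62/3.02 for healthy/chronic/blast, SDs as printed for the CML
groups), converted to a target-gene ΔCt over a gene baseline, and emitted
as technical duplicates against a GAPDH reference (Ct ≈ 20, sample jitter
SD 0.3 cycles, technical SD 0.05 cycles).  The healthy group is generated
at fold 1.0 exactly: it is its own calibrator, so the published healthy
means slightly above 1 are an estimation artefact the analysis reproduces,
not a generative property.

## The measurement chain

**Segmentation** is global Otsu on DAPI, 3D closing with a ball of radius 2
voxels, then the largest connected component; an error is raised when
foreground falls below 0.1 % of voxels.  Volume is the voxel count times
the voxel volume.  On analytic ellipsoids from 2–8 µm semi-axes the error
is below 5 %.

**Spot detection** computes the negated Laplacian-of-Gaussian response with
per-axis sigmas equal to the PSF in voxel units (this is the anisotropy
correction), estimates noise as 1.4826 × MAD of the response inside the
mask, and keeps local maxima exceeding the median response by 6× that
noise.  The threshold is set by the false-positive budget: ~10⁶ correlated
voxels leave of order 10⁻³ expected noise peaks per nucleus at 6σ, while
the dimmest telomeres in the calibrated cohorts respond at ~19σ.  Plateau
ties break toward the lowest (z, y, x) index; peaks closer than 2σ are
merged greedily, strongest first.  Each detection gets an
intensity-weighted sub-voxel centroid and a background-corrected integral
over a fixed 3σ ellipsoidal aperture, with background the median Cy3 level
inside the mask outside all apertures.  The 3σ aperture captures ~97 % of
a Gaussian spot's flux; the small constant loss cancels in every ratio the
pipeline uses.

**Aggregate calling** flags a detection as an aggregate if it lies within
the (200, 500) nm resolution limit of another detection (such clusters
count as one aggregate object), or if its integrated intensity exceeds
1.6× the median detection intensity of the nucleus.  The median is a
robust single-telomere reference because aggregates are a small minority of
detections.  The factor 1.6 sits midway between the brightest plausible
single telomere (~1.25× median for the default mixture) and the dimmest
two-member aggregate (~1.67× median); a higher factor (e.g. 1.8) sits *on*
the short+intermediate pair sum and systematically undercounts aggregates
by ~10 %, which is why it was rejected.  With 1.6 the measured bias is
about −1 % on the calibrated cohorts.

**Radial position** is the physical distance from the nuclear centroid to
the signal divided by the centroid→boundary distance along the same ray
(quarter-voxel ray marching), clamped to [0, 1].  For uniform points in a
ball its mean is 3/4, which the tests verify.

**a/c ratio** is sqrt(λ_max/λ_min) of the covariance of the signal
centroids in physical nm — rotation- and translation-invariant, ≥ 1 by
construction, and undefined (NaN) below 4 signals or for rank-deficient
clouds.  Whether the original instrument derives a/c from the telomere
cloud or from the nuclear envelope is not documented; the cloud definition
is used here because it has an analytic oracle under the generator's
flattening and reproduces the flat-disk-vs-sphere cell-cycle intuition.
Nuclei with zero detections are retained in the cohort table and excluded
only from a/c averaging, to avoid biasing counts.

**Intensity partition.**  The short/intermediate/long cut points default to
the 33.3/66.7 percentiles of the pooled distribution (the published figure
does not define its thresholds); a deterministic 1D 3-means on
log-intensity is available for recovering unequal subpopulation weights
when components are separated, and fixed thresholds can be supplied.

## Statistics

**Nested factorial ANOVA.**  Phase is fixed; patient is random, nested in
phase; nuclei are replicates.  For balanced designs the sums of squares
decompose exactly (SS_total = SS_phase + SS_patient(phase) + SS_within,
verified to 1e-8) and the phase effect is tested as
F = MS_phase / MS_patient(phase) with (g−1, Σpatients−g) degrees of
freedom — testing against patient variation, not pooled residuals, is what
"taking both patient and cellular variations into account" requires; with
one observation per patient this reduces exactly to one-way ANOVA.
Unbalanced data are conservatively collapsed to patient means with a
warning (no published unbalanced procedure exists to follow).  The
implementation agrees with an independent brute-force oracle to 1e-10 and
holds its nominal type-I error (0.05 ± 0.02 over 1000 null replicates).

**Chi-square.**  Distributions are compared on 10 equal-probability bins of
the pooled sample, pooling adjacent bins until every expected count reaches
5, then a Pearson chi-square on the 2 × B table with df = B − 1.

**Multiple testing.**  No correction is applied across the six telomere
parameters (matching the original analysis); the report states p-values
uncorrected.  The qPCR group comparison, by contrast, uses Bonferroni
pairwise adjustment (raw p × number of comparisons, capped at 1), as its
source analysis did.

**Comparative Ct.**  Technical duplicates are averaged on the Ct scale
(the standard convention; the averaging rule is not otherwise documented),
amplification efficiency is fixed at 2.0 (plain 2^(−ΔΔCt), no efficiency
correction), and group summaries are the arithmetic mean ± SD of per-sample
fold changes to mirror the "mean 2^(−ΔΔCt) ± SD" convention — geometric
summaries would be statistically cleaner on a ratio scale, and users can
compute them from the per-sample table.

## ISCN subset

The karyotype parser covers the grammar of clinical CML tables: clones
separated by `/`, modal counts and ranges (hyphen or en-dash), a sex token,
abnormality tokens (`t`, `del`, `add`, `der`, `inv`, `dup`, `ins`,
`i`/`iso`, `+N`, `−N`), and cell counts in brackets at clone or token
level.  Commas inside parentheses are normalised to semicolons and
whitespace is stripped before comparison — the printed tables contain
`t(9,22)`-style typos that would otherwise break round-tripping.
Philadelphia detection matches any translocation whose first parenthesis
group contains both 9 and 22, ignoring breakpoints: `t(9;22)(q34;q12)` is
deliberately treated as Ph-positive, since breakpoint-exact matching would
misclassify typographic variants as new abnormalities.  "Additional
abnormalities" between phases are set differences of normalised tokens,
with Ph-type tokens excluded whenever both phases are Ph-positive.  This is
deliberately not full ISCN 2020.

## Known limitations

* The simulator emits one nucleus per crop on a flat background; crowded
  fields, touching nuclei and segmentation under low contrast are untested.
* Detection performance is characterised at SNR ≥ 8 on PSF-shaped spots;
  real deconvolution residues and structured background will degrade it.
* Aggregate calling is intensity/proximity-based and inherits the
  ambiguity of any such rule when telomere intensities vary more than
  ~2-fold within a nucleus.
* The patient-level variance split is a modelling choice constrained, not
  determined, by published numbers; cohort-level conclusions are
  insensitive to it within the bound given above.
* Absolute telomere length (kb), telomerase activity, survival endpoints
  and per-patient classification are out of scope.
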