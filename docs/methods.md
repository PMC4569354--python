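# Methods

## Forward model

The head is a single homogeneous spherical conductor. The magnetic field
of a current dipole inside such a sphere has a closed form (the Sarvas
solution); volume currents cancel the radial field outside the conductor,
so only the tangential dipole component is visible and a radially
oriented dipole is exactly silent. We exploit this analytically testable
structure throughout: lead-field linearity, rotation equivariance and
radial silence are asserted against the formula rather than against a
numerical reference. The price is realism — no skull/scalp geometry, no
conductivity inhomogeneity — but the beamformer algebra downstream is
unchanged by the choice of head model.

Sources live on a regular cubic lattice aligned to the sphere centre;
points strictly inside the sphere are retained. The lattice node that
coincides with the centre is magnetically silent for every orientation;
it is flagged, its gain zeroed, and it is excluded from filters and
networks. Sensors are radial magnetometers on a spherical cap at
1.2 × the head radius (a helmet-like quasi-uniform Fibonacci layout),
275 by default, 64 in the desk-scale configurations.

## Synthetic cohorts

Source dynamics are narrow-band filtered Gaussian noise (6th-order
Butterworth, forward–backward, unit RMS). A coupled pair shares a common
band-limited signal; the second node receives the Hilbert-phase-shifted
copy mixed with an independent narrow-band component,

    s_b = c · H_phi(s_common) + sqrt(1 − c²) · s_indep,

so the source coherence magnitude equals the coupling strength `c` and
the coherency phase equals the imposed lag φ. Lags of 0 or π are rejected
at construction: they produce purely real coherency, invisible to the
imaginary-coherence measure by design. Pairs may share a `signal_id` to
form coherent clumps — every cross-clump edge is then elevated, a
dense-subgraph effect that survives region averaging.

"Patient" subjects have every coupling strength multiplied by
`planted_group_effect`; at 1.0 the groups are exchangeable by
construction (the simulation code path is then literally identical for
both labels), which is the null used for error-calibration suites.
Sensor data are lead field × sources plus white Gaussian channel noise
(default 5×10⁻¹⁴ T at full scale, a typical magnetometer noise floor per
analysis bandwidth; 1.5–2×10⁻¹⁴ T in the small demo geometries, keeping
the realized broadband SNR of order 1–5, which the manifest records
per subject).

One master seed drives everything; subject k's seed is master + k, so
cohorts are reproducible bit for bit and any subject can be regenerated
in isolation.

The generator emulates: band-limited oscillatory coupling with a stable
phase lag, linear mixing through a physical forward model, field spread
(every sensor sees every source), uncorrelated sensor noise, and
between-subject variability through independent noise realizations. It
does not emulate: 1/f background spectra, nonstationarity, epileptiform
transients (the analysis excises them in real data anyway), artifact
topographies (ocular/cardiac), head-position differences, or anatomical
variability. Passing tests therefore demonstrate correctness and
calibration of the analysis chain under its own model assumptions, not
performance on real recordings.

## Preprocessing

Interval arithmetic is half-open and 0-based. Marker excision removes
the window [t − pad, t + pad) around each marker (default pad 10 s);
overlapping windows merge through a sample-wise mask. Epoch selection
tiles each clean segment into consecutive non-overlapping windows and
draws the requested number uniformly without replacement — whether the
original procedure allowed overlap is unknowable, so non-overlap, the
conservative choice, is fixed and seeded. Resampling is polyphase with
the rate ratio represented as an exact rational (3906.2 → 409.6 is
2048/19531), anti-aliased by the scipy Kaiser default. The band-pass is
a 4th-order Butterworth applied forward–backward (zero phase; the
effective magnitude response is 8th order). The filter order is a
configurable default, not a stated value.

## Spectral estimation

Each band is centre ± halfwidth. DPSS tapers are matched to the
halfwidth with the Slepian convention K = ⌊2·T·W⌋ − 1 (10 s × 2 Hz → 39
tapers); the taper-count rule is exposed as a convention choice. The
tapered Fourier coefficient is evaluated at the band centre only —
spectral smoothing covers the band — with an optional `band_average`
mode that additionally averages the CSD over a frequency grid spanning
the band. CSD normalization is 1/(fs·Σw²) with unit-norm tapers; every
downstream quantity (coherence, filters up to scale) is invariant to it.
Per-taper coefficients are retained because the beamformer projects
coefficients, not the averaged CSD.

## DICS beamformer

Diagonal loading: S_reg = S + λ·(tr S/n)·I with λ = 0.05. Filters are
built on the real part of S_reg (standard DICS practice; the complex CSD
is kept for connectivity). For the scalar filter the lead-field block is
first reduced by SVD to its numerically non-degenerate column space —
in a sphere the radial direction is exactly silent, so the raw 3×3 inner
matrix L̂ᵀS⁻¹L̂ is rank-deficient by construction — and the orientation of
maximal output power is the eigenvector of the smallest eigenvalue of
the reduced LᵀS⁻¹L (equivalently the dominant eigenvector of its
inverse). Filters are unit-gain, w·l(θ) = 1; unit-noise-gain
normalization was the other candidate and unit gain was chosen and is
asserted to 1e-9 in tests. Nodes with no non-silent direction are
excluded and recorded. Source power is mean |coefficient|² per node,
optionally divided by ‖w‖² (neural-activity-index style) to flatten the
depth-dependent noise floor; the group power test uses the normalized
variant.

## Connectivity

Coherency C_ij = S_ij/√(S_ii·S_jj) with S averaged over epochs × tapers;
the edge weight is |Im C_ij|, taken immediately, making networks
undirected and discarding the lag sign by design. Nothing is
thresholded. Region-level ("low-resolution") networks average all
cross-region node-pair weights; within-region pairs never contribute;
band-level CSD averaging (one coherency per band) was chosen over
averaging |Im C| across within-band frequencies. The packaged toy atlas
partitions the grid into octants around its centroid; a real lookup can
be supplied as a two-column TSV. Note the measure is invariant to
per-node positive rescaling and to a global phase, but not to per-node
phase rotations — those re-time a node and legitimately change its
lagged coupling.

## Graph measures

Edge length for path computations is 1/w (the Brain Connectivity
Toolbox convention); −log w is a known alternative and the mapping is a
single documented function. Onnela clustering normalizes by the
per-network maximum weight. Disconnected networks raise: the coherence
networks this pipeline produces are dense, so disconnection signals an
upstream defect, not a topology to accommodate. Surrogates permute the
off-diagonal upper-triangle weights uniformly (preserving the weight
distribution, not the degree sequence — the literal reading of "randomly
shuffling the connections"); a degree-preserving variant that permutes
weights only across existing edges is available behind a flag, and the
two coincide on dense networks. A surrogate that comes out disconnected
is redrawn (at most 10 times). Normalized measures divide the observed
global value by the surrogate mean.

## Group statistics

The node-strength and source-power cluster tests share one engine:
pooled-variance two-sample t per node (Welch behind a flag),
thresholding (2.0 for strength, 1.9 for power), clustering by spatial
adjacency (neighbours within 1.1 × grid spacing — 6-connectivity on the
lattice), cluster mass = summed t, and a permutation null of the
per-permutation maximum cluster mass. NBS applies the same principle to
region-level edges with threshold 3.5 and the connected-component extent
(edge count) as the cluster statistic — matching the "same or greater
size" phrasing — with summed |t| available as an option.

Directions are tested separately, each at the stated alpha against its
own max-cluster null, with no alpha splitting; consequently each
direction's p-values are super-uniform while the two-direction family
rejects at up to twice the per-direction level. Permutations enumerate
all distinct label assignments when there are no more of them than the
requested permutation count; otherwise Monte-Carlo sampling that always
includes the identity relabelling, so p ≥ 1/n_permutations. All nulls
are functions of the seed and the label sequence only; reruns are exact.

Mann–Whitney U uses the exact distribution for min(n, m) ≤ 8 without
ties, otherwise mid-ranks with tie-corrected normal approximation; a
fully degenerate comparison returns p = 1. Spearman correlation uses
exact permutation over all n! rank orders for n ≤ 9 and the t
approximation above. The sex comparison is a Pearson chi-square without
continuity correction (the continuity-corrected statistic does not
reproduce the standard worked example for this table size). Regional
tests are BH-FDR corrected at q = 0.05.

## Problem sizes

Full-scale defaults (275 sensors, 1 cm grid ≈ 3000 nodes, 13 + 19
subjects, 30 × 10 s epochs, 5000 permutations) are committed in
`paper_defaults.yaml`. The test suite, demos and the acceptance script
use a desk-scale geometry the package treats as its reference test
condition: a 3 cm grid in the 9 cm sphere (93 nodes, of which the silent
centre node is dropped), 64 sensors, 30 × 2 s epochs at 256 Hz, and
500-permutation nulls. The planted-effect condition is two coherent
5-node clumps in opposite octants coupled at lag π/2 with base strength
0.28 and group multiplier 1.5 — calibrated once so the clump-to-clump
regional edge weight differs by about d = 2 between groups of 13 and 19
— which the acceptance script re-measures on every run.

## Known limitations

- The spherical head model cannot represent realistic conductor
  geometry; localization accuracy statements transfer only qualitatively.
- Scalar (dominant-orientation) beamforming assumes a single dominant
  source orientation per node; crossing sources at one node are not
  modelled. Strongly correlated sources (coupling near 1) partially
  cancel in any adaptive beamformer; the synthetic conditions keep
  planted couplings moderate.
- The octant atlas is a topological stand-in; region counts and shapes
  differ grossly from anatomical parcellations.
- Narrow-band Gaussian sources lack the 1/f background and
  nonstationarity of resting MEG; absolute coherence bias levels in real
  data will differ from the synthetic ones.
- The pipeline accepts converted HDF5 recordings only; native MEG
  formats should be converted upstream (e.g. with an established raw
  I/O library).
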