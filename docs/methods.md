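# Methods

This note documents the models implemented in `soubakit`, their
assumptions and default parameters, the design choices that were
genuinely open, and the limits of what the synthetic-data tests can
show.

## Coordinate handling and helix assignment

Structures are atom lists (chain, residue, atom name, element, Å
coordinates) read and written through gemmi's PDB support; only single
models are handled (NMR ensembles and crystallographic symmetry are out
of scope). Helices are assigned from Cα geometry alone: a window is
helical when d(Cαi, Cαi+3) ∈ [4.5, 5.6] Å and d(Cαi, Cαi+4) ∈
[5.8, 6.8] Å (an ideal α-helix gives 5.05 and 6.20 Å), and maximal
runs covering ≥ 6 residues are reported. This coordinate-only criterion
needs no hydrogens or hydrogen-bond assignment and is exact on
idealised fixtures; on real structures it approximates, rather than
reproduces, DSSP. Runs break at residue-numbering gaps, and when two
expanded segments would overlap the N-terminal segment keeps the shared
residues (a deterministic tie-break).

A solenoid of overlapping UBAs requires an odd helix count n ≥ 3; unit
*i* is helices (2i−1, 2i, 2i+1), so consecutive units share exactly one
helix and n helices give (n−1)/2 units. Signature motifs are matched
non-overlapping, left to right, with the pattern `[MLK]G[FY]` — the
canonical (M/L)-G-(Y/F) plus the KGF variant found in the second UBA of
the UBAP1 solenoid.

## Superposition

Kabsch superposition minimises least-squares Cα deviation; the
reflection case is handled by flipping the sign of the smallest
singular direction, so only proper rotations are returned. Degenerate
inputs (< 3 points, collinear sets) are rejected. The test suite
cross-checks RMSDs against an independent quaternion
characteristic-polynomial oracle to 1e-6 Å.

## CSP analysis

Amide CSPs use Δδ = √(ΔδH² + (ΔδN/5)²); the 1/5 nitrogen weight is the
standard compensation for the larger ¹⁵N shift range. Prolines and
residues unobserved in either spectrum are assigned Δδ = 0 and flagged;
flagged residues are excluded from interface calls, region statistics
and fitting. Peak matching is by residue assignment, never by
nearest-peak tracking — the workflow assumes assigned spectra.
Interface residues are those with Δδ strictly above the threshold
(default 0.2 ppm, configurable).

The titration fit assumes fast exchange: the observed shift is the
population-weighted average of free and bound states, so
Δδ_obs(j, L) = Δδ_max(j) · f_b(P_t, L, Kd) with one global Kd and a
per-residue amplitude. f_b is the closed-form root of the single-site
binding quadratic, evaluated in the cancellation-free form
2L/(b + √(b²−4PL)); a bisection oracle verifies it to 1e-10 in tests.
The fit is trust-region least squares over (log₁₀Kd, amplitudes), with
Kd initialised at the ligand concentration of half-maximal mean shift;
residues whose largest CSP is below 0.01 ppm are treated as
unresponsive and excluded (all-unresponsive series are an error).
Noiseless synthetic series are recovered to numerical precision across
Kd ∈ [1, 5000] μM at the default schedule (0–3 equivalents of a 500 μM
protein).

## Template docking

Each UBA unit is superposed onto the template's three-helix UBA by
pairing helix k with helix k, trimming Cα pairs symmetrically around
the helix midpoints to the shorter helix — a deterministic
correspondence that needs no sequence alignment. The resulting
transform is applied to the template's ubiquitin, which joins the model
as chain U1/U2/U3 in unit order. Docking is rigid: no minimisation,
repacking or scoring beyond geometry.

Clash detection reports inter-chain heavy-atom pairs below 2.4 Å (kd-tree
search, verified against an all-pairs O(N²) oracle). Contacts between a
placed ubiquitin and the receptor residues equivalent to the template's
own UBA–ubiquitin contact footprint (heavy atoms within 4.5 Å in the
template) are excluded by default — that contact *is* the modelled
interface.

Isopeptide-linkage feasibility between adjacent copies (consecutive
unit indices) is the minimum over both directions of the Lys48/Lys63 NZ
to Gly76 carbonyl-C distance, feasible when ≤ 9.0 Å. The threshold
allows ~1.3 Å of isopeptide bond plus the flexibility of the ubiquitin
C-terminal tail (residues 72–76); it is configurable, and the docking
report carries the raw distances so sensitivity to the cutoff can be
read off directly. On the synthetic model the distances are 19–22 Å,
far above any defensible threshold.

## PRE prediction

The nitroxide label is a single pseudo-atom at Cβ + 6.0 Å along the
Cα→Cβ direction (Cα + offset along the backbone normal for glycine);
no rotamer ensemble is modelled, which matches the qualitative use of
PREs here but cannot capture ensemble averaging of a real tether.
Per-residue attenuation uses Γ₂ = K_SB · r⁻⁶ · (4τc + 3τc/(1+ωH²τc²))
and I_para/I_dia = R₂·exp(−Γ₂t)/(R₂+Γ₂), with defaults
K_SB = 1.23·10¹⁶ Å⁶s⁻² (the standard electron–¹H dipolar constant),
τc = 10 ns, R₂ = 20 s⁻¹, t = 10 ms and a 700 MHz spectrometer. With
these defaults the ratio crosses the significance threshold 0.7 near
r ≈ 20 Å; r → 0 gives ratio 0 (the exponential underflows to exactly 0
below ~5 Å, the correct limit), and K_SB → 0 reproduces the
ascorbic-acid-reduced diamagnetic control (ratio 1 everywhere). Amide
positions use an explicit H if present, else H reconstructed from
N/Cα/C(prev) geometry, else the N position. Significant regions are
runs of ≥ 2 consecutive residues with ratio < 0.7 (both configurable —
no universal cutoff exists for these thresholds); prediction/observation
agreement is the Jaccard index of the residue sets covered by each
profile's regions, restricted to shared residues. Predictions assume
the fully bound complex; exchange/occupancy weighting is a known
limitation.

## ITC model

Internal units are fixed (μM, μL, μcal, cal/mol). After injection i of
volume dV the cell contents dilute by (1 − dV/V0) (perfusion
approximation, matching common instrument software; an
exact-displacement variant is selectable), the syringe species
accumulates correspondingly, and the cumulative binding heat is
Q(i) = n·M_t(i)·ΔH·V0·f_b(i). Observed injection heats add the
displaced-volume correction (dV/V0)·(Q(i)+Q(i−1))/2 and a baseline
offset. Fitting is bounded trust-region least squares over
(n, log₁₀Kd, ΔH, offset) with standard errors from the Jacobian; a Kd
at the search bound flags the fit, and a Wiseman c = n·M_cell/Kd
outside [1, 1000] logs a warning while still fitting. Noiseless
simulate→fit round trips recover all four parameters to better than
1e-4 relative.

At the 75 μM-cell protocol, c ≈ 0.5: the four parameters are strongly
correlated and the per-fit Kd uncertainty is intrinsically ~23%
(matching a numerical Cramér–Rao calculation at those conditions), so
recovered Kds are reported as medians over 20 seeded replicates.

## Synthetic data

The generators are pure functions of spec + seed (bitwise
reproducible), and the shipped fixture files regenerate identically
from the documented seed.

* **Solenoid** — ideal α-helices (1.5 Å rise, 100°/residue, 2.3 Å Cα
  radius) placed by repeating a two-helix motif under a right-handed
  screw (45° rotation, 16 Å rise per repeat; outer/inner helix radii
  13/5 Å), so every UBA unit has identical internal geometry. Defaults:
  7 helices × 11 residues with 3-residue loops (95 residues). Backbone
  N/C/O/Cβ atoms are idealised from the Cα trace (sub-Å accuracy is
  irrelevant downstream); 0.02 Å Gaussian jitter avoids exact
  degeneracies. The sequence plants one signature motif per unit (MGF,
  KGF, LGY) in the loop after the unit's first helix and prolines in
  two other loops; remaining positions draw from an alphabet that
  cannot create spurious motifs. Construction ground truth (helix
  bounds, unit count, motif positions) is returned with the structure.
* **Ubiquitin decoy** — a 76-residue four-helix decoy carrying the
  canonical ubiquitin sequence. It is a geometric stand-in, not a fold
  prediction: helix spans and phases are chosen so the Ile44/Val70
  patch markers and K6 face the binding side while D39 and S57 face
  away (> 25 Å from every receptor amide in the docked model, hence no
  predicted PRE regions — the behaviour expected of distal spin-label
  sites), with Lys NZ pseudo-side-chains and the Gly76 tail present.
* **Template complex** — the decoy posed against the helix-1/helix-3
  face of a three-helix bundle generated with the same repeat geometry,
  backed off along the face normal until the closest heavy-atom
  approach is ≥ 3.4 Å (clash-free at 2.4 Å by construction).
* **Titration** — peaks move linearly with fraction bound at 500 μM
  protein, 0–3 equivalents of ligand, true Kd 70 μM, 12 perturbed
  residues at Δδ_max 0.4 ppm split between ¹H and ¹⁵N components;
  noise 0.01 ppm on ¹H (5× on ¹⁵N); prolines omitted.
* **ITC thermograms** — 38 × 1 μL injections into a 200 μL cell (the
  cell volume of the instrument class used for such titrations), truth
  ΔH −2000 cal/mol (a typical UBA/ubiquitin exotherm; the fits assert
  only Kd against reference values), noise 2% of the largest injection
  heat. **PRE observations** — prediction plus 0.05 Gaussian noise,
  clipped at 0.

What passing on synthetic data does **not** show: robustness to peak
overlap and assignment errors in crowded spectra, real baseline and
first-injection artefacts in calorimetry, spin-label rotamer averaging,
or docking accuracy against a genuinely homologous (rather than
identical-geometry) template. The generators emulate the statistical
and geometric structure the methods assume, which is exactly what makes
recovery tests meaningful — and no more.

## Determinism

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); there is no hidden global RNG state.
Optimisers are deterministic, reports use fixed number formats and
contain no timestamps, and the pipeline is byte-identical across reruns
of the same configuration.
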