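# icdrecon

Cosparse analysis-model image reconstruction from undersampled k-space with
**iterative cosupport detection (ICD)**.

Compressed-sensing MRI acquires a fraction of an image's 2-D Fourier
coefficients and reconstructs by exploiting structure.  The *cosparse
analysis model* describes piecewise-smooth images through the zeros of
their analysis coefficients: for directional finite-difference operators
Ω₁…Ω₄ (vertical, horizontal, two diagonals), most entries of Ωᵢx vanish,
and their index sets — the per-direction *cosupports* Λᵢ — confine x to a
low-dimensional subspace.  Knowing Λ (even inexactly) lowers the number of
measurements m required for unique recovery: for an operator in general
position, m ≥ n − l with the cosupport known, m ≥ n + p − 2l knowing only
the cosparsity l, and m ≥ n + l₀ − 2l with a superset prior of size l₀;
for the finite-difference operator the subspace dimension is the graph
quantity dim W_Λ = |V| − |V(Λ)| + J(Λ).

Since the cosupport of the unknown image is itself unknown, ICD estimates
it on the fly, alternating two steps until the iterate stabilises:

1. **reconstruction** — solve the truncated-ℓ1 problem
   `min_x ‖y − F_u x‖₂² + λ Σᵢ ‖(Ωᵢx)_{Λᵢ}‖₁` (optionally + η₂‖Ψx‖₁ with an
   orthonormal wavelet Ψ) given the current {Λᵢ};
2. **detection** — re-estimate {Λᵢ} from the new iterate, either the L
   smallest coefficient magnitudes per direction (*truncated*, ICD-TR) or
   everything below the decaying threshold ‖Ωᵢx‖∞/w^{t−1} (*threshold*,
   ICD-TH; ICD-WT adds the wavelet penalty).

The package is intended for researchers studying analysis-model recovery:
it bundles the operators and their adjoints, radial / variable-density /
Cartesian k-space mask generators, the unitary undersampled Fourier
operator, a majorize–minimize truncated-ℓ1 solver (plus a direct
stacked-system oracle for small grids), the uniqueness-bound calculators,
the RLNE / HFEN / SSIM quality metrics, the Shepp-Logan phantom and seeded
piecewise-constant fixtures with known exact cosupport.

## Worked example

```python
from icdrecon import CosparseReconstruction, radial_mask, shepp_logan

phantom = shepp_logan(256)                       # exact piecewise-constant head phantom
mask = radial_mask((256, 256), num_lines=12)     # 3036 samples, 4.63% of k-space
model = CosparseReconstruction.from_image(phantom, mask)
res = model.fit(method="icd-th", lam=5e-4, w=2)  # threshold-detection ICD
print(res.summary())
```

prints (abridged):

```
               Cosparse Reconstruction Results
==============================================================
Method:                 icd-th
Mask scheme:            radial
Sampling:               3036/65536 (4.63%)
Directions:             vertical, horizontal, diag_main, diag_anti
lambda:                 0.0005
Detection:              threshold (w=2)
Outer iterations:       7
Stop reason:            relative change 1.420e-09 <= stop_tol at t=7
--------------------------------------------------------------
  t cosupport sizes                     objective       RLNE
  1 65535/65535/65535/65535            1.9839e+00 4.3136e-01
  2 65452/65218/65337/65290            1.6229e+00 3.5557e-01
  3 65074/65056/64798/64832            1.0243e+00 2.4766e-01
  4 64686/64635/64343/64379            4.5418e-01 1.0800e-01
  5 64413/64017/63748/63739            6.6557e-02 2.1661e-02
  6 64429/63920/63593/63569            1.2776e-04 1.4200e-09
  7 64466/64048/63715/63698            1.2796e-04 7.7540e-15
--------------------------------------------------------------
Final RLNE:             7.7540e-15
Final HFEN:             7.0785e-15
Final SSIM:             1.0000
==============================================================
```

Reading the table: each outer iteration first detects the four per-direction
cosupports from the current estimate (their sizes are the second column),
then re-solves the truncated-ℓ1 problem.  The detected sizes walk towards
the phantom's exact per-direction cosparsities and reach them
(64466/64048/63715/63698) at iteration 7 — every true zero and nothing
else — while the reconstruction error (RLNE, relative ℓ2-norm error
against the ground truth) collapses to machine precision: from 4.6% of
k-space the phantom is recovered exactly.  The no-prior baseline
(`method="baseline"`, ordinary wavelet+TV) on the same mask stays above
RLNE 0.4, an illustration of how much the detected cosupport is worth.

`res.error_map()` gives the absolute error image, `res.history.to_csv()`
the per-iteration detection table (sizes, true/false detections when the
truth is known), and `icdrecon.theory` the minimum-measurement bounds.

The same experiments are scriptable from a shell:

```bash
icdrecon phantom --side 256 --out truth
icdrecon mask --scheme radial --lines 12 --shape 256 --out mask12
icdrecon reconstruct --image truth.npy --mask mask12 --strategy th \
    --lambda 5e-4 --w 2 --out recon
icdrecon evaluate --recon recon.npy --truth truth.npy
```

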