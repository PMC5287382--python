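"""Quantify one noisy phantom subject end to end.

Simulates a single sham-like subject (Rician noise at peak-increment SNR
20), then runs the full chain — registration, baseline subtraction,
signal-to-concentration conversion, the joint space-time diffusion-
clearance fit, tortuosity, spreading-region volumes and half-life — and
prints every derived ISS metric next to its ground truth.
"""

import numpy as np

from issmri import (
    AcquisitionParams,
    AnalysisOptions,
    DiffusionClearanceModel,
    GroupScenario,
    VoxelGrid,
    analyze_subject,
    generate_phantom_study,
    noise_sigma_for_snr,
)

grid = VoxelGrid.centered()
acq = AcquisitionParams()
truth = DiffusionClearanceModel(D_star=2.770e-4, k_prime=0.648e-4)

scenario = GroupScenario(name="sham", true_params=truth, n_subjects=1, seed=42)
scenario.noise_sigma = noise_sigma_for_snr(truth, grid, acq, snr=20.0)
series, _ = generate_phantom_study(scenario, grid, acq)

# D_free chosen so that the true tortuosity is 1.560
opts = AnalysisOptions(D_free=1.560**2 * truth.D_star)
res = analyze_subject(series[0], acq, opts)

print(f"subject {res.subject_id} (noise sigma = {scenario.noise_sigma:.4f} x S0)")
print(f"  D*      fitted {res.fit.D_star_hat:.3e}  true {truth.D_star:.3e} mm^2/s")
print(f"  k'      fitted {res.fit.k_prime_hat:.3e}  true {truth.k_prime:.3e} /s")
print(f"  lambda  {res.tortuosity.lambda_hat:.3f}  (D_free {res.tortuosity.D_free:.3e} mm^2/s)")
print(f"  t_1/2   {res.half_life.t_half:.1f} min ({res.half_life.method}; "
      f"pure clearance would give ln2/k' = {np.log(2) / truth.k_prime / 60:.1f} min)")
print(f"  spread  v_max {res.spread.v_max:.1f} mm^3 at t = {res.spread.t_max:.1f} h "
      f"(threshold {res.spread.threshold_used:.2f} signal units)")
print(f"  fit     R^2 = {res.fit.r_squared:.4f} over {res.fit.n_voxels_used} voxels, "
      f"{res.fit.n_times_used} frames")
print(f"  95% CI  D* [{res.fit.ci_D_star[0]:.3e}, {res.fit.ci_D_star[1]:.3e}]")
print()
print("for this pure diffusion-clearance phantom t_1/2 ~ ln2/k'; the small")
print("shortfall comes from the saturated core, where the measured amount")
print("curve under-counts the earliest frames")
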