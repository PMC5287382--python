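# issmri

Tracer-based MRI quantification of brain interstitial-space (ISS)
microstructure and interstitial-fluid (ISF) clearance.

When a small Gd-DTPA bolus is injected into deep grey matter, the tracer
spreads through the interstitial space by hindered diffusion and is
cleared by ISF outflow and cellular uptake, brightening T1-weighted images
as it goes. A dynamic series of such images (pre-injection baseline plus
scans over 0.5–8 h) therefore encodes the biophysics of the tissue. This
package turns that series into numbers:

* **D\*** — effective diffusion coefficient of the tracer in the ISS
  (mm²/s), from a joint space-time fit of the point-source
  diffusion-clearance field
  `C(r,t) = (Q/α)(4πD*t)^(−3/2) exp(−r²/(4D*t) − k′t)`;
* **λ = √(D/D\*)** — tortuosity, the geometric hindrance of the ISS
  relative to a free medium with diffusion coefficient D;
* **k′** — first-order clearance rate constant (1/s), and
  **t½** — half-life of the total in-brain tracer amount (min);
* **spreading-region volumes** — the time course of the "lightened"
  voxel volume, its maximum and the time of maximum;
* **group statistics** — one-way ANOVA with Student–Newman–Keuls
  post-hoc comparisons across experimental groups (e.g. sham vs
  rotenone-lesioned vs madopar-treated).

Because no raw animal data accompany studies of this kind, the package
ships a first-class phantom simulator: ground-truth concentration fields,
a configurable MR signal law, Rician noise, and per-subject parameter
variability, so the entire chain is testable end to end against known
truth. It is intended for researchers doing dynamic-contrast ISS imaging
who want a tested, scriptable reference implementation, and for anyone
studying parameter identifiability of tracer-clearance models.

## Worked example

`examples/quantify_subject.py` simulates one sham-like subject (D\* =
2.770 × 10⁻⁴ mm²/s, k′ = 0.648 × 10⁻⁴ /s, Rician noise at peak SNR 20)
and runs the full chain — registration, baseline subtraction,
signal-to-concentration conversion, model fit, tortuosity, spread curve,
half-life:

```
subject sham_00 (noise sigma = 0.0110 x S0)
  D*      fitted 2.815e-04  true 2.770e-04 mm^2/s
  k'      fitted 6.129e-05  true 6.480e-05 /s
  lambda  1.547  (D_free 6.741e-04 mm^2/s)
  t_1/2   174.5 min (log-linear; pure clearance would give ln2/k' = 178.3 min)
  spread  v_max 163.5 mm^3 at t = 1.0 h (threshold 46.57 signal units)
  fit     R^2 = 0.6938 over 4522 voxels, 10 frames
  95% CI  D* [2.788e-04, 2.844e-04]
```

The fitted D\* lands within 2% of truth and k′ within 6% on this single
noisy subject; medians over replicates are tighter (see below). λ is
computed from the fitted D\* against the configured free coefficient; t½
is measured from the decline of the total tracer amount and, for this
pure diffusion-clearance phantom, sits near ln2/k′.

The other examples build the forward model step by step
(`examples/simulate_phantom.py`) and run a three-group comparison with
ANOVA + SNK output (`examples/compare_groups.py`).

### Command line

The same pipeline is scriptable from the shell for directory-organised
studies (NIfTI series + CSV sidecar):

```sh
issmri simulate --config config.yaml --out study/
issmri fit      --config config.yaml --in study/ --out fits/
issmri report   --config config.yaml --in fits/  --out report/
```

See `issmri.config` for the documented YAML schema. Every output
directory carries a provenance JSON (tool version, config hash, seed).

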