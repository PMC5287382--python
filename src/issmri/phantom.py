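"""Phantom study generator: forward-simulated, noisy MRI series.

Emulates the tracer study design: a 2 uL / 10 mmol/L Gd-DTPA bolus infused
into the caudate nucleus, then T1-weighted scans pre-injection and at 0.5,
1, 1.5, 2, 3, 4, 5, 6, 7 and 8 h post-injection, three groups of rats
(sham / rotenone-lesioned / rotenone+madopar), n = 10 each.  Per-subject
physiology (D*, k') is drawn log-normally around the group's central values;
images get Rician noise.  Ground truth travels alongside every simulated
series so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ImageSeries, VoxelGrid
from .model import DEFAULT_ALPHA, DiffusionClearanceModel, simulate_concentration_field
from .signal import AcquisitionParams, add_noise, concentration_to_signal, make_signal_law

__all__ = [
    "GROUP_PARAMS",
    "GroupScenario",
    "noise_sigma_for_snr",
    "generate_phantom_study",
]

#: Central ISS parameters of the three experimental groups (group means of
#: the in-vivo study this generator emulates).  D* in mm^2/s, k' in 1/s,
#: lambda dimensionless, t_half in minutes.  The ``sd`` entries are the
#: corresponding between-subject standard deviations.
GROUP_PARAMS: dict[str, dict[str, float]] = {
    "sham": {
        "D_star": 2.770e-4, "D_star_sd": 0.506e-4,
        "k_prime": 0.648e-4, "k_prime_sd": 0.082e-4,
        "lambda": 1.560, "lambda_sd": 0.320,
        "t_half_min": 114.6, "t_half_sd": 8.7,
    },
    "rotenone": {
        "D_star": 5.828e-4, "D_star_sd": 0.727e-4,
        "k_prime": 0.333e-4, "k_prime_sd": 0.093e-4,
        "lambda": 0.916, "lambda_sd": 0.209,
        "t_half_min": 156.6, "t_half_sd": 10.2,
    },
    "madopar": {
        "D_star": 3.645e-4, "D_star_sd": 0.451e-4,
        "k_prime": 0.500e-4, "k_prime_sd": 0.070e-4,
        "lambda": 1.157, "lambda_sd": 0.128,
        "t_half_min": 128.8, "t_half_sd": 7.1,
    },
}


@dataclass
class GroupScenario:
    """One simulated experimental group.

    ``between_subject_cv`` maps parameter name (``"D_star"``, ``"k_prime"``,
    ``"Q"``) to a fractional coefficient of variation; parameters not listed
    are held at their central value.  ``noise_sigma`` is the image noise
    scale as a fraction of the equilibrium signal S0.
    """

    name: str
    true_params: DiffusionClearanceModel
    between_subject_cv: dict[str, float] = field(default_factory=dict)
    noise_sigma: float = 0.0
    n_subjects: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if any(cv < 0 for cv in self.between_subject_cv.values()):
            raise ValueError("between_subject_cv entries must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    @classmethod
    def from_group(
        cls,
        group: str,
        noise_sigma: float = 0.0,
        between_subject_cv: dict[str, float] | None = None,
        n_subjects: int = 10,
        seed: int = 0,
        **model_kwargs,
    ) -> "GroupScenario":
        """Scenario at the central values of one named study group."""
        p = GROUP_PARAMS[group]
        model = DiffusionClearanceModel(D_star=p["D_star"], k_prime=p["k_prime"], **model_kwargs)
        return cls(
            name=group,
            true_params=model,
            between_subject_cv=between_subject_cv or {},
            noise_sigma=noise_sigma,
            n_subjects=n_subjects,
            seed=seed,
        )


def noise_sigma_for_snr(
    model: DiffusionClearanceModel,
    grid: VoxelGrid,
    acq: AcquisitionParams,
    snr: float,
    law: str = "saturation",
) -> float:
    """Noise scale (fraction of S0) giving a target peak-increment SNR.

    SNR is defined as (maximum noiseless signal increment over all voxels
    and times) / (per-channel noise sigma).  Deterministic: computed from
    the noiseless forward model at the acquisition schedule.
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    times_s = np.asarray(acq.time_points, dtype=float) * 3600.0
    conc = simulate_concentration_field(model, grid, times_s)
    sl = make_signal_law(acq, model.alpha, law)
    peak_inc = float(np.max(sl.signal(conc.values)) - sl.baseline_signal())
    return peak_inc / snr / acq.S0


def _lognormal_draw(rng: np.random.Generator, central: float, cv: float) -> float:
    """Log-normal with mean ``central`` and coefficient of variation ``cv``."""
    if cv == 0:
        return central
    sigma2 = np.log1p(cv**2)
    mu = np.log(central) - sigma2 / 2.0
    return float(np.exp(rng.normal(mu, np.sqrt(sigma2))))


def generate_phantom_study(
    scenario: GroupScenario,
    grid: VoxelGrid | None = None,
    acq: AcquisitionParams | None = None,
    law: str = "saturation",
) -> tuple[list[ImageSeries], pd.DataFrame]:
    """Simulate one group: noisy image series + ground-truth table.

    Per subject, D*, k' (and Q, if listed in ``between_subject_cv``) are
    drawn log-normally around the scenario's central values, the closed-form
    concentration field is evaluated at the acquisition schedule, converted
    to signal, and Rician noise at ``noise_sigma * S0`` is added to the
    baseline and every frame.  All randomness derives from ``scenario.seed``.

    Returns
    -------
    (series, truth)
        ``series`` is a list of ``n_subjects`` ImageSeries; ``truth`` one
        row per subject with the drawn parameters and simulation settings.
    """
    grid = grid or VoxelGrid.centered()
    acq = acq or AcquisitionParams()
    ss = np.random.SeedSequence(scenario.seed)
    subject_seeds = ss.spawn(scenario.n_subjects)

    times_s = np.asarray(acq.time_points, dtype=float) * 3600.0
    series: list[ImageSeries] = []
    rows = []
    for i, sseed in enumerate(subject_seeds):
        rng = np.random.default_rng(sseed)
        draws = {}
        for pname in ("D_star", "k_prime", "Q"):
            central = getattr(scenario.true_params, pname)
            cv = scenario.between_subject_cv.get(pname, 0.0)
            draws[pname] = _lognormal_draw(rng, central, cv)
        model = scenario.true_params.with_params(**draws)
        conc = simulate_concentration_field(model, grid, times_s)
        subject_id = f"{scenario.name}_{i:02d}"
        img = concentration_to_signal(
            conc, acq, alpha=model.alpha, law=law, subject_id=subject_id, group=scenario.name
        )
        sigma_abs = scenario.noise_sigma * acq.S0
        if sigma_abs > 0:
            img.baseline = add_noise(img.baseline, sigma_abs, rng)
            img.frames = add_noise(img.frames, sigma_abs, rng)
        img.meta.update(noise_sigma=scenario.noise_sigma, seed=scenario.seed)
        series.append(img)
        rows.append(
            {
                "subject_id": subject_id,
                "group": scenario.name,
                "D_star_true": model.D_star,
                "k_prime_true": model.k_prime,
                "Q_true": model.Q,
                "alpha": model.alpha,
                "source_x": model.source_position[0],
                "source_y": model.source_position[1],
                "source_z": model.source_position[2],
                "infusion_duration_s": model.infusion_duration,
                "noise_sigma": scenario.noise_sigma,
                "signal_law": law,
            }
        )
    return series, pd.DataFrame(rows)
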