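"""Digital phantom and cohort generator.

The phantom emulates a whole-brain low-leakage DCE-MRI study at desk scale:
a half-dose bolus acquisition of 300 frames at 3.2 s (injection after frame
10, TR 2.48 ms, flip 15 degrees, VFA pre-scan at 5/10/15/18 degrees,
relaxivity 4 s^-1 mM^-1), an abstract label-map geometry with arterial,
grey-matter, white-matter and enhancing-lesion compartments, and a cohort
layer reproducing the study's group structure (13 controls vs 12 patients,
normal-appearing white matter K_i means 0.020 vs 0.052 ml/100g/min).

Tissue curves follow the irreversible one-compartment (Patlak) forward
model

    C_t(t) = K_i' * int_0^t C_a dtau + V_b' * C_a(t)

with, optionally, the instantaneous vascular term replaced by a dispersed
one — the discrete convolution of the AIF with F' exp(-t/theta), theta
chosen so the discrete trapezoid area of the residue channel equals V_b'
exactly.  The instantaneous form matches the fitted Patlak model, making
closure tests exact; the dispersed form carries a recoverable flow truth
for the deconvolution path.  Concentration maps to signal through the SPGR
model with R1(t) = 1/T10 + r1 C(t); a multiplicative linear drift and
Gaussian signal noise (appropriate at region-mean SNR; not Rician) are
applied last.  All randomness is driven by a mandatory seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import integrate, optimize, special

from .aif import Aif
from .perfusion import convolution_matrix
from .relaxometry import AcquisitionParams, DynamicSeries, VfaStack, spgr_signal

__all__ = [
    "AifParams",
    "CompartmentTruth",
    "PhantomConfig",
    "GroundTruth",
    "gamma_variate",
    "make_aif",
    "make_phantom",
    "make_cohort",
]


def gamma_variate(t_s: np.ndarray, peak: float, t0_s: float, alpha: float, tp_s: float) -> np.ndarray:
    """Gamma-variate bolus curve, zero before arrival, maximum ``peak`` at t0+tp.

    ``C(t) = peak * (t'/tp)^alpha * exp(alpha (1 - t'/tp))`` with t' = t - t0.
    """
    t = np.asarray(t_s, dtype=float) - t0_s
    out = np.zeros_like(t)
    pos = t > 0
    u = t[pos] / tp_s
    out[pos] = peak * u**alpha * np.exp(alpha * (1.0 - u))
    return out


def gamma_variate_auc(peak: float, alpha: float, tp_s: float) -> float:
    """Closed-form integral of :func:`gamma_variate` over (t0, inf), in mM*s.

    Substituting u = t'/tp gives peak * tp * e^alpha * Gamma(alpha+1) /
    alpha^(alpha+1)."""
    return peak * tp_s * np.exp(alpha) * special.gamma(alpha + 1) / alpha ** (alpha + 1)


class AifParams(BaseModel):
    """Parametric arterial input: gamma-variate first pass, recirculation as
    the first pass dispersed through an exponential transit-time kernel, and
    a slow mono-exponential washout plateau.  The default peak (~3 mM)
    corresponds to a half-dose bolus; the washout keeps the late curve near
    10% of peak over a 16-minute acquisition, as blood-pool gadolinium does."""

    arrival_s: float = Field(40.0, gt=0, description="bolus arrival time (s)")
    peak_mM: float = Field(3.0, gt=0, description="first-pass peak concentration (mM)")
    alpha: float = Field(2.5, gt=0, description="gamma-variate shape")
    tp_s: float = Field(8.0, gt=0, description="time to peak after arrival (s)")
    recirc_frac: float = Field(0.25, ge=0, description="recirculated fraction of the first pass")
    recirc_tau_s: float = Field(30.0, gt=0, description="recirculation dispersion constant (s)")
    washout_frac: float = Field(0.25, ge=0, description="washout plateau fraction of peak")
    washout_tau_s: float = Field(900.0, gt=0, description="washout decay constant (s)")

    model_config = {"frozen": True}


def make_aif(params: AifParams, time_s: np.ndarray, injection_time_s: float | None = None) -> Aif:
    """Evaluate the parametric AIF on a uniform time axis (seconds).

    The curve is zero before arrival, non-negative and smooth, with a
    single local (hence global) maximum at the first-pass peak — the
    recirculation appears as a shoulder, not a second peak.  Doubling
    ``peak_mM`` doubles the whole curve.

    Raises
    ------
    ValueError
        If the bolus arrives before the injection time, or the time axis is
        not uniformly spaced (the dispersion kernel needs a regular grid).
    """
    t = np.asarray(time_s, dtype=float)
    if injection_time_s is not None and params.arrival_s < injection_time_s:
        raise ValueError("bolus arrival precedes the injection time")
    dts = np.diff(t)
    if not np.allclose(dts, dts[0]):
        raise ValueError("make_aif requires a uniform time axis")
    dt = float(dts[0])

    first = gamma_variate(t, params.peak_mM, params.arrival_s, params.alpha, params.tp_s)
    if params.recirc_frac > 0:
        s = np.arange(t.size) * dt
        kernel = np.exp(-s / params.recirc_tau_s) / params.recirc_tau_s
        recirc = params.recirc_frac * np.convolve(first, kernel)[: t.size] * dt
    else:
        recirc = np.zeros_like(first)
    # Washout onset follows the normalized cumulative first pass: it rises
    # only while the bolus is still large, which keeps the summed curve
    # unimodal (an independent rise term would produce a second maximum).
    tw = np.clip(t - params.arrival_s, 0.0, None)
    cum = np.cumsum(first) * dt
    onset = cum / cum[-1] if cum[-1] > 0 else cum
    wash = params.peak_mM * params.washout_frac * onset * np.exp(-tw / params.washout_tau_s)
    ca = first + recirc + wash
    return Aif(conc_mM=ca, time_min=t / 60.0, source_voxel=-1, peak_frame=int(np.argmax(ca)))


class CompartmentTruth(BaseModel):
    """Generating parameters for one phantom compartment.

    ki in ml (100 g)^-1 min^-1, cbv in ml (100 g)^-1, cbf in
    ml (100 g)^-1 min^-1, t10 in ms, m0 in arbitrary signal units.
    """

    n_voxels: int = Field(gt=0)
    t10_ms: float = Field(gt=0)
    m0: float = Field(gt=0)
    ki: float = 0.0
    cbv: float = Field(0.0, ge=0)
    cbf: float = Field(0.0, ge=0)
    is_artery: bool = False


#: Compartment defaults: baseline T1s are typical 3 T values; NAWM K_i is the
#: healthy-control mean, the enhancing lesion the patient lesion mean; the
#: GM/WM CBV ratio is 1.9.
DEFAULT_COMPARTMENTS: dict[str, CompartmentTruth] = {
    "artery": CompartmentTruth(n_voxels=5, t10_ms=1650.0, m0=1200.0, is_artery=True),
    "GM": CompartmentTruth(n_voxels=60, t10_ms=1600.0, m0=1000.0, ki=0.045, cbv=3.42, cbf=55.0),
    "NAWM": CompartmentTruth(n_voxels=60, t10_ms=1100.0, m0=900.0, ki=0.020, cbv=1.80, cbf=27.0),
    "CEL": CompartmentTruth(n_voxels=20, t10_ms=1400.0, m0=950.0, ki=0.139, cbv=2.20, cbf=30.0),
}


class PhantomConfig(BaseModel):
    """Full phantom specification; ``seed`` is mandatory for any noise."""

    acquisition: AcquisitionParams = AcquisitionParams()
    compartments: dict[str, CompartmentTruth] = Field(
        default_factory=lambda: dict(DEFAULT_COMPARTMENTS)
    )
    aif_params: AifParams = AifParams()
    noise_sd: float = Field(0.2, ge=0, description="Gaussian signal noise SD (a.u.)")
    drift_pct_per_min: float = 0.2
    vascular_model: str = Field("instantaneous", pattern="^(instantaneous|dispersed)$")
    seed: int = 0

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "PhantomConfig":
        if not any(c.is_artery for c in self.compartments.values()):
            raise ValueError("phantom needs an arterial compartment")
        inj_s = self.acquisition.injection_frame * self.acquisition.frame_interval_s
        if self.aif_params.arrival_s < inj_s:
            raise ValueError("bolus arrival precedes the injection time")
        return self


@dataclass
class GroundTruth:
    """Generating truths serialized alongside every phantom: per-compartment
    parameters, per-voxel labels, and the generating AIF curve."""

    compartments: dict[str, CompartmentTruth]
    labels: np.ndarray
    aif: Aif
    vascular_model: str
    noise_sd: float
    drift_pct_per_min: float
    seed: int
    theta_min: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "compartments": {k: v.model_dump() for k, v in self.compartments.items()},
                "labels": self.labels.ravel().tolist(),
                "aif_conc_mM": self.aif.conc_mM.tolist(),
                "aif_time_min": self.aif.time_min.tolist(),
                "vascular_model": self.vascular_model,
                "noise_sd": self.noise_sd,
                "drift_pct_per_min": self.drift_pct_per_min,
                "seed": self.seed,
                "theta_min": self.theta_min,
            },
            indent=1,
        )


def _dispersed_theta_min(vb_raw: float, f_raw_per_min: float, dt_min: float) -> float:
    """Decay constant theta (min) of the residue exp(-t/theta) whose discrete
    trapezoid area on the frame grid equals vb_raw / f_raw exactly.

    The trapezoid area of exp(-t/theta) sampled at dt is
    dt * (1/2 + 1/(exp(dt/theta) - 1)); its infimum (theta -> 0) is dt/2, so
    mean transit times below half a frame cannot be represented.
    """
    target = vb_raw / f_raw_per_min  # mean transit time, minutes
    if target <= dt_min / 2:
        raise ValueError(
            f"mean transit time {target * 60:.2f} s is below half the frame "
            f"interval; not representable on this grid"
        )

    def area(theta: float) -> float:
        x = dt_min / theta
        tail = 0.0 if x > 500 else 1.0 / np.expm1(x)
        return dt_min * (0.5 + tail) - target

    return float(optimize.brentq(area, dt_min * 1e-4, dt_min * 1e4))


def _tissue_concentration(
    truth: CompartmentTruth,
    aif: Aif,
    vascular_model: str,
    dt_min: float,
) -> tuple[np.ndarray, float | None]:
    """Noise-free tissue concentration for one compartment; returns the curve
    and (for the dispersed model) theta in minutes."""
    ca = aif.conc_mM
    t_min = aif.time_min
    ki_raw = truth.ki / 100.0
    vb_raw = truth.cbv / 100.0
    leak = ki_raw * integrate.cumulative_trapezoid(ca, t_min, initial=0.0)
    if vascular_model == "instantaneous" or vb_raw == 0:
        return leak + vb_raw * ca, None
    f_raw = truth.cbf / 100.0
    if f_raw <= 0:
        raise ValueError(f"dispersed vascular model needs cbf > 0 (compartment with cbv={truth.cbv})")
    theta = _dispersed_theta_min(vb_raw, f_raw, dt_min)
    h_vasc = f_raw * np.exp(-(t_min - t_min[0]) / theta)
    a = convolution_matrix(ca, dt_min)
    return leak + a @ h_vasc, theta


def make_phantom(
    config: PhantomConfig,
) -> tuple[VfaStack, DynamicSeries, dict[str, np.ndarray], GroundTruth]:
    """Synthesize a VFA stack, a dynamic series, compartment masks and truths.

    The voxel grid is an abstract (N, 1, 1) label map — compartments are
    contiguous blocks, not anatomy.  Arterial voxels carry the AIF itself.
    Identical seeds give bit-identical output.
    """
    acq = config.acquisition
    t_s = acq.time_s
    dt_min = acq.frame_interval_s / 60.0
    inj_s = acq.injection_frame * acq.frame_interval_s
    aif = make_aif(config.aif_params, t_s, injection_time_s=inj_s)

    names = list(config.compartments)
    n_total = sum(c.n_voxels for c in config.compartments.values())
    shape = (n_total, 1, 1)
    labels = np.empty(n_total, dtype=object)
    masks = {name: np.zeros(shape, dtype=bool) for name in names}

    vfa = np.zeros((len(acq.vfa_flips_deg), *shape))
    dyn = np.zeros((*shape, acq.n_frames))
    theta_used: dict[str, float] = {}

    start = 0
    for name in names:
        truth = config.compartments[name]
        stop = start + truth.n_voxels
        labels[start:stop] = name
        masks[name][start:stop, 0, 0] = True

        if truth.is_artery:
            conc = aif.conc_mM
        else:
            conc, theta = _tissue_concentration(truth, aif, config.vascular_model, dt_min)
            if theta is not None:
                theta_used[name] = theta
        r1 = 1000.0 / truth.t10_ms + acq.relaxivity_r1 * conc  # s^-1
        t1_ms_t = 1000.0 / r1
        sig = spgr_signal(truth.m0, t1_ms_t, acq.flip_deg, acq.tr_ms)
        dyn[start:stop, 0, 0, :] = sig[None, :]

        for fi, flip in enumerate(acq.vfa_flips_deg):
            vfa[fi, start:stop, 0, 0] = spgr_signal(truth.m0, truth.t10_ms, flip, acq.tr_ms)
        start = stop

    if config.drift_pct_per_min != 0:
        dyn *= 1.0 + config.drift_pct_per_min / 100.0 * (t_s / 60.0)

    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        dyn += rng.normal(0.0, config.noise_sd, size=dyn.shape)
        vfa += rng.normal(0.0, config.noise_sd, size=vfa.shape)
        np.clip(dyn, 0.0, None, out=dyn)
        np.clip(vfa, 0.0, None, out=vfa)

    stack = VfaStack(signals=vfa, flips_deg=acq.vfa_flips_deg, tr_ms=acq.tr_ms)
    series = DynamicSeries(signal=dyn, params=acq)
    truths = GroundTruth(
        compartments=dict(config.compartments),
        labels=labels.reshape(shape),
        aif=aif,
        vascular_model=config.vascular_model,
        noise_sd=config.noise_sd,
        drift_pct_per_min=config.drift_pct_per_min,
        seed=config.seed,
        theta_min=theta_used,
    )
    return stack, series, masks, truths


#: Cohort defaults mirroring the study structure: group sizes, age
#: distributions, and NAWM K_i group means/SDs (ml/100g/min).
COHORT_DEFAULTS = {
    "n_hc": 13,
    "n_rrms": 12,
    "age_mean": {"HC": 31.08, "RRMS": 42.75},
    "age_sd": {"HC": 10.38, "RRMS": 10.47},
    "ki_mean": {"HC": 0.020, "RRMS": 0.052},
    "ki_sd": {"HC": 0.038, "RRMS": 0.037},
    "cbv_mean": 1.8,
    "cbv_sd": 0.4,
    "cbf_mean": 27.0,
    "cbf_sd": 5.0,
    # Between-method (ROI vs segmentation) error SD per measurement; a pair
    # difference then has SD sqrt(2) * 0.0285 ~ 0.040.
    "method_sd": 0.0285,
    "method_bias": 0.0,
    "age_slope": 0.0,
}


def make_cohort(
    n_hc: int | None = None,
    n_rrms: int | None = None,
    seed: int = 0,
    **overrides,
):
    """Simulate a per-subject cohort table for the group-level statistics.

    Each subject gets a latent NAWM K_i drawn from their group's normal
    distribution (plus an optional linear age effect), observed twice —
    once per analysis method — with independent Gaussian method error.
    Returns ``(table, truth)``: a tidy DataFrame with columns
    subject_id/group/age/region/method/ki/cbv/cbf (one row per
    subject x method) and the generating settings.

    With ``method_sd=0`` and ``method_bias=0`` the two methods agree
    exactly (Bland-Altman mean difference 0, ICC 1).
    """
    import pandas as pd

    cfg = dict(COHORT_DEFAULTS)
    cfg.update(overrides)
    n_hc = n_hc if n_hc is not None else cfg["n_hc"]
    n_rrms = n_rrms if n_rrms is not None else cfg["n_rrms"]
    if n_hc < 2 or n_rrms < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(seed)

    rows = []
    sid = 0
    latents = {}
    for group, n in (("HC", n_hc), ("RRMS", n_rrms)):
        ages = rng.normal(cfg["age_mean"][group], cfg["age_sd"][group], size=n)
        ages = np.clip(ages, 18.0, 80.0)
        base = rng.normal(cfg["ki_mean"][group], cfg["ki_sd"][group], size=n)
        base = base + cfg["age_slope"] * (ages - cfg["age_mean"][group])
        cbv = rng.normal(cfg["cbv_mean"], cfg["cbv_sd"], size=n)
        cbf = rng.normal(cfg["cbf_mean"], cfg["cbf_sd"], size=n)
        for i in range(n):
            sid += 1
            subj = f"S{sid:03d}"
            latents[subj] = float(base[i])
            for method in ("roi", "segmentation"):
                err = rng.normal(0.0, cfg["method_sd"]) if cfg["method_sd"] > 0 else 0.0
                bias = cfg["method_bias"] if method == "segmentation" else 0.0
                rows.append(
                    {
                        "subject_id": subj,
                        "group": group,
                        "age": float(ages[i]),
                        "region": "NAWM",
                        "method": method,
                        "ki": float(base[i] + err + bias),
                        "cbv": float(max(cbv[i], 0.1)),
                        "cbf": float(max(cbf[i], 1.0)),
                    }
                )
    table = pd.DataFrame(rows)
    truth = {"settings": cfg, "latent_ki": latents, "seed": seed}
    return table, truth
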