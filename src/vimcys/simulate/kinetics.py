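"""Synthetic plate-reader kinetics with a two-ionization rate law.

The probe-incorporation rate at a given pH follows

    k(pH) = baseline_rate + sum_i limiting_rates[i] / (1 + 10**(pKa_i - pH))

and each sample well's fluorescence follows logistic growth

    F(t) = f0 * fmax * exp(k t) / (fmax + f0 * (exp(k t) - 1))

which starts at f0, saturates at fmax, and is exactly log-linear
(ln F(t)/f0 = k t) in the early phase - the property the downstream slope
estimator relies on.  A saturating-exponential alternative
(F = fmax - (fmax - f0) exp(-k t)) is available behind the preset's
``curve_family`` flag to probe estimator robustness.  Background wells
(no protein) are flat at f0 plus noise.
"""

from __future__ import annotations

import numpy as np

from ..alkylation import KineticTrace
from .presets import KineticsPreset

__all__ = ["true_kobs", "logistic_fluorescence", "exponential_fluorescence",
           "make_kinetics_plate"]


def true_kobs(preset: KineticsPreset, ph: float) -> float:
    """Closed-form generating rate law at one pH (min^-1)."""
    if not np.isfinite(ph):
        raise ValueError("pH must be finite")
    k = preset.baseline_rate
    for pka, lim in zip(preset.pka_values, preset.limiting_rates):
        k += lim / (1.0 + 10.0 ** (pka - ph))
    return float(k)


def logistic_fluorescence(t, f0: float, fmax: float, k: float):
    t = np.asarray(t, dtype=float)
    e = np.exp(np.clip(k * t, -700, 700))
    return f0 * fmax * e / (fmax + f0 * (e - 1.0))


def exponential_fluorescence(t, f0: float, fmax: float, k: float):
    t = np.asarray(t, dtype=float)
    return fmax - (fmax - f0) * np.exp(-k * t)


_FAMILIES = {"logistic": logistic_fluorescence,
             "exponential": exponential_fluorescence}


def make_kinetics_plate(preset: KineticsPreset,
                        seed: int | None = None) -> list[KineticTrace]:
    """Generate one plate: per pH, `replicates` sample wells plus
    background wells, with additive Gaussian noise.  Identical preset and
    seed give identical output."""
    rng = np.random.default_rng(preset.seed if seed is None else seed)
    curve = _FAMILIES[preset.curve_family]
    t = np.asarray(preset.times)
    traces: list[KineticTrace] = []
    for ph in preset.ph_grid:
        ph_final = float(ph + rng.normal(0.0, preset.ph_jitter_sd)) \
            if preset.ph_jitter_sd > 0 else float(ph)
        k = true_kobs(preset, ph_final)
        for rep in range(1, preset.replicates + 1):
            clean = curve(t, preset.f0, preset.fmax, k)
            noisy = clean + rng.normal(0.0, preset.noise_sd, size=t.shape) \
                if preset.noise_sd > 0 else clean
            traces.append(KineticTrace(
                well_id=f"{preset.variant}-pH{ph:g}-s{rep}",
                role="sample", variant=preset.variant, ph_nominal=float(ph),
                ph_final=ph_final, replicate=rep, times=t.copy(),
                fluorescence=noisy,
            ))
        for rep in range(1, preset.background_wells + 1):
            flat = np.full_like(t, preset.f0)
            noisy = flat + rng.normal(0.0, preset.noise_sd, size=t.shape) \
                if preset.noise_sd > 0 else flat
            traces.append(KineticTrace(
                well_id=f"{preset.variant}-pH{ph:g}-b{rep}",
                role="background", variant=preset.variant, ph_nominal=float(ph),
                ph_final=ph_final, replicate=rep, times=t.copy(),
                fluorescence=noisy,
            ))
    return traces
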