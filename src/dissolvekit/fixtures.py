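"""Synthetic dissolution data: release curves, noisy batches, raw autosampler
concentrations.

Everything here is a pure function of its arguments and a seed, so any test
or demonstration can regenerate its inputs exactly.  Noise is additive
Gaussian — a unit-level random offset (between-unit variability, e.g.
content uniformity) plus independent per-observation error (within-unit,
e.g. assay scatter) — matching the unit-weight least-squares objective used
for fitting.  Clipping to [0, 100] is off by default because it biases
estimates near the extremes; turn it on for realism demonstrations only.

`generate_raw_concentrations` inverts the sampling-volume correction: given
a target percent-dissolved curve and vessel metadata it produces the unique
concentration sequence the autosampler would have reported, time point by
time point, so that the matching correction mode maps it back exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dissolution_data import CORRECTION_MODES, DissolutionBatch, DissolutionDataError
from .release_models import get_model

__all__ = [
    "NoiseSpec",
    "generate_profile",
    "generate_batch",
    "generate_raw_concentrations",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model for synthetic batches.

    within_unit_sd : additive Gaussian SD (%) per observation.
    between_unit_sd : SD (%) of a per-unit random offset.
    seed : RNG seed; generation is deterministic given it.
    clip : clip generated values into [0, 100].
    """

    within_unit_sd: float = 0.0
    between_unit_sd: float = 0.0
    seed: int = 0
    clip: bool = False

    def __post_init__(self) -> None:
        if self.within_unit_sd < 0 or self.between_unit_sd < 0:
            raise ValueError("noise SDs must be non-negative")


def generate_profile(model: str, params, times, noise: NoiseSpec | None = None) -> np.ndarray:
    """One percent-dissolved series: model prediction plus additive noise."""
    spec = get_model(model)
    t = np.asarray(times, dtype=float)
    f = np.asarray(spec.predict(t, *params), dtype=float)
    if noise is not None and noise.within_unit_sd > 0:
        rng = np.random.default_rng(noise.seed)
        f = f + rng.normal(0.0, noise.within_unit_sd, size=f.shape)
    if noise is not None and noise.clip:
        f = np.clip(f, 0.0, 100.0)
    return f


def generate_batch(
    model: str,
    params,
    times,
    n_units: int = 12,
    noise: NoiseSpec | None = None,
    label: str = "simulated",
) -> DissolutionBatch:
    """A multi-unit percent-dissolved batch around one release curve.

    Each unit receives a between-unit offset plus independent within-unit
    noise; with zero noise all units coincide with the model curve.
    """
    if n_units < 1:
        raise ValueError("n_units must be at least 1")
    spec = get_model(model)
    t = np.asarray(times, dtype=float)
    curve = np.asarray(spec.predict(t, *params), dtype=float)
    units = np.tile(curve, (n_units, 1))
    if noise is not None:
        rng = np.random.default_rng(noise.seed)
        if noise.between_unit_sd > 0:
            units = units + rng.normal(0.0, noise.between_unit_sd, size=(n_units, 1))
        if noise.within_unit_sd > 0:
            units = units + rng.normal(0.0, noise.within_unit_sd, size=units.shape)
        if noise.clip:
            units = np.clip(units, 0.0, 100.0)
    units = np.clip(units, 0.0, None)  # a batch cannot hold negative release
    return DissolutionBatch(
        label=label, times=t, units=units, value_kind="percent_dissolved",
    )


def generate_raw_concentrations(
    f_true,
    dose: float,
    v_or: float,
    v_s: float,
    replaced: bool,
    mode: str = "as-printed",
) -> np.ndarray:
    """Concentration sequence whose correction recovers `f_true` exactly.

    Solves the correction recurrence forward: at the i-th draw (0-based),
    with vessel volume ``V_i`` (reduced by earlier draws unless replaced)
    and drug mass ``removed`` carried off by earlier aliquots,

    - as-printed:    C_i = (F_i/100) * (dose - removed) / V_i
    - mass-balance:  C_i = ((F_i/100) * dose - removed) / V_i

    Raises
    ------
    DissolutionDataError
        If the target curve is infeasible: the as-printed denominator is
        exhausted (drug removed reaches the dose) or the mass balance would
        require a negative concentration.
    """
    if mode not in CORRECTION_MODES:
        raise DissolutionDataError(f"unknown correction mode {mode!r}")
    f = np.asarray(f_true, dtype=float)
    if f.ndim != 1:
        raise DissolutionDataError("f_true must be a 1-D series")
    if np.any((f < 0) | (f > 100)):
        raise DissolutionDataError("f_true must lie in [0, 100]")
    if dose <= 0 or v_or <= 0 or v_s < 0:
        raise DissolutionDataError("dose and v_or must be positive, v_s non-negative")
    if not replaced and v_s * (f.size - 1) >= v_or:
        raise DissolutionDataError("cumulative sampled volume exhausts the vessel")

    conc = np.empty_like(f)
    removed = 0.0
    for i in range(f.size):
        vol = v_or if replaced else v_or - i * v_s
        if mode == "as-printed":
            denom = dose - removed
            if denom <= 0:
                raise DissolutionDataError(
                    f"infeasible target curve: removed drug reaches the dose "
                    f"before time index {i + 1}"
                )
            conc[i] = (f[i] / 100.0) * denom / vol
        else:
            c = ((f[i] / 100.0) * dose - removed) / vol
            if c < 0:
                raise DissolutionDataError(
                    f"infeasible target curve at time index {i + 1}: mass balance "
                    "would need a negative concentration"
                )
            conc[i] = c
        removed += conc[i] * v_s
    return conc
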