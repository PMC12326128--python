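"""Model parameters.

All scalar constants of the network live in a single validated record,
:class:`ModelParams`.  Connection effectiveness values and spreads follow the
published parameterisation of the architecture (Gaussian inter-area synapses,
Mexican-hat lateral synapses, one-to-one winner-takes-all and premotor
projections).  The visual/auditory pathway asymmetry is expressed through a
single divisor ``av_ratio`` < 1: every visual-pathway effectiveness is the
corresponding auditory one divided by ``av_ratio``, so visual-pathway synapses
are structurally stronger whenever ``av_ratio`` < 1.

Quantities the source tables leave unprinted (input spreads, input strength,
per-pathway gains, the slow offset decays of the cross-modal and interneuron
drives) are exposed as configurable fields whose shipped defaults are the
package's calibration; see ``docs/methods.md``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

__all__ = ["ModelParams", "load_params", "save_params"]


def _positive(name: str, value: float) -> None:
    if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
        raise ValueError(f"parameter {name!r} must be a finite positive number, got {value!r}")


@dataclass(frozen=True)
class ModelParams:
    """Validated record of every scalar parameter of the network.

    Invariants are enforced at construction time: time constants, spreads and
    the integration step must be strictly positive, ``rt_threshold`` lies in
    (0, 1), ``av_ratio`` in (0, 1], and the derived visual-pathway weights obey
    ``wmv0 = wma0/av_ratio``, ``wav0 = wva0/av_ratio``, ``wiv0 = wia0/av_ratio``
    by construction.
    """

    # --- geometry and single-unit properties -------------------------------
    n_units: int = 180            # units per area, 1 degree spacing
    theta: float = 25.0           # sigmoid central abscissa
    slope: float = 0.3            # sigmoid slope
    tau_unit: float = 3.0         # membrane time constant [ms]

    # --- input and synaptic dynamics [ms] -----------------------------------
    tau_a: float = 15.0           # auditory external-input filter
    tau_v: float = 25.0           # visual external-input filter
    tau_in: float = 180.0         # slow feedback inhibition onto input areas
    tau_c: float = 3.0            # cross-modal drive, rise
    tau_c_off: float = 80.0       # cross-modal drive, offset decay (calibrated)
    tau_iex: float = 15.0         # interneuron excitatory drive, rise
    tau_q_off: float = 1750.0     # interneuron excitatory drive, offset decay (calibrated)
    tau_iin: float = 15.0         # interneuron reciprocal (WTA) inhibition filter
    tau_m: float = 15.0           # feedforward drive to the multisensory area

    # --- transmission delays [ms] -------------------------------------------
    delta_t_cross: float = 16.0   # cross-modal synaptic delay
    delta_t_m: float = 50.0       # unisensory -> multisensory delay
    delta_t_pm: float = 50.0      # multisensory -> premotor delay

    # --- external input ------------------------------------------------------
    sigma_a: float = 50.0         # spatial spread of auditory input [deg] (calibrated)
    sigma_v: float = 4.0          # spatial spread of visual input [deg]
    i0_a: float = 55.0            # nominal auditory input effectiveness (calibrated)
    i0_v: float = 55.0            # nominal visual input effectiveness (calibrated)
    jitter_rel: float = 0.3       # uniform effectiveness jitter, +/- fraction of nominal (calibrated)
    stim_duration_ms: float = 60.0

    # --- pathway asymmetry ---------------------------------------------------
    av_ratio: float = 0.95        # visual/auditory asymmetry divisor (calibrated), in (0, 1]

    # --- connection effectiveness and spreads (auditory side; visual derived) -
    wma0: float = 0.12            # A -> M feedforward peak
    wm_sd: float = 5.0            # SD of A->M and V->M kernels [deg]
    wva0: float = 0.12            # A -> V cross-modal peak
    wva_sd: float = 5.0           # SD of A->V kernel [deg]
    wav_sd: float = 7.0           # SD of V->A kernel [deg]
    wia0: float = 0.2             # A -> Ia feedforward peak
    wi_sd: float = 5.0            # SD of input -> interneuron kernels [deg]
    laiv0: float = 0.0057         # Iv -> A feedback inhibition peak
    lvia0: float = 0.016          # Ia -> V feedback inhibition peak
    fb_sd: float = 15.0           # SD of feedback inhibition kernels [deg]
    wta0: float = 10.0            # Ia <-> Iv one-to-one reciprocal inhibition
    wpmm0: float = 1.0            # M -> PM one-to-one feedforward

    # Mexican-hat lateral connectivity (excitatory / inhibitory Gaussian pairs)
    la_ex0: float = 5.0
    la_ex_sd: float = 3.0
    la_in0: float = 4.0
    la_in_sd: float = 120.0
    lv_ex0: float = 5.0
    lv_ex_sd: float = 3.0
    lv_in0: float = 4.0
    lv_in_sd: float = 120.0
    lm_ex0: float = 0.4
    lm_ex_sd: float = 4.0
    lm_in0: float = 0.3
    lm_in_sd: float = 8.0

    # --- per-pathway input gains (calibration knobs, see docs/methods.md) ----
    gain_a: float = 1.0           # A-area net input
    gain_v: float = 1.0           # V-area net input
    gain_cross_a: float = 20.0    # cross-modal drive into A (from V)
    gain_cross_v: float = 23.0    # cross-modal drive into V (from A)
    gain_inh_a: float = 26.0      # interneuron feedback inhibition onto A (from Iv)
    gain_inh_v: float = 40.0      # interneuron feedback inhibition onto V (from Ia)
    gain_ie: float = 60.0         # input-area -> interneuron excitatory drive
    gain_wta: float = 3.0         # interneuron reciprocal inhibition
    gain_m: float = 95.0          # feedforward drive into the multisensory area
    gain_m_lat: float = 10.0      # lateral Mexican-hat drive within the multisensory area
    gain_pm: float = 38.0         # multisensory -> premotor drive

    # --- readout and integration ---------------------------------------------
    rt_threshold: float = 0.30    # premotor detection threshold, fraction of saturation
    anticipatory_cutoff_ms: float = 100.0
    response_window_ms: float = 1000.0
    dt_ms: float = 0.1            # explicit-Euler integration step
    rng_seed: int = 0

    # ------------------------------------------------------------------ checks
    def __post_init__(self) -> None:
        if not isinstance(self.n_units, int) or self.n_units < 3:
            raise ValueError(f"n_units must be an integer >= 3, got {self.n_units!r}")
        for name in (
            "tau_unit", "tau_a", "tau_v", "tau_in", "tau_c", "tau_c_off",
            "tau_iex", "tau_q_off", "tau_iin", "tau_m",
            "sigma_a", "sigma_v", "wm_sd", "wva_sd", "wav_sd", "wi_sd", "fb_sd",
            "la_ex_sd", "la_in_sd", "lv_ex_sd", "lv_in_sd", "lm_ex_sd", "lm_in_sd",
            "la_ex0", "la_in0", "lv_ex0", "lv_in0", "lm_ex0", "lm_in0",
            "i0_a", "i0_v", "stim_duration_ms", "dt_ms", "slope",
        ):
            _positive(name, getattr(self, name))
        for name in (
            "wma0", "wva0", "wia0", "laiv0", "lvia0", "wta0", "wpmm0",
            "delta_t_cross", "delta_t_m", "delta_t_pm", "jitter_rel",
            "gain_a", "gain_v", "gain_cross_a", "gain_cross_v", "gain_inh_a", "gain_inh_v", "gain_ie",
            "gain_wta", "gain_m", "gain_m_lat", "gain_pm",
        ):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v >= 0):
                raise ValueError(f"parameter {name!r} must be finite and >= 0, got {v!r}")
        if not 0.0 < self.rt_threshold < 1.0:
            raise ValueError(f"rt_threshold must lie in (0, 1), got {self.rt_threshold!r}")
        if not 0.0 < self.av_ratio <= 1.0:
            raise ValueError(f"av_ratio must lie in (0, 1], got {self.av_ratio!r}")
        if self.jitter_rel >= 1.0:
            raise ValueError("jitter_rel must be < 1 (effectiveness must stay positive)")
        if self.dt_ms > self.tau_unit / 3.0:
            raise ValueError(
                f"dt_ms={self.dt_ms} too large for tau_unit={self.tau_unit}: "
                "the explicit-Euler stability guard requires dt <= tau_unit/3"
            )

    # ------------------------------------------------------------- derivations
    @property
    def wmv0(self) -> float:
        """V -> M feedforward peak, wma0 / av_ratio."""
        return self.wma0 / self.av_ratio

    @property
    def wav0(self) -> float:
        """V -> A cross-modal peak, wva0 / av_ratio."""
        return self.wva0 / self.av_ratio

    @property
    def wiv0(self) -> float:
        """V -> Iv feedforward peak, wia0 / av_ratio."""
        return self.wia0 / self.av_ratio

    @property
    def positions_deg(self):
        """Azimuth of each unit: index 0..n-1 mapped to -90..+89 deg (0 deg at 90).

        Distances between units are plain absolute differences in degrees, with
        no wraparound; every protocol lives within +/-20 deg of the centre, so
        edge effects are negligible.
        """
        import numpy as np

        half = self.n_units // 2
        return np.arange(self.n_units, dtype=float) - half

    def sigma_for(self, modality: str) -> float:
        if modality == "a":
            return self.sigma_a
        if modality == "v":
            return self.sigma_v
        raise ValueError(f"unknown modality {modality!r}")

    def i0_for(self, modality: str) -> float:
        if modality == "a":
            return self.i0_a
        if modality == "v":
            return self.i0_v
        raise ValueError(f"unknown modality {modality!r}")

    # ------------------------------------------------------------------ config
    def replace(self, **changes: Any) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter key(s): {sorted(unknown)}")
        return cls(**d)


def load_params(path: str | Path) -> ModelParams:
    """Read a flat key/value YAML parameter file into a ModelParams record."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"parameter file {path} must hold a flat key/value mapping")
    return ModelParams.from_dict(data)


def save_params(params: ModelParams, path: str | Path) -> None:
    """Write a ModelParams record to a flat key/value YAML file."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
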