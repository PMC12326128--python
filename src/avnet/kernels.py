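"""Activation function and connectivity kernels.

Every inter-area projection is a Gaussian-in-distance weight matrix; lateral
intra-area connectivity is a Mexican hat (difference of two Gaussians); the
winner-takes-all projection between the interneuron pools and the multisensory
to premotor projection are one-to-one (diagonal) matrices.  Kernel builders
are pure: identical parameters yield bit-identical matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .params import ModelParams

__all__ = ["sigmoid", "gaussian_kernel", "mexican_hat_kernel", "KernelSet", "build_kernels"]


def sigmoid(u, theta: float = 25.0, slope: float = 0.3):
    """Sigmoidal activation 1 / (1 + exp(-slope * (u - theta))).

    Saturates at 1 for large net input and vanishes for strongly negative
    input; strictly increasing everywhere.  Rejects non-finite input.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("sigmoid: net input must be finite")
    with np.errstate(over="ignore"):     # exp overflow is saturation, by design
        return 1.0 / (1.0 + np.exp(-slope * (u - theta)))


def _distance_matrix(positions: np.ndarray) -> np.ndarray:
    p = np.asarray(positions, dtype=float)
    return np.abs(p[:, None] - p[None, :])


def gaussian_kernel(w0: float, sd_deg: float, positions) -> np.ndarray:
    """Gaussian weight matrix: entry (j, k) = w0 * exp(-d(j,k)^2 / (2 sd^2)).

    ``d`` is the absolute azimuthal distance in degrees between units j and k;
    the matrix is symmetric and attains its maximum ``w0`` on the diagonal.
    """
    if w0 < 0:
        raise ValueError(f"gaussian_kernel: w0 must be >= 0, got {w0}")
    if sd_deg <= 0:
        raise ValueError(f"gaussian_kernel: sd_deg must be > 0, got {sd_deg}")
    d = _distance_matrix(positions)
    return w0 * np.exp(-(d * d) / (2.0 * sd_deg * sd_deg))


def mexican_hat_kernel(lex0: float, sd_ex: float, lin0: float, sd_in: float, positions) -> np.ndarray:
    """Mexican-hat lateral kernel: difference of an excitatory and a wider
    inhibitory Gaussian, ``lex0 - lin0`` on the diagonal.

    Self-connections (d = 0) are retained: the formula is defined for all unit
    pairs and no exclusion rule applies.
    """
    for name, v in (("lex0", lex0), ("sd_ex", sd_ex), ("lin0", lin0), ("sd_in", sd_in)):
        if v <= 0:
            raise ValueError(f"mexican_hat_kernel: {name} must be > 0, got {v}")
    d2 = _distance_matrix(positions) ** 2
    return lex0 * np.exp(-d2 / (2.0 * sd_ex * sd_ex)) - lin0 * np.exp(-d2 / (2.0 * sd_in * sd_in))


@dataclass(frozen=True)
class KernelSet:
    """Precomputed weight matrices for every connection family.

    Naming: ``cross_av`` projects *into* A *from* V (and so on); ``ff_*`` are
    feedforward families, ``fb_*`` the inhibitory feedback from interneurons
    onto the opposite input area, ``lat_*`` the lateral Mexican hats, ``wta``
    the one-to-one reciprocal inhibition between interneuron pools and ``pm``
    the one-to-one multisensory-to-premotor projection.
    """

    cross_av: np.ndarray  # into A from V, peak wva0/av_ratio, SD wav_sd
    cross_va: np.ndarray  # into V from A, peak wva0, SD wva_sd
    ff_ma: np.ndarray     # into M from A
    ff_mv: np.ndarray     # into M from V
    ff_ia: np.ndarray     # into Ia from A
    ff_iv: np.ndarray     # into Iv from V
    fb_laiv: np.ndarray   # into A from Iv (inhibitory)
    fb_lvia: np.ndarray   # into V from Ia (inhibitory)
    lat_a: np.ndarray
    lat_v: np.ndarray
    lat_m: np.ndarray
    wta: np.ndarray       # Ia <-> Iv, diagonal
    pm: np.ndarray        # into PM from M, diagonal

    def __iter__(self):
        for f in fields(self):
            yield f.name, getattr(self, f.name)


def build_kernels(params: ModelParams) -> KernelSet:
    """Construct every weight matrix of the network from a parameter record."""
    pos = params.positions_deg
    n = params.n_units
    return KernelSet(
        cross_av=gaussian_kernel(params.wav0, params.wav_sd, pos),
        cross_va=gaussian_kernel(params.wva0, params.wva_sd, pos),
        ff_ma=gaussian_kernel(params.wma0, params.wm_sd, pos),
        ff_mv=gaussian_kernel(params.wmv0, params.wm_sd, pos),
        ff_ia=gaussian_kernel(params.wia0, params.wi_sd, pos),
        ff_iv=gaussian_kernel(params.wiv0, params.wi_sd, pos),
        fb_laiv=gaussian_kernel(params.laiv0, params.fb_sd, pos),
        fb_lvia=gaussian_kernel(params.lvia0, params.fb_sd, pos),
        lat_a=mexican_hat_kernel(params.la_ex0, params.la_ex_sd, params.la_in0, params.la_in_sd, pos),
        lat_v=mexican_hat_kernel(params.lv_ex0, params.lv_ex_sd, params.lv_in0, params.lv_in_sd, pos),
        lat_m=mexican_hat_kernel(params.lm_ex0, params.lm_ex_sd, params.lm_in0, params.lm_in_sd, pos),
        wta=params.wta0 * np.eye(n),
        pm=params.wpmm0 * np.eye(n),
    )
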