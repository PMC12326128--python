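"""Network dynamics: delayed, coupled first-order rate equations.

Six populations (auditory A, visual V, interneuron pools Ia and Iv,
multisensory M, premotor PM) of ``n_units`` topographic units each.  Every
population activity obeys

    tau_unit * dy/dt = -y + F(u),

with F the sigmoidal activation and ``u`` the area's gained net input.  The
synaptic drives entering ``u`` are themselves first-order filtered:

* external input ``e`` with the modality time constant (tau_a, tau_v);
* cross-modal drive ``c``: delayed (delta_t_cross) presynaptic output through
  a Gaussian kernel, fast rise (tau_c) and slow offset decay (tau_c_off);
* interneuron excitatory drive ``q``: same-modality input area through a
  Gaussian kernel, fast rise (tau_iex) and slow offset decay (tau_q_off);
* interneuron reciprocal (winner-takes-all) inhibition ``z`` (tau_iin);
* feedback inhibition onto the input areas ``i`` (slow, tau_in);
* multisensory feedforward drive ``f``: delayed (delta_t_m) A and V outputs
  (tau_m).

The two asymmetric (fast-rise / slow-decay) traces give the network its only
long memory: the cross-modal trace carries the temporal binding window and the
asynchronous ventriloquism bias, and the interneuron trace keeps the winning
modality's inhibition of its rival alive across the interstimulus intervals at
which the modality-switch cost is observed (see docs/methods.md).

Delays are pure transport delays implemented as ring buffers on presynaptic
outputs; the integrator is explicit Euler.  The engine is vectorised over a
batch of independent trials (columns), which share parameters but may have
entirely different stimulus schedules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .kernels import KernelSet, build_kernels
from .params import ModelParams
from .stimuli import StimulusEvent, TrialSequence, external_field

__all__ = ["NetworkState", "Network", "SimulationResult", "simulate", "net_input"]

AREAS = ("a", "v", "ia", "iv", "m", "pm")


@dataclass
class NetworkState:
    """Instantaneous state of all populations and synaptic filter variables.

    Activity arrays are (n_units, batch); every activity lies in [0, 1].
    Ring buffers hold past outputs of A, V (for the cross-modal and
    multisensory delays) and of M (for the premotor delay).
    """

    y: dict                    # area -> (n, b) activity
    e_a: np.ndarray            # filtered external input, auditory
    e_v: np.ndarray
    c_a: np.ndarray            # cross-modal drive into A (from V)
    c_v: np.ndarray
    q_ia: np.ndarray           # interneuron excitatory drive
    q_iv: np.ndarray
    z_ia: np.ndarray           # WTA inhibition onto Ia (from Iv)
    z_iv: np.ndarray
    i_a: np.ndarray            # slow feedback inhibition onto A (from Iv)
    i_v: np.ndarray
    f_m: np.ndarray            # feedforward drive into M
    buf_a: np.ndarray          # (depth, n, b) past y_a
    buf_v: np.ndarray
    buf_m: np.ndarray
    buf_idx: int
    t_ms: float

    @classmethod
    def zeros(cls, n: int, batch: int, depth_av: int, depth_m: int, dtype=np.float64) -> "NetworkState":
        z = lambda: np.zeros((n, batch), dtype=dtype)
        return cls(
            y={a: np.zeros((n, batch), dtype=dtype) for a in AREAS},
            e_a=z(), e_v=z(), c_a=z(), c_v=z(),
            q_ia=z(), q_iv=z(), z_ia=z(), z_iv=z(),
            i_a=z(), i_v=z(), f_m=z(),
            buf_a=np.zeros((depth_av, n, batch), dtype=dtype),
            buf_v=np.zeros((depth_av, n, batch), dtype=dtype),
            buf_m=np.zeros((depth_m, n, batch), dtype=dtype),
            buf_idx=0,
            t_ms=0.0,
        )


class _KernelView:
    """Attribute view over the dtype-cast kernel dictionary."""

    __slots__ = ("_d",)

    def __init__(self, d):
        self._d = d

    def __getattr__(self, name):
        return self._d[name]


def _sig(u, theta, slope):
    # validation-free sigmoid for the integration hot loop
    return 1.0 / (1.0 + np.exp(slope * (theta - u)))


def _asym_step(x, target, dt: float, tau_rise: float, tau_fall: float, work=None) -> None:
    """In-place Euler step of a first-order filter with distinct rise/fall rates.

    ``work`` is an optional scratch array of the same shape.
    """
    if work is None:
        work = np.empty_like(x)
    np.subtract(target, x, out=work)
    if tau_rise == tau_fall:
        work *= dt / tau_rise
    else:
        r_fall, r_rise = dt / tau_fall, dt / tau_rise
        work *= np.where(work > 0, r_rise, r_fall)
    x += work


def _sig_inplace(u, theta: float, slope: float) -> None:
    """u <- F(u), computed in place."""
    np.subtract(theta, u, out=u)
    u *= slope
    np.exp(u, out=u)
    u += 1.0
    np.reciprocal(u, out=u)


def _relax(y, f, g: float) -> None:
    """y += g * (f - y), destroying f."""
    f -= y
    f *= g
    y += f


def net_input(state: NetworkState, kernels: KernelSet, params: ModelParams, area: str) -> np.ndarray:
    """Per-unit net input of one area given the current state.

    Input areas sum the filtered external drive, their lateral Mexican-hat
    drive, the (gained) cross-modal drive and subtract the slow inhibition fed
    back from the opposite interneuron pool.  Interneurons receive their
    (gained) excitatory drive minus the one-to-one reciprocal inhibition.  M
    receives the gained delayed feedforward drive plus its lateral drive; PM a
    one-to-one gained drive from delayed M output.
    """
    p = params
    if area == "a":
        return p.gain_a * (state.e_a + kernels.lat_a @ state.y["a"]
                           + p.gain_cross_a * state.c_a - p.gain_inh_a * state.i_a)
    if area == "v":
        return p.gain_v * (state.e_v + kernels.lat_v @ state.y["v"]
                           + p.gain_cross_v * state.c_v - p.gain_inh_v * state.i_v)
    if area == "ia":
        return p.gain_ie * state.q_ia - p.gain_wta * state.z_ia
    if area == "iv":
        return p.gain_ie * state.q_iv - p.gain_wta * state.z_iv
    if area == "m":
        return p.gain_m * state.f_m + p.gain_m_lat * (kernels.lat_m @ state.y["m"])
    if area == "pm":
        lag = int(round(p.delta_t_pm / p.dt_ms))
        y_m_del = state.buf_m[(state.buf_idx - lag) % state.buf_m.shape[0]]
        return p.gain_pm * (p.wpmm0 * y_m_del)
    raise ValueError(f"unknown area {area!r}")


@dataclass
class SimulationResult:
    """Recorded output of a simulation run."""

    params: ModelParams
    dt_ms: float
    pm_max: np.ndarray                       # (n_steps, batch) max premotor activity
    traces: dict = field(default_factory=dict)        # area -> (n_rec, n, batch)
    trace_times_ms: np.ndarray | None = None
    snapshots: dict = field(default_factory=dict)     # t_ms -> {area: (n, batch)}
    events: list = field(default_factory=list)        # per-column event logs

    @property
    def pm_times_ms(self) -> np.ndarray:
        return np.arange(self.pm_max.shape[0]) * self.dt_ms

    def trace_frame(self, stride: int = 1) -> "pd.DataFrame":
        """Long-format trajectory table (time_ms, area, unit_index, activity).

        Only meaningful for single-column runs; raises otherwise.
        """
        import pandas as pd

        rows = []
        for area, arr in self.traces.items():
            if arr.shape[2] != 1:
                raise ValueError("trace_frame requires a single-trial (batch=1) run")
            for ti in range(0, arr.shape[0], stride):
                t = self.trace_times_ms[ti]
                for j in range(arr.shape[1]):
                    rows.append((t, area, j, arr[ti, j, 0]))
        return pd.DataFrame(rows, columns=["time_ms", "area", "unit_index", "activity"])


class Network:
    """Batched integrator of the full six-population network."""

    def __init__(self, params: ModelParams, kernels: KernelSet | None = None, batch: int = 1,
                 dtype=np.float32):
        self.params = params
        self.kernels = kernels if kernels is not None else build_kernels(params)
        self.batch = batch
        # working copies of the kernels in the compute dtype (float32 by default:
        # the dynamics are smooth and heavily over-resolved in time, so single
        # precision is far below the integration error; see docs/methods.md)
        self.dtype = np.dtype(dtype)
        # far Gaussian tails underflow to single-precision denormals, which
        # cripple GEMM throughput; they are physically meaningless, so flush
        self._K = {}
        for name, mat in self.kernels:
            m = np.ascontiguousarray(mat, dtype=self.dtype)
            m[np.abs(m) < 1e-25] = 0.0
            self._K[name] = m
        n, dt = params.n_units, params.dt_ms
        self._lag_cross = self._exact_lag(params.delta_t_cross, dt)
        self._lag_m = self._exact_lag(params.delta_t_m, dt)
        self._lag_pm = self._exact_lag(params.delta_t_pm, dt)
        depth_av = max(self._lag_cross, self._lag_m) + 1
        depth_m = self._lag_pm + 1
        self.state = NetworkState.zeros(n, batch, depth_av, depth_m, dtype=self.dtype)
        self._E_a = np.zeros((n, batch), dtype=self.dtype)
        self._E_v = np.zeros((n, batch), dtype=self.dtype)
        self._tmp = {name: np.empty((n, batch), dtype=self.dtype) for name in ("x", "w", "u")}

    @staticmethod
    def _exact_lag(delay_ms: float, dt_ms: float) -> int:
        lag = round(delay_ms / dt_ms)
        if not np.isclose(lag * dt_ms, delay_ms):
            raise ValueError(f"delay {delay_ms} ms is not a multiple of dt = {dt_ms} ms")
        return max(lag, 1) if delay_ms > 0 else 0

    def reset(self) -> None:
        n = self.params.n_units
        self.state = NetworkState.zeros(
            n, self.batch, self.state.buf_a.shape[0], self.state.buf_m.shape[0],
            dtype=self.dtype,
        )
        self._E_a[:] = 0.0
        self._E_v[:] = 0.0

    # -------------------------------------------------------------- stepping
    def step(self) -> None:
        """Advance the state by one Euler step using the current external drive.

        Allocation-free: every product and update is written into buffers
        preallocated at construction (the loop is memory-bound at realistic
        batch sizes, so temporaries would dominate the cost).
        """
        p, s = self.params, self.state
        k = _KernelView(self._K)
        t = self._tmp
        dt = p.dt_ms
        depth_av = s.buf_a.shape[0]
        depth_m = s.buf_m.shape[0]

        ya_cross = s.buf_a[(s.buf_idx - self._lag_cross) % depth_av]
        yv_cross = s.buf_v[(s.buf_idx - self._lag_cross) % depth_av]
        ya_m = s.buf_a[(s.buf_idx - self._lag_m) % depth_av]
        yv_m = s.buf_v[(s.buf_idx - self._lag_m) % depth_av]
        ym_pm = s.buf_m[(s.buf_idx - self._lag_pm) % depth_m]
        y = s.y

        # synaptic filters
        _asym_step(s.e_a, self._E_a, dt, p.tau_a, p.tau_a, t["w"])
        _asym_step(s.e_v, self._E_v, dt, p.tau_v, p.tau_v, t["w"])
        np.dot(k.cross_av, yv_cross, out=t["x"])
        _asym_step(s.c_a, t["x"], dt, p.tau_c, p.tau_c_off, t["w"])
        np.dot(k.cross_va, ya_cross, out=t["x"])
        _asym_step(s.c_v, t["x"], dt, p.tau_c, p.tau_c_off, t["w"])
        np.dot(k.ff_ia, y["a"], out=t["x"])
        _asym_step(s.q_ia, t["x"], dt, p.tau_iex, p.tau_q_off, t["w"])
        np.dot(k.ff_iv, y["v"], out=t["x"])
        _asym_step(s.q_iv, t["x"], dt, p.tau_iex, p.tau_q_off, t["w"])
        np.multiply(y["iv"], p.wta0, out=t["x"])
        _asym_step(s.z_ia, t["x"], dt, p.tau_iin, p.tau_iin, t["w"])
        np.multiply(y["ia"], p.wta0, out=t["x"])
        _asym_step(s.z_iv, t["x"], dt, p.tau_iin, p.tau_iin, t["w"])
        np.dot(k.fb_laiv, y["iv"], out=t["x"])
        _asym_step(s.i_a, t["x"], dt, p.tau_in, p.tau_in, t["w"])
        np.dot(k.fb_lvia, y["ia"], out=t["x"])
        _asym_step(s.i_v, t["x"], dt, p.tau_in, p.tau_in, t["w"])
        np.dot(k.ff_ma, ya_m, out=t["x"])
        np.dot(k.ff_mv, yv_m, out=t["w"])
        t["x"] += t["w"]
        _asym_step(s.f_m, t["x"], dt, p.tau_m, p.tau_m, t["w"])

        # population activities: u assembled in place, then y += g*(F(u) - y)
        g = dt / p.tau_unit

        u = t["u"]
        np.dot(k.lat_a, y["a"], out=u)
        u += s.e_a
        np.multiply(s.c_a, p.gain_cross_a, out=t["x"]); u += t["x"]
        np.multiply(s.i_a, p.gain_inh_a, out=t["x"]); u -= t["x"]
        if p.gain_a != 1.0:
            u *= p.gain_a
        _sig_inplace(u, p.theta, p.slope)
        _relax(y["a"], u, g)

        np.dot(k.lat_v, y["v"], out=u)
        u += s.e_v
        np.multiply(s.c_v, p.gain_cross_v, out=t["x"]); u += t["x"]
        np.multiply(s.i_v, p.gain_inh_v, out=t["x"]); u -= t["x"]
        if p.gain_v != 1.0:
            u *= p.gain_v
        _sig_inplace(u, p.theta, p.slope)
        _relax(y["v"], u, g)

        np.multiply(s.q_ia, p.gain_ie, out=u)
        np.multiply(s.z_ia, p.gain_wta, out=t["x"]); u -= t["x"]
        _sig_inplace(u, p.theta, p.slope)
        _relax(y["ia"], u, g)

        np.multiply(s.q_iv, p.gain_ie, out=u)
        np.multiply(s.z_iv, p.gain_wta, out=t["x"]); u -= t["x"]
        _sig_inplace(u, p.theta, p.slope)
        _relax(y["iv"], u, g)

        np.dot(k.lat_m, y["m"], out=u)
        u *= p.gain_m_lat
        np.multiply(s.f_m, p.gain_m, out=t["x"]); u += t["x"]
        _sig_inplace(u, p.theta, p.slope)
        _relax(y["m"], u, g)

        np.multiply(ym_pm, p.gain_pm * p.wpmm0, out=u)
        _sig_inplace(u, p.theta, p.slope)
        _relax(y["pm"], u, g)

        # rotate delay buffers (buf_idx counts steps; each ring is indexed mod its depth)
        s.buf_idx += 1
        s.buf_a[s.buf_idx % depth_av] = y["a"]
        s.buf_v[s.buf_idx % depth_av] = y["v"]
        s.buf_m[s.buf_idx % depth_m] = y["m"]
        s.t_ms += dt

    # ------------------------------------------------------------------- run
    def run(
        self,
        schedules: Sequence[Sequence[StimulusEvent]],
        t_end_ms: float,
        trace_areas: Sequence[str] = (),
        trace_stride: int = 10,
        snapshot_times_ms: Sequence[float] = (),
        reset: bool = True,
    ) -> SimulationResult:
        """Integrate the network under per-column stimulus schedules.

        ``schedules`` holds one event list per batch column.  Premotor peak
        activity is recorded every step; full area trajectories (optional) are
        recorded every ``trace_stride`` steps; full-area snapshots are taken at
        the requested times (rounded to the step grid).
        """
        p = self.params
        dt = p.dt_ms
        if len(schedules) != self.batch:
            raise ValueError(f"expected {self.batch} schedules, got {len(schedules)}")
        if reset:
            self.reset()
        n_steps = int(round(t_end_ms / dt))
        pos = p.positions_deg

        # event edges, keyed by step index
        edges: dict[int, list[tuple[float, str, int, np.ndarray]]] = {}
        for col, events in enumerate(schedules):
            for ev in events:
                if ev.onset_ms < 0:
                    raise ValueError("negative onsets rejected")
                profile = external_field(ev, p.sigma_for(ev.modality), pos).astype(self.dtype)
                on = int(round(ev.onset_ms / dt))
                off = int(round(ev.offset_ms / dt))
                edges.setdefault(on, []).append((+1.0, ev.modality, col, profile))
                edges.setdefault(off, []).append((-1.0, ev.modality, col, profile))

        snap_steps = {int(round(t / dt)): float(t) for t in snapshot_times_ms}
        pm_max = np.empty((n_steps, self.batch))
        traces = {a: [] for a in trace_areas}
        trace_times = []
        snapshots: dict[float, dict[str, np.ndarray]] = {}

        for step_i in range(n_steps):
            for sign, mod, col, profile in edges.get(step_i, ()):
                tgt = self._E_a if mod == "a" else self._E_v
                tgt[:, col] += sign * profile
            self.step()
            pm_max[step_i] = self.state.y["pm"].max(axis=0)
            if trace_areas and step_i % trace_stride == 0:
                trace_times.append(self.state.t_ms)
                for a in trace_areas:
                    traces[a].append(self.state.y[a].copy())
            if step_i in snap_steps:
                snapshots[snap_steps[step_i]] = {a: self.state.y[a].copy() for a in AREAS}

        return SimulationResult(
            params=p,
            dt_ms=dt,
            pm_max=pm_max,
            traces={a: np.array(v) for a, v in traces.items()},
            trace_times_ms=np.array(trace_times) if trace_times else None,
            snapshots=snapshots,
            events=[list(s) for s in schedules],
        )


def simulate(
    stimuli: TrialSequence,
    params: ModelParams,
    kernels: KernelSet | None = None,
    trace_areas: Sequence[str] = AREAS,
    trace_stride: int = 10,
    snapshot_times_ms: Sequence[float] = (),
    extra_window_ms: float | None = None,
) -> SimulationResult:
    """Run one trial sequence and return sampled trajectories plus event log.

    The simulated span covers the last stimulus offset plus the response
    window.  Deterministic: all randomness lives in the sequence generator.
    """
    events = sorted(stimuli.events, key=lambda e: e.onset_ms)
    window = params.response_window_ms if extra_window_ms is None else extra_window_ms
    t_end = (events[-1].offset_ms if events else 0.0) + window
    net = Network(params, kernels=kernels, batch=1)
    return net.run(
        [events], t_end,
        trace_areas=trace_areas, trace_stride=trace_stride,
        snapshot_times_ms=snapshot_times_ms,
    )
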