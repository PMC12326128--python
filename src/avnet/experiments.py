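"""Experimental protocols and behavioural readouts.

Reaction times are read from the premotor population: the simulated RT of a
trial is the first upward crossing of the detection threshold (30% of the
saturation activity) by any premotor unit after the trial's onset.  Perceived
stimulus positions are read from the input areas as the barycentre (activity
weighted mean azimuth) of the evoked activity, evaluated at the stimulus
offset, when the cross-modal interaction has settled.

Protocols:

* :func:`run_rt_task` - randomised A/V/AV sequences at 1000-3000 ms ISIs,
  yielding the seven repeat/switch stimulus configurations;
* :func:`run_ventriloquism` - synchronous AV pairs at 0-20 deg disparity,
  auditory localisation bias;
* :func:`run_sw_grid` - switch-trial RTs over the ISI x disparity plane;
* :func:`run_bias_vs_isi` - auditory bias for asynchronous AV pairs;
* :func:`run_sensitivity` - switch-cost sweeps over cross-modal and lateral
  connection strengths.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dynamics import Network, SimulationResult
from .kernels import build_kernels
from .params import ModelParams
from .stimuli import StimulusEvent, TrialSequence, make_av_pair, make_rt_sequence

__all__ = [
    "TrialRecord",
    "detect_rt",
    "perceived_position",
    "auditory_bias",
    "run_rt_task",
    "run_singles",
    "run_ventriloquism",
    "run_sw_grid",
    "run_bias_vs_isi",
    "run_switch_pairs",
    "run_sensitivity",
    "measure_input_latency",
    "measure_crossmodal_latency",
]


@dataclass(frozen=True)
class TrialRecord:
    """Per-trial outcome of an experiment run."""

    label: str
    rt_ms: float | None
    anticipatory: bool
    no_response: bool
    perceived_a_deg: float | None = None
    perceived_v_deg: float | None = None
    true_a_deg: float | None = None
    true_v_deg: float | None = None
    isi_ms: float | None = None
    disparity_deg: float | None = None
    rep: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.rt_ms is not None and self.rt_ms < 0:
            raise ValueError("rt_ms must be >= 0 when present")


def _records_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


# --------------------------------------------------------------------- readouts
def detect_rt(
    premotor_trace: np.ndarray,
    dt_ms: float,
    onset_ms: float,
    threshold: float = 0.30,
    response_window_ms: float | None = None,
) -> float | None:
    """Reaction time from a premotor activity trace.

    The RT is the first *upward* crossing of ``threshold`` after ``onset_ms``,
    minus the onset, with sub-step linear interpolation.  If the trace is
    still above threshold at onset (tail of a previous response), the search
    waits for it to fall below before accepting a crossing.  Returns ``None``
    if the threshold is never crossed (within the response window, when one is
    given).  The trace may be (T,) peak activity or (T, n_units).
    """
    trace = np.asarray(premotor_trace, dtype=float)
    if trace.ndim == 2:
        trace = trace.max(axis=1)
    if trace.ndim != 1:
        raise ValueError("premotor_trace must be 1- or 2-dimensional")
    i0 = int(np.ceil(onset_ms / dt_ms))
    if onset_ms < 0 or i0 >= trace.shape[0]:
        raise ValueError(f"onset {onset_ms} ms lies outside the trace")
    seg = trace[i0:]
    above = seg >= threshold
    if above[0]:
        # skip the tail of an earlier response
        below = np.nonzero(~above)[0]
        if below.size == 0:
            return None
        start = below[0]
    else:
        start = 0
    idx = np.nonzero(above[start:])[0]
    if idx.size == 0:
        return None
    k = start + idx[0]
    # linear interpolation between samples k-1 and k
    if k == 0:
        t_cross = i0 * dt_ms
    else:
        y0, y1 = seg[k - 1], seg[k]
        frac = (threshold - y0) / (y1 - y0) if y1 > y0 else 1.0
        t_cross = (i0 + k - 1 + frac) * dt_ms
    rt = t_cross - onset_ms
    if response_window_ms is not None and rt > response_window_ms:
        return None
    return float(rt)


def perceived_position(activity_vector: np.ndarray, positions: np.ndarray) -> float | None:
    """Barycentre (activity-weighted mean azimuth) of a population profile.

    Returns ``None`` (no percept) for an all-zero profile.
    """
    a = np.asarray(activity_vector, dtype=float)
    p = np.asarray(positions, dtype=float)
    total = a.sum()
    if total <= 0.0:
        return None
    return float((a * p).sum() / total)


def auditory_bias(perceived_a: float, true_a: float, true_v: float) -> float:
    """Auditory localisation bias as a percentage of the audiovisual distance.

    100% means the sound is heard at the visual position (full capture), 0%
    means veridical localisation.  Undefined at zero disparity.
    """
    if true_a == true_v:
        raise ValueError("auditory bias is undefined at zero audiovisual disparity")
    return 100.0 * (true_a - perceived_a) / (true_a - true_v)


# ------------------------------------------------------------------ internals
def _batched_run(
    params: ModelParams,
    sequences: Sequence[TrialSequence],
    t_end_ms: float,
    kernels=None,
    snapshot_times_ms: Sequence[float] = (),
) -> SimulationResult:
    net = Network(params, kernels=kernels or build_kernels(params), batch=len(sequences))
    schedules = [sorted(s.events, key=lambda e: e.onset_ms) for s in sequences]
    return net.run(schedules, t_end_ms, snapshot_times_ms=snapshot_times_ms)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Per-repetition substreams derived from one global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------- RT protocols
def _sequence_records(
    params: ModelParams,
    seqs: Sequence[TrialSequence],
    result: SimulationResult,
    exclude_anticipatory: bool = True,
) -> list[TrialRecord]:
    records = []
    for col, seq in enumerate(seqs):
        trace = result.pm_max[:, col]
        for i, (label, onset) in enumerate(zip(seq.labels, seq.onsets_ms)):
            rt = detect_rt(trace, params.dt_ms, onset,
                           threshold=params.rt_threshold,
                           response_window_ms=params.response_window_ms)
            anticipatory = rt is not None and rt < params.anticipatory_cutoff_ms
            records.append(TrialRecord(
                label=label,
                rt_ms=rt,
                anticipatory=anticipatory and exclude_anticipatory,
                no_response=rt is None,
                isi_ms=(seq.onsets_ms[i] - seq.onsets_ms[i - 1]) if i else None,
                rep=col,
                seed=seq.seed,
            ))
    return records


RT_CONFIGS = ("RpA", "SwA", "RpV", "SwV", "RpAV", "SwA->AV", "SwV->AV")


def run_rt_task(
    params: ModelParams,
    n_valid_per_config: int = 100,
    seq_len: int = 20,
    seed: int = 0,
    isi_low_ms: float = 1000.0,
    isi_high_ms: float = 3000.0,
    max_batches: int = 20,
) -> pd.DataFrame:
    """Randomised-sequence RT task over the seven stimulus configurations.

    Independent sequences are simulated (state carried across trials within a
    sequence, reset between sequences) until every configuration has at least
    ``n_valid_per_config`` valid trials (responses that are neither missing
    nor anticipatory).  Returns the per-trial record table.
    """
    kernels = build_kernels(params)
    counts = {c: 0 for c in RT_CONFIGS}
    all_records: list[TrialRecord] = []
    # expected valid trials per config per sequence ~ (seq_len - 1) / 9
    per_batch = max(4, int(np.ceil(n_valid_per_config * 9.5 / max(seq_len - 1, 1))))
    seeds = _spawn_seeds(seed, per_batch * max_batches)
    for b in range(max_batches):
        batch_seeds = seeds[b * per_batch:(b + 1) * per_batch]
        seqs = [
            make_rt_sequence(params, seq_len, isi_low_ms, isi_high_ms, seed=s)
            for s in batch_seeds
        ]
        t_end = max(s.end_ms for s in seqs) + params.response_window_ms
        result = _batched_run(params, seqs, t_end, kernels=kernels)
        recs = _sequence_records(params, seqs, result)
        all_records.extend(recs)
        for r in recs:
            if r.label in counts and not (r.anticipatory or r.no_response):
                counts[r.label] += 1
        if all(v >= n_valid_per_config for v in counts.values()):
            break
    return _records_frame(all_records)


def rt_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD/count of valid RTs per stimulus configuration."""
    valid = records[~records["anticipatory"] & ~records["no_response"]]
    valid = valid[valid["label"].isin(RT_CONFIGS)]
    g = valid.groupby("label")["rt_ms"]
    out = pd.DataFrame({"mean_rt_ms": g.mean(), "sd_rt_ms": g.std(), "n": g.count()})
    return out.reindex([c for c in RT_CONFIGS if c in out.index])


def run_singles(
    params: ModelParams,
    modalities: Sequence[str] = ("a", "v", "av"),
    n_reps: int = 100,
    seed: int = 0,
    position_deg: float = 0.0,
) -> pd.DataFrame:
    """RTs to isolated A, V and AV stimuli from the resting state.

    Used for the race-model analysis and the unisensory/multisensory RT
    ordering; every trial starts from a fully reset network.
    """
    kernels = build_kernels(params)
    # one jitter draw per repetition and modality channel, shared across the
    # A, V and AV conditions (common random numbers): condition comparisons
    # are paired, so mean differences are resolved at modest n
    rep_seeds = _spawn_seeds(seed, n_reps)
    seqs, labels = [], []
    start = 100.0
    j = params.jitter_rel
    for r in range(n_reps):
        rng = np.random.default_rng(rep_seeds[r])
        f_a, f_v = rng.uniform(1.0 - j, 1.0 + j, size=2)
        eff = {"a": params.i0_a * f_a, "v": params.i0_v * f_v}
        for m in modalities:
            events = tuple(
                StimulusEvent(comp, position_deg, start, params.stim_duration_ms,
                              eff[comp], 0)
                for comp in (("a", "v") if m == "av" else (m,))
            )
            seqs.append(TrialSequence(
                events=events, modalities=(m,), onsets_ms=(start,),
                labels=("first",), seed=rep_seeds[r]))
            labels.append(m)
    t_end = start + params.stim_duration_ms + params.response_window_ms
    result = _batched_run(params, seqs, t_end, kernels=kernels)
    rows = []
    for col, (seq, m) in enumerate(zip(seqs, labels)):
        rt = detect_rt(result.pm_max[:, col], params.dt_ms, start,
                       threshold=params.rt_threshold,
                       response_window_ms=params.response_window_ms)
        rows.append(TrialRecord(
            label=m.upper(), rt_ms=rt,
            anticipatory=rt is not None and rt < params.anticipatory_cutoff_ms,
            no_response=rt is None, rep=col, seed=seq.seed))
    return _records_frame(rows)


# -------------------------------------------------------------- space protocols
def _bias_trials(
    params: ModelParams,
    disparities_deg: Sequence[float],
    isi_ms: float,
    n_reps: int,
    seed: int,
    v_leads: bool = True,
) -> pd.DataFrame:
    """Bias measurements for signed disparities at one ISI (0 = synchronous)."""
    kernels = build_kernels(params)
    start = 100.0
    conds = [(d, r) for d in disparities_deg for r in range(n_reps)]
    seeds = _spawn_seeds(seed, len(conds))
    seqs = [
        make_av_pair(params, d, isi_ms, v_leads=v_leads, seed=s, start_ms=start)
        for (d, _), s in zip(conds, seeds)
    ]
    # the auditory percept is read at the offset of the A component
    a_onset = start + (isi_ms if v_leads else 0.0)
    snap_t = a_onset + params.stim_duration_ms
    t_end = snap_t + 50.0
    result = _batched_run(params, seqs, t_end, kernels=kernels, snapshot_times_ms=[snap_t])
    y_a = result.snapshots[snap_t]["a"]
    y_v = result.snapshots[snap_t]["v"]
    pos = params.positions_deg
    rows = []
    for col, ((d, rep), seq) in enumerate(zip(conds, seqs)):
        pa = perceived_position(y_a[:, col], pos)
        pv = perceived_position(y_v[:, col], pos)
        bias = auditory_bias(pa, true_a=d, true_v=0.0) if (pa is not None and d != 0) else None
        rows.append({
            "disparity_deg": d, "abs_disparity_deg": abs(d), "isi_ms": isi_ms,
            "rep": rep, "perceived_a_deg": pa, "perceived_v_deg": pv,
            "bias_pct": bias, "seed": seq.seed,
        })
    return pd.DataFrame(rows)


def run_ventriloquism(
    params: ModelParams,
    disparities_deg: Sequence[float] = (5.0, 10.0, 15.0, 20.0),
    n_reps: int = 100,
    seed: int = 0,
    keep_trials: bool = False,
) -> pd.DataFrame:
    """Synchronous ventriloquism protocol: V fixed at 0 deg, A displaced left
    and right by each disparity; auditory bias averaged over the two sides.

    Returns one row per |disparity| with mean bias, SEM and trial count
    (``keep_trials=True`` returns the trial-level table instead).
    """
    signed = [s * d for d in disparities_deg for s in (+1, -1) if d != 0]
    trials = _bias_trials(params, signed, isi_ms=0.0, n_reps=n_reps, seed=seed)
    if keep_trials:
        return trials
    g = trials.dropna(subset=["bias_pct"]).groupby("abs_disparity_deg")["bias_pct"]
    return pd.DataFrame({
        "mean_bias_pct": g.mean(),
        "sem_bias_pct": g.sem(),
        "n": g.count(),
    }).reset_index()


def run_bias_vs_isi(
    params: ModelParams,
    isis_ms: Sequence[float] = (200.0, 500.0, 800.0),
    disparities_deg: Sequence[float] = (5.0, 10.0, 15.0, 20.0),
    n_reps: int = 250,
    seed: int = 0,
    v_leads: bool = True,
) -> pd.DataFrame:
    """Auditory bias for asynchronous AV pairs (V leading by default).

    Returns mean bias and SEM per (ISI, |disparity|) cell, sides averaged.
    """
    frames = []
    seeds = _spawn_seeds(seed, len(isis_ms))
    for isi, s in zip(isis_ms, seeds):
        signed = [sg * d for d in disparities_deg for sg in (+1, -1) if d != 0]
        trials = _bias_trials(params, signed, isi_ms=isi, n_reps=n_reps, seed=s, v_leads=v_leads)
        frames.append(trials)
    trials = pd.concat(frames, ignore_index=True)
    g = trials.dropna(subset=["bias_pct"]).groupby(["isi_ms", "abs_disparity_deg"])["bias_pct"]
    return pd.DataFrame({
        "mean_bias_pct": g.mean(),
        "sem_bias_pct": g.sem(),
        "n": g.count(),
    }).reset_index()


# --------------------------------------------------------- spatiotemporal grid
def run_sw_grid(
    params: ModelParams,
    isis_ms: Sequence[float] = tuple(range(0, 1001, 100)),
    disparities_deg: Sequence[float] = (0.0, 5.0, 10.0, 15.0, 20.0),
    n_reps: int = 100,
    seed: int = 0,
    keep_trials: bool = False,
) -> pd.DataFrame:
    """Switch-trial RTs over the ISI x disparity plane.

    Each trial is an AV pair: at ISI 0 a synchronous (possibly disparate) AV
    stimulus; at positive ISI the two components are sequential, the second
    being a switch trial by construction.  Repetitions alternate the leading
    modality so cells average SwA and SwV.  RTs are measured from the second
    component's onset; responses faster than the anticipatory cutoff are kept
    here (at short ISIs the merged response genuinely crosses threshold early;
    see docs/methods.md), missing responses are dropped but counted.
    """
    kernels = build_kernels(params)
    start = 100.0
    rows = []
    # common random numbers: every cell reuses the same per-repetition seeds,
    # so the effectiveness jitter is paired across (isi, disparity) cells and
    # cell comparisons are far less noisy than independent draws would allow
    rep_seeds = _spawn_seeds(seed, n_reps)
    for isi in isis_ms:
        for d in disparities_deg:
            seqs = []
            for r in range(n_reps):
                v_leads = (r % 2 == 0)
                sign = +1 if (r // 2) % 2 == 0 else -1
                seqs.append(make_av_pair(params, sign * d, isi,
                                         v_leads=v_leads, seed=rep_seeds[r], start_ms=start))
            second_onset = start + isi
            t_end = second_onset + params.stim_duration_ms + params.response_window_ms
            result = _batched_run(params, seqs, t_end, kernels=kernels)
            for col, seq in enumerate(seqs):
                onset = seq.onsets_ms[-1]
                rt = detect_rt(result.pm_max[:, col], params.dt_ms, onset,
                               threshold=params.rt_threshold,
                               response_window_ms=params.response_window_ms)
                rows.append({
                    "isi_ms": isi, "disparity_deg": d,
                    "label": seq.labels[-1] if len(seq.labels) > 1 else "AV",
                    "rt_ms": rt, "no_response": rt is None,
                    "rep": col, "seed": seq.seed,
                })
    trials = pd.DataFrame(rows)
    if keep_trials:
        return trials
    ok = trials.dropna(subset=["rt_ms"])
    g = ok.groupby(["isi_ms", "disparity_deg"])["rt_ms"]
    out = pd.DataFrame({"mean_rt_ms": g.mean(), "sem_rt_ms": g.sem(), "n": g.count()})
    return out.reset_index()


# ------------------------------------------------------------------ sensitivity
def run_switch_pairs(
    params: ModelParams,
    n_reps: int = 100,
    seed: int = 0,
    isi_low_ms: float = 1000.0,
    isi_high_ms: float = 3000.0,
    modalities: Sequence[str] = ("a", "v", "av"),
) -> pd.DataFrame:
    """Repeat/switch RTs from two-stimulus trials at random long ISIs.

    For each repetition and each current modality, a repeat pair (same
    modality twice) and a switch pair (the other unisensory modality first)
    are simulated at an ISI drawn uniformly from the given range; the RT of
    the second stimulus is recorded under its condition label.  Equivalent to
    the sequence protocol at these ISIs, but cheaper and balanced by design.
    """
    from .stimuli import _trial_events, label_trials

    kernels = build_kernels(params)
    start = 100.0
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rep_seeds = _spawn_seeds(seed, n_reps)
    seqs = []
    for r in range(n_reps):
        isi = float(rng.uniform(isi_low_ms, isi_high_ms))
        rrng = np.random.default_rng(rep_seeds[r])
        for m in modalities:
            prevs = {"a": ("a", "v"), "v": ("v", "a"), "av": ("av", "a", "v")}[m]
            for prev in prevs:
                events = []
                events += _trial_events(params, prev, start, 0, rrng)
                events += _trial_events(params, m, start + isi, 1, rrng)
                mods = (prev, m)
                seqs.append(TrialSequence(
                    events=tuple(events), modalities=mods,
                    onsets_ms=(start, start + isi),
                    labels=tuple(label_trials(mods)), seed=rep_seeds[r]))
    t_end = start + isi_high_ms + params.stim_duration_ms + params.response_window_ms
    result = _batched_run(params, seqs, t_end, kernels=kernels)
    rows = []
    for col, seq in enumerate(seqs):
        onset = seq.onsets_ms[1]
        rt = detect_rt(result.pm_max[:, col], params.dt_ms, onset,
                       threshold=params.rt_threshold,
                       response_window_ms=params.response_window_ms)
        rows.append({
            "label": seq.labels[1], "rt_ms": rt,
            "isi_ms": seq.onsets_ms[1] - seq.onsets_ms[0],
            "no_response": rt is None,
            "anticipatory": rt is not None and rt < params.anticipatory_cutoff_ms,
            "rep": col, "seed": seq.seed,
        })
    return pd.DataFrame(rows)


def unisensory_switch_cost(pairs: pd.DataFrame) -> float:
    """Mean Sw - Rp RT difference per unisensory modality, averaged over A, V."""
    ok = pairs[~pairs["no_response"] & ~pairs["anticipatory"]]
    means = ok.groupby("label")["rt_ms"].mean()
    costs = []
    for m in ("A", "V"):
        costs.append(means[f"Sw{m}"] - means[f"Rp{m}"])
    return float(np.mean(costs))


def run_sensitivity(
    params: ModelParams,
    wva0_values: Sequence[float] = (0.08, 0.12, 0.16),
    lin0_values: Sequence[float] = (3.0, 4.0, 5.0),
    n_reps: int = 100,
    seed: int = 0,
    verbatim_wva0: bool = False,
) -> pd.DataFrame:
    """Switch-cost sensitivity to cross-modal and lateral connection strengths.

    One-dimensional sweeps around the base configuration: the cross-modal
    effectiveness wva0 is varied (its V->A counterpart follows through the
    AV ratio), then the lateral inhibitory strength Lin0 of both input areas is
    varied with the excitation/inhibition ratio Lex0/Lin0 held fixed.  For
    each grid point the unisensory switch cost is computed from repeat/switch
    pairs at ISIs uniform on 1000-3000 ms.  ``verbatim_wva0=True`` uses the
    source's printed sweep values {0.08, 0.012, 0.016} instead of the
    corrected {0.08, 0.12, 0.16} grid.
    """
    if verbatim_wva0:
        wva0_values = (0.08, 0.012, 0.016)
    ratio = params.la_ex0 / params.la_in0
    rows = []
    seeds = _spawn_seeds(seed, len(wva0_values) + len(lin0_values))
    si = 0
    for w in wva0_values:
        p = params.replace(wva0=w)
        pairs = run_switch_pairs(p, n_reps=n_reps, seed=seeds[si], modalities=("a", "v")); si += 1
        rows.append({"sweep": "wva0", "value": w,
                     "switch_cost_ms": unisensory_switch_cost(pairs)})
    for lin in lin0_values:
        p = params.replace(la_in0=lin, la_ex0=ratio * lin, lv_in0=lin, lv_ex0=ratio * lin)
        pairs = run_switch_pairs(p, n_reps=n_reps, seed=seeds[si], modalities=("a", "v")); si += 1
        rows.append({"sweep": "lin0", "value": lin,
                     "switch_cost_ms": unisensory_switch_cost(pairs)})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- latencies
def measure_input_latency(params: ModelParams, modality: str = "a",
                          sustain_ms: float = 400.0) -> float:
    """Response latency of an input area to a sustained nominal stimulus.

    The latency is the first time the peak unit of the stimulated area reaches
    90% of its steady-state response (the convention by which the input time
    constants were chosen).  Deterministic: no effectiveness jitter.
    """
    ev = StimulusEvent(modality, 0.0, 0.0, sustain_ms,
                       params.i0_for(modality), 0)
    net = Network(params, batch=1)
    res = net.run([[ev]], sustain_ms, trace_areas=(modality,), trace_stride=1)
    tr = res.traces[modality][:, :, 0]          # (T, n)
    peak_unit = int(tr[-1].argmax())
    y = tr[:, peak_unit]
    y_ss = y[-1]
    k = int(np.argmax(y >= 0.9 * y_ss))
    return float(res.trace_times_ms[k])


def measure_crossmodal_latency(params: ModelParams, modality: str = "a",
                               factor: float = 10.0, sustain_ms: float = 200.0) -> float:
    """Latency of the cross-modal influence on the opposite input area.

    Time after a unisensory stimulus's onset at which the *other* input
    area's peak activity first exceeds ``factor`` times its quiescent level.
    """
    other = "v" if modality == "a" else "a"
    from .kernels import sigmoid

    quiescent = float(sigmoid(np.zeros(1), params.theta, params.slope)[0])
    ev = StimulusEvent(modality, 0.0, 0.0, sustain_ms, params.i0_for(modality), 0)
    net = Network(params, batch=1)
    res = net.run([[ev]], sustain_ms, trace_areas=(other,), trace_stride=1)
    peak = res.traces[other][:, :, 0].max(axis=1)
    above = peak > factor * quiescent
    if not above.any():
        return float("inf")
    return float(res.trace_times_ms[int(np.argmax(above))])
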