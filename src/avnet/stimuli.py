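"""Stimulus construction and trial-sequence generation.

External stimuli are spatial Gaussians (centred on the stimulus azimuth, with
modality-specific spread) gated by a rectangular window in time; their
effectiveness is drawn per trial from a uniform distribution around the nominal
input strength to emulate within-subject variability.  Trial sequences carry
the repeat/switch condition labels of the reaction-time protocol: a trial is a
Repeat (Rp) if its modality matches the previous trial's, a Switch (Sw)
otherwise; audiovisual-to-unisensory transitions fit neither class and are
labelled ``excluded``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .params import ModelParams

__all__ = [
    "StimulusEvent",
    "TrialSequence",
    "external_field",
    "label_trials",
    "make_rt_sequence",
    "make_av_pair",
    "sample_effectiveness",
]

MODALITIES = ("a", "v")
TRIAL_MODALITIES = ("a", "v", "av")


@dataclass(frozen=True)
class StimulusEvent:
    """A single external input: one modality, one azimuth, one time window."""

    modality: str              # "a" or "v"
    position_deg: float        # azimuth, -90 .. +89
    onset_ms: float
    duration_ms: float
    effectiveness: float       # peak input strength (jitter already applied)
    trial_index: int = 0

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be 'a' or 'v', got {self.modality!r}")
        if self.duration_ms <= 0:
            raise ValueError(f"duration_ms must be > 0, got {self.duration_ms!r}")
        if self.onset_ms < 0:
            raise ValueError(f"onset_ms must be >= 0, got {self.onset_ms!r}")
        if not -90.0 <= self.position_deg < 90.0:
            raise ValueError(
                f"position_deg must lie within the represented space [-90, 90), "
                f"got {self.position_deg!r}"
            )
        if self.effectiveness <= 0:
            raise ValueError("effectiveness must be > 0")

    @property
    def offset_ms(self) -> float:
        return self.onset_ms + self.duration_ms


def external_field(event: StimulusEvent, sigma_r: float, positions) -> np.ndarray:
    """Spatial profile of an external stimulus over the unit grid.

    A Gaussian of amplitude ``event.effectiveness`` and spread ``sigma_r``
    centred on the stimulus azimuth.  The temporal gate is rectangular over
    [onset, onset + duration]; low-pass filtering with the modality's input
    time constant happens inside the dynamics.
    """
    if sigma_r <= 0:
        raise ValueError(f"sigma_r must be > 0, got {sigma_r}")
    p = np.asarray(positions, dtype=float)
    d2 = (p - event.position_deg) ** 2
    return event.effectiveness * np.exp(-d2 / (2.0 * sigma_r * sigma_r))


def label_trials(modalities: Sequence[str]) -> list[str]:
    """Condition labels from the modality sequence.

    The first trial is unlabelled (``first``); a trial repeating the previous
    modality is Rp, a unisensory trial after the other unisensory modality is
    Sw, a bimodal trial after a unisensory one is Sw<prev>->AV, and any
    unisensory trial following a bimodal one is ``excluded``.
    """
    labels: list[str] = []
    prev: str | None = None
    for m in modalities:
        if m not in TRIAL_MODALITIES:
            raise ValueError(f"unknown trial modality {m!r}")
        if prev is None:
            labels.append("first")
        elif m == prev:
            labels.append(f"Rp{m.upper()}")
        elif m == "av":
            labels.append(f"Sw{prev.upper()}->AV")
        elif prev == "av":
            labels.append("excluded")
        else:
            labels.append(f"Sw{m.upper()}")
        prev = m
    return labels


@dataclass(frozen=True)
class TrialSequence:
    """An ordered set of stimulus events grouped into labelled trials."""

    events: tuple[StimulusEvent, ...]
    modalities: tuple[str, ...]      # per trial: "a", "v" or "av"
    onsets_ms: tuple[float, ...]     # per trial
    labels: tuple[str, ...]          # per trial
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.modalities) != len(self.onsets_ms) or len(self.modalities) != len(self.labels):
            raise ValueError("modalities, onsets_ms and labels must have equal length")
        if list(self.labels) != label_trials(self.modalities):
            raise ValueError("labels inconsistent with the modality sequence")
        if any(e.onset_ms < 0 for e in self.events):
            raise ValueError("negative onsets rejected")

    @property
    def n_trials(self) -> int:
        return len(self.modalities)

    @property
    def end_ms(self) -> float:
        return max((e.offset_ms for e in self.events), default=0.0)

    def to_frame(self) -> pd.DataFrame:
        """One event per row: trial, modality, position, timing, label."""
        rows = [
            {
                "trial": e.trial_index,
                "modality": e.modality,
                "position_deg": e.position_deg,
                "onset_ms": e.onset_ms,
                "duration_ms": e.duration_ms,
                "effectiveness": e.effectiveness,
                "label": self.labels[e.trial_index],
            }
            for e in self.events
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, seed: int | None = None) -> "TrialSequence":
        events = tuple(
            StimulusEvent(
                modality=str(r.modality),
                position_deg=float(r.position_deg),
                onset_ms=float(r.onset_ms),
                duration_ms=float(r.duration_ms),
                effectiveness=float(r.effectiveness),
                trial_index=int(r.trial),
            )
            for r in frame.itertuples()
        )
        trial_ids = sorted({e.trial_index for e in events})
        if trial_ids != list(range(len(trial_ids))):
            raise ValueError("trial indices must be consecutive from 0")
        modalities, onsets = [], []
        for t in trial_ids:
            evs = [e for e in events if e.trial_index == t]
            mods = {e.modality for e in evs}
            modalities.append("av" if mods == {"a", "v"} else evs[0].modality)
            onsets.append(min(e.onset_ms for e in evs))
        return cls(
            events=events,
            modalities=tuple(modalities),
            onsets_ms=tuple(onsets),
            labels=tuple(label_trials(modalities)),
            seed=seed,
        )


def sample_effectiveness(params: ModelParams, modality: str, rng: np.random.Generator) -> float:
    """Effectiveness drawn uniformly on [1-j, 1+j] times the nominal strength."""
    nominal = params.i0_for(modality)
    j = params.jitter_rel
    return float(nominal * rng.uniform(1.0 - j, 1.0 + j))


def _trial_events(
    params: ModelParams,
    modality: str,
    onset_ms: float,
    trial_index: int,
    rng: np.random.Generator,
    position_a: float = 0.0,
    position_v: float = 0.0,
    soa_ms: float = 0.0,
    v_leads: bool = True,
) -> list[StimulusEvent]:
    """Events for one trial; for 'av' the two components may be offset by soa_ms."""
    events = []
    if modality in ("a", "av"):
        on = onset_ms + (soa_ms if (modality == "av" and v_leads) else 0.0)
        events.append(
            StimulusEvent("a", position_a, on, params.stim_duration_ms,
                          sample_effectiveness(params, "a", rng), trial_index)
        )
    if modality in ("v", "av"):
        on = onset_ms + (0.0 if (modality != "av" or v_leads) else soa_ms)
        events.append(
            StimulusEvent("v", position_v, on, params.stim_duration_ms,
                          sample_effectiveness(params, "v", rng), trial_index)
        )
    return events


def make_rt_sequence(
    params: ModelParams,
    n_trials: int,
    isi_low_ms: float = 1000.0,
    isi_high_ms: float = 3000.0,
    seed: int = 0,
    start_ms: float = 200.0,
    position_deg: float = 0.0,
    modality_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
) -> TrialSequence:
    """Randomised A / V / AV sequence at central fixation with uniform ISIs.

    ISIs (onset-to-onset) are uniform on [isi_low_ms, isi_high_ms]; modalities
    are drawn independently per trial (equiprobable by default); repeat/switch
    labels follow from the realised modality sequence.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    if not np.isclose(sum(modality_probs), 1.0):
        raise ValueError("modality_probs must sum to 1")
    rng = np.random.default_rng(seed)
    modalities = [TRIAL_MODALITIES[k] for k in rng.choice(3, size=n_trials, p=modality_probs)]
    onsets = start_ms + np.concatenate(
        [[0.0], np.cumsum(rng.uniform(isi_low_ms, isi_high_ms, size=n_trials - 1))]
    )
    events: list[StimulusEvent] = []
    for i, (m, t0) in enumerate(zip(modalities, onsets)):
        events.extend(
            _trial_events(params, m, float(t0), i, rng,
                          position_a=position_deg, position_v=position_deg)
        )
    return TrialSequence(
        events=tuple(events),
        modalities=tuple(modalities),
        onsets_ms=tuple(float(t) for t in onsets),
        labels=tuple(label_trials(modalities)),
        seed=seed,
    )


def make_av_pair(
    params: ModelParams,
    disparity_deg: float,
    isi_ms: float,
    v_position_deg: float = 0.0,
    v_leads: bool = True,
    seed: int = 0,
    start_ms: float = 200.0,
) -> TrialSequence:
    """One audiovisual pair: V at ``v_position_deg``, A shifted by the signed
    disparity; the components are synchronous when ``isi_ms`` is 0, otherwise
    separated by ``isi_ms`` with V leading by default.

    A synchronous pair forms a single AV trial; an asynchronous pair forms two
    unisensory trials, the second of which is a Switch trial by construction.
    """
    if isi_ms < 0:
        raise ValueError("isi_ms must be >= 0")
    rng = np.random.default_rng(seed)
    pos_a = v_position_deg + disparity_deg
    if isi_ms == 0:
        modalities = ("av",)
        onsets = (start_ms,)
        events = _trial_events(params, "av", start_ms, 0, rng,
                               position_a=pos_a, position_v=v_position_deg)
    else:
        first, second = ("v", "a") if v_leads else ("a", "v")
        modalities = (first, second)
        onsets = (start_ms, start_ms + isi_ms)
        events = []
        for i, m in enumerate(modalities):
            events.extend(
                _trial_events(params, m, onsets[i], i, rng,
                              position_a=pos_a, position_v=v_position_deg)
            )
    return TrialSequence(
        events=tuple(events),
        modalities=modalities,
        onsets_ms=onsets,
        labels=tuple(label_trials(modalities)),
        seed=seed,
    )
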