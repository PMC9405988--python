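"""Synthetic EEG recordings, emotional events and ratings with known truth.

The generator emulates the study design the pipeline targets: an 80-s
eyes-open baseline followed by a viewing period during which the subject
clicks to report emotional events; each event carries one of 24 emotion
labels (drawn from 8 latent groups laid out in valence-arousal space) and
six self-assessment ratings. Signals are sums over the six analysis bands
of narrowband oscillations plus 1/f background noise. Phase coupling
between configured channel pairs is injected as a constant lag plus
von Mises jitter whose concentration grows with the coupling strength
kappa, so the expected phase-locking value has a closed form
(I1(k)/I0(k) with k = 10*kappa/(1-kappa)) and is monotone in kappa.

Every event also carries a hidden variability index; the index modulates
how strongly the injected coupling fluctuates between consecutive
segments of that event's epoch (the ground truth behind temporal
variability) and enters the generated arousal rating linearly with slope
``tv_slope``, so downstream regression has a known target.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ingest import (
    BAND_BY_NAME,
    EPOCH_DURATION_S,
    EPOCH_PRE_S,
    EPOCH_POST_S,
    SEGMENT_STEP,
    EventRecord,
    Recording,
)

__all__ = [
    "SimConfig",
    "CouplingSpec",
    "EMOTION_GROUPS",
    "EMOTION_LABELS",
    "make_recording",
    "make_events",
    "event_ground_truth",
    "write_dataset",
    "group_discriminative_coupling",
    "expected_plv",
    "simulate_tv_records",
]

#: 10-10 montage labels in a fixed order; recordings use the first n.
MONTAGE_1010 = [
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2",
    "T9", "T10", "TP9", "TP10",
]

#: 24-label emotion vocabulary partitioned into 8 latent groups, each with
#: a (valence, arousal) center on the 1-9 scales. The vocabulary and group
#: structure mirror a naturalistic film-viewing study design (4 positive /
#: negative quadrant groups of uneven sizes summing to 24 labels).
EMOTION_GROUPS: dict[int, tuple[list[str], tuple[float, float]]] = {
    1: (["happy", "amused", "delighted", "joyous"], (7.8, 5.8)),
    2: (["aroused", "adventurous", "excited", "passionate", "lust"], (6.6, 7.2)),
    3: (["startled", "tense", "alarmed"], (4.6, 7.4)),
    4: (["disgust", "hate"], (2.6, 6.6)),
    5: (["afraid"], (1.6, 7.6)),
    6: (["distress", "angry"], (2.0, 4.6)),
    7: (
        ["miserable", "taken_aback", "dissatisfied", "melancholic",
         "depressed", "despondent"],
        (3.0, 3.0),
    ),
    8: (["sad"], (1.6, 2.2)),
}

EMOTION_LABELS = [lab for labs, _ in EMOTION_GROUPS.values() for lab in labs]
LABEL_TO_GROUP = {
    lab: g for g, (labs, _) in EMOTION_GROUPS.items() for lab in labs
}

#: Per-band oscillation RMS amplitude (microvolts), EEG-like 1/f trend.
BAND_AMPLITUDE = {
    "delta": 18.0,
    "theta": 10.0,
    "alpha": 9.0,
    "lower_beta": 5.0,
    "upper_beta": 4.0,
    "gamma": 2.5,
}

#: Jitter concentration map: kappa in [0,1] -> von Mises concentration.
_CONCENTRATION_SCALE = 10.0


@dataclass(frozen=True)
class CouplingSpec:
    """Phase coupling for one (source, target) channel pair in one band.

    ``groups`` restricts the coupling to epochs of events in those emotion
    groups; ``None`` couples the pair for the whole recording.
    """

    pair: tuple[int, int]
    kappa: float
    groups: frozenset[int] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError(f"coupling strength {self.kappa} outside [0, 1]")


@dataclass
class SimConfig:
    """Study-scale defaults: 40 subjects x 10 events, 250 Hz, 80-s baseline."""

    n_subjects: int = 40
    n_channels: int = 32
    sfreq: float = 250.0
    n_events_per_subject: int = 10
    baseline_duration: float = 80.0
    band_coupling: Mapping[str, Sequence[CouplingSpec]] = field(
        default_factory=dict
    )
    tv_slope: float = 0.5
    noise_sd: float = 0.5
    seed: int = 0
    #: mean gap between consecutive clicks; must leave 7-s windows disjoint
    event_spacing: float = 9.0
    #: fix the recording length (seconds); None sizes it to fit the events
    recording_duration: float | None = None
    #: max fractional drop of kappa in alternate segments at index +3 sigma
    tv_mod_depth: float = 0.9
    #: background 1/f noise RMS, microvolts
    background_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.sfreq <= 2 * 40.0:
            raise ValueError("sfreq must exceed twice the 40 Hz band edge")
        norm: dict[str, list[CouplingSpec]] = {}
        for band, specs in self.band_coupling.items():
            if band not in BAND_BY_NAME:
                raise ValueError(f"coupling references unknown band {band!r}")
            out = []
            for s in specs:
                if not isinstance(s, CouplingSpec):
                    pair, kappa, groups = s
                    s = CouplingSpec(
                        tuple(pair), kappa,
                        None if groups is None else frozenset(groups),
                    )
                i, j = s.pair
                if not (0 <= i < self.n_channels and 0 <= j < self.n_channels):
                    raise ValueError(
                        f"coupling pair {s.pair} outside the "
                        f"{self.n_channels}-channel montage"
                    )
                if i == j:
                    raise ValueError("coupling pair must join two channels")
                out.append(s)
            # a channel may be the coupling target of at most one spec whose
            # active windows can coincide, else its phase is over-determined
            for a in range(len(out)):
                for b in range(a + 1, len(out)):
                    if out[a].pair[1] != out[b].pair[1]:
                        continue
                    ga, gb = out[a].groups, out[b].groups
                    if ga is None or gb is None or ga & gb:
                        raise ValueError(
                            f"channel {out[a].pair[1]} is the coupling target "
                            f"of two overlapping specs in band {band!r}"
                        )
            norm[band] = out
        self.band_coupling = norm

    @property
    def channels(self) -> list[str]:
        labels = list(MONTAGE_1010)
        while len(labels) < self.n_channels:
            labels.append(f"CH{len(labels):03d}")
        return labels[: self.n_channels]

    def duration(self) -> float:
        need = (
            self.baseline_duration
            + EPOCH_PRE_S
            + self.n_events_per_subject * self.event_spacing
            + 2.0
        )
        if self.recording_duration is None:
            return need
        return self.recording_duration


def _subject_seed(cfg: SimConfig, subject: str) -> np.random.SeedSequence:
    digest = hashlib.sha256(subject.encode()).digest()
    sub_key = int.from_bytes(digest[:4], "big")
    return np.random.SeedSequence([cfg.seed, sub_key])


def subject_ids(cfg: SimConfig) -> list[str]:
    return [f"sub-{i + 1:02d}" for i in range(cfg.n_subjects)]


# ---------------------------------------------------------------------------
# Events


def _gen_events(cfg: SimConfig, subject: str) -> pd.DataFrame:
    """Deterministic per-subject event table including hidden ground truth."""
    rng = np.random.default_rng(_subject_seed(cfg, subject).spawn(2)[0])
    n = cfg.n_events_per_subject
    duration = cfg.duration()
    first = cfg.baseline_duration + EPOCH_PRE_S + 1.0
    jitter_half = max(0.0, (cfg.event_spacing - EPOCH_DURATION_S) / 2 - 0.2)
    clicks = first + cfg.event_spacing * np.arange(n)
    clicks = clicks + rng.uniform(-jitter_half, jitter_half, size=n)
    if n and clicks[-1] + EPOCH_POST_S + 0.5 > duration:
        raise ValueError(
            f"cannot place {n} events with {cfg.event_spacing:g}-s spacing "
            f"in a {duration:g}-s recording (needs "
            f"{clicks[-1] + EPOCH_POST_S + 0.5:.1f}s)"
        )
    if cfg.event_spacing < EPOCH_DURATION_S:
        raise ValueError(
            f"event_spacing {cfg.event_spacing:g}s cannot keep "
            f"{EPOCH_DURATION_S:g}-s windows non-overlapping"
        )
    groups = rng.integers(1, 9, size=n)
    rows = []
    for k in range(n):
        g = int(groups[k])
        labels, (v_c, a_c) = EMOTION_GROUPS[g]
        label = labels[rng.integers(len(labels))]
        lab_idx = labels.index(label)
        # small fixed per-label offset keeps labels of a group a tight cluster
        v_off = 0.25 * (lab_idx - (len(labels) - 1) / 2)
        v_index = float(np.clip(rng.standard_normal(), -3.0, 3.0))
        clip = lambda x, lo, hi: float(np.clip(x, lo, hi))
        rows.append(
            {
                "subject": subject,
                "stimulus": f"stim-{rng.integers(1, 17):02d}",
                "onset": float(round(clicks[k], 4)),
                "emotion": label,
                "group": g,
                "v_index": v_index,
                "valence": clip(v_c + v_off + 0.5 * rng.standard_normal(), 1, 9),
                "arousal": clip(
                    a_c
                    + cfg.tv_slope * v_index
                    + cfg.noise_sd * rng.standard_normal(),
                    1,
                    9,
                ),
                "dominance": clip(5.0 + 1.5 * rng.standard_normal(), 1, 9),
                "liking": clip(3.0 + 1.0 * rng.standard_normal(), 1, 5),
                "familiarity": clip(3.0 + 1.0 * rng.standard_normal(), 1, 5),
                "relevance": clip(3.0 + 1.0 * rng.standard_normal(), 1, 5),
            }
        )
    return pd.DataFrame(rows)


def make_events(cfg: SimConfig, subject: str) -> list[EventRecord]:
    """Generate one subject's click events with labels and ratings."""
    df = _gen_events(cfg, subject)
    return [
        EventRecord(
            subject=row["subject"],
            stimulus=row["stimulus"],
            click_time=row["onset"],
            emotion=row["emotion"],
            valence=row["valence"],
            arousal=row["arousal"],
            dominance=row["dominance"],
            liking=row["liking"],
            familiarity=row["familiarity"],
            relevance=row["relevance"],
        )
        for _, row in df.iterrows()
    ]


def event_ground_truth(cfg: SimConfig, subject: str) -> pd.DataFrame:
    """Hidden per-event truth: latent group and variability index."""
    return _gen_events(cfg, subject)[
        ["subject", "onset", "emotion", "group", "v_index"]
    ]


# ---------------------------------------------------------------------------
# Signals


def expected_plv(kappa: float) -> float:
    """Closed-form expected PLV of a pair coupled at strength kappa."""
    from scipy.special import i0, i1

    if kappa >= 1.0:
        return 1.0
    if kappa <= 0.0:
        return 0.0
    k = _CONCENTRATION_SCALE * kappa / (1.0 - kappa)
    return float(i1(k) / i0(k))


def _interp_nodes(values: np.ndarray, step: int, n: int) -> np.ndarray:
    """Linearly interpolate node values placed every ``step`` samples."""
    node_t = np.arange(values.size) * step
    return np.interp(np.arange(n), node_t, values)


def _fm_phase(rng: np.random.Generator, f_lo: float, f_hi: float,
              n: int, sfreq: float) -> np.ndarray:
    """Phase of a narrowband oscillation: carrier + smooth random FM."""
    f_c = 0.5 * (f_lo + f_hi)
    sigma = 0.25 * (f_hi - f_lo)
    step = 50  # FM node every 0.2 s
    dev = rng.normal(0.0, sigma, size=n // step + 2)
    freq = f_c + _interp_nodes(dev, step, n)
    phase = 2 * np.pi * np.cumsum(freq) / sfreq
    return phase + rng.uniform(0, 2 * np.pi)


def _jitter_series(rng: np.random.Generator, kappa_t: np.ndarray,
                   n: int) -> np.ndarray:
    """Von Mises phase jitter with time-varying concentration.

    Node values are drawn every 25 samples (0.1 s) and linearly
    interpolated; kappa==1 nodes get exactly zero jitter.
    """
    step = 25
    nodes = np.arange(0, n + step, step)
    k_node = kappa_t[np.minimum(nodes, n - 1)]
    conc = np.where(
        k_node >= 1.0, np.inf,
        _CONCENTRATION_SCALE * k_node / np.maximum(1e-12, 1.0 - k_node),
    )
    vals = np.empty(nodes.size)
    finite = np.isfinite(conc)
    vals[~finite] = 0.0
    vals[finite] = rng.vonmises(0.0, np.maximum(conc[finite], 1e-9))
    return _interp_nodes(vals, step, n)


def _coupling_weight(cfg: SimConfig, spec: CouplingSpec,
                     events: pd.DataFrame, n: int) -> np.ndarray:
    """Crossfade weight in [0,1]: 1 where the coupling is active."""
    sf = cfg.sfreq
    if spec.groups is None:
        return np.ones(n)
    w = np.zeros(n)
    ramp = int(0.2 * sf)
    for _, ev in events.iterrows():
        if int(ev["group"]) not in spec.groups:
            continue
        a = int((ev["onset"] - EPOCH_PRE_S) * sf)
        b = int((ev["onset"] + EPOCH_POST_S) * sf)
        a, b = max(a, 0), min(b, n)
        w[a:b] = 1.0
        if a - ramp >= 0:
            w[a - ramp : a] = np.maximum(
                w[a - ramp : a], np.linspace(0, 1, ramp)
            )
        if b + ramp <= n:
            w[b : b + ramp] = np.maximum(
                w[b : b + ramp], np.linspace(1, 0, ramp)
            )
    return w


def _kappa_profile(cfg: SimConfig, spec: CouplingSpec,
                   events: pd.DataFrame, n: int) -> np.ndarray:
    """Time-varying kappa: alternate-segment dips scaled by each event's
    variability index inject ground-truth temporal variability."""
    sf = cfg.sfreq
    kappa_t = np.full(n, spec.kappa)
    block = SEGMENT_STEP  # one segment step, 0.7 s
    for _, ev in events.iterrows():
        if spec.groups is not None and int(ev["group"]) not in spec.groups:
            continue
        depth = cfg.tv_mod_depth * (float(ev["v_index"]) + 3.0) / 6.0
        a = int((ev["onset"] - EPOCH_PRE_S) * sf)
        b = int((ev["onset"] + EPOCH_POST_S) * sf)
        idx = np.arange(max(a, 0), min(b, n))
        odd = ((idx - a) // block) % 2 == 1
        kappa_t[idx[odd]] = spec.kappa * (1.0 - depth)
    return kappa_t


def _one_over_f_noise(rng: np.random.Generator, n: int,
                      sfreq: float, rms: float) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1 / sfreq)
    shape = 1.0 / np.sqrt(np.maximum(f, 1.0))
    shape[f < 0.5] = 0.0  # keep the recording detrended
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def make_recording(cfg: SimConfig, subject: str) -> Recording:
    """Synthesize one subject's recording with the configured coupling."""
    ss = _subject_seed(cfg, subject).spawn(2)[1]
    rng = np.random.default_rng(ss)
    events = _gen_events(cfg, subject)
    n = int(round(cfg.duration() * cfg.sfreq))
    data = np.zeros((cfg.n_channels, n))

    for band_name, band in BAND_BY_NAME.items():
        amp = BAND_AMPLITUDE[band_name] * np.sqrt(2.0)  # cos RMS -> amp
        phases = np.vstack(
            [
                _fm_phase(rng, band.low, band.high, n, cfg.sfreq)
                for _ in range(cfg.n_channels)
            ]
        )
        components = amp * np.cos(phases)
        for spec in cfg.band_coupling.get(band_name, ()):
            src, tgt = spec.pair
            lag = rng.uniform(0, 2 * np.pi)
            kappa_t = _kappa_profile(cfg, spec, events, n)
            jitter = _jitter_series(rng, kappa_t, n)
            locked = amp * np.cos(phases[src] + lag + jitter)
            w = _coupling_weight(cfg, spec, events, n)
            components[tgt] = (1 - w) * components[tgt] + w * locked
        data += components

    for ch in range(cfg.n_channels):
        data[ch] += _one_over_f_noise(rng, n, cfg.sfreq, cfg.background_sd)

    return Recording(subject, cfg.sfreq, cfg.channels, data)


# ---------------------------------------------------------------------------
# Dataset writer


def write_dataset(cfg: SimConfig, out_dir: str | Path) -> dict:
    """Write recordings (.npy + JSON sidecar), events TSV and truth JSON.

    Re-running with the same config reproduces byte-identical TSV/JSON.
    Returns the manifest (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    recording_files = []
    frames = []
    truth_events = []
    for subject in subject_ids(cfg):
        rec = make_recording(cfg, subject)
        npy = out / f"{subject}.npy"
        np.save(npy, rec.data)
        sidecar = npy.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "subject": subject,
                    "sfreq": cfg.sfreq,
                    "channels": rec.channels,
                },
                indent=1,
            )
        )
        recording_files.append(npy.name)
        df = _gen_events(cfg, subject)
        truth_events.append(df[["subject", "onset", "group", "v_index"]])
        ev = df.drop(columns=["group", "v_index"]).copy()
        ev.insert(1, "duration", EPOCH_DURATION_S)
        frames.append(ev)

    events = pd.concat(frames, ignore_index=True)
    cols = [
        "onset", "duration", "subject", "stimulus", "emotion",
        "valence", "arousal", "dominance", "liking", "familiarity",
        "relevance",
    ]
    events = events[cols]
    events_path = out / "events.tsv"
    events.to_csv(events_path, sep="\t", index=False, float_format="%.4f")

    truth = {
        "seed": cfg.seed,
        "tv_slope": cfg.tv_slope,
        "noise_sd": cfg.noise_sd,
        "band_coupling": {
            band: [
                {
                    "pair": list(s.pair),
                    "kappa": s.kappa,
                    "groups": sorted(s.groups) if s.groups else None,
                    "expected_plv": expected_plv(s.kappa),
                }
                for s in specs
            ]
            for band, specs in cfg.band_coupling.items()
        },
        "events": pd.concat(truth_events, ignore_index=True).to_dict(
            orient="list"
        ),
    }
    truth_path = out / "ground_truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))

    manifest = {
        "recordings": recording_files,
        "events": events_path.name,
        "ground_truth": truth_path.name,
        "n_subjects": cfg.n_subjects,
        "n_channels": cfg.n_channels,
        "sfreq": cfg.sfreq,
        "seed": cfg.seed,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return manifest


# ---------------------------------------------------------------------------
# Convenience generators used by tests and the acceptance study


def group_discriminative_coupling(
    n_channels: int,
    band: str = "upper_beta",
    kappa: float = 0.9,
    n_groups: int = 8,
) -> dict[str, list[CouplingSpec]]:
    """One distinct strongly coupled pair per emotion group, in one band.

    Events of group g phase-lock a pair unique to g, so connectivity
    vectors separate the groups in that band and nowhere else.
    """
    from itertools import combinations

    pairs = list(combinations(range(n_channels), 2))
    # spread targets so no channel serves two groups (windows of different
    # groups are disjoint anyway, but distinct pairs keep the design clean)
    chosen: list[tuple[int, int]] = []
    for p in pairs:
        if len(chosen) == n_groups:
            break
        if all(p[1] != q[1] or p[0] != q[0] for q in chosen):
            chosen.append(p)
    if len(chosen) < n_groups:
        raise ValueError(
            f"{n_channels} channels cannot host {n_groups} distinct pairs"
        )
    return {
        band: [
            CouplingSpec(chosen[g - 1], kappa, frozenset({g}))
            for g in range(1, n_groups + 1)
        ]
    }


def simulate_tv_records(
    n_subjects: int,
    n_events: int,
    slope: float,
    seed: int,
    subject_sd: float = 0.5,
    scale: str = "arousal",
) -> pd.DataFrame:
    """Event-level records with a known standardized slope of a rating on tv.

    The latent outcome is ``slope * z(tv) + subject intercept + noise`` with
    the intercept/noise variances chosen so the latent scale has unit
    variance; the rating is then mapped to its 1-9 scale (clipping is
    negligible by construction).
    """
    if not 0.0 <= slope**2 + subject_sd**2 <= 1.0:
        raise ValueError("slope^2 + subject_sd^2 must stay within unit variance")
    rng = np.random.default_rng(seed)
    noise_sd = np.sqrt(1.0 - slope**2 - subject_sd**2)
    rows = []
    for s in range(n_subjects):
        b = rng.normal(0.0, subject_sd)
        tv = rng.standard_normal(n_events)
        latent = slope * tv + b + rng.normal(0.0, noise_sd, size=n_events)
        rating = np.clip(5.0 + 1.2 * latent, 1.0, 9.0)
        for k in range(n_events):
            rows.append(
                {
                    "subject": f"sub-{s + 1:02d}",
                    "event": f"sub-{s + 1:02d}-ev{k:03d}",
                    "tv": float(tv[k]),
                    scale: float(rating[k]),
                }
            )
    return pd.DataFrame(rows)
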