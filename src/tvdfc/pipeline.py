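"""End-to-end orchestration: simulate/ingest -> grouping -> PLV -> permutation
tests -> distances/Gcst/band selection -> tvDFC -> regressions -> hubs.

All randomness flows from one root seed, expanded deterministically per
stage, so a re-run with an identical config reproduces identical TSV and
JSON outputs. tvDFC and the regressions run only on the band selected by
the Gcst test unless a band is forced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import emogroup, models, netmetrics, permtest, plvnet, synthdata
from .ingest import (
    BANDS,
    BASELINE_SPAN_S,
    EPOCH_DURATION_S,
    BandDefinition,
    EventRecord,
    Recording,
    band_decompose,
    bandpass_filter,
    drop_overlapping_events,
    extract_baseline_epochs,
    extract_event_epoch,
    read_events,
    read_recording,
)

logger = logging.getLogger("tvdfc")

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """Everything one run needs; either a simulate block or input paths."""

    out_dir: str = "tvdfc-out"
    simulate: synthdata.SimConfig | None = None
    recordings: list[str] = field(default_factory=list)
    events: str | None = None
    bands: tuple[str, ...] = tuple(b.name for b in BANDS)
    n_groups: int = 8
    alpha_edges: float = 0.01
    alpha_hubs: float = 0.05
    n_perm: int = 1000
    n_random_graphs: int = 10_000
    seed: int = 0
    force_band: str | None = None
    #: baseline epochs per subject; None = that subject's retained event count
    n_baseline: int | None = None

    def __post_init__(self) -> None:
        for a in (self.alpha_edges, self.alpha_hubs):
            if not 0 < a < 1:
                raise ValueError(f"alpha {a} outside (0, 1)")
        if self.force_band is not None and self.force_band not in self.bands:
            raise ValueError(
                f"force_band {self.force_band!r} is not among the analyzed "
                f"bands {self.bands}"
            )
        if self.simulate is None:
            if not self.recordings or self.events is None:
                raise ValueError(
                    "non-simulate mode requires recordings and events paths"
                )
            missing = [
                p for p in [*self.recordings, self.events]
                if not Path(p).exists()
            ]
            if missing:
                raise FileNotFoundError(f"missing inputs: {missing}")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        sim = raw.pop("simulate", None)
        if sim is not None:
            coupling = {
                band: [
                    synthdata.CouplingSpec(
                        tuple(s["pair"]), s["kappa"],
                        None if s.get("groups") is None
                        else frozenset(s["groups"]),
                    )
                    for s in specs
                ]
                for band, specs in sim.pop("band_coupling", {}).items()
            }
            sim = synthdata.SimConfig(band_coupling=coupling, **sim)
        if "bands" in raw:
            raw["bands"] = tuple(raw["bands"])
        return cls(simulate=sim, **raw)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, frozenset):
                return sorted(o)
            raise TypeError(type(o))

        payload = dataclasses.asdict(self)
        payload.pop("out_dir")  # output location does not define the run
        blob = json.dumps(payload, default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_seed(root: int, stage: str) -> int:
    digest = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _load_inputs(
    cfg: PipelineConfig,
) -> tuple[dict[str, Recording], list[EventRecord]]:
    if cfg.simulate is not None:
        sim = cfg.simulate
        recs = {
            s: synthdata.make_recording(sim, s)
            for s in synthdata.subject_ids(sim)
        }
        events = [
            ev for s in synthdata.subject_ids(sim)
            for ev in synthdata.make_events(sim, s)
        ]
        return recs, events
    recs = {}
    for p in cfg.recordings:
        rec = read_recording(p)
        recs[rec.subject] = rec
    return recs, read_events(cfg.events)


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "files": [],
        "stages": {},
    }

    def emit(name: str, path: Path) -> None:
        manifest["files"].append(str(path.relative_to(out)))

    # ---- ingest ---------------------------------------------------------
    logger.info("stage=ingest")
    recordings, events = _load_inputs(cfg)
    events = drop_overlapping_events(events)
    events = [ev for ev in events if ev.subject in recordings]
    if not events:
        raise RuntimeError("ingest: no events retained")
    manifest["stages"]["ingest"] = {
        "n_subjects": len(recordings),
        "n_events": len(events),
    }

    # ---- emotion grouping ----------------------------------------------
    logger.info("stage=grouping")
    groups, label_to_group = emogroup.assign_groups(events, k=cfg.n_groups)
    gpath = out / "emotion_groups.tsv"
    emogroup.write_group_table(groups, gpath)
    emit("grouping", gpath)
    group_ids = sorted({g.group_id for g in groups})
    ev_group = {id(ev): label_to_group[ev.emotion] for ev in events}

    # ---- epochs and per-band PLV ---------------------------------------
    logger.info("stage=connectivity")
    bands = [b for b in BANDS if b.name in cfg.bands]
    by_subject: dict[str, list[EventRecord]] = {}
    for ev in events:
        by_subject.setdefault(ev.subject, []).append(ev)

    event_tensors: dict[str, plvnet.PLVTensor] = {}
    baseline_tensors: dict[str, plvnet.PLVTensor] = {}
    event_meta: list[EventRecord] = []
    ep_seed = _stage_seed(cfg.seed, "baseline-epochs")
    band_event_epochs: dict[str, list] = {b.name: [] for b in bands}
    band_baseline_epochs: dict[str, list] = {b.name: [] for b in bands}
    for subject, sub_events in by_subject.items():
        rec = bandpass_filter(recordings[subject], 1.0, 40.0)
        # at most 8 non-overlapping 7-s windows fit the 60-s baseline span
        max_base = int((BASELINE_SPAN_S[1] - BASELINE_SPAN_S[0])
                       // EPOCH_DURATION_S)
        n_base = cfg.n_baseline or min(len(sub_events), max_base)
        base_epochs = extract_baseline_epochs(
            rec, n_base, seed=ep_seed + _stage_seed(ep_seed, subject) % 10_000
        )
        for ev in sub_events:
            wide = extract_event_epoch(rec, ev)
            for band_ep in band_decompose(wide, bands):
                band_event_epochs[band_ep.band.name].append(band_ep)
            event_meta.append(ev)
        for bep in base_epochs:
            for band_ep in band_decompose(bep, bands):
                band_baseline_epochs[band_ep.band.name].append(band_ep)

    for band in bands:
        event_tensors[band.name] = plvnet.plv_tensor(
            band_event_epochs[band.name]
        )
        baseline_tensors[band.name] = plvnet.plv_tensor(
            band_baseline_epochs[band.name]
        )
    ref_tensor = event_tensors[bands[0].name]
    pair_index = ref_tensor.pair_index
    channels = ref_tensor.channels
    n_segments = ref_tensor.n_segments
    manifest["stages"]["connectivity"] = {
        "bands": [b.name for b in bands],
        "n_pairs": len(pair_index),
        "n_segments": n_segments,
    }

    # ---- permutation tests ---------------------------------------------
    logger.info("stage=permtest")
    ev_groups_arr = np.array([ev_group[id(ev)] for ev in event_meta])
    sig: dict[tuple[str, int, int], permtest.SignificanceResult] = {}
    mean_plv: dict[tuple[str, int, int], np.ndarray] = {}
    perm_dir = out / "permtest"
    perm_dir.mkdir(exist_ok=True)
    for band in bands:
        ev_t = event_tensors[band.name]
        base_t = baseline_tensors[band.name]
        ev_subjects = np.array(ev_t.subjects)
        base_subjects = np.array(base_t.subjects)
        for g in group_ids:
            in_g = ev_groups_arr == g
            if in_g.sum() < 2:
                logger.warning("group %s has <2 events; skipped", g)
                continue
            g_subjects = ev_subjects[in_g]
            keep_base = np.isin(base_subjects, np.unique(g_subjects))
            for s in range(n_segments):
                seed = _stage_seed(
                    cfg.seed, f"perm:{band.name}:{g}:{s}"
                )
                logger.info(
                    "permtest band=%s segment=%d group=%d n_perm=%d seed=%d",
                    band.name, s, g, cfg.n_perm, seed,
                )
                res = permtest.max_stat_test(
                    ev_t.values[in_g, s, :],
                    base_t.values[keep_base, s, :],
                    g_subjects,
                    base_subjects[keep_base],
                    alpha=cfg.alpha_edges,
                    n_perm=cfg.n_perm,
                    seed=seed,
                    band=band.name,
                    segment=s,
                    group=g,
                )
                sig[(band.name, s, g)] = res
                mean_plv[(band.name, s, g)] = ev_t.values[in_g, s, :].mean(
                    axis=0
                )
                p = perm_dir / f"edges_{band.name}_seg{s}_group{g}.tsv"
                permtest.write_edge_list(res, pair_index, channels, p)
                emit("permtest", p)
    manifest["stages"]["permtest"] = {
        "n_tests": len(sig),
        "alpha": cfg.alpha_edges,
        "n_perm": cfg.n_perm,
    }

    # ---- distances, Gcst, band selection -------------------------------
    logger.info("stage=distances")
    band_averages: dict[str, dict[tuple[int, int], float]] = {}
    dist_rows = []
    for band in bands:
        per_segment: dict[int, dict[tuple[int, int], float]] = {}
        for s in range(n_segments):
            vectors = {
                g: netmetrics.connectivity_vector(
                    sig[(band.name, s, g)].mask,
                    mean_plv[(band.name, s, g)],
                    band.name,
                    s,
                    g,
                )
                for g in group_ids
                if (band.name, s, g) in sig
            }
            per_segment[s] = netmetrics.group_pair_distances(vectors)
            for (a, b), d in per_segment[s].items():
                dist_rows.append(
                    {"band": band.name, "segment": s, "group_a": a,
                     "group_b": b, "distance": d}
                )
        band_averages[band.name] = netmetrics.band_average_distances(
            per_segment, n_segments
        )
    dist_path = out / "distances.tsv"
    pd.DataFrame(dist_rows).to_csv(dist_path, sep="\t", index=False,
                                   float_format="%.6g")
    emit("distances", dist_path)

    gcst = netmetrics.global_threshold(band_averages)
    band_tests = {}
    for name, avgs in band_averages.items():
        try:
            band_tests[name] = netmetrics.band_selection_test(
                list(avgs.values()), gcst, band=name, n_bands=len(bands)
            )
        except ValueError:
            # a band with no significant connectivity anywhere has
            # zero-variance distances; it cannot beat the global threshold
            logger.warning("band %s: degenerate distances, not selected", name)
            band_tests[name] = netmetrics.BandTestResult(
                band=name, t=float("-inf"), df=len(avgs) - 1, p=1.0,
                cohens_d=float("nan"), selected=False,
            )
    selected_bands = [n for n, r in band_tests.items() if r.selected]
    if cfg.force_band is not None:
        chosen = cfg.force_band
    elif selected_bands:
        chosen = max(selected_bands, key=lambda n: band_tests[n].t)
    else:
        chosen = max(band_tests, key=lambda n: band_tests[n].t)
        logger.warning("no band significant; falling back to %s", chosen)
    paired = None
    if len(selected_bands) >= 2:
        top2 = sorted(
            selected_bands, key=lambda n: band_tests[n].t, reverse=True
        )[:2]
        paired = {
            "bands": top2,
            **netmetrics.paired_band_comparison(
                list(band_averages[top2[0]].values()),
                list(band_averages[top2[1]].values()),
            ),
        }
    summary = {
        "gcst": gcst,
        "selected_band": chosen,
        "significant_bands": selected_bands,
        "band_tests": {
            n: dataclasses.asdict(r) for n, r in band_tests.items()
        },
        "paired_comparison": paired,
    }
    manifest["stages"]["distances"] = {"gcst": gcst, "selected": chosen}

    # ---- tvDFC on the selected band ------------------------------------
    logger.info("stage=tvdfc band=%s", chosen)
    ev_t = event_tensors[chosen]
    tv_records = []
    for k, ev in enumerate(event_meta):
        g = ev_group[id(ev)]
        seg_vectors = np.stack(
            [
                np.where(
                    sig[(chosen, s, g)].mask, ev_t.values[k, s, :], 0.0
                )
                if (chosen, s, g) in sig
                else np.zeros(len(pair_index))
                for s in range(n_segments)
            ]
        )
        tv_records.append(
            models.TvRecord(
                event=ev_t.event_ids[k],
                subject=ev.subject,
                group=g,
                band=chosen,
                tv=netmetrics.temporal_variability(seg_vectors),
                **ev.ratings(),
            )
        )
    tv_df = pd.DataFrame([dataclasses.asdict(r) for r in tv_records])
    tv_path = out / "tv_records.tsv"
    tv_df.to_csv(tv_path, sep="\t", index=False, float_format="%.6g")
    emit("tvdfc", tv_path)

    # ---- regressions ----------------------------------------------------
    logger.info("stage=regress")
    fits = {}
    if tv_df["tv"].std(ddof=0) == 0:
        logger.warning("tv has zero variance; regressions skipped")
    else:
        for scale in models.SCALES:
            fits[scale] = models.fit_scale_on_tv(tv_df, scale).to_dict()
        try:
            fits["interaction_logistic"] = models.fit_interaction_logistic(
                tv_df, seed=_stage_seed(cfg.seed, "logistic")
            )
        except ValueError as e:
            fits["interaction_logistic"] = {"error": str(e)}
    summary["regressions"] = fits

    # ---- hubs -----------------------------------------------------------
    logger.info("stage=hubs")
    masks, weights = [], []
    for (band_name, s, g), res in sig.items():
        if band_name != chosen:
            continue
        masks.append(res.mask)
        weights.append(mean_plv[(band_name, s, g)])
    adj = netmetrics.hub_adjacency(masks, weights, pair_index, len(channels))
    hub_rows = []
    if (adj > 0).any():
        try:
            hubs = netmetrics.hub_significance(
                adj,
                channels,
                n_random=cfg.n_random_graphs,
                alpha=cfg.alpha_hubs,
                seed=_stage_seed(cfg.seed, "hubs"),
            )
            hub_rows = [dataclasses.asdict(h) for h in hubs]
        except ValueError as e:
            logger.warning("hub stage degenerate: %s", e)
    hub_path = out / "hubs.tsv"
    pd.DataFrame(
        hub_rows,
        columns=["channel", "centrality", "null_percentile", "is_hub",
                 "n_random", "seed"],
    ).to_csv(hub_path, sep="\t", index=False, float_format="%.6g")
    emit("hubs", hub_path)
    summary["hubs"] = [r["channel"] for r in hub_rows if r["is_hub"]]

    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True))
    emit("summary", summary_path)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
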