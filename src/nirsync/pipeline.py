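"""End-to-end orchestration: simulate -> preprocess -> allocate -> coherence
-> real-vs-pseudo inference.

``run_full`` executes the whole analysis for a (simulated or loaded) cohort
and emits one results table per measure (co-watching coherence and
conversation-induced coherence change) in the layout of the study's results
tables, plus a per-(ROI, band) paired t-test within real dyads and a run
manifest chaining config hash and output checksums.
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

from . import io as nio
from .coherence import (
    DEFAULT_BANDS,
    WaveletTransform,
    band_average,
    extract_trial,
    wtc_from_transforms,
)
from .geometry import (
    AllocationResult,
    assign_channels_to_rois,
    channel_positions,
    cohort_mean_positions,
    roi_specs,
    validate_optode_distances,
)
from .inference import (
    DyadMeta,
    GroupValues,
    build_pseudo_dyads,
    paired_t_within_real,
    run_permutation_grid,
)
from .preprocess import (
    ActivationSignal,
    QualityThresholds,
    channel_quality,
    preprocess_to_activation,
)
from .synthetic import SessionRecording, SimulatedCohort, SimulationConfig, simulate_cohort

logger = logging.getLogger("nirsync")

MEASURES = ("cowatch1", "change")
TRIAL_PHASES = ("video1", "video2")


@dataclass
class PipelineConfig:
    """One JSON-serialisable document that reproduces a full run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    band_lo: float = 0.01
    band_hi: float = 0.4
    filter_order: int = 5
    iqr_factor: float = 1.5
    dpf: tuple[float, float, float] = (6.0, 6.0, 6.0)
    source_detector_distance_cm: float = 3.0
    apply_quality: bool = True
    quality: QualityThresholds = field(default_factory=QualityThresholds)
    exclude_coi: bool = True
    n_perm: int = 10_000
    statistic: str = "pooled"
    seed: int = 0

    def to_json(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            raise TypeError(type(obj))

        return json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        doc = json.loads(text)
        sim = SimulationConfig(**doc.pop("simulation", {}))
        sim = dataclasses.replace(sim, phase_durations=tuple(sim.phase_durations))
        qual = QualityThresholds(**doc.pop("quality", {}))
        doc["dpf"] = tuple(doc.get("dpf", (6.0, 6.0, 6.0)))
        return cls(simulation=sim, quality=qual, **doc)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


@dataclass
class ParticipantData:
    """Preprocessed per-participant state feeding the coherence stage."""

    participant: str
    activation: ActivationSignal
    allocation: AllocationResult
    quality: pd.DataFrame | None
    # (roi, phase) -> cached wavelet transform of the trial segment
    transforms: dict[tuple[str, str], WaveletTransform] = field(default_factory=dict)


@dataclass
class PipelineResult:
    tables: dict[str, pd.DataFrame]
    paired: pd.DataFrame
    values: list[GroupValues]
    draws: dict[str, int]
    manifest: dict
    participants: dict[str, ParticipantData]
    dyad_values: pd.DataFrame


def _allocate_cohort(
    sessions: Sequence[SessionRecording],
) -> dict[str, tuple[pd.DataFrame, AllocationResult]]:
    """Two-pass allocation: measured midpoints first, cohort means as the
    fallback for mis-located or unregistered probes."""
    first_pass = {}
    for s in sessions:
        for role in ("A", "B"):
            pid = getattr(s.meta, f"participant_{role.lower()}")
            geom = s.geometry[role]
            validity = validate_optode_distances(geom)
            try:
                pos = channel_positions(geom, validity)
            except ValueError:
                pos = None  # needs cohort means
            first_pass[pid] = (geom, validity, pos)
    measured = [p for _, _, p in first_pass.values() if p is not None]
    cohort_means = cohort_mean_positions(measured) if measured else None
    out = {}
    for pid, (geom, validity, pos) in first_pass.items():
        if pos is None or (pos["provenance"] != "measured-midpoint").any():
            pos = channel_positions(geom, validity, cohort_positions=cohort_means)
        out[pid] = (pos, assign_channels_to_rois(pos))
    return out


def preprocess_cohort(
    sessions: Sequence[SessionRecording], config: PipelineConfig
) -> dict[str, ParticipantData]:
    allocations = _allocate_cohort(sessions)
    participants: dict[str, ParticipantData] = {}
    for s in sessions:
        for role in ("A", "B"):
            pid = getattr(s.meta, f"participant_{role.lower()}")
            raw = s.raw[role]
            quality = None
            good_channels = set(int(c) for c in raw.channel_ids)
            if config.apply_quality:
                quality = channel_quality(raw, thresholds=config.quality)
                good_channels = set(
                    int(c) for c in quality.loc[quality["included"], "channel"]
                )
                n_bad = len(raw.channel_ids) - len(good_channels)
                if n_bad:
                    logger.info("participant %s: %d channel(s) excluded by quality", pid, n_bad)
            activation = preprocess_to_activation(
                raw,
                iqr_factor=config.iqr_factor,
                band=(config.band_lo, config.band_hi),
                filter_order=config.filter_order,
                source_detector_distance_cm=config.source_detector_distance_cm,
                dpf=config.dpf,
            )
            _, allocation = allocations[pid]
            pdata = ParticipantData(
                participant=pid, activation=activation, allocation=allocation, quality=quality
            )
            fs = activation.fs
            for ch, roi in allocation.channel_to_roi.items():
                if ch not in good_channels:
                    continue
                idx = int(np.flatnonzero(activation.channel_ids == ch)[0])
                if activation.degenerate[idx]:
                    continue
                series = activation.values[idx]
                for phase in TRIAL_PHASES:
                    seg = extract_trial(series, s.events, phase, fs)
                    pdata.transforms[(roi, phase)] = WaveletTransform(seg, fs)
            participants[pid] = pdata
    return participants


def _dyad_band_values(
    dyads: Sequence[DyadMeta],
    participants: Mapping[str, ParticipantData],
    exclude_coi: bool,
) -> pd.DataFrame:
    """Tidy per-dyad coherence measures: dyad, roi, band, measure columns."""
    rows = []
    roi_labels = [r.label for r in roi_specs()]
    for meta in dyads:
        pa = participants.get(meta.participant_a)
        pb = participants.get(meta.participant_b)
        if pa is None or pb is None:
            continue
        for roi in roi_labels:
            if any((roi, ph) not in pa.transforms or (roi, ph) not in pb.transforms
                   for ph in TRIAL_PHASES):
                continue
            per_phase = {}
            for phase in TRIAL_PHASES:
                spec = wtc_from_transforms(pa.transforms[(roi, phase)], pb.transforms[(roi, phase)])
                per_phase[phase] = {
                    b.name: band_average(spec, b, exclude_coi=exclude_coi) for b in DEFAULT_BANDS
                }
            for b in DEFAULT_BANDS:
                v1 = per_phase["video1"][b.name]
                v2 = per_phase["video2"][b.name]
                rows.append(
                    {
                        "dyad_id": meta.dyad_id,
                        "is_real": meta.is_real,
                        "roi": roi,
                        "band": b.name,
                        "cowatch1": v1.value,
                        "cowatch2": v2.value,
                        "change": v2.value - v1.value,
                        "mean": 0.5 * (v1.value + v2.value),
                        "coi_excluded_fraction": 0.5
                        * (v1.coi_excluded_fraction + v2.coi_excluded_fraction),
                    }
                )
    return pd.DataFrame(rows)


def build_group_values(dyad_values: pd.DataFrame, measures: Sequence[str] = MEASURES) -> list[GroupValues]:
    cells = []
    roi_labels = [r.label for r in roi_specs()]
    for measure in measures:
        for roi in roi_labels:
            for band in [b.name for b in DEFAULT_BANDS]:
                sel = dyad_values[(dyad_values["roi"] == roi) & (dyad_values["band"] == band)]
                real = sel.loc[sel["is_real"], measure].to_numpy(float)
                pseudo = sel.loc[~sel["is_real"], measure].to_numpy(float)
                if len(real) < 2 or len(pseudo) < 2:
                    logger.info(
                        "cell %s/%s/%s skipped: %d real, %d pseudo values",
                        measure, roi, band, len(real), len(pseudo),
                    )
                    continue
                cells.append(GroupValues(measure=measure, roi=roi, band=band, real=real, pseudo=pseudo))
    return cells


def _paired_table(dyad_values: pd.DataFrame) -> pd.DataFrame:
    rows = []
    real = dyad_values[dyad_values["is_real"]]
    for (roi, band), sel in real.groupby(["roi", "band"]):
        if len(sel) < 2:
            continue
        t, df, p, ci = paired_t_within_real(
            sel["cowatch1"].to_numpy(), sel["cowatch2"].to_numpy()
        )
        rows.append(
            {
                "region": roi,
                "band": band,
                "n": len(sel),
                "t": t,
                "df": df,
                "p_value": p,
                "ci_low": ci[0],
                "ci_high": ci[1],
            }
        )
    return pd.DataFrame(rows)


def _table_checksum(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


def run_full(
    config: PipelineConfig,
    cohort: SimulatedCohort | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute the complete pipeline; simulate the cohort unless one is given."""
    if cohort is None:
        cohort = simulate_cohort(config.simulation)
    participants = preprocess_cohort(cohort.sessions, config)
    real_metas = [s.meta for s in cohort.sessions]
    pseudo_metas = build_pseudo_dyads(real_metas)
    logger.info("%d real dyads, %d pseudo dyads", len(real_metas), len(pseudo_metas))
    dyad_values = _dyad_band_values(
        list(real_metas) + pseudo_metas, participants, config.exclude_coi
    )
    if dyad_values.empty:
        raise RuntimeError("coherence stage produced no dyad values")
    cells = build_group_values(dyad_values)

    tables: dict[str, pd.DataFrame] = {}
    draws: dict[str, int] = {}
    for i, measure in enumerate(MEASURES):
        mcells = [c for c in cells if c.measure == measure]
        table, n_draws = run_permutation_grid(
            mcells,
            n_perm=config.n_perm,
            seed=(config.seed + i) % (2**31),
            statistic=config.statistic,
        )
        tables[measure] = table
        draws[measure] = n_draws
    paired = _paired_table(dyad_values)

    from datetime import datetime, timezone

    from . import __version__

    manifest = {
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config_hash": config.config_hash(),
        "config": json.loads(config.to_json()),
        "seeds": {"simulation": config.simulation.seed, "permutation": config.seed},
        "n_real_dyads": len(real_metas),
        "n_pseudo_dyads": len(pseudo_metas),
        "permutation_draws": draws,
        "table_checksums": {m: _table_checksum(t) for m, t in tables.items()},
        "paired_checksum": _table_checksum(paired),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for measure, table in tables.items():
            table.to_csv(out / f"results_{measure}.csv", index=False)
        paired.to_csv(out / "results_paired_within_real.csv", index=False)
        dyad_values.to_csv(out / "dyad_band_values.csv", index=False)
        alloc_rows = []
        for pid, pdata in participants.items():
            for _, row in pdata.allocation.assignments.iterrows():
                alloc_rows.append({"participant": pid, **row.to_dict()})
        pd.DataFrame(alloc_rows).to_csv(out / "allocation.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return PipelineResult(
        tables=tables,
        paired=paired,
        values=cells,
        draws=draws,
        manifest=manifest,
        participants=participants,
        dyad_values=dyad_values,
    )


def make_fixtures(seed: int, out_dir: str | Path) -> SimulatedCohort:
    """Write a miniature 4-dyad cohort (short conversation phase) as TSV."""
    config = SimulationConfig(
        n_dyads=4,
        phase_durations=(120.0, 60.0, 120.0),
        seed=seed,
    )
    cohort = simulate_cohort(config)
    out = Path(out_dir)
    for session, truth in zip(cohort.sessions, cohort.truths):
        nio.write_session(session, out / session.meta.dyad_id, truth)
    cohort.meta.to_csv(out / "dyads.csv", index=False)
    return cohort
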