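"""Probe registration checks and channel-to-ROI allocation.

Channels are located in MNI space as the midpoint of their two forming
optodes.  Optodes whose measured distance to any montage neighbour falls
outside 2.5-3.5 cm are flagged as mis-located and the affected channels fall
back to cohort-mean positions.  Channels are then allocated to eight
cortical regions of interest (bilateral DLPF, vPM, TPJ, SPL) defined by MNI
centres and a 20 mm assignment radius, under a mutual-nearest rule: within a
participant each ROI receives at most one channel and each channel feeds at
most one ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .montage import OptodeSet

ROI_RADIUS_MM = 20.0
NEIGHBOR_MIN_CM = 2.5
NEIGHBOR_MAX_CM = 3.5

PROVENANCE_MEASURED = "measured-midpoint"
PROVENANCE_PARTIAL = "partial-fallback"
PROVENANCE_GROUP = "group-mean"

# MNI centres (mm) of the 8 regions of interest, frontal to parietal
_ROI_CSV = """region,laterality,x,y,z
DLPF,R,44,34,28
DLPF,L,-46,30,30
vPM,R,64,-4,20
vPM,L,-58,-8,28
TPJ,R,58,-56,18
TPJ,L,-54,-56,22
SPL,R,37,-63,59
SPL,L,-40,-64,53
"""


@dataclass(frozen=True)
class ROISpec:
    """One region of interest: named sphere in MNI space."""

    name: str
    laterality: str
    center: tuple[float, float, float]
    radius_mm: float = ROI_RADIUS_MM

    @property
    def label(self) -> str:
        return f"{self.name}_{self.laterality}"


def roi_table() -> pd.DataFrame:
    """The 8 ROI centres as a DataFrame (region, laterality, x, y, z)."""
    return pd.read_csv(StringIO(_ROI_CSV))


def roi_specs() -> list[ROISpec]:
    return [
        ROISpec(r.region, r.laterality, (float(r.x), float(r.y), float(r.z)))
        for r in roi_table().itertuples()
    ]


def validate_optode_distances(
    optodes: "OptodeSet",
    neighbor_pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.Series:
    """Flag each optode valid iff all its real-space neighbour distances lie
    in [2.5, 3.5] cm (inclusive).

    The neighbour graph defaults to the montage's channel-forming adjacency.
    """
    pairs = list(neighbor_pairs if neighbor_pairs is not None else optodes.neighbor_pairs)
    df = optodes.optodes.set_index("optode")
    degree = {oid: 0 for oid in df.index}
    valid = {oid: True for oid in df.index}
    pos = df[["x_cm", "y_cm", "z_cm"]]
    for a, b in pairs:
        d = float(np.linalg.norm(pos.loc[a].to_numpy() - pos.loc[b].to_numpy()))
        degree[a] += 1
        degree[b] += 1
        if not (NEIGHBOR_MIN_CM <= d <= NEIGHBOR_MAX_CM):
            valid[a] = False
            valid[b] = False
    isolated = [oid for oid, k in degree.items() if k == 0]
    if isolated:
        raise ValueError(f"optodes with no montage neighbours: {isolated}")
    return pd.Series(valid, name="valid").loc[df.index]


def channel_positions(
    optodes: "OptodeSet",
    validity: pd.Series | None = None,
    cohort_positions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-channel MNI coordinates with provenance.

    Both forming optodes valid -> midpoint of their MNI positions
    (``measured-midpoint``).  Any forming optode mis-located -> the cohort
    mean position for that channel (``partial-fallback``).  If more than 50%
    of the participant's optodes are mis-located, or MNI registration is
    missing, every channel takes the cohort mean (``group-mean``).

    ``cohort_positions`` is indexed by channel with columns mni_x/y/z (see
    :func:`cohort_mean_positions`).
    """
    if validity is None:
        validity = validate_optode_distances(optodes)
    opt = optodes.optodes.set_index("optode")
    frac_bad = 1.0 - float(validity.mean())
    whole_fallback = optodes.mni_missing or frac_bad > 0.5

    rows = []
    missing: list[int] = []
    for ch in optodes.channels.itertuples():
        cid = int(ch.channel)
        if whole_fallback:
            prov = PROVENANCE_GROUP
        elif validity[ch.source] and validity[ch.detector]:
            prov = PROVENANCE_MEASURED
        else:
            prov = PROVENANCE_PARTIAL
        if prov == PROVENANCE_MEASURED:
            p = 0.5 * (
                opt.loc[ch.source, ["mni_x", "mni_y", "mni_z"]].to_numpy(float)
                + opt.loc[ch.detector, ["mni_x", "mni_y", "mni_z"]].to_numpy(float)
            )
        else:
            if cohort_positions is None or cid not in cohort_positions.index:
                missing.append(cid)
                p = np.full(3, np.nan)
            else:
                p = cohort_positions.loc[cid, ["mni_x", "mni_y", "mni_z"]].to_numpy(float)
        rows.append(
            {
                "channel": cid,
                "mni_x": p[0],
                "mni_y": p[1],
                "mni_z": p[2],
                "provenance": prov,
            }
        )
    if missing:
        raise ValueError(
            "cohort_positions required for fallback channels but not supplied "
            f"for channels {sorted(set(missing))}"
        )
    return pd.DataFrame(rows)


def cohort_mean_positions(per_participant: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Per-channel mean MNI position over participants, using only channels
    with ``measured-midpoint`` provenance."""
    frames = []
    for df in per_participant:
        frames.append(df[df["provenance"] == PROVENANCE_MEASURED])
    allpos = pd.concat(frames, ignore_index=True)
    if allpos.empty:
        raise ValueError("no measured-midpoint channels available in cohort")
    return allpos.groupby("channel")[["mni_x", "mni_y", "mni_z"]].mean()


@dataclass
class AllocationResult:
    """Channel->ROI assignment for one participant."""

    assignments: pd.DataFrame  # columns: channel, roi, distance_mm
    unassigned: list[int] = field(default_factory=list)

    def roi_channel(self, roi_label: str) -> int | None:
        hit = self.assignments[self.assignments["roi"] == roi_label]
        return int(hit["channel"].iloc[0]) if len(hit) else None

    @property
    def channel_to_roi(self) -> dict[int, str]:
        return dict(zip(self.assignments["channel"].astype(int), self.assignments["roi"]))


def roi_data_sufficiency(
    allocations: Iterable[AllocationResult],
    threshold: float | None = None,
) -> pd.DataFrame:
    """Cohort-level screen of how many participants feed each ROI.

    Returns one row per ROI with its participant count and a ``sufficient``
    flag.  ``threshold`` defaults to the cohort's mean count over the ROIs
    that received any channel (the study-style data-driven cut); the fixed
    ROI table itself is not altered by this report.
    """
    counts = {r.label: 0 for r in roi_specs()}
    n = 0
    for alloc in allocations:
        n += 1
        for roi in alloc.assignments["roi"]:
            counts[roi] += 1
    nonzero = [v for v in counts.values() if v > 0]
    if threshold is None:
        threshold = float(np.mean(nonzero)) if nonzero else 0.0
    return pd.DataFrame(
        [
            {"roi": roi, "n_participants": c, "threshold": threshold,
             "sufficient": c >= threshold}
            for roi, c in counts.items()
        ]
    )


def assign_channels_to_rois(
    positions: pd.DataFrame,
    rois: Sequence[ROISpec] | None = None,
    radius_mm: float = ROI_RADIUS_MM,
) -> AllocationResult:
    """Allocate channels to ROIs under the mutual-nearest rule.

    Every channel may serve at most one ROI and vice versa; an assignment is
    only legal within ``radius_mm`` of the ROI centre.  Conflicts resolve so
    that of two channels competing for an ROI the nearer one wins and the
    loser falls back to its next-nearest available ROI.  Implemented as
    globally-nearest-pair matching, which is the unique stable matching for
    distance-induced preferences; ties break by lowest channel id, then ROI
    table order.
    """
    if rois is None:
        rois = roi_specs()
    pos = positions.dropna(subset=["mni_x", "mni_y", "mni_z"])
    chan_ids = pos["channel"].astype(int).to_numpy()
    xyz = pos[["mni_x", "mni_y", "mni_z"]].to_numpy(float)
    centers = np.array([r.center for r in rois], float)
    if len(chan_ids) == 0:
        return AllocationResult(
            assignments=pd.DataFrame(columns=["channel", "roi", "distance_mm"]),
            unassigned=[],
        )
    dist = np.linalg.norm(xyz[:, None, :] - centers[None, :, :], axis=2)

    candidates = [
        (dist[i, j], int(chan_ids[i]), j)
        for i in range(len(chan_ids))
        for j in range(len(rois))
        if dist[i, j] <= radius_mm
    ]
    candidates.sort()  # distance, then channel id, then ROI order
    taken_ch: set[int] = set()
    taken_roi: set[int] = set()
    rows = []
    for d, cid, j in candidates:
        if cid in taken_ch or j in taken_roi:
            continue
        taken_ch.add(cid)
        taken_roi.add(j)
        rows.append({"channel": cid, "roi": rois[j].label, "distance_mm": float(d)})
    assignments = pd.DataFrame(rows, columns=["channel", "roi", "distance_mm"])
    unassigned = sorted(set(chan_ids.tolist()) - taken_ch)
    return AllocationResult(assignments=assignments, unassigned=unassigned)
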