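"""Reference probe montage for the dyadic co-watching setup.

Each participant wears a bilateral cap of 7 sources and 7 detectors per
hemisphere arranged as a two-row staggered grid with 3 cm nominal spacing.
Adjacent source-detector pairs form 19 measurement channels per hemisphere
(6 + 6 horizontal pairs and 7 vertical pairs), 38 channels per participant.

Real-space coordinates are the ideal flat grid in cm.  Nominal MNI
coordinates are obtained by bending the grid along a piecewise-linear scalp
path through the four regions of interest of each hemisphere (DLPF, vPM,
TPJ, SPL), so that on the jitter-free montage one channel sits exactly on
each ROI centre.  Per-participant registration error is modelled elsewhere
(see :mod:`nirsync.synthetic`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import roi_table

N_COLUMNS = 7
N_ROWS = 2
GRID_SPACING_CM = 3.0
N_CHANNELS_PER_HEMISPHERE = 19

# approximate head centre used to orient the transverse scalp direction
_HEAD_CENTRE_MM = np.array([0.0, -20.0, 10.0])


@dataclass
class OptodeSet:
    """One participant's optode registration.

    ``optodes`` has one row per optode: ``optode`` (id), ``hemisphere``
    (``L``/``R``), ``kind`` (``source``/``detector``), real-space ``x_cm``,
    ``y_cm``, ``z_cm`` and MNI ``mni_x``, ``mni_y``, ``mni_z`` in mm (NaN when
    registration failed).  ``channels`` maps channel ids (1-38) to their
    forming optode pair.
    """

    optodes: pd.DataFrame
    channels: pd.DataFrame
    participant: str = ""
    neighbor_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def mni_missing(self) -> bool:
        return bool(
            self.optodes[["mni_x", "mni_y", "mni_z"]].isna().any(axis=None)
        )


def _grid_layout(hemisphere: str):
    """Ideal real-space grid and channel pairing for one hemisphere.

    Returns (optode rows, channel rows, neighbor pairs).  Optode ids look
    like ``L_r0c3``; kinds alternate so every adjacent pair is
    source-detector.
    """
    x_offset = 0.0 if hemisphere == "L" else 30.0
    rows = []
    kind_of = {}
    for r in range(N_ROWS):
        for c in range(N_COLUMNS):
            # row 0 starts with a source, row 1 with a detector
            kind = "source" if (r + c) % 2 == 0 else "detector"
            oid = f"{hemisphere}_r{r}c{c}"
            kind_of[oid] = kind
            rows.append(
                {
                    "optode": oid,
                    "hemisphere": hemisphere,
                    "kind": kind,
                    "x_cm": x_offset + c * GRID_SPACING_CM,
                    "y_cm": r * GRID_SPACING_CM,
                    "z_cm": 0.0,
                }
            )
    # channel-forming adjacent pairs, also the neighbor graph; vertical
    # (on-path) pairs first so montage subsets retain the ROI-covering chain
    pairs = []
    for c in range(N_COLUMNS):
        pairs.append((f"{hemisphere}_r0c{c}", f"{hemisphere}_r1c{c}"))
    for r in range(N_ROWS):
        for c in range(N_COLUMNS - 1):
            pairs.append((f"{hemisphere}_r{r}c{c}", f"{hemisphere}_r{r}c{c + 1}"))
    channels = []
    for a, b in pairs:
        src, det = (a, b) if kind_of[a] == "source" else (b, a)
        channels.append({"source": src, "detector": det, "hemisphere": hemisphere})
    return rows, channels, pairs


def _roi_path(hemisphere: str) -> np.ndarray:
    """ROI centres of one hemisphere ordered frontal to parietal."""
    rois = roi_table()
    order = ["DLPF", "vPM", "TPJ", "SPL"]
    pts = []
    for name in order:
        row = rois[(rois["region"] == name) & (rois["laterality"] == hemisphere)]
        pts.append(row[["x", "y", "z"]].to_numpy(float)[0])
    return np.asarray(pts)


class _ScalpBand:
    """Maps flat grid coordinates (u along-path mm, v transverse mm) to MNI.

    The along-path coordinate is warped so that grid columns 0, 2, 4, 6 land
    exactly on the four ROI centres; v moves along the scalp tangent plane.
    """

    def __init__(self, hemisphere: str):
        self.pts = _roi_path(hemisphere)
        seg = np.diff(self.pts, axis=0)
        self.seg_len = np.linalg.norm(seg, axis=1)
        self.arc = np.concatenate([[0.0], np.cumsum(self.seg_len)])
        # grid u of pinned columns 0,2,4,6 (30 mm column spacing)
        self.pin_u = np.array([0.0, 60.0, 120.0, 180.0])

    def _warp(self, u: float) -> float:
        """Grid coordinate -> arc length along the ROI path (linear warp)."""
        return float(np.interp(u, self.pin_u, self.arc))

    def _point_tangent(self, s: float):
        s = float(np.clip(s, 0.0, self.arc[-1]))
        i = int(np.clip(np.searchsorted(self.arc, s, side="right") - 1, 0, len(self.seg_len) - 1))
        t = (s - self.arc[i]) / self.seg_len[i]
        p = self.pts[i] + t * (self.pts[i + 1] - self.pts[i])
        tang = (self.pts[i + 1] - self.pts[i]) / self.seg_len[i]
        return p, tang

    def to_mni(self, u_mm: float, v_mm: float) -> np.ndarray:
        p, tang = self._point_tangent(self._warp(u_mm))
        radial = p - _HEAD_CENTRE_MM
        radial = radial / np.linalg.norm(radial)
        trans = np.cross(radial, tang)
        nrm = np.linalg.norm(trans)
        if nrm < 1e-9:  # degenerate tangent/radial alignment; cannot happen on Table-1 grid
            trans = np.array([0.0, 0.0, 1.0])
        else:
            trans = trans / nrm
        return p + v_mm * trans


def reference_optodes(participant: str = "", n_channels_per_hemisphere: int = N_CHANNELS_PER_HEMISPHERE) -> OptodeSet:
    """Build the nominal (jitter-free) bilateral montage.

    ``n_channels_per_hemisphere`` may be reduced below 19 to work with a
    montage subset (the first k channels of each hemisphere); optodes not
    forming any retained channel are dropped.
    """
    if not 1 <= n_channels_per_hemisphere <= N_CHANNELS_PER_HEMISPHERE:
        raise ValueError(
            f"n_channels_per_hemisphere must be in [1, {N_CHANNELS_PER_HEMISPHERE}]"
        )
    opt_rows: list[dict] = []
    chan_rows: list[dict] = []
    neighbor_pairs: list[tuple[str, str]] = []
    for hemisphere in ("L", "R"):
        rows, channels, pairs = _grid_layout(hemisphere)
        band = _ScalpBand(hemisphere)
        for row in rows:
            # grid x (cm, minus hemisphere offset) -> u mm; v centred between rows
            u = (row["x_cm"] - (0.0 if hemisphere == "L" else 30.0)) * 10.0
            v = (row["y_cm"] - GRID_SPACING_CM / 2.0) * 10.0
            mni = band.to_mni(u, v)
            row = dict(row, mni_x=mni[0], mni_y=mni[1], mni_z=mni[2])
            opt_rows.append(row)
        base = 0 if hemisphere == "L" else N_CHANNELS_PER_HEMISPHERE
        kept = channels[:n_channels_per_hemisphere]
        for i, ch in enumerate(kept):
            chan_rows.append({"channel": base + i + 1, **ch})
        neighbor_pairs.extend(pairs)

    optodes = pd.DataFrame(opt_rows)
    channels = pd.DataFrame(chan_rows)
    used = set(channels["source"]) | set(channels["detector"])
    optodes = optodes[optodes["optode"].isin(used)].reset_index(drop=True)
    neighbor_pairs = [p for p in neighbor_pairs if p[0] in used and p[1] in used]
    return OptodeSet(
        optodes=optodes,
        channels=channels,
        participant=participant,
        neighbor_pairs=neighbor_pairs,
    )
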