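"""Pseudo-dyad construction and real-vs-pseudo permutation inference.

Pseudo-dyads pair the role-A participant of one real dyad with the role-B
participant of another, within subgroups that share all experimental
features (episode order), so they differ from real dyads only in not having
done the experiment together.  For each (measure, ROI, band) cell a pooled-
variance two-sample t contrasts real against pseudo values; its null
distribution comes from label permutations, with Cohen's d and a normal-
approximation confidence interval reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class DyadMeta:
    """Identity and experimental features of one (real or pseudo) dyad."""

    dyad_id: str
    video_order: str
    participant_a: str
    participant_b: str
    is_real: bool = True

    def feature_tuple(self) -> tuple:
        return (self.video_order,)


def build_pseudo_dyads(metas: Sequence[DyadMeta]) -> list[DyadMeta]:
    """All ordered cross-pairings within each experimental-feature subgroup.

    A subgroup of size k contributes k*(k-1) pseudo dyads (role-A of dyad i
    with role-B of dyad j, i != j); singleton subgroups contribute none.
    """
    real = [m for m in metas if m.is_real]
    for m in real:
        if not m.video_order:
            raise ValueError(f"real dyad {m.dyad_id} lacks a video-order label")
        if m.participant_a == m.participant_b:
            raise ValueError(f"real dyad {m.dyad_id} has identical participants")
    groups: dict[tuple, list[DyadMeta]] = {}
    for m in real:
        groups.setdefault(m.feature_tuple(), []).append(m)
    pseudo = []
    for members in groups.values():
        for mi in members:
            for mj in members:
                if mi.dyad_id == mj.dyad_id:
                    continue
                pseudo.append(
                    DyadMeta(
                        dyad_id=f"pseudo_{mi.dyad_id}_{mj.dyad_id}",
                        video_order=mi.video_order,
                        participant_a=mi.participant_a,
                        participant_b=mj.participant_b,
                        is_real=False,
                    )
                )
    return pseudo


@dataclass
class GroupValues:
    """One inference cell: real and pseudo dyad values for a measure."""

    measure: str
    roi: str
    band: str
    real: np.ndarray
    pseudo: np.ndarray

    def __post_init__(self):
        self.real = np.asarray(self.real, float)
        self.pseudo = np.asarray(self.pseudo, float)
        if np.isnan(self.real).any() or np.isnan(self.pseudo).any():
            raise ValueError("GroupValues must not contain missing entries")


@dataclass
class PermutationResult:
    observed_diff: float
    t: float
    p: float
    d: float
    ci_low: float
    ci_high: float
    n_perm: int
    n_draws: int  # permutation t-statistics actually computed
    seed: int | None
    degenerate: bool = False


def _pooled_t(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        return 0.0
    return (x.mean() - y.mean()) / np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))


def _welch_t(x: np.ndarray, y: np.ndarray) -> float:
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    if vx + vy == 0:
        return 0.0
    return (x.mean() - y.mean()) / np.sqrt(vx + vy)


def effect_size(values: GroupValues) -> tuple[float, float, float]:
    """Cohen's d (real minus pseudo, pooled SD) with normal-approximation
    95% confidence interval."""
    x, y = values.real, values.pseudo
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("need at least 2 values per group")
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        return np.nan, np.nan, np.nan
    d = (x.mean() - y.mean()) / np.sqrt(sp2)
    se = np.sqrt((nx + ny) / (nx * ny) + d * d / (2.0 * (nx + ny)))
    return float(d), float(d - 1.959963984540054 * se), float(d + 1.959963984540054 * se)


def permutation_test(
    values: GroupValues,
    n_perm: int = 10_000,
    seed: int | None = None,
    statistic: str = "pooled",
) -> PermutationResult:
    """Two-sided label-permutation test of real vs pseudo group means.

    The observed statistic is a two-sample t (pooled variance by default,
    ``statistic="welch"`` optional).  Group labels are shuffled over the
    concatenated values preserving group sizes; p = (1 + #{|t*| >= |t|}) /
    (1 + n_perm).  The shuffle sequence is fixed by ``seed``.
    """
    import warnings

    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} is very low; p-value resolution is poor")
    tfun = {"pooled": _pooled_t, "welch": _welch_t}.get(statistic)
    if tfun is None:
        raise ValueError(f"unknown statistic {statistic!r}")
    x, y = values.real, values.pseudo
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 values per group")
    pooled = np.concatenate([x, y])
    if pooled.var() == 0:
        d, lo, hi = effect_size(values)
        return PermutationResult(
            observed_diff=float(x.mean() - y.mean()),
            t=0.0,
            p=1.0,
            d=d,
            ci_low=lo,
            ci_high=hi,
            n_perm=n_perm,
            n_draws=0,
            seed=seed,
            degenerate=True,
        )
    t_obs = tfun(x, y)
    rng = np.random.default_rng(seed)
    nx, n = len(x), len(pooled)
    t_star = np.empty(n_perm)
    # vectorised label shuffles in manageable blocks
    block = max(1, min(n_perm, int(2e6 // max(n, 1))))
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        idx = np.argsort(rng.random((b, n)), axis=1)
        perm = pooled[idx]
        px, py = perm[:, :nx], perm[:, nx:]
        if statistic == "pooled":
            sp2 = (
                (nx - 1) * px.var(axis=1, ddof=1) + (n - nx - 1) * py.var(axis=1, ddof=1)
            ) / (n - 2)
            denom = np.sqrt(sp2 * (1.0 / nx + 1.0 / (n - nx)))
        else:
            denom = np.sqrt(
                px.var(axis=1, ddof=1) / nx + py.var(axis=1, ddof=1) / (n - nx)
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            tb = (px.mean(axis=1) - py.mean(axis=1)) / denom
        t_star[done : done + b] = np.nan_to_num(tb, nan=0.0)
        done += b
    # tolerance keeps floating-point ties (e.g. the identity relabeling) in
    tol = 1e-9 * max(1.0, abs(t_obs))
    p = (1.0 + np.count_nonzero(np.abs(t_star) >= abs(t_obs) - tol)) / (1.0 + n_perm)
    d, lo, hi = effect_size(values)
    return PermutationResult(
        observed_diff=float(x.mean() - y.mean()),
        t=float(t_obs),
        p=float(p),
        d=d,
        ci_low=lo,
        ci_high=hi,
        n_perm=n_perm,
        n_draws=len(t_star),
        seed=seed,
    )


def run_permutation_grid(
    cells: Sequence[GroupValues],
    n_perm: int = 10_000,
    seed: int | None = None,
    statistic: str = "pooled",
) -> tuple[pd.DataFrame, int]:
    """Permutation tests over a grid of (measure, ROI, band) cells.

    Returns a tidy results table in the layout of the study's results tables
    and the total number of permutation draws actually executed (an
    execution counter, e.g. 8 ROIs x 3 bands x 10,000 = 240,000 per measure).
    """
    rows = []
    total_draws = 0
    ss = np.random.SeedSequence(seed)
    cell_seeds = ss.generate_state(max(len(cells), 1)) % (2**31)
    for cell, cs in zip(cells, cell_seeds):
        res = permutation_test(cell, n_perm=n_perm, seed=int(cs), statistic=statistic)
        total_draws += res.n_draws
        rows.append(
            {
                "measure": cell.measure,
                "band": cell.band,
                "region": cell.roi,
                "real_mean": float(cell.real.mean()),
                "real_sd": float(cell.real.std(ddof=1)),
                "pseudo_mean": float(cell.pseudo.mean()),
                "pseudo_sd": float(cell.pseudo.std(ddof=1)),
                "observed_diff": res.observed_diff,
                "t": res.t,
                "p_value": res.p,
                "effect_size": res.d,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "n_real": len(cell.real),
                "n_pseudo": len(cell.pseudo),
                "n_perm": res.n_perm,
            }
        )
    return pd.DataFrame(rows), total_draws


def paired_t_within_real(
    v1: np.ndarray, v2: np.ndarray
) -> tuple[float, int, float, tuple[float, float]]:
    """Classic paired t-test on v2 - v1 (e.g. post- minus pre-conversation
    coherence of the real dyads only).

    Returns (t, df, p, 95% CI of the mean difference).
    """
    v1 = np.asarray(v1, float)
    v2 = np.asarray(v2, float)
    if v1.shape != v2.shape or v1.ndim != 1:
        raise ValueError("paired test needs two equal-length vectors")
    n = len(v1)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = v2 - v1
    sd = diff.std(ddof=1)
    df = n - 1
    if sd == 0:
        return 0.0, df, 1.0, (float(diff.mean()), float(diff.mean()))
    se = sd / np.sqrt(n)
    t = diff.mean() / se
    p = 2.0 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(0.975, df)
    ci = (float(diff.mean() - tcrit * se), float(diff.mean() + tcrit * se))
    return float(t), int(df), float(p), ci


def adjust_pvalues(p: np.ndarray, method: str = "none") -> np.ndarray:
    """Multiple-comparison adjustment: 'none', 'bonferroni' or 'fdr_bh'."""
    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    if method not in ("bonferroni", "fdr_bh"):
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=method)[1]
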