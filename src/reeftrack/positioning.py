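"""Raw detections to filtered 2-D positions.

Stages: receiver clock synchronization from sync pings (linear
offset + drift per receiver, composed transitively through the
network), grouping of detections into transmissions, hyperbolic
TDOA multilateration by damped Gauss-Newton, a dimensionless
horizontal-position-error (HPE) quality metric, empirical-quantile
HPE filtering, and tag-loss / death screening.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import SOUND_SPEED, ArrayLayout

__all__ = [
    "ClockModel",
    "NoFix",
    "synchronize_clocks",
    "correct_times",
    "group_transmissions",
    "solve_position",
    "compute_hpe",
    "positions_from_detections",
    "filter_hpe",
    "screen_tag_loss",
]


@dataclass(frozen=True)
class ClockModel:
    """Linear clock error: local = true * (1 + drift) + offset."""

    receiver_id: str
    offset: float
    drift: float
    reference: str
    resid_sd: float = 0.0

    def to_true(self, t_local: np.ndarray | float):
        """Map local timestamps onto the reference clock."""
        return (np.asarray(t_local, float) - self.offset) / (1.0 + self.drift)


@dataclass(frozen=True)
class NoFix:
    tag_id: str
    t: float
    reason: str  # "insufficient_receivers" | "no_convergence"


def synchronize_clocks(
    sync_detections: pd.DataFrame,
    layout: ArrayLayout,
    reference: str,
    *,
    sound_speed: float = SOUND_SPEED,
    min_shared: int = 10,
    match_window: float = 5.0,
) -> dict[str, ClockModel]:
    """Fit per-receiver (offset, drift) against a reference receiver.

    Sync pings carry ``tag_id == "sync-<emitter>"``. For a receiver r
    and a base receiver b with an already-corrected clock, both hearing
    the same emission from s, the expected true arrival at r is
    ``t_b_true - d(s,b)/c + d(s,r)/c``; the regression of
    ``local_r - expected`` on ``expected`` has slope ``drift`` and
    intercept ``offset`` exactly. Receivers are corrected outward from
    the reference breadth-first, so a receiver that never hears the
    reference is synchronized through an intermediate. Receivers with
    no sync path to the reference are omitted from the result (their
    detections are excluded from positioning).
    """
    rec = layout.receivers.set_index("id")
    xy = {rid: (float(r["x"]), float(r["y"])) for rid, r in rec.iterrows()}
    ids = list(rec.index)
    if reference not in ids:
        raise ValueError(f"unknown reference receiver {reference!r}")

    sync = sync_detections.copy()
    sync["source"] = sync["tag_id"].str.removeprefix("sync-")

    models: dict[str, ClockModel] = {
        reference: ClockModel(reference, 0.0, 0.0, reference, 0.0)
    }
    frontier = [reference]
    while frontier:
        next_frontier = []
        for rid in ids:
            if rid in models:
                continue
            xt, yt = [], []
            det_r = sync[sync["receiver_id"] == rid]
            for base in frontier:
                mb = models[base]
                det_b = sync[sync["receiver_id"] == base]
                for src, grp_r in det_r.groupby("source"):
                    if src in (rid, base):
                        continue
                    grp_b = det_b[det_b["source"] == src]
                    if grp_b.empty:
                        continue
                    tb = np.sort(mb.to_true(grp_b["t_local"].to_numpy()))
                    d_sb = np.hypot(
                        xy[src][0] - xy[base][0], xy[src][1] - xy[base][1]
                    )
                    d_sr = np.hypot(xy[src][0] - xy[rid][0], xy[src][1] - xy[rid][1])
                    expected = tb - d_sb / sound_speed + d_sr / sound_speed
                    tl = np.sort(grp_r["t_local"].to_numpy())
                    # greedy nearest-time matching of the two pulse trains
                    j = np.searchsorted(expected, tl)
                    j = np.clip(j, 1, len(expected) - 1) if len(expected) > 1 else j * 0
                    lo = np.clip(j - 1, 0, len(expected) - 1)
                    hi = np.clip(j, 0, len(expected) - 1)
                    pick = np.where(
                        np.abs(expected[lo] - tl) <= np.abs(expected[hi] - tl), lo, hi
                    )
                    ok = np.abs(expected[pick] - tl) < match_window
                    xt.append(expected[pick[ok]])
                    yt.append(tl[ok] - expected[pick[ok]])
            if not xt:
                continue
            x = np.concatenate(xt)
            y = np.concatenate(yt)
            if len(x) < min_shared:
                continue
            A = np.column_stack([np.ones_like(x), x])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            resid = y - A @ coef
            models[rid] = ClockModel(
                rid,
                offset=float(coef[0]),
                drift=float(coef[1]),
                reference=reference,
                resid_sd=float(resid.std()),
            )
            next_frontier.append(rid)
        if not next_frontier:
            break
        frontier = list(models)  # widen: allow any corrected receiver as base
    return models


def correct_times(
    detections: pd.DataFrame, clocks: dict[str, ClockModel]
) -> pd.DataFrame:
    """Add a synchronized ``t`` column; drop receivers without a clock model."""
    det = detections[detections["receiver_id"].isin(clocks)].copy()
    offs = det["receiver_id"].map({r: m.offset for r, m in clocks.items()})
    drfs = det["receiver_id"].map({r: m.drift for r, m in clocks.items()})
    det["t"] = (det["t_local"] - offs) / (1.0 + drfs)
    return det


def group_transmissions(
    detections: pd.DataFrame,
    layout: ArrayLayout,
    *,
    sound_speed: float = SOUND_SPEED,
    window_factor: float = 1.5,
) -> pd.DataFrame:
    """Assign a transmission group id per tag by gap-splitting.

    Detections (already clock-corrected, column ``t``) closer together
    than ``window_factor * array diagonal / c`` belong to one
    transmission; groups are formed greedily in time order per tag.
    """
    window = window_factor * layout.diagonal / sound_speed
    det = detections.sort_values(["tag_id", "t"], kind="stable").copy()
    gap = det.groupby("tag_id")["t"].diff().fillna(np.inf)
    det["group"] = (gap > window).cumsum()
    return det


def solve_position(
    group: pd.DataFrame,
    layout: ArrayLayout,
    *,
    sound_speed: float = SOUND_SPEED,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> dict | NoFix:
    """TDOA multilateration of one detection group.

    Gauss-Newton with Levenberg damping on pairwise arrival-time
    differences (relative to the earliest receiver), initialized at the
    centroid of the detecting receivers. Returns a dict with keys
    ``tag_id, t, x, y, hpe, n_receivers, rms`` or a typed :class:`NoFix`.
    """
    g = group.sort_values("t").drop_duplicates("receiver_id")
    tag_id = str(g["tag_id"].iloc[0])
    t0 = float(g["t"].iloc[0])
    if len(g) < 3:
        return NoFix(tag_id, t0, "insufficient_receivers")
    rec = layout.receivers.set_index("id")
    rxy = rec.loc[g["receiver_id"], ["x", "y"]].to_numpy(float)
    t = g["t"].to_numpy(float)
    dt = t[1:] - t[0]

    p = rxy.mean(axis=0)
    lam = 0.0
    for _ in range(max_iter):
        d = np.hypot(rxy[:, 0] - p[0], rxy[:, 1] - p[1])
        d = np.maximum(d, 1e-9)
        resid = dt - (d[1:] - d[0]) / sound_speed
        u = (p - rxy) / d[:, None]  # unit vectors receiver->p
        J = (u[1:] - u[0]) / sound_speed  # d(pred)/dp, shape (n-1, 2)
        JT_J = J.T @ J
        rhs = J.T @ resid
        sse = float(resid @ resid)
        step = None
        for _try in range(8):
            try:
                step = np.linalg.solve(JT_J + lam * np.eye(2), rhs)
            except np.linalg.LinAlgError:
                lam = max(lam * 10.0, 1e-12)
                continue
            p_new = p + step
            d_new = np.maximum(
                np.hypot(rxy[:, 0] - p_new[0], rxy[:, 1] - p_new[1]), 1e-9
            )
            r_new = dt - (d_new[1:] - d_new[0]) / sound_speed
            if float(r_new @ r_new) <= sse or lam > 1e6:
                lam = lam / 10.0 if lam > 1e-12 else 0.0
                p = p_new
                break
            lam = max(lam * 10.0, 1e-8)
        else:
            return NoFix(tag_id, t0, "no_convergence")
        if step is not None and np.hypot(*step) < tol:
            break
    else:
        return NoFix(tag_id, t0, "no_convergence")

    d = np.maximum(np.hypot(rxy[:, 0] - p[0], rxy[:, 1] - p[1]), 1e-9)
    resid = dt - (d[1:] - d[0]) / sound_speed
    u = (p - rxy) / d[:, None]
    J = (u[1:] - u[0]) / sound_speed
    hpe = compute_hpe(J, sound_speed=sound_speed)
    t_emit = float(np.mean(t - d / sound_speed))
    rms = float(np.sqrt(np.mean(resid**2))) * sound_speed
    return {
        "tag_id": tag_id,
        "t": t_emit,
        "x": float(p[0]),
        "y": float(p[1]),
        "hpe": hpe,
        "n_receivers": int(len(g)),
        "rms": rms,
    }


def compute_hpe(J: np.ndarray, *, sound_speed: float = SOUND_SPEED) -> float:
    """Dimensionless positioning-quality metric from the TDOA Jacobian.

    ``sqrt(trace((J^T J)^-1)) / c`` — the square root of the trace of
    the linearized position covariance per unit timing noise, divided
    by the sound speed. Independent of the timing-noise level by
    construction, monotone in geometric dilution of precision, and
    specific to the network geometry (never comparable across set-ups).
    Collinear (singular) geometry yields ``inf``.
    """
    JT_J = J.T @ J
    if np.linalg.cond(JT_J) > 1e12 or not np.isfinite(JT_J).all():
        return float("inf")
    try:
        cov = np.linalg.inv(JT_J)
    except np.linalg.LinAlgError:
        return float("inf")
    tr = float(np.trace(cov))
    if tr < 0 or not np.isfinite(tr):
        return float("inf")
    return float(np.sqrt(tr)) / sound_speed


def positions_from_detections(
    detections: pd.DataFrame,
    layout: ArrayLayout,
    clocks: dict[str, ClockModel],
    *,
    sound_speed: float = SOUND_SPEED,
) -> tuple[pd.DataFrame, list[NoFix]]:
    """Full positioning pass: correct clocks, group, and solve each group.

    Only non-sync detections are positioned. Returns the positions
    table and the list of failed groups.
    """
    det = detections[detections["sensor"] != "sync"]
    det = correct_times(det, clocks)
    det = group_transmissions(det, layout, sound_speed=sound_speed)
    fixes, failures = [], []
    for _, grp in det.groupby("group", sort=True):
        res = solve_position(grp, layout, sound_speed=sound_speed)
        if isinstance(res, NoFix):
            failures.append(res)
        else:
            fixes.append(res)
    cols = ["tag_id", "t", "x", "y", "hpe", "n_receivers", "rms"]
    positions = pd.DataFrame(fixes, columns=cols)
    return positions, failures


def filter_hpe(
    positions: pd.DataFrame,
    quantile: float = 0.02,
    *,
    per_tag: bool = False,
) -> pd.DataFrame:
    """Drop positions above the empirical (1 - quantile) HPE percentile.

    Nearest-rank convention with strict-greater removal: with N
    positions the threshold is the ceil((1-q)*N)-th smallest HPE and
    only HPEs strictly above it are removed, so ties are retained and
    at least floor((1-q)*N) positions survive.

    The applied threshold is recorded in ``DataFrame.attrs`` so that
    re-filtering an already-filtered table reuses the original cut and
    is a no-op (the filter is idempotent).
    """
    if positions.empty:
        return positions
    if per_tag:
        out = (
            positions.groupby("tag_id", group_keys=False)
            .apply(lambda g: filter_hpe(g, quantile), include_groups=True)
            .reset_index(drop=True)
        )
        out.attrs["hpe_threshold"] = "per_tag"
        return out
    hpe = positions["hpe"].to_numpy(float)
    if "hpe_threshold" in positions.attrs:
        prior = positions.attrs["hpe_threshold"]
        if prior == "per_tag":
            return positions
        out = positions[hpe <= prior].reset_index(drop=True)
        out.attrs["hpe_threshold"] = prior
        return out
    n = len(hpe)
    rank = int(np.ceil((1.0 - quantile) * n))
    rank = min(max(rank, 1), n)
    threshold = float(np.sort(hpe)[rank - 1])
    out = positions[hpe <= threshold].reset_index(drop=True)
    out.attrs["hpe_threshold"] = threshold
    return out


def screen_tag_loss(
    positions: pd.DataFrame,
    vedba: pd.DataFrame | None = None,
    *,
    window_days: float = 7.0,
    radius: float = 5.0,
    vedba_floor: float = 0.2,
) -> dict[str, float | None]:
    """Detect tag loss / death per tag.

    A tag is truncated from the start of the first ``window_days``-long
    run in which its positions all stay within ``radius`` of their
    running centroid AND its mean VeDBA stays below ``vedba_floor``.
    ``vedba`` is a DataFrame (tag_id, t, vedba); if omitted, only the
    spatial condition applies when deciding is impossible, so no tag is
    truncated (both conditions are required).

    Returns {tag_id: truncation time in s, or None}.
    """
    out: dict[str, float | None] = {}
    win = window_days * 86400.0
    for tag_id, pos in positions.groupby("tag_id"):
        pos = pos.sort_values("t")
        t = pos["t"].to_numpy()
        xy = pos[["x", "y"]].to_numpy(float)
        vd = None
        if vedba is not None:
            v = vedba[vedba["tag_id"] == tag_id].sort_values("t")
            vd = (v["t"].to_numpy(), v["vedba"].to_numpy())
        trunc = None
        day_starts = np.arange(t.min(), t.max() - win + 1.0, 86400.0)
        for w0 in day_starts:
            sel = (t >= w0) & (t < w0 + win)
            if sel.sum() < 2:
                continue
            sub = xy[sel]
            cen = sub.mean(axis=0)
            if np.hypot(*(sub - cen).T).max() > radius:
                continue
            if vd is None:
                continue
            vsel = (vd[0] >= w0) & (vd[0] < w0 + win)
            if not vsel.any() or vd[1][vsel].mean() >= vedba_floor:
                continue
            trunc = float(w0)
            break
        out[tag_id] = trunc
    return out


def apply_truncation(
    frames: dict[str, pd.DataFrame], truncations: dict[str, float | None]
) -> dict[str, pd.DataFrame]:
    """Remove rows at/after each tag's truncation time (column ``t``)."""
    out = {}
    for name, df in frames.items():
        keep = pd.Series(True, index=df.index)
        for tag_id, t0 in truncations.items():
            if t0 is not None:
                keep &= ~((df["tag_id"] == tag_id) & (df["t"] >= t0))
        out[name] = df[keep].reset_index(drop=True)
    return out
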