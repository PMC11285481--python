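"""Behavioural-state analysis on step length and body acceleration.

Positions are grouped into 10-min bins; the step stream is the
Euclidean distance between consecutive bins' mean positions and the
VeDBA stream is the mean of in-bin acceleration payloads. A 3-state
Gamma/Gamma HMM with covariate-dependent transitions is fitted, the
covariate structure selected by AIC, states decoded by Viterbi and
mapped in space as per-state kernel densities.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import hmm as hmm_mod
from .hiding import BIN_S, _nearest_reef_distance
from .hmm import FittedHMM, GammaStream, HMMSpec
from .simulate import DEFAULT_EPOCH
from .spaceuse import UDGrid, fit_ud

__all__ = [
    "build_behaviour_bins",
    "animal_dummies",
    "covariate_columns",
    "fit_behaviour_hmm",
    "map_states",
]

BEHAVIOUR_STATES = ("BS1", "BS2", "BS3")

# covariate groups -> design columns (periodic terms as sin/cos pairs)
COVARIATE_GROUPS: dict[str, tuple[str, ...]] = {
    "current": ("current",),
    "sst": ("sst",),
    "doy": ("doy_sin", "doy_cos"),
    "hour": ("hour_sin", "hour_cos"),
    "tag_extent": ("tag_extent",),
    "dist_reef": ("dist_reef",),
}


def build_behaviour_bins(
    positions: pd.DataFrame,
    detections: pd.DataFrame,
    env: pd.DataFrame,
    structures: pd.DataFrame,
    *,
    release_times: dict[str, float] | None = None,
    epoch: pd.Timestamp = DEFAULT_EPOCH,
) -> pd.DataFrame:
    """Per (animal, 10-min bin) step/VeDBA streams plus covariates.

    Step is the distance between consecutive bins' mean positions
    (missing when either bin has no position); VeDBA is the mean of
    in-bin acceleration-sensor payloads. Environmental covariates are
    linearly interpolated to the bin midpoint; a bin range not covered
    by the series is a hard error. Tag extent runs 0 at release to 1 at
    the last detection.
    """
    acc = detections[detections["sensor"] == "acceleration"]
    t_det = "t" if "t" in detections.columns else "t_local"
    env_t = env["t"].to_numpy(float)

    rows = []
    for tag_id, pos in positions.groupby("tag_id", sort=True):
        pos = pos.sort_values("t")
        det = detections[detections["tag_id"] == tag_id]
        t_first = min(pos["t"].min(), det[t_det].min()) if len(det) else pos["t"].min()
        t_last = max(pos["t"].max(), det[t_det].max()) if len(det) else pos["t"].max()
        t0 = np.floor(t_first / BIN_S) * BIN_S
        starts = np.arange(t0, np.floor(t_last / BIN_S) * BIN_S + BIN_S, BIN_S)
        n = len(starts)
        mid = starts + BIN_S / 2.0
        if mid.min() < env_t.min() - BIN_S or mid.max() > env_t.max() + BIN_S:
            raise ValueError(
                f"environment series does not cover bins for {tag_id!r}: "
                f"need [{mid.min():.0f}, {mid.max():.0f}] s, have "
                f"[{env_t.min():.0f}, {env_t.max():.0f}] s"
            )

        pb = np.floor((pos["t"].to_numpy() - t0) / BIN_S).astype(int)
        mx = np.full(n, np.nan)
        my = np.full(n, np.nan)
        cnt = np.bincount(pb, minlength=n)
        has = cnt > 0
        mx[has] = np.bincount(pb, weights=pos["x"].to_numpy(), minlength=n)[has] / cnt[has]
        my[has] = np.bincount(pb, weights=pos["y"].to_numpy(), minlength=n)[has] / cnt[has]

        step = np.full(n, np.nan)
        step[1:] = np.hypot(np.diff(mx), np.diff(my))  # NaN propagates

        a = acc[acc["tag_id"] == tag_id]
        vedba = np.full(n, np.nan)
        if len(a):
            ab = np.floor((a[t_det].to_numpy() - t0) / BIN_S).astype(int)
            ok = (ab >= 0) & (ab < n)
            vs = np.bincount(ab[ok], weights=a["value"].to_numpy()[ok], minlength=n)
            vc = np.bincount(ab[ok], minlength=n)
            vedba[vc > 0] = vs[vc > 0] / vc[vc > 0]

        release = release_times.get(tag_id, float(t_first)) if release_times else float(t_first)
        span = max(float(t_last) - release, 1.0)
        when = pd.DatetimeIndex(epoch + pd.to_timedelta(mid, unit="s"))
        doy = when.dayofyear.to_numpy() + when.hour.to_numpy() / 24.0
        hour = when.hour.to_numpy() + when.minute.to_numpy() / 60.0

        dist_reef = np.full(n, np.nan)
        dist_reef[has] = _nearest_reef_distance(mx[has], my[has], structures)
        idx = np.arange(n)
        if has.any():
            dist_reef = np.interp(idx, idx[has], dist_reef[has])

        rows.append(
            pd.DataFrame(
                {
                    "tag_id": tag_id,
                    "t0": starts,
                    "x": mx,
                    "y": my,
                    "step": step,
                    "vedba": vedba,
                    "current": np.interp(mid, env_t, env["current"].to_numpy()),
                    "sst": np.interp(mid, env_t, env["sst"].to_numpy()),
                    "doy_sin": np.sin(2 * np.pi * doy / 365.25),
                    "doy_cos": np.cos(2 * np.pi * doy / 365.25),
                    "hour_sin": np.sin(2 * np.pi * hour / 24.0),
                    "hour_cos": np.cos(2 * np.pi * hour / 24.0),
                    "tag_extent": np.clip((mid - release) / span, 0.0, 1.0),
                    "dist_reef": dist_reef,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def animal_dummies(bins: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Append animal-id dummy columns (first animal as reference)."""
    dum = pd.get_dummies(bins["tag_id"], prefix="id", drop_first=True).astype(float)
    out = pd.concat([bins.reset_index(drop=True), dum.reset_index(drop=True)], axis=1)
    return out, list(dum.columns)


def covariate_columns(groups: tuple[str, ...]) -> tuple[str, ...]:
    cols: list[str] = []
    for g in groups:
        cols.extend(COVARIATE_GROUPS[g])
    return tuple(cols)


def _relabel_behaviour(fitted: FittedHMM) -> FittedHMM:
    """Map states to BS1 (low step, low VeDBA), BS2 (low step, high
    VeDBA), BS3 (largest step mean)."""
    step_mean = fitted.params.emission["step"]["mean"]
    ved_mean = fitted.params.emission["vedba"]["mean"]
    if not (np.isfinite(step_mean).all() and np.isfinite(ved_mean).all()):
        raise RuntimeError("behaviour-state relabelling failed: non-finite means")
    bs3 = int(np.argmax(step_mean))
    rest = [s for s in range(3) if s != bs3]
    rest.sort(key=lambda s: ved_mean[s])
    perm = np.array([rest[0], rest[1], bs3])
    return hmm_mod.permute_states(fitted, perm)


def _forward_candidates(
    bins: pd.DataFrame, id_cols: list[str], seed: int, n_starts: int,
    init: hmm_mod.HMMParams | None,
) -> list[tuple[str, ...]]:
    """Greedy forward selection over covariate groups by AIC.

    Starts from the id-only base and adds the group that lowers AIC
    most until none improves; the full covariate set is always included
    as a candidate as well.
    """
    data, _ = animal_dummies(bins)
    chosen: list[str] = []
    remaining = list(COVARIATE_GROUPS)
    candidates: list[tuple[str, ...]] = [()]

    def aic_of(groups: tuple[str, ...]) -> float:
        covs = tuple(id_cols) + covariate_columns(groups)
        spec = HMMSpec(
            n_states=3,
            streams=(GammaStream("step", zero_inflated=True), GammaStream("vedba")),
            covariates=covs,
        )
        return hmm_mod.fit_hmm(
            spec, data, seq_col="tag_id", n_starts=n_starts, seed=seed
        ).aic

    best_aic = aic_of(())
    while remaining:
        trials = {g: aic_of(tuple(chosen) + (g,)) for g in remaining}
        g_best = min(trials, key=trials.get)
        if trials[g_best] >= best_aic:
            break
        best_aic = trials[g_best]
        chosen.append(g_best)
        remaining.remove(g_best)
        candidates.append(tuple(chosen))
    full = tuple(COVARIATE_GROUPS)
    if full not in candidates:
        candidates.append(full)
    return candidates


def fit_behaviour_hmm(
    bins: pd.DataFrame,
    candidate_covariates: list[tuple[str, ...]] | str | None = None,
    *,
    seed: int = 0,
    n_starts: int = 3,
    init: hmm_mod.HMMParams | None = None,
) -> tuple[FittedHMM, pd.DataFrame, pd.DataFrame]:
    """Fit candidate 3-state models and decode with the AIC winner.

    Candidates are tuples of covariate-group names from
    :data:`COVARIATE_GROUPS` (animal-id dummies are always included
    when more than one animal is present), or the string ``"forward"``
    for greedy forward selection. Returns (best fitted model relabelled
    BS1..BS3, bins with ``state``, AIC table).
    """
    data, id_cols = animal_dummies(bins)
    if candidate_covariates == "forward":
        candidate_covariates = _forward_candidates(bins, id_cols, seed, n_starts, init)
    elif candidate_covariates is None:
        candidate_covariates = [(), tuple(COVARIATE_GROUPS)]

    fits: list[FittedHMM] = []
    labels = []
    for groups in candidate_covariates:
        covs = tuple(id_cols) + covariate_columns(tuple(groups))
        spec = HMMSpec(
            n_states=3,
            streams=(GammaStream("step", zero_inflated=True), GammaStream("vedba")),
            covariates=covs,
        )
        start = init
        if start is not None and start.beta.shape[2] != 1 + len(covs):
            beta = np.zeros((3, 3, 1 + len(covs)))
            beta[..., 0] = start.beta[..., 0]
            start = hmm_mod.HMMParams(
                {k: {p: v.copy() for p, v in d.items()} for k, d in start.emission.items()},
                beta,
            )
        fits.append(
            hmm_mod.fit_hmm(
                spec, data, seq_col="tag_id", init=start, n_starts=n_starts, seed=seed
            )
        )
        labels.append("+".join(groups) if groups else "(none)")

    table = hmm_mod.rank_models(fits)
    table["covariates"] = [labels[i] for i in table["index"]]
    best = fits[int(table.loc[0, "index"])]
    best = _relabel_behaviour(best)
    states = hmm_mod.viterbi(best.spec, best.params, data, seq_col="tag_id")
    out = bins.copy()
    out["state"] = np.array(BEHAVIOUR_STATES, dtype=object)[states]
    return best, out, table


def map_states(
    decoded_bins: pd.DataFrame,
    *,
    grid_step: float = 5.0,
    h: float = 10.0,
    min_bins: int = 10,
) -> dict[str, UDGrid]:
    """Normalized 2-D kernel density of bin positions per decoded state.

    States with fewer than ``min_bins`` positioned bins are omitted
    with a warning.
    """
    out: dict[str, UDGrid] = {}
    for state, grp in decoded_bins.groupby("state"):
        xy = grp[["x", "y"]].dropna().to_numpy(float)
        if len(xy) < min_bins:
            warnings.warn(f"state {state}: only {len(xy)} positioned bins; omitted")
            continue
        out[str(state)] = fit_ud(xy, h=h, grid_step=grid_step)
    return out
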