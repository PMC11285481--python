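"""Shelter-use inference from detection-derived streams.

Ten-minute bins built from all detections (with and without a
successful position) carry three streams: mean distance to the closest
reef (interpolated across positioning gaps), unique-receiver count, and
a binary on the presence of at least one position. A 4-state HMM
separates at-reef/away x positioned/unpositioned combinations; the
"at reef without positioning" state is read as hiding inside the
structures. The daily hiding proportion is then modelled with a
binomial penalized additive model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam

from . import hmm as hmm_mod
from .hmm import BernoulliStream, FittedHMM, GammaStream, HMMSpec
from .simulate import DEFAULT_EPOCH

__all__ = [
    "BIN_S",
    "build_bins",
    "fit_hiding_hmm",
    "daily_proportion",
    "fit_hiding_gam",
    "HidingGamResult",
]

BIN_S = 600.0  # 10-minute bins
HIDING_STATES = ("HS1", "HS2", "HS3", "HS4")


def _nearest_reef_distance(
    x: np.ndarray, y: np.ndarray, structures: pd.DataFrame
) -> np.ndarray:
    reefs = structures[structures["kind"] == "reef"]
    rx = reefs["x"].to_numpy(float)
    ry = reefs["y"].to_numpy(float)
    d = np.hypot(x[:, None] - rx[None, :], y[:, None] - ry[None, :])
    return d.min(axis=1)


def build_bins(
    detections: pd.DataFrame,
    positions: pd.DataFrame,
    structures: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the 10-min stream table per animal.

    Columns: tag_id, t0 (bin start, s), dist (m), interpolated (bool),
    n_receivers, positioned (0/1). Bins span each animal's first to
    last detection; bins without positions get a distance linearly
    interpolated in time between the nearest non-missing bins
    (nearest-value extension at the edges), flagged ``interpolated``.
    Animals with no positions at all are excluded with a warning.
    """
    det = detections[detections["sensor"] != "sync"]
    t_col = "t" if "t" in det.columns else "t_local"
    rows = []
    for tag_id, d in det.groupby("tag_id", sort=True):
        pos = positions[positions["tag_id"] == tag_id]
        if pos.empty:
            warnings.warn(f"animal {tag_id!r} has no positions; excluded")
            continue
        t0 = np.floor(d[t_col].min() / BIN_S) * BIN_S
        t1 = np.floor(d[t_col].max() / BIN_S) * BIN_S
        starts = np.arange(t0, t1 + BIN_S, BIN_S)
        det_bin = np.floor((d[t_col].to_numpy() - t0) / BIN_S).astype(int)
        n_rec = (
            d.assign(_b=det_bin).groupby("_b")["receiver_id"].nunique()
        )
        n_receivers = np.zeros(len(starts))
        n_receivers[n_rec.index.to_numpy()] = n_rec.to_numpy()

        pos_bin = np.floor((pos["t"].to_numpy() - t0) / BIN_S).astype(int)
        ok = (pos_bin >= 0) & (pos_bin < len(starts))
        pdist = _nearest_reef_distance(
            pos["x"].to_numpy(float)[ok], pos["y"].to_numpy(float)[ok], structures
        )
        dist = np.full(len(starts), np.nan)
        sums = np.bincount(pos_bin[ok], weights=pdist, minlength=len(starts))
        cnts = np.bincount(pos_bin[ok], minlength=len(starts))
        has = cnts > 0
        dist[has] = sums[has] / cnts[has]
        positioned = has.astype(float)

        interp = ~has
        if has.any():
            idx = np.arange(len(starts))
            dist = np.interp(idx, idx[has], dist[has])  # linear + edge extension
        rows.append(
            pd.DataFrame(
                {
                    "tag_id": tag_id,
                    "t0": starts,
                    "dist": np.maximum(dist, 0.05),
                    "interpolated": interp,
                    "n_receivers": n_receivers,
                    "positioned": positioned,
                }
            )
        )
    cols = ["tag_id", "t0", "dist", "interpolated", "n_receivers", "positioned"]
    return (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=cols)
    )


def _semantic_init(bins: pd.DataFrame) -> hmm_mod.HMMParams:
    """Starting values encoding the state semantics (near/far x pos/unpos)."""
    dist = bins["dist"].to_numpy(float)
    near = float(np.quantile(dist, 0.2))
    far = float(max(np.quantile(dist, 0.8), near * 3))
    cnt = bins.loc[bins["n_receivers"] > 0, "n_receivers"].to_numpy(float)
    c_lo = float(np.quantile(cnt, 0.25)) if len(cnt) else 1.0
    c_hi = float(np.quantile(cnt, 0.75)) if len(cnt) else 4.0
    frac0 = float((bins["n_receivers"] == 0).mean())
    emission = {
        "dist": {
            "mean": np.array([near, near, far, far]),
            "sd": np.array([near, near, far, far]) * 0.6,
        },
        "n_receivers": {
            "mean": np.array([c_lo, c_hi, c_hi, c_lo]),
            "sd": np.array([c_lo, c_hi, c_hi, c_lo]) * 0.6,
            "zero_mass": np.clip(
                np.array([frac0 * 2, 0.05, 0.05, frac0 * 2]), 0.01, 0.9
            ),
        },
        "positioned": {"p": np.array([0.05, 0.95, 0.95, 0.05])},
    }
    beta = np.zeros((4, 4, 1))
    beta[..., 0][~np.eye(4, dtype=bool)] = -2.0
    return hmm_mod.HMMParams(emission, beta)


def _relabel_hiding(fitted: FittedHMM) -> FittedHMM:
    """Permute states onto the HS1-HS4 semantics.

    HS1: at reef, unpositioned. HS2: at reef, positioned. HS3: away,
    positioned. HS4: away, unpositioned. "At reef" is a distance mean
    below the geometric midpoint of the smallest and largest fitted
    means; positioned is Bernoulli p above 0.5.
    """
    dist_mean = fitted.params.emission["dist"]["mean"]
    p = fitted.params.emission["positioned"]["p"]
    if not (np.isfinite(dist_mean).all() and np.isfinite(p).all()):
        raise RuntimeError("hiding-state relabelling failed: non-finite emissions")
    dn = (dist_mean - dist_mean.min()) / max(np.ptp(dist_mean), 1e-12)
    want = [(True, False), (True, True), (False, True), (False, False)]

    def score(state: int, slot: int) -> float:
        near, pos = want[slot]
        s = (1.0 - dn[state]) if near else dn[state]
        s += p[state] if pos else (1.0 - p[state])
        return s

    best_perm, best_total = None, -np.inf
    for cand in permutations(range(4)):
        total = sum(score(state, slot) for slot, state in enumerate(cand))
        if total > best_total + 1e-12:
            best_total = total
            best_perm = cand
    return hmm_mod.permute_states(fitted, np.array(best_perm))


def fit_hiding_hmm(
    bins: pd.DataFrame, *, seed: int = 0, n_starts: int = 3
) -> tuple[FittedHMM, pd.DataFrame]:
    """Fit the 4-state model and Viterbi-decode every bin.

    Returns (fitted model with states relabelled HS1..HS4, bins with a
    ``state`` column).
    """
    spec = HMMSpec(
        n_states=4,
        streams=(
            GammaStream("dist"),
            GammaStream("n_receivers", zero_inflated=True),
            BernoulliStream("positioned"),
        ),
    )
    data = bins.copy()
    data.loc[data["n_receivers"] > 0, "n_receivers"] = data.loc[
        data["n_receivers"] > 0, "n_receivers"
    ].astype(float)
    fitted = hmm_mod.fit_hmm(
        spec,
        data,
        seq_col="tag_id",
        init=_semantic_init(bins),
        n_starts=n_starts,
        seed=seed,
    )
    fitted = _relabel_hiding(fitted)
    states = hmm_mod.viterbi(spec, fitted.params, data, seq_col="tag_id")
    out = bins.copy()
    out["state"] = np.array(HIDING_STATES, dtype=object)[states]
    return fitted, out


def daily_proportion(
    decoded_bins: pd.DataFrame,
    *,
    detections: pd.DataFrame | None = None,
    positions: pd.DataFrame | None = None,
    structures: pd.DataFrame | None = None,
    env: pd.DataFrame | None = None,
    epoch: pd.Timestamp = DEFAULT_EPOCH,
) -> pd.DataFrame:
    """Per (animal, date) hiding proportion with model covariates.

    Covariates: ``reef`` (structure nearest the animal's mean position
    that day), ``current`` (daily mean current speed), ``doy`` (day of
    year), ``n_ids`` (distinct animals detected anywhere in the array
    that date). Covariates needing inputs that were not passed are
    omitted.
    """
    b = decoded_bins.copy()
    when = epoch + pd.to_timedelta(b["t0"], unit="s")
    b["date"] = when.dt.date
    daily = (
        b.groupby(["tag_id", "date"])
        .agg(n_bins=("state", "size"), n_hs1=("state", lambda s: int((s == "HS1").sum())))
        .reset_index()
    )
    daily["proportion"] = daily["n_hs1"] / daily["n_bins"]
    daily["doy"] = pd.to_datetime(daily["date"]).dt.dayofyear

    if detections is not None:
        det = detections[detections["sensor"] != "sync"]
        t_col = "t" if "t" in det.columns else "t_local"
        ddate = (epoch + pd.to_timedelta(det[t_col], unit="s")).dt.date
        n_ids = det.groupby(ddate)["tag_id"].nunique()
        daily["n_ids"] = daily["date"].map(n_ids).fillna(0).astype(int)

    if env is not None:
        edate = (epoch + pd.to_timedelta(env["t"], unit="s")).dt.date
        cur = env.groupby(edate)["current"].mean()
        daily["current"] = daily["date"].map(cur)

    if positions is not None and structures is not None:
        pos = positions.copy()
        pos["date"] = (epoch + pd.to_timedelta(pos["t"], unit="s")).dt.date
        mean_pos = pos.groupby(["tag_id", "date"])[["x", "y"]].mean().reset_index()
        sx = structures["x"].to_numpy(float)
        sy = structures["y"].to_numpy(float)
        sid = structures["id"].to_numpy(object)
        d = np.hypot(
            mean_pos["x"].to_numpy()[:, None] - sx[None, :],
            mean_pos["y"].to_numpy()[:, None] - sy[None, :],
        )
        mean_pos["reef"] = sid[np.argmin(d, axis=1)]
        daily = daily.merge(
            mean_pos[["tag_id", "date", "reef"]], on=["tag_id", "date"], how="left"
        )
        daily["reef"] = daily["reef"].fillna("other")
    return daily


@dataclass
class HidingGamResult:
    """Fitted binomial additive model plus partial-effect access."""

    result: object
    smoother: BSplines
    smooth_names: list[str]
    exog_names: list[str]
    dropped: list[str]

    @property
    def params(self) -> np.ndarray:
        return np.asarray(self.result.params)

    def partial_effect(self, name: str, grid: np.ndarray | None = None) -> pd.DataFrame:
        """Partial effect of one smooth on the linear-predictor scale."""
        if name not in self.smooth_names:
            raise KeyError(f"unknown smooth {name!r}; have {self.smooth_names}")
        j = self.smooth_names.index(name)
        sm_j = self.smoother.smoothers[j]
        x = sm_j.x if grid is None else np.asarray(grid, float)
        basis = sm_j.transform(x)
        k0 = len(self.exog_names) + sum(
            s.dim_basis for s in self.smoother.smoothers[:j]
        )
        coef = self.params[k0 : k0 + sm_j.dim_basis]
        eff = basis @ coef
        order = np.argsort(x)
        return pd.DataFrame({"x": x[order], "effect": eff[order]})


def fit_hiding_gam(
    daily: pd.DataFrame,
    *,
    df_current: int = 9,
    df_doy: int = 9,
    df_n_ids: int = 5,
    alpha: float | None = None,
) -> HidingGamResult:
    """Binomial penalized additive model of the daily hiding proportion.

    Smooth terms: current speed (basis size ``df_current``), day of
    year (``df_doy``), daily number of distinct animals detected
    (``df_n_ids``); parametric terms: animal id and reef as categorical
    dummies. Observations are weighted by the number of bins behind
    each daily proportion. Smoothing penalties default to a
    generalized-CV style selection via ``select_penweight``; pass
    ``alpha`` to fix them instead. Constant covariates are dropped with
    a warning.
    """
    if len(daily) < 30:
        raise ValueError("need at least 30 daily records")
    smooth_cfg = [("current", df_current), ("doy", df_doy), ("n_ids", df_n_ids)]
    cols, dfs, dropped = [], [], []
    for name, dfk in smooth_cfg:
        if name not in daily.columns or daily[name].nunique() < dfk:
            dropped.append(name)
            warnings.warn(f"covariate {name!r} missing or too coarse; term dropped")
            continue
        cols.append(name)
        dfs.append(dfk)
    if not cols:
        raise ValueError("no usable smooth covariates")
    X = daily[cols].to_numpy(float)
    bs = BSplines(X, df=dfs, degree=[3] * len(cols))

    exog = pd.DataFrame({"const": np.ones(len(daily))})
    for cat in ("tag_id", "reef"):
        if cat in daily.columns and daily[cat].nunique() > 1:
            dum = pd.get_dummies(daily[cat], prefix=cat, drop_first=True).astype(float)
            exog = pd.concat([exog, dum], axis=1)
        elif cat in daily.columns:
            dropped.append(cat)

    y = daily["proportion"].to_numpy(float)
    w = daily["n_bins"].to_numpy(float)
    if np.ptp(y) == 0.0:
        # a constant response is fitted exactly, which the IRLS backend
        # treats as separation; an alternating 1e-6 jitter breaks the
        # degeneracy without moving any estimate visibly
        y = y + 1e-6 * np.where(np.arange(len(y)) % 2 == 0, 1.0, -1.0)
        y = np.clip(y, 0.0, 1.0)

    def make(alphas: list[float]) -> GLMGam:
        return GLMGam(
            y,
            exog=exog,
            smoother=bs,
            family=sm.families.Binomial(),
            var_weights=w,
            alpha=alphas,
        )

    alphas = [1.0] * len(cols) if alpha is None else [alpha] * len(cols)
    if alpha is None:
        # select_penweight mutates its instance, so use a throwaway one
        try:
            best_alpha, *_ = make(alphas).select_penweight(criterion="gcv")
            alphas = list(np.maximum(np.asarray(best_alpha, float), 0.01))
        except Exception:  # keep default penalties if selection fails
            pass
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = make(alphas).fit()
        except Exception:  # heavier penalty rescues separation issues
            res = make([100.0] * len(cols)).fit()
    return HidingGamResult(
        result=res,
        smoother=bs,
        smooth_names=cols,
        exog_names=list(exog.columns),
        dropped=dropped,
    )
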