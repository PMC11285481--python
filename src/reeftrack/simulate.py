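"""Ground-truthed synthetic telemetry generator.

Produces regime-switching fish tracks, acoustic transmissions with
range-dependent detection, receiver clock errors, sync pings, and an
environmental series — everything the downstream positioning and
modelling stages consume, with the generating truth retained so that
recovery can be tested.

Coordinates are local planar metres (ENU) anchored at the array centre.
Time is seconds since a configurable epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_EPOCH = pd.Timestamp("2021-07-01T00:00:00Z")
SOUND_SPEED = 1500.0  # m/s, nominal seawater
TRACK_STEP_S = 60.0  # movement-model time step

__all__ = [
    "ArrayLayout",
    "TagConfig",
    "MovementRegime",
    "default_layout",
    "default_regimes",
    "simulate_tracks",
    "simulate_detections",
    "simulate_environment",
]


@dataclass(frozen=True)
class ArrayLayout:
    """Receiver and structure geometry plus the geographic anchor.

    ``receivers``: DataFrame with columns id, x, y, depth.
    ``structures``: DataFrame with columns id, kind, x, y, scour.
    ``origin``: (lat, lon) used only for diel computation downstream.
    """

    receivers: pd.DataFrame
    structures: pd.DataFrame
    origin: tuple[float, float] = (51.70, 3.05)

    def __post_init__(self) -> None:
        if self.receivers["id"].duplicated().any():
            raise ValueError("receiver ids must be unique")

    @property
    def receiver_xy(self) -> np.ndarray:
        return self.receivers[["x", "y"]].to_numpy(float)

    @property
    def reef_xy(self) -> np.ndarray:
        reefs = self.structures[self.structures["kind"] == "reef"]
        return reefs[["x", "y"]].to_numpy(float)

    @property
    def diagonal(self) -> float:
        xy = self.receiver_xy
        span = xy.max(axis=0) - xy.min(axis=0)
        return float(np.hypot(*span))


@dataclass(frozen=True)
class TagConfig:
    """Transmitter configuration: random delay bounds, acceleration
    averaging window, alternating payload cycle, battery life."""

    delay_min: float = 50.0
    delay_max: float = 100.0
    vedba_window: float = 37.0
    battery_life_days: float = 278.0
    sensor_cycle: tuple[str, ...] = ("pressure", "acceleration")

    def __post_init__(self) -> None:
        if not self.delay_min < self.delay_max:
            raise ValueError("delay_min must be < delay_max")


@dataclass(frozen=True)
class MovementRegime:
    name: str
    attraction: float  # 1/s pull toward the current anchor point
    step_scale: float  # m per track step
    vedba_mean: float  # m s^-2
    vedba_sd: float
    detectability: float  # multiplicative detection factor in [0, 1]

    def __post_init__(self) -> None:
        if not 0.0 <= self.detectability <= 1.0:
            raise ValueError("detectability must lie in [0, 1]")


def default_layout(
    *,
    grid_n: int = 4,
    spacing: float = 225.0,
    reef_radius: float = 280.0,
    origin: tuple[float, float] = (51.70, 3.05),
) -> ArrayLayout:
    """4x4 receiver grid with 4 reefs around a central turbine.

    Receivers sit on a square grid (nearest-neighbour spacing
    ``spacing``); reefs are placed on the diagonals at ``reef_radius``
    from the central monopile; scour protection on the southern pair.
    """
    offs = (np.arange(grid_n) - (grid_n - 1) / 2.0) * spacing
    recs = [
        {"id": f"S{ix * grid_n + iy + 1:02d}", "x": x, "y": y, "depth": 30.0}
        for ix, x in enumerate(offs)
        for iy, y in enumerate(offs)
    ]
    r = reef_radius / np.sqrt(2.0)
    structures = pd.DataFrame(
        [
            {"id": "R01", "kind": "reef", "x": -r, "y": r, "scour": False},
            {"id": "R02", "kind": "reef", "x": r, "y": r, "scour": False},
            {"id": "R03", "kind": "reef", "x": -r, "y": -r, "scour": True},
            {"id": "R04", "kind": "reef", "x": r, "y": -r, "scour": True},
            {"id": "L08", "kind": "turbine", "x": 0.0, "y": 0.0, "scour": True},
        ]
    )
    return ArrayLayout(pd.DataFrame(recs), structures, origin)


def default_regimes(hiding_detectability: float = 0.02) -> dict[str, MovementRegime]:
    """Hiding / local / transit regime set used throughout the tests."""
    return {
        "hiding": MovementRegime("hiding", 0.05, 0.3, 0.10, 0.05, hiding_detectability),
        "local": MovementRegime("local", 0.01, 3.0, 0.80, 0.40, 1.0),
        "transit": MovementRegime("transit", 0.0, 30.0, 1.20, 0.60, 1.0),
    }


def _check_stochastic(tm: np.ndarray, k: int) -> np.ndarray:
    tm = np.asarray(tm, float)
    if tm.shape != (k, k) or np.any(tm < 0) or not np.allclose(tm.sum(axis=1), 1.0):
        raise ValueError("transition matrix must be row-stochastic KxK")
    return tm


def simulate_tracks(
    layout: ArrayLayout,
    regimes: dict[str, MovementRegime],
    transition_matrix: np.ndarray,
    n_fish: int,
    duration_days: float,
    seed: int,
    *,
    start_regime: str | None = None,
    step_s: float = TRACK_STEP_S,
) -> pd.DataFrame:
    """Regime-switching tracks for ``n_fish`` over ``duration_days``.

    Returns a truth DataFrame with columns
    ``tag_id, t, x, y, regime, vedba, depth``. Each fish is anchored to
    a home reef (round-robin over reefs): hiding pins the position to
    within 2 m of the reef, local is a mean-reverting walk around it,
    transit heads toward another structure or the array exit.
    """
    names = list(regimes)
    k = len(names)
    tm = _check_stochastic(transition_matrix, k)
    rng = np.random.default_rng(seed)
    reefs = layout.structures[layout.structures["kind"] == "reef"].reset_index(drop=True)
    n_steps = int(round(duration_days * 86400.0 / step_s))
    times = np.arange(n_steps) * step_s

    half_span = np.abs(layout.receiver_xy).max() + 200.0
    frames = []
    for f in range(n_fish):
        home = reefs.iloc[f % len(reefs)]
        hx, hy = float(home["x"]), float(home["y"])
        if start_regime is None:
            state = int(rng.integers(k))
        else:
            state = names.index(start_regime)
        x, y = hx, hy
        xs = np.empty(n_steps)
        ys = np.empty(n_steps)
        states = np.empty(n_steps, dtype=int)
        target = None
        for i in range(n_steps):
            reg = regimes[names[state]]
            if reg.name == "hiding":
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(0, 2.0)
                x, y = hx + rad * np.cos(ang), hy + rad * np.sin(ang)
            elif reg.name == "transit":
                if target is None:
                    others = reefs[reefs["id"] != home["id"]]
                    if rng.random() < 0.5 and len(others):
                        row = others.iloc[int(rng.integers(len(others)))]
                        target = (float(row["x"]), float(row["y"]))
                    else:  # leave the array
                        ang = rng.uniform(0, 2 * np.pi)
                        target = (2 * half_span * np.cos(ang), 2 * half_span * np.sin(ang))
                dx, dy = target[0] - x, target[1] - y
                dist = np.hypot(dx, dy)
                if dist < reg.step_scale:
                    target = None
                else:
                    x += reg.step_scale * dx / dist + rng.normal(0, reg.step_scale / 4)
                    y += reg.step_scale * dy / dist + rng.normal(0, reg.step_scale / 4)
            else:  # local: mean-reverting walk around the home reef
                pull = min(1.0, reg.attraction * step_s)
                x += pull * (hx - x) + rng.normal(0, reg.step_scale / np.sqrt(2))
                y += pull * (hy - y) + rng.normal(0, reg.step_scale / np.sqrt(2))
            xs[i], ys[i], states[i] = x, y, state
            if reg.name != "transit":
                target = None
            state = int(rng.choice(k, p=tm[state]))
        regime_names = np.array(names, dtype=object)[states]
        vm = np.array([regimes[n].vedba_mean for n in regime_names])
        vs = np.array([regimes[n].vedba_sd for n in regime_names])
        shape = vm**2 / vs**2
        scale = vs**2 / vm
        vedba = rng.gamma(shape, scale)
        depth = 29.0 + rng.normal(0, 0.5, n_steps)
        frames.append(
            pd.DataFrame(
                {
                    "tag_id": f"F{f + 1:02d}",
                    "t": times,
                    "x": xs,
                    "y": ys,
                    "regime": regime_names,
                    "vedba": vedba,
                    "depth": depth,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _interp_track(truth_fish: pd.DataFrame, t: np.ndarray) -> dict[str, np.ndarray]:
    tt = truth_fish["t"].to_numpy()
    out = {
        c: np.interp(t, tt, truth_fish[c].to_numpy())
        for c in ("x", "y", "vedba", "depth")
    }
    idx = np.clip(np.searchsorted(tt, t, side="right") - 1, 0, len(tt) - 1)
    out["regime"] = truth_fish["regime"].to_numpy()[idx]
    return out


def simulate_detections(
    truth: pd.DataFrame,
    layout: ArrayLayout,
    tag: TagConfig,
    *,
    detection_model: tuple[float, float] = (400.0, 80.0),
    clock_models: dict[str, tuple[float, float]] | None = None,
    timing_sd: float = 1e-4,
    sound_speed: float = SOUND_SPEED,
    regimes: dict[str, MovementRegime] | None = None,
    sync_interval: float = 600.0,
    seed: int = 0,
    network_load_midpoint: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate detections of tag transmissions and receiver sync pings.

    Each transmission is detected independently per receiver with
    probability ``logistic((d50 - d) / slope)`` times the regime's
    detectability multiplier. Recorded local arrival time is
    ``(t_emit + d/c + noise) * (1 + drift) + offset`` for the
    receiver's clock. Payloads alternate pressure (depth, m) and
    acceleration (VeDBA, m s^-2). Sync pings are emitted by every
    receiver on a fixed schedule and heard by its neighbours.

    Returns ``(detections, sync_detections)`` DataFrames with columns
    ``receiver_id, tag_id, t_local, sensor, value``.
    """
    d50, slope = detection_model
    if d50 <= 0:
        raise ValueError("d50 must be positive")
    rng = np.random.default_rng(seed)
    rec_ids = layout.receivers["id"].to_numpy()
    rec_xy = layout.receiver_xy
    clocks = clock_models or {rid: (0.0, 0.0) for rid in rec_ids}
    mult = {
        name: reg.detectability for name, reg in (regimes or {}).items()
    }
    t_end = float(truth["t"].max())

    n_active = truth["tag_id"].nunique()
    load_factor = 1.0
    if network_load_midpoint is not None:
        load_factor = 1.0 / (1.0 + np.exp((n_active - network_load_midpoint) / 4.0))

    det_rows = []
    for tag_id, fish in truth.groupby("tag_id", sort=True):
        fish = fish.sort_values("t")
        # emission schedule: uniform random delays within battery life
        horizon = min(t_end, tag.battery_life_days * 86400.0)
        n_max = int(horizon / tag.delay_min) + 2
        delays = rng.uniform(tag.delay_min, tag.delay_max, n_max)
        t_emit = np.cumsum(delays)
        t_emit = t_emit[t_emit < horizon]
        st = _interp_track(fish, t_emit)
        cyc = len(tag.sensor_cycle)
        sensors = np.array(tag.sensor_cycle, dtype=object)[np.arange(len(t_emit)) % cyc]
        values = np.where(sensors == "pressure", st["depth"], st["vedba"])
        m = np.array([mult.get(r, 1.0) for r in st["regime"]])
        for j, (rid, (rx, ry)) in enumerate(zip(rec_ids, rec_xy)):
            off, drift = clocks[rid]
            d = np.hypot(st["x"] - rx, st["y"] - ry)
            p = load_factor * m / (1.0 + np.exp(-(d50 - d) / slope))
            hit = rng.random(len(t_emit)) < p
            if not hit.any():
                continue
            arr = t_emit[hit] + d[hit] / sound_speed
            if timing_sd > 0:
                arr = arr + rng.normal(0, timing_sd, hit.sum())
            det_rows.append(
                pd.DataFrame(
                    {
                        "receiver_id": rid,
                        "tag_id": tag_id,
                        "t_local": arr * (1.0 + drift) + off,
                        "sensor": sensors[hit],
                        "value": values[hit],
                    }
                )
            )

    sync_rows = []
    t_sync = np.arange(0.0, t_end, sync_interval)
    for j, (src, (sx, sy)) in enumerate(zip(rec_ids, rec_xy)):
        for rid, (rx, ry) in zip(rec_ids, rec_xy):
            if rid == src:
                continue
            off, drift = clocks[rid]
            d = float(np.hypot(sx - rx, sy - ry))
            p = 1.0 / (1.0 + np.exp(-(d50 - d) / slope))
            hit = rng.random(len(t_sync)) < p
            if not hit.any():
                continue
            arr = t_sync[hit] + d / sound_speed
            if timing_sd > 0:
                arr = arr + rng.normal(0, timing_sd, hit.sum())
            sync_rows.append(
                pd.DataFrame(
                    {
                        "receiver_id": rid,
                        "tag_id": f"sync-{src}",
                        "t_local": arr * (1.0 + drift) + off,
                        "sensor": "sync",
                        "value": 0.0,
                    }
                )
            )

    empty = pd.DataFrame(
        columns=["receiver_id", "tag_id", "t_local", "sensor", "value"]
    )
    detections = (
        pd.concat(det_rows, ignore_index=True).sort_values(
            ["tag_id", "t_local"], kind="stable"
        ).reset_index(drop=True)
        if det_rows
        else empty.copy()
    )
    sync = (
        pd.concat(sync_rows, ignore_index=True).sort_values(
            ["tag_id", "t_local"], kind="stable"
        ).reset_index(drop=True)
        if sync_rows
        else empty.copy()
    )
    return detections, sync


def random_clock_models(
    layout: ArrayLayout,
    seed: int,
    *,
    offset_sd: float = 0.5,
    drift_sd: float = 1e-5,
    reference: str | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-receiver (offset s, drift s/s); the reference keeps a perfect clock."""
    rng = np.random.default_rng(seed)
    rec_ids = list(layout.receivers["id"])
    ref = reference or rec_ids[0]
    out = {}
    for rid in rec_ids:
        if rid == ref:
            out[rid] = (0.0, 0.0)
        else:
            out[rid] = (float(rng.normal(0, offset_sd)), float(rng.normal(0, drift_sd)))
    return out


def simulate_environment(
    duration_days: float,
    seed: int,
    *,
    step_s: float = 600.0,
    tidal_period_h: float = 12.42,
    current_amp: float = 0.8,
    current_noise_sd: float = 0.05,
    sst_mean: float = 12.0,
    sst_amp: float = 7.0,
    sst_noise_sd: float = 0.3,
    epoch: pd.Timestamp = DEFAULT_EPOCH,
) -> pd.DataFrame:
    """Rectified tidal current plus seasonal SST, both with optional noise.

    Columns: ``t`` (s since epoch), ``current`` (m/s, >= 0), ``sst`` (degC).
    SST peaks around day-of-year 212 (early August).
    """
    if duration_days <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_days * 86400.0, step_s)
    current = current_amp * np.abs(np.sin(2 * np.pi * t / (tidal_period_h * 3600.0)))
    if current_noise_sd > 0:
        current = np.clip(current + rng.normal(0, current_noise_sd, len(t)), 0.0, None)
    doy = epoch.dayofyear + t / 86400.0
    sst = sst_mean + sst_amp * np.cos(2 * np.pi * (doy - 212.0) / 365.25)
    if sst_noise_sd > 0:
        sst = sst + rng.normal(0, sst_noise_sd, len(t))
    return pd.DataFrame({"t": t, "current": current, "sst": sst})
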