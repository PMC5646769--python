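"""Weather-series decomposition and interpolation to trap locations.

A station's daily series is decomposed additively into a long-term annual
smooth f_k(year), a cyclic mean seasonal smooth f_t(day-of-year), a per-year
seasonal anomaly r(year, day), a linear altitude effect a*h, and a residual.
The smooths are penalized B-splines (second-difference penalty, smoothing
chosen by generalized cross-validation); the seasonal basis is periodic so
December 31 joins January 1.  Residuals are modelled with a separable
exponential(space) x exponential(time) covariance fitted by weighted least
squares to the empirical spatio-temporal variogram, and interpolated to
trap locations by ordinary kriging of same-day residuals (exact at station
locations when the nugget is zero).  Stations farther than 100 km from the
target are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import BSpline

STATION_COLUMNS = ["station_id", "lon", "lat", "alt", "year", "day", "value"]
MAX_STATION_KM = 100.0
#: inclusive day-of-year window of the preceding winter, Nov 1 (day 304 of
#: the previous year) through end of February (day 58), non-leap convention
WINTER_WINDOW = (304, 58)

_EARTH_RADIUS_KM = 6371.0


def great_circle_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Haversine distance in kilometres."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


# ---------------------------------------------------------------------------
# penalized B-spline machinery


def _open_basis(x: np.ndarray, lo: float, hi: float, n_segments: int, degree: int = 3):
    interior = np.linspace(lo, hi, n_segments + 1)
    t = np.concatenate([[lo] * degree, interior, [hi] * degree])
    B = BSpline.design_matrix(np.clip(x, lo, hi), t, degree).toarray()
    D = np.diff(np.eye(B.shape[1]), n=2, axis=0)
    return B, D.T @ D, t


def _cyclic_basis(x: np.ndarray, period: float, n_segments: int, degree: int = 3):
    h = period / n_segments
    t = h * np.arange(-degree, n_segments + degree + 1)
    B_ext = BSpline.design_matrix(np.mod(x, period), t, degree).toarray()
    n = n_segments
    B = np.zeros((len(x), n))
    for j in range(B_ext.shape[1]):
        B[:, j % n] += B_ext[:, j]
    # circular second-difference penalty
    D = np.zeros((n, n))
    for i in range(n):
        D[i, i] = 1.0
        D[i, (i + 1) % n] = -2.0
        D[i, (i + 2) % n] = 1.0
    return B, D.T @ D


@dataclass
class _Smooth:
    """A fitted penalized smooth: evaluate(x) on the original scale."""

    kind: str  # "open" or "cyclic"
    coef: np.ndarray
    center: np.ndarray
    lo: float
    hi: float
    n_segments: int
    period: float = 0.0
    degree: int = 3

    def basis(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "open":
            B, _, _ = _open_basis(x, self.lo, self.hi, self.n_segments, self.degree)
        else:
            B, _ = _cyclic_basis(x, self.period, self.n_segments, self.degree)
        return B - self.center

    def __call__(self, x) -> np.ndarray:
        return self.basis(np.atleast_1d(x)) @ self.coef


def _gcv_fit(y: np.ndarray, X_fixed: np.ndarray, blocks, lambda_grid=None):
    """Penalized LS with per-block smoothing parameters chosen by GCV.

    blocks: list of (B, P) basis/penalty pairs (bases already centered).
    Returns (coef, block_lambdas, edf).
    """
    if lambda_grid is None:
        lambda_grid = 10.0 ** np.arange(-2, 7)
    X = np.hstack([X_fixed] + [B for B, _ in blocks])
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    p_fixed = X_fixed.shape[1]

    def penalty(lams):
        P = np.zeros((p, p))
        off = p_fixed
        for (B, Pb), lam in zip(blocks, lams):
            w = B.shape[1]
            P[off:off + w, off:off + w] = lam * Pb
            off += w
        return P

    def gcv(lams):
        A = XtX + penalty(lams) + 1e-10 * np.eye(p)
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        coef = Ainv @ Xty
        edf = float(np.trace(Ainv @ XtX))
        rss = float(np.sum((y - X @ coef) ** 2))
        denom = max(n - edf, 1.0)
        return n * rss / denom**2, coef, edf

    # coordinate-wise grid search, one pass per block twice
    lams = [float(lambda_grid[len(lambda_grid) // 2])] * len(blocks)
    for _ in range(2):
        for b in range(len(blocks)):
            best = (np.inf, None)
            for lam in lambda_grid:
                trial = list(lams)
                trial[b] = float(lam)
                score, _, _ = gcv(trial)
                if score < best[0]:
                    best = (score, lam)
            lams[b] = float(best[1])
    _, coef, edf = gcv(lams)
    return coef, lams, edf


# ---------------------------------------------------------------------------
# decomposition


@dataclass
class DecompositionResult:
    """Additive components of a station network's daily weather series.

    value = f_k(year) + f_t(day) + r(year, day) + a * altitude + residual,
    where the network-level intercept is folded into f_k.  ``residuals``
    keeps one row per station-day with the final residual; the identity
    above holds at every station-day up to numerical tolerance.
    """

    f_k: _Smooth
    f_t: _Smooth
    r: dict[int, _Smooth]
    altitude_coef: float
    intercept: float
    residuals: pd.DataFrame
    gcv_lambdas: tuple
    edf: float

    def deterministic(self, year, day, altitude) -> np.ndarray:
        """f_k + f_t + r + a*h (everything except the kriged residual)."""
        year = np.atleast_1d(np.asarray(year, dtype=float))
        day = np.atleast_1d(np.asarray(day, dtype=float))
        out = (
            self.intercept
            + self.f_k(year)
            + self.f_t(day)
            + self.altitude_coef * np.asarray(altitude, dtype=float)
        )
        anom = np.zeros(len(day))
        for i, (yy, dd) in enumerate(zip(year, day)):
            sm = self.r.get(int(yy))
            if sm is not None:
                anom[i] = float(sm(dd)[0])
        return out + anom


def decompose(
    series: pd.DataFrame,
    n_segments_annual: int = 10,
    n_segments_seasonal: int = 20,
) -> DecompositionResult:
    """Fit the additive decomposition to a station-day table.

    ``series`` columns: station_id, lon, lat, alt, year, day, value.
    Requires at least two stations with distinct altitudes and at least two
    years (otherwise the altitude coefficient and the annual smooth are
    unidentifiable).
    """
    missing = set(STATION_COLUMNS) - set(series.columns)
    if missing:
        raise ValueError(f"station table missing column(s): {sorted(missing)}")
    if series["station_id"].nunique() < 2:
        raise ValueError("need at least 2 stations (altitude effect unidentifiable)")
    if series["year"].nunique() < 2:
        raise ValueError("need at least 2 years for the annual smooth")
    if float(series.groupby("station_id")["alt"].first().std()) == 0:
        raise ValueError("stations share one altitude; altitude effect unidentifiable")

    y = series["value"].to_numpy(dtype=float)
    year = series["year"].to_numpy(dtype=float)
    day = series["day"].to_numpy(dtype=float)
    alt = series["alt"].to_numpy(dtype=float)
    alt_c = alt - alt.mean()

    y_lo, y_hi = year.min(), year.max()
    nseg_a = min(n_segments_annual, max(int(y_hi - y_lo), 1))
    B_k, P_k, _ = _open_basis(year, y_lo, y_hi, nseg_a)
    ck = B_k.mean(axis=0)
    B_t, P_t = _cyclic_basis(day, 365.0, n_segments_seasonal)
    ct = B_t.mean(axis=0)

    X_fixed = np.column_stack([np.ones(len(y)), alt_c])
    coef, lams, edf = _gcv_fit(
        y, X_fixed, [(B_k - ck, P_k), (B_t - ct, P_t)]
    )
    intercept_c, a = float(coef[0]), float(coef[1])
    nk = B_k.shape[1]
    coef_k = coef[2:2 + nk]
    coef_t = coef[2 + nk:]
    intercept = intercept_c - a * alt.mean()

    f_k = _Smooth("open", coef_k, ck, y_lo, y_hi, nseg_a)
    f_t = _Smooth("cyclic", coef_t, ct, 0.0, 365.0, n_segments_seasonal, period=365.0)

    fitted = intercept + f_k(year) + f_t(day) + a * alt
    res1 = y - fitted

    # per-year anomaly: cyclic smooth of the daily station-mean residual
    r: dict[int, _Smooth] = {}
    anomaly = np.zeros(len(y))
    tmp = pd.DataFrame({"year": year.astype(int), "day": day, "res": res1})
    for yy, grp in tmp.groupby("year"):
        daily_mean = grp.groupby("day")["res"].mean()
        dx = daily_mean.index.to_numpy(dtype=float)
        dy = daily_mean.to_numpy(dtype=float)
        nseg = min(n_segments_seasonal, max(len(dx) // 4, 4))
        B, P = _cyclic_basis(dx, 365.0, nseg)
        cmean = B.mean(axis=0)
        coef_r, _, _ = _gcv_fit(
            dy, np.zeros((len(dy), 0)), [(B - cmean, P)],
            lambda_grid=10.0 ** np.arange(-1, 5),
        )
        sm = _Smooth("cyclic", coef_r, cmean, 0.0, 365.0, nseg, period=365.0)
        r[int(yy)] = sm
        mask = tmp["year"].to_numpy() == yy
        anomaly[mask] = sm(day[mask])

    residual = res1 - anomaly
    out = series[["station_id", "lon", "lat", "alt", "year", "day"]].copy()
    out["residual"] = residual
    return DecompositionResult(
        f_k=f_k,
        f_t=f_t,
        r=r,
        altitude_coef=a,
        intercept=intercept,
        residuals=out,
        gcv_lambdas=tuple(lams),
        edf=edf,
    )


# ---------------------------------------------------------------------------
# spatio-temporal covariance of residuals


@dataclass
class CovarianceModel:
    """Separable exponential covariance of the residual field.

    C(h, u) = (sill - nugget) * exp(-h / spatial_range - u / temporal_range)
    plus a nugget at (h, u) = (0, 0).  Ranges in km and days.
    """

    spatial_range: float
    temporal_range: float
    sill: float
    nugget: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if min(self.spatial_range, self.temporal_range, self.sill, self.nugget) < 0:
            raise ValueError("covariance parameters must be non-negative")
        if self.sill < self.nugget:
            raise ValueError("sill must be at least the nugget")

    def covariance(self, h: np.ndarray, u: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        u = np.asarray(u, dtype=float)
        psill = self.sill - self.nugget
        rs = max(self.spatial_range, 1e-12)
        rt = max(self.temporal_range, 1e-12)
        c = psill * np.exp(-h / rs - u / rt)
        return c + self.nugget * ((h == 0) & (u == 0))


def empirical_variogram(
    residuals: pd.DataFrame,
    n_space_bins: int = 8,
    max_time_lag: int = 5,
) -> pd.DataFrame:
    """Binned empirical spatio-temporal semivariogram of station residuals.

    Returns rows (space_lag_km, time_lag_days, gamma, n_pairs); gamma is the
    average of half squared residual differences in the bin.
    """
    stations = residuals.groupby("station_id").first()[["lon", "lat"]]
    ids = list(stations.index)
    # wide matrix stations x (year, day)
    wide = residuals.pivot_table(
        index="station_id", columns=["year", "day"], values="residual"
    ).reindex(ids)
    M = wide.to_numpy()
    dates = np.array([y * 365 + d for y, d in wide.columns])
    order = np.argsort(dates)
    M = M[:, order]
    dates = dates[order]

    lon = stations["lon"].to_numpy()
    lat = stations["lat"].to_numpy()
    n = len(ids)
    hmat = great_circle_km(
        lon[:, None], lat[:, None], lon[None, :], lat[None, :]
    )
    max_h = hmat[hmat > 0].max() if n > 1 else 0.0
    edges = np.linspace(0.0, max_h / 1.5 + 1e-9, n_space_bins + 1)

    rows = []
    idx = {d: j for j, d in enumerate(dates)}
    for u in range(max_time_lag + 1):
        # align columns shifted by u days
        cols_a, cols_b = [], []
        for j, d in enumerate(dates):
            jj = idx.get(d + u)
            if jj is not None:
                cols_a.append(j)
                cols_b.append(jj)
        if not cols_a:
            continue
        A = M[:, cols_a]
        B = M[:, cols_b]
        MA = (~np.isnan(A)).astype(float)
        MB = (~np.isnan(B)).astype(float)
        A0 = np.nan_to_num(A)
        B0 = np.nan_to_num(B)
        # per-pair sums of half squared differences via matrix products
        G = 0.5 * ((A0**2) @ MB.T + MA @ (B0**2).T - 2.0 * A0 @ B0.T)
        cnt_mat = MA @ MB.T
        if u == 0:
            keep = np.triu(np.ones((n, n), dtype=bool), k=1)
        else:
            keep = np.ones((n, n), dtype=bool)
        for bi in range(n_space_bins):
            in_bin = (
                (hmat >= edges[bi]) & (hmat < edges[bi + 1])
                if bi > 0
                else (hmat < edges[1])
            )
            sel = keep & in_bin
            cnt = int(cnt_mat[sel].sum())
            if cnt:
                rows.append(
                    {
                        "space_lag_km": 0.5 * (edges[bi] + edges[bi + 1]),
                        "time_lag_days": float(u),
                        "gamma": float(G[sel].sum()) / cnt,
                        "n_pairs": cnt,
                    }
                )
    return pd.DataFrame(rows)


def fit_covariance(residuals: pd.DataFrame, **variogram_kwargs) -> CovarianceModel:
    """Fit the separable exponential model to the empirical variogram by WLS.

    All-zero residuals return a degenerate sill-0 model with a flag.
    """
    if len(residuals) < 30:
        raise ValueError("need at least 30 station-day residuals")
    if float(np.nanmax(np.abs(residuals["residual"]))) == 0.0:
        return CovarianceModel(0.0, 0.0, 0.0, 0.0, degenerate=True)
    vg = empirical_variogram(residuals, **variogram_kwargs)
    h = vg["space_lag_km"].to_numpy()
    u = vg["time_lag_days"].to_numpy()
    g = vg["gamma"].to_numpy()
    w = np.sqrt(vg["n_pairs"].to_numpy(dtype=float))
    var0 = float(residuals["residual"].var())

    def gamma_model(x):
        nug, psill, rs, rt = x
        return nug + psill * (1.0 - np.exp(-h / rs - u / rt))

    def loss(x):
        return w * (gamma_model(x) - g)

    x0 = [0.1 * var0, 0.9 * var0, max(h.max() / 3.0, 1.0), 2.0]
    sol = optimize.least_squares(
        loss,
        x0,
        bounds=([0.0, 0.0, 1e-6, 1e-6], [np.inf, np.inf, 1e5, 1e5]),
    )
    nug, psill, rs, rt = sol.x
    # compare against a flat (pure-nugget) variogram: if spatial/temporal
    # structure barely improves the weighted fit, the ranges are not
    # identified and the field is reported as pure nugget
    flat = float(np.sum(w * w * g) / np.sum(w * w))
    sse_flat = float(np.sum((w * (flat - g)) ** 2))
    sse_full = float(np.sum(loss(sol.x) ** 2))
    if psill < 0.05 * max(nug + psill, 1e-300) or (
        sse_flat > 0 and (sse_flat - sse_full) / sse_flat < 0.01
    ):
        rs = rt = 0.0
        psill = 0.0
        nug = flat
    return CovarianceModel(
        spatial_range=float(rs),
        temporal_range=float(rt),
        sill=float(nug + psill),
        nugget=float(nug),
    )


# ---------------------------------------------------------------------------
# kriging


def krige_daily(
    decomposition: DecompositionResult,
    model: CovarianceModel,
    lon: float,
    lat: float,
    alt: float,
    dates: list[tuple[int, int]],
) -> pd.DataFrame:
    """Predict daily values at a target location by ordinary kriging.

    For each (year, day) the deterministic components are evaluated at the
    target and the same-day station residuals within 100 km are combined
    with ordinary-kriging weights (summing to one).  With a zero nugget the
    predictor is exact at station locations.
    """
    res = decomposition.residuals
    st = res.groupby("station_id").first()[["lon", "lat", "alt"]]
    dist = great_circle_km(st["lon"].to_numpy(), st["lat"].to_numpy(), lon, lat)
    st = st.assign(dist_km=dist)
    near = st[st["dist_km"] <= MAX_STATION_KM]
    if near.empty:
        raise ValueError(f"no station within {MAX_STATION_KM:.0f} km of the target")
    lo_lon, hi_lon = st["lon"].min(), st["lon"].max()
    lo_lat, hi_lat = st["lat"].min(), st["lat"].max()
    if not (lo_lon <= lon <= hi_lon and lo_lat <= lat <= hi_lat):
        warnings.warn("target lies outside the station bounding region", stacklevel=2)

    by_date = {
        (int(r), int(d)): grp
        for (r, d), grp in res.groupby(["year", "day"])
    }
    rows = []
    for year, day in dates:
        grp = by_date.get((int(year), int(day)))
        det = float(decomposition.deterministic(year, day, alt)[0])
        if grp is None or model.degenerate or model.sill == 0.0:
            rows.append({"year": year, "day": day, "value": det})
            continue
        grp = grp[grp["station_id"].isin(near.index)]
        if grp.empty:
            raise ValueError(
                f"no station residual within {MAX_STATION_KM:.0f} km on "
                f"year {year}, day {day}"
            )
        slon = grp["lon"].to_numpy()
        slat = grp["lat"].to_numpy()
        ns = len(grp)
        hmat = great_circle_km(
            slon[:, None], slat[:, None], slon[None, :], slat[None, :]
        )
        C = model.covariance(hmat, np.zeros_like(hmat))
        h0 = great_circle_km(slon, slat, lon, lat)
        c0 = model.covariance(h0, np.zeros_like(h0))
        K = np.zeros((ns + 1, ns + 1))
        K[:ns, :ns] = C + 1e-10 * np.eye(ns)
        K[ns, :ns] = 1.0
        K[:ns, ns] = 1.0
        rhs = np.concatenate([c0, [1.0]])
        try:
            wgt = np.linalg.solve(K, rhs)[:ns]
        except np.linalg.LinAlgError:
            wgt = np.full(ns, 1.0 / ns)
        rows.append(
            {
                "year": year,
                "day": day,
                "value": det + float(wgt @ grp["residual"].to_numpy()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# winter summaries


def _winter_days(season_year: int) -> list[tuple[int, int]]:
    prev = [(season_year - 1, d) for d in range(WINTER_WINDOW[0], 365)]
    curr = [(season_year, d) for d in range(0, WINTER_WINDOW[1] + 1)]
    return prev + curr


def _winter_values(series: pd.DataFrame, season_year: int) -> np.ndarray:
    lookup = {
        (int(y), int(d)): v
        for y, d, v in zip(series["year"], series["day"], series["value"])
    }
    want = _winter_days(season_year)
    missing = [wd for wd in want if wd not in lookup]
    if missing:
        head = ", ".join(f"{y}/{d}" for y, d in missing[:5])
        raise ValueError(
            f"winter window not fully covered; {len(missing)} missing day(s): {head}"
        )
    return np.array([lookup[wd] for wd in want], dtype=float)


def frost_days(series: pd.DataFrame, season_year: int) -> int:
    """Days with daily mean temperature strictly below 0 degC in the winter
    (November-February) preceding ``season_year``."""
    return int(np.sum(_winter_values(series, season_year) < 0.0))


def winter_precip(series: pd.DataFrame, season_year: int) -> float:
    """Summed precipitation (mm) over the preceding November-February."""
    return float(np.sum(_winter_values(series, season_year)))
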