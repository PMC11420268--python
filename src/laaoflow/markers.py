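"""Surrogate markers of device-related thrombus risk.

Wall-based markers over an integration period T (by default the last cardiac
cycle), from the instantaneous wall shear vector tau_w per face:

* TAWSS = (1/T) * int |tau_w| dt                     [Pa]
* OSI   = 1/2 * (1 - |int tau_w dt| / int |tau_w| dt)  in [0, 0.5]
* ECAP  = OSI / TAWSS                                 [1/Pa]

Threshold criteria: platelet/monocyte adhesion where TAWSS < 0.36 Pa;
critically thrombogenic endothelium where ECAP > 1.4 1/Pa.  Volume-based
markers (ROI-averaged speed and vorticity, residual-blood fraction, washout
half-time) are assembled into one report row per scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LOW_WSS_THRESHOLD = 0.36   # Pa, adhesion threshold
HIGH_ECAP_THRESHOLD = 1.4  # 1/Pa, endothelial activation threshold


def _check_series(tau_series, times):
    tau_series = np.asarray(tau_series, dtype=float)
    times = np.asarray(times, dtype=float)
    if tau_series.ndim != 3 or tau_series.shape[2] != 3:
        raise ValueError("tau_series must have shape (n_times, n_faces, 3)")
    if len(times) != tau_series.shape[0] or len(times) < 2:
        raise ValueError("need >= 2 time samples matching tau_series")
    return tau_series, times


def tawss(tau_series, times) -> np.ndarray:
    """Time-averaged wall shear stress magnitude per face (Pa)."""
    tau_series, times = _check_series(tau_series, times)
    mag = np.linalg.norm(tau_series, axis=2)
    T = times[-1] - times[0]
    return np.trapezoid(mag, times, axis=0) / T


def osi(tau_series, times) -> np.ndarray:
    """Oscillatory shear index per face, in [0, 0.5].

    Faces with a vanishing shear integral are assigned OSI = 0.
    """
    tau_series, times = _check_series(tau_series, times)
    vec = np.trapezoid(tau_series, times, axis=0)
    mag = np.trapezoid(np.linalg.norm(tau_series, axis=2), times, axis=0)
    num = np.linalg.norm(vec, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(mag > 0, num / np.where(mag > 0, mag, 1.0), 1.0)
    out = 0.5 * (1.0 - np.clip(ratio, 0.0, 1.0))
    return np.where(mag > 0, out, 0.0)


TAWSS_FLOOR = 1e-6  # Pa; below solver round-off the OSI/TAWSS ratio is noise


def ecap(osi_map, tawss_map) -> np.ndarray:
    """ECAP = OSI / TAWSS per face.

    Faces with TAWSS at or below the numerical noise floor are returned as
    NaN and excluded from area statistics (a 0/0 ratio, not a physical
    value).
    """
    osi_map = np.asarray(osi_map, dtype=float)
    tawss_map = np.asarray(tawss_map, dtype=float)
    out = np.full_like(tawss_map, np.nan)
    ok = tawss_map > TAWSS_FLOOR
    out[ok] = osi_map[ok] / tawss_map[ok]
    return out


def area_average(values, areas) -> float:
    """Area-weighted mean ignoring NaN faces."""
    values = np.asarray(values, dtype=float)
    areas = np.asarray(areas, dtype=float)
    ok = np.isfinite(values)
    if not ok.any():
        return float("nan")
    return float(np.sum(values[ok] * areas[ok]) / np.sum(areas[ok]))


def exceedance_area_fraction(values, areas, threshold, above=True) -> float:
    values = np.asarray(values, dtype=float)
    areas = np.asarray(areas, dtype=float)
    ok = np.isfinite(values)
    hit = (values > threshold) if above else (values < threshold)
    return float(np.sum(areas[ok & hit]) / np.sum(areas))


def low_wss_area(tawss_map, areas, threshold: float = LOW_WSS_THRESHOLD) -> float:
    """Area fraction with TAWSS below the adhesion threshold."""
    return exceedance_area_fraction(tawss_map, areas, threshold, above=False)


def high_ecap_area(ecap_map, areas, threshold: float = HIGH_ECAP_THRESHOLD) -> float:
    """Area fraction with ECAP above the activation threshold."""
    return exceedance_area_fraction(ecap_map, areas, threshold, above=True)


@dataclass
class WallMetricMap:
    """Per-face wall metrics over the ROI surface."""

    centroid: np.ndarray
    area: np.ndarray
    is_device: np.ndarray
    tawss: np.ndarray
    osi: np.ndarray
    ecap: np.ndarray

    @property
    def low_wss_flag(self):
        return self.tawss < LOW_WSS_THRESHOLD

    @property
    def high_ecap_flag(self):
        return self.ecap > HIGH_ECAP_THRESHOLD


def wall_metrics(tau_series, times, centroids, areas, is_device) -> WallMetricMap:
    """Assemble TAWSS/OSI/ECAP maps from a wall-shear time series."""
    ta = tawss(tau_series, times)
    os_ = osi(tau_series, times)
    return WallMetricMap(centroid=np.asarray(centroids), area=np.asarray(areas),
                         is_device=np.asarray(is_device), tawss=ta, osi=os_,
                         ecap=ecap(os_, ta))


def vorticity(uc: np.ndarray, spacing_m: float, mask=None) -> np.ndarray:
    """Vorticity vectors (1/s) from a cell-centre velocity field by centred
    differences; exact for linear velocity fields away from boundaries."""
    if uc.ndim != 4 or uc.shape[-1] != 3:
        raise ValueError("expected (nx, ny, nz, 3) velocity field")
    d = [np.gradient(uc[..., a], spacing_m, axis=(0, 1, 2), edge_order=1)
         for a in range(3)]
    # d[a][b] = du_a/dx_b
    w = np.stack([d[2][1] - d[1][2], d[0][2] - d[2][0], d[1][0] - d[0][1]],
                 axis=-1)
    if mask is not None:
        w[~mask] = 0.0
    return w


def roi_flow_stats(times, roi_speed, roi_vort_mean, roi_volume_m3,
                   cycle_period: float) -> dict:
    """Time averages over the last full cycle of the ROI volume averages.

    ``roi_speed`` and ``roi_vort_mean`` are the recorded volume-averaged |u|
    (m/s) and |omega| (1/s) in the ROI.  The volume integral of |omega|
    (m^3/s, the convention used alongside the volume average) is also given.
    """
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        raise ValueError("need at least one stored cycle")
    t_end = times[-1]
    m = times >= t_end - cycle_period - 1e-9
    if m.sum() < 2:
        raise ValueError("missing last-cycle samples")
    tt = times[m]
    T = tt[-1] - tt[0]
    avg_u = float(np.trapezoid(np.asarray(roi_speed)[m], tt) / T)
    avg_w = float(np.trapezoid(np.asarray(roi_vort_mean)[m], tt) / T)
    return {
        "avg_velocity": avg_u,
        "avg_vorticity": avg_w,
        "volume_integral_vorticity": avg_w * roi_volume_m3,
    }


REPORT_COLUMNS = [
    "scenario", "avg_velocity", "avg_vorticity", "volume_integral_vorticity",
    "washout_half_time", "washout_censored", "phi_final", "avg_wss",
    "avg_ecap", "frac_area_low_wss", "frac_area_high_ecap", "laa_influx_volume",
    "lupv_ridge_length", "implant_depth_mv", "device_ridge_angle",
    "compression_rate", "deep_flag", "complete",
]


def build_report_row(scenario_id: str, flow_stats=None, washout=None,
                     wall=None, position=None, laa_influx=None) -> dict:
    """One Table-2-style report row; missing stages yield explicit nulls and
    an incomplete flag."""
    row = {c: None for c in REPORT_COLUMNS}
    row["scenario"] = scenario_id
    complete = True
    if flow_stats is not None:
        row.update(flow_stats)
    else:
        complete = False
    if washout is not None:
        t_half, censored, _ = washout["halftime"]
        row["washout_half_time"] = t_half
        row["washout_censored"] = censored
        row["phi_final"] = washout["phi_final"]
    else:
        complete = False
    if wall is not None:
        row["avg_wss"] = area_average(wall.tawss, wall.area)
        row["avg_ecap"] = area_average(wall.ecap, wall.area)
        row["frac_area_low_wss"] = low_wss_area(wall.tawss, wall.area)
        row["frac_area_high_ecap"] = high_ecap_area(wall.ecap, wall.area)
    else:
        complete = False
    if position is not None:
        row["lupv_ridge_length"] = position.lupv_ridge_length
        row["implant_depth_mv"] = position.implant_depth_mv
        row["device_ridge_angle"] = position.device_ridge_angle
        row["compression_rate"] = position.compression_rate
        row["deep_flag"] = position.deep_flag
    if laa_influx is not None:
        row["laa_influx_volume"] = laa_influx
    row["complete"] = complete
    return row


def build_report(rows) -> pd.DataFrame:
    """Stack per-scenario rows into the summary report."""
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
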