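"""GPS track and baiting-log analysis.

Takes the 2-second-fix flight tracks flown during aerial prefeeding and
the timestamped waypoints logged by ground contractors at each bait plot,
and computes: distance of every plot to its prefeed line, the fraction of
plots inside the baited swath, per-line timing (minutes per plot and bait
laying speed), grouped summary tables with a line-count-weighted combined
row, and the layout arithmetic of the sowing geometry (fraction of the
operational area actually baited, realised application rate in kg/ha).

Coordinates are planar metres throughout; longitude/latitude appear only
at the I/O boundary through a local equirectangular projection anchored
at a reference point (sub-metre distortion at the <10 km extents of an
operational block). Tracks and waypoints round-trip through GPX 1.1 and
a plain CSV dialect.
"""

from __future__ import annotations

import math
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

from .inference import weighted_mean_se

__all__ = [
    "FlightTrack",
    "BaitPlotEvent",
    "TimingRow",
    "to_planar",
    "to_geographic",
    "point_to_track_distance",
    "track_length_m",
    "swath_compliance",
    "line_timing",
    "timing_summary",
    "baited_area_fraction",
    "realized_application_rate",
    "write_gpx",
    "read_gpx",
    "tracks_to_csv",
    "tracks_from_csv",
    "events_to_csv",
    "events_from_csv",
]

# metres per degree at the equator (longitude scaled by cos(lat0))
M_PER_DEG_LON = 111320.0
M_PER_DEG_LAT = 110540.0

GPX_NS = "http://www.topografix.com/GPX/1/1"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class FlightTrack:
    """A prefeed flight line as an ordered polyline of planar GPS fixes."""

    line_id: str
    fixes: np.ndarray  # (n, 2) metres
    times: np.ndarray | None = None  # datetime64, same length as fixes
    swath_m: float = 60.0
    fps_m: float = 100.0

    def __post_init__(self) -> None:
        self.fixes = np.asarray(self.fixes, dtype=float)
        if self.fixes.ndim != 2 or self.fixes.shape[1] != 2 or len(self.fixes) < 2:
            raise ValueError("a track needs at least two (x, y) fixes")
        if self.times is not None:
            self.times = np.asarray(self.times)
            if len(self.times) != len(self.fixes):
                raise ValueError("times and fixes must have equal length")
            if not (np.diff(self.times).astype("timedelta64[ms]")
                    > np.timedelta64(0, "ms")).all():
                raise ValueError(f"track {self.line_id}: timestamps not strictly increasing")


@dataclass
class BaitPlotEvent:
    """One contractor bait placement: a timestamped waypoint with bait mass."""

    plot_id: str
    line_id: str
    x: float
    y: float
    timestamp: pd.Timestamp
    mass_g: float = 100.0
    bait_type: str = "RS5_1080_20mm"

    def __post_init__(self) -> None:
        if self.mass_g <= 0:
            raise ValueError("bait mass must be positive")
        self.timestamp = pd.Timestamp(self.timestamp)
        if self.timestamp.tzinfo is None:
            raise ValueError("bait plot timestamps must be timezone-aware (UTC)")


@dataclass
class TimingRow:
    line_id: str
    n_plots: int
    elapsed_min: float
    mean_time_per_plot_min: float
    line_length_km: float
    speed_kmh: float


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------


def to_planar(lonlat, reference) -> np.ndarray:
    """Local equirectangular projection of lon/lat degrees to metres.

    x = (lon - lon0) * cos(lat0) * 111320, y = (lat - lat0) * 110540.
    Points further than ~1 degree from the reference trigger a distortion
    warning; the projection is meant for single operational blocks.
    """
    pts = np.atleast_2d(np.asarray(lonlat, dtype=float))
    lon0, lat0 = float(reference[0]), float(reference[1])
    if np.abs(pts - [lon0, lat0]).max() > 1.0:
        warnings.warn(
            "points more than 1 degree from the projection reference; "
            "equirectangular distortion may be significant",
            RuntimeWarning,
            stacklevel=2,
        )
    x = (pts[:, 0] - lon0) * math.cos(math.radians(lat0)) * M_PER_DEG_LON
    y = (pts[:, 1] - lat0) * M_PER_DEG_LAT
    return np.column_stack([x, y])


def to_geographic(xy, reference) -> np.ndarray:
    """Inverse of :func:`to_planar`."""
    pts = np.atleast_2d(np.asarray(xy, dtype=float))
    lon0, lat0 = float(reference[0]), float(reference[1])
    lon = lon0 + pts[:, 0] / (math.cos(math.radians(lat0)) * M_PER_DEG_LON)
    lat = lat0 + pts[:, 1] / M_PER_DEG_LAT
    return np.column_stack([lon, lat])


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def point_to_track_distance(point, track: FlightTrack) -> float:
    """Minimum Euclidean distance from a planar point to the track polyline."""
    return float(LineString(track.fixes).distance(Point(point[0], point[1])))


def track_length_m(track: FlightTrack) -> float:
    return float(np.linalg.norm(np.diff(track.fixes, axis=0), axis=1).sum())


def swath_compliance(events, tracks, half_width_m: float):
    """Fraction of bait plots within ``half_width_m`` of their prefeed track.

    Events are matched to tracks by ``line_id``; an event whose line has no
    track falls back to the nearest track and is flagged in the per-event
    table. Returns ``(fraction_within, DataFrame)`` with one row per event
    (plot_id, line_id, matched_line, distance_m, within, fallback).
    """
    events = list(events)
    tracks = list(tracks)
    if not tracks:
        raise ValueError("no tracks supplied")
    if not events:
        raise ValueError("no bait plot events supplied")
    by_id = {t.line_id: t for t in tracks}
    rows = []
    for ev in events:
        if ev.line_id in by_id:
            tr = by_id[ev.line_id]
            fallback = False
        else:
            tr = min(tracks, key=lambda t: point_to_track_distance((ev.x, ev.y), t))
            fallback = True
        d = point_to_track_distance((ev.x, ev.y), tr)
        rows.append(
            {
                "plot_id": ev.plot_id,
                "line_id": ev.line_id,
                "matched_line": tr.line_id,
                "distance_m": d,
                "within": d <= half_width_m,
                "fallback": fallback,
            }
        )
    df = pd.DataFrame(rows)
    return float(df["within"].mean()), df


# ---------------------------------------------------------------------------
# timing
# ---------------------------------------------------------------------------


def line_timing(events) -> list:
    """Per-line timing rows from contractor bait-plot logs.

    Elapsed time is last minus first waypoint timestamp; mean time per
    plot divides it by the (n-1) inter-plot intervals; speed is the path
    length through consecutive plots divided by the elapsed time.
    """
    by_line: dict[str, list] = {}
    for ev in events:
        by_line.setdefault(ev.line_id, []).append(ev)
    rows = []
    for line_id in sorted(by_line):
        evs = by_line[line_id]
        if len(evs) < 2:
            raise ValueError(f"line {line_id}: need at least two plots for timing")
        times = [ev.timestamp for ev in evs]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(f"line {line_id}: timestamps not strictly increasing")
        elapsed_min = (times[-1] - times[0]).total_seconds() / 60.0
        xy = np.array([[ev.x, ev.y] for ev in evs])
        length_km = float(np.linalg.norm(np.diff(xy, axis=0), axis=1).sum()) / 1000.0
        rows.append(
            TimingRow(
                line_id=line_id,
                n_plots=len(evs),
                elapsed_min=elapsed_min,
                mean_time_per_plot_min=elapsed_min / (len(evs) - 1),
                line_length_km=length_km,
                speed_kmh=length_km / (elapsed_min / 60.0),
            )
        )
    return rows


def timing_summary(rows, group_labels=None) -> pd.DataFrame:
    """Grouped timing summary table with a combined row.

    ``group_labels`` maps line_id -> (trial, treatment); lines without a
    label fall into a single "all" group. Group means and SEs are over
    lines; the combined row is the line-count-weighted mean of the group
    means (equivalently, with groups defined as partitions of lines, the
    grand per-line mean), with its SE from the weighted dispersion of the
    group means.
    """
    recs = []
    for row in rows:
        trial, treatment = ("all", "all")
        if group_labels is not None:
            trial, treatment = group_labels[row.line_id]
        recs.append(
            {
                "trial": trial,
                "treatment": treatment,
                "n_plots": row.n_plots,
                "time_per_plot": row.mean_time_per_plot_min,
                "speed": row.speed_kmh,
            }
        )
    df = pd.DataFrame(recs)
    groups = []
    for (trial, treatment), sub in df.groupby(["trial", "treatment"], sort=True):
        n = len(sub)
        groups.append(
            {
                "trial": trial,
                "treatment": treatment,
                "n_lines": n,
                "n_plots": int(sub["n_plots"].sum()),
                "mean_time_per_plot_min": sub["time_per_plot"].mean(),
                "se_time_per_plot_min": sub["time_per_plot"].std(ddof=1) / math.sqrt(n)
                if n > 1 else math.nan,
                "mean_speed_kmh": sub["speed"].mean(),
                "se_speed_kmh": sub["speed"].std(ddof=1) / math.sqrt(n)
                if n > 1 else math.nan,
            }
        )
    out = pd.DataFrame(groups)
    combined = combine_group_rows(out)
    return pd.concat([out, combined.to_frame().T], ignore_index=True)


def combine_group_rows(group_table: pd.DataFrame) -> pd.Series:
    """Line-count-weighted combination of per-group timing means.

    ``group_table`` needs columns n_lines, n_plots, mean_time_per_plot_min
    and mean_speed_kmh (the shape of a printed summary table); returns the
    combined row.
    """
    w = group_table["n_lines"].to_numpy(dtype=float)
    if len(group_table) == 1:
        row = group_table.iloc[0].copy()
        row["trial"], row["treatment"] = "combined", "combined"
        return row
    tpp, se_tpp = weighted_mean_se(group_table["mean_time_per_plot_min"], w)
    spd, se_spd = weighted_mean_se(group_table["mean_speed_kmh"], w)
    return pd.Series(
        {
            "trial": "combined",
            "treatment": "combined",
            "n_lines": int(w.sum()),
            "n_plots": int(group_table["n_plots"].sum()),
            "mean_time_per_plot_min": tpp,
            "se_time_per_plot_min": se_tpp,
            "mean_speed_kmh": spd,
            "se_speed_kmh": se_spd,
        }
    )


# ---------------------------------------------------------------------------
# layout arithmetic
# ---------------------------------------------------------------------------


def baited_area_fraction(cluster_radius_m: float, plot_spacing_m: float,
                         fps_m: float) -> float:
    """Percent of the operational area covered by bait clusters.

    Each plot is a disc of the given radius on a plot_spacing x fps grid;
    overlapping clusters (radius >= spacing/2) are rejected.
    """
    if cluster_radius_m < 0 or plot_spacing_m <= 0 or fps_m <= 0:
        raise ValueError("radius must be >= 0 and spacings positive")
    if cluster_radius_m >= plot_spacing_m / 2.0:
        raise ValueError("cluster radius must be < half the plot spacing")
    return 100.0 * math.pi * cluster_radius_m ** 2 / (plot_spacing_m * fps_m)


def realized_application_rate(plot_mass_g: float, plot_spacing_m: float,
                              fps_m: float) -> float:
    """Area-wide application rate in kg/ha implied by the plot geometry."""
    if plot_mass_g < 0 or plot_spacing_m <= 0 or fps_m <= 0:
        raise ValueError("mass must be >= 0 and spacings positive")
    return (plot_mass_g / 1000.0) * (10000.0 / (plot_spacing_m * fps_m))


# ---------------------------------------------------------------------------
# GPX and CSV I/O
# ---------------------------------------------------------------------------


def _iso_utc(ts) -> str:
    ts = pd.Timestamp(ts)
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    return ts.tz_convert("UTC").strftime("%Y-%m-%dT%H:%M:%S.%f")[:-3] + "Z"


def write_gpx(path, tracks=(), events=(), reference=(172.0, -42.0)) -> None:
    """Write tracks as ``<trk>`` and bait plots as ``<wpt>`` in GPX 1.1.

    Planar metres are converted back to lon/lat about ``reference``.
    """
    ET.register_namespace("", GPX_NS)
    gpx = ET.Element(f"{{{GPX_NS}}}gpx", version="1.1", creator="baitline")
    for ev in events:
        lon, lat = to_geographic([(ev.x, ev.y)], reference)[0]
        wpt = ET.SubElement(gpx, f"{{{GPX_NS}}}wpt",
                            lat=f"{lat:.8f}", lon=f"{lon:.8f}")
        ET.SubElement(wpt, f"{{{GPX_NS}}}time").text = _iso_utc(ev.timestamp)
        ET.SubElement(wpt, f"{{{GPX_NS}}}name").text = ev.plot_id
        ET.SubElement(wpt, f"{{{GPX_NS}}}desc").text = (
            f"line={ev.line_id};mass_g={ev.mass_g};bait={ev.bait_type}"
        )
    for tr in tracks:
        trk = ET.SubElement(gpx, f"{{{GPX_NS}}}trk")
        ET.SubElement(trk, f"{{{GPX_NS}}}name").text = tr.line_id
        seg = ET.SubElement(trk, f"{{{GPX_NS}}}trkseg")
        lonlat = to_geographic(tr.fixes, reference)
        for i, (lon, lat) in enumerate(lonlat):
            pt = ET.SubElement(seg, f"{{{GPX_NS}}}trkpt",
                               lat=f"{lat:.8f}", lon=f"{lon:.8f}")
            if tr.times is not None:
                ET.SubElement(pt, f"{{{GPX_NS}}}time").text = _iso_utc(tr.times[i])
    ET.ElementTree(gpx).write(path, xml_declaration=True, encoding="unicode")


def _parse_time(text: str) -> pd.Timestamp:
    ts = pd.Timestamp(text)
    if ts.tzinfo is None:
        raise ValueError(f"naive GPX timestamp rejected: {text!r}")
    return ts.tz_convert("UTC")


def read_gpx(path, reference=(172.0, -42.0)):
    """Read a GPX 1.1 file back into (tracks, events) in planar metres."""
    root = ET.parse(path).getroot()
    ns = {"g": GPX_NS}
    tracks, events = [], []
    for i, wpt in enumerate(root.findall("g:wpt", ns)):
        lon, lat = float(wpt.get("lon")), float(wpt.get("lat"))
        x, y = to_planar([(lon, lat)], reference)[0]
        meta = dict(
            kv.split("=") for kv in (wpt.findtext("g:desc", "", ns) or "").split(";")
            if "=" in kv
        )
        events.append(
            BaitPlotEvent(
                plot_id=wpt.findtext("g:name", f"wpt{i}", ns),
                line_id=meta.get("line", "unknown"),
                x=float(x),
                y=float(y),
                timestamp=_parse_time(wpt.findtext("g:time", None, ns)),
                mass_g=float(meta.get("mass_g", 100.0)),
                bait_type=meta.get("bait", "unknown"),
            )
        )
    for trk in root.findall("g:trk", ns):
        name = trk.findtext("g:name", "track", ns)
        pts, times = [], []
        for pt in trk.findall("g:trkseg/g:trkpt", ns):
            pts.append((float(pt.get("lon")), float(pt.get("lat"))))
            t = pt.findtext("g:time", None, ns)
            if t is not None:
                times.append(np.datetime64(_parse_time(t).tz_localize(None)))
        fixes = to_planar(pts, reference)
        tracks.append(
            FlightTrack(
                line_id=name,
                fixes=fixes,
                times=np.array(times) if len(times) == len(pts) and times else None,
            )
        )
    return tracks, events


def tracks_to_csv(tracks, path) -> None:
    rows = []
    for tr in tracks:
        for i, (x, y) in enumerate(tr.fixes):
            rows.append(
                {
                    "line_id": tr.line_id,
                    "x_m": x,
                    "y_m": y,
                    "t_iso": _iso_utc(tr.times[i]) if tr.times is not None else "",
                }
            )
    pd.DataFrame(rows, columns=["line_id", "x_m", "y_m", "t_iso"]).to_csv(
        path, index=False
    )


def tracks_from_csv(path) -> list:
    df = pd.read_csv(path, keep_default_na=False)
    tracks = []
    for line_id, sub in df.groupby("line_id", sort=True):
        times = None
        if (sub["t_iso"] != "").all():
            times = np.array(
                [np.datetime64(_parse_time(t).tz_localize(None)) for t in sub["t_iso"]]
            )
        tracks.append(
            FlightTrack(
                line_id=str(line_id),
                fixes=sub[["x_m", "y_m"]].to_numpy(dtype=float),
                times=times,
            )
        )
    return tracks


def events_to_csv(events, path) -> None:
    rows = [
        {
            "plot_id": ev.plot_id,
            "line_id": ev.line_id,
            "x_m": ev.x,
            "y_m": ev.y,
            "t_iso": _iso_utc(ev.timestamp),
            "mass_g": ev.mass_g,
            "bait_type": ev.bait_type,
        }
        for ev in events
    ]
    pd.DataFrame(
        rows, columns=["plot_id", "line_id", "x_m", "y_m", "t_iso", "mass_g", "bait_type"]
    ).to_csv(path, index=False)


def events_from_csv(path) -> list:
    df = pd.read_csv(path)
    return [
        BaitPlotEvent(
            plot_id=str(r.plot_id),
            line_id=str(r.line_id),
            x=float(r.x_m),
            y=float(r.y_m),
            timestamp=_parse_time(r.t_iso),
            mass_g=float(r.mass_g),
            bait_type=str(r.bait_type),
        )
        for r in df.itertuples(index=False)
    ]
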