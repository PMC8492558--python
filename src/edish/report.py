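"""Self-contained interactive HTML report: eDISH figure, drill-down
profiles and hysteresis animation.

The document embeds a single JSON payload (points, per-subject profiles,
hysteresis paths, configuration and validation summary) plus a small SVG
charting runtime written inline — no external script, style, font or image
references, so the report renders with networking disabled.  Every number in
a tooltip is string-formatted once, from the same derived values that the
exported tables carry (single source of truth, see :func:`fmt_value`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from string import Template

import numpy as np
import pandas as pd

from .classify import assign_quadrants
from .config import ANALYTES, DataValidationError, EdishConfig, PAltConstants
from .derive import compute_visit_derived, hysteresis_path, subject_summary
from .ingest import Study, validate

#: point radius range (px) of the rank-affine size mapping
SIZE_RANGE = (4.0, 12.0)


def fmt_value(x) -> str:
    """Canonical string form of one derived number (tooltips and tables)."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return ""
    if isinstance(x, (bool, np.bool_)):
        return "yes" if x else "no"
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if isinstance(x, (float, np.floating)):
        return format(float(x), ".10g")
    return str(x)


@dataclass
class FigureSpec:
    """Renderable eDISH scatter: one point per evaluable subject."""

    points: list[dict]
    x_threshold: float
    y_threshold: float
    x_label: str
    y_label: str
    log_axes: bool
    groups: dict[str, list[str]] = field(default_factory=dict)
    header: dict = field(default_factory=dict)


@dataclass
class ProfileSpec:
    """Per-subject analyte and R-ratio time series (fold-ULN vs study day)."""

    subject_id: str
    series: dict[str, list[tuple[int, float]]]
    r_series: list[tuple[int, float]]


AXIS_LABELS = {
    "fold_uln": ("Peak ALT (fold ULN)", "Peak total bilirubin (fold ULN)"),
    "fold_baseline": ("Peak ALT (fold baseline)", "Peak total bilirubin (fold baseline)"),
    "nr": ("Peak nR ratio", "Peak total bilirubin (fold ULN)"),
}

TOOLTIP_FIELDS = (
    ("ALT_peak_fold", "Peak ALT fold"),
    ("TB_peak_fold", "Peak TB fold"),
    ("ALT_peak_day", "ALT peak day"),
    ("TB_peak_day", "TB peak day"),
    ("peak_time_separation_days", "Peak separation (days)"),
    ("within_window", "Within window"),
    ("injury_pattern", "Injury pattern"),
    ("p_alt_percent", "P_ALT (%)"),
)


def _sizes(labelled: pd.DataFrame, cfg: EdishConfig) -> np.ndarray:
    """Rank-affine point sizes; equal sizes when measure is ``none``."""
    n = len(labelled)
    lo, hi = SIZE_RANGE
    if cfg.point_size_measure == "none" or n == 0:
        return np.full(n, (lo + hi) / 2.0)
    col = {"alp_fold": "ALP_peak_fold", "r_ratio": "pattern_ratio"}[cfg.point_size_measure]
    vals = labelled[col].to_numpy(dtype=float)
    order = pd.Series(vals).rank(method="average", na_option="bottom").to_numpy()
    if n == 1:
        return np.array([(lo + hi) / 2.0])
    return lo + (hi - lo) * (order - 1) / (n - 1)


def build_edish(summaries: pd.DataFrame, cfg: EdishConfig = EdishConfig(),
                attributes: pd.DataFrame | None = None,
                validation: dict | None = None) -> FigureSpec:
    """Assemble the eDISH figure spec from a subject-summary table."""
    labelled = summaries if "quadrant" in summaries.columns else assign_quadrants(summaries, cfg)
    labelled = labelled[labelled["quadrant"].notna()].reset_index(drop=True)
    if labelled.empty:
        raise DataValidationError("zero evaluable subjects; nothing to plot",
                                  validation or {})
    sizes = _sizes(labelled, cfg)
    groups: dict[str, list[str]] = {}
    if attributes is not None:
        for col in attributes.columns:
            groups[col] = sorted(attributes[col].dropna().astype(str).unique())
    points = []
    for i, row in labelled.iterrows():
        tooltip = {"Subject": row["subject_id"], "Quadrant": row["quadrant"]}
        for key, label in TOOLTIP_FIELDS:
            tooltip[label] = fmt_value(row[key])
        point = {
            "subject_id": row["subject_id"],
            "x": float(row["x"]), "y": float(row["y"]),
            "size": float(sizes[i]),
            "within_window": bool(row["within_window"]),
            "quadrant": row["quadrant"],
            "tooltip": tooltip,
        }
        if attributes is not None and row["subject_id"] in attributes.index:
            point["attrs"] = {c: str(attributes.loc[row["subject_id"], c])
                              for c in attributes.columns}
        else:
            point["attrs"] = {}
        points.append(point)
    x_label, y_label = AXIS_LABELS[cfg.x_axis_mode]
    header = {
        "x_axis_mode": cfg.x_axis_mode,
        "alt_fold_threshold": cfg.alt_fold_threshold,
        "tb_fold_threshold": cfg.tb_fold_threshold,
        "nr_threshold": cfg.nr_threshold,
        "x_threshold": cfg.x_threshold,
        "peak_window_days": cfg.peak_window_days,
        "point_size_measure": cfg.point_size_measure,
        "pattern_basis": cfg.pattern_basis,
        "ratio_basis": cfg.ratio_basis,
    }
    if validation is not None:
        header["validation"] = validation
    return FigureSpec(points=points, x_threshold=cfg.x_threshold,
                      y_threshold=cfg.tb_fold_threshold, x_label=x_label,
                      y_label=y_label, log_axes=cfg.log_axes, groups=groups,
                      header=header)


def build_profile(study: Study, subject_id: str,
                  cfg: EdishConfig = EdishConfig()) -> ProfileSpec:
    """Four analyte fold-ULN series plus the companion R-ratio series."""
    rec = study.subject_records(subject_id)  # raises SubjectNotFoundError
    visits = compute_visit_derived(study, cfg)
    mine = visits[visits["subject_id"] == subject_id].sort_values("study_day")
    series = {}
    for analyte in ANALYTES:
        ok = mine.dropna(subset=[f"{analyte}_fold"])
        series[analyte] = [(int(d), float(f)) for d, f in
                           zip(ok["study_day"], ok[f"{analyte}_fold"])]
    okr = mine.dropna(subset=["r_ratio"])
    r_series = [(int(d), float(r)) for d, r in zip(okr["study_day"], okr["r_ratio"])]
    return ProfileSpec(subject_id=subject_id, series=series, r_series=r_series)


def build_hysteresis(study: Study, subject_id: str,
                     cfg: EdishConfig = EdishConfig()) -> list[pd.DataFrame]:
    """Animation frames: frame k is the hysteresis-path prefix of length k+1."""
    path = hysteresis_path(study, subject_id, cfg)
    return [path.iloc[:k + 1] for k in range(len(path))]


def build_payload(study: Study, cfg: EdishConfig = EdishConfig(),
                  constants: PAltConstants = PAltConstants()) -> dict:
    """Everything the report needs, as one JSON-serializable dict."""
    report = validate(study)
    summaries = subject_summary(study, cfg, constants)
    labelled = assign_quadrants(summaries, cfg)
    figure = build_edish(labelled, cfg, attributes=study.subject_attributes,
                         validation=report.to_dict())
    profiles = {}
    paths = {}
    for point in figure.points:
        sid = point["subject_id"]
        prof = build_profile(study, sid, cfg)
        profiles[sid] = {"series": {a: [[d, v] for d, v in s]
                                    for a, s in prof.series.items()},
                         "r_series": [[d, v] for d, v in prof.r_series]}
        path = hysteresis_path(study, sid, cfg)
        paths[sid] = [[int(d), float(a), float(t)] for d, a, t in
                      zip(path["study_day"], path["ALT_fold"], path["TB_fold"])]
    return {
        "figure": {
            "points": figure.points,
            "x_threshold": figure.x_threshold,
            "y_threshold": figure.y_threshold,
            "x_label": figure.x_label,
            "y_label": figure.y_label,
            "log_axes": figure.log_axes,
            "groups": figure.groups,
            "header": figure.header,
        },
        "profiles": profiles,
        "hysteresis": paths,
    }


def export_html(payload: dict, out_path: str | Path, timestamp: bool = False) -> Path:
    """Write the single-file report; byte-deterministic unless ``timestamp``."""
    stamp = ""
    if timestamp:
        stamp = f"<p class='stamp'>generated {datetime.now(timezone.utc).isoformat()}</p>"
    doc = _TEMPLATE.substitute(
        payload=json.dumps(payload, sort_keys=True, separators=(",", ":")),
        stamp=stamp,
    )
    out_path = Path(out_path)
    out_path.write_text(doc)
    return out_path


def build_report(study: Study, cfg: EdishConfig = EdishConfig(),
                 constants: PAltConstants = PAltConstants(),
                 out_path: str | Path = "edish_report.html",
                 timestamp: bool = False) -> Path:
    """One-call pipeline tail: derive, classify, render, write."""
    return export_html(build_payload(study, cfg, constants), out_path, timestamp)


# --------------------------------------------------------------------------
# inline document template: style and charting runtime are embedded verbatim;
# the only URL-like string is the SVG XML namespace, which is an identifier,
# never fetched.

_TEMPLATE = Template("""<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>eDISH safety report</title>
<style>
body { font-family: sans-serif; margin: 1.5em; color: #222; }
h1 { font-size: 1.3em; } h2 { font-size: 1.05em; }
.header, .legend { font-size: 0.85em; color: #444; margin-bottom: 0.6em; }
.stamp { font-size: 0.75em; color: #888; }
.panel { display: inline-block; vertical-align: top; margin-right: 1.5em; }
.controls { margin: 0.5em 0; font-size: 0.85em; }
.controls select { margin-right: 1em; }
#tooltip { position: absolute; background: #fff; border: 1px solid #999;
  padding: 6px 8px; font-size: 0.75em; pointer-events: none; display: none;
  box-shadow: 2px 2px 4px rgba(0,0,0,0.2); }
#tooltip table td { padding: 0 4px; }
circle.pt { stroke: #333; stroke-width: 0.5; cursor: pointer; opacity: 0.85; }
circle.pt.hidden { display: none; }
line.thresh { stroke: #b33; stroke-dasharray: 4 3; }
.axis line, .axis path { stroke: #888; }
.axis text { font-size: 10px; fill: #555; }
.qlabel { font-size: 10px; fill: #b33; }
button { font-size: 0.8em; }
</style>
</head>
<body>
<h1>eDISH safety report</h1>
$stamp
<div class="header" id="header"></div>
<div class="controls" id="filters"></div>
<div class="panel"><svg id="edish" width="640" height="520"></svg>
<div class="legend">Point colour: peak-time separation within window
(orange) vs outside (blue). Point size: affine in rank of the configured
measure (equal if none). Click a point for the participant profile.</div></div>
<div class="panel" id="drill" style="display:none">
  <h2 id="drill-title"></h2>
  <svg id="profile" width="460" height="260"></svg>
  <svg id="rprofile" width="460" height="140"></svg><br>
  <button id="play">Play hysteresis</button>
  <svg id="hyst" width="460" height="300"></svg>
</div>
<div id="tooltip"></div>
<script id="edish-data" type="application/json">$payload</script>
<script>
"use strict";
var DATA = JSON.parse(document.getElementById("edish-data").textContent);
var SVGNS = "http://www.w3.org/2000/svg";
function el(tag, attrs, parent) {
  var e = document.createElementNS(SVGNS, tag);
  for (var k in attrs) e.setAttribute(k, attrs[k]);
  if (parent) parent.appendChild(e);
  return e;
}
function extent(vals, pad) {
  var lo = Math.min.apply(null, vals), hi = Math.max.apply(null, vals);
  if (!isFinite(lo)) { lo = 0.1; hi = 10; }
  if (lo === hi) { lo *= 0.5; hi *= 2; }
  return [lo / pad, hi * pad];
}
function makeScale(domain, range, log) {
  var d0 = log ? Math.log10(Math.max(domain[0], 1e-6)) : domain[0];
  var d1 = log ? Math.log10(Math.max(domain[1], 1e-6)) : domain[1];
  return function (v) {
    var t = log ? Math.log10(Math.max(v, 1e-6)) : v;
    return range[0] + (t - d0) / (d1 - d0) * (range[1] - range[0]);
  };
}
function ticks(domain, log) {
  var out = [];
  if (log) {
    var e0 = Math.floor(Math.log10(Math.max(domain[0], 1e-6)));
    var e1 = Math.ceil(Math.log10(domain[1]));
    for (var e = e0; e <= e1; e++) {
      [1, 2, 5].forEach(function (m) {
        var v = m * Math.pow(10, e);
        if (v >= domain[0] && v <= domain[1]) out.push(v);
      });
    }
  } else {
    var step = Math.pow(10, Math.floor(Math.log10(domain[1] - domain[0]))) / 2;
    for (var v = Math.ceil(domain[0] / step) * step; v <= domain[1]; v += step)
      out.push(Math.round(v * 1000) / 1000);
  }
  return out;
}
function drawAxes(svg, sx, sy, xd, yd, log, m, w, h, xlab, ylab) {
  var g = el("g", {"class": "axis"}, svg);
  el("line", {x1: m.l, y1: h - m.b, x2: w - m.r, y2: h - m.b}, g);
  el("line", {x1: m.l, y1: m.t, x2: m.l, y2: h - m.b}, g);
  ticks(xd, log).forEach(function (v) {
    var x = sx(v);
    el("line", {x1: x, y1: h - m.b, x2: x, y2: h - m.b + 4}, g);
    var t = el("text", {x: x, y: h - m.b + 14, "text-anchor": "middle"}, g);
    t.textContent = v;
  });
  ticks(yd, log).forEach(function (v) {
    var y = sy(v);
    el("line", {x1: m.l - 4, y1: y, x2: m.l, y2: y}, g);
    var t = el("text", {x: m.l - 6, y: y + 3, "text-anchor": "end"}, g);
    t.textContent = v;
  });
  var tx = el("text", {x: (m.l + w - m.r) / 2, y: h - 4, "text-anchor": "middle"}, g);
  tx.textContent = xlab;
  var ty = el("text", {x: 12, y: (m.t + h - m.b) / 2, "text-anchor": "middle",
    transform: "rotate(-90 12 " + (m.t + h - m.b) / 2 + ")"}, g);
  ty.textContent = ylab;
}
function header() {
  var f = DATA.figure.header;
  var parts = ["x-axis mode: " + f.x_axis_mode,
    "ALT fold threshold: " + f.alt_fold_threshold,
    "TB fold threshold: " + f.tb_fold_threshold,
    "nR threshold: " + f.nr_threshold,
    "peak window (days): " + f.peak_window_days,
    "point size: " + f.point_size_measure,
    "pattern basis: " + f.pattern_basis + "/" + f.ratio_basis];
  var html = "<b>Configuration</b> &mdash; " + parts.join(" | ");
  if (f.validation) {
    var v = f.validation;
    html += "<br><b>Validation</b> &mdash; subjects: " + v.n_subjects +
      " | evaluable: " + v.n_evaluable + " | records: " + v.n_records;
    var excl = Object.keys(v.excluded_rows || {}).map(function (k) {
      return k + "=" + v.excluded_rows[k]; }).join(", ");
    if (excl) html += " | excluded rows: " + excl;
    if ((v.warnings || []).length)
      html += "<br><b>Warnings</b> &mdash; " + v.warnings.join("; ");
  }
  document.getElementById("header").innerHTML = html;
}
var tooltip = document.getElementById("tooltip");
function showTooltip(evt, tip) {
  var rows = Object.keys(tip).map(function (k) {
    return "<tr><td>" + k + "</td><td><b>" + tip[k] + "</b></td></tr>"; });
  tooltip.innerHTML = "<table>" + rows.join("") + "</table>";
  tooltip.style.left = (evt.pageX + 12) + "px";
  tooltip.style.top = (evt.pageY + 12) + "px";
  tooltip.style.display = "block";
}
function lineChart(svg, seriesMap, w, h, xlab, ylab) {
  svg.innerHTML = "";
  var m = {l: 42, r: 10, t: 10, b: 30};
  var xs = [], ys = [];
  Object.keys(seriesMap).forEach(function (k) {
    seriesMap[k].forEach(function (p) { xs.push(p[0]); ys.push(p[1]); });
  });
  if (!xs.length) return;
  var xd = extent(xs, 1.02), yd = extent(ys, 1.3);
  var sx = makeScale(xd, [m.l, w - m.r], false);
  var sy = makeScale(yd, [h - m.b, m.t], true);
  drawAxes(svg, sx, sy, xd, yd, true, m, w, h, xlab, ylab);
  var colors = {ALT: "#d62728", AST: "#ff7f0e", ALP: "#2ca02c", TB: "#9467bd",
                R: "#17becf"};
  Object.keys(seriesMap).forEach(function (k) {
    var pts = seriesMap[k];
    if (!pts.length) return;
    var d = pts.map(function (p, i) {
      return (i ? "L" : "M") + sx(p[0]) + "," + sy(p[1]); }).join("");
    el("path", {d: d, fill: "none", stroke: colors[k] || "#333",
      "stroke-width": 1.5}, svg);
    var lastPt = pts[pts.length - 1];
    var t = el("text", {x: sx(lastPt[0]) + 4, y: sy(lastPt[1]) + 3,
      "font-size": 9, fill: colors[k] || "#333"}, svg);
    t.textContent = k;
  });
}
var playTimer = null;
function hysteresis(svg, path) {
  svg.innerHTML = "";
  var m = {l: 42, r: 10, t: 10, b: 30}, w = 460, h = 300;
  if (!path.length) return;
  var xd = extent(path.map(function (p) { return p[1]; }), 1.3);
  var yd = extent(path.map(function (p) { return p[2]; }), 1.3);
  var sx = makeScale(xd, [m.l, w - m.r], true);
  var sy = makeScale(yd, [h - m.b, m.t], true);
  drawAxes(svg, sx, sy, xd, yd, true, m, w, h, "ALT (fold ULN)", "TB (fold ULN)");
  var k = 0;
  function frame() {
    var prefix = path.slice(0, k + 1);
    svg.querySelectorAll(".hystmark").forEach(function (e) { e.remove(); });
    var d = prefix.map(function (p, i) {
      return (i ? "L" : "M") + sx(p[1]) + "," + sy(p[2]); }).join("");
    el("path", {d: d, fill: "none", stroke: "#1f77b4", "stroke-width": 1.5,
      "class": "hystmark"}, svg);
    prefix.forEach(function (p, i) {
      el("circle", {cx: sx(p[1]), cy: sy(p[2]), r: i === prefix.length - 1 ? 5 : 2.5,
        fill: i === prefix.length - 1 ? "#d62728" : "#1f77b4",
        "class": "hystmark"}, svg);
    });
    var t = el("text", {x: w - m.r - 4, y: m.t + 12, "text-anchor": "end",
      "font-size": 10, "class": "hystmark"}, svg);
    t.textContent = "day " + path[k][0];
    k += 1;
    if (k >= path.length && playTimer) { clearInterval(playTimer); playTimer = null; }
  }
  frame();
  k = path.length;  // show full path initially
  var prefixAll = path;
  svg.querySelectorAll(".hystmark").forEach(function (e) { e.remove(); });
  var dAll = prefixAll.map(function (p, i) {
    return (i ? "L" : "M") + sx(p[1]) + "," + sy(p[2]); }).join("");
  el("path", {d: dAll, fill: "none", stroke: "#1f77b4", "stroke-width": 1.5,
    "class": "hystmark"}, svg);
  prefixAll.forEach(function (p) {
    el("circle", {cx: sx(p[1]), cy: sy(p[2]), r: 2.5, fill: "#1f77b4",
      "class": "hystmark"}, svg);
  });
  document.getElementById("play").onclick = function () {
    if (playTimer) clearInterval(playTimer);
    k = 0;
    playTimer = setInterval(frame, 500);
  };
}
function drill(sid) {
  document.getElementById("drill").style.display = "inline-block";
  document.getElementById("drill-title").textContent = "Participant " + sid;
  var prof = DATA.profiles[sid];
  lineChart(document.getElementById("profile"), prof.series, 460, 260,
    "study day", "fold ULN");
  lineChart(document.getElementById("rprofile"), {R: prof.r_series}, 460, 140,
    "study day", "R ratio");
  hysteresis(document.getElementById("hyst"), DATA.hysteresis[sid]);
}
function filters() {
  var box = document.getElementById("filters");
  var groups = DATA.figure.groups;
  Object.keys(groups).forEach(function (col) {
    var label = document.createElement("label");
    label.textContent = col + ": ";
    var sel = document.createElement("select");
    sel.dataset.col = col;
    ["(all)"].concat(groups[col]).forEach(function (v) {
      var o = document.createElement("option");
      o.value = v; o.textContent = v; sel.appendChild(o);
    });
    sel.onchange = applyFilters;
    label.appendChild(sel);
    box.appendChild(label);
  });
}
function applyFilters() {
  var active = {};
  document.querySelectorAll("#filters select").forEach(function (sel) {
    if (sel.value !== "(all)") active[sel.dataset.col] = sel.value;
  });
  document.querySelectorAll("circle.pt").forEach(function (c) {
    var attrs = JSON.parse(c.dataset.attrs);
    var show = Object.keys(active).every(function (col) {
      return attrs[col] === active[col]; });
    c.classList.toggle("hidden", !show);
  });
}
function scatter() {
  var fig = DATA.figure;
  var svg = document.getElementById("edish");
  var w = 640, h = 520, m = {l: 50, r: 15, t: 15, b: 40};
  var xs = fig.points.map(function (p) { return p.x; }).concat([fig.x_threshold]);
  var ys = fig.points.map(function (p) { return p.y; }).concat([fig.y_threshold]);
  var xd = extent(xs, 1.35), yd = extent(ys, 1.35);
  var sx = makeScale(xd, [m.l, w - m.r], fig.log_axes);
  var sy = makeScale(yd, [h - m.b, m.t], fig.log_axes);
  drawAxes(svg, sx, sy, xd, yd, fig.log_axes, m, w, h, fig.x_label, fig.y_label);
  el("line", {x1: sx(fig.x_threshold), y1: m.t, x2: sx(fig.x_threshold),
    y2: h - m.b, "class": "thresh"}, svg);
  el("line", {x1: m.l, y1: sy(fig.y_threshold), x2: w - m.r,
    y2: sy(fig.y_threshold), "class": "thresh"}, svg);
  var ql = el("text", {x: w - m.r - 4, y: m.t + 12, "text-anchor": "end",
    "class": "qlabel"}, svg);
  ql.textContent = "possible Hy's Law";
  var ql2 = el("text", {x: w - m.r - 4, y: h - m.b - 6, "text-anchor": "end",
    "class": "qlabel"}, svg);
  ql2.textContent = "Temple's Corollary";
  var ql3 = el("text", {x: m.l + 4, y: m.t + 12, "class": "qlabel"}, svg);
  ql3.textContent = "hyperbilirubinemia";
  fig.points.forEach(function (p) {
    var c = el("circle", {cx: sx(p.x), cy: sy(p.y), r: p.size / 2,
      fill: p.within_window ? "#ff7f0e" : "#1f77b4", "class": "pt"}, svg);
    c.dataset.attrs = JSON.stringify(p.attrs);
    c.addEventListener("mousemove", function (evt) { showTooltip(evt, p.tooltip); });
    c.addEventListener("mouseleave", function () { tooltip.style.display = "none"; });
    c.addEventListener("click", function () { drill(p.subject_id); });
  });
}
header();
filters();
scatter();
</script>
</body>
</html>
""")
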