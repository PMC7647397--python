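"""Figure drivers: one standard results panel per identifier.

Each driver runs the owning module's simulation with the model defaults,
writes the underlying curves as CSV and a small PNG plot, and returns a
short summary dict of headline numbers. Panels: 1A/1C/1D illumination,
2B/2C collection, 3A-3D optics comparisons, 4C/4D vessel shadowing,
5C/5D laminar attribution.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .collection import collection_efficiency_vs_depth, collection_kernel, surface_spread_quantiles
from .contribution import fluorescence_by_depth, source_volume_map
from .engine import RecorderSpec
from .expression import LINE_SOMATIC_LAYERS, line_profile
from .hemodynamics import fluorescence_under_vessel, illumination_under_vessel
from .illumination import TL2X_SAP, TL10X_2P, depth_profile, mean_cos_profile, peak_depth, run_illumination
from .optics import GREY_MATTER_480, OpticalProperties
from .scene import build_scene

_DEPTH_GRID = np.arange(0.0, 1.01, 0.1)


def _save_curve(out: Path, name: str, frame: pd.DataFrame, x: str, ys, ylabel: str):
    frame.to_csv(out / f"{name}.csv", index=False)
    fig, ax = plt.subplots(figsize=(4, 3))
    for y in ys:
        ax.plot(frame[x], frame[y], label=y)
    ax.set_xlabel(x)
    ax.set_ylabel(ylabel)
    if len(ys) > 1:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / f"{name}.png", dpi=150)
    plt.close(fig)


def _illumination_profiles(photons, seed, scenes):
    curves = {}
    for label, scene in scenes.items():
        field = run_illumination(scene, TL2X_SAP, photons, seed)
        z, surf = depth_profile(field, "surface")
        _, total = depth_profile(field, "total")
        _, mc = mean_cos_profile(field)
        curves[label] = (z, surf, total, mc)
    return curves


def reproduce(figure_id: str, photons: int, seed: int, out: Path) -> dict:
    if figure_id in ("1A", "1C", "1D"):
        scenes = {"window": build_scene("window")}
        if figure_id in ("1C", "1D"):
            scenes["skull-300um"] = build_scene("skull-300um")
        if figure_id == "1D":
            scenes["skull-100um"] = build_scene("skull-100um")
            scenes["skull-1000um"] = build_scene("skull-1000um")
        if figure_id == "1A":
            # no-scattering control: pure exponential absorption decay
            scenes["no-scatter"] = build_scene("window").with_grey_matter(
                480, OpticalProperties(GREY_MATTER_480.mu_a, 0.0, 0.0)
            )
        curves = _illumination_profiles(photons, seed, scenes)
        z = next(iter(curves.values()))[0]
        col = 1 if figure_id in ("1A",) else (3 if figure_id == "1C" else 2)
        frame = pd.DataFrame({"z_mm": z})
        for label, c in curves.items():
            frame[label] = c[col]
        ylabel = {"1A": "intensity (surface norm)", "1C": "mean cos",
                  "1D": "intensity (total norm)"}[figure_id]
        _save_curve(out, f"fig{figure_id}", frame, "z_mm", list(curves), ylabel)
        zw, sw = curves["window"][0], curves["window"][1]
        return {"peak_depth_mm": round(peak_depth(zw, sw), 3)}

    if figure_id in ("2B", "2C"):
        scene = build_scene("window")
        d, pct, results = collection_efficiency_vs_depth(
            scene, TL2X_SAP, _DEPTH_GRID, photons, seed
        )
        rows = []
        for res, p in zip(results, pct):
            q = surface_spread_quantiles(res, (0.5, 0.95))
            rows.append({"depth_mm": res.source_depth, "pct_collected": p,
                         "d50_mm": q[0.5], "d95_mm": q[0.95]})
        frame = pd.DataFrame(rows)
        if figure_id == "2B":
            _save_curve(out, "fig2B", frame, "depth_mm", ["pct_collected"], "% collected")
            return {"pct_surface": round(frame.pct_collected.iloc[0], 3),
                    "pct_1mm": round(frame.pct_collected.iloc[-1], 3)}
        _save_curve(out, "fig2C", frame, "depth_mm", ["d50_mm", "d95_mm"], "diameter (mm)")
        return {
            "d50_surface_mm": round(frame.d50_mm.iloc[0], 3),
            "d50_1mm_mm": round(frame.d50_mm.iloc[-1], 3),
            "d95_surface_mm": round(frame.d95_mm.iloc[0], 3),
            "d95_1mm_mm": round(frame.d95_mm.iloc[-1], 3),
        }

    if figure_id in ("3A", "3B", "3C", "3D"):
        scene = build_scene("window")
        if figure_id == "3A":
            variants = {
                "focus-1mm": dict(objective=TL2X_SAP.focused_at(1.0), beam="focused"),
                "focus-2mm": dict(objective=TL2X_SAP.focused_at(2.0), beam="focused"),
            }
        elif figure_id == "3B":
            variants = {
                "NA-0.1": dict(objective=TL2X_SAP),
                "NA-0.5": dict(objective=TL10X_2P),
            }
        elif figure_id == "3C":
            import dataclasses
            variants = {
                "FOV-11mm": dict(objective=TL2X_SAP),
                "FOV-4.4mm": dict(objective=dataclasses.replace(
                    TL2X_SAP, field_of_view_diameter=4.4)),
            }
        else:
            variants = {
                "window": dict(objective=TL2X_SAP),
                "skull-300um": dict(objective=TL2X_SAP,
                                    scene=build_scene("skull-300um")),
            }
        frames = {}
        summary = {}
        for label, v in variants.items():
            scn = v.get("scene", scene)
            obj = v["objective"]
            field = run_illumination(scn, obj, photons, seed,
                                     beam=v.get("beam", "conical"))
            z, surf = depth_profile(field, "surface")
            d, pct, results = collection_efficiency_vs_depth(
                scn, obj, _DEPTH_GRID, photons, seed + 1, criterion="cone"
            )
            q0 = surface_spread_quantiles(results[0], (0.5, 0.95))
            q1 = surface_spread_quantiles(results[-1], (0.5, 0.95))
            frames[label] = pd.DataFrame({
                "z_mm": z, "illum_surface_norm": surf,
            })
            frames[label].to_csv(out / f"fig{figure_id}_illum_{label}.csv", index=False)
            pd.DataFrame({"depth_mm": d, "pct_collected": pct}).to_csv(
                out / f"fig{figure_id}_collect_{label}.csv", index=False)
            summary[f"{label}_illum_peak_mm"] = round(peak_depth(z, surf), 3)
            summary[f"{label}_pct_surface"] = round(float(pct[0]), 4)
            summary[f"{label}_d95_1mm_mm"] = round(q1[0.95], 3)
        return summary

    if figure_id in ("4C", "4D"):
        scene = build_scene("vessel-250um")
        if figure_id == "4C":
            uv = illumination_under_vessel(scene, TL2X_SAP, photons, seed)
            frame = pd.DataFrame({
                "z_mm": uv.z_centers,
                "intensity_vs_novessel_surface":
                    uv.profile_normalized_to_control_surface(),
                "ratio": uv.ratio(),
            })
            _save_curve(out, "fig4C", frame, "z_mm",
                        ["intensity_vs_novessel_surface"], "intensity")
            iz = np.searchsorted(uv.z_centers, 0.55)
            return {"ratio_0.55mm": round(float(uv.ratio()[iz]), 3)}
        depths = np.arange(0.5, 1.51, 0.25)
        uv = fluorescence_under_vessel(scene, TL2X_SAP, depths, photons, seed)
        frame = pd.DataFrame({
            "depth_mm": uv.depths,
            "illum_ratio": uv.illumination_ratio,
            "collect_ratio": uv.collection_ratio,
            "fluor_ratio": uv.fluorescence_ratio,
        })
        _save_curve(out, "fig4D", frame, "depth_mm", ["fluor_ratio"],
                    "relative fluorescence")
        return {
            "fluor_pct_0.5mm": round(100 * float(uv.fluorescence_ratio[0]), 2),
            "fluor_pct_1mm": round(100 * float(uv.fluorescence_ratio[2]), 2),
        }

    if figure_id in ("5C", "5D"):
        scene = build_scene("window")
        field = run_illumination(scene, TL2X_SAP, photons, seed)
        z, illum = depth_profile(field, "surface")
        kern = collection_kernel(scene, TL2X_SAP, np.arange(0.05, 1.05, 0.1),
                                 photons, seed + 1)
        rows = []
        volumes = {}
        for line in LINE_SOMATIC_LAYERS:
            expr = line_profile(line)
            wgt = fluorescence_by_depth((z, illum), expr,
                                        (kern.depths, kern.efficiency))
            rows.append({"line": line, **wgt.layer_percentages})
            if figure_id == "5D":
                svm = source_volume_map((z, illum), expr, kern)
                volumes[line] = svm.contour_volumes
        frame = pd.DataFrame(rows)
        frame.to_csv(out / f"fig{figure_id}_layers.csv", index=False)
        if figure_id == "5C":
            return {r["line"]: round(max(v for k, v in r.items() if k != "line"), 1)
                    for r in rows}
        vf = pd.DataFrame(
            [{"line": k, **{f"V{int(100 * f)}": v for f, v in d.items()}}
             for k, d in volumes.items()]
        )
        vf.to_csv(out / "fig5D_volumes.csv", index=False)
        return {k: round(d[0.95], 2) for k, d in volumes.items()}

    raise ValueError(f"unknown figure id {figure_id!r}")
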