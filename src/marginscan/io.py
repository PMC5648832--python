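"""File formats: delimited spectra tables, PLY/OBJ meshes, PNG
silhouettes, and JSON manifests/reports/configs.

Every JSON artifact carries a ``schema_version`` tag; readers refuse
files from a different schema. Spectra tables round-trip intensities at
full double precision.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import trimesh
import yaml
from PIL import Image

from .margin_classifier import ClassificationReport
from .spectral_processing import Spectrum
from .surface_scan import MountingDisc, ScanPlan, SilhouetteSet, SurfaceMesh
from .synthetic_phantom import PhantomSpec, Spot
from .util import SCHEMA_VERSION


class SchemaError(ValueError):
    pass


def _check_schema(obj: dict, path) -> None:
    tag = obj.get("schema_version")
    if tag != SCHEMA_VERSION:
        raise SchemaError(f"{path}: schema_version {tag!r} does not match "
                          f"expected {SCHEMA_VERSION!r}")


def _dump_json(obj: dict, path) -> None:
    obj = {"schema_version": SCHEMA_VERSION, **obj}
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def _load_json(path) -> dict:
    obj = json.loads(Path(path).read_text())
    _check_schema(obj, path)
    return obj


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def write_spectrum(spectrum: Spectrum, path) -> None:
    """Two-column delimited text (wavenumber, intensity) with provenance
    stages in a comment header."""
    with open(path, "w") as fh:
        fh.write(f"# schema_version\t{SCHEMA_VERSION}\n")
        fh.write("# stages\t" + ",".join(spectrum.stages) + "\n")
        fh.write("wavenumber_cm-1\tintensity\n")
        for w, i in zip(spectrum.wavenumbers, spectrum.intensities):
            fh.write(f"{w:.17g}\t{i:.17g}\n")


def read_spectrum(path) -> Spectrum:
    stages = ("raw",)
    schema = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# schema_version"):
                schema = line.split("\t", 1)[1]
            elif line.startswith("# stages"):
                stages = tuple(line.split("\t", 1)[1].split(","))
            elif line.startswith("#") or line.startswith("wavenumber"):
                continue
            elif line:
                w, i = line.split("\t")
                rows.append((float(w), float(i)))
    if schema != SCHEMA_VERSION:
        raise SchemaError(f"{path}: schema_version {schema!r} does not match "
                          f"expected {SCHEMA_VERSION!r}")
    arr = np.array(rows)
    return Spectrum(arr[:, 0], arr[:, 1], {"stages": stages})


def write_intensity_table(wavenumbers, intensities, path, point_ids=None) -> None:
    """Long-format table (point_id, wavenumber, intensity) for many spectra."""
    Y = np.atleast_2d(intensities)
    ids = range(len(Y)) if point_ids is None else point_ids
    with open(path, "w") as fh:
        fh.write(f"# schema_version\t{SCHEMA_VERSION}\n")
        fh.write("point_id\twavenumber_cm-1\tintensity\n")
        for pid, row in zip(ids, Y):
            for w, i in zip(wavenumbers, row):
                fh.write(f"{pid}\t{w:.17g}\t{i:.17g}\n")


def read_intensity_table(path):
    import pandas as pd

    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    if first != f"# schema_version\t{SCHEMA_VERSION}":
        raise SchemaError(f"{path}: missing or mismatched schema tag")
    df = pd.read_csv(path, sep="\t", comment="#",
                     float_precision="round_trip")
    wn = np.array(sorted(df["wavenumber_cm-1"].unique()))
    ids = list(dict.fromkeys(df["point_id"]))
    Y = np.empty((len(ids), wn.size))
    for k, pid in enumerate(ids):
        sub = df[df["point_id"] == pid].sort_values("wavenumber_cm-1")
        Y[k] = sub["intensity"].to_numpy()
    return wn, Y, ids


def write_bundle(bundle, path) -> None:
    """Ring-spectra bundle as long-format delimited text
    (point_id, quadrant, ring, wavenumber, intensity)."""
    with open(path, "w") as fh:
        fh.write(f"# schema_version\t{SCHEMA_VERSION}\n")
        fh.write("point_id\tquadrant\tring\twavenumber_cm-1\tintensity\n")
        for (q, r), s in sorted(bundle.spectra.items()):
            for w, i in zip(s.wavenumbers, s.intensities):
                fh.write(f"{bundle.point_id}\t{q}\t{r}\t{w:.17g}\t{i:.17g}\n")


def read_bundle(path):
    import pandas as pd

    from .probe import RingSpectraBundle

    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    if first != f"# schema_version\t{SCHEMA_VERSION}":
        raise SchemaError(f"{path}: missing or mismatched schema tag")
    df = pd.read_csv(path, sep="\t", comment="#",
                     float_precision="round_trip")
    spectra = {}
    for (q, r), sub in df.groupby(["quadrant", "ring"]):
        sub = sub.sort_values("wavenumber_cm-1")
        spectra[(int(q), int(r))] = Spectrum(
            sub["wavenumber_cm-1"].to_numpy(), sub["intensity"].to_numpy())
    return RingSpectraBundle(spectra, point_id=int(df["point_id"].iloc[0]))


def write_library(entries, path) -> None:
    """Component library as a JSON peak list."""
    _dump_json({
        "components": [
            {"name": e.name,
             "peaks": [{"center": p.center, "width": p.width,
                        "amplitude": p.amplitude, "shape": p.shape}
                       for p in e.peaks]}
            for e in entries
        ]
    }, path)


def read_library(path):
    from .spectral_processing import ComponentLibraryEntry, PeakModel

    d = _load_json(path)
    return [
        ComponentLibraryEntry(
            c["name"],
            tuple(PeakModel(p["center"], p["width"], p["amplitude"],
                            p["shape"]) for p in c["peaks"]))
        for c in d["components"]
    ]


# ---------------------------------------------------------------------------
# Meshes and silhouettes
# ---------------------------------------------------------------------------

def write_mesh(mesh: SurfaceMesh, path) -> None:
    """PLY (binary little-endian) or OBJ, by file extension."""
    mesh.export(str(path))


def read_mesh(path) -> SurfaceMesh:
    m = trimesh.load(str(path), process=False)
    return trimesh.Trimesh(vertices=m.vertices, faces=m.faces, process=False)


def write_margin_map_ply(margin_map, path) -> None:
    """Margin map as vertex-coloured PLY (green fatty/clean, blue
    fibroadenomatoid/paraffin)."""
    mesh = margin_map.mesh.copy()
    colors = np.hstack([margin_map.vertex_colors,
                        np.full((len(margin_map.vertex_colors), 1), 255,
                                np.uint8)])
    mesh.visual.vertex_colors = colors
    mesh.export(str(path))


def write_margin_map_sidecar(margin_map, path) -> None:
    rows = []
    for i, (p, lab, fr) in enumerate(zip(margin_map.plan.points,
                                         margin_map.labels,
                                         margin_map.fractions)):
        rows.append({"point_id": i, "xyz": [float(v) for v in p],
                     "label": lab,
                     "fractions": {k: float(v) for k, v in fr.items()}})
    _dump_json({"points": rows, "orientation": margin_map.orientation}, path)


def write_silhouettes(silhouettes: SilhouetteSet, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    names = []
    for i, img in enumerate(silhouettes.images):
        name = f"view_{i:03d}.png"
        Image.fromarray((img * 255).astype(np.uint8)).save(d / name)
        names.append(name)
    _dump_json({
        "images": names,
        "angles_deg": [float(a) for a in silhouettes.angles_deg],
        "scale_mm_per_px": silhouettes.scale,
        "origin_row_col": [float(v) for v in silhouettes.origin],
    }, d / "manifest.json")


def read_silhouettes(directory) -> SilhouetteSet:
    d = Path(directory)
    man = _load_json(d / "manifest.json")
    imgs = np.stack([np.asarray(Image.open(d / n)) > 127 for n in man["images"]])
    return SilhouetteSet(imgs, np.array(man["angles_deg"]),
                         man["scale_mm_per_px"], tuple(man["origin_row_col"]))


# ---------------------------------------------------------------------------
# Plans, phantoms, reports, configs
# ---------------------------------------------------------------------------

def write_plan(plan: ScanPlan, path) -> None:
    _dump_json({
        "points": plan.points.tolist(),
        "normals": plan.normals.tolist(),
        "step": plan.step,
        "band_index": plan.band_index.tolist(),
        "angles": plan.angles.tolist(),
        "excluded_region": dataclasses.asdict(plan.excluded_region)
        if plan.excluded_region else None,
        "manual_point_required": plan.manual_point_required,
    }, path)


def read_plan(path) -> ScanPlan:
    d = _load_json(path)
    excl = d["excluded_region"]
    return ScanPlan(
        np.array(d["points"]), np.array(d["normals"]), d["step"],
        np.array(d["band_index"]), np.array(d["angles"]),
        MountingDisc(tuple(excl["center"]), excl["diameter"]) if excl else None,
        d["manual_point_required"],
    )


def write_phantom(spec: PhantomSpec, path) -> None:
    _dump_json({
        "semi_axes": list(spec.semi_axes),
        "surface_layer": list(spec.surface_layer),
        "core_component": spec.core_component,
        "spots": [dataclasses.asdict(s) for s in spec.spots],
        "seed": spec.seed,
    }, path)


def read_phantom(path) -> PhantomSpec:
    d = _load_json(path)
    spots = tuple(Spot(tuple(s["center"]), s["extent"], s["depth"],
                       s["thickness"], s["component"]) for s in d["spots"])
    return PhantomSpec(tuple(d["semi_axes"]),
                       (d["surface_layer"][0], float(d["surface_layer"][1])),
                       d["core_component"], spots, d["seed"])


def write_report(report: ClassificationReport, path) -> None:
    _dump_json({
        "counts": {"tp": report.tp, "fn": report.fn,
                   "tn": report.tn, "fp": report.fp},
        "display": report.as_display(),
        "notes": list(report.notes),
        "fold_predictions": [list(r) for r in report.fold_predictions],
    }, path)


def read_report(path) -> ClassificationReport:
    d = _load_json(path)
    c = d["counts"]
    return ClassificationReport(c["tp"], c["fn"], c["tn"], c["fp"],
                                tuple(d.get("notes", ())),
                                tuple(tuple(r) for r in
                                      d.get("fold_predictions", ())))


def write_config(config: dict, path) -> None:
    path = Path(path)
    config = {"schema_version": SCHEMA_VERSION, **config}
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(config, sort_keys=True))
    else:
        path.write_text(json.dumps(config, indent=1, sort_keys=True))


def read_config(path) -> dict:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        obj = yaml.safe_load(path.read_text())
    else:
        obj = json.loads(path.read_text())
    _check_schema(obj, path)
    return obj


__all__ = [
    "SchemaError", "write_spectrum", "read_spectrum",
    "write_intensity_table", "read_intensity_table",
    "write_bundle", "read_bundle", "write_library", "read_library",
    "write_mesh", "read_mesh", "write_margin_map_ply",
    "write_margin_map_sidecar", "write_silhouettes", "read_silhouettes",
    "write_plan", "read_plan", "write_phantom", "read_phantom",
    "write_report", "read_report", "write_config", "read_config",
]
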