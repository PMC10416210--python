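"""End-to-end analysis pipeline: structure in, JSON/Markdown report out.

Stage order follows data dependencies: I/O → register & Crick fits →
edge/vertex geometry → knot topology → crystal packing (when a cell is
present) → SAXS comparison (when a curve is given).  Optional stages that
cannot run on a given input (e.g. knobs-into-holes on a Cα-only model)
degrade to warnings recorded in the report.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict
from typing import Optional

import numpy as np

from . import __version__
from .builder import OrigamiModel, TopologySpec, build_origami, load_topology
from .coiledcoil import assign_register, detect_kih, helicity, ca_trace_segment
from .crick import fit_crick
from .geometry import (band_orientation, cavity_area, contact_map, edge_length,
                       vertex_report)
from .knots import classify_knot
from .packing import lattice_neighbors, packing_summary, unique_interfaces
from .saxs import chi2_fit, debye_profile, guinier_rg, read_saxs_curve, \
    radius_of_gyration, residue_weights
from .structures import (SegmentConfig, Structure, StructureError, average_mass,
                         load_segment_config, read_structure, write_structure)

__all__ = ["run_pipeline", "run_builder", "analyze_structure"]


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(x) for x in sorted(obj, key=str) if True] \
            if isinstance(obj, (set, frozenset)) else [_jsonable(x) for x in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def analyze_structure(structure: Structure, config: SegmentConfig,
                      saxs_curve=None, chain: Optional[str] = None,
                      contact_cutoff: float = 10.0, knot_seed: int = 0,
                      mass: Optional[float] = None) -> dict:
    """Run every applicable analysis stage on an in-memory structure."""
    report: dict = {"warnings": []}
    warn = report["warnings"].append

    main_chain = chain or next(iter(structure.chains))

    # --- coiled-coil stage: registers, Crick fits, KIH -------------------
    crick_block = {}
    register_block = {}
    kih_block = {}
    registers_by_seg: dict[str, dict[int, str]] = {}
    for a, b, orientation in config.dimers:
        pair_name = f"{a}:{b}"
        try:
            ca_a = ca_trace_segment(structure, config.segments[a])
            ca_b = ca_trace_segment(structure, config.segments[b])
            fit = fit_crick([ca_a, ca_b], orientation=orientation)
            crick_block[pair_name] = {
                "params": asdict(fit.params),
                "pitch_angle_deg": fit.params.pitch_angle,
                "rmsd_fit": fit.rmsd_fit, "n_res": fit.n_res,
            }
        except (StructureError, ValueError, RuntimeError) as exc:
            warn(f"crick fit {pair_name}: {exc}")
        try:
            contacts = detect_kih(structure, config, (a, b))
            kih_block[pair_name] = [
                {"knob": [c.knob_segment, c.knob_residue],
                 "hole": [c.hole_segment, list(c.hole_residues)],
                 "position": c.knob_position} for c in contacts]
        except StructureError as exc:
            warn(f"knobs-into-holes {pair_name}: {exc}")
    for sid in config.segments:
        try:
            reg = assign_register(structure, config, sid, method="crick_phase")
            register_block[sid] = reg.as_string()
            registers_by_seg[sid] = reg.positions
        except (StructureError, ValueError, RuntimeError) as exc:
            warn(f"register {sid}: {exc}")
    # annotate knob heptad positions now that registers are known
    for pair_name, contacts in kih_block.items():
        for c in contacts:
            seg, res = c["knob"]
            c["position"] = registers_by_seg.get(seg, {}).get(res)
    report["crick_fits"] = crick_block
    report["registers"] = register_block
    report["kih"] = kih_block

    # --- geometry stage --------------------------------------------------
    edges = {}
    for idx, (a, b, _) in enumerate(config.dimers):
        try:
            eg = edge_length(structure, config, (a, b), edge_index=idx)
            edges[f"{a}:{b}"] = {"axis_length": eg.axis_length,
                                 "direction": eg.direction.tolist()}
        except StructureError as exc:
            warn(f"edge {a}:{b}: {exc}")
    report["edges"] = edges
    try:
        report["cavity_area"] = cavity_area(structure)
    except StructureError as exc:
        warn(f"cavity: {exc}")
    try:
        cmap = contact_map(structure, cutoff=contact_cutoff)
        bands = {}
        for a, b, _ in config.dimers:
            bands[f"{a}:{b}"] = band_orientation(cmap, config, a, b)
        report["contact_map"] = {
            "n_contacts": int(np.triu(cmap.matrix, 3).sum()),
            "cutoff": cmap.cutoff,
            "dimer_band_orientation": bands,
        }
    except StructureError as exc:
        warn(f"contact map: {exc}")
    try:
        vertices = vertex_report(structure, config, registers=registers_by_seg)
        report["vertices"] = {
            " / ".join(sorted("∶".join(sorted(d)) for d in key)): [
                {"res1": list(r.res1), "res2": list(r.res2), "type": r.type,
                 "distance": round(r.distance, 3),
                 "positions": [r.position1, r.position2]}
                for r in recs]
            for key, recs in vertices.items()}
    except StructureError as exc:
        warn(f"vertices: {exc}")
    try:
        report["helicity"] = helicity(structure, main_chain)
    except StructureError as exc:
        warn(f"helicity: {exc}")

    # --- knot stage ------------------------------------------------------
    try:
        knot = classify_knot(structure, main_chain, seed=knot_seed)
        report["knot"] = {
            "determinant": knot.determinant, "call": knot.knot_call,
            "closure": knot.closure_method, "votes": knot.closure_votes,
            "core": list(knot.core) if knot.core else None,
            "depth": knot.depth,
        }
    except (StructureError, ValueError, RuntimeError) as exc:
        warn(f"knot: {exc}")

    # --- packing stage ---------------------------------------------------
    if structure.cell is not None:
        try:
            seq_mass = mass
            if seq_mass is None:
                seq_mass = sum(average_mass(structure.sequence(c))
                               for c in structure.chains)
            neighbors = lattice_neighbors(structure, structure.cell)
            summary = packing_summary(structure, structure.cell, mass=seq_mass,
                                      neighbors=neighbors)
            report["packing"] = {
                **asdict(summary),
                "interfaces": [
                    {"translation": list(c.representative),
                     "members": [list(m) for m in c.members],
                     "buried_area": round(c.buried_area, 1),
                     "heterologous": c.heterologous}
                    for c in unique_interfaces(neighbors)],
                "mass_used": seq_mass,
            }
        except StructureError as exc:
            warn(f"packing: {exc}")

    # --- SAXS stage ------------------------------------------------------
    if saxs_curve is not None:
        try:
            coords, weights = residue_weights(structure, main_chain)
            model = debye_profile(coords, weights, saxs_curve.q)
            fit = chi2_fit(model, saxs_curve)
            report["saxs"] = {
                "chi2": fit.chi2, "scale": fit.scale, "n_points": fit.n_points,
                "rg_model": radius_of_gyration(coords, weights),
                "rg_guinier_model": guinier_rg(model),
            }
        except (ValueError, StructureError) as exc:
            warn(f"saxs: {exc}")

    return report


def run_pipeline(structure_path, segments_path, saxs_path=None,
                 out_json=None, out_markdown=None, chain=None,
                 contact_cutoff: float = 10.0, knot_seed: int = 0) -> dict:
    """Analyze a structure file with a segment config; write reports."""
    structure = read_structure(structure_path)
    config = load_segment_config(segments_path)
    # validate config against the structure before any analysis
    for sid, seg in config.segments.items():
        if seg.chain not in structure.chains:
            raise StructureError(f"segment {sid}: chain {seg.chain!r} absent")
        ids = {r.seq_id for r in structure.chains[seg.chain]}
        missing = set(range(seg.first, seg.last + 1)) - ids
        if missing:
            raise StructureError(
                f"segment {sid}: residues missing from structure: "
                f"{sorted(missing)[:5]}{'...' if len(missing) > 5 else ''}")
    curve = read_saxs_curve(saxs_path) if saxs_path else None
    report = analyze_structure(structure, config, saxs_curve=curve,
                               chain=chain, contact_cutoff=contact_cutoff,
                               knot_seed=knot_seed)
    report["provenance"] = {
        "version": __version__,
        "structure": {"path": str(structure_path), "sha256": _sha256(structure_path)},
        "segments": {"path": str(segments_path), "sha256": _sha256(segments_path)},
        "saxs": ({"path": str(saxs_path), "sha256": _sha256(saxs_path)}
                 if saxs_path else None),
        "knot_seed": knot_seed,
        "contact_cutoff": contact_cutoff,
    }
    _emit(report, out_json, out_markdown)
    return report


def run_builder(topology, seed: int = 0, out_pdb=None, out_json=None,
                edge_lengths=(47.0, 34.0, 47.0), jitter: float = 0.0) -> OrigamiModel:
    """Build an origami model from a topology spec (path or object)."""
    if not isinstance(topology, TopologySpec):
        topology = load_topology(topology)
    model = build_origami(topology, edge_lengths=edge_lengths,
                          jitter=jitter, seed=seed)
    if out_pdb:
        write_structure(model.structure, out_pdb)
    if out_json:
        report = analyze_structure(model.structure, model.segment_config)
        report["provenance"] = {"version": __version__, "seed": seed,
                                "jitter": jitter,
                                "edge_lengths": list(edge_lengths)}
        _emit(report, out_json, None)
    return model


def _emit(report: dict, out_json, out_markdown) -> None:
    if out_json:
        with open(out_json, "w") as fh:
            json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
            fh.write("\n")
    if out_markdown:
        with open(out_markdown, "w") as fh:
            fh.write(render_markdown(report))


def render_markdown(report: dict) -> str:
    lines = ["# Structure analysis report", ""]
    if "edges" in report:
        lines += ["## Edge lengths", ""]
        for name, e in report["edges"].items():
            lines.append(f"- {name}: {e['axis_length']:.1f} Å")
        lines.append("")
    if "cavity_area" in report:
        lines += [f"Internal cavity (projected): {report['cavity_area']:.0f} Å²", ""]
    if "knot" in report:
        k = report["knot"]
        lines += ["## Knot topology", "",
                  f"- call: {k['call']} (determinant {k['determinant']})",
                  f"- core: {k['core']}, depth: {k['depth']}", ""]
    if "packing" in report:
        p = report["packing"]
        lines += ["## Crystal packing", "",
                  f"- neighbors: {p['n_neighbors']}, unique interfaces: "
                  f"{p['n_unique_interfaces']}",
                  f"- buried: {p['total_buried']:.0f} Å² "
                  f"({100 * p['buried_fraction']:.1f}% of surface)",
                  f"- Vm: {p['matthews_vm']:.2f} Å³/Da, solvent "
                  f"{100 * p['solvent_fraction']:.1f}%", ""]
    if "saxs" in report:
        s = report["saxs"]
        lines += [f"SAXS: chi2 = {s['chi2']:.2f} over {s['n_points']} points", ""]
    if report.get("warnings"):
        lines += ["## Warnings", ""] + [f"- {w}" for w in report["warnings"]]
    return "\n".join(lines) + "\n"
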