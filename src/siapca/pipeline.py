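"""Config-driven batch orchestration of the full analysis.

A run config is a YAML document with two modes:

``simulate+analyze``
    A ``simulation`` block (SimulationConfig fields; all optional) drives
    the synthetic-experiment generator; the resulting ensembles are
    analysed and, because ground-truth peak lists exist, the manual-SIA
    cross-check runs as well.

``analyze``
    A ``positions`` block maps each position to five spectrum files
    (``free`` and ``A``/``C``/``G``/``U``); an optional ``peaklists``
    block (same shape) enables manual SIA.

Common blocks: ``pca`` (centering, component, tol, ratio_threshold),
``sia`` (alpha, selected_ids or n_selected), ``output_dir``, ``format``.

Outputs per run: ``variance_table.csv``, ``pca_scores.csv``,
``sia_scores.csv`` (when SIA ran), ``comparison.json``,
``histogram_data.csv`` (the bar heights of a per-position preference
histogram) and ``run_log.txt``. Identical config + seed gives byte-identical
tables; positions are always processed independently, one PCA per ensemble.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import manual as manual_mod
from . import simulate as sim_mod
from .errors import ConfigurationError
from .nipals import PCAResult
from .scoring import PreferenceTable, pca_preference_table
from .spectra import BASES, AxisCalibration, PeakList
from .spectra_io import read_peaklist, read_spectrum, stack_ensemble, write_spectrum

__all__ = ["RunConfig", "validate_config", "run", "RunResult"]

PLANE_KEYS = ("free",) + BASES


@dataclass
class PCAOptions:
    centering: str = "none"
    component: int = 2
    tol: float = 1e-11
    max_iter: int = 50_000
    ratio_threshold: float = 3.0


@dataclass
class SIAOptions:
    alpha: float = 0.2
    selected_ids: Optional[List[str]] = None
    n_selected: int = 10  # auto-pick the n largest shifters when ids not given


@dataclass
class RunConfig:
    mode: str  # "analyze" | "simulate+analyze"
    output_dir: Path
    simulation: Optional[sim_mod.SimulationConfig] = None
    manifest: Optional[Dict[int, Dict[str, Path]]] = None  # position -> plane -> file
    peak_manifest: Optional[Dict[int, Dict[str, Path]]] = None
    spectrum_format: str = "matrix"
    pca: PCAOptions = field(default_factory=PCAOptions)
    sia: SIAOptions = field(default_factory=SIAOptions)


def _violations_of(doc: dict, base_dir: Path) -> Tuple[Optional[RunConfig], List[str]]:
    violations: List[str] = []
    if not isinstance(doc, dict):
        return None, ["config root must be a mapping"]
    mode = doc.get("mode")
    if mode not in ("analyze", "simulate+analyze"):
        violations.append(f"mode must be 'analyze' or 'simulate+analyze', got {mode!r}")
    has_sim = "simulation" in doc
    has_manifest = "positions" in doc
    if has_sim and has_manifest:
        violations.append("mode conflict: both 'simulation' and 'positions' given")
    if mode == "analyze" and not has_manifest:
        violations.append("analyze mode requires a 'positions' manifest")
    if mode == "simulate+analyze" and has_manifest:
        violations.append("mode conflict: simulate+analyze must not list 'positions'")

    simulation = None
    if has_sim:
        sim_doc = doc.get("simulation") or {}
        if not isinstance(sim_doc, dict):
            violations.append("'simulation' must be a mapping")
        else:
            try:
                sim_doc = dict(sim_doc)
                if "profile" in sim_doc:
                    sim_doc["profile"] = {
                        int(k): tuple(v) for k, v in sim_doc["profile"].items()
                    }
                for axis_key in ("axis_h", "axis_n"):
                    if isinstance(sim_doc.get(axis_key), dict):
                        sim_doc[axis_key] = AxisCalibration(**sim_doc[axis_key])
                if "kd_ladder" in sim_doc:
                    sim_doc["kd_ladder"] = tuple(sim_doc["kd_ladder"])
                simulation = sim_mod.SimulationConfig(**sim_doc)
            except (TypeError, ConfigurationError) as exc:
                violations.append(f"simulation block invalid: {exc}")
    elif mode == "simulate+analyze":
        simulation = sim_mod.SimulationConfig()

    def parse_manifest(key: str, require_all: bool) -> Optional[Dict[int, Dict[str, Path]]]:
        if key not in doc:
            return None
        block = doc[key]
        if not isinstance(block, dict):
            violations.append(f"'{key}' must map positions to plane files")
            return None
        out: Dict[int, Dict[str, Path]] = {}
        for pos_key, planes in block.items():
            try:
                pos = int(pos_key)
            except (TypeError, ValueError):
                violations.append(f"{key}: position {pos_key!r} is not an integer")
                continue
            if not isinstance(planes, dict):
                violations.append(f"{key}: position {pos} must map plane -> file")
                continue
            out[pos] = {}
            for plane in PLANE_KEYS:
                if plane not in planes:
                    if require_all:
                        violations.append(
                            f"{key}: position {pos} missing plane {plane!r}"
                        )
                    continue
                path = (base_dir / str(planes[plane])).resolve()
                if not path.exists():
                    violations.append(f"{key}: position {pos} plane {plane!r}: no such file {path}")
                out[pos][plane] = path
            extra = set(planes) - set(PLANE_KEYS)
            if extra:
                violations.append(f"{key}: position {pos} has unknown plane(s) {sorted(extra)}")
        return out or None

    manifest = parse_manifest("positions", require_all=True)
    peak_manifest = parse_manifest("peaklists", require_all=True)

    pca_opts = PCAOptions(**(doc.get("pca") or {})) if isinstance(doc.get("pca", {}), dict) else PCAOptions()
    if pca_opts.centering not in ("none", "mean", "reference"):
        violations.append(f"pca.centering invalid: {pca_opts.centering!r}")
    if not 1 <= pca_opts.component <= 5:
        violations.append(f"pca.component must lie in 1..5, got {pca_opts.component}")
    sia_doc = doc.get("sia") or {}
    sia_opts = SIAOptions(
        alpha=float(sia_doc.get("alpha", 0.2)),
        selected_ids=list(sia_doc["selected_ids"]) if "selected_ids" in sia_doc else None,
        n_selected=int(sia_doc.get("n_selected", 10)),
    )
    out_dir = Path(doc.get("output_dir", "siapca_out"))
    if not out_dir.is_absolute():
        out_dir = base_dir / out_dir
    fmt = doc.get("format", "matrix")
    if fmt not in ("matrix", "nmrpipe2d"):
        violations.append(f"format must be 'matrix' or 'nmrpipe2d', got {fmt!r}")
    if violations:
        return None, violations
    return (
        RunConfig(
            mode=mode,
            output_dir=out_dir,
            simulation=simulation,
            manifest=manifest,
            peak_manifest=peak_manifest,
            spectrum_format=fmt,
            pca=pca_opts,
            sia=sia_opts,
        ),
        [],
    )


def validate_config(path) -> Tuple[Optional[RunConfig], List[str]]:
    """Parse and validate a YAML run config.

    Returns ``(RunConfig, [])`` on success or ``(None, violations)`` with
    every violation listed (validation is not fail-fast). An unparseable
    file raises :class:`ConfigurationError` with the parser's line info.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such config file: {path}")
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from None
    return _violations_of(doc, path.parent)


@dataclass
class RunResult:
    pca_table: PreferenceTable
    sia_table: Optional[PreferenceTable]
    comparison: Optional[manual_mod.ComparisonReport]
    pca_results: Dict[int, PCAResult]
    output_dir: Path


def _auto_select_ids(
    free: PeakList, bound_by_position: Dict[int, Dict[str, PeakList]], n: int, alpha: float
) -> List[str]:
    """Pick the n peaks with the largest mean weighted shift over all pools.

    Mirrors the manual practice of scoring only peaks whose binding shifts
    are large enough to measure accurately.
    """
    free_map = free.by_id()
    totals: Dict[str, float] = {pid: 0.0 for pid in free_map}
    for pools in bound_by_position.values():
        for base in BASES:
            bound_map = pools[base].by_id()
            for pid, fe in free_map.items():
                totals[pid] += manual_mod.weighted_delta(fe, bound_map[pid], alpha)
    ranked = sorted(totals, key=lambda pid: (-totals[pid], pid))
    return ranked[: max(1, min(n, len(ranked)))]


def _write_outputs(cfg: RunConfig, result: RunResult, log: logging.Logger) -> None:
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    var_rows = []
    for pos, diag in sorted(result.pca_table.diagnostics.items()):
        for comp, pct in diag["variance_table"]:
            var_rows.append({"position": pos, "component": comp, "variance_pct": pct})
    pd.DataFrame(var_rows).to_csv(out / "variance_table.csv", index=False, float_format="%.6f")
    result.pca_table.to_frame().to_csv(out / "pca_scores.csv", index=False, float_format="%.8f")
    hist = result.pca_table.to_frame()[["position", "base", "abs_score"]].rename(
        columns={"abs_score": "bar_height"}
    )
    if result.sia_table is not None:
        result.sia_table.to_frame().to_csv(
            out / "sia_scores.csv", index=False, float_format="%.8f"
        )
        sia_hist = result.sia_table.to_frame()[["position", "base", "score"]]
        hist = hist.merge(
            sia_hist.rename(columns={"score": "sia_bar_height"}),
            on=["position", "base"],
        )
    hist.to_csv(out / "histogram_data.csv", index=False, float_format="%.8f")
    if result.comparison is not None:
        (out / "comparison.json").write_text(
            json.dumps(result.comparison.to_dict(), indent=2, sort_keys=True) + "\n"
        )
    for pos, diag in sorted(result.pca_table.diagnostics.items()):
        flag = diag["reliability"]
        log.info("position %d: %s (%s)", pos, "reliable" if flag.reliable else "UNRELIABLE", flag.message)


def run(cfg: RunConfig, write_spectra: bool = False) -> RunResult:
    """Execute a validated run config end to end and write the artifacts."""
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("siapca.pipeline")
    handler = logging.FileHandler(cfg.output_dir / "run_log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        sia_table = None
        comparison = None
        if cfg.mode == "simulate+analyze":
            sim_cfg = cfg.simulation or sim_mod.SimulationConfig()
            log.info("simulate+analyze: seed=%d grid=%s n_peaks=%d", sim_cfg.seed, sim_cfg.grid, sim_cfg.n_peaks)
            sim = sim_mod.simulate_sia_experiment(sim_cfg)
            stacks = sim.stacks
            if write_spectra:
                spec_dir = cfg.output_dir / "spectra"
                spec_dir.mkdir(exist_ok=True)
                for pos, stack in stacks.items():
                    for plane_label, plane in zip(stack.plane_labels, stack.planes()):
                        fname = spec_dir / f"pos{pos}_{plane_label}.{'ft2' if cfg.spectrum_format == 'nmrpipe2d' else 'mat'}"
                        write_spectrum(plane, fname, format=cfg.spectrum_format)
                        log.info("wrote %s", fname)
            selected = cfg.sia.selected_ids or _auto_select_ids(
                sim.free_peaks, sim.bound_peaks, cfg.sia.n_selected, cfg.sia.alpha
            )
            log.info("manual SIA peaks: %s", ",".join(selected))
            sia_table = manual_mod.sia_preference_table(
                {pos: sim.free_peaks for pos in stacks},
                sim.bound_peaks,
                selected,
                alpha=cfg.sia.alpha,
            )
        else:
            stacks = {}
            for pos, planes in sorted(cfg.manifest.items()):
                log.info("position %d: reading %d planes", pos, len(planes))
                spectra = {
                    plane: read_spectrum(path, format=cfg.spectrum_format)
                    for plane, path in planes.items()
                }
                stacks[pos] = stack_ensemble(
                    spectra["free"], {b: spectra[b] for b in BASES}, pos
                )
            if cfg.peak_manifest:
                free_by_pos = {}
                bound_by_pos = {}
                for pos, planes in sorted(cfg.peak_manifest.items()):
                    free_by_pos[pos] = read_peaklist(planes["free"])
                    bound_by_pos[pos] = {b: read_peaklist(planes[b]) for b in BASES}
                selected = cfg.sia.selected_ids or _auto_select_ids(
                    free_by_pos[min(free_by_pos)], bound_by_pos, cfg.sia.n_selected, cfg.sia.alpha
                )
                sia_table = manual_mod.sia_preference_table(
                    free_by_pos, bound_by_pos, selected, alpha=cfg.sia.alpha
                )

        pca_table, pca_results = pca_preference_table(
            stacks,
            component=cfg.pca.component,
            centering=cfg.pca.centering,
            ratio_threshold=cfg.pca.ratio_threshold,
            tol=cfg.pca.tol,
            max_iter=cfg.pca.max_iter,
        )
        if sia_table is not None:
            comparison = manual_mod.compare_methods(pca_table, sia_table)
            log.info(
                "best shift-correlating component: %d", comparison.best_component()
            )
        result = RunResult(
            pca_table=pca_table,
            sia_table=sia_table,
            comparison=comparison,
            pca_results=pca_results,
            output_dir=cfg.output_dir,
        )
        _write_outputs(cfg, result, log)
        return result
    finally:
        log.removeHandler(handler)
        handler.close()
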