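"""Simulation driver: the latency -> distraction -> consolidation loop.

Per distraction action (two per day, 12 h apart): stretch the callus to the
new gap by remeshing, map all tissue and stress fields onto the new mesh
(freshly distracted slab initialized to unperfused connective tissue), solve
the viscoelastic increment-and-hold event, feed the peak strain invariants
and the Gaussian-kernel neighborhood aggregates to the fuzzy controller, and
update tissue state and material properties.  After the last action the
external fixator is calibrated so the all-connective-tissue construct yields
the reference interfragmentary movement (IFM) under the consolidation load;
each consolidation day then applies that load once, records the IFM, and
runs one regulation step.  Bony bridging is declared at the first
consolidation day with IFM below 0.05 mm.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fem import (LoadCase, ResidualState, calibrate_fixator,
                  element_materials_from_state, interfragmentary_movement,
                  solve_event, strain_invariants)
from .materials import MaterialLibrary, PronyModel
from .mesh import (FieldTransferSpec, Geometry, Mesh, REGION_CALLUS,
                   REGION_CORTEX, REGION_MARROW, build_mesh, remesh,
                   transfer_fields)
from .protocols import Protocol, parse_protocol
from .regulation import (RegulationInput, RuleBase, apply_regulation,
                         bone_source_field, default_rule_base, evaluate_rules,
                         neighborhood_aggregate, perfusion_source_field)
from .vtkio import write_vtk

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulationState",
    "SimulationResult",
    "initialize",
    "run",
    "detect_bridging",
    "bone_area",
    "compare_protocols",
    "BRIDGING_IFM_MM",
]

#: IFM below this value indicates bony bridging (mm).
BRIDGING_IFM_MM = 0.05


@dataclass
class SimulationConfig:
    """Everything one run needs; defaults reproduce the reference setup."""

    geometry: Geometry = field(default_factory=Geometry)
    library: MaterialLibrary = field(default_factory=MaterialLibrary)
    rules: RuleBase = field(default_factory=default_rule_base)
    protocol: str = "control"
    fixator_target_ifm: float = 0.5      # mm, reference dynamic fixation
    consolidation_load: float = 500.0    # N, daily axial walking load
    element_size: float = 0.25           # mm, callus discretization
    bone_element_size: float | None = None   # defaults to 2 x element_size
    kernel_sigma: float | None = None        # defaults to element_size
    distraction_hold_s: float = 43200.0
    end_day: int = 120
    output_every_days: int = 7
    plateau_days: int = 7                # stop after bridging + flat IFM
    plateau_tol_mm: float = 1e-3

    def __post_init__(self) -> None:
        if self.element_size <= 0:
            raise ValueError("element size must be > 0")
        if self.fixator_target_ifm <= 0:
            raise ValueError("fixator target IFM must be > 0")
        if self.consolidation_load <= 0:
            raise ValueError("consolidation load must be > 0")

    @property
    def sigma(self) -> float:
        return self.kernel_sigma if self.kernel_sigma is not None else self.element_size

    @property
    def bone_size(self) -> float:
        return (self.bone_element_size if self.bone_element_size is not None
                else 2.0 * self.element_size)

    def parsed_protocol(self) -> Protocol:
        proto = parse_protocol(self.protocol, consolidation_end=self.end_day)
        if self.end_day < proto.distraction_end_day:
            raise ValueError(
                f"end day {self.end_day} precedes the distraction end "
                f"{proto.distraction_end_day}")
        return proto

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "geometry": {k: getattr(self.geometry, k) for k in
                         ("endosteal_diameter", "periosteal_diameter",
                          "initial_gap", "fragment_length", "current_gap")},
            "library": {k: getattr(self.library, k) for k in
                        ("E_conn", "nu_conn", "E_cart", "nu_cart",
                         "E_woven", "nu_woven", "E_cort", "nu_cort")},
            "prony": {"g": list(self.library.callus_prony.g),
                      "tau": list(self.library.callus_prony.tau)},
            "rules": self.rules.to_dict(),
            "protocol": self.protocol,
            "fixator_target_ifm": self.fixator_target_ifm,
            "consolidation_load": self.consolidation_load,
            "element_size": self.element_size,
            "bone_element_size": self.bone_element_size,
            "kernel_sigma": self.kernel_sigma,
            "distraction_hold_s": self.distraction_hold_s,
            "end_day": self.end_day,
            "output_every_days": self.output_every_days,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        kwargs = dict(d)
        geo = kwargs.pop("geometry", None)
        lib = kwargs.pop("library", None)
        prony = kwargs.pop("prony", None)
        rules = kwargs.pop("rules", None)
        cfg_geo = Geometry(**geo) if geo else Geometry()
        lib_kwargs = dict(lib) if lib else {}
        if prony:
            lib_kwargs["callus_prony"] = PronyModel(
                g=tuple(prony["g"]), tau=tuple(prony["tau"]))
        cfg_lib = MaterialLibrary(**lib_kwargs)
        cfg_rules = RuleBase.from_dict(rules) if rules else default_rule_base()
        return cls(geometry=cfg_geo, library=cfg_lib, rules=cfg_rules, **kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class SimulationState:
    """Mutable per-day state of a run."""

    mesh: Mesh
    conc: np.ndarray          # (n_elem, 4) % columns conn/cart/bone/cort
    perfusion: np.ndarray     # (n_elem,) %
    residual: ResidualState
    day: float
    gap: float

    def check(self) -> None:
        total = self.conc.sum(axis=1)
        if np.any(np.abs(total - 100.0) > 1e-6):
            raise AssertionError("tissue concentrations do not sum to 100")
        if np.any(self.conc < -1e-9) or np.any(self.perfusion < -1e-9) \
                or np.any(self.perfusion > 100 + 1e-9):
            raise AssertionError("state out of bounds")


@dataclass
class SimulationResult:
    """Time series and summary of one run."""

    label: str
    ifm_series: list[tuple[float, float]]
    bone_area_series: list[tuple[float, float]]
    concentration_series: list[tuple[float, float, float, float]]  # day, bone, cart, perf means
    bridging_day: float | None
    fixator_stiffness: float
    final_state: SimulationState

    def bone_area_at(self, day: float) -> float:
        """Bone area (mm^2) at the last record on or before ``day``."""
        best = 0.0
        for d, a in self.bone_area_series:
            if d <= day:
                best = a
        return best

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.ifm_series, columns=["day", "ifm_mm"]).to_csv(
            out / "ifm.csv", index=False)
        pd.DataFrame(self.bone_area_series, columns=["day", "bone_area_mm2"]
                     ).to_csv(out / "bone_area.csv", index=False)
        pd.DataFrame(self.concentration_series,
                     columns=["day", "mean_bone_pct", "mean_cartilage_pct",
                              "mean_perfusion_pct"]
                     ).to_csv(out / "concentrations.csv", index=False)
        summary = {
            "protocol": self.label,
            "bridging_day": self.bridging_day,
            "fixator_stiffness_n_per_mm": self.fixator_stiffness,
            "final_bone_area_mm2": (self.bone_area_series[-1][1]
                                    if self.bone_area_series else 0.0),
        }
        (out / "result.json").write_text(json.dumps(summary, indent=2))


def initialize(config: SimulationConfig) -> SimulationState:
    """Initial state at the end of latency.

    The callus starts as 100 % connective tissue with no perfusion; marrow
    and cortex are fully perfused, the cortex fully mineralized.
    """
    geo = replace(config.geometry, current_gap=config.geometry.initial_gap)
    mesh = build_mesh(geo, config.element_size, config.bone_size)
    n = mesh.n_elements
    conc = np.zeros((n, 4))
    conc[:, 0] = 100.0                       # connective everywhere...
    cortex = mesh.region == REGION_CORTEX
    conc[cortex, 0] = 0.0
    conc[cortex, 3] = 100.0                  # ...except the intact cortex
    perf = np.where(mesh.region == REGION_CALLUS, 0.0, 100.0)
    residual = ResidualState.zero(n, len(config.library.callus_prony.g))
    proto = config.parsed_protocol()
    return SimulationState(mesh=mesh, conc=conc, perfusion=perf,
                           residual=residual, day=float(proto.latency_days),
                           gap=geo.initial_gap)


def _regulation_step(state: SimulationState, config: SimulationConfig,
                     eps_dil: np.ndarray, gamma: np.ndarray,
                     dt_days: float) -> None:
    mesh = state.mesh
    cal = mesh.callus
    nb_perf = neighborhood_aggregate(
        mesh, perfusion_source_field(mesh, state.perfusion), config.sigma)
    nb_bone = neighborhood_aggregate(
        mesh, bone_source_field(mesh, state.conc), config.sigma)
    inp = RegulationInput(
        eps_dil=eps_dil[cal], gamma_dist=gamma[cal],
        perfusion=state.perfusion[cal],
        c_cart=state.conc[cal, 1], c_bone=state.conc[cal, 2],
        neighbor_perfusion=np.clip(nb_perf[cal], 0, 100),
        neighbor_bone=np.clip(nb_bone[cal], 0, 100))
    out = evaluate_rules(inp, config.rules)
    new_conc, new_perf = apply_regulation(state.conc[cal], state.perfusion[cal],
                                          out, dt_days)
    state.conc[cal] = new_conc
    state.perfusion[cal] = new_perf
    state.check()


_TISSUE_FIELDS = ("c_conn", "c_cart", "c_bone", "c_cort", "perfusion")


def _advance_mesh(state: SimulationState, config: SimulationConfig,
                  new_gap: float) -> None:
    """Remesh to ``new_gap`` and map tissue + stress state onto the new mesh."""
    old = state.mesh
    new = remesh(old, new_gap, config.element_size, config.bone_size)
    fields = {
        "c_conn": state.conc[:, 0], "c_cart": state.conc[:, 1],
        "c_bone": state.conc[:, 2], "c_cort": state.conc[:, 3],
        "perfusion": state.perfusion,
    }
    fields.update(state.residual.as_fields())
    fresh = {"c_conn": 100.0, "c_cart": 0.0, "c_bone": 0.0, "c_cort": 0.0,
             "perfusion": 0.0}
    fresh.update({k: 0.0 for k in state.residual.as_fields()})
    spec = FieldTransferSpec(sigma=config.sigma)
    mapped = transfer_fields(old, fields, new, spec, fresh_slab_values=fresh)

    conc = np.column_stack([mapped[k] for k in _TISSUE_FIELDS[:4]])
    # transfer smooths across region boundaries: restore exact region states
    cortex = new.region == REGION_CORTEX
    conc[cortex] = (0.0, 0.0, 0.0, 100.0)
    marrow = new.region == REGION_MARROW
    conc[marrow] = (100.0, 0.0, 0.0, 0.0)
    conc = np.clip(conc, 0.0, None)
    conc *= 100.0 / conc.sum(axis=1, keepdims=True)
    perf = np.clip(mapped["perfusion"], 0.0, 100.0)
    perf[cortex | marrow] = 100.0

    nb = state.residual.q.shape[1]
    state.residual = ResidualState.from_fields(mapped, nb)
    state.mesh = new
    state.conc = conc
    state.perfusion = perf
    state.gap = new_gap


def bone_area(state: SimulationState, mesh: Mesh | None = None) -> float:
    """Regenerated bone area in the callus (r-z plane, mm^2)."""
    mesh = mesh if mesh is not None else state.mesh
    cal = mesh.callus
    areas = mesh.element_areas()
    return float(np.sum(state.conc[cal, 2] / 100.0 * areas[cal]))


def detect_bridging(ifm_series, threshold: float = BRIDGING_IFM_MM):
    """First day with IFM below ``threshold``; None if never reached."""
    for day, ifm in ifm_series:
        if ifm < threshold:
            return day
    return None


def run(config: SimulationConfig, outdir=None) -> SimulationResult:
    """Run one protocol end to end.  Deterministic for a fixed config."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
    proto = config.parsed_protocol()
    state = initialize(config)
    lib = config.library
    tau = lib.callus_prony.tau
    ifm_series: list[tuple[float, float]] = []
    area_series: list[tuple[float, float]] = []
    conc_series: list[tuple[float, float, float, float]] = []

    def record(day: float) -> None:
        cal = state.mesh.callus
        area_series.append((day, bone_area(state)))
        conc_series.append((day, float(state.conc[cal, 2].mean()),
                            float(state.conc[cal, 1].mean()),
                            float(state.perfusion[cal].mean())))
        if out is not None and config.output_every_days > 0 \
                and int(day) % config.output_every_days == 0:
            write_vtk(out / f"day_{int(day):03d}.vtk", state.mesh, {
                "bone_pct": state.conc[:, 2], "cartilage_pct": state.conc[:, 1],
                "connective_pct": state.conc[:, 0],
                "perfusion_pct": state.perfusion})

    record(state.day)

    # ---- distraction phase ---------------------------------------------
    for day, time_h, inc in proto.actions():
        _advance_mesh(state, config, state.gap + inc)
        mats = element_materials_from_state(state.mesh, state.conc, lib)
        case = LoadCase.distraction(inc, hold_time=config.distraction_hold_s)
        sol = solve_event(state.mesh, mats, None, case,
                          initial_state=state.residual)
        eps_dil, gamma = strain_invariants(sol)
        _regulation_step(state, config, eps_dil, gamma, dt_days=0.5)
        state.residual = sol.residual
        state.day = day + (time_h % 24.0) / 24.0
        logger.info("day %.1f: action %.2f mm, gap %.2f mm", state.day, inc,
                    state.gap)
        if time_h % 24.0 == 12.0:
            record(day + 1)

    # ---- fixator calibration at the end-of-distraction configuration ---
    conc_ref = state.conc.copy()
    cal = state.mesh.callus
    conc_ref[cal] = (100.0, 0.0, 0.0, 0.0)   # all-connective reference state
    mats_ref = element_materials_from_state(state.mesh, conc_ref, lib)
    fixator = calibrate_fixator(state.mesh, mats_ref, config.fixator_target_ifm,
                                config.consolidation_load)
    k_fix = fixator.table[0][1] / fixator.table[0][0]
    logger.info("fixator calibrated: %.1f N/mm", k_fix)

    # ---- consolidation phase -------------------------------------------
    flat = 0
    for day in range(proto.distraction_end_day, config.end_day + 1):
        state.residual = state.residual.decayed(86400.0, tau)
        mats = element_materials_from_state(state.mesh, state.conc, lib)
        sol = solve_event(state.mesh, mats, fixator,
                          LoadCase.consolidation(config.consolidation_load),
                          initial_state=state.residual)
        ifm = interfragmentary_movement(sol)
        ifm_series.append((float(day), ifm))
        eps_dil, gamma = strain_invariants(sol)
        _regulation_step(state, config, eps_dil, gamma, dt_days=1.0)
        state.day = float(day)
        record(float(day))

        if len(ifm_series) >= 2 and \
                abs(ifm_series[-1][1] - ifm_series[-2][1]) < config.plateau_tol_mm:
            flat += 1
        else:
            flat = 0
        bridged = detect_bridging(ifm_series) is not None
        if bridged and flat >= config.plateau_days:
            logger.info("day %d: bridged and IFM plateaued, stopping", day)
            break

    result = SimulationResult(
        label=proto.label,
        ifm_series=ifm_series,
        bone_area_series=area_series,
        concentration_series=conc_series,
        bridging_day=detect_bridging(ifm_series),
        fixator_stiffness=k_fix,
        final_state=state)
    if out is not None:
        result.write(out)
    return result


def compare_protocols(labels: list[str], config: SimulationConfig,
                      outdir=None) -> dict:
    """Run several protocols under a shared config and rank the outcomes.

    Reports per-protocol bridging day and bone areas at weeks 3/6/9, plus the
    ordering relative to the control (when present).  Individual failures are
    reported without aborting the remaining runs.
    """
    if len(labels) < 2:
        raise ValueError("need at least two protocols to compare")
    report: dict = {"protocols": {}, "errors": {}}
    results: dict[str, SimulationResult] = {}
    for label in labels:
        cfg = replace(config, protocol=label)
        try:
            res = run(cfg, outdir=None if outdir is None
                      else Path(outdir) / label)
        except Exception as exc:  # propagate per-run failures in the report
            logger.exception("protocol %s failed", label)
            report["errors"][label] = str(exc)
            continue
        results[label] = res
        report["protocols"][label] = {
            "bridging_day": res.bridging_day,
            "bone_area_week3_mm2": res.bone_area_at(21.0),
            "bone_area_week6_mm2": res.bone_area_at(42.0),
            "bone_area_week9_mm2": res.bone_area_at(63.0),
        }
    if "control" in results:
        ctrl = results["control"].bridging_day
        for label, res in results.items():
            if label == "control" or res.bridging_day is None or ctrl is None:
                continue
            entry = report["protocols"][label]
            entry["vs_control_days"] = res.bridging_day - ctrl
            entry["faster_than_control"] = res.bridging_day < ctrl
    return report
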