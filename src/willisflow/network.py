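"""Arterial network data model, configuration I/O and input-vector mapping.

The network couples a tree of compliant 1D artery segments (with optional
stenosis interfaces on the internal carotids), three-element Windkessel
outlet loads, lumped RLC body blocks and a time-varying-elastance heart into
a single closed loop.  Two builders are shipped: the 83-segment systemic
tree including the circle of Willis, and a 5-segment toy loop for
desk-scale experiments.  Both carry a machine-readable manifest describing
the slots of the model input vector (diameters, lengths, outlet peripheral
resistances, total-PR scaling, age, stenosis parameters) and of the
cycle-averaged output vector.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import _defaults as dflt


class ConfigurationError(ValueError):
    """A network config violates the schema or an invariant."""


class TopologyError(ConfigurationError):
    """The junction graph is inconsistent or disconnected."""


class LayoutError(ValueError):
    """An input/output vector does not match the network's manifest."""


def eh_from_radius(r0_m: float, law=dflt.EH_LAW) -> float:
    """Wall stiffness Eh (Pa.m) from lumen radius (m).

    Exponential-plus-constant empirical fit: Eh = r0*(k1*exp(k2*r0) + k3).
    """
    k1, k2, k3 = law
    return r0_m * (k1 * math.exp(k2 * r0_m) + k3)


@dataclass
class ArterySegment:
    id: int
    name: str
    length: float              # mm
    diameter: float            # mm, lumen at reference pressure
    Eh: float                  # Pa.m
    P0: float = 85.0           # mmHg reference pressure
    poisson_ratio: float = 0.5
    n_nodes: int = 0           # 0 = derive from solver grid settings

    @property
    def A0(self) -> float:
        """Reference cross-sectional area, mm^2."""
        return math.pi * (self.diameter / 2.0) ** 2

    def validate(self) -> None:
        if not self.length > 0:
            raise ConfigurationError(f"segment {self.id}: length must be > 0")
        if not self.diameter > 0:
            raise ConfigurationError(f"segment {self.id}: diameter must be > 0")
        if not self.Eh > 0:
            raise ConfigurationError(f"segment {self.id}: Eh must be > 0")
        if self.n_nodes and (self.n_nodes < 3 or self.n_nodes % 2 == 0):
            raise ConfigurationError(
                f"segment {self.id}: n_nodes must be odd and >= 3")


@dataclass
class StenosisSpec:
    """Pressure-loss model parameters for one stenosed host segment.

    An intact specification (Rv = SR = Kt = 0, Dn = host diameter) produces
    zero pressure loss and is not inserted into the solver.
    """
    host_segment_id: int
    Rv: float                  # mmHg.s/mL viscous resistance
    Dn: float                  # mm, maximum diameter distal to the stenosis
    SR: float                  # fraction in [0, 1)
    Kt: float                  # turbulent/separation coefficient
    Ku: float = 1.2            # pulsatility coefficient
    Ls: float = dflt.STENOSIS_LS_DEFAULT   # mm

    def validate(self) -> None:
        if self.Rv < 0 or self.Kt < 0 or not (0 <= self.SR < 1) or self.Dn <= 0:
            raise ConfigurationError(
                f"stenosis on segment {self.host_segment_id}: invalid parameters")

    @property
    def is_intact(self) -> bool:
        return self.Rv == 0.0 and self.SR == 0.0 and self.Kt == 0.0


@dataclass
class WindkesselOutlet:
    segment_id: int
    R_proximal: float          # mmHg.s/mL
    compliance: float          # mL/mmHg
    R_distal: float            # mmHg.s/mL
    is_cow_outlet: bool = False
    body_block: str = "upper"

    @property
    def PR(self) -> float:
        return self.R_proximal + self.R_distal

    def set_PR(self, pr: float, proximal_fraction: float) -> None:
        self.R_proximal = pr * proximal_fraction
        self.R_distal = pr * (1.0 - proximal_fraction)

    def validate(self) -> None:
        if self.R_proximal <= 0 or self.R_distal <= 0 or self.compliance <= 0:
            raise ConfigurationError(
                f"outlet at segment {self.segment_id}: R, C must be > 0")


@dataclass
class LumpedCompartment:
    name: str
    R: float                   # mmHg.s/mL
    L: float                   # mmHg.s^2/mL
    C: float                   # mL/mmHg

    def validate(self) -> None:
        if self.R <= 0 or self.L <= 0 or self.C <= 0:
            raise ConfigurationError(f"block {self.name}: R, L, C must be > 0")


@dataclass
class HeartModel:
    E_max_lv: float            # mmHg/mL
    E_min_lv: float
    V0_lv: float               # mL
    E_max_la: float
    E_min_la: float
    V0_la: float
    Ts_lv: float               # s
    t_la: float                # s
    Ts_la: float               # s
    R_mv: float                # mmHg.s/mL
    R_av: float
    cardiac_period: float = 1.0

    def validate(self) -> None:
        if not (self.E_max_lv > self.E_min_lv > 0):
            raise ConfigurationError("heart: require E_max > E_min > 0")
        if not (self.E_max_la > self.E_min_la > 0):
            raise ConfigurationError("heart: require E_max > E_min > 0 (atrium)")
        if self.cardiac_period != 1.0:
            raise ConfigurationError("heart: cardiac period is fixed at 1 s")


@dataclass
class InputSlot:
    name: str
    kind: str                  # diameter|length|pr_cow|pr_scale|age|sten_*
    target: int                # segment id (or -1)
    side: str = ""             # "left"/"right" for stenosis slots
    lower: float = 0.0
    upper: float = 0.0
    unit: str = ""


@dataclass
class OutputSlot:
    name: str
    kind: str                  # qbar | pbar | map
    target: int                # segment id
    unit: str = ""


@dataclass
class VascularNetwork:
    segments: list[ArterySegment]
    junctions: list[list[tuple[int, str]]]
    outlets: list[WindkesselOutlet]
    body_blocks: list[LumpedCompartment]
    heart: HeartModel
    stenoses: list[StenosisSpec] = field(default_factory=list)
    inlet_segment_id: int = 0
    cow_inlet_ids: list[int] = field(default_factory=list)
    cow_outlet_ids: list[int] = field(default_factory=list)
    cow_segment_ids: list[int] = field(default_factory=list)
    aortic_ids: list[int] = field(default_factory=list)
    stenosis_hosts: dict[str, int] = field(default_factory=dict)
    map_segment_id: int = 0
    age: float = dflt.REFERENCE_AGE
    pr_proximal_fraction: float = dflt.PR_PROXIMAL_FRACTION
    eh_law: tuple = dflt.EH_LAW
    age_table: dict = field(default_factory=lambda: copy.deepcopy(dflt.AGE_TABLE))
    reference_age: float = dflt.REFERENCE_AGE
    base_outlet_pr: dict[int, float] = field(default_factory=dict)
    aortic_ref: dict[int, tuple[float, float]] = field(default_factory=dict)
    input_manifest: list[InputSlot] = field(default_factory=list)
    output_manifest: list[OutputSlot] = field(default_factory=list)

    # -- lookups ----------------------------------------------------
    def segment(self, sid: int) -> ArterySegment:
        for s in self.segments:
            if s.id == sid:
                return s
        raise KeyError(f"no segment with id {sid}")

    def outlet(self, sid: int) -> WindkesselOutlet:
        for o in self.outlets:
            if o.segment_id == sid:
                return o
        raise KeyError(f"no outlet at segment {sid}")

    def stenosis_on(self, sid: int) -> StenosisSpec | None:
        for st in self.stenoses:
            if st.host_segment_id == sid:
                return st
        return None

    @property
    def n_inputs(self) -> int:
        return len(self.input_manifest)

    @property
    def n_outputs(self) -> int:
        return len(self.output_manifest)

    # -- validation -------------------------------------------------
    def validate(self) -> None:
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate segment ids")
        idset = set(ids)
        for s in self.segments:
            s.validate()
        for o in self.outlets:
            o.validate()
            if o.segment_id not in idset:
                raise TopologyError(f"outlet references missing segment {o.segment_id}")
        for st in self.stenoses:
            st.validate()
            if st.host_segment_id not in idset:
                raise TopologyError(
                    f"stenosis references missing segment {st.host_segment_id}")
        for b in self.body_blocks:
            b.validate()
        self.heart.validate()

        # each proximal end connects exactly once (junction or inlet);
        # each distal end connects exactly once (junction or outlet).
        prox = {self.inlet_segment_id: 1}
        dist = {o.segment_id: 1 for o in self.outlets}
        for jn in self.junctions:
            if len(jn) < 2:
                raise TopologyError("junction with fewer than two ends")
            for sid, end in jn:
                if sid not in idset:
                    raise TopologyError(f"junction references missing segment {sid}")
                if end == "p":
                    prox[sid] = prox.get(sid, 0) + 1
                elif end == "d":
                    dist[sid] = dist.get(sid, 0) + 1
                else:
                    raise ConfigurationError(f"junction end must be 'p' or 'd', got {end!r}")
        for sid in idset:
            if prox.get(sid, 0) != 1:
                raise TopologyError(f"segment {sid}: proximal end connected "
                                    f"{prox.get(sid, 0)} times (expected 1)")
            if dist.get(sid, 0) != 1:
                raise TopologyError(f"segment {sid}: distal end connected "
                                    f"{dist.get(sid, 0)} times (expected 1)")

        # connectivity of the segment graph through junctions
        adj: dict[int, set[int]] = {sid: set() for sid in idset}
        for jn in self.junctions:
            sids = [sid for sid, _ in jn]
            for a in sids:
                for b in sids:
                    if a != b:
                        adj[a].add(b)
        seen = {self.inlet_segment_id}
        stack = [self.inlet_segment_id]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if seen != idset:
            raise TopologyError(
                f"network not connected: {sorted(idset - seen)} unreachable")


# ------------------------------------------------------------------
# builders
# ------------------------------------------------------------------

def _interp_factor(age: float, ages, factors) -> float:
    return float(np.interp(age, ages, factors))


def _age_factors(age: float, table: dict) -> tuple[float, float]:
    return (_interp_factor(age, table["ages"], table["eh_factor"]),
            _interp_factor(age, table["ages"], table["diameter_factor"]))


def _build_from_tables(segments_tbl, junctions, outlet_fractions, cow_outlets,
                       cow_inlets, cerebral_ids, stenosis_hosts, map_segment,
                       inlet_segment, age: float,
                       heart_params=None, block_params=None,
                       co_ref: float = dflt.CO_REF) -> VascularNetwork:
    lo, hi = 25.0, 90.0
    if not (lo <= age <= hi):
        raise ValueError(f"age {age} outside supported range [{lo}, {hi}]")

    eh_f, d_f = _age_factors(age, dflt.AGE_TABLE)
    segments, aortic_ids, aortic_ref = [], [], {}
    for sid, name, length, diam, group in segments_tbl:
        eh_ref = eh_from_radius(diam / 2.0 * 1e-3)
        d, eh = diam, eh_ref
        if group == "aorta":
            aortic_ids.append(sid)
            aortic_ref[sid] = (diam, eh_ref)
            d, eh = diam * d_f, eh_ref * eh_f
        segments.append(ArterySegment(id=sid, name=name, length=length,
                                      diameter=d, Eh=eh))

    total_frac = sum(f for f, _ in outlet_fractions.values())
    dp = dflt.MAP_REF - dflt.P_VENOUS_REF
    outlets, base_pr = [], {}
    for sid, (frac, block) in outlet_fractions.items():
        frac = frac / total_frac
        pr = dp / (co_ref * frac)
        o = WindkesselOutlet(segment_id=sid, R_proximal=0.0, compliance=0.0,
                             R_distal=0.0, is_cow_outlet=sid in cow_outlets,
                             body_block=block)
        o.set_PR(pr, dflt.PR_PROXIMAL_FRACTION)
        o.compliance = dflt.WK_TIME_CONSTANT / pr
        outlets.append(o)
        base_pr[sid] = pr

    blocks = [LumpedCompartment(name=k, **v)
              for k, v in (block_params or dflt.BODY_BLOCKS).items()]
    heart = HeartModel(**(heart_params or dflt.HEART))

    net = VascularNetwork(
        segments=segments, junctions=[list(j) for j in junctions],
        outlets=outlets, body_blocks=blocks, heart=heart,
        inlet_segment_id=inlet_segment, cow_inlet_ids=list(cow_inlets),
        cow_outlet_ids=list(cow_outlets), cow_segment_ids=list(cerebral_ids),
        aortic_ids=aortic_ids, stenosis_hosts=dict(stenosis_hosts),
        map_segment_id=map_segment, age=age, base_outlet_pr=base_pr,
        aortic_ref=aortic_ref)
    return net


def _full_input_manifest(net: VascularNetwork) -> list[InputSlot]:
    """The 60-slot input layout: 22 diameters, 22 lengths, 6 CoW outlet PRs,
    total-PR scaling factor, age, left/right stenosis {Rv, Dn, SR}, then
    left/right Kt."""
    from .design import DIAMETER_RANGES, LENGTH_RANGES, PR_RANGES
    slots = []
    for sid in net.cow_segment_ids:
        name = net.segment(sid).name
        lo, hi = DIAMETER_RANGES[name]
        slots.append(InputSlot(f"D: {name}", "diameter", sid, "", lo, hi, "mm"))
    for sid in net.cow_segment_ids:
        name = net.segment(sid).name
        lo, hi = LENGTH_RANGES[name]
        slots.append(InputSlot(f"L: {name}", "length", sid, "", lo, hi, "mm"))
    for sid in net.cow_outlet_ids:
        name = net.segment(sid).name
        lo, hi = PR_RANGES[name]
        slots.append(InputSlot(f"PR: {name}", "pr_cow", sid, "", lo, hi,
                               "mmHg.s/mL"))
    slots.append(InputSlot("total PR scaling", "pr_scale", -1, "", 0.5, 2.0, "-"))
    slots.append(InputSlot("age", "age", -1, "", 25.0, 90.0, "years"))
    for side in ("left", "right"):
        host = net.stenosis_hosts[side]
        slots.append(InputSlot(f"Rv ({side} ICA)", "sten_rv", host, side,
                               0.0, 500.0, "mmHg.s/mL"))
        slots.append(InputSlot(f"Dn ({side} ICA)", "sten_dn", host, side,
                               2.9, 7.0, "mm"))
        slots.append(InputSlot(f"SR ({side} ICA)", "sten_sr", host, side,
                               0.0, 0.99, "-"))
    for side in ("left", "right"):
        host = net.stenosis_hosts[side]
        slots.append(InputSlot(f"Kt ({side} ICA)", "sten_kt", host, side,
                               1.0, 2.699, "-"))
    return slots


def _output_manifest(net: VascularNetwork) -> list[OutputSlot]:
    slots = [OutputSlot(f"Qbar: {net.segment(sid).name}", "qbar", sid, "mL/min")
             for sid in net.cow_segment_ids]
    slots += [OutputSlot(f"Pbar: {net.segment(sid).name}", "pbar", sid, "mmHg")
              for sid in net.cow_segment_ids]
    slots.append(OutputSlot("MAP", "map", net.map_segment_id, "mmHg"))
    return slots


def build_default_network(age: float = dflt.REFERENCE_AGE) -> VascularNetwork:
    """The 83-segment systemic network with the circle of Willis.

    Aortic stiffness and diameter follow the piecewise-linear age mapping;
    all other segments are independent of age.
    """
    net = _build_from_tables(dflt.SEGMENTS, dflt.JUNCTIONS,
                             dflt.OUTLET_FRACTIONS, dflt.COW_OUTLETS,
                             dflt.COW_INLETS, dflt.CEREBRAL_IDS,
                             dflt.STENOSIS_HOSTS, dflt.MAP_SEGMENT,
                             dflt.INLET_SEGMENT, age)
    net.input_manifest = _full_input_manifest(net)
    net.output_manifest = _output_manifest(net)
    net.validate()
    return net


def build_toy_network(age: float = dflt.REFERENCE_AGE) -> VascularNetwork:
    """The shipped 5-segment toy loop (trunk + two branches + two outlet
    arteries, one branch hosting a stenosis)."""
    net = _build_from_tables(dflt.TOY_SEGMENTS, dflt.TOY_JUNCTIONS,
                             dflt.TOY_OUTLET_FRACTIONS, dflt.TOY_COW_OUTLETS,
                             dflt.TOY_COW_INLETS, dflt.TOY_CEREBRAL_IDS,
                             dflt.TOY_STENOSIS_HOSTS, dflt.TOY_MAP_SEGMENT,
                             dflt.TOY_INLET_SEGMENT, age,
                             heart_params=dflt.TOY_HEART,
                             block_params=dflt.TOY_BODY_BLOCKS,
                             co_ref=dflt.TOY_CO_REF)
    slots = []
    for sid in (1, 2):
        slots.append(InputSlot(f"D: seg{sid}", "diameter", sid, "", 3.5, 6.5, "mm"))
    for sid in (3, 4):
        slots.append(InputSlot(f"D: seg{sid}", "diameter", sid, "", 2.5, 4.5, "mm"))
    for sid in (1, 2):
        slots.append(InputSlot(f"L: seg{sid}", "length", sid, "", 50.0, 110.0, "mm"))
    for sid in (3, 4):
        slots.append(InputSlot(f"L: seg{sid}", "length", sid, "", 25.0, 55.0, "mm"))
    slots.append(InputSlot("PR: seg3", "pr_cow", 3, "", 2.0, 30.0, "mmHg.s/mL"))
    slots.append(InputSlot("total PR scaling", "pr_scale", -1, "", 0.5, 2.0, "-"))
    slots.append(InputSlot("Rv (left)", "sten_rv", 1, "left", 0.0, 500.0,
                           "mmHg.s/mL"))
    slots.append(InputSlot("Dn (left)", "sten_dn", 1, "left", 2.9, 7.0, "mm"))
    slots.append(InputSlot("SR (left)", "sten_sr", 1, "left", 0.0, 0.99, "-"))
    slots.append(InputSlot("Kt (left)", "sten_kt", 1, "left", 1.0, 2.699, "-"))
    net.input_manifest = slots
    net.output_manifest = _output_manifest(net)
    net.validate()
    return net


# ------------------------------------------------------------------
# input-vector application
# ------------------------------------------------------------------

def apply_input_vector(net: VascularNetwork, x: np.ndarray) -> VascularNetwork:
    """Return a new network with the manifest slots of ``x`` applied.

    Diameters/lengths overwrite the flagged cerebral segments (wall
    stiffness is re-derived from the stiffness-radius law), CoW outlet PRs
    are set directly, the scaling factor multiplies all non-CoW outlet PRs
    relative to their build-time base values, the age mapping rescales the
    aortic segments, and stenosis specs are installed on the host segments.
    Idempotent: applying the same ``x`` twice equals applying it once.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (len(net.input_manifest),):
        raise LayoutError(f"input vector has shape {x.shape}, expected "
                          f"({len(net.input_manifest)},)")
    out = copy.deepcopy(net)
    sten: dict[str, dict] = {}
    for slot, val in zip(out.input_manifest, x):
        if slot.kind == "diameter":
            seg = out.segment(slot.target)
            seg.diameter = float(val)
            seg.Eh = eh_from_radius(val / 2.0 * 1e-3, out.eh_law)
        elif slot.kind == "length":
            out.segment(slot.target).length = float(val)
        elif slot.kind == "pr_cow":
            out.outlet(slot.target).set_PR(float(val), out.pr_proximal_fraction)
        elif slot.kind == "pr_scale":
            for o in out.outlets:
                if not o.is_cow_outlet:
                    o.set_PR(out.base_outlet_pr[o.segment_id] * float(val),
                             out.pr_proximal_fraction)
        elif slot.kind == "age":
            out.age = float(val)
            eh_f, d_f = _age_factors(out.age, out.age_table)
            for sid in out.aortic_ids:
                d_ref, eh_ref = out.aortic_ref[sid]
                seg = out.segment(sid)
                seg.diameter = d_ref * d_f
                seg.Eh = eh_ref * eh_f
        elif slot.kind.startswith("sten_"):
            sten.setdefault(slot.side, {"host": slot.target})[
                slot.kind.removeprefix("sten_")] = float(val)
        else:
            raise LayoutError(f"unknown input slot kind {slot.kind!r}")

    for side, p in sten.items():
        host = p["host"]
        out.stenoses = [s for s in out.stenoses if s.host_segment_id != host]
        out.stenoses.append(StenosisSpec(host_segment_id=host, Rv=p["rv"],
                                         Dn=p["dn"], SR=p["sr"], Kt=p["kt"]))
    out.validate()
    return out


def extract_input_vector(net: VascularNetwork) -> np.ndarray:
    """Read the current manifest slot values back out of a network."""
    vals = []
    for slot in net.input_manifest:
        if slot.kind == "diameter":
            vals.append(net.segment(slot.target).diameter)
        elif slot.kind == "length":
            vals.append(net.segment(slot.target).length)
        elif slot.kind == "pr_cow":
            vals.append(net.outlet(slot.target).PR)
        elif slot.kind == "pr_scale":
            ref = next(o for o in net.outlets if not o.is_cow_outlet)
            vals.append(ref.PR / net.base_outlet_pr[ref.segment_id])
        elif slot.kind == "age":
            vals.append(net.age)
        elif slot.kind.startswith("sten_"):
            st = net.stenosis_on(slot.target)
            if st is None:
                host_d = net.segment(slot.target).diameter
                st = StenosisSpec(slot.target, 0.0, host_d, 0.0, 0.0)
            vals.append({"sten_rv": st.Rv, "sten_dn": st.Dn,
                         "sten_sr": st.SR, "sten_kt": st.Kt}[slot.kind])
    return np.array(vals, dtype=float)


# ------------------------------------------------------------------
# config I/O
# ------------------------------------------------------------------

_SCHEMA_VERSION = 1


def _net_to_dict(net: VascularNetwork) -> dict:
    return {
        "schema_version": _SCHEMA_VERSION,
        "label": "literature defaults",
        "segments": [asdict(s) for s in net.segments],
        "junctions": [[[sid, end] for sid, end in jn] for jn in net.junctions],
        "outlets": [asdict(o) for o in net.outlets],
        "body_blocks": [asdict(b) for b in net.body_blocks],
        "heart": asdict(net.heart),
        "stenoses": [asdict(st) for st in net.stenoses],
        "inlet_segment_id": net.inlet_segment_id,
        "cow_inlet_ids": net.cow_inlet_ids,
        "cow_outlet_ids": net.cow_outlet_ids,
        "cow_segment_ids": net.cow_segment_ids,
        "aortic_ids": net.aortic_ids,
        "stenosis_hosts": net.stenosis_hosts,
        "map_segment_id": net.map_segment_id,
        "age": net.age,
        "pr_proximal_fraction": net.pr_proximal_fraction,
        "eh_law": list(net.eh_law),
        "age_table": net.age_table,
        "reference_age": net.reference_age,
        "base_outlet_pr": {int(k): v for k, v in net.base_outlet_pr.items()},
        "aortic_ref": {int(k): list(v) for k, v in net.aortic_ref.items()},
        "input_manifest": [asdict(s) for s in net.input_manifest],
        "output_manifest": [asdict(s) for s in net.output_manifest],
    }


def _net_from_dict(d: dict) -> VascularNetwork:
    try:
        net = VascularNetwork(
            segments=[ArterySegment(**{k: v for k, v in s.items() if k != "A0"})
                      for s in d["segments"]],
            junctions=[[(int(sid), end) for sid, end in jn]
                       for jn in d["junctions"]],
            outlets=[WindkesselOutlet(**o) for o in d["outlets"]],
            body_blocks=[LumpedCompartment(**b) for b in d["body_blocks"]],
            heart=HeartModel(**d["heart"]),
            stenoses=[StenosisSpec(**s) for s in d.get("stenoses", [])],
            inlet_segment_id=d["inlet_segment_id"],
            cow_inlet_ids=list(d["cow_inlet_ids"]),
            cow_outlet_ids=list(d["cow_outlet_ids"]),
            cow_segment_ids=list(d["cow_segment_ids"]),
            aortic_ids=list(d["aortic_ids"]),
            stenosis_hosts=dict(d["stenosis_hosts"]),
            map_segment_id=d["map_segment_id"],
            age=d["age"],
            pr_proximal_fraction=d["pr_proximal_fraction"],
            eh_law=tuple(d["eh_law"]),
            age_table=d["age_table"],
            reference_age=d["reference_age"],
            base_outlet_pr={int(k): v for k, v in d["base_outlet_pr"].items()},
            aortic_ref={int(k): tuple(v) for k, v in d["aortic_ref"].items()},
            input_manifest=[InputSlot(**s) for s in d["input_manifest"]],
            output_manifest=[OutputSlot(**s) for s in d["output_manifest"]],
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"config schema violation: {exc}") from exc
    net.validate()
    return net


def write_network_config(net: VascularNetwork, path) -> None:
    """Serialize a network to YAML at full float precision."""
    with open(path, "w") as fh:
        yaml.safe_dump(_net_to_dict(net), fh, sort_keys=False)


def read_network_config(path) -> VascularNetwork:
    """Read a YAML network config; round-trips bit-identically with
    :func:`write_network_config` on all numeric fields."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ConfigurationError("config file does not contain a mapping")
    return _net_from_dict(d)
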