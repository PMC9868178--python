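"""Reference network specification, validation and per-sample instantiation.

The packaged reference network is a deliberately lumped description of
central hepatocyte metabolism: one representative reaction per pathway
(glycogen turnover, glycolysis, gluconeogenesis, pentose phosphate shunts,
fatty-acid uptake/synthesis/oxidation, triacylglycerol and lipid-droplet
turnover, VLDL export, cholesterol and ketone-body synthesis, TCA cycle and
oxidative phosphorylation with a GHK-type proton leak, urea cycle,
glutamate/glutamine handling, alanine/serine utilisation and an ethanol
stub) sharing common ATP and mitochondrial proton pools.  Stoichiometric
coefficients are lumped-carbon bookkeeping, but nitrogen is conserved
exactly by every reaction, which is validated at load time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

logger = logging.getLogger(__name__)

RATE_LAW_KINDS = ("mm_irr", "mm_rev", "mass_action", "ghk")
CAPACITY_RULES = ("max", "min")
CAPACITY_KINDS = ("flux", "pool")


class ModelValidationError(ValueError):
    """Raised when a model specification violates its structural contract."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str  # "internal" or "plasma"
    initial_mm: float
    n_atoms: int = 0  # nitrogen content used by the conservation audit


@dataclass(frozen=True)
class Reaction:
    id: str
    enzyme: str
    pathway: str
    kind: str
    vmax_ref: float  # µmol/g/h (permeability for GHK kind)
    stoichiometry: Mapping[str, float]
    km: Mapping[str, float] = field(default_factory=dict)  # mM
    keq: float | None = None
    inhibitors: Mapping[str, float] = field(default_factory=dict)  # Ki, mM
    phospho: tuple[float, float] | None = None  # (v_phospho, v_dephospho)
    ghk_params: Mapping[str, float] = field(default_factory=dict)

    @property
    def substrates(self) -> list[str]:
        return [m for m, s in self.stoichiometry.items() if s < 0]

    @property
    def products(self) -> list[str]:
        return [m for m, s in self.stoichiometry.items() if s > 0]


@dataclass(frozen=True)
class CapacityDef:
    """Extraction rule for one named metabolic capacity.

    ``flux`` capacities are a signed weighted sum of reaction fluxes with the
    extremum (max or min) taken over the glucose grid; the ``pool`` kind
    reports the extremal steady-state concentration of a metabolite (mM).
    """

    name: str
    kind: str
    rule: str
    terms: Mapping[str, float] = field(default_factory=dict)
    metabolite: str | None = None
    units: str = "umol/g/h"


@dataclass(frozen=True)
class ReferenceModelSpec:
    name: str
    metabolites: tuple[Metabolite, ...]
    reactions: tuple[Reaction, ...]
    capacity_defs: tuple[CapacityDef, ...]
    gamma_params: Mapping[str, float]
    ffa_params: Mapping[str, float]
    plasma_defaults: Mapping[str, float]

    def metabolite(self, mid: str) -> Metabolite:
        return self._met_index[mid]

    @property
    def _met_index(self):
        return {m.id: m for m in self.metabolites}

    @property
    def internal_metabolites(self) -> list[str]:
        return [m.id for m in self.metabolites if m.compartment == "internal"]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def enzyme_pathway_map(self) -> dict[str, str]:
        return {r.enzyme: r.pathway for r in self.reactions}


@dataclass(frozen=True)
class ProteomeProfile:
    """Per-sample relative enzyme abundances (ratios to the cohort mean)."""

    sample_id: str
    ratios: Mapping[str, float]

    def __post_init__(self):
        bad = [e for e, r in self.ratios.items() if not (r > 0)]
        if bad:
            raise ValueError(f"non-positive abundance ratio for enzyme(s): {bad}")


@dataclass(frozen=True)
class ModelInstance:
    spec: ReferenceModelSpec
    vmax: Mapping[str, float]
    sample_id: str


def _validate(spec: ReferenceModelSpec) -> None:
    mids = {m.id for m in spec.metabolites}
    problems: list[str] = []
    seen = set()
    for r in spec.reactions:
        if r.id in seen:
            problems.append(f"duplicate reaction id {r.id!r}")
        seen.add(r.id)
        if r.kind not in RATE_LAW_KINDS:
            problems.append(f"{r.id}: unknown rate-law kind {r.kind!r}")
        if not r.vmax_ref > 0:
            problems.append(f"{r.id}: Vmax_ref must be > 0")
        for m in list(r.stoichiometry) + list(r.km) + list(r.inhibitors):
            if m not in mids:
                problems.append(f"{r.id}: dangling metabolite reference {m!r}")
        for m, k in r.km.items():
            if not k > 0:
                problems.append(f"{r.id}: Km[{m}] must be > 0")
        if r.kind == "mm_rev" and (r.keq is None or r.keq <= 0):
            problems.append(f"{r.id}: reversible reaction needs Keq > 0")
        # nitrogen conservation per reaction
        nbal = sum(
            s * spec.metabolite(m).n_atoms
            for m, s in r.stoichiometry.items()
            if m in mids
        )
        if abs(nbal) > 1e-12:
            problems.append(f"{r.id}: nitrogen imbalance {nbal:+g}")
    # every internal metabolite needs a producer and a consumer
    for mid in spec.internal_metabolites:
        produced = any(r.stoichiometry.get(mid, 0) > 0 for r in spec.reactions)
        consumed = any(r.stoichiometry.get(mid, 0) < 0 for r in spec.reactions)
        if not produced:
            problems.append(f"internal metabolite {mid!r} is never produced")
        if not consumed:
            problems.append(f"internal metabolite {mid!r} is never consumed")
    rids = {r.id for r in spec.reactions}
    if len(spec.capacity_defs) != 16:
        problems.append(f"expected 16 capacity definitions, got {len(spec.capacity_defs)}")
    names = [c.name for c in spec.capacity_defs]
    if len(set(names)) != len(names):
        problems.append("capacity names are not unique")
    for c in spec.capacity_defs:
        if c.kind not in CAPACITY_KINDS or c.rule not in CAPACITY_RULES:
            problems.append(f"capacity {c.name!r}: bad kind/rule")
        if c.kind == "flux":
            for rid in c.terms:
                if rid not in rids:
                    problems.append(f"capacity {c.name!r}: unknown reaction {rid!r}")
        else:
            if c.metabolite not in mids:
                problems.append(f"capacity {c.name!r}: unknown metabolite {c.metabolite!r}")
    if problems:
        raise ModelValidationError(
            "invalid model specification:\n  " + "\n  ".join(problems)
        )


def _parse_spec(doc: dict) -> ReferenceModelSpec:
    metabolites = tuple(
        Metabolite(
            id=m["id"],
            compartment=m["compartment"],
            initial_mm=float(m.get("initial_mm", 1.0)),
            n_atoms=int(m.get("n_atoms", 0)),
        )
        for m in doc["metabolites"]
    )
    reactions = tuple(
        Reaction(
            id=r["id"],
            enzyme=r.get("enzyme", r["id"]),
            pathway=r["pathway"],
            kind=r["kind"],
            vmax_ref=float(r["vmax_ref"]),
            stoichiometry={m: float(s) for m, s in r["stoichiometry"].items()},
            km={m: float(k) for m, k in r.get("km", {}).items()},
            keq=(float(r["keq"]) if "keq" in r else None),
            inhibitors={m: float(k) for m, k in r.get("inhibitors", {}).items()},
            phospho=(
                (float(r["phospho"]["v_phospho"]), float(r["phospho"]["v_dephospho"]))
                if "phospho" in r
                else None
            ),
            ghk_params={k: float(v) for k, v in r.get("ghk", {}).items()},
        )
        for r in doc["reactions"]
    )
    capacity_defs = tuple(
        CapacityDef(
            name=c["name"],
            kind=c["kind"],
            rule=c["rule"],
            terms={k: float(v) for k, v in c.get("terms", {}).items()},
            metabolite=c.get("metabolite"),
            units=c.get("units", "umol/g/h"),
        )
        for c in doc["capacities"]
    )
    spec = ReferenceModelSpec(
        name=doc.get("name", "reference"),
        metabolites=metabolites,
        reactions=reactions,
        capacity_defs=capacity_defs,
        gamma_params=dict(doc.get("gamma", {"g_half": 6.0, "hill": 4.0})),
        ffa_params=dict(
            doc.get(
                "ffa",
                {"fed_plateau": 0.2, "fasted_plateau": 1.0, "g_half": 6.0, "hill": 4.0},
            )
        ),
        plasma_defaults=dict(doc.get("plasma_defaults", {})),
    )
    _validate(spec)
    return spec


def build_reference_model(config: str | dict = "default") -> ReferenceModelSpec:
    """Load and validate a kinetic network specification.

    ``config`` may be the name of a packaged model (currently ``"default"``),
    a path to a YAML file, or an already-parsed mapping.
    """
    if isinstance(config, dict):
        return _parse_spec(config)
    if config == "default":
        text = (
            resources.files("hepamre.data").joinpath("reference_model.yaml").read_text()
        )
    else:
        with open(config, "r", encoding="utf-8") as fh:
            text = fh.read()
    return _parse_spec(yaml.safe_load(text))


def instantiate(spec: ReferenceModelSpec, profile: ProteomeProfile) -> ModelInstance:
    """Scale reference maximal activities by a sample's abundance ratios.

    vmax_i = ratio(enzyme_i) * Vmax_ref,i.  Enzymes absent from the profile
    keep ratio 1 and are logged (one warning per missing enzyme).
    """
    vmax: dict[str, float] = {}
    for r in spec.reactions:
        ratio = profile.ratios.get(r.enzyme)
        if ratio is None:
            logger.warning(
                "sample %s: enzyme %s not quantified; keeping reference Vmax for %s",
                profile.sample_id,
                r.enzyme,
                r.id,
            )
            ratio = 1.0
        elif not ratio > 0 or not math.isfinite(ratio):
            raise ValueError(
                f"sample {profile.sample_id}: invalid abundance ratio "
                f"{ratio!r} for enzyme {r.enzyme}"
            )
        vmax[r.id] = ratio * r.vmax_ref
    return ModelInstance(spec=spec, vmax=vmax, sample_id=profile.sample_id)
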