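"""Domain types, parameter registry and configuration I/O.

The whole model is parameterized by a single hierarchical YAML document:
compound physicochemistry and enzyme intrinsic clearances, organ physiology,
platelet-turnover PD constants, virtual-population settings and perpetrator
(inhibitor) models.  :func:`load_config` reads and validates such a document
into a :class:`Registry`; :func:`default_fixture` returns the packaged
defaults, which are constrained so that several published anchor values hold
exactly (clopidogrel's 15% oxidative fraction, the 53% AADAC share of
vicagrel gut hydrolysis, and the 240/16 and 2,305 µL/min/mg variant
clearances for CES1 428 G/A and defective CES2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

KNOWN_ENZYMES = frozenset(
    {"CYP1A2", "CYP2B6", "CYP2C9", "CYP2C19", "CYP3A4", "CES1", "CES2", "AADAC"}
)
GUT_ENZYMES = frozenset({"CES2", "AADAC"})
PHENOTYPES = ("EM", "IM", "PM")


class ConfigSchemaError(Exception):
    """A required key is missing or has the wrong type."""


class ConfigValidationError(Exception):
    """A value violates a documented bound or cross-reference."""


@dataclass(frozen=True)
class EnzymePathway:
    """One enzymatic route: enzyme, site, intrinsic clearance and product."""

    enzyme: str
    site: str  # "gut" | "liver"
    clint: float  # µL/min/mg protein
    product: str = ""  # empty = inactivating route
    cv: float = 0.0  # inter-individual CV (fraction)

    def validate(self, owner: str) -> None:
        if self.enzyme not in KNOWN_ENZYMES:
            raise ConfigValidationError(
                f"{owner}: unknown enzyme {self.enzyme!r}"
            )
        if self.site not in ("gut", "liver"):
            raise ConfigValidationError(f"{owner}: bad site {self.site!r}")
        if self.site == "gut" and self.enzyme not in GUT_ENZYMES:
            raise ConfigValidationError(
                f"{owner}: enzyme {self.enzyme} cannot be intestinal "
                f"(gut pathways are restricted to {sorted(GUT_ENZYMES)})"
            )
        if not (self.clint >= 0 and math.isfinite(self.clint)):
            raise ConfigValidationError(f"{owner}: clint must be finite and >= 0")
        if self.cv < 0:
            raise ConfigValidationError(f"{owner}: cv must be >= 0")


@dataclass(frozen=True)
class CompoundSpec:
    """Physicochemical and kinetic parameters of one drug or metabolite."""

    name: str
    molecular_weight: float  # g/mol
    ka: Optional[float]  # 1/h; None for metabolites
    fa: float
    fu_plasma: float
    blood_plasma_ratio: float
    v_sys: float  # L
    renal_cl: float  # L/h, systemic first-order clearance
    pathways: tuple[EnzymePathway, ...] = ()

    @property
    def is_parent(self) -> bool:
        return self.ka is not None

    @property
    def fu_blood(self) -> float:
        return self.fu_plasma / self.blood_plasma_ratio

    def validate(self) -> None:
        if self.molecular_weight <= 0:
            raise ConfigValidationError(f"{self.name}: molecular_weight must be > 0")
        if self.ka is not None and self.ka <= 0:
            raise ConfigValidationError(f"{self.name}: ka must be > 0")
        for fieldname, value in (("fa", self.fa), ("fu_plasma", self.fu_plasma)):
            if not 0.0 <= value <= 1.0:
                raise ConfigValidationError(
                    f"{self.name}: {fieldname} must lie in [0, 1], got {value}"
                )
        if self.blood_plasma_ratio <= 0:
            raise ConfigValidationError(
                f"{self.name}: blood_plasma_ratio must be > 0"
            )
        if self.v_sys <= 0:
            raise ConfigValidationError(f"{self.name}: v_sys must be > 0")
        if self.renal_cl < 0:
            raise ConfigValidationError(f"{self.name}: renal_cl must be >= 0")
        for p in self.pathways:
            p.validate(self.name)
        if not self.is_parent:
            if any(p.site == "gut" for p in self.pathways):
                raise ConfigValidationError(
                    f"{self.name}: metabolites cannot carry gut pathways"
                )


@dataclass(frozen=True)
class PhysiologySpec:
    """Flows, organ sizes and protein scalars of the minimal PBPK topology."""

    q_hepatic_total: float  # L/h
    q_portal: float
    q_hepatic_arterial: float
    q_gut: float  # villous ("Qgut"-style) flow, L/h
    liver_weight: float  # g
    mppgl: float  # mg protein / g liver
    gut_protein: float  # mg
    v_portal: float  # L
    v_liver: float  # L

    @property
    def liver_protein(self) -> float:
        """Total hepatic enzyme-bearing protein, mg."""
        return self.mppgl * self.liver_weight

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0:
                raise ConfigValidationError(f"physiology: {name} must be > 0")
        if not math.isclose(
            self.q_hepatic_total,
            self.q_portal + self.q_hepatic_arterial,
            rel_tol=1e-9,
        ):
            raise ConfigValidationError(
                "physiology: q_hepatic_total must equal q_portal + q_hepatic_arterial"
            )


@dataclass(frozen=True)
class PDSpec:
    """Platelet-turnover constants for the irreversible-inactivation model."""

    kin: float  # pool-units/h
    kout: float  # 1/h
    kirre: float  # 1/(µM·h)
    mpa0: float  # % baseline maximal platelet aggregation
    cv_kin: float = 0.0
    cv_kout: float = 0.0
    cv_kirre: float = 0.0
    cv_mpa0: float = 0.0

    def validate(self) -> None:
        for name in ("kin", "kout", "mpa0"):
            if getattr(self, name) <= 0:
                raise ConfigValidationError(f"pd: {name} must be > 0")
        if self.kirre < 0:
            raise ConfigValidationError("pd: kirre must be >= 0")
        for name in ("cv_kin", "cv_kout", "cv_kirre", "cv_mpa0"):
            if getattr(self, name) < 0:
                raise ConfigValidationError(f"pd: {name} must be >= 0")
        # Baseline pool is normalized to 1, so production and loss must balance.
        if not math.isclose(self.kin, self.kout, rel_tol=1e-9):
            raise ConfigValidationError(
                "pd: kin must equal kout (normalized baseline pool = 1)"
            )
        # One shared turnover multiplier preserves kin = kout per subject.
        if not math.isclose(self.cv_kin, self.cv_kout, rel_tol=1e-9):
            raise ConfigValidationError(
                "pd: cv_kin must equal cv_kout (shared turnover variability)"
            )


@dataclass(frozen=True)
class PopulationSpec:
    ethnicity: str
    phenotype_frequencies: dict[str, float]
    genotype_settings: dict[str, bool] = field(default_factory=dict)
    n_subjects: int = 100
    n_trials: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0 or self.n_trials <= 0:
            raise ConfigValidationError("population: counts must be > 0")
        freqs = self.phenotype_frequencies
        for label, f in freqs.items():
            if label not in PHENOTYPES:
                raise ConfigValidationError(
                    f"population: unknown phenotype {label!r}"
                )
            if f < 0:
                raise ConfigValidationError(
                    f"population: phenotype_frequencies[{label}] must be >= 0"
                )
        if not math.isclose(sum(freqs.values()), 1.0, rel_tol=1e-9, abs_tol=1e-9):
            raise ConfigValidationError(
                "population: phenotype_frequencies must sum to 1"
            )


@dataclass(frozen=True)
class MBISpec:
    """Mechanism-based inactivation constants for one enzyme."""

    k_i_app: float  # µM (unbound)
    k_inact: float  # 1/h
    k_deg: float  # 1/h

    def validate(self, owner: str) -> None:
        for name in ("k_i_app", "k_inact", "k_deg"):
            if getattr(self, name) <= 0:
                raise ConfigValidationError(f"{owner}: mbi {name} must be > 0")


@dataclass(frozen=True)
class InhibitionSpec:
    """Reversible (Ki) and/or mechanism-based inhibition per enzyme."""

    ki: dict[str, float] = field(default_factory=dict)  # enzyme -> µM
    mbi: dict[str, MBISpec] = field(default_factory=dict)

    def validate(self, owner: str) -> None:
        for enzyme, ki in self.ki.items():
            if enzyme not in KNOWN_ENZYMES:
                raise ConfigValidationError(f"{owner}: unknown enzyme {enzyme!r}")
            if ki <= 0:
                raise ConfigValidationError(f"{owner}: ki[{enzyme}] must be > 0")
        for enzyme, spec in self.mbi.items():
            if enzyme not in KNOWN_ENZYMES:
                raise ConfigValidationError(f"{owner}: unknown enzyme {enzyme!r}")
            spec.validate(owner)


@dataclass(frozen=True)
class PerpetratorSpec:
    """One-compartment oral perpetrator with closed-form kinetics."""

    name: str
    molecular_weight: float  # g/mol
    dose: float  # mg
    ka: float  # 1/h
    fa: float  # net oral bioavailability into the compartment
    v: float  # L
    cl: float  # L/h
    fu_plasma: float
    inhibition: InhibitionSpec = field(default_factory=InhibitionSpec)

    def validate(self) -> None:
        for name in ("molecular_weight", "dose", "ka", "fa", "v", "cl", "fu_plasma"):
            if getattr(self, name) <= 0:
                raise ConfigValidationError(f"{self.name}: {name} must be > 0")
        self.inhibition.validate(self.name)


@dataclass(frozen=True)
class Registry:
    """Validated bundle of every model input."""

    compounds: dict[str, CompoundSpec]
    physiology: dict[str, PhysiologySpec]
    pd: PDSpec
    populations: dict[str, PopulationSpec]
    perpetrators: dict[str, PerpetratorSpec] = field(default_factory=dict)
    cv_ka: float = 0.0
    cv_v_sys: float = 0.0

    def compound(self, name: str) -> CompoundSpec:
        return self.compounds[name]

    def validate(self) -> None:
        for c in self.compounds.values():
            c.validate()
            for p in c.pathways:
                if p.product and p.product not in self.compounds:
                    raise ConfigValidationError(
                        f"{c.name}: pathway product {p.product!r} is not a "
                        "registered compound"
                    )
        self._check_acyclic()
        for phys in self.physiology.values():
            phys.validate()
        self.pd.validate()
        for pop in self.populations.values():
            pop.validate()
            if pop.ethnicity not in self.physiology:
                raise ConfigValidationError(
                    f"population: no physiology block for ethnicity "
                    f"{pop.ethnicity!r}"
                )
        for perp in self.perpetrators.values():
            perp.validate()
        if self.cv_ka < 0 or self.cv_v_sys < 0:
            raise ConfigValidationError("iiv: cv values must be >= 0")

    def _check_acyclic(self) -> None:
        # Depth-first search over the metabolite product graph.
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {name: WHITE for name in self.compounds}

        def visit(name: str) -> None:
            color[name] = GRAY
            for p in self.compounds[name].pathways:
                if not p.product:
                    continue
                if color[p.product] == GRAY:
                    raise ConfigValidationError(
                        f"metabolite product graph contains a cycle through "
                        f"{p.product!r}"
                    )
                if color[p.product] == WHITE:
                    visit(p.product)
            color[name] = BLACK

        for name in self.compounds:
            if color[name] == WHITE:
                visit(name)

    def metabolites_of(self, name: str) -> list[str]:
        """All downstream compounds reachable from ``name``."""
        out: list[str] = []
        stack = [name]
        while stack:
            current = stack.pop()
            for p in self.compounds[current].pathways:
                if p.product and p.product not in out:
                    out.append(p.product)
                    stack.append(p.product)
        return out


# ---------------------------------------------------------------------------
# YAML I/O


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ConfigSchemaError(f"{context}: missing required key {key!r}")
    return mapping[key]


def _parse_compound(name: str, raw: dict) -> CompoundSpec:
    ctx = f"compounds.{name}"
    pathways = tuple(
        EnzymePathway(
            enzyme=_require(p, "enzyme", ctx),
            site=_require(p, "site", ctx),
            clint=float(_require(p, "clint", ctx)),
            product=p.get("product", "") or "",
            cv=float(p.get("cv", 0.0)),
        )
        for p in raw.get("pathways", [])
    )
    ka = _require(raw, "ka", ctx)
    return CompoundSpec(
        name=name,
        molecular_weight=float(_require(raw, "molecular_weight", ctx)),
        ka=None if ka is None else float(ka),
        fa=float(_require(raw, "fa", ctx)),
        fu_plasma=float(_require(raw, "fu_plasma", ctx)),
        blood_plasma_ratio=float(_require(raw, "blood_plasma_ratio", ctx)),
        v_sys=float(_require(raw, "v_sys", ctx)),
        renal_cl=float(_require(raw, "renal_cl", ctx)),
        pathways=pathways,
    )


def _parse_physiology(tag: str, raw: dict) -> PhysiologySpec:
    ctx = f"physiology.{tag}"
    return PhysiologySpec(
        **{
            key: float(_require(raw, key, ctx))
            for key in (
                "q_hepatic_total",
                "q_portal",
                "q_hepatic_arterial",
                "q_gut",
                "liver_weight",
                "mppgl",
                "gut_protein",
                "v_portal",
                "v_liver",
            )
        }
    )


def _parse_perpetrator(name: str, raw: dict) -> PerpetratorSpec:
    ctx = f"perpetrators.{name}"
    inh_raw = raw.get("inhibition", {}) or {}
    inhibition = InhibitionSpec(
        ki={k: float(v) for k, v in (inh_raw.get("ki") or {}).items()},
        mbi={
            enzyme: MBISpec(
                k_i_app=float(_require(m, "k_i_app", ctx)),
                k_inact=float(_require(m, "k_inact", ctx)),
                k_deg=float(_require(m, "k_deg", ctx)),
            )
            for enzyme, m in (inh_raw.get("mbi") or {}).items()
        },
    )
    return PerpetratorSpec(
        name=name,
        molecular_weight=float(_require(raw, "molecular_weight", ctx)),
        dose=float(_require(raw, "dose", ctx)),
        ka=float(_require(raw, "ka", ctx)),
        fa=float(_require(raw, "fa", ctx)),
        v=float(_require(raw, "v", ctx)),
        cl=float(_require(raw, "cl", ctx)),
        fu_plasma=float(_require(raw, "fu_plasma", ctx)),
        inhibition=inhibition,
    )


def parse_config(doc: dict) -> Registry:
    """Build and validate a :class:`Registry` from a parsed YAML mapping."""
    if not isinstance(doc, dict):
        raise ConfigSchemaError("config root must be a mapping")
    compounds = {
        name: _parse_compound(name, raw)
        for name, raw in _require(doc, "compounds", "config").items()
    }
    physiology = {
        tag: _parse_physiology(tag, raw)
        for tag, raw in _require(doc, "physiology", "config").items()
    }
    pd_raw = _require(doc, "pd", "config")
    pd = PDSpec(
        kin=float(_require(pd_raw, "kin", "pd")),
        kout=float(_require(pd_raw, "kout", "pd")),
        kirre=float(_require(pd_raw, "kirre", "pd")),
        mpa0=float(_require(pd_raw, "mpa0", "pd")),
        cv_kin=float(pd_raw.get("cv_kin", 0.0)),
        cv_kout=float(pd_raw.get("cv_kout", 0.0)),
        cv_kirre=float(pd_raw.get("cv_kirre", 0.0)),
        cv_mpa0=float(pd_raw.get("cv_mpa0", 0.0)),
    )
    populations = {}
    for tag, raw in _require(doc, "populations", "config").items():
        ctx = f"populations.{tag}"
        populations[tag] = PopulationSpec(
            ethnicity=str(_require(raw, "ethnicity", ctx)),
            phenotype_frequencies={
                k: float(v)
                for k, v in _require(raw, "phenotype_frequencies", ctx).items()
            },
            genotype_settings={
                k: bool(v) for k, v in (raw.get("genotype_settings") or {}).items()
            },
            n_subjects=int(_require(raw, "n_subjects", ctx)),
            n_trials=int(_require(raw, "n_trials", ctx)),
            seed=int(_require(raw, "seed", ctx)),
        )
    perpetrators = {
        name: _parse_perpetrator(name, raw)
        for name, raw in (doc.get("perpetrators") or {}).items()
    }
    iiv = doc.get("iiv") or {}
    registry = Registry(
        compounds=compounds,
        physiology=physiology,
        pd=pd,
        populations=populations,
        perpetrators=perpetrators,
        cv_ka=float(iiv.get("cv_ka", 0.0)),
        cv_v_sys=float(iiv.get("cv_v_sys", 0.0)),
    )
    registry.validate()
    return registry


def load_config(path: str | Path) -> Registry:
    """Read and validate a YAML configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigSchemaError(f"config file not found: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return parse_config(doc)


def registry_to_dict(registry: Registry) -> dict:
    """Serialize a registry back to the plain-mapping config schema."""
    return {
        "compounds": {
            c.name: {
                "molecular_weight": c.molecular_weight,
                "ka": c.ka,
                "fa": c.fa,
                "fu_plasma": c.fu_plasma,
                "blood_plasma_ratio": c.blood_plasma_ratio,
                "v_sys": c.v_sys,
                "renal_cl": c.renal_cl,
                "pathways": [
                    {
                        "enzyme": p.enzyme,
                        "site": p.site,
                        "clint": p.clint,
                        "product": p.product,
                        "cv": p.cv,
                    }
                    for p in c.pathways
                ],
            }
            for c in registry.compounds.values()
        },
        "physiology": {
            tag: asdict(phys) for tag, phys in registry.physiology.items()
        },
        "pd": asdict(registry.pd),
        "populations": {
            tag: {
                "ethnicity": pop.ethnicity,
                "phenotype_frequencies": dict(pop.phenotype_frequencies),
                "genotype_settings": dict(pop.genotype_settings),
                "n_subjects": pop.n_subjects,
                "n_trials": pop.n_trials,
                "seed": pop.seed,
            }
            for tag, pop in registry.populations.items()
        },
        "iiv": {"cv_ka": registry.cv_ka, "cv_v_sys": registry.cv_v_sys},
        "perpetrators": {
            perp.name: {
                "molecular_weight": perp.molecular_weight,
                "dose": perp.dose,
                "ka": perp.ka,
                "fa": perp.fa,
                "v": perp.v,
                "cl": perp.cl,
                "fu_plasma": perp.fu_plasma,
                "inhibition": {
                    "ki": dict(perp.inhibition.ki),
                    "mbi": {
                        enzyme: asdict(m)
                        for enzyme, m in perp.inhibition.mbi.items()
                    },
                },
            }
            for perp in registry.perpetrators.values()
        },
    }


def write_config(registry: Registry, path: str | Path) -> None:
    """Write a registry to YAML such that :func:`load_config` round-trips."""
    with open(path, "w") as fh:
        yaml.safe_dump(registry_to_dict(registry), fh, sort_keys=False)


def default_fixture() -> Registry:
    """The packaged default parameterization (anchor constraints hold exactly)."""
    with resources.files("vicasim.data").joinpath("default.yaml").open() as fh:
        doc = yaml.safe_load(fh)
    return parse_config(doc)
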