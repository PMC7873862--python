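"""Biomass objective construction for an oleaginous yeast model.

The lipid term is split into two parts estimated from fatty-acid (FAME)
profiles measured across media spanning low to high lipid content.  Writing
``x`` for a sample's total fatty-acid content (wt% of cell dry weight) and
``y_k`` for the content of fatty acid ``k``, each fatty acid follows

    y_k = m_k * (x - x0) + b_k        for x >= x0,

where the shared breakpoint ``x0`` is the lean-cell fatty-acid content.
Because ``x = sum_k y_k`` by construction, the slopes close to 1
(``sum m_k = 1``) and the intercepts close to the breakpoint
(``sum b_k = x0``).  Fatty acids whose content rises with total lipid are
the lipid-body (triacylglycerol / sterol-ester) components: their
normalized slopes give the lipid-body composition, while the intercepts
give the lean-biomass composition that enters the growth objective.  Lipid
accumulation is wired as irreversible demand reactions on lipid-droplet
species and mobilization as (default-closed) sink reactions, so growth and
storage can be simulated separately.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import (
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    ReactionKind,
    formula_weight,
)

__all__ = [
    "FameSample",
    "FameDataset",
    "FameFit",
    "FitConfig",
    "read_fame",
    "fit_segmented",
    "composition_from_weights",
    "Macromolecule",
    "BiomassSpec",
    "assemble_biomass",
    "BIOMASS_ID",
    "TAG_DEMAND_ID",
    "SE_DEMAND_ID",
    "TAG_SINK_ID",
    "SE_SINK_ID",
]

BIOMASS_ID = "RT_BIOMASS"
TAG_DEMAND_ID = "RT_DM_TAG_LD"
SE_DEMAND_ID = "RT_DM_SE_LD"
TAG_SINK_ID = "RT_SK_TAG_LD"
SE_SINK_ID = "RT_SK_SE_LD"


# ---------------------------------------------------------------------------
# FAME data
# ---------------------------------------------------------------------------


@dataclass
class FameSample:
    condition: str
    y: Dict[str, float]  # fatty acid -> wt% CDW

    @property
    def x(self) -> float:
        """Total fatty-acid content (wt% CDW) — the sum of all species."""
        return float(sum(self.y.values()))


@dataclass
class FameDataset:
    samples: List[FameSample] = field(default_factory=list)

    def fatty_acids(self) -> List[str]:
        names: List[str] = []
        for s in self.samples:
            for k in s.y:
                if k not in names:
                    names.append(k)
        return names

    def arrays(self) -> Tuple[np.ndarray, np.ndarray, List[str]]:
        """(x vector, Y matrix samples x fatty-acids, fatty-acid names)."""
        names = self.fatty_acids()
        Y = np.array([[s.y.get(k, 0.0) for k in names] for s in self.samples])
        x = Y.sum(axis=1)
        return x, Y, names

    def validate(self) -> None:
        for s in self.samples:
            bad = {k: v for k, v in s.y.items() if v < 0}
            if bad:
                raise ModelError(f"negative fatty-acid content in {s.condition!r}: {bad}")
        if len(self.samples) < 3:
            raise ModelError("need at least 3 FAME samples to fit")
        x = [round(s.x, 9) for s in self.samples]
        if len(set(x)) < 2:
            raise ModelError("need at least 2 distinct total fatty-acid contents")


def read_fame(path: str) -> FameDataset:
    """TSV with columns condition, fatty_acid, wt_percent_cdw."""
    samples: Dict[str, FameSample] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            cond = row["condition"]
            samples.setdefault(cond, FameSample(cond, {}))
            samples[cond].y[row["fatty_acid"]] = float(row["wt_percent_cdw"])
    return FameDataset(list(samples.values()))


# ---------------------------------------------------------------------------
# Segmented regression
# ---------------------------------------------------------------------------


@dataclass
class FitConfig:
    grid_step: float = 0.05      # wt% CDW resolution of the breakpoint search
    slope_threshold: float = 0.02  # minimum slope to call a fatty acid "increasing"
    t_threshold: float = 2.0     # minimum slope t-statistic for the same call
    shared_breakpoint: bool = True  # one x0 for all fatty acids (per-FA otherwise)


@dataclass
class FameFit:
    fatty_acids: List[str]
    m: np.ndarray                # slopes; 0 for non-increasing species; sum = 1
    b: np.ndarray                # intercepts at x0 (wt% CDW); sum = x0
    x0: float                    # breakpoint = lean-cell fatty-acid content
    increasing: np.ndarray       # boolean mask of lipid-body species
    rss: float
    per_fa_x0: Optional[Dict[str, float]] = None

    @property
    def lean_composition(self) -> Dict[str, float]:
        total = float(self.b.sum())
        if total <= 0:
            return {k: 0.0 for k in self.fatty_acids}
        return {k: float(v / total) for k, v in zip(self.fatty_acids, self.b)}

    @property
    def lipid_body_composition(self) -> Dict[str, float]:
        return {k: float(v) for k, v in zip(self.fatty_acids, self.m)}

    def predict(self, x: float) -> Dict[str, float]:
        z = max(x - self.x0, 0.0)
        return {k: float(m * z + b) for k, m, b in zip(self.fatty_acids, self.m, self.b)}


def _constrained_line(z: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """OLS of y on z with slope >= 0 and intercept >= 0; returns (m, b, rss)."""
    zbar, ybar = z.mean(), y.mean()
    szz = float(((z - zbar) ** 2).sum())
    if szz == 0:
        m, b = 0.0, max(ybar, 0.0)
    else:
        m = float(((z - zbar) * (y - ybar)).sum() / szz)
        b = float(ybar - m * zbar)
        if m < 0:
            m, b = 0.0, max(ybar, 0.0)
        elif b < 0:
            denom = float((z ** 2).sum())
            m = float((z * y).sum() / denom) if denom > 0 else 0.0
            m, b = max(m, 0.0), 0.0
    rss = float(((y - (m * z + b)) ** 2).sum())
    return m, b, rss


def _ols_with_t(z: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """Unconstrained OLS slope, intercept, and slope t-statistic."""
    zbar, ybar = z.mean(), y.mean()
    szz = float(((z - zbar) ** 2).sum())
    if szz == 0:
        return 0.0, float(ybar), 0.0
    m = float(((z - zbar) * (y - ybar)).sum() / szz)
    b = float(ybar - m * zbar)
    dof = len(z) - 2
    rss = float(((y - (m * z + b)) ** 2).sum())
    if dof <= 0:
        return m, b, np.inf if m != 0 else 0.0
    sigma2 = rss / dof
    if sigma2 <= 1e-24:
        return m, b, np.inf if m > 0 else 0.0
    se = float(np.sqrt(sigma2 / szz))
    return m, b, m / se


def _grid(xmin: float, step: float) -> np.ndarray:
    pts = np.arange(0.0, xmin + step / 2, step)
    if pts.size == 0 or abs(pts[-1] - xmin) > 1e-12:
        pts = np.append(pts, xmin)
    return pts


def fit_segmented(data: FameDataset, config: Optional[FitConfig] = None) -> FameFit:
    """Fit the shared-breakpoint segmented model to a FAME dataset.

    The breakpoint is grid-searched over ``[0, min(x)]``; at each candidate,
    every fatty acid gets a nonnegativity-constrained least-squares line on
    ``x - x0`` and the candidate minimizing the joint residual sum of
    squares wins (ties resolve to the largest breakpoint, attributing the
    maximum content to lean mass — with data only at ``x >= x0`` the
    breakpoint is bounded above by the smallest observed total).  Increasing
    species need slope above the threshold and a slope t-statistic above 2;
    the others are pinned to slope 0.  Slopes are projected to sum to 1 and
    intercepts rescaled to sum to the breakpoint, so the compositional
    closure identities hold exactly.
    """
    config = config or FitConfig()
    data.validate()
    x, Y, names = data.arrays()
    K = Y.shape[1]

    if not config.shared_breakpoint:
        return _fit_per_fa(x, Y, names, config)

    grid = _grid(float(x.min()), config.grid_step)
    best_rss, best_x0 = np.inf, 0.0
    for x0 in grid:
        z = x - x0
        rss = sum(_constrained_line(z, Y[:, k])[2] for k in range(K))
        # strictly better, or tied (within tolerance) and larger x0
        if rss < best_rss - 1e-9 * (1 + best_rss) or (
            rss <= best_rss + 1e-9 * (1 + best_rss) and x0 > best_x0
        ):
            best_rss, best_x0 = min(rss, best_rss), float(x0)
    x0 = best_x0
    z = x - x0

    slopes = np.zeros(K)
    intercepts = np.zeros(K)
    tstats = np.zeros(K)
    for k in range(K):
        slopes[k], intercepts[k], tstats[k] = _ols_with_t(z, Y[:, k])
    increasing = (slopes > config.slope_threshold) & (tstats > config.t_threshold)
    if not increasing.any():
        raise ModelError(
            "no lipid-body signal: no fatty acid increases with total content"
        )

    m = np.zeros(K)
    m[increasing] = slopes[increasing] / slopes[increasing].sum()
    b = np.zeros(K)
    zbar = z.mean()
    for k in range(K):
        if increasing[k]:
            b[k] = Y[:, k].mean() - m[k] * zbar  # intercept refit at fixed slope
        else:
            b[k] = Y[:, k].mean()
    b = np.clip(b, 0.0, None)
    total_b = b.sum()
    if total_b > 0:
        b *= x0 / total_b
    elif x0 > 0:
        b = m * x0  # no intercept mass to distribute; fall back on slope shape
    rss = float(sum(((Y[:, k] - (m[k] * z + b[k])) ** 2).sum() for k in range(K)))
    return FameFit(names, m, b, float(x0), increasing, rss)


def _fit_per_fa(x: np.ndarray, Y: np.ndarray, names: List[str], config: FitConfig) -> FameFit:
    """Per-fatty-acid breakpoints (exploratory variant; closure still enforced)."""
    K = Y.shape[1]
    grid = _grid(float(x.min()), config.grid_step)
    per_x0: Dict[str, float] = {}
    slopes = np.zeros(K)
    intercepts = np.zeros(K)
    tstats = np.zeros(K)
    for k in range(K):
        best = (np.inf, 0.0)
        for x0 in grid:
            rss = _constrained_line(x - x0, Y[:, k])[2]
            if rss < best[0] - 1e-12 or (rss <= best[0] + 1e-12 and x0 > best[1]):
                best = (min(rss, best[0]), float(x0))
        per_x0[names[k]] = best[1]
        slopes[k], intercepts[k], tstats[k] = _ols_with_t(x - best[1], Y[:, k])
    increasing = (slopes > config.slope_threshold) & (tstats > config.t_threshold)
    if not increasing.any():
        raise ModelError("no lipid-body signal: no fatty acid increases with total content")
    m = np.zeros(K)
    m[increasing] = slopes[increasing] / slopes[increasing].sum()
    x0 = float(np.mean([per_x0[names[k]] for k in range(K) if increasing[k]]))
    z = x - x0
    b = np.array([
        Y[:, k].mean() - m[k] * z.mean() if increasing[k] else Y[:, k].mean()
        for k in range(K)
    ])
    b = np.clip(b, 0.0, None)
    if b.sum() > 0:
        b *= x0 / b.sum()
    rss = float(sum(((Y[:, k] - (m[k] * z + b[k])) ** 2).sum() for k in range(K)))
    return FameFit(names, m, b, x0, increasing, rss, per_fa_x0=per_x0)


# ---------------------------------------------------------------------------
# Monomer compositions from omics weights
# ---------------------------------------------------------------------------


def composition_from_weights(
    entities: Mapping[str, Mapping[str, float]],
    weights: Mapping[str, float],
) -> Dict[str, float]:
    """Abundance-weighted average monomer composition, normalized to sum 1.

    ``entities`` maps an entity id (gene, transcript, protein) to its own
    monomer mol-fraction composition; ``weights`` holds nonnegative
    abundances (transcriptomics for RNA, proteomics for protein).
    """
    missing = sorted(e for e in weights if e not in entities)
    if missing:
        raise ModelError(f"weighted entities lack compositions: {missing}")
    bad = {e: w for e, w in weights.items() if w < 0}
    if bad:
        raise ModelError(f"negative weights: {bad}")
    total_w = float(sum(weights.values()))
    if total_w <= 0:
        raise ModelError("weights are all zero")
    acc: Dict[str, float] = {}
    for ent, w in weights.items():
        if w == 0:
            continue
        for monomer, frac in entities[ent].items():
            acc[monomer] = acc.get(monomer, 0.0) + w * frac
    total = sum(acc.values())
    return {k: v / total for k, v in acc.items()}


# ---------------------------------------------------------------------------
# Biomass specification and assembly
# ---------------------------------------------------------------------------


@dataclass
class Macromolecule:
    """One biomass macromolecule: mass fraction, monomers, residue masses.

    ``monomers`` are mol fractions over monomer metabolite ids;
    ``residue_masses`` are polymerized-residue masses in g/mmol;
    ``releases`` optionally names carrier metabolites returned per mol of a
    monomer (e.g. CoA released when acetyl-CoA carbon enters biomass).
    """

    mass_fraction: float
    monomers: Dict[str, float]
    residue_masses: Dict[str, float]
    releases: Dict[str, Dict[str, float]] = field(default_factory=dict)


@dataclass
class BiomassSpec:
    macromolecules: Dict[str, Macromolecule]
    gam_atp: float = 30.0  # growth-associated maintenance, mmol ATP/gDW
    gam_metabolites: Dict[str, float] = field(default_factory=lambda: {
        "atp_c": -1.0, "h2o_c": -1.0, "adp_c": 1.0, "pi_c": 1.0, "h_c": 1.0,
    })
    trace: Dict[str, float] = field(default_factory=dict)  # met -> mmol/gDW
    lipid_lean_name: Optional[str] = "lipid_lean"
    fa_metabolites: Dict[str, str] = field(default_factory=dict)  # FA name -> met id
    droplet_compartment: str = "l"

    def validate(self) -> None:
        total = sum(m.mass_fraction for m in self.macromolecules.values())
        if abs(total - 1.0) > 1e-4:
            raise ModelError(f"macromolecule mass fractions sum to {total}, not 1")
        for name, macro in self.macromolecules.items():
            s = sum(macro.monomers.values())
            if abs(s - 1.0) > 1e-6:
                raise ModelError(f"{name!r} monomer fractions sum to {s}, not 1")
            missing = sorted(set(macro.monomers) - set(macro.residue_masses))
            if missing:
                raise ModelError(f"{name!r} lacks residue masses for {missing}")


def assemble_biomass(
    model: MetabolicModel,
    spec: BiomassSpec,
    fit: Optional[FameFit] = None,
    biomass_id: str = BIOMASS_ID,
    set_objective: bool = True,
) -> MetabolicModel:
    """Build the biomass reaction and the lipid-droplet demand/sink wiring.

    Monomer coefficients are ``mass_fraction * mol_fraction / residue_mass``
    in mmol/gDW; the assembled reaction carries exactly 1 g of biomass per
    gDW (audited to 1e-4).  When a FAME fit is given, the lean composition
    replaces the lipid-lean macromolecule's monomers and the lipid-body
    composition weights irreversible demand reactions for triacylglycerol
    and sterol-ester accumulation in the droplet (3 acyl equivalents per
    TAG, 1 per SE) plus matching default-closed sink reactions for
    mobilization.
    """
    spec = _with_fit(spec, fit, model)
    spec.validate()
    out = model.copy()

    stoich: Dict[str, float] = {}
    audit_mass = 0.0
    for name, macro in spec.macromolecules.items():
        for monomer, frac in macro.monomers.items():
            if frac == 0:
                continue
            if monomer not in out.metabolites:
                raise ModelError(f"biomass monomer {monomer!r} ({name}) not in model")
            coef = macro.mass_fraction * frac / macro.residue_masses[monomer]
            stoich[monomer] = stoich.get(monomer, 0.0) - coef
            audit_mass += coef * macro.residue_masses[monomer]
            for released, per_mol in macro.releases.get(monomer, {}).items():
                if released not in out.metabolites:
                    raise ModelError(f"release metabolite {released!r} not in model")
                stoich[released] = stoich.get(released, 0.0) + coef * per_mol
    if abs(audit_mass - 1.0) > 1e-4:
        raise ModelError(f"assembled biomass carries {audit_mass} g/gDW, not 1")
    for met, coef in spec.gam_metabolites.items():
        if met not in out.metabolites:
            raise ModelError(f"maintenance metabolite {met!r} not in model")
        stoich[met] = stoich.get(met, 0.0) + spec.gam_atp * coef
    for met, coef in spec.trace.items():
        if met not in out.metabolites:
            raise ModelError(f"trace metabolite {met!r} not in model")
        stoich[met] = stoich.get(met, 0.0) - coef

    if biomass_id in out.reactions:
        out.remove_reaction(biomass_id)
    out.add_reaction(Reaction(
        id=biomass_id, stoichiometry=stoich, lower_bound=0.0, upper_bound=1000.0,
        name="biomass (growth)", kind=ReactionKind.BIOMASS,
    ))
    if set_objective:
        out.objective = (biomass_id, "max")

    if fit is not None:
        _wire_lipid_droplet(out, spec, fit)
    return out


def _with_fit(spec: BiomassSpec, fit: Optional[FameFit], model: MetabolicModel) -> BiomassSpec:
    if fit is None or spec.lipid_lean_name is None:
        return spec
    if spec.lipid_lean_name not in spec.macromolecules:
        return spec
    lean = fit.lean_composition
    monomers: Dict[str, float] = {}
    residues: Dict[str, float] = {}
    # convert the lean mass composition to mol fractions through residue mass
    mols: Dict[str, float] = {}
    for fa, mass_frac in lean.items():
        if mass_frac == 0:
            continue
        met_id = spec.fa_metabolites.get(fa, fa)
        if met_id not in model.metabolites:
            raise ModelError(f"lean fatty acid {fa!r} has no metabolite {met_id!r}")
        met = model.metabolites[met_id]
        if met.formula is None:
            raise ModelError(f"fatty acid metabolite {met_id!r} lacks a formula")
        residues[met_id] = formula_weight(met.formula) / 1000.0  # g/mmol
        mols[met_id] = mass_frac / residues[met_id]
    total_mol = sum(mols.values())
    monomers = {k: v / total_mol for k, v in mols.items()}
    macro = spec.macromolecules[spec.lipid_lean_name]
    new_macros = dict(spec.macromolecules)
    new_macros[spec.lipid_lean_name] = Macromolecule(
        mass_fraction=macro.mass_fraction, monomers=monomers,
        residue_masses=residues, releases=macro.releases,
    )
    return BiomassSpec(
        macromolecules=new_macros, gam_atp=spec.gam_atp,
        gam_metabolites=spec.gam_metabolites, trace=spec.trace,
        lipid_lean_name=spec.lipid_lean_name, fa_metabolites=spec.fa_metabolites,
        droplet_compartment=spec.droplet_compartment,
    )


def _wire_lipid_droplet(model: MetabolicModel, spec: BiomassSpec, fit: FameFit) -> None:
    comp = spec.droplet_compartment
    if comp not in model.compartments:
        model.compartments[comp] = "lipid droplet"
    acyl: Dict[str, float] = {}
    for fa, m_k in fit.lipid_body_composition.items():
        if m_k == 0:
            continue
        met_id = spec.fa_metabolites.get(fa, fa)
        base = met_id.rsplit("_", 1)[0]
        droplet_id = f"{base}_{comp}"
        if droplet_id not in model.metabolites:
            template = model.metabolites.get(met_id)
            model.add_metabolite(Metabolite(
                id=droplet_id,
                name=(template.name if template else fa) + " (lipid droplet)",
                formula=dict(template.formula) if template and template.formula else None,
                charge=template.charge if template else None,
                compartment=comp,
            ))
        acyl[droplet_id] = m_k
    specs = [
        (TAG_DEMAND_ID, TAG_SINK_ID, 3.0, "triacylglycerol"),
        (SE_DEMAND_ID, SE_SINK_ID, 1.0, "sterol ester"),
    ]
    for demand_id, sink_id, acyls, label in specs:
        stoich = {met: -acyls * m_k for met, m_k in acyl.items()}
        for rid in (demand_id, sink_id):
            if rid in model.reactions:
                model.remove_reaction(rid)
        model.add_reaction(Reaction(
            id=demand_id, stoichiometry=dict(stoich), lower_bound=0.0,
            upper_bound=1000.0, name=f"{label} accumulation (lipid droplet)",
            kind=ReactionKind.DEMAND,
        ))
        # mobilization sink: reversible by design, shipped closed
        model.add_reaction(Reaction(
            id=sink_id, stoichiometry=dict(stoich), lower_bound=0.0,
            upper_bound=0.0, name=f"{label} mobilization (lipid droplet)",
            kind=ReactionKind.SINK,
        ))
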