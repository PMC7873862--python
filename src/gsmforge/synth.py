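"""Synthetic data with known ground truth for every pipeline stage.

Three generators, all pure functions of their seed and parameters:

* :func:`make_universe` — a feasible ground-truth metabolic network,
  donor-model projections of it with organism-namespaced genes, and an
  ortholog map with controlled coverage and spurious-link noise, plus
  injected duplicate metabolites/reactions and mass-imbalanced reactions,
  every defect recorded in a truth ledger;
* :func:`make_fame` — fatty-acid composition samples drawn from the
  segmented model ``y_k = m_k (x - x0) + b_k`` with additive noise and the
  compositional closure ``sum_k y_k = x`` restored;
* :func:`make_phenotype_and_fitness` — phenotype-array calls and per-gene
  fitness scores generated from a model's own predictions with controlled
  label-flip noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .biomass import FameDataset, FameSample
from .core import (
    GprExpr,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    ReactionKind,
    parse_formula,
)
from .draft import OrthologMap
from .fba import GROWTH_TOL, fba, single_gene_deletions
from .validation import (
    FITNESS_CUTOFF,
    FitnessRow,
    FitnessTable,
    PhenotypeArray,
    PhenotypeWell,
)

__all__ = [
    "UniverseSpec",
    "UniverseLedger",
    "SyntheticUniverse",
    "make_universe",
    "make_fame",
    "make_phenotype_and_fitness",
    "PhenotypeFitnessLedger",
]


# ---------------------------------------------------------------------------
# Synthetic reconstruction universe
# ---------------------------------------------------------------------------


@dataclass
class UniverseSpec:
    seed: int = 0
    n_target_genes: int = 40
    n_reactions: int = 30
    n_donors: int = 2
    coverage: float = 1.0          # fraction of target genes in the ortholog map
    spurious_rate: float = 0.0     # fraction of donor genes linked to a wrong group
    duplicate_met_rate: float = 0.0
    n_duplicate_reactions: int = 0
    imbalance_rate: float = 0.0
    target_organism: str = "RT"

    def validate(self) -> None:
        for name in ("coverage", "spurious_rate", "duplicate_met_rate", "imbalance_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ModelError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class UniverseLedger:
    """Ground truth for every generated feature and injected defect."""

    covered_genes: Set[str] = field(default_factory=set)
    transferable_reactions: Set[str] = field(default_factory=set)
    resolvable_reactions: Set[str] = field(default_factory=set)
    duplicate_metabolite_pairs: List[Tuple[str, str]] = field(default_factory=list)
    duplicate_reaction_groups: List[List[str]] = field(default_factory=list)
    imbalanced_reactions: Set[str] = field(default_factory=set)
    spurious_links: List[Tuple[str, str, str]] = field(default_factory=list)


@dataclass
class SyntheticUniverse:
    truth: MetabolicModel
    donors: List[MetabolicModel]
    omap: OrthologMap
    ledger: UniverseLedger
    medium: Dict[str, float]


_GPR_PATTERNS = ("single", "isozyme", "complex", "complex_or_isozyme")


def _chain_formula(i: int) -> Dict[str, int]:
    # each chain step releases one water: C and H/O shrink deterministically,
    # keeping every metabolite key distinct and every reaction balanced
    return parse_formula(f"C40H{100 - 2 * i}O{60 - i}")


def make_universe(spec: UniverseSpec) -> SyntheticUniverse:
    """Generate a ground-truth network, donor projections and ortholog map."""
    spec.validate()
    for attempt in range(5):
        rng = np.random.default_rng((spec.seed, attempt))
        universe = _build_universe(spec, rng)
        growth = fba(universe.truth, medium=universe.medium)
        if growth.ok and growth.objective_value > GROWTH_TOL:
            return universe
    raise ModelError("could not generate a feasible truth model")  # pragma: no cover


def _build_universe(spec: UniverseSpec, rng: np.random.Generator) -> SyntheticUniverse:
    ledger = UniverseLedger()
    truth = MetabolicModel(id="truth")
    truth.compartments = {"c": "cytosol", "e": "extracellular"}

    n = spec.n_reactions
    for i in range(n + 1):
        truth.add_metabolite(Metabolite(
            id=f"met{i:03d}_c", name=f"chain metabolite {i}",
            formula=_chain_formula(i), charge=0, compartment="c",
        ))
    truth.add_metabolite(Metabolite(
        id="h2o_c", name="water", formula={"H": 2, "O": 1}, charge=0, compartment="c"))

    gene_counter = 0

    def next_gene() -> str:
        nonlocal gene_counter
        g = f"tg{gene_counter:04d}"
        gene_counter += 1
        return g

    for i in range(n):
        pattern = _GPR_PATTERNS[i % len(_GPR_PATTERNS)]
        if pattern == "single":
            gpr = next_gene()
        elif pattern == "isozyme":
            gpr = f"{next_gene()} or {next_gene()}"
        elif pattern == "complex":
            gpr = f"{next_gene()} and {next_gene()}"
        else:
            gpr = f"({next_gene()} and {next_gene()}) or {next_gene()}"
        truth.add_reaction(Reaction(
            id=f"R{i:03d}",
            stoichiometry={f"met{i:03d}_c": -1.0, f"met{i + 1:03d}_c": 1.0, "h2o_c": 1.0},
            lower_bound=0.0, upper_bound=1000.0, gpr=gpr,
            subsystem="chain", kind=ReactionKind.METABOLIC,
        ))
    # recycle the pool so every target gene index exists even if unused
    while gene_counter < spec.n_target_genes:
        next_gene()

    # boundary scaffolding (never transferred: empty GPRs / boundary kinds)
    truth.add_reaction(Reaction(id="EX_met000_c", stoichiometry={"met000_c": -1.0},
                                lower_bound=-10.0, upper_bound=1000.0,
                                kind=ReactionKind.EXCHANGE))
    truth.add_reaction(Reaction(id="EX_h2o_c", stoichiometry={"h2o_c": -1.0},
                                lower_bound=-1000.0, upper_bound=1000.0,
                                kind=ReactionKind.EXCHANGE))
    truth.add_reaction(Reaction(
        id="BIOMASS", stoichiometry={f"met{n:03d}_c": -1.0},
        lower_bound=0.0, upper_bound=1000.0, kind=ReactionKind.BIOMASS))
    truth.objective = ("BIOMASS", "max")
    medium = {"EX_met000_c": -10.0, "EX_h2o_c": -1000.0}

    # --- duplicate metabolite injection ---------------------------------
    interior = [f"met{i:03d}_c" for i in range(1, n)]
    n_dup = int(round(spec.duplicate_met_rate * len(interior)))
    dup_targets = sorted(rng.choice(interior, size=n_dup, replace=False)) if n_dup else []
    for met_id in dup_targets:
        src = truth.metabolites[met_id]
        dup_id = met_id.replace("_c", "__dup_c")
        truth.add_metabolite(Metabolite(
            id=dup_id, name=src.name + " (duplicate id)",
            formula=dict(src.formula), charge=src.charge, compartment="c"))
        idx = int(met_id[3:6])
        consumer = truth.reactions[f"R{idx:03d}"]
        consumer.stoichiometry[dup_id] = consumer.stoichiometry.pop(met_id)
        truth.add_reaction(Reaction(
            id=f"RDUPISO{idx:03d}",
            stoichiometry={met_id: -1.0, dup_id: 1.0},
            lower_bound=0.0, upper_bound=1000.0, gpr=next_gene(),
            subsystem="chain", kind=ReactionKind.METABOLIC))
        ledger.duplicate_metabolite_pairs.append((met_id, dup_id))

    # --- duplicate reaction injection -----------------------------------
    chain_ids = [f"R{i:03d}" for i in range(n)]
    if spec.n_duplicate_reactions:
        picks = sorted(rng.choice(chain_ids, size=spec.n_duplicate_reactions,
                                  replace=False))
        for rid in picks:
            src = truth.reactions[rid]
            flip = bool(rng.integers(0, 2))
            scale = float(rng.choice([1.0, 2.0]))
            factor = -scale if flip else scale
            dup = Reaction(
                id=f"{rid}__copy",
                stoichiometry={m: c * factor for m, c in src.stoichiometry.items()},
                lower_bound=-1000.0 if flip else 0.0,
                upper_bound=0.0 if flip else 1000.0,
                gpr=next_gene(), subsystem="chain", kind=src.kind,
            )
            truth.add_reaction(dup)
            ledger.duplicate_reaction_groups.append(sorted([rid, dup.id]))

    # --- imbalance injection (drop the water product) -------------------
    n_imb = int(round(spec.imbalance_rate * len(chain_ids)))
    if n_imb:
        eligible = [r for r in chain_ids
                    if "h2o_c" in truth.reactions[r].stoichiometry]
        for rid in sorted(rng.choice(eligible, size=min(n_imb, len(eligible)),
                                     replace=False)):
            del truth.reactions[rid].stoichiometry["h2o_c"]
            ledger.imbalanced_reactions.add(rid)

    # --- ortholog map ----------------------------------------------------
    all_genes = sorted(truth.genes)
    n_cov = int(round(spec.coverage * len(all_genes)))
    covered = sorted(rng.choice(all_genes, size=n_cov, replace=False)) if n_cov else []
    ledger.covered_genes = set(covered)
    omap = OrthologMap(target_organism=spec.target_organism)
    donor_names = [f"donor{j}" for j in range(spec.n_donors)]
    group_of_gene: Dict[str, str] = {}
    for g in covered:
        gid = f"OG_{g}"
        omap.add(gid, spec.target_organism, g)
        group_of_gene[g] = gid
    group_ids = sorted(group_of_gene.values())
    for j, donor_name in enumerate(donor_names):
        for g in sorted(truth.genes):
            donor_gene = f"d{j}|{g}"
            if g in group_of_gene:
                target_group = group_of_gene[g]
                if group_ids and len(group_ids) > 1 and rng.random() < spec.spurious_rate:
                    wrong = [gid for gid in group_ids if gid != target_group]
                    target_group = str(rng.choice(wrong))
                    ledger.spurious_links.append((donor_name, donor_gene, target_group))
                omap.add(target_group, donor_name, donor_gene)
            # uncovered genes simply never appear in the map

    # --- donors: renamed projections of the truth -----------------------
    donors: List[MetabolicModel] = []
    for j, donor_name in enumerate(donor_names):
        donor = truth.copy()
        donor.id = donor_name
        rename = {g: f"d{j}|{g}" for g in donor.genes}
        donor.genes = {rename[g]: gene for g, gene in donor.genes.items()}
        for gene_obj in donor.genes.values():
            gene_obj.id = f"d{j}|{gene_obj.id}" if not gene_obj.id.startswith(f"d{j}|") else gene_obj.id

        def rn(expr: GprExpr) -> GprExpr:
            if expr.op == "leaf":
                return GprExpr.leaf(rename[expr.gene])
            if expr.op in ("and", "or"):
                return GprExpr(expr.op, children=tuple(rn(c) for c in expr.children))
            return expr

        for rxn in donor.reactions.values():
            rxn.gpr = rn(rxn.gpr)
        donors.append(donor)

    # --- transferability ground truth ------------------------------------
    for rxn in truth.reactions.values():
        genes = rxn.gpr.genes()
        if rxn.is_boundary or not genes:
            continue
        if genes & ledger.covered_genes:
            ledger.transferable_reactions.add(rxn.id)
        if any(set(branch) <= ledger.covered_genes for branch in rxn.gpr.to_dnf()):
            ledger.resolvable_reactions.add(rxn.id)

    return SyntheticUniverse(truth, donors, omap, ledger, medium)


# ---------------------------------------------------------------------------
# FAME generator
# ---------------------------------------------------------------------------


def make_fame(
    seed: int,
    b: Sequence[float],
    m: Sequence[float],
    x0: float,
    sigma: float = 0.0,
    n_samples: int = 12,
    x_span: float = 35.0,
    fatty_acids: Optional[Sequence[str]] = None,
) -> FameDataset:
    """Draw FAME samples from ``y_k = m_k (x - x0) + b_k`` plus noise.

    Total contents ``x`` are uniform on ``[x0, x0 + x_span]`` wt% CDW
    (spanning low-lipid to strongly lipid-accumulating media); Gaussian
    noise (sd ``sigma`` wt%) is truncated at zero and the closure
    ``sum_k y_k = x`` restored by rescaling.
    """
    b = np.asarray(b, dtype=float)
    m = np.asarray(m, dtype=float)
    if b.shape != m.shape:
        raise ModelError("b and m must have matching shapes")
    if (b < 0).any() or (m < 0).any():
        raise ModelError("b and m must be nonnegative")
    if abs(m.sum() - 1.0) > 1e-9:
        raise ModelError(f"slopes must sum to 1 (got {m.sum()})")
    if abs(b.sum() - x0) > 1e-9:
        raise ModelError(f"intercepts must sum to x0={x0} (got {b.sum()})")
    if n_samples < 3:
        raise ModelError("need n_samples >= 3")
    names = list(fatty_acids) if fatty_acids is not None else [
        f"fa{k}" for k in range(len(b))
    ]
    rng = np.random.default_rng(seed)
    xs = rng.uniform(x0, x0 + x_span, size=n_samples)
    samples = []
    for i, x in enumerate(sorted(xs)):
        y = m * (x - x0) + b
        if sigma > 0:
            y = np.clip(y + rng.normal(0.0, sigma, size=y.shape), 0.0, None)
        total = y.sum()
        if total > 0:
            y = y * (x / total)
        samples.append(FameSample(condition=f"cond{i:02d}",
                                  y=dict(zip(names, map(float, y)))))
    return FameDataset(samples)


# ---------------------------------------------------------------------------
# Phenotype / fitness generator
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeFitnessLedger:
    true_growth: Dict[str, bool]
    flipped_wells: List[str]
    true_essential: Dict[Tuple[str, str], bool]
    flipped_pairs: List[Tuple[str, str]]


def make_phenotype_and_fitness(
    seed: int,
    model: MetabolicModel,
    media: Mapping[str, Mapping[str, float]],
    flip_rate: float = 0.0,
    genes: Optional[Sequence[str]] = None,
    cutoff: float = FITNESS_CUTOFF,
) -> Tuple[PhenotypeArray, FitnessTable, PhenotypeFitnessLedger]:
    """Phenotype calls and fitness scores from the model's own predictions.

    Observed growth per condition is the model's FBA call XOR a Bernoulli
    flip; fitness scores are drawn from N(0, 0.5) for observed-non-essential
    and N(-4, 1) for observed-essential (gene, condition) pairs — redrawn in
    the rare case a draw crosses the distribution midpoint (the default
    cutoff), so the score binarization reproduces the intended labels
    exactly and flipped pairs coincide with the report's disagreements.
    """
    if not 0.0 <= flip_rate <= 1.0:
        raise ModelError(f"flip_rate must lie in [0,1], got {flip_rate}")
    rng = np.random.default_rng(seed)
    conditions = sorted(media)

    wells: List[PhenotypeWell] = []
    true_growth: Dict[str, bool] = {}
    flipped_wells: List[str] = []
    for i, cond in enumerate(conditions):
        res = fba(model, medium=media[cond])
        grows = bool(res.ok and res.objective_value > GROWTH_TOL)
        true_growth[cond] = grows
        observed = grows
        if rng.random() < flip_rate:
            observed = not observed
            flipped_wells.append(cond)
        a750 = 0.05
        a590 = a750 + (0.8 if observed else 0.02)
        wells.append(PhenotypeWell(
            plate="PM1", well=f"A{i + 1:02d}", substrate=cond, element_class="C",
            a590=a590, a750=a750, observed_growth=observed,
        ))

    gene_list = sorted(genes) if genes is not None else sorted(model.genes)
    rows: List[FitnessRow] = []
    true_essential: Dict[Tuple[str, str], bool] = {}
    flipped_pairs: List[Tuple[str, str]] = []
    for cond in conditions:
        deletions = single_gene_deletions(model, medium=media[cond], genes=gene_list)
        for g in gene_list:
            truth = deletions[g].essential
            true_essential[(g, cond)] = truth
            observed = truth
            if rng.random() < flip_rate:
                observed = not observed
                flipped_pairs.append((g, cond))
            if observed:
                score = float(rng.normal(-4.0, 1.0))
                while score >= cutoff:
                    score = float(rng.normal(-4.0, 1.0))
            else:
                score = float(rng.normal(0.0, 0.5))
                while score < cutoff:
                    score = float(rng.normal(0.0, 0.5))
            rows.append(FitnessRow(gene=g, condition=cond, score=score,
                                   global_essential=False))
    array = PhenotypeArray(wells)
    table = FitnessTable(rows, cutoff=cutoff)
    ledger = PhenotypeFitnessLedger(true_growth, flipped_wells,
                                    true_essential, flipped_pairs)
    return array, table, ledger
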