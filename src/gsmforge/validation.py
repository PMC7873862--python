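"""Concordance of model predictions with phenotype arrays and fitness data.

Two validation currencies:

* growth-phenotype arrays (Biolog-PM-like): per-well respiration calls on
  single-substrate media, compared with FBA growth calls after swapping the
  element-class source exchange to the well's substrate;
* gene-fitness tables (RB-TDNAseq-like): per-(gene, condition) fitness
  scores, binarized to observed essentiality, compared with in-silico
  single-gene deletions.

Both are scored with a 2x2 confusion matrix, accuracy (percent) and the
Matthews correlation coefficient, and essentiality results are partitioned
into always / never / conditionally essential genes from the observed
calls.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .core import MetabolicModel, ModelError, Reaction, ReactionKind
from .fba import (
    ESSENTIALITY_THRESHOLD,
    GROWTH_TOL,
    MediumValue,
    fba,
    single_gene_deletions,
)

__all__ = [
    "ConfusionStats",
    "confusion",
    "PhenotypeWell",
    "PhenotypeArray",
    "SubstrateMap",
    "FitnessTable",
    "read_phenotype_array",
    "read_substrate_map",
    "read_fitness_table",
    "simulate_phenotypes",
    "PhenotypeReport",
    "essentiality_concordance",
    "EssentialityReport",
    "FITNESS_CUTOFF",
]

#: Default fitness-score cutoff (log2 ratio) below which a gene is called
#: essential in a condition.
FITNESS_CUTOFF = -2.0


# ---------------------------------------------------------------------------
# Confusion statistics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionStats:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        """Accuracy in percent."""
        if self.n == 0:
            return 0.0
        return 100.0 * (self.tp + self.tn) / self.n

    @property
    def mcc(self) -> float:
        """Matthews correlation coefficient; 0 when any marginal is empty."""
        denom = ((self.tp + self.fp) * (self.tp + self.fn)
                 * (self.tn + self.fp) * (self.tn + self.fn))
        if denom == 0:
            return 0.0
        return (self.tp * self.tn - self.fp * self.fn) / math.sqrt(denom)

    def summary(self) -> Dict[str, float]:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "n": self.n, "accuracy_pct": round(self.accuracy, 1),
            "mcc": self.mcc,
        }


def confusion(pred: Sequence[bool], obs: Sequence[bool]) -> ConfusionStats:
    """2x2 confusion counts for predicted vs observed boolean calls."""
    if len(pred) != len(obs):
        raise ModelError(f"length mismatch: {len(pred)} predictions vs {len(obs)} observations")
    if len(pred) == 0:
        raise ModelError("empty prediction/observation lists")
    tp = tn = fp = fn = 0
    for p, o in zip(pred, obs):
        if p and o:
            tp += 1
        elif not p and not o:
            tn += 1
        elif p and not o:
            fp += 1
        else:
            fn += 1
    return ConfusionStats(tp, tn, fp, fn)


# ---------------------------------------------------------------------------
# Phenotype arrays
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeWell:
    plate: str
    well: str
    substrate: str
    element_class: str  # C | N | P | S
    a590: Optional[float] = None
    a750: Optional[float] = None
    observed_growth: Optional[bool] = None

    def observed(self, signal_threshold: float) -> bool:
        """Respiration call: pre-binarized value wins, else dye signal."""
        if self.observed_growth is not None:
            return self.observed_growth
        if self.a590 is None or self.a750 is None:
            raise ModelError(f"well {self.plate}/{self.well} has neither "
                             "absorbances nor an observed_growth call")
        return (self.a590 - self.a750) >= signal_threshold


@dataclass
class PhenotypeArray:
    wells: List[PhenotypeWell] = field(default_factory=list)


@dataclass
class SubstrateMap:
    """Substrate name -> metabolite ids (several for anomeric forms)."""

    entries: Dict[str, List[str]] = field(default_factory=dict)

    def lookup(self, substrate: str) -> List[str]:
        return self.entries.get(substrate, [])


def read_phenotype_array(path: str) -> PhenotypeArray:
    """TSV: plate, well, substrate, element_class, a590, a750 [, observed_growth]."""
    wells = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            obs = row.get("observed_growth", "")
            wells.append(PhenotypeWell(
                plate=row["plate"], well=row["well"], substrate=row["substrate"],
                element_class=row["element_class"],
                a590=float(row["a590"]) if row.get("a590") else None,
                a750=float(row["a750"]) if row.get("a750") else None,
                observed_growth=None if obs in ("", None) else obs.strip().lower() in ("1", "true", "yes"),
            ))
    return PhenotypeArray(wells)


def read_substrate_map(path: str) -> SubstrateMap:
    """TSV: substrate, metabolite_id (repeated rows for multiple ids)."""
    entries: Dict[str, List[str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            entries.setdefault(row["substrate"], []).append(row["metabolite_id"])
    return SubstrateMap(entries)


@dataclass
class PhenotypeReport:
    predictions: Dict[Tuple[str, str], bool]  # (plate, well) -> predicted growth
    observations: Dict[Tuple[str, str], bool]
    excluded: List[Tuple[str, str, str]]      # (plate, well, reason)
    created_exchanges: List[str]
    stats: ConfusionStats

    @property
    def n_simulable(self) -> int:
        return len(self.predictions)


def _exchange_for(model: MetabolicModel, met_id: str,
                  created: List[str]) -> str:
    """Find the exchange reaction for an extracellular metabolite, creating
    one (logged) when missing."""
    for rxn in model.reactions.values():
        if rxn.kind == ReactionKind.EXCHANGE and rxn.stoichiometry.get(met_id) is not None:
            return rxn.id
    rid = f"EX_{met_id}"
    if rid in model.reactions:
        return rid
    model.add_reaction(Reaction(id=rid, stoichiometry={met_id: -1.0},
                                lower_bound=0.0, upper_bound=1000.0,
                                kind=ReactionKind.EXCHANGE))
    created.append(rid)
    return rid


def simulate_phenotypes(
    model: MetabolicModel,
    array: PhenotypeArray,
    substrate_map: SubstrateMap,
    base_medium: Mapping[str, MediumValue],
    element_sources: Mapping[str, str],
    uptake_rate: float = 10.0,
    growth_tol: float = GROWTH_TOL,
    signal_threshold: float = 0.2,
) -> PhenotypeReport:
    """Predict growth per well by swapping the element-class source.

    ``element_sources`` names the base medium's exchange for each element
    class (e.g. carbon -> glucose exchange).  For each simulable well the
    class source is closed, the mapped substrate's exchange opened at
    ``uptake_rate`` (all ids opened for multi-metabolite substrates), and
    FBA growth-called against ``growth_tol``.  Wells whose substrate has no
    metabolite in the model are counted but excluded from the statistics.
    For nitrogen/phosphorus/sulfur plates the carbon source of the base
    medium stays open, matching how such arrays are run with glucose added.
    """
    work = model.copy()
    created: List[str] = []
    predictions: Dict[Tuple[str, str], bool] = {}
    observations: Dict[Tuple[str, str], bool] = {}
    excluded: List[Tuple[str, str, str]] = []
    for well in array.wells:
        key = (well.plate, well.well)
        met_ids = [m for m in substrate_map.lookup(well.substrate)
                   if m in work.metabolites]
        if not met_ids:
            excluded.append((well.plate, well.well,
                             f"substrate {well.substrate!r} not in model"))
            continue
        if well.element_class not in element_sources:
            excluded.append((well.plate, well.well,
                             f"no base source for element class {well.element_class!r}"))
            continue
        medium = dict(base_medium)
        medium[element_sources[well.element_class]] = 0.0
        for met_id in met_ids:
            medium[_exchange_for(work, met_id, created)] = -abs(uptake_rate)
        res = fba(work, medium=medium)
        growth = res.objective_value if res.ok else 0.0
        predictions[key] = bool(growth is not None and growth > growth_tol)
        observations[key] = well.observed(signal_threshold)
    keys = sorted(predictions)
    stats = confusion([predictions[k] for k in keys], [observations[k] for k in keys])
    return PhenotypeReport(predictions, observations, excluded, created, stats)


# ---------------------------------------------------------------------------
# Gene-fitness concordance
# ---------------------------------------------------------------------------


@dataclass
class FitnessRow:
    gene: str
    condition: str
    score: float
    global_essential: bool = False


@dataclass
class FitnessTable:
    rows: List[FitnessRow] = field(default_factory=list)
    cutoff: float = FITNESS_CUTOFF

    def observed_essential(self, row: FitnessRow) -> bool:
        return row.global_essential or row.score < self.cutoff

    def conditions(self) -> List[str]:
        seen: List[str] = []
        for r in self.rows:
            if r.condition not in seen:
                seen.append(r.condition)
        return seen

    def genes(self) -> List[str]:
        seen: List[str] = []
        for r in self.rows:
            if r.gene not in seen:
                seen.append(r.gene)
        return seen


def read_fitness_table(path: str, cutoff: float = FITNESS_CUTOFF) -> FitnessTable:
    """TSV: gene, condition, score, global_essential."""
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            rows.append(FitnessRow(
                gene=row["gene"], condition=row["condition"],
                score=float(row["score"]),
                global_essential=str(row.get("global_essential", "")).strip().lower()
                in ("1", "true", "yes"),
            ))
    return FitnessTable(rows, cutoff=cutoff)


@dataclass
class EssentialityReport:
    pooled: ConfusionStats
    per_condition: Dict[str, ConfusionStats]
    always_essential: List[str]
    never_essential: List[str]
    conditionally_essential: List[str]
    conditional_stats: Optional[ConfusionStats]
    predicted: Dict[Tuple[str, str], bool]
    observed: Dict[Tuple[str, str], bool]
    config: Dict[str, float] = field(default_factory=dict)

    @property
    def evaluated_genes(self) -> int:
        return (len(self.always_essential) + len(self.never_essential)
                + len(self.conditionally_essential))


def essentiality_concordance(
    model: MetabolicModel,
    fitness: FitnessTable,
    media: Mapping[str, Mapping[str, MediumValue]],
    exclude_genes: Iterable[str] = (),
    essentiality_threshold: float = ESSENTIALITY_THRESHOLD,
) -> EssentialityReport:
    """Score in-silico deletion essentiality against a fitness table.

    Evaluates genes present in both the model and the table (minus the
    exclusion list, e.g. mitochondrially encoded genes the insertion data
    cannot reach), over every condition in the table; each condition needs
    a medium.  Reports pooled and per-condition confusion statistics plus
    the partition of genes into always / never / conditionally essential
    from the observed calls, with accuracy scored separately on the
    conditional subset.
    """
    excluded = set(exclude_genes)
    genes = [g for g in fitness.genes() if g in model.genes and g not in excluded]
    conditions = fitness.conditions()
    for cond in conditions:
        if cond not in media:
            raise ModelError(f"condition {cond!r} has no medium")

    observed: Dict[Tuple[str, str], bool] = {}
    for row in fitness.rows:
        if row.gene in genes:
            observed[(row.gene, row.condition)] = fitness.observed_essential(row)

    predicted: Dict[Tuple[str, str], bool] = {}
    per_condition: Dict[str, ConfusionStats] = {}
    for cond in conditions:
        cond_genes = [g for g in genes if (g, cond) in observed]
        if not cond_genes:
            continue
        results = single_gene_deletions(
            model, medium=media[cond], genes=cond_genes,
            essentiality_threshold=essentiality_threshold,
        )
        for g in cond_genes:
            predicted[(g, cond)] = results[g].essential
        per_condition[cond] = confusion(
            [predicted[(g, cond)] for g in cond_genes],
            [observed[(g, cond)] for g in cond_genes],
        )

    keys = sorted(predicted)
    pooled = confusion([predicted[k] for k in keys], [observed[k] for k in keys])

    always, never, conditional = [], [], []
    for g in genes:
        calls = [observed[(g, c)] for c in conditions if (g, c) in observed]
        if not calls:
            continue
        if all(calls):
            always.append(g)
        elif not any(calls):
            never.append(g)
        else:
            conditional.append(g)

    cond_keys = [k for k in keys if k[0] in set(conditional)]
    conditional_stats = (
        confusion([predicted[k] for k in cond_keys], [observed[k] for k in cond_keys])
        if cond_keys else None
    )
    return EssentialityReport(
        pooled=pooled, per_condition=per_condition,
        always_essential=sorted(always), never_essential=sorted(never),
        conditionally_essential=sorted(conditional),
        conditional_stats=conditional_stats,
        predicted=predicted, observed=observed,
        config={"fitness_cutoff": fitness.cutoff,
                "essentiality_threshold": essentiality_threshold},
    )
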