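"""Flux-balance analysis and leave-one-out amino-acid auxotrophy screening.

FBA maximizes biomass flux over the steady-state polytope
``{v : S v = 0, l <= v <= u}``; the growth medium sets each exchange
reaction's lower bound to minus the permitted uptake rate (secretion is
always allowed up to the model's own upper bound).  A genome is called
auxotrophic for an amino acid when the model grows on the full medium
but not after removing only that amino acid's exchange entry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .aminoacids import AMINO_ACIDS
from .errors import InputError
from .model_io import GrowthMedium, MetabolicModel

logger = logging.getLogger(__name__)

#: default flux tolerance below which growth counts as "no growth"
ZERO_TOL = 1e-6


@dataclass
class FBASolution:
    status: str  # 'optimal' | 'infeasible' | 'unbounded'
    growth_rate: float | None  # biomass flux, defined iff optimal
    fluxes: dict[str, float] | None = None


@dataclass
class GenomeAuxotrophy:
    """Auxotrophy calls for one genome model."""

    genome_id: str
    calls: dict[str, bool]  # AminoAcid code -> auxotrophic?
    growth_full_medium: float
    non_growing: bool = False  # no growth even on the full medium

    @property
    def n_auxotrophies(self) -> int:
        return sum(self.calls.values())


@dataclass
class AuxotrophyProfile:
    """Genome x amino-acid auxotrophy matrix with per-genome counts."""

    entries: dict[str, GenomeAuxotrophy] = field(default_factory=dict)
    excluded: dict[str, str] = field(default_factory=dict)  # genome_id -> reason

    def is_auxotrophic(self, genome_id: str, aa: str) -> bool:
        return self.entries[genome_id].calls.get(aa, False)

    def n_auxotrophies(self, genome_id: str) -> int:
        return self.entries[genome_id].n_auxotrophies


def _medium_bounds(model: MetabolicModel, medium: GrowthMedium) -> list[tuple[float, float]]:
    """Per-reaction bounds with the medium applied to exchange reactions."""
    exchange_rids = {rid: mid for mid, rid in model.exchange_map.items()}
    bounds = []
    for r in model.reactions:
        lb, ub = r.lower_bound, r.upper_bound
        if r.id in exchange_rids:
            mid = exchange_rids[r.id]
            uptake = medium.entries.get(mid, 0.0)
            lb = -uptake
        bounds.append((lb, ub))
    return bounds


def solve_fba(
    model: MetabolicModel,
    medium: GrowthMedium,
    return_fluxes: bool = False,
) -> FBASolution:
    """Maximize biomass flux subject to steady state and medium bounds.

    Returns an optimal objective (solver feasibility tolerance 1e-9) or a
    flagged infeasible/unbounded status.
    """
    medium.validate()
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rxn_ids = model.reaction_ids()
    n = len(rxn_ids)
    S = np.zeros((len(met_index), n))
    for j, r in enumerate(model.reactions):
        for mid, coeff in r.stoichiometry.items():
            S[met_index[mid], j] = coeff
    c = np.zeros(n)
    c[rxn_ids.index(model.biomass_reaction_id)] = -1.0  # linprog minimizes
    bounds = _medium_bounds(model, medium)
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": 1e-9, "dual_feasibility_tolerance": 1e-9},
    )
    if res.status == 2:
        return FBASolution("infeasible", None)
    if res.status == 3:
        return FBASolution("unbounded", None)
    if res.status != 0:  # pragma: no cover - solver-internal failures
        raise RuntimeError(f"LP solver failure: {res.message}")
    fluxes = dict(zip(rxn_ids, res.x)) if return_fluxes else None
    return FBASolution("optimal", -res.fun, fluxes)


def predict_auxotrophies(
    model: MetabolicModel,
    medium: GrowthMedium,
    amino_acid_exchange_map: dict[str, str],
    zero_tol: float = ZERO_TOL,
) -> GenomeAuxotrophy:
    """Leave-one-out screen: for each amino acid, re-solve the model with
    that amino acid's medium entry removed.

    Auxotrophic iff growth without the amino acid < *zero_tol* while
    growth on the full medium >= *zero_tol*.  Amino acids with no
    exchange mapping in the model are prototroph-by-absence (a model
    cannot be starved of a metabolite it cannot import).  If the model
    does not grow on the full medium the genome is flagged non-growing
    and every call is False/undefined.
    """
    full = solve_fba(model, medium)
    growth_full = full.growth_rate if full.status == "optimal" else 0.0
    calls: dict[str, bool] = {}
    if growth_full is None or growth_full < zero_tol:
        logger.warning("model %s: no growth on the full medium", model.model_id)
        return GenomeAuxotrophy(model.model_id, {aa: False for aa in AMINO_ACIDS},
                                growth_full or 0.0, non_growing=True)
    for aa in AMINO_ACIDS:
        met = amino_acid_exchange_map.get(aa)
        if met is None or met not in medium.entries:
            logger.info(
                "model %s: no exchange/medium entry for %s; prototroph by absence",
                model.model_id, aa,
            )
            calls[aa] = False
            continue
        sol = solve_fba(model, medium.without(met))
        growth_without = sol.growth_rate if sol.status == "optimal" else 0.0
        calls[aa] = bool(growth_without < zero_tol)
    return GenomeAuxotrophy(model.model_id, calls, growth_full)


def screen_catalog(
    models: list[MetabolicModel],
    medium: GrowthMedium,
    amino_acid_exchange_map: dict[str, str],
    min_completeness: float = 85.0,
    zero_tol: float = ZERO_TOL,
) -> AuxotrophyProfile:
    """Screen a model catalog, profiling only models whose genome
    completeness is >= *min_completeness* percent (inclusive); excluded
    models are listed in the profile's exclusion report with a reason."""
    seen: set[str] = set()
    for m in models:
        if m.model_id in seen:
            raise InputError(f"duplicate model_id {m.model_id!r}")
        seen.add(m.model_id)
    if not models:
        logger.warning("screen_catalog: empty model list")
    profile = AuxotrophyProfile()
    for m in models:
        if m.completeness < min_completeness:
            profile.excluded[m.model_id] = (
                f"completeness {m.completeness:g} < {min_completeness:g}"
            )
            continue
        entry = predict_auxotrophies(m, medium, amino_acid_exchange_map, zero_tol)
        if entry.non_growing:
            profile.excluded[m.model_id] = "no growth on full medium"
            continue
        profile.entries[m.model_id] = entry
    return profile


def write_auxotrophy_profile(profile: AuxotrophyProfile, path) -> None:
    """Auxotrophy TSV: genome_id, one 0/1 column per amino acid,
    n_auxotrophies, growth_full."""
    with open(path, "w") as fh:
        fh.write("genome_id\t" + "\t".join(AMINO_ACIDS) + "\tn_auxotrophies\tgrowth_full\n")
        for gid, e in profile.entries.items():
            row = "\t".join(str(int(e.calls.get(aa, False))) for aa in AMINO_ACIDS)
            fh.write(f"{gid}\t{row}\t{e.n_auxotrophies}\t{e.growth_full_medium:.10g}\n")


def write_exclusion_report(profile: AuxotrophyProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\treason\n")
        for gid, reason in profile.excluded.items():
            fh.write(f"{gid}\t{reason}\n")


def read_auxotrophy_profile(path) -> AuxotrophyProfile:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    profile = AuxotrophyProfile()
    for gid, row in df.iterrows():
        calls = {aa: bool(int(row[aa])) for aa in AMINO_ACIDS}
        profile.entries[str(gid)] = GenomeAuxotrophy(
            str(gid), calls, float(row["growth_full"])
        )
    return profile
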