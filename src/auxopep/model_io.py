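"""Domain types and file I/O for genome-scale metabolic models and catalogs.

The canonical interchange format for metabolic models is a small JSON
dialect (documented below); SBML Level 3 files can be imported onto the
same in-memory type when python-libsbml is available.  Flux units are
treated as abstract, mutually consistent units throughout — no conversion
is ever performed.

JSON model schema (one object per file)::

    {
      "model_id": str,
      "metabolites": [{"id": str, "compartment": "cytosol"|"extracellular"}, ...],
      "reactions":   [{"id": str,
                       "stoichiometry": {metabolite_id: signed float, ...},
                       "lower_bound": float, "upper_bound": float}, ...],
      "biomass": str,                      # reaction id of the biomass objective
      "exchanges": {metabolite_id: reaction_id, ...},
      "completeness": float                # percent, 0..100
    }

Exchange reactions follow the usual convention: exactly one extracellular
metabolite with coefficient -1, negative flux = uptake, positive = secretion.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .errors import InputError, ParseError, ValidationError

logger = logging.getLogger(__name__)

COMPARTMENTS = ("cytosol", "extracellular")


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str  # 'cytosol' | 'extracellular'


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: dict[str, float]  # metabolite id -> signed coefficient
    lower_bound: float
    upper_bound: float


@dataclass
class MetabolicModel:
    """A stoichiometric network with flux bounds and a biomass objective."""

    model_id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_reaction_id: str
    exchange_map: dict[str, str]  # extracellular metabolite id -> reaction id
    completeness: float  # percent in [0, 100]

    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def validate(self) -> None:
        """Check every structural invariant; raise ValidationError listing
        all failures at once."""
        failures: list[str] = []
        met_ids = self.metabolite_ids()
        if len(set(met_ids)) != len(met_ids):
            failures.append("duplicate metabolite ids")
        rxn_ids = self.reaction_ids()
        if len(set(rxn_ids)) != len(rxn_ids):
            failures.append("duplicate reaction ids")
        comp = {m.id: m.compartment for m in self.metabolites}
        for m in self.metabolites:
            if m.compartment not in COMPARTMENTS:
                failures.append(
                    f"metabolite {m.id}: unknown compartment {m.compartment!r}"
                )
        for r in self.reactions:
            for mid in r.stoichiometry:
                if mid not in comp:
                    failures.append(
                        f"reaction {r.id}: undeclared metabolite {mid}"
                    )
            if r.lower_bound > r.upper_bound:
                failures.append(
                    f"reaction {r.id}: lower_bound {r.lower_bound} > "
                    f"upper_bound {r.upper_bound}"
                )
        if self.biomass_reaction_id not in rxn_ids:
            failures.append(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )
        by_id = {r.id: r for r in self.reactions}
        for mid, rid in self.exchange_map.items():
            r = by_id.get(rid)
            if r is None:
                failures.append(f"exchange for {mid}: reaction {rid} missing")
                continue
            if len(r.stoichiometry) != 1:
                failures.append(
                    f"exchange {rid}: must involve exactly one metabolite"
                )
                continue
            (only_mid, coeff), = r.stoichiometry.items()
            if only_mid != mid:
                failures.append(
                    f"exchange {rid}: maps metabolite {mid} but touches {only_mid}"
                )
            if comp.get(only_mid) != "extracellular":
                failures.append(f"exchange {rid}: metabolite not extracellular")
            if coeff != -1:
                failures.append(
                    f"exchange {rid}: coefficient must be -1, got {coeff}"
                )
        if not (0 <= self.completeness <= 100):
            failures.append(f"completeness {self.completeness} outside [0, 100]")
        if failures:
            raise ValidationError(failures)


@dataclass
class GrowthMedium:
    """Maximum uptake rate per extracellular metabolite (nonnegative flux)."""

    entries: dict[str, float]

    def validate(self) -> None:
        bad = [m for m, v in self.entries.items() if v < 0]
        if bad:
            raise ValidationError(
                [f"medium uptake rate for {m} is negative" for m in bad]
            )

    def without(self, metabolite_id: str) -> "GrowthMedium":
        """A copy of the medium with one component removed (leave-one-out)."""
        return GrowthMedium(
            {m: v for m, v in self.entries.items() if m != metabolite_id}
        )


@dataclass
class GenomeEntry:
    ssu_sequences: list[str]  # 16S rRNA gene sequences (nucleotide)
    protein_sequences: dict[str, str]  # protein id -> amino-acid sequence
    completeness: float  # percent


@dataclass
class ReferenceGenomeCatalog:
    """Per-genome 16S genes, proteome and assembly completeness."""

    genomes: dict[str, GenomeEntry] = field(default_factory=dict)

    def validate(self) -> None:
        failures = []
        for gid, g in self.genomes.items():
            if not (0 <= g.completeness <= 100):
                failures.append(f"{gid}: completeness outside [0, 100]")
            if any(not s for s in g.ssu_sequences):
                failures.append(f"{gid}: empty 16S sequence")
            if any(not s for s in g.protein_sequences.values()):
                failures.append(f"{gid}: empty protein sequence")
        if failures:
            raise ValidationError(failures)


# ---------------------------------------------------------------------------
# JSON model I/O


def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "model_id": model.model_id,
        "metabolites": [
            {"id": m.id, "compartment": m.compartment} for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
            }
            for r in model.reactions
        ],
        "biomass": model.biomass_reaction_id,
        "exchanges": dict(model.exchange_map),
        "completeness": model.completeness,
    }


def _model_from_dict(d: dict, source: str) -> MetabolicModel:
    try:
        mets = [
            Metabolite(m["id"], m["compartment"]) for m in d["metabolites"]
        ]
        rxns = [
            Reaction(
                r["id"],
                {k: float(v) for k, v in r["stoichiometry"].items()},
                float(r["lower_bound"]),
                float(r["upper_bound"]),
            )
            for r in d["reactions"]
        ]
        model = MetabolicModel(
            model_id=d["model_id"],
            metabolites=mets,
            reactions=rxns,
            biomass_reaction_id=d["biomass"],
            exchange_map=dict(d["exchanges"]),
            completeness=float(d["completeness"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{source}: malformed model element: {exc!r}") from exc
    model.validate()
    return model


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Serialize a model to the canonical JSON dialect (stable key order)."""
    payload = json.dumps(_model_to_dict(model), indent=1, sort_keys=True)
    Path(path).write_text(payload + "\n")


def read_model(path: str | Path, format: str = "json") -> MetabolicModel:
    """Read and validate a metabolic model from *path*.

    Parameters
    ----------
    path : file path
    format : {'json', 'sbml'}
        'json' reads the canonical dialect; 'sbml' imports SBML Level 3
        (requires python-libsbml).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"model file does not exist: {path}")
    if format == "json":
        try:
            d = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON: {exc}") from exc
        return _model_from_dict(d, str(path))
    if format == "sbml":
        return _read_sbml(path)
    raise InputError(f"unknown model format: {format!r}")


def _read_sbml(path: Path) -> MetabolicModel:
    """Import an SBML Level 3 (FBC) model onto the canonical type.

    Boundary species are treated as extracellular; compartments other
    than a recognised cytosol/extracellular pair map to cytosol with a
    warning.  Exchange reactions are detected as single-species reactions
    on extracellular metabolites with coefficient -1.
    """
    try:
        import libsbml
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise InputError("SBML import requires python-libsbml") from exc

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getError(0)
        raise ParseError(f"{path}: SBML error: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ParseError(f"{path}: no model element in SBML document")

    extracellular_compartments = set()
    for i in range(sbml_model.getNumCompartments()):
        c = sbml_model.getCompartment(i)
        name = (c.getName() or c.getId()).lower()
        if "extracellular" in name or name in ("e", "e0", "out", "external"):
            extracellular_compartments.add(c.getId())

    mets: list[Metabolite] = []
    for i in range(sbml_model.getNumSpecies()):
        s = sbml_model.getSpecies(i)
        if s.getBoundaryCondition() or s.getCompartment() in extracellular_compartments:
            comp = "extracellular"
        else:
            if s.getCompartment() not in extracellular_compartments and sbml_model.getNumCompartments() > 2:
                logger.warning(
                    "SBML compartment %s mapped to cytosol", s.getCompartment()
                )
            comp = "cytosol"
        mets.append(Metabolite(s.getId(), comp))
    comp_of = {m.id: m.compartment for m in mets}

    fbc = sbml_model.getPlugin("fbc")
    biomass_id = None
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getActiveObjective() or fbc.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            biomass_id = obj.getFluxObjective(0).getReaction()

    def _bound(rxn, which: str) -> float:
        plug = rxn.getPlugin("fbc")
        default = -1000.0 if which == "lower" else 1000.0
        if plug is not None:
            pid = (
                plug.getLowerFluxBound()
                if which == "lower"
                else plug.getUpperFluxBound()
            )
            if pid:
                par = sbml_model.getParameter(pid)
                if par is not None:
                    return par.getValue()
        kl = rxn.getKineticLaw()
        if kl is not None:
            par = kl.getParameter("LOWER_BOUND" if which == "lower" else "UPPER_BOUND")
            if par is not None:
                return par.getValue()
        return default if rxn.getReversible() or which == "upper" else 0.0

    rxns: list[Reaction] = []
    exchange_map: dict[str, str] = {}
    for i in range(sbml_model.getNumReactions()):
        r = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(r.getNumReactants()):
            sr = r.getReactant(j)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for j in range(r.getNumProducts()):
            sr = r.getProduct(j)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        rxns.append(
            Reaction(r.getId(), stoich, _bound(r, "lower"), _bound(r, "upper"))
        )
        if (
            len(stoich) == 1
            and next(iter(stoich.values())) == -1
            and comp_of[next(iter(stoich))] == "extracellular"
        ):
            exchange_map[next(iter(stoich))] = r.getId()

    if biomass_id is None:
        candidates = [r.id for r in rxns if "biomass" in r.id.lower()]
        if not candidates:
            raise ParseError(f"{path}: cannot identify a biomass objective")
        biomass_id = candidates[0]

    model = MetabolicModel(
        model_id=sbml_model.getId() or path.stem,
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id=biomass_id,
        exchange_map=exchange_map,
        completeness=100.0,
    )
    model.validate()
    return model


def write_medium(medium: GrowthMedium, path: str | Path) -> None:
    medium.validate()
    Path(path).write_text(json.dumps(medium.entries, indent=1, sort_keys=True) + "\n")


def read_medium(path: str | Path) -> GrowthMedium:
    path = Path(path)
    if not path.exists():
        raise InputError(f"medium file does not exist: {path}")
    try:
        entries = {str(k): float(v) for k, v in json.loads(path.read_text()).items()}
    except (json.JSONDecodeError, TypeError, ValueError, AttributeError) as exc:
        raise ParseError(f"{path}: malformed medium file: {exc!r}") from exc
    medium = GrowthMedium(entries)
    medium.validate()
    return medium


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of (header, sequence).

    Sequences are uppercased; multi-line records are concatenated; an
    empty file yields an empty list; a record with an empty sequence is
    a parse error.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file does not exist: {path}")
    from Bio import SeqIO

    records: list[tuple[str, str]] = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            if not seq:
                raise ParseError(f"{path}: record {rec.description!r} has empty sequence")
            records.append((rec.description, seq))
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# catalog I/O (FASTA per genome + completeness table)


def write_catalog(catalog: ReferenceGenomeCatalog, directory: str | Path) -> None:
    """Write a catalog as ssu.fasta / proteins.fasta / completeness.tsv.

    FASTA headers carry the genome id as prefix: ``genome|seqname``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ssu, prot = [], []
    with open(directory / "completeness.tsv", "w") as fh:
        fh.write("genome_id\tcompleteness\n")
        for gid, g in catalog.genomes.items():
            for i, s in enumerate(g.ssu_sequences):
                ssu.append((f"{gid}|ssu_{i}", s))
            for pid, s in g.protein_sequences.items():
                prot.append((f"{gid}|{pid}", s))
            fh.write(f"{gid}\t{g.completeness}\n")
    write_fasta(ssu, directory / "ssu.fasta")
    write_fasta(prot, directory / "proteins.fasta")


def read_catalog(directory: str | Path) -> ReferenceGenomeCatalog:
    directory = Path(directory)
    import csv

    genomes: dict[str, GenomeEntry] = {}
    with open(directory / "completeness.tsv") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            genomes[row["genome_id"]] = GenomeEntry([], {}, float(row["completeness"]))
    for header, seq in read_fasta(directory / "ssu.fasta"):
        gid, _ = header.split("|", 1)
        genomes[gid].ssu_sequences.append(seq)
    for header, seq in read_fasta(directory / "proteins.fasta"):
        gid, pid = header.split("|", 1)
        genomes[gid].protein_sequences[pid] = seq
    catalog = ReferenceGenomeCatalog(genomes)
    catalog.validate()
    return catalog
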