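"""Synthetic study generator with planted ground truth.

Emulates every input the pipeline consumes — a reference genome catalog
(16S genes, proteomes, completeness), per-genome metabolic models with
planted amino-acid knockouts, a MEROPS-style scan database with planted
(possibly mutated) peptidase domains and signal peptides, and a 16S
amplicon study (ASV sequences, read counts, region/group metadata) whose
community composition is tilted toward high- or low-auxotrophy and
peptidase-rich genomes per region and disease group.  The emitted truth
object records every planted feature, so each pipeline stage can be
scored for recall and precision.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .aminoacids import AMINO_ACIDS
from .errors import InputError
from .mapping import ASVTable, REGION_ORDER
from .model_io import (
    GenomeEntry,
    GrowthMedium,
    Metabolite,
    MetabolicModel,
    Reaction,
    ReferenceGenomeCatalog,
)
from .peptidases import ScanSequence, toy_signal_peptide

NT = "ACGT"
AA20 = "ARNDCQEGHILKMFPSTWYV"

#: 25-residue leader satisfying the toy signal-peptide rule
SIGNAL_PREFIX = "MKRALLAVLLAIFAQSTPALAGDSA"

#: default carbon uptake and per-amino-acid uptake rates of the full medium
CARBON_UPTAKE = 1000.0
AA_UPTAKE = 20.0
BIOMASS_CAP = 10.0


# ---------------------------------------------------------------------------
# template model and knockouts


def amino_acid_exchange_map(aa_list: tuple[str, ...] = AMINO_ACIDS) -> dict[str, str]:
    return {aa: f"{aa.lower()}_e" for aa in aa_list}


def full_medium(aa_list: tuple[str, ...] = AMINO_ACIDS) -> GrowthMedium:
    entries = {"carbon_e": CARBON_UPTAKE}
    entries.update({f"{aa.lower()}_e": AA_UPTAKE for aa in aa_list})
    return GrowthMedium(entries)


def make_template_model(aa_list: tuple[str, ...] = AMINO_ACIDS) -> MetabolicModel:
    """Minimal prototrophic model: carbon uptake feeds a generic
    biosynthetic precursor; every amino acid can be made from the
    precursor or imported; biomass consumes the precursor plus all 20
    cytosolic amino acids.

    The biomass upper bound (10) sits below the carbon-limited optimum,
    so growth is identical on the full medium and on carbon alone — the
    signature of a complete prototroph.  Reaction count is
    3 + 3 * n_aa + 1 (64 for the 20 amino acids).
    """
    mets = [
        Metabolite("carbon_e", "extracellular"),
        Metabolite("carbon_c", "cytosol"),
        Metabolite("precursor_c", "cytosol"),
    ]
    rxns = [
        Reaction("EX_carbon", {"carbon_e": -1.0}, -1000.0, 1000.0),
        Reaction("T_carbon", {"carbon_e": -1.0, "carbon_c": 1.0}, 0.0, 1000.0),
        Reaction("R_precursor", {"carbon_c": -1.0, "precursor_c": 1.0}, 0.0, 1000.0),
    ]
    exchange_map = {"carbon_e": "EX_carbon"}
    biomass_stoich: dict[str, float] = {"precursor_c": -1.0}
    for aa in aa_list:
        lo = aa.lower()
        mets.append(Metabolite(f"{lo}_e", "extracellular"))
        mets.append(Metabolite(f"{lo}_c", "cytosol"))
        rxns.append(Reaction(f"EX_{lo}", {f"{lo}_e": -1.0}, -1000.0, 1000.0))
        rxns.append(Reaction(f"T_{lo}", {f"{lo}_e": -1.0, f"{lo}_c": 1.0}, 0.0, 1000.0))
        rxns.append(
            Reaction(f"BS_{lo}", {"precursor_c": -1.0, f"{lo}_c": 1.0}, 0.0, 1000.0)
        )
        exchange_map[f"{lo}_e"] = f"EX_{lo}"
        biomass_stoich[f"{lo}_c"] = -1.0
    rxns.append(Reaction("biomass", biomass_stoich, 0.0, BIOMASS_CAP))
    model = MetabolicModel(
        model_id="template",
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id="biomass",
        exchange_map=exchange_map,
        completeness=100.0,
    )
    model.validate()
    return model


def knockout(model: MetabolicModel, aas: set[str] | frozenset[str]) -> MetabolicModel:
    """Copy of *model* with the biosynthesis reaction of each listed
    amino acid removed; the result is auxotrophic exactly for *aas*."""
    unknown = set(aas) - set(AMINO_ACIDS)
    if unknown:
        raise InputError(f"unknown amino acids in knockout set: {sorted(unknown)}")
    remove = {f"BS_{aa.lower()}" for aa in aas}
    rxns = [r for r in model.reactions if r.id not in remove]
    out = MetabolicModel(
        model_id=model.model_id,
        metabolites=list(model.metabolites),
        reactions=rxns,
        biomass_reaction_id=model.biomass_reaction_id,
        exchange_map=dict(model.exchange_map),
        completeness=model.completeness,
    )
    out.validate()
    return out


# ---------------------------------------------------------------------------
# truth bookkeeping


@dataclass
class GenomeTruth:
    auxotrophies: list[str]
    extracellular_peptidases: list[str]
    intracellular_peptidases: list[str]
    completeness: float


@dataclass
class ASVTruth:
    genome_id: str
    identity: float  # percent identity to the source genome's 16S gene


@dataclass
class SampleTruth:
    region: str | None
    group: str | None
    aux_tilt: float
    pep_tilt: float


@dataclass
class SyntheticTruth:
    genomes: dict[str, GenomeTruth] = field(default_factory=dict)
    asvs: dict[str, ASVTruth] = field(default_factory=dict)
    samples: dict[str, SampleTruth] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genomes": {g: vars(t) for g, t in self.genomes.items()},
            "asvs": {a: vars(t) for a, t in self.asvs.items()},
            "samples": {s: vars(t) for s, t in self.samples.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        truth = cls()
        truth.genomes = {g: GenomeTruth(**t) for g, t in payload["genomes"].items()}
        truth.asvs = {a: ASVTruth(**t) for a, t in payload["asvs"].items()}
        truth.samples = {s: SampleTruth(**t) for s, t in payload["samples"].items()}
        return truth


# ---------------------------------------------------------------------------
# catalog generation


def _random_seq(rng: np.random.Generator, alphabet: str, length: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), length))


def _mutate(rng: np.random.Generator, seq: str, n_mut: int, alphabet: str) -> str:
    """Substitute exactly *n_mut* distinct positions (always to a
    different character)."""
    if n_mut == 0:
        return seq
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for p in pos:
        choices = [c for c in alphabet if c != out[p]]
        out[p] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def default_scan_db(rng: np.random.Generator, n_scan: int = 12) -> list[ScanSequence]:
    """MEROPS-style scan database: random 200-residue sequences with the
    peptidase unit annotated at positions 11-190, ids drawn across
    several families (serine, cysteine, metallo, threonine)."""
    families = ["S01", "S08", "S09", "S11", "C01", "C40", "M16", "M23", "T03", "A01"]
    db = []
    for i in range(n_scan):
        fam = families[i % len(families)]
        merops_id = f"{fam}.{i + 1:03d}"
        seq = _random_seq(rng, AA20, 200)
        db.append(ScanSequence(merops_id, seq, (11, 190)))
    return db


def make_catalog(
    n_genomes: int,
    aux_rate_per_aa: float = 0.10,
    pep_gene_rate: float = 0.35,
    seed: int = 0,
    n_scan: int = 12,
    domain_mutation_rate: float = 0.01,
    ssu_length: int = 300,
    n_background_proteins: int = 4,
) -> tuple[ReferenceGenomeCatalog, list[MetabolicModel], list[ScanSequence],
           dict[str, bool], SyntheticTruth]:
    """Generate a reference catalog with planted auxotrophies and
    peptidase genes.

    Per genome: one 16S gene mutated from a shared 300-nt ancestor
    (8-15 substitutions, keeping pairwise identities >= 90%); a proteome
    of background proteins, scrambled decoys and planted scan-database
    domains (mutated at *domain_mutation_rate* per residue, secreted
    copies behind a signal-peptide leader); a knockout model for the
    drawn auxotrophy set; completeness cycling over {80, 90, 100} so the
    85%-completeness gate is exercised.  Deterministic under *seed*.
    """
    if n_genomes < 2:
        raise InputError("need at least 2 genomes")
    if not (0 <= aux_rate_per_aa <= 1 and 0 <= pep_gene_rate <= 1):
        raise InputError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ancestor = _random_seq(rng, NT, ssu_length)
    scan_db = default_scan_db(rng, n_scan)
    template = make_template_model()

    catalog = ReferenceGenomeCatalog()
    models: list[MetabolicModel] = []
    signal_table: dict[str, bool] = {}
    truth = SyntheticTruth()
    completeness_cycle = (100.0, 90.0, 80.0)

    for g in range(n_genomes):
        gid = f"G{g:04d}"
        ssu = _mutate(rng, ancestor, int(rng.integers(8, 16)), NT)
        aux_set = sorted(
            aa for aa in AMINO_ACIDS if rng.random() < aux_rate_per_aa
        )
        model = knockout(template, set(aux_set))
        model.model_id = gid
        model.completeness = completeness_cycle[g % len(completeness_cycle)]

        proteins: dict[str, str] = {}
        for b in range(n_background_proteins):
            proteins[f"{gid}_bg{b}"] = _random_seq(rng, AA20, int(rng.integers(150, 301)))
        extracellular: list[str] = []
        intracellular: list[str] = []
        for scan in scan_db:
            r = rng.random()
            n_mut = int(round(domain_mutation_rate * len(scan.sequence)))
            if r < pep_gene_rate:
                domain = _mutate(rng, scan.sequence, n_mut, AA20)
                pid = f"{gid}_sec_{scan.merops_id}"
                proteins[pid] = SIGNAL_PREFIX + domain
                extracellular.append(scan.merops_id)
            elif r < pep_gene_rate * 1.5:
                domain = _mutate(rng, scan.sequence, n_mut, AA20)
                pid = f"{gid}_cyt_{scan.merops_id}"
                proteins[pid] = "MST" + domain
                intracellular.append(scan.merops_id)
        # scrambled decoy of one scan sequence per genome
        decoy_src = scan_db[g % len(scan_db)].sequence
        decoy = "".join(
            random.Random(int(rng.integers(0, 2**31))).sample(decoy_src, len(decoy_src))
        )
        proteins[f"{gid}_decoy"] = SIGNAL_PREFIX + decoy

        for pid, seq in proteins.items():
            signal_table[pid] = toy_signal_peptide(seq)
        catalog.genomes[gid] = GenomeEntry([ssu], proteins, model.completeness)
        models.append(model)
        truth.genomes[gid] = GenomeTruth(
            auxotrophies=list(aux_set),
            extracellular_peptidases=extracellular,
            intracellular_peptidases=intracellular,
            completeness=model.completeness,
        )
    catalog.validate()
    return catalog, models, scan_db, signal_table, truth


# ---------------------------------------------------------------------------
# sample generation


@dataclass
class SampleBlock:
    """One homogeneous block of samples: region/group labels and the
    direction of the planted composition tilt (positive aux_tilt favours
    high-auxotrophy genomes; positive pep_tilt favours peptidase-rich
    genomes)."""

    region: str | None
    group: str | None
    n: int
    aux_tilt: float
    pep_tilt: float


@dataclass
class EffectConfig:
    blocks: list[SampleBlock]
    base_concentration: float = 1.0
    #: when set, the auxotrophy tilt acts on the combination of the
    #: total auxotrophy count and the indicator "genome is auxotrophic
    #: for at least one focal amino acid", so both the aggregate
    #: weighted-average effect and every focal amino acid's community
    #: abundance move in the tilt direction
    focal_amino_acids: list[str] | None = None

    @classmethod
    def region_study(cls, n_per_region: int = 30,
                     aux_effect: float = 1.0, pep_effect: float = 0.8) -> "EffectConfig":
        """Four-region design mirroring a small-vs-large-intestine study:
        auxotroph-tilted communities in the small intestine, decreasing
        along the tract, and peptidase-rich communities in the large
        intestine."""
        aux = {"duodenum": 1.0, "jejunum": 0.7, "farthest_distance": 0.4,
               "large_intestine": -1.0}
        pep = {"duodenum": -1.0, "jejunum": -0.5, "farthest_distance": -0.25,
               "large_intestine": 1.0}
        return cls([
            SampleBlock(r, None, n_per_region, aux_effect * aux[r], pep_effect * pep[r])
            for r in REGION_ORDER
        ])

    @classmethod
    def sibo_study(cls, n_per_group: int = 30,
                   aux_effect: float = 1.0, pep_effect: float = 0.8) -> "EffectConfig":
        """Duodenal case-control design: the overgrowth group shifts
        toward prototrophic, peptidase-rich genomes."""
        return cls([
            SampleBlock("duodenum", "non-SIBO", n_per_group, aux_effect, -pep_effect),
            SampleBlock("duodenum", "SIBO", n_per_group, -aux_effect, pep_effect),
        ])

    @classmethod
    def null_study(cls, n_per_region: int = 10) -> "EffectConfig":
        """Zero tilt everywhere: region labels are exchangeable."""
        return cls([SampleBlock(r, None, n_per_region, 0.0, 0.0) for r in REGION_ORDER])


#: per-ASV identity classes planted around the 97% mapping threshold
_MAPPABLE_IDENTITIES = (100.0, 98.5, 97.0)
_UNMAPPABLE_IDENTITIES = (96.0, 95.0)
ASV_LENGTH = 200


def _derive_asvs(
    rng: np.random.Generator,
    catalog: ReferenceGenomeCatalog,
    truth: SyntheticTruth,
) -> dict[str, tuple[str, str, float]]:
    """Plant one mappable ASV per genome (identity cycling over 100 /
    98.5 / 97.0) and, for every fourth genome, an additional unmappable
    ASV below the threshold.  Returns asv_id -> (sequence, genome_id,
    identity)."""
    asvs: dict[str, tuple[str, str, float]] = {}
    for g, (gid, genome) in enumerate(sorted(catalog.genomes.items())):
        ssu = genome.ssu_sequences[0]
        start = int(rng.integers(0, len(ssu) - ASV_LENGTH + 1))
        window = ssu[start : start + ASV_LENGTH]
        ident = _MAPPABLE_IDENTITIES[g % len(_MAPPABLE_IDENTITIES)]
        n_mut = int(round((100.0 - ident) / 100.0 * ASV_LENGTH))
        seq = _mutate(rng, window, n_mut, NT)
        asv_id = f"ASV_{gid}_map"
        asvs[asv_id] = (seq, gid, ident)
        truth.asvs[asv_id] = ASVTruth(gid, ident)
        if g % 4 == 0:
            ident_u = _UNMAPPABLE_IDENTITIES[(g // 4) % len(_UNMAPPABLE_IDENTITIES)]
            n_mut_u = int(round((100.0 - ident_u) / 100.0 * ASV_LENGTH))
            seq_u = _mutate(rng, window, n_mut_u, NT)
            asv_id_u = f"ASV_{gid}_unmap"
            asvs[asv_id_u] = (seq_u, gid, ident_u)
            truth.asvs[asv_id_u] = ASVTruth(gid, ident_u)
    return asvs


def make_samples(
    catalog: ReferenceGenomeCatalog,
    truth: SyntheticTruth,
    n_per_region: int = 30,
    effect_config: EffectConfig | None = None,
    seed: int = 0,
    depth: int = 10_000,
) -> tuple[ASVTable, dict[str, tuple[str | None, str | None]]]:
    """Draw a synthetic amplicon study over the catalog.

    Per sample, genome weights come from a Dirichlet whose concentration
    is ``base * exp(aux_tilt * z_aux + pep_tilt * z_pep)`` with z the
    genome's standardized planted auxotrophy (peptidase) count; reads are
    multinomial at *depth* over the planted ASVs (a genome's weight is
    split 85/15 between its mappable and unmappable ASV when both
    exist).  Region/group labels and tilts are recorded in *truth*.
    """
    if effect_config is None:
        effect_config = EffectConfig.region_study(n_per_region)
    if any(b.n < 3 for b in effect_config.blocks):
        raise InputError("each sample block needs n >= 3")
    rng = np.random.default_rng(seed)
    gids = sorted(catalog.genomes)
    n_aux = np.array(
        [len(truth.genomes[g].auxotrophies) for g in gids], dtype=float
    )
    focal = effect_config.focal_amino_acids
    focal_ind = None
    if focal:
        unknown = set(focal) - set(AMINO_ACIDS)
        if unknown:
            raise InputError(f"unknown focal amino acids: {sorted(unknown)}")
        focal_ind = np.array(
            [float(bool(set(truth.genomes[g].auxotrophies) & set(focal)))
             for g in gids],
            dtype=float,
        )
    n_pep = np.array(
        [len(truth.genomes[g].extracellular_peptidases) for g in gids], dtype=float
    )

    def _z(v: np.ndarray) -> np.ndarray:
        s = v.std()
        return (v - v.mean()) / s if s > 0 else np.zeros_like(v)

    z_aux, z_pep = _z(n_aux), _z(n_pep)
    if focal_ind is not None:
        z_aux = _z(z_aux + _z(focal_ind))

    asv_defs = _derive_asvs(rng, catalog, truth)
    asv_ids = list(asv_defs)
    # per-genome ASV weight split
    by_genome: dict[str, list[tuple[int, float]]] = {g: [] for g in gids}
    for i, aid in enumerate(asv_ids):
        _, gid, _ = asv_defs[aid]
        by_genome[gid].append((i, 1.0))
    for gid, lst in by_genome.items():
        if len(lst) == 2:
            by_genome[gid] = [(lst[0][0], 0.85), (lst[1][0], 0.15)]

    counts = {}
    metadata: dict[str, tuple[str | None, str | None]] = {}
    for block in effect_config.blocks:
        alpha = effect_config.base_concentration * np.exp(
            block.aux_tilt * z_aux + block.pep_tilt * z_pep
        )
        label = block.group or block.region or "sample"
        for k in range(block.n):
            sid = f"{label}_{k:03d}"
            w = rng.dirichlet(alpha)
            p = np.zeros(len(asv_ids))
            for gi, gid in enumerate(gids):
                for ai, share in by_genome[gid]:
                    p[ai] = w[gi] * share
            p /= p.sum()
            counts[sid] = rng.multinomial(depth, p)
            metadata[sid] = (block.region, block.group)
            truth.samples[sid] = SampleTruth(
                block.region, block.group, block.aux_tilt, block.pep_tilt
            )
    table = ASVTable(
        sequences={aid: asv_defs[aid][0] for aid in asv_ids},
        counts=pd.DataFrame(counts, index=pd.Index(asv_ids, name="asv_id")),
    )
    table.validate()
    return table, metadata


# ---------------------------------------------------------------------------
# one-call dataset directory


def generate_dataset(
    directory: str | Path,
    n_genomes: int = 40,
    n_per_region: int = 30,
    seed: int = 0,
    effect_config: EffectConfig | None = None,
    sibo: bool = True,
    **catalog_kwargs,
) -> SyntheticTruth:
    """Write a complete synthetic dataset directory in the exact file
    formats the pipeline consumes, plus the truth JSON.

    Layout: catalog/ (ssu.fasta, proteins.fasta, completeness.tsv),
    models/<genome>.json, medium.json, scan_db.fasta, signal_table.tsv,
    asvs.fasta, asv_counts.tsv, metadata.tsv, truth.json.
    """
    from .mapping import write_asv_table, write_metadata
    from .model_io import write_catalog, write_medium, write_model
    from .peptidases import write_scan_db, write_signal_table

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    catalog, models, scan_db, signal_table, truth = make_catalog(
        n_genomes, seed=seed, **catalog_kwargs
    )
    write_catalog(catalog, directory / "catalog")
    (directory / "models").mkdir(exist_ok=True)
    for m in models:
        write_model(m, directory / "models" / f"{m.model_id}.json")
    write_medium(full_medium(), directory / "medium.json")
    write_scan_db(scan_db, directory / "scan_db.fasta")
    write_signal_table(signal_table, directory / "signal_table.tsv")

    if effect_config is None:
        blocks = EffectConfig.region_study(n_per_region).blocks
        if sibo:
            blocks = blocks + EffectConfig.sibo_study(n_per_region).blocks
        effect_config = EffectConfig(blocks)
    table, metadata = make_samples(
        catalog, truth, effect_config=effect_config, seed=seed + 1
    )
    write_asv_table(table, directory / "asvs.fasta", directory / "asv_counts.tsv")
    write_metadata(metadata, directory / "metadata.tsv")
    truth.to_json(directory / "truth.json")
    return truth
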