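"""Peptidase gene calling against a MEROPS-style scan-sequence database.

Every scan sequence (the query) is locally aligned against every genome
protein; hits must jointly satisfy four filters — E-value < 0.01, query
coverage > 85%, bitscore > 100 and coverage of the annotated peptidase
unit >= 95% — and are then restricted to proteins carrying a signal
peptide to obtain putatively extracellular peptidase genes per genome.

Bitscores follow the Karlin-Altschul transformation with gapped BLOSUM62
defaults (lambda = 0.267, K = 0.041); the database length is the total
residue count of the proteome being searched, which makes scores
reproducible without delegating to an external search tool.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

from ._align import encode_aa, get_blosum62, local_affine_kernel
from .errors import InputError
from .model_io import ReferenceGenomeCatalog

logger = logging.getLogger(__name__)

LAMBDA = 0.267
K = 0.041

#: family letter + 2 digits, '.', 3-character member (letter allowed first,
#: e.g. S09.A41)
_MEROPS_RE = re.compile(r"^[A-Z]\d{2}\.[A-Z0-9]\d{2}$")


@dataclass(frozen=True)
class ScanSequence:
    """One MEROPS-style scan entry: full sequence plus the peptidase-unit
    span (1-based inclusive, on the scan sequence)."""

    merops_id: str
    sequence: str
    unit_span: tuple[int, int]

    @property
    def family(self) -> str:
        return self.merops_id[:3]


@dataclass(frozen=True)
class PeptidaseHit:
    protein_id: str
    genome_id: str
    merops_id: str
    raw_score: int
    bitscore: float
    evalue: float
    query_coverage: float  # percent of the scan sequence aligned
    unit_coverage: float  # percent of the peptidase unit covered

    @property
    def family(self) -> str:
        return self.merops_id[:3]


@dataclass
class GenomePeptidases:
    merops_ids_present: set[str] = field(default_factory=set)
    gene_copies: int = 0  # retained (protein, merops_id) pairs
    proteins: set[str] = field(default_factory=set)


@dataclass
class PeptidaseProfile:
    """Per-genome extracellular peptidase content."""

    genomes: dict[str, GenomePeptidases] = field(default_factory=dict)

    def count(self, genome_id: str, mode: str = "copies") -> int:
        g = self.genomes.get(genome_id)
        if g is None:
            return 0
        if mode == "copies":
            return g.gene_copies
        if mode == "distinct":
            return len(g.merops_ids_present)
        raise InputError(f"unknown counting mode {mode!r}")

    def carries(self, genome_id: str, merops_id: str) -> bool:
        g = self.genomes.get(genome_id)
        return g is not None and merops_id in g.merops_ids_present

    def all_merops_ids(self) -> list[str]:
        ids: set[str] = set()
        for g in self.genomes.values():
            ids |= g.merops_ids_present
        return sorted(ids)


def check_merops_id(merops_id: str) -> str:
    if not _MEROPS_RE.match(merops_id):
        raise InputError(f"malformed MEROPS identifier {merops_id!r}")
    return merops_id


def local_align_protein(
    query: str,
    target: str,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> tuple[int, tuple[int, int], tuple[int, int]]:
    """Optimal local alignment score of two protein sequences under
    BLOSUM62 with affine gaps (gap of length L costs open + L*extend).

    Returns (raw_score, query_span, target_span) with 1-based inclusive
    spans; a score of 0 yields empty spans (0, 0).
    """
    if not query or not target:
        raise InputError("empty sequence in local alignment")
    try:
        q = encode_aa(query)
        t = encode_aa(target)
    except ValueError as exc:
        raise InputError(str(exc)) from exc
    score, qs, qe, ts, te = local_affine_kernel(q, t, get_blosum62(), gap_open, gap_extend)
    return int(score), (int(qs), int(qe)), (int(ts), int(te))


def karlin_altschul(raw_score: float, m: int, n: int,
                    lam: float = LAMBDA, k: float = K) -> tuple[float, float]:
    """Bitscore and E-value for a raw alignment score.

    bitscore = (lambda*raw - ln K) / ln 2;  evalue = m*n*2^(-bitscore),
    with m the query length and n the total database length in residues.
    """
    if m <= 0 or n <= 0:
        raise InputError("query and database lengths must be positive")
    if raw_score < 0:
        raise InputError("raw alignment score must be nonnegative")
    bitscore = (lam * raw_score - math.log(k)) / math.log(2)
    evalue = m * n * 2.0 ** (-bitscore)
    return bitscore, evalue


def call_peptidases(
    catalog: ReferenceGenomeCatalog,
    scan_db: list[ScanSequence],
    max_evalue: float = 0.01,
    min_query_cov: float = 85.0,
    min_bitscore: float = 100.0,
    min_unit_cov: float = 95.0,
) -> list[PeptidaseHit]:
    """Scan every genome proteome with every scan sequence and retain
    hits with evalue < *max_evalue*, query coverage > *min_query_cov*,
    bitscore > *min_bitscore* and unit coverage >= *min_unit_cov*.

    All four filters are applied conjunctively in one pass.  A protein
    may carry hits to multiple MEROPS identifiers.
    """
    if not scan_db:
        raise InputError("scan database is empty")
    for s in scan_db:
        check_merops_id(s.merops_id)
        lo, hi = s.unit_span
        if not (1 <= lo <= hi <= len(s.sequence)):
            raise InputError(
                f"{s.merops_id}: unit span {s.unit_span} outside scan sequence"
            )

    hits: list[PeptidaseHit] = []
    for gid in sorted(catalog.genomes):
        genome = catalog.genomes[gid]
        db_len = sum(len(p) for p in genome.protein_sequences.values())
        if db_len == 0:
            continue
        for scan in scan_db:
            qlen = len(scan.sequence)
            unit_lo, unit_hi = scan.unit_span
            unit_len = unit_hi - unit_lo + 1
            for pid in sorted(genome.protein_sequences):
                target = genome.protein_sequences[pid]
                raw, (qs, qe), _tspan = local_align_protein(scan.sequence, target)
                if raw <= 0:
                    continue
                bitscore, evalue = karlin_altschul(raw, qlen, db_len)
                query_cov = 100.0 * (qe - qs + 1) / qlen
                overlap = max(0, min(qe, unit_hi) - max(qs, unit_lo) + 1)
                unit_cov = 100.0 * overlap / unit_len
                if (
                    evalue < max_evalue
                    and query_cov > min_query_cov
                    and bitscore > min_bitscore
                    and unit_cov >= min_unit_cov
                ):
                    hits.append(
                        PeptidaseHit(
                            protein_id=pid,
                            genome_id=gid,
                            merops_id=scan.merops_id,
                            raw_score=raw,
                            bitscore=bitscore,
                            evalue=evalue,
                            query_coverage=query_cov,
                            unit_coverage=unit_cov,
                        )
                    )
    return hits


def flag_extracellular(
    hits: list[PeptidaseHit],
    signal_table: dict[str, bool],
    genome_ids: list[str] | None = None,
) -> PeptidaseProfile:
    """Restrict hits to signal-peptide-positive proteins and aggregate
    per genome.

    Proteins missing from *signal_table* are treated as signal-negative
    (logged).  ``genome_ids`` forces genomes with zero retained hits to
    still appear in the profile.
    """
    profile = PeptidaseProfile()
    if genome_ids:
        for gid in genome_ids:
            profile.genomes[gid] = GenomePeptidases()
    seen_pairs: set[tuple[str, str]] = set()
    for h in hits:
        if h.protein_id not in signal_table:
            logger.warning(
                "protein %s absent from signal table; treated as signal-negative",
                h.protein_id,
            )
        if not signal_table.get(h.protein_id, False):
            continue
        pair = (h.protein_id, h.merops_id)
        if pair in seen_pairs:
            continue
        seen_pairs.add(pair)
        g = profile.genomes.setdefault(h.genome_id, GenomePeptidases())
        g.merops_ids_present.add(h.merops_id)
        g.gene_copies += 1
        g.proteins.add(h.protein_id)
    return profile


def toy_signal_peptide(sequence: str) -> bool:
    """Toy signal-peptide rule used for synthetic data: positive iff
    residues 2-4 contain at least one K/R (n-region charge) and residues
    5-25 contain a run of >= 8 hydrophobics from {L, A, V, I, F}
    (h-region).  This is a documented stand-in for a trained predictor;
    real analyses should supply an external annotation table."""
    n_region = sequence[1:4]
    if not any(c in "KR" for c in n_region):
        return False
    h_region = sequence[4:25]
    run = 0
    for c in h_region:
        if c in "LAVIF":
            run += 1
            if run >= 8:
                return True
        else:
            run = 0
    return False


# ---------------------------------------------------------------------------
# I/O: scan db FASTA ("merops_id|unit_start-unit_end"), signal TSV, hits TSV


def write_scan_db(scan_db: list[ScanSequence], path: str | Path) -> None:
    from .model_io import write_fasta

    write_fasta(
        [(f"{s.merops_id}|{s.unit_span[0]}-{s.unit_span[1]}", s.sequence) for s in scan_db],
        path,
    )


def read_scan_db(path: str | Path) -> list[ScanSequence]:
    from .model_io import read_fasta

    out = []
    for header, seq in read_fasta(path):
        try:
            merops_id, span = header.split("|")
            lo, hi = span.split("-")
            out.append(ScanSequence(check_merops_id(merops_id), seq, (int(lo), int(hi))))
        except ValueError as exc:
            raise InputError(f"malformed scan db header {header!r}") from exc
    return out


def write_signal_table(table: dict[str, bool], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tsignal\n")
        for pid, flag in table.items():
            fh.write(f"{pid}\t{int(flag)}\n")


def read_signal_table(path: str | Path) -> dict[str, bool]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return {str(r.protein_id): bool(int(r.signal)) for r in df.itertuples(index=False)}


def write_peptidase_hits(hits: list[PeptidaseHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "protein_id\tgenome_id\tmerops_id\tfamily\traw_score\tbitscore\t"
            "evalue\tquery_coverage\tunit_coverage\n"
        )
        for h in hits:
            fh.write(
                f"{h.protein_id}\t{h.genome_id}\t{h.merops_id}\t{h.family}\t"
                f"{h.raw_score}\t{h.bitscore:.4f}\t{h.evalue:.6g}\t"
                f"{h.query_coverage:.4f}\t{h.unit_coverage:.4f}\n"
            )
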