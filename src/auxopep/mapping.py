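"""Map ASV representative sequences to catalog genomes and derive
per-sample genome relative abundances.

Mapping mirrors the standard 16S workflow: each ASV is aligned against
every 16S gene in the reference catalog (both orientations, best one
kept), hits must reach 97% identity and 95% query coverage (inclusive),
and only hits at the ASV's maximum passing identity are retained — so an
ASV can map to several genomes tied at the top identity.  Tied counts
are split equally between the tied genomes by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._align import encode_nt, reverse_complement, semiglobal_identity
from .errors import InputError
from .model_io import ReferenceGenomeCatalog

logger = logging.getLogger(__name__)

#: gut regions as ordered factor levels (small to large intestine)
REGION_ORDER = ("duodenum", "jejunum", "farthest_distance", "large_intestine")
REGION_RANK = {r: i + 1 for i, r in enumerate(REGION_ORDER)}
GROUPS = ("SIBO", "non-SIBO")


@dataclass
class ASVTable:
    """ASV sequences plus a read-count matrix over a shared sample set."""

    sequences: dict[str, str]  # asv_id -> nucleotide sequence
    counts: pd.DataFrame  # rows = asv_id, columns = sample_id, integer reads

    def validate(self) -> None:
        from .errors import ValidationError

        failures = []
        if set(self.sequences) != set(self.counts.index):
            failures.append("count matrix rows do not match ASV sequence ids")
        if any(not s for s in self.sequences.values()):
            failures.append("empty ASV sequence")
        if (self.counts.values < 0).any():
            failures.append("negative read counts")
        if failures:
            raise ValidationError(failures)


@dataclass(frozen=True)
class MappingHit:
    asv_id: str
    genome_id: str
    identity: float  # percent
    query_coverage: float  # percent


@dataclass
class SampleAbundance:
    """Relative genome abundances for one sample plus its metadata."""

    sample_id: str
    abundances: dict[str, float]  # genome_id -> relative abundance
    region: str | None = None  # ordered label, REGION_ORDER
    group: str | None = None  # 'SIBO' | 'non-SIBO'

    @property
    def region_rank(self) -> int | None:
        return REGION_RANK.get(self.region) if self.region else None


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def map_asvs(
    asvs: ASVTable,
    catalog: ReferenceGenomeCatalog,
    min_identity: float = 97.0,
    min_query_cov: float = 95.0,
    prefilter_k: int | None = 12,
) -> list[MappingHit]:
    """Align every ASV against every catalog 16S gene and keep, per ASV,
    the hits that pass both thresholds (inclusive) at the maximum passing
    identity.

    A genome's identity for an ASV is the maximum over its 16S genes and
    over the two ASV orientations.  ``prefilter_k`` enables a shared-k-mer
    prefilter that skips clearly unalignable pairs; it is a pure speedup.
    ASVs with no passing hit are absent from the result.
    """
    if not catalog.genomes:
        raise InputError("reference catalog is empty")
    asvs.validate()

    hits: list[MappingHit] = []
    for asv_id, seq in asvs.sequences.items():
        try:
            fwd = encode_nt(seq)
            rev = encode_nt(reverse_complement(seq))
        except ValueError as exc:
            raise InputError(f"ASV {asv_id}: {exc}") from exc
        kmers_fwd = _kmer_set(seq, prefilter_k) if prefilter_k else None
        kmers_rev = (
            _kmer_set(reverse_complement(seq), prefilter_k) if prefilter_k else None
        )
        per_genome: dict[str, tuple[float, float]] = {}
        for gid, genome in catalog.genomes.items():
            best: tuple[float, float] | None = None
            for ref_seq in genome.ssu_sequences:
                ref_kmers = _kmer_set(ref_seq, prefilter_k) if prefilter_k else None
                ref = None
                for enc, km in ((fwd, kmers_fwd), (rev, kmers_rev)):
                    if ref_kmers is not None and not (km & ref_kmers):
                        continue
                    if ref is None:
                        ref = encode_nt(ref_seq)
                    ident, cov, _ = semiglobal_identity(enc, ref)
                    if best is None or (ident, cov) > best:
                        best = (ident, cov)
            if best is not None:
                per_genome[gid] = best
        passing = {
            gid: (ident, cov)
            for gid, (ident, cov) in per_genome.items()
            if ident >= min_identity and cov >= min_query_cov
        }
        if not passing:
            continue
        max_ident = max(ident for ident, _ in passing.values())
        for gid in sorted(passing):
            ident, cov = passing[gid]
            if ident == max_ident:
                hits.append(MappingHit(asv_id, gid, ident, cov))
    return hits


def assign_abundance(
    asvs: ASVTable,
    hits: list[MappingHit],
    metadata: dict[str, tuple[str | None, str | None]] | None = None,
    tie_mode: str = "equal_split",
) -> list[SampleAbundance]:
    """Turn mapping hits and per-sample ASV counts into genome relative
    abundances.

    Each mapped ASV's counts are split equally among its tied genomes
    (``tie_mode='equal_split'``) or the ASV is discarded when ambiguous
    (``'drop_ambiguous'``); per sample, genome totals are normalized by
    the sample's total mapped reads.  Samples where nothing maps get an
    empty abundance map and a log warning.
    """
    if tie_mode not in ("equal_split", "drop_ambiguous"):
        raise InputError(f"unknown tie_mode {tie_mode!r}")
    genomes_of: dict[str, list[str]] = {}
    for h in hits:
        if h.asv_id not in asvs.sequences:
            raise InputError(f"hit references unknown ASV {h.asv_id}")
        genomes_of.setdefault(h.asv_id, []).append(h.genome_id)

    out: list[SampleAbundance] = []
    for sample_id in asvs.counts.columns:
        col = asvs.counts[sample_id]
        weights: dict[str, float] = {}
        for asv_id, genome_ids in genomes_of.items():
            n_reads = float(col.loc[asv_id])
            if n_reads == 0:
                continue
            if len(genome_ids) > 1 and tie_mode == "drop_ambiguous":
                continue
            share = n_reads / len(genome_ids)
            for gid in genome_ids:
                weights[gid] = weights.get(gid, 0.0) + share
        total = sum(weights.values())
        if total == 0:
            logger.warning("sample %s: no reads mapped to any genome", sample_id)
            abund: dict[str, float] = {}
        else:
            abund = {gid: w / total for gid, w in sorted(weights.items())}
        region, group = (None, None)
        if metadata and sample_id in metadata:
            region, group = metadata[sample_id]
        out.append(SampleAbundance(sample_id, abund, region=region, group=group))
    return out


# ---------------------------------------------------------------------------
# tabular I/O


def read_asv_table(fasta_path: str | Path, counts_path: str | Path) -> ASVTable:
    """Read an ASV table from a FASTA of representative sequences and a
    TSV count matrix (asv_id, one column per sample)."""
    from .model_io import read_fasta

    seqs = {h.split()[0]: s for h, s in read_fasta(fasta_path)}
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    table = ASVTable(seqs, counts)
    table.validate()
    return table


def write_asv_table(table: ASVTable, fasta_path: str | Path, counts_path: str | Path) -> None:
    from .model_io import write_fasta

    write_fasta(sorted(table.sequences.items()), fasta_path)
    table.counts.rename_axis("asv_id").to_csv(counts_path, sep="\t")


def read_metadata(path: str | Path) -> dict[str, tuple[str | None, str | None]]:
    """Sample metadata TSV: sample_id, region, group ('' for absent)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    meta: dict[str, tuple[str | None, str | None]] = {}
    for row in df.itertuples(index=False):
        region = row.region or None
        group = row.group or None
        if region is not None and region not in REGION_RANK:
            raise InputError(f"unknown region label {region!r}")
        if group is not None and group not in GROUPS:
            raise InputError(f"unknown group label {group!r}")
        meta[row.sample_id] = (region, group)
    return meta


def write_metadata(meta: dict[str, tuple[str | None, str | None]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tregion\tgroup\n")
        for sid, (region, group) in meta.items():
            fh.write(f"{sid}\t{region or ''}\t{group or ''}\n")


def write_hits(hits: list[MappingHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("asv_id\tgenome_id\tidentity\tquery_coverage\n")
        for h in hits:
            fh.write(f"{h.asv_id}\t{h.genome_id}\t{h.identity:.4f}\t{h.query_coverage:.4f}\n")


def write_abundances(samples: list[SampleAbundance], path: str | Path) -> None:
    """Long-format abundance TSV: sample_id, genome_id, rel_abundance."""
    with open(path, "w") as fh:
        fh.write("sample_id\tgenome_id\trel_abundance\n")
        for s in samples:
            for gid, ab in s.abundances.items():
                fh.write(f"{s.sample_id}\t{gid}\t{ab:.10g}\n")


def read_abundances(
    path: str | Path,
    metadata: dict[str, tuple[str | None, str | None]] | None = None,
) -> list[SampleAbundance]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for sid, sub in df.groupby("sample_id", sort=True):
        region, group = (None, None)
        if metadata and sid in metadata:
            region, group = metadata[sid]
        out.append(
            SampleAbundance(
                str(sid),
                dict(zip(sub["genome_id"], sub["rel_abundance"])),
                region=region,
                group=group,
            )
        )
    return out
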