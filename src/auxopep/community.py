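"""Community-level metrics: auxotrophy/peptidase abundances, abundance-
weighted averages, range scaling and Bray-Curtis dissimilarities.

Auxotrophy abundance of an amino acid in a sample is the summed relative
abundance of genomes auxotrophic for it; the abundance-weighted average
of auxotrophies is sum_i w_i * n_i with w the relative abundances
(renormalized over profiled genomes) and n_i the per-genome auxotrophy
count (0-20).  Peptidase abundance uses presence semantics: the summed
abundance of genomes carrying at least one gene for the peptidase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aminoacids import AMINO_ACIDS
from .errors import InputError
from .fba import AuxotrophyProfile
from .mapping import SampleAbundance
from .peptidases import PeptidaseProfile

logger = logging.getLogger(__name__)


def _profiled_weights(
    sample: SampleAbundance, profiled: set[str]
) -> tuple[dict[str, float], float]:
    """Abundances restricted to profiled genomes, renormalized; also the
    dropped (unprofiled) fraction."""
    kept = {g: w for g, w in sample.abundances.items() if g in profiled}
    total = sum(kept.values())
    dropped = 1.0 - total if sample.abundances else 0.0
    if total == 0:
        return {}, dropped
    return {g: w / total for g, w in kept.items()}, dropped


def auxotrophy_abundance(
    sample: SampleAbundance, profile: AuxotrophyProfile, aa: str
) -> float:
    """Summed (renormalized) relative abundance of genomes auxotrophic
    for *aa* in this sample."""
    w, _ = _profiled_weights(sample, set(profile.entries))
    return sum(wi for g, wi in w.items() if profile.is_auxotrophic(g, aa))


def weighted_avg_auxotrophies(
    sample: SampleAbundance, profile: AuxotrophyProfile
) -> float:
    """Abundance-weighted mean number of auxotrophies per genome (0-20).

    Undefined (NaN) when the sample shares no genome with the profile.
    """
    w, dropped = _profiled_weights(sample, set(profile.entries))
    if not w:
        logger.warning(
            "sample %s: no overlap with auxotrophy profile (dropped %.3f)",
            sample.sample_id, dropped,
        )
        return float("nan")
    return sum(wi * profile.n_auxotrophies(g) for g, wi in w.items())


def peptidase_abundance(
    sample: SampleAbundance, pep: PeptidaseProfile, merops_id: str
) -> float:
    """Summed (renormalized) abundance of genomes harboring at least one
    gene for *merops_id* (presence semantics: copies do not matter)."""
    w, _ = _profiled_weights(sample, set(pep.genomes))
    return sum(wi for g, wi in w.items() if pep.carries(g, merops_id))


def weighted_avg_peptidases(
    sample: SampleAbundance, pep: PeptidaseProfile, mode: str = "copies"
) -> float:
    """Abundance-weighted mean number of extracellular peptidase genes
    per genome; *mode* counts gene copies (default) or distinct MEROPS
    identifiers."""
    w, dropped = _profiled_weights(sample, set(pep.genomes))
    if not w:
        logger.warning(
            "sample %s: no overlap with peptidase profile (dropped %.3f)",
            sample.sample_id, dropped,
        )
        return float("nan")
    return sum(wi * pep.count(g, mode) for g, wi in w.items())


def bray_curtis(x: dict[str, float], y: dict[str, float]) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min)/(sum x + sum y) over the
    union of keys (absent = 0).  Raises when both profiles are all-zero."""
    keys = sorted(set(x) | set(y))  # deterministic summation order
    sx = sum(x.get(k, 0.0) for k in keys)
    sy = sum(y.get(k, 0.0) for k in keys)
    if any(v < 0 for v in x.values()) or any(v < 0 for v in y.values()):
        raise InputError("Bray-Curtis requires nonnegative profiles")
    if sx + sy == 0:
        raise InputError("Bray-Curtis undefined for two all-zero profiles")
    shared = sum(min(x.get(k, 0.0), y.get(k, 0.0)) for k in keys)
    return 1.0 - 2.0 * shared / (sx + sy)


def median_dissimilarity_to_reference(
    sample_profile: dict[str, float],
    reference_profiles: list[dict[str, float]],
) -> float:
    """Median Bray-Curtis distance from one sample's profile to every
    profile in a reference set (midpoint convention for even counts)."""
    if not reference_profiles:
        raise InputError("reference profile set is empty")
    d = [bray_curtis(sample_profile, ref) for ref in reference_profiles]
    return float(np.median(d))


def range_scale(values) -> np.ndarray:
    """(v - min) / (max - min) elementwise; a constant vector maps to all
    zeros; an empty vector is an error."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InputError("cannot range-scale an empty vector")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# per-sample metric tables


@dataclass
class CommunityMetrics:
    """All community metrics for a set of samples, as tidy DataFrames."""

    #: sample x amino acid auxotrophy abundances
    aux_abundance: pd.DataFrame
    #: sample x merops_id peptidase abundances
    pep_abundance: pd.DataFrame
    #: per-sample scalars: weighted_avg_auxotrophies, weighted_avg_peptidases,
    #: dropped fractions; indexed by sample_id
    summary: pd.DataFrame


def compute_community_metrics(
    samples: list[SampleAbundance],
    aux_profile: AuxotrophyProfile,
    pep_profile: PeptidaseProfile,
    mode: str = "copies",
    amino_acids: tuple[str, ...] = AMINO_ACIDS,
) -> CommunityMetrics:
    """Evaluate every per-sample metric over a sample collection.

    Samples with empty abundance maps are kept in the tables with NaN
    metrics so downstream statistics can drop them explicitly.
    """
    merops_ids = pep_profile.all_merops_ids()
    aux_rows, pep_rows, summary_rows = [], [], []
    for s in samples:
        if not s.abundances:
            aux_rows.append({aa: np.nan for aa in amino_acids})
            pep_rows.append({m: np.nan for m in merops_ids})
            summary_rows.append(
                dict(weighted_avg_auxotrophies=np.nan, weighted_avg_peptidases=np.nan,
                     dropped_aux_fraction=np.nan, dropped_pep_fraction=np.nan)
            )
            continue
        _, dropped_aux = _profiled_weights(s, set(aux_profile.entries))
        _, dropped_pep = _profiled_weights(s, set(pep_profile.genomes))
        aux_rows.append({aa: auxotrophy_abundance(s, aux_profile, aa) for aa in amino_acids})
        pep_rows.append({m: peptidase_abundance(s, pep_profile, m) for m in merops_ids})
        summary_rows.append(
            dict(
                weighted_avg_auxotrophies=weighted_avg_auxotrophies(s, aux_profile),
                weighted_avg_peptidases=weighted_avg_peptidases(s, pep_profile, mode),
                dropped_aux_fraction=dropped_aux,
                dropped_pep_fraction=dropped_pep,
            )
        )
    idx = pd.Index([s.sample_id for s in samples], name="sample_id")
    summary = pd.DataFrame(summary_rows, index=idx)
    summary["region"] = [s.region for s in samples]
    summary["group"] = [s.group for s in samples]
    return CommunityMetrics(
        aux_abundance=pd.DataFrame(aux_rows, index=idx),
        pep_abundance=pd.DataFrame(pep_rows, index=idx),
        summary=summary,
    )


def peptidase_distance_matrix(pep_abundance: pd.DataFrame) -> pd.DataFrame:
    """Square symmetric Bray-Curtis distance matrix between per-sample
    peptidase abundance profiles.  Samples whose profile is all-zero or
    all-NaN are excluded (they have no defined dissimilarity)."""
    clean = pep_abundance.dropna(how="all")
    keep = clean.index[(clean.fillna(0.0).sum(axis=1) > 0)]
    clean = clean.loc[keep].fillna(0.0)
    ids = list(clean.index)
    n = len(ids)
    D = np.zeros((n, n))
    rows = clean.values
    for i in range(n):
        for j in range(i + 1, n):
            x, y = rows[i], rows[j]
            shared = np.minimum(x, y).sum()
            D[i, j] = D[j, i] = 1.0 - 2.0 * shared / (x.sum() + y.sum())
    return pd.DataFrame(D, index=ids, columns=ids)


def write_metrics(metrics: CommunityMetrics, directory) -> None:
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    metrics.aux_abundance.to_csv(directory / "auxotrophy_abundance.tsv", sep="\t")
    metrics.pep_abundance.to_csv(directory / "peptidase_abundance.tsv", sep="\t")
    metrics.summary.to_csv(directory / "community_summary.tsv", sep="\t")
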