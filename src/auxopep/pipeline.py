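"""End-to-end orchestration: map -> abundances -> auxotrophy screen ->
peptidase calling -> community metrics -> statistics.

Every stage writes self-describing TSVs into the output directory and a
manifest (JSON) records the configuration hash, per-stage row counts and
machine-readable warnings, so a run can be reproduced from the manifest
plus the inputs alone.  Reruns with identical inputs and seed are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .aminoacids import AMINO_ACIDS
from .errors import AuxopepError, InputError
from . import community, fba, mapping, peptidases, stats
from .model_io import read_catalog, read_medium, read_model

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths, thresholds and statistics options for a full run.

    Thresholds default to the canonical analysis values: 97% mapping
    identity / 95% query coverage, peptidase filters E < 0.01 /
    query coverage > 85 / bitscore > 100 / unit coverage >= 95,
    completeness gate 85%, growth tolerance 1e-6.
    """

    # inputs
    asv_fasta: str = "asvs.fasta"
    asv_counts: str = "asv_counts.tsv"
    metadata: str = "metadata.tsv"
    catalog_dir: str = "catalog"
    models_dir: str = "models"
    medium: str = "medium.json"
    scan_db: str = "scan_db.fasta"
    signal_table: str = "signal_table.tsv"
    outdir: str = "results"
    # thresholds
    min_identity: float = 97.0
    min_query_cov: float = 95.0
    max_evalue: float = 0.01
    pep_min_query_cov: float = 85.0
    min_bitscore: float = 100.0
    min_unit_cov: float = 95.0
    min_completeness: float = 85.0
    zero_tol: float = 1e-6
    # statistics
    n_perm: int = 999
    seed: int = 1
    alpha: float = 0.001
    screen_alpha_adjusted: bool = True
    counting_mode: str = "copies"  # 'copies' | 'distinct'
    tie_mode: str = "equal_split"  # 'equal_split' | 'drop_ambiguous'
    amino_acid_subset: list[str] = field(default_factory=list)  # empty = all 20

    def validate(self) -> None:
        checks = [
            (0 <= self.min_identity <= 100, "min_identity outside [0, 100]"),
            (0 <= self.min_query_cov <= 100, "min_query_cov outside [0, 100]"),
            (0 <= self.pep_min_query_cov <= 100, "pep_min_query_cov outside [0, 100]"),
            (0 <= self.min_unit_cov <= 100, "min_unit_cov outside [0, 100]"),
            (0 <= self.min_completeness <= 100, "min_completeness outside [0, 100]"),
            (self.max_evalue > 0, "max_evalue must be positive"),
            (self.zero_tol > 0, "zero_tol must be positive"),
            (self.n_perm >= 1, "n_perm must be >= 1"),
            (0 < self.alpha < 1, "alpha must lie in (0, 1)"),
            (self.counting_mode in ("copies", "distinct"), "bad counting_mode"),
            (self.tie_mode in ("equal_split", "drop_ambiguous"), "bad tie_mode"),
            (all(aa in AMINO_ACIDS for aa in self.amino_acid_subset),
             "amino_acid_subset contains unknown codes"),
        ]
        bad = [msg for ok, msg in checks if not ok]
        if bad:
            raise InputError("; ".join(bad))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        data.update(overrides)
        cfg = cls(**data)
        cfg.validate()
        return cfg


def run_pipeline(config: PipelineConfig, base_dir: str | Path = ".") -> dict:
    """Execute all stages; returns the manifest dict (also written to
    <outdir>/manifest.json).  Raises on stage failure after writing the
    partial manifest with a stage marker."""
    config.validate()
    base = Path(base_dir)
    outdir = base / config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": [],
        "warnings": [],
    }

    def _finish_stage(name: str, t0: float, **info) -> None:
        manifest["stages"].append(
            {"stage": name, "seconds": round(time.time() - t0, 3), **info}
        )

    def _fail(stage: str, exc: Exception) -> None:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")

    stage = "map"
    try:
        t0 = time.time()
        catalog = read_catalog(base / config.catalog_dir)
        asvs = mapping.read_asv_table(base / config.asv_fasta, base / config.asv_counts)
        meta = mapping.read_metadata(base / config.metadata)
        hits = mapping.map_asvs(
            asvs, catalog, config.min_identity, config.min_query_cov
        )
        mapping.write_hits(hits, outdir / "mapping_hits.tsv")
        unmapped = sorted(set(asvs.sequences) - {h.asv_id for h in hits})
        if unmapped:
            manifest["warnings"].append({"stage": stage, "unmapped_asvs": unmapped})
        _finish_stage(stage, t0, n_hits=len(hits), n_asvs=len(asvs.sequences))

        stage = "abundances"
        t0 = time.time()
        samples = mapping.assign_abundance(asvs, hits, meta, config.tie_mode)
        mapping.write_abundances(samples, outdir / "abundances.tsv")
        empty = [s.sample_id for s in samples if not s.abundances]
        if empty:
            manifest["warnings"].append({"stage": stage, "empty_samples": empty})
        _finish_stage(stage, t0, n_samples=len(samples))

        stage = "screen-auxotrophy"
        t0 = time.time()
        models = [
            read_model(p) for p in sorted((base / config.models_dir).glob("*.json"))
        ]
        medium = read_medium(base / config.medium)
        from .synthetic import amino_acid_exchange_map

        aux_profile = fba.screen_catalog(
            models, medium, amino_acid_exchange_map(),
            config.min_completeness, config.zero_tol,
        )
        fba.write_auxotrophy_profile(aux_profile, outdir / "auxotrophies.tsv")
        fba.write_exclusion_report(aux_profile, outdir / "model_exclusions.tsv")
        if aux_profile.excluded:
            manifest["warnings"].append(
                {"stage": stage, "excluded_models": aux_profile.excluded}
            )
        _finish_stage(stage, t0, n_profiled=len(aux_profile.entries),
                      n_excluded=len(aux_profile.excluded))

        stage = "call-peptidases"
        t0 = time.time()
        scan_db = peptidases.read_scan_db(base / config.scan_db)
        signal_table = peptidases.read_signal_table(base / config.signal_table)
        pep_hits = peptidases.call_peptidases(
            catalog, scan_db, config.max_evalue, config.pep_min_query_cov,
            config.min_bitscore, config.min_unit_cov,
        )
        peptidases.write_peptidase_hits(pep_hits, outdir / "peptidase_hits.tsv")
        pep_profile = peptidases.flag_extracellular(
            pep_hits, signal_table, genome_ids=sorted(catalog.genomes)
        )
        _finish_stage(stage, t0, n_hits=len(pep_hits),
                      n_extracellular_pairs=sum(
                          g.gene_copies for g in pep_profile.genomes.values()))

        stage = "metrics"
        t0 = time.time()
        aa_list = tuple(config.amino_acid_subset) or AMINO_ACIDS
        metrics = community.compute_community_metrics(
            samples, aux_profile, pep_profile, config.counting_mode, aa_list
        )
        community.write_metrics(metrics, outdir)
        dist = community.peptidase_distance_matrix(metrics.pep_abundance)
        dist.to_csv(outdir / "peptidase_braycurtis.tsv", sep="\t")
        _finish_stage(stage, t0, n_samples=len(metrics.summary))

        stage = "stats"
        t0 = time.time()
        results = compute_statistics(metrics, dist, config)
        for name, df in results.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        _finish_stage(stage, t0, n_tables=len(results))
    except AuxopepError as exc:
        _fail(stage, exc)
        raise
    except Exception as exc:  # pragma: no cover - unexpected failures
        _fail(stage, exc)
        raise

    manifest["n_stages"] = len(manifest["stages"])
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest


def compute_statistics(
    metrics: community.CommunityMetrics,
    dist: pd.DataFrame,
    config: PipelineConfig,
) -> dict[str, pd.DataFrame]:
    """The statistical contrasts of the analysis, as tidy tables.

    Produces whichever contrasts the metadata supports: per-amino-acid
    Kendall trend over ordered regions; region/group contrasts of the
    weighted averages; PERMANOVA on the peptidase Bray-Curtis matrix;
    the duodenum-vs-large-intestine differential peptidase screen; the
    auxotrophy x peptidase Spearman matrix; and per-sample median
    dissimilarity of small-intestine profiles to the large-intestine
    reference set.
    """
    summary = metrics.summary
    out: dict[str, pd.DataFrame] = {}

    regional = summary[summary["region"].notna() & summary["group"].isna()]
    has_regions = regional["region"].nunique() >= 2
    if has_regions:
        ranks = regional["region"].map(mapping.REGION_RANK)
        rows = []
        for aa in metrics.aux_abundance.columns:
            vals = metrics.aux_abundance.loc[regional.index, aa]
            ok = vals.notna()
            try:
                res = stats.kendall_ordered(vals[ok], ranks[ok])
                rows.append((aa, res.statistic, res.p_value, res.note))
            except InputError as exc:
                rows.append((aa, np.nan, np.nan, str(exc)))
        df = pd.DataFrame(rows, columns=["amino_acid", "tau", "p_value", "note"])
        okp = df["p_value"].notna()
        df["p_adjusted"] = np.nan
        if okp.any():
            df.loc[okp, "p_adjusted"] = stats.bh_fdr(df.loc[okp, "p_value"])
        out["kendall_region_trend"] = df

        rows = []
        regs = list(regional["region"].unique())
        for i in range(len(regs)):
            for j in range(i + 1, len(regs)):
                for metric in ("weighted_avg_auxotrophies", "weighted_avg_peptidases"):
                    a = regional.loc[regional["region"] == regs[i], metric].dropna()
                    b = regional.loc[regional["region"] == regs[j], metric].dropna()
                    if len(a) and len(b):
                        res = stats.wilcoxon_rank_sum(a, b)
                        rows.append((metric, regs[i], regs[j], res.statistic, res.p_value))
        out["weighted_avg_contrasts"] = pd.DataFrame(
            rows, columns=["metric", "region_a", "region_b", "U", "p_value"]
        )

        # PERMANOVA of peptidase profiles over regions
        ids = dist.index.intersection(regional.index)
        labels = regional.loc[ids, "region"]
        if labels.nunique() >= 2 and labels.value_counts().min() >= 2:
            res = stats.permanova(
                dist.loc[ids, ids].values, labels.values,
                n_perm=config.n_perm, seed=config.seed,
            )
            out["permanova_region"] = pd.DataFrame(
                [{"F": res.statistic, "R2": res.effect, "p_value": res.p_value,
                  "n_perm": config.n_perm, "n_samples": len(ids)}]
            )

        # duodenum vs large intestine differential peptidase screen
        duo = metrics.pep_abundance.loc[
            regional.index[regional["region"] == "duodenum"]]
        li = metrics.pep_abundance.loc[
            regional.index[regional["region"] == "large_intestine"]]
        if len(duo) and len(li):
            out["differential_peptidases_duo_vs_li"] = stats.differential_peptidase_screen(
                li, duo, paired=False, alpha=config.alpha,
                adjust=config.screen_alpha_adjusted,
            )

        # auxotrophy x peptidase correlation in the duodenum
        if (regional["region"] == "duodenum").sum() >= 4:
            duo_ids = regional.index[regional["region"] == "duodenum"]
            out["spearman_aux_pep_duodenum"] = stats.spearman_matrix(
                metrics.aux_abundance.loc[duo_ids].dropna(how="all"),
                metrics.pep_abundance.loc[duo_ids].dropna(how="all"),
            )

    grouped = summary[summary["group"].notna()]
    if grouped["group"].nunique() == 2:
        g1, g2 = "non-SIBO", "SIBO"
        rows = []
        for aa in metrics.aux_abundance.columns:
            a = metrics.aux_abundance.loc[grouped.index[grouped["group"] == g1], aa].dropna()
            b = metrics.aux_abundance.loc[grouped.index[grouped["group"] == g2], aa].dropna()
            if len(a) and len(b) and (a.nunique() > 1 or b.nunique() > 1):
                res = stats.wilcoxon_rank_sum(a, b)
                rows.append((aa, res.statistic, res.p_value,
                             float(a.median() - b.median())))
        df = pd.DataFrame(rows, columns=["amino_acid", "U", "p_value",
                                         "median_diff_nonSIBO_minus_SIBO"])
        if len(df):
            df["p_adjusted"] = stats.bh_fdr(df["p_value"])
        out["sibo_aux_contrasts"] = df

        rows = []
        for metric in ("weighted_avg_auxotrophies", "weighted_avg_peptidases"):
            a = grouped.loc[grouped["group"] == g1, metric].dropna()
            b = grouped.loc[grouped["group"] == g2, metric].dropna()
            if len(a) and len(b):
                res = stats.wilcoxon_rank_sum(a, b)
                rows.append((metric, res.statistic, res.p_value,
                             float(a.median()), float(b.median())))
        out["sibo_weighted_avg"] = pd.DataFrame(
            rows, columns=["metric", "U", "p_value", "median_nonSIBO", "median_SIBO"]
        )

        ids = dist.index.intersection(grouped.index)
        labels = grouped.loc[ids, "group"]
        if labels.nunique() == 2 and labels.value_counts().min() >= 2:
            res = stats.permanova(
                dist.loc[ids, ids].values, labels.values,
                n_perm=config.n_perm, seed=config.seed,
            )
            out["permanova_sibo"] = pd.DataFrame(
                [{"F": res.statistic, "R2": res.effect, "p_value": res.p_value,
                  "n_perm": config.n_perm, "n_samples": len(ids)}]
            )

        # median dissimilarity of each grouped (small-intestine) sample to
        # the large-intestine reference profiles
        if has_regions:
            li_ids = regional.index[regional["region"] == "large_intestine"]
            li_profiles = [
                metrics.pep_abundance.loc[i].dropna().to_dict() for i in li_ids
                if metrics.pep_abundance.loc[i].fillna(0).sum() > 0
            ]
            rows = []
            if li_profiles:
                for sid in grouped.index:
                    prof = metrics.pep_abundance.loc[sid].dropna().to_dict()
                    if sum(prof.values()) == 0:
                        continue
                    med = community.median_dissimilarity_to_reference(prof, li_profiles)
                    rows.append((sid, grouped.loc[sid, "group"], med))
            df = pd.DataFrame(rows, columns=["sample_id", "group", "median_bc_to_li"])
            if len(df) and df["group"].nunique() == 2:
                res = stats.wilcoxon_rank_sum(
                    df.loc[df["group"] == g1, "median_bc_to_li"],
                    df.loc[df["group"] == g2, "median_bc_to_li"],
                )
                df["group_test_p"] = res.p_value
            out["median_dissimilarity_to_li"] = df

    # PCoA coordinates of the full peptidase distance matrix
    if len(dist) >= 3:
        coords, eigvals = stats.pcoa(dist.values)
        k = min(coords.shape[1], 5)
        pco = pd.DataFrame(
            coords[:, :k], columns=[f"PCo{i+1}" for i in range(k)]
        )
        pco.insert(0, "sample_id", list(dist.index))
        out["pcoa_coordinates"] = pco
    return out
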