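"""A complete synthetic study, end to end.

Generates a 20-genome catalog and a four-region + SIBO amplicon study
with planted effects (small-intestine communities tilted toward
auxotrophic genomes, SIBO communities toward peptidase-rich genomes),
runs every pipeline stage, and prints the headline statistics.
"""

import tempfile
from pathlib import Path

import pandas as pd

from auxopep import PipelineConfig, generate_dataset, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    ds = Path(tmp) / "ds"
    generate_dataset(ds, n_genomes=20, n_per_region=10, seed=42)
    cfg = PipelineConfig(
        asv_fasta=str(ds / "asvs.fasta"),
        asv_counts=str(ds / "asv_counts.tsv"),
        metadata=str(ds / "metadata.tsv"),
        catalog_dir=str(ds / "catalog"),
        models_dir=str(ds / "models"),
        medium=str(ds / "medium.json"),
        scan_db=str(ds / "scan_db.fasta"),
        signal_table=str(ds / "signal_table.tsv"),
        outdir=str(Path(tmp) / "results"),
        n_perm=999,
        seed=43,
    )
    manifest = run_pipeline(cfg)
    res = Path(tmp) / "results"

    print("stages:", [s["stage"] for s in manifest["stages"]])
    perma = pd.read_csv(res / "permanova_region.tsv", sep="\t").iloc[0]
    print(f"region PERMANOVA on peptidase profiles: "
          f"R2 = {perma.R2:.3f}, p = {perma.p_value}")
    kend = pd.read_csv(res / "kendall_region_trend.tsv", sep="\t")
    sig = kend[(kend.tau < 0) & (kend.p_adjusted < 0.05)]
    print(f"amino acids decreasing along the tract (tau < 0, p_adj < 0.05): "
          f"{len(sig)} of {kend.tau.notna().sum()} testable")
    sibo = pd.read_csv(res / "sibo_weighted_avg.tsv", sep="\t").set_index("metric")
    row = sibo.loc["weighted_avg_peptidases"]
    print(f"SIBO vs non-SIBO weighted peptidase genes: medians "
          f"{row.median_SIBO:.2f} vs {row.median_nonSIBO:.2f}, p = {row.p_value:.2e}")

# The planted structure is recovered: peptidase profiles separate the
# regions (large R2 at the permutation floor p = 0.001), several planted
# amino-acid auxotrophies decline from duodenum to large intestine, and
# the SIBO group carries significantly more extracellular peptidase
# genes per genome.
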