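"""Plain-text readers/writers for the pipeline's tables.

Conventions: expression and methylation matrices are TSV with the feature
identifier in the first column (genes x samples / CpGs x samples); site
annotation is TSV keyed by cpg_id; fusion calls are TSV; clinical and truth
tables are CSV keyed by sample_id.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .cohort import SyntheticCohort


def write_matrix_tsv(matrix: pd.DataFrame, path, index_label: str = "gene") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Write all cohort tables under ``outdir``; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "fusions": out / "fusions.tsv",
        "methylation": out / "methylation.tsv",
        "methylation_sites": out / "methylation_sites.tsv",
        "clinical": out / "clinical.csv",
        "truth": out / "truth.csv",
        "implanted_dmrs": out / "implanted_dmrs.csv",
    }
    write_matrix_tsv(cohort.expression, paths["expression"], "gene")
    cohort.fusions.to_csv(paths["fusions"], sep="\t", index=False)
    write_matrix_tsv(cohort.methylation, paths["methylation"], "cpg_id")
    cohort.methylation_sites.to_csv(paths["methylation_sites"], sep="\t", index_label="cpg_id")
    cohort.clinical.to_csv(paths["clinical"])
    cohort.truth.to_csv(paths["truth"])
    cohort.implanted_dmrs.to_csv(paths["implanted_dmrs"], index=False)
    return {k: str(v) for k, v in paths.items()}


def read_config(path) -> dict:
    """Flat key-value config file (YAML mapping)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a flat key-value mapping")
    return data
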