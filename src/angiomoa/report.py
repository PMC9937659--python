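"""Human-readable markdown summary of a pipeline run.

Assembles the four result views from the stage TSVs: top enriched targets per
phenotype, the recurrent-pathway matrix, cross-validation metrics, and the
ranked predictions for unknown compounds. Stages whose outputs are absent are
reported as MISSING rather than failing the report.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .config import INHIBIT, PROMOTE

logger = logging.getLogger(__name__)


def _table(df: pd.DataFrame, max_rows: int | None = None) -> str:
    if max_rows is not None:
        df = df.head(max_rows)
    return "```\n" + df.to_string(index=False) + "\n```"


def write_report(out_dir: str | Path, top_k: int = 10) -> Path:
    out = Path(out_dir)
    lines: list[str] = ["# Mode-of-action analysis report", ""]

    lines.append("## 1. Enriched predicted targets per phenotype")
    for phenotype in (PROMOTE, INHIBIT):
        path = out / f"enrichment_{phenotype}.tsv"
        lines.append(f"\n### {phenotype}\n")
        if path.exists():
            df = pd.read_csv(path, sep="\t")
            cols = ["target_id", "a", "b", "c", "d", "odds_ratio", "p_value", "significant"]
            lines.append(_table(df[cols], max_rows=top_k))
        else:
            lines.append("MISSING: enrichment output not found")

    lines.append("\n## 2. Recurrent enriched pathways (−log10 adjusted p)\n")
    path = out / "pathway_matrix.tsv"
    if path.exists():
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.empty:
            lines.append("No pathway was significantly enriched in two or more compounds.")
        else:
            lines.append(_table(df.round(3).reset_index()))
    else:
        lines.append("MISSING: pathway matrix not found")

    lines.append("\n## 3. Leave-one-out cross-validation\n")
    path = out / "cv_report.tsv"
    if path.exists():
        df = pd.read_csv(path, sep="\t")
        lines.append(_table(df))
    else:
        lines.append("MISSING: CV report not found")

    lines.append("\n## 4. Ranked predictions for unknown compounds\n")
    path = out / "predictions.tsv"
    if path.exists():
        df = pd.read_csv(path, sep="\t")
        if df.empty:
            lines.append("No unknown compounds were supplied; nothing to rank.")
        else:
            lines.append(_table(df))
    else:
        lines.append("MISSING: predictions not found")

    report = out / "report.md"
    report.write_text("\n".join(lines) + "\n")
    logger.info("report written to %s", report.name)
    return report
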