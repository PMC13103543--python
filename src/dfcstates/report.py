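"""Human-readable run report rendered from pipeline artifacts.

Every number in the report is read back from the TSVs the pipeline wrote —
the renderer recomputes nothing.
"""
from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import io as dio


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing pipeline artifact: {path.name}")
    return path


def _md_table(df: pd.DataFrame, floatfmt: str = "{:.3f}") -> str:
    def fmt(v):
        if isinstance(v, float):
            return floatfmt.format(v)
        return str(v)

    header = "| " + " | ".join(df.columns) + " |"
    sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
    rows = ["| " + " | ".join(fmt(v) for v in row) + " |" for row in df.itertuples(index=False)]
    return "\n".join([header, sep] + rows)


def make_report(output_dir: str | Path, plots: bool = True) -> Path:
    out = Path(output_dir)
    manifest = json.loads(_require(out / "manifest.json").read_text())
    lines = ["# Dynamic connectivity state analysis — run report", ""]
    lines.append(f"k = {manifest['k']}, seed = {manifest['seed']}, "
                 f"final WCSS = {manifest['wcss']:.4g}")
    if not manifest.get("harmonized", False):
        lines.append("")
        lines.append("**Note: features are unharmonized (no site adjustment was applied).**")
    lines.append("")

    for name, title in [
        ("stats_temporal.tsv", "Group comparison of temporal metrics"),
        ("stats_transitions.tsv", "Group comparison of pairwise state transitions"),
    ]:
        p = out / name
        if p.exists():
            df = dio.read_table(p)
            lines += [f"## {title}", "", _md_table(df), ""]

    anova_p = out / "statewise_anova.tsv"
    if anova_p.exists():
        lines += ["## Within-subject state-wise FC strength", "",
                  _md_table(dio.read_table(anova_p)), ""]
        ph = out / "stats_statewise_posthoc.tsv"
        if ph.exists():
            lines += [_md_table(dio.read_table(ph)), ""]

    adj = out / "stats_adjusted.tsv"
    if adj.exists():
        lines += ["## Covariate-adjusted group effects", "",
                  _md_table(dio.read_table(adj)), ""]

    eng = dio.read_table(_require(out / "engagement.tsv"))
    lines += ["## Participants engaging each state at least once", "",
              _md_table(eng), ""]

    if plots:
        centroid_files = sorted(out.glob("centroid_state*.tsv"))
        if centroid_files:
            fig, axes = plt.subplots(1, len(centroid_files),
                                     figsize=(4 * len(centroid_files), 3.6))
            if len(centroid_files) == 1:
                axes = [axes]
            for ax, f in zip(axes, centroid_files):
                mat = dio.read_table(f).to_numpy(float)
                im = ax.imshow(mat, cmap="RdBu_r", vmin=-0.6, vmax=0.6)
                ax.set_title(f.stem.replace("centroid_", ""))
            fig.colorbar(im, ax=axes, shrink=0.8, label="Fisher z")
            fig.savefig(out / "centroids.png", dpi=110)
            plt.close(fig)
            lines += ["![state centroids](centroids.png)", ""]
        elbow_p = out / "elbow.tsv"
        if elbow_p.exists():
            df = dio.read_table(elbow_p)
            fig, ax = plt.subplots(figsize=(4.2, 3.2))
            ax.plot(df["k"], df["wcss"], "o-")
            ax.set_xlabel("k")
            ax.set_ylabel("WCSS")
            fig.tight_layout()
            fig.savefig(out / "elbow.png", dpi=110)
            plt.close(fig)
            lines += ["![elbow curve](elbow.png)", ""]

    report_path = out / "report.md"
    report_path.write_text("\n".join(lines))
    return report_path
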