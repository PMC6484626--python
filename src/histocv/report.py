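"""Report bundle writer: CSV tables, a JSON run manifest, a text summary.

The three CSV tables mirror the usual presentation of this kind of study:
per-scheme per-task mean (SD) rates, a lower-triangular McNemar p-value
matrix (formatted "<.001" below the significance threshold), and the
trainer x evaluator agreement matrix of the cross-expert experiment.
Outputs are byte-stable given identical inputs, and nothing is written if
the comparison is empty.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .experiments import CrossExpertResult, CVComparison
from .stats_compare import ALPHA


def format_p(p: float) -> str:
    """Journal-style p formatting: '<.001' below threshold, else '.ddd'."""
    if pd.isna(p):
        return "NA"
    if p < ALPHA:
        return "<.001"
    return f"{p:.3f}".lstrip("0") or ".000"


def _metrics_table(comparison: CVComparison) -> pd.DataFrame:
    rows = []
    for _, r in comparison.metrics.iterrows():
        rows.append({
            "cv_method": r["scheme"],
            "classification": {"detection": "benign vs cancer",
                               "grading": "low-grade vs high-grade"}.get(r["task"], r["task"]),
            "accuracy_mean_sd_pct": f"{r['accuracy_mean']:.1f} ({r['accuracy_sd']:.1f})",
            "sensitivity_mean_sd_pct": f"{r['sensitivity_mean']:.1f} ({r['sensitivity_sd']:.1f})",
            "specificity_mean_sd_pct": f"{r['specificity_mean']:.1f} ({r['specificity_sd']:.1f})",
        })
    return pd.DataFrame(rows)


def write_report(
    out_dir: str | Path,
    comparison: CVComparison | None = None,
    cross_expert: CrossExpertResult | None = None,
    manifest: dict | None = None,
) -> dict[str, Path]:
    """Write all available outputs under ``out_dir``; returns written paths.

    Raises before touching the filesystem if there is nothing to write or a
    comparison is present but empty (no partial bundles).
    """
    if comparison is None and cross_expert is None:
        raise ValueError("nothing to write: no comparison and no cross-expert result")
    if comparison is not None and len(comparison.schemes) == 0:
        raise ValueError("empty comparison: no schemes to report")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    summary_lines: list[str] = []

    if comparison is not None:
        path = out_dir / "cv_metrics.csv"
        _metrics_table(comparison).to_csv(path, index=False)
        written["cv_metrics"] = path
        summary_lines.append("Cross-validation metrics (mean (SD) %, across folds):")
        for _, r in comparison.metrics.iterrows():
            summary_lines.append(
                f"  {r['scheme']:>28s} | {r['task']:<9s} | "
                f"acc {r['accuracy_mean']:5.1f} ({r['accuracy_sd']:4.1f}) | "
                f"sens {r['sensitivity_mean']:5.1f} ({r['sensitivity_sd']:4.1f}) | "
                f"spec {r['specificity_mean']:5.1f} ({r['specificity_sd']:4.1f})"
            )
        for task_name, pmat in comparison.pvalues.items():
            path = out_dir / f"mcnemar_{task_name}.csv"
            pmat.map(format_p).to_csv(path)
            written[f"mcnemar_{task_name}"] = path
            summary_lines.append(f"McNemar p values ({task_name}):")
            for i, si in enumerate(pmat.index):
                for sj in pmat.columns[:i]:
                    summary_lines.append(
                        f"  {si} vs {sj}: p = {format_p(pmat.loc[si, sj])}"
                    )

    if cross_expert is not None:
        path = out_dir / "cross_expert_agreement.csv"
        cross_expert.agreement.round(4).rename_axis("trained_on").to_csv(path)
        written["cross_expert_agreement"] = path
        summary_lines.append(
            f"Cross-expert quadratic-weighted kappa "
            f"(overall rule: {cross_expert.overall_rule}):"
        )
        for trainer, row in cross_expert.agreement.iterrows():
            summary_lines.append(f"  trained on {trainer}: overall {row['overall']:.2f}")

    manifest = dict(manifest or {})
    manifest.setdefault("outputs", sorted(str(p.name) for p in written.values()))
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    written["manifest"] = path

    path = out_dir / "summary.txt"
    path.write_text("\n".join(summary_lines) + "\n")
    written["summary"] = path
    return written
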