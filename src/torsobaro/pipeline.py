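"""End-to-end orchestration: recording -> indices -> cohort report.

``analyze_subject`` runs preprocessing, landmark detection and index
extraction on one recording and attaches the severity label from the
radiographic Cobb angle.  ``run_validity_study`` aggregates a cohort into
the group-comparison, post hoc and correlation tables, derives percentage
increases between group means, and optionally renders QC box/scatter
plots.  Every output carries the configuration hash for provenance.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import ValidationError
from .frame_io import PressureRecording
from .indices import INDEX_NAMES, compute_all
from .preprocess import preprocess_recording
from .stats import SEVERITIES, SubjectRecord, validity_analysis

__all__ = [
    "analyze_subject",
    "run_validity_study",
    "percent_increases",
    "subject_to_json",
]


def analyze_subject(
    rec: PressureRecording,
    cobb_angle_deg: float,
    config: PipelineConfig | None = None,
    subject_id: str = "",
) -> SubjectRecord:
    """Deterministic single-subject analysis; per-index failures are
    recorded in the IndexSet rather than aborting."""
    cfg = config or PipelineConfig()
    roi = preprocess_recording(rec, cfg.preprocess)
    index_set = compute_all(roi, cfg.landmarks, cfg.indices)
    index_set.diagnostics["config_hash"] = cfg.config_hash()
    index_set.diagnostics["provenance"] = roi.provenance
    sid = subject_id or str((rec.subject_meta or {}).get("id", ""))
    return SubjectRecord(
        id=sid, index_set=index_set, cobb_angle_deg=float(cobb_angle_deg)
    )


def percent_increases(means) -> dict:
    """Percentage increases between severity-group means, rounded to the
    nearest whole percent: none->mild, none->moderate, mild->moderate."""
    none, mild, moderate = (float(m) for m in means)
    if none <= 0 or mild <= 0:
        raise ValidationError("group means must be positive for increase ratios")
    return {
        "none_to_mild": int(round(100.0 * (mild - none) / none)),
        "none_to_moderate": int(round(100.0 * (moderate - none) / none)),
        "mild_to_moderate": int(round(100.0 * (moderate - mild) / mild)),
    }


def _tables(comparisons, correlations, config: PipelineConfig):
    rows = []
    for c in comparisons:
        row = {"index": c.index}
        for s in SEVERITIES:
            row[f"n_{s}"] = c.group_n[s]
            row[f"mean_{s}"] = c.group_mean[s]
            row[f"sd_{s}"] = c.group_sd[s]
        row.update(H=c.h_statistic, p_raw=c.p_raw, p_adjusted=c.p_adjusted,
                   n_excluded=c.n_excluded)
        rows.append(row)
    groups_df = pd.DataFrame(rows)

    pair_rows = []
    for c in comparisons:
        for (a, b), z, p_raw, p_adj, es, cat in c.pairwise:
            pair_rows.append(
                dict(index=c.index, group_1=a, group_2=b, z=z, p_raw=p_raw,
                     p_adjusted=p_adj, es=es, es_category=cat)
            )
    pairwise_df = pd.DataFrame(
        pair_rows,
        columns=["index", "group_1", "group_2", "z", "p_raw", "p_adjusted", "es",
                 "es_category"],
    )

    corr_df = pd.DataFrame(
        [dict(index=r.index, rho=r.rho, p=r.p, category=r.category, n=r.n)
         for r in correlations]
    )

    inc_rows = []
    for c in comparisons:
        means = [c.group_mean[s] for s in SEVERITIES]
        if all(np.isfinite(means)) and means[0] > 0 and means[1] > 0:
            inc = percent_increases(means)
            inc_rows.append(dict(index=c.index, **inc))
    increases_df = pd.DataFrame(inc_rows)
    for df in (groups_df, pairwise_df, corr_df, increases_df):
        df.attrs["config_hash"] = config.config_hash()
    return {
        "groups": groups_df,
        "pairwise": pairwise_df,
        "correlation": corr_df,
        "increases": increases_df,
    }


def _plots(records, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 3, figsize=(12, 7))
    for ax, name in zip(axes.ravel(), INDEX_NAMES):
        data = []
        for s in SEVERITIES:
            data.append(
                [getattr(r.index_set, name) for r in records
                 if r.severity == s and getattr(r.index_set, name) is not None]
            )
        ax.boxplot(data, tick_labels=SEVERITIES)
        ax.set_title(name.upper())
    fig.tight_layout()
    fig.savefig(out_dir / "boxplots.png", dpi=100)
    plt.close(fig)

    fig, axes = plt.subplots(2, 3, figsize=(12, 7))
    for ax, name in zip(axes.ravel(), INDEX_NAMES):
        xy = [
            (r.cobb_angle_deg, getattr(r.index_set, name))
            for r in records
            if getattr(r.index_set, name) is not None
        ]
        if xy:
            x, y = zip(*xy)
            ax.scatter(x, y, s=10)
            coeff = np.polyfit(x, y, 1)
            xs = np.linspace(min(x), max(x), 20)
            ax.plot(xs, np.polyval(coeff, xs), "r-", lw=1)
        ax.set_xlabel("Cobb angle (deg)")
        ax.set_title(name.upper())
    fig.tight_layout()
    fig.savefig(out_dir / "scatterplots.png", dpi=100)
    plt.close(fig)


def run_validity_study(
    subjects,
    config: PipelineConfig | None = None,
    out_dir=None,
    make_plots: bool = False,
) -> dict:
    """Cohort-level report: tables (CSV when ``out_dir`` given), derived
    percentage increases, optional QC plots.  Invariant to subject order."""
    cfg = config or PipelineConfig()
    subjects = list(subjects)
    comparisons, correlations = validity_analysis(subjects)
    report = _tables(comparisons, correlations, cfg)
    report["comparisons"] = comparisons
    report["correlations"] = correlations
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for key in ("groups", "pairwise", "correlation", "increases"):
            # %.17g round-trips doubles exactly
            report[key].to_csv(out_dir / f"{key}.csv", index=False, float_format="%.17g")
        (out_dir / "run.json").write_text(
            json.dumps({"config": cfg.to_dict(), "config_hash": cfg.config_hash(),
                        "n_subjects": len(subjects)}, indent=1)
        )
        if make_plots:
            _plots(subjects, out_dir)
    return report


def subject_to_json(record: SubjectRecord, config: PipelineConfig | None = None) -> str:
    """Versioned subject JSON: indices, diagnostics, provenance."""
    cfg = config or PipelineConfig()

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return None  # nested landmark objects are not serialized
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return obj

    payload = {
        "schema_version": cfg.version,
        "id": record.id,
        "cobb_angle_deg": record.cobb_angle_deg,
        "severity": record.severity,
        "indices": record.index_set.as_dict(),
        "failures": record.index_set.failures,
        "diagnostics": _clean(
            {k: v for k, v in record.index_set.diagnostics.items() if k != "landmarks"}
        ),
        "config_hash": cfg.config_hash(),
    }
    return json.dumps(payload, indent=1)
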