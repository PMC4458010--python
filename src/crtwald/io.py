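"""Dataset serialization and the per-trial analysis report.

Datasets travel as delimited text with header ``cluster,arm,y`` — one row
per subject, arm coded 0 = control / 1 = intervention, outcome 0/1.  The
analysis report mirrors the conventional mixed-model output: one row per
DDF method with the intervention estimate (log odds ratio), its standard
error, the Wald F value, numerator/denominator degrees of freedom, and the
p-value, plus a dataset summary and the ANOVA moment estimate of the ICC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ddf import DDF_METHODS, TestResult, run_all_tests
from .glmm import FitOptions, FitResult, anova_icc, fit_glmm
from .simulate import CRTDataset

__all__ = [
    "AnalysisReport",
    "read_trial_csv",
    "write_trial_csv",
    "analyze",
    "render_report",
]

METHOD_LABELS = {
    "residual": "Residual",
    "containment": "Containment",
    "between_within": "B-W",
    "satterthwaite": "Satterthwaite",
    "kenward_roger": "K-R",
}


@dataclass
class AnalysisReport:
    """Five-method small-sample inference summary for one trial."""

    K: int
    N: int
    clusters_per_arm: dict
    event_rate_per_arm: dict
    icc_anova: float
    fit: FitResult
    tests: list[TestResult]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.tests:
            rows.append({
                "method": METHOD_LABELS.get(t.method, t.method),
                "estimate": t.estimate,
                "se": t.se,
                "F": t.F,
                "num_df": t.num_df,
                "ddf": t.ddf,
                "p": t.p_value,
            })
        return pd.DataFrame(rows)


def write_trial_csv(data: CRTDataset, path) -> None:
    pd.DataFrame({
        "cluster": data.cluster_ids,
        "arm": data.arm,
        "y": data.y,
    }).to_csv(path, index=False)


def read_trial_csv(path, arm_map: dict | None = None) -> CRTDataset:
    """Read and validate a ``cluster,arm,y`` subject-level file.

    ``arm_map`` optionally translates non-0/1 arm codes (e.g.
    {"control": 0, "active": 1}).  Validation errors name the offending
    clusters or rows.
    """
    df = pd.read_csv(path)
    required = ["cluster", "arm", "y"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}; "
                         f"expected header 'cluster,arm,y'")
    if arm_map:
        df["arm"] = df["arm"].map(lambda a: arm_map.get(a, a))
    bad_y = df.loc[~df["y"].isin([0, 1])]
    if len(bad_y):
        raise ValueError(
            f"non-binary outcomes at rows {list(bad_y.index[:10])} "
            f"(values {sorted(bad_y['y'].unique().tolist())})")
    bad_arm = df.loc[~df["arm"].isin([0, 1])]
    if len(bad_arm):
        raise ValueError(
            f"arm codes must be 0/1 (or provide arm_map); offending rows "
            f"{list(bad_arm.index[:10])}")
    mixed = df.groupby("cluster")["arm"].nunique()
    mixed = mixed[mixed > 1]
    if len(mixed):
        raise ValueError(
            f"clusters containing both arms: {list(mixed.index)}")
    if df["arm"].nunique() < 2:
        raise ValueError("dataset contains a single arm; two arms required")
    return CRTDataset(cluster_ids=df["cluster"].to_numpy(),
                      arm=df["arm"].to_numpy(),
                      y=df["y"].to_numpy())


def analyze(data: CRTDataset | str, options: FitOptions | None = None,
            methods=DDF_METHODS) -> AnalysisReport:
    """Fit the GLMM once and compute all five DDF tests."""
    if not isinstance(data, CRTDataset):
        data = read_trial_csv(data)
    fit = fit_glmm(data, options)
    tests = run_all_tests(fit, methods)
    arm_of_cluster = {}
    for lab in np.unique(data.cluster_ids):
        arm_of_cluster[lab] = int(data.arm[data.cluster_ids == lab][0])
    arms = np.array(list(arm_of_cluster.values()))
    return AnalysisReport(
        K=data.K,
        N=data.N,
        clusters_per_arm={0: int((arms == 0).sum()), 1: int((arms == 1).sum())},
        event_rate_per_arm={a: float(data.y[data.arm == a].mean())
                            for a in (0, 1)},
        icc_anova=anova_icc(data.cluster_ids, data.y, data.arm),
        fit=fit,
        tests=tests,
    )


def render_report(report: AnalysisReport, decimals: int = 4) -> str:
    """Aligned plain-text report (numbers at 4 decimals)."""
    lines = []
    lines.append("GLMM small-sample inference of the intervention effect")
    lines.append(f"clusters: {report.K} "
                 f"(control {report.clusters_per_arm[0]}, "
                 f"intervention {report.clusters_per_arm[1]}); "
                 f"subjects: {report.N}")
    lines.append(f"crude event rates: control "
                 f"{report.event_rate_per_arm[0]:.{decimals}f}, intervention "
                 f"{report.event_rate_per_arm[1]:.{decimals}f}")
    lines.append(f"ANOVA ICC estimate: {report.icc_anova:.{decimals}f}; "
                 f"tau2 (PQL/REML): {report.fit.varcomp.tau2:.{decimals}f}; "
                 f"phi: {report.fit.varcomp.phi:.{decimals}f}")
    if report.fit.flags:
        lines.append(f"fit flags: {', '.join(report.fit.flags)}")
    df = report.to_frame()
    header = (f"{'Method':<14}{'Estimate':>10}{'SE':>10}{'F':>10}"
              f"{'NumDF':>7}{'DenDF':>10}{'P':>10}")
    lines.append(header)
    lines.append("-" * len(header))
    for _, r in df.iterrows():
        ddf = r["ddf"]
        ddf_str = f"{ddf:.2f}".rstrip("0").rstrip(".") \
            if np.isfinite(ddf) else "--"
        f_str = f"{r['F']:.{decimals}f}" if np.isfinite(r["F"]) else "--"
        p_str = f"{r['p']:.{decimals}f}" if np.isfinite(r["p"]) else "--"
        lines.append(f"{r['method']:<14}{r['estimate']:>10.{decimals}f}"
                     f"{r['se']:>10.{decimals}f}{f_str:>10}"
                     f"{int(r['num_df']):>7}{ddf_str:>10}{p_str:>10}")
    return "\n".join(lines)
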