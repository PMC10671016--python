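"""Group tables and one-way repeated-measures ANOVA with vs-control post hocs.

Each animal contributes one complete row of 15-min interval means, with the
pre-injection control bin (-15, 0] stored under the label ``"pre"``.  The
omnibus test partitions SS_total = SS_subject + SS_time + SS_error (the
two-way subject x time layout without replication, computed from first
principles) and refers F = MS_time / MS_error to F(k-1, (n-1)(k-1)).

Post-hoc comparisons test each post-injection label against the pre control
and are Holm-adjusted.  The default ("pooled") uses the ANOVA error term
(MS_error with its (n-1)(k-1) degrees of freedom) as a protected
vs-control comparison; ``posthoc="paired"`` gives the classic per-pair
paired t with n-1 degrees of freedom, and ``adjust`` can be set to
"holm" (default), "bonferroni" or "none".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PRE_LABEL",
    "GroupTimeSeries",
    "PosthocComparison",
    "RmAnovaResult",
    "build_group_table",
    "rm_anova",
    "significance_report",
]

PRE_LABEL = "pre"
_EPS_P = float(np.finfo(float).eps)   # reported bound when MS_error degenerates


@dataclass
class GroupTimeSeries:
    """Complete animals x time-point table of dF/F0 % interval means.

    Columns are the pre-control label ``"pre"`` followed by post-injection
    interval end-times in minutes; every animal is measured at every label
    (repeated measures, no missing cells).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 animals")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 time labels")
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()
            raise ValueError(f"missing cells at labels {bad}; no imputation is done")

    @property
    def animals(self) -> list[str]:
        return [str(a) for a in self.data.index]

    @property
    def labels(self) -> list:
        return list(self.data.columns)

    def post_labels(self) -> list[float]:
        return [float(c) for c in self.data.columns if c != PRE_LABEL]


@dataclass
class PosthocComparison:
    label: float
    mean_diff: float     # label mean minus pre-control mean
    t_stat: float
    df: float
    p_raw: float
    p_adjusted: float
    significant_05: bool = False
    significant_01: bool = False


@dataclass
class RmAnovaResult:
    f_stat: float
    df_time: int
    df_error: int
    p_omnibus: float
    ss_subject: float
    ss_time: float
    ss_error: float
    ss_total: float
    degenerate_variance: bool
    posthoc: list[PosthocComparison] = field(default_factory=list)
    label_means: dict = field(default_factory=dict)
    label_sd: dict = field(default_factory=dict)
    label_sem: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "f_stat": self.f_stat, "df_time": self.df_time,
            "df_error": self.df_error, "p_omnibus": self.p_omnibus,
            "ss": {"subject": self.ss_subject, "time": self.ss_time,
                   "error": self.ss_error, "total": self.ss_total},
            "degenerate_variance": self.degenerate_variance,
            "posthoc": [vars(c) for c in self.posthoc],
        }


def build_group_table(sessions, labels=None) -> GroupTimeSeries:
    """Assemble animal rows from per-session interval traces.

    ``sessions`` maps animal id to ``(interval_labels, interval_values)``;
    the interval labelled 0 (the (-15, 0] bin) becomes the ``"pre"`` control
    column.  ``labels`` restricts/orders the requested post labels; by
    default every session must share the full label set of the first.
    """
    if hasattr(sessions, "items"):
        items = list(sessions.items())
    else:
        items = [(f"animal{i + 1}", s) for i, s in enumerate(sessions)]
    if not items:
        raise ValueError("no sessions supplied")

    rows = {}
    for animal, (lab, val) in items:
        lab = np.asarray(lab, dtype=float)
        val = np.asarray(val, dtype=float)
        mapping = {}
        for l, v in zip(lab, val):
            key = PRE_LABEL if abs(l) < 1e-9 else float(l)
            mapping[key] = float(v)
        rows[str(animal)] = mapping

    if labels is None:
        first = next(iter(rows.values()))
        labels = [k for k in first if k == PRE_LABEL or k > 0]
    for animal, mapping in rows.items():
        missing = [l for l in labels if l not in mapping]
        if missing:
            raise ValueError(
                f"session {animal!r} does not cover requested labels {missing}")

    frame = pd.DataFrame({l: {a: rows[a][l] for a in rows} for l in labels},
                         columns=list(labels))
    frame.index.name = "animal_id"
    return GroupTimeSeries(frame)


def _holm_like(p_raw: np.ndarray, method: str) -> np.ndarray:
    if method == "none":
        return p_raw.copy()
    name = {"holm": "holm", "bonferroni": "bonferroni"}.get(method)
    if name is None:
        raise ValueError(f"unknown adjustment {method!r}")
    return multipletests(p_raw, method=name)[1]


def rm_anova(table: GroupTimeSeries, posthoc: str = "pooled",
             adjust: str = "holm") -> RmAnovaResult:
    """One-way repeated-measures ANOVA over time with vs-pre post hocs."""
    x = table.data.to_numpy(dtype=float)
    n, k = x.shape
    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    ss_subject = float(k * ((x.mean(axis=1) - grand) ** 2).sum())
    ss_time = float(n * ((x.mean(axis=0) - grand) ** 2).sum())
    ss_error = max(ss_total - ss_subject - ss_time, 0.0)
    df_time, df_error = k - 1, (n - 1) * (k - 1)
    degenerate = ss_error <= 1e-12 * max(ss_total, 1e-30)

    ms_time = ss_time / df_time
    ms_error = ss_error / df_error
    if degenerate:
        if ss_time <= 1e-12 * max(ss_total, 1e-30):
            f_stat, p_omni = 0.0, 1.0
        else:
            f_stat, p_omni = float("inf"), _EPS_P
    else:
        f_stat = ms_time / ms_error
        p_omni = float(sps.f.sf(f_stat, df_time, df_error))

    comparisons: list[PosthocComparison] = []
    if PRE_LABEL in table.labels:
        pre = x[:, table.labels.index(PRE_LABEL)]
        post_labels = [l for l in table.labels if l != PRE_LABEL]
        t_stats, dfs, p_raws, diffs = [], [], [], []
        for l in post_labels:
            d = x[:, table.labels.index(l)] - pre
            diff = float(d.mean())
            if posthoc == "pooled":
                se = np.sqrt(2.0 * ms_error / n)
                df = df_error
            elif posthoc == "paired":
                se = d.std(ddof=1) / np.sqrt(n)
                df = n - 1
            else:
                raise ValueError(f"unknown posthoc {posthoc!r}")
            if se == 0:
                t = 0.0 if diff == 0 else np.sign(diff) * float("inf")
                p = 1.0 if diff == 0 else _EPS_P
            else:
                t = diff / se
                p = float(2.0 * sps.t.sf(abs(t), df))
            t_stats.append(t); dfs.append(df); p_raws.append(p); diffs.append(diff)
        p_adj = _holm_like(np.asarray(p_raws), adjust)
        for l, diff, t, df, pr, pa in zip(post_labels, diffs, t_stats, dfs,
                                          p_raws, p_adj):
            comparisons.append(PosthocComparison(
                label=float(l), mean_diff=diff, t_stat=float(t), df=float(df),
                p_raw=float(pr), p_adjusted=float(pa),
                significant_05=bool(pa < 0.05), significant_01=bool(pa < 0.01)))

    means = {str(l): float(x[:, i].mean()) for i, l in enumerate(table.labels)}
    sds = {str(l): float(x[:, i].std(ddof=1)) for i, l in enumerate(table.labels)}
    sems = {str(l): float(x[:, i].std(ddof=1) / np.sqrt(n))
            for i, l in enumerate(table.labels)}
    return RmAnovaResult(
        f_stat=float(f_stat), df_time=df_time, df_error=df_error,
        p_omnibus=float(p_omni), ss_subject=ss_subject, ss_time=ss_time,
        ss_error=ss_error, ss_total=ss_total, degenerate_variance=degenerate,
        posthoc=comparisons, label_means=means, label_sd=sds, label_sem=sems)


def stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def significance_report(result: RmAnovaResult,
                        table: GroupTimeSeries | None = None) -> pd.DataFrame:
    """Per-label summary: mean, SD, SEM, vs-pre difference, adjusted p, stars.

    SD is what the group figures plot; SEM is also reported.
    """
    rows = []
    all_labels = list(result.label_means)
    by_label = {str(c.label): c for c in result.posthoc}
    for l in all_labels:
        c = by_label.get(l)
        rows.append({
            "label": l,
            "mean_dff_pct": result.label_means[l],
            "sd": result.label_sd[l],
            "sem": result.label_sem[l],
            "mean_diff_vs_pre": c.mean_diff if c else np.nan,
            "t_stat": c.t_stat if c else np.nan,
            "p_raw": c.p_raw if c else np.nan,
            "p_adjusted": c.p_adjusted if c else np.nan,
            "stars": stars(c.p_adjusted) if c else "",
        })
    frame = pd.DataFrame(rows).set_index("label")
    frame.attrs["p_omnibus"] = result.p_omnibus
    frame.attrs["f_stat"] = result.f_stat
    return frame
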