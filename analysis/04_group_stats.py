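#!/usr/bin/env python
"""Group-level repeated-measures ANOVA per drug, vs the pre-15-min control.

Builds the animals x 15-min-interval tables from results/traces.csv, runs
the one-way repeated-measures ANOVA with Holm-adjusted post-hoc comparisons
against the pre-injection control bin, and writes the tables and annotated
summaries under results/stats/.
"""

from pathlib import Path

import pandas as pd

from microdff import (build_group_table, rm_anova, significance_report,
                      write_results)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    traces = pd.read_csv(RESULTS / "traces.csv")
    for drug in ("morphine", "cocaine", "saline"):
        sessions = {}
        for name, grp in traces.groupby("session"):
            if name.startswith(drug):
                sessions[name] = (grp["time_min"].to_numpy(),
                                  grp["dff_pct"].to_numpy())
        table = build_group_table(sessions)
        result = rm_anova(table)
        report = significance_report(result, table)
        marks = report.index[report["stars"] != ""].tolist()
        print(f"{drug}: F({result.df_time}, {result.df_error}) = "
              f"{result.f_stat:.1f}, omnibus p = {result.p_omnibus:.3g}; "
              f"labels marked vs pre: {marks if marks else 'none'}")
        write_results(RESULTS / "stats" / drug,
                      tables={"group_table": table.data,
                              "group_report": report},
                      records={"anova": result})
    print(f"\nstatistics under {RESULTS.relative_to(ROOT)}/stats/")


if __name__ == "__main__":
    main()
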