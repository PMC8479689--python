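"""JSON report writer for cohort summaries and comparisons."""
from __future__ import annotations

import json
from typing import Optional, Sequence

from .cohort_stats import CohortSummary, ComparisonReport

REPORT_SCHEMA_VERSION = "1"


def report_payload(
    comparisons: Sequence[ComparisonReport],
    summaries: Sequence[CohortSummary],
    seed: Optional[int] = None,
    config_hash: Optional[str] = None,
) -> dict:
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": seed,
        "config_hash": config_hash,
        "summaries": [
            {"metric": s.metric, "n": s.n, "mean": s.mean, "sd": s.sd,
             "min": s.min, "max": s.max}
            for s in summaries
        ],
        "comparisons": [
            {"metric": c.metric,
             "pooled": {"t": c.pooled.t, "df": c.pooled.df, "p": c.pooled.p},
             "welch": {"t": c.welch.t, "df": c.welch.df, "p": c.welch.p},
             "significant_at_0p05": c.significant_at_0p05,
             "significant_at_0p01": c.significant_at_0p01}
            for c in comparisons
        ],
    }


def write_report(
    comparisons: Sequence[ComparisonReport],
    summaries: Sequence[CohortSummary],
    path,
    seed: Optional[int] = None,
    config_hash: Optional[str] = None,
) -> None:
    """Write a stable-key-order JSON report; identical inputs give identical files."""
    payload = report_payload(comparisons, summaries, seed=seed, config_hash=config_hash)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
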