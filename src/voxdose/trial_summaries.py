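"""Published cohort summaries for the three prostate EBRT trials.

Per-endpoint analysis-set sizes and late-toxicity event counts as published
for the RADAR (TROG 03.04), RT01 and CHHiP trials, after exclusions for loss
of follow-up, missing data, baseline toxicity and non-EBRT treatment.  The
combined column pools the three trials by simple concatenation, so its
counts are the per-trial sums.  These summaries are the public face of
cohorts whose underlying dose and outcome data are not deposited; the
package uses them to anchor its event-rate arithmetic and as the conditions
the synthetic cohorts emulate.
"""

from __future__ import annotations

import pandas as pd

TRIALS = ("RADAR", "RT01", "CHHiP")
ENDPOINT_GRADE_THRESHOLDS = {"dysuria": 2, "haematuria": 1,
                             "incontinence": 2, "frequency": 2}

#: endpoint -> trial -> (events, analysis-set size)
EVENT_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "dysuria":      {"RADAR": (79, 595),  "RT01": (36, 388),  "CHHiP": (11, 242)},
    "haematuria":   {"RADAR": (86, 619),  "RT01": (52, 388),  "CHHiP": (21, 247)},
    "incontinence": {"RADAR": (24, 647),  "RT01": (26, 354),  "CHHiP": (6, 242)},
    "frequency":    {"RADAR": (125, 416), "RT01": (131, 264), "CHHiP": (33, 206)},
}


def pooled_counts(endpoint: str) -> tuple[int, int]:
    """Combined-cohort (events, n): the sum over the three trials."""
    per_trial = EVENT_COUNTS[endpoint]
    events = sum(e for e, _ in per_trial.values())
    n = sum(n for _, n in per_trial.values())
    return events, n


def event_percentage(endpoint: str, trial: str = "COMBINED") -> float:
    """Event rate in percent, rounded to one decimal (as conventionally printed)."""
    if trial == "COMBINED":
        events, n = pooled_counts(endpoint)
    else:
        events, n = EVENT_COUNTS[endpoint][trial]
    return round(100.0 * events / n, 1)


def summary_table() -> pd.DataFrame:
    """All endpoints x (three trials + combined): events, n, percent."""
    rows = []
    for endpoint in EVENT_COUNTS:
        for trial in (*TRIALS, "COMBINED"):
            events, n = (pooled_counts(endpoint) if trial == "COMBINED"
                         else EVENT_COUNTS[endpoint][trial])
            rows.append({"endpoint": endpoint, "trial": trial, "events": events,
                         "n": n, "event_pct": event_percentage(endpoint, trial)})
    return pd.DataFrame(rows)
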