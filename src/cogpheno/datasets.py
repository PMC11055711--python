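"""Published summary tables of a long-standing MS cohort, as inputs.

These are printed group-level counts from a 348-patient study usable as
worked-example inputs: the baseline phenotype distribution and the
baseline-by-follow-up transition cross-tabulation.  Only counts are
published; per-subject expansions below realise them minimally (the
expansion is synthetic in every respect other than the counts it
reproduces).
"""

from __future__ import annotations

import pandas as pd

from .phenotyping import PHENOTYPES
from .registry import DOMAINS

#: Baseline-by-follow-up transition counts among the 240 patients with
#: cognitive follow-up data; rows = baseline phenotype, columns =
#: follow-up phenotype.
TRANSITION_COUNTS = {
    "isolated_ips": [5, 0, 0, 0, 11, 0],
    "isolated_memory": [0, 9, 0, 0, 5, 2],
    "isolated_efwm": [1, 1, 9, 0, 7, 6],
    "isolated_attention": [0, 2, 3, 2, 3, 7],
    "multidomain": [4, 4, 3, 2, 80, 2],
    "preserved": [2, 10, 10, 8, 9, 33],
}

#: Baseline phenotype counts in the full cohort of 348 patients.
BASELINE_COUNTS = {
    "isolated_ips": 25,
    "isolated_memory": 23,
    "isolated_efwm": 37,
    "isolated_attention": 23,
    "multidomain": 148,
    "preserved": 92,
}

#: Among the 148 multi-domain patients, 108 had processing speed affected.
MULTIDOMAIN_IPS_INVOLVED = 108

#: Distribution of the number of impaired domains among impaired patients.
N_IMPAIRED_DISTRIBUTION = {2: 93, 3: 44, 4: 11}


def published_transition_counts() -> pd.DataFrame:
    """Transition cross-tabulation as a 6x6 count table."""
    cats = list(PHENOTYPES)
    return pd.DataFrame.from_dict(
        TRANSITION_COUNTS, orient="index", columns=cats
    ).reindex(cats)


def expand_transitions(counts: pd.DataFrame | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject baseline and follow-up label frames realising a count table.

    Returns two frames with ``subject_id`` and ``phenotype`` suitable for
    :func:`cogpheno.longitudinal.classify_trajectories` (category-level
    accounting; no impaired-domain counts are published per subject).
    """
    if counts is None:
        counts = published_transition_counts()
    bl_rows, fu_rows = [], []
    i = 0
    for b in counts.index:
        for f in counts.columns:
            for _ in range(int(counts.loc[b, f])):
                sid = f"S{i:04d}"
                bl_rows.append({"subject_id": sid, "phenotype": b})
                fu_rows.append({"subject_id": sid, "phenotype": f})
                i += 1
    return pd.DataFrame(bl_rows), pd.DataFrame(fu_rows)


def published_baseline_profiles() -> pd.DataFrame:
    """Per-subject label frame realising the baseline phenotype counts.

    Impairment flags are set so the phenotype counts, the number-impaired
    distribution and the multi-domain processing-speed involvement (108 of
    148) are reproduced exactly.  The published per-domain involvement
    counts (108/100/106/55) sum to 369 affected-domain slots, while the
    published 2/3/4-domain distribution provides 362; the two cannot be
    realised jointly, so only the processing-speed involvement is pinned.
    """
    rows = []
    i = 0

    def add(category, isolated_domain, impaired, n):
        nonlocal i
        for _ in range(n):
            row = {
                "subject_id": f"P{i:04d}",
                "timepoint": 1,
                "category": category,
                "isolated_domain": isolated_domain,
                "n_impaired": len(impaired),
            }
            for d in DOMAINS:
                row[f"imp_{d}"] = d in impaired
            row["phenotype"] = (
                f"isolated_{isolated_domain}" if category == "isolated" else category
            )
            rows.append(row)
            i += 1

    add("preserved", None, (), BASELINE_COUNTS["preserved"])
    for dom in DOMAINS:
        add("isolated", dom, (dom,), BASELINE_COUNTS[f"isolated_{dom}"])
    # multi-domain: 11 quadruple, 44 triple, 93 double; 108 involve IPS
    add("multidomain", None, ("ips", "memory", "efwm", "attention"), 11)
    add("multidomain", None, ("ips", "memory", "efwm"), 44)
    add("multidomain", None, ("ips", "memory"), 53)  # 11 + 44 + 53 = 108 with IPS
    add("multidomain", None, ("memory", "efwm"), 40)
    df = pd.DataFrame(rows)
    df["unclassifiable"] = False
    return df
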