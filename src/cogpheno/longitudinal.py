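"""Reliable change and longitudinal phenotype transitions.

The reliable change index corrects a subject's five-year score change for
the mean practice effect observed in healthy controls and scales it by
the standard error of the difference score:

    RCI = [(x2 - x1) - (mean(HC2) - mean(HC1))] / SEd

``|RCI| >= 1.64`` (inclusive) flags reliable change.  Two SEd estimators
are offered: the Jacobson-Truax form ``sqrt(SEM1^2 + SEM2^2)`` with
``SEM_i = SD_i * sqrt(1 - r12)`` (default), and the plain SD of the
control difference scores.

Trajectories are labelled from impaired-domain counts: *declining* when
more domains are impaired at follow-up than at baseline, *stable* when
the count is unchanged (switching the single impaired domain counts as
stable), and *improving* when a subject moves from multi-domain to
isolated impairment or from isolated impairment to preserved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phenotyping import PHENOTYPES
from .registry import RCI_THRESHOLD

logger = logging.getLogger(__name__)

MIN_HC_PAIRS = 20


class RCIError(RuntimeError):
    """Reliable-change norms could not be estimated."""


class TrajectoryError(RuntimeError):
    """Baseline/follow-up label collections are inconsistent."""


@dataclass(frozen=True)
class ChangeNorm:
    """Healthy-control change distribution for one score."""

    name: str
    hc_mean_change: float
    se_diff: float
    r12: float
    sd1: float
    sd2: float
    n: int


def estimate_change_norms(
    hc_t1: pd.DataFrame,
    hc_t2: pd.DataFrame,
    estimator: str = "jacobson_truax",
) -> dict[str, ChangeNorm]:
    """Estimate per-score HC mean change and SEd from paired control data.

    Inputs are wide tables (subjects x score names) for the two
    timepoints, index-aligned on subject.
    """
    norms: dict[str, ChangeNorm] = {}
    common = [c for c in hc_t1.columns if c in hc_t2.columns]
    for name in common:
        pair = pd.concat([hc_t1[name], hc_t2[name]], axis=1, keys=["x1", "x2"]).dropna()
        n = len(pair)
        if n < MIN_HC_PAIRS:
            raise RCIError(f"{name}: only {n} control pairs (< {MIN_HC_PAIRS})")
        x1, x2 = pair["x1"].to_numpy(), pair["x2"].to_numpy()
        sd1, sd2 = float(np.std(x1, ddof=1)), float(np.std(x2, ddof=1))
        r12 = float(np.corrcoef(x1, x2)[0, 1])
        if estimator == "jacobson_truax":
            sem1 = sd1 * math.sqrt(max(1.0 - r12, 0.0))
            sem2 = sd2 * math.sqrt(max(1.0 - r12, 0.0))
            se = math.sqrt(sem1**2 + sem2**2)
        elif estimator == "sd_of_differences":
            se = float(np.std(x2 - x1, ddof=1))
        else:
            raise ValueError(f"unknown SEd estimator {estimator!r}")
        if not se > 0:
            raise RCIError(f"{name}: zero SEd (degenerate control change scores)")
        norms[name] = ChangeNorm(
            name=name,
            hc_mean_change=float(np.mean(x2) - np.mean(x1)),
            se_diff=se,
            r12=r12,
            sd1=sd1,
            sd2=sd2,
            n=n,
        )
    return norms


def compute_rci(
    t1: pd.DataFrame,
    t2: pd.DataFrame,
    hc_t1: pd.DataFrame,
    hc_t2: pd.DataFrame,
    level: str = "domain",
    threshold: float = RCI_THRESHOLD,
    sed_estimator: str = "jacobson_truax",
) -> pd.DataFrame:
    """Per subject and score: practice-corrected reliable change index.

    All four inputs are wide tables (subjects x names); patients lacking a
    follow-up value are omitted for that score.  Returns a long table with
    x1, x2, hc_mean_change, se_diff, rci and the inclusive ``reliable``
    flag at ``|rci| >= threshold``.
    """
    change_norms = estimate_change_norms(hc_t1, hc_t2, estimator=sed_estimator)
    rows = []
    for name, cn in change_norms.items():
        if name not in t1.columns or name not in t2.columns:
            continue
        pair = pd.concat([t1[name], t2[name]], axis=1, keys=["x1", "x2"]).dropna()
        rci = ((pair["x2"] - pair["x1"]) - cn.hc_mean_change) / cn.se_diff
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": pair.index,
                    "level": level,
                    "name": name,
                    "x1": pair["x1"].to_numpy(),
                    "x2": pair["x2"].to_numpy(),
                    "hc_mean_change": cn.hc_mean_change,
                    "se_diff": cn.se_diff,
                    "rci": rci.to_numpy(),
                    "reliable": np.abs(rci.to_numpy()) >= threshold,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["subject_id", "level", "name", "x1", "x2",
                     "hc_mean_change", "se_diff", "rci", "reliable"]
        )
    return pd.concat(rows, ignore_index=True)


_CATEGORY_RANK = {"preserved": 0, "isolated": 1, "multidomain": 2}


def _rank(phenotype: str) -> int:
    return _CATEGORY_RANK["isolated" if phenotype.startswith("isolated") else phenotype]


def classify_trajectories(
    baseline: pd.DataFrame,
    followup: pd.DataFrame,
    rci: pd.DataFrame | None = None,
    rci_gated: bool = False,
    rci_threshold: float = RCI_THRESHOLD,
    multidomain_declines: bool = False,
) -> pd.DataFrame:
    """Label each followed-up subject declining / stable / improving.

    ``baseline`` and ``followup`` carry ``subject_id`` and ``phenotype``
    (six-level) and, when available, ``n_impaired``; counts are used when
    present, otherwise the category rank (preserved 0, isolated 1,
    multi-domain 2) stands in.  Subjects lacking follow-up are excluded
    and counted in ``result.attrs['n_no_followup']``; a follow-up subject
    absent at baseline raises.

    With ``rci_gated=True`` a decline/improve label additionally requires
    a reliable domain-level RCI in the matching direction (``rci`` must
    then hold domain-level results with oriented Z inputs, so negative
    RCI means worsening).  ``multidomain_declines=True`` reproduces the
    printed cross-tabulation accounting in which every multi-domain ->
    multi-domain subject is counted as declining.
    """
    bl = baseline.set_index("subject_id")
    fu = followup.set_index("subject_id")
    orphan = fu.index.difference(bl.index)
    if len(orphan):
        raise TrajectoryError(
            f"subject(s) present at follow-up but not baseline: {sorted(orphan)[:5]}"
        )
    matched = bl.index.intersection(fu.index)
    n_lost = len(bl.index) - len(matched)

    use_counts = "n_impaired" in bl.columns and "n_impaired" in fu.columns
    gate_neg: set = set()
    gate_pos: set = set()
    if rci_gated:
        if rci is None or rci.empty:
            raise TrajectoryError("rci_gated=True requires domain-level RCI results")
        rel = rci[rci["reliable"]]
        gate_neg = set(rel.loc[rel["rci"] <= -rci_threshold, "subject_id"])
        gate_pos = set(rel.loc[rel["rci"] >= rci_threshold, "subject_id"])

    records = []
    n_md_shrink = 0
    for sid in matched:
        p_bl, p_fu = bl.loc[sid, "phenotype"], fu.loc[sid, "phenotype"]
        if use_counts:
            c_bl, c_fu = int(bl.loc[sid, "n_impaired"]), int(fu.loc[sid, "n_impaired"])
        else:
            c_bl, c_fu = _rank(p_bl), _rank(p_fu)
        r_bl, r_fu = _rank(p_bl), _rank(p_fu)
        if c_fu > c_bl:
            change = "declining"
        elif (r_bl, r_fu) in ((2, 1), (1, 0)):
            change = "improving"
        else:
            change = "stable"
            if r_bl == r_fu == 2 and c_fu < c_bl:
                n_md_shrink += 1
        if multidomain_declines and r_bl == r_fu == 2 and change == "stable":
            change = "declining"
        if rci_gated:
            if change == "declining" and sid not in gate_neg:
                change = "stable"
            elif change == "improving" and sid not in gate_pos:
                change = "stable"
        records.append(
            {
                "subject_id": sid,
                "baseline_phenotype": p_bl,
                "followup_phenotype": p_fu,
                "n_impaired_bl": c_bl,
                "n_impaired_fu": c_fu,
                "change": change,
            }
        )
    if n_md_shrink and not multidomain_declines:
        logger.info(
            "%d multi-domain subject(s) impaired in fewer (but >= 2) domains at "
            "follow-up labelled stable under the count rule",
            n_md_shrink,
        )
    out = pd.DataFrame(records)
    out.attrs["n_no_followup"] = n_lost
    return out


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class TransitionTable:
    """Baseline x follow-up phenotype cross-tabulation with decline accounting."""

    counts: pd.DataFrame
    row_totals: pd.Series
    decline_counts: pd.Series
    stable_counts: pd.Series
    improve_counts: pd.Series
    decline_pct: pd.Series = field(default=None)  # exact percentages
    decline_pct_display: pd.Series = field(default=None)  # half-up integers

    @property
    def n_followed(self) -> int:
        return int(self.row_totals.sum())

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["total"] = self.row_totals
        out["declining"] = self.decline_counts
        out["stable"] = self.stable_counts
        out["improving"] = self.improve_counts
        out["decline_pct"] = self.decline_pct
        out["decline_pct_display"] = self.decline_pct_display
        return out

    def to_dict(self) -> dict:
        return {
            "categories": list(self.counts.index),
            "counts": {b: self.counts.loc[b].to_dict() for b in self.counts.index},
            "row_totals": self.row_totals.to_dict(),
            "decline_counts": self.decline_counts.to_dict(),
            "stable_counts": self.stable_counts.to_dict(),
            "improve_counts": self.improve_counts.to_dict(),
            "decline_pct": self.decline_pct.to_dict(),
            "decline_pct_display": self.decline_pct_display.to_dict(),
            "n_followed": self.n_followed,
        }


def build_transition_table(trajectories: pd.DataFrame) -> TransitionTable:
    """Six-by-six transition counts plus per-row decline totals."""
    if len(trajectories) == 0:
        raise ValueError("build_transition_table: empty trajectory collection")
    cats = list(PHENOTYPES)
    counts = (
        trajectories.groupby(["baseline_phenotype", "followup_phenotype"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(index=cats, columns=cats, fill_value=0)
    )
    counts.index.name = "baseline"
    counts.columns.name = "followup"
    row_totals = counts.sum(axis=1)
    by_change = (
        trajectories.groupby(["baseline_phenotype", "change"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(index=cats, fill_value=0)
    )
    decline = by_change.get("declining", pd.Series(0, index=cats)).reindex(cats, fill_value=0)
    stable = by_change.get("stable", pd.Series(0, index=cats)).reindex(cats, fill_value=0)
    improve = by_change.get("improving", pd.Series(0, index=cats)).reindex(cats, fill_value=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * decline / row_totals.replace(0, np.nan)
    display = pct.map(lambda x: _round_half_up(x) if pd.notna(x) else 0)
    return TransitionTable(
        counts=counts,
        row_totals=row_totals,
        decline_counts=decline,
        stable_counts=stable,
        improve_counts=improve,
        decline_pct=pct.fillna(0.0),
        decline_pct_display=display,
    )
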