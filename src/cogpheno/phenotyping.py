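"""Domain composition and cognitive phenotype classification.

Each domain score is the unweighted mean of its constituent oriented
sub-score Z-scores (processing speed is the SDMT Z alone).  A domain with
Z strictly below -1.5 is impaired; exactly -1.5 counts as preserved.
Subjects are then assigned one of three phenotypes: *preserved* (no
impaired domain), *isolated* (exactly one), *multi-domain* (two or more).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registry import IMPAIRMENT_THRESHOLD, load_registry

logger = logging.getLogger(__name__)

PHENOTYPES = (
    "isolated_ips",
    "isolated_memory",
    "isolated_efwm",
    "isolated_attention",
    "multidomain",
    "preserved",
)


class ClassificationError(RuntimeError):
    """A subject cannot be classified (missing domain score)."""


@dataclass(frozen=True)
class PhenotypeLabel:
    category: str  # preserved | isolated | multidomain
    isolated_domain: str | None = None
    efwm_subprofile: tuple[str, ...] = ()

    @property
    def phenotype(self) -> str:
        """Six-level label used in transition tables."""
        if self.category == "isolated":
            return f"isolated_{self.isolated_domain}"
        return self.category


def compose_domains(
    z: pd.DataFrame,
    threshold: float = IMPAIRMENT_THRESHOLD,
    min_present_frac: float = 0.5,
) -> pd.DataFrame:
    """Average sub-score Z-scores into the four domain scores.

    ``z`` is the long Z table (subject_id, timepoint, subscore, z).  A
    domain is averaged over its present constituents when at least
    ``min_present_frac`` of them are present, otherwise it is missing and
    the subject-timepoint is flagged unclassifiable.  Returns one row per
    subject-timepoint with domain scores, impairment flags, the impaired
    count and the EF/WM facet flags (inhibition, flexibility, fluency,
    working memory).
    """
    reg = load_registry()
    wide = z.pivot(index=["subject_id", "timepoint"], columns="subscore", values="z")
    out = pd.DataFrame(index=wide.index)
    for dom in reg.domains:
        members = reg.domain_members(dom)
        cols = [m for m in members if m in wide.columns]
        if cols:
            block = wide[cols]
            frac = block.notna().mean(axis=1) * len(cols) / len(members)
            out[dom] = block.mean(axis=1).where(frac >= min_present_frac)
        else:
            out[dom] = np.nan
    for dom in reg.domains:
        out[f"imp_{dom}"] = out[dom] < threshold
    flags = out[[f"imp_{d}" for d in reg.domains]]
    out["n_impaired"] = flags.sum(axis=1).astype(int)
    out["unclassifiable"] = out[list(reg.domains)].isna().any(axis=1)
    for facet, sub in reg.efwm_facets.items():
        if sub in wide.columns:
            out[f"facet_{facet}"] = wide[sub] < threshold
        else:
            out[f"facet_{facet}"] = False
    return out.reset_index()


def classify(profile: pd.Series | dict) -> PhenotypeLabel:
    """Classify one domain profile row into a phenotype label."""
    reg = load_registry()
    p = dict(profile)
    missing = [d for d in reg.domains if pd.isna(p.get(d))]
    if missing:
        raise ClassificationError(
            f"subject {p.get('subject_id', '?')}: missing domain score(s) {missing}"
        )
    impaired = [d for d in reg.domains if p[d] < IMPAIRMENT_THRESHOLD]
    subprofile = tuple(
        facet for facet in reg.efwm_facets if p.get(f"facet_{facet}", False)
    )
    if len(impaired) == 0:
        return PhenotypeLabel("preserved", efwm_subprofile=subprofile)
    if len(impaired) == 1:
        return PhenotypeLabel("isolated", impaired[0], subprofile)
    return PhenotypeLabel("multidomain", efwm_subprofile=subprofile)


def classify_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Vectorised classification; unclassifiable rows are dropped with a warning."""
    reg = load_registry()
    df = profiles.copy()
    bad = df["unclassifiable"]
    if bad.any():
        logger.warning("dropping %d unclassifiable subject-timepoint(s)", int(bad.sum()))
        df = df[~bad]
    n_imp = df["n_impaired"]
    df["category"] = np.select(
        [n_imp == 0, n_imp == 1], ["preserved", "isolated"], default="multidomain"
    )
    iso = pd.Series(pd.NA, index=df.index, dtype="object")
    only_one = n_imp == 1
    for dom in reg.domains:
        iso[only_one & df[f"imp_{dom}"]] = dom
    df["isolated_domain"] = iso
    df["phenotype"] = np.where(
        df["category"] == "isolated",
        "isolated_" + df["isolated_domain"].astype(str),
        df["category"],
    )
    return df


def phenotype_frequencies(labels: pd.DataFrame) -> dict:
    """Counts and percentages of the phenotype distribution.

    Expects the output of :func:`classify_profiles` (one timepoint).
    Reports category counts, the isolated share of the impaired, per-domain
    isolated counts, per-domain involvement among multi-domain subjects,
    and the distribution of the number of impaired domains.
    """
    if len(labels) == 0:
        raise ValueError("phenotype_frequencies: empty label collection")
    reg = load_registry()
    n = len(labels)
    cat = labels["category"].value_counts()
    n_preserved = int(cat.get("preserved", 0))
    n_isolated = int(cat.get("isolated", 0))
    n_multi = int(cat.get("multidomain", 0))
    n_impaired = n_isolated + n_multi

    iso = labels[labels["category"] == "isolated"]
    iso_by_domain = {
        d: int((iso["isolated_domain"] == d).sum()) for d in reg.domains
    }
    multi = labels[labels["category"] == "multidomain"]
    multi_involvement = {
        d: int(multi[f"imp_{d}"].sum()) for d in reg.domains
    }
    n_imp_dist = {
        int(k): int(v) for k, v in labels["n_impaired"].value_counts().items()
    }

    def pct(a, b):
        return 100.0 * a / b if b else float("nan")

    return {
        "n_total": n,
        "counts": {"preserved": n_preserved, "isolated": n_isolated, "multidomain": n_multi},
        "percent_of_total": {
            "preserved": pct(n_preserved, n),
            "isolated": pct(n_isolated, n),
            "multidomain": pct(n_multi, n),
            "impaired": pct(n_impaired, n),
        },
        "n_impaired_any": n_impaired,
        "isolated_share_of_impaired_pct": pct(n_isolated, n_impaired),
        "multidomain_share_of_impaired_pct": pct(n_multi, n_impaired),
        "isolated_by_domain": iso_by_domain,
        "isolated_by_domain_pct": {d: pct(v, n_isolated) for d, v in iso_by_domain.items()},
        "multidomain_involvement": multi_involvement,
        "multidomain_involvement_pct": {
            d: pct(v, n_multi) for d, v in multi_involvement.items()
        },
        "n_impaired_distribution": dict(sorted(n_imp_dist.items())),
    }
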