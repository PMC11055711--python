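"""Sub-score registry: test names, scoring directions and domain membership.

The four cognitive domains are fixed a priori by test construct:

* ``ips`` — information processing speed (SDMT alone),
* ``memory`` — verbal (SRT) and visuospatial (SPART) memory,
* ``efwm`` — executive functioning / working memory (Stroop interference,
  CST shifting, WLG total, MCT slope),
* ``attention`` — Stroop cards 1–2, CST number and letter conditions.

The registry ships as a versioned YAML data file so the battery can be
edited without code changes; this module is the typed loader.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import yaml

HIGHER_IS_BETTER = "higher_is_better"
LOWER_IS_BETTER = "lower_is_better"


@dataclass(frozen=True)
class SubscoreDef:
    name: str
    domain: str | None
    direction: str
    efwm_facet: str | None = None

    @property
    def sign(self) -> int:
        """+1 if a larger raw score is better, -1 for timed scores."""
        return 1 if self.direction == HIGHER_IS_BETTER else -1


@dataclass(frozen=True)
class Registry:
    version: int
    domains: tuple[str, ...]
    subscores: dict[str, SubscoreDef]
    raw_inputs: tuple[str, ...]
    derived: dict[str, dict]

    @property
    def scored(self) -> list[str]:
        """Sub-scores that receive a normative Z (registry order)."""
        return list(self.subscores)

    def domain_members(self, domain: str) -> list[str]:
        return [s.name for s in self.subscores.values() if s.domain == domain]

    @property
    def efwm_facets(self) -> dict[str, str]:
        """facet name -> sub-score, e.g. inhibition -> stroop_interference."""
        return {
            s.efwm_facet: s.name
            for s in self.subscores.values()
            if s.efwm_facet is not None
        }

    @property
    def all_raw_names(self) -> list[str]:
        """Every name a raw-score table may carry (non-derived + trial inputs)."""
        non_derived = [n for n in self.subscores if n not in self.derived]
        return non_derived + list(self.raw_inputs)


@lru_cache(maxsize=1)
def load_registry() -> Registry:
    text = resources.files("cogpheno.data").joinpath("subscores.yaml").read_text()
    spec = yaml.safe_load(text)
    subs = {
        name: SubscoreDef(
            name=name,
            domain=entry.get("domain"),
            direction=entry["direction"],
            efwm_facet=entry.get("efwm_facet"),
        )
        for name, entry in spec["subscores"].items()
    }
    return Registry(
        version=spec["version"],
        domains=tuple(spec["domains"]),
        subscores=subs,
        raw_inputs=tuple(spec["raw_inputs"]),
        derived=spec["derived"],
    )


DOMAINS = ("ips", "memory", "efwm", "attention")

#: Impairment boundary on oriented domain Z: strictly below means impaired,
#: exactly -1.5 is preserved.
IMPAIRMENT_THRESHOLD = -1.5

#: Reliable-change boundary on |RCI| (inclusive).
RCI_THRESHOLD = 1.64
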