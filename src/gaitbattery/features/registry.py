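"""Single source of truth for the 210-characteristic gait battery.

The registry enumerates every feature with its domain, unit, and a short
definition; the feature matrix columns, VIP tables and documentation are
all generated from it.  Domain sizes: spatiotemporal 25, frequency 56,
regularity 20, magnitude 84, complexity 25.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import complexity, frequency, magnitude, regularity, spatiotemporal

DOMAIN_SIZES = {
    "spatiotemporal": 25,
    "frequency": 56,
    "regularity": 20,
    "magnitude": 84,
    "complexity": 25,
}
DOMAINS = tuple(DOMAIN_SIZES)
N_GAIT_FEATURES = sum(DOMAIN_SIZES.values())  # 210
N_DEMOGRAPHICS = 6
N_DESIGN_COLUMNS = N_GAIT_FEATURES + N_DEMOGRAPHICS  # 216


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    domain: str
    unit: str
    definition: str


def _unit_for(name: str) -> str:
    if name.startswith("st_"):
        if "cv" in name:
            return "%"
        if "cadence" in name:
            return "steps/min"
        if "velocity" in name:
            return "m/s"
        if "length" in name:
            return "m"
        return "s"
    if name.startswith("fr_"):
        if "freq" in name or "width" in name:
            return "Hz"
        if "hr" in name or "ih" in name:
            return "unitless"
        return "power"
    if name.startswith("rg_"):
        return "unitless"
    if name.startswith("mg_"):
        return "unitless" if "ratio" in name else (
            "m/s^3" if "jerk" in name else "m/s^2")
    if name.startswith("cx_lle"):
        return "1/s"
    return "unitless"


def _definition_for(name: str, domain: str) -> str:
    return f"{domain} characteristic {name.split('_', 1)[1]}"


def build_registry() -> list[FeatureSpec]:
    specs: list[FeatureSpec] = []
    sources = (
        ("spatiotemporal", spatiotemporal.FEATURE_NAMES),
        ("frequency", frequency.FEATURE_NAMES),
        ("regularity", regularity.FEATURE_NAMES),
        ("magnitude", magnitude.FEATURE_NAMES),
        ("complexity", complexity.FEATURE_NAMES),
    )
    for domain, names in sources:
        if len(names) != DOMAIN_SIZES[domain]:
            raise AssertionError(
                f"{domain} enumerates {len(names)} features, "
                f"expected {DOMAIN_SIZES[domain]}")
        if len(set(names)) != len(names):
            raise AssertionError(f"duplicate names in {domain}")
        for name in names:
            specs.append(FeatureSpec(name, domain, _unit_for(name),
                                     _definition_for(name, domain)))
    assert len(specs) == N_GAIT_FEATURES
    return specs


REGISTRY = build_registry()
FEATURE_NAMES = tuple(s.name for s in REGISTRY)
DOMAIN_OF = {s.name: s.domain for s in REGISTRY}


def registry_frame() -> pd.DataFrame:
    return pd.DataFrame([{
        "feature": s.name, "domain": s.domain, "unit": s.unit,
        "definition": s.definition,
    } for s in REGISTRY])


def features_in_domains(domains) -> list[str]:
    wanted = set(domains)
    unknown = wanted - set(DOMAINS)
    if unknown:
        raise KeyError(f"unknown feature domains: {sorted(unknown)}")
    return [s.name for s in REGISTRY if s.domain in wanted]
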