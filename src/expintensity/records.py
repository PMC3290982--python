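"""Applicator and monitoring records.

An :class:`ApplicatorRecord` is one application scenario as reported on an
enrollment-style questionnaire: how often the applicator mixed or loaded the
pesticide, which application method(s) were used, whether application
equipment was repaired, and which pieces of personal protective equipment
(PPE) were worn.  A :class:`MonitoringRecord` adds the post-application
urinary biomarker concentration measured for that application day.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace  # noqa: F401  (replace re-exported)
from typing import Iterable, Optional, Sequence

MIX_LEVELS = ("did_not_mix", "mix_lt50", "mix_ge50")

PPE_ITEMS = frozenset(
    {
        "cr_gloves",
        "fabric_gloves",
        "cartridge_respirator",
        "tyvek_coveralls",
        "face_shield",
        "goggles",
        "boots",
        "apron",
        "other",
    }
)

#: Items other than gloves; eligible for the per-item / category reductions.
NON_GLOVE_PPE = frozenset(PPE_ITEMS - {"cr_gloves", "fabric_gloves"})

# Accepts the verbatim table spellings plus common field shorthands for
# application methods; keys are matched after lower-casing and collapsing
# whitespace/punctuation to underscores.
METHOD_ALIASES = {
    "air_blast": "air_blast",
    "airblast": "air_blast",
    "hand_spray": "hand_spray",
    "mist_blower_or_fogger": "mist_blower_or_fogger",
    "fog_or_mist_animals": "fog_or_mist_animals",
    "greenhouse_sprayer": "greenhouse_sprayer",
    "pour_fumigant_from_bucket": "pour_fumigant_from_bucket",
    "powder_duster": "powder_duster",
    "backpack_sprayer": "backpack_sprayer",
    "dust_animals": "dust_animals",
    "pour_on_animals": "pour_on_animals",
    "garden_hose": "garden_hose",
    "hand_held_squeeze_or_squirt_bottle": "hand_held_squeeze_or_squirt_bottle",
    "squeeze_bottle": "hand_held_squeeze_or_squirt_bottle",
    "watering_can": "watering_can",
    "watering_can_sprinkling_can": "watering_can",
    "sprinkling_can": "watering_can",
    "soil_injected_or_drilled": "soil_injected_or_drilled",
    "spray_over_rows": "spray_over_rows",
    "boom_on_tractor": "boom_on_tractor",
    "boom_spray": "boom_on_tractor",
    "broadcast_application": "broadcast_application",
    "personally_applied_to_seed": "personally_applied_to_seed",
    "banded_directed_spray_liquid": "banded_directed_spray_liquid",
    "banded_directed_spray": "banded_directed_spray_liquid",
    "banded_application_granular": "banded_application_granular",
    "banded_application": "banded_application_granular",
    "gas_canister": "gas_canister",
    "hang_pest_strips_in_barn": "hang_pest_strips_in_barn",
    "in_furrow": "in_furrow",
    "infurrow": "in_furrow",
    "incorporated": "incorporated",
    "inject_animals": "inject_animals",
    "seed_treatment": "seed_treatment",
    "hand_spreader_or_push_spreader": "hand_spreader_or_push_spreader",
    "push_spreader": "hand_spreader_or_push_spreader",
    "planter_box": "planter_box",
    "aerial": "aerial",
}


def canonical_method(label: str) -> str:
    """Map an application-method spelling to its canonical snake-case label."""
    key = "".join(c if c.isalnum() else "_" for c in label.strip().lower())
    key = "_".join(filter(None, key.split("_")))
    try:
        return METHOD_ALIASES[key]
    except KeyError:
        raise ValueError(
            f"unknown application method {label!r}; "
            f"known labels include {sorted(set(METHOD_ALIASES.values()))}"
        ) from None


@dataclass(frozen=True)
class ApplicatorRecord:
    """One applicator-scenario from the questionnaire."""

    id: str
    mix_level: str
    methods: tuple[str, ...]
    repair: bool = False
    ppe_items: frozenset[str] = field(default_factory=frozenset)
    lifetime_days: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mix_level not in MIX_LEVELS:
            raise ValueError(
                f"record {self.id!r}: mix_level {self.mix_level!r} "
                f"not one of {MIX_LEVELS}"
            )
        methods = tuple(canonical_method(m) for m in self.methods)
        if not methods:
            raise ValueError(f"record {self.id!r}: at least one method required")
        object.__setattr__(self, "methods", methods)
        ppe = frozenset(self.ppe_items)
        unknown = ppe - PPE_ITEMS
        if unknown:
            raise ValueError(
                f"record {self.id!r}: unrecognized PPE {sorted(unknown)}; "
                f"valid labels are {sorted(PPE_ITEMS)}"
            )
        object.__setattr__(self, "ppe_items", ppe)
        if self.lifetime_days is not None and not self.lifetime_days >= 0:
            raise ValueError(
                f"record {self.id!r}: lifetime_days must be nonnegative"
            )

    @property
    def mixes(self) -> bool:
        return self.mix_level != "did_not_mix"

    @property
    def wears_cr_gloves(self) -> bool:
        return "cr_gloves" in self.ppe_items

    @property
    def wears_other_ppe(self) -> bool:
        """Any PPE item other than gloves (the Eq.-style binary indicator)."""
        return bool(self.ppe_items & NON_GLOVE_PPE)


@dataclass(frozen=True)
class MonitoringRecord(ApplicatorRecord):
    """Applicator scenario plus a post-application urinary biomarker level."""

    concentration: float = float("nan")  # µg/L
    analyte: str = ""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not self.concentration > 0:
            raise ValueError(
                f"record {self.id!r}: concentration must be positive "
                f"(got {self.concentration})"
            )


def primary_method(record: ApplicatorRecord) -> str:
    """First reported method; scoring uses the max-weight method instead."""
    return record.methods[0]


def as_records(items: Iterable[ApplicatorRecord]) -> list[ApplicatorRecord]:
    out = list(items)
    if not all(isinstance(r, ApplicatorRecord) for r in out):
        raise TypeError("expected ApplicatorRecord instances")
    return out
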