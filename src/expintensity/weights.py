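"""Exposure-intensity weight tables and scoring.

The AHS algorithm converts questionnaire responses into a relative
exposure-intensity score::

    score = (MIX + APPLY + REPAIR) * PPE

where MIX, APPLY and REPAIR are tabulated weights for mixing/loading
frequency, application method and equipment repair, and PPE is a
multiplicative reduction factor (1 minus the summed protective-equipment
reductions, never removing more than 90% of the exposure).  Two frozen
weight tables ship with the package: version 1 (the original,
expert-judgment weights, scores 0.1-20) and version 2 (the field-study
revision, integer scores 1-220).  Custom tables load from YAML.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import yaml

from .records import (
    MIX_LEVELS,
    NON_GLOVE_PPE,
    PPE_ITEMS,
    ApplicatorRecord,
    canonical_method,
)

__all__ = [
    "UNASSIGNED",
    "PpeRules",
    "WeightTable",
    "load_weight_table",
    "lookup_weight",
    "ppe_multiplier",
    "intensity_score",
    "method_scores",
    "score_range",
    "intensity_weighted_days",
    "categorize_score",
    "category_labels",
    "IntensityScorer",
]


class _Unassigned:
    """Marker for methods with no weight under a table version."""

    def __repr__(self) -> str:  # pragma: no cover
        return "UNASSIGNED"


UNASSIGNED = _Unassigned()


class UnassignedWeightError(LookupError):
    """Raised when scoring a method that has no weight in the active table."""


@dataclass(frozen=True)
class PpeRules:
    """PPE reduction specification.

    ``other_item_rule`` is either ``"per_item"`` (each distinct non-glove
    item contributes ``per_item_reduction``, capped at ``per_item_cap``;
    the version-2 rule) or ``"categories"`` (each category contributes a
    fixed reduction if at least one of its items is worn; the version-1
    rule).  The total reduction from gloves plus other items is capped at
    ``total_cap``, so the multiplier never drops below ``1 - total_cap``.
    """

    glove_cr_reduction: float
    fabric_glove_reduction: float
    other_item_rule: str
    total_cap: float = 0.90
    per_item_reduction: float = 0.0
    per_item_cap: float = 0.0
    categories: tuple[tuple[frozenset[str], float], ...] = ()

    def __post_init__(self) -> None:
        if self.other_item_rule not in ("per_item", "categories"):
            raise ValueError(f"unknown other_item_rule {self.other_item_rule!r}")
        for frac in (
            self.glove_cr_reduction,
            self.fabric_glove_reduction,
            self.total_cap,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("PPE reduction fractions must lie in [0, 1]")

    def multiplier(self, ppe_items: Iterable[str]) -> float:
        items = frozenset(ppe_items)
        unknown = items - PPE_ITEMS
        if unknown:
            raise ValueError(
                f"unrecognized PPE {sorted(unknown)}; "
                f"valid labels are {sorted(PPE_ITEMS)}"
            )
        if not items:
            return 1.0
        # CR gloves dominate: fabric/leather gloves are ignored when both
        # glove types are reported.
        if "cr_gloves" in items:
            glove = self.glove_cr_reduction
        elif "fabric_gloves" in items:
            glove = self.fabric_glove_reduction
        else:
            glove = 0.0
        other_items = items & NON_GLOVE_PPE
        if self.other_item_rule == "per_item":
            other = min(
                self.per_item_reduction * len(other_items), self.per_item_cap
            )
        else:
            other = sum(
                red for members, red in self.categories if items & members
            )
        # round away binary dust from summed decimal fractions so that
        # e.g. 0.6 + 0.3 caps cleanly and multipliers are exact decimals
        return round(1.0 - min(glove + other, self.total_cap), 12)

    def achievable_multipliers(self) -> set[float]:
        """All multipliers reachable over the power set of PPE items."""
        out = set()
        for r in range(len(PPE_ITEMS) + 1):
            for combo in itertools.combinations(sorted(PPE_ITEMS), r):
                out.add(self.multiplier(combo))
        return out


@dataclass(frozen=True)
class WeightTable:
    """Versioned lookup of MIX/APPLY/REPAIR weights plus PPE rules."""

    version: str
    mix_weights: Mapping[str, float]
    apply_weights: Mapping[str, Union[float, _Unassigned]]
    repair_weights: Mapping[bool, float]
    ppe_rules: PpeRules

    def __post_init__(self) -> None:
        if set(self.mix_weights) != set(MIX_LEVELS):
            raise ValueError(
                f"mix_weights must cover exactly {MIX_LEVELS}, "
                f"got {sorted(self.mix_weights)}"
            )
        if set(self.repair_weights) != {False, True}:
            raise ValueError("repair_weights must cover {no, yes}")
        for name, w in self.apply_weights.items():
            if w is not UNASSIGNED and not w >= 0:
                raise ValueError(f"apply weight for {name!r} must be >= 0")
        for m in (self.mix_weights, self.repair_weights):
            if any(not w >= 0 for w in m.values()):
                raise ValueError("weights must be nonnegative")

    @property
    def assigned_methods(self) -> list[str]:
        return [m for m, w in self.apply_weights.items() if w is not UNASSIGNED]


def _build_ppe_rules(cfg: Mapping) -> PpeRules:
    cats = tuple(
        (frozenset(c["items"]), float(c["reduction"]))
        for c in cfg.get("categories", [])
    )
    return PpeRules(
        glove_cr_reduction=float(cfg["glove_cr_reduction"]),
        fabric_glove_reduction=float(cfg["fabric_glove_reduction"]),
        other_item_rule=str(cfg["other_item_rule"]),
        total_cap=float(cfg.get("total_cap", 0.90)),
        per_item_reduction=float(cfg.get("per_item_reduction", 0.0)),
        per_item_cap=float(cfg.get("per_item_cap", 0.0)),
        categories=cats,
    )


def _table_from_config(cfg: Mapping) -> WeightTable:
    apply_weights = {}
    for label, w in cfg["apply_weights"].items():
        name = canonical_method(label)
        apply_weights[name] = (
            UNASSIGNED
            if isinstance(w, str) and w.lower() == "unassigned"
            else float(w)
        )
    repair = cfg["repair_weights"]
    # YAML may deliver the keys as the strings "no"/"yes" or as booleans.
    repair_weights = {}
    for key, w in repair.items():
        flag = key if isinstance(key, bool) else str(key).lower() in ("yes", "true", "1")
        repair_weights[flag] = float(w)
    return WeightTable(
        version=str(cfg.get("version", "custom")),
        mix_weights={k: float(v) for k, v in cfg["mix_weights"].items()},
        apply_weights=apply_weights,
        repair_weights=repair_weights,
        ppe_rules=_build_ppe_rules(cfg["ppe_rules"]),
    )


def _validate_shipped(table: WeightTable) -> None:
    """Sanity checks on the two frozen tables at load time."""
    aw = [w for w in table.apply_weights.values() if w is not UNASSIGNED]
    if table.version == "v2":
        assert sorted(table.mix_weights.values()) == [0, 20, 50]
        assert sorted(table.repair_weights.values()) == [0, 20]
        assert all(float(w).is_integer() and 10 <= w <= 150 for w in aw)
        assert len(table.apply_weights) == 29
    elif table.version == "v1":
        assert sorted(table.mix_weights.values()) == [0, 3, 9]
        assert sorted(table.repair_weights.values()) == [0, 2]
        assert all(1 <= w <= 9 for w in aw)
        unassigned = {
            m for m, w in table.apply_weights.items() if w is UNASSIGNED
        }
        assert unassigned == {
            "garden_hose",
            "hand_held_squeeze_or_squirt_bottle",
            "watering_can",
            "hand_spreader_or_push_spreader",
            "planter_box",
        }


_TABLE_CACHE: dict[str, WeightTable] = {}


def load_weight_table(source: Union[str, Path, Mapping] = "v2") -> WeightTable:
    """Load a weight table.

    ``source`` may be ``"v1"`` or ``"v2"`` (the shipped tables), a path to
    a YAML config, or an already-parsed mapping.
    """
    if isinstance(source, Mapping):
        return _table_from_config(source)
    key = str(source)
    if key in ("v1", "v2"):
        if key not in _TABLE_CACHE:
            text = (
                resources.files("expintensity.data")
                .joinpath(f"weights_{key}.yaml")
                .read_text()
            )
            table = _table_from_config(yaml.safe_load(text))
            _validate_shipped(table)
            _TABLE_CACHE[key] = table
        return _TABLE_CACHE[key]
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(
            f"weight table {source!r} is neither 'v1', 'v2' nor an existing file"
        )
    return _table_from_config(yaml.safe_load(path.read_text()))


def lookup_weight(table: WeightTable, variable: str, response: str) -> float:
    """Tabulated weight for one response of one algorithm variable."""
    if variable == "mix":
        mapping: Mapping = table.mix_weights
    elif variable == "apply":
        mapping = table.apply_weights
        response = canonical_method(response)
    elif variable == "repair":
        if isinstance(response, str):
            response = response.lower() in ("yes", "true", "1")
        mapping = table.repair_weights
    else:
        raise ValueError(
            f"variable must be one of mix/apply/repair, got {variable!r}"
        )
    try:
        w = mapping[response]
    except KeyError:
        raise KeyError(
            f"unknown {variable} response {response!r}; "
            f"valid responses: {sorted(map(str, mapping))}"
        ) from None
    if w is UNASSIGNED:
        raise UnassignedWeightError(
            f"method {response!r} is unassigned under version {table.version}"
        )
    return w


def ppe_multiplier(table: WeightTable, ppe_items: Iterable[str]) -> float:
    """Exposure multiplier (1 minus total PPE reduction, floored at 0.10)."""
    return table.ppe_rules.multiplier(ppe_items)


def method_scores(
    record: ApplicatorRecord, table: WeightTable
) -> dict[str, float]:
    """Per-method intensity scores for a record reporting several methods."""
    base = lookup_weight(table, "mix", record.mix_level) + lookup_weight(
        table, "repair", record.repair
    )
    mult = ppe_multiplier(table, record.ppe_items)
    return {
        m: (base + lookup_weight(table, "apply", m)) * mult
        for m in record.methods
    }


def intensity_score(record: ApplicatorRecord, table: WeightTable) -> float:
    """(MIX + APPLY + REPAIR) x PPE for one record.

    When several application methods are reported, the APPLY weight is the
    maximum over the reported methods, mirroring the assignment of mixed
    boom/hand applications to the higher-exposure hand-spray group.
    """
    return max(method_scores(record, table).values())


def score_range(table: WeightTable) -> tuple[float, float]:
    """(smallest strictly positive score, largest score), by enumeration."""
    multipliers = table.ppe_rules.achievable_multipliers()
    best_min, best_max = float("inf"), 0.0
    for mix_w in table.mix_weights.values():
        for method in table.assigned_methods:
            apply_w = table.apply_weights[method]
            for repair_w in table.repair_weights.values():
                base = mix_w + apply_w + repair_w
                for mult in multipliers:
                    s = base * mult
                    if s > 0:
                        best_min = min(best_min, s)
                    best_max = max(best_max, s)
    return best_min, best_max


def intensity_weighted_days(score: float, days: float) -> float:
    """Lifetime intensity-weighted days: score x days of use."""
    if not score >= 0:
        raise ValueError(f"score must be nonnegative, got {score}")
    if not days >= 0:
        raise ValueError(f"days must be nonnegative, got {days}")
    return score * days


def categorize_score(score: float, cutpoints: Sequence[float]) -> int:
    """Bin index for a score against ordered cutpoints.

    With cutpoints ``(50, 100)``: scores below 50 fall in bin 0, scores in
    the closed interval [50, 100] in bin 1, and scores above 100 in bin 2.
    The bottom bin is open, the top bin is open, and the middle bins are
    closed, matching the printed "<50 / 50-100 / >100" category labels.
    """
    cuts = list(cutpoints)
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise ValueError("cutpoints must be strictly increasing")
    if score < cuts[0]:
        return 0
    for i in range(1, len(cuts)):
        if score <= cuts[i]:
            return i
    return len(cuts)


def category_labels(cutpoints: Sequence[float]) -> list[str]:
    """Printable labels for the bins of :func:`categorize_score`."""
    cuts = [f"{c:g}" for c in cutpoints]
    if len(cuts) == 1:
        return [f"<{cuts[0]}", f">={cuts[0]}"]
    labels = [f"<{cuts[0]}"]
    labels += [f"{a}-{b}" for a, b in zip(cuts, cuts[1:])]
    labels.append(f">{cuts[-1]}")
    return labels


class IntensityScorer:
    """Transformer computing exposure-intensity scores for record frames.

    A stateless sklearn-style transformer: ``fit`` resolves and validates
    the weight table, ``transform`` maps records to scores.

    Parameters
    ----------
    version : str or path or mapping, default "v2"
        Weight table to use ("v1", "v2", a YAML path, or a parsed config).
    cutpoints : sequence of float, default (50, 100)
        Category cutpoints used by :meth:`transform_frame`.
    """

    def __init__(self, version="v2", cutpoints=(50.0, 100.0)):
        self.version = version
        self.cutpoints = cutpoints

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"version": self.version, "cutpoints": self.cutpoints}

    def set_params(self, **params) -> "IntensityScorer":
        for k, v in params.items():
            if k not in ("version", "cutpoints"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # ---------------------------------------------------------------------
    def fit(self, X=None, y=None) -> "IntensityScorer":
        self.table_ = load_weight_table(self.version)
        self.cutpoints_ = tuple(float(c) for c in self.cutpoints)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "table_"):
            self.fit()

    def transform(self, X) -> "np.ndarray":  # noqa: F821
        """Scores for a sequence of records (or a record frame).

        Returns an ``(n, 1)`` float array so the transformer composes with
        sklearn pipelines.
        """
        import numpy as np

        self._check_fitted()
        records = _coerce_records(X)
        return np.array(
            [[intensity_score(r, self.table_) for r in records]], dtype=float
        ).T

    def fit_transform(self, X, y=None):
        return self.fit().transform(X)

    def score_record(self, record: ApplicatorRecord) -> float:
        self._check_fitted()
        return intensity_score(record, self.table_)

    def transform_frame(self, X) -> "pd.DataFrame":  # noqa: F821
        """Augment a record frame with score, category and weighted days."""
        import pandas as pd

        self._check_fitted()
        records = _coerce_records(X)
        col = f"score_{self.table_.version}"
        scores = [intensity_score(r, self.table_) for r in records]
        labels = category_labels(self.cutpoints_)
        out = pd.DataFrame(
            {
                "id": [r.id for r in records],
                col: scores,
                "category": [
                    labels[categorize_score(s, self.cutpoints_)] for s in scores
                ],
                "intensity_weighted_days": [
                    intensity_weighted_days(s, r.lifetime_days)
                    if r.lifetime_days is not None
                    else float("nan")
                    for s, r in zip(scores, records)
                ],
            }
        )
        return out


def _coerce_records(X) -> list[ApplicatorRecord]:
    """Accept a list of records or a DataFrame in the applicator format."""
    if hasattr(X, "iterrows"):
        from .io import frame_to_records

        return frame_to_records(X)
    return list(X)
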