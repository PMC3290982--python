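"""Synthetic applicator cohorts and monitoring data.

The generator emulates a small field-monitoring campaign: applicators are
allocated to cells defined by application method and chemically-resistant
(CR) glove use, their remaining questionnaire factors (mixing, equipment
repair, other PPE) are drawn independently, and each application day
receives a post-application urinary biomarker concentration.

The concentration model is multiplicative: the deterministic mean

    mu = (a0 + a1*mix + a2*method + a3*repair) * (1 - b1*gloves - b2*other)

is treated as the *median* of a lognormal, i.e. concentration =
mu * exp(eps) with eps ~ Normal(0, ln(GSD)).  With GSD = 1 the data are
noise-free and equal the model mean exactly, which gives downstream fits
an exact round-trip target.  The default parameters are the published
2,4-D fit (a0=27, a1=58, a2=123, a3=32 µg/L; b1=0.75, b2=0.26) and a GSD
of 3.5, mid-range of the observed per-cell GSDs (3.0-4.9).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .records import NON_GLOVE_PPE, ApplicatorRecord, MonitoringRecord

#: Default cell sizes: the 2,4-D monitoring layout (method x CR-glove use).
DEFAULT_CELLS: dict[tuple[str, bool], int] = {
    ("boom_on_tractor", True): 32,
    ("boom_on_tractor", False): 14,
    ("hand_spray", True): 21,
    ("hand_spray", False): 21,
}


@dataclass(frozen=True)
class TrueParams:
    """Ground-truth coefficients of the multiplicative concentration model.

    Defaults follow the published 2,4-D fit, except that the other-PPE
    reduction is trimmed from 0.26 to 0.24: the published point estimates
    sum with the glove reduction to 1.01, which would imply a negative
    mean concentration for an applicator wearing gloves plus other PPE.
    A valid generating model needs beta1 + beta2 < 1.
    """

    alpha0: float = 27.0
    alpha1: float = 58.0
    alpha2: float = 123.0
    alpha3: float = 32.0
    beta1: float = 0.75
    beta2: float = 0.24

    def __post_init__(self) -> None:
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("beta fractions must lie in [0, 1)")
        if self.beta1 + self.beta2 >= 1:
            raise ValueError("beta1 + beta2 must be < 1")
        for combo in itertools.product((0, 1), repeat=5):
            if self.mean(*combo) <= 0:
                raise ValueError(
                    "mean concentration must be positive for every factor "
                    f"combination; fails at (mix, method, repair, gloves, "
                    f"other) = {combo}"
                )

    def mean(
        self, mix: int, method: int, repair: int, gloves: int, other: int
    ) -> float:
        additive = (
            self.alpha0
            + self.alpha1 * mix
            + self.alpha2 * method
            + self.alpha3 * repair
        )
        return additive * (1.0 - self.beta1 * gloves - self.beta2 * other)


@dataclass
class SimConfig:
    """Knobs of the synthetic monitoring campaign."""

    n_per_cell: Mapping[tuple[str, bool], int] = field(
        default_factory=lambda: dict(DEFAULT_CELLS)
    )
    mix_prob: float = 83 / 88  # all but five applicators mixed/loaded
    repair_prob: float = 26 / 88
    other_ppe_prob: float = 0.5
    true_params: TrueParams = field(default_factory=TrueParams)
    gsd: float = 3.5
    seed: int = 0
    analyte: str = "24d"
    #: Method labels coded 1 in the concentration model (the rest code 0).
    method_coded_one: frozenset = frozenset({"hand_spray"})

    def __post_init__(self) -> None:
        for name in ("mix_prob", "repair_prob", "other_ppe_prob"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if any(n < 0 for n in self.n_per_cell.values()):
            raise ValueError("cell counts must be nonnegative")
        if sum(self.n_per_cell.values()) == 0:
            raise ValueError("at least one cell must be nonempty")
        if not self.gsd >= 1:
            raise ValueError(f"gsd must be >= 1, got {self.gsd}")
        self.method_coded_one = frozenset(self.method_coded_one)


def generate_cohort(config: SimConfig) -> list[ApplicatorRecord]:
    """Draw a cohort of applicator records with the configured cell sizes.

    Deterministic given ``config.seed``: cell counts are exact and the
    within-cell factors (mixing, repair, one randomly chosen non-glove PPE
    item) are Bernoulli draws from a seeded generator.
    """
    rng = np.random.default_rng(config.seed)
    other_items = sorted(NON_GLOVE_PPE)
    records = []
    i = 0
    for (method, gloves), n in sorted(config.n_per_cell.items()):
        for _ in range(n):
            i += 1
            mixes = rng.random() < config.mix_prob
            repair = rng.random() < config.repair_prob
            ppe = set()
            if gloves:
                ppe.add("cr_gloves")
            if rng.random() < config.other_ppe_prob:
                ppe.add(other_items[rng.integers(len(other_items))])
            records.append(
                ApplicatorRecord(
                    id=f"A{i:04d}",
                    mix_level="mix_ge50" if mixes else "did_not_mix",
                    methods=(method,),
                    repair=bool(repair),
                    ppe_items=frozenset(ppe),
                )
            )
    return records


def eq1_covariates(
    record: ApplicatorRecord, method_coded_one=frozenset({"hand_spray"})
) -> tuple[int, int, int, int, int]:
    """(mix, method, repair, gloves, other) 0/1 coding of a record."""
    return (
        int(record.mixes),
        int(bool(set(record.methods) & set(method_coded_one))),
        int(record.repair),
        int(record.wears_cr_gloves),
        int(record.wears_other_ppe),
    )


def generate_monitoring(
    cohort: Sequence[ApplicatorRecord],
    params: Optional[TrueParams] = None,
    gsd: float = 3.5,
    seed: int = 0,
    analyte: str = "24d",
    method_coded_one=frozenset({"hand_spray"}),
) -> list[MonitoringRecord]:
    """Attach lognormal biomarker concentrations to a cohort.

    The model mean is the lognormal median; ``gsd=1`` returns the mean
    exactly (no noise).
    """
    params = params or TrueParams()
    if not gsd >= 1:
        raise ValueError(f"gsd must be >= 1, got {gsd}")
    rng = np.random.default_rng(seed)
    sigma = math.log(gsd)
    out = []
    for r in cohort:
        cov = eq1_covariates(r, method_coded_one)
        mu = params.mean(*cov)
        if mu <= 0:
            raise ValueError(
                f"nonpositive model mean for record {r.id!r} with "
                f"(mix, method, repair, gloves, other) = {cov}"
            )
        conc = mu * math.exp(rng.normal(0.0, sigma)) if sigma > 0 else mu
        out.append(
            MonitoringRecord(
                id=r.id,
                mix_level=r.mix_level,
                methods=r.methods,
                repair=r.repair,
                ppe_items=r.ppe_items,
                lifetime_days=r.lifetime_days,
                concentration=conc,
                analyte=analyte,
            )
        )
    return out


def simulate(config: SimConfig) -> list[MonitoringRecord]:
    """Cohort generation plus monitoring in one deterministic call."""
    cohort = generate_cohort(config)
    return generate_monitoring(
        cohort,
        params=config.true_params,
        gsd=config.gsd,
        seed=config.seed + 1,
        analyte=config.analyte,
        method_coded_one=config.method_coded_one,
    )
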