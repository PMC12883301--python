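"""Construction of the two strategy arms compared by the analysis.

Upfront surgery
    A gland-conserving excision (partial parotidectomy or
    submandibulectomy, by site) with intraoperative frozen section is
    performed without cytologic triage.  If final histology is malignant
    the patient enters a revision-surgery arm: a completion oncologic
    procedure is appended (total parotidectomy + neck dissection for
    parotid lesions; neck dissection for submandibular lesions, whose
    gland is already excised).

FNAC first
    An ultrasound-guided FNAC is reported in one of the seven Milan
    (MSRSGC) categories, each with its own pathway:

    * I, III — one repeat FNAC.  A second I/III result goes straight to
      partial surgery (no third pass); malignancy on histology appends a
      neck dissection.  Any other second result continues down that
      category's pathway.
    * II — clinical/radiological follow-up, no surgery.
    * IVa — surgery (partial excision, revision on malignancy) with
      probability ``iva_surgery_rate``, otherwise follow-up.  This rate is
      the scenario knob of the analysis (1.0 / 0.7 / 0.0).
    * IVb — partial surgery; revision neck dissection on malignancy.
    * V, VI — surgery with intraoperative frozen section: a primary
      oncologic resection if the lesion is malignant (probability = the
      category's risk of malignancy), otherwise partial excision only.

Malignancy missed under conservative management (II, non-operated IVa)
incurs no modeled downstream cost: the model covers a single diagnostic
episode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .params import (
    CostTable,
    Currency,
    MilanCategory,
    ModelParameters,
    Procedure,
)
from .tree import DecisionTree, Node, chance, terminal

__all__ = ["ArmSpec", "build_upfront_arm", "build_fnac_arm", "apply_iva_scenario"]

PAROTID = "parotid"
SUBMANDIBULAR = "submandibular"

_BUILTIN_CURRENCY = {
    "1a": Currency.USD,
    "1b": Currency.EUR,
    "1c": Currency.EUR,
}

_REPEAT_CATEGORIES = (MilanCategory.I, MilanCategory.III)


@dataclass(frozen=True)
class ArmSpec:
    """Inputs for building one strategy arm.

    ``completion_mode`` controls the malignant pathway of the upfront arm:
    ``"append"`` bills the completion oncologic procedure as a second full
    procedure on top of the already-performed partial excision (default);
    ``"replace"`` bills only the difference up to the oncologic tariff,
    for sensitivity analysis.
    """

    params: ModelParameters
    costs: CostTable
    completion_mode: str = "append"

    def __post_init__(self) -> None:
        if self.completion_mode not in ("append", "replace"):
            raise ValueError(f"completion_mode must be 'append' or 'replace', got {self.completion_mode!r}")
        # built-in models are tied to a jurisdiction; reject mixed tariffs
        expected = _BUILTIN_CURRENCY.get(self.params.model_id)
        if expected is not None and self.costs.currency is not expected:
            raise ValueError(
                f"currency mismatch: model {self.params.model_id!r} uses "
                f"{expected.value} tariffs, got a {self.costs.currency.value} cost table"
            )


def _partial(costs: CostTable, site: str) -> float:
    return costs[Procedure.partial_parotidectomy if site == PAROTID else Procedure.submandibulectomy]


def _oncologic(costs: CostTable, site: str) -> float:
    return costs[Procedure.total_parotidectomy_nd if site == PAROTID else Procedure.submandibulectomy_nd]


def _completion(spec: ArmSpec, site: str) -> float:
    """Cost of completion oncologic surgery after a partial excision."""
    if spec.completion_mode == "replace":
        return max(_oncologic(spec.costs, site) - _partial(spec.costs, site), 0.0)
    if site == PAROTID:
        # a second full procedure: total parotidectomy + neck dissection
        return _oncologic(spec.costs, site)
    # gland already excised: completion is the neck dissection alone
    return spec.costs[Procedure.neck_dissection]


def _site_chance(label: str, site_mix: float, make: "callable", cost: float = 0.0) -> Node:
    return chance(
        label,
        cost,
        [(site_mix, make(PAROTID)), (1.0 - site_mix, make(SUBMANDIBULAR))],
    )


def build_upfront_arm(spec: ArmSpec) -> DecisionTree:
    """Decision tree of the upfront-surgery strategy."""
    p, c = spec.params, spec.costs
    m = p.upfront_malignancy_rate

    def site_path(site: str) -> Node:
        return chance(
            f"partial_surgery_{site}",
            _partial(c, site) + c[Procedure.frozen_section],
            [
                (
                    m,
                    terminal(
                        "completion_oncologic_surgery",
                        _completion(spec, site),
                        tags=("surgery", "malignant"),
                    ),
                ),
                (1.0 - m, terminal("benign_histology")),
            ],
            tags=("surgery", "frozen_section"),
        )

    root = _site_chance("site", p.site_mix, site_path)
    return DecisionTree(
        root=root,
        currency=c.currency,
        metadata={
            "model_id": p.model_id,
            "arm": "upfront_surgery",
            "iva_surgery_rate": p.iva_surgery_rate,
        },
    )


def _surgery_with_revision(spec: ArmSpec, site: str, rom: float, label: str) -> Node:
    """Partial excision; malignant histology appends a neck dissection."""
    return chance(
        label,
        _partial(spec.costs, site),
        [
            (
                rom,
                terminal(
                    "revision_neck_dissection",
                    spec.costs[Procedure.neck_dissection],
                    tags=("surgery", "malignant"),
                ),
            ),
            (1.0 - rom, terminal("benign_histology")),
        ],
        tags=("surgery",),
    )


def _frozen_section_surgery(spec: ArmSpec, site: str, rom: float) -> Node:
    """Surgery for category V/VI with intraoperative frozen section."""
    c = spec.costs
    return chance(
        "surgery_with_frozen_section",
        c[Procedure.frozen_section],
        [
            (
                rom,
                terminal(
                    "primary_oncologic_resection",
                    _oncologic(c, site),
                    tags=("surgery", "malignant", "frozen_section"),
                ),
            ),
            (
                1.0 - rom,
                terminal(
                    "partial_resection",
                    _partial(c, site),
                    tags=("surgery", "frozen_section"),
                ),
            ),
        ],
    )


def _category_path(
    spec: ArmSpec, cat: MilanCategory, site: str, iva_rate: float, allow_repeat: bool
) -> Node:
    p, c = spec.params, spec.costs
    if cat in _REPEAT_CATEGORIES:
        if not allow_repeat:
            # second I/III result: immediate surgery, no third FNAC
            return _surgery_with_revision(
                spec, site, p.rom[cat], f"immediate_surgery_{cat.value}"
            )
        return chance(
            f"repeat_fnac_after_{cat.value}",
            c[Procedure.repeat_fnac],
            [
                (
                    p.second_fnac_dist[c2],
                    _labeled(
                        _category_path(spec, c2, site, iva_rate, allow_repeat=False),
                        f"second_result_{c2.value}",
                    ),
                )
                for c2 in MilanCategory
            ],
            tags=("fnac",),
        )
    if cat is MilanCategory.II:
        return terminal("clinical_follow_up", c[Procedure.follow_up])
    if cat is MilanCategory.IVa:
        return chance(
            "iva_management",
            0.0,
            [
                (iva_rate, _surgery_with_revision(spec, site, p.rom[cat], "partial_surgery")),
                (1.0 - iva_rate, terminal("conservative_follow_up", c[Procedure.follow_up])),
            ],
        )
    if cat is MilanCategory.IVb:
        return _surgery_with_revision(spec, site, p.rom[cat], "partial_surgery")
    # V / VI
    return _frozen_section_surgery(spec, site, p.rom[cat])


def _labeled(node: Node, label: str) -> Node:
    node.label = f"{label}:{node.label}"
    return node


def build_fnac_arm(spec: ArmSpec, iva_surgery_rate: Optional[float] = None) -> DecisionTree:
    """Decision tree of the FNAC-first strategy.

    ``iva_surgery_rate`` overrides the rate stored in the parameters (the
    100 % / 70 % / 0 % scenario analysis); both must lie in [0, 1].
    """
    p, c = spec.params, spec.costs
    rate = p.iva_surgery_rate if iva_surgery_rate is None else iva_surgery_rate
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"iva_surgery_rate must be in [0, 1], got {rate!r}")

    def site_path(site: str) -> Node:
        return chance(
            f"cytology_{site}",
            0.0,
            [
                (
                    p.category_dist[cat],
                    _labeled(
                        _category_path(spec, cat, site, rate, allow_repeat=True),
                        f"category_{cat.value}",
                    ),
                )
                for cat in MilanCategory
            ],
        )

    root = _site_chance("fnac", p.site_mix, site_path, cost=c[Procedure.fnac])
    root.tags = frozenset({"fnac"})
    return DecisionTree(
        root=root,
        currency=c.currency,
        metadata={"model_id": p.model_id, "arm": "fnac_first", "iva_surgery_rate": rate},
    )


def apply_iva_scenario(params: ModelParameters, rate: float) -> ModelParameters:
    """Return a copy of ``params`` with ``iva_surgery_rate`` set to ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"iva_surgery_rate must be in [0, 1], got {rate!r}")
    return params.model_copy(update={"iva_surgery_rate": rate})
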