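"""The Japan new-drug pricing decision evaluation model.

Japan's National Health Insurance (NHI) prices a new drug from a comparable
listed drug and then applies corrective premiums when the drug demonstrates
innovative value: a *value premium* (new clinically useful mechanism, superior
efficacy/safety, improvement of treatment, formulation improvements), two
*marketability premiums* (orphan / rare-disease drugs and small-market drugs),
a *pediatrics premium*, and a *SAKIGAKE premium* for products designated under
Japan's fast-track scheme for innovative medicines.

This module encodes that decision system as a system-dynamics model: every
scoring item is a dimensionless score, the five premium subsystems aggregate
them, a weighted sum of the subsystems forms the pricing-decision flow, and a
single stock accumulates it over time. Interactions between criteria are
wired in explicitly — e.g. an early "new mechanism" certification feeds the
"new action part" and "new target" items, and a SAKIGAKE designation raises
the rare-disease / small-market / pediatric scores after a first-order delay
(designation effects take years to show up in those portfolios).

Variable census: 17 constants (16 item scores plus one shared special-
designation base), 33 auxiliaries (every scoring row and subsystem), and one
stock, initialized at 0. Scores are dimensionless; time is in years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import ModelSpec, Term, Trajectory, VariableSpec

__all__ = ["JapanModelCatalog", "CATALOG", "build_japan_model", "census", "premium_components"]

# internal shorthands for the long roster names
_NHS = "additional clinical significance of nhs accreditation"
_SERIOUS = "serious diseases without standard treatment"
_SAK = "sakigake premium"

#: weights of the five premium subsystems in the pricing-decision flow
FLOW_WEIGHTS = (1.8, 1.15, 1.05, 1.125, 1.15)

# (normalized name, printed spelling, score) of the 16 single-score items
_SCORED_ITEMS: tuple[tuple[str, str, float], ...] = (
    (_SERIOUS, "Serious diseases without standard treatment", 1),
    (_NHS, "Additional clinical significance of NHS accreditation", 1),
    ("safety better than comparator", "Safety better than comparator", 1),
    ("evidence from rct", "Evidence from RCT", 2),
    ("evidence from other", "Evidence from other", 1),
    ("favouring patient groups with poor outcomes", "Favouring patient groups with poor outcomes", 1),
    ("becoming a standard treatment option", "Becoming a standard treatment option", 1),
    ("faster onset/longing effects", "Faster onset/longing effects", 1),
    ("combination to enhance effectiveness", "Combination to enhance effectiveness", 1),
    ("reducing invasiveness of drug delivery", "Reducing invasiveness of drug delivery", 1),
    ("easy administration", "Easy administration", 1),
    ("stable blood level", "Stable blood level", 1),
    ("new mechanism", "New mechanism", 2),
    ("major disease", "Major disease", 2),
    ("significant improvement in efficacy", "Significant improvement in efficacy", 2),
    ("japan premiere/global synchronisation", "Japan premiere/global synchronisation", 2),
)

#: the base score shared by the rare-disease, small-market and children's rows
SPECIAL_BASE = "special-designation base"
SPECIAL_BASE_VALUE = 5.0

#: years for a SAKIGAKE designation to influence the special-designation rows
SAKIGAKE_DELAY = 5.0
#: years for an efficacy-improvement certification to influence the validity row
EFFICACY_DELAY = 0.5


@dataclass(frozen=True)
class JapanModelCatalog:
    """Census and naming of the bundled model, plus printed spellings."""

    constant_names: tuple[str, ...]
    auxiliary_names: tuple[str, ...]
    stock_name: str
    flow_name: str
    subsystem_names: tuple[str, ...]  # the five premium auxiliaries, in flow order
    flow_weights: tuple[float, ...]
    printed: dict[str, str] = field(default_factory=dict)

    def printed_name(self, name: str) -> str:
        return self.printed.get(name, name)


def _score_const(name: str) -> str:
    return f"{name} score"


def build_japan_model() -> ModelSpec:
    """Construct the bundled Japan pricing-decision model.

    Every scoring row is an auxiliary; the 16 single-score rows read their
    value from a named score constant so the exogenous inputs form an
    explicit, individually perturbable parameter set. The three special-
    designation rows (rare disease, small market, children's drug) share one
    base constant and each adds a 5-year first-order delay of the SAKIGAKE
    premium.
    """
    variables: list[VariableSpec] = []

    for name, _printed, score in _SCORED_ITEMS:
        variables.append(VariableSpec.constant(_score_const(name), score))
    variables.append(VariableSpec.constant(SPECIAL_BASE, SPECIAL_BASE_VALUE))

    # pass-through auxiliaries for the scored items
    for name, _printed, _score in _SCORED_ITEMS:
        variables.append(VariableSpec.auxiliary(name, [Term.ref(_score_const(name))]))

    def aux(name: str, terms: list[Term]) -> None:
        variables.append(VariableSpec.auxiliary(name, terms))

    aux("new action part", [Term.lit(2), Term.ref("new mechanism")])
    aux("new target", [Term.lit(1), Term.ref("new mechanism")])
    aux(
        "validity better than comparator",
        [
            Term.lit(2),
            Term.delay1("significant improvement in efficacy", EFFICACY_DELAY),
            Term.ref("combination to enhance effectiveness"),
        ],
    )
    aux("no standard in disease areas", [Term.lit(1), Term.ref(_SERIOUS)])
    for special in ("rare disease drug", "small market size", "children's drug"):
        aux(special, [Term.ref(SPECIAL_BASE), Term.delay1(_SAK, SAKIGAKE_DELAY)])
    aux(
        "new clinically useful mechanism",
        [Term.ref(_NHS), Term.ref("new action part"), Term.ref("new target"), Term.ref(_SERIOUS)],
    )
    aux(
        "more effective/safe than comparable drugs",
        [
            Term.ref(_NHS),
            Term.ref("safety better than comparator"),
            Term.ref("validity better than comparator"),
            Term.ref("evidence from rct"),
            Term.ref("evidence from other"),
        ],
    )
    aux(
        "may improve disease or injury",
        [
            Term.ref(_NHS),
            Term.ref("becoming a standard treatment option"),
            Term.ref("favouring patient groups with poor outcomes"),
            Term.ref("no standard in disease areas"),
            Term.ref("combination to enhance effectiveness"),
            Term.ref("faster onset/longing effects"),
        ],
    )
    aux(
        "formulation improvements to enhance utility",
        [
            Term.ref("reducing invasiveness of drug delivery"),
            Term.ref("easy administration"),
            Term.ref("stable blood level"),
            Term.ref(_NHS),
        ],
    )
    aux(
        "value premium",
        [
            Term.ref("formulation improvements to enhance utility"),
            Term.ref("may improve disease or injury"),
            Term.ref("new clinically useful mechanism"),
            Term.ref("more effective/safe than comparable drugs"),
        ],
    )
    aux("marketability premium i", [Term.ref("rare disease drug")])
    aux("marketability premium ii", [Term.ref("small market size")])
    aux("pediatrics premium", [Term.ref("children's drug")])
    aux(
        _SAK,
        [
            Term.ref("new mechanism"),
            Term.ref("significant improvement in efficacy"),
            Term.ref("japan premiere/global synchronisation"),
            Term.ref("major disease"),
        ],
    )
    aux(
        "new drug pricing decision variation",
        [
            Term.ref("value premium", FLOW_WEIGHTS[0]),
            Term.ref("marketability premium i", FLOW_WEIGHTS[1]),
            Term.ref("marketability premium ii", FLOW_WEIGHTS[2]),
            Term.ref("pediatrics premium", FLOW_WEIGHTS[3]),
            Term.ref(_SAK, FLOW_WEIGHTS[4]),
        ],
    )
    variables.append(
        VariableSpec.stock("new drug pricing decision evaluation", "new drug pricing decision variation", 0.0)
    )

    return ModelSpec(
        variables=variables,
        metadata={
            "name": "japan-new-drug-pricing",
            "description": "Japan NHI new-drug pricing decision evaluation (premium scoring system)",
        },
    )


def _build_catalog() -> JapanModelCatalog:
    spec = build_japan_model()
    printed = {name: shown for name, shown, _ in _SCORED_ITEMS}
    printed.update(
        {
            _NHS: "Additional clinical significance of NHS accreditation",
            "marketability premium i": "Marketability premium (I)",
            "marketability premium ii": "Marketability premium (II)",
            "pediatrics premium": "Pediatrics premium",
            _SAK: "SAKIGAKE premium",
            "value premium": "Value premium",
            "new drug pricing decision variation": "New drug pricing decision variation",
            "new drug pricing decision evaluation": "New drug pricing decision evaluation",
        }
    )
    return JapanModelCatalog(
        constant_names=tuple(v.name for v in spec.constants),
        auxiliary_names=tuple(v.name for v in spec.auxiliaries),
        stock_name="new drug pricing decision evaluation",
        flow_name="new drug pricing decision variation",
        subsystem_names=(
            "value premium",
            "marketability premium i",
            "marketability premium ii",
            "pediatrics premium",
            _SAK,
        ),
        flow_weights=FLOW_WEIGHTS,
        printed=printed,
    )


CATALOG = _build_catalog()


def census(spec: ModelSpec) -> dict[str, int]:
    """Counts of declared variables by kind."""
    return {
        "constant": len(spec.constants),
        "auxiliary": len(spec.auxiliaries),
        "stock": len(spec.stocks),
    }


def premium_components(traj: Trajectory, t: float) -> tuple[float, ...]:
    """The five premium-subsystem values at time ``t`` (must lie on the save
    grid), in catalog order: value, marketability I, marketability II,
    pediatrics, SAKIGAKE."""
    return tuple(traj.value_at(name, t) for name in CATALOG.subsystem_names)
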