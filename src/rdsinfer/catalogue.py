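"""Typed descriptions of survey variables.

A :class:`VariableCatalogue` declares, for every analysis variable, whether it
is binary or categorical, the admissible level labels, and the reference level
used when the variable enters a regression contrast.  The catalogue is the
single source of truth for level coding: the CSV reader validates against it
and the modelling code expands categorical variables against the declared
reference levels.

Binary variables are coded with the string levels ``"0"``/``"1"`` on disk and
held as 0/1 integers (``NaN`` when missing) in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

BINARY_LEVELS = ("0", "1")


@dataclass(frozen=True)
class Variable:
    """One survey variable: name, type, levels and reference level."""

    name: str
    kind: str = "binary"  # "binary" | "categorical"
    levels: tuple[str, ...] = BINARY_LEVELS
    reference: str | None = None
    definition: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "categorical"):
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if self.kind == "binary" and self.levels != BINARY_LEVELS:
            object.__setattr__(self, "levels", BINARY_LEVELS)
        if len(set(self.levels)) != len(self.levels) or len(self.levels) < 2:
            raise ValueError(f"{self.name}: levels must be >=2 distinct labels")
        if self.reference is None:
            object.__setattr__(self, "reference", self.levels[0])
        if self.reference not in self.levels:
            raise ValueError(
                f"{self.name}: reference level {self.reference!r} not among "
                f"declared levels {self.levels}"
            )

    @property
    def contrast_levels(self) -> tuple[str, ...]:
        """Non-reference levels, in declared order."""
        return tuple(l for l in self.levels if l != self.reference)


@dataclass
class VariableCatalogue:
    """Ordered collection of :class:`Variable` with an optional outcome name."""

    variables: list[Variable] = field(default_factory=list)
    outcome: str | None = None

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in catalogue")
        if self.outcome is not None and self.outcome not in names:
            raise ValueError(f"outcome {self.outcome!r} not in catalogue")

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def __contains__(self, name: object) -> bool:
        return name in self.names

    def __getitem__(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def __iter__(self):
        return iter(self.variables)

    def covariate_names(self) -> list[str]:
        """Names of all variables except the declared outcome."""
        return [n for n in self.names if n != self.outcome]


def default_study_catalogue() -> VariableCatalogue:
    """Catalogue for the young-adult opioid user overdose survey.

    Covers the sociodemographic and drug-use variables of the source survey:
    age group, gender, race/ethnicity, childhood household income, education,
    lifetime homelessness, HCV antibody status, seven lifetime/recent drug-use
    indicators, lifetime non-fatal overdose (the outcome) and the >=2 overdose
    recode used for the repeat-overdose model.  "Regular" use means three or
    more times a week for at least one month.
    """
    cat = lambda *a, **k: Variable(*a, kind="categorical", **k)  # noqa: E731
    variables = [
        Variable("age_24_29", definition="aged 24-29 vs 18-23"),
        cat(
            "gender",
            levels=("male", "female", "transgender"),
            reference="male",
        ),
        cat(
            "race_ethnicity",
            levels=("hispanic", "white_nonhispanic", "nonwhite_nonhispanic"),
            reference="hispanic",
        ),
        cat(
            "income_growing_up",
            levels=("50_100k", "le_50k", "gt_100k", "dont_know_missing"),
            reference="50_100k",
            definition="annual household income while growing up; "
            "'do not know/missing' retained as an explicit level",
        ),
        cat(
            "education",
            levels=("less_than_hs", "hs_grad_ged", "beyond_hs"),
            reference="less_than_hs",
        ),
        Variable("ever_homeless", definition="lifetime homelessness"),
        Variable("hcv_positive", definition="reactive rapid HCV antibody test"),
        Variable(
            "benzo_regular",
            definition="lifetime regular nonmedical benzodiazepine use",
        ),
        Variable("po_regular", definition="lifetime regular nonmedical PO use"),
        Variable("heroin_regular", definition="lifetime regular heroin use"),
        Variable(
            "heroin_injection_regular",
            definition="lifetime regular heroin injection",
        ),
        Variable(
            "po_injection_regular",
            definition="lifetime regular injection of dissolved opioid pills",
        ),
        Variable(
            "nonsterile_syringe",
            definition="receptive non-sterile syringe use, past 12 months",
        ),
        Variable("drug_binging", definition="drug binging, past 30 days"),
        Variable(
            "ever_overdose",
            definition="ever lost consciousness, stopped breathing or was "
            "unresponsive after taking drugs by any route",
        ),
        Variable(
            "multiple_overdose",
            definition=">=2 lifetime overdoses among those with any overdose; "
            "missing for respondents who never overdosed",
        ),
    ]
    return VariableCatalogue(variables, outcome="ever_overdose")
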