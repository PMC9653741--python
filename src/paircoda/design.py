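"""Shared specification of an association analysis.

Every statistical routine in the package (per-taxon clr regression,
PERMANOVA, alpha-diversity models, cooperative-balance models) is driven
by the same small design object: which metadata column is being tested,
which columns enter as fixed covariates, which column defines the random
grouping (patients for paired designs, batch otherwise), and which column
restricts permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class AssociationDesign:
    """Design of a single-factor association analysis.

    Parameters
    ----------
    factor:
        Metadata column whose effect is tested. May be binary categorical
        or numeric.
    covariates:
        Metadata columns entered as fixed covariates before the factor
        (e.g. the Shannon index).
    random_group:
        Metadata column defining the random grouping (e.g. ``patient_id``
        for paired stool/biopsy designs, ``batch`` otherwise). ``None``
        means independent samples.
    strata:
        Metadata column restricting permutations: labels are shuffled only
        within each stratum (e.g. within each patient's stool/biopsy pair).
    response:
        Optional name of the modelled response, purely descriptive.
    """

    factor: str
    covariates: tuple[str, ...] = field(default=())
    random_group: str | None = None
    strata: str | None = None
    response: str | None = None

    def __post_init__(self) -> None:
        if not self.factor:
            raise ValueError("factor must be a non-empty column name")
        if self.factor in self.covariates:
            raise ValueError(f"factor {self.factor!r} cannot also be a covariate")

    def required_columns(self) -> tuple[str, ...]:
        cols = [self.factor, *self.covariates]
        if self.random_group:
            cols.append(self.random_group)
        if self.strata:
            cols.append(self.strata)
        return tuple(dict.fromkeys(cols))
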