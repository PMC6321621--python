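"""Formula-level molecular properties and the Lipinski 'rule of five' filter.

The screen keeps molecules with molecular weight < 500 Da, fewer than 5
hydrogen-bond donors (O-H plus N-H count), fewer than 10 acceptors (N plus
O count) and logP < 5 -- all strict inequalities.  logP is always an input
field (AlogP/ClogP-style values come from external predictors); when it is
missing the logP rule is skipped and the record flagged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .errors import TWNError

__all__ = [
    "ATOMIC_WEIGHTS",
    "parse_formula",
    "molecular_weight",
    "MoleculeRecord",
    "LipinskiResult",
    "lipinski_filter",
    "record_from_smiles",
]

logger = logging.getLogger(__name__)

#: IUPAC 2021 abridged standard atomic weights, Da.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "He": 4.0026,
    "Li": 6.94,
    "Be": 9.0122,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Ne": 20.180,
    "Na": 22.990,
    "Mg": 24.305,
    "Al": 26.982,
    "Si": 28.085,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "Ar": 39.95,
    "K": 39.098,
    "Ca": 40.078,
    "Mn": 54.938,
    "Fe": 55.845,
    "Co": 58.933,
    "Ni": 58.693,
    "Cu": 63.546,
    "Zn": 65.38,
    "As": 74.922,
    "Se": 78.971,
    "Br": 79.904,
    "Sn": 118.71,
    "I": 126.90,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation molecular formula (e.g. ``C20H15N5``)."""
    if not formula or not formula.strip():
        raise ValueError("empty molecular formula")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula.strip()):
        if m.start() != pos:
            raise ValueError(f"unparsable formula {formula!r} at {formula[pos:]!r}")
        pos = m.end()
        el, num = m.group(1), int(m.group(2) or 1)
        counts[el] = counts.get(el, 0) + num
    if pos != len(formula.strip()):
        raise ValueError(f"unparsable formula {formula!r}")
    return counts


def molecular_weight(formula: dict[str, int] | str) -> float:
    """Molecular weight in Da from an element->count map or formula string."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    if not formula:
        raise ValueError("empty molecular formula")
    mw = 0.0
    for el, n in formula.items():
        if el not in ATOMIC_WEIGHTS:
            raise ValueError(f"unknown element symbol {el!r}")
        if n < 0:
            raise ValueError(f"negative count for {el}")
        mw += n * ATOMIC_WEIGHTS[el]
    return mw


@dataclass(frozen=True)
class MoleculeRecord:
    """A formula-level molecule for the drug-likeness screen."""

    identifier: str
    formula: str
    hbd: int
    hba: int
    logp: float | None = None
    rotatable_bonds: int | None = None

    def __post_init__(self) -> None:
        if self.hbd < 0 or self.hba < 0:
            raise ValueError(f"{self.identifier}: negative donor/acceptor count")
        parse_formula(self.formula)  # validates

    @property
    def mw(self) -> float:
        return molecular_weight(self.formula)


@dataclass(frozen=True)
class LipinskiResult:
    identifier: str
    passes: bool
    violations: tuple[str, ...]
    skipped_rules: tuple[str, ...]
    mw: float


def _evaluate(record: MoleculeRecord) -> LipinskiResult:
    violations, skipped = [], []
    mw = record.mw
    if not mw < 500.0:
        violations.append("mw")
    if not record.hbd < 5:
        violations.append("hbd")
    if not record.hba < 10:
        violations.append("hba")
    if record.logp is None:
        skipped.append("logp")
        logger.warning("%s: logP missing, rule skipped", record.identifier)
    elif not record.logp < 5.0:
        violations.append("logp")
    return LipinskiResult(
        identifier=record.identifier,
        passes=not violations,
        violations=tuple(violations),
        skipped_rules=tuple(skipped),
        mw=mw,
    )


def lipinski_filter(records) -> list[LipinskiResult]:
    """Apply the rule-of-five screen to each record independently.

    A record passes iff MW < 500, HBD < 5, HBA < 10 and logP < 5 (strict).
    Records with missing logP are evaluated on the remaining rules and the
    skip is recorded, never silently dropped.
    """
    return [_evaluate(r) for r in records]


def results_to_dataframe(results):
    import pandas as pd

    return pd.DataFrame(
        {
            "identifier": [r.identifier for r in results],
            "mw": [r.mw for r in results],
            "passes": [r.passes for r in results],
            "violations": [",".join(r.violations) for r in results],
            "skipped_rules": [",".join(r.skipped_rules) for r in results],
        }
    )


def record_from_smiles(identifier: str, smiles: str, logp: float | None = None) -> MoleculeRecord:
    """Derive formula and Lipinski donor/acceptor counts from SMILES via RDKit.

    Donors are O-H plus N-H counts and acceptors are N plus O atom counts
    (the original rule-of-five definitions).
    """
    from rdkit import Chem
    from rdkit.Chem import Lipinski, rdMolDescriptors

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise TWNError(f"{identifier}: could not parse SMILES {smiles!r}")
    formula = rdMolDescriptors.CalcMolFormula(mol)
    # strip charge suffixes like '+' / '-' that cannot appear in a neutral record
    formula = re.sub(r"[+-]\d*$", "", formula)
    return MoleculeRecord(
        identifier=identifier,
        formula=formula,
        hbd=Lipinski.NHOHCount(mol),
        hba=Lipinski.NOCount(mol),
        logp=logp,
    )
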