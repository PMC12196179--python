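"""Lipinski rule-of-five and oral-bioavailability screening.

Descriptor records (MW, logP, H-bond donors/acceptors, Abbott
bioavailability score) are ingested from tables rather than computed; an
optional helper can populate the physicochemical fields from a SMILES string
when a cheminformatics toolkit is importable.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .exceptions import ValidationError

__all__ = ["CompoundDescriptor", "lipinski_violations", "screen",
           "descriptor_from_smiles"]

#: Lipinski limits; a violation is a strict exceedance of any limit.
_LIPINSKI_LIMITS = {"mw": 500.0, "logp": 5.0, "hbd": 5, "hba": 10}


@dataclass
class CompoundDescriptor:
    """Physicochemical descriptors of one compound."""

    name: str
    mw: float
    logp: float
    hbd: int
    hba: int
    bioavailability_score: float
    smiles: str | None = None

    def __post_init__(self):
        for f in ("mw", "logp", "hbd", "hba", "bioavailability_score"):
            if getattr(self, f) is None:
                raise ValidationError(f"{self.name}: missing field {f!r}")
        if self.mw <= 0:
            raise ValidationError(f"{self.name}: mw must be positive")
        if self.hbd < 0 or self.hba < 0:
            raise ValidationError(f"{self.name}: hbd/hba must be >= 0")
        if not 0.0 <= self.bioavailability_score <= 1.0:
            raise ValidationError(
                f"{self.name}: bioavailability score must lie in [0, 1]")


def lipinski_violations(d: CompoundDescriptor) -> int:
    """Number of rule-of-five violations (0-4).

    Violations are strict exceedances of MW > 500 Da, logP > 5, H-bond
    donors > 5, H-bond acceptors > 10; a compound sitting exactly on a limit
    does not violate it.
    """
    return sum((
        d.mw > _LIPINSKI_LIMITS["mw"],
        d.logp > _LIPINSKI_LIMITS["logp"],
        d.hbd > _LIPINSKI_LIMITS["hbd"],
        d.hba > _LIPINSKI_LIMITS["hba"],
    ))


def screen(descs: Sequence[CompoundDescriptor], max_violations: int = 1,
           min_bioavailability: float = 0.5) -> pd.DataFrame:
    """Drug-likeness pass/fail report.

    A compound passes iff its Lipinski violation count is at most
    ``max_violations`` (default 1, the original allowance) and its Abbott
    bioavailability score is at least ``min_bioavailability`` (default 0.5).
    The report lists per-rule outcomes alongside the combined verdict.
    """
    if not descs:
        raise ValidationError("empty descriptor list")
    rows = []
    for d in descs:
        v = lipinski_violations(d)
        bio_ok = d.bioavailability_score >= min_bioavailability
        rows.append({
            "name": d.name, "mw": d.mw, "logp": d.logp,
            "hbd": d.hbd, "hba": d.hba,
            "bioavailability_score": d.bioavailability_score,
            "mw_ok": d.mw <= _LIPINSKI_LIMITS["mw"],
            "logp_ok": d.logp <= _LIPINSKI_LIMITS["logp"],
            "hbd_ok": d.hbd <= _LIPINSKI_LIMITS["hbd"],
            "hba_ok": d.hba <= _LIPINSKI_LIMITS["hba"],
            "violations": v,
            "bioavailability_ok": bio_ok,
            "passes": v <= max_violations and bio_ok,
        })
    return pd.DataFrame(rows).set_index("name")


def descriptor_from_smiles(name: str, smiles: str,
                           bioavailability_score: float) -> CompoundDescriptor:
    """Populate MW/logP/HBD/HBA from a SMILES string via RDKit.

    The Abbott bioavailability score is not derivable from structure alone
    and must be supplied. Raises ImportError when RDKit is unavailable.
    """
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors, Lipinski

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"{name}: unparsable SMILES {smiles!r}")
    return CompoundDescriptor(
        name=name,
        mw=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        hbd=Lipinski.NumHDonors(mol),
        hba=Lipinski.NumHAcceptors(mol),
        bioavailability_score=bioavailability_score,
        smiles=smiles,
    )
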