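"""Compound container and structure I/O (SMILES / SDF) on top of RDKit."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from rdkit import Chem
from rdkit import RDLogger

from .errors import ValidationError

# RDKit is chatty about kekulisation on perfectly valid aromatic input.
RDLogger.DisableLog("rdApp.*")


@dataclass
class Compound:
    """A small molecule identified by ``compound_id`` with a SMILES structure.

    The parsed RDKit molecule is cached after the first access; ``properties``
    holds optional computed annotations (e.g. Lipinski inputs).
    """

    compound_id: str
    smiles: str
    properties: dict = field(default_factory=dict)
    _mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    @property
    def mol(self) -> Chem.Mol:
        if self._mol is None:
            mol = Chem.MolFromSmiles(self.smiles)
            if mol is None:
                raise ValidationError(
                    f"compound {self.compound_id!r}: SMILES does not parse: {self.smiles!r}"
                )
            self._mol = mol
        return self._mol

    def parses(self) -> bool:
        try:
            self.mol
        except ValidationError:
            return False
        return True


def read_smiles_file(path: str | Path) -> list[Compound]:
    """Read a ``SMILES<TAB>id`` file (one compound per line, '#' comments)."""
    compounds = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"{path}:{lineno}: expected 'SMILES<TAB>id', got {line!r}")
        smiles, cid = parts
        compounds.append(Compound(compound_id=cid, smiles=smiles))
    return compounds


def write_smiles_file(compounds: Iterable[Compound], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in compounds:
            fh.write(f"{c.smiles}\t{c.compound_id}\n")


def read_sdf(path: str | Path) -> list[Compound]:
    """Read an SDF; the molecule title (or ``_Name``) becomes the compound id."""
    compounds = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol_{i}"
        compounds.append(Compound(compound_id=cid, smiles=Chem.MolToSmiles(mol), _mol=mol))
    return compounds


def write_sdf(compounds: Iterable[Compound], path: str | Path) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for c in compounds:
            mol = Chem.Mol(c.mol)
            mol.SetProp("_Name", c.compound_id)
            writer.write(mol)
    finally:
        writer.close()


def iter_parsed(compounds: Iterable[Compound]) -> Iterator[Compound]:
    """Yield only compounds whose structures parse (skipped ones are dropped silently;
    callers that must report failures check ``Compound.parses`` themselves)."""
    for c in compounds:
        if c.parses():
            yield c
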