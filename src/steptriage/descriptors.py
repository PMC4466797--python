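"""2D molecular descriptors in three families.

The table schema mirrors the classical HTS-descriptor layout: 147 binary
pharmacophore-pair fingerprint bits, 24 weighted Burden-eigenvalue (BCUT-style)
descriptors and 8 continuous property descriptors — 179 columns in total before
redundancy removal.

Pharmacophore fingerprint layout (schema version 1, fixed):

* six chemical features — H-bond donor, H-bond acceptor, aromatic ring atom,
  hydrophobic atom, positive centre, negative centre — assigned by the bundled
  SMARTS definitions (``data/pharmacophore_features.tsv``);
* 21 unordered feature pairs x 4 topological-distance bins (bond counts
  1–2, 3–4, 5–6, 7+; atom pairs in different fragments fall in the 7+ bin)
  = 84 pair bits;
* per-feature count-threshold bits (count >= 1 .. 10, 6 x 10 = 60 bits) and
  three molecule-level ring-count bits (rings >= 1, 2, 3) = 63 single bits.

Burden descriptors: for each of three diagonal weightings (atomic mass,
Gasteiger partial charge including attached hydrogens, tabulated atomic
polarizability) the 4 largest and 4 smallest eigenvalues of the Burden
connectivity matrix (off-diagonal 0.1 x bond order for bonded pairs, 0.001 for
non-bonded pairs within a connected component).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors, rdMolDescriptors

from .chem import Compound
from .errors import ValidationError

logger = logging.getLogger(__name__)

FAMILIES = ("pharmacophore", "burden", "property")
DTYPES = ("binary", "continuous")

_FEATURE_ORDER = ("donor", "acceptor", "aromatic", "hydrophobic", "positive", "negative")
_DISTANCE_BINS = ((1, 2), (3, 4), (5, 6), (7, None))  # bond counts; None = unbounded
_COUNT_THRESHOLDS = range(1, 11)
_RING_THRESHOLDS = (1, 2, 3)

_BURDEN_WEIGHTINGS = ("mass", "charge", "polarizability")
_BURDEN_BONDED = 0.1  # multiplied by bond order
_BURDEN_NONBONDED = 0.001

PROPERTY_NAMES = (
    "mol_weight",       # g/mol
    "logp",             # Wildman–Crippen estimate, unitless
    "h_donors",         # atoms matching the bundled donor SMARTS
    "h_acceptors",      # atoms matching the bundled acceptor SMARTS
    "rotatable_bonds",
    "tpsa",             # Å^2
    "heavy_atoms",
    "formal_charge",
)


def _read_tsv_resource(filename: str) -> list[tuple[str, ...]]:
    text = resources.files("steptriage.data").joinpath(filename).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(tuple(line.split("\t")))
    return rows


def _load_feature_patterns() -> dict[str, Chem.Mol]:
    patterns = {}
    for name, smarts in _read_tsv_resource("pharmacophore_features.tsv"):
        query = Chem.MolFromSmarts(smarts)
        if query is None:  # pragma: no cover - bundled file is validated by tests
            raise ValidationError(f"bundled feature SMARTS does not compile: {name}")
        patterns[name] = query
    return patterns


_FEATURE_PATTERNS = _load_feature_patterns()
_POLARIZABILITY = {sym: float(val) for sym, val in _read_tsv_resource("polarizability.tsv")}


# ---------------------------------------------------------------------------
# schema


@dataclass(frozen=True)
class ColumnSchema:
    name: str
    family: str
    dtype: str

    def __post_init__(self):
        if self.family not in FAMILIES or self.dtype not in DTYPES:
            raise ValidationError(f"bad column schema: {self}")


def pharmacophore_bit_names() -> list[str]:
    """The fixed, ordered 147-bit pharmacophore fingerprint schema."""
    names = []
    for i, fi in enumerate(_FEATURE_ORDER):
        for fj in _FEATURE_ORDER[i:]:
            for lo, hi in _DISTANCE_BINS:
                label = f"d{lo}-{hi}" if hi is not None else f"d{lo}+"
                names.append(f"pair:{fi}-{fj}:{label}")
    for feat in _FEATURE_ORDER:
        for c in _COUNT_THRESHOLDS:
            names.append(f"count:{feat}>={c}")
    for r in _RING_THRESHOLDS:
        names.append(f"rings>={r}")
    assert len(names) == 147
    return names


def burden_names() -> list[str]:
    names = []
    for w in _BURDEN_WEIGHTINGS:
        names += [f"burden:{w}:hi{k}" for k in range(1, 5)]
        names += [f"burden:{w}:lo{k}" for k in range(1, 5)]
    return names


def full_schema() -> list[ColumnSchema]:
    cols = [ColumnSchema(n, "pharmacophore", "binary") for n in pharmacophore_bit_names()]
    cols += [ColumnSchema(n, "burden", "continuous") for n in burden_names()]
    cols += [ColumnSchema(n, "property", "continuous") for n in PROPERTY_NAMES]
    return cols


# ---------------------------------------------------------------------------
# descriptor table container


@dataclass
class DescriptorTable:
    """Compound-by-descriptor numeric matrix with a typed column schema."""

    compound_ids: list[str]
    columns: list[ColumnSchema]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.compound_ids), len(self.columns)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.compound_ids)} compounds x {len(self.columns)} columns"
            )
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate descriptor column names")

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.compound_ids, columns=self.column_names)

    def select(self, names: Sequence[str]) -> "DescriptorTable":
        """Project onto the given columns (validated), keeping their given order."""
        by_name = {c.name: i for i, c in enumerate(self.columns)}
        missing = [n for n in names if n not in by_name]
        if missing:
            raise ValidationError(f"unknown descriptor columns: {missing}")
        idx = [by_name[n] for n in names]
        return DescriptorTable(
            compound_ids=list(self.compound_ids),
            columns=[self.columns[i] for i in idx],
            values=self.values[:, idx],
        )

    def write_csv(self, path: str | Path) -> None:
        """Header cells encode ``name:family:dtype``; first column is compound_id."""
        header = ["compound_id"] + [f"{c.name}:{c.family}:{c.dtype}" for c in self.columns]
        df = pd.DataFrame(self.values, columns=header[1:])
        df.insert(0, "compound_id", self.compound_ids)
        df.columns = header
        df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "DescriptorTable":
        df = pd.read_csv(path)
        if df.columns[0] != "compound_id":
            raise ValidationError("descriptor CSV must start with a compound_id column")
        cols = []
        for cell in df.columns[1:]:
            # header cell is name:family:dtype; name itself may contain ':'
            parts = cell.rsplit(":", 2)
            if len(parts) != 3:
                raise ValidationError(f"bad descriptor header cell {cell!r}")
            cols.append(ColumnSchema(parts[0], parts[1], parts[2]))
        return cls(
            compound_ids=[str(c) for c in df["compound_id"]],
            columns=cols,
            values=df.iloc[:, 1:].to_numpy(dtype=float),
        )


# ---------------------------------------------------------------------------
# pharmacophore fingerprint


def _feature_atoms(mol: Chem.Mol) -> dict[str, set[int]]:
    return {
        name: {match[0] for match in mol.GetSubstructMatches(query)}
        for name, query in _FEATURE_PATTERNS.items()
    }


def pharmacophore_fingerprint(compound: Compound) -> np.ndarray:
    """147-bit binary pharmacophore fingerprint (fixed schema, see module docs)."""
    mol = compound.mol
    atoms = _feature_atoms(mol)
    n = mol.GetNumAtoms()
    dist = Chem.GetDistanceMatrix(mol) if n else np.zeros((0, 0))

    bits = np.zeros(147, dtype=int)
    pos = 0
    for i, fi in enumerate(_FEATURE_ORDER):
        for fj in _FEATURE_ORDER[i:]:
            for lo, hi in _DISTANCE_BINS:
                hit = 0
                for a in atoms[fi]:
                    for b in atoms[fj]:
                        if a == b:
                            continue
                        d = dist[a, b]
                        if d >= lo and (hi is None or d <= hi):
                            hit = 1
                            break
                    if hit:
                        break
                bits[pos] = hit
                pos += 1
    for feat in _FEATURE_ORDER:
        count = len(atoms[feat])
        for c in _COUNT_THRESHOLDS:
            bits[pos] = int(count >= c)
            pos += 1
    n_rings = rdMolDescriptors.CalcNumRings(mol)
    for r in _RING_THRESHOLDS:
        bits[pos] = int(n_rings >= r)
        pos += 1
    return bits


# ---------------------------------------------------------------------------
# Burden eigenvalue descriptors


def _atom_weights(mol: Chem.Mol, weighting: str) -> np.ndarray:
    if weighting == "mass":
        return np.array([a.GetMass() for a in mol.GetAtoms()])
    if weighting == "charge":
        AllChem.ComputeGasteigerCharges(mol)
        out = []
        for a in mol.GetAtoms():
            q = a.GetDoubleProp("_GasteigerCharge")
            qh = a.GetDoubleProp("_GasteigerHCharge") if a.HasProp("_GasteigerHCharge") else 0.0
            total = q + qh
            out.append(0.0 if not np.isfinite(total) else total)
        return np.array(out)
    if weighting == "polarizability":
        vals = []
        for a in mol.GetAtoms():
            sym = a.GetSymbol()
            if sym not in _POLARIZABILITY:
                logger.warning("no polarizability tabulated for %s; using the carbon value", sym)
            vals.append(_POLARIZABILITY.get(sym, _POLARIZABILITY["C"]))
        return np.array(vals)
    raise ValidationError(f"unknown Burden weighting {weighting!r}")


def burden_matrix(mol: Chem.Mol, weighting: str) -> np.ndarray:
    """Symmetric Burden connectivity matrix over the heavy atoms of ``mol``."""
    n = mol.GetNumAtoms()
    frag_of = np.zeros(n, dtype=int)
    for k, frag in enumerate(Chem.GetMolFrags(mol)):
        for a in frag:
            frag_of[a] = k
    same_frag = frag_of[:, None] == frag_of[None, :]
    B = np.where(same_frag, _BURDEN_NONBONDED, 0.0)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        B[i, j] = B[j, i] = _BURDEN_BONDED * bond.GetBondTypeAsDouble()
    np.fill_diagonal(B, _atom_weights(mol, weighting))
    return B


def _extreme_eigenvalues(eigs: np.ndarray, k: int = 4) -> tuple[np.ndarray, np.ndarray]:
    desc = np.sort(eigs)[::-1]
    asc = np.sort(eigs)
    hi = desc[np.minimum(np.arange(k), len(eigs) - 1)]
    lo = asc[np.minimum(np.arange(k), len(eigs) - 1)]
    return hi, lo


def burden_descriptors(compound: Compound) -> np.ndarray:
    """24 Burden-eigenvalue descriptors: per weighting, 4 largest then 4 smallest."""
    mol = compound.mol
    if mol.GetNumAtoms() < 1:
        raise ValidationError(f"compound {compound.compound_id!r} has no heavy atoms")
    if mol.GetNumAtoms() == 1:
        warnings.warn(
            f"compound {compound.compound_id!r} has a single heavy atom; "
            "its Burden eigenvalue is replicated across all slots"
        )
    out = []
    for w in _BURDEN_WEIGHTINGS:
        eigs = np.linalg.eigvalsh(burden_matrix(mol, w))
        hi, lo = _extreme_eigenvalues(eigs)
        out += list(hi) + list(lo)
    return np.array(out)


# ---------------------------------------------------------------------------
# property descriptors


def property_descriptors(compound: Compound) -> np.ndarray:
    """(MW, logP, donors, acceptors, rotatable bonds, TPSA, heavy atoms, formal charge)."""
    mol = compound.mol
    donors = len(mol.GetSubstructMatches(_FEATURE_PATTERNS["donor"]))
    acceptors = len(mol.GetSubstructMatches(_FEATURE_PATTERNS["acceptor"]))
    return np.array([
        Descriptors.MolWt(mol),
        Descriptors.MolLogP(mol),
        donors,
        acceptors,
        Descriptors.NumRotatableBonds(mol),
        Descriptors.TPSA(mol),
        mol.GetNumHeavyAtoms(),
        Chem.GetFormalCharge(mol),
    ])


# ---------------------------------------------------------------------------
# full table


def descriptor_table(compounds: Iterable[Compound]) -> DescriptorTable:
    """Compute the full 179-column table; unparseable structures are skipped with a log entry."""
    ids, rows = [], []
    for c in compounds:
        if not c.parses():
            logger.error("compound %s: structure does not parse; row skipped", c.compound_id)
            continue
        row = np.concatenate([
            pharmacophore_fingerprint(c).astype(float),
            burden_descriptors(c),
            property_descriptors(c),
        ])
        ids.append(c.compound_id)
        rows.append(row)
    if not rows:
        raise ValidationError("no parseable compounds; descriptor table would be empty")
    return DescriptorTable(compound_ids=ids, columns=full_schema(), values=np.vstack(rows))
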