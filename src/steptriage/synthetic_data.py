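"""Synthetic imbalanced bioassay libraries with planted substructure signal.

Real phosphatase-inhibition HTS campaigns screen hundreds of thousands of
compounds of which only a fraction of a percent are active (the emulated
screen has 887 actives among 359,231 compounds, an active fraction of about
0.25%). This module generates desk-scale libraries with the same shape:

* compounds are assembled from a bundled grammar of ~20 drug-like scaffolds
  and ~30 substituents, so every structure is chemically valid and its
  fragment content is known;
* each compound receives a latent activity propensity; compounds containing
  an *enriched fragment* (named in the bundled substructure dictionary) have
  their activity odds multiplied by the requested factor;
* the continuous readout is % inhibition = 100·sigmoid(propensity) + noise,
  clipped to [-20, 120], so the 40% labeling rule induces the two classes;
* a baseline logit is calibrated so the realized active fraction matches the
  requested one.

Everything is driven by a single integer seed and is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from rdkit import Chem

from .bioassay import AssayRecord
from .chem import Compound
from .errors import ConfigurationError, ValidationError
from .fragments import load_default_dictionary

_CLIP_LO, _CLIP_HI = -20.0, 120.0
_MAX_SUBSTITUENTS = 3


def _read_grammar(filename: str) -> list[tuple[str, str]]:
    text = resources.files("steptriage.data").joinpath(filename).read_text()
    out = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, smiles = line.split("\t")
        out.append((name, smiles))
    return out


@dataclass
class LibrarySpec:
    """Parameters of a synthetic screening library.

    ``active_fraction`` defaults to 0.0025, the prevalence of the emulated
    screen; desk-scale test libraries typically use 0.02–0.05 so that folds
    and fragment tables are populated. ``enriched_fragments`` maps names from
    the bundled substructure dictionary to odds multipliers >= 1 applied to
    the activity propensity of every compound containing that fragment.
    ``noise_sd`` is the readout noise (percentage points of inhibition) and
    ``latent_sd`` the spread of the per-compound latent propensity (logits).
    """

    n_compounds: int
    active_fraction: float = 0.0025
    enriched_fragments: list[tuple[str, float]] = field(default_factory=list)
    noise_sd: float = 5.0
    seed: int = 0
    latent_sd: float = 2.0
    base_logit: float | None = None  # overrides calibration when set

    def validate(self) -> None:
        if self.n_compounds < 1:
            raise ValidationError("n_compounds must be >= 1")
        if not 0.0 < self.active_fraction < 1.0:
            raise ValidationError("active_fraction must be in (0, 1)")
        if self.base_logit is None and self.active_fraction * self.n_compounds < 1:
            raise ValidationError(
                "active_fraction * n_compounds must be >= 1 so at least one active exists"
            )
        if self.noise_sd < 0 or self.latent_sd < 0:
            raise ValidationError("noise_sd and latent_sd must be >= 0")
        known = {e.name for e in load_default_dictionary().entries}
        for name, mult in self.enriched_fragments:
            if name not in known:
                raise ConfigurationError(
                    f"enriched fragment {name!r} is not in the bundled fragment dictionary"
                )
            if mult < 1:
                raise ValidationError(f"enrichment multiplier for {name!r} must be >= 1")


def _assemble(rng: np.random.Generator, scaffolds, substituents) -> str:
    """Attach 1–3 substituents to random H-bearing scaffold atoms; returns canonical SMILES."""
    while True:
        _, scaffold_smiles = scaffolds[rng.integers(len(scaffolds))]
        scaffold = Chem.MolFromSmiles(scaffold_smiles)
        sites = [
            a.GetIdx()
            for a in scaffold.GetAtoms()
            if a.GetTotalNumHs() >= 1 and a.GetSymbol() in ("C", "N")
        ]
        k = int(rng.integers(1, _MAX_SUBSTITUENTS + 1))
        k = min(k, len(sites))
        chosen = sorted(rng.choice(len(sites), size=k, replace=False))
        combined = Chem.RWMol(scaffold)
        attach_pairs = []
        for pick in chosen:
            site = sites[pick]
            _, sub_smiles = substituents[rng.integers(len(substituents))]
            sub = Chem.MolFromSmiles(sub_smiles)
            base = combined.GetNumAtoms()
            combined = Chem.RWMol(Chem.CombineMols(combined, sub))
            attach_pairs.append((site, base))
        for site, sub_atom in attach_pairs:
            combined.AddBond(site, sub_atom, Chem.BondType.SINGLE)
        mol = combined.GetMol()
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            continue  # rare valence clash; resample
        return Chem.MolToSmiles(mol)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-z))


def _calibrate_base_logit(crit: np.ndarray, k: int) -> float:
    """Baseline logit placing exactly k compounds at or above the 40% threshold.

    ``crit[i]`` is the smallest baseline at which compound i crosses the
    threshold; choosing the midpoint between the k-th and (k+1)-th order
    statistics makes the realized count exact and numerically robust.
    """
    order = np.sort(crit)
    b = order[k - 1]
    if k < len(order) and np.isfinite(order[k]) and np.isfinite(b):
        b = 0.5 * (b + order[k])
        if b >= order[k]:  # degenerate tie
            b = order[k - 1]
    return float(b)


def generate_library(spec: LibrarySpec) -> tuple[list[Compound], list[AssayRecord]]:
    """Generate a library and its assay table; deterministic for a fixed seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    scaffolds = _read_grammar("scaffolds.txt")
    substituents = _read_grammar("substituents.txt")
    dictionary = load_default_dictionary()
    enriched = []
    for name, mult in spec.enriched_fragments:
        entry = next(e for e in dictionary.entries if e.name == name)
        enriched.append((entry.query, float(mult)))

    width = len(str(spec.n_compounds - 1)) if spec.n_compounds > 1 else 1
    compounds = []
    log_odds_boost = np.zeros(spec.n_compounds)
    for i in range(spec.n_compounds):
        smiles = _assemble(rng, scaffolds, substituents)
        mol = Chem.MolFromSmiles(smiles)
        boost = 0.0
        for query, mult in enriched:
            if mol.HasSubstructMatch(query):
                boost += np.log(mult)
        log_odds_boost[i] = boost
        compounds.append(Compound(compound_id=f"SYN{i:0{width}d}", smiles=smiles))

    latent = rng.normal(0.0, spec.latent_sd, size=spec.n_compounds)
    eps = (
        rng.normal(0.0, spec.noise_sd, size=spec.n_compounds)
        if spec.noise_sd > 0
        else np.zeros(spec.n_compounds)
    )
    z = latent + log_odds_boost

    if spec.base_logit is not None:
        b0 = spec.base_logit
    else:
        # critical baseline per compound: smallest b0 at which it becomes active
        frac = (40.0 - eps) / 100.0
        with np.errstate(divide="ignore"):
            crit = np.where(
                frac <= 0.0,
                -np.inf,
                np.where(frac >= 1.0, np.inf, np.log(frac / (1.0 - frac)) - z),
            )
        k = int(round(spec.active_fraction * spec.n_compounds))
        k = max(1, min(k, spec.n_compounds))
        b0 = _calibrate_base_logit(crit, k)

    inhibition = np.clip(100.0 * _sigmoid(b0 + z) + eps, _CLIP_LO, _CLIP_HI)
    records = [
        AssayRecord.from_readout(c.compound_id, round(float(v), 6))
        for c, v in zip(compounds, inhibition)
    ]
    return compounds, records


def write_assay_csv(records, path: str | Path) -> None:
    """Write the generator's assay table as ``compound_id,percent_inhibition``."""
    with open(path, "w") as fh:
        fh.write("compound_id,percent_inhibition\n")
        for r in records:
            fh.write(f"{r.compound_id},{r.percent_inhibition}\n")
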