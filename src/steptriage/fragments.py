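"""Substructure-fingerprint generation and fragment class-enrichment statistics.

A fragment dictionary is a list of named SMARTS patterns; the fingerprint of a
compound is the binary presence vector over the dictionary. For each fragment
the enrichment of a class (actives or inactives) is expressed as

    frequency = (N_fragment_class * N_total) / (N_fragment_total * N_class)

which equals 1 when the fragment is distributed uniformly over the classes,
with a two-sided Fisher's exact test on the 2x2 presence-by-class table as the
significance filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from scipy.stats import fisher_exact

from .chem import Compound
from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FragmentEntry:
    fragment_id: str
    name: str
    smarts: str
    query: Chem.Mol = field(repr=False, compare=False, default=None)


@dataclass
class FragmentDictionary:
    entries: list[FragmentEntry]

    def __post_init__(self):
        ids = [e.fragment_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate fragment ids in dictionary")

    def __len__(self) -> int:
        return len(self.entries)

    def by_name(self, name: str) -> FragmentEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise ConfigurationError(f"fragment {name!r} not in dictionary")


def _parse_dictionary_lines(lines: Iterable[str], source: str) -> FragmentDictionary:
    entries = []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ConfigurationError(
                f"{source}:{lineno}: expected 'fragment_id<TAB>name<TAB>SMARTS'"
            )
        fid, name, smarts = parts
        query = Chem.MolFromSmarts(smarts)
        if query is None:
            raise ConfigurationError(f"{source}:{lineno}: SMARTS does not compile: {smarts!r}")
        entries.append(FragmentEntry(fid, name, smarts, query))
    return FragmentDictionary(entries)


def load_dictionary(path: str | Path) -> FragmentDictionary:
    return _parse_dictionary_lines(Path(path).read_text().splitlines(), str(path))


@lru_cache(maxsize=1)
def load_default_dictionary() -> FragmentDictionary:
    """The bundled substructure dictionary (subset of a 307-pattern scheme)."""
    text = resources.files("steptriage.data").joinpath("subfp_dictionary.tsv").read_text()
    return _parse_dictionary_lines(text.splitlines(), "subfp_dictionary.tsv")


def fingerprint(compound: Compound, dictionary: FragmentDictionary | None = None) -> np.ndarray:
    """Binary presence vector over the dictionary's fragment ids."""
    dictionary = dictionary or load_default_dictionary()
    mol = compound.mol
    return np.array(
        [int(mol.HasSubstructMatch(e.query)) for e in dictionary.entries], dtype=int
    )


def fragment_frequency(
    n_fragment_class: int, n_class: int, n_fragment_total: int, n_total: int
) -> float:
    """Class-enrichment ratio of a fragment; 1.0 means no enrichment."""
    if n_fragment_total <= 0 or n_class <= 0:
        raise ValidationError(
            "fragment frequency undefined: fragment absent from the data or empty class"
        )
    if n_fragment_class > min(n_class, n_fragment_total) or n_total < n_fragment_total:
        raise ValidationError("inconsistent fragment counts")
    return (n_fragment_class * n_total) / (n_fragment_total * n_class)


@dataclass(frozen=True)
class FragmentStats:
    fragment_id: str
    name: str
    n_active_with: int
    n_inactive_with: int
    n_active: int
    n_inactive: int
    frequency_active: float
    frequency_inactive: float
    p_value: float


def enrichment_table(
    compounds: Sequence[Compound],
    labels: Sequence[int],
    dictionary: FragmentDictionary | None = None,
    alpha: float = 0.01,
    bh_correct: bool = False,
) -> list[FragmentStats]:
    """Per-fragment class frequencies with a Fisher-exact significance filter.

    ``labels`` are 1 for actives, 0 for inactives; both classes must be
    non-empty. Unparseable compounds are excluded with a log entry. Returns
    fragments with (optionally Benjamini-Hochberg-adjusted) p < ``alpha``,
    sorted by active-class frequency descending.
    """
    if len(compounds) != len(labels):
        raise ValidationError("compounds and labels differ in length")
    dictionary = dictionary or load_default_dictionary()
    labels = np.asarray(labels, dtype=int)

    kept_rows, kept_labels = [], []
    for c, y in zip(compounds, labels):
        if not c.parses():
            logger.error("compound %s: structure does not parse; excluded", c.compound_id)
            continue
        kept_rows.append(fingerprint(c, dictionary))
        kept_labels.append(y)
    y = np.array(kept_labels, dtype=int)
    if y.size == 0 or y.min() == y.max():
        raise ValidationError("both activity classes must be non-empty")
    X = np.vstack(kept_rows)

    n_active = int(y.sum())
    n_inactive = int((1 - y).sum())
    n_total = n_active + n_inactive

    raw = []
    for j, entry in enumerate(dictionary.entries):
        with_frag = X[:, j]
        n_ft = int(with_frag.sum())
        if n_ft == 0:
            continue  # absent fragment: frequency undefined, reported as absent
        n_fa = int(with_frag[y == 1].sum())
        n_fi = n_ft - n_fa
        table = [[n_fa, n_active - n_fa], [n_fi, n_inactive - n_fi]]
        _, p = fisher_exact(table, alternative="two-sided")
        raw.append(
            FragmentStats(
                fragment_id=entry.fragment_id,
                name=entry.name,
                n_active_with=n_fa,
                n_inactive_with=n_fi,
                n_active=n_active,
                n_inactive=n_inactive,
                frequency_active=fragment_frequency(n_fa, n_active, n_ft, n_total),
                frequency_inactive=fragment_frequency(n_fi, n_inactive, n_ft, n_total),
                p_value=float(p),
            )
        )

    if bh_correct and raw:
        order = np.argsort([s.p_value for s in raw])
        m = len(raw)
        adj = np.empty(m)
        prev = 1.0
        for rank_pos in range(m - 1, -1, -1):
            idx = order[rank_pos]
            prev = min(prev, raw[idx].p_value * m / (rank_pos + 1))
            adj[idx] = prev
        significant = [s for s, q in zip(raw, adj) if q < alpha]
    else:
        significant = [s for s in raw if s.p_value < alpha]

    return sorted(significant, key=lambda s: (-s.frequency_active, s.fragment_id))


def write_enrichment_csv(stats: Iterable[FragmentStats], path: str | Path) -> None:
    """CSV report: name, frequency in inhibitors / non-inhibitors, counts, p-value."""
    import pandas as pd

    pd.DataFrame(
        [
            (
                s.fragment_id,
                s.name,
                s.frequency_active,
                s.frequency_inactive,
                s.n_active_with,
                s.n_inactive_with,
                s.n_active,
                s.n_inactive,
                s.p_value,
            )
            for s in stats
        ],
        columns=[
            "fragment_id",
            "name",
            "frequency_in_inhibitors",
            "frequency_in_noninhibitors",
            "n_inhibitors_with_fragment",
            "n_noninhibitors_with_fragment",
            "n_inhibitors",
            "n_noninhibitors",
            "p_value",
        ],
    ).to_csv(path, index=False)
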