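"""SMARTS structural-alert filtering and the Lipinski drug-likeness check.

Five named alert families are bundled (PAINS-, Glaxo-, Oprea-, Pfizer LINT-
and ALARM NMR-style); each is a small representative demonstration subset
written for this package, and complete curated lists can be loaded from user
files in the same plain-text format. A compound fails a filter set when any of
its patterns matches as a substructure, and passes overall only when it
matches no pattern in any set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

from rdkit import Chem

from .chem import Compound
from .errors import ConfigurationError

DEFAULT_FILTER_FILES = {
    "PAINS": "pains.smarts",
    "Glaxo": "glaxo.smarts",
    "ALARM NMR": "alarm_nmr.smarts",
    "Pfizer LINT": "lint.smarts",
    "Oprea": "oprea.smarts",
}

LIPINSKI_LIMITS = {"mw": 500.0, "hbd": 5.0, "hba": 10.0, "logp": 5.0}


@dataclass
class FilterSet:
    """A named set of structural-alert SMARTS patterns."""

    name: str
    patterns: list[tuple[str, str]]  # (pattern_name, SMARTS)
    _queries: list[tuple[str, Chem.Mol]] = field(default_factory=list, repr=False)

    def __post_init__(self):
        names = [n for n, _ in self.patterns]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate pattern names in filter set {self.name!r}")
        self._queries = []
        for pname, smarts in self.patterns:
            query = Chem.MolFromSmarts(smarts)
            if query is None:
                raise ConfigurationError(
                    f"filter set {self.name!r}: SMARTS for {pname!r} does not compile: {smarts!r}"
                )
            self._queries.append((pname, query))

    def matches(self, mol: Chem.Mol) -> list[str]:
        """Names of the patterns that match ``mol`` as a substructure."""
        return [pname for pname, query in self._queries if mol.HasSubstructMatch(query)]


def load_filter_file(path: str | Path, name: str | None = None) -> FilterSet:
    """Read a ``name<TAB>SMARTS`` filter file ('#' comments allowed)."""
    patterns = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ConfigurationError(f"{path}:{lineno}: expected 'name<TAB>SMARTS'")
        patterns.append((parts[0], parts[1]))
    return FilterSet(name=name or Path(path).stem, patterns=patterns)


def load_default_filter_sets() -> list[FilterSet]:
    sets = []
    for name, filename in DEFAULT_FILTER_FILES.items():
        text = resources.files("steptriage.data").joinpath(filename).read_text()
        patterns = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pname, smarts = line.split("\t")
            patterns.append((pname, smarts))
        sets.append(FilterSet(name=name, patterns=patterns))
    return sets


@dataclass
class FilterReport:
    """Per-compound and per-set outcome of structural-alert filtering.

    ``fail_counts``/``fail_percentages`` are per filter set, computed over all
    parseable input compounds (a compound matching several sets is counted in
    each of them, so the per-set percentages can sum past 100). ``errors``
    lists compounds whose structures did not parse; they are excluded from the
    percentages.
    """

    per_compound: dict[str, dict[str, list[str]]]  # id -> set name -> matched patterns
    passed: list[str]
    failed: list[str]
    errors: list[str]
    fail_counts: dict[str, int]
    fail_percentages: dict[str, float]
    n_evaluated: int

    def passes(self, compound_id: str) -> bool:
        return compound_id in set(self.passed)

    def to_json_dict(self) -> dict:
        return {
            "n_evaluated": self.n_evaluated,
            "n_passed": len(self.passed),
            "n_failed": len(self.failed),
            "n_errors": len(self.errors),
            "fail_counts": self.fail_counts,
            "fail_percentages": self.fail_percentages,
            "passed": self.passed,
        }


def apply_filters(
    compounds: Sequence[Compound], filter_sets: Sequence[FilterSet] | None = None
) -> FilterReport:
    """Run every compound through every filter set.

    A compound fails a set iff at least one of the set's patterns matches;
    the overall pass list contains compounds matching no pattern in any set.
    """
    if filter_sets is None:
        filter_sets = load_default_filter_sets()
    per_compound: dict[str, dict[str, list[str]]] = {}
    passed, failed, errors = [], [], []
    fail_counts = {fs.name: 0 for fs in filter_sets}
    for c in compounds:
        if not c.parses():
            errors.append(c.compound_id)
            continue
        hits = {}
        for fs in filter_sets:
            matched = fs.matches(c.mol)
            if matched:
                hits[fs.name] = matched
                fail_counts[fs.name] += 1
        per_compound[c.compound_id] = hits
        (failed if hits else passed).append(c.compound_id)
    n_eval = len(passed) + len(failed)
    fail_percentages = {
        name: (100.0 * count / n_eval if n_eval else 0.0)
        for name, count in fail_counts.items()
    }
    return FilterReport(
        per_compound=per_compound,
        passed=passed,
        failed=failed,
        errors=errors,
        fail_counts=fail_counts,
        fail_percentages=fail_percentages,
        n_evaluated=n_eval,
    )


def write_filter_report_csv(report: FilterReport, path: str | Path) -> None:
    import pandas as pd

    set_names = sorted(report.fail_counts)
    rows = []
    for cid, hits in report.per_compound.items():
        row = {"compound_id": cid, "passed": not hits}
        for name in set_names:
            row[f"fails_{name}"] = name in hits
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def lipinski(
    mw: float, hbd: float, hba: float, logp: float
) -> tuple[bool, list[str]]:
    """Rule-of-five check: violations are MW > 500, HBD > 5, HBA > 10, logP > 5.

    ``hba`` may be fractional (averaged acceptor counts are commonplace in
    screening reports). Returns (pass, violation list); pass means none.
    """
    values = {"mw": mw, "hbd": hbd, "hba": hba, "logp": logp}
    violations = [
        f"{key} > {LIPINSKI_LIMITS[key]:g}"
        for key in ("mw", "hbd", "hba", "logp")
        if values[key] > LIPINSKI_LIMITS[key]
    ]
    return len(violations) == 0, violations


def lipinski_for_compound(compound: Compound) -> tuple[bool, list[str]]:
    """Lipinski check with properties computed from the structure."""
    from .descriptors import property_descriptors

    props = property_descriptors(compound)
    return lipinski(mw=props[0], hbd=props[2], hba=props[3], logp=props[1])
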