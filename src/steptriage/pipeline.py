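"""End-to-end triage funnel with a JSON run configuration and a manifest.

Stage order follows the screening methodology: ingest or generate the library,
label activity, compute descriptors, drop near-constant columns, select a
descriptor subset, tune the FN cost per learner family against the FP-rate
ceiling, cross-validate, predict on the screening library, form the consensus
active set, apply the structural-alert filters and the Lipinski check, and
tabulate fragment enrichment. Every stage writes its outputs under the run
directory and records its counts in ``manifest.json``; re-running an identical
configuration reproduces identical outputs (the manifest timestamp aside).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path


from . import bioassay, chem, chem_filters, classify, evaluate, feature_selection, fragments
from .descriptors import descriptor_table
from .errors import ConfigurationError
from .synthetic_data import LibrarySpec, generate_library, write_assay_csv

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``RunConfig.from_json``)."""

    seed: int
    output_dir: str
    synthetic: dict | None = None           # LibrarySpec fields (seed defaults to run seed)
    smiles_path: str | None = None          # alternative to synthetic
    assay_path: str | None = None
    learner_families: list[str] = field(
        default_factory=lambda: list(classify.LEARNER_FAMILIES)
    )
    fp_ceiling: float = 0.20
    folds: int = 5
    max_identical_fraction: float = 0.99
    selection_direction: str = "forward"
    selection_stale_limit: int = 5
    filter_set_paths: list[str] | None = None  # None -> bundled five sets
    dictionary_path: str | None = None         # None -> bundled dictionary
    enrichment_alpha: float = 0.01
    smarts_stage: str = "after_consensus"      # or "before_consensus"

    def validate(self) -> None:
        if self.folds < 2:
            raise ConfigurationError("folds must be >= 2")
        if not 0.0 < self.fp_ceiling < 1.0:
            raise ConfigurationError("fp_ceiling must be in (0, 1)")
        if self.smarts_stage not in ("after_consensus", "before_consensus"):
            raise ConfigurationError(f"unknown smarts_stage {self.smarts_stage!r}")
        unknown = set(self.learner_families) - set(classify.LEARNER_FAMILIES)
        if unknown:
            raise ConfigurationError(f"unknown learner families: {sorted(unknown)}")
        if self.synthetic is None and (self.smiles_path is None or self.assay_path is None):
            raise ConfigurationError(
                "either a synthetic library spec or smiles_path + assay_path is required"
            )
        for path_attr in ("smiles_path", "assay_path", "dictionary_path"):
            p = getattr(self, path_attr)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{path_attr} does not exist: {p}")
        for p in self.filter_set_paths or []:
            if not Path(p).exists():
                raise ConfigurationError(f"filter set file does not exist: {p}")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        if "seed" not in payload:
            raise ConfigurationError("run configuration must set a seed")
        cfg = cls(**payload)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full funnel; returns the run directory containing the manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
    }
    stage = "ingest"
    try:
        # ingest / generate ------------------------------------------------
        if config.synthetic is not None:
            spec_fields = dict(config.synthetic)
            spec_fields.setdefault("seed", config.seed)
            spec = LibrarySpec(**spec_fields)
            compounds, records = generate_library(spec)
            chem.write_smiles_file(compounds, out / "library.smi")
            write_assay_csv(records, out / "assay.csv")
        else:
            compounds = chem.read_smiles_file(config.smiles_path)
            records = bioassay.read_assay_csv(config.assay_path)
            manifest["inputs"] = {
                "smiles_sha256": _sha256(Path(config.smiles_path)),
                "assay_sha256": _sha256(Path(config.assay_path)),
            }
        bioassay.write_labeled_csv(records, out / "assay_labeled.csv")
        n_active = sum(1 for r in records if r.activity_class == "active")
        manifest["stages"]["ingest"] = {
            "n_compounds": len(compounds),
            "n_active": n_active,
            "n_inactive": len(records) - n_active,
        }

        # descriptors ------------------------------------------------------
        stage = "descriptors"
        table = descriptor_table(compounds)
        labels = bioassay.labels_for(records, table.compound_ids)
        table.write_csv(out / "descriptors_full.csv")
        manifest["stages"]["descriptors"] = {
            "n_columns": len(table.columns),
            "schema_version": SCHEMA_VERSION,
        }

        stage = "remove_useless"
        reduced = bioassay.remove_useless(table, config.max_identical_fraction)
        reduced.write_csv(out / "descriptors_reduced.csv")
        manifest["stages"]["remove_useless"] = {"n_columns": len(reduced.columns)}

        # selection --------------------------------------------------------
        stage = "feature_selection"
        selection = feature_selection.best_first_search(
            reduced,
            labels,
            direction=config.selection_direction,
            stale_limit=config.selection_stale_limit,
        )
        feature_selection.write_selected(selection, out / "selected_descriptors.txt")
        selected = reduced.select(list(selection.subset))
        manifest["stages"]["feature_selection"] = {
            "n_selected": selection.k,
            "merit": selection.merit,
        }

        # cost tuning + CV evaluation + prediction -------------------------
        stage = "classification"
        metric_rows = {}
        active_sets: list[set[str]] = []
        tuned = {}
        for family in config.learner_families:
            model, c_fn, cv_cm = classify.tune_fn_cost(
                family, selected, labels,
                fp_ceiling=config.fp_ceiling, folds=config.folds, seed=config.seed,
            )
            pooled, _, auc = evaluate.cross_validate(
                family, selected, labels,
                cost=model.cost, folds=config.folds, seed=config.seed,
            )
            metric_rows[family] = (pooled, evaluate.metrics(pooled, auc=auc))
            model.save(out / f"model_{family}.pkl")
            pred, _ = classify.predict(model, selected)
            active_sets.append(
                {cid for cid, p in zip(selected.compound_ids, pred) if p == 1}
            )
            tuned[family] = {
                "c_fn": c_fn,
                "cv_fp_rate": cv_cm.fp_rate,
                "n_predicted_active": len(active_sets[-1]),
                "warning": model.warning,
            }
        evaluate.write_metric_table(metric_rows, out / "cv_metrics.tsv")
        evaluate.write_metric_json(metric_rows, out / "cv_metrics.json")
        manifest["stages"]["classification"] = tuned

        # consensus + structural filters ------------------------------------
        stage = "consensus_and_filters"
        filter_sets = (
            [chem_filters.load_filter_file(p) for p in config.filter_set_paths]
            if config.filter_set_paths
            else chem_filters.load_default_filter_sets()
        )
        by_id = {c.compound_id: c for c in compounds}
        if config.smarts_stage == "before_consensus":
            filtered_sets = []
            for s in active_sets:
                report = chem_filters.apply_filters([by_id[i] for i in sorted(s)], filter_sets)
                filtered_sets.append(set(report.passed))
            consensus_ids = evaluate.consensus(filtered_sets)
            filter_report = chem_filters.apply_filters(
                [by_id[i] for i in sorted(consensus_ids)], filter_sets
            )
            pass_ids = sorted(consensus_ids)
        else:
            consensus_ids = evaluate.consensus(active_sets)
            filter_report = chem_filters.apply_filters(
                [by_id[i] for i in sorted(consensus_ids)], filter_sets
            )
            pass_ids = sorted(filter_report.passed)
        chem_filters.write_filter_report_csv(filter_report, out / "filter_report.csv")
        (out / "filter_report.json").write_text(
            json.dumps(filter_report.to_json_dict(), indent=2) + "\n"
        )

        stage = "lipinski"
        druglike = []
        for cid in pass_ids:
            ok, violations = chem_filters.lipinski_for_compound(by_id[cid])
            if ok:
                druglike.append(cid)
        final = [by_id[cid] for cid in druglike]
        chem.write_smiles_file(final, out / "final_candidates.smi")
        chem.write_sdf(final, out / "final_candidates.sdf")
        manifest["stages"]["funnel"] = {
            "n_consensus_active": len(consensus_ids),
            "n_smarts_pass": len(pass_ids),
            "n_lipinski_pass": len(druglike),
        }

        # fragment enrichment ------------------------------------------------
        stage = "fragments"
        dictionary = (
            fragments.load_dictionary(config.dictionary_path)
            if config.dictionary_path
            else fragments.load_default_dictionary()
        )
        stats = fragments.enrichment_table(
            compounds, labels, dictionary, alpha=config.enrichment_alpha
        )
        fragments.write_enrichment_csv(stats, out / "fragment_enrichment.csv")
        manifest["stages"]["fragments"] = {"n_significant": len(stats)}
    except Exception as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
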