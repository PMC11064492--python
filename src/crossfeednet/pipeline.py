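"""End-to-end orchestration: encode -> folds -> cross-validate -> report.

A single JSON config drives a full run; every intermediate artifact is
persisted with a content hash so stages can be re-run from disk and mixing
artifacts from different pools is refused.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

from ._exceptions import StageError, ValidationError
from .classifiers import ClassifierSpec
from .encoding import augment_dataset, build_reaction_pool, encode_profile
from .folding import assemble_folds, audit_leakage, cluster_pairs
from .model import InteractionModel

logger = logging.getLogger(__name__)

DEFAULT_STAGES = ("encode", "folds", "cross_validate", "report")


@dataclass
class RunConfig:
    """Validated configuration of one experiment run."""

    pool_path: Path
    networks_dir: Path
    interactions_path: Path
    out_dir: Path
    stages: tuple[str, ...] = DEFAULT_STAGES
    classifier_family: str = "knn"
    classifier_params: dict = field(default_factory=lambda: {"k": 3})
    n_clusters: int = 10
    n_folds: int = 4
    seed: int = 0

    @classmethod
    def from_json(cls, obj: dict) -> "RunConfig":
        if "seed" not in obj:
            raise ValidationError("config must set a seed")
        return cls(
            pool_path=Path(obj["pool"]),
            networks_dir=Path(obj["networks"]),
            interactions_path=Path(obj["interactions"]),
            out_dir=Path(obj["out_dir"]),
            stages=tuple(obj.get("stages", DEFAULT_STAGES)),
            classifier_family=obj.get("classifier", {}).get("family", "knn"),
            classifier_params=obj.get("classifier", {}).get("params", {"k": 3}),
            n_clusters=int(obj.get("n_clusters", 10)),
            n_folds=int(obj.get("n_folds", 4)),
            seed=int(obj["seed"]),
        )

    def validate(self) -> None:
        for path in (self.pool_path, self.networks_dir, self.interactions_path):
            if not Path(path).exists():
                raise ValidationError(f"path does not exist: {path}")
        unknown = set(self.stages) - set(DEFAULT_STAGES)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")


def _file_hash(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def load_networks(networks_dir: Path):
    """Read every reaction network (plain list or SBML) in a directory."""
    from . import io as io_formats

    organisms = []
    for path in sorted(Path(networks_dir).iterdir()):
        if path.suffix in (".txt", ".tsv", ".list"):
            organisms.append(io_formats.read_reaction_list(path))
        elif path.suffix in (".xml", ".sbml"):
            organisms.append(io_formats.read_sbml_reactions(path))
    if not organisms:
        raise ValidationError(f"no network files found under {networks_dir}")
    return organisms


def run_experiment(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the run report.

    Any stage failure raises ``StageError`` naming the stage; artifacts
    written by earlier stages are left on disk.
    """
    from . import io as io_formats

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "stages": list(config.stages),
        "classifier": {"family": config.classifier_family, "params": config.classifier_params},
        "artifacts": {},
    }

    dataset = None
    try:
        reference = io_formats.read_reference_pool(config.pool_path)
        organisms = load_networks(config.networks_dir)
        records = io_formats.read_interaction_table(config.interactions_path)
        pool = build_reaction_pool(reference, organisms)
        profiles = {o.organism_id: encode_profile(o, pool) for o in organisms}
        dataset = augment_dataset(records, profiles, pool)
        report["pool_hash"] = pool.content_hash
        report["P"] = len(pool)
        report["n_vectors"] = len(dataset)
        report["class_counts"] = dataset.class_counts
        if "encode" in config.stages:
            ds_path = out / "dataset.tsv.gz"
            io_formats.write_pair_dataset(dataset, ds_path)
            report["artifacts"]["dataset"] = {"path": str(ds_path), "sha256": _file_hash(ds_path)}
            logger.info("encode: %d vectors of length %d", len(dataset), 2 * len(pool))
    except StageError:
        raise
    except Exception as exc:
        raise StageError("encode", str(exc)) from exc

    folds = None
    if "folds" in config.stages:
        try:
            clusters = cluster_pairs(dataset, n_clusters=config.n_clusters, seed=config.seed)
            folds = assemble_folds(clusters, dataset, n_folds=config.n_folds)
            audit = audit_leakage(folds, dataset)
            folds_path = out / "folds.json"
            io_formats.write_json(
                {**folds.to_json(), "audit": audit.to_json()}, folds_path
            )
            report["artifacts"]["folds"] = {"path": str(folds_path),
                                            "sha256": _file_hash(folds_path)}
            report["leakage_audit"] = audit.to_json()
            logger.info("folds: %d folds, audit %s", folds.n_folds,
                        "clean" if audit.ok else "VIOLATIONS")
        except Exception as exc:
            raise StageError("folds", str(exc)) from exc

    if "cross_validate" in config.stages:
        try:
            spec = ClassifierSpec(config.classifier_family, config.classifier_params,
                                  seed=config.seed)
            model = InteractionModel(dataset, classifier=spec, folds=folds,
                                     n_clusters=config.n_clusters, n_folds=config.n_folds,
                                     seed=config.seed)
            results = model.fit()
            report["results"] = results.to_report()
            logger.info("cross_validate: accuracy %.3f", results.accuracy)
        except Exception as exc:
            raise StageError("cross_validate", str(exc)) from exc

    if "report" in config.stages:
        try:
            report_path = out / "report.json"
            io_formats.write_json(report, report_path)
            report["artifacts"]["report"] = {"path": str(report_path),
                                             "sha256": _file_hash(report_path)}
        except Exception as exc:
            raise StageError("report", str(exc)) from exc
    return report
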