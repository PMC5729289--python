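"""End-to-end orchestration: discover modules, train a predictor, validate it.

The three phases mirror the study workflow: ``run_discover`` turns a PPI
edge list into GTOM-derived sub-modules; ``run_train`` scores a training
cohort, screens treatment-interaction modules, clusters patients, selects a
minimal panel by backward-elimination random forest, and trains the final
predictor; ``run_validate`` applies a trained predictor to an independent
cohort and evaluates the treatment benefit in each predicted sub-group.
In-memory variants (``discover_modules``, ``train_signature``,
``validate_signature``) back the file-based runners and are the interface
used programmatically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pickle
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .gsva import GsvaParams, GsvaProfile, gsva_profile
from .modules import (
    ModuleSet,
    dynamic_tree_cut,
    hierarchical_cluster,
    modules_to_gene_sets,
    read_gmt,
    write_gmt,
)
from .network import PPINetwork, compute_gtom, gtom_dissimilarity, parse_ppi_edgelist
from .prep import (
    ClinicalTable,
    ExpressionMatrix,
    check_sample_alignment,
    map_modules_to_expression,
    read_clinical,
    read_expression,
)
from .signature import (
    BenefitReport,
    Predictor,
    SelectionTrace,
    cluster_patients,
    evaluate_benefit,
    predict_cohort,
    rf_backward_select,
    roc_auc,
    train_predictor,
)
from .survival import ScreenResult, interaction_screen

__all__ = [
    "RunConfig",
    "NoModulesSelectedError",
    "discover_modules",
    "train_signature",
    "validate_signature",
    "run_discover",
    "run_train",
    "run_validate",
    "save_predictor",
    "load_predictor",
    "TrainResult",
    "ValidationResult",
]


class NoModulesSelectedError(RuntimeError):
    """The interaction screen selected no module at the FDR threshold."""


@dataclass
class RunConfig:
    """All pipeline inputs and tunables; defaults are the study settings.

    Network: 2-step GTOM, tree cut at height 0.6, minimum module size 5,
    deep split on.  Expression: detection fraction 0.2, minimum 2 mapped
    genes per module.  Modeling: FDR 0.05 on the interaction screen, two
    patient clusters, random forests of 5000/3000 trees dropping 20% of
    modules per iteration, probability cut-off 0.5.
    """

    network_path: str | None = None
    expression_path: str | None = None
    clinical_path: str | None = None
    detection_path: str | None = None
    modules_path: str | None = None
    output_dir: str = "ppisig_out"

    edgelist_columns: str | tuple[int, int] = "simple"
    gtom_steps: int = 2
    cut_height: float = 0.6
    min_module_size: int = 5
    deep_split: bool = True
    detection_fraction: float = 0.2
    min_mapped_genes: int = 2
    gsva_tau: float = 1.0
    fdr_threshold: float = 0.05
    n_clusters: int = 2
    ntree_first: int = 5000
    ntree_iter: int = 3000
    drop_fraction: float = 0.2
    importance_repeats: int = 5
    probability_cutoff: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def gsva_params(self) -> GsvaParams:
        return GsvaParams(tau=self.gsva_tau)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_manifest(out: Path, stage: str, config: RunConfig, inputs: dict,
                    counts: dict, elapsed: float) -> None:
    manifest = {
        "stage": stage,
        "version": __version__,
        "config": dataclasses.asdict(config),
        "input_checksums": {k: _sha256(v) for k, v in inputs.items() if v},
        "record_counts": counts,
        "wall_clock_seconds": round(elapsed, 3),
    }
    out.mkdir(parents=True, exist_ok=True)
    (out / f"manifest_{stage}.json").write_text(
        json.dumps(manifest, indent=1, default=str)
    )


# ---------------------------------------------------------------------------
# in-memory pipeline


def discover_modules(
    network: PPINetwork,
    gtom_steps: int = 2,
    cut_height: float = 0.6,
    min_module_size: int = 5,
    deep_split: bool = True,
) -> ModuleSet:
    """PPI network -> GTOM -> dendrogram -> dynamic tree cut -> ModuleSet."""
    gtom = compute_gtom(network, m=gtom_steps)
    dend = hierarchical_cluster(
        gtom_dissimilarity(gtom), leaf_ids=gtom.node_order
    )
    assignment = dynamic_tree_cut(
        dend,
        max_height=cut_height,
        min_size=min_module_size,
        deep_split=deep_split,
    )
    return modules_to_gene_sets(
        assignment,
        gtom.node_order,
        provenance={"gtom_steps": gtom_steps, "n_nodes": network.n_nodes},
    )


@dataclass
class TrainResult:
    profile: GsvaProfile
    screen: ScreenResult
    cluster_labels: pd.Series
    trace: SelectionTrace
    predictor: Predictor
    training_predictions: pd.DataFrame
    roc: object
    benefit: BenefitReport


def train_signature(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    modules: ModuleSet,
    config: RunConfig = RunConfig(),
) -> TrainResult:
    """Full training phase on one cohort.

    Maps modules onto the measured genes, computes the module x sample
    profile, screens treatment x module interactions (BH FDR), clusters
    patients on the screened modules, selects a minimal panel by
    backward-elimination random forest (OOB 1-SE rule), trains the final
    predictor, and evaluates OOB ROC/AUC and per-cluster treatment benefit.
    Raises :class:`NoModulesSelectedError` if the screen is empty.
    """
    check_sample_alignment(expr.samples, clinical)
    mapped = map_modules_to_expression(modules, expr, config.min_mapped_genes)
    profile = gsva_profile(expr, mapped, config.gsva_params())
    screen = interaction_screen(
        profile, clinical, fdr_threshold=config.fdr_threshold
    )
    selected = screen.selected_modules
    if not selected:
        raise NoModulesSelectedError(
            f"no module passed the interaction screen at FDR "
            f"{config.fdr_threshold} (smallest q = "
            f"{screen.table['q'].min() if len(screen.table) else 'n/a'})"
        )
    screened_profile = profile.subset(selected)
    clustering = cluster_patients(screened_profile, k=config.n_clusters)
    trace = rf_backward_select(
        screened_profile.values,
        clustering.labels.to_numpy(),
        ntree_first=config.ntree_first,
        ntree_iter=config.ntree_iter,
        drop_fraction=config.drop_fraction,
        seed=config.seed,
        importance_repeats=config.importance_repeats,
    )
    panel = trace.chosen_features
    predictor = train_predictor(
        profile.subset(panel).values,
        clustering.labels.to_numpy(),
        ntree=config.ntree_first,
        seed=config.seed,
        cutoff=config.probability_cutoff,
    )
    predictions = predict_cohort(predictor, profile)
    oob = predictor.oob_probabilities
    roc = roc_auc(oob.to_numpy(), (clustering.labels == 1).astype(int).to_numpy())
    oob_labels = pd.Series(
        (oob > config.probability_cutoff).map({True: 1, False: 2}),
        index=oob.index,
        name="cluster",
    )
    benefit = evaluate_benefit(clinical, oob_labels)
    return TrainResult(
        profile=profile,
        screen=screen,
        cluster_labels=clustering.labels,
        trace=trace,
        predictor=predictor,
        training_predictions=predictions,
        roc=roc,
        benefit=benefit,
    )


@dataclass
class ValidationResult:
    profile: GsvaProfile
    predictions: pd.DataFrame
    benefit: BenefitReport


def validate_signature(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    modules: ModuleSet,
    predictor: Predictor,
    config: RunConfig = RunConfig(),
) -> ValidationResult:
    """Apply a trained predictor to an independent cohort."""
    check_sample_alignment(expr.samples, clinical)
    mapped = map_modules_to_expression(modules, expr, config.min_mapped_genes)
    missing = [m for m in predictor.modules if m not in mapped.sets]
    if missing:
        raise ValueError(
            f"validation expression lacks selected module(s): {missing}"
        )
    profile = gsva_profile(expr, mapped, config.gsva_params())
    predictions = predict_cohort(predictor, profile)
    benefit = evaluate_benefit(clinical, predictions["cluster"])
    return ValidationResult(
        profile=profile, predictions=predictions, benefit=benefit
    )


# ---------------------------------------------------------------------------
# predictor persistence


def save_predictor(predictor: Predictor, path: str | Path) -> None:
    """Persist panel + model + cut-off with an integrity checksum."""
    blob = pickle.dumps(
        {
            "modules": predictor.modules,
            "model": predictor.model,
            "cutoff": predictor.cutoff,
            "version": __version__,
        }
    )
    payload = hashlib.sha256(blob).hexdigest().encode() + b"\n" + blob
    Path(path).write_bytes(payload)


def load_predictor(path: str | Path) -> Predictor:
    payload = Path(path).read_bytes()
    digest, _, blob = payload.partition(b"\n")
    if hashlib.sha256(blob).hexdigest().encode() != digest:
        raise ValueError("predictor archive is corrupted (checksum mismatch)")
    data = pickle.loads(blob)
    return Predictor(
        modules=data["modules"], model=data["model"], cutoff=data["cutoff"]
    )


# ---------------------------------------------------------------------------
# file-based runners


def run_discover(config: RunConfig) -> ModuleSet:
    """Edge list on disk -> module GMT + manifest in the output directory."""
    if not config.network_path or not Path(config.network_path).exists():
        raise FileNotFoundError(f"network input not found: {config.network_path}")
    t0 = time.perf_counter()
    network = parse_ppi_edgelist(config.network_path, columns=config.edgelist_columns)
    modules = discover_modules(
        network,
        gtom_steps=config.gtom_steps,
        cut_height=config.cut_height,
        min_module_size=config.min_module_size,
        deep_split=config.deep_split,
    )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_gmt(modules, out / "modules.gmt")
    _write_manifest(
        out,
        "discover",
        config,
        {"network": config.network_path},
        {
            "nodes": network.n_nodes,
            "edges": network.n_edges,
            "modules": len(modules),
            "assigned_proteins": sum(modules.sizes().values()),
        },
        time.perf_counter() - t0,
    )
    return modules


def _load_cohort(config: RunConfig) -> tuple[ExpressionMatrix, ClinicalTable]:
    for attr in ("expression_path", "clinical_path"):
        p = getattr(config, attr)
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"{attr} not found: {p}")
    expr = read_expression(config.expression_path)
    if config.detection_path:
        from .prep import filter_by_detection, read_detection

        det = read_detection(config.detection_path)
        expr = filter_by_detection(expr, det, config.detection_fraction)
    clinical = read_clinical(config.clinical_path)
    return expr, clinical


def run_train(config: RunConfig) -> TrainResult:
    """Training phase from files; writes reports, predictor, and manifest."""
    if not config.modules_path or not Path(config.modules_path).exists():
        raise FileNotFoundError(f"modules GMT not found: {config.modules_path}")
    t0 = time.perf_counter()
    expr, clinical = _load_cohort(config)
    modules = read_gmt(config.modules_path)
    result = train_signature(expr, clinical, modules, config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.profile.to_tsv(out / "training_profile.tsv")
    result.screen.to_tsv(out / "screen.tsv")
    result.trace.steps.drop(columns="members").to_csv(
        out / "selection_trace.tsv", sep="\t", index=False
    )
    result.training_predictions.to_csv(
        out / "training_predictions.tsv", sep="\t", index_label="id"
    )
    result.benefit.to_frame().to_csv(out / "training_benefit.tsv", sep="\t", index=False)
    save_predictor(result.predictor, out / "predictor.bin")
    panel = ModuleSet(
        sets={m: modules[m] for m in result.predictor.modules},
        provenance={"description": "selected panel"},
    )
    write_gmt(panel, out / "panel.gmt")
    _write_manifest(
        out,
        "train",
        config,
        {
            "expression": config.expression_path,
            "clinical": config.clinical_path,
            "modules": config.modules_path,
        },
        {
            "samples": len(expr.samples),
            "modules_screened": len(result.screen.table),
            "modules_selected_fdr": len(result.screen.selected_modules),
            "panel_size": len(result.predictor.modules),
        },
        time.perf_counter() - t0,
    )
    return result


def run_validate(config: RunConfig, predictor_path: str | Path) -> ValidationResult:
    """Validation phase from files; writes predictions, benefit report, manifest."""
    t0 = time.perf_counter()
    expr, clinical = _load_cohort(config)
    modules = read_gmt(config.modules_path)
    predictor = load_predictor(predictor_path)
    result = validate_signature(expr, clinical, modules, predictor, config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.predictions.to_csv(out / "validation_predictions.tsv", sep="\t",
                              index_label="id")
    result.benefit.to_frame().to_csv(
        out / "validation_benefit.tsv", sep="\t", index=False
    )
    _write_manifest(
        out,
        "validate",
        config,
        {
            "expression": config.expression_path,
            "clinical": config.clinical_path,
            "predictor": str(predictor_path),
        },
        {"samples": len(expr.samples)},
        time.perf_counter() - t0,
    )
    return result
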