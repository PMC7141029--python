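"""Three-stage discovery → training → validation orchestration.

Discovery compares promoter coverage between a small case/control subset
(default 10 vs 10, reused inside the training cohort) and keeps promoters
with FDR <= 0.1 and |log2FC| >= 1.  Training discretizes the surviving
promoters at their optimal cutoffs, runs stepwise logistic selection, and
scores the model by leave-one-out cross-validated ROC.  Validation applies
the frozen model (features, cutoffs, coefficients, threshold unchanged) to
disjoint cohorts.  Variants restrict the candidate pool to tissue-specific
gene lists (set-P/W/PW) or append pre-pregnancy BMI as a raw covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation import PromoterWindow, build_ptss_windows, read_annotation
from .coverage import (
    ConfigurationError,
    CoverageMatrix,
    FragmentSet,
    MetageneProfile,
    build_coverage_matrix,
    metagene_profile,
    read_fragments_bed,
)
from .differential import select_differential
from .classifier import (
    PromoterClassifier,
    RocResult,
    binarize,
    compare_auc,
    fit_logistic,
    learn_discretization,
    loocv_probabilities,
    predict,
    roc_analysis,
    stepwise_select,
)

logger = logging.getLogger("promoterfoot")

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_discovery",
    "run_training",
    "run_validation",
    "run_geneset_classifier",
    "run_bmi_combination",
    "run_expression_validation",
    "load_cohort",
    "classifier_feature_frame",
]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Pipeline thresholds and options; all values are logged when used."""

    flank: int = 1000
    fdr_max: float = 0.1
    lfc_min: float = 1.0
    pseudocount: float = 0.01
    discovery_n_cases: int = 10
    discovery_n_controls: int = 10
    max_features: int = 15
    loocv_mode: str = "fixed"  # "fixed": refit coefficients only; "strict": redo selection per fold
    bin_size: int = 20
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.flank <= 0 or self.fdr_max <= 0 or self.lfc_min < 0:
            raise ValueError("thresholds must be positive")
        if self.loocv_mode not in ("fixed", "strict"):
            raise ValueError("loocv_mode must be 'fixed' or 'strict'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------

def load_cohort(
    directory: str | Path, flank: int = 1000
) -> tuple[list[PromoterWindow], list[FragmentSet], pd.DataFrame]:
    """Load fixture-style cohort: annotation TSV, metadata TSV, per-sample BED."""
    directory = Path(directory)
    transcripts = read_annotation(directory / "annotation.refflat.tsv", "refflat")
    windows = build_ptss_windows(transcripts, flank=flank)
    metadata = pd.read_csv(directory / "metadata.tsv", sep="\t")
    samples = [
        read_fragments_bed(directory / f"{sid}.bed", sample_id=sid)
        for sid in metadata["sample_id"]
    ]
    return windows, samples, metadata


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def _discovery_subset(matrix: CoverageMatrix, config: PipelineConfig) -> CoverageMatrix:
    meta = matrix.meta
    if "cohort" in meta.columns and (meta["cohort"] == "discovery").any():
        ids = list(meta.index[meta["cohort"] == "discovery"])
    else:
        cases = list(meta.index[meta["label"] == "case"])[: config.discovery_n_cases]
        controls = list(meta.index[meta["label"] == "control"])[
            : config.discovery_n_controls
        ]
        ids = cases + controls
    sub = matrix.subset_samples(ids)
    n_case = int((sub.meta["label"] == "case").sum())
    n_control = int((sub.meta["label"] == "control").sum())
    if n_case < config.discovery_n_cases or n_control < config.discovery_n_controls:
        raise ConfigurationError(
            f"discovery stage needs {config.discovery_n_cases} cases and "
            f"{config.discovery_n_controls} controls; got {n_case}/{n_control}"
        )
    return sub


def run_discovery(matrix: CoverageMatrix, config: PipelineConfig) -> pd.DataFrame:
    """Differential promoter table on the discovery subset.

    The discovery samples are those flagged ``cohort == "discovery"`` in
    the metadata or, absent that, the first configured numbers of cases
    and controls in metadata order (they remain part of training, per the
    three-stage design).
    """
    sub = _discovery_subset(matrix, config)
    logger.info(
        "discovery: %d samples, fdr_max=%g lfc_min=%g",
        len(sub.sample_ids), config.fdr_max, config.lfc_min,
    )
    return select_differential(
        sub,
        fdr_max=config.fdr_max,
        lfc_min=config.lfc_min,
        pseudocount=config.pseudocount,
    )


def _gene_level_features(table: pd.DataFrame) -> pd.DataFrame:
    """One representative window per gene: the smallest discovery p-value."""
    sel = table[table["selected"]]
    if sel.empty:
        return sel
    # table is sorted by p then |lfc|; first occurrence per gene wins
    return sel.drop_duplicates(subset="gene", keep="first")


def _training_path(
    matrix: CoverageMatrix,
    candidates: pd.DataFrame,  # columns: window, gene
    config: PipelineConfig,
    name: str,
    provenance: dict,
    strict_differential: bool = False,
) -> tuple[PromoterClassifier, RocResult]:
    labels = (matrix.meta["label"] == "case").to_numpy()
    gene_of = dict(zip(candidates["window"], candidates["gene"]))
    feature_frame = matrix.values[list(candidates["window"])].rename(columns=gene_of)
    cutoffs = learn_discretization(feature_frame, labels)
    binary = binarize(feature_frame, cutoffs)
    subset = stepwise_select(binary, labels, max_features=config.max_features)
    fit = fit_logistic(binary[subset].to_numpy(), labels) if subset else None
    if config.loocv_mode == "strict":
        probs = _strict_loocv(matrix, candidates, config, strict_differential)
    else:
        probs = loocv_probabilities(binary, labels, subset)
    roc = roc_analysis(probs, labels)
    threshold = float(np.clip(roc.threshold, 1e-6, 1 - 1e-6))
    if fit is None:
        coefficients, intercept = {}, float(np.log(labels.mean() / (1 - labels.mean())))
    else:
        coefficients = dict(zip(subset, fit.coefficients.tolist()))
        intercept = fit.intercept
    model = PromoterClassifier(
        name=name,
        features=list(subset),
        cutoffs={g: cutoffs[g] for g in subset},
        coefficients=coefficients,
        intercept=intercept,
        probability_threshold=threshold,
        provenance={
            **provenance,
            "representative_window": {g: w for w, g in gene_of.items() if g in subset},
            "training_samples": list(matrix.sample_ids),
            "loocv_mode": config.loocv_mode,
            "seed": config.seed,
        },
    )
    return model, roc


def _strict_loocv(
    matrix: CoverageMatrix,
    candidates: pd.DataFrame,
    config: PipelineConfig,
    redo_differential: bool,
) -> np.ndarray:
    """LOOCV re-running the whole selection path inside each fold.

    Per fold: (optionally) differential selection on the n-1 training
    samples, then cutoff learning, stepwise selection, and the coefficient
    fit — the withheld sample touches nothing.  A fold ending up with no
    features predicts the overall prevalence (a constant carries no rank
    information, so it scores AUC 0.5).
    """
    labels = (matrix.meta["label"] == "case").to_numpy()
    n = len(labels)
    prevalence = float(labels.mean())
    probs = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_tr = labels[mask]
        if y_tr.min() == y_tr.max():
            logger.warning("strict LOOCV: fold %d single-class; using prevalence", i)
            probs[i] = prevalence
            continue
        sub = matrix.subset_samples(list(np.array(matrix.sample_ids)[mask]))
        if redo_differential:
            table = select_differential(
                sub, fdr_max=config.fdr_max, lfc_min=config.lfc_min,
                pseudocount=config.pseudocount,
            )
            pool = _gene_level_features(table)[["window", "gene"]] if table["selected"].any() else pd.DataFrame(columns=["window", "gene"])
        else:
            pool = candidates
        if pool.empty:
            probs[i] = prevalence
            continue
        gene_of = dict(zip(pool["window"], pool["gene"]))
        tr = sub.values[list(pool["window"])].rename(columns=gene_of)
        cutoffs = learn_discretization(tr, y_tr)
        binary_tr = binarize(tr, cutoffs)
        subset = stepwise_select(binary_tr, y_tr, max_features=config.max_features)
        if not subset:
            probs[i] = prevalence
            continue
        fit = fit_logistic(binary_tr[subset].to_numpy(), y_tr)
        held = matrix.values.iloc[i]
        inv = {g: w for w, g in gene_of.items()}
        x_i = np.array([1.0 if held[inv[g]] > cutoffs[g] else 0.0 for g in subset])
        eta = fit.intercept + x_i @ fit.coefficients
        probs[i] = 1.0 / (1.0 + np.exp(-eta))
    return probs


def run_training(
    matrix: CoverageMatrix,
    differential_table: pd.DataFrame,
    config: PipelineConfig,
    name: str = "set-A",
) -> tuple[PromoterClassifier, RocResult]:
    """Train a set-A classifier on the differential survivors.

    Cutoffs, the stepwise feature subset, and coefficients are learned on
    the training cohort; robustness is reported as the LOOCV ROC.  When
    several transcripts of a gene survive discovery, the transcript with
    the smallest discovery p-value represents the gene.
    """
    candidates = _gene_level_features(differential_table)
    if candidates.empty:
        raise PipelineError(
            "differential table has no selected promoters; relax fdr_max/lfc_min"
        )
    logger.info(
        "training %s: %d candidate genes, max_features=%d, loocv=%s",
        name, len(candidates), config.max_features, config.loocv_mode,
    )
    return _training_path(
        matrix, candidates[["window", "gene"]], config, name,
        provenance={"candidate_pool": "differential"},
        strict_differential=True,
    )


def classifier_feature_frame(
    model: PromoterClassifier, matrix: CoverageMatrix
) -> pd.DataFrame:
    """Per-sample raw values of the model's features, gene-keyed.

    Promoter features are pulled from their representative window column;
    ``bmi`` comes from the metadata.
    """
    rep = model.provenance.get("representative_window", {})
    cols = {}
    for f in model.features:
        if f == "bmi":
            cols[f] = matrix.meta["bmi"].to_numpy(dtype=float)
        else:
            window = rep.get(f, f)
            if window not in matrix.values.columns:
                raise ConfigurationError(f"matrix lacks window for feature {f!r}")
            cols[f] = matrix.values[window].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=matrix.values.index)


def run_validation(
    matrix: CoverageMatrix, model: PromoterClassifier, config: PipelineConfig
) -> RocResult:
    """Apply a frozen model to a validation cohort and report its ROC.

    Validation samples must be disjoint from the training samples recorded
    in the model's provenance.
    """
    if not matrix.sample_ids:
        raise PipelineError("validation cohort is empty")
    overlap = set(matrix.sample_ids) & set(model.provenance.get("training_samples", []))
    if overlap:
        raise PipelineError(
            f"validation cohort overlaps training samples: {sorted(overlap)[:5]}"
        )
    frame = classifier_feature_frame(model, matrix)
    probs = np.array([predict(model, frame.loc[i])[1] for i in frame.index])
    labels = (matrix.meta["label"] == "case").to_numpy()
    return roc_analysis(probs, labels)


def run_geneset_classifier(
    matrix: CoverageMatrix,
    gene_list: Sequence[str],
    config: PipelineConfig,
    name: str = "set-P",
) -> tuple[PromoterClassifier, RocResult]:
    """Train with the candidate pool restricted to a tissue gene list.

    ``gene_list`` holds gene symbols (or window ids); set-PW is simply the
    union of the placenta- and blood-specific lists.
    """
    if not len(gene_list):
        raise ConfigurationError("gene list is empty")
    wanted = set(gene_list)
    rows = [
        {"window": w, "gene": g}
        for w, g in matrix.window_genes.items()
        if (g in wanted or w in wanted) and w in matrix.values.columns
    ]
    if not rows:
        raise ConfigurationError("no matrix windows match the gene list")
    candidates = pd.DataFrame(rows).drop_duplicates(subset="gene", keep="first")
    model, roc = _training_path(
        matrix, candidates, config, name, provenance={"candidate_pool": name}
    )
    model.provenance["gene_list_size"] = len(wanted)
    return model, roc


def run_bmi_combination(
    matrix: CoverageMatrix, model: PromoterClassifier, config: PipelineConfig
) -> tuple[PromoterClassifier, RocResult, float]:
    """Append BMI as a raw covariate to a trained promoter classifier.

    Coefficients are refit on the training cohort over the fixed promoter
    features plus BMI, LOOCV is re-evaluated, and the paired DeLong
    p-value against the promoter-only LOOCV ROC is returned.
    """
    if "bmi" not in matrix.meta.columns:
        raise ConfigurationError("metadata lacks a bmi column")
    if matrix.meta["bmi"].isna().any():
        bad = list(matrix.meta.index[matrix.meta["bmi"].isna()])
        raise ConfigurationError(f"missing BMI for sample(s): {bad}")
    labels = (matrix.meta["label"] == "case").to_numpy()
    frame = classifier_feature_frame(model, matrix)
    design = pd.DataFrame(index=frame.index)
    for f in model.features:
        if f in model.cutoffs:
            design[f] = (frame[f] > model.cutoffs[f]).astype(float)
        else:
            design[f] = frame[f]
    base_probs = loocv_probabilities(design, labels, model.features)
    base_roc = roc_analysis(base_probs, labels)
    design_bmi = design.copy()
    design_bmi["bmi"] = matrix.meta["bmi"].to_numpy(dtype=float)
    features = model.features + ["bmi"]
    probs = loocv_probabilities(design_bmi, labels, features)
    roc = roc_analysis(probs, labels)
    fit = fit_logistic(design_bmi[features].to_numpy(), labels)
    combined = PromoterClassifier(
        name=f"{model.name}+BMI",
        features=features,
        cutoffs=dict(model.cutoffs),
        coefficients=dict(zip(features, fit.coefficients.tolist())),
        intercept=fit.intercept,
        probability_threshold=float(np.clip(roc.threshold, 1e-6, 1 - 1e-6)),
        provenance={**model.provenance, "bmi_combined": True},
    )
    p_value = compare_auc(roc, base_roc)
    logger.info(
        "BMI combination: AUC %.3f vs %.3f (paired DeLong p=%.3g)",
        roc.auc, base_roc.auc, p_value,
    )
    return combined, roc, p_value


def run_expression_validation(
    samples: Sequence[FragmentSet],
    windows: Sequence[PromoterWindow],
    gene_sets: Mapping[str, Sequence[str]],
    config: PipelineConfig,
    out_dir: str | Path | None = None,
) -> dict[str, MetageneProfile]:
    """TSS metagene profiles per gene set, with central/flank ratios logged.

    Reproduces the expression-vs-coverage comparison: promoters of highly
    expressed genes show a central coverage dip, unexpressed genes a flat
    profile.
    """
    by_id = {w.transcript_id: w for w in windows}
    profiles: dict[str, MetageneProfile] = {}
    for name, members in gene_sets.items():
        subset = [by_id[t] for t in members if t in by_id]
        if not subset:
            raise ConfigurationError(f"gene set {name!r} matches no windows")
        prof = metagene_profile(samples, subset, bin_size=config.bin_size, gene_set=name)
        profiles[name] = prof
        logger.info(
            "metagene %s: n=%d central/flank ratio %.3f",
            name, prof.n_genes, prof.central_flank_ratio(),
        )
        if out_dir is not None:
            Path(out_dir).mkdir(parents=True, exist_ok=True)
            prof.to_tsv(Path(out_dir) / f"metagene_{name}.tsv")
    return profiles
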