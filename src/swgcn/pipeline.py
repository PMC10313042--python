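"""End-to-end orchestration: similarity -> RWR features -> splits ->
supplementary weighting -> GCN training -> scoring -> evaluation.

Two entry points:

* :func:`run_pipeline` — file-based, resumable, writes every stage output
  plus a JSON manifest into a run directory (this is what the CLI wraps);
* :func:`run_study` / :func:`run_benchmark` — in-memory, used for the
  synthetic ablation study that contrasts the weighting modes.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io_formats as iof
from .evaluation import EvalReport, evaluate_split
from .io_formats import DiseaseDAG, RunConfig, SequenceSet, _parse_boolean_mode
from .model import (
    SWGCNModel,
    build_hetero_adjacency,
    enhanced_target,
    normalize_adjacency,
    train_model,
)
from .node_features import rwr_features
from .similarity import ScoringScheme, sequence_similarity, semantic_similarity
from .synthetic import generate
from .weighting import (
    BasicEnsemble,
    SplitSpec,
    boolean_topk_adjacency,
    make_splits,
    supplementary_weighted_adjacency,
    train_basic_ensemble,
)

__all__ = ["StudyResult", "RunManifest", "run_study", "run_benchmark", "run_pipeline"]


@dataclass
class StudyResult:
    """Everything one in-memory pipeline run produces."""

    report: EvalReport
    scores: np.ndarray
    splits: SplitSpec
    weighted: np.ndarray
    log_losses: list[float]


def _weighted_adjacency(
    mode: str,
    a: np.ndarray,
    ensemble: BasicEnsemble | None,
    splits: SplitSpec,
    fp: np.ndarray,
    fd: np.ndarray,
) -> np.ndarray:
    """Dispatch on the weighting mode; 'none' keeps Boolean training edges."""
    train_pos = splits.ben2_pos
    if mode == "none":
        out = np.zeros_like(np.asarray(a, dtype=np.float64))
        out[train_pos[:, 0], train_pos[:, 1]] = 1.0
        return out
    if ensemble is None:
        raise ValueError(f"mode {mode!r} needs a trained basic ensemble")
    if mode == "weighted":
        return supplementary_weighted_adjacency(a, ensemble, train_pos, fp, fd)
    k = _parse_boolean_mode(mode)
    if k is None:
        raise ValueError(f"unknown weighting mode {mode!r}")
    return boolean_topk_adjacency(a, ensemble, k, train_pos, fp, fd)


def run_study(
    seqs: SequenceSet,
    dag: DiseaseDAG,
    a: np.ndarray,
    config: RunConfig,
    *,
    precomputed: dict | None = None,
) -> StudyResult:
    """Run the full method in memory and evaluate on the held-out pairs.

    ``precomputed`` may carry any of ``p_seq, d_sem, fp, fd, splits,
    ensemble`` so ablation runs can share the mode-independent stages.
    """
    pre = precomputed or {}
    scoring = ScoringScheme(
        config.sw_match, config.sw_mismatch, config.sw_gap_open, config.sw_gap_extend
    )
    p_seq = pre.get("p_seq")
    if p_seq is None:
        p_seq = sequence_similarity(seqs, scoring)
    d_sem = pre.get("d_sem")
    if d_sem is None:
        d_sem = semantic_similarity(dag.with_theta(config.theta))
    fp = pre.get("fp")
    if fp is None:
        fp = rwr_features(p_seq, restart=config.rwr_restart)
    fd = pre.get("fd")
    if fd is None:
        fd = rwr_features(d_sem, restart=config.rwr_restart)
    splits = pre.get("splits")
    if splits is None:
        splits = make_splits(a, seed=config.seed)
    ensemble = pre.get("ensemble")
    if ensemble is None and config.weighting_mode != "none":
        ensemble = train_basic_ensemble(splits, fp, fd)

    weighted = _weighted_adjacency(
        config.weighting_mode, a, ensemble, splits, fp, fd
    )
    operator = normalize_adjacency(build_hetero_adjacency(p_seq, d_sem, weighted))
    # Positives not in ind2 become beta; ind2 and unknown cells become 0,
    # so held-out pairs never enter the objective.
    target = enhanced_target(a, splits.ind2_pos, config.beta)

    model = SWGCNModel(
        m=len(seqs),
        n=len(dag),
        embed_dim=config.embed_dim,
        head_dims=config.head_dims,
        gcn_layers=config.gcn_layers,
        seed=config.seed,
    )
    log = train_model(
        model,
        fp,
        fd,
        operator,
        target,
        epochs=config.epochs,
        learning_rate=config.learning_rate,
        lr_decay=config.lr_decay,
        mu=config.mu,
    )
    u = model.predict(fp, fd, operator)
    report = evaluate_split(u, splits, mode=config.weighting_mode)
    return StudyResult(
        report=report,
        scores=u,
        splits=splits,
        weighted=weighted,
        log_losses=log.losses,
    )


def run_benchmark(
    modes: tuple[str, ...] = ("weighted", "boolean:20", "none"),
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
    m: int = 300,
    n: int = 15,
    rank: int = 4,
    density: float = 0.06,
    signal: float = 3.0,
    config: RunConfig | None = None,
) -> dict[str, list[EvalReport]]:
    """The synthetic ablation study: one world per seed, all modes on it.

    The similarity matrices, RWR features, splits and basic ensemble are
    computed once per seed and shared across modes, so mode differences
    reflect only the weighting strategy.
    """
    base = config or RunConfig()
    results: dict[str, list[EvalReport]] = {mode: [] for mode in modes}
    for seed in seeds:
        world = generate(
            m=m, n=n, rank=rank, density=density, seed=seed, signal=signal
        )
        cfg0 = iof.RunConfig(**{**vars(base), "seed": seed})
        scoring = ScoringScheme(
            cfg0.sw_match, cfg0.sw_mismatch, cfg0.sw_gap_open, cfg0.sw_gap_extend
        )
        p_seq = sequence_similarity(world.seqs, scoring)
        d_sem = semantic_similarity(world.dag.with_theta(cfg0.theta))
        fp = rwr_features(p_seq, restart=cfg0.rwr_restart)
        fd = rwr_features(d_sem, restart=cfg0.rwr_restart)
        splits = make_splits(world.a, seed=seed)
        ensemble = (
            train_basic_ensemble(splits, fp, fd)
            if any(mode != "none" for mode in modes)
            else None
        )
        shared = {
            "p_seq": p_seq,
            "d_sem": d_sem,
            "fp": fp,
            "fd": fd,
            "splits": splits,
            "ensemble": ensemble,
        }
        for mode in modes:
            cfg = iof.RunConfig(**{**vars(base), "seed": seed, "weighting_mode": mode})
            result = run_study(world.seqs, world.dag, world.a, cfg, precomputed=shared)
            results[mode].append(result.report)
    return results


# ---------------------------------------------------------------------------
# File-based, resumable pipeline (the CLI surface)


@dataclass
class RunManifest:
    """Record of one pipeline run, sufficient to re-run it identically."""

    config: dict
    inputs: dict[str, str]  # path -> sha256
    seed: int
    stages: dict[str, float] = field(default_factory=dict)  # stage -> seconds
    outputs: dict[str, str] = field(default_factory=dict)  # stage -> path
    status: str = "incomplete"

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    fasta: str | Path,
    associations: str | Path,
    dag_path: str | Path,
    out_dir: str | Path,
    config: RunConfig | None = None,
    resume: bool = True,
) -> tuple[RunManifest, EvalReport]:
    """File-based full pipeline with per-stage caching.

    Every stage writes its output (long-form TSV / JSON) into ``out_dir``;
    with ``resume=True`` a stage whose output file already exists is
    loaded instead of recomputed.  The manifest records input digests,
    per-stage wall-clock seconds and all output paths.
    """
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for path in (fasta, associations, dag_path):
        if not Path(path).exists():
            raise FileNotFoundError(f"pipeline input not found: {path}")
    manifest = RunManifest(
        config={
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        inputs={str(p): _digest(p) for p in (fasta, associations, dag_path)},
        seed=config.seed,
    )
    manifest_path = out / "manifest.json"

    seqs = iof.read_fasta(fasta)
    dag = iof.read_dag(dag_path, theta=config.theta)
    a = iof.read_associations(associations, seqs, dag)

    def stage(name: str, filename: str, compute, reader, writer):
        path = out / filename
        start = time.perf_counter()
        if resume and path.exists():
            value = reader(path)
        else:
            value = compute()
            writer(value, path)
        manifest.stages[name] = round(time.perf_counter() - start, 4)
        manifest.outputs[name] = str(path)
        manifest.save(manifest_path)
        return value

    def _read_square(path):
        mat, _, _ = iof.read_scores(path)
        return mat

    def _read_rect(path):
        mat, _, _ = iof.read_scores(path)
        return mat

    scoring = ScoringScheme(
        config.sw_match, config.sw_mismatch, config.sw_gap_open, config.sw_gap_extend
    )
    try:
        p_seq = stage(
            "sequence_similarity",
            "p_seq.tsv",
            lambda: sequence_similarity(seqs, scoring),
            _read_square,
            lambda v, p: iof.write_scores(v, seqs.ids, seqs.ids, p),
        )
        d_sem = stage(
            "semantic_similarity",
            "d_sem.tsv",
            lambda: semantic_similarity(dag),
            _read_square,
            lambda v, p: iof.write_scores(v, dag.terms, dag.terms, p),
        )
        fp = stage(
            "pirna_features",
            "f_pirna.tsv",
            lambda: rwr_features(p_seq, restart=config.rwr_restart),
            _read_square,
            lambda v, p: iof.write_scores(v, seqs.ids, seqs.ids, p),
        )
        fd = stage(
            "disease_features",
            "f_disease.tsv",
            lambda: rwr_features(d_sem, restart=config.rwr_restart),
            _read_square,
            lambda v, p: iof.write_scores(v, dag.terms, dag.terms, p),
        )

        start = time.perf_counter()
        splits = make_splits(a, seed=config.seed)
        manifest.stages["splits"] = round(time.perf_counter() - start, 4)

        ensemble = None
        if config.weighting_mode != "none":
            start = time.perf_counter()
            ensemble = train_basic_ensemble(splits, fp, fd)
            manifest.stages["basic_ensemble"] = round(
                time.perf_counter() - start, 4
            )
        weighted = stage(
            "weighting",
            "a_weighted.tsv",
            lambda: _weighted_adjacency(
                config.weighting_mode, a, ensemble, splits, fp, fd
            ),
            _read_rect,
            lambda v, p: iof.write_scores(v, seqs.ids, dag.terms, p),
        )

        start = time.perf_counter()
        result = run_study(
            seqs,
            dag,
            a,
            config,
            precomputed={
                "p_seq": p_seq,
                "d_sem": d_sem,
                "fp": fp,
                "fd": fd,
                "splits": splits,
                "ensemble": ensemble,
            },
        )
        manifest.stages["train_predict"] = round(time.perf_counter() - start, 4)

        scores_path = out / "scores.tsv"
        iof.write_scores(result.scores, seqs.ids, dag.terms, scores_path)
        manifest.outputs["scores"] = str(scores_path)
        report_path = out / "report.json"
        with open(report_path, "w") as fh:
            json.dump(asdict(result.report), fh, indent=2)
        manifest.outputs["report"] = str(report_path)
        manifest.status = "complete"
    finally:
        manifest.save(manifest_path)
    return manifest, result.report
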