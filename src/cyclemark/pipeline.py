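"""One-command orchestration of the full marker-discovery workflow.

Stages: (1) load or synthesize a labeled matrix; (2) shadow-feature
filtering; (3) three rankings of the confirmed genes; (4) IFS for every
(list x classifier) pair; (5) optimal subset per pair and feasible subset
per list from the random-forest curve; (6) intersection of the feasible
subsets; (7) a decision-tree rule set per list at the DT-optimal k;
(8) a machine-readable run report.

All stage seeds fan out deterministically from one global seed, so two
runs with the same config produce byte-identical artifacts (timing
information in the report aside). Completed stages are skipped on re-run
when their inputs and config hash identically (simple content-hash
caching; IFS dominates the cost).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as cio
from .boruta import BorutaConfig, run_boruta
from .evaluation import ClassifierSpec, CVConfig
from .ifs import IFSCurve, SubsetResult, feasible_subset, intersect_subsets, optimal_subset, run_ifs
from .ranking import MCFSParams, RankedList, rank_mcfs, rank_mrmr, rank_shap
from .rules import extract_rules, rules_per_class, train_tree
from .synthetic import SyntheticSpec, generate

logger = logging.getLogger("cyclemark")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "export_gene_lists", "load_config"]

RANKERS = ("mrmr", "mcfs", "shap")
CLASSIFIERS = ("rf", "svm", "knn", "dt")

_STAGES = ("data", "boruta", "rank", "ifs", "subsets", "rules")


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one of expression path / synthetic spec."""

    out_dir: str = "cyclemark_run"
    expression_path: str | None = None
    expression_format: str = "dense-tsv"
    cells_as_rows: bool = True
    labels_path: str | None = None
    synthetic: SyntheticSpec | None = None
    boruta: BorutaConfig = field(default_factory=BorutaConfig)
    mcfs: MCFSParams = field(default_factory=MCFSParams)
    mrmr_criterion: str = "difference"
    cv: CVConfig = field(default_factory=CVConfig)
    classifiers: tuple[str, ...] = CLASSIFIERS
    tau: float = 0.05
    k_max: int | None = None
    feasible_k_override: dict[str, int] = field(default_factory=dict)
    fallback_all: bool = False
    seed: int = 0

    def validate(self) -> None:
        has_files = self.expression_path is not None
        if has_files == (self.synthetic is not None):
            raise ValueError("exactly one of expression_path / synthetic must be given")
        if has_files and self.labels_path is None:
            raise ValueError("labels_path required with expression_path")
        self.boruta.validate()
        self.mcfs.validate()
        self.cv.validate()
        for c in self.classifiers:
            ClassifierSpec(kind=c).validate()
        if not 0.0 <= self.tau < 1.0:
            raise ValueError("tau must be in [0, 1)")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML or JSON config file into a PipelineConfig."""
    raw = Path(path).read_text()
    data = yaml.safe_load(raw)
    kwargs = dict(data)
    if "synthetic" in kwargs and kwargs["synthetic"] is not None:
        syn = dict(kwargs["synthetic"])
        if "n_per_class" in syn:
            syn["n_per_class"] = tuple(syn["n_per_class"])
        kwargs["synthetic"] = SyntheticSpec(**syn)
    if "boruta" in kwargs and kwargs["boruta"] is not None:
        kwargs["boruta"] = BorutaConfig(**kwargs["boruta"])
    if "mcfs" in kwargs and kwargs["mcfs"] is not None:
        kwargs["mcfs"] = MCFSParams(**kwargs["mcfs"])
    if "cv" in kwargs and kwargs["cv"] is not None:
        kwargs["cv"] = CVConfig(**kwargs["cv"])
    if "classifiers" in kwargs:
        kwargs["classifiers"] = tuple(kwargs["classifiers"])
    return PipelineConfig(**kwargs)


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run; paths are out_dir-relative."""

    config: dict
    seeds: dict
    boruta_summary: dict
    ranked_paths: dict
    curve_paths: dict
    optimal_subsets: dict
    feasible_subsets: dict
    intersection: list
    intersection_pairwise: dict
    ruleset_paths: dict
    rule_counts: dict
    timing_sec: dict

    def to_json_dict(self) -> dict:
        return asdict(self)


def _stage_seeds(global_seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(global_seed)
    names = ("synthetic", "boruta", "mrmr", "mcfs", "shap", "cv", "tree")
    state = ss.generate_state(len(names)) % (2**31 - 1)
    return {name: int(s) for name, s in zip(names, state)}


def _config_hash(cfg: PipelineConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    d = asdict(cfg)
    d.pop("out_dir")  # the run's location must not invalidate its cache
    blob = json.dumps(d, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full workflow; artifacts land in ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    cfg_hash = _config_hash(config)
    manifest_path = out / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    cache_valid = manifest.get("config_hash") == cfg_hash
    timing: dict[str, float] = {}

    def timed(stage):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                logger.info("stage %s: start", stage)
                return self_

            def __exit__(self_, *exc):
                timing[stage] = round(time.perf_counter() - self_.t0, 3)
                logger.info("stage %s: %.2fs", stage, timing[stage])

        return _T()

    # ---- stage 1: data -------------------------------------------------
    with timed("data"):
        if config.synthetic is not None:
            # the data seed is part of the data specification, not derived
            # from the global seed: the same study design can be re-analyzed
            # under different analysis seeds
            em, truth = generate(config.synthetic)
            cio.write_labels(em.cell_ids, em.labels, out / "labels.tsv")
            (out / "ground_truth.json").write_text(
                json.dumps(
                    {
                        "marker_sets": {p: sorted(s) for p, s in truth.marker_sets.items()},
                        "noise_genes": sorted(truth.noise_genes),
                    },
                    indent=1,
                )
            )
        else:
            em, report = cio.read_expression(
                config.expression_path, fmt=config.expression_format,
                cells_as_rows=config.cells_as_rows,
            )
            labels = cio.read_labels(config.labels_path, em.cell_ids)
            em = em.with_labels(labels)
            if report.zero_variance_genes:
                logger.warning("%d zero-variance genes flagged", len(report.zero_variance_genes))

    # ---- stage 2: Boruta filter ---------------------------------------
    boruta_path = out / "boruta.json"
    with timed("boruta"):
        from dataclasses import replace

        bcfg = replace(config.boruta, seed=seeds["boruta"])
        if cache_valid and boruta_path.exists():
            bres = cio.read_boruta_result(boruta_path)
            logger.info("boruta: cache hit")
        else:
            bres = run_boruta(em, config=bcfg)
            cio.write_table(bres, boruta_path)
    confirmed = sorted(bres.confirmed)
    if not confirmed:
        if config.fallback_all:
            logger.warning("empty confirmed set; falling back to all genes")
            zv = em.zero_variance_mask()
            confirmed = [g for g, z in zip(em.gene_ids, zv) if not z]
        else:
            raise RuntimeError(
                "stage boruta: no genes confirmed; re-run with fallback_all=True "
                "to rank all genes (partial outputs preserved in out_dir)"
            )
    elif len(confirmed) < 10:
        logger.warning("only %d genes confirmed; downstream lists are tiny", len(confirmed))
    em_conf = em.subset_genes(confirmed)

    # ---- stage 3: three rankings --------------------------------------
    ranked: dict[str, RankedList] = {}
    ranked_paths: dict[str, str] = {}
    with timed("rank"):
        from dataclasses import replace

        for method in RANKERS:
            path = out / f"ranked_{method}.tsv"
            ranked_paths[method] = path.name
            if cache_valid and path.exists():
                ranked[method] = cio.read_ranked_list(path)
                continue
            if method == "mrmr":
                rl = rank_mrmr(em_conf, criterion=config.mrmr_criterion)
            elif method == "mcfs":
                rl = rank_mcfs(em_conf, params=replace(config.mcfs, seed=seeds["mcfs"]))
            else:
                rl = rank_shap(em_conf, seed=seeds["shap"])
            ranked[method] = rl
            cio.write_table(rl, path)

    # ---- stage 4: IFS curves ------------------------------------------
    from dataclasses import replace

    cv = replace(config.cv, seed=seeds["cv"])
    curves: dict[tuple[str, str], IFSCurve] = {}
    curve_paths: dict[str, str] = {}
    with timed("ifs"):
        for method in RANKERS:
            for clf_kind in config.classifiers:
                path = out / f"curve_{method}_{clf_kind}.tsv"
                curve_paths[f"{method}/{clf_kind}"] = path.name
                if cache_valid and path.exists():
                    curves[(method, clf_kind)] = cio.read_ifs_curve(path)
                    continue
                clf = ClassifierSpec(kind=clf_kind, seed=seeds["tree"])
                curve = run_ifs(em_conf, em_conf.labels, ranked[method], clf, cv,
                                k_max=config.k_max)
                curves[(method, clf_kind)] = curve
                cio.write_table(curve, path)

    # ---- stage 5: optimal + feasible subsets --------------------------
    with timed("subsets"):
        optimal: dict[str, dict] = {}
        feasible: dict[str, SubsetResult] = {}
        for (method, clf_kind), curve in curves.items():
            res = optimal_subset(curve, ranked[method])
            optimal[f"{method}/{clf_kind}"] = {
                "k": res.k, "mcc": res.metrics.mcc, "acc": res.metrics.acc,
                "genes": res.genes,
            }
        feas_json: dict[str, dict] = {}
        ref_clf = "rf" if "rf" in config.classifiers else config.classifiers[0]
        for method in RANKERS:
            curve = curves[(method, ref_clf)]
            if method in config.feasible_k_override:
                k = int(config.feasible_k_override[method])
                res = SubsetResult(kind="feasible", k=k, genes=ranked[method].top(k),
                                   metrics=curve.points[k - 1][1])
            else:
                res = feasible_subset(curve, ranked[method], tau=config.tau)
            feasible[method] = res
            feas_json[method] = {
                "k": res.k, "mcc": res.metrics.mcc, "acc": res.metrics.acc,
                "genes": res.genes,
            }
        common, pairwise = intersect_subsets([feasible[m] for m in RANKERS])
        (out / "subsets.json").write_text(
            json.dumps({"optimal": optimal, "feasible": feas_json,
                        "intersection": sorted(common)}, indent=1, sort_keys=True)
        )

    # ---- stage 6/7: rule sets from the DT-optimal prefix ---------------
    ruleset_paths: dict[str, str] = {}
    rule_counts: dict[str, dict] = {}
    with timed("rules"):
        dt_ref = "dt" if "dt" in config.classifiers else ref_clf
        for method in RANKERS:
            curve = curves[(method, dt_ref)]
            res = optimal_subset(curve, ranked[method])
            tree = train_tree(em_conf, em_conf.labels, res.genes, seed=seeds["tree"])
            rs = extract_rules(tree, res.genes, source=(method, res.k))
            path = out / f"rules_{method}.json"
            cio.write_table(rs, path)
            (out / f"rules_{method}.txt").write_text(rs.render() + "\n")
            ruleset_paths[method] = path.name
            rule_counts[method] = rules_per_class(rs)

    report = RunReport(
        config=json.loads(json.dumps(asdict(config), default=str)),
        seeds=seeds,
        boruta_summary={
            "confirmed": len(bres.confirmed), "rejected": len(bres.rejected),
            "tentative": len(bres.tentative), "excluded": len(bres.excluded),
            "n_iterations": bres.n_iterations,
        },
        ranked_paths=ranked_paths,
        curve_paths=curve_paths,
        optimal_subsets={k: {kk: vv for kk, vv in v.items() if kk != "genes"}
                         for k, v in optimal.items()},
        feasible_subsets={k: {kk: vv for kk, vv in v.items() if kk != "genes"}
                          for k, v in feas_json.items()},
        intersection=sorted(common),
        intersection_pairwise={f"{i}-{j}": v for (i, j), v in pairwise.items()},
        ruleset_paths=ruleset_paths,
        rule_counts=rule_counts,
        timing_sec=timing,
    )
    (out / "report.json").write_text(json.dumps(report.to_json_dict(), indent=1, sort_keys=True))
    manifest_path.write_text(json.dumps({"config_hash": cfg_hash}))
    return report


def export_gene_lists(out_dir: str | Path, which: str) -> list[Path]:
    """Write plain one-gene-per-line files for external enrichment tooling.

    ``which`` is "optimal", "feasible" or "intersection"; reads the
    subsets.json written by :func:`run_pipeline`.
    """
    out = Path(out_dir)
    subsets = json.loads((out / "subsets.json").read_text())
    written: list[Path] = []
    if which == "intersection":
        genes = subsets["intersection"]
        path = out / "genes_intersection.txt"
        path.write_text("\n".join(genes) + ("\n" if genes else ""))
        if not genes:
            logger.warning("intersection is empty")
        written.append(path)
    elif which == "feasible":
        for method, info in subsets["feasible"].items():
            path = out / f"genes_feasible_{method}.txt"
            path.write_text("\n".join(info["genes"]) + "\n")
            written.append(path)
    elif which == "optimal":
        for key, info in subsets["optimal"].items():
            method, clf = key.split("/")
            path = out / f"genes_optimal_{method}_{clf}.txt"
            path.write_text("\n".join(info["genes"]) + "\n")
            written.append(path)
    else:
        raise ValueError(f"unknown selector: {which!r}")
    return written
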