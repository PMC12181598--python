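"""End-to-end orchestration of the biomarker-discovery workflow.

One YAML config drives the whole chain: (optional) simulation of inputs,
gene-set harvesting and knowledge-base filtering, sex-stratified
dual-correlation ranking, overlap/direction analysis, serum tertile
validation, and panel ROC comparison.  Every stage writes its TSV/JSON
artifacts under the configured output directory and contributes counts to
a machine-readable run report that is byte-identical for identical
config + seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import read_cohort, read_expression, read_serum
from .overlap import (
    cross_sex_overlap, direction_consistency, export_heatmap_matrix, unique_union, venn3,
)
from .predict import compare_models
from .ranking import all_correlations, ranked_list_frame, run_all
from .selection import (
    FilterCriteria, filter_biomarkers, harvest_genes, qualifying_record_counts,
    read_gmt, read_knowledge_base,
)
from .simulate import (
    ConfigurationError, KBComposition, PlantedMarker, SerumSpec, SimConfig,
    reference_criteria, write_outputs,
)
from .tertiles import assign_tertiles, compare_age_groups, compare_tertiles, serum_pairwise_correlations

log = logging.getLogger("frailmark")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated view of the YAML pipeline configuration."""

    seed: int = 0
    outdir: Path = Path("frailmark_out")
    k: int = 40
    score_mode: str = "min"
    sexes: tuple = ("F", "M")
    tests: tuple = ("walk400", "gait4", "chair5")
    term_ids: list | str = "all"
    criteria: FilterCriteria = field(
        default_factory=lambda: FilterCriteria.from_dict(reference_criteria())
    )
    simulate: SimConfig | None = None
    paths: dict = field(default_factory=dict)
    validate_markers: dict = field(default_factory=dict)
    predict: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict, seed: int | None = None) -> "PipelineConfig":
        d = dict(d)
        if seed is not None:
            d["seed"] = seed
        sim = None
        if "simulate" in d:
            s = dict(d["simulate"])
            s["planted_markers"] = tuple(PlantedMarker(**m) for m in s.get("planted_markers", []))
            s["serum_markers"] = tuple(SerumSpec(**m) for m in s.get("serum_markers", []))
            kb_comp = s.pop("kb_composition", {})
            if "force_qualify" in kb_comp:
                kb_comp["force_qualify"] = tuple(kb_comp["force_qualify"])
            s["kb_composition"] = KBComposition(**kb_comp)
            s["seed"] = int(d.get("seed", 0))
            sim = SimConfig(**s)
        criteria = (
            FilterCriteria.from_dict(d["criteria"]) if "criteria" in d
            else FilterCriteria.from_dict(reference_criteria())
        )
        cfg = cls(
            seed=int(d.get("seed", 0)),
            outdir=Path(d.get("outdir", "frailmark_out")),
            k=int(d.get("k", 40)),
            score_mode=str(d.get("score_mode", "min")),
            sexes=tuple(d.get("sexes", ("F", "M"))),
            tests=tuple(d.get("tests", ("walk400", "gait4", "chair5"))),
            term_ids=d.get("term_ids", "all"),
            criteria=criteria,
            simulate=sim,
            paths={k_: Path(v) for k_, v in d.get("paths", {}).items()},
            validate_markers=dict(d.get("validate", {}).get("markers", {})),
            predict=dict(d.get("predict", {})),
            raw=d,
        )
        cfg._check()
        return cfg

    @classmethod
    def from_yaml(cls, path, seed: int | None = None, outdir=None) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if outdir is not None:
            d["outdir"] = str(outdir)
        return cls.from_dict(d, seed=seed)

    def _check(self) -> None:
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")
        if self.simulate is None:
            required = {"gmt", "kb", "expression", "cohort"}
            if self.validate_markers or self.predict:
                required.add("serum")
            missing = required - set(self.paths)
            if missing:
                raise ConfigurationError(
                    f"config must provide a simulate block or input paths; missing: {sorted(missing)}"
                )
            for name, p in self.paths.items():
                if not Path(p).exists():
                    raise ConfigurationError(f"input path {name!r} does not exist: {p}")


@dataclass
class RunReport:
    """Stage-by-stage counts plus config echo; serialized as sorted JSON."""

    seed: int
    version: str
    config: dict
    stages: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed, "version": self.version,
            "config": self.config, "stages": self.stages,
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages; returns the run report (also written to report.json)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed, version=__version__, config=_echo_config(config))

    stage = "inputs"
    try:
        if config.simulate is not None:
            sim = write_outputs(out / "inputs", config.simulate)
            cohort, expr, serum = sim["cohort"], sim["expression"], sim["serum"]
            kb = sim["knowledge_base"]
            gmt_path = sim["paths"]["gmt"]
            ground_truth = sim["ground_truth"]
        else:
            cohort = read_cohort(config.paths["cohort"])
            expr = read_expression(config.paths["expression"])
            serum = read_serum(config.paths["serum"]) if "serum" in config.paths else None
            kb = read_knowledge_base(config.paths["kb"])
            gmt_path = config.paths["gmt"]
            ground_truth = None
        report.stages["inputs"] = {
            "n_samples": int(len(cohort)),
            "n_old": int((cohort["age_group"] == "old").sum()),
            "n_genes": int(len(expr)),
            "n_kb_records": int(len(kb)),
            "simulated": config.simulate is not None,
        }
        log.info("inputs: %d samples, %d genes, %d KB records",
                 len(cohort), len(expr), len(kb))

        stage = "candidate_selection"
        collection = read_gmt(gmt_path)
        term_ids = (
            sorted(collection.sets) if config.term_ids == "all" else list(config.term_ids)
        )
        harvested = harvest_genes(collection, term_ids)
        described, qualified = filter_biomarkers(harvested, kb, config.criteria)
        candidates = sorted(qualified & set(expr.index))
        qual_counts = qualifying_record_counts(kb, config.criteria)
        cand_df = pd.DataFrame({"gene_id": candidates})
        cand_df["n_qualifying_records"] = [int(qual_counts.get(g, 0)) for g in candidates]
        _write_tsv(cand_df, out / "selection" / "candidates.tsv")
        report.stages["candidate_selection"] = {
            "n_terms": len(term_ids),
            "n_harvested": len(harvested),
            "n_described": len(described),
            "n_qualified": len(qualified),
            "n_candidates_in_matrix": len(candidates),
        }
        log.info("funnel: %d terms -> %d harvested -> %d described -> %d qualified",
                 len(term_ids), len(harvested), len(described), len(qualified))

        stage = "corr_rank"
        lists, skipped = run_all(
            expr, cohort, candidates, k=config.k, score_mode=config.score_mode,
            sexes=config.sexes, tests=config.tests,
        )
        corr_table = all_correlations(
            expr, cohort, candidates, k=config.k, score_mode=config.score_mode,
            sexes=config.sexes, tests=config.tests,
        )
        _write_tsv(corr_table, out / "ranking" / "all_correlations.tsv")
        for (sex, test), rl in sorted(lists.items()):
            _write_tsv(ranked_list_frame(rl), out / "ranking" / f"top{config.k}_{sex}_{test}.tsv")
        report.stages["corr_rank"] = {
            "list_sizes": {f"{s}_{t}": len(rl) for (s, t), rl in sorted(lists.items())},
            "skipped_strata": [f"{s}_{t}" for s, t in skipped],
        }

        stage = "overlap_analysis"
        overlap_report: dict = {}
        for sex in config.sexes:
            per_test = [
                lists[(sex, t)].gene_set() for t in config.tests if (sex, t) in lists
            ]
            if len(per_test) == 3:
                v = venn3(*per_test)
                overlap_report[f"venn_{sex}"] = v.as_dict()
                overlap_report[f"n_unique_{sex}"] = len(unique_union(per_test))
                mat = export_heatmap_matrix(
                    corr_table, sorted(unique_union(per_test)), config.tests, sex=sex
                )
                _write_tsv(mat, out / "overlap" / f"heatmap_{sex}.tsv", index=True)
        candidate_pairs = []
        for (sex, test), rl in lists.items():
            candidate_pairs += [(g, test) for g in rl.gene_ids()]
        shared = {}
        for test in config.tests:
            if ("F", test) in lists and ("M", test) in lists:
                inter = cross_sex_overlap(lists[("F", test)].gene_set(), lists[("M", test)].gene_set())
                shared[test] = sorted(inter)
        if {"F", "M"} <= set(config.sexes):
            dc = direction_consistency(corr_table, candidate_pairs)
            _write_tsv(dc.table, out / "overlap" / "direction_consistency.tsv")
            paired = export_heatmap_matrix(
                corr_table, sorted({g for g, _ in candidate_pairs}), config.tests, sex=None
            )
            _write_tsv(paired, out / "overlap" / "heatmap_paired_sexes.tsv", index=True)
            overlap_report["cross_sex_shared"] = {t: len(v) for t, v in shared.items()}
            overlap_report["direction"] = {
                "n_evaluated": dc.n_evaluated,
                "n_inconsistent": dc.n_inconsistent,
                "inconsistent_fraction": (
                    None if np.isnan(dc.inconsistent_fraction) else round(dc.inconsistent_fraction, 6)
                ),
            }
        (out / "overlap").mkdir(parents=True, exist_ok=True)
        with open(out / "overlap" / "venn_summary.json", "w") as fh:
            json.dump(overlap_report, fh, indent=2, sort_keys=True, default=_jsonable)
        report.stages["overlap_analysis"] = overlap_report

        stage = "tertile_validation"
        if config.validate_markers and serum is not None:
            rows = []
            corr_out = {}
            for sex in config.sexes:
                old = cohort[(cohort["sex"] == sex) & (cohort["age_group"] == "old")]
                young = cohort[(cohort["sex"] == sex) & (cohort["age_group"] == "young")]
                for marker, spec in sorted(config.validate_markers.items()):
                    if marker not in serum.columns:
                        raise ConfigurationError(f"validation marker {marker!r} not in serum table")
                    test = spec["test"]
                    assignment = assign_tertiles(old[test], sex=sex, test=test)
                    res = compare_tertiles(
                        serum[marker], assignment,
                        alternative=spec.get("direction", "greater"), marker=marker,
                    )
                    tmeans = {
                        t: float(serum[marker].reindex(assignment.group(t)).mean())
                        for t in ("T1", "T2", "T3")
                    }
                    age_res = compare_age_groups(
                        serum[marker].reindex(old.index), serum[marker].reindex(young.index),
                        marker=marker, sex=sex,
                    ) if len(young) >= 2 else None
                    rows.append(
                        {
                            "marker": marker, "sex": sex, "test": test,
                            "path": res.path,
                            "mean_T1": tmeans["T1"], "mean_T2": tmeans["T2"], "mean_T3": tmeans["T3"],
                            "p_T2_vs_T1": res.p_values["T2_vs_T1"],
                            "p_T3_vs_T1": res.p_values["T3_vs_T1"],
                            "alternative": res.alternative,
                            "age_path": age_res.path if age_res else "",
                            "p_old_vs_young": age_res.p_values["old_vs_young"] if age_res else np.nan,
                        }
                    )
                r, p = serum_pairwise_correlations(serum, samples=old.index)
                _write_tsv(r, out / "validation" / f"serum_correlations_r_{sex}.tsv", index=True)
                _write_tsv(p, out / "validation" / f"serum_correlations_p_{sex}.tsv", index=True)
                corr_out[sex] = int(r.notna().sum().sum())
            comp_df = pd.DataFrame(rows)
            _write_tsv(comp_df, out / "validation" / "tertile_comparisons.tsv")
            report.stages["tertile_validation"] = {
                "n_comparisons": len(rows),
                "paths": sorted(set(comp_df["path"])),
                "min_p_T3_vs_T1": float(np.nanmin(comp_df["p_T3_vs_T1"])) if rows else None,
            }

        stage = "predictive_model"
        if config.predict and serum is not None:
            summary_rows = []
            for sex, block in sorted(config.predict.items()):
                results, split = compare_models(
                    cohort, serum, sex, tuple(block["tests"]), dict(block["panels"])
                )
                for res in results:
                    roc_df = pd.DataFrame({"fpr": res.fpr, "tpr": res.tpr})
                    _write_tsv(roc_df, out / "prediction" / f"roc_{sex}_{res.name}.tsv")
                    summary_rows.append(
                        {
                            "sex": sex, "panel": res.name,
                            "features": "|".join(res.features),
                            "auc": res.auc, "p_vs_chance": res.p_vs_chance,
                            "n_pos": res.n_pos, "n_neg": res.n_neg,
                            "flags": "|".join(res.flags),
                        }
                    )
            summary = pd.DataFrame(summary_rows)
            _write_tsv(summary, out / "prediction" / "model_comparison.tsv")
            report.stages["predictive_model"] = {
                f"{r['sex']}_{r['panel']}": {"auc": round(r["auc"], 6), "p": round(r["p_vs_chance"], 6)}
                for r in summary_rows
            }

        if ground_truth is not None:
            planted = {m["gene_id"] for m in ground_truth["planted_markers"]}
            recovered = set()
            for (sex, test), rl in lists.items():
                recovered |= {
                    m["gene_id"] for m in ground_truth["planted_markers"]
                    if m["sex"] == sex and m["test"] == test and m["gene_id"] in rl.gene_set()
                }
            report.stages["ground_truth"] = {
                "n_planted": len(planted),
                "n_recovered_in_matched_list": len(recovered),
                "kb_truth_described": ground_truth["knowledge_base"]["n_described"],
                "kb_truth_qualified": ground_truth["knowledge_base"]["n_qualified"],
            }
    except PipelineError:
        raise
    except Exception as exc:  # annotate with the failing stage, keep partial outputs
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        raise PipelineError(stage, str(exc)) from exc

    with open(out / "report.json", "w") as fh:
        fh.write(report.to_json())
    return report


def _echo_config(config: PipelineConfig) -> dict:
    echo = {k: v for k, v in config.raw.items() if k != "outdir"}
    return json.loads(json.dumps(echo, default=_jsonable, sort_keys=True))
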