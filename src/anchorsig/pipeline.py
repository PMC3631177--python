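"""Configuration-driven end-to-end orchestration.

A run configuration (YAML or dict) names either the four input files
(expression, sample table, probe annotation, categories) or a ``simulate``
block of generator parameters, plus the per-stage settings.  ``run_pipeline``
executes simulate/load → screen → enrich → stratify → cluster → survive,
writes every stage artifact as TSV/JSON under the output directory, and
records a manifest with the fully resolved configuration and stage counts.
Reruns with the same configuration and seed are byte-identical (floats are
written at fixed precision); a failed stage leaves a ``FAILED`` marker naming
the stage.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_data import (
    align_cohort,
    read_categories,
    read_expression_matrix,
    read_probe_annotation,
    read_sample_table,
    write_expression_matrix,
    write_probe_annotation,
    write_sample_table,
)
from .enrichment import enrich_screen_hits
from .screen import ScreenConfig, build_ranked_table, run_screen
from .stratify import (
    CutpointConfig,
    cluster_composition,
    cluster_samples,
    cooccurrence_counts,
    dichotomize,
    ordered_matrix,
)
from .survival import stratify_and_test
from .synthetic import SyntheticParams, simulate_cohort

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "screen": {
        "anchor_probe": None,
        "r_up": 0.6,
        "r_down": -0.6,
        "p_max": 0.05,
        "direction_rule": "tc_and_p",
        "gene_level": False,
        "test_variant": "pooled",
    },
    "enrichment": {"category": "cell cycle"},
    "stratify": {"statistic": "median", "tie_policy": "strict", "markers": None},
    "cluster": {
        "k": 2,
        "linkage": "complete",
        "distance": "euclidean",
        "row_standardize": True,
        "signature": None,
    },
    "survival": {"marker_a": None, "marker_b": None, "scheme": "combined", "horizon": None},
}


def _merge(base: Mapping[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, Mapping) and isinstance(out.get(key), Mapping):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return validate_config(cfg)


def validate_config(cfg: Mapping[str, Any]) -> dict[str, Any]:
    """Resolve defaults and validate the run configuration upfront."""
    cfg = _merge(DEFAULT_CONFIG, cfg)
    has_inputs = bool(cfg.get("inputs"))
    has_sim = cfg.get("simulate") is not None
    if has_inputs == has_sim:
        raise ValueError("config must contain exactly one of 'inputs' or 'simulate'")
    if has_inputs:
        for key in ("expression", "samples", "annotation"):
            if key not in cfg["inputs"]:
                raise ValueError(f"inputs block missing {key!r}")
            p = Path(cfg["inputs"][key])
            if not p.exists():
                raise ValueError(f"input file does not exist: {p}")
        if not cfg["screen"]["anchor_probe"]:
            raise ValueError("screen.anchor_probe is required with file inputs")
    return cfg


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index, lineterminator="\n")


def run_pipeline(config: Mapping[str, Any] | str | Path, outdir: str | Path) -> dict[str, Any]:
    """Execute every stage and write the artifact bundle; returns the manifest."""
    cfg = load_config(config) if isinstance(config, (str, Path)) else validate_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    failed = out / "FAILED"
    if failed.exists():
        failed.unlink()

    stage = "setup"
    manifest: dict[str, Any] = {"config": _jsonable(cfg), "version": __version__}
    try:
        # ------------------------------------------------------------ inputs
        stage = "inputs"
        if cfg.get("simulate") is not None:
            params = SyntheticParams(**{**cfg["simulate"], "seed": cfg["seed"]})
            cohort, metadata, annotation, truth = simulate_cohort(params)
            write_expression_matrix(cohort, out / "expression.tsv")
            write_sample_table(metadata, out / "samples.tsv")
            write_probe_annotation(annotation, out / "annotation.tsv")
            with open(out / "truth.json", "w") as fh:
                json.dump(
                    {
                        "anchor_probe": truth.anchor_probe,
                        "module_probes": truth.module_probes,
                        "anti_probes": truth.anti_probes,
                        "hazard_gamma": truth.hazard_gamma,
                    },
                    fh,
                    indent=2,
                    sort_keys=True,
                )
            anchor = truth.anchor_probe
            manifest["simulate"] = params.to_dict()
            universe = None
        else:
            cohort = read_expression_matrix(cfg["inputs"]["expression"])
            metadata = read_sample_table(cfg["inputs"]["samples"])
            annotation = read_probe_annotation(cfg["inputs"]["annotation"])
            anchor = cfg["screen"]["anchor_probe"]
            universe = None
            if cfg["inputs"].get("categories"):
                universe = read_categories(
                    cfg["inputs"]["categories"],
                    cfg["inputs"].get("categories_dialect", "gmt"),
                    cfg["inputs"].get("categories_level", "probe"),
                    int(cfg["inputs"]["universe_size"]),
                )
        cohort, groups = align_cohort(cohort, metadata)
        manifest["counts"] = {
            "n_probes": len(cohort.probe_ids),
            "n_tumor": len(groups["tumor"]),
            "n_control": len(groups["control"]),
        }

        # ------------------------------------------------------------ screen
        stage = "screen"
        scfg = ScreenConfig(anchor_probe=anchor, **{
            k: v for k, v in cfg["screen"].items() if k != "anchor_probe"
        })
        screen_res = run_screen(cohort, groups, scfg, annotation)
        _write_tsv(screen_res.records, out / "screen_records.tsv")
        _write_tsv(screen_res.up_correlated, out / "screen_up.tsv")
        _write_tsv(screen_res.down_correlated, out / "screen_down.tsv")
        ranked, _missing = build_ranked_table(screen_res.up_correlated, annotation)
        _write_tsv(ranked, out / "ranked_table.tsv")
        manifest["counts"]["n_up_correlated"] = len(screen_res.up_correlated)
        manifest["counts"]["n_down_correlated"] = len(screen_res.down_correlated)

        # ------------------------------------------------------------ enrich
        stage = "enrichment"
        category = cfg["enrichment"]["category"]
        if universe is not None:
            enr = enrich_screen_hits(
                list(screen_res.up_correlated["probe_id"]), universe, category
            )
        else:
            # simulate mode: category membership comes from the annotation and
            # the background is the full probe registry of the cohort
            members = frozenset(
                p for p, a in annotation.items() if category in a.categories
            )
            from .core_data import CategoryUniverse

            universe_sim = CategoryUniverse(
                {category: members}, len(cohort.probe_ids), "probe"
            )
            enr = enrich_screen_hits(
                list(screen_res.up_correlated["probe_id"]), universe_sim, category
            )
        with open(out / "enrichment.json", "w") as fh:
            json.dump(enr.to_dict(), fh, indent=2, sort_keys=True)
        manifest["enrichment"] = enr.to_dict()

        # ---------------------------------------------------------- stratify
        stage = "stratify"
        markers_cfg = cfg["stratify"].get("markers")
        if not markers_cfg:
            markers_cfg = [{"probe": anchor, "direction": "high_is_hit"}]
            if len(screen_res.down_correlated):
                markers_cfg.append(
                    {
                        "probe": screen_res.down_correlated.iloc[0]["probe_id"],
                        "direction": "low_is_hit",
                    }
                )
        markers = [(m["probe"], m["direction"]) for m in markers_cfg]
        ccfg = CutpointConfig(cfg["stratify"]["statistic"], cfg["stratify"]["tie_policy"])
        strat = dichotomize(cohort, markers, ccfg)
        _write_tsv(strat.calls.reset_index(), out / "strata.tsv")
        subsets = [[m] for m, _ in markers]
        if len(markers) >= 2:
            subsets.append([m for m, _ in markers])
        cooc = cooccurrence_counts(strat, subsets, groups)
        _write_tsv(cooc, out / "cooccurrence.tsv")
        manifest["cutpoints"] = strat.cutpoints

        # ----------------------------------------------------------- cluster
        stage = "cluster"
        signature = cfg["cluster"].get("signature")
        if not signature:
            signature = list(screen_res.up_correlated["probe_id"])
        if len(signature) >= 2 and cfg["cluster"]["k"] <= len(cohort.sample_ids):
            clus = cluster_samples(
                cohort,
                signature,
                k=int(cfg["cluster"]["k"]),
                linkage=cfg["cluster"]["linkage"],
                distance=cfg["cluster"]["distance"],
                row_standardize=bool(cfg["cluster"]["row_standardize"]),
            )
            assign = pd.DataFrame(
                {"sample_id": list(clus.assignments), "cluster": list(clus.assignments.values())}
            )
            _write_tsv(assign, out / "clusters.tsv")
            comp = cluster_composition(clus, metadata)
            _write_tsv(comp, out / "cluster_composition.tsv")
            _write_tsv(ordered_matrix(cohort, clus, signature), out / "ordered_matrix.tsv", index=True)
            manifest["counts"]["cluster_sizes"] = {
                str(c): len(clus.cluster_samples(c)) for c in sorted(set(clus.assignments.values()))
            }
        else:
            logger.warning("cluster stage skipped: signature too small")

        # ---------------------------------------------------------- survival
        stage = "survival"
        n_surv = sum(1 for m in metadata if m.survival_months is not None)
        if n_surv >= 10:
            marker_a = cfg["survival"]["marker_a"]
            if not marker_a:
                non_anchor = screen_res.up_correlated[
                    screen_res.up_correlated["probe_id"] != anchor
                ]
                marker_a = (
                    non_anchor.iloc[0]["probe_id"] if len(non_anchor) else anchor
                )
            marker_b = cfg["survival"]["marker_b"]
            scheme = cfg["survival"]["scheme"]
            if scheme == "combined" and not marker_b:
                marker_b = anchor
            surv = stratify_and_test(
                cohort,
                metadata,
                marker_a,
                marker_b=marker_b,
                scheme=scheme,
                horizon=cfg["survival"]["horizon"],
            )
            for label, curve in surv.curves.items():
                safe = label.replace("/", "-")
                _write_tsv(curve.to_frame(), out / f"survival_curve_{safe}.tsv")
            tests = {
                name: {
                    "chi_square": t.chi_square,
                    "df": t.df,
                    "p_value": t.p_value,
                    "group_sizes": t.group_sizes,
                }
                for name, t in surv.tests.items()
            }
            with open(out / "survival_tests.json", "w") as fh:
                json.dump({"tests": tests, "skipped": surv.skipped}, fh, indent=2, sort_keys=True)
            manifest["survival"] = {"marker_a": marker_a, "marker_b": marker_b, "tests": tests}
        else:
            logger.warning("survival stage skipped: %d samples with survival data", n_surv)

        stage = "manifest"
        with open(out / "manifest.json", "w") as fh:
            json.dump(_jsonable(manifest), fh, indent=2, sort_keys=True)
        return manifest
    except Exception as err:
        failed.write_text(f"stage: {stage}\nerror: {err}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def render_report(outdir: str | Path) -> str:
    """Human-readable markdown summary of a run directory's artifacts."""
    out = Path(outdir)
    manifest = json.loads((out / "manifest.json").read_text())
    lines = ["# Anchor co-expression signature run", ""]
    counts = manifest.get("counts", {})
    lines.append(
        f"Cohort: {counts.get('n_probes', '?')} probes, "
        f"{counts.get('n_tumor', '?')} tumors, {counts.get('n_control', '?')} controls."
    )
    lines.append(
        f"Screen: {counts.get('n_up_correlated', 0)} up-correlated and "
        f"{counts.get('n_down_correlated', 0)} down-correlated probes "
        "(ranked_table.tsv mirrors the top-ranked gene table; screen_up.tsv / "
        "screen_down.tsv are the threshold partitions)."
    )
    enr = manifest.get("enrichment")
    if enr:
        lines.append(
            f"Enrichment: {enr['hits_in_category']}/{enr['hits_total']} hits "
            f"({enr['hit_percent']:g}%) in '{enr['category']}' vs "
            f"{enr['background_in_category']}/{enr['background_total']} "
            f"({enr['background_percent']:g}%) on the platform — "
            f"{enr['fold']:.1f}-fold (enrichment.json)."
        )
    lines.append(
        "Stratification: strata.tsv holds per-sample high/low calls; "
        "cooccurrence.tsv the marker-combination counts per group."
    )
    if "cluster_sizes" in counts:
        lines.append(
            f"Clustering: {counts['cluster_sizes']} samples per cluster "
            "(clusters.tsv, cluster_composition.tsv, ordered_matrix.tsv for "
            "heat-map rendering)."
        )
    surv = manifest.get("survival")
    if surv:
        for name, t in surv["tests"].items():
            lines.append(
                f"Survival ({name}): chi-square {t['chi_square']:.2f}, "
                f"p = {t['p_value']:.3g} (survival_curve_*.tsv, survival_tests.json)."
            )
    return "\n".join(lines) + "\n"
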