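"""End-to-end orchestration: (signature x adjustment) classification cells,
pairwise agreement, consistent-sample clinical tables and optional survival
comparison, emitted as one deterministic JSON report plus TSV side files."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import io as sio
from .agreement import agreement, multi_way_consistent
from .clinical_survival import (
    clinical_by_subtype,
    filter_survival,
    km_curve,
    logrank_test,
)
from .core import SUBTYPES, UNCLASSIFIED, BatchDesign, ValidationError
from .dwd import dwd_adjust, fit_dwd
from .preprocess import mean_center_genes
from .simulate import SimulationConfig, simulate_all
from .subtype import classify_cohort

logger = logging.getLogger(__name__)

ADJUSTMENTS = ("none", "center", "dwd")


def validate_config(config: Mapping[str, Any]) -> list[str]:
    """Collect every schema violation at once; empty list means ok."""
    errors: list[str] = []
    if not isinstance(config, Mapping):
        return ["config: must be a mapping"]
    if ("simulate" in config) == ("inputs" in config):
        errors.append("config: exactly one of 'simulate' or 'inputs' is required")
    threshold = config.get("threshold", 0.1)
    if not isinstance(threshold, (int, float)) or not 0.0 <= threshold <= 1.0:
        errors.append(f"threshold: {threshold!r} outside [0, 1]")
    min_genes = config.get("min_genes", 10)
    if not isinstance(min_genes, int) or min_genes < 3:
        errors.append(f"min_genes: {min_genes!r} must be an integer >= 3")
    adjustments = config.get("adjustments", ["none"])
    if not isinstance(adjustments, list) or not adjustments:
        errors.append("adjustments: must be a non-empty list")
    else:
        for adj in adjustments:
            if adj not in ADJUSTMENTS:
                errors.append(f"adjustments: unknown token {adj!r}; allowed {list(ADJUSTMENTS)}")
    if "simulate" in config:
        try:
            _sim_config(config)
        except (ValidationError, TypeError, KeyError) as exc:
            errors.append(f"simulate: {exc}")
    if "inputs" in config:
        inputs = config["inputs"]
        if not isinstance(inputs, Mapping):
            errors.append("inputs: must be a mapping")
        else:
            if "expression" not in inputs:
                errors.append("inputs.expression: required")
            sigs = config.get("signatures")
            if not isinstance(sigs, list) or not sigs:
                errors.append("signatures: required with file inputs")
            else:
                for i, sig in enumerate(sigs):
                    if not isinstance(sig, Mapping) or "name" not in sig:
                        errors.append(f"signatures[{i}]: needs a 'name'")
                    elif "centroids" not in sig and not (
                        "training" in sig and "labels" in sig and "signature" in sig
                    ):
                        errors.append(
                            f"signatures[{i}]: needs 'centroids' or training+labels+signature"
                        )
            if "dwd" in (adjustments or []) and "batches" not in inputs:
                errors.append("inputs.batches: required when 'dwd' is requested")
    return errors


def _sim_config(config: Mapping[str, Any]) -> SimulationConfig:
    sim = dict(config["simulate"] or {})
    sim.setdefault("seed", config.get("seed", 0))
    if "subtype_sizes" in sim:
        sim["subtype_sizes"] = tuple(sim["subtype_sizes"])
    return SimulationConfig(**sim)


def _load_data(config: Mapping[str, Any]):
    """Returns (matrix, centroid sets by name, batches, clinical, survival, truth)."""
    if "simulate" in config:
        sim = _sim_config(config)
        centroids, matrix, truth, design, clinical, survival = simulate_all(sim)
        return matrix, {"simulated": centroids}, design, clinical, survival, truth
    inputs = config["inputs"]
    matrix = sio.read_expression_matrix(
        inputs["expression"], dialect=inputs.get("dialect", "tsv")
    )
    centroid_sets = {}
    for sig in config["signatures"]:
        if "centroids" in sig:
            centroid_sets[sig["name"]] = sio.read_centroids(sig["centroids"], sig["name"])
        else:
            from .subtype import compute_centroids

            training = sio.read_expression_matrix(sig["training"])
            labels = dict(
                np.loadtxt(sig["labels"], dtype=str, delimiter="\t", skiprows=1)
            )
            signature = sio.read_signature(sig["signature"], sig["name"])
            centroid_sets[sig["name"]] = compute_centroids(training, labels, signature)
    design = sio.read_batches(inputs["batches"]) if "batches" in inputs else None
    clinical = sio.read_clinical(inputs["clinical"]) if "clinical" in inputs else None
    survival = sio.read_survival(inputs["survival"]) if "survival" in inputs else None
    return matrix, centroid_sets, design, clinical, survival, None


def _adjusted(matrix, adjustment: str, design: BatchDesign | None):
    if adjustment == "none":
        return matrix
    if adjustment == "center":
        return mean_center_genes(matrix)
    if adjustment == "dwd":
        if design is None:
            raise ValidationError("dwd adjustment requires a batch design")
        model = fit_dwd(matrix, design, cost="auto")
        return dwd_adjust(matrix, model, design)
    raise ValidationError(f"unknown adjustment {adjustment!r}")


def run_full(config: Mapping[str, Any], out_dir: str | Path | None = None) -> dict:
    """Execute classification, agreement, clinical and survival stages.

    Any stage failure re-raises with the stage name prefixed. The report is a
    plain-JSON-serializable dict; with ``out_dir`` set, the report and per-cell
    call tables are persisted as text files.
    """
    errors = validate_config(config)
    if errors:
        raise ValidationError("invalid config: " + "; ".join(errors))
    threshold = float(config.get("threshold", 0.1))
    min_genes = int(config.get("min_genes", 10))
    adjustments = list(config.get("adjustments", ["none"]))

    stage = "load"
    try:
        matrix, centroid_sets, design, clinical, survival, truth = _load_data(config)
        report: dict[str, Any] = {
            "config_hash": hashlib.sha256(
                json.dumps(config, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "seed": config.get("seed"),
            "n_samples": matrix.n_samples,
            "n_genes": matrix.n_genes,
            "cells": {},
            "agreement": {},
        }
        cells: dict[str, list] = {}
        for sig_name, centroids in centroid_sets.items():
            for adj in adjustments:
                stage = f"classify[{sig_name}/{adj}]"
                adjusted = _adjusted(matrix, adj, design)
                calls, dist = classify_cohort(adjusted, centroids, threshold, min_genes)
                key = f"{sig_name}/{adj}"
                cells[key] = calls
                report["cells"][key] = {
                    "distribution": {k: int(v) for k, v in dist.items()},
                    "n_unclassified": int(dist[UNCLASSIFIED]),
                }
                logger.info("%s: %s", stage, dict(dist))

        stage = "agreement"
        keys = list(cells)
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                res = agreement(
                    cells[keys[i]], cells[keys[j]],
                    unclassified=config.get("unclassified", "category"),
                )
                report["agreement"][f"{keys[i]} vs {keys[j]}"] = res.to_dict()

        if len(keys) >= 2:
            stage = "consistency"
            consistent = multi_way_consistent([cells[k] for k in keys])
            report["consistent_samples"] = {"n": len(consistent), "ids": consistent}
            if clinical is not None and consistent:
                stage = "clinical"
                keep = set(consistent)
                sub_calls = [c for c in cells[keys[0]] if c.sample_id in keep]
                tables = clinical_by_subtype(
                    sub_calls, [r for r in clinical if r.sample_id in keep]
                )
                report["clinical"] = {
                    f: {
                        "counts": t["counts"].to_dict(),
                        "missing": t["missing"].to_dict(),
                    }
                    for f, t in tables.items()
                }

        if survival is not None and config.get("survival", True):
            stage = "survival"
            groups = filter_survival(cells[keys[0]], survival, labels=SUBTYPES)
            groups = {k: v for k, v in groups.items() if v}
            surv_report: dict[str, Any] = {
                "groups": {k: len(v) for k, v in groups.items()},
                "km": {k: km_curve(v).to_dict() for k, v in groups.items()},
            }
            if len(groups) >= 2 and any(r.event for v in groups.values() for r in v):
                chi2, df, p = logrank_test(list(groups.values()))
                surv_report["logrank"] = {"chi2": chi2, "df": df, "p": p}
            report["survival"] = surv_report

        if truth is not None:
            stage = "truth"
            first = cells[keys[0]]
            acc = float(
                np.mean([c.label == truth[c.sample_id] for c in first])
            )
            report["truth_accuracy_first_cell"] = acc
    except ValidationError as exc:
        raise ValidationError(f"stage {stage}: {exc}") from exc

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for key, calls in cells.items():
            sio.write_calls(calls, out_dir / (key.replace("/", "_") + ".calls.tsv"))
        with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report
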