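"""End-to-end pipeline driver: QC -> score -> filter -> index -> optimize.

A single JSON/YAML config describes the inputs (a simulated cohort, a
pre-computed score table, or an expression matrix plus signature files) and
per-stage parameters.  Outputs land in one artifact directory together with
a manifest recording the config hash, seeds, input checksums and stage
timings, so a rerun on identical inputs reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import dysfunction, preprocess, scoring, simulate, threshold
from .patient_index import ThresholdPair, cohort_indices, records_frame
from .signatures import load_gene_list, load_signature, default_housekeeping

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


DEFAULTS = {
    "seed": 0,
    "qc": {"min_genes": 1000, "housekeeping_threshold": 2.5, "mito_prefix": "MT-"},
    "filter": {"enabled": True, "p_low": 20.0, "p_high": 80.0},
    "index": {"min_cells": 10, "ps": 0.01},
    "optimize": {},
}


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yml", ".yaml"):
        import yaml

        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict) or "input" not in cfg:
        raise PipelineError("config", "config must be a mapping with an 'input' section")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _merged(cfg: dict, section: str) -> dict:
    out = dict(DEFAULTS.get(section, {}))
    out.update(cfg.get(section, {}))
    return out


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Execute the pipeline; returns the manifest (also written to disk)."""
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", DEFAULTS["seed"]))
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "inputs": {},
        "stages": {},
        "artifacts": {},
    }

    def stage(name):
        t0 = time.monotonic()

        def done(**artifacts):
            manifest["stages"][name] = {"seconds": round(time.monotonic() - t0, 3)}
            for key, p in artifacts.items():
                manifest["artifacts"][key] = str(p)
            logger.info("stage %s done (%.2fs)", name, time.monotonic() - t0)

        return done

    # ---- input / simulate / qc / score -> (scores, meta) -----------------
    inp = config["input"]
    mode = inp.get("mode")
    if mode == "simulate":
        done = stage("simulate")
        cfg = simulate.preset(inp.get("preset", "weak"),
                              **inp.get("overrides", {}), seed=seed)
        scores, meta = simulate.generate_scores(cfg)
        simulate.write_cohort(scores, meta, outdir)
        done(scores=outdir / "scores.tsv", metadata=outdir / "cell_metadata.tsv")
    elif mode == "scores":
        done = stage("load")
        for key in ("scores", "metadata"):
            p = Path(inp[key])
            manifest["inputs"][key] = _checksum(p)
        scores = scoring.load_score_table(inp["scores"])
        meta = pd.read_csv(inp["metadata"], sep="\t", dtype=str)
        done()
    elif mode == "expression":
        done = stage("load")
        m = preprocess.read_mtx(inp["mtx"], inp["genes"], inp["barcodes"],
                                layer=inp.get("layer", "counts"))
        meta = preprocess.read_cell_metadata(inp["metadata"])
        for key in ("mtx", "genes", "barcodes", "metadata"):
            manifest["inputs"][key] = _checksum(Path(inp[key]))
        done()

        qc_cfg = _merged(config, "qc")
        done = stage("qc")
        reports = []
        m, rep = preprocess.filter_min_genes(m, int(qc_cfg["min_genes"]))
        reports.append(("min_genes", rep))
        m, rep = preprocess.remove_mito(m, qc_cfg["mito_prefix"])
        reports.append(("mito", rep))
        if m.layer == "counts":
            m = preprocess.to_log_tpm(m)
        hk = (load_gene_list(qc_cfg["housekeeping"]) if qc_cfg.get("housekeeping")
              else default_housekeeping())
        try:
            m, rep = preprocess.housekeeping_filter(
                m, hk, float(qc_cfg["housekeeping_threshold"]))
            reports.append(("housekeeping", rep))
        except ValueError as e:
            raise PipelineError("qc", str(e)) from e
        qc_path = outdir / "qc_report.json"
        qc_path.write_text(json.dumps(
            [{"filter": n, "n_in": r.n_cells_in, "n_kept": r.n_cells_kept,
              "removals": r.removals, "thresholds": r.thresholds, "notes": r.notes}
             for n, r in reports], indent=2))
        done(qc_report=qc_path)

        done = stage("score")
        sig_cfg = config.get("signatures")
        if not sig_cfg:
            raise PipelineError("score", "expression mode requires a 'signatures' section")
        sigs = {name: load_signature(spec["path"], spec.get("dialect", "gmt_directional"))
                for name, spec in sig_cfg.items()}
        rank_cfg = scoring.RankConfig(int(config.get("score", {}).get("max_rank", 1500)))
        scores = scoring.score_by_celltype(m, meta, sigs, rank_cfg)
        scores_path = outdir / "scores.tsv"
        scoring.save_score_table(scores, scores_path)
        meta = meta[meta["cell_id"].isin(scores.index)]
        done(scores=scores_path)
    else:
        raise PipelineError("config", f"unknown input mode {mode!r}")

    meta_idx = meta.set_index("cell_id")

    # ---- dysfunction filter ---------------------------------------------
    f_cfg = _merged(config, "filter")
    if f_cfg.get("enabled", True) and {"senescence", "exhaustion"} <= set(scores.columns):
        done = stage("filter")
        kept, report = dysfunction.joint_percentile_filter(
            scores, p_low=float(f_cfg["p_low"]), p_high=float(f_cfg["p_high"]),
            stratify_by=meta_idx["cell_type"],
        )
        scores = scores.loc[kept]
        kept_path = outdir / "kept_cells.tsv"
        pd.Series(kept, name="cell_id").to_csv(kept_path, sep="\t", index=False)
        (outdir / "filter_report.json").write_text(json.dumps(report, indent=2))
        done(kept_cells=kept_path, filter_report=outdir / "filter_report.json")

    # ---- optimize (grid search per cell type) ---------------------------
    o_cfg = _merged(config, "optimize")
    if "response" not in meta.columns or meta["response"].isna().all():
        raise PipelineError(
            "optimize",
            "response labels (R/NR) are required for ROC threshold optimization; "
            "add a 'response' column to the cell metadata",
        )
    meta_idx = meta_idx.loc[scores.index]
    cell_types = o_cfg.get("cell_types") or sorted(meta_idx["cell_type"].unique())
    upper = o_cfg.get("upper", list(threshold.DEFAULT_UPPER))
    lower = o_cfg.get("lower", list(threshold.DEFAULT_LOWER))
    i_cfg = _merged(config, "index")
    summaries = {}
    for ct in cell_types:
        done = stage(f"optimize[{ct}]")
        result = threshold.grid_search(
            scores, meta_idx, upper_range=upper, lower_range=lower,
            min_cells=int(i_cfg["min_cells"]), ps=float(i_cfg["ps"]), cell_type=ct,
        )
        grid_path = outdir / f"grid_{ct}.tsv"
        summary_path = outdir / f"optimum_{ct}.json"
        threshold.save_grid(result, grid_path, summary_path)
        # patient index table at the selected optimum
        ct_mask = (meta_idx["cell_type"] == ct).to_numpy()
        recs, _ = cohort_indices(
            scores.loc[ct_mask], meta_idx.loc[ct_mask],
            ThresholdPair(result.best_pair.upper_pct, result.best_pair.lower_pct),
            min_cells=int(i_cfg["min_cells"]), ps=float(i_cfg["ps"]),
        )
        idx_path = outdir / f"patient_index_{ct}.tsv"
        records_frame(recs).to_csv(idx_path, sep="\t", index=False)
        summaries[ct] = json.loads(summary_path.read_text())
        done(**{f"grid_{ct}": grid_path, f"optimum_{ct}": summary_path,
                f"patient_index_{ct}": idx_path})

    manifest["optima"] = summaries
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
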